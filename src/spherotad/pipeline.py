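"""One-command comparative run: configuration, orchestration, reporting.

``run_compare`` drives the full monolayer-vs-spheroid comparison on a
fixture (or user) directory: balancing, eigenvector correlation at 1 Mb,
compartment transitions, TAD calling and change classification, aggregate
corner tests, and peak/gene integration, writing a machine-readable JSON
report plus Markdown summary and per-table TSVs.  Outputs contain no
timestamps, so identical (config, seed) runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .matrix import (ContactMatrix, read_contacts, ice_balance,
                     observed_over_expected, eigen_correlation, coarsen)
from .compartments import (compartment_eigenvector, orient_track,
                           call_transitions, metagene_ab, gene_ab_score)
from .tads import call_tads, tad_stats
from .tadcompare import compare_tads, tad_class_membership
from .aggregate import aggregate_rescaled_tads, compare_aggregates
from .features import (PeakSet, read_bed, read_gene_table, overlap_peaks,
                       peak_density_by_tad_class, call_super_enhancers,
                       assign_se_genes, de_summary, enhancer_distance)

log = logging.getLogger("spherotad")

CONDITIONS = ("2D", "3D")


@dataclass
class RunConfig:
    """Paths, resolutions, thresholds and seeds for a comparative run."""

    bins: str
    contacts: dict                      # cond -> triplet path
    genes: str
    peaks: dict = field(default_factory=dict)   # name -> cond -> BED path
    out_dir: str = "results"
    seed: int = 0
    # resolutions
    coarsen_factor_1mb: int = 10
    tad_window_bins: int = 5
    flank_bins: int = 20
    # thresholds
    min_abs: float | None = None
    delta_thresh: float = 0.2
    min_tad_bins: int = 3
    tolerance_bins: int = 1
    min_overlap_frac: float = 0.5
    lfc_thresh: float = 1.0
    p_thresh: float = 0.01
    # aggregates
    n_perm: int = 1000
    expand_factor: float = 3.0
    k_pixels: int = 90
    corner_box: int = 5
    # super-enhancers
    stitch_bp: int = 12_500
    se_window_bp: int = 50_000

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output location
        does not change what is computed)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(path) -> RunConfig:
    """Load a YAML run config and check that every referenced path exists."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    missing = []
    for p in [cfg.bins, cfg.genes, *cfg.contacts.values(),
              *(p for conds in cfg.peaks.values() for p in conds.values())]:
        if not Path(p).exists():
            missing.append(str(p))
    if missing:
        raise FileNotFoundError(f"config references missing paths: {missing}")
    return cfg


def fixture_config(fixture_dir, out_dir="results", seed: int = 0, **overrides) -> RunConfig:
    """RunConfig pointing at a directory written by synth.write_fixture."""
    d = Path(fixture_dir)
    return RunConfig(
        bins=str(d / "bins.bed"),
        contacts={c: str(d / f"contacts_{c}.tsv") for c in CONDITIONS},
        genes=str(d / "genes.tsv"),
        peaks={name: {c: str(d / f"peaks_{name}_{c}.bed") for c in CONDITIONS}
               for name in ("ctcf", "pr", "h3k27ac")},
        out_dir=str(out_dir), seed=seed, **overrides)


def _gene_density(genes: pd.DataFrame, bin_size: int, n_bins: int,
                  smooth_bp: int = 1_000_000) -> np.ndarray:
    """Gene-TSS density smoothed to compartment scale (orientation reference)."""
    b = (genes["tss"] // bin_size).astype(int)
    d = np.bincount(b[(b >= 0) & (b < n_bins)], minlength=n_bins).astype(float)
    w = max(int(round(smooth_bp / bin_size)), 1)
    if w > 1:
        d = np.convolve(d, np.ones(w) / w, mode="same")
    return d


def _tads_containing(tadset, genes: pd.DataFrame, bin_size: int):
    """Unique (start_bin, end_bin) TAD intervals containing a TSS of the set."""
    bounds = np.array([t.start_bin for t in tadset.tads] + [tadset.tads[-1].end_bin])
    out, seen = [], set()
    for tss in genes["tss"]:
        b = int(tss) // bin_size
        k = np.searchsorted(bounds, b, side="right") - 1
        if 0 <= k < len(tadset.tads):
            t = tadset.tads[k]
            if t.start_bin <= b < t.end_bin and (t.start_bin, t.end_bin) not in seen:
                seen.add((t.start_bin, t.end_bin))
                out.append((t.start_bin, t.end_bin))
    return out


def run_compare(cfg: RunConfig) -> dict:
    """Execute the full comparative analysis and write the report bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    report: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }

    def stage(name):
        log.info("stage: %s", name)

    # --- hic_core ------------------------------------------------------
    stage("balance")
    raw, bal, oe = {}, {}, {}
    for cond in CONDITIONS:
        raw[cond] = read_contacts(cfg.contacts[cond], cfg.bins)
        bal[cond] = ice_balance(raw[cond])
        oe[cond] = observed_over_expected(bal[cond])
    bin_size = raw["2D"].bin_size
    n_bins = raw["2D"].n_bins
    genes = read_gene_table(cfg.genes)
    density = _gene_density(genes, bin_size, n_bins)

    stage("eigenvector correlation at 1 Mb")
    factor = cfg.coarsen_factor_1mb
    # orient the reference condition by gene density, the other condition
    # consistently against it (compartment changes are sparse, so the
    # cross-condition sign is unambiguous)
    eig1mb = {c: compartment_eigenvector(observed_over_expected(
        ice_balance(coarsen(raw[c], factor)))) for c in CONDITIONS}
    ref1 = np.add.reduceat(density, np.arange(0, len(density), factor))
    t2 = orient_track(eig1mb["2D"], ref1)
    t3 = orient_track(eig1mb["3D"], t2.pc1)
    report["eigenvector_correlation_1mb"] = round(eigen_correlation(t2, t3), 6)

    # --- compartments --------------------------------------------------
    stage("compartments")
    eig = {c: compartment_eigenvector(oe[c]) for c in CONDITIONS}
    tracks = {"2D": orient_track(eig["2D"], density)}
    tracks["3D"] = orient_track(eig["3D"], tracks["2D"].pc1)
    regions, counts = call_transitions(tracks["2D"], tracks["3D"],
                                       min_abs=cfg.min_abs)
    report["compartment_transitions"] = counts
    pd.DataFrame([{
        "chrom": raw["2D"].chrom,
        "start": r.start_bin * bin_size, "end": r.end_bin * bin_size,
        "name": r.kind,
    } for r in regions]).to_csv(out / "transitions.bed", sep="\t",
                                header=False, index=False)
    for cond in CONDITIONS:
        tracks[cond].to_bedgraph(out / f"pc1_{cond}.bedgraph")

    gene_sets = {"up": genes[genes["de_class"] == "up"],
                 "down": genes[genes["de_class"] == "down"]}
    ns = genes[genes["de_class"] == "ns"]
    n_rand = min(len(ns), max(len(s) for s in gene_sets.values()))
    gene_sets["random"] = ns.sample(n=n_rand,
                                    random_state=int(rng.integers(2 ** 31)))
    report["ab_metagene"] = {}
    for name in ("up", "down"):
        m = metagene_ab(tracks["2D"], tracks["3D"], gene_sets[name])
        report["ab_metagene"][name] = {
            "delta": round(m["delta"], 4), "p_value": float(m["p_value"]),
            "direction": m["direction"], "n_genes": m["n_genes"]}

    # --- TADs ----------------------------------------------------------
    stage("tads")
    tsets = {}
    report["tads"] = {}
    for cond in CONDITIONS:
        ts = call_tads(bal[cond], window_bins=cfg.tad_window_bins,
                       delta_thresh=cfg.delta_thresh,
                       min_tad_bins=cfg.min_tad_bins)
        tsets[cond] = ts
        st = tad_stats(ts)
        report["tads"][cond] = {"count": st["count"],
                                "median_size_bp": st["median_size_bp"]}
        ts.to_bed(out / f"tads_{cond}.bed")

    stage("compare-tads")
    changes = compare_tads(tsets["2D"], tsets["3D"],
                           tolerance_bins=cfg.tolerance_bins,
                           min_overlap_frac=cfg.min_overlap_frac)
    report["tad_changes"] = dict(changes.counts)
    report["boundary_conservation_fraction"] = round(
        changes.boundary_conservation_fraction, 4)
    changes.to_frame().to_csv(out / "tad_changes.tsv", sep="\t", index=False)

    membership = tad_class_membership(genes, changes)
    report["gene_class_by_tad_class"] = {}
    for name, sub in gene_sets.items():
        frac = membership.loc[sub.index].value_counts(normalize=True)
        report["gene_class_by_tad_class"][name] = {
            k: round(float(v), 4) for k, v in frac.items()}

    # --- aggregates ----------------------------------------------------
    stage("aggregates")
    report["aggregate_corner"] = {}
    for name in ("down", "up", "random"):
        anchors = _tads_containing(tsets["2D"], gene_sets[name], bin_size)
        if not anchors:
            continue
        agg = aggregate_rescaled_tads(oe["3D"], anchors,
                                      expand_factor=cfg.expand_factor,
                                      k_pixels=cfg.k_pixels,
                                      corner_box=cfg.corner_box)
        cmp_res = compare_aggregates(anchors, oe["2D"], oe["3D"],
                                     statistic="corner", n_perm=cfg.n_perm,
                                     seed=int(rng.integers(2 ** 31)),
                                     expand_factor=cfg.expand_factor,
                                     k_pixels=cfg.k_pixels,
                                     corner_box=cfg.corner_box)
        report["aggregate_corner"][name] = {
            "n_tads": cmp_res["n_anchors"],
            "corner_score_3d": round(agg.corner_score, 4),
            "delta_2d_minus_3d": round(cmp_res["delta"], 4),
            "p": cmp_res["p"]}

    # --- feature integration -------------------------------------------
    stage("integrate")
    peaksets = {name: {c: read_bed(cfg.peaks[name][c], name=f"{name}_{c}")
                       for c in conds}
                for name, conds in cfg.peaks.items()}
    report["peak_overlaps"] = {}
    for name, conds in peaksets.items():
        ov = overlap_peaks(conds["2D"], conds["3D"])
        report["peak_overlaps"][name] = ov
        if name == "ctcf":
            report["ctcf_loss_pct"] = round(
                100.0 * (1 - len(conds["3D"]) / len(conds["2D"])), 2)

    if "ctcf" in peaksets:
        dens = peak_density_by_tad_class(peaksets["ctcf"]["3D"], changes)
        report["ctcf_density_by_tad_class_3d"] = {
            k: round(v, 4) for k, v in dens["mean_density"].items()}

    if "h3k27ac" in peaksets:
        report["super_enhancers"] = {}
        ses = {}
        for cond in CONDITIONS:
            se = call_super_enhancers(peaksets["h3k27ac"][cond],
                                      stitch_bp=cfg.stitch_bp)
            ses[cond] = se
            n_genes_se = assign_se_genes(se, genes, window_bp=cfg.se_window_bp)
            report["super_enhancers"][cond] = {
                "n_super": se.n_super,
                "n_stitched": len(se.regions),
                "n_genes_assigned": int(n_genes_se["gene_id"].nunique())
                if len(n_genes_se) else 0}
        sup2, sup3 = (PeakSet(f"se_{c}", ses[c].supers()[["chrom", "start", "end"]]
                              .sort_values(["chrom", "start"])
                              .assign(score=0.0).reset_index(drop=True))
                      for c in CONDITIONS)
        if len(sup2) and len(sup3):
            report["super_enhancers"]["overlap"] = overlap_peaks(sup2, sup3)

    if "pr" in peaksets and "h3k27ac" in peaksets:
        de_set = genes[genes["de_class"] != "ns"]
        ed = enhancer_distance(peaksets["pr"]["3D"], peaksets["h3k27ac"]["3D"],
                               genes, de_set,
                               seed=int(rng.integers(2 ** 31)))
        report["enhancer_distance"] = {
            "n_enhancers": ed["n_enhancers"], "p": float(ed["p"]),
            "median_set_bp": ed.get("median_set", float("nan")),
            "median_random_bp": ed.get("median_random", float("nan"))}

    report["de_summary"] = de_summary(genes, lfc_thresh=cfg.lfc_thresh,
                                      p_thresh=cfg.p_thresh)

    # --- report bundle -------------------------------------------------
    stage("report")
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                default=float) + "\n")
    (out / "report.md").write_text(_markdown_report(report))
    per_gene = pd.DataFrame({
        "ab_score_2d": gene_ab_score(tracks["2D"], genes),
        "ab_score_3d": gene_ab_score(tracks["3D"], genes),
        "tad_class": membership,
    })
    per_gene.to_csv(out / "gene_scores.tsv", sep="\t", float_format="%.5g")
    return report


def _markdown_report(report: dict) -> str:
    lines = ["# Comparative 2D/3D genome report", ""]
    lines.append(f"- package version: {report['version']}")
    lines.append(f"- config hash: {report['config_hash']}  seed: {report['seed']}")
    lines.append("")
    lines.append(f"Eigenvector correlation (1 Mb): "
                 f"**{report['eigenvector_correlation_1mb']}**")
    ct = report["compartment_transitions"]
    lines.append(f"Compartment transitions: {ct['AtoB']} AtoB, {ct['BtoA']} BtoA")
    for cond, st in report["tads"].items():
        lines.append(f"TADs {cond}: {st['count']} "
                     f"(median {st['median_size_bp'] / 1e6:.2f} Mb)")
    tc = report["tad_changes"]
    lines.append(f"TAD changes: {tc.get('fused', 0)} fused, "
                 f"{tc.get('split', 0)} split, {tc.get('shifted', 0)} shifted, "
                 f"{tc.get('conserved', 0)} conserved")
    lines.append(f"Boundary conservation: "
                 f"{100 * report['boundary_conservation_fraction']:.1f}%")
    if "ctcf_loss_pct" in report:
        lines.append(f"CTCF peaks lost in 3D: {report['ctcf_loss_pct']}%")
    de = report["de_summary"]
    lines.append(f"DE genes: {de['n_up']} up, {de['n_down']} down "
                 f"({de['n_total']} total)")
    lines.append("")
    return "\n".join(lines) + "\n"
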