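"""Between-condition TAD matching and change classification.

TADs from the two conditions are joined into a bipartite overlap graph;
each connected component becomes one change event, classified as
conserved, shifted, fused (several reference TADs merging into one),
split (the transpose) or complex.  Boundary conservation is the fraction
of internal reference boundaries found within tolerance in the other
condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tads import TADSet

__all__ = [
    "ChangeEvent",
    "TADChangeSet",
    "match_tads",
    "classify_changes",
    "compare_tads",
    "tad_class_membership",
]

KINDS = ("conserved", "shifted", "fused", "split", "complex")


@dataclass(frozen=True)
class ChangeEvent:
    kind: str
    tads_a: tuple[int, ...]    # TAD indices in condition A (reference, e.g. 2D)
    tads_b: tuple[int, ...]    # TAD indices in condition B (e.g. 3D)
    start_bin: int
    end_bin: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start_bin, self.end_bin)


@dataclass
class TADChangeSet:
    events: list[ChangeEvent]
    counts: dict
    boundary_conservation_fraction: float
    tolerance_bins: int
    chrom: str = "chr"
    bin_size: int = 100_000

    def events_of_kind(self, kind: str) -> list[ChangeEvent]:
        return [e for e in self.events if e.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "kind": e.kind,
            "start_bin": e.start_bin,
            "end_bin": e.end_bin,
            "start_bp": e.start_bin * self.bin_size,
            "end_bp": e.end_bin * self.bin_size,
            "tads_a": ",".join(map(str, e.tads_a)),
            "tads_b": ",".join(map(str, e.tads_b)),
        } for e in self.events])


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def match_tads(tads_a: TADSet, tads_b: TADSet,
               min_overlap_frac: float = 0.5) -> list[tuple[list[int], list[int]]]:
    """Bipartite overlap components between two TAD tilings.

    An edge joins an A-TAD and a B-TAD when their overlap covers at least
    ``min_overlap_frac`` of the smaller of the two.  Returns the connected
    components as (a_indices, b_indices) pairs sorted by genomic position;
    unmatched TADs form singleton components.
    """
    if tads_a.chrom != tads_b.chrom or tads_a.bin_size != tads_b.bin_size:
        raise ValueError("TADSets must share chromosome and bin size")
    na, nb = len(tads_a.tads), len(tads_b.tads)
    uf = _UnionFind(na + nb)
    for i, ta in enumerate(tads_a.tads):
        for j, tb in enumerate(tads_b.tads):
            if tb.start_bin >= ta.end_bin:
                break
            ov = min(ta.end_bin, tb.end_bin) - max(ta.start_bin, tb.start_bin)
            if ov <= 0:
                continue
            smaller = min(ta.n_bins, tb.n_bins)
            if ov >= min_overlap_frac * smaller:
                uf.union(i, na + j)
    comps: dict[int, tuple[list[int], list[int]]] = {}
    for i in range(na):
        comps.setdefault(uf.find(i), ([], []))[0].append(i)
    for j in range(nb):
        comps.setdefault(uf.find(na + j), ([], []))[1].append(j)

    def comp_start(c):
        aa, bb = c
        starts = [tads_a.tads[i].start_bin for i in aa] + \
                 [tads_b.tads[j].start_bin for j in bb]
        return min(starts)

    return sorted(comps.values(), key=comp_start)


def _span(tads, idx):
    return (min(tads[i].start_bin for i in idx), max(tads[i].end_bin for i in idx))


def classify_changes(components, tads_a: TADSet, tads_b: TADSet,
                     tolerance_bins: int = 1) -> TADChangeSet:
    """Classify overlap components into the change taxonomy.

    Per component: 1-to-1 with both boundaries within tolerance ->
    conserved; 1-to-1 with >=1 boundary displaced beyond tolerance ->
    shifted; m-to-1 (m>=2) whose single B TAD spans the A TADs -> fused;
    1-to-m transpose -> split; anything else -> complex.
    """
    tol = int(tolerance_bins)
    events: list[ChangeEvent] = []
    for aa, bb in components:
        if aa and bb:
            sa, ea = _span(tads_a.tads, aa)
            sb, eb = _span(tads_b.tads, bb)
            start, end = min(sa, sb), max(ea, eb)
            ends_match = abs(sa - sb) <= tol and abs(ea - eb) <= tol
            if len(aa) == 1 and len(bb) == 1:
                kind = "conserved" if ends_match else "shifted"
            elif len(aa) >= 2 and len(bb) == 1:
                kind = "fused" if ends_match else "complex"
            elif len(aa) == 1 and len(bb) >= 2:
                kind = "split" if ends_match else "complex"
            else:
                kind = "complex"
        else:
            tads, idx = (tads_a.tads, aa) if aa else (tads_b.tads, bb)
            start, end = _span(tads, idx)
            kind = "complex"
        events.append(ChangeEvent(kind, tuple(aa), tuple(bb), start, end))

    counts = {k: sum(e.kind == k for e in events) for k in KINDS}
    # conservation over internal reference boundaries (ends exist by construction)
    int_a = tads_a.internal_boundaries
    int_b = np.asarray(tads_b.internal_boundaries)
    if int_a:
        conserved = sum(1 for b in int_a
                        if int_b.size and np.min(np.abs(int_b - b)) <= tol)
        frac = conserved / len(int_a)
    else:
        frac = 1.0
    return TADChangeSet(events=events, counts=counts,
                        boundary_conservation_fraction=float(frac),
                        tolerance_bins=tol, chrom=tads_a.chrom,
                        bin_size=tads_a.bin_size)


def compare_tads(tads_a: TADSet, tads_b: TADSet, tolerance_bins: int = 1,
                 min_overlap_frac: float = 0.5) -> TADChangeSet:
    """match_tads + classify_changes in one call."""
    comps = match_tads(tads_a, tads_b, min_overlap_frac=min_overlap_frac)
    return classify_changes(comps, tads_a, tads_b, tolerance_bins=tolerance_bins)


def tad_class_membership(genes: pd.DataFrame, changes: TADChangeSet) -> pd.Series:
    """Assign each gene to the change event containing its TSS.

    Returns a per-gene Series of event kinds; 'none' for TSSs outside the
    tiled region.  Per-set fractions follow with a simple value_counts.
    """
    if genes.empty:
        return pd.Series(dtype=object, name="tad_class")
    starts = np.array([e.start_bin * changes.bin_size for e in changes.events])
    ends = np.array([e.end_bin * changes.bin_size for e in changes.events])
    kinds = np.array([e.kind for e in changes.events], dtype=object)
    order = np.argsort(starts)
    starts, ends, kinds = starts[order], ends[order], kinds[order]
    tss = genes["tss"].to_numpy()
    pos = np.searchsorted(starts, tss, side="right") - 1
    out = np.full(len(genes), "none", dtype=object)
    ok = pos >= 0
    ok[ok] &= tss[ok] < ends[pos[ok]]
    out[ok] = kinds[pos[ok]]
    return pd.Series(out, index=genes.index, name="tad_class")
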