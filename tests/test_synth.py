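"""Synthetic-data generator: truth invariants, contact model, determinism."""

import json

import numpy as np
import pytest

from spherotad import synth
from spherotad.matrix import read_contacts


def _no_event_config(**kw):
    return synth.scaled_config(400, n_atob=0, n_btoa=0, n_fusions=0,
                               n_splits=0, n_shifts=0, **kw)


class TestTruth:
    def test_zero_events_conditions_identical(self):
        truth = synth.make_truth(_no_event_config(), seed=1)
        assert truth.tad_boundaries["2D"] == truth.tad_boundaries["3D"]
        np.testing.assert_array_equal(truth.compartments["2D"],
                                      truth.compartments["3D"])

    def test_boundary_invariants(self, default_truth):
        for cond in ("2D", "3D"):
            b = default_truth.tad_boundaries[cond]
            assert b[0] == 0 and b[-1] == default_truth.n_bins
            assert all(x < y for x, y in zip(b, b[1:]))

    def test_fusions_remove_distinct_boundaries(self, default_truth):
        truth = default_truth
        fusions = truth.events_of("fusion")
        assert len(fusions) == 20
        removed = [e["removed_boundary"] for e in fusions]
        assert len(set(removed)) == 20
        b3 = set(truth.tad_boundaries["3D"])
        assert all(b in truth.tad_boundaries["2D"] and b not in b3
                   for b in removed)

    def test_splits_add_and_shifts_move(self, default_truth):
        truth = default_truth
        b2, b3 = set(truth.tad_boundaries["2D"]), set(truth.tad_boundaries["3D"])
        for e in truth.events_of("split"):
            assert e["added_boundary"] in b3 and e["added_boundary"] not in b2
        for e in truth.events_of("shift"):
            assert e["old_boundary"] in b2 and e["old_boundary"] not in b3
            assert e["new_boundary"] in b3 and e["new_boundary"] not in b2
            assert abs(e["new_boundary"] - e["old_boundary"]) > 1

    def test_compartments_differ_exactly_at_flips(self, default_truth):
        truth = default_truth
        diff = truth.compartments["2D"] != truth.compartments["3D"]
        flip_bins = np.zeros(truth.n_bins, dtype=bool)
        for e in truth.events:
            if e["kind"] in ("AtoB", "BtoA"):
                flip_bins[e["start_bin"]:e["end_bin"]] = True
        np.testing.assert_array_equal(diff, flip_bins)

    def test_deterministic_serialization(self):
        cfg = synth.scaled_config(400)
        t1 = synth.make_truth(cfg, seed=3)
        t2 = synth.make_truth(cfg, seed=3)
        assert t1.to_json() == t2.to_json()
        t3 = synth.make_truth(cfg, seed=4)
        assert t1.to_json() != t3.to_json()

    def test_unplaceable_events_raise_naming_kind(self):
        with pytest.raises(ValueError, match="fusion"):
            synth.make_truth(synth.scaled_config(400, n_fusions=500), seed=1)
        with pytest.raises(ValueError, match="AtoB"):
            synth.make_truth(synth.scaled_config(400, n_atob=100), seed=1)

    def test_n_bins_floor(self):
        with pytest.raises(ValueError):
            synth.SimConfig(n_bins=100)


class TestContacts:
    def test_symmetric_nonnegative_integers(self):
        truth = synth.make_truth(synth.scaled_config(300), seed=2)
        cm = synth.simulate_contacts(truth, "2D", seed=5)
        assert cm.check_symmetric()
        assert (cm.values >= 0).all()
        assert np.all(cm.values == np.round(cm.values))

    def test_unknown_condition_raises(self):
        truth = synth.make_truth(synth.scaled_config(300), seed=2)
        with pytest.raises(ValueError, match="condition"):
            synth.simulate_contacts(truth, "4D", seed=1)

    def test_zero_depth_all_zero(self):
        truth = synth.make_truth(synth.scaled_config(300, ), seed=2)
        truth.config.depth = 0.0
        cm = synth.simulate_contacts(truth, "2D", seed=1)
        assert np.all(cm.values == 0)

    def test_structureless_limit_depends_on_distance_only(self):
        cfg = _no_event_config()
        cfg.comp_factor = cfg.tad_factor = cfg.loop_factor = 1.0
        truth = synth.make_truth(cfg, seed=3)
        cm = synth.simulate_contacts(truth, "2D", seed=4)
        n = cm.n_bins
        for d in (1, 5, 20):
            diag = np.diagonal(cm.values, offset=d)
            lam = cfg.depth * (1 + d) ** -cfg.alpha
            se = np.sqrt(lam / len(diag))
            assert abs(diag.mean() - lam) < 5 * se

    def test_within_vs_between_tad_ratio_near_tad_factor(self):
        cfg = _no_event_config()
        cfg.comp_factor = cfg.loop_factor = 1.0
        truth = synth.make_truth(cfg, seed=6)
        cm = synth.simulate_contacts(truth, "2D", seed=7)
        bounds = np.asarray(truth.tad_boundaries["2D"])
        tad_id = np.searchsorted(bounds, np.arange(cm.n_bins), side="right")
        # brute-force averaging at a fixed distance so decay cancels
        d = 4
        i = np.arange(cm.n_bins - d)
        j = i + d
        same = tad_id[i] == tad_id[j]
        ratio = cm.values[i[same], j[same]].mean() / cm.values[i[~same], j[~same]].mean()
        assert ratio == pytest.approx(cfg.tad_factor, rel=0.1)

    def test_poisson_marginals(self):
        cfg = synth.scaled_config(200)
        truth = synth.make_truth(cfg, seed=9)
        lam = synth.expected_lambda(truth, "2D")
        rng = np.random.default_rng(0)
        cells = list(zip(rng.integers(0, 200, 40), rng.integers(0, 200, 40)))
        reps = np.stack([synth.simulate_contacts(truth, "2D", seed=100 + r).values
                         for r in range(100)])
        violations = 0
        for (i, j) in cells:
            mean = reps[:, i, j].mean()
            se = np.sqrt(lam[i, j] / 100)
            if abs(mean - lam[i, j]) > 3 * max(se, 1e-9):
                violations += 1
        assert violations <= 3


class TestPeaksAndGenes:
    def test_zero_loss_identical_ctcf(self):
        truth = synth.make_truth(_no_event_config(ctcf_loss_fraction=0.0), seed=4)
        p2 = truth.peak_truth["ctcf"]["2D"]
        p3 = truth.peak_truth["ctcf"]["3D"]
        assert p2[["start", "end"]].equals(p3[["start", "end"]])

    def test_loss_fraction_binomial(self):
        cfg = _no_event_config(ctcf_loss_fraction=0.75, n_ctcf_background=1000)
        truth = synth.make_truth(cfg, seed=4)
        n2 = len(truth.peak_truth["ctcf"]["2D"])
        n3 = len(truth.peak_truth["ctcf"]["3D"])
        expect = 0.25 * n2
        sd = np.sqrt(n2 * 0.25 * 0.75)
        assert abs(n3 - expect) < 4 * sd

    def test_gene_classes_and_thresholds_consistent(self):
        truth = synth.make_truth(synth.scaled_config(400), seed=5)
        genes = synth.simulate_genes(truth, seed=6)
        cfg = truth.config
        up = genes["de_class"] == "up"
        down = genes["de_class"] == "down"
        ns = genes["de_class"] == "ns"
        assert (genes.loc[up, "log2FC"] >= cfg.lfc_thresh).all()
        assert (genes.loc[up, "padj"] < cfg.p_thresh).all()
        assert (genes.loc[down, "log2FC"] <= -cfg.lfc_thresh).all()
        assert not ((genes.loc[ns, "log2FC"].abs() >= cfg.lfc_thresh)
                    & (genes.loc[ns, "padj"] < cfg.p_thresh)).any()
        assert ((genes["tss"] >= genes["start"]) & (genes["tss"] <= genes["end"])).all()

    def test_pr_gains_in_3d(self):
        truth = synth.make_truth(synth.scaled_config(400), seed=5)
        assert len(truth.peak_truth["pr"]["3D"]) > len(truth.peak_truth["pr"]["2D"])


class TestFixtureFiles:
    def test_manifest_checksums_reproduce(self, tmp_path):
        cfg = synth.scaled_config(300)
        truth = synth.make_truth(cfg, seed=8)
        m1 = synth.write_fixture(truth, tmp_path / "a")
        m2 = synth.write_fixture(truth, tmp_path / "b")
        assert m1 == m2
        assert "truth.json" in m1 and "contacts_2D.tsv" in m1

    def test_contacts_round_trip_through_files(self, tmp_path):
        cfg = synth.scaled_config(300)
        truth = synth.make_truth(cfg, seed=8)
        synth.write_fixture(truth, tmp_path)
        cm_file = read_contacts(tmp_path / "contacts_3D.tsv", tmp_path / "bins.bed")
        cm_mem = synth.simulate_contacts(truth, "3D", seed=truth.seed + 2)
        np.testing.assert_array_equal(cm_file.values, cm_mem.values)

    def test_truth_json_parses(self, tmp_path):
        truth = synth.make_truth(synth.scaled_config(300), seed=8)
        payload = json.loads(truth.to_json())
        assert payload["seed"] == 8
        assert len(payload["tad_boundaries"]["2D"]) >= 2
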