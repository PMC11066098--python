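"""Shared fixtures: the default planted-event study and the corner-loss
study, computed once per session (the expensive pieces are the 2000-bin
Poisson matrices and their balancing/eigendecomposition)."""

from __future__ import annotations

import numpy as np
import pytest

from spherotad import synth
from spherotad.matrix import ice_balance, observed_over_expected
from spherotad.compartments import compartment_eigenvector, orient_track, call_transitions
from spherotad.tads import call_tads
from spherotad.tadcompare import compare_tads

DEFAULT_SEED = 7
CORNER_SEED = 11


@pytest.fixture(scope="session")
def default_truth():
    return synth.make_truth(synth.SimConfig(), seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_run(default_truth):
    """Full end-to-end state on the default fixture: balanced + O/E
    matrices, oriented compartment tracks, called TADs and change set."""
    truth = default_truth
    bal, oe = {}, {}
    for k, cond in enumerate(("2D", "3D")):
        cm = synth.simulate_contacts(truth, cond, seed=DEFAULT_SEED + 1 + k)
        bal[cond] = ice_balance(cm)
        oe[cond] = observed_over_expected(bal[cond])
    ref = synth.gene_density_track(truth)
    tracks = {"2D": orient_track(compartment_eigenvector(oe["2D"]), ref)}
    tracks["3D"] = orient_track(compartment_eigenvector(oe["3D"]),
                                tracks["2D"].pc1)
    regions, counts = call_transitions(tracks["2D"], tracks["3D"])
    tsets = {c: call_tads(bal[c]) for c in bal}
    changes = compare_tads(tsets["2D"], tsets["3D"])
    return {"truth": truth, "bal": bal, "oe": oe, "tracks": tracks,
            "regions": regions, "counts": counts, "tsets": tsets,
            "changes": changes}


@pytest.fixture(scope="session")
def corner_run():
    """Corner-loss study: loop losses planted at down-gene domains only."""
    truth = synth.make_truth(synth.corner_loss_config(), seed=CORNER_SEED)
    oe = {}
    for k, cond in enumerate(("2D", "3D")):
        cm = synth.simulate_contacts(truth, cond, seed=CORNER_SEED + 1 + k)
        oe[cond] = observed_over_expected(ice_balance(cm))
    tads2 = call_tads(ice_balance(
        synth.simulate_contacts(truth, "2D", seed=CORNER_SEED + 1)))
    return {"truth": truth, "oe": oe, "tads2": tads2}


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """A written 600-bin fixture directory for pipeline/CLI tests."""
    d = tmp_path_factory.mktemp("fixture600")
    truth = synth.make_truth(synth.scaled_config(600), seed=DEFAULT_SEED)
    synth.write_fixture(truth, d)
    return d


def tads_containing_genes(tadset, genes, bin_size):
    """Unique TAD intervals holding a TSS of the gene set."""
    bounds = np.array([t.start_bin for t in tadset.tads]
                      + [tadset.tads[-1].end_bin])
    out, seen = [], set()
    for tss in genes["tss"]:
        b = int(tss) // bin_size
        k = np.searchsorted(bounds, b, side="right") - 1
        if 0 <= k < len(tadset.tads):
            t = tadset.tads[k]
            key = (t.start_bin, t.end_bin)
            if t.start_bin <= b < t.end_bin and key not in seen:
                seen.add(key)
                out.append(key)
    return out
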