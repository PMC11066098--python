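"""Peak and gene integration statistics.

Peak-set overlap accounting (including count-mode from published totals),
DE-table summarization, enhancer-to-gene distances and the comparative-Ct
qPCR fold."""

from spherotad import synth
from spherotad.features import (overlap_peaks, overlap_counts, de_summary,
                                enhancer_distance, chip_qpcr_enrichment)

truth = synth.make_truth(synth.scaled_config(600), seed=7)
peaks = {c: synth.simulate_peaks(truth, c, seed=18 + k)
         for k, c in enumerate(("2D", "3D"))}

ov = overlap_peaks(peaks["2D"]["ctcf"], peaks["3D"]["ctcf"])
print(f"CTCF peaks: {ov['n_a']} in 2D, {ov['n_b']} in 3D "
      f"({100 * (1 - ov['n_b'] / ov['n_a']):.1f}% lost in 3D)")
print(f"  of the 3D peaks, {ov['pct_shared_b']}% are also present in 2D")

# count-mode works directly from published totals, e.g. accessible-chromatin
# peaks: 37,342 of 38,542 3D peaks shared with 2D
ov = overlap_counts(93_850, 38_542, 37_342)
print(f"count-mode example: {ov['pct_shared_b']}% of 3D peaks shared")

genes = synth.simulate_genes(truth, seed=31)
de = de_summary(genes, lfc_thresh=1.0, p_thresh=0.01)
print(f"DE summary: {de['n_up']} up + {de['n_down']} down "
      f"= {de['n_total']} regulated genes")

# enhancer-associated PR sites: PR peaks overlapping H3K27ac; their distance
# to the nearest DE-gene TSS vs a size-matched random gene control
res = enhancer_distance(peaks["3D"]["pr"], peaks["3D"]["h3k27ac"], genes,
                        genes[genes.de_class != "ns"], seed=3)
print(f"enhancer-associated PR peaks: {res['n_enhancers']}; "
      f"median distance to DE-gene TSS {res['median_set'] / 1e3:.0f} kb "
      f"vs random {res['median_random'] / 1e3:.0f} kb (one-sided p = {res['p']:.3g})")

fold = chip_qpcr_enrichment(ct_ip=22.0, ct_ref=25.3)
print(f"ChIP-qPCR comparative-Ct fold for a 3.3-cycle difference: {fold:.2f}")
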