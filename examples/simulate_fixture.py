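"""Generate a paired 2D/3D synthetic fixture and inspect its ground truth.

Builds a 60-Mb toy chromosome (600 bins at 100 kb) with planted compartment
flips, TAD fusions/splits/shifts and condition-lost CTCF peaks, then writes
the fixture files and prints what was planted."""

from spherotad import synth

cfg = synth.scaled_config(600)
truth = synth.make_truth(cfg, seed=7)
manifest = synth.write_fixture(truth, "scratch/fixture600")

print(f"chromosome: {cfg.chrom}, {cfg.n_bins} bins x {cfg.bin_size // 1000} kb")
print(f"TADs: {len(truth.tad_boundaries['2D']) - 1} in 2D, "
      f"{len(truth.tad_boundaries['3D']) - 1} in 3D")
for kind in ("AtoB", "BtoA", "fusion", "split", "shift"):
    print(f"planted {kind}: {len(truth.events_of(kind))}")
print(f"genes: {len(truth.genes)} "
      f"({(truth.genes.de_class == 'down').sum()} down, "
      f"{(truth.genes.de_class == 'up').sum()} up)")
print(f"wrote {len(manifest)} files (checksummed) to scratch/fixture600")

# The planted events are the ground truth every downstream analysis is
# scored against: e.g. each fusion names the 2D boundary that vanishes in 3D.
fusion = truth.events_of("fusion")[0]
print(f"example fusion: 2D boundary at bin {fusion['removed_boundary']} "
      f"absent in 3D (event spans bins {fusion['start_bin']}-{fusion['end_bin']})")
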