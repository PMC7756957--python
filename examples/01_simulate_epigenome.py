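"""Build a synthetic epigenome and inspect its planted truth.

The generator plants transposable elements (TEs) carrying family
consensus sequences, phases nucleosomes every 150 bp across TE bodies,
and records a 20-bp hypermethylation patch in the middle of every
linker — the geometry the downstream DMR and periodicity stages are
built to detect.
"""

import numpy as np

from epiphase.simulate import GenomeSpec, GenotypeProfile, build_genome, simulate_methylome

spec = GenomeSpec(chromosome_length=300_000, te_count=20, gene_count=20)
genome = build_genome(spec, seed=1)

tes = genome.features.tes()
peri = sum(f.compartment == "pericentromeric" for f in tes)
print(f"genome: {spec.chromosome_length:,} bp, {len(tes)} TEs ({peri} pericentromeric), "
      f"{len(genome.features.genes())} genes")
print(f"nucleosome centers: {len(genome.nucleosomes):,}; "
      f"linker patches: {len(genome.linker_patches):,} "
      f"(width {spec.patch_width} bp, repeat {spec.nrl} bp)")

m = simulate_methylome(genome, GenotypeProfile.wt(coverage=20), seed=2)
cg = m.subset_context("CG").frame
print(f"WT methylome: {len(m):,} cytosines, mean coverage "
      f"{cg['n_total'].mean():.1f}x, pooled mCG/CG = "
      f"{cg['n_meth'].sum() / cg['n_total'].sum():.3f}")
# The pooled CG methylation mixes heterochromatic TEs (~0.85) with
# unmethylated genes and intergenic space, so it sits well below 0.85.

spacing = np.diff(genome.nucleosomes.centers["chr1"])
print(f"median nucleosome spacing within TEs: {np.median(spacing[spacing <= 300]):.0f} bp")
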