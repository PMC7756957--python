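"""Set-level statistics: overlap, motif and family enrichment, allele
fractions, and fold-change summaries over a TE subset."""

import numpy as np
import pandas as pd

from epiphase.setstats import (
    allele_fraction,
    default_motifs,
    family_composition,
    fc_summary,
    motif_enrichment,
    overlap_enrichment,
)
from epiphase.simulate import GenomeSpec, build_genome

genome = build_genome(GenomeSpec(chromosome_length=500_000, te_count=60, gene_count=20), seed=8)
tes = genome.features.tes()
universe = set(tes.ids())

# do TEs carrying a planted PRE-like motif overlap pericentromeric TEs by chance?
motif_pos = set(genome.motif_positive_ids)
peri = {f.id for f in tes if f.compartment == "pericentromeric"}
res = overlap_enrichment(motif_pos, peri, universe)
print(f"overlap: {res.n_observed} of expected {res.expected:.1f} "
      f"-> fold {res.fold:.2f}, hypergeometric P = {res.p:.3g}")
print("(motifs are planted independently of compartment, so fold ~ 1 is correct)")

# motif enrichment of motif-positive TEs against the rest
seqs = {
    f.id: genome.sequences[f.interval.chrom][f.interval.start : f.interval.end]
    for f in tes
}
target = {i: seqs[i] for i in motif_pos}
background = {i: s for i, s in seqs.items() if i not in motif_pos}
enr = motif_enrichment(target, background, default_motifs())
print(enr.round(4).to_string(index=False))

comp, p = family_composition(peri, tes, universe)
print(f"family composition of pericentromeric TEs vs all: chi-square p = {p:.3f}")

pct_evd, pct_atr = allele_fraction(count_g=870, count_t=130)
print(f"pyrosequencing-style allele split: {pct_evd:.0f}% EVD / {pct_atr:.0f}% ATR")

rng = np.random.default_rng(0)
ids = sorted(universe)
de = pd.DataFrame({
    "feature_id": ids * 2,
    "group": ["ddm1"] * len(ids) + ["ddm1_clf"] * len(ids),
    "log2FC": np.concatenate([rng.normal(2, 1, len(ids)), rng.normal(0.8, 1, len(ids))]),
})
summaries, tests = fc_summary(de, peri, reference_group="ddm1")
for s in summaries:
    print(f"{s.group}: median log2FC {s.median:.2f} (IQR {s.q1:.2f}..{s.q3:.2f}, n={s.n})")
print(tests.round(4).to_string(index=False))
print("the lower fold changes in the double mutant flag re-silencing of these TEs")
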