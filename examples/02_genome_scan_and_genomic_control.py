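"""Naive vs eigenvector-adjusted genome scan under population structure.

Simulates 295 samples in two subpopulations (Fst = 0.05) with a phenotype
linked to ancestry, encodes naive summary statistics, and compares the
no-covariate scan against the saturated five-eigenvector scan.
"""

import numpy as np

import oathgwas as og
from oathgwas.synthetic import SimConfig, encode_panel, sim_genotypes, sim_phenotype

cfg = SimConfig(n_samples=295, n_loci=2000, n_subpops=2, fst=0.05,
                causal=((50, 0.10),), seed=7)
sim = sim_genotypes(cfg)
V = og.top_eigenvectors(og.grm(sim.genotypes), 5)
y = sim_phenotype(sim.genotypes, cfg.causal, covariates=V,
                  covariate_effects=np.array([1.0, 0.5, 0, 0, 0]),
                  seed=8, standardize=True)
generic, loci = encode_panel(sim, y, V, [f"EV{j}" for j in range(1, 6)])

naive = og.scan(generic, loci, og.SubsetSpec(()))
saturated = og.scan(generic, loci)
print(f"lambda_GC naive:     {naive.lambda_gc:.3f}")
print(f"lambda_GC saturated: {saturated.lambda_gc:.3f}")

threshold_hits = og.call_hits(saturated, alpha=0.05)
print(f"Bonferroni threshold at {len(loci)} loci: {threshold_hits.threshold:.2f}")
print(f"saturated-model hits: {threshold_hits.hits.SNP.tolist()}")

adj = og.gc_adjust(naive)
top = adj.records.nlargest(1, "MLOG10P_RAW").iloc[0]
print(f"top naive locus {top.SNP}: -log10 p {top.MLOG10P_RAW:.2f} raw, "
      f"{top.MLOG10P:.2f} after genomic-control deflation")

print("\nThe ancestry-linked phenotype inflates the naive scan's lambda_GC "
      "above the adjusted scan's; the causal locus snp51 survives in the "
      "saturated model.")
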