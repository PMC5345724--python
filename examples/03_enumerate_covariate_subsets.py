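"""Recover the results of every covariate-subset model for one locus.

With five candidate eigenvector covariates there are 2^5 = 32 possible
models.  A locus is an "OATH hit" if any of them clears the Bonferroni line;
the spread of its 32 -log10(p) values is then summarized by gap-partitioning
them into groups and testing group separation with a one-way ANOVA F.
"""

import numpy as np

import oathgwas as og
from oathgwas.synthetic import SimConfig, encode_panel, sim_genotypes, sim_phenotype

cfg = SimConfig(n_samples=295, n_loci=500, n_subpops=2, fst=0.08,
                causal=((42, 0.12),), seed=11)
sim = sim_genotypes(cfg)
V = og.top_eigenvectors(og.grm(sim.genotypes), 5)
y = sim_phenotype(sim.genotypes, cfg.causal, covariates=V,
                  covariate_effects=np.array([1.2, 0, 0, 0, 0]),
                  seed=12, standardize=True)
generic, loci = encode_panel(sim, y, V, [f"EV{j}" for j in range(1, 6)])

locus = loci[42]
fits = og.enumerate_models(generic, locus)
print(f"{len(fits)} models fitted for {locus.snp_id}")

vals = np.array([f.mlog10p for f in fits.values()])
print(f"-log10 p range across models: {vals.min():.2f} .. {vals.max():.2f}")

hits = og.call_hits({locus.snp_id: fits}, alpha=0.05, n_tests=len(loci))
if len(hits.hits):
    best = hits.hits.iloc[0]
    print(f"OATH hit above threshold {hits.threshold:.2f}: best model "
          f"{best.SUBSET} at -log10 p {best.MLOG10P:.2f}")

groups = og.partition_pvalues(vals)
F, mp = og.anova_f(groups) if len(groups) > 1 else (float("nan"), float("nan"))
print(f"p-value groups (gap > 1 unit): {len(groups)}, sizes "
      f"{[len(g) for g in groups]}, ANOVA F = {F:.1f}")

if len(groups) == 1:
    print("\nA single tight group: this hit is robust to the covariate "
          "choice -- every one of the 32 models tells the same story.")
else:
    print("\nMultiple groups mean the covariate choice moves this locus "
          "across significance regimes -- exactly the modelling sensitivity "
          "the enumeration is designed to expose.")
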