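"""Fit the hierarchical enrichment model for TWAS hits inside DEG sets.

Builds paired binomial counts (hits among DEGs vs among the remaining
expressed genes), estimates gene-wise tetrachoric correlation matrices
with nearest-PSD repair, samples the correlated hierarchical binomial
model by NUTS and prints posterior-mass enrichment calls.
"""

from exertrait import deg_sets, generate_de_study, generate_twas
from exertrait.config import PlantedEffects, SamplerConfig, SimConfig
from exertrait.intersect import (
    build_intersect_counts,
    fit_intersect_model,
    intersect_correlation,
    summarize_enrichment,
)

cfg = SimConfig(
    n_tissues=4, n_traits=6, n_categories=3, n_genes=1200,
    n_samples_human=60, n_snps=120, de_fraction=0.15, seed=3,
    planted_effects=PlantedEffects(alpha=1.0),  # planted log-odds difference
)
de = generate_de_study(cfg)
twas = generate_twas(cfg, de)
degs = deg_sets(de)

counts = build_intersect_counts(degs, twas, alpha=0.05)
print(f"{counts.n_traits_nonzero_intersect}/{len(counts.traits)} traits have a "
      "nonzero DEG intersect")
corr = intersect_correlation(degs, counts)
mcmc = SamplerConfig(chains=2, warmup=500, samples=500, seed=9)
fit = fit_intersect_model(counts, corr, mcmc)
print(f"divergent iterations: {fit.n_divergent}/{fit.n_iterations}")

summary = summarize_enrichment(fit, mass_rule=0.95, require_diagnostics=False)
overall = summary[summary["level"] == "overall"].iloc[0]
print(f"overall enrichment alpha: posterior mean {overall['post_mean']:.2f} "
      f"(planted 1.0), P(alpha > 0) = {overall['p_positive']:.3f}")
print(summary[summary["level"] == "tissue"][
    ["unit", "post_mean", "ci5", "ci95", "flagged"]
].to_string(index=False))
# alpha near 1 recovers the planted log-odds enrichment of TWAS hits in
# DEG sets; flagged units place >= 95% posterior mass on one side of 0.
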