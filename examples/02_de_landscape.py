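"""Summarize the differential-expression landscape.

Computes signed DE z-scores, cross-condition Spearman concordance, DEG-set
Jaccard overlap, tissue specificity and the evidence-score intersection.
"""

import exertrait
from exertrait.config import SimConfig

cfg = SimConfig(
    n_tissues=5, n_traits=8, n_categories=4, n_genes=1000,
    n_samples_human=80, n_snps=150, seed=42,
)
de = exertrait.generate_de_study(cfg)
evidence = exertrait.generate_evidence(cfg)
degs = exertrait.deg_sets(de)

z = exertrait.zscore_matrix(de)
concord = exertrait.concordance_matrix(z)
print(f"z-matrix: {z.shape[0]} complete genes x {z.shape[1]} conditions")
off = concord.to_numpy()[~(concord.to_numpy() == 1.0)]
print(f"median cross-condition Spearman rho: {off.mean():.3f}")

jac = exertrait.jaccard_matrix(degs)
print("max off-diagonal Jaccard:",
      round(float((jac.to_numpy() - __import__('numpy').eye(5)).max()), 3))

spec = exertrait.tissue_specificity_counts(degs)
print("tissue specificity (how many tissues share each DE gene):")
print(spec.to_string(index=False))

triplets, summary = exertrait.evidence_intersect(
    degs, evidence, threshold=0.8, exclude_tissues=["BLOOD", "SKM-GN", "SKM-VL"]
)
print(f"high-evidence (score > 0.8) DEG-trait triplets: {len(triplets)}")
print(summary.to_string(index=False))
# Low Jaccard values and a specificity histogram dominated by k = 1 mean
# exercise adaptation is largely tissue-private, as in real training data.
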