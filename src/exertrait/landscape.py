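"""Differential-expression landscape summaries.

Signed z-transform of DE results, cross-condition Spearman concordance,
gene-set Jaccard overlap, tissue-specificity histograms and intersection
of DEG sets with gene-disease evidence scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import spearmanr

from exertrait.simulate import DEStudy, EvidenceTable


@dataclass
class DegSetCollection:
    """Per-tissue sets of 8-week sex-consistent DE genes with signed direction.

    Members are genes whose 8-week state is (1, 1) (up in both sexes) or
    (-1, -1) (down in both sexes); ``direction`` maps (tissue, gene) to +1/-1.
    """

    tissues: list[str]
    sets: dict[str, set[str]]
    direction: dict[tuple[str, str], int]
    universe: set[str]

    def genes(self, tissue: str) -> set[str]:
        return self.sets[tissue]


def de_zscore(p_value: float, log2fc: float) -> float:
    """Signed z-score of a two-sided DE p-value.

    z = Phi^-1(1 - p/2) * sign(log2fc); sign(0) is taken as +1.  p must lie
    in (0, 1]: p = 0 would map to an infinite z.
    """
    p = float(p_value)
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value must lie in (0, 1], got {p}")
    if not np.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    sign = -1.0 if log2fc < 0 else 1.0
    return float(ndtri(1.0 - p / 2.0) * sign)


def zscore_matrix(de: DEStudy) -> pd.DataFrame:
    """Gene x condition matrix of signed DE z-scores.

    Conditions are (tissue, sex, timepoint) combinations; genes with any
    missing condition are dropped listwise.
    """
    res = de.results.copy()
    if (res["p_value"] <= 0).any() or (res["p_value"] > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    sign = np.where(res["log2fc"] < 0, -1.0, 1.0)
    res["z"] = ndtri(1.0 - res["p_value"] / 2.0) * sign
    res["condition"] = (
        res["tissue"] + ":" + res["sex"] + ":" + res["timepoint"]
    )
    mat = res.pivot_table(index="gene", columns="condition", values="z", aggfunc="first")
    return mat.dropna(axis=0, how="any")


def concordance_matrix(z: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation between every pair of conditions.

    Requires at least 3 complete genes; a condition with zero rank variance
    produces missing entries against every other condition.
    """
    if z.shape[0] < 3:
        raise ValueError("need at least 3 complete genes for concordance")
    cols = list(z.columns)
    values = z.to_numpy()
    degenerate = np.array([np.unique(values[:, i]).size < 2 for i in range(len(cols))])
    rho, _ = spearmanr(values)
    rho = np.atleast_2d(np.asarray(rho, float))
    rho[degenerate, :] = np.nan
    rho[:, degenerate] = np.nan
    idx = np.arange(len(cols))
    rho[idx[~degenerate], idx[~degenerate]] = 1.0
    return pd.DataFrame(rho, index=cols, columns=cols)


def deg_sets(de: DEStudy) -> DegSetCollection:
    """Extract 8-week sex-consistent DEG sets with signed directions."""
    last = de.timepoints[-1]
    st = de.states[de.states["timepoint"] == last]
    member = (st["state_F"] == st["state_M"]) & (st["state_F"] != 0)
    sets: dict[str, set[str]] = {t: set() for t in de.tissues}
    direction: dict[tuple[str, str], int] = {}
    sub = st[member]
    for tissue, gene, s in zip(sub["tissue"], sub["gene"], sub["state_F"]):
        sets[tissue].add(gene)
        direction[(tissue, gene)] = int(s)
    return DegSetCollection(
        tissues=list(de.tissues),
        sets=sets,
        direction=direction,
        universe=set(de.genes),
    )


def jaccard_matrix(degs: DegSetCollection) -> pd.DataFrame:
    """Jaccard similarity |A & B| / |A | B| between all tissue DEG sets.

    J of two empty sets is defined as 0; the diagonal is 1 for nonempty sets.
    """
    tissues = degs.tissues
    n = len(tissues)
    mat = np.zeros((n, n))
    for i in range(n):
        a = degs.sets[tissues[i]]
        for j in range(i, n):
            b = degs.sets[tissues[j]]
            union = len(a | b)
            mat[i, j] = mat[j, i] = (len(a & b) / union) if union else 0.0
    return pd.DataFrame(mat, index=tissues, columns=tissues)


def tissue_specificity_counts(degs: DegSetCollection) -> pd.DataFrame:
    """Histogram over k = number of tissues sharing each DE gene.

    Returns counts and cumulative fractions over k in {1..n_tissues};
    counts sum to the number of unique DE genes.
    """
    n_tissues = len(degs.tissues)
    tally: dict[str, int] = {}
    for t in degs.tissues:
        for g in degs.sets[t]:
            tally[g] = tally.get(g, 0) + 1
    counts = np.zeros(n_tissues, dtype=int)
    for k in tally.values():
        counts[k - 1] += 1
    total = counts.sum()
    frac = counts / total if total else np.zeros(n_tissues)
    return pd.DataFrame(
        {
            "n_tissues_shared": np.arange(1, n_tissues + 1),
            "count": counts,
            "fraction": frac,
            "cumulative_fraction": np.cumsum(frac),
        }
    )


def evidence_intersect(
    degs: DegSetCollection,
    ev: EvidenceTable,
    threshold: float = 0.8,
    exclude_tissues: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-reference DEG sets with gene-disease evidence scores.

    Returns (triplets, summary): triplets are exactly the (gene, trait,
    tissue) rows with gene in the tissue's DEG set and evidence score
    strictly above ``threshold``.  The summary gives per-tissue counts plus
    an ``excluding_listed`` row restricted to tissues outside
    ``exclude_tissues`` (e.g. the easily biopsied ones).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    exclude = list(exclude_tissues or [])
    unknown = [t for t in exclude if t not in degs.tissues]
    if unknown:
        raise ValueError(f"unknown tissues in exclusion list: {unknown}")
    strong = ev.table[ev.table["score"] > threshold]
    rows = []
    for tissue in degs.tissues:
        members = degs.sets[tissue]
        if not members:
            continue
        sub = strong[strong["gene"].isin(members)]
        if len(sub):
            rows.append(sub.assign(tissue=tissue))
    triplets = (
        pd.concat(rows, ignore_index=True)[["gene", "trait", "tissue", "score"]]
        if rows
        else pd.DataFrame(columns=["gene", "trait", "tissue", "score"])
    )
    per_tissue = (
        triplets.groupby("tissue").size().reindex(degs.tissues, fill_value=0)
    )
    kept = triplets[~triplets["tissue"].isin(exclude)]
    summary = pd.DataFrame(
        {
            "tissue": list(per_tissue.index) + ["excluding_listed"],
            "n_triplets": list(per_tissue.to_numpy()) + [len(kept)],
            "n_unique_genes": [
                triplets.loc[triplets["tissue"] == t, "gene"].nunique()
                for t in per_tissue.index
            ]
            + [kept["gene"].nunique()],
            "n_unique_traits": [
                triplets.loc[triplets["tissue"] == t, "trait"].nunique()
                for t in per_tissue.index
            ]
            + [kept["trait"].nunique()],
        }
    )
    return triplets, summary
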