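"""Hierarchical Bayesian enrichment of TWAS hits inside DEG sets.

Per tissue i and trait j the counts of TWAS hits among the 8-week
sex-consistent DEGs (y_deg of n_deg) and among the remaining expressed
genes (y_nondeg of n_nondeg) are modeled as binomials whose logit-scale
locations sit symmetrically around a cell baseline pi_ij:

    logit p_deg    = pi_ij + (alpha + beta_i + gamma_j + eps_ij) / 2
    logit p_nondeg = pi_ij - (alpha + beta_i + gamma_j + eps_ij) / 2

The difference decomposition has an overall term alpha ~ N(0,1), tissue
terms beta ~ MVN(0, s_b^2 Sigma_tissue), trait terms gamma ~
MVN(mu_k, s_g^2 Sigma_trait) nested in category means mu_k ~ N(0, s_m),
and cell terms eps ~ MVN(0, s_e^2 Sigma_cell).  The baseline is given the
mirror-image hierarchy (pi ~ MVN(eta_j, s_p^2 Sigma_cell), eta ~
MVN(lambda_k, s_h^2 Sigma_trait), lambda_k ~ N(mu, s_l), mu ~ N(0,2)).
All scales are half-normal(0,1).  The fixed unit-level correlation
matrices guard against pseudo-replication: the same genes underlie many
cells, so unit effects cannot be treated as independent evidence.

Sampling uses the in-repo NUTS engine with a non-centered
parameterization at every multivariate-normal level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from exertrait.config import SamplerConfig
from exertrait.correlation import CorrelationSet, correlation_set
from exertrait.hmc import PosteriorDraws, make_posterior, sample_nuts
from exertrait.landscape import DegSetCollection
from exertrait.simulate import TwasTable


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

@dataclass
class IntersectCounts:
    """Paired binomial count grids over tissue x trait."""

    tissues: list[str]
    traits: list[str]
    categories: list[str]
    cat_index: np.ndarray  # per trait, index into categories
    y_deg: np.ndarray  # tissues x traits
    n_deg: np.ndarray
    y_nondeg: np.ndarray
    n_nondeg: np.ndarray
    hits: pd.DataFrame  # gene, tissue, trait, hit flag (post-FDR)
    meta: dict = field(default_factory=dict)

    @property
    def n_traits_nonzero_intersect(self) -> int:
        return int((self.y_deg.sum(axis=0) > 0).sum())


def call_hits(twas: TwasTable, alpha: float = 0.05) -> pd.DataFrame:
    """Flag significant TWAS associations by stratified BH.

    Benjamini-Hochberg is applied within each tissue x trait stratum at
    ``alpha`` (a stratified-FDR stand-in for covariate-weighted FDR with
    tissue x trait as the covariate).
    """
    tab = twas.table.copy()
    tab["hit"] = False
    for _, idx in tab.groupby(["tissue", "trait"]).groups.items():
        pvals = tab.loc[idx, "p_value"].to_numpy()
        reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        tab.loc[idx, "hit"] = reject
    return tab[["gene", "tissue", "trait", "hit", "effect_sign"]]


def build_intersect_counts(
    degs: DegSetCollection,
    twas: TwasTable,
    alpha: float = 0.05,
    hits: pd.DataFrame | None = None,
) -> IntersectCounts:
    """Count TWAS hits inside and outside each tissue's DEG set.

    Pools are restricted to genes present in the TWAS table for that
    tissue (the mutually expressed universe), so n_deg + n_nondeg equals
    the expressed-gene total per (tissue, trait).  Traits whose intersect
    is zero everywhere are retained; their number is reported in ``meta``.
    """
    if not degs.universe:
        raise ValueError("empty gene universe")
    if hits is None:
        hits = call_hits(twas, alpha=alpha)
    tissues, traits = twas.tissues, twas.traits
    cat_index = np.array(
        [twas.categories.index(twas.trait_category[t]) for t in traits]
    )
    i_n, j_n = len(tissues), len(traits)
    y_deg = np.zeros((i_n, j_n), dtype=int)
    n_deg = np.zeros((i_n, j_n), dtype=int)
    y_non = np.zeros((i_n, j_n), dtype=int)
    n_non = np.zeros((i_n, j_n), dtype=int)
    for ti, tissue in enumerate(tissues):
        sub = hits[hits["tissue"] == tissue]
        deg_genes = degs.sets[tissue]
        for tj, trait in enumerate(traits):
            cell = sub[sub["trait"] == trait]
            in_deg = cell["gene"].isin(deg_genes).to_numpy()
            hit = cell["hit"].to_numpy(bool)
            y_deg[ti, tj] = int(np.sum(hit & in_deg))
            n_deg[ti, tj] = int(np.sum(in_deg))
            y_non[ti, tj] = int(np.sum(hit & ~in_deg))
            n_non[ti, tj] = int(np.sum(~in_deg))
    counts = IntersectCounts(
        tissues=list(tissues),
        traits=list(traits),
        categories=list(twas.categories),
        cat_index=cat_index,
        y_deg=y_deg,
        n_deg=n_deg,
        y_nondeg=y_non,
        n_nondeg=n_non,
        hits=hits,
        meta={"hit_fdr_alpha": alpha, "fdr_method": "stratified-BH (IHW stand-in)"},
    )
    counts.meta["n_traits_nonzero_intersect"] = counts.n_traits_nonzero_intersect
    return counts


def intersect_indicators(
    degs: DegSetCollection, counts: IntersectCounts
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Binary gene x unit indicator matrices for the correlation structure.

    Tissue units: DEG membership; trait units: hit membership pooled over
    tissues; cell units: DEG x hit intersect membership.  All over the
    mutual gene universe (genes appearing in every tissue's TWAS table).
    """
    hits = counts.hits
    present = hits.groupby("gene")["tissue"].nunique()
    universe = sorted(present[present == len(counts.tissues)].index)
    ind_tissue = pd.DataFrame(
        {t: [g in degs.sets[t] for g in universe] for t in counts.tissues},
        index=universe,
        dtype=int,
    )
    hit_any = (
        hits[hits["hit"]]
        .groupby(["gene", "trait"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=universe, columns=counts.traits, fill_value=0)
    )
    ind_trait = (hit_any > 0).astype(int)
    cell_cols = {}
    hit_by_tissue = {
        t: hits[(hits["tissue"] == t) & hits["hit"]] for t in counts.tissues
    }
    for tissue in counts.tissues:
        sub = hit_by_tissue[tissue]
        deg_genes = degs.sets[tissue]
        by_trait = sub.groupby("trait")["gene"].apply(set).to_dict()
        for trait in counts.traits:
            members = by_trait.get(trait, set()) & deg_genes
            cell_cols[f"{tissue}|{trait}"] = [int(g in members) for g in universe]
    ind_cell = pd.DataFrame(cell_cols, index=universe)
    return ind_tissue, ind_trait, ind_cell


def intersect_correlation(
    degs: DegSetCollection, counts: IntersectCounts, tol: float = 1e-8
) -> CorrelationSet:
    """Pairwise tetrachoric + PSD repair over the intersect indicator sets."""
    ind_tissue, ind_trait, ind_cell = intersect_indicators(degs, counts)
    return correlation_set(ind_tissue, ind_trait, ind_cell, tol=tol)


# ---------------------------------------------------------------------------
# model: log posterior and analytic gradient
# ---------------------------------------------------------------------------

class IntersectModel:
    """Non-centered parameterization of the enrichment model.

    Unconstrained vector layout:
    [alpha, mu, z_beta(I), z_gamma(J), z_eps(IJ), z_muk(K),
     z_pi(IJ), z_eta(J), z_lamk(K), log_sigma(7)]
    with sigma order (beta, gamma, eps, mu, pi, eta, lambda).
    """

    SIGMA_NAMES = ("beta", "gamma", "eps", "mu", "pi", "eta", "lambda")

    def __init__(self, counts: IntersectCounts, corr: CorrelationSet | None):
        self.I = len(counts.tissues)
        self.J = len(counts.traits)
        self.K = len(counts.categories)
        self.kidx = counts.cat_index
        self.y_deg = counts.y_deg.astype(float).ravel()
        self.n_deg = counts.n_deg.astype(float).ravel()
        self.y_non = counts.y_nondeg.astype(float).ravel()
        self.n_non = counts.n_nondeg.astype(float).ravel()
        cells = self.I * self.J

        def _chol(mat, dim):
            if mat is None:
                return np.eye(dim)
            m = np.asarray(mat, float)
            if m.shape != (dim, dim):
                raise ValueError(f"correlation matrix has shape {m.shape}, need {dim}")
            try:
                return np.linalg.cholesky(m)
            except np.linalg.LinAlgError:
                return np.linalg.cholesky(m + 1e-8 * np.eye(dim))

        if corr is None:
            self.L_i = np.eye(self.I)
            self.L_j = np.eye(self.J)
            self.L_c = np.eye(cells)
        else:
            self.L_i = _chol(
                corr.sigma_tissue.loc[counts.tissues, counts.tissues].to_numpy(), self.I
            )
            self.L_j = _chol(
                corr.sigma_trait.loc[counts.traits, counts.traits].to_numpy(), self.J
            )
            labels = [f"{t}|{tr}" for t in counts.tissues for tr in counts.traits]
            self.L_c = _chol(corr.sigma_cell.loc[labels, labels].to_numpy(), cells)

        self.slices = {}
        off = 0
        for name, size in [
            ("alpha", 1),
            ("mu", 1),
            ("z_beta", self.I),
            ("z_gamma", self.J),
            ("z_eps", cells),
            ("z_muk", self.K),
            ("z_pi", cells),
            ("z_eta", self.J),
            ("z_lamk", self.K),
            ("log_sigma", 7),
        ]:
            self.slices[name] = slice(off, off + size)
            off += size
        self.ndim = off
        # broadcast helpers: cell (i, j) at flat index i * J + j
        self.cell_i = np.repeat(np.arange(self.I), self.J)
        self.cell_j = np.tile(np.arange(self.J), self.I)

    # -- forward transform -------------------------------------------------
    def _forward(self, q: np.ndarray):
        s = self.slices
        alpha = q[s["alpha"]][0]
        mu = q[s["mu"]][0]
        z_beta = q[s["z_beta"]]
        z_gamma = q[s["z_gamma"]]
        z_eps = q[s["z_eps"]]
        z_muk = q[s["z_muk"]]
        z_pi = q[s["z_pi"]]
        z_eta = q[s["z_eta"]]
        z_lamk = q[s["z_lamk"]]
        ls = q[s["log_sigma"]]
        sig = np.exp(ls)
        sb, sg, se, sm, sp, sh, sl = sig
        mu_k = sm * z_muk
        lam_k = mu + sl * z_lamk
        Lb = self.L_i @ z_beta
        Lg = self.L_j @ z_gamma
        Le = self.L_c @ z_eps
        Lp = self.L_c @ z_pi
        Lh = self.L_j @ z_eta
        beta = sb * Lb
        gamma = mu_k[self.kidx] + sg * Lg
        eps = se * Le
        eta = lam_k[self.kidx] + sh * Lh
        pi = eta[self.cell_j] + sp * Lp
        d = alpha + beta[self.cell_i] + gamma[self.cell_j] + eps
        return dict(
            alpha=alpha, mu=mu, z_beta=z_beta, z_gamma=z_gamma, z_eps=z_eps,
            z_muk=z_muk, z_pi=z_pi, z_eta=z_eta, z_lamk=z_lamk, ls=ls, sig=sig,
            mu_k=mu_k, lam_k=lam_k, Lb=Lb, Lg=Lg, Le=Le, Lp=Lp, Lh=Lh,
            beta=beta, gamma=gamma, eps=eps, eta=eta, pi=pi, d=d,
        )

    @staticmethod
    def _binom_ll_grad(y, n, x):
        ll = float(np.sum(y * x - n * np.logaddexp(0.0, x)))
        return ll, y - n * expit(x)

    def logp_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        f = self._forward(q)
        p_deg = f["pi"] + f["d"] / 2.0
        p_non = f["pi"] - f["d"] / 2.0
        ll1, g_pdeg = self._binom_ll_grad(self.y_deg, self.n_deg, p_deg)
        ll2, g_pnon = self._binom_ll_grad(self.y_non, self.n_non, p_non)

        sig = f["sig"]
        logp = ll1 + ll2
        logp += -0.5 * f["alpha"] ** 2
        logp += -f["mu"] ** 2 / 8.0
        for name in ("z_beta", "z_gamma", "z_eps", "z_muk", "z_pi", "z_eta", "z_lamk"):
            logp += -0.5 * float(np.sum(f[name] ** 2))
        logp += float(np.sum(-0.5 * sig**2 + f["ls"]))  # half-normal + Jacobian

        g = np.zeros(self.ndim)
        s = self.slices
        g_pi = g_pdeg + g_pnon
        g_d = 0.5 * (g_pdeg - g_pnon)

        # difference branch
        g_alpha = float(np.sum(g_d)) - f["alpha"]
        g_beta = np.bincount(self.cell_i, weights=g_d, minlength=self.I)
        g_gamma = np.bincount(self.cell_j, weights=g_d, minlength=self.J)
        g_eps = g_d
        sb, sg, se, sm, sp, sh, sl = sig
        g[s["z_beta"]] = sb * (self.L_i.T @ g_beta) - f["z_beta"]
        g[s["z_eps"]] = se * (self.L_c.T @ g_eps) - f["z_eps"]
        g_mu_k = np.bincount(self.kidx, weights=g_gamma, minlength=self.K)
        g[s["z_gamma"]] = sg * (self.L_j.T @ g_gamma) - f["z_gamma"]
        g[s["z_muk"]] = sm * g_mu_k - f["z_muk"]

        # baseline branch
        g_eta = np.bincount(self.cell_j, weights=g_pi, minlength=self.J)
        g_lam_k = np.bincount(self.kidx, weights=g_eta, minlength=self.K)
        g[s["z_pi"]] = sp * (self.L_c.T @ g_pi) - f["z_pi"]
        g[s["z_eta"]] = sh * (self.L_j.T @ g_eta) - f["z_eta"]
        g[s["z_lamk"]] = sl * g_lam_k - f["z_lamk"]
        g_mu = float(np.sum(g_lam_k)) - f["mu"] / 4.0

        g[s["alpha"]] = g_alpha
        g[s["mu"]] = g_mu
        # scale gradients: d(param)/d(log sigma) = sigma * z-part
        g_ls = np.empty(7)
        g_ls[0] = sb * float(np.dot(f["Lb"], g_beta))
        g_ls[1] = sg * float(np.dot(f["Lg"], g_gamma))
        g_ls[2] = se * float(np.dot(f["Le"], g_eps))
        g_ls[3] = sm * float(np.dot(f["z_muk"], g_mu_k))
        g_ls[4] = sp * float(np.dot(f["Lp"], g_pi))
        g_ls[5] = sh * float(np.dot(f["Lh"], g_eta))
        g_ls[6] = sl * float(np.dot(f["z_lamk"], g_lam_k))
        g_ls += -sig**2 + 1.0
        g[s["log_sigma"]] = g_ls
        return logp, g

    def unpack(self, q: np.ndarray) -> dict[str, np.ndarray]:
        f = self._forward(q)
        out = {
            "alpha": np.array(f["alpha"]),
            "beta": f["beta"],
            "gamma": f["gamma"],
            "epsilon": f["eps"].reshape(self.I, self.J),
            "mu_category": f["mu_k"],
            "pi": f["pi"].reshape(self.I, self.J),
            "eta": f["eta"],
            "lambda_category": f["lam_k"],
            "mu_grand": np.array(f["mu"]),
        }
        for i, name in enumerate(self.SIGMA_NAMES):
            out[f"sigma_{name}"] = np.array(f["sig"][i])
        return out


def fit_intersect_model(
    counts: IntersectCounts,
    corr: CorrelationSet | None = None,
    mcmc: SamplerConfig | None = None,
) -> PosteriorDraws:
    """Sample the enrichment model posterior.

    ``corr=None`` uses identity correlation matrices (independent units).
    The returned draws are flagged ``passed=False`` when the diagnostics
    contract fails; partial output is retained either way.
    """
    mcmc = mcmc or SamplerConfig()
    model = IntersectModel(counts, corr)
    raw = sample_nuts(
        model.logp_grad,
        model.ndim,
        chains=mcmc.chains,
        warmup=mcmc.warmup,
        samples=mcmc.samples,
        target_accept=mcmc.target_accept,
        max_treedepth=mcmc.max_treedepth,
        seed=mcmc.seed,
    )
    notes = {
        "model": "intersect_enrichment",
        "tissues": counts.tissues,
        "traits": counts.traits,
        "categories": counts.categories,
        "cat_index": counts.cat_index.tolist(),
        "step_size": raw.step_size.tolist(),
    }
    return make_posterior(raw, model.unpack, notes=notes)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def _level_summary(values: np.ndarray, labels: list[str], level: str,
                   mass_rule: float) -> pd.DataFrame:
    """Posterior mean, middle-90% interval, P(>0) and one-sided-mass flag."""
    values = values.reshape(values.shape[0], -1)
    mean = values.mean(axis=0)
    lo, hi = np.quantile(values, [0.05, 0.95], axis=0)
    p_pos = (values > 0).mean(axis=0)
    flag = np.minimum(p_pos, 1 - p_pos) < (1 - mass_rule)
    return pd.DataFrame(
        {
            "level": level,
            "unit": labels,
            "post_mean": mean,
            "ci5": lo,
            "ci95": hi,
            "p_positive": p_pos,
            "flagged": flag,
        }
    )


def summarize_enrichment(
    draws: PosteriorDraws,
    mass_rule: float = 0.95,
    require_diagnostics: bool = True,
) -> pd.DataFrame:
    """Per-level enrichment summaries with the one-sided posterior-mass rule.

    Levels: overall (alpha), tissue (beta), category (mu_category), trait
    (gamma), and the cell-level composite alpha + beta_i + gamma_j +
    eps_ij evaluated per draw.
    """
    if require_diagnostics and not draws.passed:
        raise RuntimeError(
            "fit failed MCMC diagnostics; pass require_diagnostics=False to "
            "summarize anyway"
        )
    notes = draws.notes
    tissues = notes.get("tissues", [])
    traits = notes.get("traits", [])
    cats = notes.get("categories", [])
    alpha = draws.stacked("alpha").reshape(-1, 1)
    beta = draws.stacked("beta")
    gamma = draws.stacked("gamma")
    eps = draws.stacked("epsilon")
    mu_k = draws.stacked("mu_category")
    composite = (
        alpha[:, :, None] + beta[:, :, None] + gamma[:, None, :] + eps
    ).reshape(alpha.shape[0], -1)
    cell_labels = [f"{t}|{tr}" for t in tissues for tr in traits]
    out = pd.concat(
        [
            _level_summary(alpha, ["overall"], "overall", mass_rule),
            _level_summary(beta, tissues, "tissue", mass_rule),
            _level_summary(mu_k, cats, "category", mass_rule),
            _level_summary(gamma, traits, "trait", mass_rule),
            _level_summary(composite, cell_labels, "cell", mass_rule),
        ],
        ignore_index=True,
    )
    return out


def null_calibration(
    degs: DegSetCollection,
    counts: IntersectCounts,
    corr: CorrelationSet | None,
    mcmc: SamplerConfig | None = None,
    n_draws: int = 10,
    seed: int = 0,
    mass_rule: float = 0.95,
) -> pd.DataFrame:
    """Refit the model on size-matched random gene sets.

    Each replicate resamples, per tissue, a uniform random gene set of the
    original DEG-set size from that tissue's expressed universe, rebuilds
    the counts against the same hit calls, and refits the model (reusing
    the supplied correlation matrices as fixed plug-ins).  Reports, per
    replicate, P(alpha > 0) and the flagged fraction of cells.
    """
    mcmc = mcmc or SamplerConfig()
    rng = np.random.default_rng(seed)
    hits = counts.hits
    rows = []
    for rep in range(n_draws):
        fake_sets = {}
        for tissue in counts.tissues:
            pool = sorted(set(hits.loc[hits["tissue"] == tissue, "gene"]))
            size = min(len(degs.sets[tissue]), len(pool))
            fake_sets[tissue] = set(rng.choice(pool, size=size, replace=False))
        fake = DegSetCollection(
            tissues=degs.tissues,
            sets=fake_sets,
            direction={},
            universe=degs.universe,
        )
        c = build_intersect_counts(fake, _twas_stub(counts), hits=hits)
        rep_mcmc = SamplerConfig(**{**mcmc.to_dict(), "seed": mcmc.seed + rep + 1})
        fit = fit_intersect_model(c, corr, rep_mcmc)
        summary = summarize_enrichment(fit, mass_rule, require_diagnostics=False)
        cells = summary[summary["level"] == "cell"]
        alpha_row = summary[summary["level"] == "overall"].iloc[0]
        rows.append(
            {
                "replicate": rep,
                "p_alpha_positive": float(alpha_row["p_positive"]),
                "alpha_flagged": bool(alpha_row["flagged"]),
                "cell_flag_fraction": float(cells["flagged"].mean()),
                "diagnostics_passed": fit.passed,
            }
        )
    return pd.DataFrame(rows)


class _twas_stub:
    """Adapter letting build_intersect_counts reuse precomputed hit calls."""

    def __init__(self, counts: IntersectCounts):
        self.tissues = counts.tissues
        self.traits = counts.traits
        self.categories = counts.categories
        self.trait_category = {
            t: counts.categories[counts.cat_index[j]]
            for j, t in enumerate(counts.traits)
        }
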