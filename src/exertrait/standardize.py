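"""Standardization of exercise effects into SD units of human expression.

Exercise-induced log2 fold-changes are re-expressed in units of the
within-population phenotypic standard deviation of that gene's (log2)
expression, and -- for genes with significantly nonzero SNP-heritability --
in units of the genetic standard deviation:

    sd_pheno = log2FC / sqrt(Var(log2 expression))
    sd_geno  = log2FC / sqrt(h2 * Var(log2 expression))

The per-gene variance is an empirical-Bayes posterior mean: an
inverse-gamma prior is fit to the stratum's sample variances by minimum
goodness-of-fit, then conjugately updated per gene (zero-mean normal
likelihood on residualized expression).  Heritability comes from a
single-GRM REML fit of y ~ N(0, sg2 * GRM + se2 * I) per gene, with a
one-sided boundary-mixture likelihood-ratio p-value, thresholded by
within-tissue Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, invgamma
from statsmodels.stats.multitest import multipletests

from exertrait.simulate import DEStudy, HumanCohort


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

def pseudolog(x):
    """log2(x + 1); exact inverse of the counts-like mapping 2**y - 1."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("pseudolog requires nonnegative input")
    return np.log2(x + 1.0)


def residualize(expr: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each gene's expression on the covariates.

    An intercept column is appended.  The design must be full column rank;
    collinear columns are named in the error.
    """
    expr = np.atleast_2d(np.asarray(expr, float))
    cov = np.atleast_2d(np.asarray(covariates, float))
    n, q = cov.shape
    if expr.shape[0] != n:
        raise ValueError("expression and covariates disagree on sample count")
    if n <= q + 1:
        raise ValueError("need more samples than covariates (plus intercept)")
    design = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = []
        for j in range(1, design.shape[1]):
            sub = design[:, [c for c in range(design.shape[1]) if c != j]]
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(j - 1)
        raise ValueError(f"rank-deficient design; collinear covariate columns: {bad}")
    coef, *_ = np.linalg.lstsq(design, expr, rcond=None)
    return expr - design @ coef


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------

@dataclass
class VariancePrior:
    """Inverse-gamma prior on per-gene expression variance within a stratum."""

    shape: float  # a
    rate: float  # b (scale of the inverse-gamma)
    stratum: str = ""
    method: str = "cvm"
    converged: bool = True
    fallback: bool = False

    @property
    def prior_mean(self) -> float:
        if self.shape <= 1:
            raise ValueError("prior mean undefined for shape <= 1")
        return self.rate / (self.shape - 1)


@dataclass
class PosteriorVariance:
    gene: str
    stratum: str
    a_post: float
    b_post: float
    post_mean_var: float
    n_obs: int
    s2: float


def _moment_match_invgamma(s2: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(s2))
    v = float(np.var(s2))
    if v <= 0:
        a = 1e6
        return a, m * (a - 1)
    a = m * m / v + 2.0
    return a, m * (a - 1)


def fit_variance_prior(
    s2_values, method: str = "cvm", stratum: str = ""
) -> VariancePrior:
    """Fit an inverse-gamma distribution to sample variances.

    Minimum goodness-of-fit estimation: the (shape, rate) pair minimizing
    the Cramer-von Mises distance between the fitted CDF and the empirical
    CDF (``method='ks'`` / ``'ad'`` select the Kolmogorov-Smirnov /
    Anderson-Darling distance instead).  The objective is deterministic, so
    repeated fits agree exactly.  Degenerate (zero-variance) input or
    optimizer failure falls back to moment matching, flagged on the result.
    """
    s2 = np.sort(np.asarray(s2_values, float))
    if s2.size < 50:
        raise ValueError("need at least 50 sample variances to fit the prior")
    if np.any(s2 <= 0):
        raise ValueError("sample variances must be positive")
    if method not in ("cvm", "ks", "ad"):
        raise ValueError(f"unknown distance: {method!r}")

    a0, b0 = _moment_match_invgamma(s2)
    if np.var(s2) <= 0 or not np.isfinite(a0) or not np.isfinite(b0) or b0 <= 0:
        return VariancePrior(a0, max(b0, 1e-12), stratum, method, False, True)

    n = s2.size
    i = np.arange(1, n + 1)

    def distance(params: np.ndarray) -> float:
        a, b = np.exp(params)
        cdf = invgamma.cdf(s2, a, scale=b)
        if method == "cvm":
            return 1.0 / (12 * n) + float(np.sum((cdf - (2 * i - 1) / (2 * n)) ** 2))
        if method == "ks":
            return float(
                max(np.max(i / n - cdf), np.max(cdf - (i - 1) / n))
            )
        # Anderson-Darling
        cdf = np.clip(cdf, 1e-12, 1 - 1e-12)
        return float(
            -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log1p(-cdf[::-1])))
        )

    res = optimize.minimize(
        distance,
        x0=np.log([a0, b0]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
    )
    if not res.success or not np.all(np.isfinite(res.x)):
        return VariancePrior(a0, b0, stratum, method, False, True)
    a, b = np.exp(res.x)
    return VariancePrior(float(a), float(b), stratum, method, True, False)


def posterior_variance(
    s2: float, n: int, prior: VariancePrior, gene: str = "", stratum: str | None = None
) -> PosteriorVariance:
    """Conjugate inverse-gamma update for a zero-mean normal variance.

    With sufficient statistic n * s2 = sum(x^2): a_post = a + n/2,
    b_post = b + n * s2 / 2; the posterior mean is b_post / (a_post - 1).
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    a_post = prior.shape + n / 2.0
    b_post = prior.rate + n * float(s2) / 2.0
    if a_post <= 1:
        raise ValueError("posterior mean undefined (a_post <= 1)")
    return PosteriorVariance(
        gene=gene,
        stratum=prior.stratum if stratum is None else stratum,
        a_post=float(a_post),
        b_post=float(b_post),
        post_mean_var=float(b_post / (a_post - 1)),
        n_obs=int(n),
        s2=float(s2),
    )


# ---------------------------------------------------------------------------
# REML heritability
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityEstimate:
    gene: str
    tissue: str
    h2: float
    p_value: float
    converged: bool
    loglik: float = np.nan


def grm_eigen(grm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a GRM, validating symmetry and PSD-ness."""
    grm = np.asarray(grm, float)
    if grm.ndim != 2 or grm.shape[0] != grm.shape[1]:
        raise ValueError("GRM must be square")
    if not np.allclose(grm, grm.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    vals, vecs = np.linalg.eigh(grm)
    if vals.min() < -1e-8 * max(vals.max(), 1.0):
        raise ValueError("GRM is not positive semi-definite")
    vals = np.clip(vals, 0.0, None)
    if vals.max() - vals.min() < 1e-8:
        raise ValueError(
            "GRM eigenvalues are constant (identity-like); heritability is "
            "unidentifiable"
        )
    return vals, vecs


def _profile_loglik(h: float, lam: np.ndarray, y2: np.ndarray) -> float:
    """Profiled (over total variance) log-likelihood of the variance ratio."""
    n = lam.size
    w = h * lam + (1.0 - h)
    sigma2 = float(np.mean(y2 / w))
    return -0.5 * (n * np.log(sigma2) + float(np.sum(np.log(w))) + n)


def estimate_h2_reml(
    y: np.ndarray,
    grm: np.ndarray | tuple[np.ndarray, np.ndarray],
    gene: str = "",
    tissue: str = "",
) -> HeritabilityEstimate:
    """REML estimate of h2 = sg2 / (sg2 + se2) under y ~ N(0, sg2*GRM + se2*I).

    The GRM is eigendecomposed (pass a precomputed ``(eigvals, eigvecs)``
    pair to amortize across genes) and the likelihood profiled down to a
    1-D optimization over the variance ratio, constrained to [0, 1].  The
    one-sided p-value against h2 = 0 uses the 50:50 chi2_0/chi2_1 boundary
    mixture of the likelihood-ratio statistic.
    """
    if isinstance(grm, tuple):
        lam, vecs = grm
    else:
        lam, vecs = grm_eigen(grm)
    y = np.asarray(y, float).ravel()
    n = y.size
    if n != lam.size:
        raise ValueError("y and GRM disagree on sample count")
    if n < 30:
        raise ValueError("need at least 30 samples for REML")
    y2 = (vecs.T @ y) ** 2

    hi = 1.0 - 1e-9
    res = optimize.minimize_scalar(
        lambda h: -_profile_loglik(h, lam, y2),
        bounds=(0.0, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    candidates = [(float(res.x), _profile_loglik(float(res.x), lam, y2))]
    for h in (0.0, hi):
        candidates.append((h, _profile_loglik(h, lam, y2)))
    h_hat, ll_hat = max(candidates, key=lambda c: c[1])
    ll0 = _profile_loglik(0.0, lam, y2)
    stat = max(0.0, 2.0 * (ll_hat - ll0))
    p = 1.0 if stat <= 0 else 0.5 * float(chi2.sf(stat, df=1))
    return HeritabilityEstimate(
        gene=gene,
        tissue=tissue,
        h2=min(h_hat, 1.0),
        p_value=p,
        converged=bool(res.success),
        loglik=ll_hat,
    )


def h2_significance_filter(
    estimates: pd.DataFrame, alpha: float = 0.10, tissue_col: str = "tissue"
) -> tuple[pd.DataFrame, float]:
    """Within-tissue Benjamini-Hochberg on heritability p-values.

    Returns the frame with a boolean ``passed_h2_filter`` column and the
    removed fraction.  (A stratified-FDR stand-in for covariate-weighted
    FDR with tissue as the covariate.)
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if "p_value" not in estimates.columns:
        raise ValueError("estimates must carry a p_value column")
    out = estimates.copy()
    out["passed_h2_filter"] = False
    for _, idx in out.groupby(tissue_col).groups.items():
        pvals = out.loc[idx, "p_value"].to_numpy()
        reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        out.loc[idx, "passed_h2_filter"] = reject
    removed = 1.0 - out["passed_h2_filter"].mean() if len(out) else 0.0
    return out, float(removed)


# ---------------------------------------------------------------------------
# standardized effects
# ---------------------------------------------------------------------------

@dataclass
class StandardizedEffect:
    gene: str
    tissue: str
    sex: str
    log2fc: float
    sd_pheno_units: float
    sd_geno_units: float | None
    passed_h2_filter: bool


def standardize_effects(
    log2fc: float,
    post_var: PosteriorVariance,
    h2: HeritabilityEstimate | None = None,
    passed_h2_filter: bool = False,
    tissue: str = "",
    sex: str = "",
) -> StandardizedEffect:
    """Express a log2FC in phenotypic-SD and (when filtered) genetic-SD units."""
    if post_var.post_mean_var <= 0:
        raise ValueError("posterior variance must be positive")
    sd_pheno = log2fc / np.sqrt(post_var.post_mean_var)
    sd_geno = None
    if passed_h2_filter:
        if h2 is None or h2.h2 <= 0:
            raise ValueError("filtered gene requires a positive heritability estimate")
        sd_geno = log2fc / np.sqrt(h2.h2 * post_var.post_mean_var)
    return StandardizedEffect(
        gene=post_var.gene,
        tissue=tissue,
        sex=sex,
        log2fc=float(log2fc),
        sd_pheno_units=float(sd_pheno),
        sd_geno_units=None if sd_geno is None else float(sd_geno),
        passed_h2_filter=bool(passed_h2_filter),
    )


def standardize_study(
    cohort: HumanCohort,
    de: DEStudy,
    alpha: float = 0.10,
    pooled: bool = False,
    prior_method: str = "cvm",
) -> pd.DataFrame:
    """Standardize all 8-week exercise effects against a human cohort.

    Per tissue: pseudolog-transform expression, residualize covariates,
    compute per-gene sample variances per sex stratum (or pooled with
    ``pooled=True``), shrink them through the stratum's inverse-gamma
    prior, estimate per-gene heritability by REML on the pooled residuals,
    apply the within-tissue BH filter at ``alpha``, and convert each
    8-week log2FC into SD units.

    Returns one row per gene x tissue x sex with columns log2fc,
    sd_pheno_units, sd_geno_units (NaN when unfiltered), h2, h2_p and
    passed_h2_filter.
    """
    last = de.timepoints[-1]
    res8 = de.results[de.results["timepoint"] == last]
    lfc = res8.pivot_table(
        index="gene", columns=["tissue", "sex"], values="log2fc", aggfunc="first"
    )

    frames = []
    for tissue in cohort.tissues:
        tc = cohort.per_tissue[tissue]
        logx = pseudolog(tc.expression)
        resid_all = residualize(logx, tc.covariates)

        # heritability on pooled residuals, one REML fit per gene
        lam, vecs = grm_eigen(tc.grm)
        proj2 = (vecs.T @ resid_all) ** 2
        h2_rows = []
        for gi, gene in enumerate(cohort.genes):
            hi = 1.0 - 1e-9
            y2 = proj2[:, gi]
            r = optimize.minimize_scalar(
                lambda h: -_profile_loglik(h, lam, y2),
                bounds=(0.0, hi),
                method="bounded",
                options={"xatol": 1e-8},
            )
            cand = [(float(r.x), _profile_loglik(float(r.x), lam, y2)),
                    (0.0, _profile_loglik(0.0, lam, y2))]
            h_hat, ll_hat = max(cand, key=lambda c: c[1])
            stat = max(0.0, 2.0 * (ll_hat - cand[1][1]))
            p = 1.0 if stat <= 0 else 0.5 * float(chi2.sf(stat, df=1))
            h2_rows.append((gene, tissue, h_hat, p))
        h2_df = pd.DataFrame(h2_rows, columns=["gene", "tissue", "h2", "p_value"])
        h2_df, _ = h2_significance_filter(h2_df, alpha=alpha)
        h2_map = h2_df.set_index("gene")

        strata = (
            {"pooled": np.ones(len(tc.sex), bool)}
            if pooled
            else {s: tc.sex == s for s in np.unique(tc.sex)}
        )
        for sex_label, mask in strata.items():
            resid = resid_all[mask]
            n_obs = int(mask.sum())
            s2 = np.mean(resid**2, axis=0)  # divisor n: sum(x^2)/n
            prior = fit_variance_prior(
                s2, method=prior_method, stratum=f"{tissue}:{sex_label}"
            )
            a_post = prior.shape + n_obs / 2.0
            b_post = prior.rate + n_obs * s2 / 2.0
            post_var = b_post / (a_post - 1.0)
            sexes_out = list(de.sexes) if pooled else [sex_label]
            for sex_out in sexes_out:
                if (tissue, sex_out) not in lfc.columns:
                    continue
                fc = lfc[(tissue, sex_out)].reindex(cohort.genes).to_numpy()
                h2v = h2_map["h2"].reindex(cohort.genes).to_numpy()
                h2p = h2_map["p_value"].reindex(cohort.genes).to_numpy()
                passed = h2_map["passed_h2_filter"].reindex(cohort.genes).to_numpy(bool)
                sd_pheno = fc / np.sqrt(post_var)
                with np.errstate(divide="ignore", invalid="ignore"):
                    sd_geno = np.where(
                        passed, fc / np.sqrt(h2v * post_var), np.nan
                    )
                frames.append(
                    pd.DataFrame(
                        {
                            "gene": cohort.genes,
                            "tissue": tissue,
                            "sex": sex_out,
                            "log2fc": fc,
                            "sd_pheno_units": sd_pheno,
                            "sd_geno_units": sd_geno,
                            "h2": h2v,
                            "h2_p": h2p,
                            "passed_h2_filter": passed,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)
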