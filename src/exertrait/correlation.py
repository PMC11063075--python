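"""Gene-wise tetrachoric correlation matrices and nearest-PSD repair.

The hierarchical enrichment model treats tissues, traits and tissue x
trait cells as units whose binomial counts aggregate over genes; because
the same genes underlie many units, unit-level effects are correlated.
Those correlations are estimated pairwise as tetrachoric correlations
(the maximum-likelihood latent bivariate-normal correlation of a 2x2
binary table, with thresholds fixed by the marginal frequencies), then the
pairwise-assembled matrix is projected to the nearest unit-diagonal
positive semi-definite correlation matrix by alternating projections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri

RHO_CLAMP = 0.999  # keeps downstream Cholesky factorizations stable


# ---------------------------------------------------------------------------
# bivariate-normal CDF (Drezner-Wesolowsky quadrature form)
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho.

    Computed as Phi(h)Phi(k) plus a Gauss-Legendre quadrature of the
    correlation integral; accurate to ~1e-10 for |rho| <= 0.999.
    """
    if abs(rho) < 1e-14:
        return float(ndtr(h) * ndtr(k))
    r = 0.5 * rho * (_GL_NODES + 1.0)  # nodes mapped to [0, rho]
    one_m = 1.0 - r * r
    integrand = np.exp(-(h * h - 2.0 * r * h * k + k * k) / (2.0 * one_m)) / np.sqrt(
        one_m
    )
    integral = 0.5 * rho * float(np.dot(_GL_WEIGHTS, integrand))
    return float(ndtr(h) * ndtr(k) + integral / (2.0 * np.pi))


# ---------------------------------------------------------------------------
# tetrachoric correlation
# ---------------------------------------------------------------------------

def tetrachoric(table) -> float:
    """ML tetrachoric correlation of a 2x2 table [[n11, n10], [n01, n00]].

    Rows index the first indicator (1 then 0), columns the second.  Zero
    cells receive a 0.5 continuity correction; a zero margin makes the
    correlation undefined and returns NaN.  The estimate is clamped to
    |rho| <= 0.999.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a 2x2 nonnegative count matrix")
    if t.sum() < 4:
        raise ValueError("need a total count of at least 4")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return np.nan  # zero margin: thresholds undefined
    if np.any(t == 0):
        t = t + 0.5
    n = t.sum()
    p_x = t[0].sum() / n  # P(first indicator = 1)
    p_y = t[:, 0].sum() / n
    tau_x = ndtri(1.0 - p_x)
    tau_y = ndtri(1.0 - p_y)

    def negloglik(rho: float) -> float:
        phi2 = bvn_cdf(tau_x, tau_y, rho)
        p00 = phi2
        p01 = ndtr(tau_x) - phi2
        p10 = ndtr(tau_y) - phi2
        p11 = 1.0 - ndtr(tau_x) - ndtr(tau_y) + phi2
        probs = np.array([[p11, p10], [p01, p00]])
        probs = np.clip(probs, 1e-300, None)
        return -float(np.sum(t * np.log(probs)))

    res = optimize.minimize_scalar(
        negloglik,
        bounds=(-RHO_CLAMP, RHO_CLAMP),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.clip(res.x, -RHO_CLAMP, RHO_CLAMP))


def _table_from_indicators(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n11 = int(np.sum(x & y))
    n10 = int(np.sum(x & ~y))
    n01 = int(np.sum(~x & y))
    n00 = int(np.sum(~x & ~y))
    return np.array([[n11, n10], [n01, n00]], float)


def pairwise_matrix(ind: pd.DataFrame) -> pd.DataFrame:
    """Raw unit x unit tetrachoric correlation matrix from binary indicators.

    ``ind`` is genes x units with entries in {0, 1}.  Undefined pairs
    (zero margins) are imputed as 0 with a warning; the diagonal is 1.
    """
    if ind.shape[1] < 2:
        raise ValueError("need at least 2 units")
    cols = list(ind.columns)
    x = ind.to_numpy().astype(bool)
    m = len(cols)
    mat = np.eye(m)
    n_missing = 0
    for i in range(m):
        for j in range(i + 1, m):
            r = tetrachoric(_table_from_indicators(x[:, i], x[:, j]))
            if np.isnan(r):
                n_missing += 1
                r = 0.0
            mat[i, j] = mat[j, i] = r
    if n_missing:
        warnings.warn(
            f"{n_missing} unit pairs had a zero margin; their correlations "
            "were imputed as 0",
            stacklevel=2,
        )
    return pd.DataFrame(mat, index=cols, columns=cols)


# ---------------------------------------------------------------------------
# nearest correlation matrix (alternating projections)
# ---------------------------------------------------------------------------

def nearest_psd(
    raw: np.ndarray | pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 1000,
    conv_tol: float = 1e-12,
):
    """Nearest unit-diagonal PSD correlation matrix by alternating projections.

    Alternates projection onto the PSD cone (eigenvalue clipping) and onto
    the unit-diagonal affine set, with a Dykstra correction so the iterates
    converge to the nearest correlation matrix in Frobenius norm.  An input
    that is already a PSD correlation matrix is a fixed point.
    """
    is_frame = isinstance(raw, pd.DataFrame)
    labels = raw.index if is_frame else None
    a = np.asarray(raw, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    y = a.copy()
    ds = np.zeros_like(a)
    for _ in range(max_iter):
        r = y - ds
        vals, vecs = np.linalg.eigh(r)
        x = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        x = 0.5 * (x + x.T)
        ds = x - r
        y_new = x.copy()
        np.fill_diagonal(y_new, 1.0)
        if np.linalg.norm(y_new - y, "fro") < conv_tol * max(
            1.0, np.linalg.norm(y, "fro")
        ):
            y = y_new
            break
        y = y_new
    vals = np.linalg.eigvalsh(y)
    if vals.min() < -tol:
        # final safeguard: one last clip + renormalization
        vals_c, vecs = np.linalg.eigh(y)
        y = (vecs * np.clip(vals_c, 0.0, None)) @ vecs.T
        d = np.sqrt(np.clip(np.diag(y), 1e-12, None))
        y = y / np.outer(d, d)
        np.fill_diagonal(y, 1.0)
    y = 0.5 * (y + y.T)
    if is_frame:
        return pd.DataFrame(y, index=labels, columns=labels)
    return y


# ---------------------------------------------------------------------------
# assembled correlation structure for the enrichment model
# ---------------------------------------------------------------------------

@dataclass
class CorrelationSet:
    """Unit-level correlation matrices: tissues, traits, tissue x trait cells."""

    sigma_tissue: pd.DataFrame
    sigma_trait: pd.DataFrame
    sigma_cell: pd.DataFrame


def correlation_set(
    ind_tissue: pd.DataFrame,
    ind_trait: pd.DataFrame,
    ind_cell: pd.DataFrame,
    tol: float = 1e-8,
) -> CorrelationSet:
    """Pairwise tetrachoric matrices for each indicator family, PSD-repaired.

    ``ind_tissue``: genes x tissues DEG membership; ``ind_trait``: genes x
    traits hit membership pooled over tissues; ``ind_cell``: genes x
    (tissue, trait) intersect membership -- each over the mutual gene
    universe.
    """
    return CorrelationSet(
        sigma_tissue=nearest_psd(pairwise_matrix(ind_tissue), tol=tol),
        sigma_trait=nearest_psd(pairwise_matrix(ind_trait), tol=tol),
        sigma_cell=nearest_psd(pairwise_matrix(ind_cell), tol=tol),
    )
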