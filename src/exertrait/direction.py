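"""Disease-like direction of exercise effects in DEG x TWAS-hit intersects.

For every gene in a tissue's DEG set that is also a TWAS hit for a trait,
the sign product sign(log2FC) * sign(TWAS effect) says whether exercise
pushes expression in the trait-increasing ("disease-like") or
trait-decreasing direction.  Per cell (tissue i, trait j) the count y of
positive products out of the intersect size n is compared against a null
frequency of one half via zero-centered logit-scale priors:

    y_ij ~ Binomial(n_ij, inv-logit(pi_ij))
    pi_ij ~ Normal(mu_j, sigma_j)                    sigma_j = rho * e^lambda_j
    mu ~ MVN(0, S R S^T)    diag(S) = delta * e^gamma_k(j)
    R = theta * G_SNP + (1 - theta) * I              theta ~ Beta(1, 1)

Direction signal cannot be pooled across traits (traits differ in whether
an increase is harmful), so pooling acts on scales only; cross-trait
dependence enters through the trait genetic-correlation matrix G_SNP,
mixed with the identity by the estimated weight theta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from exertrait.config import SamplerConfig
from exertrait.hmc import PosteriorDraws, make_posterior, sample_nuts
from exertrait.landscape import DegSetCollection
from exertrait.simulate import DEStudy, GSnpMatrix, TwasTable


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

@dataclass
class DirectionCounts:
    tissues: list[str]
    traits: list[str]
    categories: list[str]
    cat_index: np.ndarray
    y: np.ndarray  # tissues x traits: positive sign products
    n: np.ndarray  # tissues x traits: intersect sizes
    detail: pd.DataFrame  # gene, tissue, trait, de_sign, twas_sign, product
    meta: dict = field(default_factory=dict)


def build_direction_counts(
    degs: DegSetCollection, twas: TwasTable, hits: pd.DataFrame
) -> DirectionCounts:
    """Count positive DE x TWAS sign products over DEG-hit intersect genes.

    ``hits`` carries post-FDR hit flags and effect signs per (gene,
    tissue, trait).  Sign products are strictly +1/-1; a DEG member with
    no recorded direction raises an error naming the gene.
    """
    tissues, traits = twas.tissues, twas.traits
    cat_index = np.array(
        [twas.categories.index(twas.trait_category[t]) for t in traits]
    )
    y = np.zeros((len(tissues), len(traits)), dtype=int)
    n = np.zeros((len(tissues), len(traits)), dtype=int)
    rows = []
    hit_only = hits[hits["hit"]]
    for ti, tissue in enumerate(tissues):
        deg_genes = degs.sets[tissue]
        sub = hit_only[
            (hit_only["tissue"] == tissue) & hit_only["gene"].isin(deg_genes)
        ]
        for tj, trait in enumerate(traits):
            cell = sub[sub["trait"] == trait]
            for gene, twas_sign in zip(cell["gene"], cell["effect_sign"]):
                de_sign = degs.direction.get((tissue, gene))
                if de_sign is None or de_sign == 0:
                    raise ValueError(
                        f"gene {gene} in DEG set of {tissue} has no direction"
                    )
                if twas_sign == 0:
                    raise ValueError(f"gene {gene} has zero TWAS effect sign")
                product = int(de_sign) * int(twas_sign)
                rows.append((gene, tissue, trait, int(de_sign), int(twas_sign), product))
                n[ti, tj] += 1
                if product > 0:
                    y[ti, tj] += 1
    detail = pd.DataFrame(
        rows, columns=["gene", "tissue", "trait", "de_sign", "twas_sign", "product"]
    )
    return DirectionCounts(
        tissues=list(tissues),
        traits=list(traits),
        categories=list(twas.categories),
        cat_index=cat_index,
        y=y,
        n=n,
        detail=detail,
    )


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _chol_derivative(L: np.ndarray, dR: np.ndarray) -> np.ndarray:
    """Derivative of the Cholesky factor: dL = L * Phi(L^-1 dR L^-T).

    Phi takes the lower triangle with the diagonal halved (forward-mode
    differentiation of the Cholesky decomposition).
    """
    inner = np.linalg.solve(L, np.linalg.solve(L, dR.T).T)
    phi = np.tril(inner)
    np.fill_diagonal(phi, 0.5 * np.diag(inner))
    return L @ phi


class DirectionModel:
    """Direction model over the unconstrained vector
    [pi(IJ), z_mu(J), z_lam(J), z_gam(K), logit_theta, log_rho,
     log_delta, log_sig_gamma, log_sig_lambda].

    The multivariate-normal trait level is non-centered (mu = S L(R) z);
    the univariate cell level is centered, which conditions better because
    the binomial counts inform each cell proportion directly.
    """

    def __init__(self, counts: DirectionCounts, gsnp: GSnpMatrix):
        self.I = len(counts.tissues)
        self.J = len(counts.traits)
        self.K = len(counts.categories)
        self.kidx = counts.cat_index
        self.y = counts.y.astype(float).ravel()
        self.n = counts.n.astype(float).ravel()
        g = np.asarray(gsnp.matrix, float)
        if g.shape != (self.J, self.J):
            raise ValueError("G_SNP dimension does not match trait count")
        if not np.allclose(g, g.T, atol=1e-8) or not np.allclose(np.diag(g), 1.0):
            raise ValueError("G_SNP must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(g).min() < -1e-8:
            raise ValueError("G_SNP must be PSD (repair it with nearest_psd first)")
        self.G = g
        self.dR = g - np.eye(self.J)  # dR/dtheta
        self.cell_j = np.tile(np.arange(self.J), self.I)
        cells = self.I * self.J
        self.slices = {}
        off = 0
        for name, size in [
            ("pi", cells),
            ("z_mu", self.J),
            ("z_lam", self.J),
            ("z_gam", self.K),
            ("logit_theta", 1),
            ("log_rho", 1),
            ("log_delta", 1),
            ("log_sig_gamma", 1),
            ("log_sig_lambda", 1),
        ]:
            self.slices[name] = slice(off, off + size)
            off += size
        self.ndim = off

    def _forward(self, q: np.ndarray):
        s = self.slices
        pi = q[s["pi"]]
        z_mu = q[s["z_mu"]]
        z_lam = q[s["z_lam"]]
        z_gam = q[s["z_gam"]]
        lt = q[s["logit_theta"]][0]
        theta = expit(lt)
        rho = np.exp(q[s["log_rho"]][0])
        delta = np.exp(q[s["log_delta"]][0])
        sig_gamma = np.exp(q[s["log_sig_gamma"]][0])
        sig_lambda = np.exp(q[s["log_sig_lambda"]][0])
        gamma_k = sig_gamma * z_gam
        lambda_j = sig_lambda * z_lam
        S = delta * np.exp(gamma_k[self.kidx])  # per-trait scale
        R = theta * self.G + (1.0 - theta) * np.eye(self.J)
        L = np.linalg.cholesky(R + 1e-10 * np.eye(self.J))
        Lz = L @ z_mu
        mu = S * Lz
        sigma_j = rho * np.exp(lambda_j)
        return dict(
            pi=pi, z_mu=z_mu, z_lam=z_lam, z_gam=z_gam, lt=lt, theta=theta,
            rho=rho, delta=delta, sig_gamma=sig_gamma, sig_lambda=sig_lambda,
            gamma_k=gamma_k, lambda_j=lambda_j, S=S, L=L, Lz=Lz, mu=mu,
            sigma_j=sigma_j,
        )

    def logp_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        f = self._forward(q)
        x = f["pi"]
        ll = float(np.sum(self.y * x - self.n * np.logaddexp(0.0, x)))
        g_pi_lik = self.y - self.n * expit(x)

        theta, rho, delta = f["theta"], f["rho"], f["delta"]
        sg, sl = f["sig_gamma"], f["sig_lambda"]
        mu_cells = f["mu"][self.cell_j]
        sigma_cells = f["sigma_j"][self.cell_j]
        resid = (x - mu_cells) / sigma_cells**2
        logp = ll
        logp += float(
            np.sum(-0.5 * (x - mu_cells) ** 2 / sigma_cells**2 - np.log(sigma_cells))
        )
        for name in ("z_mu", "z_lam", "z_gam"):
            logp += -0.5 * float(np.sum(f[name] ** 2))
        # flat Beta(1,1) on theta: only the logit Jacobian survives
        logp += np.log(theta) + np.log1p(-theta)
        # half-normal(0, 2) on rho and delta, half-normal(0, 1) on the
        # hyper-scales; log-transform Jacobians included
        logp += -(rho**2) / 8.0 + np.log(rho)
        logp += -(delta**2) / 8.0 + np.log(delta)
        logp += -0.5 * sg**2 + np.log(sg)
        logp += -0.5 * sl**2 + np.log(sl)

        g = np.zeros(self.ndim)
        s = self.slices
        g[s["pi"]] = g_pi_lik - resid
        g_mu = np.bincount(self.cell_j, weights=resid, minlength=self.J)
        g_sigma_j = np.bincount(
            self.cell_j,
            weights=(x - mu_cells) ** 2 / sigma_cells**3 - 1.0 / sigma_cells,
            minlength=self.J,
        )
        # sigma_j = rho * exp(lambda_j)
        g_lambda = f["sigma_j"] * g_sigma_j
        g[s["z_lam"]] = sl * g_lambda - f["z_lam"]
        g[s["log_rho"]] = float(np.sum(g_lambda)) - rho**2 / 4.0 + 1.0
        g[s["log_sig_lambda"]] = (
            float(np.dot(f["lambda_j"], g_lambda)) - sl**2 + 1.0
        )
        # mu = S * (L z_mu)
        g_S = f["Lz"] * g_mu
        g_Lz = f["S"] * g_mu
        g[s["z_mu"]] = f["L"].T @ g_Lz - f["z_mu"]
        # S_j = delta * exp(gamma_k): dS/dgamma_k = S, dS/dlog_delta = S
        g_gamma_k = np.bincount(self.kidx, weights=f["S"] * g_S, minlength=self.K)
        g[s["z_gam"]] = sg * g_gamma_k - f["z_gam"]
        g[s["log_delta"]] = float(np.dot(f["S"], g_S)) - delta**2 / 4.0 + 1.0
        g[s["log_sig_gamma"]] = (
            float(np.dot(f["gamma_k"], g_gamma_k)) - sg**2 + 1.0
        )
        # theta through the Cholesky factor of R(theta)
        dL = _chol_derivative(f["L"], self.dR)
        g_theta = float(np.dot(g_Lz, dL @ f["z_mu"]))
        g[s["logit_theta"]] = g_theta * theta * (1.0 - theta) + (1.0 - 2.0 * theta)
        return logp, g

    def unpack(self, q: np.ndarray) -> dict[str, np.ndarray]:
        f = self._forward(q)
        return {
            "pi": f["pi"].reshape(self.I, self.J),
            "mu_trait": f["mu"],
            "sigma_trait": f["sigma_j"],
            "scale_trait": f["S"],
            "gamma_category": f["gamma_k"],
            "lambda_trait": f["lambda_j"],
            "theta": np.array(f["theta"]),
            "rho": np.array(f["rho"]),
            "delta": np.array(f["delta"]),
            "sigma_gamma": np.array(f["sig_gamma"]),
            "sigma_lambda": np.array(f["sig_lambda"]),
        }


def fit_direction_model(
    counts: DirectionCounts,
    gsnp: GSnpMatrix,
    mcmc: SamplerConfig | None = None,
) -> PosteriorDraws:
    """Sample the direction-model posterior (cells with n = 0 contribute a
    constant likelihood and are retained so the grid stays rectangular)."""
    mcmc = mcmc or SamplerConfig()
    model = DirectionModel(counts, gsnp)
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
        "model": "direction_of_effect",
        "tissues": counts.tissues,
        "traits": counts.traits,
        "categories": counts.categories,
        "step_size": raw.step_size.tolist(),
    }
    return make_posterior(raw, model.unpack, notes=notes)


def summarize_direction(
    draws: PosteriorDraws,
    confident_rule: float = 0.90,
    strong_rule: float = 0.95,
    require_diagnostics: bool = True,
) -> pd.DataFrame:
    """Per-trait and per-cell direction summaries with 90%/95% mass flags."""
    if require_diagnostics and not draws.passed:
        raise RuntimeError(
            "fit failed MCMC diagnostics; pass require_diagnostics=False to "
            "summarize anyway"
        )
    notes = draws.notes
    tissues = notes.get("tissues", [])
    traits = notes.get("traits", [])
    mu = draws.stacked("mu_trait")
    pi = draws.stacked("pi").reshape(mu.shape[0], -1)
    theta = draws.stacked("theta").reshape(-1)

    def _summ(values, labels, level):
        mean = values.mean(axis=0)
        lo, hi = np.quantile(values, [0.05, 0.95], axis=0)
        p_pos = (values > 0).mean(axis=0)
        one_sided = np.maximum(p_pos, 1 - p_pos)
        return pd.DataFrame(
            {
                "level": level,
                "unit": labels,
                "post_mean": mean,
                "ci5": lo,
                "ci95": hi,
                "p_positive": p_pos,
                "confident": one_sided > confident_rule,
                "strong": one_sided > strong_rule,
            }
        )

    cell_labels = [f"{t}|{tr}" for t in tissues for tr in traits]
    out = pd.concat(
        [_summ(mu, traits, "trait"), _summ(pi, cell_labels, "cell")],
        ignore_index=True,
    )
    theta_row = pd.DataFrame(
        {
            "level": "theta",
            "unit": ["theta"],
            "post_mean": [float(theta.mean())],
            "ci5": [float(np.quantile(theta, 0.05))],
            "ci95": [float(np.quantile(theta, 0.95))],
            "p_positive": [float((theta > 0.5).mean())],  # mass above 1/2
            "confident": [bool((theta > 0.5).mean() > confident_rule)],
            "strong": [bool((theta > 0.5).mean() > strong_rule)],
        }
    )
    return pd.concat([out, theta_row], ignore_index=True)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def trace_trajectory(
    de: DEStudy, detail: pd.DataFrame, trait: str
) -> pd.DataFrame:
    """Trace a trait's 8-week intersect gene set backwards in time.

    For each tissue with a nonempty 8-week intersect for ``trait`` (and a
    pooled ALL line), the proportion of positive effects is computed at
    every timepoint: genes with a sex-consistent DE state contribute 1
    (positive product) or 0, genes without a DE state contribute 0.5.
    """
    sub = detail[detail["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} has an empty intersect everywhere")
    st = de.states.copy()
    st["has_state"] = (st["state_F"] == st["state_M"]) & (st["state_F"] != 0)
    st = st.set_index(["gene", "tissue", "timepoint"])

    rows = []
    groups = [(t, sub[sub["tissue"] == t]) for t in de.tissues] + [("ALL", sub)]
    for tissue, grp in groups:
        if grp.empty:
            if tissue != "ALL":
                warnings.warn(
                    f"tissue {tissue} has an empty 8-week set for {trait}; omitted",
                    stacklevel=2,
                )
            continue
        for tp in de.timepoints:
            positives = 0.0
            for gene, gene_tissue, twas_sign in zip(
                grp["gene"], grp["tissue"], grp["twas_sign"]
            ):
                rec = st.loc[(gene, gene_tissue, tp)]
                if bool(rec["has_state"]):
                    positives += 1.0 if int(rec["state_F"]) * int(twas_sign) > 0 else 0.0
                else:
                    positives += 0.5
            rows.append((tissue, tp, len(grp), positives / len(grp)))
    return pd.DataFrame(rows, columns=["tissue", "timepoint", "n", "proportion"])
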