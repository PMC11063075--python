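"""Synthetic-data generation with recorded ground truth.

Every generator is a pure function of a :class:`~exertrait.config.SimConfig`
(plus upstream artifacts where stated); identical configs produce
byte-identical outputs.  Planted truth is recorded alongside each artifact
so downstream recovery tests read truth from generator records only.

The statistical structure emulated:

* ``generate_de_study`` -- per gene x tissue x sex x timepoint log2
  fold-changes and p-values with sex-consistent differential-expression
  (DE) states at the adapted 8-week timepoint.  Null genes carry
  Uniform(0,1) p-values; planted genes carry p-values from a noncentral-z
  alternative with sign-matched fold-changes.
* ``generate_human_cohort`` -- per-tissue expression matrices on a
  nonnegative counts-like scale whose log2 signal decomposes into a
  genetic value (variance h2 * var, structured by a genetic relatedness
  matrix), covariate effects, and residual noise (variance (1-h2) * var).
* ``generate_twas`` -- per gene x tissue x trait association z-scores with
  a planted logit-additive enrichment of hits inside DEG sets, gene-wise
  latent correlation across units, and direction structure mixed across
  traits through a trait genetic-correlation matrix.
* ``generate_evidence`` / ``generate_gsnp`` -- gene x trait evidence
  scores and the trait genetic-correlation matrix itself.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr
from scipy.stats import invgamma

from exertrait.config import ConfigError, SimConfig


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DEStudy:
    """Differential-expression study output plus planted truth.

    ``results`` has one row per gene x tissue x sex x timepoint with columns
    ``log2fc`` and ``p_value``; ``states`` one row per gene x tissue x
    timepoint with integer columns ``state_F``/``state_M`` in {-1, 0, 1}.
    ``expressed`` maps each tissue to the boolean expressed-gene mask over
    the common gene universe.
    """

    genes: list[str]
    tissues: list[str]
    timepoints: list[str]
    sexes: list[str]
    results: pd.DataFrame
    states: pd.DataFrame
    expressed: dict[str, np.ndarray]
    truth: pd.DataFrame  # gene, tissue, de_true, sign_true, onset

    def expressed_genes(self, tissue: str) -> list[str]:
        mask = self.expressed[tissue]
        return [g for g, m in zip(self.genes, mask) if m]


@dataclass
class TissueCohort:
    expression: np.ndarray  # samples x genes, counts-like scale
    covariates: np.ndarray  # samples x q
    sex: np.ndarray  # per-sample 'F'/'M'
    grm: np.ndarray  # samples x samples
    h2_true: np.ndarray  # per gene
    var_true: np.ndarray  # per gene, log2-scale total variance
    genetic_component: np.ndarray  # samples x genes (log2 scale)
    residual_component: np.ndarray  # samples x genes (log2 scale)
    grm_identity_warning: bool = False


@dataclass
class HumanCohort:
    genes: list[str]
    tissues: list[str]
    per_tissue: dict[str, TissueCohort]


@dataclass
class TwasTable:
    """Per gene x tissue x trait association results plus planted truth."""

    genes: list[str]
    tissues: list[str]
    traits: list[str]
    categories: list[str]
    trait_category: dict[str, str]
    table: pd.DataFrame  # gene,tissue,trait,zscore,p_value,effect_sign
    truth: pd.DataFrame  # gene,tissue,trait,hit_true,sign_true
    direction_means_true: np.ndarray  # per trait, logit scale


@dataclass
class EvidenceTable:
    table: pd.DataFrame  # gene, trait, score


@dataclass
class GSnpMatrix:
    traits: list[str]
    matrix: np.ndarray


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _two_sided_p(z: np.ndarray) -> np.ndarray:
    """Two-sided standard-normal p-value of z, kept inside (0, 1]."""
    p = 2.0 * ndtr(-np.abs(z))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def generate_de_study(config: SimConfig) -> DEStudy:
    """Simulate a multi-tissue differential-expression study.

    For each tissue a ``de_fraction`` of expressed genes is planted as DE
    with a random sign and a random onset timepoint; from onset onwards the
    gene carries sex-consistent states (s, s) and noncentral-z statistics
    whose sign matches the planted fold-change direction.  All other
    (gene, timepoint) combinations are null: z ~ N(0,1), hence p ~ U(0,1).
    """
    config.validate()
    rng = config.rng("de_study")
    genes = config.gene_labels
    tissues = config.tissue_labels
    tps = list(config.timepoints)
    n_g, n_t, n_tp = config.n_genes, config.n_tissues, len(tps)

    expressed = {
        t: rng.random(n_g) < config.expressed_fraction for t in tissues
    }

    res_rows = []
    state_rows = []
    truth_rows = []
    onset_p = np.asarray(config.onset_probs, float)
    onset_p = onset_p / onset_p.sum()
    for ti, tissue in enumerate(tissues):
        expr_mask = expressed[tissue]
        de_mask = expr_mask & (rng.random(n_g) < config.de_fraction)
        sign = np.where(rng.random(n_g) < config.de_up_fraction, 1, -1)
        onset = rng.choice(n_tp, size=n_g, p=onset_p)
        for gi in range(n_g):
            truth_rows.append(
                (genes[gi], tissue, bool(de_mask[gi]),
                 int(sign[gi]) if de_mask[gi] else 0,
                 tps[onset[gi]] if de_mask[gi] else "")
            )
        # active[g, tp] = planted DE and timepoint at/after onset
        active = de_mask[:, None] & (np.arange(n_tp)[None, :] >= onset[:, None])
        for sex in config.sexes:
            z = rng.standard_normal((n_g, n_tp))
            z_alt = sign[:, None] * np.abs(
                rng.normal(config.de_noncentrality, 1.0, size=(n_g, n_tp))
            )
            z = np.where(active, z_alt, z)
            lfc = np.where(active, z * 0.25, z * 0.1)
            p = _two_sided_p(z)
            for tpi, tp in enumerate(tps):
                res_rows.append(
                    pd.DataFrame(
                        {
                            "gene": genes,
                            "tissue": tissue,
                            "sex": sex,
                            "timepoint": tp,
                            "log2fc": lfc[:, tpi],
                            "p_value": p[:, tpi],
                        }
                    )
                )
        st = np.where(active, sign[:, None], 0)
        for tpi, tp in enumerate(tps):
            state_rows.append(
                pd.DataFrame(
                    {
                        "gene": genes,
                        "tissue": tissue,
                        "timepoint": tp,
                        "state_F": st[:, tpi],
                        "state_M": st[:, tpi],
                    }
                )
            )

    results = pd.concat(res_rows, ignore_index=True)
    states = pd.concat(state_rows, ignore_index=True)
    truth = pd.DataFrame(
        truth_rows, columns=["gene", "tissue", "de_true", "sign_true", "onset"]
    )
    return DEStudy(
        genes=genes,
        tissues=tissues,
        timepoints=tps,
        sexes=list(config.sexes),
        results=results,
        states=states,
        expressed=expressed,
        truth=truth,
    )


def _simulate_grm(n: int, n_snps: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """GRM from standardized simulated dosages: Z Z^T / m (PSD, diag ~ 1)."""
    freqs = rng.uniform(0.05, 0.95, size=n_snps)
    dosages = rng.binomial(2, freqs, size=(n, n_snps)).astype(float)
    z = (dosages - 2 * freqs) / np.sqrt(2 * freqs * (1 - freqs))
    grm = z @ z.T / n_snps
    return grm, z


def generate_human_cohort(config: SimConfig) -> HumanCohort:
    """Simulate per-tissue human expression with planted heritability.

    On the log2 scale each gene's signal is mean + C beta + g + e with
    Cov(g) = h2 * var * GRM and Var(e) = (1 - h2) * var; the counts-like
    matrix is 2**signal - 1 clamped at 0, which the analysis-side pseudolog
    (log2(x + 1)) inverts exactly for nonnegative signal.
    """
    config.validate()
    rng = config.rng("human_cohort")
    n = config.n_samples_human
    q = config.n_covariates
    if n < q + 2:
        raise ConfigError("n_samples_human too small for residualization")
    genes = config.gene_labels
    per_tissue: dict[str, TissueCohort] = {}
    for tissue in config.tissue_labels:
        grm, z_dosage = _simulate_grm(n, config.n_snps, rng)
        identity_like = np.allclose(grm, np.eye(n), atol=1e-12)
        if identity_like:
            warnings.warn(
                f"GRM for tissue {tissue} is the identity: genetic and "
                "residual components are confounded",
                stacklevel=2,
            )
        h2 = config.h2_distribution.draw(config.n_genes, rng)
        var = invgamma.rvs(
            config.var_prior_shape,
            scale=config.var_prior_rate,
            size=config.n_genes,
            random_state=rng,
        )
        base = rng.uniform(2.0, 8.0, size=config.n_genes)
        covariates = rng.standard_normal((n, q))
        beta = rng.normal(0.0, 0.3, size=(q, config.n_genes))
        sex = np.where(rng.random(n) < 0.5, "F", "M")

        if config.grm_mode == "snp":
            effects = rng.standard_normal((config.n_snps, config.n_genes))
            raw = z_dosage @ effects
            raw_sd = raw.std(axis=0, ddof=0)
            raw_sd[raw_sd == 0] = 1.0
            genetic = raw / raw_sd * np.sqrt(h2 * var)
        else:
            # draw genetic values directly from MVN(0, h2 * var * GRM)
            jitter = 1e-8 * np.eye(n)
            chol = np.linalg.cholesky(grm + jitter)
            genetic = (chol @ rng.standard_normal((n, config.n_genes))) * np.sqrt(h2 * var)
        residual = rng.standard_normal((n, config.n_genes)) * np.sqrt((1 - h2) * var)
        signal = base[None, :] + covariates @ beta + genetic + residual
        expression = np.clip(np.exp2(signal) - 1.0, 0.0, None)
        per_tissue[tissue] = TissueCohort(
            expression=expression,
            covariates=covariates,
            sex=sex,
            grm=grm,
            h2_true=h2,
            var_true=var,
            genetic_component=genetic,
            residual_component=residual,
            grm_identity_warning=identity_like,
        )
    return HumanCohort(genes=genes, tissues=config.tissue_labels, per_tissue=per_tissue)


def _de_8w_sex_consistent(de: DEStudy) -> pd.DataFrame:
    """Per (gene, tissue): sex-consistent DE indicator and sign at 8 weeks."""
    last = de.timepoints[-1]
    st = de.states[de.states["timepoint"] == last]
    consistent = (st["state_F"] == st["state_M"]) & (st["state_F"] != 0)
    out = st[["gene", "tissue"]].copy()
    out["deg"] = consistent.to_numpy()
    out["sign"] = np.where(consistent, st["state_F"], 0)
    return out


def generate_twas(config: SimConfig, de: DEStudy) -> TwasTable:
    """Simulate TWAS-style association tables with planted enrichment.

    Hit probability is inverse-logit(base + deviation * 1[DEG]) where the
    deviation is the planted alpha + beta_i + gamma_j + epsilon_ij grid;
    hit indicators share a gene-wise latent Gaussian (Gaussian copula) so
    units are correlated within genes.  Signs of hits in the DEG intersect
    follow per-trait direction means drawn (unless supplied) from a
    multivariate normal with correlation theta_true * G_SNP +
    (1 - theta_true) * I.
    """
    config.validate()
    if list(de.genes) != config.gene_labels:
        raise ConfigError("DE study was generated under a different gene universe")
    rng = config.rng("twas")
    tissues = config.tissue_labels
    traits = config.trait_labels
    cats = config.category_labels
    cat_idx = config.trait_category_index()
    trait_category = {t: cats[cat_idx[j]] for j, t in enumerate(traits)}

    alpha, beta, gamma, eps = config.planted_effects.resolve(
        config.n_tissues, config.n_traits
    )
    gsnp = generate_gsnp(config)
    if config.planted_direction_means is None:
        r_mix = config.theta_true * gsnp.matrix + (1 - config.theta_true) * np.eye(
            config.n_traits
        )
        chol = np.linalg.cholesky(r_mix + 1e-10 * np.eye(config.n_traits))
        mu_dir = config.direction_scale * (chol @ rng.standard_normal(config.n_traits))
    else:
        mu_dir = np.asarray(config.planted_direction_means, float)
        if mu_dir.shape != (config.n_traits,):
            raise ConfigError("planted_direction_means must have one entry per trait")

    deg = _de_8w_sex_consistent(de)
    deg_flag = {
        t: deg[deg["tissue"] == t].set_index("gene")["deg"] for t in tissues
    }
    deg_sign = {
        t: deg[deg["tissue"] == t].set_index("gene")["sign"] for t in tissues
    }

    rho = config.twas_latent_rho
    u_gene = rng.standard_normal(config.n_genes)

    rows = []
    truth_rows = []
    gene_arr = np.asarray(de.genes)
    for ti, tissue in enumerate(tissues):
        expr_mask = de.expressed[tissue]
        g_idx = np.flatnonzero(expr_mask)
        g_names = gene_arr[g_idx]
        is_deg = deg_flag[tissue].reindex(g_names).to_numpy(dtype=bool)
        de_sign = deg_sign[tissue].reindex(g_names).to_numpy(dtype=float)
        for tj, trait in enumerate(traits):
            dev = alpha + beta[ti] + gamma[tj] + eps[ti, tj]
            logit_p = config.twas_base_logit + dev * is_deg
            p_hit = expit(logit_p)
            latent = np.sqrt(rho) * u_gene[g_idx] + np.sqrt(1 - rho) * rng.standard_normal(
                len(g_idx)
            )
            hit = ndtr(latent) < p_hit
            n_here = len(g_idx)
            z = rng.standard_normal(n_here)
            z_mag = np.abs(rng.normal(config.twas_signal, 1.0, size=n_here))
            # sign structure: DEG-intersect hits follow the planted per-trait
            # direction mean; other hits are symmetric coin flips
            prob_pos = expit(mu_dir[tj])
            prod_sign = np.where(rng.random(n_here) < prob_pos, 1.0, -1.0)
            coin = np.where(rng.random(n_here) < 0.5, 1.0, -1.0)
            hit_sign = np.where(is_deg, de_sign * prod_sign, coin)
            z = np.where(hit, hit_sign * z_mag, z)
            z = np.where(z == 0.0, 1e-12, z)
            p = _two_sided_p(z)
            rows.append(
                pd.DataFrame(
                    {
                        "gene": g_names,
                        "tissue": tissue,
                        "trait": trait,
                        "zscore": z,
                        "p_value": p,
                        "effect_sign": np.sign(z).astype(int),
                    }
                )
            )
            truth_rows.append(
                pd.DataFrame(
                    {
                        "gene": g_names,
                        "tissue": tissue,
                        "trait": trait,
                        "hit_true": hit,
                        "sign_true": np.where(hit, hit_sign, 0).astype(int),
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return TwasTable(
        genes=list(de.genes),
        tissues=tissues,
        traits=traits,
        categories=cats,
        trait_category=trait_category,
        table=table,
        truth=truth,
        direction_means_true=mu_dir,
    )


def generate_evidence(config: SimConfig) -> EvidenceTable:
    """Gene x trait evidence-score table drawn from the configured law."""
    config.validate()
    rng = config.rng("evidence")
    genes = np.repeat(config.gene_labels, config.n_traits)
    traits = np.tile(config.trait_labels, config.n_genes)
    scores = config.evidence_score_law.draw(len(genes), rng)
    return EvidenceTable(
        table=pd.DataFrame({"gene": genes, "trait": traits, "score": scores})
    )


def generate_gsnp(config: SimConfig) -> GSnpMatrix:
    """Trait genetic-correlation matrix (unit diagonal, PSD).

    Default: a low-rank factor model normalized to a correlation matrix
    (PSD by construction).  With ``gsnp_block_r`` set, traits of the same
    category form exchangeable blocks with that within-block correlation.
    """
    config.validate()
    rng = config.rng("gsnp")
    j = config.n_traits
    if j == 1:
        return GSnpMatrix(traits=config.trait_labels, matrix=np.ones((1, 1)))
    if config.gsnp_block_r is not None:
        cat = config.trait_category_index()
        mat = np.where(cat[:, None] == cat[None, :], config.gsnp_block_r, 0.0)
        np.fill_diagonal(mat, 1.0)
    else:
        loadings = rng.normal(0.0, 0.6, size=(j, 3))
        cov = loadings @ loadings.T + np.diag(rng.uniform(0.3, 1.0, size=j))
        d = np.sqrt(np.diag(cov))
        mat = cov / np.outer(d, d)
        np.fill_diagonal(mat, 1.0)
    return GSnpMatrix(traits=config.trait_labels, matrix=mat)


# ---------------------------------------------------------------------------
# plain-tabular writers / readers
# ---------------------------------------------------------------------------

def write_study(
    outdir,
    config: SimConfig,
    de: DEStudy,
    twas: TwasTable | None = None,
    evidence: EvidenceTable | None = None,
    gsnp: GSnpMatrix | None = None,
    cohort: HumanCohort | None = None,
) -> dict:
    """Write all study tables as TSV plus a manifest JSON; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "files": {}, "truth_files": {}}

    def _save(df: pd.DataFrame, name: str, truth: bool = False) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        (manifest["truth_files"] if truth else manifest["files"])[name] = str(path)

    config.to_yaml(outdir / "config.yaml")
    manifest["files"]["config.yaml"] = str(outdir / "config.yaml")
    _save(de.results, "de_results.tsv")
    _save(de.states, "de_states.tsv")
    expressed = pd.DataFrame(
        {t: m.astype(int) for t, m in de.expressed.items()}, index=de.genes
    )
    expressed.index.name = "gene"
    expressed.reset_index().to_csv(outdir / "expressed.tsv", sep="\t", index=False)
    manifest["files"]["expressed.tsv"] = str(outdir / "expressed.tsv")
    _save(de.truth, "de_truth.tsv", truth=True)
    if twas is not None:
        _save(twas.table, "twas.tsv")
        _save(twas.truth, "twas_truth.tsv", truth=True)
        pd.DataFrame(
            {
                "trait": twas.traits,
                "category": [twas.trait_category[t] for t in twas.traits],
                "direction_mean_true": twas.direction_means_true,
            }
        ).to_csv(outdir / "trait_truth.tsv", sep="\t", index=False)
        manifest["truth_files"]["trait_truth.tsv"] = str(outdir / "trait_truth.tsv")
    if evidence is not None:
        _save(evidence.table, "evidence.tsv")
    if gsnp is not None:
        gdf = pd.DataFrame(gsnp.matrix, index=gsnp.traits, columns=gsnp.traits)
        gdf.index.name = "trait"
        gdf.reset_index().to_csv(outdir / "gsnp.tsv", sep="\t", index=False)
        manifest["files"]["gsnp.tsv"] = str(outdir / "gsnp.tsv")
    if cohort is not None:
        for tissue, tc in cohort.per_tissue.items():
            tdir = outdir / f"cohort_{tissue}"
            tdir.mkdir(exist_ok=True)
            pd.DataFrame(tc.expression, columns=cohort.genes).to_csv(
                tdir / "expression.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                tc.covariates, columns=[f"cov{i + 1}" for i in range(tc.covariates.shape[1])]
            ).assign(sex=tc.sex).to_csv(tdir / "covariates.tsv", sep="\t", index=False)
            pd.DataFrame(tc.grm).to_csv(tdir / "grm.tsv", sep="\t", index=False)
            pd.DataFrame(
                {"gene": cohort.genes, "h2_true": tc.h2_true, "var_true": tc.var_true}
            ).to_csv(tdir / "cohort_truth.tsv", sep="\t", index=False)
            manifest["files"][f"cohort_{tissue}"] = str(tdir)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
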