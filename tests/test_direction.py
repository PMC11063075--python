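"""Direction-of-effect counts, model and trajectory tracing."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import kstest

import exertrait
from exertrait.config import SamplerConfig, SimConfig
from exertrait.direction import (
    DirectionCounts,
    DirectionModel,
    build_direction_counts,
    fit_direction_model,
    summarize_direction,
    trace_trajectory,
)
from exertrait.hmc import PosteriorDraws
from exertrait.landscape import DegSetCollection
from exertrait.simulate import GSnpMatrix


class _ToyTwas:
    tissues = ["A"]
    traits = ["t1"]
    categories = ["C1"]
    trait_category = {"t1": "C1"}


def _toy_hits(records):
    # records: (gene, twas_sign)
    return pd.DataFrame(
        [(g, "A", "t1", True, s) for g, s in records],
        columns=["gene", "tissue", "trait", "hit", "effect_sign"],
    )


def _toy_degs(directions):
    return DegSetCollection(
        tissues=["A"],
        sets={"A": set(directions)},
        direction={("A", g): s for g, s in directions.items()},
        universe=set(directions),
    )


class TestCounts:
    def test_four_gene_enumeration(self):
        degs = _toy_degs({"g1": 1, "g2": 1, "g3": -1, "g4": -1})
        hits = _toy_hits([("g1", 1), ("g2", -1), ("g3", -1), ("g4", 1)])
        c = build_direction_counts(degs, _ToyTwas(), hits)
        assert c.n[0, 0] == 4 and c.y[0, 0] == 2

    def test_all_concordant(self):
        degs = _toy_degs({"g1": 1, "g2": 1})
        hits = _toy_hits([("g1", 1), ("g2", 1)])
        c = build_direction_counts(degs, _ToyTwas(), hits)
        assert c.y[0, 0] == c.n[0, 0] == 2

    def test_missing_direction_names_gene(self):
        degs = _toy_degs({"g1": 1})
        degs.direction = {}
        with pytest.raises(ValueError, match="g1"):
            build_direction_counts(degs, _ToyTwas(), _toy_hits([("g1", 1)]))

    def test_independent_coins_concentrate_at_half(self):
        rng = np.random.default_rng(30)
        genes = [f"g{i}" for i in range(1000)]
        de_signs = rng.choice([-1, 1], 1000)
        tw_signs = rng.choice([-1, 1], 1000)
        degs = _toy_degs(dict(zip(genes, de_signs)))
        hits = _toy_hits(list(zip(genes, tw_signs)))
        c = build_direction_counts(degs, _ToyTwas(), hits)
        assert abs(c.y[0, 0] / c.n[0, 0] - 0.5) < 0.05


def _direct_counts(y, n, cat, detail=None):
    i_n, j_n = np.asarray(y).shape
    return DirectionCounts(
        tissues=[f"T{i}" for i in range(i_n)],
        traits=[f"tr{j}" for j in range(j_n)],
        categories=[f"C{k}" for k in range(cat.max() + 1)],
        cat_index=cat,
        y=np.asarray(y),
        n=np.asarray(n),
        detail=detail if detail is not None else pd.DataFrame(),
    )


class TestModel:
    def test_gradient_matches_finite_differences(self, rng):
        cat = np.arange(5) % 2
        g = GSnpMatrix(
            traits=[f"tr{j}" for j in range(5)],
            matrix=0.5 * np.ones((5, 5)) + 0.5 * np.eye(5),
        )
        c = _direct_counts(
            rng.binomial(50, 0.5, (3, 5)), np.full((3, 5), 50), cat
        )
        m = DirectionModel(c, g)
        q = rng.normal(0, 0.4, m.ndim)
        _, grad = m.logp_grad(q)
        num = np.zeros(m.ndim)
        h = 1e-6
        for i in range(m.ndim):
            qp, qm = q.copy(), q.copy()
            qp[i] += h
            qm[i] -= h
            num[i] = (m.logp_grad(qp)[0] - m.logp_grad(qm)[0]) / (2 * h)
        assert np.abs(grad - num).max() < 1e-4

    def test_centered_data_gives_null_trait_means(self):
        cat = np.arange(6) % 2
        n = np.full((4, 6), 400)
        g = GSnpMatrix(traits=[f"tr{j}" for j in range(6)], matrix=np.eye(6))
        c = _direct_counts(n // 2, n, cat)
        mc = SamplerConfig(chains=1, warmup=400, samples=600, target_accept=0.9, seed=31)
        fit = fit_direction_model(c, g, mc)
        mu = fit.stacked("mu_trait").mean(axis=0)
        assert np.abs(mu).max() < 0.1

    def test_theta_prior_preserved_when_gsnp_identity(self):
        # with G = I the mixing weight is unidentifiable: posterior ~ prior
        rng = np.random.default_rng(32)
        cat = np.arange(6) % 2
        n = np.full((3, 6), 100)
        y = rng.binomial(100, expit(rng.normal(0, 0.5, 6))[None, :], (3, 6))
        g = GSnpMatrix(traits=[f"tr{j}" for j in range(6)], matrix=np.eye(6))
        c = _direct_counts(y, n, cat)
        mc = SamplerConfig(chains=2, warmup=400, samples=800, target_accept=0.9, seed=33)
        fit = fit_direction_model(c, g, mc)
        theta = fit.stacked("theta")
        assert kstest(theta, "uniform").statistic <= 0.15

    def test_monotone_in_positive_count(self):
        rng = np.random.default_rng(34)
        cat = np.arange(4) % 2
        n = np.full((3, 4), 200)
        y = rng.binomial(200, 0.5, (3, 4))
        g = GSnpMatrix(traits=[f"tr{j}" for j in range(4)], matrix=np.eye(4))
        mc = SamplerConfig(chains=1, warmup=300, samples=500, target_accept=0.9, seed=35)
        fit0 = fit_direction_model(_direct_counts(y, n, cat), g, mc)
        y2 = y.copy()
        y2[1, 2] += 50
        fit1 = fit_direction_model(_direct_counts(y2, n, cat), g, mc)
        pi0 = fit0.stacked("pi")[:, 1, 2].mean()
        pi1 = fit1.stacked("pi")[:, 1, 2].mean()
        assert pi1 > pi0


class TestSummaries:
    def _fake(self, mu_values, theta=0.5):
        arr = np.asarray(mu_values, float).reshape(1, -1, 1)
        n = arr.shape[1]
        return PosteriorDraws(
            draws={
                "mu_trait": arr[:, :, :],
                "pi": np.zeros((1, n, 1, 1)),
                "theta": np.full((1, n), theta),
            },
            diagnostics=pd.DataFrame(),
            n_divergent=0,
            n_iterations=n,
            passed=True,
            notes={"tissues": ["T0"], "traits": ["tr0"]},
        )

    def test_symmetric_draws_unflagged(self):
        s = summarize_direction(self._fake([-1, -0.5, 0.5, 1]))
        row = s[(s["level"] == "trait")].iloc[0]
        assert not row["confident"] and not row["strong"]

    def test_ninety_three_percent_positive_sets_only_confident_flag(self):
        vals = [1.0] * 93 + [-1.0] * 7
        s = summarize_direction(self._fake(vals))
        row = s[(s["level"] == "trait")].iloc[0]
        assert row["confident"] and not row["strong"]

    def test_p_positive_by_counting(self):
        s = summarize_direction(self._fake([0.1, 0.2, 0.3, -0.1]))
        assert s[s["level"] == "trait"].iloc[0]["p_positive"] == 0.75


class TestTrajectory:
    def _study(self, states_by_tp, sign=1):
        """One gene, one tissue; states_by_tp maps timepoint -> state."""
        cfg = SimConfig(
            n_tissues=1, n_traits=1, n_categories=1, n_genes=1,
            n_samples_human=50, n_snps=50, seed=0,
        )
        de = exertrait.generate_de_study(cfg)
        st = de.states.copy()
        for tp, s in states_by_tp.items():
            st.loc[st["timepoint"] == tp, ["state_F", "state_M"]] = s
        de.states = st
        return de

    def test_full_half_fill_before_8w(self):
        de = self._study({"1w": 0, "2w": 0, "4w": 0, "8w": 1})
        detail = pd.DataFrame(
            [("G00001", "BLOOD", "t", 1, 1, 1)],
            columns=["gene", "tissue", "trait", "de_sign", "twas_sign", "product"],
        )
        traj = trace_trajectory(de, detail, "t")
        by_tp = traj[traj["tissue"] == "BLOOD"].set_index("timepoint")["proportion"]
        assert by_tp["1w"] == by_tp["2w"] == by_tp["4w"] == 0.5
        assert by_tp["8w"] == 1.0

    def test_always_positive_is_flat_one(self):
        de = self._study({"1w": 1, "2w": 1, "4w": 1, "8w": 1})
        detail = pd.DataFrame(
            [("G00001", "BLOOD", "t", 1, 1, 1)],
            columns=["gene", "tissue", "trait", "de_sign", "twas_sign", "product"],
        )
        traj = trace_trajectory(de, detail, "t")
        assert (traj["proportion"] == 1.0).all()

    def test_mixed_cell_with_half_fill(self):
        # n=4 at 2w: 1 positive, 1 negative, 2 unassigned -> (1 + 1)/4 = 0.5
        cfg = SimConfig(
            n_tissues=1, n_traits=1, n_categories=1, n_genes=4,
            n_samples_human=50, n_snps=50, seed=0,
        )
        de = exertrait.generate_de_study(cfg)
        st = de.states.copy()
        st[["state_F", "state_M"]] = 0
        genes = [f"G{i:05d}" for i in range(1, 5)]
        for g in genes:
            st.loc[
                (st["gene"] == g) & (st["timepoint"] == "8w"),
                ["state_F", "state_M"],
            ] = 1
        for g, s in [(genes[0], 1), (genes[1], -1)]:
            st.loc[
                (st["gene"] == g) & (st["timepoint"] == "2w"),
                ["state_F", "state_M"],
            ] = s
        de.states = st
        detail = pd.DataFrame(
            [(g, "BLOOD", "t", 1, 1, 1) for g in genes],
            columns=["gene", "tissue", "trait", "de_sign", "twas_sign", "product"],
        )
        traj = trace_trajectory(de, detail, "t")
        at_2w = traj[
            (traj["tissue"] == "BLOOD") & (traj["timepoint"] == "2w")
        ].iloc[0]
        assert at_2w["proportion"] == pytest.approx(0.5)

    def test_empty_trait_rejected(self, small_de):
        with pytest.raises(ValueError):
            trace_trajectory(small_de, pd.DataFrame(columns=["trait"]), "none")
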