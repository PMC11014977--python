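"""Behavioral covariates and panel regressions with cluster-robust errors."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import expit

from mixedintentions.models import get_model
from mixedintentions.stats import (
    CollinearityError,
    SeparationError,
    covariates_table,
    derive_covariates,
    marginal_effects,
    panel_linear,
    panel_logit,
    vif_check,
)
from mixedintentions.task import (
    Mode,
    SessionData,
    TrialRecord,
    build_schedule,
)


def _session(pc, aa, subject="s1"):
    sched = build_schedule(len(pc), 0, 13, 10)
    recs, prev_p, prev_a = [], None, None
    for e, p, a in zip(sched.entries, pc, aa):
        recs.append(
            TrialRecord(
                e.trial, e.mode, p, a, int(p == a),
                participant_stay=None if prev_p is None else int(prev_p == p),
                aa_stay=None if prev_a is None else int(prev_a == a),
            )
        )
        prev_p, prev_a = p, a
    return SessionData(subject, tuple(recs), sched)


class TestCovariates:
    def test_cooperativity_signature_definition(self):
        """Signature = AA stays after the participant's win, or switches
        after the participant's loss."""
        # trial 1: pc=1, aa=1 (win); trial 2: aa stays -> signature at t2 = 1
        s = _session([1, 0, 1, 0, 1, 0, 1, 1], [1, 1, 0, 0, 0, 1, 1, 1])
        df = derive_covariates(s, drop_first=0)
        # reconstruct signature at each trial independently
        pc = [r.participant_choice for r in s.records]
        aa = [r.aa_choice for r in s.records]
        win = [r.outcome for r in s.records]
        for _, row in df.iterrows():
            t = int(row["trial"]) - 1  # 0-based
            for lag in (1, 2, 3):
                k = t - lag  # trial where the signature variable is defined
                aa_stay = int(aa[k] == aa[k - 1])
                expected = aa_stay if win[k - 1] == 1 else 1 - aa_stay
                assert row[f"coop_sig_tm{lag}"] == expected

    def test_lag_structure_and_exclusions(self, wsls_session):
        df = derive_covariates(wsls_session)
        assert df["trial"].min() == 6  # first 5 trials excluded
        assert df["trial"].max() == 163
        pc = [r.participant_choice for r in wsls_session.records]
        for _, row in df.iterrows():
            t = int(row["trial"]) - 1
            assert row["stay"] == int(pc[t] == pc[t - 1])
            assert row["win_tm2"] == wsls_session.records[t - 2].outcome
            assert row["switch_tm1"] == int(pc[t - 1] != pc[t - 2])

    def test_trace_columns_attached(self, mixed_session, mixed_params):
        m = get_model("INF_MIXED")
        tr = m.run(mixed_params, mixed_session)
        df = derive_covariates(mixed_session, tr)
        assert {"delta", "omega", "valence", "rpe_tm1", "classification"} <= set(
            df.columns
        )
        idx = df["trial"].to_numpy() - 1
        assert np.allclose(df["delta"].to_numpy(), tr.delta[idx])
        assert np.allclose(df["rpe_tm1"].to_numpy(), tr.rpe[idx - 1])
        v = np.where(tr.classification[idx] == "COOPERATIVE", 1.0, -1.0)
        assert np.array_equal(df["valence"].to_numpy(), v)

    def test_too_short_session_rejected(self):
        s = _session([1, 0], [0, 1])
        with pytest.raises(ValueError):
            derive_covariates(s)


class TestPanelLogit:
    def test_intercept_only_single_cluster(self):
        df = pd.DataFrame({"subject_id": "a", "y": [1.0] * 60 + [0.0] * 40})
        fit = panel_logit(df, "y", [], compute_vif=False)
        assert fit.params[0] == pytest.approx(math.log(0.6 / 0.4), abs=1e-4)
        assert fit.n_clusters == 1

    def test_matches_quadrature_grid_oracle(self):
        """Converged GH fit equals an independently coded adaptive-quadrature
        likelihood maximized by nested grid refinement (3 x 20 toy)."""
        rng = np.random.default_rng(12)
        rows = []
        for s in range(3):
            b = rng.normal(0, 0.8)
            for _ in range(20):
                x = float(rng.integers(0, 2))
                p = expit(-0.3 + 0.8 * x + b)
                rows.append(
                    {"subject_id": f"s{s}", "x": x, "y": float(rng.random() < p)}
                )
        df = pd.DataFrame(rows)
        fit = panel_logit(df, "y", ["x"], fixed_sigma=0.8, n_quad=40,
                          compute_vif=False)

        def loglik(b0, b1):
            tot = 0.0
            for _, g in df.groupby("subject_id"):
                y, x = g["y"].to_numpy(), g["x"].to_numpy()

                def f(u):
                    p = expit(b0 + b1 * x + 0.8 * u)
                    return (
                        np.prod(np.where(y == 1, p, 1 - p))
                        * math.exp(-0.5 * u * u) / math.sqrt(2 * math.pi)
                    )

                tot += math.log(quad(f, -8, 8, limit=100)[0])
            return tot

        c0, c1, w = 0.0, 0.0, 2.0
        for _ in range(6):
            g0 = np.linspace(c0 - w, c0 + w, 21)
            g1 = np.linspace(c1 - w, c1 + w, 21)
            vals = np.array([[loglik(a, b) for b in g1] for a in g0])
            i, j = np.unravel_index(vals.argmax(), vals.shape)
            c0, c1, w = g0[i], g1[j], w / 5
        assert fit.params[0] == pytest.approx(c0, abs=1e-3)
        assert fit.params[1] == pytest.approx(c1, abs=1e-3)

    def test_row_duplication_preserves_coefficients(self):
        rng = np.random.default_rng(5)
        rows = []
        for s in range(4):
            for _ in range(25):
                x = float(rng.integers(0, 2))
                rows.append(
                    {"subject_id": f"s{s}", "x": x,
                     "y": float(rng.random() < expit(0.3 + 0.6 * x))}
                )
        df = pd.DataFrame(rows)
        f1 = panel_logit(df, "y", ["x"], compute_vif=False)
        f2 = panel_logit(
            pd.concat([df, df], ignore_index=True), "y", ["x"], compute_vif=False
        )
        assert f2.params == pytest.approx(f1.params, abs=1e-3)
        assert f2.n_clusters == f1.n_clusters

    def test_perfect_separation_raises(self):
        df = pd.DataFrame(
            {"subject_id": ["a"] * 10 + ["b"] * 10,
             "x": [1.0] * 10 + [0.0] * 10,
             "y": [1.0] * 10 + [0.0] * 10}
        )
        with pytest.raises(SeparationError):
            panel_logit(df, "y", ["x"], compute_vif=False)

    def test_singular_design_names_columns(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {"subject_id": "a", "x": rng.normal(size=30),
             "y": (rng.random(30) < 0.5).astype(float)}
        )
        df["x2"] = df["x"]
        with pytest.raises(CollinearityError, match="x2|x"):
            panel_logit(df, "y", ["x", "x2"], compute_vif=False)

    def test_wald_statistics_consistent(self):
        rng = np.random.default_rng(7)
        rows = []
        for s in range(6):
            for _ in range(40):
                x = rng.normal()
                rows.append(
                    {"subject_id": f"s{s}", "x": x,
                     "y": float(rng.random() < expit(0.8 * x))}
                )
        fit = panel_logit(pd.DataFrame(rows), "y", ["x"], compute_vif=False)
        assert fit.chi2[1] == pytest.approx((fit.params[1] / fit.se[1]) ** 2)
        lo, hi = fit.conf_int()[1]
        assert lo < fit.params[1] < hi


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(8)
    rows = []
    for s in range(5):
        for _ in range(40):
            x = rng.normal()
            d = float(rng.integers(0, 2))
            p = expit(0.2 + 0.5 * x + 0.7 * d)
            rows.append(
                {"subject_id": f"s{s}", "x": x, "d": d,
                 "y": float(rng.random() < p)}
            )
    return panel_logit(pd.DataFrame(rows), "y", ["x", "d"], compute_vif=False)


class TestMarginalEffects:

    def test_continuous_ame_matches_finite_difference(self, fitted):
        from mixedintentions.stats import _gh_nodes

        ame = marginal_effects(fitted, "x")
        z, w = _gh_nodes(24)
        X = fitted._X
        h = 1e-6

        def meanp(Xm):
            eta = Xm @ fitted.params
            return float(np.mean(expit(eta[:, None] + fitted.sigma_b * z) @ w))

        Xp, Xm_ = X.copy(), X.copy()
        Xp[:, 1] += h
        Xm_[:, 1] -= h
        assert ame == pytest.approx((meanp(Xp) - meanp(Xm_)) / (2 * h), abs=1e-6)

    def test_binary_ame_is_discrete_change(self, fitted):
        ame = marginal_effects(fitted, "d")
        assert 0.0 < ame < 1.0  # positive effect on probability scale

    def test_literal_formula_flag(self, fitted):
        lit = marginal_effects(fitted, "d", literal=True)
        j = fitted.names.index("d")
        assert lit == pytest.approx(float(expit(fitted.params[j])))
        # a null coefficient maps to 0.5 under the literal form
        assert float(expit(0.0)) == 0.5

    def test_zero_coefficient_gives_zero_ame(self):
        rng = np.random.default_rng(9)
        rows = []
        for s in range(4):
            for _ in range(50):
                rows.append(
                    {"subject_id": f"s{s}", "x": rng.normal(),
                     "y": float(rng.random() < 0.5)}
                )
        fit = panel_logit(pd.DataFrame(rows), "y", ["x"], compute_vif=False)
        fit.params[1] = 0.0
        assert marginal_effects(fit, "x") == pytest.approx(0.0, abs=1e-12)


class TestPanelLinear:
    def test_outcome_identical_to_covariate(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {"subject_id": np.repeat(["a", "b"], 20),
             "x": rng.normal(size=40), "z": rng.normal(size=40)}
        )
        df["y"] = df["x"]
        fit = panel_linear(df, "y", ["x", "z"], compute_vif=False)
        assert fit.coef("x") == pytest.approx(1.0, abs=1e-10)
        assert fit.coef("z") == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_single_cluster(self):
        rng = np.random.default_rng(11)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = X @ np.array([0.5, -1.2]) + rng.normal(0, 0.3, 30)
        df = pd.DataFrame({"subject_id": "a", "x": X[:, 1], "y": y})
        fit = panel_linear(df, "y", ["x"], compute_vif=False)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.params == pytest.approx(beta, abs=1e-10)

    def test_cluster_sandwich_matches_hand_formula(self):
        rng = np.random.default_rng(12)
        rows = []
        for s in range(5):
            shock = rng.normal(0, 1.0)
            for _ in range(15):
                x = rng.normal()
                rows.append(
                    {"subject_id": f"s{s}", "x": x,
                     "y": 0.4 * x + shock + rng.normal(0, 0.5)}
                )
        df = pd.DataFrame(rows)
        fit = panel_linear(df, "y", ["x"], compute_vif=False)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        y = df["y"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        bread = np.linalg.inv(X.T @ X)
        meat = np.zeros((2, 2))
        for _, g in df.groupby("subject_id"):
            Xi = np.column_stack([np.ones(len(g)), g["x"]])
            ui = resid[g.index]
            sg = Xi.T @ ui
            meat += np.outer(sg, sg)
        n, k, G = len(df), 2, 5
        corr = (G / (G - 1)) * ((n - 1) / (n - k))  # statsmodels small-sample factor
        cov = corr * bread @ meat @ bread
        assert fit.cov == pytest.approx(cov, rel=1e-6)


class TestVif:
    def test_orthogonal_design_unit_vif(self):
        # columns orthogonal to each other and to the intercept
        rng = np.random.default_rng(13)
        q, _ = np.linalg.qr(
            np.column_stack([np.ones(60), rng.normal(size=(60, 3))])
        )
        df = pd.DataFrame(q[:, 1:], columns=["a", "b", "c"])
        vif = vif_check(df, ["a", "b", "c"])
        assert vif.to_numpy() == pytest.approx(np.ones(3), abs=1e-8)

    def test_duplicated_column_rejected(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame({"a": rng.normal(size=30)})
        df["b"] = df["a"]
        with pytest.raises(CollinearityError):
            vif_check(df, ["a", "b"])

    def test_matches_auxiliary_regression_oracle(self):
        rng = np.random.default_rng(15)
        a = rng.normal(size=80)
        b = 0.7 * a + rng.normal(0, 0.5, 80)
        c = rng.normal(size=80)
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        vif = vif_check(df, ["a", "b", "c"])
        X = np.column_stack([np.ones(80), b, c])
        beta = np.linalg.lstsq(X, a, rcond=None)[0]
        resid = a - X @ beta
        r2 = 1 - resid.var() / a.var()
        assert vif["a"] == pytest.approx(1 / (1 - r2), rel=1e-6)


def test_covariates_table_stacks_population(wsls_session, mixed_session):
    df = covariates_table([wsls_session, mixed_session])
    assert set(df["subject_id"]) == {"w1", "m1"}
    assert len(df) == 2 * 158
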