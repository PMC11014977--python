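"""The mixed-intentions controller: arbitration, combination, classification."""

import math

import numpy as np
import pytest
from scipy.special import expit

from mixedintentions.models import (
    COMPETITIVE,
    COOPERATIVE,
    arbitrate,
    classify_trial,
    combine_and_choose,
    get_model,
    model_pe,
    reliability,
)
from mixedintentions.models.influence import expert_values
from mixedintentions.task import Mode, build_schedule, play_session


class TestControllerOps:
    def test_expert_values(self):
        assert expert_values(0.5, 1.0) == (0.5, 0.5)
        assert expert_values(0.9, 1.0) == (pytest.approx(0.1), pytest.approx(0.9))
        assert expert_values(1.0, 0.0) == (0.0, 0.0)

    def test_reliability(self):
        assert reliability(0.5, 0.5) == 0.0
        assert reliability(0.9, 0.1) == pytest.approx(0.8)
        assert reliability(0.1, 0.9) == reliability(0.9, 0.1)

    def test_arbitration_sigmoid(self):
        assert arbitrate(0.3, 0.1, slope=5.0, delta_bias=0.2) == pytest.approx(0.5)
        assert arbitrate(0.5, 0.0, slope=2.0, delta_bias=0.0) == pytest.approx(
            expit(1.0)
        )
        assert arbitrate(0.5, 0.0, slope=500.0, delta_bias=0.0) == pytest.approx(1.0)

    def test_combination_and_choice(self):
        dv0, dv1, _ = combine_and_choose((0.2, 0.9), (0.7, 0.2), omega=1.0, beta=2.0)
        assert (dv0, dv1) == (pytest.approx(0.2), pytest.approx(0.9))
        _, dv1, _ = combine_and_choose(
            (0.1, 0.9), (0.8, 0.2), omega=0.7311, beta=2.0
        )
        assert dv1 == pytest.approx(0.7117, abs=1e-4)
        # DV fixed at (0.30, 0.71) by direct construction: p1 = expit(3 * 0.41)
        _, _, p1 = combine_and_choose((0.30, 0.71), (0.30, 0.71), 0.5, beta=3.0)
        assert p1 == pytest.approx(float(expit(3 * 0.41)), abs=1e-12)
        assert p1 == pytest.approx(0.774, abs=1e-3)

    def test_prediction_error(self):
        assert model_pe(0.6, 0.6) == 0.0
        assert model_pe(0.7117, 1.0) == pytest.approx(0.2883)
        assert model_pe(1.0, 0.0) == -1.0

    def test_classification_rule(self):
        assert classify_trial(0.2, 0.1) == COOPERATIVE
        assert classify_trial(0.05, 0.1) == COMPETITIVE
        assert classify_trial(0.1, 0.1) == COMPETITIVE  # tie -> competitive
        assert classify_trial(-0.05, 0.1, use_bias=False) == COMPETITIVE
        assert classify_trial(0.05, 0.1, use_bias=False) == COOPERATIVE


class TestMixtureModel:
    def test_identical_experts_give_zero_delta(self, mixed_session):
        """kappa = 0 makes the experts identical: Delta is exactly 0 and the
        arbitration weight is pinned at sigmoid(-slope * delta)."""
        m = get_model("INF_MIXED")
        params = {"eta": 0.3, "kappa": 1e-300, "beta": 2.0, "slope": 5.0,
                  "delta_bias": 0.2}
        trace = m.run(params, mixed_session)
        assert np.all(trace.delta == 0.0)
        assert np.allclose(trace.omega, expit(-5.0 * 0.2))

    def test_sign_symmetry_flips_classification(self, mixed_session, mixed_params):
        """Swapping the experts' roles and negating the bias mirrors every
        classification (ties break the same way up to boundary trials)."""
        m = get_model("INF_MIXED")
        trace = m.run(mixed_params, mixed_session)
        swapped = get_model("INF_MIXED")
        swapped._factory = lambda p, f=m._factory: f(p)[::-1]
        params_neg = dict(mixed_params, delta_bias=-mixed_params["delta_bias"])
        trace2 = swapped.run(params_neg, mixed_session)
        assert np.allclose(trace2.delta, -trace.delta)
        strict = np.abs(trace.delta - mixed_params["delta_bias"]) > 1e-12
        flipped = np.where(
            trace.classification == COOPERATIVE, COMPETITIVE, COOPERATIVE
        )
        assert np.array_equal(trace2.classification[strict], flipped[strict])

    def test_random_choice_limit(self, mixed_session):
        m = get_model("INF_MIXED")
        params = {"eta": 0.3, "kappa": 0.5, "beta": 1e-12, "slope": 5.0,
                  "delta_bias": 0.0}
        assert m.loglik(params, mixed_session) == pytest.approx(
            len(mixed_session) * math.log(0.5)
        )

    def test_trace_is_deterministic_and_consistent(self, mixed_session, mixed_params):
        m = get_model("INF_MIXED")
        t1 = m.run(mixed_params, mixed_session)
        t2 = m.run(mixed_params, mixed_session)
        assert np.array_equal(t1.omega, t2.omega)
        assert np.array_equal(t1.trial_loglik, t2.trial_loglik)
        assert t1.loglik == pytest.approx(m.loglik(mixed_params, mixed_session))
        # controller identities hold on every trial
        assert np.allclose(t1.delta, t1.rel_coop - t1.rel_comp)
        assert np.allclose(
            t1.omega, expit(mixed_params["slope"] * (t1.delta - mixed_params["delta_bias"]))
        )
        assert np.all((t1.omega > 0) & (t1.omega < 1))
        assert np.all(np.abs(t1.rpe) <= 1.0)
        assert np.isnan(t1.dv_stay[0]) and np.isfinite(t1.dv_stay[1:]).all()

    def test_probabilities_bounded_for_random_parameters(self, mixed_session):
        from mixedintentions.inference import to_natural

        m = get_model("INF_MIXED")
        rng = np.random.default_rng(0)
        for _ in range(10):
            params = to_natural(m.param_defs, rng.normal(0, 2, 5))
            tr = m.run(params, mixed_session)
            assert np.all((tr.p_choice1 >= 0) & (tr.p_choice1 <= 1))
            assert np.all((tr.omega > 0) & (tr.omega < 1))

    def test_omega_tracks_block_structure(self, mixed_params):
        """Population-mean arbitration weight is higher in cooperative blocks
        than in competitive blocks."""
        m = get_model("INF_MIXED")
        schedule = build_schedule()
        modes = np.array([e.mode for e in schedule.entries], dtype=object)
        omegas = []
        for seed in range(100):
            s = play_session(m, mixed_params, schedule, seed=seed,
                             subject_id=f"o{seed}")
            omegas.append(m.run(mixed_params, s).omega)
        mean_omega = np.mean(omegas, axis=0)
        assert (
            mean_omega[modes == Mode.COOPERATIVE].mean()
            > mean_omega[modes == Mode.COMPETITIVE].mean()
        )

    def test_stay_after_negative_pe_higher_when_classified_cooperative(
        self, mixed_params
    ):
        """Fig-3c-direction signature: generated stay probability after a
        negative prediction error is higher on cooperative-classified trials."""
        m = get_model("INF_MIXED")
        schedule = build_schedule()
        stay_by_class = {COOPERATIVE: [], COMPETITIVE: []}
        for seed in range(60):
            s = play_session(m, mixed_params, schedule, seed=seed,
                             subject_id=f"p{seed}")
            tr = m.run(mixed_params, s)
            pc = [r.participant_choice for r in s.records]
            for t in range(1, len(s)):
                if tr.rpe[t - 1] < 0:
                    stay_by_class[tr.classification[t]].append(int(pc[t] == pc[t - 1]))
        assert np.mean(stay_by_class[COOPERATIVE]) > np.mean(
            stay_by_class[COMPETITIVE]
        )


class TestMixedWrap:
    def test_identical_expert_pair_has_zero_delta(self, mixed_session):
        from mixedintentions.models.influence import InfluenceExpert
        from mixedintentions.models.mixture import MixtureModel
        from mixedintentions.models.base import ParamDef

        same = MixtureModel(
            "SAME",
            lambda p: (
                InfluenceExpert(+1, p["eta"], p["kappa"], p["eta"]),
                InfluenceExpert(+1, p["eta"], p["kappa"], p["eta"]),
            ),
            (ParamDef("eta", "logit"), ParamDef("kappa", "log")),
        )
        tr = same.run(
            {"eta": 0.3, "kappa": 0.4, "beta": 2.0, "slope": 5.0, "delta_bias": 0.0},
            mixed_session,
        )
        assert np.all(tr.delta == 0.0)

    def test_registered_mixture_matches_manual_wrap(self, mixed_session, mixed_params):
        from mixedintentions.models.influence import InfluenceExpert
        from mixedintentions.models.mixture import MixtureModel
        from mixedintentions.models.base import ParamDef

        manual = MixtureModel(
            "MANUAL",
            lambda p: (
                InfluenceExpert(+1, p["eta"], p["kappa"], p["eta"]),
                InfluenceExpert(-1, p["eta"], p["kappa"], p["eta"]),
            ),
            (ParamDef("eta", "logit"), ParamDef("kappa", "log")),
        )
        a = get_model("INF_MIXED").run(mixed_params, mixed_session)
        b = manual.run(mixed_params, mixed_session)
        assert np.array_equal(a.trial_loglik, b.trial_loglik)
        assert np.array_equal(a.omega, b.omega)

    def test_tom_mixture_likelihood_finite(self, mixed_session):
        m = get_model("TOM1_MIXED")
        ll = m.loglik(
            {"vol": 0.3, "beta": 2.0, "slope": 5.0, "delta_bias": 0.1},
            mixed_session,
        )
        assert math.isfinite(ll)
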