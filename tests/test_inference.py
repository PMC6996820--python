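"""AICc ranking, Akaike weights, evidence sums, model averaging."""

import math

import numpy as np
import pytest

import densdep as dd
from densdep.calibration import FitResult


def fake_fit(aicc, forms, sharing=None, params=None):
    cfg = dd.ModelConfig.build(forms, sharing)
    return FitResult(
        config=cfg, params=params or {}, nll=0.0, n=33, k=cfg.k, aicc=aicc
    )


class TestAkaikeWeights:
    def test_reported_top_three_gaps(self):
        # the published ranking separated the top three by 0.071 and 0.324
        fits = [
            fake_fit(100.0, {"A": "random_walk"}),
            fake_fit(100.071, {"A": "exponential"}),
            fake_fit(100.324, {"A": "ricker"}),
        ]
        r = dd.rank_models(fits)
        expected = np.exp(-0.5 * np.array([0.0, 0.071, 0.324]))
        expected /= expected.sum()
        np.testing.assert_allclose(r.weights, expected, atol=1e-12)
        np.testing.assert_allclose(r.weights, [0.3552, 0.3428, 0.3020], atol=1e-4)

    def test_equal_aicc_splits_evenly(self):
        fits = [
            fake_fit(10.0, {"A": "random_walk"}),
            fake_fit(10.0, {"A": "exponential"}),
        ]
        np.testing.assert_allclose(dd.rank_models(fits).weights, [0.5, 0.5])

    def test_single_fit_gets_unit_weight(self):
        r = dd.rank_models([fake_fit(3.0, {"A": "ricker"})])
        assert r.weights[0] == pytest.approx(1.0)

    def test_weights_invariant_to_constant_shift(self):
        base = [10.0, 12.0, 15.0]
        forms = ["random_walk", "exponential", "ricker"]
        r1 = dd.rank_models([fake_fit(a, {"A": f}) for a, f in zip(base, forms)])
        r2 = dd.rank_models([fake_fit(a + 57.3, {"A": f}) for a, f in zip(base, forms)])
        np.testing.assert_allclose(r1.weights, r2.weights, atol=1e-12)

    def test_ranking_contract(self):
        fits = [fake_fit(a, {"A": f}) for a, f in
                zip([20.0, 11.0, 15.0], ["ricker", "random_walk", "gompertz"])]
        r = dd.rank_models(fits)
        assert r.delta[0] == 0.0
        assert np.all(np.diff(r.delta) >= 0)
        assert np.all(np.diff(r.weights) <= 0)
        assert r.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dropping_worst_preserves_order(self):
        fits = [fake_fit(a, {"A": f}) for a, f in
                zip([20.0, 11.0, 15.0], ["ricker", "random_walk", "gompertz"])]
        full = dd.rank_models(fits)
        trimmed = dd.rank_models(fits[:2] + fits[2:])  # same set
        reduced = dd.rank_models([f for f in fits if f.aicc < 20.0])
        ids_full = [f.config.config_id for f in full.fits][:2]
        ids_reduced = [f.config.config_id for f in reduced.fits]
        assert ids_full == ids_reduced
        assert len(trimmed) == 3


class TestEvidence:
    def _ranking(self):
        return dd.rank_models(
            [
                fake_fit(10.0, {"A": "ricker"}),
                fake_fit(10.0 + 2 * math.log(0.6 / 0.4), {"A": "random_walk"}),
            ]
        )

    def test_trivial_predicates(self):
        r = self._ranking()
        assert dd.evidence_sum(r, lambda c: True) == pytest.approx(100.0)
        assert dd.evidence_sum(r, lambda c: False) == pytest.approx(0.0)

    def test_sixty_forty_split(self):
        r = self._ranking()  # weights 0.6 / 0.4 by construction
        assert dd.evidence_sum(r, dd.form_at("A", "ricker")) == pytest.approx(60.0)

    def test_partition_sums_to_hundred(self):
        r = self._ranking()
        total = sum(
            dd.evidence_sum(r, dd.form_at("A", f))
            for f in ["random_walk", "exponential", "ricker", "gompertz"]
        )
        assert total == pytest.approx(100.0)

    def test_theta_logistic_excluded_and_renormalized(self):
        fits = [
            fake_fit(10.0, {"A": "ricker"}),
            fake_fit(10.0, {"A": "theta_logistic"}),
        ]
        r = dd.rank_models(fits)
        assert dd.evidence_sum(r, dd.form_at("A", "ricker")) == pytest.approx(100.0)
        with pytest.raises(ValueError, match="excluded"):
            dd.evidence_sum(r, lambda c: True, excluded_forms=tuple(dd.FORMS))

    def test_form_table_columns_sum_to_hundred(self):
        fits = [fake_fit(10.0 + i, {"A": f, "B": f}) for i, f in enumerate(dd.FORMS)]
        table = dd.form_evidence_table(dd.rank_models(fits), locations=["A", "B"])
        np.testing.assert_allclose(table.sum(axis=0), [100.0, 100.0])
        assert "theta_logistic" not in table.index

    def test_shared_dynamics_and_shared_beta_predicates(self):
        shared = dd.ModelConfig.build(
            {"A": "ricker", "B": "ricker"},
            {"lambda": [["A", "B"]], "beta": [["A", "B"]]},
        )
        beta_only = dd.ModelConfig.build(
            {"A": "ricker", "B": "ricker"}, {"beta": [["A", "B"]]}
        )
        independent = dd.ModelConfig.build({"A": "ricker", "B": "gompertz"})
        assert dd.shared_dynamics(["A", "B"])(shared)
        assert not dd.shared_dynamics(["A", "B"])(beta_only)
        assert not dd.shared_dynamics(["A", "B"])(independent)
        assert dd.shared_beta(["A", "B"])(shared)
        assert dd.shared_beta(["A", "B"])(beta_only)
        assert not dd.shared_beta(["A", "B"])(independent)


class TestMultimodelPredict:
    def _fits(self):
        f1 = fake_fit(
            10.0,
            {"A": "exponential"},
            params={"lambda@A": 2.0, "sigma@A": 0.01},
        )
        f2 = fake_fit(
            10.0,
            {"A": "random_walk"},
            params={"sigma@A": 0.01},
        )
        return f1, f2

    def test_top_one_is_single_model_prediction(self):
        f1, f2 = self._fits()
        r = dd.rank_models([f1, f2])
        best = r.best
        expected = dd.predict_next(
            best.config.form_at("A"), best.location_params("A"), 0.05
        )
        assert dd.multimodel_predict(r, "A", 0.05, top_m=1) == pytest.approx(expected)

    def test_equal_weights_average_predictions(self):
        f1, f2 = self._fits()
        r = dd.rank_models([f1, f2])
        # exponential(lam=2): 0.10; random walk: 0.05 -> mean 0.075
        assert dd.multimodel_predict(r, "A", 0.05, top_m=2) == pytest.approx(0.075)

    def test_renormalized_weights_sum_to_one(self):
        fits = [
            fake_fit(10.0 + i, {"A": "random_walk"}, params={"sigma@A": 0.01})
            for i in range(1)
        ] + [
            fake_fit(11.0, {"A": "exponential"}, params={"lambda@A": 1.0, "sigma@A": 0.01}),
            fake_fit(13.0, {"A": "exponential"}, params={"lambda@A": 1.1, "sigma@A": 0.01}),
        ]
        members = dd.top_models(dd.rank_models(fits), top_m=2)
        assert sum(w for _, w in members) == pytest.approx(1.0, abs=1e-12)
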