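"""Concentrated lognormal likelihood and the multi-start MLE."""

import math

import numpy as np
import pytest

from mirharmonic import (
    FitConfig,
    HarmonicParams,
    SimulationConfig,
    fit,
    neg2_log_likelihood,
    simulate,
)
from mirharmonic.likelihood_fit import (
    DegenerateFitError,
    InsufficientDataError,
    fit_report,
    wald_se,
)
from mirharmonic.mir_core import MIRDataset, dataset_from_arrays


def deviance_oracle(psi_o, psi_e):
    """Literal term-by-term transcription of the concentrated objective."""
    n = len(psi_o)
    s = 0.0
    for o, e in zip(psi_o, psi_e):
        s += (math.log(o) - math.log(e)) ** 2
    return n * (math.log(2.0 * math.pi * s / n) + 1.0)


class TestObjective:
    def test_single_unit_log_residual(self):
        # one observation at e times the curve: S = 1, objective ln(2*pi)+1
        p = HarmonicParams(1, 50.0, 0.0, 0.0, 12.0)
        d = dataset_from_arrays([4], [50.0 * math.e])
        assert neg2_log_likelihood(d, p) == pytest.approx(math.log(2 * math.pi) + 1)
        assert neg2_log_likelihood(d, p) == pytest.approx(2.8379, abs=1e-4)

    def test_two_half_log_residuals(self):
        p = HarmonicParams(1, 50.0, 0.0, 0.0, 12.0)
        d = dataset_from_arrays([4, 9], [50.0 * math.exp(0.5)] * 2)
        expected = 2 * (math.log(2 * math.pi * 0.25) + 1)
        assert neg2_log_likelihood(d, p) == pytest.approx(expected)
        assert neg2_log_likelihood(d, p) == pytest.approx(2.90317, abs=1e-4)

    def test_exact_data_is_degenerate(self, order1_truth):
        d = simulate(SimulationConfig(true_params=order1_truth, sigma_log=0.0, seed=0))
        with pytest.raises(DegenerateFitError):
            neg2_log_likelihood(d, order1_truth)

    def test_nonpositive_prediction_gives_inf(self):
        p = HarmonicParams(1, 1.0, 0.0, -50.0, 12.0)  # negative near t=12
        d = dataset_from_arrays([12], [40.0])
        assert neg2_log_likelihood(d, p) == math.inf

    def test_replicated_dataset_doubles_n_and_objective(self, clean_dataset, order1_truth):
        from mirharmonic import replicate_two_periods

        single = neg2_log_likelihood(clean_dataset, order1_truth)
        double = neg2_log_likelihood(replicate_two_periods(clean_dataset), order1_truth)
        assert double == pytest.approx(2.0 * single, rel=1e-12)

    def test_oracle_equivalence_at_random_points(self, clean_dataset, rng):
        # 50 random parameter points, both model orders
        t = clean_dataset.times
        psi_o = clean_dataset.mir
        for _ in range(50):
            order = int(rng.integers(1, 3))
            vec = [
                rng.uniform(40, 80),
                rng.uniform(-30, 30),
                rng.uniform(-30, 30),
                *([rng.uniform(-10, 10), rng.uniform(-10, 10)] if order == 2 else []),
                rng.uniform(8, 16),
            ]
            p = HarmonicParams.from_vector(order, vec)
            from mirharmonic.harmonic_models import predict

            psi_e = predict(p, t)
            if np.any(psi_e <= 0):
                continue
            assert neg2_log_likelihood(clean_dataset, p) == pytest.approx(
                deviance_oracle(psi_o, psi_e), rel=1e-10
            )


class TestFit:
    def test_parameter_recovery_single_dataset(self, clean_dataset, order1_truth):
        res = fit(clean_dataset, 1)
        truth = order1_truth.to_vector()
        est = res.params.to_vector()
        assert res.converged
        assert np.all(np.abs(est - truth) / np.abs(truth) < 0.05)
        # two-period replication doubles the count entering the objective
        assert res.n_used == 2 * clean_dataset.n_original

    def test_record_order_invariance(self, clean_dataset, rng):
        res = fit(clean_dataset, 1)
        perm = rng.permutation(clean_dataset.n_original)
        shuffled = MIRDataset(
            tuple(clean_dataset.records[i] for i in perm),
            period_unit=clean_dataset.period_unit,
        )
        res_s = fit(shuffled, 1)
        assert res_s.neg2lnL == pytest.approx(res.neg2lnL, abs=1e-8)
        assert np.allclose(res_s.params.to_vector(), res.params.to_vector(), atol=1e-6)

    def test_nesting_objective_inequality(self, clean_dataset):
        r1 = fit(clean_dataset, 1)
        r2 = fit(clean_dataset, 2)
        assert r2.neg2lnL <= r1.neg2lnL + 1e-6

    def test_gamma_stays_within_bounds(self, clean_dataset):
        res = fit(clean_dataset, 1, FitConfig(gamma_bounds=(10.0, 14.0)))
        assert 10.0 <= res.params.gamma <= 14.0

    def test_fixed_parameter_is_honoured(self, clean_dataset):
        res = fit(clean_dataset, 1, fixed={"gamma": 11.5})
        assert res.params.gamma == 11.5
        assert res.neg2lnL >= fit(clean_dataset, 1).neg2lnL

    def test_insufficient_data(self, order1_truth):
        d = dataset_from_arrays([1, 5], [40.0, 60.0])
        with pytest.raises(InsufficientDataError):
            fit(d, 2, FitConfig(replicate=False))

    def test_no_replication_flag(self, clean_dataset):
        res = fit(clean_dataset, 1, FitConfig(replicate=False))
        assert res.n_used == clean_dataset.n_original

    def test_report_is_json_serializable(self, clean_dataset):
        import json

        res = fit(clean_dataset, 1)
        blob = json.loads(json.dumps(fit_report(res)))
        assert blob["model"] == "H1"
        assert set(blob["params"]) == {"beta0", "beta1", "beta2", "gamma"}
        assert blob["n_used"] == res.n_used


def test_wald_se_positive_and_reasonable(clean_dataset):
    res = fit(clean_dataset, 1)
    se = wald_se(clean_dataset, res)
    assert se.shape == (4,)
    assert np.all(se > 0)
    # at n=600 effective with 5 % noise the SEs are small fractions of the estimates
    assert np.all(se < np.abs(res.params.to_vector()) * 0.2)
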