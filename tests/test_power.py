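import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import esmpower as ep
from esmpower import PowerCell, ValidationError
from conftest import make_dataset


class TestSimulateOutcome:
    def test_exact_mode_hits_target_correlation(self):
        rng = np.random.default_rng(0)
        y = rng.normal(50, 10, 100)
        out = ep.simulate_outcome(y, 0.5, rng, mode="exact")
        assert np.corrcoef(y, out)[0, 1] == pytest.approx(0.5, abs=1e-10)

    def test_exact_mode_zero_target_is_orthogonal(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 50)
        out = ep.simulate_outcome(y, 0.0, rng, mode="exact")
        assert np.corrcoef(y, out)[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_population_mode_correlation_in_expectation(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 20_000)
        out = ep.simulate_outcome(y, 0.3, rng, mode="population")
        assert np.corrcoef(y, out)[0, 1] == pytest.approx(0.3, abs=0.03)

    def test_invalid_inputs(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError):
            ep.simulate_outcome(np.ones(10), 0.3, rng)
        with pytest.raises(ValidationError):
            ep.simulate_outcome(np.arange(10.0), 1.0, rng)


class TestPearsonTest:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, t, p, sig = ep.pearson_test(x, x)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-10 and sig

    def test_exact_null_point(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 30)
        y = ep.simulate_outcome(x, 0.0, rng, mode="exact")
        r, t, p, sig = ep.pearson_test(x, y)
        assert t == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-8)
        assert not sig

    def test_threshold_example_n20(self):
        # r = 0.444 at n = 20: t = 2.102, two-tailed p just under 0.05
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 20)
        y = ep.simulate_outcome(x, 0.444, rng, mode="exact")
        r, t, p, sig = ep.pearson_test(x, y, alpha=0.05)
        assert t == pytest.approx(2.102, abs=5e-3)
        assert p == pytest.approx(0.0499, abs=5e-4)
        assert sig

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(5, 60))
            x, y = rng.normal(0, 1, (2, n))
            r, t, p, _ = ep.pearson_test(x, y)
            ref = st.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            ep.pearson_test(np.ones(10), np.arange(10.0))


def test_fisher_z_power_values():
    # hand-checked: atanh(.3)*sqrt(77) - 1.96 = 0.756 -> Phi = 0.775
    assert ep.fisher_z_power(0.3, 80) == pytest.approx(0.7752, abs=5e-4)
    # atanh(.5)*sqrt(27) - 1.96 = 0.894 -> Phi = 0.814
    assert ep.fisher_z_power(0.5, 30) == pytest.approx(0.8144, abs=1e-3)
    # atanh(.1)*sqrt(97) - 1.96 = -0.972 -> Phi = 0.166
    assert ep.fisher_z_power(0.1, 100) == pytest.approx(0.1656, abs=1e-3)


@pytest.fixture(scope="module")
def power_dataset(synth_default):
    return synth_default[0]


class TestPowerCell:
    def test_cell_fields_and_mc_se(self, power_dataset):
        cell = ep.power_cell(power_dataset, "mean", 40, 10, 0.3, 0.05, 200,
                             np.random.default_rng(0), min_reports_truth=50)
        assert 0.0 <= cell.power <= 1.0
        assert cell.mc_se == pytest.approx(
            math.sqrt(cell.power * (1 - cell.power) / 200)
        )

    def test_power_monotone_in_participants(self, power_dataset):
        rng = np.random.default_rng(1)
        p_small = ep.power_cell(power_dataset, "mean", 20, None, 0.3, 0.05,
                                1500, rng).power
        p_large = ep.power_cell(power_dataset, "mean", 160, None, 0.3, 0.05,
                                1500, rng).power
        assert p_large > p_small

    def test_measurement_noise_attenuates_power(self, power_dataset):
        rng = np.random.default_rng(2)
        noisy = ep.power_cell(power_dataset, "rmssd", 80, 5, 0.5, 0.05, 800, rng).power
        clean = ep.power_cell(power_dataset, "rmssd", 80, 50, 0.5, 0.05, 800, rng).power
        assert clean > noisy

    def test_pool_mode_agrees_with_per_sim(self, power_dataset):
        a = ep.power_cell(power_dataset, "mean", 80, None, 0.3, 0.05, 1500,
                          np.random.default_rng(3)).power
        b = ep.power_cell(power_dataset, "mean", 80, None, 0.3, 0.05, 1500,
                          np.random.default_rng(4), outcome_mode="pool").power
        se = math.sqrt(2 * 0.78 * 0.22 / 1500)
        assert abs(a - b) < 4 * se

    def test_without_replacement_requires_enough_persons(self, power_dataset):
        with pytest.raises(ValidationError):
            ep.power_cell(power_dataset, "mean", 10_000, None, 0.3, 0.05, 10,
                          np.random.default_rng(0), replace=False)


class TestPowerGrid:
    def test_product_count_and_determinism(self, power_dataset):
        kwargs = dict(
            measures=["mean"], participant_grid=[20, 40], obs_grid=[5, 10],
            r_targets=[0.5], n_sims=100, min_reports_truth=50,
        )
        a = ep.power_grid(power_dataset, rng=np.random.default_rng(7), **kwargs)
        b = ep.power_grid(power_dataset, rng=np.random.default_rng(7), **kwargs)
        assert len(a) == 4
        assert [c.power for c in a] == [c.power for c in b]

    def test_grid_agreement_across_sim_counts(self, power_dataset):
        small = ep.power_grid(power_dataset, measures=["mean"],
                              participant_grid=[80], obs_grid=[20],
                              r_targets=[0.3], n_sims=300,
                              rng=np.random.default_rng(8))[0]
        large = ep.power_grid(power_dataset, measures=["mean"],
                              participant_grid=[80], obs_grid=[20],
                              r_targets=[0.3], n_sims=1200,
                              rng=np.random.default_rng(9))[0]
        combined_se = math.sqrt(small.mc_se**2 + large.mc_se**2)
        assert abs(small.power - large.power) < 4 * max(combined_se, 0.01)


def _cell(npart, nobs, power):
    return PowerCell("mean", npart, nobs, 0.3, 0.05, power, 0.01, 100)


class TestMinimalDesigns:
    def test_hand_built_table_matches_manual_scan(self):
        cells = [
            _cell(10, 5, 0.2), _cell(10, 10, 0.5), _cell(10, 20, 0.85),
            _cell(20, 5, 0.4), _cell(20, 10, 0.82), _cell(20, 20, 0.9),
            _cell(40, 5, 0.81), _cell(40, 10, 0.9), _cell(40, 20, 0.95),
        ]
        fr = ep.minimal_designs(cells, 0.80)
        assert fr.points == ((10, 20), (20, 10), (40, 5))

    def test_all_cells_above_threshold(self):
        cells = [_cell(10, 5, 0.9), _cell(10, 10, 0.95), _cell(20, 5, 0.92)]
        fr = ep.minimal_designs(cells, 0.80)
        assert fr.points == ((10, 5), (20, 5))

    def test_no_cell_reaches_threshold(self):
        fr = ep.minimal_designs([_cell(10, 5, 0.2)], 0.80)
        assert fr.points == ()

    def test_isotonic_cleanup_removes_mc_inversion(self):
        # 40 participants appears to need more observations than 20: carry
        # the stricter requirement down to the smaller design instead
        cells = [
            _cell(20, 5, 0.81), _cell(20, 10, 0.9),
            _cell(40, 5, 0.79), _cell(40, 10, 0.9),
        ]
        fr = ep.minimal_designs(cells, 0.80)
        assert fr.points == ((20, 10), (40, 10))
        obs = [nobs for _, nobs in fr.points]
        assert obs == sorted(obs, reverse=True) or len(set(obs)) == 1

    def test_mixed_measures_rejected(self):
        cells = [_cell(10, 5, 0.9),
                 PowerCell("sd", 10, 5, 0.3, 0.05, 0.9, 0.01, 100)]
        with pytest.raises(ValidationError):
            ep.minimal_designs(cells)


class TestEffectBenchmarks:
    def test_self_correlation_is_one(self, power_dataset):
        truths = ep.true_measures(power_dataset, min_reports=50)
        cov = pd.DataFrame(
            {"trait": {pid: ms.mean for pid, ms in truths.items()}}
        )
        table = ep.effect_benchmarks(truths, cov)
        assert table.loc["mean", "trait"] == pytest.approx(1.0)

    def test_independent_covariate_near_zero(self, power_dataset):
        truths = ep.true_measures(power_dataset, min_reports=50)
        rng = np.random.default_rng(11)
        cov = pd.DataFrame({"noise": rng.normal(0, 1, len(truths))},
                           index=list(truths))
        table = ep.effect_benchmarks(truths, cov)
        assert abs(table.loc["mean", "noise"]) < 0.35

    def test_four_person_hand_table(self):
        truths = pd.DataFrame({"mean": [1.0, 2.0, 3.0, 4.0]},
                              index=["a", "b", "c", "d"])
        cov = pd.DataFrame({"age": [2.0, 1.0, 4.0, 3.0]},
                           index=["a", "b", "c", "d"])
        table = ep.effect_benchmarks(truths, cov)
        expected = np.corrcoef([1, 2, 3, 4], [2, 1, 4, 3])[0, 1]
        assert table.loc["mean", "age"] == pytest.approx(expected)

    def test_insufficient_overlap_is_nan(self):
        truths = pd.DataFrame({"mean": [1.0, 2.0]}, index=["a", "b"])
        cov = pd.DataFrame({"age": [1.0, 2.0]}, index=["a", "b"])
        assert math.isnan(ep.effect_benchmarks(truths, cov).loc["mean", "age"])
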