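"""Composite likelihood, fixed-breakpoint fits and the stepwise search."""

import itertools

import numpy as np
import pytest

from stepsfs import (
    BreakpointModel,
    Demography,
    SiteFrequencySpectrum,
    composite_log_likelihood,
    expected_sfs,
    fit_fixed_breakpoints,
    fold,
    history_to_steps,
    level_start_times,
    stepwise_fit,
    watterson_theta,
)

U = 1e-8


def sfs_from_expectations(model: BreakpointModel, u, L, folded=False):
    """Integer SFS equal to the (integer-valued) model expectations."""
    exp = expected_sfs(model.expand(), u, L, folded=folded)
    counts = np.round(exp.counts)
    assert np.allclose(counts, exp.counts, atol=1e-6), "pick uL making mu integral"
    return SiteFrequencySpectrum(
        n=model.n, L=int(L), counts=counts.astype(np.int64), folded=folded
    )


class TestBreakpointModel:
    def test_group_assignment_splits_at_breakpoint(self):
        # breakpoint b: levels i > b in one group, i <= b in the next
        m = BreakpointModel(n=6, breakpoints=(4,), group_sizes=np.array([1.0, 2.0]))
        d = m.expand()
        assert [d.size_at_level(k) for k in (6, 5, 4, 3, 2)] == [1, 1, 2, 2, 2]

    def test_two_breakpoints_three_groups(self):
        m = BreakpointModel(
            n=8, breakpoints=(6, 3), group_sizes=np.array([1.0, 2.0, 3.0])
        )
        d = m.expand()
        assert [d.size_at_level(k) for k in range(8, 1, -1)] == [1, 1, 2, 2, 2, 3, 3]

    @pytest.mark.parametrize(
        "bps,sizes",
        [((1,), [1.0, 2.0]), ((5,), [1.0, 2.0]), ((3, 4), [1, 2, 3]), ((), [1, 2])],
    )
    def test_invalid_models_rejected(self, bps, sizes):
        with pytest.raises(ValueError):
            BreakpointModel(n=5, breakpoints=bps, group_sizes=np.array(sizes, float))


class TestCompositeLikelihood:
    def test_score_zero_at_saturation(self):
        # counts equal to expectations -> gradient wrt each group size is 0
        model = BreakpointModel(
            n=4, breakpoints=(3, 2), group_sizes=np.array([1000.0, 2000.0, 4000.0])
        )
        L = 7.5e7  # 4uL = 3 makes every expectation an integer
        sfs = sfs_from_expectations(model, U, L)
        eps = 1e-4
        for g in range(3):
            lls = []
            for sign in (+1, -1):
                perturbed = model.group_sizes.copy()
                perturbed[g] *= 1 + sign * eps
                bumped = BreakpointModel(
                    n=4, breakpoints=(3, 2), group_sizes=perturbed
                )
                lls.append(composite_log_likelihood(sfs, bumped, U))
            deriv = (lls[0] - lls[1]) / (2 * model.group_sizes[g] * eps)
            assert abs(deriv) < 1e-6

    def test_u_times_N_identifiability(self):
        sfs = SiteFrequencySpectrum(n=5, L=10**6, counts=np.array([50, 22, 18, 9]))
        m1 = BreakpointModel(n=5, breakpoints=(), group_sizes=np.array([2000.0]))
        m2 = BreakpointModel(n=5, breakpoints=(), group_sizes=np.array([1000.0]))
        assert composite_log_likelihood(sfs, m1, U) == pytest.approx(
            composite_log_likelihood(sfs, m2, 2 * U), rel=1e-12
        )

    def test_excluded_class_drops_out(self):
        counts_a = np.array([50, 22, 18, 9])
        counts_b = counts_a.copy()
        counts_b[0] = 999  # different singleton count
        m = BreakpointModel(n=5, breakpoints=(), group_sizes=np.array([1500.0]))
        lls = [
            composite_log_likelihood(
                SiteFrequencySpectrum(
                    n=5, L=10**6, counts=c, excluded_classes=frozenset({1})
                ),
                m,
                U,
            )
            for c in (counts_a, counts_b)
        ]
        assert lls[0] == lls[1]

    def test_monomorphic_switch_changes_value(self):
        sfs = SiteFrequencySpectrum(n=5, L=10**6, counts=np.array([50, 22, 18, 9]))
        m = BreakpointModel(n=5, breakpoints=(), group_sizes=np.array([1500.0]))
        without = composite_log_likelihood(sfs, m, U)
        with_mono = composite_log_likelihood(sfs, m, U, include_monomorphic=True)
        assert with_mono != without


class TestFixedBreakpointFit:
    def test_zero_breakpoints_equals_watterson(self):
        sfs = SiteFrequencySpectrum(n=4, L=10**6, counts=np.array([70, 25, 15]))
        fit = fit_fixed_breakpoints(sfs, (), U)
        assert fit.converged
        assert fit.model.group_sizes[0] == pytest.approx(1500.0, rel=1e-8)
        assert watterson_theta(sfs, U)["Ne_hat"] == pytest.approx(1500.0)

    def test_noiseless_one_breakpoint_inversion(self):
        # 4uL = 2520 makes all n=10 expectations integers
        truth = BreakpointModel(
            n=10, breakpoints=(5,), group_sizes=np.array([1000.0, 10000.0])
        )
        L = 2520.0 / (4 * U)
        sfs = sfs_from_expectations(truth, U, L)
        fit = fit_fixed_breakpoints(sfs, (5,), U)
        assert fit.converged
        assert np.allclose(fit.model.group_sizes, truth.group_sizes, rtol=1e-6)

    def test_noiseless_two_breakpoint_inversion(self):
        truth = BreakpointModel(
            n=10, breakpoints=(7, 4), group_sizes=np.array([500.0, 5000.0, 2000.0])
        )
        L = 2520.0 / (4 * U)
        sfs = sfs_from_expectations(truth, U, L)
        fit = fit_fixed_breakpoints(sfs, (7, 4), U)
        assert fit.converged
        assert np.allclose(fit.model.group_sizes, truth.group_sizes, rtol=1e-6)

    def test_zero_count_class_is_finite(self):
        sfs = SiteFrequencySpectrum(n=5, L=10**5, counts=np.array([30, 0, 5, 2]))
        fit = fit_fixed_breakpoints(sfs, (3,), U)
        assert fit.converged and np.isfinite(fit.log_likelihood)

    def test_grid_search_oracle_on_noiseless_sfs(self):
        # dense 2-D grid around the optimum cannot beat the Newton fit
        rng = np.random.default_rng(12)
        for _ in range(5):
            sizes = rng.uniform(500, 5000, size=2)
            truth = BreakpointModel(n=8, breakpoints=(4,), group_sizes=sizes)
            exp = expected_sfs(truth.expand(), U, 1e7).counts
            sfs = SiteFrequencySpectrum(
                n=8, L=10**7, counts=np.round(exp).astype(np.int64)
            )
            fit = fit_fixed_breakpoints(sfs, (4,), U)
            grid = sizes[:, None] * (1 + np.linspace(-0.02, 0.02, 41))[None, :]
            best_grid = max(
                composite_log_likelihood(
                    sfs,
                    BreakpointModel(
                        n=8, breakpoints=(4,), group_sizes=np.array([a, b])
                    ),
                    U,
                )
                for a, b in itertools.product(grid[0], grid[1])
            )
            assert fit.log_likelihood >= best_grid - 1e-6


class TestStepwise:
    def test_constant_truth_keeps_zero_breakpoints(self):
        model = BreakpointModel(n=6, breakpoints=(), group_sizes=np.array([3000.0]))
        L = 60.0 / (4 * U)  # 4uL = 60: constant-N expectations 60*3000/r... integral
        exp = expected_sfs(model.expand(), U, L).counts
        sfs = SiteFrequencySpectrum(n=6, L=int(L), counts=np.round(exp).astype(int))
        fit = stepwise_fit(sfs, U)
        assert fit.model.breakpoints == ()
        assert fit.model.group_sizes[0] == pytest.approx(3000.0, rel=1e-3)

    def test_selects_true_breakpoint_count_and_levels(self):
        truth = BreakpointModel(
            n=10, breakpoints=(5,), group_sizes=np.array([1000.0, 10000.0])
        )
        L = 2520.0 / (4 * U)
        sfs = sfs_from_expectations(truth, U, L)
        greedy = stepwise_fit(sfs, U, mode="greedy")
        exhaustive = stepwise_fit(sfs, U, mode="exhaustive")
        assert greedy.model.breakpoints == (5,)
        assert exhaustive.model.breakpoints == (5,)
        assert np.allclose(greedy.model.group_sizes, truth.group_sizes, rtol=1e-4)

    def test_accepted_steps_gain_at_least_threshold(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(
            expected_sfs(
                Demography.from_levels(
                    8, {k: (800.0 if k > 4 else 6000.0) for k in range(2, 9)}
                ),
                U,
                1e7,
            ).counts
        )
        sfs = SiteFrequencySpectrum(n=8, L=10**7, counts=counts)
        fit = stepwise_fit(sfs, U, threshold=2.0)
        gains = np.diff(fit.ll_trace)
        assert np.all(gains >= 2.0)
        assert np.all(np.diff(fit.ll_trace) >= 0)

    def test_folded_fit_uses_folded_means(self):
        truth = BreakpointModel(
            n=10, breakpoints=(5,), group_sizes=np.array([1000.0, 10000.0])
        )
        L = 2520.0 / (4 * U)
        unfolded = sfs_from_expectations(truth, U, L)
        folded = fold(unfolded)
        fit = fit_fixed_breakpoints(folded, (5,), U)
        assert fit.converged
        assert np.allclose(fit.model.group_sizes, truth.group_sizes, rtol=1e-6)

    def test_max_breakpoints_caps_model_size(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(
            expected_sfs(
                Demography(n=12, sizes=rng.uniform(500, 20000, 11)), U, 1e7
            ).counts
        )
        sfs = SiteFrequencySpectrum(n=12, L=10**7, counts=counts)
        fit = stepwise_fit(sfs, U, max_breakpoints=1)
        assert len(fit.model.breakpoints) <= 1

    def test_exclude_argument_ignores_singletons(self):
        base = np.array([50, 22, 18, 9])
        different = base.copy()
        different[0] = 500
        fits = [
            stepwise_fit(SiteFrequencySpectrum(n=5, L=10**6, counts=c), U, exclude={1})
            for c in (base, different)
        ]
        assert np.allclose(fits[0].model.group_sizes, fits[1].model.group_sizes)


class TestStepPlot:
    def test_constant_fit_single_step(self):
        sfs = SiteFrequencySpectrum(n=4, L=10**6, counts=np.array([70, 25, 15]))
        fit = fit_fixed_breakpoints(sfs, (), U)
        assert history_to_steps(fit) == [(0.0, pytest.approx(1500.0, rel=1e-8))]

    def test_one_breakpoint_start_time_hand_sum(self):
        truth = BreakpointModel(
            n=10, breakpoints=(5,), group_sizes=np.array([1000.0, 10000.0])
        )
        L = 2520.0 / (4 * U)
        fit = fit_fixed_breakpoints(sfs_from_expectations(truth, U, L), (5,), U)
        steps = history_to_steps(fit)
        expected_start = sum(
            4 * fit.demography.size_at_level(j) / (j * (j - 1)) for j in range(6, 11)
        )
        assert steps[1][0] == pytest.approx(expected_start, rel=1e-9)
        times = [t for t, _ in steps]
        assert all(b > a for a, b in zip(times, times[1:]))
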