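"""Composite Poisson likelihood and stepwise breakpoint search.

The inference model pools coalescent levels into contiguous groups,
each sharing one effective size.  A breakpoint at level b splits the
levels into "i > b" and "i <= b"; m breakpoints give m+1 groups.  The
per-class expected counts mu_r are *linear* in the group sizes, so the
composite Poisson log-likelihood

    l = sum_r [ G_r ln mu_r - mu_r ]        (log-factorials dropped)

is concave in them; the maximiser is found by quasi-Newton ascent on
log sizes (positivity for free) with a Newton polish.  The search over
breakpoints is stepwise: start from the constant-size model (whose
MLE is Watterson's estimator), add one breakpoint per iteration, and
stop when the log-likelihood gain drops below a threshold (default
2.0, the AIC-flavoured rule).  Greedy mode keeps accepted breakpoints
and tries each unused level; exhaustive mode re-evaluates all
positions each iteration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .expectations import Demography, level_start_times, level_weight_matrix
from .sfs import SiteFrequencySpectrum, harmonic_number, watterson_theta

__all__ = [
    "BreakpointModel",
    "FitResult",
    "composite_log_likelihood",
    "fit_fixed_breakpoints",
    "stepwise_fit",
    "history_to_steps",
]

GRAD_TOL = 1e-8  # projected-gradient criterion, relative to |l|
MAX_ITER = 200


@dataclass(frozen=True)
class BreakpointModel:
    """A partition of levels n..2 into groups sharing one Ne each.

    ``breakpoints`` is a strictly decreasing tuple of levels in
    {2..n-1}; breakpoint b assigns levels i > b to one group and
    i <= b to the next.  ``group_sizes`` runs from the tip group
    (containing level n) to the root group (containing level 2).
    """

    n: int
    breakpoints: tuple[int, ...]
    group_sizes: np.ndarray

    def __post_init__(self) -> None:
        bps = tuple(int(b) for b in self.breakpoints)
        if any(not 2 <= b <= self.n - 1 for b in bps):
            raise ValueError(f"breakpoints must lie in 2..{self.n - 1}: {bps}")
        if any(a <= b for a, b in zip(bps, bps[1:])):
            raise ValueError(f"breakpoints must be strictly decreasing: {bps}")
        sizes = np.asarray(self.group_sizes, dtype=float)
        if sizes.shape != (len(bps) + 1,):
            raise ValueError(
                f"{len(bps)} breakpoints need {len(bps) + 1} group sizes"
            )
        if np.any(sizes <= 0) or not np.all(np.isfinite(sizes)):
            raise ValueError("group sizes must be positive and finite")
        sizes.setflags(write=False)
        object.__setattr__(self, "breakpoints", bps)
        object.__setattr__(self, "group_sizes", sizes)

    @property
    def n_groups(self) -> int:
        return len(self.breakpoints) + 1

    def group_of_level(self) -> np.ndarray:
        """Group index for each level 2..n (index k-2)."""
        groups = np.zeros(self.n - 1, dtype=np.int64)
        levels = np.arange(2, self.n + 1)
        for g, b in enumerate(self.breakpoints):
            groups[levels <= b] = g + 1
        return groups

    def expand(self) -> Demography:
        """Per-level demography with each level at its group's size."""
        return Demography(n=self.n, sizes=self.group_sizes[self.group_of_level()])


@dataclass(frozen=True)
class FitResult:
    """A maximised breakpoint model and its provenance."""

    model: BreakpointModel
    log_likelihood: float
    demography: Demography
    step_plot: list[tuple[float, float]]
    n_iterations: int
    converged: bool
    ll_trace: tuple[float, ...] = ()


def _design_matrix(
    sfs: SiteFrequencySpectrum, model_breakpoints, u: float, n: int, L: float
) -> np.ndarray:
    """A with mu = A @ group_sizes for the given breakpoint set."""
    weights = level_weight_matrix(n)  # (n-1 classes, n-1 levels)
    r = np.arange(1, n)
    per_level = (4.0 * u * L / r)[:, None] * weights  # coefficient of N_k in mu_r
    model = BreakpointModel(
        n=n, breakpoints=model_breakpoints, group_sizes=np.ones(len(model_breakpoints) + 1)
    )
    groups = model.group_of_level()
    n_groups = model.n_groups
    A = np.zeros((n - 1, n_groups))
    for g in range(n_groups):
        A[:, g] = per_level[:, groups == g].sum(axis=1)
    if sfs.folded:
        half = n // 2
        folded = A[:half].copy()
        for rr in range(1, half + 1):
            if n - rr != rr:
                folded[rr - 1] += A[n - rr - 1]
        A = folded
    return A


def _likelihood_rows(sfs: SiteFrequencySpectrum):
    """Observed counts and row mask after class exclusion."""
    counts = sfs.counts.astype(float)
    keep = np.array(
        [r not in sfs.excluded_classes for r in range(1, sfs.n_classes + 1)]
    )
    return counts[keep], keep


def composite_log_likelihood(
    sfs: SiteFrequencySpectrum,
    model: BreakpointModel,
    u: float,
    include_monomorphic: bool = False,
) -> float:
    """Composite Poisson log-likelihood of an SFS under a model.

    Sums G_r ln mu_r - mu_r over non-excluded polymorphic classes; by
    default the monomorphic class does not enter, so L acts only
    through the means.  ``include_monomorphic=True`` adds a Poisson
    term for G_0 with mean L minus the summed polymorphic means (a
    sensitivity switch).  Returns -inf if any retained class has
    mu_r = 0 with G_r > 0.
    """
    if model.n != sfs.n:
        raise ValueError(f"model n={model.n} != sfs n={sfs.n}")
    A, counts, offset = _likelihood_system(
        sfs, model.breakpoints, u, include_monomorphic
    )
    mu = A @ model.group_sizes + offset
    return _poisson_ll(counts, mu)


def _likelihood_system(sfs, breakpoints, u, include_monomorphic):
    """(A, counts, offset) with mu = A @ sizes + offset over retained rows."""
    A_full = _design_matrix(sfs, breakpoints, u, sfs.n, sfs.L)
    counts, keep = _likelihood_rows(sfs)
    A = A_full[keep]
    offset = np.zeros(A.shape[0])
    if include_monomorphic:
        # G_0 row: mu_0 = L - sum of all polymorphic means
        A = np.vstack([A, -A_full.sum(axis=0)])
        counts = np.append(counts, float(sfs.monomorphic))
        offset = np.append(offset, float(sfs.L))
    return A, counts, offset


def _poisson_ll(counts: np.ndarray, mu: np.ndarray) -> float:
    bad = (mu <= 0) & (counts > 0)
    if np.any(bad):
        return -np.inf
    pos = mu > 0
    return float(np.sum(counts[pos] * np.log(mu[pos])) - np.sum(mu))


def fit_fixed_breakpoints(
    sfs: SiteFrequencySpectrum,
    breakpoints,
    u: float,
    init=None,
    max_iter: int = MAX_ITER,
    include_monomorphic: bool = False,
) -> FitResult:
    """Maximise the composite likelihood over group sizes.

    The likelihood is concave in the (linear) group sizes; the ascent
    runs on log sizes (L-BFGS-B then Newton polish) and must reach a
    projected-gradient norm below ``GRAD_TOL * max(1, |l|)``, else the
    result is flagged ``converged=False``.  Group sizes start at the
    Watterson estimate unless ``init`` is given, and are bounded below
    by 1e-6 times that estimate.
    """
    breakpoints = tuple(int(b) for b in breakpoints)
    n, L = sfs.n, sfs.L
    n_groups = len(breakpoints) + 1
    A, counts, offset = _likelihood_system(sfs, breakpoints, u, include_monomorphic)

    ne_w = watterson_theta(sfs, u)["Ne_hat"]
    if not ne_w or ne_w <= 0:
        ne_w = 1.0
    floor = 1e-6 * ne_w
    x0 = np.full(n_groups, float(ne_w)) if init is None else np.asarray(init, float)
    x0 = np.maximum(x0, floor)

    def neg_ll_grad(theta):
        sizes = np.exp(theta)
        mu = A @ sizes + offset
        if np.any(mu <= 0):
            return np.inf, np.zeros_like(theta)
        ll = np.sum(counts * np.log(mu)) - np.sum(mu)
        grad_sizes = A.T @ (counts / mu - 1.0)
        return -ll, -(grad_sizes * sizes)

    lo, hi = np.log(floor), np.log(1e9 * ne_w)
    res = scipy.optimize.minimize(
        neg_ll_grad,
        np.log(x0),
        jac=True,
        method="L-BFGS-B",
        bounds=[(lo, hi)] * n_groups,
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-12},
    )
    theta = res.x
    n_iter = res.nit

    def projected_grad(theta, grad):
        proj = grad.copy()
        proj[(theta <= lo + 1e-12) & (grad > 0)] = 0.0
        proj[(theta >= hi - 1e-12) & (grad < 0)] = 0.0
        return proj

    # Newton polish in log space (exact Hessian of the concave problem)
    converged = False
    for _ in range(50):
        sizes = np.exp(theta)
        mu = A @ sizes + offset
        ll = np.sum(counts * np.log(mu)) - np.sum(mu)
        grad_sizes = A.T @ (counts / mu - 1.0)
        grad = -grad_sizes * sizes  # gradient of -ll wrt theta
        if np.linalg.norm(projected_grad(theta, grad)) <= GRAD_TOL * max(1.0, abs(ll)):
            converged = True
            break
        As = A * sizes  # d mu / d theta
        H = As.T @ ((counts / mu**2)[:, None] * As) - np.diag(grad_sizes * sizes)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(n_groups), -grad)
        except np.linalg.LinAlgError:
            step = -grad
        # backtracking on -ll
        scale = 1.0
        for _ in range(40):
            trial = np.clip(theta + scale * step, lo, hi)
            mu_t = A @ np.exp(trial) + offset
            if np.any(mu_t <= 0):
                scale *= 0.5
                continue
            ll_t = np.sum(counts * np.log(mu_t)) - np.sum(mu_t)
            if ll_t >= ll - 1e-14 * max(1.0, abs(ll)):
                break
            scale *= 0.5
        else:
            break
        theta = trial
        n_iter += 1

    sizes = np.exp(theta)
    mu = A @ sizes + offset
    ll = float(np.sum(counts * np.log(mu)) - np.sum(mu))
    model = BreakpointModel(n=n, breakpoints=breakpoints, group_sizes=sizes)
    demog = model.expand()
    return FitResult(
        model=model,
        log_likelihood=ll,
        demography=demog,
        step_plot=history_to_steps_from(model, demog),
        n_iterations=int(n_iter),
        converged=bool(converged),
    )


def stepwise_fit(
    sfs: SiteFrequencySpectrum,
    u: float,
    threshold: float = 2.0,
    mode: str = "greedy",
    max_breakpoints: int | None = None,
    exclude=(),
    seed=None,
    include_monomorphic: bool = False,
) -> FitResult:
    """Stepwise breakpoint search with a log-likelihood stopping rule.

    Starts from the constant-size model and adds one breakpoint per
    iteration; a step is accepted only if it improves the
    log-likelihood by at least ``threshold``.  ``mode='greedy'`` adds
    one level at a time to the accepted set (re-optimising all sizes
    jointly); ``mode='exhaustive'`` re-evaluates every breakpoint
    combination of the new cardinality.  Equal-likelihood candidates
    tie-break to the smallest (most ancient) level.  Fully
    deterministic; ``seed`` is accepted for interface symmetry only.
    """
    if mode not in ("greedy", "exhaustive"):
        raise ValueError(f"mode must be greedy|exhaustive, got {mode!r}")
    if exclude:
        sfs = sfs.with_excluded(set(sfs.excluded_classes) | set(exclude))
    n = sfs.n
    cap = n - 2 if max_breakpoints is None else min(max_breakpoints, n - 2)

    current = fit_fixed_breakpoints(
        sfs, (), u, include_monomorphic=include_monomorphic
    )
    trace = [current.log_likelihood]
    candidates = list(range(2, n))

    for m in range(1, cap + 1):
        if mode == "greedy":
            trial_sets = [
                tuple(sorted(current.model.breakpoints + (b,), reverse=True))
                for b in sorted(candidates)
                if b not in current.model.breakpoints
            ]
        else:
            trial_sets = [
                tuple(sorted(combo, reverse=True))
                for combo in itertools.combinations(sorted(candidates), m)
            ]
        best = None
        for bps in trial_sets:
            fit = fit_fixed_breakpoints(
                sfs,
                bps,
                u,
                init=_warm_start(current.model, bps),
                include_monomorphic=include_monomorphic,
            )
            if best is None or fit.log_likelihood > best.log_likelihood + 1e-9:
                best = fit
        if best is None:
            break
        if best.log_likelihood - current.log_likelihood >= threshold:
            current = best
            trace.append(current.log_likelihood)
        else:
            break

    return FitResult(
        model=current.model,
        log_likelihood=current.log_likelihood,
        demography=current.demography,
        step_plot=current.step_plot,
        n_iterations=current.n_iterations,
        converged=current.converged,
        ll_trace=tuple(trace),
    )


def _warm_start(previous: BreakpointModel, breakpoints) -> np.ndarray:
    """Seed new group sizes from the previous model's per-level sizes."""
    demog = previous.expand()
    groups = BreakpointModel(
        n=previous.n,
        breakpoints=breakpoints,
        group_sizes=np.ones(len(breakpoints) + 1),
    ).group_of_level()
    sizes = np.empty(len(breakpoints) + 1)
    for g in range(len(sizes)):
        sizes[g] = demog.sizes[groups == g].mean()
    return sizes


def history_to_steps_from(model: BreakpointModel, demography: Demography):
    """(start_time, Ne) pairs at each group boundary.

    The first step starts at time 0 with the tip group's size; each
    breakpoint b starts a new step at tau_b (the expected start of
    the level-b interval under the fitted sizes).
    """
    times = level_start_times(demography)
    steps = [(0.0, float(model.group_sizes[0]))]
    for g, b in enumerate(model.breakpoints):
        steps.append((times[b], float(model.group_sizes[g + 1])))
    return steps


def history_to_steps(fit: FitResult):
    """Step-plot of a fit: list of (start_generation, Ne) pairs."""
    return history_to_steps_from(fit.model, fit.demography)
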