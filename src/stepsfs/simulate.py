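"""Coalescent simulator: genealogies, SFS samples and mutation ages.

This is the Monte-Carlo oracle for the closed-form machinery and the
synthetic-data source for recovery experiments.  Two demography modes:

* level-indexed — exactly the inference model: while k lineages
  remain, the waiting time to the next coalescence is exponential
  with mean 4 N_k / (k (k-1)) generations;
* time-indexed — piecewise-constant N(t) epochs on the generation
  axis, with the pairwise coalescence rate k(k-1)/(4 N(t)) rescaled
  across epoch boundaries (the shape of standard ms-style scenarios).

Mutations follow the infinite-sites model: the count on a branch is
Poisson with mean u * L * branch length, so per-class counts can be
drawn from aggregated per-class branch lengths without touching
individual sites.  Mutation positions along a branch are uniform,
which is what makes the n=2 closed form E[A_1] = 2N hold.

No recombination, selection or population structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expectations import Demography
from .sfs import SiteFrequencySpectrum

__all__ = [
    "SimDemography",
    "MutationRecord",
    "Genealogy",
    "simulate_genealogy",
    "simulate_sfs",
    "simulate_mutation_ages",
    "simulate_class_lengths",
    "scenario_presets",
]


@dataclass(frozen=True)
class SimDemography:
    """Either a level-indexed demography or time-indexed epochs.

    Exactly one of ``levels`` (a :class:`~stepsfs.expectations.Demography`)
    or ``epochs`` (list of ``(start_generation, N)`` with starts strictly
    increasing from 0) is set.
    """

    levels: Demography | None = None
    epochs: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if (self.levels is None) == (self.epochs is None):
            raise ValueError("set exactly one of levels / epochs")
        if self.epochs is not None:
            epochs = tuple((float(t), float(N)) for t, N in self.epochs)
            starts = [t for t, _ in epochs]
            if starts[0] != 0.0:
                raise ValueError("first epoch must start at generation 0")
            if any(b <= a for a, b in zip(starts, starts[1:])):
                raise ValueError("epoch starts must be strictly increasing")
            if any(N <= 0 for _, N in epochs):
                raise ValueError("all epoch sizes must be positive")
            object.__setattr__(self, "epochs", epochs)

    @property
    def mode(self) -> str:
        return "level" if self.levels is not None else "time"

    def size_at_time(self, t, realized_level_times=None):
        """N(t) along the population history (vectorised over t).

        For a level-indexed demography the size at a time depends on
        the realized coalescence times of the genealogy in question;
        pass the per-level interval boundaries for that tree.
        """
        t = np.asarray(t, dtype=float)
        if self.epochs is not None:
            starts = np.array([s for s, _ in self.epochs])
            sizes = np.array([N for _, N in self.epochs])
        else:
            if realized_level_times is None:
                raise ValueError(
                    "level-indexed N(t) needs the realized level times"
                )
            starts, sizes = realized_level_times
        idx = np.searchsorted(starts, t, side="right") - 1
        return sizes[np.clip(idx, 0, len(sizes) - 1)]


@dataclass(frozen=True)
class MutationRecord:
    """One simulated mutation: class, realized age, and int_0^age N(s) ds.

    ``tree`` indexes the genealogy the mutation arose on; mutations on
    one genealogy share its coalescence times and are correlated, so
    summaries cluster on it.
    """

    r: int
    age: float
    n_integral: float
    tree: int = -1


@dataclass
class Genealogy:
    """Branches of one simulated tree.

    Arrays are parallel over branches: descendant count, start time
    (closer to the present) and end time (the coalescence that absorbs
    the branch).  ``level_starts``/``level_sizes`` give the realized
    piecewise N(t) this tree experienced (used for level-indexed
    n_integrals).
    """

    n: int
    branch_r: np.ndarray
    branch_start: np.ndarray
    branch_end: np.ndarray
    level_starts: np.ndarray = field(repr=False, default=None)
    level_sizes: np.ndarray = field(repr=False, default=None)

    @property
    def total_length(self) -> float:
        return float(np.sum(self.branch_end - self.branch_start))

    def class_lengths(self) -> np.ndarray:
        """Total branch length carrying each class r = 1..n-1."""
        lengths = np.zeros(self.n - 1)
        np.add.at(lengths, self.branch_r - 1, self.branch_end - self.branch_start)
        return lengths


def _level_waiting_times(n, demography: SimDemography, rng) -> np.ndarray:
    """Realized interval lengths for levels n..2 (in that order)."""
    ks = np.arange(n, 1, -1)
    if demography.mode == "level":
        if demography.levels.n != n:
            raise ValueError(
                f"level-indexed demography has n={demography.levels.n}, "
                f"sample has n={n}"
            )
        means = 4.0 * demography.levels.sizes[ks - 2] / (ks * (ks - 1))
        return rng.exponential(means)
    # time-indexed: integrate the hazard k(k-1)/(4N(t)) through epochs
    starts = np.array([s for s, _ in demography.epochs])
    sizes = np.array([N for _, N in demography.epochs])
    times = np.empty(n - 1)
    t = 0.0
    for i, k in enumerate(ks):
        target = rng.exponential(1.0)
        rate_scale = k * (k - 1) / 4.0
        while True:
            epoch = np.searchsorted(starts, t, side="right") - 1
            rate = rate_scale / sizes[epoch]
            boundary = starts[epoch + 1] if epoch + 1 < len(starts) else np.inf
            hazard_to_boundary = rate * (boundary - t)
            if target <= hazard_to_boundary:
                t += target / rate
                break
            target -= hazard_to_boundary
            t = boundary
        times[i] = t
        t = times[i]
    return np.diff(np.concatenate([[0.0], times])) if demography.mode == "time" else times


def simulate_genealogy(n: int, demography: SimDemography, seed) -> Genealogy:
    """Simulate one Kingman genealogy; deterministic given the seed.

    ``seed`` may be an int or a numpy Generator.
    """
    if n < 2:
        raise ValueError("need n >= 2 lineages")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    waits = _level_waiting_times(n, demography, rng)

    # track active lineages: descendant count and birth time of each
    desc = list(np.ones(n, dtype=np.int64))
    birth = [0.0] * n
    branch_r = np.empty(2 * n - 2, dtype=np.int64)
    branch_start = np.empty(2 * n - 2)
    branch_end = np.empty(2 * n - 2)
    t = 0.0
    out = 0
    for wait, k in zip(waits, range(n, 1, -1)):
        t += wait
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        for idx in (i, j):
            branch_r[out] = desc[idx]
            branch_start[out] = birth[idx]
            branch_end[out] = t
            out += 1
        desc[i] += desc[j]
        birth[i] = t
        del desc[j], birth[j]

    if demography.mode == "level":
        level_bounds = np.concatenate([[0.0], np.cumsum(waits)[:-1]])
        level_sizes = demography.levels.sizes[np.arange(n, 1, -1) - 2]
    else:
        level_bounds = np.array([s for s, _ in demography.epochs])
        level_sizes = np.array([N for _, N in demography.epochs])
    return Genealogy(
        n=n,
        branch_r=branch_r,
        branch_start=branch_start,
        branch_end=branch_end,
        level_starts=level_bounds,
        level_sizes=level_sizes,
    )


def simulate_class_lengths(
    n: int, demography: SimDemography, reps: int, seed
) -> np.ndarray:
    """Per-class total branch lengths for ``reps`` genealogies.

    Shape (reps, n-1); row means times u*L estimate the expected SFS.
    """
    rng = np.random.default_rng(seed)
    out = np.empty((reps, n - 1))
    for i in range(reps):
        out[i] = simulate_genealogy(n, demography, rng).class_lengths()
    return out


def simulate_sfs(
    n: int,
    demography: SimDemography,
    u: float,
    L: int,
    seed,
    num_genealogies: int = 1,
) -> SiteFrequencySpectrum:
    """Simulate an unfolded SFS under the infinite-sites model.

    With ``num_genealogies`` > 1 the L sites are split evenly across
    independent genealogies (a proxy for free recombination between
    blocks), which is what real multi-locus spectra look like; the
    expectation is unchanged, only the sampling variance shrinks.
    Raises if the polymorphic total exceeds L (infinite sites broken
    at this mutation pressure).
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros(n - 1, dtype=np.int64)
    sites = np.full(num_genealogies, L // num_genealogies, dtype=np.int64)
    sites[: L % num_genealogies] += 1
    for block_sites in sites:
        lengths = simulate_genealogy(n, demography, rng).class_lengths()
        counts += rng.poisson(u * block_sites * lengths)
    if counts.sum() > L:
        raise ValueError(
            f"simulated {int(counts.sum())} polymorphic sites > L={L}; "
            "infinite-sites assumption violated at this u*L"
        )
    return SiteFrequencySpectrum(n=n, L=L, counts=counts, folded=False)


def _piecewise_integral(age: float, starts: np.ndarray, sizes: np.ndarray) -> float:
    """int_0^age N(s) ds for a piecewise-constant N with given breaks."""
    total = 0.0
    for i, (s, N) in enumerate(zip(starts, sizes)):
        if age <= s:
            break
        end = starts[i + 1] if i + 1 < len(starts) else np.inf
        total += N * (min(age, end) - s)
    return total


def simulate_mutation_ages(
    n: int,
    demography: SimDemography,
    u: float,
    reps: int,
    seed,
    L: int = 1,
) -> list[MutationRecord]:
    """Mutation-age records over ``reps`` genealogies.

    Each branch receives Poisson(u * L * length) mutations placed
    uniformly along it; age is the time coordinate of the mutation
    (generations before present) and ``n_integral`` the exact
    integral of the (realized) population-size path over [0, age].
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[MutationRecord] = []
    for tree in range(reps):
        g = simulate_genealogy(n, demography, rng)
        lengths = g.branch_end - g.branch_start
        n_mut = rng.poisson(u * L * lengths)
        for b in np.nonzero(n_mut)[0]:
            for _ in range(n_mut[b]):
                age = rng.uniform(g.branch_start[b], g.branch_end[b])
                records.append(
                    MutationRecord(
                        r=int(g.branch_r[b]),
                        age=float(age),
                        n_integral=_piecewise_integral(
                            age, g.level_starts, g.level_sizes
                        ),
                        tree=tree,
                    )
                )
    return records


def mutation_age_summary(records: list[MutationRecord], n: int) -> dict:
    """Per-class mean age and mean integral, with cluster-robust SEs.

    Mutations on the same genealogy share its coalescence times, so
    standard errors come from the ratio estimator over per-genealogy
    (sum, count) pairs rather than treating mutations as independent.
    """
    out = {}
    by_class: dict[int, list[MutationRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.r, []).append(rec)
    for r in range(1, n):
        recs = by_class.get(r, [])
        if not recs:
            continue
        ages = np.array([m.age for m in recs])
        integrals = np.array([m.n_integral for m in recs])
        out[r] = {
            "count": len(recs),
            "mean_age": float(ages.mean()),
            "se_age": _cluster_se(recs, ages),
            "mean_integral": float(integrals.mean()),
            "se_integral": _cluster_se(recs, integrals),
        }
    return out


def _cluster_se(recs: list[MutationRecord], values: np.ndarray) -> float:
    """SE of the mean of ``values`` clustered by genealogy.

    Ratio-estimator variance: with per-tree sums s_i and counts c_i,
    se^2 = sum_i (s_i - mean * c_i)^2 / (sum_i c_i)^2.
    """
    trees = np.array([m.tree for m in recs])
    if len(recs) < 2:
        return np.inf
    order = np.argsort(trees, kind="stable")
    trees, values = trees[order], values[order]
    _, start = np.unique(trees, return_index=True)
    sums = np.add.reduceat(values, start)
    counts = np.diff(np.append(start, len(values)))
    mean = values.mean()
    resid = sums - mean * counts
    return float(np.sqrt(np.sum(resid**2)) / len(values))


def experienced_ne_oracle(records: list[MutationRecord], n: int) -> dict:
    """Per-class ratio (mean integral)/(mean age) with a cluster-robust SE.

    This is the Monte-Carlo counterpart of the experienced-Ne ratio of
    expectations; the SE comes from the ratio-estimator variance over
    per-genealogy sums.
    """
    out = {}
    by_class: dict[int, list[MutationRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.r, []).append(rec)
    for r, recs in sorted(by_class.items()):
        if len(recs) < 2:
            continue
        trees = np.array([m.tree for m in recs])
        ages = np.array([m.age for m in recs])
        integrals = np.array([m.n_integral for m in recs])
        order = np.argsort(trees, kind="stable")
        trees, ages, integrals = trees[order], ages[order], integrals[order]
        _, start = np.unique(trees, return_index=True)
        age_sums = np.add.reduceat(ages, start)
        int_sums = np.add.reduceat(integrals, start)
        ratio = integrals.sum() / ages.sum()
        resid = int_sums - ratio * age_sums
        se = np.sqrt(np.sum(resid**2)) / ages.sum()
        out[r] = {"ratio": float(ratio), "se": float(se), "count": len(recs)}
    return out


_PRESETS = {
    # time-indexed fixtures for tests and demos; N0 = 1000 reference size
    "constant": ((0.0, 10_000.0),),
    "two_epoch_decline": ((0.0, 1_000.0), (500.0, 10_000.0)),
    "two_epoch_expansion": ((0.0, 10_000.0), (500.0, 1_000.0)),
    "bottleneck": ((0.0, 10_000.0), (500.0, 1_000.0), (1_500.0, 10_000.0)),
}


def scenario_presets(name: str) -> SimDemography:
    """Named time-indexed demography fixtures.

    ``constant``: one epoch at N=10^4.  ``two_epoch_decline``: N
    drops tenfold to 10^3 at 500 generations ago (looking backwards,
    the older epoch is 10^4).  ``two_epoch_expansion``: the mirror
    image.  ``bottleneck``: tenfold crash between 500 and 1500
    generations ago with full recovery.
    """
    try:
        return SimDemography(epochs=_PRESETS[name])
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
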