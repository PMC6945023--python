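"""Closed-form expected SFS under level-indexed piecewise-constant Ne.

A genealogy of ``n`` samples passes through coalescent levels
``k = n, n-1, ..., 2`` (level k = the epoch with exactly k ancestral
lineages).  Each level is assigned its own effective population size
``N_k`` (diploid individuals), and the expected waiting time at level k
is ``4 N_k / (k (k-1))`` generations.  Averaging over all Kingman
topologies, the expected count of sites with the derived allele in r
copies is a weighted average of the N_k:

    E[G_r] = (4 u L / r) * sum_{k=2}^{n-r+1} w(n, r, k) * N_k,
    w(n, r, k) = C(n-k, r-1) / C(n-1, r),

with the weights for each r summing to one (hockey-stick identity).
For r = 1 this reduces to 4 u L times the arithmetic mean of
N_2..N_n; for constant N it reduces to the classic 4 N u L / r.

An alternative derivation route sums, per starting level k, the
expected number of order-r branch segments alive at k against the mean
size below k; :func:`expected_sfs_via_W` implements it as an
independent cross-check of the weighted-average form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .sfs import fold_counts

__all__ = [
    "Demography",
    "ExpectedSfs",
    "interval_time",
    "level_start_times",
    "level_weight",
    "level_weight_matrix",
    "expected_sfs",
    "expected_sfs_via_W",
]


@dataclass(frozen=True)
class Demography:
    """Per-level effective sizes N_k, k = 2..n.

    ``sizes[0]`` is N_2 (the last interval before the root) and
    ``sizes[-1]`` is N_n (the tip interval).  All sizes are in diploid
    individuals and must be positive and finite.
    """

    n: int
    sizes: np.ndarray  # index k-2 -> N_k

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        sizes = np.asarray(self.sizes, dtype=float)
        if sizes.shape != (self.n - 1,):
            raise ValueError(
                f"need one size per level 2..{self.n} "
                f"({self.n - 1} values), got shape {sizes.shape}"
            )
        if not np.all(np.isfinite(sizes)) or np.any(sizes <= 0):
            raise ValueError("all N_k must be positive and finite")
        sizes.setflags(write=False)
        object.__setattr__(self, "sizes", sizes)

    @classmethod
    def constant(cls, n: int, N: float) -> "Demography":
        return cls(n=n, sizes=np.full(n - 1, float(N)))

    @classmethod
    def from_levels(cls, n: int, mapping: dict) -> "Demography":
        """Build from a {level: N_k} mapping covering every level 2..n."""
        missing = set(range(2, n + 1)) - set(mapping)
        if missing:
            raise ValueError(f"missing levels: {sorted(missing)}")
        return cls(n=n, sizes=np.array([mapping[k] for k in range(2, n + 1)]))

    def size_at_level(self, k: int) -> float:
        if not 2 <= k <= self.n:
            raise ValueError(f"level {k} outside 2..{self.n}")
        return float(self.sizes[k - 2])

    def scaled(self, c: float) -> "Demography":
        return Demography(n=self.n, sizes=self.sizes * c)


@dataclass(frozen=True)
class ExpectedSfs:
    """Expected per-class site counts under a demography."""

    n: int
    counts: np.ndarray  # E[G_r] at counts[r-1] (or E[F_r] when folded)
    folded: bool
    u: float
    L: float


def interval_time(k: int, N_k: float) -> float:
    """Expected generations spent at level k: 4 N_k / (k (k-1))."""
    if k < 2:
        raise ValueError(f"level k must be >= 2, got {k}")
    return 4.0 * N_k / (k * (k - 1))


def level_start_times(demography: Demography) -> dict[int, float]:
    """Expected time before present at which each level begins.

    tau_k = sum_{j=k+1}^{n} 4 N_j / (j (j-1)); tau_n = 0.  Times grow
    as k decreases (deeper into the past).
    """
    n = demography.n
    times: dict[int, float] = {}
    acc = 0.0
    for k in range(n, 1, -1):
        times[k] = acc
        acc += interval_time(k, demography.size_at_level(k))
    return times


def _log_binom(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def level_weight(n: int, r: int, k: int) -> float:
    """Weight of N_k in E[G_r]: C(n-k, r-1) / C(n-1, r).

    Computed in log space so large n (hundreds of samples) cannot
    overflow.  For fixed r the weights over k = 2..n-r+1 sum to one.
    """
    if not 1 <= r <= n - 1:
        raise ValueError(f"class r={r} outside 1..{n - 1}")
    if not 2 <= k <= n - r + 1:
        raise ValueError(f"level k={k} outside 2..{n - r + 1} for r={r}")
    return float(np.exp(_log_binom(n - k, r - 1) - _log_binom(n - 1, r)))


def level_weight_matrix(n: int) -> np.ndarray:
    """All level weights at once: W[r-1, k-2] = C(n-k, r-1)/C(n-1, r).

    Shape (n-1, n-1); entries with k > n-r+1 are exactly zero.
    """
    r = np.arange(1, n)[:, None]
    k = np.arange(2, n + 1)[None, :]
    with np.errstate(invalid="ignore"):
        logw = _log_binom(n - k, r - 1) - _log_binom(n - 1, r)
    weights = np.exp(logw)
    weights[(n - k) < (r - 1)] = 0.0  # binomial C(a,b)=0 for a<b
    return weights


def expected_sfs(
    demography: Demography,
    u: float,
    L: float,
    folded: bool = False,
    haploid: bool = False,
) -> ExpectedSfs:
    """Expected SFS counts under a level-indexed demography.

    E[G_r] = (4uL/r) sum_k w(n,r,k) N_k; folding pairs classes r and
    n-r afterwards.  ``haploid=True`` switches the coalescent scaling
    from theta = 4 N u to theta = 2 N u.
    """
    if u <= 0:
        raise ValueError("mutation rate u must be positive")
    if L <= 0:
        raise ValueError("site count L must be positive")
    n = demography.n
    scale = 2.0 if haploid else 4.0
    weights = level_weight_matrix(n)
    r = np.arange(1, n)
    unfolded = (scale * u * L / r) * (weights @ demography.sizes)
    counts = fold_counts(n, unfolded) if folded else unfolded
    return ExpectedSfs(n=n, counts=counts, folded=folded, u=u, L=L)


def _order_r_branch_counts(n: int, k: np.ndarray, r: int) -> np.ndarray:
    """Expected number of order-r branch segments alive at level k.

    Classic Kingman result: each of the k lineages at level k subtends
    r of the n tips with probability C(n-r-1, k-2)/C(n-1, k-1), so the
    expectation is k * C(n-r-1, k-2) / C(n-1, k-1).
    """
    with np.errstate(invalid="ignore"):
        logw = _log_binom(n - r - 1, k - 2) - _log_binom(n - 1, k - 1)
    counts = k * np.exp(logw)
    counts[(n - r - 1) < (k - 2)] = 0.0
    return counts


def expected_sfs_via_W(demography: Demography, u: float, L: float) -> ExpectedSfs:
    """Expected SFS via per-starting-level branch-segment counts.

    Independent route to the same expectation: an order-r branch
    segment starting at level k carries a mutation with probability
    4 u * mean(N_2..N_k) / k (allowing for any ending level), and the
    expected number of order-r segments *starting* at level k is
    (r-1)/(n-k) times the number alive at k.  Singletons (r=1) all
    start at the tips; their expectation is 4uL times the arithmetic
    mean of N_2..N_n.  Agrees with :func:`expected_sfs` to rounding.
    """
    if u <= 0 or L <= 0:
        raise ValueError("u and L must be positive")
    n = demography.n
    sizes = demography.sizes  # index k-2 -> N_k
    # mean(N_2..N_k) for every k
    nbar = np.cumsum(sizes) / np.arange(1, n)  # index k-2 -> N̄(k)
    expected = np.empty(n - 1, dtype=float)
    expected[0] = 4.0 * u * L * nbar[-1]  # r = 1: mean over all levels
    for r in range(2, n):
        k = np.arange(2, n - r + 2)
        alive = _order_r_branch_counts(n, k, r)
        starting = (r - 1) / (n - k) * alive
        per_branch = 4.0 * u * nbar[k - 2] / k
        expected[r - 1] = L * np.sum(starting * per_branch)
    return ExpectedSfs(n=n, counts=expected, folded=False, u=u, L=L)
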