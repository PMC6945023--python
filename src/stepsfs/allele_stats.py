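"""Allele-age moments and long-term experienced Ne per frequency class.

A neutral mutation now present in r of n sampled genomes arose on an
order-r branch of the genealogy.  Conditioning on the branch's
starting level and averaging over topologies gives closed forms for
the mean and second moment of the allele's age (in generations) and
for the mean population size it experienced over its lifetime,
P_r = E[int_0^{A_r} N(s) ds] / E[A_r] — a ratio of expectations, not
an expectation of ratios.

All formulas are weighted sums over starting levels k with weights
N_k * C(n-k, r-1); the inner sums over deeper levels are suffix
cumulative arrays, so each class costs O(n) after O(n) setup.
Binomials are kept in log space with a common normalisation so large
samples (n in the hundreds) do not overflow.

Folded spectra mix derived order-r and ancestral order-(n-r) alleles
with probabilities pd = E[G_r] / (E[G_r] + E[G_{n-r}]) and pa = 1-pd.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expectations import Demography, _log_binom, expected_sfs

__all__ = [
    "AlleleClassSummary",
    "allele_age_moments",
    "derived_fraction",
    "folded_age_moments",
    "experienced_ne",
    "folded_experienced_ne",
    "class_summaries",
]


@dataclass(frozen=True)
class AlleleClassSummary:
    """Per-frequency-class allele statistics.

    mean_age and age_variance are in generations and generations^2;
    mean_experienced_ne in diploid individuals.  pd/pa are the folded
    derived/ancestral mixture probabilities (pd = 1 for unfolded).
    """

    r: int
    mean_age: float
    age_variance: float
    mean_experienced_ne: float
    pd: float = 1.0

    @property
    def pa(self) -> float:
        return 1.0 - self.pd

    @property
    def sd_age(self) -> float:
        return float(np.sqrt(self.age_variance))


def _start_level_weights(demography: Demography, r: int) -> np.ndarray:
    """N_k * C(n-k, r-1) over k = 2..n, normalised log-safely."""
    n = demography.n
    k = np.arange(2, n + 1)
    with np.errstate(invalid="ignore"):
        logb = _log_binom(n - k, r - 1)
    valid = (n - k) >= (r - 1)
    logb = np.where(valid, logb, -np.inf)
    logb = logb - np.max(logb[valid])
    return demography.sizes * np.exp(logb)


def allele_age_moments(demography: Demography, r: int) -> dict:
    """Mean, second moment and variance of the age of an order-r SNP.

    With D(k) = sum_{l=k}^{n} N_l / (l (l-1)) (half the expected time
    from level k to the root, in units of 4 generations):

        E[A_r]   =  4 * sum_k w_k D(k)            / sum_k w_k
        E[A_r^2] = 32 * sum_k w_k T(k)            / sum_k w_k,
        T(k) = sum_{l=k}^{n} N_l/(l(l-1)) * D(l),

    with w_k = N_k C(n-k, r-1).  Ages scale linearly, second moments
    quadratically, in any common rescaling of the N_k.
    """
    n = demography.n
    if not 1 <= r <= n - 1:
        raise ValueError(f"class r={r} outside 1..{n - 1}")
    k = np.arange(2, n + 1)
    rate_terms = demography.sizes / (k * (k - 1))  # N_l / (l(l-1)) at index l-2
    D = np.cumsum(rate_terms[::-1])[::-1]  # suffix sums, index k-2
    T = np.cumsum((rate_terms * D)[::-1])[::-1]
    w = _start_level_weights(demography, r)
    denom = np.sum(w)
    mean = 4.0 * np.sum(w * D) / denom
    second = 32.0 * np.sum(w * T) / denom
    return {
        "mean": float(mean),
        "second_moment": float(second),
        "variance": float(second - mean * mean),
    }


def derived_fraction(demography: Demography, u: float, L: float, r: int) -> float:
    """Probability pd that a minor-allele class-r SNP is the derived variant.

    pd = E[G_r] / (E[G_r] + E[G_{n-r}]); under constant Ne this is
    (n-r)/n.  The self-paired middle class of even n has pd = 1/2.
    """
    n = demography.n
    if not 1 <= r <= n // 2:
        raise ValueError(f"folded class r={r} outside 1..{n // 2}")
    exp_g = expected_sfs(demography, u, L).counts
    g_r, g_nr = exp_g[r - 1], exp_g[n - r - 1]
    return float(g_r / (g_r + g_nr))


def folded_age_moments(demography: Demography, u: float, L: float, r: int) -> dict:
    """Age moments for a minor-allele (folded) class.

    Mixture of the derived order-r and ancestral order-(n-r)
    components: E[A*_r] = pd E[A_r] + pa E[A_{n-r}] and
    Var(A*_r) = pd^2 Var(A_r) + pa^2 Var(A_{n-r}).
    """
    n = demography.n
    pd = derived_fraction(demography, u, L, r)
    lo = allele_age_moments(demography, r)
    hi = lo if n - r == r else allele_age_moments(demography, n - r)
    pa = 1.0 - pd
    return {
        "mean": pd * lo["mean"] + pa * hi["mean"],
        "variance": pd**2 * lo["variance"] + pa**2 * hi["variance"],
        "pd": pd,
    }


def experienced_ne(demography: Demography, r: int) -> float:
    """Mean population size experienced by an order-r SNP over its life.

    E[P_r] = sum_k w_k sum_{l>=k} 4 N_l^2/(l(l-1))
           / sum_k w_k sum_{l>=k} 4 N_l  /(l(l-1)),

    a weighted average of the N_k: it always lies in
    [min N_k, max N_k] and equals N exactly under constant size.
    """
    n = demography.n
    if not 1 <= r <= n - 1:
        raise ValueError(f"class r={r} outside 1..{n - 1}")
    k = np.arange(2, n + 1)
    lin = demography.sizes / (k * (k - 1))
    quad = demography.sizes**2 / (k * (k - 1))
    lin_suffix = np.cumsum(lin[::-1])[::-1]
    quad_suffix = np.cumsum(quad[::-1])[::-1]
    w = _start_level_weights(demography, r)
    return float(np.sum(w * quad_suffix) / np.sum(w * lin_suffix))


def folded_experienced_ne(demography: Demography, u: float, L: float, r: int) -> float:
    """Folded-class experienced Ne: pd/pa mixture of orders r and n-r."""
    n = demography.n
    pd = derived_fraction(demography, u, L, r)
    lo = experienced_ne(demography, r)
    hi = lo if n - r == r else experienced_ne(demography, n - r)
    return pd * lo + (1.0 - pd) * hi


def class_summaries(
    demography: Demography,
    u: float,
    L: float,
    folded: bool = False,
) -> list[AlleleClassSummary]:
    """Ages and experienced Ne for every class, as a report-ready list."""
    n = demography.n
    out = []
    if folded:
        for r in range(1, n // 2 + 1):
            ages = folded_age_moments(demography, u, L, r)
            out.append(
                AlleleClassSummary(
                    r=r,
                    mean_age=ages["mean"],
                    age_variance=ages["variance"],
                    mean_experienced_ne=folded_experienced_ne(demography, u, L, r),
                    pd=ages["pd"],
                )
            )
    else:
        for r in range(1, n):
            ages = allele_age_moments(demography, r)
            out.append(
                AlleleClassSummary(
                    r=r,
                    mean_age=ages["mean"],
                    age_variance=ages["variance"],
                    mean_experienced_ne=experienced_ne(demography, r),
                )
            )
    return out
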