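"""Site-frequency spectrum container, file I/O, folding and resampling.

The site-frequency spectrum (SFS) is the sole observed input of the
inference machinery in this package.  For a sample of ``n`` haploid
genomes scored at ``L`` nucleotide sites, the unfolded SFS stores the
number of sites ``G_r`` carrying the derived allele in ``r`` copies
(``r = 1..n-1``); the folded SFS stores minor-allele counts
``F_r = G_r + G_{n-r}`` (``r = 1..n//2``).  The monomorphic count
``G_0 = L - sum(counts)`` is always derived, never stored.

File dialect
------------
Plain text; header lines ``#n <int>``, ``#L <int>``, ``#folded <0|1>``,
then one ``r<TAB>count`` line per class with ``r`` strictly increasing.
Missing classes are zero.  Other ``#`` lines are comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SiteFrequencySpectrum",
    "SfsParseError",
    "read_sfs",
    "write_sfs",
    "fold",
    "bootstrap_sfs",
    "watterson_theta",
]


class SfsParseError(ValueError):
    """Raised when an SFS file is malformed; the message names the line."""


def _n_classes(n: int, folded: bool) -> int:
    return n // 2 if folded else n - 1


@dataclass(frozen=True)
class SiteFrequencySpectrum:
    """A validated site-frequency spectrum.

    Parameters
    ----------
    n
        Number of sampled haploid genomes (>= 2).
    L
        Total number of sites scored, monomorphic plus polymorphic.
    counts
        Per-class site counts, class ``r`` at ``counts[r-1]``.
        Length ``n-1`` (unfolded) or ``n//2`` (folded).
    folded
        Whether counts are minor-allele classes.
    excluded_classes
        Class indices to skip inside likelihood sums (e.g. ``{1}`` when
        singletons are unreliable).  Folding and bootstrapping ignore
        this set; only model fitting consults it.
    """

    n: int
    L: int
    counts: np.ndarray
    folded: bool = False
    excluded_classes: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"sample size n must be >= 2, got {self.n}")
        counts = np.asarray(self.counts)
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("SFS counts must be integers")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        expected = _n_classes(self.n, self.folded)
        if counts.shape != (expected,):
            kind = "folded" if self.folded else "unfolded"
            raise ValueError(
                f"{kind} SFS for n={self.n} needs {expected} classes, "
                f"got {counts.shape[0]}"
            )
        if np.any(counts < 0):
            raise ValueError("SFS counts must be non-negative")
        if self.L < int(counts.sum()):
            raise ValueError(
                f"L={self.L} is smaller than the polymorphic total "
                f"{int(counts.sum())}"
            )
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "excluded_classes", frozenset(self.excluded_classes))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def segregating_sites(self) -> int:
        """Total polymorphic sites S across all classes."""
        return int(self.counts.sum())

    @property
    def monomorphic(self) -> int:
        """Derived monomorphic count G_0 = L - sum(counts)."""
        return self.L - self.segregating_sites

    def with_excluded(self, classes) -> "SiteFrequencySpectrum":
        return replace(self, excluded_classes=frozenset(classes))


def read_sfs(path) -> SiteFrequencySpectrum:
    """Read an SFS text file (dialect in the module docstring)."""
    n = L = None
    folded = False
    entries: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                fields = line[1:].split()
                if not fields:
                    continue
                key = fields[0].lower()
                if key in ("n", "l", "folded"):
                    if len(fields) != 2:
                        raise SfsParseError(
                            f"line {lineno}: header '#{key}' needs one value"
                        )
                    try:
                        value = int(fields[1])
                    except ValueError:
                        raise SfsParseError(
                            f"line {lineno}: non-integer header value {fields[1]!r}"
                        ) from None
                    if key == "n":
                        n = value
                    elif key == "l":
                        L = value
                    else:
                        folded = bool(value)
                continue
            fields = line.split()
            if len(fields) != 2:
                raise SfsParseError(
                    f"line {lineno}: expected 'class count', got {line!r}"
                )
            try:
                r, count = int(fields[0]), int(fields[1])
            except ValueError:
                raise SfsParseError(
                    f"line {lineno}: non-integer field in {line!r}"
                ) from None
            if count < 0:
                raise SfsParseError(f"line {lineno}: negative count {count}")
            if entries and r <= entries[-1][0]:
                raise SfsParseError(
                    f"line {lineno}: class index {r} not strictly increasing"
                )
            entries.append((r, count))

    if n is None:
        raise SfsParseError("missing '#n' header")
    if L is None:
        raise SfsParseError("missing '#L' header")
    if n < 2:
        raise SfsParseError(f"header n={n} must be >= 2")
    n_classes = _n_classes(n, folded)
    counts = np.zeros(n_classes, dtype=np.int64)
    for r, count in entries:
        if not 1 <= r <= n_classes:
            raise SfsParseError(
                f"class index {r} out of range 1..{n_classes} "
                f"for {'folded ' if folded else ''}n={n}"
            )
        counts[r - 1] = count
    if counts.sum() > L:
        raise SfsParseError(
            f"polymorphic total {int(counts.sum())} exceeds L={L}"
        )
    return SiteFrequencySpectrum(n=n, L=L, counts=counts, folded=folded)


def write_sfs(sfs: SiteFrequencySpectrum, path) -> None:
    """Write the same dialect ``read_sfs`` reads; round-trip exact."""
    with open(path, "w") as fh:
        fh.write(f"#n {sfs.n}\n#L {sfs.L}\n#folded {int(sfs.folded)}\n")
        for r, count in enumerate(sfs.counts, start=1):
            fh.write(f"{r}\t{count}\n")


def fold(sfs: SiteFrequencySpectrum) -> SiteFrequencySpectrum:
    """Fold an unfolded SFS into minor-allele classes.

    F_r = G_r + G_{n-r} for r < n/2, and F_{n/2} = G_{n/2} when n is even.
    Total polymorphic count is preserved.
    """
    if sfs.folded:
        raise ValueError("SFS is already folded")
    return SiteFrequencySpectrum(
        n=sfs.n,
        L=sfs.L,
        counts=fold_counts(sfs.n, sfs.counts),
        folded=True,
        excluded_classes=sfs.excluded_classes,
    )


def fold_counts(n: int, counts: np.ndarray) -> np.ndarray:
    """Fold an array of n-1 unfolded class values into n//2 folded ones.

    Works on integer counts and on real-valued expectations alike.
    """
    counts = np.asarray(counts)
    half = n // 2
    folded = counts[:half].copy()
    # pair class r with n-r; the middle class of even n pairs with itself
    for r in range(1, half + 1):
        if n - r != r:
            folded[r - 1] += counts[n - r - 1]
    return folded


def bootstrap_sfs(sfs: SiteFrequencySpectrum, replicates: int, seed: int):
    """Multinomial site-level bootstrap of an SFS.

    Each replicate redraws the L sites across classes 0..n_classes with
    class probabilities G_r / L (class 0 = monomorphic).  Total L is
    conserved exactly; the draw is deterministic given ``seed``.

    Returns a list of ``replicates`` new spectra.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if sfs.L == 0:
        raise ValueError("cannot bootstrap an SFS with L = 0")
    rng = np.random.default_rng(seed)
    probs = np.empty(sfs.n_classes + 1, dtype=float)
    probs[0] = sfs.monomorphic / sfs.L
    probs[1:] = sfs.counts / sfs.L
    draws = rng.multinomial(sfs.L, probs, size=replicates)
    return [
        replace(sfs, counts=draw[1:].astype(np.int64))
        for draw in draws
    ]


def watterson_theta(sfs: SiteFrequencySpectrum, u: float | None = None) -> dict:
    """Watterson's estimator from the SFS.

    Returns ``{"S": .., "theta_per_site": .., "Ne_hat": ..}`` with
    theta = S / (L a_n), a_n the harmonic number sum_{i=1}^{n-1} 1/i,
    and Ne_hat = theta / (4u) (diploid scaling).  ``Ne_hat`` is None
    when no mutation rate is supplied.
    """
    S = sfs.segregating_sites
    a = harmonic_number(sfs.n - 1)
    theta = S / (sfs.L * a) if sfs.L > 0 else 0.0
    result = {"S": S, "theta_per_site": theta, "Ne_hat": None}
    if u is not None:
        result["Ne_hat"] = theta / (4.0 * u)
    return result


def harmonic_number(m: int) -> float:
    """sum_{i=1}^{m} 1/i (a_n of Watterson's estimator for m = n-1)."""
    return float(np.sum(1.0 / np.arange(1, m + 1))) if m >= 1 else 0.0
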