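"""Genome-size estimation from the k-mer multiplicity spectrum of reads.

Counting the frequency of each k-mer (k = 17 by default) in whole-genome
shotgun reads and plotting the copy-number distribution yields a curve
whose main peak sits at the overall sequencing depth; genome size is the
total k-mer count divided by that depth:

    G = k_num / k_depth        (and equivalently  G = b_num / b_depth,
    b_depth = k_depth * L / (L - k + 1) for read length L)

k-mers are strand-canonicalized (the lexicographic minimum of a k-mer
and its reverse complement is counted) and windows containing N are
excluded.  The low-multiplicity error peak is excluded by locating the
first local minimum of the spectrum and taking the mode beyond it; the
integer mode is refined by quadratic interpolation over its 3 bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class NoMainPeakError(ValueError):
    """Raised when the spectrum decreases monotonically (no coverage peak)."""


@dataclass
class KmerSpectrum:
    """Multiplicity histogram of canonical k-mers in a read set."""

    k: int
    histogram: dict[int, int]   # multiplicity -> number of distinct k-mers
    k_num: int                  # total retained k-mer windows
    b_num: int                  # total read bases
    read_length: float          # mean read length

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if any(m < 1 for m in self.histogram):
            raise ValueError("multiplicities must be >= 1")
        total = sum(m * c for m, c in self.histogram.items())
        if total != self.k_num:
            raise ValueError("k_num does not equal sum(multiplicity * count)")

    def to_frame(self):
        import pandas as pd
        items = sorted(self.histogram.items())
        return pd.DataFrame(items, columns=["multiplicity", "count"])


@dataclass
class GenomeSizeEstimate:
    k_depth: float      # peak k-mer multiplicity (refined)
    b_depth: float      # per-base sequencing depth
    genome_size: float  # G = k_num / k_depth
    genome_size_bases: float  # base formulation, b_num / b_depth


def _dense_histogram(spectrum: KmerSpectrum) -> np.ndarray:
    mmax = max(spectrum.histogram)
    y = np.zeros(mmax + 2, dtype=float)
    for m, c in spectrum.histogram.items():
        y[m] = c
    return y


def _find_valley(y: np.ndarray, mmax: int) -> int:
    """First local minimum of the dense spectrum (error-peak boundary)."""
    for m in range(1, mmax):
        if y[m + 1] > y[m]:
            return m
    raise NoMainPeakError("no main peak: spectrum decreases monotonically")


_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def count_kmers(reads: list[tuple[str, str]] | list[str], k: int = 17) -> KmerSpectrum:
    """Count canonical k-mers over a read set into a multiplicity spectrum.

    ``reads`` is a list of sequences or (id, sequence) pairs.  Windows
    containing any non-ACGT character are dropped; each remaining window
    is counted under its canonical (strand-collapsed) form.
    """
    if k < 1 or k > 31:
        raise ValueError("k must be in [1, 31]")
    seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
    if not seqs:
        raise ValueError("empty read set")
    if min(len(s) for s in seqs) < k:
        raise ValueError("k exceeds the shortest read length")
    b_num = sum(len(s) for s in seqs)
    read_length = b_num / len(seqs)

    # one pass over all reads joined with 'N' separators: windows that
    # straddle a separator are dropped by the N-exclusion rule anyway
    joined = "N".join(seqs).encode()
    codes = _CODE[np.frombuffer(joined, dtype=np.uint8)]
    n = codes.size
    valid_base = codes >= 0
    win_valid = np.lib.stride_tricks.sliding_window_view(valid_base, k).all(axis=1)

    u = np.where(valid_base, codes, 0).astype(np.uint64)
    weights = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd = np.lib.stride_tricks.sliding_window_view(u, k) @ weights
    rc_codes = np.where(valid_base, 3 - codes, 0).astype(np.uint64)[::-1]
    rev = np.lib.stride_tricks.sliding_window_view(rc_codes, k) @ weights
    rev = rev[::-1]  # window j of the rc strand aligns with forward window j

    canonical = np.minimum(fwd, rev)[win_valid]
    k_num = int(canonical.size)
    if k_num == 0:
        raise ValueError("no valid k-mer windows (all contain N)")
    _, mult = np.unique(canonical, return_counts=True)
    ms, cs = np.unique(mult, return_counts=True)
    histogram = {int(m): int(c) for m, c in zip(ms, cs)}
    assert n - k + 1 == win_valid.size
    return KmerSpectrum(k, histogram, k_num, b_num, read_length)


def peak_depth(spectrum: KmerSpectrum, mode_to_mean: bool = True) -> float:
    """Locate the main (coverage) peak of the spectrum.

    The error peak at multiplicity 1 is excluded by finding the first
    local minimum of the dense histogram; the mode beyond it is refined
    by a least-squares parabola on log-counts over the half-height
    window around it.  For a Poisson-distributed coverage component the
    log-spectrum is nearly an exact parabola whose vertex sits half a
    bin below the mean depth, so with ``mode_to_mean`` (default) that
    half bin is added back; the peak itself (unlike the spectrum mean)
    is insensitive to the high-multiplicity repeat tail.  Raises
    :class:`NoMainPeakError` when the curve only decreases.
    """
    if not spectrum.histogram:
        raise ValueError("empty histogram")
    mmax = max(spectrum.histogram)
    y = _dense_histogram(spectrum)

    valley = _find_valley(y, mmax)
    mode = valley + 1 + int(np.argmax(y[valley + 1:mmax + 1]))
    half = 0.5 * y[mode]
    lo = mode
    while lo - 1 > valley and y[lo - 1] >= half:
        lo -= 1
    hi = mode
    while hi + 1 <= mmax and y[hi + 1] >= half:
        hi += 1
    xs = np.arange(lo, hi + 1, dtype=float)
    correction = 0.5 if mode_to_mean else 0.0
    if xs.size < 3:
        return float(mode) + correction
    coef = np.polyfit(xs, np.log(y[lo:hi + 1]), 2)
    if coef[0] >= 0:  # degenerate window, fall back to the integer mode
        return float(mode) + correction
    vertex = float(np.clip(-coef[1] / (2 * coef[0]), lo, hi))
    return vertex + correction


def estimate_size(spectrum: KmerSpectrum, k_depth: float | None = None,
                  exclude_error_kmers: bool = True) -> GenomeSizeEstimate:
    """Genome size from total k-mers (or bases) divided by peak depth.

    With ``exclude_error_kmers`` (default) the k-mer total entering the
    formula omits the error component below the spectrum's first local
    minimum, the same boundary used to exclude the error peak when
    locating the depth; sequencing-error k-mers otherwise inflate the
    numerator but not the peak, biasing the size upward.  The base
    formulation ``b_num / b_depth`` is scaled by the same retained
    fraction.
    """
    if k_depth is None:
        k_depth = peak_depth(spectrum)
    if k_depth <= 0:
        raise ValueError("k_depth must be positive")
    k_num_used = spectrum.k_num
    if exclude_error_kmers:
        mmax = max(spectrum.histogram)
        try:
            valley = _find_valley(_dense_histogram(spectrum), mmax)
        except NoMainPeakError:
            valley = 0
        k_num_used = sum(m * c for m, c in spectrum.histogram.items() if m > valley)
    g_kmer = k_num_used / k_depth
    b_depth = k_depth * spectrum.read_length / (spectrum.read_length - spectrum.k + 1)
    b_num_used = spectrum.b_num * (k_num_used / spectrum.k_num)
    g_base = b_num_used / b_depth
    return GenomeSizeEstimate(k_depth, b_depth, g_kmer, g_base)
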