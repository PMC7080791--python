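"""K-mer spectrum and k-mer dump I/O.

Reads the two-column text dialects emitted by the standard k-mer counters
(jellyfish `histo`, KMC `transform histogram` / `dump`): whitespace- or
tab-separated, optional '#' comment lines. Also provides the coverage-times-
frequency transform used as the default fitting surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kmers import canonical_kmer

#: counters commonly truncate histograms here unless told otherwise
DEFAULT_MAX_COUNTER = 10_000


class SpectrumTruncationWarning(UserWarning):
    """The final histogram bin looks like an overflow/truncation bin."""


@dataclass
class KmerSpectrum:
    """Histogram of k-mer coverage: frequency f(x) of distinct k-mers at depth x."""

    k: int
    coverages: np.ndarray
    frequencies: np.ndarray
    max_counter: int | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        self.coverages = np.asarray(self.coverages, dtype=np.int64)
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        if self.coverages.size != self.frequencies.size:
            raise ValueError("coverage and frequency arrays differ in length")
        if self.coverages.size:
            if self.coverages[0] < 1:
                raise ValueError("coverages must be >= 1")
            if (np.diff(self.coverages) <= 0).any():
                raise ValueError("coverages must be strictly increasing")
        if (self.frequencies < 0).any():
            raise ValueError("frequencies must be non-negative")

    @property
    def bins(self) -> list[tuple[int, float]]:
        return list(zip(self.coverages.tolist(), self.frequencies.tolist()))

    def total_mass(self) -> float:
        """Total k-mer mass: sum of coverage x frequency over all bins."""
        return float(np.sum(self.coverages * self.frequencies))

    def frequency_at(self, x: int) -> float:
        idx = np.searchsorted(self.coverages, x)
        if idx < len(self.coverages) and self.coverages[idx] == x:
            return float(self.frequencies[idx])
        return 0.0


@dataclass
class TransformedSpectrum:
    """Coverage-times-frequency spectrum: (x, x * f(x)); the default fit target."""

    coverages: np.ndarray
    values: np.ndarray

    @property
    def bins(self) -> list[tuple[int, float]]:
        return list(zip(self.coverages.tolist(), self.values.tolist()))


@dataclass
class KmerDump:
    """Canonical k-mer -> count mapping, the text counterpart of a counter dump."""

    k: int
    records: dict[str, int] = field(default_factory=dict)
    skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)


def read_histogram(path: str | Path, k: int) -> KmerSpectrum:
    """Parse a two-column coverage/frequency histogram.

    Flags truncation when the final bin's frequency exceeds 10x the median of
    the preceding 10 bins (overflow bins aggregate everything past the
    counter's maximum); the overflow bin is dropped and recorded as
    ``max_counter``.
    """
    covs: list[int] = []
    freqs: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                cov = int(parts[0])
                freq = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field in {line!r}") from exc
            covs.append(cov)
            freqs.append(freq)
    if not covs:
        raise ValueError(f"{path}: empty histogram")
    if len(set(covs)) != len(covs):
        raise ValueError(f"{path}: duplicate coverage values")
    order = np.argsort(covs)
    cov_arr = np.asarray(covs, dtype=np.int64)[order]
    freq_arr = np.asarray(freqs, dtype=np.float64)[order]

    truncated = False
    max_counter = None
    if len(cov_arr) >= 11:
        tail_median = float(np.median(freq_arr[-11:-1]))
        if tail_median > 0 and freq_arr[-1] > 10 * tail_median:
            truncated = True
            max_counter = int(cov_arr[-1])
            warnings.warn(
                f"histogram appears truncated at coverage {max_counter}; "
                "genome size estimates will be lower bounds",
                SpectrumTruncationWarning,
                stacklevel=2,
            )
            cov_arr, freq_arr = cov_arr[:-1], freq_arr[:-1]
    return KmerSpectrum(
        k=k,
        coverages=cov_arr,
        frequencies=freq_arr,
        max_counter=max_counter,
        truncated=truncated,
    )


def write_histogram(spectrum: KmerSpectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cov, freq in zip(spectrum.coverages, spectrum.frequencies):
            if float(freq).is_integer():
                fh.write(f"{cov}\t{int(freq)}\n")
            else:
                fh.write(f"{cov}\t{freq}\n")


def transform(spectrum: KmerSpectrum) -> TransformedSpectrum:
    """Map each bin (x, f) to (x, x*f), preserving order.

    The transform amplifies higher-order peaks, which is what lets the
    mixture fit converge for highly heterozygous or high-ploidy spectra.
    """
    if spectrum.coverages.size == 0:
        raise ValueError("cannot transform an empty spectrum")
    return TransformedSpectrum(
        coverages=spectrum.coverages.copy(),
        values=spectrum.coverages * spectrum.frequencies,
    )


def read_dump(path: str | Path, k: int | None = None) -> KmerDump:
    """Parse a two-column k-mer/count dump, canonicalizing sequences.

    Counts of a k-mer and its reverse complement are merged by summation.
    Records containing non-ACGT characters are skipped (tallied in
    ``skipped``); inconsistent k-mer lengths raise.
    """
    records: dict[str, int] = {}
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            seq, count_s = parts[0].upper(), parts[1]
            try:
                count = int(count_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric count {count_s!r}") from exc
            if k is None:
                k = len(seq)
            if len(seq) != k:
                raise ValueError(
                    f"{path}:{lineno}: k-mer length {len(seq)} != expected {k}"
                )
            if any(c not in "ACGT" for c in seq):
                skipped += 1
                continue
            canon = canonical_kmer(seq)
            records[canon] = records.get(canon, 0) + count
    if k is None:
        raise ValueError(f"{path}: empty dump")
    return KmerDump(k=k, records=records, skipped=skipped)


def write_dump(dump: KmerDump, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq in sorted(dump.records):
            fh.write(f"{seq}\t{dump.records[seq]}\n")
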