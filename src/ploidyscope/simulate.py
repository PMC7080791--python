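"""Polyploid genome and short-read simulator with known truth.

Generates a random monoploid progenitor with a controlled two-copy repeat
fraction, evolves p homologs from it by drawing a heterozygosity form per
site, samples uniform error-prone short reads at a fixed fold coverage per
homolog, and counts canonical k-mers — yielding the k-mer spectrum and dump
a real pipeline would produce, plus the realized ground truth for recovery
tests.

Default conditions: 15x per homolog, 1% per-base substitution error, 100 bp
single-end reads, k = 21.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kmers import BASES, KmerCounts, count_canonical, rolling_codes
from .model import (
    FormRates,
    Topology,
    forms_for_topology,
    nucleotide_divergence,
)
from .spectra import KmerSpectrum

DUP_SEGMENT_LENGTH = 5_000


@dataclass
class SimulationDesign:
    """One simulated dataset: genome, evolution, and sequencing settings."""

    progenitor_size: int
    p: int
    topology: Topology
    form_rates: FormRates
    d: float = 0.0
    coverage_per_homolog: float = 15.0
    error_rate: float = 0.01
    read_length: int = 100
    k: int = 21
    seed: int = 0


@dataclass
class SimulationTruth:
    """Realized (not just designed) parameter values of one simulation."""

    monoploid_length: int
    divergence: float
    repetitiveness: float
    designed_divergence: float
    designed_repetitiveness: float
    form_site_fractions: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationResult:
    spectrum: KmerSpectrum
    counts: KmerCounts
    truth: SimulationTruth
    homologs: list[np.ndarray] | None = None
    reads: np.ndarray | None = None


def divergence_form_rates(topology: Topology, divergence: float) -> FormRates:
    """Per-form rates realizing a single nucleotide-divergence value.

    The whole divergence is assigned to the coarsest heterozygosity form
    (aab for a triploid, aaab/aabb for tetraploids): one homolog group
    diverging is the first-order mode of heterozygosity, while finer forms
    require multiple hits at the same site and are second-order.
    """
    forms = forms_for_topology(topology)
    return FormRates({f: (divergence if i == 0 else 0.0) for i, f in enumerate(forms)})


def generate_progenitor(
    size: int,
    d: float,
    seed: int | np.random.Generator,
    k: int = 21,
    segment_length: int = DUP_SEGMENT_LENGTH,
) -> np.ndarray:
    """Random monoploid sequence (uint8 codes) of ~`size` bases in which a
    fraction ~d of distinct k-mers occur exactly twice.

    The duplicated mass is realized as exact extra copies of contiguous
    segments of the unique part, appended at the end: with unique length U
    and appended copies totalling d*U, the two-copy distinct-k-mer fraction
    is ~d and the total length is ~size = U*(1+d).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if size < 10 * k:
        raise ValueError(f"progenitor size must be at least 10*k = {10 * k}")
    if not 0 <= d < 1:
        raise ValueError("repetitiveness d must lie in [0, 1)")
    unique_len = int(round(size / (1.0 + d)))
    dup_target = size - unique_len
    if d > 0 and unique_len < 2 * segment_length:
        raise ValueError("genome too small to realize the requested repetitiveness")
    base = rng.integers(0, 4, size=unique_len, dtype=np.uint8)
    pieces = [base]
    if dup_target > 0:
        # copy disjoint slots so no k-mer lands in three or more copies
        n_slots = unique_len // segment_length
        n_seg = -(-dup_target // segment_length)
        if n_seg > n_slots:
            raise ValueError("genome too small to realize the requested repetitiveness")
        chosen = rng.choice(n_slots, size=n_seg, replace=False)
        copied = 0
        for slot in chosen:
            seg = min(segment_length, dup_target - copied)
            start = int(slot) * segment_length
            pieces.append(base[start : start + seg].copy())
            copied += seg
    return np.concatenate(pieces)


def evolve_homologs(
    progenitor: np.ndarray,
    topology: Topology,
    form_rates: FormRates,
    seed: int | np.random.Generator,
) -> tuple[list[np.ndarray], SimulationTruth]:
    """Derive p homolog sequences by drawing a heterozygosity form per site.

    At a site with form partition {B0, B1, ...}, the block containing
    homolog 0 keeps the progenitor base (the ancestral state) and each other
    block receives a distinct substitute drawn from the 3 alternative
    nucleotides. Forms with more than 4 blocks cannot be realized on a
    4-letter alphabet and are rejected if their rate is nonzero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = topology.p
    L = len(progenitor)
    forms = forms_for_topology(topology)
    rates = [form_rates.rates[f] for f in forms]
    for f, r in zip(forms, rates):
        if r > 0 and len(f.partition) > 4:
            raise ValueError(
                f"form {f.pattern} has {len(f.partition)} blocks; at most 4 distinct "
                "nucleotides exist per site"
            )

    edges = np.cumsum([form_rates.homozygous_rate] + list(rates))
    u = rng.random(L)
    category = np.searchsorted(edges, u, side="right")  # 0 = homozygous

    homologs = [progenitor.copy() for _ in range(p)]
    form_fractions: dict[str, float] = {}
    het_sites = 0
    for j, form in enumerate(forms, start=1):
        sites = np.nonzero(category == j)[0]
        form_fractions[form.pattern] = len(sites) / L
        if len(sites) == 0:
            continue
        het_sites += len(sites)
        non_anc = [b for b in form.partition if 0 not in b]
        m = len(non_anc)
        # random ordering of the 3 alternative offsets per site; block b gets
        # offset perm[:, b], guaranteeing distinct non-ancestral letters
        perm = np.argsort(rng.random((len(sites), 3)), axis=1)[:, :m] + 1
        anc_base = progenitor[sites]
        for bi, block in enumerate(non_anc):
            letters = (anc_base + perm[:, bi].astype(np.uint8)) % 4
            for h in block:
                homologs[h][sites] = letters

    truth = SimulationTruth(
        monoploid_length=L,
        divergence=het_sites / L,
        repetitiveness=float("nan"),  # filled by run_design via k-mer census
        designed_divergence=nucleotide_divergence(form_rates),
        designed_repetitiveness=float("nan"),
        form_site_fractions=form_fractions,
    )
    return homologs, truth


def simulate_reads(
    homologs: list[np.ndarray],
    coverage_per_homolog: float,
    read_length: int,
    error_rate: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Uniform single-end reads as a (n_reads, read_length) uint8 matrix."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if coverage_per_homolog <= 0:
        raise ValueError("coverage must be positive")
    chunks = []
    for hom in homologs:
        L = len(hom)
        if read_length > L:
            raise ValueError("read length exceeds homolog length")
        n = int(round(coverage_per_homolog * L / read_length))
        starts = rng.integers(0, L - read_length + 1, size=n)
        chunks.append(hom[starts[:, None] + np.arange(read_length)])
    reads = np.concatenate(chunks)
    if error_rate > 0:
        flat = reads.reshape(-1)
        n_err = rng.binomial(flat.size, error_rate)
        pos = rng.integers(0, flat.size, size=n_err)
        offsets = rng.integers(1, 4, size=n_err).astype(np.uint8)
        flat[pos] = (flat[pos] + offsets) % 4
    return reads


def count_kmers(reads: np.ndarray, k: int) -> tuple[KmerCounts, KmerSpectrum]:
    """Canonical k-mer counts over all reads plus the derived spectrum."""
    codes = rolling_codes(reads, k)
    counts = count_canonical(codes, k)
    cov, freq = counts.histogram()
    spectrum = KmerSpectrum(k=k, coverages=cov, frequencies=freq)
    return counts, spectrum


def measure_repetitiveness(progenitor: np.ndarray, k: int) -> float:
    """Realized fraction of distinct monoploid k-mers occurring exactly twice."""
    census = count_canonical(rolling_codes(progenitor, k), k)
    return float(np.mean(census.counts == 2))


def run_design(
    design: SimulationDesign, keep_homologs: bool = False, keep_reads: bool = False
) -> SimulationResult:
    """Run the full protocol: progenitor -> homologs -> reads -> k-mer counts."""
    rng = np.random.default_rng(design.seed)
    progenitor = generate_progenitor(design.progenitor_size, design.d, rng, k=design.k)
    homologs, truth = evolve_homologs(progenitor, design.topology, design.form_rates, rng)
    truth.repetitiveness = measure_repetitiveness(progenitor, design.k)
    truth.designed_repetitiveness = design.d
    reads = simulate_reads(
        homologs, design.coverage_per_homolog, design.read_length, design.error_rate, rng
    )
    counts, spectrum = count_kmers(reads, design.k)
    return SimulationResult(
        spectrum=spectrum,
        counts=counts,
        truth=truth,
        homologs=homologs if keep_homologs else None,
        reads=reads if keep_reads else None,
    )


# ---------------------------------------------------------------------------
# Text output helpers (CLI)


def codes_to_string(arr: np.ndarray) -> str:
    return "".join(BASES[b] for b in arr)


def write_fasta(homologs: list[np.ndarray], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for i, hom in enumerate(homologs, start=1):
            fh.write(f">homolog_{i}\n")
            seq = codes_to_string(hom)
            for j in range(0, len(seq), width):
                fh.write(seq[j : j + width] + "\n")


def write_fastq(reads: np.ndarray, path: str | Path) -> None:
    qual = "I" * reads.shape[1]
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read_{i}\n{codes_to_string(read)}\n+\n{qual}\n")
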