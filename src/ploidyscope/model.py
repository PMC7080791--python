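"""Polyploid k-mer mixture model.

The k-mer spectrum of a p-ploid genome is modeled as a mixture of 2p
negative binomials with means i*lambda (i = 1..2p), where lambda is the
per-homolog (monoploid) k-mer coverage:

    f(x) = G * sum_{i=1}^{2p} alpha_i * NB(x; i*lambda, i*lambda/rho)

G is the number of distinct k-mers in the monoploid genome and alpha_i is
the expected number of k-mer sequences at copy number i contributed by one
distinct monoploid k-mer. The alphas are determined by the ploidy, the
k-mer length, the two-copy repeat fraction d, and the per-form
heterozygosity rates of a homolog topology; they are computed exactly via
Moebius inversion on the set-partition lattice of the homologs.

A "topology" is a ranked binary tree shape on the p homologs, represented
as a maximal refinement chain in the partition lattice; each chain
partition induces one heterozygosity form (aab, aabb, ...), the pattern of
which homologs share a nucleotide at a locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import nbinom

Partition = tuple[tuple[int, ...], ...]


# ---------------------------------------------------------------------------
# Set partitions and the Moebius function of the partition lattice


def normalize_partition(blocks: Iterable[Iterable[int]]) -> Partition:
    """Canonical labeled form: blocks internally sorted, ordered by minimum."""
    norm = tuple(sorted(tuple(sorted(b)) for b in blocks))
    seen = [e for b in norm for e in b]
    if sorted(seen) != list(range(len(seen))):
        raise ValueError("blocks must partition 0..n-1 without repeats")
    return norm


def top_partition(p: int) -> Partition:
    return (tuple(range(p)),)


def singleton_partition(p: int) -> Partition:
    return tuple((i,) for i in range(p))


@lru_cache(maxsize=None)
def all_partitions(p: int) -> tuple[Partition, ...]:
    """Every set partition of {0..p-1} (restricted-growth enumeration)."""
    results: list[Partition] = []

    def rec(i: int, blocks: list[list[int]]) -> None:
        if i == p:
            results.append(tuple(tuple(b) for b in blocks))
            return
        for b in blocks:
            b.append(i)
            rec(i + 1, blocks)
            b.pop()
        blocks.append([i])
        rec(i + 1, blocks)
        blocks.pop()

    rec(0, [])
    return tuple(normalize_partition(q) for q in results)


def refines(tau: Partition, upsilon: Partition) -> bool:
    """True if every block of tau lies inside a block of upsilon."""
    where = {}
    for bi, block in enumerate(upsilon):
        for e in block:
            where[e] = bi
    for block in tau:
        first = where[block[0]]
        if any(where[e] != first for e in block[1:]):
            return False
    return True


def partition_moebius(tau: Partition, upsilon: Partition) -> int:
    """Moebius function of the partition-lattice interval [tau, upsilon].

    Zero unless tau refines upsilon; otherwise the interval factors over the
    blocks of upsilon into full partition lattices, whose bottom-to-top
    Moebius value is (-1)^(n-1) (n-1)! for n sub-blocks.
    """
    tau = normalize_partition(tau)
    upsilon = normalize_partition(upsilon)
    if not refines(tau, upsilon):
        return 0
    where = {}
    for bi, block in enumerate(upsilon):
        for e in block:
            where[e] = bi
    counts = [0] * len(upsilon)
    for block in tau:
        counts[where[block[0]]] += 1
    result = 1
    for n in counts:
        result *= (-1) ** (n - 1) * math.factorial(n - 1)
    return result


# ---------------------------------------------------------------------------
# Topologies: ranked binary tree shapes as maximal chains of partitions


def _split_children(p: int, chain: Sequence[Partition]) -> dict[Partition | tuple, tuple]:
    """Map each split block to (rank, (child_block, child_block))."""
    parts = [top_partition(p)] + list(chain)
    children: dict = {}
    for rank in range(1, len(parts)):
        prev, cur = set(parts[rank - 1]), set(parts[rank])
        split = prev - cur
        new = cur - prev
        if len(split) != 1 or len(new) != 2:
            raise ValueError("chain must split exactly one block per rank")
        (old_block,) = split
        children[old_block] = (rank, tuple(sorted(new)))
    return children


def _chain_encoding(p: int, chain: Sequence[Partition]):
    """Label-free canonical encoding of a (possibly partial) ranked chain."""
    children = _split_children(p, chain)

    def enc(block: tuple) -> tuple:
        if block not in children:
            return ("L", len(block))
        rank, (b1, b2) = children[block]
        sub = sorted((enc(b1), enc(b2)), key=repr)
        return (rank, sub[0], sub[1])

    return enc(tuple(range(p)))


def _chain_newick(p: int, chain: Sequence[Partition]) -> str:
    children = _split_children(p, chain)

    def render(block: tuple) -> str:
        if block not in children:
            return ""
        _, (b1, b2) = children[block]
        parts = sorted((render(b1), render(b2)), key=lambda s: (len(s), s))
        return "(" + ", ".join(parts) + ")"

    return render(tuple(range(p))) + ";"


@dataclass(frozen=True)
class Topology:
    """A ranked homolog tree: maximal refinement chain in the partition lattice.

    ``chain`` runs from the first split (2 blocks) down to all singletons
    (p blocks), one block split per rank. Two topologies are equal iff their
    chains are isomorphic under homolog relabeling.
    """

    p: int
    chain: tuple[Partition, ...] = field(compare=False)
    newick: str = field(compare=False)
    _encoding: tuple = field(compare=True, repr=False)

    @classmethod
    def from_chain(cls, chain: Sequence[Partition]) -> "Topology":
        chain = tuple(normalize_partition(c) for c in chain)
        p = sum(len(b) for b in chain[0])
        if len(chain) != p - 1:
            raise ValueError("chain must contain p-1 partitions")
        return cls(
            p=p,
            chain=chain,
            newick=_chain_newick(p, chain),
            _encoding=_chain_encoding(p, chain),
        )

    def __hash__(self) -> int:
        return hash(self._encoding)


def _block_splits(block: tuple[int, ...]) -> Iterable[tuple[tuple, tuple]]:
    """All unordered ways to split a block into two non-empty parts."""
    rest = block[1:]
    n = len(rest)
    for mask in range(2 ** n - 1):  # block[0] stays in the first part
        left = [block[0]]
        right = []
        for j in range(n):
            (left if (mask >> j) & 1 else right).append(rest[j])
        if right:
            yield tuple(left), tuple(right)


@lru_cache(maxsize=None)
def enumerate_topologies(p: int) -> tuple[Topology, ...]:
    """All non-isomorphic ranked homolog tree shapes for ploidy p.

    Counts for p = 2..6 are 1, 1, 2, 5, 16. Partial chains are deduplicated
    by their label-free ranked-tree encoding, so symmetric labelings are
    pruned early.
    """
    if not 2 <= p <= 8:
        raise ValueError("ploidy must be between 2 and 8")
    found: dict[tuple, tuple[Partition, ...]] = {}
    seen_partial: set[tuple[int, tuple]] = set()

    def rec(chain: list[Partition]) -> None:
        current = chain[-1] if chain else top_partition(p)
        if len(current) == p:
            enc = _chain_encoding(p, chain)
            if enc not in found:
                found[enc] = tuple(chain)
            return
        for bi, block in enumerate(current):
            if len(block) < 2:
                continue
            for left, right in _block_splits(block):
                nxt = normalize_partition(
                    [b for j, b in enumerate(current) if j != bi] + [left, right]
                )
                chain.append(nxt)
                key = (len(chain), _chain_encoding(p, chain))
                if key not in seen_partial:
                    seen_partial.add(key)
                    rec(chain)
                chain.pop()

    rec([])
    topologies = [Topology.from_chain(c) for c in found.values()]
    topologies.sort(key=lambda t: t.newick)
    return tuple(topologies)


def caterpillar_topology(p: int) -> Topology:
    """The fully nested (chain/caterpillar) topology, the default for fitting."""
    chain = []
    blocks: list[tuple[int, ...]] = [tuple(range(p))]
    while len(blocks) < p:
        big = max(blocks, key=len)
        blocks.remove(big)
        blocks.extend([big[:-1], big[-1:]])
        chain.append(normalize_partition(blocks))
    return Topology.from_chain(chain)


# ---------------------------------------------------------------------------
# Heterozygosity forms and rates


@dataclass(frozen=True)
class HeterozygosityForm:
    """A nucleotide-sharing pattern across homologs, e.g. 'aaab'.

    ``partition`` is the labeled partition (from the topology chain) whose
    blocks are the groups of homologs sharing a nucleotide. The pattern is
    the canonical lowercase string: letters introduced in first-use order,
    blocks taken in decreasing size.
    """

    pattern: str
    partition: Partition


def pattern_of_partition(partition: Partition) -> str:
    sizes = sorted((len(b) for b in partition), reverse=True)
    letters = "abcdefgh"
    return "".join(letters[i] * s for i, s in enumerate(sizes))


def forms_for_topology(topology: Topology) -> list[HeterozygosityForm]:
    """The p-1 heterozygosity forms of a topology, coarsest (aab...) first.

    The homozygous pattern aa...a is excluded; its rate is the complement of
    the form rates.
    """
    return [
        HeterozygosityForm(pattern_of_partition(part), part)
        for part in topology.chain
    ]


@dataclass
class FormRates:
    """Per-form heterozygosity proportions; the homozygous rate is the complement."""

    rates: dict[HeterozygosityForm, float]

    def __post_init__(self) -> None:
        vals = list(self.rates.values())
        if any(v < 0 for v in vals):
            raise ValueError("form rates must be non-negative")
        if sum(vals) > 1 + 1e-12:
            raise ValueError("form rates must sum to at most 1")

    @property
    def homozygous_rate(self) -> float:
        return 1.0 - sum(self.rates.values())

    @classmethod
    def for_topology(
        cls,
        topology: Topology,
        rates: Sequence[float] | Mapping[str, float],
    ) -> "FormRates":
        """Build rates for a topology from a coarse-to-fine sequence or a
        pattern->rate mapping."""
        forms = forms_for_topology(topology)
        if isinstance(rates, Mapping):
            unknown = set(rates) - {f.pattern for f in forms}
            if unknown:
                raise ValueError(f"patterns {sorted(unknown)} not in topology")
            return cls({f: float(rates.get(f.pattern, 0.0)) for f in forms})
        if len(rates) != len(forms):
            raise ValueError(f"expected {len(forms)} rates, got {len(rates)}")
        return cls(dict(zip(forms, (float(r) for r in rates))))

    def by_pattern(self) -> dict[str, float]:
        return {f.pattern: r for f, r in self.rates.items()}


def nucleotide_divergence(rates: FormRates) -> float:
    """Proportion of loci at which the homologs are not all identical."""
    return sum(rates.rates.values())


# ---------------------------------------------------------------------------
# Model parameters


@dataclass
class ModelParams:
    """Point parameters of the 2p-component mixture."""

    p: int
    k: int
    lam: float          # per-homolog (monoploid) k-mer coverage
    rho: float          # overdispersion: NB variance = mu * (1 + rho)
    d: float            # fraction of distinct monoploid k-mers occurring twice
    G: float            # distinct k-mers in the monoploid genome
    topology: Topology
    form_rates: FormRates

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.rho <= 0 or self.G <= 0:
            raise ValueError("lam, rho and G must be positive")
        if not 0 <= self.d <= 1:
            raise ValueError("d must lie in [0, 1]")
        if self.topology.p != self.p:
            raise ValueError("topology ploidy does not match p")


# ---------------------------------------------------------------------------
# Partition probabilities and alpha coefficients


def kmer_partition_probability(
    tau: Partition, rates: FormRates, k: int, p: int | None = None
) -> float:
    """P(the identity partition of the p homologous k-mers equals tau).

    With per-site forms drawn independently, the probability that all
    homologs agree within every block of a partition upsilon over all k sites
    is Q(upsilon)^k, where Q(upsilon) sums the rates of the forms whose
    partition upsilon refines (the homozygous form always qualifies).
    Moebius inversion over the partition lattice then isolates the exact-
    partition probability:

        P(tau) = sum_{upsilon >= tau} mu(tau, upsilon) * Q(upsilon)^k
    """
    tau = normalize_partition(tau)
    if p is None:
        p = sum(len(b) for b in tau)
    total = 0.0
    for upsilon in all_partitions(p):
        mu = partition_moebius(tau, upsilon)
        if mu == 0:
            continue
        q = rates.homozygous_rate
        for form, r in rates.rates.items():
            if refines(upsilon, form.partition):
                q += r
        total += mu * q ** k
    return total


def _support_probabilities(
    topology: Topology, rates: FormRates, k: int
) -> list[tuple[Partition, float]]:
    """Distribution of the k-mer identity partition over its support.

    Site partitions live on the totally ordered chain {top} + chain, so the
    k-mer partition is simply the finest site partition; cumulative rates
    give the exact distribution without summing over the whole lattice.
    Agrees with :func:`kmer_partition_probability` (property-tested).
    """
    forms = forms_for_topology(topology)
    r = [rates.rates[f] for f in forms]
    hom = rates.homozygous_rate
    out: list[tuple[Partition, float]] = [(top_partition(topology.p), hom ** k)]
    cum = hom
    for form, rate in zip(forms, r):
        prev = cum
        cum += rate
        out.append((form.partition, cum ** k - prev ** k))
    return out


@dataclass
class AlphaVector:
    """Expected per-monoploid-k-mer contributions to peaks 1..2p."""

    alphas: np.ndarray

    def alpha(self, i: int) -> float:
        return float(self.alphas[i - 1])

    def copy_mass(self) -> float:
        i = np.arange(1, len(self.alphas) + 1)
        return float(np.sum(i * self.alphas))


def alpha_coefficients(params: ModelParams) -> AlphaVector:
    """Exact mixture weights alpha_1..alpha_2p for the model parameters.

    Unique k-mers (weight 1-d) contribute the expected number of identity-
    partition blocks of each size. Two-copy k-mers (weight d) occupy two
    loci with independent identity partitions; the block containing homolog
    0 at each locus carries the shared ancestral sequence, so those two
    blocks merge into one k-mer sequence whose copy number is the sum of the
    two block sizes, while every other block stays a distinct sequence.
    Specializes exactly to the printed diploid closed form at p = 2.
    """
    p = params.p
    alphas = np.zeros(2 * p)
    support = _support_probabilities(params.topology, params.form_rates, params.k)

    for part, prob in support:
        if prob == 0.0:
            continue
        for block in part:
            alphas[len(block) - 1] += (1.0 - params.d) * prob

    if params.d > 0:
        for part1, prob1 in support:
            anc1 = next(len(b) for b in part1 if 0 in b)
            for part2, prob2 in support:
                w = params.d * prob1 * prob2
                if w == 0.0:
                    continue
                anc2 = next(len(b) for b in part2 if 0 in b)
                alphas[anc1 + anc2 - 1] += w
                for block in part1:
                    if 0 not in block:
                        alphas[len(block) - 1] += w
                for block in part2:
                    if 0 not in block:
                        alphas[len(block) - 1] += w
    return AlphaVector(alphas=alphas)


def mixture_density(params: ModelParams, x) -> np.ndarray | float:
    """Expected spectrum frequency f(x) = G * sum_i alpha_i NB(x; i*lam, i*lam/rho)."""
    x_arr = np.atleast_1d(np.asarray(x))
    alphas = alpha_coefficients(params).alphas
    out = np.zeros(x_arr.shape, dtype=np.float64)
    for i in range(1, 2 * params.p + 1):
        a = alphas[i - 1]
        if a == 0.0:
            continue
        mu = i * params.lam
        size = mu / params.rho
        out += a * nbinom.pmf(x_arr, size, size / (size + mu))
    out *= params.G
    return float(out[0]) if np.isscalar(x) or np.asarray(x).ndim == 0 else out


def count_design_points(p: int, rep_values: int, het_values: int) -> int:
    """Size of a full simulation sweep: repeats x het-grid^(p-1) x topologies."""
    return rep_values * het_values ** (p - 1) * len(enumerate_topologies(p))
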