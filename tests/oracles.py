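"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the pair
oracle is an all-against-all Hamming comparison, the alpha oracle is a
direct Monte-Carlo simulation of distinct monoploid k-mers, and the Moebius
oracle is the defining recursion over the interval.
"""

from __future__ import annotations

import numpy as np

from ploidyscope.kmers import revcomp_codes
from ploidyscope.model import (
    ModelParams,
    forms_for_topology,
    normalize_partition,
    refines,
    top_partition,
)


def brute_force_pairs(codes: np.ndarray, k: int) -> set[tuple[int, int]]:
    """All-pairs Hamming-1 search over both orientations + ambiguity rule.

    Returns index pairs (i < j) of k-mers one nucleotide apart in either the
    forward/forward or forward/reverse-complement alignment, keeping only
    k-mers that participate in exactly one pair.
    """
    n = len(codes)
    fwd = codes.astype(np.uint64)
    rev = revcomp_codes(fwd, k)
    odd = np.uint64(sum(1 << (2 * i) for i in range(k)))

    def ham1_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        z = a[:, None] ^ b[None, :]
        groups = (z | (z >> np.uint64(1))) & odd
        return np.bitwise_count(groups) == 1

    pairs: set[tuple[int, int]] = set()
    chunk = 512
    for s in range(0, n, chunk):
        rows = slice(s, min(s + chunk, n))
        hit = ham1_matrix(fwd[rows], fwd) | ham1_matrix(fwd[rows], rev)
        ii, jj = np.nonzero(hit)
        for i, j in zip(ii + s, jj):
            if i != j:
                pairs.add((min(int(i), int(j)), max(int(i), int(j))))
    degree = np.zeros(n, dtype=np.int64)
    for a, b in pairs:
        degree[a] += 1
        degree[b] += 1
    return {(a, b) for a, b in pairs if degree[a] == 1 and degree[b] == 1}


def mc_alpha(params: ModelParams, n_rep: int, seed: int):
    """Monte-Carlo estimate of the alpha coefficients with standard errors.

    Simulates n_rep distinct monoploid k-mers: each is duplicated with
    probability d; every locus draws k independent site forms; homologs with
    identical k-mer sequences merge; for duplicated k-mers the blocks
    containing homolog 0 share the ancestral sequence across the two loci.
    """
    rng = np.random.default_rng(seed)
    p, k, d = params.p, params.k, params.d
    forms = forms_for_topology(params.topology)
    rates = [params.form_rates.rates[f] for f in forms]
    parts = [top_partition(p)] + [f.partition for f in forms]
    block_of = np.zeros((len(parts), p), dtype=np.int64)
    for ci, part in enumerate(parts):
        for bi, block in enumerate(part):
            for h in block:
                block_of[ci, h] = bi
    edges = np.cumsum([1.0 - sum(rates)] + rates)
    powers = (p + 1) ** np.arange(k, dtype=np.int64)

    def locus(n: int):
        cats = np.searchsorted(edges, rng.random((n, k)), side="right")
        keys = np.zeros((n, p), dtype=np.int64)
        for s in range(k):
            keys += block_of[cats[:, s]] * powers[s]
        sizes = (keys[:, :, None] == keys[:, None, :]).sum(axis=2)
        return keys, sizes

    contrib = np.zeros((n_rep, 2 * p))
    is_dup = rng.random(n_rep) < d
    n_dup = int(is_dup.sum())
    keys, sizes = locus(n_rep - n_dup)
    for i in range(1, p + 1):
        contrib[~is_dup, i - 1] = (sizes == i).sum(axis=1) / i
    if n_dup:
        k1, s1 = locus(n_dup)
        k2, s2 = locus(n_dup)
        dup = np.zeros((n_dup, 2 * p))
        anc = s1[:, 0] + s2[:, 0]
        for i in range(2, 2 * p + 1):
            dup[:, i - 1] += anc == i
        for s, kk in ((s1, k1), (s2, k2)):
            non_anc = kk != kk[:, [0]]
            for i in range(1, p + 1):
                dup[:, i - 1] += ((s == i) & non_anc).sum(axis=1) / i
        contrib[is_dup] = dup
    return contrib.mean(axis=0), contrib.std(axis=0) / np.sqrt(n_rep)


def moebius_recursive(tau, upsilon, partitions, _memo=None):
    """Defining recursion of the Moebius function on the partition lattice."""
    tau = normalize_partition(tau)
    upsilon = normalize_partition(upsilon)
    if _memo is None:
        _memo = {}
    key = (tau, upsilon)
    if key in _memo:
        return _memo[key]
    if tau == upsilon:
        result = 1
    elif not refines(tau, upsilon):
        result = 0
    else:
        result = -sum(
            moebius_recursive(tau, sigma, partitions, _memo)
            for sigma in partitions
            if sigma != upsilon and refines(tau, sigma) and refines(sigma, upsilon)
        )
    _memo[key] = result
    return result


def random_planted_kmer_set(rng: np.random.Generator, k: int, n_base: int) -> np.ndarray:
    """Random canonical k-mer codes with planted one-away neighbors and triples."""
    from ploidyscope.kmers import canonical_codes

    base = rng.integers(0, 1 << (2 * k), size=n_base, dtype=np.uint64)
    extra = []
    for code in base[: n_base // 3]:
        pos = int(rng.integers(0, k))
        delta = int(rng.integers(1, 4))
        extra.append(np.uint64(int(code) ^ (delta << (2 * (k - 1 - pos)))))
        if rng.random() < 0.3:
            delta2 = (delta + int(rng.integers(1, 3))) % 4
            if delta2:
                extra.append(np.uint64(int(code) ^ (delta2 << (2 * (k - 1 - pos)))))
    allc = np.concatenate([base, np.asarray(extra, dtype=np.uint64)])
    return np.unique(canonical_codes(allc, k))
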