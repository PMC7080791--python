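"""Ploidy inference from one-nucleotide-apart k-mer pairs.

Heterozygous loci produce pairs of genomic k-mers differing at exactly one
position. Writing the pair coverages as CovA >= CovB, each genomic
structure (AB, AAB, AABB, ...) projects onto a characteristic point in the
(CovA+CovB, CovB/(CovA+CovB)) plane: a structure with a major and b minor
copies sits at ((a+b)*lambda, b/(a+b)), lambda being the monoploid
coverage. The densest cluster ("smudge") identifies the ploidy.

Pair detection scans every k-mer position with that position masked:
k-mers colliding on a masked key differ at exactly that nucleotide. Both
orientations of each canonical k-mer are scanned so that pairs whose
alignment needs a reverse complement are found. A k-mer participating in
more than one pair signals repeat structure and is dropped together with
all its pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .fitting import find_error_valley
from .kmers import KmerCounts, decode_kmer, revcomp_codes
from .spectra import KmerDump, KmerSpectrum

MAX_TOTAL_COPY = 8  # annotate structures up to total copy number 8 (octoploid)


@dataclass
class KmerPair:
    """Two canonical k-mers one nucleotide apart, coverage-ordered."""

    seq_a: str
    seq_b: str
    cov_a: int
    cov_b: int


@dataclass
class PairCoordinates:
    total: float
    ratio: float


@dataclass
class PairSet:
    """Array-backed collection of one-away k-mer pairs (cov_a >= cov_b)."""

    k: int
    code_a: np.ndarray
    code_b: np.ndarray
    cov_a: np.ndarray
    cov_b: np.ndarray

    def __len__(self) -> int:
        return len(self.cov_a)

    def __iter__(self) -> Iterator[KmerPair]:
        for ca, cb, na, nb in zip(self.code_a, self.code_b, self.cov_a, self.cov_b):
            yield KmerPair(
                seq_a=decode_kmer(int(ca), self.k),
                seq_b=decode_kmer(int(cb), self.k),
                cov_a=int(na),
                cov_b=int(nb),
            )

    @property
    def totals(self) -> np.ndarray:
        return self.cov_a + self.cov_b

    @property
    def ratios(self) -> np.ndarray:
        return self.cov_b / (self.cov_a + self.cov_b)


@dataclass
class SmudgeAnnotation:
    """One genomic structure: a major copies, b minor copies."""

    label: str
    a: int
    b: int
    center_total: float
    center_ratio: float
    pair_count: int = 0


@dataclass
class LambdaEstimate:
    lam: float
    score: float
    n_pairs: int
    low_structure: bool

    def __float__(self) -> float:
        return self.lam


@dataclass
class PloidyEstimate:
    ploidy: int
    lambda_est: float
    smudge_table: list[SmudgeAnnotation]
    low_confidence: bool
    n_pairs: int


@dataclass
class SmudgeGrid:
    """2D pair-density histogram over (coverage sum, minor coverage ratio)."""

    counts: np.ndarray
    total_edges: np.ndarray
    ratio_edges: np.ndarray


def _as_counts(kmers: KmerCounts | KmerDump) -> KmerCounts:
    if isinstance(kmers, KmerDump):
        return KmerCounts.from_dict(kmers.records, kmers.k)
    return kmers


def select_genomic(
    kmers: KmerCounts | KmerDump, L: int | None = None
) -> KmerCounts:
    """Retain k-mers with count > L; by default L is the error valley of the
    count histogram, separating error k-mers from genomic ones."""
    counts = _as_counts(kmers)
    if L is None:
        cov, freq = counts.histogram()
        L = find_error_valley(KmerSpectrum(k=counts.k, coverages=cov, frequencies=freq))
    if L < 0:
        raise ValueError("coverage threshold must be non-negative")
    keep = counts.counts > L
    if not keep.any():
        raise ValueError(
            f"no k-mers above coverage threshold {L}; lower L or check coverage"
        )
    return KmerCounts(k=counts.k, codes=counts.codes[keep], counts=counts.counts[keep])


def _collision_pairs(keys: np.ndarray, owners: np.ndarray) -> tuple[list, set]:
    """Pairs and banned owners from one masked-key array (must be sorted by key)."""
    pairs: list[tuple[int, int]] = []
    banned: set[int] = set()
    eq = keys[1:] == keys[:-1]
    if not eq.any():
        return pairs, banned
    idx = np.nonzero(eq)[0]
    # group consecutive equal-key runs
    start = idx[0]
    prev = idx[0]
    runs = []
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((start, prev + 2))
            start = i
        prev = i
    runs.append((start, prev + 2))
    for s, e in runs:
        members = np.unique(owners[s:e])
        if len(members) == 1:
            continue  # palindrome colliding with its own reverse complement
        if len(members) == 2:
            pairs.append((int(members[0]), int(members[1])))
        else:
            # >=3 mutually one-away k-mers: every member is multi-paired and
            # would be removed by the ambiguity rule anyway
            banned.update(int(m) for m in members)
    return pairs, banned


def find_one_away_pairs(kmers: KmerCounts | KmerDump) -> PairSet:
    """All unambiguous pairs of k-mers differing at exactly one nucleotide.

    For each position, every retained k-mer (both orientations) is bucketed
    by its sequence with that position masked; bucket collisions are the
    one-away pairs. Pairs are deduplicated across positions/orientations,
    and any k-mer involved in more than one pair is discarded along with all
    its pairs.
    """
    counts = _as_counts(kmers)
    k = counts.k
    n = len(counts.codes)
    if n == 0:
        return PairSet(k=k, code_a=np.empty(0, np.uint64), code_b=np.empty(0, np.uint64),
                       cov_a=np.empty(0, np.int64), cov_b=np.empty(0, np.int64))
    fwd = counts.codes
    rev = revcomp_codes(fwd, k)
    oriented = np.concatenate([fwd, rev])
    owners_all = np.concatenate([np.arange(n, dtype=np.uint64)] * 2)

    compact = 2 * n < (1 << 24) and 2 * (k - 1) + 24 <= 64
    all_pairs: set[tuple[int, int]] = set()
    banned: set[int] = set()
    for pos in range(k):
        shift = np.uint64(2 * (k - 1 - pos))
        low_mask = (np.uint64(1) << shift) - np.uint64(1)
        high = (oriented >> (shift + np.uint64(2))) << shift
        masked_compact = high | (oriented & low_mask)  # gap removed: 2(k-1) bits
        if compact:
            packed = (masked_compact << np.uint64(24)) | owners_all
            packed = np.sort(packed)
            keys = packed >> np.uint64(24)
            owners = (packed & np.uint64((1 << 24) - 1)).astype(np.int64)
        else:
            order = np.argsort(masked_compact, kind="stable")
            keys = masked_compact[order]
            owners = owners_all[order].astype(np.int64)
        pairs, pos_banned = _collision_pairs(keys, owners)
        banned.update(pos_banned)
        for a, b in pairs:
            all_pairs.add((a, b) if a < b else (b, a))

    if not all_pairs:
        return PairSet(k=k, code_a=np.empty(0, np.uint64), code_b=np.empty(0, np.uint64),
                       cov_a=np.empty(0, np.int64), cov_b=np.empty(0, np.int64))
    pair_arr = np.asarray(sorted(all_pairs), dtype=np.int64)
    degree = np.bincount(pair_arr.ravel(), minlength=n)
    ok = (degree[pair_arr[:, 0]] == 1) & (degree[pair_arr[:, 1]] == 1)
    if banned:
        banned_arr = np.zeros(n, dtype=bool)
        banned_arr[list(banned)] = True
        ok &= ~banned_arr[pair_arr[:, 0]] & ~banned_arr[pair_arr[:, 1]]
    pair_arr = pair_arr[ok]

    cov = counts.counts
    i, j = pair_arr[:, 0], pair_arr[:, 1]
    swap = cov[j] > cov[i]
    a_idx = np.where(swap, j, i)
    b_idx = np.where(swap, i, j)
    return PairSet(
        k=k,
        code_a=counts.codes[a_idx],
        code_b=counts.codes[b_idx],
        cov_a=cov[a_idx],
        cov_b=cov[b_idx],
    )


def coordinates(pair: KmerPair) -> PairCoordinates:
    """Coverage-sum / minor-ratio coordinates of one pair; ratio <= 0.5."""
    total = pair.cov_a + pair.cov_b
    return PairCoordinates(total=float(total), ratio=pair.cov_b / total)


def smudge_centers(lambda_est: float, max_total: int = MAX_TOTAL_COPY) -> list[SmudgeAnnotation]:
    """Predicted smudge centers for all structures with a+b <= max_total."""
    if lambda_est <= 0:
        raise ValueError("lambda must be positive")
    if max_total > MAX_TOTAL_COPY:
        raise ValueError(f"max_total must be <= {MAX_TOTAL_COPY}")
    out = []
    for total_copy in range(2, max_total + 1):
        for b in range(1, total_copy // 2 + 1):
            a = total_copy - b
            out.append(
                SmudgeAnnotation(
                    label="A" * a + "B" * b,
                    a=a,
                    b=b,
                    center_total=total_copy * lambda_est,
                    center_ratio=b / total_copy,
                )
            )
    return out


_DISPERSION_INFLATION = 2.0  # variance headroom over pure Poisson coverage


def _nearest_center_dist2(
    lam: float, totals: np.ndarray, ratios: np.ndarray, max_total: int
) -> np.ndarray:
    """Squared Mahalanobis-style distance of each pair to its nearest center.

    Per-center variances follow Poisson coverage counting statistics: the
    coverage sum at a center of total T has variance ~T, and the minor
    ratio has variance ~r(1-r)/T, both inflated by a fixed factor to allow
    mild overdispersion.
    """
    best = np.full(len(totals), np.inf)
    for c in smudge_centers(lam, max_total):
        var_t = _DISPERSION_INFLATION * c.center_total
        var_r = _DISPERSION_INFLATION * c.center_ratio * (1 - c.center_ratio) / c.center_total
        d2 = (totals - c.center_total) ** 2 / var_t + (ratios - c.center_ratio) ** 2 / var_r
        np.minimum(best, d2, out=best)
    return best


def _score_lambda(
    lam: float, totals: np.ndarray, ratios: np.ndarray, max_total: int
) -> tuple[float, float]:
    """Soft likelihood-style score of a candidate lambda.

    Each pair contributes a Gaussian kernel of its distance to the nearest
    predicted center, so clouds sitting *between* or *offset from* centers
    are penalized, not merely uncounted. Returns (score, fraction of pairs
    within ~2 sigma of some center).
    """
    d2 = _nearest_center_dist2(lam, totals, ratios, max_total)
    return float(np.exp(-0.5 * d2).sum()), float(np.mean(d2 <= 4.0))


def _covb_mode(cov_b: np.ndarray) -> float:
    """Smoothed mode of the minor coverage CovB.

    Almost every genomic structure (AB, AAB, AAAB, AAABB, ...) has exactly
    one minor copy, so CovB piles up at 1 * lambda regardless of ploidy;
    unlike the coverage-sum marginal this carries no total-copy-number
    ambiguity. Structures with b minor copies contribute at b * lambda
    instead and are handled downstream.
    """
    hist = np.bincount(np.round(cov_b).astype(np.int64)).astype(float)
    width = max(3, int(np.argmax(hist) / 8) | 1)
    smooth = np.convolve(hist, np.ones(width) / width, mode="same")
    return float(np.argmax(smooth))


def _refine_lambda(
    lam: float, totals: np.ndarray, ratios: np.ndarray, max_total: int, iters: int = 4
) -> float:
    """Iteratively re-center lambda on the dominant smudge's median total."""
    for _ in range(iters):
        centers = smudge_centers(lam, max_total)
        best_count, best = -1, None
        for c in centers:
            sel = (np.abs(totals - c.center_total) <= lam / 2) & (
                np.abs(ratios - c.center_ratio) <= 0.08
            )
            cnt = int(sel.sum())
            if cnt > best_count:
                best_count, best = cnt, (c, sel)
        if best is None or best_count < 20:
            break
        c, sel = best
        lam_new = float(np.median(totals[sel])) / (c.a + c.b)
        if abs(lam_new - lam) < 1e-3 * lam:
            return lam_new
        lam = lam_new
    return lam


def estimate_lambda(
    pairs: PairSet, max_total: int = MAX_TOTAL_COPY, min_pairs: int = 100
) -> LambdaEstimate:
    """Monoploid coverage from the minor-coverage marginal of the pair cloud.

    The initial estimate is the smoothed mode of CovB (the minor copy of
    nearly every structure occurs once, so CovB concentrates at lambda
    independent of ploidy); it is then refined by re-centering on the median
    coverage sum of the dominant smudge. If a substantial share of pairs
    then sits below the lowest predicted structure (coverage sums under
    ~1.5 lambda), the scale was read one octave high -- the signature of a
    repeat-dominated cloud whose CovB mode is 2 lambda -- and lambda is
    halved and re-refined.
    """
    if len(pairs) < min_pairs:
        raise ValueError(f"need at least {min_pairs} pairs, got {len(pairs)}")
    totals = pairs.totals.astype(float)
    ratios = pairs.ratios

    lam = _covb_mode(pairs.cov_b)
    if lam < 2:
        raise ValueError("minor coverage mode too low to estimate lambda")
    lam = _refine_lambda(lam, totals, ratios, max_total)
    if np.mean(totals < 1.55 * lam) > 0.10:
        lam = _refine_lambda(lam / 2, totals, ratios, max_total)

    final_score, matched_frac = _score_lambda(lam, totals, ratios, max_total)
    return LambdaEstimate(
        lam=lam,
        score=final_score,
        n_pairs=len(pairs),
        low_structure=matched_frac < 0.5,
    )


def infer_ploidy(
    pairs: PairSet,
    lambda_est: float | LambdaEstimate,
    max_total: int = MAX_TOTAL_COPY,
) -> PloidyEstimate:
    """Assign pairs to their nearest smudge; ploidy = total copy number of
    the dominant smudge.

    Distance is normalized: coverage totals in units of lambda, ratios
    absolute. Pairs with totals beyond (max_total + 0.5) * lambda lie outside
    the annotated structures and are left unassigned. The estimate is
    flagged low-confidence when the dominant smudge holds <10% of pairs, or
    when the dominant structure is a multiple of a smaller one (e.g. AABB =
    2 x AB), since the same cloud then admits a coarser reading at a
    rescaled lambda.
    """
    lam = float(lambda_est)
    if lam <= 0:
        raise ValueError("lambda must be positive")
    centers = smudge_centers(lam, max_total)
    totals = pairs.totals.astype(float)
    ratios = pairs.ratios
    in_range = totals <= (max_total + 0.5) * lam
    t, r = totals[in_range], ratios[in_range]
    dist = np.full((len(centers), len(t)), np.inf)
    for ci, c in enumerate(centers):
        dist[ci] = ((t - c.center_total) / lam) ** 2 + (r - c.center_ratio) ** 2
    nearest = np.argmin(dist, axis=0)
    tally = np.bincount(nearest, minlength=len(centers))
    for ci, c in enumerate(centers):
        c.pair_count = int(tally[ci])
    table = sorted(centers, key=lambda c: -c.pair_count)
    dominant = table[0]
    low_confidence = (
        len(t) == 0
        or dominant.pair_count < 0.1 * len(pairs)
        or math.gcd(dominant.a, dominant.b) > 1
    )
    return PloidyEstimate(
        ploidy=dominant.a + dominant.b,
        lambda_est=lam,
        smudge_table=table,
        low_confidence=low_confidence,
        n_pairs=len(pairs),
    )


def make_grid(
    pairs: PairSet, lam: float, max_total: int = MAX_TOTAL_COPY, bins_per_lambda: int = 4
) -> SmudgeGrid:
    total_edges = np.arange(0, (max_total + 1) * lam + 1e-9, lam / bins_per_lambda)
    ratio_edges = np.linspace(0.0, 0.5, 2 * bins_per_lambda * max_total + 1)
    counts, te, re_ = np.histogram2d(
        pairs.totals.astype(float), pairs.ratios, bins=(total_edges, ratio_edges)
    )
    return SmudgeGrid(counts=counts, total_edges=te, ratio_edges=re_)


def render_smudgeplot(
    pairs: PairSet, estimate: PloidyEstimate, out: str | Path
) -> Path:
    """2D pair-density plot with smudge labels and the inferred ploidy."""
    if len(pairs) == 0:
        raise ValueError("cannot render a smudge plot without pairs")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lam = estimate.lambda_est
    grid = make_grid(pairs, lam)
    fig, ax = plt.subplots(figsize=(7, 6))
    ax.pcolormesh(
        grid.ratio_edges, grid.total_edges, grid.counts, cmap="viridis", shading="auto"
    )
    for c in estimate.smudge_table:
        if c.pair_count > 0:
            ax.text(c.center_ratio, c.center_total, c.label, color="white",
                    ha="center", va="center", fontsize=8)
    ax.set_xlim(0.0, 0.5)
    ax.set_xlabel("minor coverage ratio CovB / (CovA + CovB)")
    ax.set_ylabel("coverage sum CovA + CovB")
    ax.set_title(
        f"inferred ploidy = {estimate.ploidy} "
        f"(monoploid coverage ~ {lam:.1f}, {estimate.n_pairs} pairs)"
    )
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=100)
    plt.close(fig)
    return out
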