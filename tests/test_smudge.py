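import numpy as np
import pytest

from conftest import synthetic_pairs
from oracles import brute_force_pairs, random_planted_kmer_set
from ploidyscope.kmers import KmerCounts, canonical_kmer, encode_kmer
from ploidyscope.smudge import (
    KmerPair,
    PairSet,
    coordinates,
    estimate_lambda,
    find_one_away_pairs,
    infer_ploidy,
    render_smudgeplot,
    select_genomic,
    smudge_centers,
)
from ploidyscope.spectra import KmerDump


class TestSelectGenomic:
    def test_threshold_filters(self):
        dump = KmerDump(k=4, records={"AAAA": 1, "ACGT": 50})
        kept = select_genomic(dump, L=10)
        assert kept.to_dict() == {"ACGT": 50}

    def test_zero_threshold_is_identity(self):
        dump = KmerDump(k=4, records={"AAAA": 1, "ACGT": 50})
        kept = select_genomic(dump, L=0)
        assert kept.to_dict() == {"AAAA": 1, "ACGT": 50}

    def test_empty_result_advises_lower_threshold(self):
        dump = KmerDump(k=4, records={"AAAA": 1})
        with pytest.raises(ValueError, match="lower L"):
            select_genomic(dump, L=10)

    def test_default_threshold_from_count_valley(self, triploid_sim):
        genomic = select_genomic(triploid_sim.counts)
        # errors at 25x per homolog sit well below the genomic peak
        assert genomic.counts.min() > 2
        assert len(genomic) < len(triploid_sim.counts) / 4


class TestFindOneAwayPairs:
    def test_single_pair_detected_with_coverages(self):
        dump = KmerDump(k=5, records={"ACGTA": 30, "ACCTA": 28, "GGGGG": 40})
        pairs = list(find_one_away_pairs(dump))
        assert len(pairs) == 1
        pair = pairs[0]
        assert pair.cov_a == 30 and pair.cov_b == 28
        assert {pair.seq_a, pair.seq_b} == {
            canonical_kmer("ACGTA"), canonical_kmer("ACCTA")
        }

    def test_multi_paired_kmer_excluded_with_its_partners(self):
        # X pairs with both Y and Z: nothing is emitted
        dump = KmerDump(
            k=5, records={"ACGTA": 30, "ACCTA": 28, "ACTTA": 25, "GGGGG": 40}
        )
        assert len(find_one_away_pairs(dump)) == 0

    def test_pair_detectable_only_via_reverse_complement(self):
        # search for a canonical pair whose forward forms are >1 apart but
        # whose reverse-complement alignment is exactly 1 apart
        rng = np.random.default_rng(42)
        found = None
        while found is None:
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 5))
            rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            pos = int(rng.integers(0, 5))
            sub = "ACGT"[int(rng.integers(0, 4))]
            if sub == rc[pos]:
                continue
            mut = rc[:pos] + sub + rc[pos + 1 :]
            x, y = canonical_kmer(seq), canonical_kmer(mut)
            if x == y:
                continue
            fwd_ham = sum(a != b for a, b in zip(x, y))
            rc_y = y.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            rc_ham = sum(a != b for a, b in zip(x, rc_y))
            if fwd_ham > 1 and rc_ham == 1:
                found = (x, y)
        x, y = found
        dump = KmerDump(k=5, records={x: 12, y: 9, "GGGGG": 30})
        pairs = list(find_one_away_pairs(dump))
        assert len(pairs) == 1
        assert pairs[0].cov_a == 12 and pairs[0].cov_b == 9

    def test_matches_brute_force_oracle_on_planted_sets(self):
        # k = 25 exercises the wide-k search path (owner indices no longer
        # fit beside the masked key in one machine word)
        rng = np.random.default_rng(77)
        for trial in range(15):
            k = 25 if trial == 0 else int(rng.integers(5, 14))
            codes = random_planted_kmer_set(rng, k, int(rng.integers(50, 400)))
            counts = KmerCounts(
                k=k, codes=codes, counts=rng.integers(10, 90, len(codes)).astype(np.int64)
            )
            ps = find_one_away_pairs(counts)
            idx = {int(c): i for i, c in enumerate(counts.codes)}
            got = {
                tuple(sorted((idx[int(a)], idx[int(b)])))
                for a, b in zip(ps.code_a, ps.code_b)
            }
            assert got == brute_force_pairs(codes, k)


class TestCoordinates:
    def test_arithmetic(self):
        c = coordinates(KmerPair("A" * 5, "C" * 5, 67, 33))
        assert c.total == 100
        assert c.ratio == pytest.approx(0.33)

    def test_balanced_pair_is_half(self):
        c = coordinates(KmerPair("A" * 5, "C" * 5, 50, 50))
        assert c.ratio == 0.5

    def test_ratio_never_exceeds_half(self, triploid_pairs):
        assert (triploid_pairs.ratios <= 0.5).all()
        assert (triploid_pairs.cov_a >= triploid_pairs.cov_b).all()


class TestSmudgeCenters:
    def test_reference_layout_at_lambda_100(self):
        centers = {c.label: c for c in smudge_centers(100.0)}
        assert (centers["AB"].center_total, centers["AB"].center_ratio) == (200, 0.5)
        assert centers["AAB"].center_total == 300
        assert centers["AAB"].center_ratio == pytest.approx(1 / 3)
        assert centers["AAAB"].center_total == 400
        assert centers["AAAB"].center_ratio == pytest.approx(0.25)
        assert centers["AABB"].center_total == 400
        assert centers["AABB"].center_ratio == pytest.approx(0.5)

    def test_zero_lambda_rejected(self):
        with pytest.raises(ValueError):
            smudge_centers(0.0)

    def test_centers_pairwise_distinct(self):
        seen = set()
        for c in smudge_centers(100.0):
            key = (c.center_total, round(c.center_ratio, 9))
            assert key not in seen
            seen.add(key)


class TestEstimateLambda:
    def test_synthetic_centers_recovered_within_5_percent(self):
        rng = np.random.default_rng(31)
        pairs = synthetic_pairs(
            [(1, 1, 6000), (2, 1, 2000), (3, 1, 1000), (2, 2, 1000)], 100.0, rng
        )
        est = estimate_lambda(pairs)
        assert est.lam == pytest.approx(100.0, rel=0.05)
        assert not est.low_structure

    def test_too_few_pairs_rejected(self):
        rng = np.random.default_rng(32)
        pairs = synthetic_pairs([(1, 1, 50)], 100.0, rng)
        with pytest.raises(ValueError, match="at least"):
            estimate_lambda(pairs)

    def test_unstructured_pairs_flagged(self):
        rng = np.random.default_rng(33)
        n = 3000
        total = rng.uniform(40, 700, n)
        ratio = rng.uniform(0.02, 0.5, n)
        cov_b = np.maximum(np.round(total * ratio), 1).astype(np.int64)
        cov_a = np.maximum(np.round(total).astype(np.int64) - cov_b, cov_b)
        pairs = PairSet(
            k=21, code_a=np.zeros(n, np.uint64), code_b=np.zeros(n, np.uint64),
            cov_a=cov_a, cov_b=cov_b,
        )
        assert estimate_lambda(pairs).low_structure

    def test_simulated_triploid_lambda_matches_kmer_coverage(
        self, triploid_pairs, triploid_kmer_lambda
    ):
        est = estimate_lambda(triploid_pairs)
        assert est.lam == pytest.approx(triploid_kmer_lambda, rel=0.10)


class TestInferPloidy:
    def test_simulated_triploid_dominated_by_aab(self, triploid_pairs):
        est = infer_ploidy(triploid_pairs, estimate_lambda(triploid_pairs))
        assert est.ploidy == 3
        assert est.smudge_table[0].label == "AAB"
        assert not est.low_confidence

    def test_repeat_dominated_cloud_overcalls_with_warning(self):
        # synthetic stand-in for a genome whose repeat-borne AABB pairs
        # outnumber the heterozygous AB pairs (duplicated-after-divergence
        # repeats, outside the simulator's model): ploidy is overcalled as
        # tetraploid and the divisible dominant structure raises the flag
        rng = np.random.default_rng(34)
        pairs = synthetic_pairs([(2, 2, 6000), (1, 1, 3000), (3, 1, 800)], 100.0, rng)
        est = infer_ploidy(pairs, estimate_lambda(pairs))
        assert est.ploidy == 4
        assert est.smudge_table[0].label == "AABB"
        assert est.low_confidence

    def test_repeat_share_grows_with_repetitiveness(self):
        from ploidyscope.model import FormRates, caterpillar_topology
        from ploidyscope.simulate import SimulationDesign, run_design

        top = caterpillar_topology(2)
        shares = []
        for d in (0.05, 0.35):
            design = SimulationDesign(
                progenitor_size=400_000, p=2, topology=top,
                form_rates=FormRates.for_topology(top, [0.02]),
                d=d, coverage_per_homolog=25.0, seed=600,
            )
            sim = run_design(design)
            pairs = find_one_away_pairs(select_genomic(sim.counts))
            est = infer_ploidy(pairs, estimate_lambda(pairs))
            by_label = {c.label: c.pair_count for c in est.smudge_table}
            shares.append(by_label.get("AAAB", 0) / max(by_label.get("AB", 1), 1))
            assert est.ploidy == 2
        assert shares[1] > 2 * shares[0]

    def test_zero_lambda_rejected(self, triploid_pairs):
        with pytest.raises(ValueError):
            infer_ploidy(triploid_pairs, 0.0)


class TestRenderSmudgeplot:
    def test_smoke(self, tmp_path, triploid_pairs):
        est = infer_ploidy(triploid_pairs, estimate_lambda(triploid_pairs))
        out = render_smudgeplot(triploid_pairs, est, tmp_path / "smudge.png")
        assert out.exists() and out.stat().st_size > 0

    def test_empty_pairs_rejected(self, tmp_path):
        empty = PairSet(
            k=21, code_a=np.empty(0, np.uint64), code_b=np.empty(0, np.uint64),
            cov_a=np.empty(0, np.int64), cov_b=np.empty(0, np.int64),
        )
        est = None
        with pytest.raises(ValueError):
            render_smudgeplot(empty, est, tmp_path / "x.png")
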