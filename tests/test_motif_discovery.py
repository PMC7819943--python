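"""Seed-template clustering, membership rule and PWM construction."""

import itertools

import numpy as np
import pytest

from pbmotif import build_cluster, build_pwm, cluster_all, is_cluster_member
from pbmotif.kmer_stats import KmerStat
from pbmotif.motif_discovery import ClusterMember, MotifCluster


def member_oracle(candidate, seed, max_mismatch=2, core_len=5):
    """Exhaustive sliding-offset oracle for the membership rule."""
    k = len(seed)
    hits = []
    for off in range(-(k - core_len), k - core_len + 1):
        lo, hi = max(0, off), min(k, len(candidate) + off)
        if hi - lo < core_len:
            continue
        pairs = [(seed[i], candidate[i - off]) for i in range(lo, hi)]
        mism = sum(a != b for a, b in pairs)
        run = best = 0
        for a, b in pairs:
            run = run + 1 if a == b else 0
            best = max(best, run)
        if best >= core_len and (max_mismatch is None or mism <= max_mismatch):
            hits.append((mism, abs(off), 0 if off < 0 else 1, off))
    if not hits:
        return False, 0, 0
    mism, _, _, off = min(hits)
    return True, off, mism


class TestMembership:
    def test_identity(self):
        assert is_cluster_member("GATTGATTG", "GATTGATTG") == (True, 0, 0)

    def test_shift_by_one(self):
        ok, off, mism = is_cluster_member("ATTGATTGA", "GATTGATTG")
        assert ok and off == 1 and mism == 0

    def test_three_mismatches_everywhere_rejected(self):
        # candidate differs from an A-homopolymer seed at >2 positions in
        # every admissible offset and has no 5-nt exact run
        ok, _, _ = is_cluster_member("ACACACACA", "AAAAAAAAA")
        assert not ok

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            is_cluster_member("ACGT", "ACGTA")

    def test_oracle_agreement_all_5mers(self):
        seed = "ACGTA"
        for tup in itertools.product("ACGT", repeat=5):
            cand = "".join(tup)
            got = is_cluster_member(cand, seed, max_mismatch=2, core_len=3)
            assert got == member_oracle(cand, seed, 2, 3), cand

    def test_oracle_agreement_random_9mers(self):
        rng = np.random.default_rng(21)
        seed = "GATTGATTG"
        for _ in range(300):
            cand = "".join(rng.choice(list("ACGT"), size=9))
            assert is_cluster_member(cand, seed) == member_oracle(cand, seed)

    def test_mismatch_symmetry(self):
        rng = np.random.default_rng(22)
        for _ in range(100):
            a = "".join(rng.choice(list("ACGT"), size=9))
            b = "".join(rng.choice(list("ACGT"), size=9))
            ok_ab, off_ab, m_ab = is_cluster_member(a, b)
            ok_ba, off_ba, m_ba = is_cluster_member(b, a)
            assert ok_ab == ok_ba
            if ok_ab:
                assert m_ab == m_ba

    def test_core_only_rule(self):
        # max_mismatch=None: any 5-nt exact match suffices
        ok, _, _ = is_cluster_member("GACTTCGAT", "GACTTAAAA", max_mismatch=None)
        assert ok
        ok2, _, _ = is_cluster_member("GACTTCGAT", "GACTTAAAA", max_mismatch=2)
        assert not ok2


def _stat(kmer, inten=100.0, occ=10):
    return KmerStat(kmer, inten, occ, 1)


class TestBuildCluster:
    def test_seed_only(self):
        cl = build_cluster([_stat("GATTGATTG")])
        assert cl.n_members == 1 and cl.seed == "GATTGATTG"
        assert cl.consensus == "GATTGATTG"

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_cluster([])

    def test_planted_variants_recovered(self):
        rng = np.random.default_rng(23)
        seed = "GATTGATTG"
        planted = {seed}
        while len(planted) < 31:
            kmer = list(seed)
            for pos in rng.choice(9, size=rng.integers(1, 3), replace=False):
                kmer[pos] = rng.choice(list("ACGT"))
            cand = "".join(kmer)
            if member_oracle(cand, seed)[0]:
                planted.add(cand)
        randoms = set()
        while len(randoms) < 20:
            cand = "".join(rng.choice(list("ACGT"), size=9))
            if cand not in planted:
                randoms.add(cand)
        ranked = [_stat(seed, 1000.0)] + [
            _stat(k, 500.0) for k in sorted(planted - {seed})
        ] + [_stat(k, 100.0) for k in sorted(randoms)]
        cl = build_cluster(ranked)
        got = {m.kmer for m in cl.members}
        assert planted <= got
        chance = got - planted
        assert all(member_oracle(k, seed)[0] for k in chance)


class TestClusterAll:
    def test_mutually_nonmatching_singletons(self):
        kmers = ["AAAAAAAAA", "CCCCCCCCC", "GGGGGGGGG", "TTTTTTTTT"]
        clusters = cluster_all([_stat(k) for k in kmers])
        assert [c.seed for c in clusters] == kmers
        assert all(c.n_members == 1 for c in clusters)

    def test_partition_property(self):
        rng = np.random.default_rng(24)
        kmers = {"".join(rng.choice(list("ACGT"), size=9)) for _ in range(120)}
        ranked = [_stat(k, float(rng.integers(1, 1000))) for k in sorted(kmers)]
        clusters = cluster_all(ranked, max_clusters=1000)
        assigned = [m.kmer for c in clusters for m in c.members]
        assert len(assigned) == len(set(assigned))  # no k-mer in two clusters
        assert set(assigned) == kmers  # everything assigned

    def test_two_planted_families(self):
        fam1, fam2 = "GATTGATTG", "CCACGTCAG"
        ranked = [_stat(fam1, 1000.0), _stat(fam2, 900.0)]
        for i, base in enumerate("ACGT"):
            ranked.append(_stat(fam1[:3] + base + fam1[4:], 800.0 - i))
            ranked.append(_stat(fam2[:6] + base + fam2[7:], 700.0 - i))
        ranked.sort(key=lambda s: -s.intensity_ave)
        clusters = cluster_all(ranked)
        assert len(clusters) == 2
        assert clusters[0].seed == fam1 and clusters[1].seed == fam2
        assert fam1[1:] in clusters[0].consensus or fam1 in clusters[0].consensus
        assert clusters[0].n_members >= 4 and clusters[1].n_members >= 4


class TestBuildPwm:
    def test_identical_members_unit_columns(self):
        cl = MotifCluster(
            seed="ACGTACGTA",
            members=[ClusterMember("ACGTACGTA", 0, 0)] * 5,
        )
        counts, probs, consensus = build_pwm(cl)
        assert consensus == "ACGTACGTA"
        assert np.allclose(probs.max(axis=0), 1.0)
        assert counts.sum() == 5 * 9

    def test_hand_tally_with_offset(self):
        members = [
            ClusterMember("AAAAA", 0, 0),
            ClusterMember("AAAAA", 0, 0),
            ClusterMember("CAAAA", 1, 0),
        ]
        cl = MotifCluster(seed="AAAAA", members=members)
        counts, probs, consensus = build_pwm(cl, trim_support=0.0)
        # columns 0..5 (seed coords 0..4 plus offset+1 extension)
        assert counts.shape == (4, 6)
        # column 0: two A votes; column 1: A,A,C; column 5: one A
        assert counts[0, 0] == 2 and counts[1, 1] == 1 and counts[0, 5] == 1
        assert consensus[:2] == "AA"

    def test_column_normalisation(self):
        rng = np.random.default_rng(25)
        members = [
            ClusterMember("".join(rng.choice(list("ACGT"), size=9)), int(o), 0)
            for o in rng.integers(-2, 3, size=30)
        ]
        cl = MotifCluster(seed="GATTGATTG", members=members)
        _, probs, consensus = build_pwm(cl)
        assert np.allclose(probs.sum(axis=0), 1.0, atol=1e-9)
        assert len(consensus) == probs.shape[1]

    def test_low_support_ends_trimmed(self):
        members = [ClusterMember("GATTG", 0, 0)] * 10 + [ClusterMember("TGATT", -1, 0)]
        cl = MotifCluster(seed="GATTG", members=members)
        _, _, consensus = build_pwm(cl)
        # the single member extending one column 5' (support 1/11 < 25%) is trimmed
        assert consensus == "GATTG"

    def test_tie_goes_alphabetical_and_flagged(self):
        members = [ClusterMember("AAAAA", 0, 0), ClusterMember("CAAAA", 0, 0)]
        cl = MotifCluster(seed="AAAAA", members=members)
        _, _, consensus = build_pwm(cl)
        assert consensus[0] == "A"
        assert cl.tie_columns == [0]
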