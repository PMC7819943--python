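"""Mann-Whitney motif tests and steep/tail enrichment summaries."""

import itertools

import numpy as np
import pytest

from pbmotif import enrichment_summary, mwu_motif_test
from pbmotif.enrichment_stats import P_FLOOR
from pbmotif.signal_threshold import SegmentFit

from conftest import make_table


def mwu_enumeration_p(group1, group2):
    """Exact two-sided Mann-Whitney p by enumerating all group labellings."""
    pooled = sorted(group1 + group2)
    n1, n2 = len(group1), len(group2)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # no ties by construction

    def u_of(sel):
        r1 = sum(ranks[v] for v in sel)
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_of(group1)
    us = [u_of(c) for c in itertools.combinations(pooled, n1)]
    lo, hi = min(u_obs, n1 * n2 - u_obs), max(u_obs, n1 * n2 - u_obs)
    p = (sum(u <= lo for u in us) + sum(u >= hi for u in us)) / len(us)
    return min(1.0, p)


def motif_table(with_motif, without, motif="ACGTT", pad="AAAAAAAAAA"):
    """Intensity table whose first len(with_motif) probes contain the motif."""
    seqs, intens = {}, {}
    for i, v in enumerate(with_motif):
        pid = f"m{i}_1"
        seqs[pid] = pad + motif + pad
        intens[pid] = float(v)
    for i, v in enumerate(without):
        pid = f"n{i}_1"
        seqs[pid] = pad * 3
        intens[pid] = float(v)
    return make_table(seqs, intens)


class TestMwuMotifTest:
    def test_separated_triples_exact(self):
        t = motif_table([4, 5, 6], [1, 2, 3])
        stat, p = mwu_motif_test(t, "ACGTT")
        assert p == pytest.approx(0.1)
        # U for the motif group is maximal: 9; statistic reported for group 1
        assert stat in (0.0, 9.0)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 5), (6, 6), (1, 6)])
    def test_matches_full_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        vals = rng.permutation(np.arange(1, n1 + n2 + 1) * 7.0)
        g1, g2 = list(vals[:n1]), list(vals[n1:])
        t = motif_table(g1, g2)
        _, p = mwu_motif_test(t, "ACGTT")
        assert p == pytest.approx(mwu_enumeration_p(g1, g2))

    def test_rank_transform_invariance(self):
        rng = np.random.default_rng(41)
        g1 = list(rng.lognormal(1, 0.5, 30))
        g2 = list(rng.lognormal(1.3, 0.5, 40))
        t1 = motif_table(g1, g2)
        t2 = motif_table([v**3 for v in g1], [v**3 for v in g2])  # monotone map
        assert mwu_motif_test(t1, "ACGTT")[1] == pytest.approx(
            mwu_motif_test(t2, "ACGTT")[1]
        )

    def test_empty_group_errors(self):
        t = motif_table([1, 2], [])
        with pytest.raises(ValueError, match="every probe"):
            mwu_motif_test(t, "ACGTT")
        t2 = motif_table([], [1, 2])
        with pytest.raises(ValueError, match="no probe"):
            mwu_motif_test(t2, "ACGTT")

    def test_strong_separation_hits_floor(self):
        rng = np.random.default_rng(42)
        g1 = list(rng.normal(1e5, 10, 500))
        g2 = list(rng.normal(10, 1, 500))
        _, p = mwu_motif_test(motif_table(g1, g2), "ACGTT")
        assert p == P_FLOOR


def hand_fit(cutoff):
    return SegmentFit(-1, 1, -1, cutoff, 1, cutoff, 6, 0.0)


class TestEnrichmentSummary:
    def test_hand_tally_six_features(self):
        motif = "ATTGATTG"
        rc = "CAATCAAT"
        pad = "TTTTTTTTTTTTTTTT"
        seqs = {
            "a_1": pad + motif + pad,  # forward, steep
            "b_1": pad + motif + pad,  # forward, tail
            "c_1": pad + rc + pad,  # reverse, steep
            "d_1": pad * 3,  # none, steep
            "e_1": pad * 3,  # none, tail
            "f_1": pad * 3,  # none, tail
        }
        intens = {"a_1": 900.0, "b_1": 100.0, "c_1": 800.0, "d_1": 700.0, "e_1": 50.0, "f_1": 150.0}
        enr = enrichment_summary(make_table(seqs, intens), hand_fit(500.0), motif)
        assert enr.counts[("forward", "steep")] == 1
        assert enr.counts[("forward", "tail")] == 1
        assert enr.counts[("reverse", "steep")] == 1
        assert enr.counts[("reverse", "tail")] == 0
        assert enr.counts[("none", "steep")] == 1
        assert enr.counts[("none", "tail")] == 2
        assert enr.means_sd["forward"][0] == pytest.approx(500.0)
        assert enr.fold_forward == pytest.approx(500.0 / 300.0)
        assert enr.fold_reverse == pytest.approx(800.0 / 300.0)
        assert enr.strong_fraction == pytest.approx(2 / 3)

    def test_no_motif_reported_as_such(self):
        seqs = {"a_1": "A" * 30, "b_1": "A" * 30}
        enr = enrichment_summary(
            make_table(seqs, {"a_1": 10.0, "b_1": 20.0}), hand_fit(15.0), "CGCGCG"
        )
        assert enr.group_total("forward") == 0
        assert enr.fold_forward is None and enr.strong_fraction is None

    def test_partition_of_zones(self):
        rng = np.random.default_rng(43)
        seqs = {
            f"g{i}_1": "".join(rng.choice(list("ACGT"), size=40)) for i in range(200)
        }
        intens = {k: float(rng.lognormal(5, 1)) for k in seqs}
        t = make_table(seqs, intens)
        fit = hand_fit(float(np.median(list(intens.values()))))
        enr = enrichment_summary(t, fit, "ACGT")
        for zone in ("steep", "tail"):
            zone_n = sum(enr.counts[(g, zone)] for g in ("forward", "reverse", "none"))
            expected = int(
                np.sum(t.intensities > fit.cutoff)
                if zone == "steep"
                else np.sum(t.intensities <= fit.cutoff)
            )
            assert zone_n == expected

    def test_both_orientations_priority_forward(self):
        motif = "ATTGATTG"
        rc = "CAATCAAT"
        seqs = {"a_1": "TTTT" + motif + "TTTT" + rc + "TTTT", "b_1": "T" * 28}
        enr = enrichment_summary(
            make_table(seqs, {"a_1": 100.0, "b_1": 10.0}), hand_fit(50.0), motif
        )
        assert enr.n_both == 1
        assert enr.group_total("forward") == 1 and enr.group_total("reverse") == 0

    def test_palindrome_collapses_groups(self):
        motif = "ACGCGT"  # its own reverse complement
        seqs = {"a_1": "TTTT" + motif + "TTTT", "b_1": "T" * 14}
        enr = enrichment_summary(
            make_table(seqs, {"a_1": 100.0, "b_1": 10.0}), hand_fit(50.0), motif
        )
        assert enr.palindromic
        assert enr.group_total("forward") == 1 and enr.group_total("reverse") == 0
        assert enr.fold_reverse is None

    def test_planted_fold_recovered(self):
        # plant a motif with a known multiplicative boost; the measured fold
        # approaches the boost at 10^4 probes
        rng = np.random.default_rng(44)
        motif, boost, n = "ATTGATTG", 6.0, 10_000
        seqs, intens = {}, {}
        for i in range(n):
            pid = f"g{i}_1"
            core = "".join(rng.choice(list("ACT"), size=40))  # G-free background
            base = float(rng.lognormal(0, 0.5) * 1000)
            if i < n // 10:
                core = core[:16] + motif + core[24:]
                base *= boost
            seqs[pid] = core
            intens[pid] = base
        enr = enrichment_summary(
            make_table(seqs, intens), hand_fit(2000.0), motif
        )
        assert enr.fold_forward == pytest.approx(boost, rel=0.2)
        assert enr.p_value == P_FLOOR

    def test_strong_fraction_monotone_in_boost(self):
        rng = np.random.default_rng(45)
        motif = "ATTGATTG"
        fracs = []
        for boost in (1.5, 4.0, 16.0):
            seqs, intens = {}, {}
            for i in range(2000):
                pid = f"g{i}_1"
                core = "".join(rng.choice(list("ACT"), size=40))
                base = float(rng.lognormal(0, 0.5) * 1000)
                if i % 10 == 0:
                    core = core[:16] + motif + core[24:]
                    base *= boost
                seqs[pid] = core
                intens[pid] = base
            enr = enrichment_summary(make_table(seqs, intens), hand_fit(3000.0), motif)
            fracs.append(enr.strong_fraction)
        assert fracs == sorted(fracs)
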