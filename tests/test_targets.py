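"""Duplex scoring, transcript scanning, consensus, inhibition and cleavage."""

import math

import numpy as np
import pytest

from mirkit import targets
from mirkit.seqio import SequenceRecord, reverse_complement
from mirkit.targets import (
    classify_inhibition,
    intersect_modes,
    pair_class,
    position_weight,
    predict_cleavage_site,
    scan_transcript,
    score_duplex,
)

MIRNA = "UGACAGAAGAGAGUGAGCACA"  # 21 nt


def site_with(mirna: str, edits: dict) -> str:
    """Reverse complement with per-miRNA-position edits ('gu' or a base)."""
    site = list(reverse_complement(mirna))
    L = len(mirna)
    for pos, what in edits.items():
        j = L - pos  # site index facing miRNA position pos
        if what == "gu":
            b = mirna[pos - 1]
            site[j] = {"G": "U", "U": "G"}[b]
        else:
            site[j] = what
    return "".join(site)


def enumerate_min_cost(mirna: str, site: str) -> float:
    """Exhaustive alignment enumeration oracle (short miRNAs only).

    All monotone alignments consuming the full miRNA, target overhangs free
    at both ends; penalties mismatch 1 / G:U 0.5 / indel 2, doubled at
    miRNA positions 2-13.
    """
    rev = site[::-1]
    I, J = len(mirna), len(rev)
    best = [math.inf]

    def rec(i, j, cost):
        if cost >= best[0]:
            return
        if i == I:
            best[0] = cost  # trailing target overhang free
            return
        pos = i + 1
        w = position_weight(pos)
        if j < J:
            cls = pair_class(mirna[i], rev[j])
            c = {"match": 0.0, "gu": 0.5 * w, "mismatch": 1.0 * w}[cls]
            rec(i + 1, j + 1, cost + c)
            if i > 0:  # target bulge between consumed miRNA bases
                rec(i, j + 1, cost + 2.0 * position_weight(min(i + 1, I)))
        rec(i + 1, j, cost + 2.0 * w)  # miRNA base unpaired

    # leading target overhang: any starting j is free
    for j0 in range(J + 1):
        rec(0, j0, 0.0)
    return best[0]


class TestScoreDuplex:
    def test_perfect_site_scores_zero(self):
        site = reverse_complement(MIRNA)
        for mode in targets.MODES:
            assert score_duplex(MIRNA, site, mode).expectation == 0.0

    def test_gu_position_weighting(self):
        # G:U outside the core (position 15) costs 0.5; inside (position 6) 1.0
        assert score_duplex(MIRNA, site_with(MIRNA, {15: "gu"})).expectation == 0.5
        assert score_duplex(MIRNA, site_with(MIRNA, {6: "gu"})).expectation == 1.0

    def test_core_mismatch_doubled(self):
        site = site_with(MIRNA, {5: "G"})  # miRNA pos 5 is A; target G mismatches
        sc = score_duplex(MIRNA, site)
        assert sc.expectation == 2.0
        assert sc.per_position[4] == "mismatch"

    def test_hspsize_window_excludes_terminal_penalty(self):
        site = site_with(MIRNA, {21: "C"})  # mismatch at the miRNA 3' end (A->site C)
        tf = score_duplex(MIRNA, site, "targetfinder_like")
        psr = score_duplex(MIRNA, site, "psrnatarget_like")
        assert tf.expectation == 1.0
        assert psr.expectation == 0.0  # best 20-nt window skips position 21

    def test_expectation_equals_per_position_penalty_sum(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            m = "".join(rng.choice(list("ACGU"), size=21))
            site = "".join(rng.choice(list("ACGU"), size=21))
            sc = score_duplex(m, site, "targetfinder_like")
            total = 0.0
            for pos, st in enumerate(sc.per_position, start=1):
                w = position_weight(pos)
                total += {"match": 0.0, "gu": 0.5 * w, "mismatch": 1.0 * w,
                          "gap": 2.0 * w, "unscored": 0.0}[st]
            # target insertions are not visible per-position; expectation >= sum
            assert sc.expectation >= total - 1e-9

    def test_matches_enumeration_oracle_short(self):
        """The DP core agrees with exhaustive alignment enumeration."""
        rng = np.random.default_rng(9)
        for _ in range(30):
            m = "".join(rng.choice(list("ACGU"), size=8))
            near = list(reverse_complement(m))
            for k in rng.choice(8, size=2, replace=False):
                near[k] = str(rng.choice(list("ACGU")))
            site = "".join(near)
            cost, _, _ = targets._align_window(m, 1, site[::-1])
            assert cost == pytest.approx(enumerate_min_cost(m, site))

    def test_wobble_costs_half_a_mismatch_everywhere(self):
        # at any G/U miRNA position, a wobble costs exactly half a mismatch
        rng = np.random.default_rng(12)
        for _ in range(10):
            m = "".join(rng.choice(list("ACGU"), size=21))
            eligible = [p for p in range(2, 21) if m[p - 1] in "GU"]
            if not eligible:
                continue
            pos = int(rng.choice(eligible))
            gu = score_duplex(m, site_with(m, {pos: "gu"})).expectation
            mm_base = sorted(set("ACGU") - set(
                {"A": "U", "C": "G", "G": "CU", "U": "AG"}[m[pos - 1]]
            ))[0]
            mm = score_duplex(m, site_with(m, {pos: mm_base})).expectation
            assert gu == pytest.approx(mm / 2)

    def test_length_precondition(self):
        with pytest.raises(ValueError):
            score_duplex("ACGUACGU", "ACGUACGU")


class TestScanTranscript:
    def _embed(self, site, rng, length=400, pos=150):
        bg = "".join(rng.choice(list("ACGU"), size=length))
        return bg[:pos] + site + bg[pos + len(site):]

    def test_designed_site_found_in_both_modes(self):
        rng = np.random.default_rng(21)
        site = reverse_complement(MIRNA)
        tr = SequenceRecord("t", self._embed(site, rng))
        mir = SequenceRecord("m", MIRNA)
        hits_tf = scan_transcript(mir, tr, "targetfinder_like")
        assert len(hits_tf) == 1
        assert (hits_tf[0].site_start, hits_tf[0].site_end) == (151, 171)
        # the windowed mode pairs only its best 20-nt window (positions 1-20),
        # leaving the site base opposite miRNA position 21 outside the interval
        hits_psr = scan_transcript(mir, tr, "psrnatarget_like")
        assert len(hits_psr) == 1
        assert (hits_psr[0].site_start, hits_psr[0].site_end) == (152, 171)

    def test_threshold_semantics_differ(self):
        # penalty 3.5: reportable under score<4 but not expectation<=3
        rng = np.random.default_rng(22)
        site = site_with(MIRNA, {6: "gu", 15: "G", 16: "G", 17: "gu"})
        # core wobble 1.0 + two outer mismatches 2.0 + outer wobble 0.5
        assert score_duplex(MIRNA, site).expectation == 3.5
        tr = SequenceRecord("t", self._embed(site, rng))
        mir = SequenceRecord("m", MIRNA)
        assert scan_transcript(mir, tr, "psrnatarget_like") == []
        assert len(scan_transcript(mir, tr, "targetfinder_like")) == 1

    def test_background_rate_is_negligible(self):
        """A 21-nt miRNA almost never hits a random 2-kb transcript at <= 3."""
        total = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            mir = SequenceRecord("m", "".join(rng.choice(list("ACGU"), size=21)))
            tr = SequenceRecord("t", "".join(rng.choice(list("ACGU"), size=2000)))
            total += len(scan_transcript(mir, tr, "psrnatarget_like"))
        assert total == 0

    def test_transcript_shorter_than_mirna(self):
        with pytest.raises(ValueError):
            scan_transcript(SequenceRecord("m", MIRNA), SequenceRecord("t", "ACGU"))


class TestIntersectModes:
    def _hit(self, start=151, end=171, mode="psrnatarget_like"):
        sc = score_duplex(MIRNA, reverse_complement(MIRNA), mode)
        return targets.TargetHit("m", "t", start, end, sc, inhibition="cleavage")

    def test_one_mode_only_excluded(self):
        assert intersect_modes([self._hit()], []) == []

    def test_identical_hits_become_one_consensus(self):
        cons = intersect_modes([self._hit()], [self._hit(mode="targetfinder_like")])
        assert len(cons) == 1
        assert cons[0].psr_expectation == cons[0].tf_score == 0.0

    def test_disjoint_intervals_excluded(self):
        cons = intersect_modes(
            [self._hit(100, 120)], [self._hit(300, 320, "targetfinder_like")]
        )
        assert cons == []


class TestInhibitionAndCleavage:
    def _scan_one(self, site, pos=150, length=400):
        rng = np.random.default_rng(31)
        bg = "".join(rng.choice(list("ACGU"), size=length))
        tr = SequenceRecord("t", bg[:pos] + site + bg[pos + len(site):])
        hits = scan_transcript(SequenceRecord("m", MIRNA), tr, "targetfinder_like")
        assert len(hits) == 1
        return hits[0]

    def test_perfect_duplex_is_cleavage(self):
        h = self._scan_one(reverse_complement(MIRNA))
        assert h.inhibition == "cleavage"

    def test_mismatch_at_position_10_is_translation(self):
        # miRNA pos 10 is A; target A cannot pair, forcing a central mismatch
        h = self._scan_one(site_with(MIRNA, {10: "A"}))
        assert h.inhibition == "translation"
        with pytest.raises(ValueError):
            predict_cleavage_site(h)

    def test_wobble_at_position_11_counts_as_pairing(self):
        h = self._scan_one(site_with(MIRNA, {11: "gu"}))
        assert h.inhibition == "cleavage"
        assert classify_inhibition(h, central_gu_is_mismatch=True) == "translation"

    def test_cleavage_coordinate_opposite_position_10(self):
        # perfect 21-nt duplex at transcript positions 151-171:
        # miRNA nt 1 pairs 171, nt 10 pairs 162; cut between 161 and 162
        h = self._scan_one(reverse_complement(MIRNA))
        assert (h.site_start, h.site_end) == (151, 171)
        assert h.cleavage_position == 162
        assert predict_cleavage_site(h) == 162

    def test_cleavage_follows_pairing_map_with_bulge(self):
        # a target bulge 3' of the cut shifts the register; the coordinate
        # follows the pairing map rather than a fixed offset
        site = reverse_complement(MIRNA)
        bulged = site[:4] + "A" + site[4:]  # insertion opposite miRNA pos ~17
        sc = score_duplex(MIRNA, bulged, "targetfinder_like")
        h = targets.classify_and_annotate(
            targets.TargetHit("m", "t", 151, 151 + len(bulged) - 1, sc)
        )
        assert h.cleavage_position == 151 + sc.pair_map[10] - 1
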