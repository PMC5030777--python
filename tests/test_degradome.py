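import numpy as np
import pytest

from srnakit._seq import revcomp
from srnakit.degradome import (
    DegradomeProfile,
    call_targets,
    classify_category,
    predict_cleavage,
    preprocess_degradome,
    score_alignment,
)

MIR = "TGGAGCTCCCTTCATTCCAAT"  # 21 nt
TARGET_SITE = revcomp(MIR)  # perfectly complementary window

WOBBLE_PARTNER = {"G": "T", "T": "G"}  # miRNA base -> target base forming G:U


def brute_force_score(mirna, window):
    """Independent ungapped scorer: walk miRNA 5'->3' against the
    antiparallel target window, position weights applied directly."""
    assert len(mirna) == len(window)
    total = 0.0
    for i, mb in enumerate(mirna):  # i+1 = miRNA position from 5' end
        tb = window[len(window) - 1 - i]  # antiparallel partner
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}[mb]
        if tb == comp:
            pen = 0.0
        elif WOBBLE_PARTNER.get(mb) == tb:
            pen = 0.5
        else:
            pen = 1.0
        total += pen * (2.0 if 2 <= i + 1 <= 13 else 1.0)
    return total


class TestPreprocess:
    def test_polyn_strictly_above_70pct(self):
        tags = {"A" * 15 + "CGTGC": 3, "A" * 14 + "CGTGCC": 2}
        survivors, ledger = preprocess_degradome(tags)
        assert ledger == {"A" * 15 + "CGTGC": "polyN"}  # 75% removed
        assert "A" * 14 + "CGTGCC" in survivors  # exactly 70% kept

    def test_priority_rfam_over_genbank_over_polyn(self):
        polya = "A" * 16 + "CGTG"
        db = {polya: "Rfam", "CCCCGGGGCCCCGGGGAAAA": "GenBank"}
        survivors, ledger = preprocess_degradome(
            {polya: 1, "CCCCGGGGCCCCGGGGAAAA": 1, "TTTTTTTTTTTTTTTTTGCA": 1}, db
        )
        assert ledger[polya] == "Rfam"  # not polyN
        assert ledger["CCCCGGGGCCCCGGGGAAAA"] == "GenBank"
        assert ledger["TTTTTTTTTTTTTTTTTGCA"] == "polyN"
        assert survivors == {}


class TestScore:
    def test_perfect_complement_scores_zero(self):
        assert score_alignment(MIR, TARGET_SITE).score == 0.0

    def test_gu_outside_core_half_point(self):
        # G:U at miRNA position 17: miRNA G pairs target T
        m = list(MIR)
        pos = 17
        m[pos - 1] = "G"
        window = list(revcomp("".join(m)))
        window[len(window) - pos] = "T"  # antiparallel partner of position 17
        aln = score_alignment("".join(m), "".join(window))
        assert aln.score == 0.5

    def test_mismatch_in_core_doubled(self):
        window = list(TARGET_SITE)
        # mismatch opposite miRNA position 5 (inside the 2-13 core)
        idx = len(window) - 5
        window[idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[window[idx]]
        assert score_alignment(MIR, "".join(window)).score == 2.0

    def test_brute_force_oracle_all_single_mismatches(self):
        """DP scorer equals the independent positional scorer for every
        single-mismatch and single-wobble variant."""
        for pos in range(1, 22):
            for alt in "ACGT":
                window = list(TARGET_SITE)
                idx = len(window) - pos
                if window[idx] == alt:
                    continue
                w = "".join(window[:idx] + [alt] + window[idx + 1 :])
                expected = brute_force_score(MIR, w)
                got = score_alignment(MIR, w).score
                assert got == pytest.approx(expected)

    def test_monotone_under_added_mismatches(self, rng):
        window = list(TARGET_SITE)
        prev = 0.0
        for pos in rng.permutation(21)[:6]:
            window[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[window[pos]]
            score = score_alignment(MIR, "".join(window)).score
            assert score >= prev
            prev = score

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            score_alignment("", TARGET_SITE)


class TestCleavage:
    def test_coordinate_arithmetic(self):
        aln = score_alignment(MIR, TARGET_SITE)
        # ungapped 21-nt window starting at 925: position 10 of the miRNA
        # pairs transcript coordinate 925 + 21 - 10
        assert predict_cleavage(aln, 925, 21) == 936

    def test_shift_equivariance(self):
        aln = score_alignment(MIR, TARGET_SITE)
        assert predict_cleavage(aln, 926, 21) == predict_cleavage(aln, 925, 21) + 1

    def test_window_outside_transcript_errors(self):
        aln = score_alignment(MIR, TARGET_SITE)
        with pytest.raises(ValueError, match="outside"):
            predict_cleavage(aln, 990, 21, transcript_length=1000)

    def test_gapped_alignment_site_consistent(self):
        """A 1-nt bulge in the target shifts coordinates through the
        alignment columns exactly as an enumeration of columns predicts."""
        window = TARGET_SITE[:3] + "A" + TARGET_SITE[3:]  # insertion near 3' end
        aln = score_alignment(MIR, window)
        site = predict_cleavage(aln, 100, len(window))
        col = next(c for c in aln.columns if c.mirna_pos == 10)
        expected = 100 + (len(window) - 1 - col.target_idx)
        assert site == expected


class TestCategories:
    @pytest.mark.parametrize(
        "profile,site,expected",
        [
            ({100: 10, 200: 3, 300: 2}, 100, 0),
            ({100: 10, 200: 10, 300: 2}, 100, 1),
            ({100: 5, 200: 10, 300: 2, 400: 2, 500: 2}, 100, 2),
            ({100: 2, 200: 10, 300: 5, 400: 5}, 100, 3),
            ({100: 1}, 100, 4),
            ({100: 1, 200: 50}, 100, 4),  # single raw read wins over 0-3
        ],
    )
    def test_examples(self, profile, site, expected):
        assert classify_category(profile, site) == expected

    def test_unsupported_site_errors(self):
        with pytest.raises(ValueError):
            classify_category({100: 5}, 200)

    def test_brute_force_oracle_random_profiles(self):
        """Direct max/median comparison agrees on 1000 random profiles."""
        from statistics import median

        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            positions = rng.choice(np.arange(1, 2000), size=n, replace=False)
            values = rng.geometric(0.2, size=n)
            profile = {int(p): int(v) for p, v in zip(positions, values)}
            site = int(rng.choice(list(profile)))
            a = profile[site]
            if a == 1:
                expected = 4
            else:
                mx, med = max(profile.values()), median(profile.values())
                if a == mx:
                    expected = 0 if list(profile.values()).count(mx) == 1 else 1
                elif a > med:
                    expected = 2
                else:
                    expected = 3
            assert classify_category(profile, site) == expected


class TestCallTargets:
    def _setup(self, extra_mm=0):
        rng = np.random.default_rng(8)
        body = "".join(rng.choice(list("ACGT"), size=400))
        site = 201
        window = list(TARGET_SITE)
        for i in range(extra_mm):  # mismatches outside the core (positions 14+)
            pos = 14 + i
            idx = len(window) - pos
            window[idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[window[idx]]
        wstart = site - (21 - 10)
        seq = body[: wstart - 1] + "".join(window) + body[wstart + 20 :]
        profile = DegradomeProfile("t1", len(seq), {site: 30, 50: 4, 300: 2})
        return {"m1": MIR}, {"t1": seq}, {"t1": profile}, site

    def test_planted_target_category0(self):
        mirnas, transcripts, profiles, site = self._setup()
        out = call_targets(mirnas, transcripts, profiles)
        assert len(out) == 1
        t = out[0]
        assert (t.mirna, t.transcript, t.category) == ("m1", "t1", 0)
        assert t.cleavage_position == site
        assert t.fragment_abundance == 30

    def test_score_threshold_boundary(self):
        # 4 mismatches (positions 14-17) + 1 wobble (position 21),
        # all outside the core: score exactly 4.5 -> reported
        mirnas, transcripts, profiles, site = self._setup(extra_mm=4)
        tseq = list(transcripts["t1"])
        wstart = site - 11
        idx21 = wstart - 1 + (21 - 21)  # window base pairing miRNA position 21
        assert MIR[20] in WOBBLE_PARTNER
        tseq[idx21] = WOBBLE_PARTNER[MIR[20]]
        transcripts["t1"] = "".join(tseq)
        out = call_targets(mirnas, transcripts, profiles, max_score=4.5)
        assert out and out[0].score == pytest.approx(4.5)
        # 5 mismatches outside the core = 5.0 -> rejected
        mirnas, transcripts, profiles, site = self._setup(extra_mm=5)
        assert call_targets(mirnas, transcripts, profiles, max_score=4.5) == []
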