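import numpy as np
import pytest

from srnakit._seq import revcomp
from srnakit.annotation import match_genome
from srnakit.io_formats import TagTable
from srnakit.mirna import (
    MirbaseEntry,
    align_to_mirbase,
    build_family_representatives,
    check_star_overhang,
    evaluate_hairpin,
    fold_hairpin,
    is_single_hairpin,
    merge_replicates,
    predict_novel,
    quantify_known,
)
from srnakit.synthetic import SimConfig, gen_mirna_locus, gen_srna_libraries

MAT = "TGGATTGAAGGGAGCTCTACA"  # 21 nt


def mutate(seq, positions, to="A"):
    out = list(seq)
    for p in positions:
        out[p] = "C" if seq[p] == to else to
    return "".join(out)


class TestAlignToMirbase:
    db = [
        MirbaseEntry("m1", "fam1", MAT),
        MirbaseEntry("m1-pre", "fam1", "GCGC" + MAT + "ATAT", kind="precursor"),
        MirbaseEntry("m2", "fam2", "ACACACACACACACACACACA"),
    ]

    def test_identical_tag_zero_edits(self):
        out = align_to_mirbase(MAT, self.db)
        assert out[0].family == "fam1"
        assert (out[0].mismatches, out[0].gaps) == (0, 0)

    def test_two_substitutions_assigned(self):
        tag = mutate(MAT, [4, 9])
        out = align_to_mirbase(tag, self.db)
        assert any(a.family == "fam1" and a.mismatches == 2 for a in out)

    def test_three_substitutions_rejected(self):
        tag = mutate(MAT, [4, 9, 14])
        assert all(a.family != "fam1" for a in align_to_mirbase(tag, [self.db[0]]))

    def test_gap_budget(self):
        # homopolymer-run reference makes gap placement unambiguous; only
        # internal runs are mutated so free reference ends cannot absorb them
        ref = "AAAA" + "CCCC" + "GGGG" + "TTTT" + "CCCC" + "A"
        db = [MirbaseEntry("r", "famR", ref)]
        one_del = ref[:6] + ref[7:]
        out = align_to_mirbase(one_del, db)
        assert out and out[0].gaps == 1 and out[0].mismatches == 0
        four_del = "AAAA" + "CCC" + "GGG" + "TTT" + "CCC" + "A"
        assert align_to_mirbase(four_del, db) == []

    def test_infix_alignment_into_precursor(self):
        out = align_to_mirbase(MAT, [self.db[1]])
        assert out and (out[0].mismatches, out[0].gaps) == (0, 0)


class TestRepresentatives:
    def test_argmax_and_ties(self):
        tags = TagTable.from_rows(
            [("AAAA", {"l": 10}), ("CCCC", {"l": 3}), ("GGGG", {"l": 10})],
            ["l"],
        )
        reps = build_family_representatives(
            {"AAAA": ["f"], "CCCC": ["f"], "GGGG": ["f"]}, tags
        )
        assert reps == {"f": "AAAA"}  # tie 10 vs 10 -> lexicographically smaller

    def test_single_tag_family(self):
        tags = TagTable.from_rows([("ACGT", {"l": 1})], ["l"])
        assert build_family_representatives({"ACGT": ["f"]}, tags) == {"f": "ACGT"}


class TestQuantifyKnown:
    def test_sum_within_two_mismatches(self):
        variant = mutate(MAT, [3])
        tags = TagTable.from_rows([(MAT, {"l": 7}), (variant, {"l": 3})], ["l"])
        counts = quantify_known(tags, {"fam1": MAT})
        assert counts["fam1"]["l"] == 10

    def test_three_mismatches_excluded(self):
        variant = mutate(MAT, [3, 8, 13])
        tags = TagTable.from_rows([(MAT, {"l": 7}), (variant, {"l": 3})], ["l"])
        assert quantify_known(tags, {"fam1": MAT})["fam1"]["l"] == 7

    def test_equidistant_tag_counted_once(self):
        rep_a = MAT
        rep_b = mutate(MAT, [0, 1, 2, 3])
        tag = mutate(MAT, [0, 1])  # 2 mm from both representatives
        tags = TagTable.from_rows(
            [(rep_a, {"l": 50}), (rep_b, {"l": 5}), (tag, {"l": 3})], ["l"]
        )
        counts = quantify_known(tags, {"famA": rep_a, "famB": rep_b})
        assert counts["famA"]["l"] == 53  # tie -> higher-expressed representative
        assert counts["famB"]["l"] == 5
        total = sum(sum(v.values()) for v in counts.values())
        assert total == 58  # no tag counted twice


class TestFolding:
    def test_perfect_inverted_repeat_single_hairpin(self, rng):
        stem = "".join(rng.choice(list("ACGT"), size=30))
        seq = stem + "TTCTTTCT" + revcomp(stem)
        hp = fold_hairpin(seq)
        assert hp.mfe < 0
        assert is_single_hairpin(hp, (0, 21))

    def test_homopolymer_no_structure(self):
        hp = fold_hairpin("A" * 100)
        assert hp.structure == "." * 100
        assert not is_single_hairpin(hp, (0, 21))

    def test_deterministic(self, canonical_locus):
        a = fold_hairpin(canonical_locus.precursor)
        b = fold_hairpin(canonical_locus.precursor)
        assert a.structure == b.structure and a.mfe == b.mfe

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            fold_hairpin("ACGTX" * 20)

    def test_length_window_enforced(self):
        with pytest.raises(ValueError, match="length"):
            fold_hairpin("ACGT" * 5)

    def test_mfe_monotone_in_stem_length(self, rng):
        """Extending a perfectly complementary stem never destabilises."""
        core = "".join(rng.choice(list("ACGT"), size=60))
        mfes = []
        for n in range(25, 55, 5):
            stem = core[:n]
            mfes.append(fold_hairpin(stem + "TTTCTTTC" + revcomp(stem)).mfe)
        assert all(b <= a + 1e-6 for a, b in zip(mfes, mfes[1:]))


class TestStarOverhang:
    def test_canonical_locus_star_found(self, sim_config, canonical_locus):
        t = canonical_locus
        hp = fold_hairpin(t.precursor)
        star = check_star_overhang(hp, (t.mature_offset, t.mature_offset + 21))
        assert star is not None
        assert t.precursor[star[0] : star[1]] == t.star

    def test_blunt_end_fails(self, rng):
        # mature flush at the precursor 5' end leaves no room for the
        # star's 2-nt 3' overhang
        stem = "".join(rng.choice(list("ACGT"), size=30))
        seq = stem + "TTCTTTCT" + revcomp(stem)
        hp = fold_hairpin(seq)
        assert check_star_overhang(hp, (0, 21)) is None

    def test_mature_spanning_loop_fails(self, canonical_locus):
        hp = fold_hairpin(canonical_locus.precursor)
        centre = len(canonical_locus.precursor) // 2
        assert check_star_overhang(hp, (centre - 10, centre + 11)) is None


class TestPredictNovel:
    def _dataset(self, n_loci=4, min_counts=20, star_counts=8, seed=1):
        cfg = SimConfig(seed=seed, n_mirna_loci=n_loci, genome_length=20000,
                        noise_tag_rate=0.0)
        loci = [gen_mirna_locus(cfg, arm="5p" if i % 2 else "3p", seed=seed * 50 + i,
                                name=f"L{i}") for i in range(n_loci)]
        rng = np.random.default_rng(seed)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=20000))}
        g = list(genome["chr1"])
        rows = []
        for i, t in enumerate(loci):
            start = 2000 + 4000 * i
            g[start : start + len(t.precursor)] = list(t.precursor)
            rows.append((t.mature, {"l1": min_counts, "l2": min_counts}))
            rows.append((t.star, {"l1": star_counts, "l2": star_counts}))
        genome["chr1"] = "".join(g)
        tags = TagTable.from_rows(rows, ["l1", "l2"])
        return loci, genome, tags

    def test_full_recall_on_planted_loci(self):
        loci, genome, tags = self._dataset()
        hits = match_genome(tags, genome)
        records = predict_novel(tags, genome, hits)
        recovered = {r.mature for r in records}
        assert {t.mature for t in loci} <= recovered

    def test_count_threshold_inclusive(self, sim_config):
        """A summed mature count of exactly 5 is accepted; 4 is not."""
        for total, expected in ((5, True), (4, False)):
            loci, genome, tags = self._dataset(n_loci=1, min_counts=0, star_counts=1)
            mature = loci[0].mature
            tags.counts.loc[mature, "l1"] = total
            hits = match_genome(tags, genome)
            found = any(r.mature == mature for r in predict_novel(tags, genome, hits))
            assert found == expected

    def test_unobserved_star_rejected(self):
        loci, genome, tags = self._dataset(n_loci=1)
        dropped = TagTable(tags.counts.drop(index=loci[0].star))
        hits = match_genome(dropped, genome)
        assert predict_novel(dropped, genome, hits) == []


class TestMergeReplicates:
    groups = {"MT": ["MT_bio1", "MT_bio2"], "WT": ["WT_bio1", "WT_bio2"]}

    def test_single_replicate_dropped(self):
        out = merge_replicates({"x": {"MT_bio1"}}, self.groups)
        assert out["x"] == set()

    def test_both_replicates_kept(self):
        out = merge_replicates({"x": {"WT_bio1", "WT_bio2"}}, self.groups)
        assert out["x"] == {"WT"}

    def test_both_genotypes(self):
        libs = {"MT_bio1", "MT_bio2", "WT_bio1", "WT_bio2"}
        assert merge_replicates({"x": libs}, self.groups)["x"] == {"MT", "WT"}


class TestCriterionAblation:
    """Each structural/expression criterion independently flips acceptance
    of a locus that otherwise satisfies all of them."""

    def test_bulge_toggle(self, sim_config):
        ok = gen_mirna_locus(sim_config, seed=3)
        bad = gen_mirna_locus(sim_config, seed=3, bulge_in_duplex=8)
        ev_ok = evaluate_hairpin(ok.precursor, (ok.mature_offset, ok.mature_offset + 21))
        ev_bad = evaluate_hairpin(bad.precursor, (bad.mature_offset, bad.mature_offset + 21))
        assert ev_ok.passed and ev_ok.bulge_ok
        assert not ev_bad.bulge_ok

    def test_overhang_toggle(self, sim_config):
        blunt = gen_mirna_locus(sim_config, seed=3, overhang=0)
        ev = evaluate_hairpin(blunt.precursor, (blunt.mature_offset, blunt.mature_offset + 21))
        # structure is fine but the planted (observed) star is not the
        # canonical 2-nt-overhang star, so the star requirement fails
        assert ev.star_sequence != blunt.star

    def test_mfe_boundary(self, rng):
        """Binary-search the stem length bracketing the -18 kcal/mol bound:
        the stronger stem passes, the weaker one fails."""
        core = "".join(rng.choice(list("ACGT"), size=80))
        lo, hi = 5, 60  # stem lengths bracketing the threshold

        def mfe(n):
            stem = core[:n]
            return fold_hairpin(stem + "TTTCTTTC" + revcomp(stem), min_len=18).mfe

        assert mfe(lo) > -18.0 and mfe(hi) <= -18.0
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if mfe(mid) <= -18.0:
                hi = mid
            else:
                lo = mid
        assert mfe(lo) > -18.0 >= mfe(hi)
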