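"""Compiled-gene completeness re-rating: parsing, compilation, coverage,
rating logic, summaries, and transcript-mapping counts."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from asmqc.buscomp import (
    BuscoGeneRecord,
    BuscoTableError,
    RatingThresholds,
    TranscriptMapping,
    assess_transcript_mapping,
    best_rating,
    compile_buscos,
    coverage_union,
    parse_busco_full_table,
    rate_busco,
    summarize_buscomp,
)
from asmqc.paf import AlignmentHit


def hit(gene="g1", qlen=100, qs=0, qe=96, target="sA", ident=1.0, strand="+"):
    span = qe - qs
    return AlignmentHit(
        query_id=gene, query_length=qlen, query_start=qs, query_end=qe,
        strand=strand, target_id=target, target_length=10_000,
        target_start=1000, target_end=1000 + span,
        n_matches=int(round(ident * span)), block_length=span, mapq=60,
    )


class TestFullTableParsing:
    def test_complete_and_missing_rows(self, tmp_path):
        p = tmp_path / "full_table.tsv"
        p.write_text(
            "# BUSCO version is: 3.0.2\n"
            "EOG1\tComplete\ts1\t100\t900\t512.3\t450\n"
            "EOG2\tMissing\n"
        )
        recs = parse_busco_full_table(p)
        assert recs[0].status == "Complete" and recs[0].scaffold_id == "s1"
        assert recs[1].status == "Missing" and recs[1].scaffold_id is None

    def test_unknown_status_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("EOG1\tPartial\ts1\t1\t2\t3\t4\n")
        with pytest.raises(BuscoTableError, match="Partial"):
            parse_busco_full_table(p)

    def test_v4_table_rejected_with_message(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("# BUSCO version is: 4.1.4\nEOG1\tComplete\ts1\t1\t9\t1.0\t8\n")
        with pytest.raises(BuscoTableError, match="v3 dialect"):
            parse_busco_full_table(p)

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("EOG1\tComplete\ts1\t100\n")
        with pytest.raises(BuscoTableError, match=":1"):
            parse_busco_full_table(p)


class TestCompilation:
    def test_highest_score_wins(self):
        runs = {
            "A": ([BuscoGeneRecord("g1", "Complete", "s1", 0, 10, 500.0, 450)], {"g1": "AAA"}),
            "B": ([BuscoGeneRecord("g1", "Complete", "s2", 0, 10, 510.0, 440)], {"g1": "CCC"}),
        }
        compiled = compile_buscos(runs)
        assert compiled["g1"].source_run == "B"
        assert compiled["g1"].sequence == "CCC"

    def test_never_complete_excluded(self):
        runs = {
            "A": ([BuscoGeneRecord("g1", "Fragmented", "s1", 0, 10, 100.0, 50)], {}),
            "B": ([BuscoGeneRecord("g1", "Fragmented", "s1", 0, 10, 100.0, 50)], {}),
        }
        assert compile_buscos(runs) == {}

    def test_set_size_counts_any_complete(self):
        rec = lambda g, status: BuscoGeneRecord(g, status, "s", 0, 9, 1.0, 9) if status != "Missing" else BuscoGeneRecord(g, status)
        runs = {
            "A": ([rec("g1", "Complete"), rec("g2", "Fragmented"), rec("g3", "Missing")], {"g1": "A"}),
            "B": ([rec("g1", "Duplicated"), rec("g2", "Complete"), rec("g3", "Missing")], {"g2": "C"}),
            "C": ([rec("g1", "Missing"), rec("g2", "Missing"), rec("g3", "Fragmented")], {}),
        }
        assert set(compile_buscos(runs)) == {"g1", "g2"}

    def test_tie_breaks_score_then_length_then_run(self):
        runs = {
            "B": ([BuscoGeneRecord("g1", "Complete", "s", 0, 9, 100.0, 60)], {"g1": "B"}),
            "A": ([BuscoGeneRecord("g1", "Complete", "s", 0, 9, 100.0, 60)], {"g1": "A"}),
        }
        assert compile_buscos(runs)["g1"].source_run == "A"

    def test_complete_without_sequence_rejected(self):
        runs = {"A": ([BuscoGeneRecord("g1", "Complete", "s", 0, 9, 1.0, 9)], {})}
        with pytest.raises(KeyError, match="g1"):
            compile_buscos(runs)


class TestCoverageUnion:
    @pytest.mark.parametrize(
        "intervals,expected",
        [([(0, 50), (40, 96)], 96), ([(0, 10), (20, 30)], 20), ([(5, 6)], 1)],
    )
    def test_examples(self, intervals, expected):
        assert coverage_union(intervals) == expected

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            coverage_union([(5, 5)])

    def test_matches_boolean_mask_oracle(self):
        rnd = random.Random(42)
        for _ in range(200):
            n = rnd.randint(1, 30)
            ivs = []
            for _ in range(n):
                s = rnd.randint(0, 500)
                ivs.append((s, s + rnd.randint(1, 80)))
            mask = [False] * 600
            for s, e in ivs:
                for k in range(s, e):
                    mask[k] = True
            assert coverage_union(ivs) == sum(mask)


class TestRating:
    def test_single_scaffold_96pct_complete(self):
        r = rate_busco("g1", [hit(qs=0, qe=96)], 100)
        assert r.rating == "Complete"
        assert r.combined_coverage == pytest.approx(0.96)

    def test_split_coverage_fragmented(self):
        hits = [hit(qs=0, qe=50, target="sA"), hit(qs=40, qe=96, target="sB")]
        r = rate_busco("g1", hits, 100)
        assert r.rating == "Fragmented"
        assert r.combined_coverage == pytest.approx(0.96)
        assert r.best_single_coverage == pytest.approx(0.56)

    def test_two_full_scaffolds_duplicated(self):
        hits = [hit(qs=0, qe=96, target="sA"), hit(qs=0, qe=96, target="sB")]
        assert rate_busco("g1", hits, 100).rating == "Duplicated"

    def test_ghost_and_missing(self):
        # 30% combined coverage with a cutoff-passing hit -> Ghost
        assert rate_busco("g1", [hit(qs=0, qe=300, qlen=1000)], 1000).rating == "Ghost"
        assert rate_busco("g1", [], 100).rating == "Missing"

    def test_boundaries_inclusive(self):
        # exactly 95% coverage rates Complete, exactly 40% rates Partial
        assert rate_busco("g1", [hit(qs=0, qe=95)], 100).rating == "Complete"
        assert rate_busco("g1", [hit(qs=0, qe=40)], 100).rating == "Partial"

    def test_local_cutoff_discards_low_identity_and_short_hits(self):
        low_ident = hit(qs=0, qe=96, ident=0.5)
        short = hit(qs=0, qe=30, qlen=1000)  # 30 bp < min_hit_bp 40
        assert rate_busco("g1", [low_ident], 100).rating == "Missing"
        assert rate_busco("g1", [short], 1000).rating == "Missing"

    def test_foreign_hit_rejected(self):
        with pytest.raises(ValueError, match="g2"):
            rate_busco("g1", [hit(gene="g2")], 100)

    def test_invariant_under_strand_flip(self):
        """Re-rating depends only on query-side coverage, so reverse
        complementing the target scaffold cannot change the rating."""
        hits = [hit(qs=0, qe=50, target="sA"), hit(qs=45, qe=100, target="sA")]
        flipped = [
            AlignmentHit(
                query_id=h.query_id, query_length=h.query_length,
                query_start=h.query_start, query_end=h.query_end,
                strand="-", target_id=h.target_id, target_length=h.target_length,
                target_start=h.target_length - h.target_end,
                target_end=h.target_length - h.target_start,
                n_matches=h.n_matches, block_length=h.block_length, mapq=h.mapq,
            )
            for h in hits
        ]
        assert rate_busco("g1", hits, 100) == rate_busco("g1", flipped, 100)

    @settings(max_examples=150, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 90),
                st.integers(41, 100),
                st.sampled_from(["sA", "sB", "sC"]),
            ).filter(lambda t: t[0] < t[1] and t[1] - t[0] >= 40),
            min_size=0,
            max_size=8,
        ),
        st.tuples(
            st.integers(0, 55), st.integers(41, 100), st.sampled_from(["sA", "sB", "sC"])
        ).filter(lambda t: t[0] < t[1] and t[1] - t[0] >= 40),
    )
    def test_extra_hit_never_worsens_rating(self, base, extra):
        """Adding a hit can only improve the rating, except the legitimate
        Complete -> Duplicated transition when a second scaffold fills up."""
        order = {r: i for i, r in enumerate(
            ["Complete", "Duplicated", "Fragmented", "Partial", "Ghost", "Missing"])}
        mk = lambda t: hit(qs=t[0], qe=t[1], target=t[2])
        before = rate_busco("g1", [mk(t) for t in base], 100)
        after = rate_busco("g1", [mk(t) for t in base + [extra]], 100)
        if before.rating == "Complete" and after.rating == "Duplicated":
            return
        assert order[after.rating] <= order[before.rating]


class TestSummary:
    def _rating(self, gene, rating):
        from asmqc.buscomp import BuscompRating

        cov = {"Complete": 1.0, "Duplicated": 1.0, "Fragmented": 1.0,
               "Partial": 0.6, "Ghost": 0.2, "Missing": 0.0}[rating]
        return BuscompRating(gene, rating, cov, cov, ("s",) if cov else ())

    def test_best_of_compilation(self):
        ratings = {
            "A": [self._rating("g1", "Fragmented")],
            "B": [self._rating("g1", "Complete")],
        }
        df = summarize_buscomp(ratings)
        assert df.loc["compiled", "Complete"] == 1
        assert df.loc["compiled", "completeness_pct"] == 100.0

    def test_all_missing_gives_zero(self):
        ratings = {"A": [self._rating("g1", "Missing"), self._rating("g2", "Missing")]}
        df = summarize_buscomp(ratings)
        assert df.loc["compiled", "completeness_pct"] == 0.0

    def test_completeness_counts_complete_plus_duplicated(self):
        genes = [f"g{i}" for i in range(10)]
        plan = ["Complete"] * 7 + ["Duplicated"] + ["Partial"] * 2
        ratings = {"A": [self._rating(g, r) for g, r in zip(genes, plan)]}
        df = summarize_buscomp(ratings)
        assert df.loc["compiled", "completeness_pct"] == pytest.approx(80.0)

    def test_mismatched_gene_sets_rejected(self):
        ratings = {
            "A": [self._rating("g1", "Complete")],
            "B": [self._rating("g2", "Complete")],
        }
        with pytest.raises(ValueError):
            summarize_buscomp(ratings)

    def test_compiled_completeness_monotone_in_assemblies(self):
        """Adding an assembly can only improve each gene's best rating."""
        rnd = random.Random(5)
        genes = [f"g{i}" for i in range(30)]
        cats = ["Complete", "Duplicated", "Fragmented", "Partial", "Ghost", "Missing"]
        assemblies = {
            f"asm{k}": [self._rating(g, rnd.choice(cats)) for g in genes]
            for k in range(5)
        }
        prev = 0.0
        included = {}
        for aid, rs in assemblies.items():
            included[aid] = rs
            cur = summarize_buscomp(included).loc["compiled", "completeness_pct"]
            assert cur >= prev
            prev = cur

    def test_duplicated_outranks_fragmented(self):
        assert best_rating(["Fragmented", "Duplicated"]) == "Duplicated"


class TestTranscriptMapping:
    def test_three_way_split(self):
        ms = [
            TranscriptMapping("t1", None),
            TranscriptMapping("t2", 30),
            TranscriptMapping("t3", 60),
            TranscriptMapping("t4", 60),
            TranscriptMapping("t5", 60),
        ]
        counts = assess_transcript_mapping(ms)
        assert counts == {"total": 5, "unmapped": 1, "mapq_below_60": 1, "mapped_q60": 3}

    def test_all_unmapped(self):
        ms = [TranscriptMapping(f"t{i}", None) for i in range(4)]
        counts = assess_transcript_mapping(ms)
        assert counts == {"total": 4, "unmapped": 4, "mapq_below_60": 0, "mapped_q60": 0}

    def test_mapq_60_is_confident(self):
        # the rule is strictly "below 60": 59 is flagged, 60 is not
        below = assess_transcript_mapping([TranscriptMapping("t", 59)])
        at = assess_transcript_mapping([TranscriptMapping("t", 60)])
        assert below["mapq_below_60"] == 1 and at["mapped_q60"] == 1

    def test_duplicate_transcript_rejected(self):
        ms = [TranscriptMapping("t1", 60), TranscriptMapping("t1", 60)]
        with pytest.raises(ValueError, match="t1"):
            assess_transcript_mapping(ms)
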