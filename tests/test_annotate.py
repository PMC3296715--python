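import numpy as np
import pytest
from scipy.stats import hypergeom

from numts.annotate import (
    MergeConflict,
    RepeatAssociation,
    associate_repeats,
    classify_rearrangements,
    group_hits,
    intron_overlap,
    merge_group,
)
from numts.types import Fragment, GenomeSequence, Hsp, LinkedHit, NumtAnnotation

MITO_LEN = 16000


def hit(ss, se, qs, qe, strand="+", scaffold="scaf"):
    return LinkedHit(
        hsps=[
            Hsp(
                query_start=qs, query_end=qe, subject_start=ss, subject_end=se,
                strand=strand, score=(qe - qs) * 2, bit_score=10.0, e_value=1e-12,
                identity=0.95,
            )
        ],
        subject_id=scaffold,
        query_id="mt",
    )


class TestGroupHits:
    def test_19kb_gap_groups(self):
        groups = group_hits([hit(0, 1000, 0, 1000), hit(20000, 21000, 2000, 3000)], 25000)
        assert len(groups) == 1

    def test_29kb_gap_splits(self):
        groups = group_hits([hit(0, 1000, 0, 1000), hit(30000, 31000, 2000, 3000)], 25000)
        assert len(groups) == 2

    def test_matches_connected_components_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 12))
            hits = []
            for _ in range(n):
                s = int(rng.integers(0, 200000))
                ln = int(rng.integers(100, 3000))
                hits.append(hit(s, s + ln, 0, ln))
            groups = group_hits(hits, 25000)
            # oracle: connected components of the gap graph
            import networkx as nx

            g = nx.Graph()
            g.add_nodes_from(range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = hits[i].subject_interval, hits[j].subject_interval
                    gap = max(a[0], b[0]) - min(a[1], b[1])
                    if gap < 25000:
                        g.add_edge(i, j)
            want = {frozenset(c) for c in nx.connected_components(g)}
            got = {frozenset(hits.index(h) for h in grp) for grp in groups}
            assert got == want


class TestMergeGroup:
    def test_mito_gap_merges_with_deletion_candidate(self):
        group = [hit(0, 2000, 0, 2000), hit(2000, 3500, 2500, 4000)]
        numts = merge_group(group, MITO_LEN)
        assert len(numts) == 1
        events = classify_rearrangements(numts[0], MITO_LEN)
        assert [e.type for e in events] == ["deletion"]
        assert events[0].size == 500

    def test_repeated_mito_interval_merges_with_duplication(self):
        group = [hit(0, 2000, 0, 2000), hit(2000, 4000, 0, 2000)]
        numts = merge_group(group, MITO_LEN)
        assert len(numts) == 1
        events = classify_rearrangements(numts[0], MITO_LEN)
        assert any(e.type == "internal_duplication" and e.size == 2000 for e in events)

    def test_contradictory_nuclear_overlap_rejected(self):
        group = [hit(0, 2000, 0, 2000), hit(1000, 3000, 8000, 10000)]
        with pytest.raises(MergeConflict):
            merge_group(group, MITO_LEN)

    def test_double_event_junction_splits(self):
        # 5 kb nuclear gap AND unrelated mito origin: two numts, not one
        group = [hit(0, 2000, 0, 2000), hit(7000, 9000, 9000, 11000)]
        numts = merge_group(group, MITO_LEN)
        assert len(numts) == 2

    def test_interruption_only_junction_stays_merged(self):
        group = [hit(0, 2000, 0, 2000), hit(7000, 9000, 2010, 4010)]
        numts = merge_group(group, MITO_LEN)
        assert len(numts) == 1


class TestClassifyRearrangements:
    def numt(self, frags):
        return NumtAnnotation(numt_id="n", species="s", scaffold="c", fragments=frags)

    def test_deletion_of_700_mito_bases(self):
        numt = self.numt([
            Fragment(0, 400, 100, 500, "+", 0.95),
            Fragment(400, 800, 1200, 1600, "+", 0.95),
        ])
        events = classify_rearrangements(numt, MITO_LEN)
        assert [(e.type, e.size) for e in events] == [("deletion", 700)]

    def test_interruption_of_5000_nuclear_bases(self):
        numt = self.numt([
            Fragment(0, 400, 100, 500, "+", 0.95),
            Fragment(5400, 5800, 500, 900, "+", 0.95),
        ])
        events = classify_rearrangements(numt, MITO_LEN)
        assert [(e.type, e.size) for e in events] == [("interruption", 5000)]

    def test_inversion_size_is_inverted_fragment_length(self):
        numt = self.numt([
            Fragment(0, 400, 100, 500, "+", 0.95),
            Fragment(400, 800, 500, 900, "-", 0.95),
        ])
        events = classify_rearrangements(numt, MITO_LEN)
        assert [(e.type, e.size) for e in events] == [("inversion", 400)]

    def test_events_below_min_size_ignored(self):
        numt = self.numt([
            Fragment(0, 400, 100, 500, "+", 0.95),
            Fragment(450, 850, 650, 1050, "+", 0.95),  # 50 nuc gap, 150 mito gap
        ])
        assert classify_rearrangements(numt, MITO_LEN, min_event=200) == []

    def test_fragment_sum_never_exceeds_span(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 5))
            frags, pos = [], 0
            for _ in range(k):
                ln = int(rng.integers(100, 900))
                m = int(rng.integers(0, 14000))
                frags.append(Fragment(pos, pos + ln, m, m + ln, "+", 0.9))
                pos += ln + int(rng.integers(0, 800))
            numt = self.numt(frags)
            span_len = numt.span[1] - numt.span[0]
            assert numt.total_numt_length <= span_len
            for e in classify_rearrangements(numt, MITO_LEN):
                assert e.size >= 200


class TestAssociateRepeats:
    def build(self, repeat_offset, rng):
        numt = NumtAnnotation(
            numt_id="n0", species="s", scaffold="c",
            fragments=[Fragment(5000, 6000, 0, 1000, "+", 0.9)],
        )
        repeats = [("c", 6000 + repeat_offset, 6300 + repeat_offset, "rep")]
        return associate_repeats(
            [numt], repeats, {"c": 50000}, adjacency=200, rng=rng, n_controls=50
        )

    def test_repeat_150b_away_flags(self, rng):
        assert self.build(150, rng).flags["n0"] is True

    def test_repeat_300b_away_does_not_flag(self, rng):
        assert self.build(300, rng).flags["n0"] is False

    def test_short_scaffold_numts_excluded(self, rng):
        numt = NumtAnnotation(
            numt_id="n0", species="s", scaffold="c",
            fragments=[Fragment(10, 400, 0, 390, "+", 0.9)],
        )
        res = associate_repeats([numt], [("c", 0, 5, "r")], {"c": 450}, rng=rng, n_controls=10)
        assert res.excluded == ["n0"]

    def test_empty_repeat_annotation(self, rng):
        numt = NumtAnnotation(
            numt_id="n0", species="s", scaffold="c",
            fragments=[Fragment(5000, 6000, 0, 1000, "+", 0.9)],
        )
        res = associate_repeats([numt], [], {"c": 50000}, rng=rng)
        assert res.flags == {"n0": False} and res.p_value == 1.0

    def test_published_contingency_significant_by_hypergeometric(self):
        """92/233 numt-adjacent vs a 15% background over 1000 controls."""
        table = ((92, 141), (150, 850))
        # one-sided exact hypergeometric tail as the independent oracle
        n_draws = 92 + 141
        p = hypergeom.sf(92 - 1, 233 + 1000, 92 + 150, n_draws)
        assert p < 0.01
        from scipy.stats import fisher_exact

        _, p2 = fisher_exact(table)
        assert p2 < 0.01


GFF = """##gff-version 3
c\tsrc\tgene\t1001\t9000\t.\t+\t.\tID=g1
c\tsrc\tmRNA\t1001\t9000\t.\t+\t.\tID=t1;Parent=g1
c\tsrc\texon\t1001\t2000\t.\t+\t.\tID=e1;Parent=t1
c\tsrc\texon\t8001\t9000\t.\t+\t.\tID=e2;Parent=t1
"""


class TestIntronOverlap:
    def numt(self, s, e, nid="n0"):
        return NumtAnnotation(
            numt_id=nid, species="sp", scaffold="c",
            fragments=[Fragment(s, e, 0, e - s, "+", 0.9)],
        )

    def test_numt_inside_intron_counted(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(GFF)
        count, frac, ids = intron_overlap([self.numt(3000, 4000)], gff)
        assert count == 1 and ids == ["n0"] and frac == 1.0

    def test_numt_touching_exon_not_counted(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(GFF)
        count, _, _ = intron_overlap([self.numt(1500, 4000)], gff)
        assert count == 0

    def test_numt_outside_transcript_not_counted(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(GFF)
        count, frac, _ = intron_overlap(
            [self.numt(3000, 4000), self.numt(20000, 21000, "n1")], gff
        )
        assert count == 1 and frac == pytest.approx(0.5)
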