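"""Homology search, LD scoring, hit selection, windows and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from premir.align import (
    best_local_alignment,
    evalue,
    nucleotide_aligner,
    trace_counts,
)
from premir.formats import Interval, SeqRecord, reverse_complement
from premir.homology import (
    AlignmentHit,
    HomologyParams,
    cluster_representatives,
    compute_ld,
    extract_window,
    find_hits,
    select_hits,
)


def _hit(Q=21, Qa=21, G=0, M=0, ev=1e-5, start=0, end=21, strand="+"):
    return AlignmentHit(
        query_id="q",
        Q=Q,
        Qa=Qa,
        G=G,
        M=M,
        evalue=ev,
        subject_interval=Interval("s", start, end, strand),
        aligned_query_span=(1, Qa - G),
    )


class TestComputeLD:
    @pytest.mark.parametrize(
        "Q,Qa,G,M,expected",
        [(21, 21, 0, 0, 0), (21, 19, 0, 1, 3), (24, 20, 1, 1, 6)],
    )
    def test_formula(self, Q, Qa, G, M, expected):
        assert compute_ld(_hit(Q=Q, Qa=Qa, G=G, M=M)) == expected

    @given(
        st.integers(15, 30), st.integers(0, 3), st.integers(0, 4), st.integers(0, 5)
    )
    @settings(max_examples=100, deadline=None)
    def test_never_negative_without_gaps(self, Q, short, G, M):
        Qa = Q - short + G
        if Qa <= 0:
            return
        assert compute_ld(_hit(Q=Q, Qa=Qa, G=G, M=M)) >= 0


class TestFindHits:
    def test_planted_forward_hit(self, rng):
        bg = "".join(rng.choice(list("ACGT"), 10_000))
        q = "".join(rng.choice(list("ACGT"), 21))
        subject = bg[:1000] + q + bg[1000:]
        hits = find_hits([SeqRecord("q1", q)], [SeqRecord("s", subject)])
        exact = [h for h in hits if h.ld == 0]
        assert len(exact) == 1
        iv = exact[0].subject_interval
        assert (iv.start, iv.end, iv.strand) == (1000, 1021, "+")

    def test_planted_reverse_complement_hit(self, rng):
        bg = "".join(rng.choice(list("ACGT"), 10_000))
        q = "".join(rng.choice(list("ACGT"), 21))
        subject = bg[:1000] + reverse_complement(q) + bg[1000:]
        hits = find_hits([SeqRecord("q1", q)], [SeqRecord("s", subject)])
        exact = [h for h in hits if h.ld == 0]
        assert len(exact) == 1
        iv = exact[0].subject_interval
        assert (iv.start, iv.end, iv.strand) == (1000, 1021, "-")

    def test_empty_inputs_are_errors(self):
        with pytest.raises(ValueError):
            find_hits([], [SeqRecord("s", "ACGTACGT")])
        with pytest.raises(ValueError):
            find_hits([SeqRecord("q", "ACGTACGT")], [])

    def test_blastn_adapter_agrees_with_builtin(self, rng):
        """The external adapter and the exhaustive aligner find the same
        planted locus with the same dissimilarity."""
        bg = "".join(rng.choice(list("ACGT"), 5_000))
        q = "".join(rng.choice(list("ACGT"), 24))
        subject = bg[:2000] + q + bg[2000:]
        queries = [SeqRecord("q1", q)]
        subjects = [SeqRecord("s", subject)]
        builtin = [h for h in find_hits(queries, subjects) if h.ld == 0]
        external = [h for h in find_hits(queries, subjects, backend="blastn") if h.ld == 0]
        assert len(builtin) == 1
        assert len(external) >= 1
        b, e = builtin[0], external[0]
        assert (b.subject_interval.start, b.subject_interval.end) == (
            e.subject_interval.start,
            e.subject_interval.end,
        )
        assert b.ld == e.ld == 0


class TestLDRecountOracle:
    def test_ld_matches_brute_force_recount(self, rng):
        """LD from the hit fields equals an independent recount of
        unaligned query nucleotides + gaps + mismatches on the raw trace,
        for 200 random query/subject pairs."""
        aligner = nucleotide_aligner()
        checked = 0
        while checked < 200:
            q = "".join(rng.choice(list("ACGT"), int(rng.integers(12, 26))))
            s = "".join(rng.choice(list("ACGT"), int(rng.integers(60, 200))))
            aln = best_local_alignment(aligner, s, q)
            if aln is None:
                continue
            tr = trace_counts(aln)
            # independent recount straight off the aligned blocks
            t_blocks, q_blocks = aln.aligned
            unaligned_query = len(q) - sum(qe - qs for qs, qe in q_blocks)
            gaps = 0
            for k in range(1, len(t_blocks)):
                gaps += t_blocks[k][0] - t_blocks[k - 1][1]
                gaps += q_blocks[k][0] - q_blocks[k - 1][1]
            mism = 0
            for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
                mism += sum(1 for a, b in zip(s[ts:te], q[qs:qe]) if a != b)
            brute_ld = unaligned_query + gaps + mism
            hit = AlignmentHit(
                query_id="q",
                Q=len(q),
                Qa=tr.columns,
                G=tr.gaps,
                M=tr.mismatches,
                evalue=evalue(tr.score, len(q), len(s)),
                subject_interval=Interval("s", *tr.target_span),
                aligned_query_span=(tr.query_span[0] + 1, tr.query_span[1]),
            )
            assert compute_ld(hit) == brute_ld
            checked += 1


class TestSelectHits:
    def _band(self):
        return [
            _hit(Qa=21, M=0),            # LD 0
            _hit(Qa=18, M=0),            # LD 3
            _hit(Qa=16, M=0),            # LD 5
            _hit(Qa=15, M=0),            # LD 6
            _hit(Qa=14, M=0),            # LD 7
        ]

    def test_decoy_mode_keeps_dissimilarity_band(self):
        kept = select_hits(self._band(), "decoy")
        assert sorted(h.ld for h in kept) == [5, 6]

    def test_prediction_mode_keeps_ld_up_to_three(self):
        kept = select_hits(self._band(), "prediction", HomologyParams(ld_max=3))
        assert sorted(h.ld for h in kept) == [0, 3]

    def test_positive_mode_keeps_perfect_full_length_only(self):
        hits = self._band() + [_hit(Qa=21, M=1)]
        kept = select_hits(hits, "positive")
        assert [h.ld for h in kept] == [0]

    def test_decoy_mode_enforces_evalue(self):
        hits = [_hit(Qa=16, ev=0.1)]
        assert select_hits(hits, "decoy") == []

    def test_empty_and_unknown_mode(self):
        assert select_hits([], "decoy") == []
        with pytest.raises(ValueError):
            select_hits([], "bogus")

    def test_selection_is_subset_and_idempotent(self):
        hits = self._band()
        for mode in ("positive", "decoy", "prediction"):
            kept = select_hits(hits, mode)
            assert set(kept) <= set(hits)
            assert select_hits(kept, mode) == kept


class TestExtractWindow:
    def _subject(self, rng, n=10_000):
        return SeqRecord("s", "".join(rng.choice(list("ACGT"), n)))

    def test_flank_200_arithmetic(self, rng):
        subj = self._subject(rng)
        hit = _hit(start=1000, end=1021)
        w = extract_window(hit, [subj], 200)
        assert (w.interval.start, w.interval.end) == (800, 1221)
        assert len(w.seq) == 421

    def test_left_clipping(self, rng):
        subj = self._subject(rng)
        hit = _hit(start=5, end=26)
        w = extract_window(hit, [subj], 200)
        assert (w.interval.start, w.interval.end) == (0, 226)
        assert w.hit_span_in_window == (6, 26)

    def test_flank_20_gives_61nt_window(self, rng):
        subj = self._subject(rng)
        w = extract_window(_hit(start=1000, end=1021), [subj], 20)
        assert len(w.seq) == 61

    def test_window_substring_equals_hit_segment(self, rng):
        subj = self._subject(rng)
        for strand in "+-":
            hit = _hit(start=1000, end=1021, strand=strand)
            w = extract_window(hit, [subj], 50)
            segment = subj.seq[1000:1021]
            if strand == "-":
                segment = reverse_complement(segment)
            assert w.hit_seq == segment


class TestClusterRepresentatives:
    def test_identical_sequences_merge(self, rng):
        s = "".join(rng.choice(list("ACGT"), 40))
        reps = cluster_representatives(
            [SeqRecord("a", s), SeqRecord("b", s)], 0.9
        )
        assert len(reps) == 1

    def test_unrelated_sequences_stay_apart(self):
        reps = cluster_representatives(
            [SeqRecord("a", "ACCA" * 10), SeqRecord("b", "AGGA" * 10)], 0.9
        )
        assert len(reps) == 2

    def test_one_mismatch_variant_merges_at_090(self, rng):
        s = "".join(rng.choice(list("ACGT"), 21))
        v = s[:10] + ("A" if s[10] != "A" else "C") + s[11:]
        reps = cluster_representatives([SeqRecord("a", s), SeqRecord("b", v)], 0.90)
        assert len(reps) == 1  # identity 20/21 ~ 0.952 >= 0.90

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            cluster_representatives([], 0.5)
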