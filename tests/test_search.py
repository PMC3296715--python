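import itertools
import math

import numpy as np
import pytest

from numts.config import PipelineConfig
from numts.masking import mask_low_complexity
from numts.search import (
    _linkable,
    base_frequencies,
    find_hsps,
    flag_mito_artifacts,
    karlin_params,
    link_hsps,
    recompute_score,
)
from numts.types import GenomeSequence, Hsp, revcomp


def masked(seq_id, residues, topology="linear"):
    return mask_low_complexity(GenomeSequence(id=seq_id, residues=residues, topology=topology))


class TestKarlinParams:
    def test_lambda_solves_identity(self, cfg):
        fq = np.array([0.39, 0.11, 0.11, 0.39])
        fs = np.array([0.29, 0.21, 0.21, 0.29])
        kp = karlin_params(fq, fs, cfg.match_score, cfg.mismatch_score)
        p = float(fq @ fs)
        val = p * math.exp(kp.lam * cfg.match_score) + (1 - p) * math.exp(
            kp.lam * cfg.mismatch_score
        )
        assert val == pytest.approx(1.0, abs=1e-9)
        assert kp.K > 0 and kp.H > 0

    def test_base_frequencies_ignore_n(self):
        f = base_frequencies("AANNTT")
        assert f[0] == pytest.approx(0.5) and f[3] == pytest.approx(0.5)


class TestFindHsps:
    def test_planted_exact_copy_found_once(self, rng, make_dna, cfg):
        mito = make_dna(rng, 16000, at=0.78)
        bg = make_dna(rng, 60000, at=0.58)
        subject = bg[:30000] + mito[3000:3500] + bg[30000:]
        hsps = find_hsps(masked("mt", mito, "circular"), masked("s", subject), cfg)
        assert len(hsps) == 1
        h = hsps[0]
        assert h.e_value < 1e-6
        assert h.strand == "+"
        # covers the planted segment (ends may wander a few bases by chance)
        assert h.query_start <= 3005 and h.query_end >= 3495
        assert abs(h.subject_start - 30000) <= 10 and abs(h.subject_end - 30500) <= 10

    def test_reverse_complement_copy_maps_to_same_mito_interval(self, rng, make_dna, cfg):
        mito = make_dna(rng, 16000, at=0.78)
        bg = make_dna(rng, 60000, at=0.58)
        fwd = bg[:30000] + mito[3000:3500] + bg[30000:]
        rev = bg[:30000] + revcomp(mito[3000:3500]) + bg[30000:]
        h_fwd = find_hsps(masked("mt", mito, "circular"), masked("s", fwd), cfg)[0]
        h_rev = find_hsps(masked("mt", mito, "circular"), masked("s", rev), cfg)[0]
        assert h_rev.strand == "-"
        assert abs(h_rev.query_start - h_fwd.query_start) <= 10
        assert abs(h_rev.query_end - h_fwd.query_end) <= 10

    def test_random_subject_yields_no_hits(self, make_dna, cfg):
        """Empirical false-positive check of the E-value calibration."""
        rng = np.random.default_rng(99)
        mito = masked("mt", make_dna(rng, 16000, at=0.78), "circular")
        for _ in range(20):
            subject = masked("s", make_dna(rng, 100000, at=0.58))
            assert find_hsps(mito, subject, cfg) == []

    def test_subject_shorter_than_word_empty(self, cfg):
        q = GenomeSequence(id="q", residues="ACGTACGTACGTACGT")
        s = GenomeSequence(id="s", residues="ACGT")
        assert find_hsps(q, s, cfg) == []

    def test_reported_scores_recompute_exactly(self, rng, make_dna, cfg):
        from numts.simulate import evolve, random_sequence
        from numts.f84 import F84Params
        from numts.types import decode

        model = F84Params(freqs=np.array([0.39, 0.11, 0.11, 0.39]))
        mito_codes = random_sequence(rng, 16000, 0.78)
        copy = evolve(mito_codes[2000:4000], model, 1.0, 0.1, rng)
        bg = make_dna(rng, 40000, at=0.58)
        subject = bg[:20000] + decode(copy) + bg[20000:]
        q = masked("mt", decode(mito_codes), "circular")
        s = masked("s", subject)
        hsps = find_hsps(q, s, cfg)
        assert hsps
        for h in hsps:
            assert recompute_score(h, q, s, cfg) == h.score

    def test_whole_genome_artifact_flagged(self, rng, make_dna, cfg):
        mito = make_dna(rng, 8000, at=0.78)
        subject = make_dna(rng, 3000, at=0.58) + mito + make_dna(rng, 3000, at=0.58)
        q = masked("mt", mito, "circular")
        s = masked("s", subject)
        hits = link_hsps(find_hsps(q, s, cfg), cfg.hsp_sep_max_bases)
        assert flag_mito_artifacts(hits, len(mito))


def make_hsp(qs, qe, ss, se, strand="+", score=None):
    return Hsp(
        query_start=qs, query_end=qe, subject_start=ss, subject_end=se,
        strand=strand, score=score if score is not None else (qe - qs) * 2,
        bit_score=10.0, e_value=1e-9,
    )


def chain_partition_oracle(hsps, sep_max):
    """Exhaustive chain extraction: repeatedly remove the highest-scoring
    valid chain (tie: leftmost subject start)."""
    remaining = list(range(len(hsps)))
    chains = []
    while remaining:
        best = None
        for r in range(1, len(remaining) + 1):
            for subset in itertools.combinations(remaining, r):
                ordered = sorted(subset, key=lambda i: (hsps[i].query_start, hsps[i].query_end))
                if all(
                    _linkable(hsps[a], hsps[b], sep_max)
                    for a, b in zip(ordered, ordered[1:])
                ):
                    score = sum(hsps[i].score for i in subset)
                    start = min(hsps[i].subject_start for i in subset)
                    cand = (-score, start, ordered)
                    if best is None or cand < best:
                        best = cand
        chains.append(frozenset(best[2]))
        remaining = [i for i in remaining if i not in best[2]]
    return set(chains)


class TestLinkHsps:
    def test_forty_base_gap_links(self):
        a = make_hsp(0, 100, 0, 100)
        b = make_hsp(140, 240, 140, 240)
        hits = link_hsps([a, b], sep_max=50)
        assert len(hits) == 1 and len(hits[0].hsps) == 2

    def test_sixty_base_subject_gap_splits(self):
        a = make_hsp(0, 100, 0, 100)
        b = make_hsp(140, 240, 160, 260)  # query gap 40, subject gap 60
        hits = link_hsps([a, b], sep_max=50)
        assert len(hits) == 2

    def test_strands_never_mix(self):
        a = make_hsp(0, 100, 0, 100, "+")
        b = make_hsp(120, 220, 120, 220, "-")
        assert len(link_hsps([a, b], sep_max=50)) == 2

    def test_minus_strand_colinearity(self):
        # along the query, minus-strand chains run right-to-left on subject
        a = make_hsp(0, 100, 200, 300, "-")
        b = make_hsp(120, 220, 80, 180, "-")
        assert len(link_hsps([a, b], sep_max=50)) == 1

    def test_random_sets_match_exhaustive_oracle(self, rng):
        for rep in range(15):
            n = int(rng.integers(2, 8))
            hsps = []
            pos = 0
            for _ in range(n):
                qs = pos + int(rng.integers(-30, 80))
                length = int(rng.integers(20, 90))
                diag = int(rng.choice([0, 0, 5, 200]))
                strand = "+" if rng.random() < 0.8 else "-"
                hsps.append(
                    make_hsp(
                        max(qs, 0), max(qs, 0) + length,
                        max(qs, 0) + diag, max(qs, 0) + diag + length,
                        strand, score=int(rng.integers(50, 300)),
                    )
                )
                pos = max(qs, 0) + length
            got = set(
                frozenset(hsps.index(h) for h in hit.hsps)
                for hit in link_hsps(hsps, sep_max=50)
            )
            assert got == chain_partition_oracle(hsps, 50), f"rep {rep}"
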