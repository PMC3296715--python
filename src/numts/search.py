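"""Seed-and-extend local similarity search with HSP linking.

Reimplements the nucleotide search used to annotate numts: exact-word
seeding on both strands, ungapped X-drop extension into high-scoring
segment pairs (HSPs), Karlin-Altschul E-values, and linking of colinear
HSPs separated by at most ``hsp_sep_max_bases`` on both query and subject.
HSPs are ungapped; insertions and deletions between fragments are absorbed
by the linking step and, at larger scales, by the downstream merge rules.

Masked (lowercase) residues are excluded from seeding but allowed in
extension; N scores as a mismatch and never seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy.optimize import brentq

from .config import PipelineConfig
from .types import GenomeSequence, Hsp, LinkedHit, encode, mask_array, revcomp

EULER_GAMMA = 0.5772156649015329


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KarlinParams:
    lam: float  # scale of the score distribution (nats per score unit)
    K: float  # search-space constant
    H: float  # relative entropy per aligned pair (nats)


def base_frequencies(seq: str) -> np.ndarray:
    codes = encode(seq)
    counts = np.bincount(codes[codes < 4], minlength=4).astype(float)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


def _solve_lambda(p_match: float, match: int, mismatch: int) -> float:
    """Unique positive root of p e^{lam*match} + (1-p) e^{lam*mismatch} = 1."""

    def f(lam):
        return (
            p_match * math.exp(lam * match)
            + (1.0 - p_match) * math.exp(lam * mismatch)
            - 1.0
        )

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return brentq(f, 1e-9, hi, xtol=1e-12)


def _max_segment_scores(
    rng: np.random.Generator,
    freqs_q: np.ndarray,
    freqs_s: np.ndarray,
    match: int,
    mismatch: int,
    n_pairs: int,
    length: int,
) -> np.ndarray:
    """Exact maximal ungapped local alignment scores of random pairs.

    Kadane's maximum-subarray recurrence run along every diagonal of the
    comparison, vectorized across diagonals.
    """
    out = np.empty(n_pairs)
    n_diags = 2 * length - 1  # diagonal d = j - i, offset by length-1
    for rep in range(n_pairs):
        q = rng.choice(4, size=length, p=freqs_q)
        s = rng.choice(4, size=length, p=freqs_s)
        cur = np.zeros(n_diags)
        best = np.zeros(n_diags)
        for i in range(length):
            # diagonals valid at row i: j = i + d in [0, length)
            lo, hi = (length - 1) - i, (2 * length - 1) - i
            x = np.where(s == q[i], match, mismatch).astype(float)
            cur[lo:hi] = np.maximum(0.0, cur[lo:hi] + x)
            np.maximum(best[lo:hi], cur[lo:hi], out=best[lo:hi])
        out[rep] = best.max()
    return out


_KARLIN_CACHE: Dict[tuple, KarlinParams] = {}


def karlin_params(
    freqs_q: np.ndarray,
    freqs_s: np.ndarray,
    match: int = 5,
    mismatch: int = -4,
    n_calibration_pairs: int = 60,
    calibration_length: int = 400,
) -> KarlinParams:
    """Estimate lambda exactly and K by Gumbel-location calibration.

    lambda solves the standard identity for the two-valued score
    distribution under the observed background compositions. K is fitted
    from the mean maximal segment score of random comparisons via
    ``E[M] = (ln(K m n) + gamma) / lambda`` (a fixed internal stream keeps
    the calibration deterministic; results are cached per scoring scheme
    and composition).
    """
    key = (
        match,
        mismatch,
        tuple(np.round(freqs_q, 3)),
        tuple(np.round(freqs_s, 3)),
    )
    if key in _KARLIN_CACHE:
        return _KARLIN_CACHE[key]
    p_match = float(np.dot(freqs_q, freqs_s))
    lam = _solve_lambda(p_match, match, mismatch)
    H = lam * (
        p_match * match * math.exp(lam * match)
        + (1 - p_match) * mismatch * math.exp(lam * mismatch)
    )
    rng = np.random.default_rng(20120307)
    scores = _max_segment_scores(
        rng, freqs_q, freqs_s, match, mismatch, n_calibration_pairs, calibration_length
    )
    mn = float(calibration_length) ** 2
    K = math.exp(lam * float(scores.mean()) - EULER_GAMMA) / mn
    params = KarlinParams(lam=lam, K=K, H=H)
    _KARLIN_CACHE[key] = params
    return params


def e_value(score: float, m: int, n: int, kp: KarlinParams) -> float:
    return kp.K * m * n * math.exp(-kp.lam * score)


def bit_score(score: float, kp: KarlinParams) -> float:
    return (kp.lam * score - math.log(kp.K)) / math.log(2.0)


# ---------------------------------------------------------------------------
# Seeding and ungapped X-drop extension
# ---------------------------------------------------------------------------


def _word_values(codes: np.ndarray, valid: np.ndarray, w: int) -> Tuple[np.ndarray, np.ndarray]:
    """Packed base-4 values and start positions of valid length-w words."""
    n = codes.size
    if n < w:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    vals = np.zeros(n - w + 1, dtype=np.int64)
    ok = np.ones(n - w + 1, dtype=bool)
    for k in range(w):
        vals = vals * 4 + codes[k : n - w + 1 + k]
        ok &= valid[k : n - w + 1 + k]
    pos = np.flatnonzero(ok)
    return vals[pos], pos


def _find_seeds(
    qcodes: np.ndarray,
    qvalid: np.ndarray,
    scodes: np.ndarray,
    svalid: np.ndarray,
    w: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """All (query_pos, subject_pos) pairs sharing an exact valid w-word."""
    qv, qp = _word_values(qcodes, qvalid, w)
    sv, sp = _word_values(scodes, svalid, w)
    if qv.size == 0 or sv.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(sv, kind="stable")
    sv_sorted, sp_sorted = sv[order], sp[order]
    lo = np.searchsorted(sv_sorted, qv, side="left")
    hi = np.searchsorted(sv_sorted, qv, side="right")
    counts = hi - lo
    hit = counts > 0
    if not hit.any():
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    q_seed = np.repeat(qp[hit], counts[hit])
    idx = np.concatenate([np.arange(l, h) for l, h in zip(lo[hit], hi[hit])])
    s_seed = sp_sorted[idx]
    return q_seed, s_seed


def _xdrop_extend(
    eq: np.ndarray, match: int, mismatch: int, xdrop: int, chunk: int = 512
) -> Tuple[int, int]:
    """Best (gain, length) prefix of the match/mismatch sequence ``eq``
    under X-drop termination. ``eq`` is boolean: True = match."""
    best, best_len = 0, 0
    g = 0.0
    n = eq.size
    start = 0
    while start < n:
        a = np.where(eq[start : start + chunk], match, mismatch).astype(float)
        cs = g + np.cumsum(a)
        runmax = np.maximum.accumulate(np.maximum(cs, best))
        dropped = runmax - cs > xdrop
        stop = int(np.argmax(dropped)) if dropped.any() else a.size
        if stop > 0:
            seg = cs[:stop]
            i = int(np.argmax(seg))
            if seg[i] > best:
                best = seg[i]
                best_len = start + i + 1
        if stop < a.size:
            break
        g = cs[-1]
        start += a.size
    return int(best), best_len


def _extend_seed(
    qcodes, scodes, qi: int, si: int, w: int, match: int, mismatch: int, xdrop: int
) -> Tuple[int, int, int]:
    """Extend an exact word seed at (qi, si) both ways ungapped.

    Returns (score, left_extension, right_extension).
    """
    nq, ns = qcodes.size, scodes.size
    # rightwards from the end of the word
    lim = min(nq - (qi + w), ns - (si + w))
    eq_r = (
        (qcodes[qi + w : qi + w + lim] == scodes[si + w : si + w + lim])
        & (qcodes[qi + w : qi + w + lim] < 4)
    )
    gain_r, len_r = _xdrop_extend(eq_r, match, mismatch, xdrop)
    # leftwards from the start of the word
    lim = min(qi, si)
    eq_l = (
        (qcodes[qi - lim : qi][::-1] == scodes[si - lim : si][::-1])
        & (qcodes[qi - lim : qi][::-1] < 4)
    )
    gain_l, len_l = _xdrop_extend(eq_l, match, mismatch, xdrop)
    return w * match + gain_r + gain_l, len_l, len_r


def _search_one_strand(
    qcodes, qvalid, scodes, svalid, cfg: PipelineConfig
) -> List[Tuple[int, int, int, int, int, float]]:
    """Ungapped HSPs of one strand as (qs, qe, ss, se, score, identity)."""
    w = cfg.word_size
    q_seed, s_seed = _find_seeds(qcodes, qvalid, scodes, svalid, w)
    if q_seed.size == 0:
        return []
    diag = s_seed - q_seed
    order = np.lexsort((s_seed, diag))
    covered_end: Dict[int, int] = {}
    out = []
    for k in order:
        qi, si = int(q_seed[k]), int(s_seed[k])
        d = int(diag[k])
        if si < covered_end.get(d, -1):
            continue
        score, left, right = _extend_seed(
            qcodes, scodes, qi, si, w, cfg.match_score, cfg.mismatch_score, cfg.xdrop
        )
        qs, qe = qi - left, qi + w + right
        ss, se = si - left, si + w + right
        covered_end[d] = se
        ident = float(np.mean(qcodes[qs:qe] == scodes[ss:se]))
        out.append((qs, qe, ss, se, score, ident))
    return out


def find_hsps(
    query: GenomeSequence,
    subject: GenomeSequence,
    cfg: PipelineConfig,
    evalue_threshold: float = None,
) -> List[Hsp]:
    """Search ``subject`` (a nuclear scaffold) with ``query`` (the
    mitochondrial genome) on both strands.

    Minus-strand HSPs report both intervals in forward coordinates of
    their sequences; the aligned text is query vs reverse-complemented
    subject. HSPs with E-value above the threshold (default: the
    configured one) are discarded; pipelines pass a weaker floor here and
    re-filter after HSP linking, so short terminal fragments survive to
    be chained to an anchoring significant HSP.
    """
    if len(subject) < cfg.word_size or len(query) < cfg.word_size:
        return []
    if evalue_threshold is None:
        evalue_threshold = cfg.evalue_threshold
    kp = karlin_params(
        base_frequencies(query.residues),
        base_frequencies(subject.residues),
        cfg.match_score,
        cfg.mismatch_score,
    )
    qcodes = encode(query.residues)
    qvalid = (qcodes < 4) & ~mask_array(query.residues)
    m, n = len(query), len(subject)

    hsps: List[Hsp] = []
    for strand in "+-":
        if strand == "+":
            subj = subject.residues
        else:
            subj = revcomp(subject.residues)
        scodes = encode(subj)
        svalid = (scodes < 4) & ~mask_array(subj)
        for qs, qe, ss, se, score, ident in _search_one_strand(
            qcodes, qvalid, scodes, svalid, cfg
        ):
            ev = e_value(score, m, n, kp)
            if ev > evalue_threshold:
                continue
            if strand == "-":
                ss, se = n - se, n - ss
            hsps.append(
                Hsp(
                    query_start=qs,
                    query_end=qe,
                    subject_start=ss,
                    subject_end=se,
                    strand=strand,
                    score=int(score),
                    bit_score=bit_score(score, kp),
                    e_value=ev,
                    identity=ident,
                )
            )
    hsps.sort(key=lambda h: (h.subject_start, h.query_start))
    return hsps


def recompute_score(
    hsp: Hsp, query: GenomeSequence, subject: GenomeSequence, cfg: PipelineConfig
) -> int:
    """Rescore an HSP from its coordinates (invariant check)."""
    q = encode(query.residues)[hsp.query_start : hsp.query_end]
    s_txt = subject.residues[hsp.subject_start : hsp.subject_end]
    if hsp.strand == "-":
        s_txt = revcomp(s_txt)
    s = encode(s_txt)
    eq = (q == s) & (q < 4)
    return int(np.where(eq, cfg.match_score, cfg.mismatch_score).sum())


# ---------------------------------------------------------------------------
# HSP linking
# ---------------------------------------------------------------------------


CHAIN_OVERLAP_TOL = 25  # bases of tolerated extension-jitter overlap in chains


def _linkable(a: Hsp, b: Hsp, sep_max: int) -> bool:
    """May chain a -> b (a before b along the query)?

    Colinear, same strand, separated by at most ``sep_max`` on both axes;
    overlaps beyond the jitter tolerance break the chain (a large query
    overlap is evidence of an internal duplication, not one hit).
    """
    if a.strand != b.strand:
        return False
    if not (b.query_start >= a.query_start and b.query_end >= a.query_end):
        return False
    gap_q = b.query_start - a.query_end
    if not -CHAIN_OVERLAP_TOL <= gap_q <= sep_max:
        return False
    if a.strand == "+":
        if not (b.subject_start >= a.subject_start and b.subject_end >= a.subject_end):
            return False
        gap_s = b.subject_start - a.subject_end
    else:
        if not (b.subject_start <= a.subject_start and b.subject_end <= a.subject_end):
            return False
        gap_s = a.subject_start - b.subject_end
    return -CHAIN_OVERLAP_TOL <= gap_s <= sep_max


def link_hsps(
    hsps: List[Hsp],
    sep_max: int,
    query_id: str = "mito",
    subject_id: str = "scaffold",
    query_length: int = 0,
    subject_length: int = 0,
    kp: KarlinParams = None,
    anchor_evalue: float = None,
) -> List[LinkedHit]:
    """Partition HSPs into maximal colinear same-strand chains.

    Chains are extracted greedily by total score: the highest-scoring
    valid chain is removed first, ties broken by leftmost subject start.
    The combined E-value uses the summed chain score over the same search
    space. With ``anchor_evalue`` set, chains are kept only when both the
    combined E-value and the best member HSP E-value pass it — weak
    terminal fragments ride along with an anchoring significant HSP while
    chains made only of weak HSPs are dropped.
    """
    remaining = list(hsps)
    chains: List[List[Hsp]] = []
    while remaining:
        remaining.sort(key=lambda h: (h.query_start, h.query_end))
        n = len(remaining)
        best_score = [h.score for h in remaining]
        back = [-1] * n
        for j in range(n):
            for i in range(j):
                if _linkable(remaining[i], remaining[j], sep_max):
                    cand = best_score[i] + remaining[j].score
                    if cand > best_score[j]:
                        best_score[j] = cand
                        back[j] = i
        # best chain endpoint: max score, tie -> leftmost subject start
        j = min(
            range(n),
            key=lambda k: (-best_score[k], min_subject_start_of_chain(remaining, back, k)),
        )
        chain = []
        while j != -1:
            chain.append(remaining[j])
            j = back[j]
        chain.reverse()
        chains.append(chain)
        taken = set(id(h) for h in chain)
        remaining = [h for h in remaining if id(h) not in taken]

    hits = []
    for chain in chains:
        total = sum(h.score for h in chain)
        if kp is not None and query_length and subject_length:
            ev = e_value(total, query_length, subject_length, kp)
        else:
            ev = min(h.e_value for h in chain)
        if anchor_evalue is not None:
            if ev > anchor_evalue or min(h.e_value for h in chain) > anchor_evalue:
                continue
        hits.append(
            LinkedHit(
                hsps=chain,
                subject_id=subject_id,
                query_id=query_id,
                combined_score=total,
                combined_e_value=ev,
            )
        )
    hits.sort(key=lambda h: h.subject_interval)
    return hits


def min_subject_start_of_chain(hsps, back, j) -> int:
    s = hsps[j].subject_start
    while back[j] != -1:
        j = back[j]
        s = min(s, hsps[j].subject_start)
    return s


def flag_mito_artifacts(
    hits: List[LinkedHit], mito_length: int, coverage: float = 0.95, identity: float = 0.99
) -> List[LinkedHit]:
    """Hits covering nearly the whole mitochondrial genome at near-perfect
    identity: likely the organelle genome itself misassembled into the
    nuclear scaffold set; flagged for review instead of annotated."""
    flagged = []
    for hit in hits:
        cov = sum(h.query_end - h.query_start for h in hit.hsps) / mito_length
        aligned = sum(h.query_end - h.query_start for h in hit.hsps)
        ident = (
            sum(h.identity * (h.query_end - h.query_start) for h in hit.hsps) / aligned
            if aligned
            else 0.0
        )
        if cov >= coverage and ident >= identity:
            flagged.append(hit)
    return flagged
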