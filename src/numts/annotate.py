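"""Group linked hits into numt annotations and classify rearrangements.

Linked hits on one scaffold that overlap or are separated by less than the
merge window (default 25 kb) are grouped. A group is merged into a single
numt when every junction between consecutive nuclear fragments is
explainable by at most one gross event of the grammar (interruption,
deletion, inversion, internal duplication); junctions that would require
two simultaneous events mark split points into separate numts, and
contradictory assignments of the same nuclear bases to two mitochondrial
origins reject the group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import fisher_exact

from .types import (
    Fragment,
    LinkedHit,
    NumtAnnotation,
    RearrangementEvent,
    ValidationError,
)

NUCLEAR_OVERLAP_TOL = 25  # bases of tolerated extension jitter between fragments


class MergeConflict(ValidationError):
    """Same nuclear bases assigned two mitochondrial origins."""


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------


def group_hits(linked_hits: Sequence[LinkedHit], merge_window: int) -> List[List[LinkedHit]]:
    """Single-linkage clustering of hits per scaffold with gap < merge_window.

    Separation is measured end-to-end between nearest fragment boundaries;
    overlapping hits always group.
    """
    by_scaffold: Dict[str, List[LinkedHit]] = {}
    for hit in linked_hits:
        by_scaffold.setdefault(hit.subject_id, []).append(hit)
    groups: List[List[LinkedHit]] = []
    for scaffold in sorted(by_scaffold):
        hits = sorted(by_scaffold[scaffold], key=lambda h: h.subject_interval)
        cur = [hits[0]]
        cur_end = hits[0].subject_interval[1]
        for hit in hits[1:]:
            s, e = hit.subject_interval
            if s - cur_end < merge_window:
                cur.append(hit)
                cur_end = max(cur_end, e)
            else:
                groups.append(cur)
                cur = [hit]
                cur_end = e
        groups.append(cur)
    return groups


# ---------------------------------------------------------------------------
# Merging under the event grammar
# ---------------------------------------------------------------------------


def _hit_to_fragment(hit: LinkedHit) -> Fragment:
    qs, qe = hit.query_interval
    ss, se = hit.subject_interval
    aligned = sum(h.query_end - h.query_start for h in hit.hsps)
    ident = (
        sum(h.identity * (h.query_end - h.query_start) for h in hit.hsps) / aligned
        if aligned
        else 0.0
    )
    return Fragment(
        nuc_start=ss, nuc_end=se, mito_start=qs, mito_end=qe,
        strand=hit.strand, identity=ident,
    )


def circular_gap(gap: int, mito_length: int) -> int:
    """Representative of ``gap`` modulo the circle in (-L/2, L/2]."""
    g = gap % mito_length
    if g > mito_length / 2:
        g -= mito_length
    return g


def _mito_gap(a: Fragment, b: Fragment, mito_length: int) -> Optional[int]:
    """Signed mito-coordinate gap between nuclear-consecutive fragments of
    the same strand (None when strands differ)."""
    if a.strand != b.strand:
        return None
    raw = (b.mito_start - a.mito_end) if a.strand == "+" else (a.mito_start - b.mito_end)
    return circular_gap(raw, mito_length)


def _junction_consistent(a: Fragment, b: Fragment, mito_length: int, min_event: int) -> bool:
    """One gross event at most may separate consecutive fragments."""
    nuclear_event = (b.nuc_start - a.nuc_end) >= min_event
    gap = _mito_gap(a, b, mito_length)
    mito_event = gap is None or abs(gap) >= min_event
    return not (nuclear_event and mito_event)


def _trim_overlaps(frags: List[Fragment]) -> List[Fragment]:
    """Resolve nuclear overlaps between fragments deterministically.

    The later fragment is trimmed back (its mito interval adjusted in
    step); fragments consumed entirely by the overlap are dropped.
    """
    out: List[Fragment] = []
    for frag in sorted(frags, key=lambda f: (f.nuc_start, f.nuc_end)):
        if out and frag.nuc_start < out[-1].nuc_end:
            overlap = out[-1].nuc_end - frag.nuc_start
            if overlap >= frag.nuc_length():
                continue
            frag = Fragment(
                nuc_start=frag.nuc_start + overlap,
                nuc_end=frag.nuc_end,
                mito_start=frag.mito_start + (overlap if frag.strand == "+" else 0),
                mito_end=frag.mito_end - (0 if frag.strand == "+" else overlap),
                strand=frag.strand,
                identity=frag.identity,
            )
        out.append(frag)
    return out


def merge_group(
    group: Sequence[LinkedHit],
    mito_length: int,
    species: str = "",
    min_event: int = 200,
    id_prefix: str = "numt",
    start_index: int = 0,
    resolve_overlaps: bool = False,
) -> List[NumtAnnotation]:
    """Merge a 25-kb group into one or more numt annotations.

    Raises MergeConflict when fragments overlap contradictorily in
    nuclear coordinates (unless ``resolve_overlaps`` trims them); splits
    at junctions that would require two simultaneous gross events.
    """
    if not group:
        raise ValueError("empty group")
    scaffold = group[0].subject_id
    frags = sorted((_hit_to_fragment(h) for h in group), key=lambda f: f.nuc_start)
    if resolve_overlaps:
        frags = _trim_overlaps(frags)
    for a, b in zip(frags, frags[1:]):
        overlap = a.nuc_end - b.nuc_start
        if overlap > NUCLEAR_OVERLAP_TOL:
            same_origin = (
                a.strand == b.strand
                and abs(_mito_gap(a, b, mito_length) or 0) <= NUCLEAR_OVERLAP_TOL
            )
            if not same_origin:
                raise MergeConflict(
                    f"scaffold {scaffold}: nuclear bases "
                    f"[{b.nuc_start},{a.nuc_end}) claimed by two mito origins "
                    f"[{a.mito_start},{a.mito_end}){a.strand} and "
                    f"[{b.mito_start},{b.mito_end}){b.strand}"
                )
    pieces: List[List[Fragment]] = [[frags[0]]]
    for a, b in zip(frags, frags[1:]):
        if _junction_consistent(a, b, mito_length, min_event):
            pieces[-1].append(b)
        else:
            pieces.append([b])
    out = []
    for i, piece in enumerate(pieces):
        out.append(
            NumtAnnotation(
                numt_id=f"{id_prefix}{start_index + i}",
                species=species,
                scaffold=scaffold,
                fragments=piece,
            )
        )
    return out


def annotate_hits(
    linked_hits: Sequence[LinkedHit],
    mito_length: int,
    species: str = "",
    merge_window: int = 25000,
    min_event: int = 200,
) -> List[NumtAnnotation]:
    """Full grouping + merging pass over one species' linked hits."""
    numts: List[NumtAnnotation] = []
    for group in group_hits(linked_hits, merge_window):
        numts.extend(
            merge_group(
                group,
                mito_length,
                species=species,
                min_event=min_event,
                id_prefix=f"{species}_numt" if species else "numt",
                start_index=len(numts),
                resolve_overlaps=True,
            )
        )
    return numts


# ---------------------------------------------------------------------------
# Rearrangement classification
# ---------------------------------------------------------------------------


def classify_rearrangements(
    numt: NumtAnnotation, mito_length: int, min_event: int = 200
) -> List[RearrangementEvent]:
    """Classify gross post-insertion events within a merged numt.

    Sizes follow the natural evidence axis of each class: interruptions in
    nuclear bases, deletions and duplications in mitochondrial bases,
    inversions as the inverted fragments' mitochondrial length.
    """
    events: List[RearrangementEvent] = []
    frags = numt.fragments

    # interruptions: non-numt nuclear sequence between consecutive fragments
    for a, b in zip(frags, frags[1:]):
        gap = b.nuc_start - a.nuc_end
        if gap >= min_event:
            events.append(
                RearrangementEvent(
                    numt_id=numt.numt_id,
                    type="interruption",
                    size=gap,
                    nuc_interval=(a.nuc_end, b.nuc_start),
                )
            )

    # deletions: missing mito sequence between same-strand colinear fragments
    for a, b in zip(frags, frags[1:]):
        gap = _mito_gap(a, b, mito_length)
        if gap is not None and gap >= min_event:
            mito_iv = (a.mito_end, b.mito_start) if a.strand == "+" else (b.mito_end, a.mito_start)
            events.append(
                RearrangementEvent(
                    numt_id=numt.numt_id, type="deletion", size=gap, mito_interval=mito_iv
                )
            )

    # inversions: maximal runs of minority-strand fragments
    if len({f.strand for f in frags}) > 1:
        plus_len = sum(f.mito_length() for f in frags if f.strand == "+")
        minus_len = sum(f.mito_length() for f in frags if f.strand == "-")
        minority = "-" if minus_len <= plus_len else "+"
        run: List[Fragment] = []
        for f in frags + [None]:
            if f is not None and f.strand == minority:
                run.append(f)
            elif run:
                size = sum(r.mito_length() for r in run)
                if size >= min_event:
                    events.append(
                        RearrangementEvent(
                            numt_id=numt.numt_id,
                            type="inversion",
                            size=size,
                            nuc_interval=(run[0].nuc_start, run[-1].nuc_end),
                        )
                    )
                run = []

    # internal duplications: mito positions covered twice or more
    cover = np.zeros(mito_length, dtype=np.int16)
    for f in frags:
        s, e = f.mito_start % mito_length, f.mito_end
        if e <= mito_length:
            cover[s:e] += 1
        else:  # origin-spanning
            cover[s:] += 1
            cover[: e % mito_length] += 1
    dup = cover >= 2
    if dup.any():
        edges = np.flatnonzero(np.diff(dup.astype(np.int8)))
        starts = np.concatenate(([0], edges + 1))
        ends = np.concatenate((edges + 1, [mito_length]))
        for s, e in zip(starts, ends):
            if dup[s] and e - s >= min_event:
                events.append(
                    RearrangementEvent(
                        numt_id=numt.numt_id,
                        type="internal_duplication",
                        size=int(e - s),
                        mito_interval=(int(s), int(e)),
                    )
                )
    return events


# ---------------------------------------------------------------------------
# Repeat adjacency and intron overlap
# ---------------------------------------------------------------------------


@dataclass
class RepeatAssociation:
    flags: Dict[str, bool]  # numt_id -> adjacent to a repeat
    excluded: List[str]  # numts without retrievable flanks
    n_adjacent: int
    n_tested: int
    p_value: float
    table: tuple


def _near(
    intervals: Sequence[Tuple[int, int]], pos_s: int, pos_e: int, within: int
) -> bool:
    return any(s < pos_e + within and e > pos_s - within for s, e in intervals)


def associate_repeats(
    numts: Sequence[NumtAnnotation],
    repeats: Sequence[tuple],
    scaffold_lengths: Dict[str, int],
    adjacency: int = 200,
    min_flank: int = 100,
    n_controls: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> RepeatAssociation:
    """Flag numts with a repeat within ``adjacency`` bases of a boundary or
    inside interrupting sequence; test association against uniformly
    sampled control loci with the same flank requirement (Fisher exact).

    ``repeats`` are BED-style tuples (chrom, start, end, ...).
    """
    rng = rng or np.random.default_rng(0)
    rep_by_scaffold: Dict[str, List[Tuple[int, int]]] = {}
    for r in repeats:
        rep_by_scaffold.setdefault(r[0], []).append((r[1], r[2]))

    flags: Dict[str, bool] = {}
    excluded: List[str] = []
    numt_spans: Dict[str, List[Tuple[int, int]]] = {}
    for numt in numts:
        s, e = numt.span
        numt_spans.setdefault(numt.scaffold, []).append((s, e))
        limit = scaffold_lengths.get(numt.scaffold, 0)
        if s < min_flank or limit - e < min_flank:
            excluded.append(numt.numt_id)
            continue
        ivs = rep_by_scaffold.get(numt.scaffold, [])
        hit = _near(ivs, s, e, adjacency)
        if not hit:  # repeats inside interrupting sequence also count
            for a, b in zip(numt.fragments, numt.fragments[1:]):
                if b.nuc_start > a.nuc_end and _near(ivs, a.nuc_end, b.nuc_start, 0):
                    hit = True
                    break
        flags[numt.numt_id] = hit

    n_adj = sum(flags.values())
    n_tested = len(flags)
    if not repeats or n_tested == 0:
        return RepeatAssociation(flags, excluded, n_adj, n_tested, 1.0, ((0, 0), (0, 0)))

    # control loci: uniform non-numt positions with the flank requirement
    scaffolds = sorted(s for s, L in scaffold_lengths.items() if L > 2 * min_flank)
    lengths = np.array([scaffold_lengths[s] for s in scaffolds], dtype=float)
    ctrl_adj = 0
    drawn = 0
    while drawn < n_controls:
        i = int(rng.choice(len(scaffolds), p=lengths / lengths.sum()))
        sc = scaffolds[i]
        pos = int(rng.integers(min_flank, scaffold_lengths[sc] - min_flank))
        if _near(numt_spans.get(sc, []), pos, pos, 0):
            continue
        drawn += 1
        if _near(rep_by_scaffold.get(sc, []), pos, pos, adjacency):
            ctrl_adj += 1
    table = ((n_adj, n_tested - n_adj), (ctrl_adj, n_controls - ctrl_adj))
    _, p = fisher_exact(table, alternative="two-sided")
    return RepeatAssociation(flags, excluded, n_adj, n_tested, float(p), table)


def intron_overlap(numts: Sequence[NumtAnnotation], gff3_path) -> Tuple[int, float, List[str]]:
    """Count numts whose span lies inside a transcript without touching an
    exon. Returns (count, fraction of all numts, intronic numt ids)."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts: Dict[str, List[Tuple[int, int]]] = {}
    exons: Dict[str, List[Tuple[int, int]]] = {}
    for ft in db.all_features():
        iv = (ft.start - 1, ft.end)  # GFF3 1-based inclusive -> half-open
        if ft.featuretype in ("mRNA", "transcript"):
            transcripts.setdefault(ft.seqid, []).append(iv)
        elif ft.featuretype == "exon":
            exons.setdefault(ft.seqid, []).append(iv)
    intronic = []
    for numt in numts:
        s, e = numt.span
        inside = any(ts <= s and e <= te for ts, te in transcripts.get(numt.scaffold, []))
        touches_exon = _near(exons.get(numt.scaffold, []), s, e, 0)
        if inside and not touches_exon:
            intronic.append(numt.numt_id)
    frac = len(intronic) / len(numts) if numts else 0.0
    return len(intronic), frac, intronic
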