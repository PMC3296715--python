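"""Synthetic genome evolution with numt insertions at known times.

Simulates an A+T-rich circular mitochondrial genome evolving along a
calibrated tree under F84, nuclear scaffolds evolving at a rate slower by
the nuclear rate divisor (Drosophila nuclear synonymous rates are 4.5-9x
slower than mitochondrial ones), numt insertions as a Poisson process per
branch copying the mitochondrial ancestral sequence at the insertion time,
post-insertion duplications (with flanks) and deletions as per-numt
processes, and gross rearrangements applied per class probabilities at
insertion. Every event is logged as ground truth for recovery testing.

No selection, no recombination between numts, and no indel process within
un-rearranged numt bodies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .f84 import F84Params
from .tree import CalibratedTree
from .types import GenomeSequence, TruthRecord, decode

DEFAULT_REARRANGEMENT_PROBS = {
    "interruption": 0.15,
    "deletion": 0.12,
    "inversion": 0.02,
    "internal_duplication": 0.05,
}


@dataclass
class SimulationParams:
    tree: CalibratedTree
    mito_length: int = 16000
    at_fraction: float = 0.78
    mito_subst_rate: float = 0.007  # substitutions/site/My
    nuclear_rate_divisor: float = 6.0  # in the observed 4.5-9.0 band
    insertion_rate_per_my: float = 0.75
    duplication_rate_per_numt_per_my: float = 0.010
    deletion_rate_per_numt_per_my: float = 0.052
    rearrangement_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_REARRANGEMENT_PROBS)
    )
    fragment_log_median: float = 600.0  # bases; log-normal median
    fragment_log_sigma: float = 1.2
    min_fragment: int = 200
    scaffold_lengths: tuple = (120_000, 80_000)
    nuclear_at_fraction: float = 0.58
    duplication_flank_bases: int = 1000
    min_event_bases: int = 200
    ts_tv_ratio: float = 2.0
    outgroup_label: str = "A_gambiae"
    initial_numts: int = 0
    control_region: bool = False
    track_sequences: bool = True  # False: event history only (no substitutions)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.at_fraction < 1:
            raise ValueError("at_fraction must be in (0, 1)")
        if self.nuclear_rate_divisor < 1:
            raise ValueError("nuclear_rate_divisor must be >= 1")
        for name in (
            "mito_subst_rate",
            "insertion_rate_per_my",
            "duplication_rate_per_numt_per_my",
            "deletion_rate_per_numt_per_my",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimulatedDataset:
    params: SimulationParams
    scaffolds: Dict[str, List[GenomeSequence]]  # species -> nuclear scaffolds
    mito: Dict[str, GenomeSequence]  # species -> mitochondrial genome
    truth: List[TruthRecord]  # extant numts per species + deletion log
    node_mito: Dict[str, np.ndarray]  # ancestral mito at every node

    def truth_for(self, species: str) -> List[TruthRecord]:
        return [t for t in self.truth if t.species == species and not t.deleted]


# ---------------------------------------------------------------------------
# Elementary sequence operations
# ---------------------------------------------------------------------------


def random_sequence(rng: np.random.Generator, length: int, at_fraction: float) -> np.ndarray:
    p = np.array(
        [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    )
    return rng.choice(4, size=length, p=p).astype(np.int8)


def evolve(
    codes: np.ndarray, model: F84Params, rate: float, duration_my: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One jump of F84 evolution over ``rate * duration`` expected
    substitutions per site (exact transition sampling, not per-event)."""
    t = rate * duration_my
    if t <= 0:
        return codes.copy()
    P = model.transition_matrix(t)
    cum = np.cumsum(P, axis=1)
    r = rng.random(codes.size)
    return (r[:, None] > cum[codes]).sum(axis=1).astype(np.int8)


def complement(codes: np.ndarray) -> np.ndarray:
    return np.where(codes < 4, 3 - codes, 4).astype(np.int8)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return complement(codes)[::-1]


def simulate_sequence_evolution(
    root_sequence: np.ndarray,
    tree: CalibratedTree,
    rate: float,
    model: F84Params,
    rng: np.random.Generator,
    sample_points: Optional[List[Tuple[str, float]]] = None,
) -> Tuple[Dict[str, np.ndarray], Dict[Tuple[str, float], np.ndarray]]:
    """Evolve a sequence down the calibrated tree under F84.

    Returns per-node sequences and, optionally, the ancestral sequence at
    arbitrary (branch_label, age) time points on branches.
    """
    samples: Dict[Tuple[str, float], np.ndarray] = {}
    wanted: Dict[str, List[float]] = {}
    for label, age in sample_points or []:
        wanted.setdefault(label, []).append(age)
    node_seqs: Dict[str, np.ndarray] = {tree.root_label: root_sequence.copy()}

    def walk(node, seq: np.ndarray, age: float) -> None:
        for child in node.child_nodes():
            child_age = tree.node_age(child.label)
            cur, t = seq, age
            for point in sorted(wanted.get(child.label, []), reverse=True):
                if child_age <= point <= age:
                    cur = evolve(cur, model, rate, t - point, rng)
                    t = point
                    samples[(child.label, point)] = cur.copy()
            cur = evolve(cur, model, rate, t - child_age, rng)
            node_seqs[child.label] = cur
            walk(child, cur, child_age)

    walk(tree.node(tree.root_label), root_sequence, tree.root_age)
    return node_seqs, samples


# ---------------------------------------------------------------------------
# Numt history simulation
# ---------------------------------------------------------------------------


@dataclass
class _Numt:
    numt_id: str
    scaffold: int
    start: int
    end: int
    mito_start: int
    mito_end: int  # may exceed mito_length (origin-spanning)
    strand: str
    branch: str
    time_my: float
    parent: Optional[str]
    rearrangements: list


class _Lineage:
    """Mutable per-lineage state walked down the tree."""

    def __init__(self, mito: np.ndarray, scaffolds: List[np.ndarray], age: float):
        self.mito = mito
        self.mito_age = age
        self.scaffolds = scaffolds
        self.scaffold_age = [age] * len(scaffolds)
        self.numts: List[_Numt] = []

    def clone(self) -> "_Lineage":
        other = _Lineage(self.mito.copy(), [s.copy() for s in self.scaffolds], 0.0)
        other.mito_age = self.mito_age
        other.scaffold_age = list(self.scaffold_age)
        other.numts = [
            _Numt(**{**n.__dict__, "rearrangements": list(n.rearrangements)})
            for n in self.numts
        ]
        return other


class NumtHistorySimulator:
    """Gillespie simulation of insertion/duplication/deletion along the tree."""

    def __init__(self, params: SimulationParams):
        self.p = params
        ss = np.random.SeedSequence(params.seed)
        kids = ss.spawn(3)
        self.rng_root = np.random.default_rng(kids[0])
        self.rng_events = np.random.default_rng(kids[1])
        self.rng_subst = np.random.default_rng(kids[2])
        at = params.at_fraction
        self.mito_model = F84Params(
            freqs=np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]),
            ts_tv_ratio=params.ts_tv_ratio,
        )
        nat = params.nuclear_at_fraction
        self.nuc_model = F84Params(
            freqs=np.array([nat / 2, (1 - nat) / 2, (1 - nat) / 2, nat / 2]),
            ts_tv_ratio=params.ts_tv_ratio,
        )
        self.nuclear_rate = params.mito_subst_rate / params.nuclear_rate_divisor
        self._counter = 0
        self._deleted_log: List[TruthRecord] = []
        self.node_mito: Dict[str, np.ndarray] = {}

    # -- helpers ---------------------------------------------------------

    def _next_id(self, prefix: str) -> str:
        self._counter += 1
        return f"{prefix}{self._counter}"

    def _fragment_length(self) -> int:
        p = self.p
        for _ in range(100):
            ln = int(
                math.exp(
                    math.log(p.fragment_log_median)
                    + p.fragment_log_sigma * self.rng_events.standard_normal()
                )
            )
            if p.min_fragment <= ln <= p.mito_length:
                return ln
        return p.min_fragment

    def _event_size(self, median: float, lo: int, hi: int) -> Optional[int]:
        if hi < lo:
            return None
        size = int(math.exp(math.log(median) + 0.8 * self.rng_events.standard_normal()))
        return int(min(max(size, lo), hi))

    def _evolve_scaffold(self, lin: _Lineage, idx: int, to_age: float) -> None:
        if not self.p.track_sequences:
            lin.scaffold_age[idx] = to_age
            return
        dt = lin.scaffold_age[idx] - to_age
        if dt > 0:
            lin.scaffolds[idx] = evolve(
                lin.scaffolds[idx], self.nuc_model, self.nuclear_rate, dt, self.rng_subst
            )
            lin.scaffold_age[idx] = to_age

    def _evolve_mito(self, lin: _Lineage, to_age: float) -> None:
        if not self.p.track_sequences:
            lin.mito_age = to_age
            return
        dt = lin.mito_age - to_age
        if dt > 0:
            lin.mito = evolve(
                lin.mito, self.mito_model, self.p.mito_subst_rate, dt, self.rng_subst
            )
            lin.mito_age = to_age

    def _shift(self, lin: _Lineage, scaffold: int, at: int, delta: int) -> None:
        for numt in lin.numts:
            if numt.scaffold == scaffold and numt.start >= at:
                numt.start += delta
                numt.end += delta

    def _free_position(self, lin: _Lineage, sc: int) -> int:
        """Uniform position outside existing numt bodies (no nesting:
        a copy landing inside a numt would corrupt its recorded extent),
        resampled up to a bound, logged fallback otherwise."""
        size = lin.scaffolds[sc].size
        spans = [(n.start, n.end) for n in lin.numts if n.scaffold == sc]
        for _ in range(200):
            pos = int(self.rng_events.integers(0, size + 1))
            if not any(s < pos < e for s, e in spans):
                return pos
        return 0

    # -- events ----------------------------------------------------------

    def _build_insert_sequence(self, lin: _Lineage) -> Tuple[np.ndarray, dict]:
        p = self.p
        L = p.mito_length
        frag_len = self._fragment_length()
        mstart = int(self.rng_events.integers(0, L))
        strand = "+" if self.rng_events.random() < 0.5 else "-"
        idx = (mstart + np.arange(frag_len)) % L
        seq = lin.mito[idx].copy()
        if strand == "-":
            seq = revcomp_codes(seq)
        rearr: List[Tuple[str, int]] = []
        me = p.min_event_bases
        # at most one event per class, applied to the fresh copy
        if self.rng_events.random() < p.rearrangement_probs.get("deletion", 0):
            size = self._event_size(1000, me, seq.size - 2 * me)
            if size:
                pos = int(self.rng_events.integers(me, seq.size - me - size + 1))
                seq = np.concatenate([seq[:pos], seq[pos + size :]])
                rearr.append(("deletion", size))
        if self.rng_events.random() < p.rearrangement_probs.get("internal_duplication", 0):
            size = self._event_size(1000, me, min(seq.size - 2 * me, 4000))
            if size and size > 0:
                pos = int(self.rng_events.integers(me, seq.size - me - size + 1))
                seq = np.concatenate([seq[: pos + size], seq[pos : ]])
                rearr.append(("internal_duplication", size))
        if self.rng_events.random() < p.rearrangement_probs.get("inversion", 0):
            size = self._event_size(600, me, seq.size - 2 * me)
            if size:
                pos = int(self.rng_events.integers(me, seq.size - me - size + 1))
                seq = np.concatenate(
                    [seq[:pos], revcomp_codes(seq[pos : pos + size]), seq[pos + size :]]
                )
                rearr.append(("inversion", size))
        if self.rng_events.random() < p.rearrangement_probs.get("interruption", 0):
            size = self._event_size(2000, me, 10000)
            if size and seq.size >= 2 * me:
                pos = int(self.rng_events.integers(me, seq.size - me + 1))
                foreign = random_sequence(self.rng_events, size, p.nuclear_at_fraction)
                seq = np.concatenate([seq[:pos], foreign, seq[pos:]])
                rearr.append(("interruption", size))
        info = {
            "mito_start": mstart,
            "mito_end": mstart + frag_len,
            "strand": strand,
            "rearrangements": rearr,
        }
        return seq, info

    def _insert(self, lin: _Lineage, branch: str, age: float) -> None:
        seq, info = self._build_insert_sequence(lin)
        sizes = np.array([s.size for s in lin.scaffolds], dtype=float)
        sc = int(self.rng_events.choice(len(lin.scaffolds), p=sizes / sizes.sum()))
        self._evolve_scaffold(lin, sc, age)
        pos = self._free_position(lin, sc)
        lin.scaffolds[sc] = np.concatenate(
            [lin.scaffolds[sc][:pos], seq, lin.scaffolds[sc][pos:]]
        )
        self._shift(lin, sc, pos, seq.size)
        lin.numts.append(
            _Numt(
                numt_id=self._next_id("ins"),
                scaffold=sc,
                start=pos,
                end=pos + seq.size,
                mito_start=info["mito_start"],
                mito_end=info["mito_end"],
                strand=info["strand"],
                branch=branch,
                time_my=age,
                parent=None,
                rearrangements=info["rearrangements"],
            )
        )

    def _duplicate(self, lin: _Lineage, branch: str, age: float) -> None:
        if not lin.numts:
            return
        src = lin.numts[int(self.rng_events.integers(len(lin.numts)))]
        sc = src.scaffold
        self._evolve_scaffold(lin, sc, age)
        flank = self.p.duplication_flank_bases
        lo = max(0, src.start - flank)
        hi = min(lin.scaffolds[sc].size, src.end + flank)
        # clip flanks at neighbouring numt bodies so copies stay traceable
        for other in lin.numts:
            if other is src or other.scaffold != sc:
                continue
            if other.end <= src.start:
                lo = max(lo, other.end)
            if other.start >= src.end:
                hi = min(hi, other.start)
        copy = lin.scaffolds[sc][lo:hi].copy()
        left = src.start - lo
        sizes = np.array([s.size for s in lin.scaffolds], dtype=float)
        dest = int(self.rng_events.choice(len(lin.scaffolds), p=sizes / sizes.sum()))
        self._evolve_scaffold(lin, dest, age)
        pos = self._free_position(lin, dest)
        lin.scaffolds[dest] = np.concatenate(
            [lin.scaffolds[dest][:pos], copy, lin.scaffolds[dest][pos:]]
        )
        self._shift(lin, dest, pos, copy.size)
        body = src.end - src.start
        lin.numts.append(
            _Numt(
                numt_id=self._next_id("dup"),
                scaffold=dest,
                start=pos + left,
                end=pos + left + body,
                mito_start=src.mito_start,
                mito_end=src.mito_end,
                strand=src.strand,
                branch=branch,
                time_my=age,
                parent=src.numt_id,
                rearrangements=list(src.rearrangements),
            )
        )

    def _delete(self, lin: _Lineage, branch: str, age: float) -> None:
        if not lin.numts:
            return
        k = int(self.rng_events.integers(len(lin.numts)))
        numt = lin.numts.pop(k)
        sc = numt.scaffold
        self._evolve_scaffold(lin, sc, age)
        lin.scaffolds[sc] = np.concatenate(
            [lin.scaffolds[sc][: numt.start], lin.scaffolds[sc][numt.end :]]
        )
        self._shift(lin, sc, numt.end, -(numt.end - numt.start))
        self._deleted_log.append(
            TruthRecord(
                numt_id=numt.numt_id,
                species=branch,
                insertion_branch=numt.branch,
                insertion_time_my=numt.time_my,
                mito_start=numt.mito_start,
                mito_end=numt.mito_end,
                strand=numt.strand,
                parent_numt_id=numt.parent,
                deleted=True,
                rearrangements=list(numt.rearrangements),
            )
        )

    # -- tree walk ---------------------------------------------------------

    def run(self) -> SimulatedDataset:
        p = self.p
        tree = p.tree
        mito_root = random_sequence(self.rng_root, p.mito_length, p.at_fraction)
        if p.control_region:
            # A+T-richer control-region analogue in the last ~2 kb
            n = min(2000, p.mito_length // 4)
            mito_root[-n:] = random_sequence(self.rng_root, n, 0.95)
        scaffolds_root = [
            random_sequence(self.rng_root, L, p.nuclear_at_fraction)
            for L in p.scaffold_lengths
        ]
        root_age = tree.root_age
        lineage = _Lineage(mito_root, scaffolds_root, root_age)

        # the event processes act within the focal radiation only; the
        # deep outgroup lineage contributes its mitochondrial sequence
        if p.outgroup_label in tree.taxa:
            ingroup_root_age = max(
                tree.node_age(br.label)
                for br in tree.branches()
                if br.label != p.outgroup_label and br.parent_label == tree.root_label
            )
        else:
            ingroup_root_age = root_age
        self._events_below = ingroup_root_age + 1e-9

        for k in range(p.initial_numts):
            self._insert(lineage, tree.root_label, root_age)
            lineage.numts[-1].time_my = root_age

        self.node_mito[tree.root_label] = lineage.mito.copy()
        scaffold_out: Dict[str, List[GenomeSequence]] = {}
        mito_out: Dict[str, GenomeSequence] = {}
        truth: List[TruthRecord] = []

        def walk(node, lin: _Lineage, age: float) -> None:
            children = node.child_nodes()
            for i, child in enumerate(children):
                sub = lin if i == len(children) - 1 else lin.clone()
                child_age = tree.node_age(child.label)
                self._branch(sub, child.label, age, child_age)
                self.node_mito[child.label] = sub.mito.copy()
                if child.is_leaf():
                    self._emit(sub, child.label, scaffold_out, mito_out, truth)
                else:
                    walk(child, sub, child_age)

        walk(tree.node(tree.root_label), lineage, root_age)
        truth.extend(self._deleted_log)
        return SimulatedDataset(
            params=p,
            scaffolds=scaffold_out,
            mito=mito_out,
            truth=truth,
            node_mito=self.node_mito,
        )

    def _branch(self, lin: _Lineage, label: str, top_age: float, bottom_age: float) -> None:
        p = self.p
        t = top_age
        active = top_age <= self._events_below
        while active:
            n = len(lin.numts)
            lam = p.insertion_rate_per_my + n * (
                p.duplication_rate_per_numt_per_my + p.deletion_rate_per_numt_per_my
            )
            if lam <= 0:
                break
            t_next = t - self.rng_events.exponential(1.0 / lam)
            if t_next <= bottom_age:
                break
            t = t_next
            self._evolve_mito(lin, t)
            u = self.rng_events.random() * lam
            if u < p.insertion_rate_per_my:
                self._insert(lin, label, t)
            elif u < p.insertion_rate_per_my + n * p.duplication_rate_per_numt_per_my:
                self._duplicate(lin, label, t)
            else:
                self._delete(lin, label, t)
        self._evolve_mito(lin, bottom_age)
        for idx in range(len(lin.scaffolds)):
            self._evolve_scaffold(lin, idx, bottom_age)

    def _emit(self, lin, species, scaffold_out, mito_out, truth) -> None:
        scaffold_out[species] = [
            GenomeSequence(id=f"{species}_scaf{i}", residues=decode(s))
            for i, s in enumerate(lin.scaffolds)
        ]
        mito_out[species] = GenomeSequence(
            id=f"{species}_mt", residues=decode(lin.mito), topology="circular"
        )
        for numt in lin.numts:
            truth.append(
                TruthRecord(
                    numt_id=numt.numt_id,
                    species=species,
                    insertion_branch=numt.branch,
                    insertion_time_my=numt.time_my,
                    mito_start=numt.mito_start,
                    mito_end=numt.mito_end,
                    strand=numt.strand,
                    scaffold=f"{species}_scaf{numt.scaffold}",
                    nuc_start=numt.start,
                    nuc_end=numt.end,
                    parent_numt_id=numt.parent,
                    rearrangements=list(numt.rearrangements),
                )
            )


def simulate_numt_history(params: SimulationParams) -> SimulatedDataset:
    """Run the full generative model; see :class:`NumtHistorySimulator`."""
    return NumtHistorySimulator(params).run()


# ---------------------------------------------------------------------------
# Repeat planting
# ---------------------------------------------------------------------------


def plant_repeats(
    scaffolds: List[GenomeSequence],
    repeat_library: List[GenomeSequence],
    density_per_100kb: float,
    adjacency_bias: float,
    rng: np.random.Generator,
    numt_spans: Optional[List[tuple]] = None,
    adjacency_bases: int = 200,
) -> Tuple[List[GenomeSequence], List[tuple]]:
    """Insert repeat-library copies uniformly, plus a numt-adjacent excess.

    ``adjacency_bias`` is the expected number of extra repeat copies per
    numt placed within ``adjacency_bases`` of a numt boundary. Returns the
    modified scaffolds and a truth BED list (chrom, start, end, name);
    ``numt_spans`` tuples (chrom, start, end) are updated in place when
    insertions fall before them.
    """
    if not repeat_library:
        raise ValueError("repeat library is empty")
    numt_spans = numt_spans if numt_spans is not None else []
    plan: Dict[str, List[Tuple[int, np.ndarray, str]]] = {}

    def schedule(chrom: str, pos: int, rep: GenomeSequence):
        from .types import encode as _enc

        plan.setdefault(chrom, []).append((pos, _enc(rep.residues), rep.id))

    for scaf in scaffolds:
        n_uniform = rng.poisson(density_per_100kb * len(scaf) / 100_000)
        for _ in range(n_uniform):
            rep = repeat_library[int(rng.integers(len(repeat_library)))]
            schedule(scaf.id, int(rng.integers(0, len(scaf) + 1)), rep)
    if adjacency_bias > 0:
        by_chrom = {s.id: len(s) for s in scaffolds}
        for chrom, start, end in list(numt_spans):
            n_extra = rng.poisson(adjacency_bias)
            for _ in range(n_extra):
                rep = repeat_library[int(rng.integers(len(repeat_library)))]
                side = rng.random() < 0.5
                offs = int(rng.integers(0, adjacency_bases))
                pos = max(0, start - offs - len(rep)) if side else min(
                    by_chrom[chrom], end + offs
                )
                schedule(chrom, pos, rep)

    out_scaffolds = []
    bed: List[tuple] = []
    spans_by_chrom: Dict[str, List[int]] = {}
    for i, (chrom, s, e) in enumerate(numt_spans):
        spans_by_chrom.setdefault(chrom, []).append(i)
    for scaf in scaffolds:
        inserts = sorted(plan.get(scaf.id, []), key=lambda t: t[0], reverse=True)
        from .types import encode as _enc

        codes = _enc(scaf.residues)
        for pos, rep_codes, rep_id in inserts:
            codes = np.concatenate([codes[:pos], rep_codes, codes[pos:]])
            for i in spans_by_chrom.get(scaf.id, []):
                c, s, e = numt_spans[i]
                if s >= pos:
                    numt_spans[i] = (c, s + rep_codes.size, e + rep_codes.size)
            for j in range(len(bed)):
                c, s, e, name = bed[j]
                if c == scaf.id and s >= pos:
                    bed[j] = (c, s + rep_codes.size, e + rep_codes.size, name)
            bed.append((scaf.id, pos, pos + rep_codes.size, rep_id))
        out_scaffolds.append(
            GenomeSequence(id=scaf.id, residues=decode(codes), topology=scaf.topology)
        )
    return out_scaffolds, sorted(bed)
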