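"""Self-contained validation experiments on synthetic data.

Each function generates its own data from a seed, runs the relevant
pipeline stages, and returns summary statistics. The same experiments back
the test suite and the reproduction script, so every reported number is
recomputed from scratch at run time.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional

import numpy as np
from scipy.optimize import brentq

from .config import PipelineConfig
from .f84 import F84Params
from .homology import test_paralogy
from .pipeline import DatingContext, annotate_species
from .rates import branch_set, deletion_rate_steady_state, estimate_rates
from .simulate import (
    SimulationParams,
    evolve,
    random_sequence,
    revcomp_codes,
    simulate_numt_history,
)
from .tree import CalibratedTree, drosophila_tree
from .types import GenomeSequence, PlacementResult, decode

MITO_RATE = 0.007  # substitutions/site/My, generator default
AT_MITO = 0.78
AT_NUC = 0.58


def _mito_model() -> F84Params:
    return F84Params(
        freqs=np.array([AT_MITO / 2, (1 - AT_MITO) / 2, (1 - AT_MITO) / 2, AT_MITO / 2]),
        ts_tv_ratio=2.0,
    )


def _time_for_divergence(model: F84Params, p_dist: float) -> float:
    """Branch duration (in model units) giving an expected p-distance."""
    return brentq(lambda t: model.expected_p_distance(t) - p_dist, 1e-9, 50.0)


# ---------------------------------------------------------------------------
# Annotation recall and rearrangement classification
# ---------------------------------------------------------------------------


def annotation_recall_experiment(
    seed: int,
    n_numts: int = 60,
    max_divergence: float = 0.14,
    boundary_tol: int = 10,
    cfg: Optional[PipelineConfig] = None,
) -> Dict[str, float]:
    """Plant diverged mitochondrial copies at known, well-separated
    positions; measure recovery, boundary accuracy and rearrangement
    classification.

    Numts are spaced beyond the merge window so each planted copy maps to
    one annotation; divergences are uniform up to ``max_divergence``;
    every third numt long enough carries a single planted gross event
    (>= 400 b, classes cycled).
    """
    rng = np.random.default_rng(seed)
    model = _mito_model()
    cfg = cfg or PipelineConfig()
    L = 16000
    mito_codes = random_sequence(rng, L, AT_MITO)
    spacing = 30000
    lengths_cycle = [300, 500, 1000, 2000, 3500, 6000]
    classes = ["deletion", "interruption", "inversion", "internal_duplication"]

    pieces: List[np.ndarray] = []
    truth = []  # (start, end, planted_class or None, event_size)
    cursor = 0
    class_i = 0
    for i in range(n_numts):
        gap = spacing + int(rng.integers(0, 2000))
        pieces.append(random_sequence(rng, gap, AT_NUC))
        cursor += gap
        frag_len = lengths_cycle[i % len(lengths_cycle)]
        mstart = int(rng.integers(0, L))
        seq = mito_codes[(mstart + np.arange(frag_len)) % L].copy()
        d = float(rng.uniform(0.02, max_divergence))
        seq = evolve(seq, model, 1.0, _time_for_divergence(model, d), rng)
        planted_class = None
        event_size = 0
        if frag_len >= 2000:
            planted_class = classes[class_i % len(classes)]
            class_i += 1
            event_size = int(rng.integers(400, min(1200, frag_len - 1100)))
            pos = int(rng.integers(500, frag_len - 500 - event_size))
            if planted_class == "deletion":
                seq = np.concatenate([seq[:pos], seq[pos + event_size :]])
            elif planted_class == "interruption":
                foreign = random_sequence(rng, event_size, AT_NUC)
                seq = np.concatenate([seq[:pos], foreign, seq[pos:]])
            elif planted_class == "inversion":
                seq = np.concatenate(
                    [seq[:pos], revcomp_codes(seq[pos : pos + event_size]), seq[pos + event_size :]]
                )
            else:  # internal duplication
                seq = np.concatenate([seq[: pos + event_size], seq[pos:]])
        if rng.random() < 0.5:
            seq = revcomp_codes(seq)
        pieces.append(seq)
        truth.append((cursor, cursor + seq.size, planted_class, event_size))
        cursor += seq.size
    pieces.append(random_sequence(rng, spacing, AT_NUC))

    scaffold = GenomeSequence(id="scaf", residues=decode(np.concatenate(pieces)))
    mito = GenomeSequence(id="mt", residues=decode(mito_codes), topology="circular")
    numts, events = annotate_species(mito, [scaffold], cfg)
    events_by_numt: Dict[str, list] = {}
    for e in events:
        events_by_numt.setdefault(e.numt_id, []).append(e)

    recovered = 0
    boundary_ok = 0
    class_total = 0
    class_ok = 0
    for start, end, planted_class, _ in truth:
        overlapping = [
            n for n in numts if n.span[0] < end and n.span[1] > start
        ]
        if not overlapping:
            continue
        recovered += 1
        s = min(n.span[0] for n in overlapping)
        e = max(n.span[1] for n in overlapping)
        if abs(s - start) <= boundary_tol and abs(e - end) <= boundary_tol:
            boundary_ok += 1
        if planted_class is not None:
            class_total += 1
            found = {
                ev.type
                for n in overlapping
                for ev in events_by_numt.get(n.numt_id, [])
            }
            if planted_class in found:
                class_ok += 1
    return {
        "n_planted": n_numts,
        "recall": recovered / n_numts,
        "boundary_rate": boundary_ok / n_numts,
        "n_events_planted": class_total,
        "class_accuracy": class_ok / class_total if class_total else float("nan"),
    }


# ---------------------------------------------------------------------------
# Placement coverage
# ---------------------------------------------------------------------------


def _truth_numt_row(record, scaffold: GenomeSequence, mito_length: int) -> np.ndarray:
    from .types import encode, revcomp

    seq = scaffold.residues[record.nuc_start : record.nuc_end]
    if record.strand == "-":
        seq = revcomp(seq)
    codes = encode(seq)
    row = np.full(mito_length, -1, dtype=np.int8)
    pos = np.arange(record.mito_start, record.mito_end) % mito_length
    m = min(codes.size, pos.size)
    row[pos[:m]] = codes[:m]
    return row


def placement_coverage_experiment(
    seed: int,
    n_numts: int = 50,
    alpha: float = 0.05,
    min_length: int = 300,
) -> Dict[str, float]:
    """Simulate the full radiation at generator defaults, place each clean
    original insertion on the fixed tree, and measure how often the true
    insertion branch falls in the KH significance set.

    Duplicates are excluded (their mitochondrial anchor dates the founding
    insertion, not the copy event), as are rearranged copies (the dating
    operation receives single-origin rows; rearranged numts enter through
    their annotation fragments in the full pipeline).
    """
    tree = drosophila_tree(with_outgroup=True)
    cfg = PipelineConfig(significance_alpha=alpha)
    params = SimulationParams(tree=tree, seed=seed)
    data = simulate_numt_history(params)
    candidates: Dict[str, list] = {}
    for t in data.truth:
        if t.deleted or t.parent_numt_id or t.rearrangements:
            continue
        if t.nuc_end - t.nuc_start < min_length:
            continue
        candidates.setdefault(t.species, []).append(t)
    order = sorted(candidates, key=lambda sp: -len(candidates[sp]))
    covered = 0
    placed = 0
    window_spans = []
    for sp in order:
        if placed >= n_numts:
            break
        ctx = DatingContext(sp, data.mito, tree, cfg)
        scaffolds = {s.id: s for s in data.scaffolds[sp]}
        for t in candidates[sp]:
            if placed >= n_numts:
                break
            row = _truth_numt_row(t, scaffolds[t.scaffold], params.mito_length)
            from .placement import place_numt, project_alignment

            aln = project_alignment(row, ctx.panel, numt_label=t.numt_id)
            if aln is None:
                continue
            res = place_numt(aln, ctx.panel_tree, tree, ctx.model, alpha=alpha)
            placed += 1
            if t.insertion_branch in res.significance_set:
                covered += 1
            window_spans.append(res.age_window[1] - res.age_window[0])
    return {
        "n_placed": placed,
        "coverage": covered / placed if placed else float("nan"),
        "mean_window_my": float(np.mean(window_spans)) if window_spans else float("nan"),
    }


# ---------------------------------------------------------------------------
# Homology calibration
# ---------------------------------------------------------------------------


def homology_power_experiment(
    seed: int,
    n_reps: int = 50,
    length: int = 3000,
    parent_age_my: float = 15.0,
    copy_age_my: float = 1.0,
    sister_split_my: float = 19.0,
    alpha: float = 0.05,
) -> Dict[str, float]:
    """Paralog-test power on true duplicate pairs.

    A numt inserted ``parent_age_my`` ago is duplicated ``copy_age_my``
    ago; both copies evolve at the nuclear rate. The alignment holds the
    host and its sister mitochondrial genomes plus a deep outgroup.
    """
    rng = np.random.default_rng(seed)
    model = _mito_model()
    nr = MITO_RATE / 6.0
    calls = 0
    for _ in range(n_reps):
        anc = random_sequence(rng, length, AT_MITO)
        sister = evolve(anc, model, MITO_RATE, sister_split_my, rng)
        anc_ins = evolve(anc, model, MITO_RATE, sister_split_my - parent_age_my, rng)
        host = evolve(anc_ins, model, MITO_RATE, parent_age_my, rng)
        stem = evolve(anc_ins, model, nr, parent_age_my - copy_age_my, rng)
        n1 = evolve(stem, model, nr, copy_age_my, rng)
        n2 = evolve(stem, model, nr, copy_age_my, rng)
        out = evolve(anc, model, MITO_RATE, 200.0, rng)
        rows = {
            "n1": n1, "n2": n2, "host": host, "sister": sister, "out": out,
        }
        verdict = test_paralogy(
            rows, "n1", "n2", "host", "out", sister="sister", alpha=alpha
        )
        calls += verdict.relation == "paralog"
    return {"n_reps": n_reps, "power": calls / n_reps}


def homology_type1_experiment(
    seed: int,
    n_reps: int = 50,
    length: int = 3000,
    old_age_my: float = 15.0,
    young_age_my: float = 3.0,
    sister_split_my: float = 19.0,
    alpha: float = 0.05,
) -> Dict[str, float]:
    """Paralog-test false-positive rate on independent co-located
    insertions of the same mitochondrial region at well-separated times."""
    rng = np.random.default_rng(seed)
    model = _mito_model()
    nr = MITO_RATE / 6.0
    calls = 0
    for _ in range(n_reps):
        anc = random_sequence(rng, length, AT_MITO)
        sister = evolve(anc, model, MITO_RATE, sister_split_my, rng)
        anc_old = evolve(anc, model, MITO_RATE, sister_split_my - old_age_my, rng)
        n1 = evolve(anc_old, model, nr, old_age_my, rng)
        anc_young = evolve(anc_old, model, MITO_RATE, old_age_my - young_age_my, rng)
        n2 = evolve(anc_young, model, nr, young_age_my, rng)
        host = evolve(anc_young, model, MITO_RATE, young_age_my, rng)
        out = evolve(anc, model, MITO_RATE, 200.0, rng)
        rows = {
            "n1": n1, "n2": n2, "host": host, "sister": sister, "out": out,
        }
        verdict = test_paralogy(
            rows, "n1", "n2", "host", "out", sister="sister", alpha=alpha
        )
        calls += verdict.relation == "paralog"
    return {"n_reps": n_reps, "type1_rate": calls / n_reps}


# ---------------------------------------------------------------------------
# Rate recovery
# ---------------------------------------------------------------------------


def star_tree(n_lineages: int = 16, depth_my: float = 20.0) -> CalibratedTree:
    """Calibrated comb of independent lineages: numt complements
    accumulate from zero, so the half-branch exposure convention of the
    duplication estimator holds exactly."""
    nwk = "(" + ",".join(f"L{i}:{depth_my}" for i in range(n_lineages)) + ")root;"
    return CalibratedTree.from_newick(nwk)


def count_duplications_from_truth(
    truth, durations: Dict[str, float], cutoff_my: float
) -> float:
    """Dp: one duplication event per paralog set, requiring an extant
    observable pair (the duplicate and its source), dated to the chosen
    branch set."""
    extant_ids = {t.numt_id for t in truth if not t.deleted}
    founders = set()
    for t in truth:
        if t.deleted or not t.parent_numt_id:
            continue
        if t.parent_numt_id not in extant_ids:
            continue
        if t.insertion_branch in durations and t.insertion_time_my <= cutoff_my:
            founders.add(t.parent_numt_id)
    return float(len(founders))


def rate_recovery_experiment(
    seed: int,
    n_seeds: int = 30,
    n_lineages: int = 24,
    depth_my: float = 20.0,
    true_insertion: float = 0.75,
    true_duplication: float = 0.010,
) -> Dict[str, float]:
    """Recover planted insertion and duplication rates from truth-dated
    events over independent simulations (history level; deletion off so
    turnover censoring does not bias the recovery — observed rates on
    real data are lower bounds, as the analysis itself notes)."""
    tree = star_tree(n_lineages, depth_my)
    labels = [f"L{i}" for i in range(n_lineages)]
    durations = branch_set(tree, labels, cutoff_my=depth_my)
    ins_estimates = []
    dup_estimates = []
    base = np.random.SeedSequence(seed).generate_state(n_seeds, dtype=np.uint32)
    for s in base:
        params = SimulationParams(
            tree=tree,
            seed=int(s) % (2**31),
            track_sequences=False,
            insertion_rate_per_my=true_insertion,
            duplication_rate_per_numt_per_my=true_duplication,
            deletion_rate_per_numt_per_my=0.0,
            outgroup_label="none",
        )
        data = simulate_numt_history(params)
        extant = [t for t in data.truth if not t.deleted]
        placements = [
            PlacementResult(
                numt_id=t.numt_id, branch_loglik={}, best_branch=t.insertion_branch,
                significance_set=[t.insertion_branch],
                age_window=(0.0, depth_my), density={t.insertion_branch: 1.0},
            )
            for t in {t.numt_id: t for t in extant if not t.parent_numt_id}.values()
        ]
        dp = count_duplications_from_truth(data.truth, durations, depth_my)
        n_mean = float(np.mean([
            len([t for t in extant if t.species == sp]) for sp in labels
        ]))
        _, est = estimate_rates(
            placements, tree, n_paralog_sets=dp, n_duplicates_total=dp,
            mean_numts_per_genome=n_mean, branch_labels=labels, cutoff_my=depth_my,
        )
        ins_estimates.append(est.insertion_rate)
        dup_estimates.append(est.duplication_rate)
    ins_err = np.median([abs(x - true_insertion) / true_insertion for x in ins_estimates])
    dup_err = np.median([abs(x - true_duplication) / true_duplication for x in dup_estimates])
    return {
        "n_seeds": n_seeds,
        "insertion_median": float(np.median(ins_estimates)),
        "insertion_median_rel_err": float(ins_err),
        "duplication_median": float(np.median(dup_estimates)),
        "duplication_median_rel_err": float(dup_err),
    }


def steady_state_deletion_experiment(
    seed: int,
    n_seeds: int = 30,
    true_deletion: float = 0.052,
) -> Dict[str, float]:
    """Recover the planted deletion rate from the steady-state identity
    (gain rate / complement size) at gain-loss equilibrium."""
    tree = drosophila_tree(with_outgroup=True)
    params0 = SimulationParams(tree=tree, seed=0)
    # equilibrium complement: insertions + duplications balance deletions
    n_eq = params0.insertion_rate_per_my / (
        true_deletion - params0.duplication_rate_per_numt_per_my
    )
    estimates = []
    base = np.random.SeedSequence(seed).generate_state(n_seeds, dtype=np.uint32)
    from .tree import RECENT_BRANCH_LABELS

    durations = branch_set(tree, RECENT_BRANCH_LABELS, cutoff_my=20.0)
    T = sum(durations.values())
    species = [lbl for lbl in durations if tree.has_node(lbl) and not tree.node(lbl).child_nodes()]
    for s in base:
        params = SimulationParams(
            tree=tree, seed=int(s) % (2**31), track_sequences=False,
            deletion_rate_per_numt_per_my=true_deletion,
            initial_numts=int(round(n_eq)),
        )
        data = simulate_numt_history(params)
        gains = sum(
            1
            for t in {t.numt_id: t for t in data.truth}.values()
            if t.insertion_branch in durations and t.insertion_time_my <= 20.0
        )
        extant = [t for t in data.truth if not t.deleted]
        n_mean = float(np.mean([
            len([t for t in extant if t.species == sp]) for sp in species
        ]))
        rate, _ = deletion_rate_steady_state(gains / T, n_mean)
        estimates.append(rate)
    mean = float(np.mean(estimates))
    se = float(np.std(estimates, ddof=1) / math.sqrt(n_seeds))
    return {
        "n_seeds": n_seeds,
        "deletion_mean": mean,
        "deletion_se": se,
        "z": (mean - true_deletion) / se if se > 0 else float("nan"),
    }
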