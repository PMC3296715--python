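"""Insertion, duplication and steady-state deletion rate estimation.

Insertion rate = N_i / T, where N_i is the density-weighted number of
insertions attributed to a chosen set of recent branches and T the summed
time along those branches. Duplication rate = Dp / (N x T_half), where Dp
counts duplications (one per paralog set by default), N is the average
numt complement per genome and T_half is half the summed branch time,
since the mean age of a duplication on a branch is about half the branch.
Assuming a steady-state complement, deletion rate = gain rate / N and the
numt half-life is ln 2 / deletion rate.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .tree import CalibratedTree
from .types import PlacementResult, RateEstimates, RateInputs


def branch_set(
    tree: CalibratedTree,
    labels: Optional[Sequence[str]] = None,
    cutoff_my: Optional[float] = None,
) -> Dict[str, float]:
    """Durations (My) of the branches entering the rate calculation.

    An explicit label list wins; otherwise branches whose parent node is
    younger than the cutoff are selected. Stem branches older than the
    cutoff are clipped at it.
    """
    durations: Dict[str, float] = {}
    if labels:
        for label in labels:
            br = tree.branch(label)
            top = br.parent_age if cutoff_my is None else min(br.parent_age, cutoff_my)
            durations[label] = max(top - br.child_age, 0.0)
    else:
        if cutoff_my is None:
            raise ValueError("need labels or cutoff_my")
        for br in tree.recent_branches(cutoff_my):
            durations[br.label] = br.duration
    return durations


def attribute_insertions(
    placements: Iterable[PlacementResult],
    durations: Dict[str, float],
) -> Tuple[float, Dict[str, float]]:
    """Density mass per branch restricted to the chosen branch set.

    Each dated numt carries total density 1 spread over its window; only
    the mass falling on the chosen branches is counted.
    """
    per_branch = {label: 0.0 for label in durations}
    total = 0.0
    for pl in placements:
        for label, w in pl.density.items():
            if label in per_branch:
                per_branch[label] += w
                total += w
    return total, per_branch


def insertion_rate(inputs: RateInputs) -> Tuple[float, Dict[str, float]]:
    """Genus rate N_i / T and per-branch rates (mass over duration)."""
    if inputs.total_time_my <= 0:
        raise ValueError("empty branch set: T must be > 0")
    genus = inputs.n_insertions / inputs.total_time_my
    per_branch = {
        label: (mass / dur if dur > 0 else 0.0)
        for label, (mass, dur) in inputs.per_branch.items()
    }
    return genus, per_branch


def duplication_rate(inputs: RateInputs, count_mode: str = "one_per_set") -> float:
    """Dp / (N x T_half); ``count_mode`` chooses one event per paralog set
    (default) or the total duplicate count."""
    if count_mode not in ("one_per_set", "total"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    if inputs.mean_numts_per_genome <= 0:
        raise ValueError("N (average numts per genome) must be > 0")
    if inputs.total_time_my <= 0:
        raise ValueError("empty branch set: T must be > 0")
    t_half = inputs.total_time_my / 2.0
    return inputs.n_duplications / (inputs.mean_numts_per_genome * t_half)


def deletion_rate_steady_state(gain_rate: float, n_numts: float) -> Tuple[float, float]:
    """(deletion rate, half-life) under a constant-complement assumption."""
    if n_numts <= 0:
        raise ValueError("N must be > 0")
    rate = gain_rate / n_numts
    half_life = math.log(2.0) / rate if rate > 0 else math.inf
    return rate, half_life


def estimate_rates(
    placements: Sequence[PlacementResult],
    tree: CalibratedTree,
    n_paralog_sets: float,
    n_duplicates_total: float,
    mean_numts_per_genome: float,
    branch_labels: Optional[Sequence[str]] = None,
    cutoff_my: float = 20.0,
) -> Tuple[RateInputs, RateEstimates]:
    """End-to-end rate estimation from dated placements.

    ``placements`` must already exclude numts whose window crosses the
    configured deep split. Duplication gains should not be in
    ``placements`` when an insertion rate proper (not a gain rate) is
    wanted.
    """
    durations = branch_set(tree, branch_labels, cutoff_my)
    n_ins, per_branch_mass = attribute_insertions(placements, durations)
    total_t = sum(durations.values())
    inputs = RateInputs(
        n_insertions=n_ins,
        total_time_my=total_t,
        n_duplications=n_paralog_sets,
        mean_numts_per_genome=mean_numts_per_genome,
        per_branch={
            label: (per_branch_mass[label], durations[label]) for label in durations
        },
    )
    ins_rate, per_branch_rates = insertion_rate(inputs)
    dup_rate = duplication_rate(inputs, "one_per_set")
    del_rate, half_life = deletion_rate_steady_state(ins_rate, mean_numts_per_genome)
    return inputs, RateEstimates(
        insertion_rate=ins_rate,
        duplication_rate=dup_rate,
        deletion_rate=del_rate,
        half_life_my=half_life,
        per_branch=per_branch_rates,
    )


# ---------------------------------------------------------------------------
# Correlation suite and summary tables
# ---------------------------------------------------------------------------


def correlation_suite(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Pearson on raw values; Spearman as Pearson on average ranks;
    two-sided P values via the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return {
            "pearson_r": float("nan"), "pearson_p": float("nan"),
            "spearman_r": float("nan"), "spearman_p": float("nan"),
        }
    pr, pp = stats.pearsonr(x, y)
    sr, sp = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pr), "pearson_p": float(pp),
        "spearman_r": float(sr), "spearman_p": float(sp),
    }


def species_summary(numts_by_species: Dict[str, list]) -> pd.DataFrame:
    """Per-species annotation counts, average and total lengths.

    Average numt length uses the fragment-sum basis: interrupting
    sequence and internally duplicated mitochondrial coverage excluded.
    """
    rows = []
    for species in sorted(numts_by_species):
        numts = numts_by_species[species]
        lengths = [n.total_numt_length for n in numts]
        rows.append(
            {
                "species": species,
                "n_numts": len(numts),
                "avg_length": float(np.mean(lengths)) if lengths else float("nan"),
                "total_numt_bp": int(np.sum(lengths)) if lengths else 0,
            }
        )
    return pd.DataFrame(rows).set_index("species")


def rearrangement_summary(
    events_by_species: Dict[str, list],
) -> pd.DataFrame:
    """Events per class and species, with affected-numt counts shown in
    parentheses; one Totals row closes the table."""
    classes = ["interruption", "deletion", "inversion", "internal_duplication"]
    rows = {}
    totals = {c: [0, set()] for c in classes}
    for species in sorted(events_by_species):
        cells = {}
        for c in classes:
            evs = [e for e in events_by_species[species] if e.type == c]
            affected = {e.numt_id for e in evs}
            cells[c] = f"{len(evs)} ({len(affected)})" if evs else "-"
            totals[c][0] += len(evs)
            totals[c][1] |= affected
        rows[species] = cells
    rows["Total"] = {
        c: f"{totals[c][0]} ({len(totals[c][1])})" if totals[c][0] else "-"
        for c in classes
    }
    return pd.DataFrame.from_dict(rows, orient="index")[classes]


def terminal_insertion_fraction(
    placements: Sequence[PlacementResult], tree: CalibratedTree
) -> Tuple[float, float, float]:
    """(terminal mass, total mass, terminal fraction) over dated numts."""
    terminal_labels = set(tree.taxa)
    term = 0.0
    total = 0.0
    for pl in placements:
        for label, w in pl.density.items():
            total += w
            if label in terminal_labels:
                term += w
    return term, total, (term / total if total else float("nan"))


def rates_table(
    per_branch_rates: Dict[str, float],
    per_branch_dup: Optional[Dict[str, Tuple[float, float]]] = None,
) -> pd.DataFrame:
    """Per-branch insertion (and optional duplication) rate table."""
    rows = []
    for label in sorted(per_branch_rates):
        row = {"branch": label, "insertion_rate": per_branch_rates[label]}
        if per_branch_dup and label in per_branch_dup:
            row["dup_rate_one_per_set"], row["dup_rate_total"] = per_branch_dup[label]
        rows.append(row)
    return pd.DataFrame(rows).set_index("branch")
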