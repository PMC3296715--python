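import math

import numpy as np
import pytest

from numts import datasets
from numts.rates import (
    attribute_insertions,
    branch_set,
    correlation_suite,
    deletion_rate_steady_state,
    duplication_rate,
    insertion_rate,
    rearrangement_summary,
    species_summary,
    terminal_insertion_fraction,
)
from numts.tree import RECENT_BRANCH_LABELS, drosophila_tree
from numts.types import (
    Fragment,
    NumtAnnotation,
    PlacementResult,
    RateInputs,
    RearrangementEvent,
)


def placement(numt_id, density):
    return PlacementResult(
        numt_id=numt_id, branch_loglik={}, best_branch=max(density, key=density.get),
        significance_set=list(density), age_window=(0.0, 10.0), density=density,
    )


class TestInsertionRate:
    def test_direct_formula(self):
        inputs = RateInputs(19.2, 10.0, 0, 1.0)
        rate, _ = insertion_rate(inputs)
        assert rate == pytest.approx(1.92)

    def test_zero_insertions(self):
        rate, _ = insertion_rate(RateInputs(0.0, 10.0, 0, 1.0))
        assert rate == 0.0

    def test_empty_branch_set_rejected(self):
        with pytest.raises(ValueError, match="T must be > 0"):
            insertion_rate(RateInputs(1.0, 0.0, 0, 1.0))

    def test_density_mass_conservation(self):
        """Attributed masses sum to the dated, non-excluded numt count
        when every window branch is in the set."""
        tree = drosophila_tree()
        durations = branch_set(tree, [b.label for b in tree.branches()])
        placements = [
            placement("a", {"D_virilis": 0.6, "moj_vir": 0.4}),
            placement("b", {"D_melanogaster": 1.0}),
        ]
        total, per_branch = attribute_insertions(placements, durations)
        assert total == pytest.approx(2.0)
        assert sum(per_branch.values()) == pytest.approx(2.0)

    def test_invariant_to_branch_order(self):
        tree = drosophila_tree()
        placements = [placement("a", {"D_virilis": 1.0}), placement("b", {"sim_sec": 1.0})]
        d1 = branch_set(tree, RECENT_BRANCH_LABELS, cutoff_my=20.0)
        d2 = dict(reversed(list(d1.items())))
        assert attribute_insertions(placements, d1)[0] == attribute_insertions(placements, d2)[0]


class TestDuplicationRate:
    def test_direct_formula(self):
        # Dp=1, N=20, branch time 10 My -> T_half = 5 -> 0.01
        inputs = RateInputs(0, 10.0, 1.0, 20.0)
        assert duplication_rate(inputs) == pytest.approx(0.01)

    def test_zero_duplications(self):
        assert duplication_rate(RateInputs(0, 10.0, 0.0, 20.0)) == 0.0

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError, match="N"):
            duplication_rate(RateInputs(0, 10.0, 1.0, 0.0))

    def test_duplicate_derived_count_from_printed_sets(self):
        """93 paralogous numts in 26 founding sets leave 67 duplicates."""
        derived = datasets.PARALOGOUS_NUMTS - datasets.PARALOG_SETS
        assert derived == 67
        dated = datasets.TERMINAL_INSERTION_MASS + datasets.INTERNAL_INSERTION_MASS
        assert derived / dated == pytest.approx(0.25, abs=0.005)


class TestDeletionRate:
    def test_direct_formula_and_half_life(self):
        rate, half = deletion_rate_steady_state(1.0, 20.0)
        assert rate == pytest.approx(0.05)
        assert half == pytest.approx(math.log(2) / 0.05)  # ~13.86 My

    def test_zero_gain_infinite_half_life(self):
        rate, half = deletion_rate_steady_state(0.0, 20.0)
        assert rate == 0.0 and math.isinf(half)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            deletion_rate_steady_state(1.0, 0.0)


class TestCorrelations:
    def test_monotone_pair_is_one(self):
        stats = correlation_suite([1, 2, 3, 5], [2, 4, 9, 11])
        assert stats["spearman_r"] == pytest.approx(1.0)
        stats2 = correlation_suite([1, 2, 3], [2, 4, 6])
        assert stats2["pearson_r"] == pytest.approx(1.0)

    def test_constant_column_reported_undefined(self):
        stats = correlation_suite([1, 1, 1, 1], [2, 4, 9, 11])
        assert math.isnan(stats["pearson_r"])

    def test_published_genome_size_vs_numt_content(self):
        table = datasets.species_numt_table()
        stats = correlation_suite(table["genome_size_mb"], table["total_numt_bp"])
        assert stats["pearson_r"] == pytest.approx(0.57, abs=0.005)
        assert stats["spearman_r"] == pytest.approx(0.72, abs=0.005)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            correlation_suite([1, 2], [3, 4])


class TestSummaries:
    def test_species_summary_lengths_and_zero_row(self):
        numts = {
            "A": [
                NumtAnnotation("n1", "A", "s", [Fragment(0, 500, 0, 500, "+", 0.9)]),
                NumtAnnotation(
                    "n2", "A", "s",
                    [Fragment(0, 300, 0, 300, "+", 0.9), Fragment(800, 1100, 700, 1000, "+", 0.9)],
                ),
            ],
            "B": [],
        }
        df = species_summary(numts)
        assert df.loc["A", "n_numts"] == 2
        # interruption excluded from length: 500 and 600
        assert df.loc["A", "avg_length"] == pytest.approx(550)
        assert df.loc["B", "n_numts"] == 0 and math.isnan(df.loc["B", "avg_length"])

    def test_rearrangement_summary_schema_and_totals(self):
        events = {
            "A": [
                RearrangementEvent("n1", "deletion", 300),
                RearrangementEvent("n1", "deletion", 400),
                RearrangementEvent("n2", "inversion", 250),
            ],
            "B": [RearrangementEvent("n3", "deletion", 500)],
        }
        df = rearrangement_summary(events)
        assert df.loc["A", "deletion"] == "2 (1)"
        assert df.loc["Total", "deletion"] == "3 (2)"
        assert df.loc["Total", "interruption"] == "-"

    def test_terminal_fraction_matches_published_arithmetic(self):
        tree = drosophila_tree()
        term_mass = datasets.TERMINAL_INSERTION_MASS
        total = term_mass + datasets.INTERNAL_INSERTION_MASS
        assert term_mass / total == pytest.approx(0.897, abs=0.001)
        placements = [
            placement("a", {"D_virilis": 1.0}),
            placement("b", {"moj_vir": 0.5, "Drosophila_subgenus": 0.5}),
        ]
        term, tot, frac = terminal_insertion_fraction(placements, tree)
        assert (term, tot) == (1.0, 2.0) and frac == pytest.approx(0.5)


class TestBranchSet:
    def test_published_branch_list_clips_stems(self):
        tree = drosophila_tree()
        durations = branch_set(tree, RECENT_BRANCH_LABELS, cutoff_my=20.0)
        assert len(durations) == 10
        # subgroup stem starts at the ananassae split; clipped at 20 My
        assert durations["melanogaster_subgroup"] == pytest.approx(20.0 - 12.8)
        assert durations["D_virilis"] == pytest.approx(19.0)

    def test_rule_based_selection(self):
        tree = drosophila_tree()
        durations = branch_set(tree, cutoff_my=20.0)
        assert set(durations) == {
            "D_melanogaster", "D_simulans", "D_sechellia", "D_yakuba", "D_erecta",
            "D_mojavensis", "D_virilis", "sim_sec", "yak_ere", "mel_sim_sec",
        }
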