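import numpy as np
import pytest

from numts.f84 import F84Params
from numts.simulate import (
    SimulationParams,
    evolve,
    plant_repeats,
    random_sequence,
    simulate_numt_history,
    simulate_sequence_evolution,
)
from numts.tree import CalibratedTree, drosophila_tree
from numts.types import GenomeSequence, decode, encode


@pytest.fixture(scope="module")
def outgroup_tree():
    return drosophila_tree(with_outgroup=True)


class TestSequenceEvolution:
    def test_zero_rate_keeps_sequences_identical(self, rng, outgroup_tree):
        model = F84Params(freqs=np.array([0.39, 0.11, 0.11, 0.39]))
        root = random_sequence(rng, 500, 0.78)
        node_seqs, _ = simulate_sequence_evolution(root, outgroup_tree, 0.0, model, rng)
        assert all(np.array_equal(s, root) for s in node_seqs.values())

    def test_two_leaf_p_distance_matches_f84_expectation(self, rng):
        """Mean observed per-site difference across replicates within 3 SE
        of the closed-form F84 p-distance."""
        model = F84Params(freqs=np.array([0.39, 0.11, 0.11, 0.39]))
        tree = CalibratedTree.from_newick("(A:5,B:5)r;")
        rate, L, reps = 0.01, 400, 200
        expected = model.expected_p_distance(2 * 5 * rate)
        diffs = []
        for _ in range(reps):
            root = random_sequence(rng, L, 0.78)
            node_seqs, _ = simulate_sequence_evolution(root, tree, rate, model, rng)
            diffs.append(float(np.mean(node_seqs["A"] != node_seqs["B"])))
        mean = np.mean(diffs)
        se = np.std(diffs, ddof=1) / np.sqrt(reps)
        assert abs(mean - expected) < 3 * se + 1e-12

    def test_root_composition_matches_at_fraction(self, rng):
        seq = random_sequence(rng, 20000, 0.78)
        at = float(np.mean((seq == 0) | (seq == 3)))
        assert at == pytest.approx(0.78, abs=3 * np.sqrt(0.78 * 0.22 / 20000))

    def test_branch_time_point_sampling(self, rng, outgroup_tree):
        model = F84Params()
        root = random_sequence(rng, 300, 0.78)
        _, samples = simulate_sequence_evolution(
            root, outgroup_tree, 0.01, model, rng,
            sample_points=[("D_virilis", 10.0)],
        )
        assert ("D_virilis", 10.0) in samples
        assert samples[("D_virilis", 10.0)].size == 300


class TestNumtHistory:
    def test_null_process_yields_no_records(self, outgroup_tree):
        params = SimulationParams(
            tree=outgroup_tree, seed=1, insertion_rate_per_my=0.0,
            duplication_rate_per_numt_per_my=0.0, deletion_rate_per_numt_per_my=0.0,
            track_sequences=False,
        )
        assert simulate_numt_history(params).truth == []

    def test_duplication_only_regime_shares_origin(self):
        tree = CalibratedTree.from_newick("(A:10,B:10)r;")
        params = SimulationParams(
            tree=tree, seed=2, insertion_rate_per_my=0.0,
            duplication_rate_per_numt_per_my=0.2, deletion_rate_per_numt_per_my=0.0,
            initial_numts=1, track_sequences=False, outgroup_label="none",
        )
        data = simulate_numt_history(params)
        founders = {t.numt_id for t in data.truth if t.parent_numt_id is None}
        dups = [t for t in data.truth if t.parent_numt_id is not None]
        assert len(founders) == 1
        assert dups, "duplication-only regime produced no copies"
        origin = {(t.mito_start, t.mito_end, t.strand) for t in data.truth}
        assert len(origin) == 1

    def test_poisson_insertion_mean(self):
        """Expected insertions = rate x total ingroup branch time."""
        tree = CalibratedTree.from_newick("((A:10,B:10)ab:10,C:20)r;")
        total_time = 10 + 10 + 10 + 20
        rate = 0.4
        counts = []
        for seed in range(100):
            params = SimulationParams(
                tree=tree, seed=seed, insertion_rate_per_my=rate,
                duplication_rate_per_numt_per_my=0.0,
                deletion_rate_per_numt_per_my=0.0,
                track_sequences=False, outgroup_label="none",
            )
            data = simulate_numt_history(params)
            counts.append(len({t.numt_id for t in data.truth}))
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - rate * total_time) < 3 * se

    def test_truth_and_fasta_mutually_consistent(self, outgroup_tree):
        params = SimulationParams(tree=outgroup_tree, seed=7, scaffold_lengths=(50000,))
        data = simulate_numt_history(params)
        checked = 0
        for t in data.truth:
            if t.deleted:
                continue
            scaf = {s.id: s for s in data.scaffolds[t.species]}[t.scaffold]
            assert 0 <= t.nuc_start < t.nuc_end <= len(scaf)
            checked += 1
        assert checked > 0

    def test_insertion_times_within_branch(self, outgroup_tree):
        params = SimulationParams(tree=outgroup_tree, seed=8, track_sequences=False)
        data = simulate_numt_history(params)
        for t in data.truth:
            if t.insertion_branch == outgroup_tree.root_label:
                continue
            br = outgroup_tree.branch(t.insertion_branch)
            assert br.child_age - 1e-9 <= t.insertion_time_my <= br.parent_age + 1e-9

    def test_no_deletion_counts_nondecreasing_to_leaves(self, outgroup_tree):
        params = SimulationParams(
            tree=outgroup_tree, seed=9, deletion_rate_per_numt_per_my=0.0,
            track_sequences=False,
        )
        data = simulate_numt_history(params)
        # every insertion on an internal branch must appear in all leaves below
        by_id: dict = {}
        for t in data.truth:
            by_id.setdefault(t.numt_id, []).append(t)
        for numt_id, records in by_id.items():
            branch = records[0].insertion_branch
            leaves = set(outgroup_tree.leaves_under(branch))
            assert {r.species for r in records} == leaves

    def test_numt_divergence_bounded_by_nuclear_rate(self, outgroup_tree):
        """Truth copies match the donor-lineage mito at insertion time at
        least as well as nuclear-rate divergence predicts."""
        params = SimulationParams(tree=outgroup_tree, seed=10, scaffold_lengths=(50000,))
        data = simulate_numt_history(params)
        model = F84Params(freqs=np.array([0.39, 0.11, 0.11, 0.39]))
        nuc_rate = params.mito_subst_rate / params.nuclear_rate_divisor
        checked = 0
        for t in data.truth_for("D_virilis"):
            if t.rearrangements or t.parent_numt_id or t.nuc_end - t.nuc_start < 400:
                continue
            scaf = {s.id: s for s in data.scaffolds[t.species]}[t.scaffold]
            seq = encode(scaf.residues[t.nuc_start : t.nuc_end])
            if t.strand == "-":
                seq = seq[::-1]
                seq = np.where(seq < 4, 3 - seq, 4)
            host = data.mito["D_virilis"].residues
            idx = (t.mito_start + np.arange(seq.size)) % params.mito_length
            host_codes = encode(host)[idx]
            p_obs = float(np.mean(seq != host_codes))
            # divergence numt<->host = mito path + slow nuclear path
            t_total = params.mito_subst_rate * t.insertion_time_my + nuc_rate * t.insertion_time_my
            p_exp = model.expected_p_distance(t_total)
            assert p_obs < p_exp + 3 * np.sqrt(p_exp * (1 - p_exp) / seq.size) + 0.02
            checked += 1
        assert checked > 0


class TestPlantRepeats:
    def test_zero_density_leaves_scaffolds_unchanged(self, rng):
        scaf = GenomeSequence(id="s", residues=decode(random_sequence(rng, 5000, 0.58)))
        lib = [GenomeSequence(id="rep1", residues="ACGT" * 100)]
        out, bed = plant_repeats([scaf], lib, density_per_100kb=0.0, adjacency_bias=0.0, rng=rng)
        assert out[0].residues == scaf.residues and bed == []

    def test_truth_bed_extracts_planted_copies(self, rng):
        scaf = GenomeSequence(id="s", residues=decode(random_sequence(rng, 30000, 0.58)))
        lib = [GenomeSequence(id="rep1", residues=decode(random_sequence(rng, 300, 0.5)))]
        out, bed = plant_repeats([scaf], lib, density_per_100kb=20.0, adjacency_bias=0.0, rng=rng)
        assert bed
        for chrom, s, e, name in bed:
            assert out[0].residues[s:e].upper() == lib[0].residues.upper()

    def test_adjacency_bias_places_near_numts(self, rng):
        scaf = GenomeSequence(id="s", residues=decode(random_sequence(rng, 50000, 0.58)))
        lib = [GenomeSequence(id="rep1", residues=decode(random_sequence(rng, 200, 0.5)))]
        spans = [("s", 20000, 21000)]
        out, bed = plant_repeats(
            [scaf], lib, density_per_100kb=0.0, adjacency_bias=3.0, rng=rng,
            numt_spans=spans, adjacency_bases=200,
        )
        assert bed
        (chrom, ns, ne) = spans[0]
        for _, s, e, _ in bed:
            assert s >= ns - 400 - 200 and s <= ne + 400

    def test_empty_library_rejected(self, rng):
        scaf = GenomeSequence(id="s", residues="ACGT" * 100)
        with pytest.raises(ValueError, match="empty"):
            plant_repeats([scaf], [], 1.0, 0.0, rng)
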