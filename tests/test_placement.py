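import numpy as np
import pytest

from numts.f84 import F84Params
from numts.likelihood import PhyloNode, log_likelihood_with_sites
from numts.placement import (
    GAP,
    MitoPanel,
    PlacementEngine,
    ProjectedAlignment,
    build_panel,
    fit_panel_tree,
    is_excluded,
    kh_pvalue,
    numt_row_from_annotation,
    place_numt,
    project_alignment,
)
from numts.simulate import SimulationParams, simulate_numt_history
from numts.tree import drosophila_tree
from numts.types import Fragment, GenomeSequence, NumtAnnotation, decode, encode


@pytest.fixture(scope="module")
def small_dataset():
    """One simulated dataset shared by the placement tests."""
    tree = drosophila_tree(with_outgroup=True)
    params = SimulationParams(tree=tree, seed=11, scaffold_lengths=(60000,))
    return tree, params, simulate_numt_history(params)


def test_projection_identity_rows(rng):
    seqs = {
        "a": GenomeSequence(id="a", residues="ACGTACGTAC", topology="circular"),
        "b": GenomeSequence(id="b", residues="ACGTACGAAC", topology="circular"),
    }
    panel = build_panel(seqs, reference="a")
    numt_row = encode("ACGTACGTAC").astype(np.int8)
    aln = project_alignment(numt_row, panel)
    i_a = aln.taxa.index("a")
    i_n = aln.taxa.index("numt")
    assert np.array_equal(aln.columns[i_a], aln.columns[i_n])


def test_projection_removes_gap_and_n_columns():
    seqs = {
        "a": GenomeSequence(id="a", residues="ACGTACGTAC", topology="circular"),
        "out": GenomeSequence(id="out", residues="ACNTACGTAC", topology="circular"),
    }
    panel = build_panel(seqs, reference="a")
    numt_row = encode("ACGTACGTAC").astype(np.int8)
    numt_row[5] = GAP
    aln = project_alignment(numt_row, panel)
    # column 2 (N in out) and column 5 (gap in numt) removed
    assert aln.columns.shape[1] == 8
    assert 2 not in aln.column_map and 5 not in aln.column_map


def test_engine_matches_direct_pruning(rng):
    a, b = PhyloNode("a", 0.1), PhyloNode("b", 0.2)
    c, d = PhyloNode("c", 0.15), PhyloNode("d", 0.3)
    root = PhyloNode(
        "r",
        children=[
            PhyloNode("ab", 0.12, children=[a, b]),
            PhyloNode("cd", 0.18, children=[c, d]),
        ],
    )
    taxa = ["a", "b", "c", "d", "numt"]
    cols = rng.integers(0, 4, size=(5, 40)).astype(np.int8)
    model = F84Params(freqs=np.array([0.3, 0.2, 0.2, 0.3]))
    aln = ProjectedAlignment(taxa=taxa, columns=cols, column_map=np.arange(40))
    engine = PlacementEngine(root, aln, model)

    def direct(edge_name, at, pend):
        t = root.copy()
        e = t.find(edge_name)
        parent = t.parent_of(e)
        L = e.length
        e.length = at
        joint = PhyloNode("X", L - at, children=[e, PhyloNode("numt", pend)])
        parent.children[parent.children.index(e)] = joint
        return log_likelihood_with_sites(t, cols, taxa, model)[0]

    for edge in root.edges():
        for at, pend in [(0.0, 0.05), (edge.length / 2, 0.2), (edge.length, 0.01)]:
            assert engine.branch_loglik(edge, at, pend) == pytest.approx(
                direct(edge.name, at, pend), abs=1e-8
            )


def test_kh_pvalue_behaviour():
    rng = np.random.default_rng(0)
    base = rng.normal(size=500)
    assert kh_pvalue(base, base) == 1.0
    worse = base - 0.5 - 0.05 * rng.random(500)
    assert kh_pvalue(base, worse) < 1e-6
    noisy = base + rng.normal(scale=0.01, size=500)
    assert kh_pvalue(base, noisy) > 0.05


class TestPlaceNumt:
    @pytest.fixture(scope="class")
    def context(self, small_dataset):
        from numts.config import PipelineConfig
        from numts.pipeline import DatingContext

        tree, params, data = small_dataset
        return tree, params, data, DatingContext("D_virilis", data.mito, tree, PipelineConfig())

    def test_species_own_mito_places_on_terminal_branch(self, context):
        tree, params, data, ctx = context
        # the host's own mitochondrial sequence as a pseudo-numt
        row = encode(data.mito["D_virilis"].residues[:4000]).astype(np.int8)
        full = np.full(params.mito_length, GAP, dtype=np.int8)
        full[:4000] = row
        aln = project_alignment(full, ctx.panel, numt_label="self")
        res = place_numt(aln, ctx.panel_tree, tree, ctx.model, alpha=0.05)
        assert res.best_branch == "D_virilis"
        assert res.best_branch in res.significance_set

    def test_density_proportional_to_branch_durations(self, context):
        tree, params, data, ctx = context
        t = next(
            t for t in data.truth_for("D_virilis")
            if not t.rearrangements and not t.parent_numt_id
            and t.nuc_end - t.nuc_start >= 500
        )
        scaf = {s.id: s for s in data.scaffolds["D_virilis"]}[t.scaffold]
        numt = NumtAnnotation(
            numt_id="x", species="D_virilis", scaffold=t.scaffold,
            fragments=[
                Fragment(t.nuc_start, t.nuc_end, t.mito_start % params.mito_length,
                         t.mito_start % params.mito_length + (t.nuc_end - t.nuc_start),
                         t.strand, 0.9)
            ],
        )
        res = ctx.place(numt, scaf)
        assert res is not None
        assert sum(res.density.values()) == pytest.approx(1.0)
        durations = {
            br.label: br.duration for br in tree.branches() if br.label in res.density
        }
        total = sum(durations.values())
        for label, w in res.density.items():
            assert w == pytest.approx(durations[label] / total, abs=1e-9)

    def test_significance_set_shrinks_as_alpha_grows(self, context):
        tree, params, data, ctx = context
        row = encode(data.mito["D_virilis"].residues[2000:4500]).astype(np.int8)
        full = np.full(params.mito_length, GAP, dtype=np.int8)
        full[2000:4500] = row
        aln = project_alignment(full, ctx.panel, numt_label="self")
        sizes = []
        for alpha in (0.01, 0.05, 0.25):
            res = place_numt(aln, ctx.panel_tree, tree, ctx.model, alpha=alpha)
            sizes.append(len(res.significance_set))
            assert res.best_branch in res.significance_set
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_exclusion_rule_on_window_reaching_deep_split(self, context):
        tree, *_ = context
        from numts.types import PlacementResult

        deep = PlacementResult(
            numt_id="x", branch_loglik={}, best_branch="Sophophora",
            significance_set=["Sophophora", "Drosophila_subgenus"],
            age_window=(10.0, 63.0), density={"Sophophora": 1.0},
        )
        recent = PlacementResult(
            numt_id="y", branch_loglik={}, best_branch="D_virilis",
            significance_set=["D_virilis"], age_window=(0.0, 19.0),
            density={"D_virilis": 1.0},
        )
        assert is_excluded(deep, tree, "Drosophila_Sophophora")
        assert not is_excluded(recent, tree, "Drosophila_Sophophora")


def test_panel_tree_lengths_track_mito_divergence(small_dataset):
    """Fitted branch lengths approximate rate x My durations."""
    tree, params, data = small_dataset
    panel = build_panel(data.mito, reference="D_virilis")
    keep = np.all((panel.rows >= 0) & (panel.rows <= 3), axis=0)
    model = F84Params.from_alignment(panel.rows[:, keep].astype(np.int8))
    fitted = fit_panel_tree(tree, panel, model)
    expected = params.mito_subst_rate * 19.0  # D_virilis terminal, 19 My
    got = fitted.find("D_virilis").length
    assert got == pytest.approx(expected, rel=0.35)
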