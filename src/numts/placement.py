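"""Phylogenetic placement of numts on the fixed mitochondrial species tree.

Each numt is projected into the coordinate frame of its host mitochondrial
genome, stacked with the panel of mitochondrial genomes (plus outgroup),
and attached as a pendant leaf to every branch of the fixed topology in
turn. Attachment position along the branch and pendant length are
optimized (coarse grid, then golden-section refinement via Brent). The set
of branches not significantly worse than the best (one-sided KH test on
per-site log-likelihood differences) defines the insertion age window;
density weights distribute one insertion across the window's branches in
proportion to their durations in My.

The panel tree's branch lengths (substitutions/site) are optimized once on
the panel-only alignment and frozen; placement re-evaluates likelihoods
through cached inner (subtree) and outer (rest-of-tree) conditional
likelihood vectors, so each candidate attachment costs O(patterns) work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .f84 import F84Params
from .likelihood import (
    MIN_BRANCH,
    PhyloNode,
    compress_columns,
    optimize_branch_lengths,
)
from .tree import CalibratedTree
from .types import GenomeSequence, NumtAnnotation, PlacementResult, encode, revcomp

MAX_PENDANT = 5.0  # substitutions/site


# ---------------------------------------------------------------------------
# Panel alignment and projection
# ---------------------------------------------------------------------------

GAP = -1


@dataclass
class MitoPanel:
    """Reference-projected alignment of the mitochondrial genomes.

    Rows live in the coordinate frame of the host reference genome; columns
    where another genome has an insertion relative to the reference are
    dropped (reference projection). For same-length, unrearranged genomes
    the projection is the identity.
    """

    reference: str  # taxon label of the host reference
    taxa: List[str]
    rows: np.ndarray  # (n_taxa, ref_length), codes 0..4, GAP for gaps


def build_panel(
    mito: Dict[str, GenomeSequence],
    reference: str,
    aligner=None,
) -> MitoPanel:
    """Project every mitochondrial genome onto the reference coordinates.

    Uses a global pairwise alignment per non-reference genome when lengths
    differ; identical-length genomes map positionally.
    """
    ref_seq = mito[reference].residues
    n_ref = len(ref_seq)
    taxa = sorted(mito)
    rows = np.full((len(taxa), n_ref), GAP, dtype=np.int8)
    for i, taxon in enumerate(taxa):
        seq = mito[taxon].residues
        if len(seq) == n_ref:
            rows[i] = encode(seq)
        else:
            rows[i] = _project_pairwise(ref_seq, seq, aligner)
    return MitoPanel(reference=reference, taxa=taxa, rows=rows)


def _default_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -2
    return aligner


def _project_pairwise(ref: str, other: str, aligner=None) -> np.ndarray:
    aligner = aligner or _default_aligner()
    aln = aligner.align(ref.upper(), other.upper())[0]
    out = np.full(len(ref), GAP, dtype=np.int8)
    codes = encode(other)
    for (rs, re), (os_, oe) in zip(*aln.aligned):
        out[rs:re] = codes[os_:oe]
    return out


@dataclass
class ProjectedAlignment:
    """Gap/N-free columns over {panel taxa + numt} in host coordinates."""

    taxa: List[str]
    columns: np.ndarray  # (n_taxa, n_cols), codes 0..3
    column_map: np.ndarray  # host mito coordinate of each column
    numt_label: str = "numt"


def numt_row_from_annotation(
    numt: NumtAnnotation, scaffold: GenomeSequence, mito_length: int
) -> np.ndarray:
    """Numt residues placed at their mitochondrial coordinates.

    Fragment coordinate correspondences come from the ungapped HSPs, so no
    realignment is needed; duplicated coverage keeps the first fragment.
    """
    row = np.full(mito_length, GAP, dtype=np.int8)
    for frag in numt.fragments:
        text = scaffold.residues[frag.nuc_start : frag.nuc_end]
        if frag.strand == "-":
            text = revcomp(text)
        codes = encode(text)
        pos = np.arange(frag.mito_start, frag.mito_end) % mito_length
        length = min(codes.size, pos.size)
        vacant = row[pos[:length]] == GAP
        row[pos[:length][vacant]] = codes[:length][vacant]
    return row


def project_alignment(
    numt_row: np.ndarray,
    panel: MitoPanel,
    numt_label: str = "numt",
) -> Optional[ProjectedAlignment]:
    """Stack a numt row (host coordinates, GAP where absent) on the panel
    and remove every column containing a gap or N in any row.

    Returns None when no columns survive (numt untestable).
    """
    stacked = np.vstack([panel.rows, numt_row[None, : panel.rows.shape[1]]])
    keep = np.all((stacked >= 0) & (stacked <= 3), axis=0)
    if not keep.any():
        return None
    return ProjectedAlignment(
        taxa=list(panel.taxa) + [numt_label],
        columns=stacked[:, keep].astype(np.int8),
        column_map=np.flatnonzero(keep),
        numt_label=numt_label,
    )


# ---------------------------------------------------------------------------
# Species tree -> likelihood tree
# ---------------------------------------------------------------------------


def phylo_tree_from_calibrated(
    ctree: CalibratedTree, rate: float = 0.01
) -> PhyloNode:
    """Topology copy with initial branch lengths = My duration x rate."""

    def build(node) -> PhyloNode:
        out = PhyloNode(name=node.label, length=max((node.edge.length or 0.0) * rate, MIN_BRANCH))
        for child in node.child_nodes():
            out.children.append(build(child))
        return out

    root = build(ctree.tree.seed_node)
    root.length = 0.0
    return root


def fit_panel_tree(
    ctree: CalibratedTree,
    panel: MitoPanel,
    model: F84Params,
    rate_guess: float = 0.005,
    rounds: int = 3,
    max_columns: int = 6000,
) -> PhyloNode:
    """Optimize panel branch lengths on the panel-only alignment; frozen
    afterwards for all placements.

    Long alignments are strided down to ``max_columns`` sites for the fit;
    branch-length standard errors at that depth are already far below the
    placement signal.
    """
    tree = phylo_tree_from_calibrated(ctree, rate_guess)
    keep = np.all((panel.rows >= 0) & (panel.rows <= 3), axis=0)
    cols = panel.rows[:, keep].astype(np.int8)
    if cols.shape[1] > max_columns:
        stride = int(np.ceil(cols.shape[1] / max_columns))
        cols = cols[:, ::stride]
    optimize_branch_lengths(tree, cols, panel.taxa, model, rounds=rounds)
    return tree


# ---------------------------------------------------------------------------
# Placement engine
# ---------------------------------------------------------------------------


def kh_pvalue(site_best: np.ndarray, site_alt: np.ndarray) -> float:
    """One-sided KH test: is the alternative significantly worse?

    Normal approximation on the per-site log-likelihood differences.
    Returns the probability of a total difference this negative under the
    null of equal expected likelihood; large p = not significantly worse.
    """
    d = site_alt - site_best
    n = d.size
    total = float(d.sum())
    sd = float(d.std(ddof=1)) if n > 1 else 0.0
    if sd == 0.0 or n < 2:
        return 1.0 if total >= 0 else 0.0
    z = total / (sd * np.sqrt(n))
    return float(norm.cdf(z))


class PlacementEngine:
    """Pendant-leaf attachment likelihoods on a fixed panel tree.

    Inner (subtree) and outer (rest-of-tree, prior folded in) conditional
    likelihood vectors are computed once per alignment; each candidate
    (branch, attachment position, pendant length) then costs a handful of
    4x4 products per site pattern.
    """

    def __init__(self, tree: PhyloNode, aln: ProjectedAlignment, model: F84Params):
        self.tree = tree
        self.model = model
        self.aln = aln
        idx_of = {t: i for i, t in enumerate(aln.taxa)}
        patterns, counts, site_idx = compress_columns(aln.columns)
        self.counts = counts
        self.site_idx = site_idx
        self.n_patterns = patterns.shape[1]
        self._leaf_states = {
            lf.name: patterns[idx_of[lf.name]] for lf in tree.leaves()
        }
        self.numt_states = patterns[idx_of[aln.numt_label]]
        self._numt_onehot = np.zeros((self.n_patterns, 4))
        self._numt_onehot[np.arange(self.n_patterns), self.numt_states] = 1.0
        self._compute_partials()

    # -- cached partials -------------------------------------------------

    def _compute_partials(self) -> None:
        model = self.model
        inner: Dict[int, np.ndarray] = {}
        inner_scale: Dict[int, np.ndarray] = {}

        def post(node: PhyloNode):
            if node.is_leaf():
                states = self._leaf_states[node.name]
                part = np.zeros((self.n_patterns, 4))
                part[np.arange(self.n_patterns), states] = 1.0
                inner[id(node)] = part
                inner_scale[id(node)] = np.zeros(self.n_patterns)
                return
            part = None
            scale = None
            for child in node.children:
                post(child)
                term = inner[id(child)] @ model.transition_matrix(child.length).T
                part = term if part is None else part * term
                cs = inner_scale[id(child)]
                scale = cs if scale is None else scale + cs
            mx = part.max(axis=1)
            mx[mx == 0.0] = 1.0
            inner[id(node)] = part / mx[:, None]
            inner_scale[id(node)] = scale + np.log(mx)

        post(self.tree)

        # outer partials: O_edge(x at parent end) of everything outside the
        # child subtree, stationary prior folded in at the root
        outer: Dict[int, np.ndarray] = {}
        outer_scale: Dict[int, np.ndarray] = {}

        def pre(node: PhyloNode, o_part: np.ndarray, o_scale: np.ndarray):
            for child in node.children:
                sib_part = o_part.copy()
                sib_scale = o_scale.copy()
                for sib in node.children:
                    if sib is child:
                        continue
                    term = inner[id(sib)] @ model.transition_matrix(sib.length).T
                    sib_part = sib_part * term
                    sib_scale = sib_scale + inner_scale[id(sib)]
                mx = sib_part.max(axis=1)
                mx[mx == 0.0] = 1.0
                sib_part = sib_part / mx[:, None]
                sib_scale = sib_scale + np.log(mx)
                outer[id(child)] = sib_part
                outer_scale[id(child)] = sib_scale
                if not child.is_leaf():
                    down = sib_part @ model.transition_matrix(child.length)
                    pre(child, down, sib_scale)

        prior = np.tile(self.model.freqs, (self.n_patterns, 1))
        pre(self.tree, prior, np.zeros(self.n_patterns))
        self._inner = inner
        self._inner_scale = inner_scale
        self._outer = outer
        self._outer_scale = outer_scale

    # -- attachment likelihood -------------------------------------------

    def edge_list(self) -> List[PhyloNode]:
        return self.tree.edges()

    def _site_loglik(self, edge: PhyloNode, a: float, p: float) -> np.ndarray:
        """Per-pattern log-likelihood with the numt attached to ``edge`` at
        distance ``a`` above the child, pendant length ``p``."""
        model = self.model
        L = edge.length
        a = min(max(a, 0.0), L)
        A = self._outer[id(edge)] @ model.transition_matrix(L - a)  # state at X
        B = self._inner[id(edge)] @ model.transition_matrix(a).T
        C = self._numt_onehot @ model.transition_matrix(p).T
        site = np.einsum("ij,ij,ij->i", A, B, C)
        site = np.maximum(site, 1e-300)
        return (
            np.log(site)
            + self._outer_scale[id(edge)]
            + self._inner_scale[id(edge)]
        )

    def branch_loglik(self, edge: PhyloNode, a: float, p: float) -> float:
        return float(np.dot(self.counts, self._site_loglik(edge, a, p)))

    def optimize_edge(
        self, edge: PhyloNode, grid: int = 4, tol: float = 1e-4
    ) -> Tuple[float, float, float]:
        """Maximize over attachment position and pendant length.

        Returns (logL, a, p). Coarse grid over the attachment position,
        Brent (bounded golden-section/parabolic) refinement of both
        coordinates.
        """
        L = edge.length

        def best_p(a: float) -> Tuple[float, float]:
            res = minimize_scalar(
                lambda p: -self.branch_loglik(edge, a, p),
                bounds=(MIN_BRANCH, MAX_PENDANT),
                method="bounded",
                options={"xatol": max(tol, 1e-4)},
            )
            return -res.fun, float(res.x)

        candidates = np.linspace(0.0, L, grid + 1)
        scored = [(best_p(a), a) for a in candidates]
        (ll0, p0), a0 = max(scored, key=lambda t: t[0][0])
        if L > 10 * tol:
            res = minimize_scalar(
                lambda a: -best_p(a)[0],
                bounds=(0.0, L),
                method="bounded",
                options={"xatol": max(tol, L * 1e-3)},
            )
            a1 = float(res.x)
            ll1, p1 = best_p(a1)
            if ll1 > ll0:
                return ll1, a1, p1
        return ll0, a0, p0


def place_numt(
    aln: ProjectedAlignment,
    panel_tree: PhyloNode,
    species_tree: CalibratedTree,
    model: F84Params,
    alpha: float = 0.05,
) -> PlacementResult:
    """Attach the numt to every branch; KH significance set; age window.

    Age window bounds use whole-branch node ages over the significance
    set; density weights are proportional to branch durations in My
    (branches absent from the calibrated tree, e.g. toward the outgroup,
    carry zero density).
    """
    engine = PlacementEngine(panel_tree, aln, model)
    per_branch: Dict[str, Tuple[float, float, float]] = {}
    site_ll: Dict[str, np.ndarray] = {}
    for edge in engine.edge_list():
        ll, a, p = engine.optimize_edge(edge)
        per_branch[edge.name] = (ll, a, p)
        site_ll[edge.name] = engine._site_loglik(edge, a, p)[engine.site_idx]
    best = max(per_branch, key=lambda k: per_branch[k][0])
    pvals = {
        label: kh_pvalue(site_ll[best], site_ll[label]) for label in per_branch
    }
    sig = [label for label, p in pvals.items() if p >= alpha]
    if best not in sig:
        sig.append(best)

    ages = {}
    for label in sig:
        if species_tree.has_node(label) and label != species_tree.root_label:
            br = species_tree.branch(label)
            ages[label] = (br.child_age, br.parent_age)
    low_information = len(sig) == len(per_branch)
    if ages:
        t_min = min(a for a, _ in ages.values())
        t_max = max(b for _, b in ages.values())
        durations = {k: b - a for k, (a, b) in ages.items()}
        total = sum(durations.values())
        density = {k: v / total for k, v in durations.items()}
    else:  # zero-signal or outgroup-only placement
        t_min, t_max = 0.0, species_tree.root_age
        density = {}
        low_information = True
    return PlacementResult(
        numt_id=aln.numt_label,
        branch_loglik={k: v[0] for k, v in per_branch.items()},
        best_branch=best,
        significance_set=sorted(sig),
        age_window=(t_min, t_max),
        density=density,
        low_information=low_information,
    )


def is_excluded(result: PlacementResult, species_tree: CalibratedTree, split_label: str) -> bool:
    """Insertion-window exclusion rule: the window reaches the configured
    deep split (or deeper), so the numt cannot be dated within the genus."""
    split_age = species_tree.node_age(split_label)
    return result.age_window[1] >= split_age or result.low_information
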