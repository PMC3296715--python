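"""Paralog/ortholog tests for numts sharing a mitochondrial origin.

Two numts overlapping in their region of origin either arose by repeated
independent insertion of the same mitochondrial fragment or by duplication
of one nuclear copy. The test fixes the mitochondrial species topology,
optimizes branch lengths for the candidate arrangements of the numt
leaves, and calls a duplication (paralogy) or shared insertion (orthology)
when the numts-clustered tree is significantly more likely than the best
alternative arrangement (one-sided KH test on per-site log-likelihood
differences).

Micro-synteny confirmation cross-searches masked flanking and interrupting
sequence between paralog candidates; any significant hit confirms shared
nuclear context.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig
from .f84 import F84Params
from .likelihood import (
    PhyloNode,
    log_likelihood_with_sites,
    optimize_branch_lengths,
)
from .masking import low_complexity_mask, apply_softmask
from .placement import GAP, kh_pvalue
from .search import find_hsps
from .types import GenomeSequence, HomologyVerdict, NumtAnnotation

MIN_SHARED_COLUMNS = 100


def _shared_columns(
    rows: Dict[str, np.ndarray], labels: Sequence[str]
) -> Tuple[np.ndarray, List[str]]:
    """Stack coordinate-frame rows and keep columns valid in every row."""
    mat = np.vstack([rows[lbl] for lbl in labels])
    keep = np.all((mat >= 0) & (mat <= 3), axis=0)
    return mat[:, keep].astype(np.int8), list(labels)


def _optimized_loglik(
    tree: PhyloNode,
    columns: np.ndarray,
    taxa: List[str],
    model: F84Params,
    rounds: int = 2,
) -> Tuple[float, np.ndarray]:
    optimize_branch_lengths(
        tree, columns, taxa, model, rounds=rounds, joint_refine=True
    )
    return log_likelihood_with_sites(tree, columns, taxa, model)


def _attach(tree: PhyloNode, edge_name: str, leaf: str, pendant: float = 0.05) -> PhyloNode:
    """Copy of ``tree`` with ``leaf`` attached at the midpoint of an edge."""
    out = tree.copy()
    edge = out.find(edge_name)
    parent = out.parent_of(edge)
    half = edge.length / 2.0
    edge.length = half
    joint = PhyloNode(
        name=f"at_{edge_name}_{leaf}",
        length=half,
        children=[edge, PhyloNode(name=leaf, length=pendant)],
    )
    parent.children[parent.children.index(edge)] = joint
    return out


def _cluster_test(
    rows: Dict[str, np.ndarray],
    numt_a: str,
    numt_b: str,
    backbone: PhyloNode,
    attach_edges: List[str],
    relation_name: str,
    model: Optional[F84Params],
    alpha: float,
    min_shared: int,
    rounds: int = 2,
) -> HomologyVerdict:
    """Best numts-clustered arrangement vs best arrangement apart.

    The backbone (mitochondrial species tree) is fixed; the two numt
    leaves are attached in turn to every allowed edge, branch lengths are
    re-optimized per arrangement, and a one-sided KH test on per-site
    log-likelihood differences decides whether clustering is
    significantly more likely.
    """
    leaf_labels = [lf.name for lf in backbone.leaves()]
    columns, taxa = _shared_columns(rows, [numt_a, numt_b] + leaf_labels)
    if columns.shape[1] < min_shared:
        return HomologyVerdict(
            numt_ids=(numt_a, numt_b), relation="unresolved",
            delta_loglik=0.0, p_value=1.0, synteny_confirmed="untestable",
        )
    model = model or F84Params.from_alignment(columns)
    best_clust: Tuple[float, Optional[np.ndarray]] = (-np.inf, None)
    best_apart: Tuple[float, Optional[np.ndarray]] = (-np.inf, None)
    for e1 in attach_edges:
        with_a = _attach(backbone, e1, numt_a)
        # allowed second attachments: numt_a's pendant (clustered), either
        # half of the split edge, and every other allowed backbone edge
        allowed = {numt_a, e1, f"at_{e1}_{numt_a}"} | (set(attach_edges) - {e1})
        for e2 in [e.name for e in with_a.edges() if e.name in allowed]:
            tree = _attach(with_a, e2, numt_b)
            ll, site = _optimized_loglik(tree, columns, taxa, model, rounds=rounds)
            if e2 == numt_a:
                if ll > best_clust[0]:
                    best_clust = (ll, site)
            elif ll > best_apart[0]:
                best_apart = (ll, site)
    delta = best_clust[0] - best_apart[0]
    p = kh_pvalue(best_clust[1], best_apart[1]) if delta > 0 else 1.0
    relation = relation_name if (delta > 0 and p < alpha) else "unresolved"
    return HomologyVerdict(
        numt_ids=(numt_a, numt_b), relation=relation, delta_loglik=delta, p_value=p
    )


def test_paralogy(
    rows: Dict[str, np.ndarray],
    numt_a: str,
    numt_b: str,
    host: str,
    outgroup: str,
    sister: Optional[str] = None,
    model: Optional[F84Params] = None,
    alpha: float = 0.05,
    min_shared: int = MIN_SHARED_COLUMNS,
) -> HomologyVerdict:
    """Same-host-species numt pair: duplication vs repeated insertion.

    ``rows`` hold the two numts, the host mitochondrial genome, optionally
    the host's closest panel relative (``sister`` — strongly recommended:
    it polarizes the host lineage, which a deep outgroup alone cannot) and
    the outgroup, all in the host coordinate frame (GAP where absent).
    Numts attach on the host's mitochondrial lineage, as copies of it;
    the clustered arrangement is compared against serial independent
    attachments.
    """
    if sister is not None:
        hp = PhyloNode(name="hp", length=0.3, children=[
            PhyloNode(name=host, length=0.1), PhyloNode(name=sister, length=0.1)])
        backbone = PhyloNode(name="r", children=[hp, PhyloNode(name=outgroup, length=1.0)])
    else:
        backbone = PhyloNode(name="r", children=[
            PhyloNode(name=host, length=0.1), PhyloNode(name=outgroup, length=1.0)])
    return _cluster_test(
        rows, numt_a, numt_b, backbone, attach_edges=[host],
        relation_name="paralog", model=model, alpha=alpha, min_shared=min_shared,
    )


def test_orthology(
    rows: Dict[str, np.ndarray],
    numt_a: str,
    numt_b: str,
    host_a: str,
    host_b: str,
    outgroup: str,
    model: Optional[F84Params] = None,
    alpha: float = 0.05,
    min_shared: int = MIN_SHARED_COLUMNS,
) -> HomologyVerdict:
    """Cross-species numt pair dated to the same internal branches: one
    inherited insertion vs independent insertions.

    All placements of the two numt leaves on the fixed ((hostA,hostB),out)
    backbone are scored; the verdict compares the best numts-clustered
    arrangement against the best arrangement with the numts apart.
    """
    hostpair = PhyloNode(name="hp", length=0.1, children=[
        PhyloNode(name=host_a, length=0.1), PhyloNode(name=host_b, length=0.1)])
    backbone = PhyloNode(name="r", children=[hostpair, PhyloNode(name=outgroup, length=1.0)])
    return _cluster_test(
        rows, numt_a, numt_b, backbone,
        attach_edges=[host_a, host_b, "hp", outgroup],
        relation_name="ortholog", model=model, alpha=alpha, min_shared=min_shared,
    )


def paralog_sets(verdicts: Sequence[HomologyVerdict]) -> List[set]:
    """Transitive closure of pairwise paralog calls into paralog sets.

    Each set derives from a single founding insertion and counts as one
    duplication event in the rate calculation.
    """
    parent: Dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for v in verdicts:
        if v.relation != "paralog":
            continue
        a, b = v.numt_ids[0], v.numt_ids[1]
        parent[find(a)] = find(b)
    groups: Dict[str, set] = {}
    for x in parent:
        groups.setdefault(find(x), set()).add(x)
    return [g for g in groups.values() if len(g) > 1]


# ---------------------------------------------------------------------------
# Micro-synteny confirmation
# ---------------------------------------------------------------------------


def _masked_context(
    numt: NumtAnnotation,
    scaffold: GenomeSequence,
    all_numts: Sequence[NumtAnnotation],
    repeats: Sequence[tuple],
    cfg: PipelineConfig,
) -> Optional[GenomeSequence]:
    """Flanks + interrupting sequence of a numt with every numt body,
    repeat and low-complexity segment masked; None when too short."""
    s, e = numt.span
    lo = max(0, s - cfg.synteny_flank_bases)
    hi = min(len(scaffold), e + cfg.synteny_flank_bases)
    region = scaffold.residues[lo:hi]
    mask = np.zeros(hi - lo, dtype=bool)
    for other in all_numts:
        if other.scaffold != numt.scaffold:
            continue
        for f in other.fragments:
            a, b = max(f.nuc_start - lo, 0), min(f.nuc_end - lo, hi - lo)
            if b > a:
                mask[a:b] = True
    for rep in repeats:
        if rep[0] != numt.scaffold:
            continue
        a, b = max(rep[1] - lo, 0), min(rep[2] - lo, hi - lo)
        if b > a:
            mask[a:b] = True
    mask |= low_complexity_mask(
        region, cfg.mask_window, cfg.mask_locut, cfg.mask_hicut
    )
    masked = apply_softmask(region.upper(), mask)
    unmasked = int((~mask).sum())
    if unmasked < cfg.min_unmasked_flank_bases:
        return None
    return GenomeSequence(id=f"{numt.numt_id}_context", residues=masked)


def confirm_microsynteny(
    numt_a: NumtAnnotation,
    numt_b: NumtAnnotation,
    scaffolds: Dict[str, GenomeSequence],
    all_numts: Sequence[NumtAnnotation],
    cfg: PipelineConfig,
    repeats: Sequence[tuple] = (),
) -> str:
    """Shared flanking/interrupting sequence between two numt loci.

    Returns "yes" on any significant cross-hit between the masked
    contexts, "no" otherwise, "untestable" when either context retains
    fewer than the minimum unmasked bases.
    """
    ctx_a = _masked_context(numt_a, scaffolds[numt_a.scaffold], all_numts, repeats, cfg)
    ctx_b = _masked_context(numt_b, scaffolds[numt_b.scaffold], all_numts, repeats, cfg)
    if ctx_a is None or ctx_b is None:
        return "untestable"
    hits = find_hsps(ctx_a, ctx_b, cfg)
    return "yes" if hits else "no"
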