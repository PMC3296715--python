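"""Felsenstein pruning on a fixed topology under F84.

Trees here carry branch lengths in expected substitutions per site; they
are plain node objects independent of the calibrated species tree (whose
branches are in My). Alignments are matrices of encoded bases (0..3) with
no gaps or Ns — column filtering happens upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .f84 import F84Params

MAX_BRANCH = 20.0  # substitutions/site; effectively saturated
MIN_BRANCH = 1e-8


@dataclass
class PhyloNode:
    name: str = ""
    length: float = 0.0  # substitutions/site on the edge to the parent
    children: list = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> List["PhyloNode"]:
        return [n for n in self.postorder() if n.is_leaf()]

    def copy(self) -> "PhyloNode":
        return PhyloNode(
            name=self.name,
            length=self.length,
            children=[c.copy() for c in self.children],
        )

    def find(self, name: str) -> Optional["PhyloNode"]:
        for n in self.postorder():
            if n.name == name:
                return n
        return None

    def parent_of(self, target: "PhyloNode") -> Optional["PhyloNode"]:
        for n in self.postorder():
            if target in n.children:
                return n
        return None

    def edges(self) -> List["PhyloNode"]:
        """All non-root nodes, i.e. all edges (identified by child node)."""
        return [n for n in self.postorder() if n is not self]

    def newick(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}){self.name}:{self.length:.6g}"


def compress_columns(columns: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns of a (taxa x sites) matrix.

    Returns (patterns, counts, pattern_index_per_site).
    """
    cols = np.ascontiguousarray(columns.T)
    patterns, idx, counts = np.unique(
        cols, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T, counts, idx.ravel()


def _partials(
    node: PhyloNode, data: Dict[str, np.ndarray], model: F84Params
) -> Tuple[np.ndarray, np.ndarray]:
    """Conditional likelihoods (patterns x 4) with per-pattern log scaling."""
    if node.is_leaf():
        states = data[node.name]
        partial = np.zeros((states.size, 4))
        partial[np.arange(states.size), states] = 1.0
        return partial, np.zeros(states.size)
    partial = None
    logscale = None
    for child in node.children:
        child_partial, child_scale = _partials(child, data, model)
        P = model.transition_matrix(child.length)
        term = child_partial @ P.T
        partial = term if partial is None else partial * term
        logscale = child_scale if logscale is None else logscale + child_scale
    mx = partial.max(axis=1)
    mx[mx == 0.0] = 1.0
    partial /= mx[:, None]
    logscale = logscale + np.log(mx)
    return partial, logscale


def _leaf_patterns(
    tree: PhyloNode, columns: np.ndarray, taxa: List[str]
) -> Tuple[Dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Pattern-compressed leaf state arrays (computed once per alignment)."""
    if columns.shape[1] == 0:
        raise ValueError("alignment has zero columns")
    patterns, counts, idx = compress_columns(columns)
    row = {t: i for i, t in enumerate(taxa)}
    leaf_names = [lf.name for lf in tree.leaves()]
    missing = [n for n in leaf_names if n not in row]
    if missing:
        raise ValueError(f"tree leaves absent from alignment: {missing}")
    data = {name: patterns[row[name]] for name in leaf_names}
    return data, counts, idx


def _ll_patterns(
    tree: PhyloNode, data: Dict[str, np.ndarray], counts: np.ndarray, model: F84Params
) -> Tuple[float, np.ndarray]:
    partial, logscale = _partials(tree, data, model)
    log_pattern = np.log(partial @ model.freqs) + logscale
    return float(np.dot(counts, log_pattern)), log_pattern


def log_likelihood_with_sites(
    tree: PhyloNode,
    columns: np.ndarray,
    taxa: List[str],
    model: F84Params,
) -> Tuple[float, np.ndarray]:
    """Pruning log-likelihood: (total, per-site array).

    Row order of ``columns`` follows ``taxa``; extra alignment rows are
    ignored, so the result is invariant under row relabeling.
    """
    data, counts, idx = _leaf_patterns(tree, columns, taxa)
    total, log_pattern = _ll_patterns(tree, data, counts, model)
    return total, log_pattern[idx]


def log_likelihood(
    tree: PhyloNode, columns: np.ndarray, taxa: List[str], model: F84Params
) -> float:
    return log_likelihood_with_sites(tree, columns, taxa, model)[0]


# alias matching the operation naming used across the pipeline
tree_log_likelihood = log_likelihood


def optimize_branch_lengths(
    tree: PhyloNode,
    columns: np.ndarray,
    taxa: List[str],
    model: F84Params,
    rounds: int = 3,
    tol: float = 1e-4,
    joint_refine: bool = False,
) -> float:
    """Branch-length optimization in place; returns the final logL.

    Coordinate-wise Brent passes (early stop when a full round improves
    by < 1e-3) with an optional joint L-BFGS-B refinement over
    log-lengths; the joint step escapes the ridges that coordinate
    ascent cannot cross (e.g. a pendant-pair stem trading against its
    host edge).
    """
    data, counts, _ = _leaf_patterns(tree, columns, taxa)

    def ll() -> float:
        return _ll_patterns(tree, data, counts, model)[0]

    best = ll()
    for _ in range(rounds):
        for edge in tree.edges():
            def neg(t, edge=edge):
                edge.length = t
                return -ll()

            res = minimize_scalar(
                neg, bounds=(MIN_BRANCH, MAX_BRANCH), method="bounded",
                options={"xatol": tol},
            )
            edge.length = float(res.x)
        new = ll()
        if new - best < 1e-3:
            best = new
            break
        best = new
    if joint_refine:
        from scipy.optimize import minimize

        edges = tree.edges()
        x0 = np.log(np.maximum([e.length for e in edges], MIN_BRANCH))

        def neg_joint(x):
            for e, v in zip(edges, x):
                e.length = float(np.exp(v))
            return -ll()

        res = minimize(
            neg_joint, x0, method="L-BFGS-B",
            bounds=[(np.log(MIN_BRANCH), np.log(MAX_BRANCH))] * len(edges),
            options={"maxiter": 200, "ftol": 1e-10},
        )
        if -res.fun > best:
            best = -res.fun
            neg_joint(res.x)
        else:  # keep the coordinate-ascent solution
            for e, v in zip(edges, x0):
                e.length = float(np.exp(v))
    return best
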