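"""Stage-wise pipeline glue: search -> annotate -> date -> rates.

Each function is a thin composition of the module operations with the
shared configuration; the CLI subcommands call straight into these.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotate import annotate_hits, classify_rearrangements
from .config import PipelineConfig
from .f84 import F84Params
from .masking import mask_low_complexity
from .placement import (
    build_panel,
    fit_panel_tree,
    is_excluded,
    numt_row_from_annotation,
    place_numt,
    project_alignment,
)
from .search import find_hsps, flag_mito_artifacts, link_hsps
from .tree import CalibratedTree
from .types import GenomeSequence, NumtAnnotation, PlacementResult

log = logging.getLogger("numts")


def annotate_species(
    mito: GenomeSequence,
    scaffolds: Sequence[GenomeSequence],
    cfg: PipelineConfig,
    species: str = "",
) -> Tuple[List[NumtAnnotation], list]:
    """Mask, search, link and merge one species' numt annotations.

    Returns (annotations, rearrangement events). Linked hits covering
    nearly the whole mitochondrial genome at near-perfect identity are
    excluded as probable organelle-assembly artifacts (logged).
    """
    masked_mito = mask_low_complexity(
        mito, cfg.mask_window, cfg.mask_locut, cfg.mask_hicut
    )
    numts: List[NumtAnnotation] = []
    events: list = []
    hits_all = []
    weak_floor = max(cfg.evalue_threshold, 0.1)  # rescued if chained to an anchor
    for scaffold in scaffolds:
        masked_scaf = mask_low_complexity(
            scaffold, cfg.mask_window, cfg.mask_locut, cfg.mask_hicut
        )
        hsps = find_hsps(masked_mito, masked_scaf, cfg, evalue_threshold=weak_floor)
        if not hsps:
            continue
        from .search import base_frequencies, karlin_params

        kp = karlin_params(
            base_frequencies(masked_mito.residues),
            base_frequencies(masked_scaf.residues),
            cfg.match_score,
            cfg.mismatch_score,
        )
        hits = link_hsps(
            hsps, cfg.hsp_sep_max_bases, query_id=mito.id, subject_id=scaffold.id,
            query_length=len(mito), subject_length=len(scaffold),
            kp=kp, anchor_evalue=cfg.evalue_threshold,
        )
        artifacts = flag_mito_artifacts(hits, len(mito))
        if artifacts:
            log.warning(
                "%s: %d hit(s) on %s look like the mitochondrial genome itself; excluded",
                species or mito.id, len(artifacts), scaffold.id,
            )
            hits = [h for h in hits if h not in artifacts]
        hits_all.extend(hits)
    if hits_all:
        numts = annotate_hits(
            hits_all, len(mito), species=species,
            merge_window=cfg.merge_window_bases, min_event=cfg.min_event_bases,
        )
        for numt in numts:
            events.extend(
                classify_rearrangements(numt, len(mito), cfg.min_event_bases)
            )
    return numts, events


class DatingContext:
    """Per-host-species panel alignment and frozen panel tree."""

    def __init__(
        self,
        host: str,
        mito: Dict[str, GenomeSequence],
        species_tree: CalibratedTree,
        cfg: PipelineConfig,
    ):
        self.host = host
        self.cfg = cfg
        self.species_tree = species_tree
        self.panel = build_panel(mito, reference=host)
        keep = np.all((self.panel.rows >= 0) & (self.panel.rows <= 3), axis=0)
        cols = self.panel.rows[:, keep].astype(np.int8)
        self.model = F84Params.from_alignment(cols, ts_tv_ratio=cfg.ts_tv_ratio)
        self.panel_tree = fit_panel_tree(species_tree, self.panel, self.model)
        self.mito_length = len(mito[host])

    def place(self, numt: NumtAnnotation, scaffold: GenomeSequence) -> Optional[PlacementResult]:
        row = numt_row_from_annotation(numt, scaffold, self.mito_length)
        aln = project_alignment(row, self.panel, numt_label=numt.numt_id)
        if aln is None or aln.columns.shape[1] < 1:
            return None
        # guard: the numt must not collide with a panel taxon label
        result = place_numt(
            aln, self.panel_tree, self.species_tree, self.model,
            alpha=self.cfg.significance_alpha,
        )
        return result

    def excluded(self, result: PlacementResult) -> bool:
        return is_excluded(result, self.species_tree, self.cfg.exclusion_split_label)


def date_species_numts(
    numts: Sequence[NumtAnnotation],
    scaffolds: Dict[str, GenomeSequence],
    context: DatingContext,
) -> Tuple[List[PlacementResult], List[str]]:
    """Place every numt of one species; returns (dated, excluded ids)."""
    placements: List[PlacementResult] = []
    excluded: List[str] = []
    for numt in numts:
        result = context.place(numt, scaffolds[numt.scaffold])
        if result is None:
            excluded.append(numt.numt_id)
            continue
        if context.excluded(result):
            excluded.append(numt.numt_id)
        else:
            placements.append(result)
    return placements, excluded
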