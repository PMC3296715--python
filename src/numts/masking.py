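"""Entropy-based low-complexity masking for nucleotide sequence.

A two-threshold segmentation: any window whose Shannon entropy (bits) falls
to ``locut`` or below triggers a candidate segment, which is extended over
every adjacent window whose entropy stays at or below ``hicut``. Residues
covered by the extended run of windows are softmasked (lowercased); residue
identity is never changed. Needed because A+T-rich mitochondrial genomes
otherwise produce large numbers of spurious similarity hits.
"""

from __future__ import annotations

import numpy as np

from .types import GenomeSequence, encode


def window_entropy(seq: str, window: int) -> np.ndarray:
    """Shannon entropy (bits) of every length-``window`` window.

    Case-insensitive; computed over the 5-symbol alphabet A,C,G,T,N.
    Returns an array of length ``len(seq) - window + 1`` (empty if the
    sequence is shorter than the window).
    """
    codes = encode(seq)
    n = codes.size
    if n < window:
        return np.empty(0)
    onehot = np.zeros((n + 1, 5), dtype=np.int32)
    onehot[np.arange(1, n + 1), codes] = 1
    cum = np.cumsum(onehot, axis=0)
    counts = cum[window:] - cum[:-window]
    p = counts / window
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(p), 0.0)
    return terms.sum(axis=1)


def low_complexity_mask(
    seq: str, window: int = 21, locut: float = 1.4, hicut: float = 1.6
) -> np.ndarray:
    """Boolean mask of residues inside low-complexity segments."""
    if window < 4:
        raise ValueError("window must be >= 4")
    n = len(seq)
    masked = np.zeros(n, dtype=bool)
    ent = window_entropy(seq, window)
    if ent.size == 0:
        return masked
    trigger = ent <= locut
    extend = ent <= hicut
    if not trigger.any():
        return masked
    # runs of extendable windows containing at least one trigger window
    boundaries = np.flatnonzero(np.diff(extend.astype(np.int8)))
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries + 1, [extend.size]))
    for s, e in zip(starts, ends):
        if extend[s] and trigger[s:e].any():
            masked[s : e - 1 + window] = True
    return masked


def apply_softmask(seq: str, mask: np.ndarray) -> str:
    chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    upper = (chars >= ord("A")) & (chars <= ord("Z"))
    to_lower = mask & upper
    chars[to_lower] += ord("a") - ord("A")
    return chars.tobytes().decode("ascii")


def mask_low_complexity(
    seq: GenomeSequence, window: int = 21, locut: float = 1.4, hicut: float = 1.6
) -> GenomeSequence:
    """Return a copy of ``seq`` with low-complexity segments softmasked.

    Idempotent: entropy is computed case-insensitively, so re-masking a
    masked sequence yields the identical result.
    """
    mask = low_complexity_mask(seq.residues, window=window, locut=locut, hicut=hicut)
    return GenomeSequence(
        id=seq.id, residues=apply_softmask(seq.residues, mask), topology=seq.topology
    )
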