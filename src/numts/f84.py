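"""F84 nucleotide substitution model.

F84 extends the equal-input model with an extra within-group (purine or
pyrimidine) exchange term, giving unequal base frequencies plus a
transition/transversion bias; it is the model of the classic maximum
likelihood DNA phylogeny program whose defaults (ts/tv ratio 2.0, no rate
variation among sites, empirical base frequencies) this package mirrors.

The model is parameterized here by the *expected* transition/transversion
ratio; the internal within-group rate ``kappa`` is solved numerically from
it. Transition probabilities come from the spectral decomposition of the
reversible rate matrix, normalized to one expected substitution per site
per unit branch length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.optimize import brentq

PURINES = (0, 2)  # A, G
PYRIMIDINES = (1, 3)  # C, T
_TRANSITIONS = [(0, 2), (2, 0), (1, 3), (3, 1)]


def _rate_matrix(freqs: np.ndarray, kappa: float) -> np.ndarray:
    """Unnormalized F84 generator: q_ij = pi_j (+ kappa pi_j / pi_group(j)
    for within-group changes)."""
    pur = freqs[0] + freqs[2]
    pyr = freqs[1] + freqs[3]
    Q = np.tile(freqs, (4, 1))
    for i, j in _TRANSITIONS:
        group = pur if j in PURINES else pyr
        Q[i, j] += kappa * freqs[j] / group
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _flux_ratio(freqs: np.ndarray, kappa: float) -> float:
    """Expected transition/transversion ratio at stationarity."""
    Q = _rate_matrix(freqs, kappa)
    ts = sum(freqs[i] * Q[i, j] for i, j in _TRANSITIONS)
    tv = -np.sum(freqs * np.diag(Q)) - ts
    return ts / tv


def solve_kappa(freqs: np.ndarray, ts_tv_ratio: float) -> float:
    """Within-group rate giving the requested expected ts/tv ratio.

    Ratios at or below the equal-input baseline (kappa = 0) clamp to 0.
    """
    base = _flux_ratio(freqs, 0.0)
    if ts_tv_ratio <= base:
        return 0.0
    hi = 1.0
    while _flux_ratio(freqs, hi) < ts_tv_ratio:
        hi *= 2.0
    return brentq(lambda k: _flux_ratio(freqs, k) - ts_tv_ratio, 0.0, hi, xtol=1e-12)


@dataclass
class F84Params:
    """F84 model with stationary frequencies and expected ts/tv ratio."""

    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    ts_tv_ratio: float = 2.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0):
            raise ValueError("base frequencies must be 4 positive values")
        if abs(self.freqs.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        if self.ts_tv_ratio <= 0:
            raise ValueError("ts_tv_ratio must be > 0")
        self.kappa = solve_kappa(self.freqs, self.ts_tv_ratio)
        Q = _rate_matrix(self.freqs, self.kappa)
        scale = -np.sum(self.freqs * np.diag(Q))
        Q /= scale  # one expected substitution per site per unit time
        self.Q = Q
        # reversible: symmetrize with sqrt(pi) and eigendecompose once
        d = np.sqrt(self.freqs)
        S = (Q / d[None, :]) * d[:, None]
        w, U = np.linalg.eigh((S + S.T) / 2.0)
        self._w = w
        self._left = U / d[:, None] * 1.0
        self._right = (U * d[:, None]).T

    @classmethod
    def from_alignment(cls, columns: np.ndarray, ts_tv_ratio: float = 2.0) -> "F84Params":
        """Empirical base frequencies from encoded alignment columns."""
        counts = np.bincount(columns[columns < 4].ravel(), minlength=4).astype(float)
        counts += 1.0  # avoid zero frequencies on short alignments
        return cls(freqs=counts / counts.sum(), ts_tv_ratio=ts_tv_ratio)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, detailed balance holds."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self._left * np.exp(self._w * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def expected_p_distance(self, t: float) -> float:
        """Probability a site differs after total divergence time t."""
        P = self.transition_matrix(t)
        return float(1.0 - np.sum(self.freqs * np.diag(P)))
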