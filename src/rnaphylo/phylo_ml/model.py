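"""Reversible n-state substitution models with Gamma rates and invariant sites.

A model is a GTR-family CTMC: Q = S diag(pi) off-diagonal (S symmetric
exchangeabilities, one entry fixed to 1 for identifiability), diagonal set so
rows sum to zero, then rescaled so the expected number of substitutions per
unit branch length under the full +I+Gamma mixture equals 1. Rate
heterogeneity uses the discrete Gamma with k categories and mean-category
rates; a fraction p_inv of sites is invariant.

4-state presets: JC, K80, HKY, TN, TVM, GTR. The 12-state model used for
sequence-structure data is a free GTR over the 12-letter alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import gammaincinv, gammainc

PRESETS = ("JC", "K80", "HKY", "TN", "TVM", "GTR")

# 4-state order A C G U; upper-triangle exchangeability order:
# (AC, AG, AU, CG, CU, GU); transitions are AG and CU.
_UT4 = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean-category rates of the discretised Gamma(alpha, alpha) (mean 1)."""
    if alpha <= 0:
        raise ValueError("gamma shape must be > 0")
    if k == 1:
        return np.ones(1)
    # category boundaries at quantiles i/k of Gamma(alpha, rate=alpha)
    probs = np.arange(1, k) / k
    bounds = gammaincinv(alpha, probs) / alpha
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    # mean within category: k * [F_{alpha+1}(b_{i+1}) - F_{alpha+1}(b_i)]
    upper = gammainc(alpha + 1, np.minimum(bounds[1:] * alpha, 1e300))
    lower = gammainc(alpha + 1, bounds[:-1] * alpha)
    rates = k * (upper - lower)
    return rates / rates.mean()  # guard tiny numerical drift


@dataclass
class SubstitutionModel:
    """GTR-family reversible model over 4 or 12 states."""

    n_states: int
    exchangeabilities: np.ndarray  # symmetric (n, n); diagonal ignored
    freqs: np.ndarray
    alpha: Optional[float] = None  # None = homogeneous rates
    n_cats: int = 4
    p_inv: float = 0.0
    preset: Optional[str] = None  # 4-state constraint preset name
    _eig: Optional[tuple] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.n_states not in (4, 12):
            raise ValueError("n_states must be 4 or 12")
        if self.exchangeabilities.shape != (self.n_states, self.n_states):
            raise ValueError("exchangeability matrix shape mismatch")
        if not np.allclose(self.exchangeabilities, self.exchangeabilities.T):
            raise ValueError("exchangeabilities must be symmetric")
        off = self.exchangeabilities[~np.eye(self.n_states, dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("exchangeabilities must be positive")
        if self.freqs.shape != (self.n_states,) or np.any(self.freqs <= 0):
            raise ValueError("frequencies must be positive")
        if abs(self.freqs.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must sum to 1")
        self.freqs = self.freqs / self.freqs.sum()
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must be in [0, 1)")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")

    # -- rate matrix ---------------------------------------------------------

    def rate_matrix(self) -> np.ndarray:
        """Q rescaled so the +I+Gamma mixture has mean rate 1."""
        Q = self.exchangeabilities * self.freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(self.freqs, np.diag(Q)))
        scale = mu * (1.0 - self.p_inv)
        return Q / scale

    def gamma_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.n_cats)

    def _eigendecomposition(self):
        if self._eig is None:
            Q = self.rate_matrix()
            sq = np.sqrt(self.freqs)
            B = (Q * sq[:, None]) / sq[None, :]
            B = 0.5 * (B + B.T)  # enforce symmetry against roundoff
            lam, U = np.linalg.eigh(B)
            left = U.T * sq[None, :] / 1.0  # U^T diag(sqrt pi)
            right = (U.T / sq[None, :]).T  # diag(1/sqrt pi) U
            self._eig = (lam, right, left)
        return self._eig

    def invalidate_cache(self):
        self._eig = None

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) for one rate category: exp(Q * rate * t)."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        lam, right, left = self._eigendecomposition()
        P = (right * np.exp(lam * rate * t)[None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(t) across the Gamma categories, shape (k, n, n)."""
        rates = self.gamma_rates()
        return np.stack([self.transition_matrix(t, r) for r in rates])

    # -- parameter bookkeeping ----------------------------------------------

    def detailed_balance_residual(self) -> float:
        Q = self.rate_matrix()
        F = self.freqs[:, None] * Q
        return float(np.max(np.abs(F - F.T)))

    def n_free_params(self) -> int:
        """Substitution-model free parameters (used for AICc; branch lengths
        are counted separately by the model-selection routine)."""
        if self.n_states == 12:
            k = 65 + 11  # free exchangeabilities + free frequencies
        else:
            k = {
                "JC": 0,
                "K80": 1,
                "HKY": 1 + 3,
                "TN": 2 + 3,
                "TVM": 4 + 3,
                "GTR": 5 + 3,
                None: 5 + 3,
            }[self.preset]
        if self.alpha is not None:
            k += 1
        if self.p_inv > 0 or getattr(self, "_fit_pinv", False):
            k += 1
        return k


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    """Module-level convenience: P(t) at the mean rate (rate = 1)."""
    return model.transition_matrix(t)


# ---------------------------------------------------------------------------
# Preset construction and free-parameter mapping
# ---------------------------------------------------------------------------


def _exch_from_six(six: np.ndarray) -> np.ndarray:
    S = np.ones((4, 4))
    for val, (i, j) in zip(six, _UT4):
        S[i, j] = S[j, i] = val
    np.fill_diagonal(S, 0.0)
    return S


def make_model(
    preset: str,
    freqs: Optional[np.ndarray] = None,
    alpha: Optional[float] = None,
    p_inv: float = 0.0,
    n_cats: int = 4,
    rates: Optional[dict] = None,
) -> SubstitutionModel:
    """Build a 4-state preset model. ``rates`` carries the preset's free
    exchangeability parameters (e.g. {"kappa": 2.0} for K80/HKY)."""
    rates = rates or {}
    if preset in ("JC", "K80"):
        freqs = np.full(4, 0.25)
    elif freqs is None:
        freqs = np.full(4, 0.25)
    six = np.ones(6)
    if preset in ("K80", "HKY"):
        kappa = rates.get("kappa", 2.0)
        six[1] = six[4] = kappa  # AG, CU
    elif preset == "TN":
        six[1] = rates.get("kappa_ag", 2.0)
        six[4] = rates.get("kappa_cu", 2.0)
    elif preset == "TVM":
        six[0] = rates.get("ac", 1.0)
        six[2] = rates.get("au", 1.0)
        six[3] = rates.get("cg", 1.0)
        six[1] = six[4] = rates.get("agcu", 1.0)
    elif preset == "GTR":
        for k, name in enumerate(("ac", "ag", "au", "cg", "cu")):
            six[k] = rates.get(name, 1.0)
    elif preset != "JC":
        raise ValueError(f"unknown preset {preset!r}")
    return SubstitutionModel(
        4, _exch_from_six(six), np.asarray(freqs, float), alpha, n_cats, p_inv, preset
    )


def make_gtr12(
    freqs: Optional[np.ndarray] = None,
    exchangeabilities: Optional[np.ndarray] = None,
    alpha: Optional[float] = None,
    p_inv: float = 0.0,
    n_cats: int = 4,
) -> SubstitutionModel:
    """Free GTR over the 12-letter sequence-structure alphabet."""
    if freqs is None:
        freqs = np.full(12, 1.0 / 12)
    if exchangeabilities is None:
        exchangeabilities = np.ones((12, 12))
        np.fill_diagonal(exchangeabilities, 0.0)
    return SubstitutionModel(
        12, np.asarray(exchangeabilities, float), np.asarray(freqs, float),
        alpha, n_cats, p_inv, None,
    )


def free_exchange_positions(model: SubstitutionModel) -> list[list[tuple[int, int]]]:
    """Groups of upper-triangle positions tied to one free parameter each;
    the last upper-triangle entry stays fixed at its value (identifiability)."""
    if model.n_states == 12:
        ut = [(i, j) for i in range(12) for j in range(i + 1, 12)]
        return [[p] for p in ut[:-1]]  # 65 free, last fixed
    preset = model.preset or "GTR"
    if preset == "JC":
        return []
    if preset in ("K80", "HKY"):
        return [[_UT4[1], _UT4[4]]]  # kappa ties AG and CU
    if preset == "TN":
        return [[_UT4[1]], [_UT4[4]]]
    if preset == "TVM":
        return [[_UT4[0]], [_UT4[2]], [_UT4[3]], [_UT4[1], _UT4[4]]]
    return [[p] for p in _UT4[:-1]]  # GTR: GU fixed to 1


def with_updated_exchange(
    model: SubstitutionModel, group: list[tuple[int, int]], value: float
) -> SubstitutionModel:
    S = model.exchangeabilities.copy()
    for i, j in group:
        S[i, j] = S[j, i] = value
    return replace(model, exchangeabilities=S, _eig=None)


def empirical_freqs(rows: list[str], letters: str, pseudocount: float = 0.5) -> np.ndarray:
    """Empirical state frequencies with a small pseudocount."""
    counts = np.full(len(letters), pseudocount)
    index = {c: k for k, c in enumerate(letters)}
    for row in rows:
        for ch in row:
            k = index.get(ch)
            if k is not None:
                counts[k] += 1
    return counts / counts.sum()
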