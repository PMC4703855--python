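"""Eigen-analysis of the community matrix: leading modes, reactivity, IPR.

The asymptotic response to a pulse perturbation is governed by the leading
eigenvalue λ1 of Φ and its right/left eigenvectors v1/u1; because the
off-diagonal entries of Φ are nonnegative (Metzler matrix), Perron–Frobenius
guarantees λ1 real with a nonnegative eigenvector.  The transient response
is governed by the reactivity λ_H, the top eigenvalue of the symmetric part
H = (Φ + Φᵀ)/2, which always satisfies λ_H ≥ λ1; λ1 < 0 < λ_H is the
"stable but reactive" regime where perturbations grow before decaying.

Localization — the concentration of an eigenvector on few species — is
quantified by the inverse participation ratio IPR(q) = Σ_i |q̂_i|⁴ of the
L2-normalized vector: 1/S for a uniform (extended) vector, 1 for a vector
supported on a single species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .parametrization import CommunityMatrix

__all__ = [
    "SpectralSummary",
    "LocalizationReport",
    "leading_modes",
    "reactivity",
    "ipr",
    "localized_species",
    "localization_report",
]

_REAL_TOL = 1e-8
_GAP_TOL = 1e-10


@dataclass
class SpectralSummary:
    """Spectrum and leading structure of a community matrix.

    ``eigenvalues`` are sorted by descending real part (ties: descending
    imaginary part, then index).  ``v1``/``u1`` are the unit-norm right/left
    Perron eigenvectors, sign-fixed entrywise nonnegative; ``wH`` is the
    unit top eigenvector of the symmetric part.
    """

    eigenvalues: np.ndarray
    lambda1: float
    v1: np.ndarray
    u1: np.ndarray
    lambdaH: float
    wH: np.ndarray
    right_vectors: np.ndarray = field(repr=False)  # columns, sorted order

    def to_dict(self) -> dict:
        return {
            "lambda1": self.lambda1,
            "lambdaH": self.lambdaH,
            "eigenvalues_real": self.eigenvalues.real.tolist(),
            "eigenvalues_imag": self.eigenvalues.imag.tolist(),
            "v1": self.v1.tolist(),
            "u1": self.u1.tolist(),
            "wH": self.wH.tolist(),
        }


@dataclass(frozen=True)
class LocalizationReport:
    ipr_v1: float
    ipr_u1: float
    ipr_wH: float
    localized_indices: dict
    n_localized: dict
    theta: float


def _as_matrix(Phi) -> np.ndarray:
    M = Phi.Phi if isinstance(Phi, CommunityMatrix) else np.asarray(Phi, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("community matrix must be square")
    if not np.isfinite(M).all():
        raise ValueError("community matrix has non-finite entries")
    return M


def _sign_fix(v: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude component positive (reproducible sign)."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def _sorted_eig(M: np.ndarray):
    vals, vecs = linalg.eig(M)
    order = np.lexsort((np.arange(len(vals)), -vals.imag, -vals.real))
    return vals[order], vecs[:, order]


def leading_modes(Phi) -> SpectralSummary:
    """Full spectrum plus unit-norm Perron eigenvectors and reactivity.

    Raises if the leading eigenvalue has an imaginary part beyond tolerance
    (a sign the Perron assumptions — nonnegative off-diagonals — fail).
    """
    M = _as_matrix(Phi)
    vals, vecs = _sorted_eig(M)
    lam1 = vals[0]
    if abs(lam1.imag) > _REAL_TOL * max(1.0, abs(lam1.real)):
        raise ValueError(f"leading eigenvalue is complex ({lam1:.4g})")
    if len(vals) > 1 and abs(vals[0] - vals[1]) < _GAP_TOL:
        warnings.warn("near-degenerate leading eigenvalue; modes may be unstable")
    v1 = _sign_fix(vecs[:, 0].real)
    v1 = v1 / np.linalg.norm(v1)

    # left eigenvectors of M are right eigenvectors of M.T at the same eigenvalues
    lvals, lvecs = _sorted_eig(M.T)
    u1 = _sign_fix(lvecs[:, 0].real)
    u1 = u1 / np.linalg.norm(u1)
    if float(u1 @ v1) < 0:
        u1 = -u1

    lamH, wH = reactivity(M)
    return SpectralSummary(
        eigenvalues=vals,
        lambda1=float(lam1.real),
        v1=v1,
        u1=u1,
        lambdaH=lamH,
        wH=wH,
        right_vectors=vecs,
    )


def reactivity(Phi) -> tuple[float, np.ndarray]:
    """(λ_H, w_H): top eigenpair of the symmetric part H = (Φ + Φᵀ)/2."""
    M = _as_matrix(Phi)
    H = (M + M.T) / 2.0
    vals, vecs = linalg.eigh(H)
    w = _sign_fix(vecs[:, -1])
    return float(vals[-1]), w / np.linalg.norm(w)


def ipr(q: np.ndarray) -> float:
    """Inverse participation ratio Σ|q̂_i|⁴ of the L2-normalized vector."""
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n == 0:
        raise ValueError("IPR of the zero vector is undefined")
    qn = q / n
    return float(np.sum(qn**4))


def localized_species(q: np.ndarray, theta: float | None = None) -> tuple[np.ndarray, int]:
    """Species whose |component| exceeds θ (default 1/√S, the uniform —
    fully extended — benchmark value)."""
    q = np.asarray(q, dtype=float)
    S = len(q)
    if theta is None:
        theta = 1.0 / np.sqrt(S)
    if theta <= 0:
        raise ValueError("theta must be > 0")
    idx = np.flatnonzero(np.abs(q) > theta)
    return idx, int(len(idx))


def localization_report(summary: SpectralSummary, theta: float | None = None) -> LocalizationReport:
    """IPR and localized-species counts for v1, u1 and wH."""
    out_idx, out_n = {}, {}
    for name, q in (("v1", summary.v1), ("u1", summary.u1), ("wH", summary.wH)):
        idx, n = localized_species(q, theta)
        out_idx[name] = idx
        out_n[name] = n
    S = len(summary.v1)
    return LocalizationReport(
        ipr_v1=ipr(summary.v1),
        ipr_u1=ipr(summary.u1),
        ipr_wH=ipr(summary.wH),
        localized_indices=out_idx,
        n_localized=out_n,
        theta=theta if theta is not None else 1.0 / np.sqrt(S),
    )
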