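"""Polar (Lu-Chipman) decomposition of normalized Mueller matrices.

Factorizes ``M = M_Delta . M_R . M_D`` — a depolarizer applied last, a
retarder, and a diattenuator applied first (the canonical factor order) —
and derives the four scalar parameters used throughout the analysis:

* ``D``     diattenuation magnitude, from the first row,
* ``P``     polarizance magnitude, from the first column,
* ``R``     retardance in radians, from the retarder factor's rotation angle,
* ``Delta`` depolarization power ``1 - |tr(m_Delta)| / 3`` over the 3x3 block.

Numerical guards: eigenvalues of ``m' m'^T`` are clamped at zero before the
square root (noise can produce small negatives); a near-singular
diattenuator (``D >= 1 - eps``) is inverted through a regularized inverse so
polarizer-like pixels do not crash image-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reconstruction import MuellerImage, SampleMeta

__all__ = [
    "DecompositionResult",
    "DecompositionMaps",
    "diattenuation",
    "polarizance",
    "decompose",
    "decompose_image",
]

#: Threshold for the singular-diattenuator branch.
SINGULAR_EPS = 1e-6


def diattenuation(m: np.ndarray) -> float:
    """``D = sqrt(m12^2 + m13^2 + m14^2) / m11``."""
    m = np.asarray(m, dtype=float)
    if m[0, 0] == 0:
        raise ValueError("diattenuation undefined for m11 = 0")
    return float(np.linalg.norm(m[0, 1:]) / m[0, 0])


def polarizance(m: np.ndarray) -> float:
    """``P = sqrt(m21^2 + m31^2 + m41^2) / m11``."""
    m = np.asarray(m, dtype=float)
    if m[0, 0] == 0:
        raise ValueError("polarizance undefined for m11 = 0")
    return float(np.linalg.norm(m[1:, 0]) / m[0, 0])


@dataclass
class DecompositionResult:
    """Factors and scalar parameters of one decomposed Mueller matrix."""

    D: float
    P: float
    R: float
    Delta: float
    M_D: np.ndarray
    M_R: np.ndarray
    M_Delta: np.ndarray
    status: str = "ok"  # ok | singular_diattenuator | clamped

    def reassemble(self) -> np.ndarray:
        return self.M_Delta @ self.M_R @ self.M_D


@dataclass
class DecompositionMaps:
    """Per-pixel scalar maps from decomposing a Mueller image."""

    D: np.ndarray
    P: np.ndarray
    R: np.ndarray
    Delta: np.ndarray
    mask: np.ndarray
    meta: SampleMeta = field(default_factory=SampleMeta)
    n_singular: int = 0
    n_clamped: int = 0

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"D": self.D, "P": self.P, "R": self.R, "Delta": self.Delta}


def _batched(m: np.ndarray, eps: float = SINGULAR_EPS):
    """Vectorized polar decomposition of normalized matrices, shape (n,4,4).

    Returns (D, P, R, Delta, M_D, M_R, M_Delta, singular, clamped).
    """
    n = m.shape[0]
    d_vec = m[:, 0, 1:]
    big_d = np.linalg.norm(d_vec, axis=1)
    p_vec = m[:, 1:, 0]
    big_p = np.linalg.norm(p_vec, axis=1)

    singular = big_d >= 1.0 - eps
    # Regularize the diattenuation magnitude used to build M_D^-1 so the
    # polarizer-like branch stays finite; D itself is reported unregularized.
    d_eff = np.minimum(big_d, 1.0 - eps)
    q = np.sqrt(1.0 - d_eff**2)

    with np.errstate(invalid="ignore", divide="ignore"):
        dhat = np.where(big_d[:, None] > 0, d_vec / np.maximum(big_d, 1e-300)[:, None], 0.0)
    outer = dhat[:, :, None] * dhat[:, None, :]
    eye3 = np.broadcast_to(np.eye(3), (n, 3, 3))
    m_d_small = q[:, None, None] * eye3 + (1.0 - q)[:, None, None] * outer
    m_d = np.zeros((n, 4, 4))
    m_d[:, 0, 0] = 1.0
    m_d[:, 0, 1:] = d_eff[:, None] * dhat
    m_d[:, 1:, 0] = d_eff[:, None] * dhat
    m_d[:, 1:, 1:] = m_d_small

    m_d_inv = np.linalg.inv(m_d)
    m_prime = m @ m_d_inv
    mp = m_prime[:, 1:, 1:]

    g = mp @ np.transpose(mp, (0, 2, 1))
    lam, vec = np.linalg.eigh(g)
    clamped = lam[:, 0] < -1e-12
    lam = np.clip(lam, 0.0, None)
    sqrt_lam = np.sqrt(lam)
    s_mat = np.einsum("nik,nk,njk->nij", vec, sqrt_lam, vec)
    det_mp = np.linalg.det(mp)
    sign = np.where(det_mp < 0, -1.0, 1.0)
    m_delta_small = sign[:, None, None] * s_mat

    tr_s = np.trace(s_mat, axis1=1, axis2=2)
    delta = np.clip(1.0 - tr_s / 3.0, 0.0, 1.0)

    # Regularized inverse of the depolarizer block for the retarder factor.
    inv_sqrt = 1.0 / np.maximum(sqrt_lam, eps)
    s_inv = np.einsum("nik,nk,njk->nij", vec, inv_sqrt, vec)
    m_r_small = sign[:, None, None] * s_inv @ mp

    tr_r = np.trace(m_r_small, axis1=1, axis2=2)
    big_r = np.arccos(np.clip((tr_r + 1.0) / 2.0 - 1.0, -1.0, 1.0))

    # Depolarizer polarizance vector, needed so the factors reassemble M.
    denom = np.maximum(1.0 - d_eff**2, eps**2)
    p_delta = (p_vec - np.einsum("nij,nj->ni", m[:, 1:, 1:], d_vec)) / denom[:, None]

    m_delta = np.zeros((n, 4, 4))
    m_delta[:, 0, 0] = 1.0
    m_delta[:, 1:, 0] = p_delta
    m_delta[:, 1:, 1:] = m_delta_small

    m_r = np.zeros((n, 4, 4))
    m_r[:, 0, 0] = 1.0
    m_r[:, 1:, 1:] = m_r_small

    return big_d, big_p, big_r, delta, m_d, m_r, m_delta, singular, clamped


def decompose(m: np.ndarray, eps: float = SINGULAR_EPS) -> DecompositionResult:
    """Polar-decompose a single normalized Mueller matrix.

    The input must have ``m11 = 1`` (normalize first) and be finite.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4):
        raise ValueError("expected a single 4x4 matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("decompose requires a finite matrix")
    if abs(m[0, 0] - 1.0) > 1e-8:
        raise ValueError("decompose requires an m11-normalized matrix (m11 = 1)")
    d, p, r, delta, m_d, m_r, m_delta, singular, clamped = _batched(
        m[None, :, :], eps=eps
    )
    status = "ok"
    if singular[0]:
        status = "singular_diattenuator"
    elif clamped[0]:
        status = "clamped"
    return DecompositionResult(
        D=float(d[0]),
        P=float(p[0]),
        R=float(r[0]),
        Delta=float(delta[0]),
        M_D=m_d[0],
        M_R=m_r[0],
        M_Delta=m_delta[0],
        status=status,
    )


def decompose_image(img: MuellerImage, eps: float = SINGULAR_EPS) -> DecompositionMaps:
    """Decompose every masked-in pixel of a normalized Mueller image.

    Masked-out pixels stay NaN in all four maps; per-image counts of
    singular-diattenuator and clamped-eigenvalue pixels are recorded.
    """
    if not img.normalized:
        raise ValueError("decompose_image requires an m11-normalized image")
    rows, cols = img.shape
    flat = img.elements.reshape(-1, 4, 4)
    valid = img.mask.reshape(-1) & np.all(np.isfinite(flat), axis=(1, 2))

    maps = {k: np.full(rows * cols, np.nan) for k in ("D", "P", "R", "Delta")}
    n_sing = n_clamp = 0
    if np.any(valid):
        d, p, r, delta, _, _, _, singular, clamped = _batched(flat[valid], eps=eps)
        maps["D"][valid] = d
        maps["P"][valid] = p
        maps["R"][valid] = r
        maps["Delta"][valid] = delta
        n_sing = int(np.sum(singular))
        n_clamp = int(np.sum(clamped))

    return DecompositionMaps(
        D=maps["D"].reshape(rows, cols),
        P=maps["P"].reshape(rows, cols),
        R=maps["R"].reshape(rows, cols),
        Delta=maps["Delta"].reshape(rows, cols),
        mask=valid.reshape(rows, cols),
        meta=img.meta,
        n_singular=n_sing,
        n_clamped=n_clamp,
    )
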