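"""Stokes/Mueller algebra: polarization states, elementary optical elements,
and physical-realizability checks.

Conventions
-----------
* Stokes vectors are length-4 float arrays ``(s0, s1, s2, s3)`` in intensity
  units (not normalized): total intensity, H/V linear, +/-45 deg linear, and
  circular components.
* Right circular polarization is ``s3 = +1``.  Any consistent handedness
  convention yields identical reconstructions from the 36-state scheme; this
  one is fixed here and used by both the forward model and the tests.
* Mueller matrices are 4x4 float arrays.  Elements are referred to 1-based
  (``m11`` .. ``m44``) in the API surface and in reports; storage is the
  ordinary 0-based numpy layout.
"""

from __future__ import annotations

import io

import numpy as np

__all__ = [
    "POL_STATES",
    "stokes_of_state",
    "degree_of_polarization",
    "apply_mueller",
    "analyzer_intensity",
    "mueller_linear_polarizer",
    "mueller_retarder",
    "mueller_rotator",
    "mueller_depolarizer",
    "mueller_diattenuator",
    "is_physical",
    "element",
    "matrix_to_csv",
    "matrix_from_csv",
]

#: The six generator/analyzer polarization states of the 36-state scheme:
#: H horizontal, V vertical, P +45 deg, M -45 deg, R right circular,
#: L left circular.
POL_STATES = ("H", "V", "P", "M", "R", "L")

_STATE_STOKES = {
    "H": np.array([1.0, 1.0, 0.0, 0.0]),
    "V": np.array([1.0, -1.0, 0.0, 0.0]),
    "P": np.array([1.0, 0.0, 1.0, 0.0]),
    "M": np.array([1.0, 0.0, -1.0, 0.0]),
    "R": np.array([1.0, 0.0, 0.0, 1.0]),
    "L": np.array([1.0, 0.0, 0.0, -1.0]),
}


def stokes_of_state(state: str) -> np.ndarray:
    """Unit-intensity, fully polarized Stokes vector of one of the six states.

    Parameters
    ----------
    state : str
        One of ``H, V, P, M, R, L``.
    """
    try:
        return _STATE_STOKES[state].copy()
    except KeyError:
        raise ValueError(
            f"unknown polarization state {state!r}; admissible labels are "
            f"{', '.join(POL_STATES)}"
        ) from None


def degree_of_polarization(s: np.ndarray) -> float:
    """sqrt(s1^2+s2^2+s3^2)/s0; 1 for fully polarized light."""
    s = np.asarray(s, dtype=float)
    if s[0] <= 0:
        raise ValueError("degree of polarization undefined for s0 <= 0")
    return float(np.sqrt(np.sum(s[1:] ** 2)) / s[0])


def apply_mueller(m: np.ndarray, s_in: np.ndarray) -> np.ndarray:
    """Propagate a Stokes vector through a sample: ``S_out = M . S_in``."""
    return np.asarray(m, dtype=float) @ np.asarray(s_in, dtype=float)


def analyzer_intensity(analyzer: str, s: np.ndarray) -> float:
    """Detected intensity behind an ideal analyzer in the given state.

    The ideal analyzer projects onto its fully polarized state:
    ``I = (s0 + a . (s1, s2, s3)) / 2`` with ``a`` the polarized part of the
    analyzer's Stokes vector.
    """
    a = stokes_of_state(analyzer)
    s = np.asarray(s, dtype=float)
    return float(0.5 * (s[0] + a[1:] @ s[1:]))


def mueller_linear_polarizer(angle: float) -> np.ndarray:
    """Ideal linear polarizer with transmission axis at ``angle`` (radians)
    from horizontal."""
    c = np.cos(2.0 * angle)
    s = np.sin(2.0 * angle)
    return 0.5 * np.array(
        [
            [1.0, c, s, 0.0],
            [c, c * c, c * s, 0.0],
            [s, c * s, s * s, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )


def mueller_retarder(retardance: float, fast_axis: float = 0.0) -> np.ndarray:
    """Linear retarder with given retardance (radians, in [0, 2*pi)) and fast
    axis orientation (radians from horizontal).

    The matrix leaves ``s0`` unchanged, has determinant 1, and its lower-right
    3x3 block is orthogonal.
    """
    if not 0.0 <= retardance < 2.0 * np.pi:
        raise ValueError("retardance must lie in [0, 2*pi)")
    c = np.cos(2.0 * fast_axis)
    s = np.sin(2.0 * fast_axis)
    cd = np.cos(retardance)
    sd = np.sin(retardance)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c * c + s * s * cd, c * s * (1.0 - cd), -s * sd],
            [0.0, c * s * (1.0 - cd), s * s + c * c * cd, c * sd],
            [0.0, s * sd, -c * sd, cd],
        ]
    )


def mueller_rotator(angle: float) -> np.ndarray:
    """Circular retarder (optical rotator) turning the linear-polarization
    plane by ``angle`` radians."""
    c = np.cos(2.0 * angle)
    s = np.sin(2.0 * angle)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c, -s, 0.0],
            [0.0, s, c, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def mueller_depolarizer(a: float, b: float, c: float) -> np.ndarray:
    """Diagonal depolarizer ``diag(1, a, b, c)``.

    ``a, b, c`` are the retention factors of the two linear and the circular
    polarization channels; all must have magnitude <= 1.
    """
    for name, v in (("a", a), ("b", b), ("c", c)):
        if abs(v) > 1.0:
            raise ValueError(f"depolarizer factor {name}={v} outside [-1, 1]")
    return np.diag([1.0, float(a), float(b), float(c)])


def mueller_diattenuator(d: np.ndarray) -> np.ndarray:
    """Pure (normalized) diattenuator with diattenuation vector ``d``.

    ``M_D = [[1, d^T], [d, m_D]]`` with
    ``m_D = sqrt(1-D^2) I + (1 - sqrt(1-D^2)) dhat dhat^T`` and ``D = |d| <= 1``.
    """
    d = np.asarray(d, dtype=float)
    if d.shape != (3,):
        raise ValueError("diattenuation vector must have 3 components")
    big_d = float(np.linalg.norm(d))
    if big_d > 1.0:
        raise ValueError(f"diattenuation magnitude {big_d} exceeds 1")
    q = np.sqrt(max(1.0 - big_d**2, 0.0))
    if big_d > 0:
        dhat = d / big_d
        m_small = q * np.eye(3) + (1.0 - q) * np.outer(dhat, dhat)
    else:
        m_small = np.eye(3)
    m = np.empty((4, 4))
    m[0, 0] = 1.0
    m[0, 1:] = d
    m[1:, 0] = d
    m[1:, 1:] = m_small
    return m


def is_physical(m: np.ndarray, tol: float = 1e-9) -> tuple[bool, list[str]]:
    """Quick physical-realizability screen for a Mueller matrix.

    Checks (with relative tolerance ``tol``):

    * ``m11 > 0`` — the sample transmits,
    * ``|m_ij| <= m11`` for all elements,
    * ``tr(M^T M) <= 4 m11^2`` (a necessary passivity condition).

    Returns ``(passed, violations)``; never raises — this is a diagnostic
    used to guard reconstruction output, where noise may push valid pixels
    slightly outside the physical cone (use ``tol=1e-2`` for noisy data).
    """
    m = np.asarray(m, dtype=float)
    violations: list[str] = []
    m11 = m[0, 0]
    if not m11 > 0:
        violations.append(f"m11 = {m11} is not > 0")
        return False, violations
    bound = m11 * (1.0 + tol)
    if np.any(np.abs(m) > bound):
        i, j = np.unravel_index(np.argmax(np.abs(m)), m.shape)
        violations.append(
            f"|m{i + 1}{j + 1}| = {abs(m[i, j]):.6g} exceeds the "
            f"|m_ij| <= m11 bound (m11 = {m11:.6g})"
        )
    if np.trace(m.T @ m) > 4.0 * m11**2 * (1.0 + tol):
        violations.append(
            f"tr(M^T M) = {np.trace(m.T @ m):.6g} exceeds 4*m11^2 = "
            f"{4 * m11**2:.6g}"
        )
    return not violations, violations


def element(m: np.ndarray, i: int, j: int) -> float:
    """1-based element accessor: ``element(m, 2, 2)`` is m22."""
    if not (1 <= i <= 4 and 1 <= j <= 4):
        raise ValueError("Mueller element indices are 1-based in 1..4")
    return float(np.asarray(m)[i - 1, j - 1])


def matrix_to_csv(m: np.ndarray) -> str:
    """Serialize a 4x4 Mueller matrix to a CSV block with m1..m4 headers."""
    m = np.asarray(m, dtype=float)
    lines = ["," + ",".join(f"m{j}" for j in range(1, 5))]
    for i in range(4):
        lines.append(f"m{i + 1}," + ",".join(repr(float(v)) for v in m[i]))
    return "\n".join(lines) + "\n"


def matrix_from_csv(text: str) -> np.ndarray:
    """Inverse of :func:`matrix_to_csv`."""
    rows = []
    for line in io.StringIO(text):
        line = line.strip()
        if not line or line.startswith(","):
            continue
        parts = line.split(",")
        rows.append([float(v) for v in parts[1:5]])
    m = np.array(rows)
    if m.shape != (4, 4):
        raise ValueError(f"expected a 4x4 CSV block, got shape {m.shape}")
    return m
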