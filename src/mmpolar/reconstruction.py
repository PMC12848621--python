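"""Per-pixel Mueller-matrix image reconstruction from the 36-state scheme.

Each of the 16 matrix elements is a signed sum of exactly four intensity
images, one per (generator, analyzer) polarization-state pair.  With ideal
generator and analyzer states the signed sums evaluate to ``2 * m_ij`` at
every pixel; the factor of two is removed by the m11 normalization step.

State-pair keys are ordered ``(generator, analyzer)``: the image ``("H","V")``
was generated in H and analyzed in V.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import POL_STATES

__all__ = [
    "SampleMeta",
    "IntensityStack",
    "MuellerImage",
    "STATE_PAIRS",
    "reconstruct_mueller",
    "normalize_by_m11",
    "tissue_mask",
]

#: All 36 ordered (generator, analyzer) state pairs.
STATE_PAIRS = tuple((g, a) for g in POL_STATES for a in POL_STATES)

# Signed state bases of the reconstruction: Stokes component k of the
# generated (column index) or analyzed (row index) light is isolated by the
# signed combination of these two states.  Expanding the double sum
# reproduces the published 36-state element equations term by term
# (e.g. m11 = HH+HV+VH+VV, m12 = HH+HV-VH-VV, m21 = HH-HV+VH-VV, ...,
# m44 = RR-RL-LR+LL).
_BASIS = (
    (("H", 1.0), ("V", 1.0)),
    (("H", 1.0), ("V", -1.0)),
    (("P", 1.0), ("M", -1.0)),
    (("R", 1.0), ("L", -1.0)),
)


def element_terms(i: int, j: int) -> list[tuple[str, str, float]]:
    """The four ``(generator, analyzer, sign)`` terms of element ``m_ij``
    (1-based indices)."""
    if not (1 <= i <= 4 and 1 <= j <= 4):
        raise ValueError("element indices are 1-based in 1..4")
    return [
        (g, a, sg * sa)
        for g, sg in _BASIS[j - 1]
        for a, sa in _BASIS[i - 1]
    ]


@dataclass(frozen=True)
class SampleMeta:
    """Sample-level metadata carried through the pipeline."""

    sample_id: str = "unknown"
    age_days: int = 0
    wavelength_nm: int = 632
    preparation: str = "no_paraffin"

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "age_days": self.age_days,
            "wavelength_nm": self.wavelength_nm,
            "preparation": self.preparation,
        }


@dataclass
class IntensityStack:
    """The 36 registered intensity images of one sample.

    ``images`` maps ``(generator, analyzer)`` state pairs to 2-D nonnegative
    arrays of a common shape.
    """

    images: Mapping[tuple[str, str], np.ndarray]
    meta: SampleMeta = field(default_factory=SampleMeta)

    def validate(self) -> None:
        missing = [p for p in STATE_PAIRS if p not in self.images]
        if missing:
            names = ", ".join(g + a for g, a in missing)
            raise ValueError(f"intensity stack is missing state pair(s): {names}")
        shape = None
        for (g, a), img in self.images.items():
            img = np.asarray(img)
            if img.ndim != 2:
                raise ValueError(f"image {g}{a} is not 2-D")
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(
                    f"image {g}{a} has shape {img.shape}, expected {shape}"
                )
            if np.any(img < 0):
                raise ValueError(f"image {g}{a} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(next(iter(self.images.values()))).shape


@dataclass
class MuellerImage:
    """Per-pixel 4x4 Mueller matrix field with a validity mask.

    ``elements`` has shape ``(rows, cols, 4, 4)``.  Masked-out pixels carry
    NaN in all 16 planes.  When ``normalized`` is set, ``m11 == 1`` at every
    masked-in pixel.
    """

    elements: np.ndarray
    normalized: bool = False
    mask: np.ndarray | None = None
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=float)
        if self.elements.ndim != 4 or self.elements.shape[2:] != (4, 4):
            raise ValueError("elements must have shape (rows, cols, 4, 4)")
        if self.mask is None:
            self.mask = np.ones(self.elements.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.elements.shape[:2]:
                raise ValueError("mask shape does not match image shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elements.shape[:2]

    def plane(self, i: int, j: int) -> np.ndarray:
        """1-based element plane: ``plane(4, 4)`` is the m44 image."""
        if not (1 <= i <= 4 and 1 <= j <= 4):
            raise ValueError("element indices are 1-based in 1..4")
        return self.elements[:, :, i - 1, j - 1]


def reconstruct_mueller(stack: IntensityStack) -> MuellerImage:
    """Build the (unnormalized) Mueller image from a 36-image stack.

    Every element plane is the pixelwise four-term signed sum of the scheme;
    for ideal states the result equals ``2 * M`` at each pixel.
    """
    stack.validate()
    rows, cols = stack.shape
    elements = np.zeros((rows, cols, 4, 4))
    for i in range(1, 5):
        for j in range(1, 5):
            plane = np.zeros((rows, cols))
            for g, a, sign in element_terms(i, j):
                plane += sign * np.asarray(stack.images[(g, a)], dtype=float)
            elements[:, :, i - 1, j - 1] = plane
    return MuellerImage(elements, normalized=False, meta=stack.meta)


def normalize_by_m11(img: MuellerImage, floor: float = 0.01) -> MuellerImage:
    """Divide every element plane by the m11 plane pixelwise.

    Pixels whose m11 falls at or below ``floor * max(m11)`` (or is
    nonpositive) are masked out and set to NaN; no division occurs there.
    """
    if img.normalized:
        raise ValueError("image is already m11-normalized")
    if not 0.0 < floor < 1.0:
        raise ValueError("normalization floor must lie in (0, 1)")
    m11 = img.plane(1, 1)
    finite = np.isfinite(m11)
    peak = np.max(m11[finite & img.mask], initial=0.0)
    valid = img.mask & finite & (m11 > floor * peak) & (m11 > 0)
    elements = np.where(
        valid[:, :, None, None],
        img.elements / np.where(valid, m11, 1.0)[:, :, None, None],
        np.nan,
    )
    return MuellerImage(elements, normalized=True, mask=valid, meta=img.meta)


def tissue_mask(
    img: MuellerImage, method: str = "percentile", param: float = 50.0
) -> np.ndarray:
    """Region-of-interest mask from the m11 (total transmittance) plane.

    ``percentile`` keeps pixels with m11 above the ``param``-th percentile of
    the image; ``fixed`` keeps pixels with ``m11 >= param * max(m11)``.  The
    result is AND-combined with the image's validity mask.  The segmentation
    rule for tissue statistics is deliberately explicit and configurable.
    """
    m11 = img.plane(1, 1)
    finite = np.isfinite(m11)
    values = m11[finite]
    if values.size == 0 or np.max(values) <= 0:
        return np.zeros(img.shape, dtype=bool)
    if method == "percentile":
        if not 0.0 <= param <= 100.0:
            raise ValueError("percentile parameter must lie in [0, 100]")
        thresh = np.percentile(values, param)
        keep = finite & (m11 >= thresh)
    elif method == "fixed":
        if not 0.0 <= param <= 1.0:
            raise ValueError("fixed-threshold parameter must lie in [0, 1]")
        keep = finite & (m11 >= param * np.max(values))
    else:
        raise ValueError(f"unknown mask method {method!r}; use percentile or fixed")
    return keep & img.mask
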