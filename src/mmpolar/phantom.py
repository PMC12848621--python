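"""Synthetic tissue-phantom generator with a Rayleigh-to-Mie age transition.

The phantom is a per-pixel *effective-Mueller* model, not a photon-transport
Monte Carlo: each pixel carries a true normalized Mueller matrix composed as

    M = M_depol(a1, a2, c) . M_retarder(delta, theta) . M_diattenuator(D)

so every pipeline stage has exact, exportable ground truth.  The biological
story it emulates: a brain-tissue background of small (Rayleigh-like)
scatterers that preserve linear polarization better than circular
(``m22 ~ m33 > m44``), with amyloid-plaque inclusions acting as enlarged
Mie-like scattering centres that preserve helicity (``m44 >= m22``) and
locally raise depolarization.  Plaque coverage grows linearly with age from
an onset at 45 days, so the plaque-pixel fraction — and with it the
skewness of the m44 and depolarization maps — rises along the age ladder
while the depolarization kurtosis falls.

Retention channels
------------------
Depolarization is parameterized by three per-channel retention factors
``(linear1, linear2, circular)`` acting on s1, s2, s3.  Plaques raise the
circular retention (the Mie helicity signature), leave the first linear
channel nearly unchanged (so the m22 moments stay flat with age), and
strongly depress the second linear channel, which makes plaque pixels *more*
depolarizing overall (Delta above background) — the ingredient that drives
the positive age trend of depolarization skewness.

Jitter
------
Pixel-to-pixel variability is a shared heavy-tailed retention jitter
(Student-t, nu=5, clamped) plus small independent per-channel terms.  The
heavy tail gives the background maps an elevated baseline kurtosis, so the
growing plaque mixture *lowers* kurtosis with age while raising skewness —
the qualitative trend structure the statistics layer is meant to recover.
All jitters are clamped tightly enough that the Rayleigh/Mie orderings hold
at every generated pixel by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    mueller_depolarizer,
    mueller_diattenuator,
    mueller_retarder,
    stokes_of_state,
    POL_STATES,
)
from .decomposition import DecompositionMaps
from .moments import MomentSummary, central_moments
from .reconstruction import IntensityStack, SampleMeta

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PLAQUE_ONSET_AGE_DAYS",
    "DEFAULT_AGES",
    "default_age_schedule",
    "generate_phantom",
    "forward_measure",
    "iter_age_series",
    "make_age_series",
]

#: Age (days) at which plaque deposition begins in the emulated mouse model.
PLAQUE_ONSET_AGE_DAYS = 45

#: The cohort's age ladder (days).
DEFAULT_AGES = (75, 100, 125, 150, 175, 200, 225)

#: Plaque area-fraction growth rate: fraction f(age) = KAPPA * (age - onset),
#: reaching 0.07 of the tissue footprint at 225 days.
DEFAULT_KAPPA = 0.07 / 180.0

#: Multiplicative retention scaling per wavelength: shorter wavelengths
#: scatter more strongly, retaining less polarization.  No dispersion model
#: beyond this scaling.
WAVELENGTH_RETENTION_SCALE = {445: 0.94, 532: 0.97, 632: 1.0}

LABEL_OUTSIDE, LABEL_TISSUE, LABEL_PLAQUE = 0, 1, 2

#: Parameters the generator exports ground-truth moment summaries for.
TRUTH_PARAMETERS = ("m22", "m33", "m44", "D", "P", "R", "Delta")


def default_age_schedule(age_days: float, kappa: float = DEFAULT_KAPPA) -> float:
    """Expected plaque area fraction of the tissue footprint at a given age.

    Zero before the 45-day deposition onset, then linear:
    ``kappa * (age_days - 45)``.
    """
    if age_days < 0:
        raise ValueError("age_days must be nonnegative")
    return kappa * max(0.0, float(age_days) - PLAQUE_ONSET_AGE_DAYS)


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic sample.

    Retention triples are ``(linear1, linear2, circular)`` channel factors of
    the diagonal depolarizer; all must lie in [0, 1] with the background
    circular retention below its linear retentions (Rayleigh-like) and the
    plaque circular retention at or above its linear retentions' m44/m22
    ordering (Mie-like).
    """

    shape: tuple[int, int] = (256, 256)
    age_days: int = 150
    wavelength_nm: int = 632
    preparation: str = "no_paraffin"
    sample_id: str = "phantom"
    seed: int = 0

    # Geometry
    tissue_footprint: float = 0.8  # ellipse semi-axes as fraction of half-frame
    plaque_radius_px: tuple[float, float] = (1.2, 2.4)  # uniform radius range
    plaque_kappa: float = DEFAULT_KAPPA

    # Regime parameters
    scatterer_radius_nm: float = 1000.0  # representative Mie scatterer size
    background_depol: tuple[float, float, float] = (0.88, 0.84, 0.84)
    plaque_depol: tuple[float, float, float] = (0.87, 0.60, 0.92)
    background_retardance: float = 0.20  # radians
    retarder_axis: float = np.pi / 8.0
    background_diatten: float = 0.05
    outside_depol: tuple[float, float, float] = (0.99, 0.99, 0.985)

    # Transmittance (sets the m11 contrast the tissue mask segments on)
    tissue_transmittance: float = 0.70
    outside_transmittance: float = 0.15

    # Jitter scales (see module docstring).  The common-jitter clamp (6 sigma)
    # exactly exhausts the headroom between the plaque circular retention and
    # the 0.995 factor ceiling, so no per-channel clipping can break the
    # Rayleigh/Mie orderings.
    jitter_common: float = 0.0105  # shared heavy-tailed retention jitter (std)
    jitter_common_df: float = 3.0  # Student-t degrees of freedom
    jitter_channel: float = 0.003  # independent per-channel retention jitter
    # Diffuse age-growing heterogeneity: Gaussian retention jitter on the
    # second linear channel whose variance scales with plaque load,
    # reaching this std at 225 days.  It broadens the depolarization
    # distribution without touching the m22 or m44 channels, so the
    # depolarization kurtosis falls with age while its mean stays put.
    jitter_hetero: float = 0.03
    jitter_retardance: float = 0.01
    jitter_axis: float = 0.05
    jitter_diatten: float = 0.005
    jitter_transmittance: float = 0.02

    # Measurement
    noise_snr: float = 50.0
    exposure: float = 1.0

    def validate(self) -> None:
        rows, cols = self.shape
        if rows < 8 or cols < 8:
            raise ValueError("phantom shape must be at least 8x8")
        if self.wavelength_nm not in WAVELENGTH_RETENTION_SCALE:
            raise ValueError(
                f"wavelength {self.wavelength_nm} nm not in "
                f"{sorted(WAVELENGTH_RETENTION_SCALE)}"
            )
        if not 0.0 < self.tissue_footprint <= 1.0:
            raise ValueError("tissue_footprint must lie in (0, 1]")
        rmin, rmax = self.plaque_radius_px
        semi = self.tissue_footprint * min(rows, cols) / 2.0
        if rmax > semi:
            raise ValueError(
                f"plaque radius {rmax} px exceeds the tissue footprint "
                f"semi-axis {semi:.1f} px"
            )
        for name, triple in (
            ("background_depol", self.background_depol),
            ("plaque_depol", self.plaque_depol),
            ("outside_depol", self.outside_depol),
        ):
            if any(not 0.0 <= v <= 1.0 for v in triple):
                raise ValueError(f"{name} factors must lie in [0, 1]")
        b1, _, bc = self.background_depol
        if not bc < b1:
            raise ValueError(
                "background circular retention must be below linear "
                "(Rayleigh-like ordering)"
            )
        if not self.plaque_depol[2] >= self.plaque_depol[0]:
            raise ValueError(
                "plaque circular retention must be >= its first linear "
                "retention (Mie-like ordering)"
            )

    def plaque_area_fraction(self) -> float:
        return default_age_schedule(self.age_days, self.plaque_kappa)

    @property
    def meta(self) -> SampleMeta:
        return SampleMeta(
            sample_id=self.sample_id,
            age_days=self.age_days,
            wavelength_nm=self.wavelength_nm,
            preparation=self.preparation,
        )


@dataclass
class GroundTruth:
    """Exact per-pixel ground truth of one phantom sample."""

    mueller_map: np.ndarray  # (rows, cols, 4, 4), m11-normalized
    transmittance: np.ndarray  # (rows, cols) total-intensity scale
    label_map: np.ndarray  # uint8: 0 outside, 1 tissue, 2 plaque
    true_decomposition: DecompositionMaps
    true_moments: dict[str, MomentSummary]
    spec: PhantomSpec

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.label_map >= LABEL_TISSUE

    def element_map(self, i: int, j: int) -> np.ndarray:
        return self.mueller_map[:, :, i - 1, j - 1]


def _clamped_t(rng: np.random.Generator, df: float, std: float, size, clamp_sigmas: float = 4.0) -> np.ndarray:
    """Student-t noise scaled to the given std, clamped at +/- clamp_sigmas*std.

    ``df=inf`` is the Gaussian limit (used by tests with exact closed-form
    mixture oracles)."""
    if np.isinf(df):
        draw = rng.normal(0.0, std, size=size)
    else:
        draw = rng.standard_t(df, size=size) * (std / np.sqrt(df / (df - 2.0)))
    return np.clip(draw, -clamp_sigmas * std, clamp_sigmas * std)


def _clamped_normal(rng: np.random.Generator, std: float, size, clamp_sigmas: float = 3.0) -> np.ndarray:
    draw = rng.normal(0.0, std, size=size)
    return np.clip(draw, -clamp_sigmas * std, clamp_sigmas * std)


def _footprint_mask(shape: tuple[int, int], fraction: float) -> np.ndarray:
    rows, cols = shape
    r = (np.arange(rows) - (rows - 1) / 2.0) / (fraction * rows / 2.0)
    c = (np.arange(cols) - (cols - 1) / 2.0) / (fraction * cols / 2.0)
    return (r[:, None] ** 2 + c[None, :] ** 2) <= 1.0


def _place_plaques(
    rng: np.random.Generator, spec: PhantomSpec, footprint: np.ndarray
) -> np.ndarray:
    """Poisson plaque disks (union, overlaps allowed) inside the footprint."""
    rows, cols = spec.shape
    rmin, rmax = spec.plaque_radius_px
    mean_r2 = (rmin**2 + rmin * rmax + rmax**2) / 3.0
    tissue_area = float(np.sum(footprint))
    frac = spec.plaque_area_fraction()
    expected = frac * tissue_area / (np.pi * mean_r2)
    n = int(rng.poisson(expected)) if expected > 0 else 0
    plaque = np.zeros(spec.shape, dtype=bool)
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    placed = 0
    while placed < n:
        y = rng.uniform(0, rows)
        x = rng.uniform(0, cols)
        if not footprint[min(int(y), rows - 1), min(int(x), cols - 1)]:
            continue  # centers uniform over the tissue footprint
        radius = rng.uniform(rmin, rmax)
        plaque |= (rr - y) ** 2 + (cc - x) ** 2 <= radius**2
        placed += 1
    return plaque & footprint


def generate_phantom(spec: PhantomSpec) -> GroundTruth:
    """Build the exact ground-truth Mueller field of one phantom sample."""
    spec.validate()
    rows, cols = spec.shape
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    footprint = _footprint_mask(spec.shape, spec.tissue_footprint)
    plaque = _place_plaques(rng, spec, footprint)
    label = np.full(spec.shape, LABEL_OUTSIDE, dtype=np.uint8)
    label[footprint] = LABEL_TISSUE
    label[plaque] = LABEL_PLAQUE

    ws = WAVELENGTH_RETENTION_SCALE[spec.wavelength_nm]
    base = np.empty((rows, cols, 3))
    for k in range(3):
        chan = np.full(spec.shape, spec.outside_depol[k])
        chan[label == LABEL_TISSUE] = spec.background_depol[k] * ws
        chan[label == LABEL_PLAQUE] = spec.plaque_depol[k] * ws
        base[:, :, k] = chan

    eta = _clamped_t(
        rng, spec.jitter_common_df, spec.jitter_common, spec.shape, clamp_sigmas=6.0
    )
    eps = _clamped_normal(rng, spec.jitter_channel, (rows, cols, 3))
    # Age-dependent diffuse heterogeneity on the second linear channel:
    # variance proportional to the plaque-load schedule.
    load = spec.plaque_area_fraction() / default_age_schedule(225, spec.plaque_kappa)
    hetero_std = spec.jitter_hetero * np.sqrt(max(load, 0.0))
    if hetero_std > 0:
        eps[:, :, 1] += np.clip(
            rng.normal(0.0, hetero_std, spec.shape), -0.08, 0.08
        )
    retention = np.clip(base + eta[:, :, None] + eps, 0.01, 0.995)

    delta = np.clip(
        spec.background_retardance
        + _clamped_normal(rng, spec.jitter_retardance, spec.shape),
        0.0,
        np.pi - 1e-6,
    )
    theta = spec.retarder_axis + _clamped_normal(rng, spec.jitter_axis, spec.shape)
    diatt = np.clip(
        spec.background_diatten
        + _clamped_normal(rng, spec.jitter_diatten, spec.shape),
        0.0,
        0.3,
    )
    outside = label == LABEL_OUTSIDE
    delta[outside] = 0.0
    diatt[outside] = 0.0

    tau = np.where(
        outside,
        spec.outside_transmittance,
        np.clip(
            spec.tissue_transmittance
            + _clamped_normal(rng, spec.jitter_transmittance, spec.shape),
            0.05,
            1.0,
        ),
    )

    mueller = _compose_field(retention, delta, theta, diatt)

    true_decomp = DecompositionMaps(
        D=diatt.copy(),
        P=np.linalg.norm(mueller[:, :, 1:, 0], axis=2),
        R=delta.copy(),
        Delta=1.0 - np.sum(retention, axis=2) / 3.0,
        mask=np.ones(spec.shape, dtype=bool),
        meta=spec.meta,
    )

    gt = GroundTruth(
        mueller_map=mueller,
        transmittance=tau,
        label_map=label,
        true_decomposition=true_decomp,
        true_moments={},
        spec=spec,
    )
    tissue = gt.tissue_mask
    for name in TRUTH_PARAMETERS:
        values = _parameter_map(gt, name)[tissue]
        gt.true_moments[name] = central_moments(values, name, spec.meta)
    return gt


def _parameter_map(gt: GroundTruth, name: str) -> np.ndarray:
    if name in ("m22", "m33", "m44"):
        i = int(name[1])
        return gt.element_map(i, i)
    return gt.true_decomposition.as_dict()[name]


def _compose_field(
    retention: np.ndarray, delta: np.ndarray, theta: np.ndarray, diatt: np.ndarray
) -> np.ndarray:
    """Vectorized M = depolarizer . retarder . diattenuator per pixel."""
    rows, cols = delta.shape
    c2 = np.cos(2.0 * theta)
    s2 = np.sin(2.0 * theta)
    cd = np.cos(delta)
    sd = np.sin(delta)

    m_r = np.zeros((rows, cols, 4, 4))
    m_r[:, :, 0, 0] = 1.0
    m_r[:, :, 1, 1] = c2 * c2 + s2 * s2 * cd
    m_r[:, :, 1, 2] = c2 * s2 * (1.0 - cd)
    m_r[:, :, 1, 3] = -s2 * sd
    m_r[:, :, 2, 1] = c2 * s2 * (1.0 - cd)
    m_r[:, :, 2, 2] = s2 * s2 + c2 * c2 * cd
    m_r[:, :, 2, 3] = c2 * sd
    m_r[:, :, 3, 1] = s2 * sd
    m_r[:, :, 3, 2] = -c2 * sd
    m_r[:, :, 3, 3] = cd

    q = np.sqrt(1.0 - diatt**2)
    m_d = np.zeros((rows, cols, 4, 4))
    m_d[:, :, 0, 0] = 1.0
    m_d[:, :, 0, 1] = diatt  # diattenuation axis fixed along s1 (horizontal)
    m_d[:, :, 1, 0] = diatt
    m_d[:, :, 1, 1] = 1.0
    m_d[:, :, 2, 2] = q
    m_d[:, :, 3, 3] = q

    m = np.einsum("hwij,hwjk->hwik", m_r, m_d)
    m[:, :, 1, :] *= retention[:, :, 0, None]
    m[:, :, 2, :] *= retention[:, :, 1, None]
    m[:, :, 3, :] *= retention[:, :, 2, None]
    return m


_ANALYZER_VECS = {a: stokes_of_state(a) for a in POL_STATES}


def forward_measure(
    gt: GroundTruth,
    noise_snr: float | None = None,
    seed: int = 0,
    exposure: float | None = None,
) -> IntensityStack:
    """Simulate the 36-state measurement of a phantom.

    For each (generator, analyzer) pair the noiseless image is
    ``exposure * tau * analyzer_intensity(a, M . s_g)``; seeded Gaussian
    noise with per-pixel standard deviation ``signal / noise_snr`` is added
    and the result clipped at zero.  ``noise_snr=None`` means noiseless;
    nonpositive values are rejected.
    """
    if noise_snr is not None and noise_snr <= 0:
        raise ValueError("noise_snr must be positive (use None for noiseless)")
    if exposure is None:
        exposure = gt.spec.exposure
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scale = exposure * gt.transmittance
    images: dict[tuple[str, str], np.ndarray] = {}
    for g in POL_STATES:
        s_out = np.einsum("hwij,j->hwi", gt.mueller_map, stokes_of_state(g))
        for a in POL_STATES:
            av = _ANALYZER_VECS[a]
            img = scale * 0.5 * (s_out[:, :, 0] + np.einsum("hwi,i->hw", s_out[:, :, 1:], av[1:]))
            if noise_snr is not None:
                img = img + rng.normal(0.0, 1.0, img.shape) * (img / noise_snr)
            images[(g, a)] = np.clip(img, 0.0, None)
    return IntensityStack(images=images, meta=gt.spec.meta)


def _derive_seed(base_seed: int, age: int, replicate: int, salt: int = 0) -> int:
    """Deterministic per-sample seed; wavelength is deliberately excluded so
    the same cohort geometry is reused across wavelengths."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(age, replicate, salt))
    return int(ss.generate_state(1, np.uint32)[0]) % (2**31)


def iter_age_series(
    base: PhantomSpec,
    ages: tuple[int, ...] = DEFAULT_AGES,
    replicates: int = 3,
    seed: int | None = None,
):
    """Yield ``(spec, ground_truth, stack)`` for every cohort sample.

    The default cohort mirrors the emulated study: 7 ages x 3 replicates =
    21 samples.  Each sample gets a distinct derived seed; identical inputs
    reproduce identical datasets bit for bit.
    """
    if not ages:
        raise ValueError("age ladder must be nonempty")
    base_seed = base.seed if seed is None else seed
    for age in ages:
        for rep in range(replicates):
            spec = dataclasses.replace(
                base,
                age_days=int(age),
                seed=_derive_seed(base_seed, int(age), rep),
                sample_id=f"age{age:03d}_rep{rep}",
            )
            gt = generate_phantom(spec)
            stack = forward_measure(
                gt,
                noise_snr=spec.noise_snr,
                seed=_derive_seed(base_seed, int(age), rep, salt=1),
            )
            yield spec, gt, stack


def make_age_series(
    base: PhantomSpec,
    out_dir,
    ages: tuple[int, ...] = DEFAULT_AGES,
    replicates: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Write a full cohort to disk and return its manifest.

    Layout: ``<out>/<sample_id>/`` with the 36 intensity TIFFs
    (``<sample_id>_<G><A>.tif``), ``meta.yaml``, ``ground_truth.tif``
    (16 Mueller planes + label plane) and ``truth_moments.csv``; plus a
    top-level ``manifest.csv``.
    """
    from . import io as mmio  # deferred: keeps phantom importable without I/O deps

    records = []
    for spec, gt, stack in iter_age_series(base, ages, replicates, seed):
        sample_dir = mmio.write_sample(out_dir, spec, gt, stack)
        records.append(
            {
                **spec.meta.as_dict(),
                "seed": spec.seed,
                "path": str(sample_dir),
                "plaque_area_fraction": spec.plaque_area_fraction(),
            }
        )
    manifest = pd.DataFrame.from_records(records)
    mmio.write_manifest(out_dir, manifest)
    return manifest
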