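"""Central-moment statistics of parameter maps and age-trend fitting.

The four moments are the population (1/N) forms, exactly as used in the
analysis this package implements:

* mean        ``mu = sum(x) / N``
* std         ``sigma = sqrt(sum((x - mu)^2) / N)``
* skewness    ``sum((x - mu)^3) / (N sigma^3)``
* kurtosis    ``sum((x - mu)^4) / (N sigma^4)``  (non-excess; Gaussian -> 3)

Per-sample summaries are aggregated by age group (arithmetic mean across the
samples of a group, across-sample standard deviation as the error bar) and
the group means are fitted against age: ordinary least squares for the
first two moments, a three-parameter exponential
``y = alpha * exp(beta * x) + offset`` for skewness and kurtosis.  The
offset term is required because skewness can be negative, which a
two-parameter exponential cannot represent.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .reconstruction import SampleMeta

__all__ = [
    "MomentSummary",
    "FitResult",
    "GroupTrend",
    "central_moments",
    "moments_by_group",
    "fit_linear",
    "fit_exponential",
    "bootstrap_beta_interval",
    "trend_table",
    "parse_trend_table",
    "MOMENT_NAMES",
]

MOMENT_NAMES = ("mean", "std", "skewness", "kurtosis")

#: Fit model used per moment order when aggregating trends: the first two
#: moments are fitted linearly, the higher-order moments exponentially.
DEFAULT_FIT_MODELS = {
    "mean": "linear",
    "std": "linear",
    "skewness": "exponential",
    "kurtosis": "exponential",
}


@dataclass
class MomentSummary:
    """(mean, std, skewness, kurtosis) of one parameter map over a mask."""

    parameter_name: str
    mean: float
    std: float
    skewness: float | None
    kurtosis: float | None
    n_pixels: int
    meta: SampleMeta = field(default_factory=SampleMeta)

    def moment(self, name: str) -> float | None:
        if name not in MOMENT_NAMES:
            raise ValueError(f"unknown moment {name!r}")
        return getattr(self, name if name != "std" else "std")


def central_moments(
    values: np.ndarray,
    parameter_name: str = "",
    meta: SampleMeta | None = None,
) -> MomentSummary:
    """Population central moments of a flat value vector.

    ``values`` must be finite (sentinel/masked entries removed beforehand)
    and contain at least two points; skewness and kurtosis additionally
    require a nonzero standard deviation and are reported as ``None``
    (undefined) otherwise.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("central moments require at least 2 data points")
    if not np.all(np.isfinite(x)):
        raise ValueError("central moments require finite values; mask first")
    n = x.size
    mu = float(np.sum(x) / n)
    dev = x - mu
    sigma = float(math.sqrt(np.sum(dev**2) / n))
    if sigma > 0 and n >= 3:
        skew = float(np.sum(dev**3) / (n * sigma**3))
        kurt = float(np.sum(dev**4) / (n * sigma**4))
    else:
        skew = None
        kurt = None
    return MomentSummary(
        parameter_name=parameter_name,
        mean=mu,
        std=sigma,
        skewness=skew,
        kurtosis=kurt,
        n_pixels=n,
        meta=meta or SampleMeta(),
    )


@dataclass
class FitResult:
    """Trend-fit result for one moment-vs-age series."""

    model: str  # "linear" | "exponential"
    params: tuple[float, ...]  # (slope, intercept) or (alpha, beta, offset)
    residual_norm: float
    converged: bool
    status: str = "ok"

    @property
    def trend_sign(self) -> int:
        """Sign of the fitted derivative dy/dx (0 for a flat fit)."""
        if self.model == "linear":
            v = self.params[0]
        else:
            alpha, beta, _ = self.params
            v = alpha * beta
        if v > 0:
            return 1
        if v < 0:
            return -1
        return 0

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "linear":
            slope, intercept = self.params
            return slope * x + intercept
        alpha, beta, offset = self.params
        return alpha * np.exp(beta * x) + offset


def fit_linear(x: np.ndarray, y: np.ndarray) -> FitResult:
    """Ordinary least-squares line ``y = slope * x + intercept``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("linear fit requires at least 2 distinct x values")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return FitResult(
        model="linear",
        params=(float(slope), float(intercept)),
        residual_norm=float(np.linalg.norm(resid)),
        converged=True,
    )


def _exp_residuals(p: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    alpha, beta, offset = p
    return alpha * np.exp(np.clip(beta * x, -700, 700)) + offset - y


def fit_exponential(x: np.ndarray, y: np.ndarray) -> FitResult:
    """Nonlinear least squares for ``y = alpha * exp(beta * x) + offset``.

    Initialized from log-linear regressions on the shifted series (both
    orientations are tried and the lower-cost solution kept).  A constant
    series short-circuits to the offset-dominated degenerate fit.  The
    convergence flag is honest: a failed solve is returned as
    ``converged=False`` with the best iterate, never silently replaced.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("exponential fit requires at least 4 points")
    span = float(np.max(y) - np.min(y))
    scale = max(abs(float(np.mean(y))), span, 1e-12)
    if span < 1e-12 * scale:
        return FitResult(
            model="exponential",
            params=(0.0, 0.0, float(np.mean(y))),
            residual_norm=float(np.linalg.norm(y - np.mean(y))),
            converged=True,
            status="degenerate_constant",
        )

    shift = 0.05 * span
    starts: list[tuple[float, float, float]] = []
    # Rising orientation: log-linear fit of (y - min + shift).
    z = np.log(y - np.min(y) + shift)
    b1, a1 = np.polyfit(x, z, 1)
    starts.append((math.exp(a1), b1, float(np.min(y)) - shift))
    # Falling orientation: log-linear fit of (max - y + shift), alpha < 0.
    z = np.log(np.max(y) - y + shift)
    b2, a2 = np.polyfit(x, z, 1)
    starts.append((-math.exp(a2), b2, float(np.max(y)) + shift))
    # Near-linear fallback.
    slope, intercept = np.polyfit(x, y, 1)
    beta0 = 1.0 / max(np.ptp(x), 1.0)
    starts.append((slope / beta0 * math.exp(-beta0 * float(np.mean(x))), beta0,
                   float(intercept + slope * np.mean(x)) - slope / beta0))

    best = None
    for p0 in starts:
        try:
            sol = least_squares(
                _exp_residuals, p0, args=(x, y), method="lm", max_nfev=5000
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FitResult(
            model="exponential",
            params=starts[0],
            residual_norm=float(np.linalg.norm(_exp_residuals(np.array(starts[0]), x, y))),
            converged=False,
            status="solver_failure",
        )
    alpha, beta, offset = best.x
    return FitResult(
        model="exponential",
        params=(float(alpha), float(beta), float(offset)),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=bool(best.status > 0),
    )


def bootstrap_beta_interval(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 200,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Residual-bootstrap confidence interval for the exponential rate beta."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fit = fit_exponential(x, y)
    resid = y - fit.predict(x)
    rng = np.random.default_rng(seed)
    betas = []
    for _ in range(n_boot):
        y_star = fit.predict(x) + rng.choice(resid, size=resid.size, replace=True)
        try:
            betas.append(fit_exponential(x, y_star).params[1])
        except ValueError:
            continue
    lo, hi = np.quantile(betas, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


@dataclass
class GroupTrend:
    """Per-age aggregation of one parameter's moments, with trend fits."""

    parameter_name: str
    ages: list[int]
    group_means: dict[str, np.ndarray]  # moment -> value per age
    group_errors: dict[str, np.ndarray]  # across-sample std per age
    n_samples: dict[int, int]
    fits: dict[str, FitResult]


def moments_by_group(
    summaries: list[MomentSummary],
    fit_models: dict[str, str] | None = None,
) -> GroupTrend:
    """Group per-sample summaries by age and fit each moment against age.

    All summaries must describe the same parameter and wavelength.  Group
    means are arithmetic means across the samples of an age group; the
    across-sample standard deviation is reported as the error bar.
    """
    if not summaries:
        raise ValueError("moments_by_group requires at least one summary")
    params = {s.parameter_name for s in summaries}
    if len(params) != 1:
        raise ValueError(f"mixed parameters in one trend: {sorted(params)}")
    wavelengths = {s.meta.wavelength_nm for s in summaries}
    if len(wavelengths) != 1:
        raise ValueError(f"mixed wavelengths in one trend: {sorted(wavelengths)}")
    fit_models = {**DEFAULT_FIT_MODELS, **(fit_models or {})}

    ages = sorted({s.meta.age_days for s in summaries})
    group_means: dict[str, np.ndarray] = {}
    group_errors: dict[str, np.ndarray] = {}
    n_samples = {
        age: sum(1 for s in summaries if s.meta.age_days == age) for age in ages
    }
    for name in MOMENT_NAMES:
        means, errs = [], []
        for age in ages:
            vals = [
                getattr(s, name)
                for s in summaries
                if s.meta.age_days == age and getattr(s, name) is not None
            ]
            if not vals:
                raise ValueError(
                    f"no defined {name} values in age group {age} "
                    f"for parameter {summaries[0].parameter_name}"
                )
            means.append(float(np.mean(vals)))
            errs.append(float(np.std(vals)))
        group_means[name] = np.array(means)
        group_errors[name] = np.array(errs)

    fits: dict[str, FitResult] = {}
    x = np.array(ages, dtype=float)
    for name in MOMENT_NAMES:
        model = fit_models[name]
        if model not in ("linear", "exponential"):
            raise ValueError(f"unknown fit model {model!r} for moment {name}")
        if x.size < 2:
            continue  # a single age group carries no trend
        if model == "linear" or x.size < 4:
            fits[name] = fit_linear(x, group_means[name])
        else:
            fits[name] = fit_exponential(x, group_means[name])

    return GroupTrend(
        parameter_name=summaries[0].parameter_name,
        ages=[int(a) for a in ages],
        group_means=group_means,
        group_errors=group_errors,
        n_samples=n_samples,
        fits=fits,
    )


_ROW_LABELS = {"mean": "Mean", "std": "Std", "skewness": "Skew", "kurtosis": "Kurt"}


def trend_table(trends: list[GroupTrend]) -> pd.DataFrame:
    """Tabular report: one block per parameter, rows Mean/Std/Skew/Kurt,
    one column per age group (ascending)."""
    all_ages = sorted({a for t in trends for a in t.ages})
    records = []
    for t in trends:
        for name in MOMENT_NAMES:
            row: dict[str, object] = {
                "parameter": t.parameter_name,
                "moment": _ROW_LABELS[name],
            }
            for age in all_ages:
                if age in t.ages:
                    row[str(age)] = t.group_means[name][t.ages.index(age)]
                else:
                    row[str(age)] = np.nan
            records.append(row)
    return pd.DataFrame.from_records(records)


def render_trend_table(table: pd.DataFrame) -> str:
    """Plain-text rendering of :func:`trend_table` output."""
    out = io.StringIO()
    age_cols = [c for c in table.columns if c not in ("parameter", "moment")]
    header = f"{'':>10}" + "".join(f"{c:>10}" for c in age_cols)
    for param, block in table.groupby("parameter", sort=False):
        print(param, file=out)
        print(header, file=out)
        for _, row in block.iterrows():
            cells = "".join(
                f"{row[c]:>10.3f}" if np.isfinite(row[c]) else f"{'--':>10}"
                for c in age_cols
            )
            print(f"{row['moment']:>10}" + cells, file=out)
        print(file=out)
    return out.getvalue()


def parse_trend_table(csv_text: str) -> pd.DataFrame:
    """Read back a trend table written with ``DataFrame.to_csv(index=False)``."""
    return pd.read_csv(io.StringIO(csv_text))
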