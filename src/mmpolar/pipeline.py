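"""End-to-end orchestration: reconstruct -> normalize -> mask -> decompose ->
moments -> group trends -> reports, for a manifest of samples or an
in-memory phantom cohort.

The run is deterministic given the configuration (including seeds); a
structured run log records per-sample pixel counts, singular-pixel counts
and skip reasons, so input samples are always accounted for as
processed + skipped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as mmio
from .decomposition import decompose_image
from .moments import (
    MomentSummary,
    central_moments,
    moments_by_group,
    render_trend_table,
    trend_table,
)
from .phantom import PhantomSpec, iter_age_series
from .reconstruction import (
    IntensityStack,
    MuellerImage,
    normalize_by_m11,
    reconstruct_mueller,
    tissue_mask,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "analyze_stack"]

logger = logging.getLogger("mmpolar")

#: Parameter names the statistics layer accepts.
ANALYZABLE = ("m22", "m33", "m44", "D", "P", "R", "Delta")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    manifest: str | None = None  # path to a manifest.csv of measured samples
    phantom: PhantomSpec | None = None  # or: simulate this cohort in memory
    ages: tuple[int, ...] | None = None
    replicates: int = 3
    seed: int = 0

    parameters: tuple[str, ...] = ("m22", "m44", "Delta")
    roi_method: str = "percentile"
    roi_param: float = 50.0
    normalization_floor: float = 0.01
    fit_models: dict[str, str] | None = None
    out_dir: str | None = None
    write_maps: bool = False

    def validate(self) -> None:
        if (self.manifest is None) == (self.phantom is None):
            raise ValueError("configure exactly one of manifest or phantom")
        if not self.parameters:
            raise ValueError("parameters-to-analyze must be nonempty")
        unknown = [p for p in self.parameters if p not in ANALYZABLE]
        if unknown:
            raise ValueError(
                f"unknown parameter(s) {unknown}; choose from {ANALYZABLE}"
            )


@dataclass
class PipelineResult:
    """All artifacts of one run."""

    moments: pd.DataFrame  # one row per sample x parameter
    trends: pd.DataFrame  # fit parameters per parameter x moment
    table: pd.DataFrame  # age-group moment table (report layout)
    group_trends: dict  # parameter -> GroupTrend
    log: dict  # machine-readable run log

    def table_text(self) -> str:
        return render_trend_table(self.table)


def analyze_stack(
    stack: IntensityStack, config: RunConfig
) -> tuple[MuellerImage, dict[str, np.ndarray], np.ndarray, dict]:
    """Single-sample stage chain: reconstruction through parameter maps.

    Returns the normalized Mueller image, the parameter maps requested by the
    configuration, the ROI mask, and a per-sample log record.
    """
    recon = reconstruct_mueller(stack)
    norm = normalize_by_m11(recon, floor=config.normalization_floor)
    # ROI segmentation uses the unnormalized m11 (total transmittance) plane;
    # after normalization m11 is identically 1 and carries no contrast.
    roi = tissue_mask(recon, method=config.roi_method, param=config.roi_param)
    roi &= norm.mask

    maps: dict[str, np.ndarray] = {}
    element_params = [p for p in config.parameters if p.startswith("m")]
    scalar_params = [p for p in config.parameters if not p.startswith("m")]
    for p in element_params:
        i = int(p[1])
        maps[p] = norm.plane(i, int(p[2]))
    record = {
        "sample_id": stack.meta.sample_id,
        "n_pixels_valid": int(np.sum(norm.mask)),
        "n_pixels_roi": int(np.sum(roi)),
    }
    if scalar_params:
        decomp = decompose_image(norm)
        for p in scalar_params:
            maps[p] = decomp.as_dict()[p]
        record["n_singular"] = decomp.n_singular
        record["n_clamped"] = decomp.n_clamped
    return norm, maps, roi, record


def _iter_samples(config: RunConfig):
    if config.phantom is not None:
        ages = config.ages or None
        kwargs = {"replicates": config.replicates, "seed": config.seed}
        if ages:
            kwargs["ages"] = tuple(ages)
        for _spec, _gt, stack in iter_age_series(config.phantom, **kwargs):
            yield stack
    else:
        manifest = mmio.read_manifest(config.manifest)
        root = Path(config.manifest).parent
        for _, row in manifest.iterrows():
            path = Path(row["path"])
            if not path.is_absolute():
                path = root / path
            yield path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis over every sample of the configured input.

    Samples failing I/O or stage preconditions are skipped with a logged
    reason; an empty result set raises.
    """
    config.validate()
    summaries: list[MomentSummary] = []
    processed, skipped = [], []

    for item in _iter_samples(config):
        try:
            stack = item if isinstance(item, IntensityStack) else mmio.read_stack(item)
            norm, maps, roi, record = analyze_stack(stack, config)
            if not np.any(roi):
                raise ValueError("empty ROI mask; statistics refuse to run")
            for p, arr in maps.items():
                values = arr[roi & np.isfinite(arr)]
                summaries.append(central_moments(values, p, stack.meta))
            processed.append(record)
            if config.out_dir and config.write_maps:
                sample_out = Path(config.out_dir) / stack.meta.sample_id
                sample_out.mkdir(parents=True, exist_ok=True)
                mmio.write_mueller_image(sample_out / "mueller.tif", norm)
        except Exception as exc:  # per-sample isolation, reason logged
            name = getattr(item, "meta", None)
            name = name.sample_id if name is not None else str(item)
            logger.warning("skipping sample %s: %s", name, exc)
            skipped.append({"sample_id": name, "reason": str(exc)})

    if not processed:
        raise RuntimeError("no sample processed successfully")

    moments_rows = [
        {
            **s.meta.as_dict(),
            "parameter": s.parameter_name,
            "mean": s.mean,
            "std": s.std,
            "skewness": s.skewness,
            "kurtosis": s.kurtosis,
            "n_pixels": s.n_pixels,
        }
        for s in summaries
    ]
    moments_df = pd.DataFrame.from_records(moments_rows)

    group_trends = {}
    trend_rows = []
    for p in config.parameters:
        per_param = [s for s in summaries if s.parameter_name == p]
        trend = moments_by_group(per_param, fit_models=config.fit_models)
        group_trends[p] = trend
        for moment, fit in trend.fits.items():
            row = {
                "parameter": p,
                "moment": moment,
                "model": fit.model,
                "residual_norm": fit.residual_norm,
                "converged": fit.converged,
                "trend_sign": fit.trend_sign,
            }
            if fit.model == "linear":
                row["slope"], row["intercept"] = fit.params
            else:
                row["alpha"], row["beta"], row["offset"] = fit.params
            trend_rows.append(row)
    trends_df = pd.DataFrame.from_records(trend_rows)
    table = trend_table(list(group_trends.values()))

    log = {
        "software": f"mmpolar {__version__}",
        "config": _config_fingerprint(config),
        "n_input": len(processed) + len(skipped),
        "n_processed": len(processed),
        "n_skipped": len(skipped),
        "processed": processed,
        "skipped": skipped,
    }

    result = PipelineResult(
        moments=moments_df,
        trends=trends_df,
        table=table,
        group_trends=group_trends,
        log=log,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        moments_df.to_csv(out / "moments.csv", index=False)
        trends_df.to_csv(out / "trends.csv", index=False)
        table.to_csv(out / "moment_table.csv", index=False)
        (out / "moment_table.txt").write_text(result.table_text())
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
    return result


def _config_fingerprint(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("phantom") is not None:
        d["phantom"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in d["phantom"].items()
        }
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
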