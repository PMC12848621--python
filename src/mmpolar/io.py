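"""File I/O: intensity stacks, Mueller-image TIFFs, parameter maps, metadata.

Formats: single-channel TIFF for the 36 intensity images (16-bit with a
recorded count scale, or float32), multi-plane float32 TIFF for Mueller
images (plane order m11, m12, ..., m44, then the validity mask) and for the
phantom ground truth (16 Mueller planes + label plane), YAML for per-sample
metadata, CSV for manifests and statistics tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .decomposition import DecompositionMaps
from .reconstruction import IntensityStack, MuellerImage, SampleMeta, STATE_PAIRS

__all__ = [
    "read_stack",
    "write_stack",
    "write_sample",
    "write_manifest",
    "read_manifest",
    "write_mueller_image",
    "read_mueller_image",
    "write_decomposition_maps",
]

#: Fixed plane order of multi-plane Mueller TIFFs.
ELEMENT_ORDER = tuple(f"m{i}{j}" for i in range(1, 5) for j in range(1, 5))


def _meta_from_dict(d: dict) -> SampleMeta:
    return SampleMeta(
        sample_id=str(d.get("sample_id", "unknown")),
        age_days=int(d.get("age_days", 0)),
        wavelength_nm=int(d.get("wavelength_nm", 632)),
        preparation=str(d.get("preparation", "no_paraffin")),
    )


def write_stack(
    out_dir, stack: IntensityStack, dtype: str = "uint16", extra_meta: dict | None = None
) -> Path:
    """Write the 36 intensity images of one sample plus ``meta.yaml``.

    16-bit output records the count scale (counts per intensity unit) in the
    metadata so floating-point values survive the round trip up to
    quantization; ``dtype='float32'`` is lossless for float32 data.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sample_id = stack.meta.sample_id
    stack.validate()

    if dtype == "uint16":
        peak = max(float(np.max(img)) for img in stack.images.values())
        scale = 65535.0 / peak if peak > 0 else 1.0
    elif dtype == "float32":
        scale = 1.0
    else:
        raise ValueError("dtype must be uint16 or float32")

    for (g, a), img in stack.images.items():
        path = out_dir / f"{sample_id}_{g}{a}.tif"
        if dtype == "uint16":
            data = np.round(np.asarray(img) * scale).astype(np.uint16)
        else:
            data = np.asarray(img, dtype=np.float32)
        tifffile.imwrite(path, data)

    meta = {
        **stack.meta.as_dict(),
        "intensity_scale": float(scale),
        "dtype": dtype,
        "file_pattern": f"{sample_id}_{{G}}{{A}}.tif",
        **(extra_meta or {}),
    }
    with open(out_dir / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return out_dir


def read_stack(sample_dir) -> IntensityStack:
    """Read a sample directory written by :func:`write_stack`.

    Integer images are promoted to float64 raw counts; the recorded
    ``intensity_scale`` stays available in ``meta.yaml`` (reconstruction is
    scale-invariant after m11 normalization).  A missing state pair or a
    shape mismatch is reported by name.
    """
    sample_dir = Path(sample_dir)
    meta_path = sample_dir / "meta.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"no meta.yaml in {sample_dir}")
    with open(meta_path) as fh:
        meta_dict = yaml.safe_load(fh)
    meta = _meta_from_dict(meta_dict)
    pattern = meta_dict.get("file_pattern", f"{meta.sample_id}_{{G}}{{A}}.tif")

    images: dict[tuple[str, str], np.ndarray] = {}
    missing = []
    for g, a in STATE_PAIRS:
        path = sample_dir / pattern.format(G=g, A=a)
        if not path.exists():
            missing.append(g + a)
            continue
        images[(g, a)] = np.asarray(tifffile.imread(path), dtype=np.float64)
    if missing:
        raise FileNotFoundError(
            f"sample {meta.sample_id}: missing intensity image(s) for state "
            f"pair(s) {', '.join(missing)}"
        )
    stack = IntensityStack(images=images, meta=meta)
    stack.validate()
    return stack


def write_sample(out_root, spec, gt, stack: IntensityStack) -> Path:
    """Write one phantom sample: intensity stack, ground truth, truth moments."""
    out_root = Path(out_root)
    sample_dir = out_root / stack.meta.sample_id
    write_stack(
        sample_dir,
        stack,
        extra_meta={"seed": int(spec.seed), "noise_snr": float(spec.noise_snr)},
    )

    planes = [gt.mueller_map[:, :, i, j].astype(np.float32) for i in range(4) for j in range(4)]
    planes.append(gt.label_map.astype(np.float32))
    tifffile.imwrite(sample_dir / "ground_truth.tif", np.stack(planes))

    rows = []
    for name, summ in gt.true_moments.items():
        rows.append(
            {
                "parameter": name,
                "mean": summ.mean,
                "std": summ.std,
                "skewness": summ.skewness,
                "kurtosis": summ.kurtosis,
                "n_pixels": summ.n_pixels,
            }
        )
    pd.DataFrame.from_records(rows).to_csv(sample_dir / "truth_moments.csv", index=False)
    return sample_dir


def write_manifest(out_root, manifest: pd.DataFrame) -> Path:
    path = Path(out_root) / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_mueller_image(path, img: MuellerImage) -> Path:
    """Multi-plane float32 TIFF: 16 element planes in ELEMENT_ORDER + mask."""
    path = Path(path)
    planes = [
        img.elements[:, :, i, j].astype(np.float32) for i in range(4) for j in range(4)
    ]
    planes.append(img.mask.astype(np.float32))
    tifffile.imwrite(path, np.stack(planes))
    sidecar = {
        "planes": list(ELEMENT_ORDER) + ["mask"],
        "normalized": bool(img.normalized),
        **img.meta.as_dict(),
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    return path


def read_mueller_image(path) -> MuellerImage:
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=np.float64)
    if data.ndim != 3 or data.shape[0] != 17:
        raise ValueError(f"{path}: expected 17 planes (16 elements + mask)")
    with open(path.with_suffix(".yaml")) as fh:
        sidecar = yaml.safe_load(fh)
    elements = np.moveaxis(data[:16], 0, -1).reshape(data.shape[1], data.shape[2], 4, 4)
    return MuellerImage(
        elements=elements,
        normalized=bool(sidecar.get("normalized", False)),
        mask=data[16] > 0.5,
        meta=_meta_from_dict(sidecar),
    )


def write_decomposition_maps(out_dir, maps: DecompositionMaps, prefix: str = "") -> None:
    """One float32 TIFF per scalar map plus a value-convention sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, arr in maps.as_dict().items():
        tifffile.imwrite(out_dir / f"{prefix}{name}.tif", arr.astype(np.float32))
    sidecar = {
        "maps": {
            "D": "diattenuation magnitude, unitless in [0, 1]",
            "P": "polarizance magnitude, unitless in [0, 1]",
            "R": "retardance, radians in [0, pi]",
            "Delta": "depolarization power 1 - |tr(m_Delta)|/3, unitless in [0, 1]",
        },
        "masked_value": "NaN",
        "n_singular": int(maps.n_singular),
        "n_clamped": int(maps.n_clamped),
        **maps.meta.as_dict(),
    }
    with open(out_dir / f"{prefix}maps.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
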