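"""File formats, seeding, and provenance.

Schemes are stored as one CSV row per shot (positions, times, b-values,
analysis mask) plus a JSON sidecar carrying the configuration; the derived
W and TR matrices are re-computed on load from this single source of truth
and validated against checksums stored at write time.  Parameter columns
and shot signals are CSV; parameter volumes are NIfTI (one file per
parameter plus a label map) so they open in standard neuroimaging viewers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .phantoms import ParameterVolume
from .schemes import AcquisitionScheme, SchemeConfig, SchemeError
from .signal import ParameterColumn, ShotSignals

__all__ = [
    "SchemeIOError",
    "write_scheme",
    "read_scheme",
    "write_column",
    "read_column",
    "write_signals",
    "read_signals",
    "write_volume",
    "read_volume",
    "derive_seed",
    "provenance_record",
    "write_provenance",
]

logger = logging.getLogger("sero")

SCHEME_COLUMNS = ["shot", "time_s", "start_index", "k", "b_ms_per_um2", "analysis_mask"]


class SchemeIOError(ValueError):
    """A scheme file violates the format or fails validation."""


def _sidecar(path: Path) -> Path:
    return Path(path).with_suffix(".json")


def _matrix_checksum(arr: np.ndarray) -> str:
    """Stable checksum of a derived matrix (NaN/inf-safe)."""
    a = np.ascontiguousarray(np.nan_to_num(arr, nan=-1.0, posinf=-2.0), dtype=np.float64)
    return hashlib.sha256(np.round(a, 9).tobytes()).hexdigest()


def write_scheme(scheme: AcquisitionScheme, path) -> Path:
    """Write a scheme as CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "shot": np.arange(scheme.m),
            "time_s": scheme.shot_time,
            "start_index": scheme.start_index,
            "k": np.full(scheme.m, scheme.config.k if scheme.method != "direct" else 1),
            "b_ms_per_um2": scheme.b,
            "analysis_mask": scheme.analysis_mask.astype(int),
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "format": "sero-scheme",
        "version": 1,
        "method": scheme.method,
        "config": dataclasses.asdict(scheme.config),
        "checksums": {
            "W": _matrix_checksum(scheme.W),
            "TR": _matrix_checksum(scheme.TR),
        },
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_scheme(path) -> AcquisitionScheme:
    """Read a scheme CSV (+ JSON sidecar), re-deriving W and TR.

    The re-derived matrices are validated against the stored checksums when
    present.  A legacy file without an ``analysis_mask`` column defaults to
    all shots analyzed, with a logged warning.
    """
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    cfg_dict = dict(meta["config"])
    cfg_dict["b_levels"] = tuple(cfg_dict["b_levels"])
    config = SchemeConfig(**cfg_dict)
    method = meta["method"]
    df = pd.read_csv(path, float_precision="round_trip")
    for col in SCHEME_COLUMNS[:-1]:
        if col not in df.columns:
            raise SchemeIOError(f"{path}: missing required column {col!r}")
    if "analysis_mask" in df.columns:
        mask = df["analysis_mask"].to_numpy().astype(bool)
    else:
        logger.warning("%s: no analysis_mask column; defaulting to all shots", path)
        mask = np.ones(len(df), dtype=bool)
    start = df["start_index"].to_numpy(dtype=int)
    hi = config.n - config.k if method in ("sero", "direct") else config.n - 1
    bad = np.flatnonzero((start < 0) | (start > hi))
    if bad.size:
        raise SchemeIOError(
            f"{path}: row {bad[0]}: start_index {start[bad[0]]} outside [0, {hi}]"
        )
    try:
        scheme = AcquisitionScheme.from_shots(
            config,
            method,
            start,
            df["b_ms_per_um2"].to_numpy(dtype=float),
            df["time_s"].to_numpy(dtype=float),
            mask,
        )
    except SchemeError as exc:
        raise SchemeIOError(f"{path}: {exc}") from exc
    stored = meta.get("checksums")
    if stored:
        derived = {"W": _matrix_checksum(scheme.W), "TR": _matrix_checksum(scheme.TR)}
        for key, want in stored.items():
            if derived.get(key) != want:
                raise SchemeIOError(
                    f"{path}: re-derived {key} matrix does not match stored checksum"
                )
    return scheme


# ---------------------------------------------------------------------------
# columns and signals


def write_column(params: ParameterColumn, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "position": np.arange(params.n),
            "S0": params.s0,
            "D": params.d,
            "V": params.v,
            "T1": params.t1,
        }
    ).to_csv(path, index=False)
    return path


def read_column(path) -> ParameterColumn:
    df = pd.read_csv(path, float_precision="round_trip")
    return ParameterColumn(
        df["S0"].to_numpy(), df["D"].to_numpy(), df["V"].to_numpy(), df["T1"].to_numpy()
    )


def write_signals(signals: ShotSignals, path, scheme_path=None) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"shot": np.arange(signals.m), "magnitude": signals.values}
    ).to_csv(path, index=False)
    meta = {
        "format": "sero-signals",
        "noiseless": signals.noiseless,
        "sigma": signals.sigma,
        "seed": signals.seed,
        "scheme": str(scheme_path) if scheme_path else None,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_signals(path) -> ShotSignals:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = _sidecar(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ShotSignals(
        df["magnitude"].to_numpy(dtype=float),
        noiseless=bool(meta.get("noiseless", False)),
        sigma=float(meta.get("sigma", 0.0)),
        seed=meta.get("seed"),
    )


# ---------------------------------------------------------------------------
# volumes (NIfTI)

VOLUME_KEYS = ("s0", "d", "v", "t1")


def write_volume(volume: ParameterVolume, out_dir, prefix: str = "map") -> Path:
    """Write one NIfTI per parameter plus the label map and a JSON sidecar."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([volume.voxel_size] * 3 + [1.0])
    for name, arr in volume.items():
        nib.save(
            nib.Nifti1Image(arr.astype(np.float64), affine),
            out_dir / f"{prefix}_{name}.nii",
        )
    nib.save(
        nib.Nifti1Image(volume.labels.astype(np.int16), affine),
        out_dir / f"{prefix}_labels.nii",
    )
    meta = {
        "format": "sero-volume",
        "voxel_size_mm": volume.voxel_size,
        "through_slice_axis": 2,
        "shape": list(volume.shape),
    }
    (out_dir / f"{prefix}.json").write_text(json.dumps(meta, indent=2))
    return out_dir


def read_volume(in_dir, prefix: str = "map") -> ParameterVolume:
    """Read a parameter volume written by :func:`write_volume`.

    Images are reoriented to canonical axis order using their affine before
    use, so axis-permuted inputs are handled transparently.  Inconsistent
    voxel sizes across the parameter images are an error.
    """
    import nibabel as nib

    in_dir = Path(in_dir)
    meta_path = in_dir / f"{prefix}.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing volume sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    arrays = {}
    zooms = None
    for name in VOLUME_KEYS + ("labels",):
        img = nib.as_closest_canonical(nib.load(in_dir / f"{prefix}_{name}.nii"))
        z = tuple(round(float(x), 6) for x in img.header.get_zooms()[:3])
        if zooms is None:
            zooms = z
        elif z != zooms:
            raise ValueError(f"inconsistent voxel sizes across volume files: {z} vs {zooms}")
        arrays[name] = np.asarray(img.dataobj)
    if abs(zooms[0] - float(meta["voxel_size_mm"])) > 1e-6:
        raise ValueError("voxel size in NIfTI header disagrees with sidecar metadata")
    return ParameterVolume(
        s0=arrays["s0"].astype(float),
        d=arrays["d"].astype(float),
        v=arrays["v"].astype(float),
        t1=arrays["t1"].astype(float),
        labels=arrays["labels"].astype(np.int8),
        voxel_size=float(meta["voxel_size_mm"]),
    )


# ---------------------------------------------------------------------------
# seeding and provenance


def derive_seed(base_seed: int, *parts) -> int:
    """Derive a named-substream seed from a global seed, deterministically.

    ``parts`` may mix integers and strings (strings are CRC32-hashed); the
    result is a non-negative integer below 2**31 suitable for any NumPy
    generator.  Distinct part tuples give independent streams.
    """
    entropy = [int(base_seed) & 0xFFFFFFFF]
    for p in parts:
        if isinstance(p, str):
            entropy.append(zlib.crc32(p.encode()))
        else:
            entropy.append(int(p) & 0xFFFFFFFF)
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def provenance_record(config: dict, seeds: dict | None = None) -> dict:
    """Assemble a provenance record sufficient to reproduce a run."""
    import datetime
    import platform

    import scipy

    from . import __version__

    return {
        "sero_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "python_version": platform.python_version(),
        "config": config,
        "seeds": seeds or {},
        "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


def write_provenance(path, config: dict, seeds: dict | None = None) -> Path:
    path = Path(path)
    path.write_text(json.dumps(provenance_record(config, seeds), indent=2))
    return path
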