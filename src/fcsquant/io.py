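"""Readers and writers binding the pipeline stages together.

Formats are deliberately plain: two-column delimited text for traces,
CSV for correlation curves and per-cell tables, JSON for fit and
calibration artifacts, 16-bit grayscale TIFF for images and label-image
TIFF for masks.  Every writer embeds enough provenance to regenerate the
artifact; every numeric field round-trips at full precision (counts
exactly, floats at 17 significant digits).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd
import tifffile

from .correlate import CorrelationCurve
from .model import FcsModelParams, FitResult, VolumeCalibration
from .traces import IntensityTrace

__all__ = [
    "write_trace", "read_trace",
    "write_curve", "read_curve",
    "write_fit", "read_fit",
    "write_calibration", "read_calibration",
    "write_image", "read_image",
    "write_table", "read_table",
]

PathLike = Union[str, Path]


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# -- traces -----------------------------------------------------------------


def write_trace(path: PathLike, trace: IntensityTrace) -> None:
    """Two-column text: time (s) and counts, with a JSON metadata header."""
    path = Path(path)
    header = json.dumps(
        _jsonify({"bin_width": trace.bin_width, "metadata": trace.metadata})
    )
    with path.open("w") as fh:
        fh.write(f"# fcsquant-trace {header}\n")
        fh.write("# time_s\tcounts\n")
        bw = trace.bin_width
        for i, c in enumerate(trace.counts):
            fh.write(f"{i * bw:.9e}\t{int(c)}\n")


def read_trace(path: PathLike) -> IntensityTrace:
    path = Path(path)
    bin_width = None
    metadata: dict[str, Any] = {}
    counts = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# fcsquant-trace "):
                    head = json.loads(line[len("# fcsquant-trace "):])
                    bin_width = head["bin_width"]
                    metadata = head.get("metadata", {})
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            try:
                counts.append(int(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad counts field") from exc
    if bin_width is None:
        raise ValueError(f"{path}: missing fcsquant-trace header")
    return IntensityTrace(np.array(counts, dtype=np.int64), bin_width, metadata)


# -- correlation curves -----------------------------------------------------


def write_curve(path: PathLike, curve: CorrelationCurve) -> None:
    """CSV with columns lag_s, g, g_err, n."""
    df = pd.DataFrame(
        {
            "lag_s": curve.lags,
            "g": curve.g,
            "g_err": curve.g_err if curve.g_err is not None
            else np.full(len(curve), np.nan),
            "n": curve.n_samples if curve.n_samples is not None
            else np.zeros(len(curve), dtype=int),
        }
    )
    with Path(path).open("w") as fh:
        fh.write(f"# fcsquant-curve {json.dumps(_jsonify(curve.source))}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_curve(path: PathLike) -> CorrelationCurve:
    path = Path(path)
    source: dict[str, Any] = {}
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# fcsquant-curve "):
            source = json.loads(first[len("# fcsquant-curve "):])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, comment="#")
    for col in ("lag_s", "g"):
        if col not in df:
            raise ValueError(f"{path}: missing column {col!r}")
    g_err = df["g_err"].to_numpy() if "g_err" in df else None
    if g_err is not None and np.all(np.isnan(g_err)):
        g_err = None
    n = df["n"].to_numpy() if "n" in df else None
    return CorrelationCurve(
        df["lag_s"].to_numpy(), df["g"].to_numpy(), g_err, n, source
    )


# -- fits and calibrations --------------------------------------------------


def write_fit(path: PathLike, fit: FitResult,
              extra: Optional[dict[str, Any]] = None) -> None:
    """Fit report as JSON: parameters, stderrs, diagnostics, extras."""
    payload = {
        "params": fit.params.as_dict(),
        "stderrs": fit.stderrs,
        "chi_square": fit.chi_square,
        "reduced_chi_square": fit.reduced_chi_square,
        "converged": fit.converged,
        "fixed_params": list(fit.fixed_params),
        "message": fit.message,
        "lags": fit.lags,
        "residuals": fit.residuals,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(_jsonify(payload), indent=1))


def read_fit(path: PathLike) -> tuple[FitResult, dict[str, Any]]:
    """Load a fit JSON; returns the FitResult and any extra fields."""
    payload = json.loads(Path(path).read_text())
    known = {
        "params", "stderrs", "chi_square", "reduced_chi_square",
        "converged", "fixed_params", "message", "lags", "residuals",
    }
    fit = FitResult(
        params=FcsModelParams(**payload["params"]),
        stderrs=payload["stderrs"],
        residuals=np.asarray(payload["residuals"], dtype=float),
        chi_square=payload["chi_square"],
        reduced_chi_square=payload["reduced_chi_square"],
        converged=payload["converged"],
        fixed_params=tuple(payload["fixed_params"]),
        message=payload.get("message", ""),
        lags=np.asarray(payload["lags"], dtype=float),
    )
    extra = {k: v for k, v in payload.items() if k not in known}
    return fit, extra


def write_calibration(path: PathLike, cal: VolumeCalibration) -> None:
    Path(path).write_text(json.dumps(_jsonify(dataclasses.asdict(cal)), indent=1))


def read_calibration(path: PathLike) -> VolumeCalibration:
    return VolumeCalibration(**json.loads(Path(path).read_text()))


# -- images -----------------------------------------------------------------


def write_image(path: PathLike, pixels: np.ndarray,
                masks: Optional[np.ndarray] = None,
                mask_path: Optional[PathLike] = None) -> None:
    """16-bit grayscale TIFF; masks as a separate label-image TIFF."""
    tifffile.imwrite(Path(path), np.asarray(pixels, dtype=np.uint16))
    if masks is not None:
        if mask_path is None:
            p = Path(path)
            mask_path = p.with_name(p.stem + "_masks" + p.suffix)
        tifffile.imwrite(Path(mask_path), np.asarray(masks, dtype=np.uint16))


def read_image(path: PathLike) -> np.ndarray:
    return tifffile.imread(Path(path))


# -- tables -----------------------------------------------------------------


def write_table(path: PathLike, df: pd.DataFrame) -> None:
    df.to_csv(Path(path), index=False, float_format="%.17g")


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(Path(path))
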