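"""Readers and writers for landmark configurations and analysis results.

Supported formats: a simple labelled CSV dialect (``label,x,y,z``), the
classic TPS landmark format of geometric morphometrics (``LM``/``LM3``
blocks), ASCII PLY point clouds for dysmorphogram viewing, a CSV bilateral
correspondence map, and a self-describing JSON archive for PDMs.
Coordinates are millimetres in a right-handed frame; nothing is flipped or
rescaled on read.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    PDM,
    BilateralMap,
    Configuration,
    Dysmorphogram,
    LandmarkParseError,
)

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_bilateral_map",
    "write_bilateral_map",
    "write_dysmorphogram",
    "save_pdm",
    "load_pdm",
]

PDM_FORMAT_TAG = "dysmorph-pdm-1"


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "tps", "ply"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def read_landmarks(path, format: str | None = None):
    """Read a landmark file into one Configuration (or a list for multi-specimen TPS).

    CSV dialect: header ``label,x,y,z`` (or ``label,x,y``), one row per
    landmark, file order preserved.  TPS: standard ``LM=``/``LM3=`` blocks;
    labels are synthesized as ``lm0000`` ... in block order since TPS carries
    none.  Malformed rows raise :class:`LandmarkParseError` with the line
    number.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "tps":
        return _read_tps(path)
    raise ValueError(f"unsupported landmark format {fmt!r}")


def _read_csv(path: Path) -> Configuration:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise LandmarkParseError(f"{path}: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "label" not in cols or "x" not in cols or "y" not in cols:
        raise LandmarkParseError(
            f"{path}: expected header label,x,y[,z]; got {list(df.columns)}"
        )
    axes = ["x", "y", "z"] if "z" in cols else ["x", "y"]
    coords = df[axes].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        row = int(np.argwhere(~np.isfinite(coords))[0, 0]) + 2  # header is line 1
        raise LandmarkParseError(f"{path}: non-finite coordinate at line {row}")
    labels = [str(l) for l in df["label"]]
    if len(set(labels)) != len(labels):
        dup = next(l for l in labels if labels.count(l) > 1)
        raise LandmarkParseError(f"{path}: duplicate landmark label {dup!r}")
    return Configuration(coords, labels)


def _read_tps(path: Path):
    configs: list[Configuration] = []
    block: list[np.ndarray] = []
    expected = dim = 0
    start_line = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                if block or expected:
                    configs.append(
                        _close_tps_block(path, block, expected, dim, start_line)
                    )
                    block = []
                dim = 3 if upper.startswith("LM3") else 2
                try:
                    expected = int(line.split("=", 1)[1])
                except ValueError:
                    raise LandmarkParseError(
                        f"{path}:{lineno}: malformed count record {line!r}"
                    ) from None
                start_line = lineno
            elif "=" in line and not _is_coords(line):
                continue  # ID=, IMAGE=, SCALE= and friends
            else:
                parts = line.split()
                if len(parts) != dim:
                    raise LandmarkParseError(
                        f"{path}:{lineno}: expected {dim} coordinates, got {len(parts)}"
                    )
                try:
                    block.append(np.array([float(p) for p in parts]))
                except ValueError:
                    raise LandmarkParseError(
                        f"{path}:{lineno}: non-numeric coordinate in {line!r}"
                    ) from None
    if block or expected:
        configs.append(_close_tps_block(path, block, expected, dim, start_line))
    if not configs:
        raise LandmarkParseError(f"{path}: no landmark blocks found")
    if any(c.dim == 2 for c in configs):
        warnings.warn(f"{path}: 2D TPS data read; z coordinate set to 0")
        configs = [
            c if c.dim == 3 else Configuration(
                np.column_stack([c.coords, np.zeros(c.n_landmarks)]), c.labels
            )
            for c in configs
        ]
    return configs[0] if len(configs) == 1 else configs


def _is_coords(line: str) -> bool:
    try:
        [float(p) for p in line.split()]
        return True
    except ValueError:
        return False


def _close_tps_block(path, block, expected, dim, start_line) -> Configuration:
    if len(block) != expected:
        raise LandmarkParseError(
            f"{path}:{start_line}: block declares {expected} landmarks "
            f"but contains {len(block)}"
        )
    coords = np.stack(block)
    labels = [f"lm{i:04d}" for i in range(len(block))]
    return Configuration(coords, labels)


def write_landmarks(config: Configuration, path, format: str | None = None) -> None:
    """Write a configuration as labelled CSV or as a single-specimen TPS block."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        axes = ["x", "y", "z"][: config.dim]
        df = pd.DataFrame(config.coords, columns=axes)
        df.insert(0, "label", list(config.labels))
        df.to_csv(path, index=False, float_format="%.12g")
    elif fmt == "tps":
        key = "LM3" if config.dim == 3 else "LM"
        with open(path, "w") as fh:
            fh.write(f"{key}={config.n_landmarks}\n")
            for row in config.coords:
                fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")
            fh.write("ID=0\n")
    else:
        raise ValueError(f"unsupported landmark format {fmt!r}")


def read_bilateral_map(path) -> BilateralMap:
    """Read a CSV with columns ``left,right``; rows with left == right are midline."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "left" not in df.columns or "right" not in df.columns:
        raise LandmarkParseError(f"{path}: expected header left,right")
    pairs, midline = [], []
    for left, right in zip(df["left"], df["right"]):
        left, right = str(left), str(right)
        if left == right:
            midline.append(left)
        else:
            pairs.append((left, right))
    return BilateralMap(tuple(pairs), tuple(midline))


def write_bilateral_map(bmap: BilateralMap, path) -> None:
    rows = [{"left": a, "right": b} for a, b in bmap.pairs]
    rows += [{"left": m, "right": m} for m in bmap.midline]
    pd.DataFrame(rows, columns=["left", "right"]).to_csv(path, index=False)


def write_dysmorphogram(
    dg: Dysmorphogram, config: Configuration, path, format: str | None = None
) -> None:
    """Serialize a dysmorphogram painted onto its configuration.

    CSV columns: ``label,x,y,z,score,magnitude_mm``.  PLY: an ASCII point
    cloud with a per-vertex ``quality`` property holding the outlier score,
    for external viewers.
    """
    if dg.labels != config.labels:
        raise ValueError("dysmorphogram and configuration are not aligned")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        axes = ["x", "y", "z"][: config.dim]
        df = pd.DataFrame(config.coords, columns=axes)
        df.insert(0, "label", list(config.labels))
        df["score"] = dg.scores
        df["magnitude_mm"] = dg.magnitudes
        df.to_csv(path, index=False, float_format="%.12g")
    elif fmt == "ply":
        coords = config.coords
        if config.dim == 2:
            coords = np.column_stack([coords, np.zeros(len(coords))])
        with open(path, "w") as fh:
            fh.write(
                "ply\nformat ascii 1.0\n"
                f"element vertex {config.n_landmarks}\n"
                "property float x\nproperty float y\nproperty float z\n"
                "property float quality\nend_header\n"
            )
            for row, score in zip(coords, dg.scores):
                fh.write(f"{row[0]:.6f} {row[1]:.6f} {row[2]:.6f} {score:.6f}\n")
    else:
        raise ValueError(f"unsupported dysmorphogram format {fmt!r}")


def save_pdm(pdm: PDM, path) -> None:
    """Write a PDM as a versioned, self-describing JSON archive (full precision)."""
    payload = {
        "format": PDM_FORMAT_TAG,
        "dim": pdm.dim,
        "labels": list(pdm.labels),
        "consensus": pdm.consensus.coords.tolist(),
        "modes": pdm.modes.tolist(),
        "mode_sd": pdm.mode_sd.tolist(),
        "variance_fraction": pdm.variance_fraction,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_pdm(path) -> PDM:
    with open(path) as fh:
        payload = json.load(fh)
    tag = payload.get("format")
    if tag != PDM_FORMAT_TAG:
        raise ValueError(f"{path}: not a PDM archive (format tag {tag!r})")
    consensus = Configuration(
        np.asarray(payload["consensus"], dtype=float), payload["labels"]
    )
    return PDM(
        consensus,
        np.asarray(payload["modes"], dtype=float),
        np.asarray(payload["mode_sd"], dtype=float),
        float(payload["variance_fraction"]),
    )
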