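"""Reading and writing the pipeline's on-disk formats.

B-scan stacks travel as multi-page TIFF (or a PNG-per-frame directory)
with a JSON sidecar ``{timestamps_s, axial_spacing_um_per_px, on_region}``;
waveform stages as two-column CSV plus a JSON parameter sidecar; subject
tables as CSV with the canonical column set; ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .datatypes import BScanSequence, ThicknessWaveform
from .synthetic import GroundTruth

__all__ = [
    "write_bscan_stack",
    "read_bscan_stack",
    "write_ground_truth",
    "read_ground_truth",
    "write_waveform",
    "read_waveform",
]

SIDECAR_SUFFIX = ".sidecar.json"


def _sidecar_path(stack_path: Path) -> Path:
    return stack_path.parent / (stack_path.stem + SIDECAR_SUFFIX)


def write_bscan_stack(seq: BScanSequence, path) -> Path:
    """Write a sequence as multi-page TIFF (or PNG directory) + JSON sidecar.

    A path ending in ``.tif``/``.tiff`` produces one multi-page 8-bit
    grayscale TIFF; any other path is treated as a directory receiving
    ``frame_0000.png`` etc.  Returns the sidecar path.
    """
    path = Path(path)
    frames8 = np.clip(seq.frames, 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, frames8, photometric="minisblack")
        sidecar = _sidecar_path(path)
    else:
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        for i, fr in enumerate(frames8):
            iio.imwrite(path / f"frame_{i:04d}.png", fr)
        sidecar = path / ("stack" + SIDECAR_SUFFIX)
    meta = {
        "timestamps_s": seq.timestamps_s.tolist(),
        "axial_spacing_um_per_px": seq.axial_spacing_um_per_px,
        "on_region": list(seq.on_region),
    }
    sidecar.write_text(json.dumps(meta))
    return sidecar


def read_bscan_stack(path) -> BScanSequence:
    """Load a stack written by :func:`write_bscan_stack`.

    The sidecar must be present and carry timestamps for every frame;
    mismatches raise with the offending counts named rather than assuming
    uniform timing.
    """
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        frame_files = sorted(path.glob("frame_*.png"))
        if not frame_files:
            raise FileNotFoundError(f"no frame_*.png files under {path}")
        frames = np.stack([iio.imread(f) for f in frame_files])
        sidecar = path / ("stack" + SIDECAR_SUFFIX)
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar {sidecar} missing")
    meta = json.loads(sidecar.read_text())
    for key in ("timestamps_s", "axial_spacing_um_per_px", "on_region"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing required key {key!r}")
    ts = np.asarray(meta["timestamps_s"], dtype=float)
    if ts.size != frames.shape[0]:
        raise ValueError(
            f"sidecar has {ts.size} timestamps but stack has {frames.shape[0]} frames"
        )
    return BScanSequence(
        frames=frames.astype(np.float32),
        timestamps_s=ts,
        axial_spacing_um_per_px=float(meta["axial_spacing_um_per_px"]),
        on_region=tuple(meta["on_region"]),
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(
            {
                "cht_um_per_frame": truth.cht_um_per_frame.tolist(),
                "true_delta_t_um": truth.true_delta_t_um,
                "timestamps_s": truth.timestamps_s.tolist(),
            }
        )
    )


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_waveform(wf: ThicknessWaveform, path) -> None:
    """Waveform stage as CSV (time_s, cht_um) + JSON parameter sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": wf.times_s, "cht_um": wf.cht_um}).to_csv(path, index=False)
    meta = {
        "stage": wf.stage,
        "sample_rate_hz": wf.sample_rate_hz,
        "heart_rate_hz": wf.heart_rate_hz,
        "delta_t_um": wf.delta_t_um,
        "params": {k: v for k, v in wf.params.items() if _jsonable(v)},
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def read_waveform(path, stage: Optional[str] = None) -> ThicknessWaveform:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ThicknessWaveform(
        stage=stage or meta.get("stage", "raw"),
        times_s=df["time_s"].to_numpy(),
        cht_um=df["cht_um"].to_numpy(),
        sample_rate_hz=meta.get("sample_rate_hz"),
        heart_rate_hz=meta.get("heart_rate_hz"),
        delta_t_um=meta.get("delta_t_um"),
        params=meta.get("params", {}),
    )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
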