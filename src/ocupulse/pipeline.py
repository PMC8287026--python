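"""End-to-end run: stack -> segmentation -> waveform -> rigidity -> report.

Each run writes its stage artifacts plus a machine-readable manifest
(config hash, seed, package and dependency versions) so the outputs are
reproducible from the manifest alone, and logs the five scientific
observables at stage boundaries: usable frames, heart rate, delta-t,
delta-V, and k.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, io, rigidity, segmentation, stats, waveform
from .config import PipelineConfig, config_hash
from .datatypes import CohortTable, SubjectRecord

logger = logging.getLogger("ocupulse")

__all__ = ["run_pipeline", "process_stack", "compute_cohort"]


def process_stack(stack_path, config: Optional[PipelineConfig] = None, out_dir=None):
    """Segment a stack and extract delta-t; returns the filtered waveform.

    Writes the raw and filtered waveform CSVs under ``out_dir`` when given.
    """
    cfg = config or PipelineConfig()
    try:
        seq = io.read_bscan_stack(stack_path)
    except (OSError, ValueError) as e:
        raise RuntimeError(f"[read] {e}") from e
    try:
        raw_wf, seg = segmentation.segment_sequence(seq, cfg.segmentation)
    except (segmentation.FrameUnusableError, ValueError) as e:
        raise RuntimeError(f"[segment] {e}") from e
    logger.info(
        "segment: %d/%d usable frames", int(seg.usable.sum()), seq.n_frames
    )
    try:
        filtered = waveform.extract_delta_t(raw_wf, cfg.waveform)
    except ValueError as e:
        raise RuntimeError(f"[waveform] {e}") from e
    logger.info(
        "waveform: HR %.3f Hz, delta-t %.3f um",
        filtered.heart_rate_hz, filtered.delta_t_um,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        io.write_waveform(raw_wf, out_dir / "waveform_raw.csv")
        io.write_waveform(filtered, out_dir / "waveform_filtered.csv")
    return filtered, seg


def compute_cohort(table: CohortTable, config: Optional[PipelineConfig] = None) -> CohortTable:
    """Fill derived biomechanics for every subject in a table."""
    cfg = config or PipelineConfig()
    out = []
    for rec in table:
        out.append(
            rigidity.compute_subject(
                rec,
                volume_model=cfg.model.volume_model,
                eye_constants=cfg.model.schematic_eye,
            )
        )
    return CohortTable(out)


def run_pipeline(
    stack_path,
    subjects_csv,
    out_dir,
    config: Optional[PipelineConfig] = None,
    subject_id: Optional[str] = None,
) -> dict:
    """Full reproducible run over one B-scan video and a subject table.

    The video's delta-t is attached to ``subject_id`` (or to the only
    subject when the table has a single row); all subjects with a delta-t
    then get derived volumes, rigidity and stiffness, and the cohort report
    is built when at least one group comparison or correlation is possible.
    Partial outputs are kept on stage failure.
    """
    cfg = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    filtered, seg = process_stack(stack_path, cfg, out_dir)

    table = CohortTable.from_csv(subjects_csv)
    if subject_id is None:
        if len(table) == 1:
            subject_id = table.records[0].subject_id
        else:
            raise RuntimeError(
                "[rigidity] subject_id required when the table has several rows"
            )
    matched = False
    for rec in table:
        if rec.subject_id == subject_id:
            rec.delta_t_um = float(filtered.delta_t_um)
            matched = True
    if not matched:
        raise RuntimeError(f"[rigidity] subject {subject_id!r} not in table")

    derivable = [r for r in table if r.delta_t_um is not None]
    derived = compute_cohort(CohortTable(derivable), cfg)
    derived.to_csv(out_dir / "subjects_derived.csv")
    target = next(r for r in derived if r.subject_id == subject_id)
    logger.info(
        "rigidity: delta-V %.3f uL, k %.5f 1/uL", target.dv_ul, target.k_per_ul
    )

    report = None
    if len(derived) >= 3:
        try:
            report = stats.build_report(
                derived,
                alpha=cfg.stats.alpha,
                exact_threshold=cfg.stats.exact_threshold,
                holm_adjust=cfg.stats.holm_adjust,
            )
            for name, df in report.items():
                df.to_csv(out_dir / f"report_{name}.csv", index=False)
            (out_dir / "report.md").write_text(stats.report_to_markdown(report))
        except ValueError as e:
            logger.warning("stats skipped: %s", e)

    manifest = {
        "ocupulse_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
        "config_hash": config_hash(cfg),
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "stack_path": str(stack_path),
        "subjects_csv": str(subjects_csv),
        "subject_id": subject_id,
        "observables": {
            "n_frames_usable": int(seg.usable.sum()),
            "heart_rate_hz": float(filtered.heart_rate_hz),
            "delta_t_um": float(filtered.delta_t_um),
            "dv_ul": float(target.dv_ul),
            "k_per_ul": float(target.k_per_ul),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
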