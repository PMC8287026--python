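"""Core containers shared across the pipeline stages.

Conventions: image arrays are (depth, width) with row index 0 at the
vitreous side and depth increasing posteriorly; columns are A-scans;
column intervals are half-open ``[lo, hi)``; all coordinates 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class BScanSequence:
    """Time-stamped stack of grayscale B-scan frames.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, depth, width)
        Grayscale intensities.
    timestamps_s : ndarray, shape (n_frames,)
        Acquisition time of each frame, strictly increasing, seconds.
    axial_spacing_um_per_px : float
        Physical depth of one pixel row, micrometres.
    on_region : tuple (lo, hi)
        Half-open column interval covering the optic-nerve head; these
        A-scans are excluded from all segmentation and thickness math.
    """

    frames: np.ndarray
    timestamps_s: np.ndarray
    axial_spacing_um_per_px: float
    on_region: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, depth, width) stack")
        if len(self.timestamps_s) != self.n_frames:
            raise ValueError(
                f"{len(self.timestamps_s)} timestamps for {self.n_frames} frames"
            )
        if self.n_frames >= 2 and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.axial_spacing_um_per_px <= 0:
            raise ValueError("axial_spacing_um_per_px must be positive")
        lo, hi = self.on_region
        if not (0 <= lo <= hi <= self.width):
            raise ValueError(f"on_region {self.on_region} outside [0, {self.width}]")
        self.on_region = (int(lo), int(hi))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def depth(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def included_columns(self) -> np.ndarray:
        """Column indices outside the optic-nerve exclusion region."""
        lo, hi = self.on_region
        return np.concatenate([np.arange(0, lo), np.arange(hi, self.width)])


@dataclass
class SegmentationResult:
    """Per-frame RPE and CSI depth profiles plus mean choroidal thickness.

    ``rpe_depth_px`` and ``csi_depth_px`` are (n_frames, width) float arrays;
    NaN marks excluded or undetermined columns.  ``cht_um`` is NaN for frames
    marked unusable; ``usable`` records which frames produced a thickness and
    ``drop_reasons`` why the others did not.
    """

    rpe_depth_px: np.ndarray
    csi_depth_px: np.ndarray
    cht_um: np.ndarray
    usable: np.ndarray
    drop_reasons: dict[int, str] = field(default_factory=dict)
    node_candidates: Optional[list] = None


@dataclass
class ThicknessWaveform:
    """A (time, choroidal thickness) series at one processing stage.

    Stages form a provenance chain: ``raw`` -> ``cleaned`` -> ``uniform``
    -> ``filtered``; each stage keeps a reference to its parent together
    with the parameters that produced it, so a filtered waveform can be
    audited back to the raw segmentation output.
    """

    stage: str
    times_s: np.ndarray
    cht_um: np.ndarray
    sample_rate_hz: Optional[float] = None
    heart_rate_hz: Optional[float] = None
    delta_t_um: Optional[float] = None
    params: dict = field(default_factory=dict)
    parent: Optional["ThicknessWaveform"] = None

    _STAGES = ("raw", "cleaned", "uniform", "filtered")

    def __post_init__(self) -> None:
        if self.stage not in self._STAGES:
            raise ValueError(f"stage must be one of {self._STAGES}")
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.cht_um = np.asarray(self.cht_um, dtype=float)
        if self.times_s.shape != self.cht_um.shape:
            raise ValueError("times_s and cht_um must have the same length")
        if len(self.times_s) >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")
        if self.delta_t_um is not None and self.delta_t_um < 0:
            raise ValueError("delta_t_um must be non-negative")

    def lineage(self) -> list["ThicknessWaveform"]:
        """Chain of stages from raw to this stage, oldest first."""
        chain: list[ThicknessWaveform] = []
        node: Optional[ThicknessWaveform] = self
        while node is not None:
            chain.append(node)
            node = node.parent
        return chain[::-1]


# Columns of a subject table, in canonical CSV order.  Measured quantities
# first, then the derived biomechanical outputs.
SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "age_years",
    "iop_mmhg",
    "opa_mmhg",
    "acv_ul",
    "cct_um",
    "corneal_radius_mm",
    "refraction_se_d",
    "heart_rate_hz",
    "al_mm",
    "ap1_adj_mmhg",
    "biop_mmhg",
    "delta_a1_mm",
    "delta_hc_mm",
    "delta_t_um",
    "dv_ul",
    "k_per_ul",
    "sp_a1",
    "sp_hc",
    "pv_ratio_mmhg_per_ul",
    "al_source",
]

GROUPS = ("control", "glaucoma")


@dataclass
class SubjectRecord:
    """Tonometry, morphology and air-puff quantities for one eye.

    ``iop_mmhg`` is the diastolic dynamic-contour-tonometry reading (IOP2);
    systolic IOP1 = iop + opa.  Corvis fields (``ap1_adj_mmhg``, ``biop_mmhg``,
    ``delta_a1_mm``, ``delta_hc_mm``) are optional; stiffness parameters are
    derived only when they are present.  Derived fields are filled by
    :func:`ocupulse.rigidity.compute_subject`.
    """

    subject_id: str
    group: str = "control"
    age_years: Optional[float] = None
    iop_mmhg: Optional[float] = None
    opa_mmhg: Optional[float] = None
    acv_ul: Optional[float] = None
    cct_um: Optional[float] = None
    corneal_radius_mm: Optional[float] = None
    refraction_se_d: Optional[float] = None
    heart_rate_hz: Optional[float] = None
    al_mm: Optional[float] = None
    ap1_adj_mmhg: Optional[float] = None
    biop_mmhg: Optional[float] = None
    delta_a1_mm: Optional[float] = None
    delta_hc_mm: Optional[float] = None
    delta_t_um: Optional[float] = None
    # derived
    dv_ul: Optional[float] = None
    k_per_ul: Optional[float] = None
    sp_a1: Optional[float] = None
    sp_hc: Optional[float] = None
    pv_ratio_mmhg_per_ul: Optional[float] = None
    al_source: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.iop_mmhg is not None and self.iop_mmhg <= 0:
            raise ValueError("iop_mmhg must be positive")
        if self.opa_mmhg is not None and self.opa_mmhg < 0:
            raise ValueError("opa_mmhg must be non-negative")
        if self.acv_ul is not None and self.acv_ul <= 0:
            raise ValueError("acv_ul must be positive")
        if self.al_mm is not None and self.al_mm <= 0:
            raise ValueError("al_mm must be positive")
        if (
            self.delta_a1_mm is not None
            and self.delta_hc_mm is not None
            and not (self.delta_hc_mm > self.delta_a1_mm > 0)
        ):
            raise ValueError("require delta_hc_mm > delta_a1_mm > 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class CohortTable:
    """A collection of :class:`SubjectRecord` with unique subject ids.

    One eye per subject; backed by a pandas DataFrame for CSV round-trips
    and the statistics layer.
    """

    def __init__(self, records: list[SubjectRecord]):
        ids = [r.subject_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def groups(self) -> list[str]:
        return [r.group for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([r.to_dict() for r in self.records])
        if df.empty:
            df = pd.DataFrame(columns=SUBJECT_COLUMNS)
        return df[SUBJECT_COLUMNS]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortTable":
        records = []
        for _, row in df.iterrows():
            kwargs = {}
            for col in SUBJECT_COLUMNS:
                if col not in row.index:
                    continue
                val = row[col]
                if pd.isna(val):
                    val = None
                elif col not in ("subject_id", "group", "al_source"):
                    val = float(val)
                kwargs[col] = val
            kwargs["subject_id"] = str(kwargs["subject_id"])
            if kwargs.get("group") is None:
                kwargs["group"] = "control"
            records.append(SubjectRecord(**kwargs))
        return cls(records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass
class StatResult:
    """Outcome of one statistical test or correlation."""

    test_name: str
    statistic: float
    p_value: float
    estimate: Optional[float] = None
    n: Optional[tuple] = None
    ci: Optional[tuple] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
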