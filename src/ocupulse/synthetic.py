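"""Synthetic dynamic OCT sequences and cohort tables with known ground truth.

The B-scan simulator renders a layered posterior-eye phantom: dark vitreous,
mid-intensity retina, a bright retinal-pigment-epithelium (RPE) band, a
darker choroid with smooth vessel texture, and a brighter sclera.  The
choroidal thickness pulses sinusoidally at the heart rate (plus optional
slow drift), the RPE carries a linear tilt across A-scans, a central
vertical band stands in for the optic-nerve head, frame timing includes
eye-tracker pauses, and multiplicative speckle corrupts the intensities.
Every quantity a downstream stage should recover is recorded in
:class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, signal

from .datatypes import BScanSequence, CohortTable, SubjectRecord
from . import rigidity

__all__ = [
    "BScanSimParams",
    "GroundTruth",
    "CohortSimParams",
    "simulate_bscan_sequence",
    "simulate_irregular_timestamps",
    "simulate_cohort",
]

# Mean intensity of each layer (8-bit scale), vitreous to sclera.  The only
# contract the segmentation relies on is bright RPE and a dark->bright
# choroid->sclera transition.
_LEVELS = {"vitreous": 15.0, "retina": 90.0, "rpe": 230.0, "choroid": 60.0, "sclera": 150.0}
_RETINA_PX = 30.0   # retina band thickness above the RPE
_RPE_BAND_PX = 5.0  # RPE band thickness
_EDGE_SOFT_PX = 0.75  # logistic softness of layer transitions


@dataclass
class BScanSimParams:
    """Parameters of the dynamic B-scan phantom.

    The defaults emulate a clinical optic-nerve-head video: 599 frames over
    roughly five seconds, axial sampling 3.87 um/pixel, a ~300 um choroid
    pulsing 10 um peak-to-valley at 1.2 Hz.  ``pulse_amplitude_um`` is the
    sinusoid amplitude A, so the noise-free peak-to-valley equals 2A.
    """

    n_frames: int = 599
    duration_s: float = 5.0
    width_px: int = 496
    depth_px: int = 256
    axial_spacing_um_per_px: float = 3.87
    rpe_depth_px: float = 70.0
    baseline_cht_um: float = 300.0
    pulse_amplitude_um: float = 5.0
    heart_rate_hz: float = 1.2
    drift_amplitude_um: float = 3.0
    drift_freq_hz: float = 0.1
    speckle_sigma: float = 0.2
    tilt_px_per_ascan: float = 0.05
    on_gap_frac: float = 0.15
    pause_prob: float = 0.01
    pause_len_s: float = 0.3
    harmonic_frac: float = 0.0  # optional 2xHR harmonic, fraction of A
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.axial_spacing_um_per_px <= 0:
            raise ValueError("axial_spacing_um_per_px must be positive")
        if not (0 <= self.on_gap_frac < 1):
            raise ValueError("on_gap_frac must be in [0, 1)")
        if self.pulse_amplitude_um < 0:
            raise ValueError("pulse_amplitude_um must be non-negative")


@dataclass
class GroundTruth:
    """Everything the pipeline should recover from a simulated sequence."""

    cht_um_per_frame: np.ndarray
    true_delta_t_um: float
    rpe_depth_px_per_ascan_per_frame: np.ndarray
    csi_depth_px_per_ascan_per_frame: np.ndarray
    timestamps_s: np.ndarray
    params: BScanSimParams = field(repr=False, default=None)


def simulate_irregular_timestamps(
    n_frames: int,
    duration_s: float,
    pause_prob: float = 0.0,
    pause_len_s: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """Frame times with a nominal uniform period plus random tracker pauses.

    Times start at 0 and are strictly increasing; each inter-frame gap is
    the nominal period ``duration_s / (n_frames - 1)`` except where a pause
    of ``pause_len_s`` is inserted (probability ``pause_prob`` per gap), so
    the total span is at least the nominal duration.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    period = duration_s / (n_frames - 1)
    gaps = np.full(n_frames - 1, period)
    if pause_prob > 0:
        gaps = gaps + (rng.random(n_frames - 1) < pause_prob) * pause_len_s
    return np.concatenate([[0.0], np.cumsum(gaps)])


def _cht_model(p: BScanSimParams, t: np.ndarray) -> np.ndarray:
    """Noise-free choroidal thickness (um) at times t."""
    cht = p.baseline_cht_um + p.pulse_amplitude_um * np.sin(
        2 * np.pi * p.heart_rate_hz * t
    )
    if p.harmonic_frac:
        cht = cht + p.harmonic_frac * p.pulse_amplitude_um * np.sin(
            2 * np.pi * 2 * p.heart_rate_hz * t
        )
    if p.drift_amplitude_um:
        cht = cht + p.drift_amplitude_um * np.sin(2 * np.pi * p.drift_freq_hz * t)
    return cht


def _true_delta_t(p: BScanSimParams, t_span: float) -> float:
    """Mean peak-to-valley of the noise-free thickness signal.

    Evaluated on a dense grid of the continuous model so that sparse or
    paused frame sampling cannot bias the reference value.
    """
    if p.pulse_amplitude_um == 0 and p.drift_amplitude_um == 0:
        return 0.0
    t = np.arange(0.0, t_span, 1e-3)
    x = _cht_model(p, t)
    peaks, _ = signal.find_peaks(x)
    valleys, _ = signal.find_peaks(-x)
    deltas = []
    for pk in peaks:
        nxt = valleys[valleys > pk]
        if nxt.size:
            deltas.append(x[pk] - x[nxt[0]])
    return float(np.mean(deltas)) if deltas else 0.0


def _vessel_field(rng: np.random.Generator, depth: int, width: int) -> np.ndarray:
    """Smooth zero-mean blob texture emulating choroidal vessels."""
    coarse = rng.standard_normal((max(depth // 16, 2), max(width // 16, 2)))
    fine = ndimage.zoom(coarse, (depth / coarse.shape[0], width / coarse.shape[1]), order=3)
    fine = fine[:depth, :width]
    if fine.shape != (depth, width):  # zoom rounding
        pad = ((0, depth - fine.shape[0]), (0, width - fine.shape[1]))
        fine = np.pad(fine, pad, mode="edge")
    return fine / max(np.abs(fine).max(), 1e-9)


def _render_frame(
    rows: np.ndarray,
    rpe_depth: np.ndarray,
    csi_depth: np.ndarray,
    vessels: np.ndarray,
) -> np.ndarray:
    """Render one frame from per-column RPE/CSI depths (float, sub-pixel)."""

    def soft_step(edge_depth: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(rows - edge_depth[None, :]) / _EDGE_SOFT_PX))

    L = _LEVELS
    b1 = rpe_depth - _RPE_BAND_PX - _RETINA_PX  # vitreous -> retina
    b2 = rpe_depth - _RPE_BAND_PX               # retina -> RPE
    b3 = rpe_depth                               # RPE -> choroid (posterior edge)
    b4 = csi_depth                               # choroid -> sclera (CSI)
    img = (
        L["vitreous"]
        + (L["retina"] - L["vitreous"]) * soft_step(b1)
        + (L["rpe"] - L["retina"]) * soft_step(b2)
        + (L["choroid"] - L["rpe"]) * soft_step(b3)
        + (L["sclera"] - L["choroid"]) * soft_step(b4)
    )
    in_choroid = (rows > b3[None, :] + 2) & (rows < b4[None, :] - 2)
    img = img + in_choroid * 15.0 * vessels
    return img


def simulate_bscan_sequence(
    params: Optional[BScanSimParams] = None,
) -> tuple[BScanSequence, GroundTruth]:
    """Generate a pulsating layered B-scan video plus its ground truth.

    Returns the sequence (uint8-scaled float intensities, timestamps,
    axial spacing, optic-nerve exclusion interval) and a
    :class:`GroundTruth` carrying the per-frame noise-free thickness, the
    true mean peak-to-valley, and the exact per-column layer depths.
    """
    p = params or BScanSimParams()
    p.validate()
    rng = np.random.default_rng(p.seed)

    t = simulate_irregular_timestamps(
        p.n_frames, p.duration_s, p.pause_prob, p.pause_len_s, seed=p.seed
    )
    cht_um = _cht_model(p, t)

    cols = np.arange(p.width_px)
    rows = np.arange(p.depth_px, dtype=float)[:, None]
    # linear tilt about the frame centre exercises the flattening stage
    rpe_profile = p.rpe_depth_px + p.tilt_px_per_ascan * (cols - p.width_px / 2)

    gap_w = int(round(p.on_gap_frac * p.width_px))
    lo = (p.width_px - gap_w) // 2
    hi = lo + gap_w

    vessels = _vessel_field(rng, p.depth_px, p.width_px)

    frames = np.empty((p.n_frames, p.depth_px, p.width_px), dtype=np.float32)
    rpe_truth = np.empty((p.n_frames, p.width_px))
    csi_truth = np.empty((p.n_frames, p.width_px))
    for i in range(p.n_frames):
        csi_profile = rpe_profile + cht_um[i] / p.axial_spacing_um_per_px
        img = _render_frame(rows, rpe_profile, csi_profile, vessels)
        if gap_w:
            # unlayered optic-nerve stand-in: smooth axial ramp, no bands
            onh = 40.0 + 60.0 * (rows / p.depth_px) + 10.0 * vessels[:, lo:hi]
            img[:, lo:hi] = onh
        if p.speckle_sigma > 0:
            img = img * np.exp(
                p.speckle_sigma * rng.standard_normal(img.shape).astype(np.float32)
            )
        frames[i] = np.clip(img, 0, 255)
        rpe_truth[i] = rpe_profile
        csi_truth[i] = csi_profile
    rpe_truth[:, lo:hi] = np.nan
    csi_truth[:, lo:hi] = np.nan

    seq = BScanSequence(
        frames=frames,
        timestamps_s=t,
        axial_spacing_um_per_px=p.axial_spacing_um_per_px,
        on_region=(lo, hi),
    )
    truth = GroundTruth(
        cht_um_per_frame=cht_um,
        true_delta_t_um=_true_delta_t(p, t[-1]),
        rpe_depth_px_per_ascan_per_frame=rpe_truth,
        csi_depth_px_per_ascan_per_frame=csi_truth,
        timestamps_s=t,
        params=p,
    )
    return seq, truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

_COHORT_VARS = ("k", "al", "acv", "opa", "sp_a1", "sp_hc")


def _default_correlations() -> np.ndarray:
    """Plausible correlation structure among (k, AL, ACV, OPA, SP-A1, SP-HC).

    Signs and magnitudes follow the clinical pattern this pipeline is built
    to detect: rigidity falls with longer eyes and larger anterior chambers
    and rises with pulse amplitude and corneoscleral stiffness.
    """
    c = np.eye(6)
    pairs = {
        ("k", "al"): -0.5,
        ("k", "acv"): -0.6,
        ("k", "opa"): 0.5,
        ("k", "sp_a1"): 0.4,
        ("k", "sp_hc"): 0.6,
        ("al", "acv"): 0.4,
        ("sp_a1", "sp_hc"): 0.5,
    }
    idx = {v: i for i, v in enumerate(_COHORT_VARS)}
    for (a, b), r in pairs.items():
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r
    # the pairwise pattern alone is slightly indefinite; shrink toward the
    # identity until positive semidefinite so the draw is well-posed
    shrink = 1.0
    while np.linalg.eigvalsh(c).min() < 1e-6:
        shrink *= 0.95
        c = np.eye(6) + shrink * (np.asarray(c) - np.eye(6))
    return c


@dataclass
class CohortSimParams:
    """Population parameters for simulated subject tables.

    Means and spreads follow a typical adult cohort: rigidity k around
    0.015 per uL, axial length around 24.8 mm, anterior chamber volume
    around 175 uL, diastolic IOP around 17 mmHg.
    """

    n_subjects: int = 29
    group_fractions: tuple[float, float] = (23 / 29, 6 / 29)  # control, glaucoma
    k_mean: float = 0.015
    k_sd: float = 0.005
    al_mean: float = 24.8
    al_sd: float = 0.9
    acv_mean: float = 175.0
    acv_sd: float = 30.0
    iop_mean: float = 17.0
    iop_sd: float = 2.0
    opa_mean: float = 2.5
    opa_sd: float = 1.1
    sp_a1_mean: float = 129.0
    sp_a1_sd: float = 15.0
    sp_hc_mean: float = 15.2
    sp_hc_sd: float = 3.4
    delta_t_mean_um: float = 5.0
    delta_t_sd_um: float = 1.2
    target_correlations: np.ndarray = field(default_factory=_default_correlations)
    seed: int = 0

    def validate(self) -> None:
        c = np.asarray(self.target_correlations, dtype=float)
        if c.shape != (6, 6):
            raise ValueError("target_correlations must be 6x6 over (k, AL, ACV, OPA, SP-A1, SP-HC)")
        if not np.allclose(c, c.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semidefinite")
        for name in ("k_sd", "al_sd", "acv_sd", "iop_sd", "opa_sd",
                     "sp_a1_sd", "sp_hc_sd", "delta_t_sd_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")


def simulate_cohort(params: Optional[CohortSimParams] = None) -> tuple[CohortTable, np.ndarray]:
    """Draw a subject table with known ground-truth rigidity.

    Latent (k, AL, ACV, OPA, SP-A1, SP-HC) are multivariate Gaussian with
    the target correlations, then shifted/scaled to physiological ranges.
    The measured OPA column is then *back-computed* from each subject's k
    and thin-shell volume change via the exact Friedenwald relation
    ``OPA = IOP2 * (exp(k dV) - 1)``, so the analysis pipeline can recover
    the generating k exactly; the latent OPA draw only orders subjects.
    Corvis deflections are likewise constructed so SP-A1/SP-HC round-trip.

    Returns the table and the ground-truth k array (also retrievable from
    the exact relation).
    """
    p = params or CohortSimParams()
    p.validate()
    rng = np.random.default_rng(p.seed)

    n = p.n_subjects
    if n == 0:
        return CohortTable([]), np.array([])

    corr = np.asarray(p.target_correlations, dtype=float)
    # eigenvalue clip guards the PSD boundary against roundoff
    w, v = np.linalg.eigh(corr)
    L = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    z = rng.standard_normal((n, 6)) @ L.T

    means = [p.k_mean, p.al_mean, p.acv_mean, p.opa_mean, p.sp_a1_mean, p.sp_hc_mean]
    sds = [p.k_sd, p.al_sd, p.acv_sd, p.opa_sd, p.sp_a1_sd, p.sp_hc_sd]
    vals = {name: means[i] + sds[i] * z[:, i] for i, name in enumerate(_COHORT_VARS)}
    # keep strictly positive where physiology requires it
    vals["k"] = np.clip(vals["k"], 1e-4, None)
    vals["al"] = np.clip(vals["al"], 18.0, 32.0)
    vals["acv"] = np.clip(vals["acv"], 60.0, None)
    vals["sp_a1"] = np.clip(vals["sp_a1"], 20.0, None)
    vals["sp_hc"] = np.clip(vals["sp_hc"], 2.0, None)

    n_glaucoma = int(round(p.group_fractions[1] * n))
    groups = np.array(["control"] * n, dtype=object)
    if n_glaucoma:
        groups[rng.choice(n, size=n_glaucoma, replace=False)] = "glaucoma"

    iop = np.clip(rng.normal(p.iop_mean, p.iop_sd, n), 8.0, None)
    age = np.where(
        groups == "glaucoma", rng.normal(61.5, 8.4, n), rng.normal(40.0, 12.6, n)
    )
    cct = rng.normal(557.0, 32.0, n)
    radius = np.clip(rng.normal(7.76, 0.22, n), 6.5, 9.0)
    hr = np.clip(rng.normal(1.2, 0.15, n), 0.8, 1.9)
    delta_t = np.clip(rng.normal(p.delta_t_mean_um, p.delta_t_sd_um, n), 0.5, None)

    records = []
    k_true = vals["k"]
    for i in range(n):
        dv = rigidity.volume_change_thin_shell(vals["al"][i], delta_t[i])
        opa = iop[i] * np.expm1(k_true[i] * dv)
        ap1 = rng.normal(100.0, 8.0)
        biop = np.clip(rng.normal(iop[i], 1.0), 5.0, ap1 - 5.0)
        d_a1 = (ap1 - biop) / vals["sp_a1"][i]
        d_hc = d_a1 + (ap1 - biop) / vals["sp_hc"][i]
        records.append(
            SubjectRecord(
                subject_id=f"S{i:04d}",
                group=str(groups[i]),
                age_years=float(age[i]),
                iop_mmhg=float(iop[i]),
                opa_mmhg=float(opa),
                acv_ul=float(vals["acv"][i]),
                cct_um=float(cct[i]),
                corneal_radius_mm=float(radius[i]),
                refraction_se_d=0.0,
                heart_rate_hz=float(hr[i]),
                al_mm=float(vals["al"][i]),
                ap1_adj_mmhg=float(ap1),
                biop_mmhg=float(biop),
                delta_a1_mm=float(d_a1),
                delta_hc_mm=float(d_hc),
                delta_t_um=float(delta_t[i]),
            )
        )
    return CohortTable(records), k_true
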