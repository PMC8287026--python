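"""Closed-form ocular biomechanics.

The eye is treated as a thin spherical shell of radius R = AL/2.  A
pulsatile choroidal thickening dt changes the ocular volume by
dV = 4*pi*R^2*dt (thin shell) or exactly by the two-sphere difference
(4/3)*pi*[(R+dt)^3 - R^3].  Friedenwald's empirical pressure-volume law
ln(IOP1) - ln(IOP2) = k*dV then yields the rigidity coefficient k (1/uL),
with IOP1 = diastolic IOP + ocular pulse amplitude and IOP2 the diastolic
reading.  Air-puff stiffness parameters and the static pressure-volume
ratio are simple quotients of device exports; axial length, when not
measured, is derived from refraction and corneal radius through a
paraxial schematic eye.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .datatypes import SubjectRecord

__all__ = [
    "volume_change_thin_shell",
    "volume_change_exact",
    "friedenwald_rigidity",
    "stiffness_a1",
    "stiffness_hc",
    "pv_ratio",
    "SchematicEyeConstants",
    "axial_length_from_schematic_eye",
    "compute_subject",
]


def volume_change_thin_shell(al_mm: float, delta_t_um: float) -> float:
    """Pulsatile ocular volume change dV = 4*pi*R^2*dt, in uL (= mm^3).

    R = al_mm / 2; dt is converted from micrometres to millimetres.
    """
    if al_mm <= 0:
        raise ValueError("al_mm must be positive")
    if delta_t_um < 0:
        raise ValueError("delta_t_um must be non-negative")
    r = al_mm / 2.0
    return 4.0 * math.pi * r * r * (delta_t_um / 1000.0)


def volume_change_exact(al_mm: float, delta_t_um: float) -> float:
    """Exact two-sphere volume difference (4/3)*pi*[(R+dt)^3 - R^3], uL."""
    if al_mm <= 0:
        raise ValueError("al_mm must be positive")
    if delta_t_um < 0:
        raise ValueError("delta_t_um must be non-negative")
    r = al_mm / 2.0
    dt = delta_t_um / 1000.0
    return (4.0 / 3.0) * math.pi * ((r + dt) ** 3 - r**3)


def friedenwald_rigidity(iop_mmhg: float, opa_mmhg: float, dv_ul: float) -> float:
    """Rigidity k = [ln(IOP + OPA) - ln(IOP)] / dV, in 1/uL."""
    if iop_mmhg <= 0:
        raise ValueError("iop_mmhg must be positive")
    if opa_mmhg < 0:
        raise ValueError("opa_mmhg must be non-negative")
    if dv_ul <= 0:
        raise ValueError("dv_ul must be positive")
    return math.log1p(opa_mmhg / iop_mmhg) / dv_ul


def stiffness_a1(ap1_adj_mmhg: float, biop_mmhg: float, delta_a1_mm: float) -> float:
    """Corneal stiffness parameter at first applanation, (AP1_adj - bIOP)/dA1."""
    if delta_a1_mm <= 0:
        raise ValueError("delta_a1_mm must be positive")
    return (ap1_adj_mmhg - biop_mmhg) / delta_a1_mm


def stiffness_hc(
    ap1_adj_mmhg: float, biop_mmhg: float, delta_a1_mm: float, delta_hc_mm: float
) -> float:
    """Scleral stiffness parameter at highest concavity, (AP1_adj - bIOP)/(dHC - dA1)."""
    if delta_hc_mm <= delta_a1_mm:
        raise ValueError("require delta_hc_mm > delta_a1_mm")
    return (ap1_adj_mmhg - biop_mmhg) / (delta_hc_mm - delta_a1_mm)


def pv_ratio(iop_mmhg: float, acv_ul: float) -> float:
    """Static pressure-volume ratio IOP/ACV, mmHg per uL."""
    if acv_ul <= 0:
        raise ValueError("acv_ul must be positive")
    return iop_mmhg / acv_ul


# ---------------------------------------------------------------------------
# Schematic eye
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SchematicEyeConstants:
    """Paraxial constants of the simplified (Gullstrand-Emsley style) eye.

    A single corneal refracting surface separates air from a homogeneous
    ocular medium of index ``n_medium``; a thin crystalline lens of power
    ``lens_power_d`` sits ``lens_distance_mm`` behind it.  ``lens_power_d``
    left as None is solved at first use so that an eye with zero refractive
    error and the reference corneal radius has exactly
    ``emmetropic_al_mm`` of axial length — the calibration anchor.
    """

    n_medium: float = 4.0 / 3.0
    lens_distance_mm: float = 5.7
    reference_radius_mm: float = 7.8
    emmetropic_al_mm: float = 23.89
    lens_power_d: Optional[float] = None

    def corneal_power_d(self, radius_mm: float) -> float:
        if radius_mm <= 0:
            raise ValueError("corneal radius must be positive")
        return (self.n_medium - 1.0) * 1000.0 / radius_mm

    def calibrated(self) -> "SchematicEyeConstants":
        """Return a copy with ``lens_power_d`` solved from the anchor."""
        if self.lens_power_d is not None:
            return self
        # invert the vergence chain at SE = 0, r = reference:
        # image must land on the retina at the emmetropic length.
        fc = self.corneal_power_d(self.reference_radius_mm)
        d = self.lens_distance_mm / 1000.0
        n = self.n_medium
        l1 = fc  # vergence after cornea for a distant object (SE = 0)
        l2 = l1 / (1.0 - (d / n) * l1)  # propagated to the lens plane
        x = (self.emmetropic_al_mm - self.lens_distance_mm) / 1000.0
        l3 = n / x  # vergence required to focus on the retina
        return replace(self, lens_power_d=l3 - l2)


def axial_length_from_schematic_eye(
    refraction_se_d: float,
    corneal_radius_mm: float,
    eye_constants: Optional[SchematicEyeConstants] = None,
) -> float:
    """Axial length (mm) from spherical-equivalent refraction and corneal radius.

    Axial-ametropia assumption: the refractive error is attributed entirely
    to globe length.  A paraxial vergence chain — object at the far point
    (vergence SE at the cornea), corneal surface, translation to the thin
    lens inside the medium, lens — is solved for the image distance; axial
    length is lens position plus image distance.  Myopic eyes (SE < 0) come
    out longer than emmetropic, hyperopic shorter; steeper corneas shorter.
    """
    if corneal_radius_mm <= 0:
        raise ValueError("corneal_radius_mm must be positive")
    if abs(refraction_se_d) > 6.0:
        raise ValueError("spherical equivalent outside the +/-6 D study range")
    c = (eye_constants or SchematicEyeConstants()).calibrated()
    n = c.n_medium
    d = c.lens_distance_mm / 1000.0
    l1 = refraction_se_d + c.corneal_power_d(corneal_radius_mm)
    denom = 1.0 - (d / n) * l1
    if denom <= 0:
        raise ValueError("vergence chain degenerate for these inputs")
    l2 = l1 / denom
    l3 = l2 + c.lens_power_d
    if l3 <= 0:
        raise ValueError("image not formed behind the lens")
    al_mm = c.lens_distance_mm + 1000.0 * n / l3
    if not (15.0 < al_mm < 35.0):
        raise ValueError(f"non-physical axial length {al_mm:.2f} mm")
    return al_mm


# ---------------------------------------------------------------------------
# Per-subject assembly
# ---------------------------------------------------------------------------


def compute_subject(
    record: SubjectRecord,
    delta_t_um: Optional[float] = None,
    volume_model: str = "thin_shell",
    eye_constants: Optional[SchematicEyeConstants] = None,
) -> SubjectRecord:
    """Fill all derivable biomechanical fields of a subject record.

    ``delta_t_um`` overrides the record's stored pulsatile thickness change
    (e.g. when freshly measured from a B-scan video).  Axial length is taken
    from the record when present, otherwise derived from refraction and
    corneal radius through the schematic eye; the choice is recorded in
    ``al_source``.  Stiffness parameters are computed only when the air-puff
    exports are present.  Field-level failures are aggregated into one error.
    """
    rec = replace(record)
    if delta_t_um is not None:
        rec.delta_t_um = float(delta_t_um)

    problems: list[str] = []

    if rec.al_mm is not None:
        rec.al_source = "measured"
    elif rec.refraction_se_d is not None and rec.corneal_radius_mm is not None:
        try:
            rec.al_mm = axial_length_from_schematic_eye(
                rec.refraction_se_d, rec.corneal_radius_mm, eye_constants
            )
            rec.al_source = "schematic_eye"
        except ValueError as e:
            problems.append(f"al_mm: {e}")
    else:
        problems.append("al_mm: not given and not derivable")

    if rec.al_mm is not None and rec.delta_t_um is not None:
        vol = volume_change_exact if volume_model == "exact" else volume_change_thin_shell
        if volume_model not in ("thin_shell", "exact"):
            raise ValueError(f"unknown volume_model {volume_model!r}")
        try:
            rec.dv_ul = vol(rec.al_mm, rec.delta_t_um)
        except ValueError as e:
            problems.append(f"dv_ul: {e}")

    if rec.dv_ul is not None and rec.iop_mmhg is not None and rec.opa_mmhg is not None:
        try:
            rec.k_per_ul = friedenwald_rigidity(rec.iop_mmhg, rec.opa_mmhg, rec.dv_ul)
        except ValueError as e:
            problems.append(f"k_per_ul: {e}")

    corvis = (rec.ap1_adj_mmhg, rec.biop_mmhg, rec.delta_a1_mm, rec.delta_hc_mm)
    if all(v is not None for v in corvis[:3]):
        try:
            rec.sp_a1 = stiffness_a1(rec.ap1_adj_mmhg, rec.biop_mmhg, rec.delta_a1_mm)
        except ValueError as e:
            problems.append(f"sp_a1: {e}")
    if all(v is not None for v in corvis):
        try:
            rec.sp_hc = stiffness_hc(*corvis)
        except ValueError as e:
            problems.append(f"sp_hc: {e}")

    if rec.iop_mmhg is not None and rec.acv_ul is not None:
        try:
            rec.pv_ratio_mmhg_per_ul = pv_ratio(rec.iop_mmhg, rec.acv_ul)
        except ValueError as e:
            problems.append(f"pv_ratio: {e}")

    if problems:
        raise ValueError(
            f"subject {rec.subject_id}: " + "; ".join(problems)
        )
    return rec
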