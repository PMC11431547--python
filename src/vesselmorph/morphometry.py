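"""Arteriolar morphometry: LD, ED, mean wall thickness and WLR, plus the
inter-grader area-agreement QC.

Conventions (fixed for the whole package):

* per-sample luminal diameter = (left + right lumen radius) x pixel scale;
  the external diameter likewise; vessel-level LD and ED are simple means
  over kept samples;
* mean wall thickness W = (ED - LD) / 2, i.e. the single-wall thickness
  averaged over the two sides;
* WLR = W / LD (single-wall thickness over luminal diameter), computed from
  the vessel-mean W and vessel-mean LD (a ratio of means, robust to
  per-sample lumen noise), so ED = LD * (1 + 2 * WLR) holds exactly;
* grader agreement requires < 10% relative area difference (strict) for the
  lumen and the wall annulus, overall and on four equal arc-length
  sub-regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .segmentation import VesselSegmentation


class MorphometryError(ValueError):
    pass


@dataclass
class VesselMorphometry:
    ld_um: float
    ed_um: float
    wall_um: float
    wlr: float
    n_samples: int
    per_sample: pd.DataFrame  # audit table; per-side thicknesses retained


def wall_thickness(ed_um: float, ld_um: float) -> float:
    """Mean wall thickness W = (ED - LD) / 2 in micrometres."""
    if not ed_um > ld_um > 0:
        raise MorphometryError("requires ED > LD > 0")
    return (ed_um - ld_um) / 2.0


def wall_to_lumen_ratio(wall_um: float, ld_um: float) -> float:
    """WLR = W / LD (single-wall convention)."""
    if wall_um <= 0 or ld_um <= 0:
        raise MorphometryError("wall thickness and LD must be positive")
    return wall_um / ld_um


def compute_morphometry(
    seg: VesselSegmentation, pixel_scale: float, *, min_samples: int = 10
) -> VesselMorphometry:
    """Collapse a segmentation into the four arteriolar parameters."""
    if pixel_scale <= 0:
        raise MorphometryError("pixel_scale must be positive")
    kept = seg.kept_mask()
    n = int(kept.sum())
    if n < min_samples:
        raise MorphometryError(f"vessel rejected: {n} kept samples < {min_samples}")
    lum = seg.lumen_radius[kept]
    ext = seg.external_radius[kept]
    if not np.all(ext > lum):
        raise MorphometryError("invariant violated: external <= lumen at a kept sample")
    ld_samples = lum.sum(axis=1) * pixel_scale
    ed_samples = ext.sum(axis=1) * pixel_scale
    per_sample = pd.DataFrame(
        {
            "sample": np.flatnonzero(kept),
            "ld_um": ld_samples,
            "ed_um": ed_samples,
            "wall_left_um": (ext[:, 0] - lum[:, 0]) * pixel_scale,
            "wall_right_um": (ext[:, 1] - lum[:, 1]) * pixel_scale,
        }
    )
    ld = float(ld_samples.mean())
    ed = float(ed_samples.mean())
    w = wall_thickness(ed, ld)
    return VesselMorphometry(
        ld_um=ld,
        ed_um=ed,
        wall_um=w,
        wlr=wall_to_lumen_ratio(w, ld),
        n_samples=n,
        per_sample=per_sample,
    )


# ---------------------------------------------------------------------------
# areas and grader agreement
# ---------------------------------------------------------------------------

def contour_area(contour: np.ndarray, pixel_scale: float) -> float:
    """Shoelace area of a simple closed polygon, in um^2 (orientation-free)."""
    poly = Polygon(np.asarray(contour, dtype=float))
    if not poly.is_valid or not poly.is_simple:
        raise MorphometryError("contour polygon is self-intersecting")
    return float(poly.area) * pixel_scale**2


@dataclass
class AgreementReport:
    lumen_area_delta: float
    wall_area_delta: float
    sub_region_deltas: list  # per quarter: (lumen delta, wall delta)
    passed: bool


def _strip_areas(arc, lumen, ext, edges):
    """Lumen and wall-annulus areas per arc-length bin by strip integration."""
    width_l = lumen.sum(axis=1)
    width_w = (ext - lumen).sum(axis=1)
    lum_areas, wall_areas = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        grid = np.linspace(a, b, 64)
        lum_areas.append(np.trapezoid(np.interp(grid, arc, width_l), grid))
        wall_areas.append(np.trapezoid(np.interp(grid, arc, width_w), grid))
    return np.array(lum_areas), np.array(wall_areas)


def _rel_delta(a: float, b: float) -> float:
    m = 0.5 * (a + b)
    return abs(a - b) / m if m > 0 else 0.0


def area_agreement(
    seg_a: VesselSegmentation,
    seg_b: VesselSegmentation,
    pixel_scale: float,
    *,
    threshold: float = 0.10,
) -> AgreementReport:
    """Relative lumen / wall-annulus area difference between two graders.

    Both segmentations must cover an overlapping centerline extent; grader
    B's radii are interpolated onto grader A's arc-length samples.  The
    report passes iff every delta (overall and per arc-length quarter) is
    strictly below ``threshold``.  Areas scale with ``pixel_scale**2`` but
    the deltas are scale-free.
    """
    kept_a, kept_b = seg_a.kept_mask(), seg_b.kept_mask()
    arc_a, arc_b = seg_a.trace.arc[kept_a], seg_b.trace.arc[kept_b]
    if arc_a.size < 4 or arc_b.size < 4:
        raise MorphometryError("too few kept samples for agreement")
    lo, hi = max(arc_a[0], arc_b[0]), min(arc_a[-1], arc_b[-1])
    if hi <= lo:
        raise MorphometryError("graders cover disjoint centerline extents")
    # the arc parameterisations must describe the same vessel in space
    mids = [np.interp((lo + hi) / 2, arc, seg.trace.points[kept][:, i])
            for seg, kept, arc in ((seg_a, kept_a, arc_a), (seg_b, kept_b, arc_b))
            for i in (0, 1)]
    gap = np.hypot(mids[0] - mids[2], mids[1] - mids[3])
    if gap > 2.0 * float(np.nanmax(seg_a.external_radius)):
        raise MorphometryError("graders cover disjoint centerline extents")

    def on_common(seg, kept, arc):
        common = np.linspace(lo, hi, 256)
        lum = np.column_stack(
            [np.interp(common, arc, seg.lumen_radius[kept][:, s]) for s in range(2)]
        )
        ext = np.column_stack(
            [np.interp(common, arc, seg.external_radius[kept][:, s]) for s in range(2)]
        )
        return common, lum, ext

    common, lum_a, ext_a = on_common(seg_a, kept_a, arc_a)
    _, lum_b, ext_b = on_common(seg_b, kept_b, arc_b)

    quarters = np.linspace(lo, hi, 5)
    la_q, wa_q = _strip_areas(common, lum_a, ext_a, quarters)
    lb_q, wb_q = _strip_areas(common, lum_b, ext_b, quarters)
    sub = [(_rel_delta(la, lb), _rel_delta(wa, wb))
           for la, lb, wa, wb in zip(la_q, lb_q, wa_q, wb_q)]
    lum_delta = _rel_delta(la_q.sum(), lb_q.sum())
    wall_delta = _rel_delta(wa_q.sum(), wb_q.sum())
    deltas = [lum_delta, wall_delta] + [d for pair in sub for d in pair]
    return AgreementReport(
        lumen_area_delta=lum_delta,
        wall_area_delta=wall_delta,
        sub_region_deltas=sub,
        passed=bool(all(d < threshold for d in deltas)),
    )


def morphometry_record(
    morph: VesselMorphometry,
    *,
    vessel_id: str,
    eye_id: str = "",
    patient_id: str = "",
    dr_group: str = "",
    t1d: bool = False,
    qc_pass: bool = True,
) -> dict:
    """One cohort-CSV row for this vessel."""
    return {
        "vessel_id": vessel_id,
        "eye_id": eye_id,
        "patient_id": patient_id,
        "t1d": bool(t1d),
        "dr_group": dr_group,
        "LD": morph.ld_um,
        "ED": morph.ed_um,
        "W": morph.wall_um,
        "WLR": morph.wlr,
        "n_samples": morph.n_samples,
        "qc_pass": bool(qc_pass),
    }
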