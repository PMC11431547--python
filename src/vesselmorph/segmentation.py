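"""Vessel tracing and dual-image lumen / external-wall segmentation.

The lumen boundary (green contour) is the border of the blood-flow region
in the motion-contrast STD image, located per radial profile as the
half-height crossing between the flow plateau and the background level.
The external wall boundary (magenta contour) is a local maximum of the MPG
profile outside the lumen; the maximum nearest the lumen is taken because
the outer wall edge is the first structural discontinuity beyond the flow
column.

Mural-cell edges can masquerade as the outer wall.  ``enforce_continuity``
plays the role of a discrete snake: radius samples that break from a running
median by more than 3 median absolute deviations are re-chosen as the next
admissible MPG maximum (or excluded), and the surviving sequence is smoothed
by a second-difference penalty that also bridges gaps.  Residual cases are
handled by a replayable edit journal rather than interactive state, so every
grader action is reproducible and diffable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
from scipy.interpolate import splev, splprep
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

FLAG_AUTO = "auto"
FLAG_CORRECTED = "corrected"
FLAG_EXCLUDED = "excluded"

SIDES = ("left", "right")


class SegmentationError(ValueError):
    pass


class VesselRejectedError(SegmentationError):
    """Too few usable samples to segment this vessel."""


class EditError(SegmentationError):
    pass


# ---------------------------------------------------------------------------
# centerline tracing
# ---------------------------------------------------------------------------

@dataclass
class VesselTrace:
    """Ordered subpixel centerline samples with unit normals."""

    points: np.ndarray        # (N, 2) (row, col)
    normals: np.ndarray       # (N, 2) unit, +normal defines the "left" side
    sample_spacing: float     # px
    r_init: float             # initial lumen-radius estimate (px)

    @property
    def n_samples(self) -> int:
        return self.points.shape[0]

    @property
    def arc(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


def _skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Longest path through the skeleton (double BFS), as ordered coords."""
    coords = np.argwhere(skel)
    if coords.shape[0] < 2:
        raise SegmentationError("skeleton too small to trace")
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    nbrs = [[] for _ in range(coords.shape[0])]
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = index.get((int(r) + dr, int(c) + dc))
                if j is not None:
                    nbrs[i].append(j)

    def bfs(start):
        dist = np.full(coords.shape[0], -1, dtype=int)
        parent = np.full(coords.shape[0], -1, dtype=int)
        dist[start] = 0
        queue = [start]
        while queue:
            nxt = []
            for u in queue:
                for v in nbrs[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        parent[v] = u
                        nxt.append(v)
            queue = nxt
        return dist, parent

    d0, _ = bfs(0)
    e1 = int(np.argmax(d0))
    d1, parent = bfs(e1)
    e2 = int(np.argmax(d1))
    path = [e2]
    while parent[path[-1]] >= 0:
        path.append(int(parent[path[-1]]))
    return coords[np.array(path[::-1])]


def trace_centerline(
    std_image: np.ndarray,
    seed_point,
    *,
    sample_spacing: float = 2.0,
    min_length: float = 50.0,
    trim_factor: float = 1.35,
) -> VesselTrace:
    """Extract the vessel centerline from the motion-contrast image.

    Flow mask = STD >= Otsu threshold (finite pixels); the mask skeleton
    branch through the seed is spline-smoothed and resampled at
    ``sample_spacing``.  Ends are trimmed by ``trim_factor`` times the
    initial lumen-radius estimate to avoid end-cap distortion.
    """
    std = np.asarray(std_image, dtype=float)
    finite = np.isfinite(std)
    if not finite.any():
        raise SegmentationError("STD image has no finite pixels")
    thr = threshold_otsu(std[finite])
    mask = finite & (std >= thr)

    sr, sc = int(round(seed_point[0])), int(round(seed_point[1]))
    if not (0 <= sr < std.shape[0] and 0 <= sc < std.shape[1]) or not mask[sr, sc]:
        raise SegmentationError("seed point lies outside the flow region")

    # keep only the connected component containing the seed; fill speckle
    # holes (isolated sub-threshold pixels inside the flow column) so the
    # skeleton and the distance transform see a solid lumen
    labels, _ = ndi.label(mask)
    mask = ndi.binary_fill_holes(labels == labels[sr, sc])

    skel = skeletonize(mask)
    path = _skeleton_path(skel).astype(float)

    edt = ndi.distance_transform_edt(mask)
    r_init = float(np.median(edt[path[:, 0].astype(int), path[:, 1].astype(int)]))
    if r_init <= 1.0:
        raise SegmentationError("flow region too thin to segment")

    k = min(3, path.shape[0] - 1)
    smooth = 0.5 * path.shape[0]
    (tck, _) = splprep([path[:, 0], path[:, 1]], s=smooth, k=k)
    ud = np.linspace(0.0, 1.0, max(2000, 5 * path.shape[0]))
    dr, dc = splev(ud, tck)
    dense = np.column_stack([dr, dc])
    seglen = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arc[-1]

    trim = trim_factor * r_init
    if total - 2 * trim < min_length:
        raise SegmentationError(
            f"segment too short: {total - 2 * trim:.1f} px usable < {min_length} px"
        )
    s_targets = np.arange(trim, total - trim + sample_spacing / 2, sample_spacing)
    u_targets = np.interp(s_targets, arc, ud)
    pr, pc = splev(u_targets, tck)
    tr, tc = splev(u_targets, tck, der=1)
    tangents = np.column_stack([tr, tc])
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    return VesselTrace(
        points=np.column_stack([pr, pc]),
        normals=normals,
        sample_spacing=float(sample_spacing),
        r_init=r_init,
    )


# ---------------------------------------------------------------------------
# radial profiles
# ---------------------------------------------------------------------------

@dataclass
class RadialProfileSet:
    """STD and MPG sampled along each normal, both sides, at a fixed step."""

    r: np.ndarray             # (K,) radii from the centerline, px
    std: np.ndarray           # (N, 2, K); NaN outside the valid region
    mpg: np.ndarray           # (N, 2, K)
    r_init: float
    step: float
    trace: VesselTrace


def _sample(img: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return ndi.map_coordinates(
        img, [pts[..., 0], pts[..., 1]], order=1, mode="constant", cval=np.nan
    )


def sample_profiles(
    trace: VesselTrace,
    std_image: np.ndarray,
    mpg_image: np.ndarray,
    *,
    step: float = 0.25,
    half_length_factor: float = 2.5,
) -> RadialProfileSet:
    if step <= 0:
        raise SegmentationError("profile step must be positive")
    half_len = half_length_factor * trace.r_init
    r = np.arange(0.0, half_len + step / 2, step)
    # (N, 2, K, 2) sample coordinates: side 0 = +normal (left), side 1 = -normal
    p = trace.points[:, None, None, :]
    n = trace.normals[:, None, None, :]
    sign = np.array([1.0, -1.0])[None, :, None, None]
    coords = p + sign * n * r[None, None, :, None]
    return RadialProfileSet(
        r=r,
        std=_sample(np.asarray(std_image, float), coords),
        mpg=_sample(np.asarray(mpg_image, float), coords),
        r_init=trace.r_init,
        step=step,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# boundary detection
# ---------------------------------------------------------------------------

def detect_lumen_boundary(profiles: RadialProfileSet) -> np.ndarray:
    """Half-height crossing of the STD profile, per sample per side.

    The boundary is the outermost radius where the profile falls to
    background + 50% of (plateau - background); plateau = median STD over
    the inner half of the profile, background = median beyond 1.8x the
    initial radius estimate.  Samples without a crossing are NaN (excluded).
    """
    r = profiles.r
    n_samples = profiles.std.shape[0]
    out = np.full((n_samples, 2), np.nan)
    inner = r <= r[-1] / 2
    outer = r > 1.8 * profiles.r_init
    for i in range(n_samples):
        for side in range(2):
            prof = profiles.std[i, side]
            if np.sum(np.isfinite(prof)) < 8:
                continue
            plateau = np.nanmedian(prof[inner])
            if not np.any(np.isfinite(prof[outer])):
                continue
            background = np.nanmedian(prof[outer])
            if not plateau > background:
                continue
            thr = background + 0.5 * (plateau - background)
            above = prof >= thr
            cross = np.flatnonzero(
                above[:-1] & ~above[1:] & np.isfinite(prof[:-1]) & np.isfinite(prof[1:])
            )
            if cross.size == 0:
                continue
            j = cross[-1]
            frac = (prof[j] - thr) / (prof[j] - prof[j + 1])
            out[i, side] = r[j] + frac * profiles.step
    return out


def _parabolic_refine(prof: np.ndarray, j: int, r: np.ndarray, step: float) -> float:
    if 0 < j < prof.size - 1 and np.all(np.isfinite(prof[j - 1 : j + 2])):
        denom = prof[j - 1] - 2 * prof[j] + prof[j + 1]
        if denom != 0:
            delta = 0.5 * (prof[j - 1] - prof[j + 1]) / denom
            return float(r[j] + np.clip(delta, -1.0, 1.0) * step)
    return float(r[j])


def detect_external_boundary(
    profiles: RadialProfileSet,
    lumen_radius: np.ndarray,
    *,
    prominence_frac: float = 0.2,
    min_wall_offset: float = 2.0,
):
    """Nearest admissible MPG maximum outside the lumen, per sample per side.

    Candidates are local maxima with prominence >= ``prominence_frac`` of
    the profile's maximum prominence, lying more than ``min_wall_offset``
    px beyond the lumen radius (which excludes the inner-wall MPG peak).
    Returns the selected radii and the full per-sample candidate lists so
    the continuity stage can re-choose.
    """
    r = profiles.r
    n_samples = profiles.mpg.shape[0]
    ext = np.full((n_samples, 2), np.nan)
    candidates: list[list[np.ndarray]] = []
    for i in range(n_samples):
        row = []
        for side in range(2):
            lum = lumen_radius[i, side]
            prof = profiles.mpg[i, side]
            finite = np.isfinite(prof)
            stop = int(np.argmax(~finite)) if not finite.all() else prof.size
            prof_f = prof[:stop]
            cand = np.empty(0)
            if np.isfinite(lum) and prof_f.size >= 5:
                peaks, props = find_peaks(prof_f, prominence=0.0)
                if peaks.size:
                    p_min = prominence_frac * props["prominences"].max()
                    keep = (props["prominences"] >= p_min) & (r[peaks] > lum + min_wall_offset)
                    sel = peaks[keep]
                    cand = np.array(
                        [_parabolic_refine(prof_f, j, r, profiles.step) for j in sel]
                    )
                    cand.sort()
            row.append(cand)
            if cand.size:
                ext[i, side] = cand[0]
        candidates.append(row)
    return ext, candidates


# ---------------------------------------------------------------------------
# segmentation container
# ---------------------------------------------------------------------------

@dataclass
class VesselSegmentation:
    trace: VesselTrace
    lumen_radius: np.ndarray        # (N, 2), px, NaN = excluded
    external_radius: np.ndarray     # (N, 2)
    ext_candidates: list            # per sample, per side: sorted candidate radii
    flags: np.ndarray               # (N, 2) strings auto/corrected/excluded
    hard_excluded: np.ndarray       # (N,) bool; never re-filled
    lumen_contour: np.ndarray | None = None
    external_contour: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def kept_mask(self) -> np.ndarray:
        ok = (
            np.all(np.isfinite(self.lumen_radius), axis=1)
            & np.all(np.isfinite(self.external_radius), axis=1)
            & ~self.hard_excluded
        )
        return ok & np.all(self.external_radius > self.lumen_radius, axis=1)

    def copy(self) -> "VesselSegmentation":
        return copy.deepcopy(self)


def _initial_flags(lumen, ext):
    flags = np.full(lumen.shape, FLAG_AUTO, dtype=object)
    flags[~np.isfinite(lumen) | ~np.isfinite(ext)] = FLAG_EXCLUDED
    return flags


def build_contours(seg: VesselSegmentation) -> VesselSegmentation:
    """Closed lumen/external polygons from kept samples (green/magenta)."""
    kept = seg.kept_mask()
    if kept.sum() < 3:
        raise VesselRejectedError("too few kept samples to build contours")
    p = seg.trace.points[kept]
    n = seg.trace.normals[kept]
    for attr, radii in (
        ("lumen_contour", seg.lumen_radius[kept]),
        ("external_contour", seg.external_radius[kept]),
    ):
        left = p + n * radii[:, 0:1]
        right = p - n * radii[:, 1:2]
        setattr(seg, attr, np.vstack([left, right[::-1]]))
    return seg


# ---------------------------------------------------------------------------
# continuity enforcement (discrete snake)
# ---------------------------------------------------------------------------

def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    import pandas as pd

    return (
        pd.Series(x).rolling(window, center=True, min_periods=3).median().to_numpy()
    )


def _penalized_smooth(r: np.ndarray, weights: np.ndarray, lam: float) -> np.ndarray:
    """Minimise sum w_i (x_i - r_i)^2 + lam * sum (second difference)^2."""
    n = r.size
    if lam == 0 or n < 3:
        return r.copy()
    if not np.any(weights > 0):
        return r.copy()
    d = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    a = sp.diags(weights) + lam * (d.T @ d)
    b = weights * np.nan_to_num(r)
    return sp.linalg.spsolve(a.tocsc(), b)


def enforce_continuity(
    seg: VesselSegmentation,
    stiffness: float = 2.0,
    *,
    window: int = 11,
    mad_mult: float = 3.0,
    mad_floor: float = 0.25,
    max_excluded_frac: float = 0.5,
) -> VesselSegmentation:
    """Outlier screening, candidate re-choice and snake smoothing.

    Samples deviating from a running median (window 11) by more than
    ``mad_mult`` x MAD are spurious: for the external boundary the next
    admissible MPG maximum is tried, otherwise the sample is excluded.
    Surviving sequences are smoothed by a second-difference penalty which
    also bridges excluded gaps.  Raises :class:`VesselRejectedError` when
    more than half the samples are excluded.
    """
    seg = seg.copy()
    n = seg.trace.n_samples
    if int(np.sum(seg.kept_mask())) < 10:
        raise VesselRejectedError("fewer than 10 kept samples before continuity")

    for side in range(2):
        # --- external boundary: screen + re-choose -----------------------
        ext = seg.external_radius[:, side]
        runmed = _running_median(ext, window)
        resid = ext - runmed
        mad = np.nanmedian(np.abs(resid))
        mad = max(mad if np.isfinite(mad) else 0.0, mad_floor)
        spurious = np.isfinite(resid) & (np.abs(resid) > mad_mult * mad)
        for i in np.flatnonzero(spurious):
            cand = seg.ext_candidates[i][side]
            replaced = False
            for c in cand[cand > ext[i] + 1e-9]:
                if not np.isfinite(runmed[i]) or abs(c - runmed[i]) <= mad_mult * mad:
                    ext[i] = c
                    seg.flags[i, side] = FLAG_CORRECTED
                    replaced = True
                    break
            if not replaced:
                ext[i] = np.nan
                seg.flags[i, side] = FLAG_EXCLUDED

        # --- lumen boundary: screen only ---------------------------------
        lum = seg.lumen_radius[:, side]
        runmed_l = _running_median(lum, window)
        resid_l = lum - runmed_l
        mad_l = np.nanmedian(np.abs(resid_l))
        mad_l = max(mad_l if np.isfinite(mad_l) else 0.0, mad_floor)
        bad = np.isfinite(resid_l) & (np.abs(resid_l) > mad_mult * mad_l)
        lum[bad] = np.nan
        seg.flags[bad, side] = FLAG_EXCLUDED

        excluded = ~np.isfinite(ext) | ~np.isfinite(lum)
        if excluded.sum() > max_excluded_frac * n:
            raise VesselRejectedError(
                f"{excluded.sum()}/{n} samples excluded on side {SIDES[side]}"
            )

        # --- snake smoothing / gap bridging -------------------------------
        if stiffness > 0:
            for radii in (ext, lum):
                w = np.isfinite(radii).astype(float)
                w[seg.hard_excluded] = 0.0
                smoothed = _penalized_smooth(radii, w, stiffness)
                filled = ~np.isfinite(radii) & ~seg.hard_excluded
                moved = np.isfinite(radii) & (np.abs(smoothed - np.nan_to_num(radii)) > 0.5)
                radii[~seg.hard_excluded] = smoothed[~seg.hard_excluded]
                for i in np.flatnonzero(filled | moved):
                    if seg.flags[i, side] != FLAG_EXCLUDED or filled[i]:
                        seg.flags[i, side] = FLAG_CORRECTED

    # hard invariant: external > lumen at every kept sample
    bad = np.isfinite(seg.external_radius) & np.isfinite(seg.lumen_radius)
    bad &= seg.external_radius <= seg.lumen_radius
    seg.external_radius[bad] = np.nan
    seg.flags[bad] = FLAG_EXCLUDED
    seg.params["stiffness"] = stiffness
    return seg


# ---------------------------------------------------------------------------
# edit journal
# ---------------------------------------------------------------------------

VALID_ACTIONS = ("erase_external", "set_external_radius", "exclude_sample")


@dataclass
class Edit:
    action: str
    start: int
    end: int              # inclusive
    side: str = "both"    # left | right | both
    value: float | None = None


@dataclass
class EditJournal:
    edits: list

    @classmethod
    def from_dict(cls, d) -> "EditJournal":
        return cls(edits=[Edit(**e) for e in (d or {}).get("edits", [])])

    def to_dict(self) -> dict:
        return {
            "edits": [
                {k: v for k, v in vars(e).items() if v is not None} for e in self.edits
            ]
        }


def _edit_sides(edit: Edit):
    if edit.side == "both":
        return (0, 1)
    if edit.side not in SIDES:
        raise EditError(f"edit {edit.action}: unknown side {edit.side!r}")
    return (SIDES.index(edit.side),)


def apply_edit_journal(seg: VesselSegmentation, journal: EditJournal) -> VesselSegmentation:
    """Replay manual corrections deterministically.

    ``erase_external`` removes radii over a sample range and re-completes
    them with the continuity smoother; ``set_external_radius`` pins a value;
    ``exclude_sample`` drops samples permanently.  Replaying the same
    journal twice gives the same result.
    """
    seg = seg.copy()
    n = seg.trace.n_samples
    needs_fill = False
    for k, edit in enumerate(journal.edits):
        if edit.action not in VALID_ACTIONS:
            raise EditError(f"edit #{k}: unknown action {edit.action!r}")
        if not (0 <= edit.start <= edit.end < n):
            raise EditError(
                f"edit #{k} ({edit.action}): range [{edit.start}, {edit.end}] "
                f"outside vessel with {n} samples"
            )
        rng_ = slice(edit.start, edit.end + 1)
        sides = _edit_sides(edit)
        if edit.action == "erase_external":
            for s in sides:
                seg.external_radius[rng_, s] = np.nan
                seg.flags[rng_, s] = FLAG_EXCLUDED
            needs_fill = True
        elif edit.action == "set_external_radius":
            if edit.value is None or edit.value <= 0:
                raise EditError(f"edit #{k}: set_external_radius needs a positive value")
            for s in sides:
                seg.external_radius[rng_, s] = float(edit.value)
                seg.flags[rng_, s] = FLAG_CORRECTED
        else:  # exclude_sample
            seg.hard_excluded[rng_] = True
            for s in sides:
                seg.lumen_radius[rng_, s] = np.nan
                seg.external_radius[rng_, s] = np.nan
                seg.flags[rng_, s] = FLAG_EXCLUDED

    if needs_fill:
        lam = float(seg.params.get("stiffness", 2.0)) or 2.0
        for side in range(2):
            radii = seg.external_radius[:, side]
            w = np.isfinite(radii).astype(float)
            w[seg.hard_excluded] = 0.0
            smoothed = _penalized_smooth(radii, w, lam)
            filled = ~np.isfinite(radii) & ~seg.hard_excluded
            radii[filled] = smoothed[filled]
            seg.flags[filled, side] = FLAG_CORRECTED
    build_contours(seg)
    return seg


# ---------------------------------------------------------------------------
# orchestration, serialization, QC rendering
# ---------------------------------------------------------------------------

def segment_vessel(
    std_image: np.ndarray,
    mpg_image: np.ndarray,
    seed_point,
    *,
    sample_spacing: float = 2.0,
    min_length: float = 50.0,
    profile_step: float = 0.25,
    prominence_frac: float = 0.2,
    min_wall_offset: float = 2.0,
    stiffness: float = 2.0,
    continuity: bool = True,
) -> VesselSegmentation:
    """Trace the vessel and delineate both boundaries end to end."""
    trace = trace_centerline(
        std_image, seed_point, sample_spacing=sample_spacing, min_length=min_length
    )
    profiles = sample_profiles(trace, std_image, mpg_image, step=profile_step)
    lumen = detect_lumen_boundary(profiles)
    ext, cand = detect_external_boundary(
        profiles, lumen, prominence_frac=prominence_frac, min_wall_offset=min_wall_offset
    )
    seg = VesselSegmentation(
        trace=trace,
        lumen_radius=lumen,
        external_radius=ext,
        ext_candidates=cand,
        flags=_initial_flags(lumen, ext),
        hard_excluded=np.zeros(trace.n_samples, dtype=bool),
        params={
            "sample_spacing": sample_spacing,
            "profile_step": profile_step,
            "prominence_frac": prominence_frac,
            "min_wall_offset": min_wall_offset,
        },
    )
    if continuity:
        seg = enforce_continuity(seg, stiffness)
    build_contours(seg)
    return seg


def segmentation_to_dict(seg: VesselSegmentation) -> dict:
    return {
        "points": seg.trace.points,
        "normals": seg.trace.normals,
        "sample_spacing": seg.trace.sample_spacing,
        "r_init": seg.trace.r_init,
        "lumen_radius": seg.lumen_radius,
        "external_radius": seg.external_radius,
        "flags": seg.flags.tolist(),
        "hard_excluded": seg.hard_excluded,
        "params": seg.params,
    }


def segmentation_from_dict(d: dict) -> VesselSegmentation:
    trace = VesselTrace(
        points=np.asarray(d["points"], float),
        normals=np.asarray(d["normals"], float),
        sample_spacing=float(d["sample_spacing"]),
        r_init=float(d["r_init"]),
    )
    lumen = np.asarray(d["lumen_radius"], float)
    ext = np.asarray(d["external_radius"], float)
    seg = VesselSegmentation(
        trace=trace,
        lumen_radius=lumen,
        external_radius=ext,
        ext_candidates=[[np.empty(0), np.empty(0)] for _ in range(trace.n_samples)],
        flags=np.asarray(d["flags"], dtype=object),
        hard_excluded=np.asarray(d["hard_excluded"], bool),
        params=dict(d.get("params", {})),
    )
    build_contours(seg)
    return seg


def render_overlay(mean_image: np.ndarray, seg: VesselSegmentation, path) -> None:
    """QC overlay: lumen contour in green, external contour in magenta."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(mean_image, cmap="gray", interpolation="nearest")
    for contour, color in ((seg.lumen_contour, "lime"), (seg.external_contour, "magenta")):
        if contour is not None:
            closed = np.vstack([contour, contour[:1]])
            ax.plot(closed[:, 1], closed[:, 0], color=color, lw=1.0)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
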