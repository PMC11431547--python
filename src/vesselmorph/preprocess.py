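"""Frame selection, rigid registration and mean/STD (motion-contrast) images.

An AOSLO acquisition yields 100-200 frames per retinal location for each
detection channel (one confocal plus four offset apertures, acquired
simultaneously).  The best frames are selected by a quality score, aligned
by rigid translation, and collapsed into a per-pixel mean image and a
per-pixel temporal standard deviation (STD) image.  Moving blood cells
produce large temporal variance inside the perfused lumen, so the STD image
is a dye-free motion-contrast map of the blood column.

Registration is driven by the confocal channel; because all five channels
are acquired through the same scanner simultaneously, the confocal shifts
are applied verbatim to the offset channels (:func:`apply_shifts`).

Coordinate convention: 0-based ``(row, col)``, origin at the top-left pixel
centre; shifts are ``(dy, dx)`` such that ``frame[r, c] ~ scene[r - dy, c - dx]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.registration import phase_cross_correlation

logger = logging.getLogger(__name__)

CHANNELS = ("confocal", "offset_up", "offset_down", "offset_left", "offset_right")

#: shifts with magnitude below this (px) are snapped to zero so that an
#: already-aligned stack is not resampled at all
SHIFT_SNAP_PX = 0.1


class PreprocessError(ValueError):
    pass


@dataclass
class FrameStack:
    """One channel's temporal image stack.

    pixels: ``(frames, rows, cols)`` nonnegative intensities.
    pixel_scale: micrometres per pixel.
    frame_rate: frames per second (metadata only; no temporal model is used).
    """

    pixels: np.ndarray
    channel_label: str
    pixel_scale: float
    frame_rate: float = 30.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if not np.issubdtype(self.pixels.dtype, np.floating):
            self.pixels = self.pixels.astype(np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[0] < 1:
            raise PreprocessError("frame stack must be (frames, rows, cols) with >= 1 frame")
        if self.channel_label not in CHANNELS:
            raise PreprocessError(f"unknown channel label {self.channel_label!r}")
        if not self.pixel_scale > 0:
            raise PreprocessError("pixel_scale must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self):
        return self.pixels.shape[1:]


@dataclass
class RegisteredStack:
    """Aligned frames with their shifts and the jointly covered region."""

    pixels: np.ndarray           # (kept, rows, cols); NaN where a frame was shifted away
    shifts: np.ndarray           # (kept, 2) applied (dy, dx)
    kept_frames: np.ndarray      # indices into the original stack
    valid_mask: np.ndarray       # bool; pixels covered by all kept frames
    pixel_scale: float

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]


@dataclass
class DerivedImages:
    """Registered mean and temporal-STD image for one channel/location."""

    mean_image: np.ndarray
    std_image: np.ndarray
    pixel_scale: float
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# frame selection
# ---------------------------------------------------------------------------

def frame_quality_scores(stack: FrameStack) -> np.ndarray:
    """Normalised cross-correlation of each frame against the stack median.

    The median image is robust to a minority of distorted frames, so frames
    corrupted by blinks/saccades score low and fall out of the selection.
    """
    median = np.median(stack.pixels, axis=0)
    m = median - median.mean()
    m_norm = np.sqrt((m**2).sum())
    scores = np.empty(stack.n_frames)
    for i, frame in enumerate(stack.pixels):
        f = frame - frame.mean()
        denom = np.sqrt((f**2).sum()) * m_norm
        scores[i] = (f * m).sum() / denom if denom > 0 else 0.0
    return scores


def select_best_frames(stack: FrameStack, k: int) -> np.ndarray:
    """Indices of the ``k`` highest-quality frames, ascending; ties keep the
    lower frame index."""
    if not 1 <= k <= stack.n_frames:
        raise PreprocessError(f"k={k} outside [1, {stack.n_frames}]")
    scores = frame_quality_scores(stack)
    order = np.lexsort((np.arange(stack.n_frames), -scores))
    return np.sort(order[:k])


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _shift_frame(frame: np.ndarray, shift) -> np.ndarray:
    """Translate by ``(dy, dx)`` with linear interpolation; uncovered pixels NaN."""
    if shift[0] == 0.0 and shift[1] == 0.0:
        return frame.copy()
    return ndi.shift(frame, shift, order=1, mode="constant", cval=np.nan, prefilter=False)


def register_frames(
    stack: FrameStack,
    indices=None,
    *,
    upsample_factor: int = 20,
    max_shift_frac: float = 0.2,
) -> RegisteredStack:
    """Align selected frames to the highest-quality frame by phase correlation.

    Subpixel shifts come from upsampled phase correlation; frames whose
    estimated shift exceeds ``max_shift_frac`` of the image width are dropped
    with a warning (they are typically saccade-corrupted).
    """
    if indices is None:
        indices = np.arange(stack.n_frames)
    indices = np.asarray(indices, dtype=int)
    if indices.size < 2:
        raise PreprocessError("registration needs at least 2 frames")
    scores = frame_quality_scores(stack)
    ref_idx = indices[np.argmax(scores[indices])]
    # mean-subtract + Hann window before correlation: kills wrap-around edge
    # bias, which otherwise reaches ~0.2 px on smooth retinal scenes
    window = np.outer(
        np.hanning(stack.frame_shape[0]), np.hanning(stack.frame_shape[1])
    )
    ref = (stack.pixels[ref_idx] - stack.pixels[ref_idx].mean()) * window

    bound = max_shift_frac * stack.frame_shape[1]
    kept, shifts, aligned = [], [], []
    for i in indices:
        if i == ref_idx or np.ptp(stack.pixels[i]) == 0 or np.ptp(ref) == 0:
            sh = np.zeros(2)  # constant frames carry no registration signal
        else:
            frame = (stack.pixels[i] - stack.pixels[i].mean()) * window
            sh, _, _ = phase_cross_correlation(
                ref, frame, upsample_factor=upsample_factor, normalization=None
            )
            sh = np.asarray(sh, dtype=float)
        sh[np.abs(sh) < SHIFT_SNAP_PX] = 0.0
        if np.any(np.abs(sh) > bound):
            logger.warning("frame %d dropped: shift %s exceeds bound %.1f px", i, sh, bound)
            continue
        kept.append(i)
        shifts.append(sh)
        aligned.append(_shift_frame(stack.pixels[i], sh))

    if len(kept) < 2:
        raise PreprocessError("fewer than 2 frames survived registration")
    pixels = np.stack(aligned)
    valid = np.all(np.isfinite(pixels), axis=0)
    if not valid.any():
        raise PreprocessError("registered frames share no common footprint")
    return RegisteredStack(
        pixels=pixels,
        shifts=np.stack(shifts),
        kept_frames=np.asarray(kept),
        valid_mask=valid,
        pixel_scale=stack.pixel_scale,
    )


def apply_shifts(stack: FrameStack, kept_frames, shifts) -> RegisteredStack:
    """Apply shifts estimated on another (simultaneous) channel to this stack."""
    kept_frames = np.asarray(kept_frames, dtype=int)
    shifts = np.asarray(shifts, dtype=float)
    if kept_frames.shape[0] != shifts.shape[0]:
        raise PreprocessError("kept_frames and shifts length mismatch")
    pixels = np.stack([_shift_frame(stack.pixels[i], sh) for i, sh in zip(kept_frames, shifts)])
    valid = np.all(np.isfinite(pixels), axis=0)
    return RegisteredStack(
        pixels=pixels,
        shifts=shifts.copy(),
        kept_frames=kept_frames.copy(),
        valid_mask=valid,
        pixel_scale=stack.pixel_scale,
    )


# ---------------------------------------------------------------------------
# mean / STD images
# ---------------------------------------------------------------------------

def compute_mean_std(reg: RegisteredStack) -> DerivedImages:
    """Per-pixel mean and sample (n-1) standard deviation over kept frames.

    Pixels outside the jointly covered region are set to NaN and excluded
    from every downstream profile.
    """
    if reg.n_frames < 2:
        raise PreprocessError("STD needs at least 2 frames")
    if not reg.valid_mask.any():
        raise PreprocessError("empty valid mask")
    pixels = reg.pixels.astype(np.float64, copy=False)
    mean = np.mean(pixels, axis=0)
    std = np.std(pixels, axis=0, ddof=1)
    mean[~reg.valid_mask] = np.nan
    std[~reg.valid_mask] = np.nan
    return DerivedImages(
        mean_image=mean,
        std_image=std,
        pixel_scale=reg.pixel_scale,
        params={"n_frames": int(reg.n_frames), "ddof": 1},
    )


def default_keep_count(n_frames: int) -> int:
    """Default number of frames to keep: ``min(50, frames)``."""
    return min(50, n_frames)


def preprocess_acquisition(
    channels: dict[str, FrameStack],
    *,
    frames_keep: int | None = None,
    upsample_factor: int = 20,
    max_shift_frac: float = 0.2,
) -> tuple[dict[str, DerivedImages], RegisteredStack]:
    """Run selection + registration on the confocal channel and propagate the
    shifts to all offset channels; return derived images per channel.
    """
    if "confocal" not in channels:
        raise PreprocessError("acquisition lacks a confocal channel")
    conf = channels["confocal"]
    k = frames_keep if frames_keep is not None else default_keep_count(conf.n_frames)
    idx = select_best_frames(conf, k)
    reg = register_frames(
        conf, idx, upsample_factor=upsample_factor, max_shift_frac=max_shift_frac
    )
    derived = {"confocal": compute_mean_std(reg)}
    for name, stack in channels.items():
        if name == "confocal":
            continue
        derived[name] = compute_mean_std(apply_shifts(stack, reg.kept_frames, reg.shifts))
    return derived, reg
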