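"""Tail and eye kinematics from behavioural recordings.

Works on grayscale frame stacks (dark larva on a light background by
default) or directly on landmark/angle tables.  The tail midline is traced
from the swim-bladder anchor by stepping tailward along local intensity
centroids; the deflection angle is the signed angle between the body axis
and the distal chord of the midline (its 70 % point to the tip) — a
definition robust to proximal tracking noise.  Swim bouts (rapid side-to-
side oscillation) are separated from slow postural changes by the
zero-crossing rate of the detrended angle.  Eye roll is the rotation of the
chord between two pigment landmarks per eye, reported relative to the
pre-stimulus baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FrameSequence",
    "TailTrackingConfig",
    "TailTrace",
    "EyeTrace",
    "BoutEvent",
    "extract_tail_midline",
    "tail_deflection_angle",
    "track_tail",
    "detect_bouts",
    "eye_rotation",
    "detect_eye_landmarks",
]


@dataclass(frozen=True)
class FrameSequence:
    """Grayscale stack with acquisition geometry and body-axis anchors.

    ``head_px`` and ``swim_bladder_px`` are (x, y) pixel coordinates; the
    body axis points from head to swim bladder (i.e. tailward).
    """

    frames: np.ndarray  # (t, h, w)
    frame_rate_hz: float
    pixel_size_um: float
    head_px: tuple[float, float]
    swim_bladder_px: tuple[float, float]

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be > 0")
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("need a (t, h, w) stack with >= 2 frames")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) / self.frame_rate_hz


@dataclass(frozen=True)
class TailTrackingConfig:
    """Parameters of the centroid-stepping midline tracer."""

    n_points: int = 20
    tail_length_px: float = 280.0
    dark_on_light: bool = True
    search_half_angle_deg: float = 40.0
    n_probe: int = 81
    #: intensity (after inversion) below this fraction of the frame's dynamic
    #: range is treated as background
    threshold_frac: float = 0.3

    @property
    def step_px(self) -> float:
        return self.tail_length_px / (self.n_points - 1)


@dataclass
class TailTrace:
    """Per-frame tail deflection (degrees, signed) with midlines."""

    time_s: np.ndarray
    deflection_deg: np.ndarray
    midlines: list  # per-frame (n_points, 2) arrays or None on failure
    failed: np.ndarray  # bool per frame
    frame_rate_hz: float = 0.0


@dataclass
class EyeTrace:
    """Per-frame left/right eye rotation vs. the body midline (degrees)."""

    time_s: np.ndarray
    left_deg: np.ndarray
    right_deg: np.ndarray
    flagged: np.ndarray  # frames with missing landmarks
    baseline_deg: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class BoutEvent:
    """One episode of rhythmic tail oscillation."""

    onset_s: float
    offset_s: float
    dominant_freq_hz: float
    classification: str = "swim"  # {"swim", "escape"}

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must follow onset")
        if self.dominant_freq_hz <= 0:
            raise ValueError("frequency must be > 0")


def _bilinear(img: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Bilinear image samples at float (x, y); outside points give 0."""
    h, w = img.shape
    x, y = xy[:, 0], xy[:, 1]
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    inside = (x0 >= 0) & (x0 < w - 1) & (y0 >= 0) & (y0 < h - 1)
    out = np.zeros(xy.shape[0])
    if not np.any(inside):
        return out
    xi, yi = x0[inside], y0[inside]
    fx, fy = x[inside] - xi, y[inside] - yi
    out[inside] = (
        img[yi, xi] * (1 - fx) * (1 - fy)
        + img[yi, xi + 1] * fx * (1 - fy)
        + img[yi + 1, xi] * (1 - fx) * fy
        + img[yi + 1, xi + 1] * fx * fy
    )
    return out


def extract_tail_midline(
    frame: np.ndarray,
    head_px: tuple[float, float],
    swim_bladder_px: tuple[float, float],
    config: TailTrackingConfig | None = None,
) -> tuple[np.ndarray | None, bool]:
    """Trace the tail midline from the swim bladder tailward.

    At each of ``n_points - 1`` steps, candidate directions within
    ``±search_half_angle_deg`` of the previous heading are probed at the
    step radius; the next heading is the intensity-weighted circular mean of
    candidates above threshold.  Returns ``(points, ok)``; a lost tail (no
    above-threshold probe at some step) returns the partial result with
    ``ok = False``.
    """
    cfg = config or TailTrackingConfig()
    img = np.asarray(frame, dtype=float)
    if cfg.dark_on_light:
        img = img.max() - img
    lo, hi = np.percentile(img, [50.0, 99.8])
    if hi <= lo:
        return None, False
    thresh = lo + cfg.threshold_frac * (hi - lo)

    p = np.asarray(swim_bladder_px, dtype=float)
    heading = np.arctan2(
        swim_bladder_px[1] - head_px[1], swim_bladder_px[0] - head_px[0]
    )
    pts = [p.copy()]
    half = np.radians(cfg.search_half_angle_deg)
    cand_rel = np.linspace(-half, half, cfg.n_probe)
    for _ in range(cfg.n_points - 1):
        angles = heading + cand_rel
        probes = p[None, :] + cfg.step_px * np.column_stack(
            [np.cos(angles), np.sin(angles)]
        )
        vals = _bilinear(img, probes) - thresh
        vals[vals < 0] = 0.0
        if vals.sum() <= 0:
            return (np.asarray(pts) if len(pts) > 1 else None), False
        heading = heading + float(np.sum(cand_rel * vals) / vals.sum())
        p = p + cfg.step_px * np.array([np.cos(heading), np.sin(heading)])
        pts.append(p.copy())
    return np.asarray(pts), True


def tail_deflection_angle(
    midline: np.ndarray,
    body_axis: np.ndarray,
    chord_start_frac: float = 0.7,
) -> float:
    """Signed angle (degrees) of the distal midline chord vs. the body axis.

    The chord runs from the point at ``chord_start_frac`` of the midline's
    arclength to the tip.  Sign follows the right-handed (x, y) convention:
    with the fish pointing along +x, positive means a bend toward +y
    (leftward for a dorsal view with y up the image).  Mirroring the frame
    negates the angle.
    """
    m = np.asarray(midline, dtype=float)
    seg = np.linalg.norm(np.diff(m, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total <= 0:
        return 0.0
    s0 = chord_start_frac * total
    start = np.array(
        [np.interp(s0, arclen, m[:, 0]), np.interp(s0, arclen, m[:, 1])]
    )
    chord = m[-1] - start
    ax = np.asarray(body_axis, dtype=float)
    ang = np.arctan2(
        ax[0] * chord[1] - ax[1] * chord[0], ax[0] * chord[0] + ax[1] * chord[1]
    )
    return float(np.degrees(ang))


def track_tail(
    stack: FrameSequence, config: TailTrackingConfig | None = None
) -> TailTrace:
    """Run midline extraction + deflection angle on every frame."""
    cfg = config or TailTrackingConfig()
    axis = np.asarray(stack.swim_bladder_px) - np.asarray(stack.head_px)
    angles, midlines, failed = [], [], []
    for frame in stack.frames:
        mid, ok = extract_tail_midline(
            frame, stack.head_px, stack.swim_bladder_px, cfg
        )
        midlines.append(mid)
        failed.append(not ok)
        angles.append(tail_deflection_angle(mid, axis) if ok else np.nan)
    return TailTrace(
        time_s=stack.times_s,
        deflection_deg=np.asarray(angles),
        midlines=midlines,
        failed=np.asarray(failed),
        frame_rate_hz=stack.frame_rate_hz,
    )


def detect_bouts(
    angle_deg: np.ndarray,
    frame_rate_hz: float,
    crossing_rate_hz: float = 10.0,
    min_cycles: int = 3,
    merge_gap_s: float = 0.1,
    amplitude_deg: float = 4.0,
    detrend_window_s: float = 0.25,
    escape_velocity_dps: float = 3000.0,
) -> list[BoutEvent]:
    """Detect rhythmic swim bouts in a deflection-angle trace.

    The trace is detrended by a running mean (so slow postural ramps drop
    out), and sign crossings are counted with hysteresis: a crossing
    registers only once the signal exceeds ``amplitude_deg`` on the new
    side, which makes pure noise (SD up to ~2 deg) crossing-free.  Runs of
    crossings at a rate above ``crossing_rate_hz`` form a bout if they span
    at least ``min_cycles`` cycles — k full cycles above threshold produce
    2k - 1 interior sign alternations; bouts closer than ``merge_gap_s``
    are merged.  A bout whose peak angular velocity
    exceeds ``escape_velocity_dps`` is classified "escape".
    """
    x = np.asarray(angle_deg, dtype=float)
    x = np.where(np.isfinite(x), x, 0.0)
    n = x.size
    win = max(3, int(round(detrend_window_s * frame_rate_hz)) | 1)
    kernel = np.ones(win) / win
    trend = np.convolve(np.pad(x, win // 2, mode="edge"), kernel, mode="valid")
    # light smoothing: cuts measurement noise without touching bout-band signal
    smooth_w = max(3, int(round(frame_rate_hz / 60.0)) | 1)
    sk = np.ones(smooth_w) / smooth_w
    d = np.convolve(np.pad(x - trend, smooth_w // 2, mode="edge"), sk, mode="valid")

    # hysteresis crossings
    crossings = []
    state = 0  # last confirmed side: -1, 0 (unknown), +1
    for i in range(n):
        if d[i] > amplitude_deg and state <= 0:
            if state < 0:
                crossings.append(i)
            state = 1
        elif d[i] < -amplitude_deg and state >= 0:
            if state > 0:
                crossings.append(i)
            state = -1
    if len(crossings) < 2 * min_cycles - 1:
        return []

    max_gap = frame_rate_hz / crossing_rate_hz  # frames between crossings
    groups, current = [], [crossings[0]]
    for c in crossings[1:]:
        if c - current[-1] <= max_gap:
            current.append(c)
        else:
            if len(current) >= 2 * min_cycles - 1:
                groups.append(current)
            current = [c]
    if len(current) >= 2 * min_cycles - 1:
        groups.append(current)

    events = []
    half_period = 0.5 * frame_rate_hz / crossing_rate_hz
    for g in groups:
        onset = max(0.0, (g[0] - half_period)) / frame_rate_hz
        offset = min(n - 1.0, (g[-1] + half_period)) / frame_rate_hz
        # crossing rate / 2 = oscillation frequency
        freq = 0.5 * (len(g) - 1) / ((g[-1] - g[0]) / frame_rate_hz)
        i0, i1 = int(onset * frame_rate_hz), int(np.ceil(offset * frame_rate_hz))
        vel = np.abs(np.gradient(x[i0 : i1 + 1]) * frame_rate_hz)
        cls = "escape" if vel.max() > escape_velocity_dps else "swim"
        events.append(
            BoutEvent(onset_s=onset, offset_s=offset, dominant_freq_hz=freq,
                      classification=cls)
        )

    # merge bouts separated by short gaps
    merged: list[BoutEvent] = []
    for ev in events:
        if merged and ev.onset_s - merged[-1].offset_s < merge_gap_s:
            prev = merged.pop()
            dur_a = prev.offset_s - prev.onset_s
            dur_b = ev.offset_s - ev.onset_s
            freq = (prev.dominant_freq_hz * dur_a + ev.dominant_freq_hz * dur_b) / (
                dur_a + dur_b
            )
            cls = "escape" if "escape" in (prev.classification, ev.classification) else "swim"
            merged.append(
                BoutEvent(prev.onset_s, ev.offset_s, freq, cls)
            )
        else:
            merged.append(ev)
    return merged


def _chord_angle_deg(p0: np.ndarray, p1: np.ndarray, axis: np.ndarray) -> float:
    """Angle of the undirected chord p0->p1 vs. axis, wrapped to (-90, 90]."""
    chord = p1 - p0
    ang = np.degrees(
        np.arctan2(
            axis[0] * chord[1] - axis[1] * chord[0],
            axis[0] * chord[0] + axis[1] * chord[1],
        )
    )
    ang = np.mod(ang + 90.0, 180.0) - 90.0
    return float(90.0 if ang == -90.0 else ang)


def eye_rotation(
    landmarks: np.ndarray,
    midline_axis,
    frame_rate_hz: float,
    baseline_window_s: tuple[float, float] | None = None,
) -> EyeTrace:
    """Eye-roll traces from pigment-landmark pairs.

    ``landmarks`` has shape (t, 2 eyes, 2 points, 2 xy) — left eye first.
    Per frame and eye, the angle of the landmark chord vs. the body midline
    is computed; frames with any non-finite landmark are flagged and carry
    NaN.  If ``baseline_window_s`` is given, the mean angle over that window
    is subtracted so traces read as change from baseline.
    """
    lm = np.asarray(landmarks, dtype=float)
    if lm.ndim != 4 or lm.shape[1:] != (2, 2, 2):
        raise ValueError("landmarks must have shape (t, 2, 2, 2)")
    axis = np.asarray(midline_axis, dtype=float)
    t = lm.shape[0]
    flagged = ~np.isfinite(lm).all(axis=(1, 2, 3))
    left = np.full(t, np.nan)
    right = np.full(t, np.nan)
    for i in range(t):
        if flagged[i]:
            continue
        left[i] = _chord_angle_deg(lm[i, 0, 0], lm[i, 0, 1], axis)
        right[i] = _chord_angle_deg(lm[i, 1, 0], lm[i, 1, 1], axis)
    times = np.arange(t) / frame_rate_hz

    base = (0.0, 0.0)
    if baseline_window_s is not None:
        sel = (times >= baseline_window_s[0]) & (times < baseline_window_s[1])
        sel &= ~flagged
        if np.any(sel):
            base = (float(np.mean(left[sel])), float(np.mean(right[sel])))
            left = left - base[0]
            right = right - base[1]
    return EyeTrace(
        time_s=times, left_deg=left, right_deg=right, flagged=flagged,
        baseline_deg=base,
    )


def detect_eye_landmarks(
    frame: np.ndarray,
    eye_centres_px,
    roi_half_px: int = 20,
    n_landmarks: int = 2,
    dark_on_light: bool = True,
) -> np.ndarray:
    """Locate pigment-landmark dots near each eye centre.

    Within a square ROI around each given eye centre, pixels in the darkest
    (or brightest) intensity tail are segmented; the ``n_landmarks`` largest
    connected components give intensity-weighted centroids.  Returns an
    array (n_eyes, n_landmarks, 2) of (x, y); missing landmarks are NaN.
    Within each eye, landmarks are ordered by x for frame-to-frame
    correspondence.
    """
    img = np.asarray(frame, dtype=float)
    if dark_on_light:
        img = img.max() - img
    out = np.full((len(eye_centres_px), n_landmarks, 2), np.nan)
    h, w = img.shape
    for e, (cx, cy) in enumerate(eye_centres_px):
        x0, x1 = max(0, int(cx) - roi_half_px), min(w, int(cx) + roi_half_px)
        y0, y1 = max(0, int(cy) - roi_half_px), min(h, int(cy) + roi_half_px)
        roi = img[y0:y1, x0:x1]
        if roi.size == 0:
            continue
        thresh = roi.min() + 0.6 * (roi.max() - roi.min())
        mask = roi > thresh
        labels, n_found = ndimage.label(mask)
        if n_found == 0:
            continue
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_found + 1))
        order = np.argsort(sizes)[::-1][:n_landmarks]
        weights = np.where(mask, roi - thresh, 0.0)
        pts = []
        for lab in order + 1:
            wsel = np.where(labels == lab, weights, 0.0)
            cy_i, cx_i = ndimage.center_of_mass(wsel)
            pts.append((x0 + cx_i, y0 + cy_i))
        pts.sort(key=lambda p: (p[0], p[1]))  # by x: stable for roll < ~45 deg
        for k, p in enumerate(pts):
            out[e, k] = p
    return out
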