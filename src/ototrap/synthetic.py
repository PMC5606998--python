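"""Seeded generators for every input the analysis pipeline consumes.

Three generators cover the experimental observables:

``generate_scan``
    A trap-force deflection scan over a circular particle: a radial field
    peaked at the particle edge, modulated by angular sectors (two wide
    strong arcs and two narrow weak arcs, emulating otolith birefringence)
    plus Gaussian heterogeneity noise.
``generate_trial_set``
    Trial-level tail/eye traces for the behavioural protocol: power-scaled
    contralateral tail deflection with saturating power dependence,
    probabilistic swim bouts at high power, flat-then-rebound responses to
    medial traps, additive dual-trap responses, unison eye roll for lateral
    traps only, and injected contamination (spontaneous bouts, escapes).
``render_frames``
    Synthetic microscopy frames (dark larva on light background) drawn from
    specified tail/eye angles, solvable by :mod:`ototrap.tracking`.

Every generator takes a seed, records it, and returns its ground truth; the
same seed reproduces output bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .forcemap import DeflectionScan
from .tracking import BoutEvent, FrameSequence
from .trialstats import ProtocolConfig, TrialRecord

__all__ = [
    "ScanGeneratorConfig",
    "BehaviorGeneratorConfig",
    "FrameGeometry",
    "generate_scan",
    "generate_trial_set",
    "render_frames",
]


# --------------------------------------------------------------------------
# force scans
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanGeneratorConfig:
    """Parameters of the synthetic deflection scan.

    Default sector amplitudes follow the measured birefringence pattern:
    two wide 5.0 pN arcs and two narrow 3.0 pN arcs; heterogeneity noise
    0.5 pN.  The radial profile is flat within ``edge_flat_um`` of the
    particle radius and falls off with a Gaussian shoulder outside that.
    """

    centre_um: tuple[float, float] = (0.0, 0.0)
    radius_um: float = 27.5
    sector_edges_deg: tuple = (0.0, 110.0, 180.0, 290.0)
    sector_amplitudes_pn: tuple = (5.0, 3.0, 5.0, 3.0)
    noise_sd_pn: float = 0.5
    grid_step_um: float = 0.5
    grid_extent_factor: float = 1.3
    edge_flat_um: float = 2.0
    edge_falloff_um: float = 3.0
    power_mw: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.sector_amplitudes_pn):
            raise ValueError("sector amplitudes must be >= 0")
        if len(self.sector_amplitudes_pn) != len(self.sector_edges_deg):
            raise ValueError("one amplitude per sector edge")


def _sector_amplitude(angles_deg: np.ndarray, edges, amplitudes) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    rel = np.mod(angles_deg - edges[0], 360.0)
    rel_edges = np.concatenate([np.mod(edges - edges[0], 360.0), [360.0]])
    out = np.empty(angles_deg.shape)
    for i in range(edges.size):
        sel = (rel >= rel_edges[i]) & (rel < rel_edges[i + 1])
        out[sel] = amplitudes[i]
    return out


def generate_scan(config: ScanGeneratorConfig) -> tuple[DeflectionScan, dict]:
    """Synthesise a deflection scan and return it with its ground truth.

    The noiseless field at a node with polar coordinates (r, phi) about the
    particle centre is ``A(phi) * bump(r)`` pointing radially inward (the
    beam-reaction convention of the optics model and PSD measurements),
    where ``bump`` is 1 on the edge plateau and Gaussian outside it.
    """
    rng = np.random.default_rng(config.seed)
    half = config.grid_extent_factor * config.radius_um
    coords = np.arange(-half, half + 1e-9, config.grid_step_um)
    xx, yy = np.meshgrid(coords, coords)
    x = (xx + config.centre_um[0]).ravel()
    y = (yy + config.centre_um[1]).ravel()

    dx, dy = x - config.centre_um[0], y - config.centre_um[1]
    r = np.hypot(dx, dy)
    ang = np.mod(np.degrees(np.arctan2(dy, dx)), 360.0)

    dr = np.abs(r - config.radius_um) - config.edge_flat_um
    bump = np.where(dr <= 0, 1.0, np.exp(-(dr**2) / (2 * config.edge_falloff_um**2)))
    amp = _sector_amplitude(ang, config.sector_edges_deg, config.sector_amplitudes_pn)
    mag = amp * bump

    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, dx / r, 0.0)
        uy = np.where(r > 0, dy / r, 0.0)
    fx = -mag * ux
    fy = -mag * uy
    fx_noisy = fx + rng.normal(0.0, config.noise_sd_pn, fx.shape)
    fy_noisy = fy + rng.normal(0.0, config.noise_sd_pn, fy.shape)

    scan = DeflectionScan(
        x_um=x, y_um=y, fx_pn=fx_noisy, fy_pn=fy_noisy,
        metadata={"power_mw": config.power_mw,
                  "grid_step_um": config.grid_step_um,
                  "seed": config.seed},
    )
    truth = {
        "config": asdict(config),
        "fx_clean_pn": fx,
        "fy_clean_pn": fy,
        "centre_um": config.centre_um,
        "radius_um": config.radius_um,
        "sector_edges_deg": config.sector_edges_deg,
        "sector_amplitudes_pn": config.sector_amplitudes_pn,
        "seed": config.seed,
    }
    return scan, truth


# --------------------------------------------------------------------------
# behavioural trials
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorGeneratorConfig:
    """Parameters of the behavioural trial generator.

    Responses use the protocol's power ladder and trap loci.  The power →
    plateau map saturates as ``p^2 / (p^2 + p_half^2)`` (quadratic at low
    power, capped at high power) so that the 600 mW response sits near the
    maximum and the curve is well described by a second-order polynomial
    over the tested range.  Magnitudes are in the spirit of the in-vivo
    observations, not reproductions of them.
    """

    powers_mw: tuple = (50.0, 100.0, 200.0, 400.0, 600.0)
    tail_max_deg: float = 25.0
    eye_max_deg: float = 10.0
    power_half_mw: float = 300.0
    swim_p50_mw: float = 300.0
    swim_slope_mw: float = 80.0
    medial_rebound_deg: float = -8.0
    dual_additivity: float = 1.0
    ramp_tau_s: float = 0.15
    decay_tau_s: float = 0.3
    tail_noise_sd_deg: float = 0.5
    eye_noise_sd_deg: float = 0.2
    larva_gain_sd: float = 0.1
    swim_bout_amp_deg: float = 10.0
    swim_bout_freq_hz: float = 20.0
    swim_bout_duration_s: float = 0.35
    spont_bout_rate: float = 0.0  # probability per trial of a pre/post bout
    escape_rate: float = 0.0
    frame_rate_hz: float = 200.0
    pre_s: float = 2.0
    exposure_s: float = 1.0
    post_s: float = 2.0
    n_larvae: int = 6
    trials_per_condition: int = 3
    seed: int = 0

    def plateau_deg(self, power_mw: float, peak_deg: float) -> float:
        p2 = power_mw**2
        return peak_deg * p2 / (p2 + self.power_half_mw**2)

    def swim_probability(self, power_mw: float) -> float:
        return 1.0 / (1.0 + math.exp(-(power_mw - self.swim_p50_mw) / self.swim_slope_mw))

    def protocol(self) -> ProtocolConfig:
        return ProtocolConfig(
            exposure_s=self.exposure_s,
            trials_per_condition=self.trials_per_condition,
            powers_mw=self.powers_mw,
            onset_s=self.pre_s,
        )


def _sine_bout(
    t: np.ndarray, onset: float, duration: float, amp: float, freq: float
) -> np.ndarray:
    env = np.zeros_like(t)
    sel = (t >= onset) & (t <= onset + duration)
    phase = (t[sel] - onset) / duration
    env[sel] = np.sin(np.pi * phase) ** 2  # smooth on/off
    return amp * env * np.sin(2 * np.pi * freq * (t - onset))


def _postural_trace(
    t: np.ndarray, on: float, off: float, plateau: float,
    ramp_tau: float, decay_tau: float, rebound: float = 0.0,
) -> np.ndarray:
    x = np.zeros_like(t)
    during = (t >= on) & (t <= off)
    x[during] = plateau * (1.0 - np.exp(-(t[during] - on) / ramp_tau))
    after = t > off
    level = plateau * (1.0 - np.exp(-(off - on) / ramp_tau))
    x[after] = level * np.exp(-(t[after] - off) / decay_tau)
    if rebound != 0.0:
        # offset rebound: difference of exponentials, peak-normalised so the
        # transient's extremum equals `rebound`
        tau2 = 0.4 * decay_tau
        t_peak = math.log(decay_tau / tau2) / (1.0 / tau2 - 1.0 / decay_tau)
        peak = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / tau2)
        x[after] += (rebound / peak) * (
            np.exp(-(t[after] - off) / decay_tau)
            - np.exp(-(t[after] - off) / tau2)
        )
    return x


def generate_trial_set(
    config: BehaviorGeneratorConfig,
) -> tuple[list[TrialRecord], dict]:
    """Generate the full behavioural trial set with ground truth.

    Conditions per larva: ``lateral`` at every power, ``centre`` / ``medial``
    / ``dual`` at the top power.  Lateral trials bend the tail (reported
    positive, i.e. contralateral) toward a power-dependent plateau and may
    superimpose a swim bout with the power-dependent probability; medial
    trials are flat during the trap and rebound in the opposite direction at
    offset; dual trials are the additivity-weighted sum of the two; centre
    trials are baseline only.  Eyes roll in unison for conditions with a
    lateral trap and stay flat otherwise.  Contamination (spontaneous
    pre/post bouts, escapes) is injected at the configured rates and
    recorded in the truth table.
    """
    rng = np.random.default_rng(config.seed)
    proto = config.protocol()
    on, off = proto.onset_s, proto.offset_s
    n_t = int(round((config.pre_s + config.exposure_s + config.post_s)
                    * config.frame_rate_hz)) + 1
    t = np.arange(n_t) / config.frame_rate_hz
    top = max(config.powers_mw)

    conditions = [("lateral", p) for p in config.powers_mw]
    conditions += [("centre", top), ("medial", top), ("dual", top)]

    trials: list[TrialRecord] = []
    truth_rows: list[dict] = []
    for larva in range(config.n_larvae):
        gain = 1.0 + rng.normal(0.0, config.larva_gain_sd)
        for cond, power in conditions:
            for trial_ix in range(config.trials_per_condition):
                lat_plateau = gain * config.plateau_deg(power, config.tail_max_deg)
                eye_plateau = gain * config.plateau_deg(power, config.eye_max_deg)

                if cond == "lateral":
                    tail = _postural_trace(
                        t, on, off, lat_plateau, config.ramp_tau_s, config.decay_tau_s
                    )
                    eye = _postural_trace(
                        t, on, off, eye_plateau, config.ramp_tau_s, config.decay_tau_s
                    )
                elif cond == "medial":
                    tail = _postural_trace(
                        t, on, off, 0.0, config.ramp_tau_s, config.decay_tau_s,
                        rebound=gain * config.medial_rebound_deg,
                    )
                    eye = np.zeros_like(t)
                elif cond == "dual":
                    lat = _postural_trace(
                        t, on, off, lat_plateau, config.ramp_tau_s, config.decay_tau_s
                    )
                    med = _postural_trace(
                        t, on, off, 0.0, config.ramp_tau_s, config.decay_tau_s,
                        rebound=gain * config.medial_rebound_deg,
                    )
                    tail = config.dual_additivity * (lat + med)
                    eye = _postural_trace(
                        t, on, off, eye_plateau, config.ramp_tau_s, config.decay_tau_s
                    )
                else:  # centre: no coherent force, no response
                    tail = np.zeros_like(t)
                    eye = np.zeros_like(t)

                bouts: list[BoutEvent] = []
                swam = False
                if cond in ("lateral", "dual") and rng.random() < config.swim_probability(power):
                    swam = True
                    b_on = on + rng.uniform(0.05, 0.4)
                    tail = tail + _sine_bout(
                        t, b_on, config.swim_bout_duration_s,
                        config.swim_bout_amp_deg, config.swim_bout_freq_hz,
                    )
                    bouts.append(BoutEvent(
                        b_on, b_on + config.swim_bout_duration_s,
                        config.swim_bout_freq_hz, "swim",
                    ))

                contamination = "none"
                u = rng.random()
                if u < config.escape_rate:
                    contamination = "escape"
                    e_on = on + rng.uniform(0.0, config.exposure_s - 0.2)
                    tail = tail + _sine_bout(t, e_on, 0.15, 35.0, 35.0)
                    bouts.append(BoutEvent(e_on, e_on + 0.15, 35.0, "escape"))
                elif u < config.escape_rate + config.spont_bout_rate:
                    if rng.random() < 0.5:
                        contamination = "pre_swim"
                        b_end = on - rng.uniform(0.2, 0.8)
                        b_on = b_end - 0.3
                    else:
                        contamination = "post_swim"
                        b_on = off + rng.uniform(0.2, 0.8)
                        b_end = b_on + 0.3
                    tail = tail + _sine_bout(
                        t, b_on, b_end - b_on,
                        config.swim_bout_amp_deg, config.swim_bout_freq_hz,
                    )
                    bouts.append(BoutEvent(
                        b_on, b_end, config.swim_bout_freq_hz, "swim"
                    ))

                tail_noisy = tail + rng.normal(0, config.tail_noise_sd_deg, n_t)
                roll = eye + rng.normal(0, config.eye_noise_sd_deg, n_t)
                eye_l = roll + rng.normal(0, config.eye_noise_sd_deg, n_t)
                eye_r = roll + rng.normal(0, config.eye_noise_sd_deg, n_t)

                lid = f"larva{larva:02d}"
                trials.append(TrialRecord(
                    larva_id=lid, condition=cond, power_mw=power,
                    time_s=t, tail_deg=tail_noisy,
                    eye_left_deg=eye_l, eye_right_deg=eye_r,
                    bouts=bouts,
                ))
                truth_rows.append({
                    "larva_id": lid, "condition": cond, "power_mw": power,
                    "trial_index": trial_ix,
                    "tail_plateau_deg": lat_plateau if cond in ("lateral", "dual") else 0.0,
                    "eye_plateau_deg": eye_plateau if cond in ("lateral", "dual") else 0.0,
                    "gain": gain, "swam": swam,
                    "contamination": contamination,
                })
    truth = {
        "config": asdict(config),
        "seed": config.seed,
        "trials": truth_rows,
        "protocol": proto,
    }
    return trials, truth


# --------------------------------------------------------------------------
# frame rendering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameGeometry:
    """Synthetic frame layout: 600x300 px at 2 µm/px, fish along +x."""

    width_px: int = 600
    height_px: int = 300
    pixel_size_um: float = 2.0
    frame_rate_hz: float = 200.0
    head_px: tuple[float, float] = (150.0, 150.0)
    swim_bladder_px: tuple[float, float] = (260.0, 150.0)
    tail_length_px: float = 280.0
    eye_centres_px: tuple = ((150.0, 105.0), (150.0, 195.0))
    eye_landmark_radius_px: float = 12.0
    background: float = 200.0
    body_intensity: float = 60.0
    noise_sd: float = 4.0
    max_angle_deg: float = 45.0


def _tail_midline_arc(geom: FrameGeometry, angle_deg: float, n: int = 200) -> np.ndarray:
    """Constant-curvature tail whose distal chord (70 % -> tip) makes
    ``angle_deg`` with the body axis.

    For an arc of length L with curvature k starting tangent to +x, the
    chord from arclength s0 to L makes the angle k (L + s0) / 2 with the
    axis, so k = theta / (0.85 L) exactly.
    """
    if abs(angle_deg) > geom.max_angle_deg:
        raise ValueError(
            f"tail angle {angle_deg} beyond drawable range ±{geom.max_angle_deg}"
        )
    L = geom.tail_length_px
    theta = math.radians(angle_deg)
    k = theta / (0.85 * L)
    s = np.linspace(0.0, L, n)
    if abs(k) < 1e-12:
        x, y = s, np.zeros_like(s)
    else:
        x = np.sin(k * s) / k
        y = (1.0 - np.cos(k * s)) / k
    sb = np.asarray(geom.swim_bladder_px)
    return np.column_stack([sb[0] + x, sb[1] + y])


def _stamp_gaussian(darkness: np.ndarray, cx: float, cy: float,
                    sigma: float, amp: float) -> None:
    h, w = darkness.shape
    r = int(math.ceil(3 * sigma))
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    g = amp * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma**2))
    np.maximum(darkness[y0:y1, x0:x1], g, out=darkness[y0:y1, x0:x1])


def _eye_landmarks(geom: FrameGeometry, eye_angles_deg) -> np.ndarray:
    """Landmark positions (2 eyes, 2 points, 2 xy) for given eye rotations."""
    out = np.empty((2, 2, 2))
    base = np.radians([180.0, 0.0])  # diametral: chord angle == roll angle
    for e, (cx, cy) in enumerate(geom.eye_centres_px):
        rot = math.radians(eye_angles_deg[e])
        for k, b in enumerate(base):
            a = b + rot
            out[e, k] = (
                cx + geom.eye_landmark_radius_px * math.cos(a),
                cy + geom.eye_landmark_radius_px * math.sin(a),
            )
    return out


def render_frames(
    tail_angles_deg,
    geometry: FrameGeometry | None = None,
    eye_angles_deg=None,
    seed: int = 0,
) -> tuple[FrameSequence, np.ndarray]:
    """Draw a frame stack from per-frame tail (and optional eye) angles.

    Returns the stack and the ground-truth eye-landmark coordinates
    (t, 2, 2, 2).  The larva is dark on a light noisy background: an
    elliptical body between head and swim bladder, a tapering constant-
    curvature tail, and two near-black pigment dots per eye.
    """
    geom = geometry or FrameGeometry()
    tail_angles = np.atleast_1d(np.asarray(tail_angles_deg, dtype=float))
    if eye_angles_deg is None:
        eye_arr = np.zeros((tail_angles.size, 2))
    else:
        eye_arr = np.atleast_2d(np.asarray(eye_angles_deg, dtype=float))
        if eye_arr.shape == (1, tail_angles.size) and tail_angles.size != 2:
            eye_arr = np.repeat(eye_arr.T, 2, axis=1)
        if eye_arr.shape != (tail_angles.size, 2):
            raise ValueError("eye_angles_deg must broadcast to (t, 2)")

    rng = np.random.default_rng(seed)
    h, w = geom.height_px, geom.width_px
    head = np.asarray(geom.head_px)
    sb = np.asarray(geom.swim_bladder_px)

    frames = np.empty((tail_angles.size, h, w), dtype=np.uint8)
    landmarks = np.empty((tail_angles.size, 2, 2, 2))
    body_dark = geom.background - geom.body_intensity

    for i, ang in enumerate(tail_angles):
        darkness = np.zeros((h, w))
        # body: overlapping discs from head to swim bladder
        for f in np.linspace(-0.15, 1.0, 14):
            c = head + f * (sb - head)
            _stamp_gaussian(darkness, c[0], c[1], 11.0, body_dark)
        # tail: tapering soft polyline
        mid = _tail_midline_arc(geom, ang)
        sigmas = np.linspace(5.0, 1.6, mid.shape[0])
        for (px, py), sg in zip(mid[::2], sigmas[::2]):
            _stamp_gaussian(darkness, px, py, sg, body_dark)
        # eye pigment dots: darker than the body
        lm = _eye_landmarks(geom, eye_arr[i])
        landmarks[i] = lm
        for e in range(2):
            for k in range(2):
                _stamp_gaussian(darkness, lm[e, k, 0], lm[e, k, 1], 1.8,
                                geom.background)
        img = geom.background - darkness + rng.normal(0, geom.noise_sd, (h, w))
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)

    stack = FrameSequence(
        frames=frames,
        frame_rate_hz=geom.frame_rate_hz,
        pixel_size_um=geom.pixel_size_um,
        head_px=tuple(head),
        swim_bladder_px=tuple(sb),
    )
    return stack, landmarks
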