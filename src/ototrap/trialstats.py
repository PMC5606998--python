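"""Trial-level protocol encoding, exclusion criteria and summary statistics.

The behavioural protocol presents 1 s optical-trap stimuli with 9 s rest,
three trials per condition, over a ladder of laser powers and trap loci
(lateral edge, medial edge, otolith centre, single or dual traps).  Trials
contaminated by spontaneous behaviour are excluded: a spontaneous swim bout
ending within 1 s before trap onset, a bout starting within 1 s after trap
offset, or an escape during / within 1 s of the trap.  Condition summaries
then average the two or three surviving trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .tracking import BoutEvent

__all__ = [
    "ProtocolConfig",
    "TrialRecord",
    "ConditionSummary",
    "apply_exclusion",
    "onset_offset_response",
    "linear_summation_test",
    "swim_probability",
    "power_response_fit",
    "paired_t_test",
]

EXCLUSION_REASONS = ("none", "pre_swim", "post_swim", "escape")


@dataclass(frozen=True)
class ProtocolConfig:
    """Stimulus timing and condition ladder."""

    exposure_s: float = 1.0
    inter_trial_s: float = 9.0
    trials_per_condition: int = 3
    powers_mw: tuple = (50.0, 100.0, 200.0, 400.0, 600.0)
    #: trace time of trap onset (s from trace start)
    onset_s: float = 2.0
    baseline_window_s: float = 1.0
    post_window_s: float = 1.0

    def __post_init__(self) -> None:
        if self.exposure_s <= 0 or self.inter_trial_s <= 0:
            raise ValueError("exposure and inter-trial intervals must be > 0")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.exposure_s


@dataclass
class TrialRecord:
    """One stimulus presentation."""

    larva_id: str
    condition: str  # e.g. "lateral", "medial", "centre", "dual"
    power_mw: float
    time_s: np.ndarray
    tail_deg: np.ndarray
    eye_left_deg: np.ndarray | None = None
    eye_right_deg: np.ndarray | None = None
    bouts: list = field(default_factory=list)  # list[BoutEvent]
    excluded: bool = False
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")
        if self.excluded != (self.exclusion_reason != "none"):
            raise ValueError("excluded flag must mirror the reason")


@dataclass(frozen=True)
class ConditionSummary:
    """Across-trial summary for one condition of one larva."""

    larva_id: str
    condition: str
    power_mw: float
    mean_trace_deg: np.ndarray
    max_deflection_deg: float
    onset_response_deg: float
    offset_response_deg: float
    n_trials_used: int
    max_eye_roll_deg: float = np.nan


def _exclusion_reason(
    bouts, onset_s: float, offset_s: float, window_s: float = 1.0
) -> str:
    """Reason (or "none") per the three protocol criteria.

    Precedence when several apply: escape > pre_swim > post_swim.
    """
    for b in bouts:
        if b.classification == "escape" and (
            b.offset_s >= onset_s - window_s and b.onset_s <= offset_s + window_s
        ):
            return "escape"
    for b in bouts:
        if b.classification != "escape" and onset_s - window_s <= b.offset_s < onset_s:
            return "pre_swim"
    for b in bouts:
        if b.classification != "escape" and offset_s < b.onset_s <= offset_s + window_s:
            return "post_swim"
    return "none"


def apply_exclusion(
    trials: list[TrialRecord], protocol: ProtocolConfig, window_s: float = 1.0
) -> list[TrialRecord]:
    """Flag contaminated trials; returns new records (input left untouched).

    Idempotent and order independent: each trial is judged solely on its own
    bout annotations.  If more than one trial of a condition is excluded the
    condition is still processed (the protocol expects one or zero); callers
    can detect it from the per-condition counts.
    """
    out = []
    for t in trials:
        reason = _exclusion_reason(
            t.bouts, protocol.onset_s, protocol.offset_s, window_s
        )
        out.append(replace(t, excluded=reason != "none", exclusion_reason=reason))
    return out


def mask_bouts(
    time_s: np.ndarray, angle_deg: np.ndarray, bouts
) -> np.ndarray:
    """Replace bout intervals by linear interpolation across their edges.

    Recovers the underlying postural deflection beneath superimposed swim
    oscillations before extremum-taking.
    """
    x = np.array(angle_deg, dtype=float)
    keep = np.ones(x.size, dtype=bool)
    for b in bouts:
        keep &= ~((time_s >= b.onset_s) & (time_s <= b.offset_s))
    if keep.all() or not keep.any():
        return x
    x[~keep] = np.interp(time_s[~keep], time_s[keep], x[keep])
    return x


def _signed_extremum(x: np.ndarray) -> float:
    if x.size == 0 or not np.any(np.isfinite(x)):
        return np.nan
    i = int(np.nanargmax(np.abs(x)))
    return float(x[i])


def onset_offset_response(
    time_s: np.ndarray,
    angle_deg: np.ndarray,
    protocol: ProtocolConfig,
    bouts=(),
) -> tuple[float, float]:
    """Onset and offset response amplitudes (degrees).

    Onset: signed extremum of (angle − pre-onset baseline mean) during the
    trap window.  Offset: signed extremum, within 1 s after trap end, of
    (angle − level just before offset).  Bout intervals are masked by
    interpolation first.  NaN is returned for a window that is entirely
    masked/invalid.
    """
    t = np.asarray(time_s, dtype=float)
    x = mask_bouts(t, np.asarray(angle_deg, dtype=float), bouts)
    on, off = protocol.onset_s, protocol.offset_s

    base_sel = (t >= on - protocol.baseline_window_s) & (t < on)
    baseline = np.nanmean(x[base_sel]) if np.any(base_sel) else 0.0

    during = (t >= on) & (t <= off)
    onset_amp = _signed_extremum(x[during] - baseline)

    pre_off = (t >= off - 0.1) & (t <= off)
    level = np.nanmean(x[pre_off]) if np.any(pre_off) else baseline
    after = (t > off) & (t <= off + protocol.post_window_s)
    offset_amp = _signed_extremum(x[after] - level)
    return onset_amp, offset_amp


def linear_summation_test(
    resp_lateral: np.ndarray,
    resp_medial: np.ndarray,
    resp_dual: np.ndarray,
) -> dict:
    """Compare a dual-trap response with the sum of the single-trap ones.

    Returns the residual trace ``dual − (lateral + medial)`` and summary
    numbers.  Fractions are normalised by the amplitude (max |·|) of the
    linear prediction, so a dual response generated as ``c · (lat + med)``
    yields ``residual_fraction ≈ |1 − c|``.
    """
    lat = np.asarray(resp_lateral, dtype=float)
    med = np.asarray(resp_medial, dtype=float)
    dual = np.asarray(resp_dual, dtype=float)
    if not (lat.shape == med.shape == dual.shape):
        raise ValueError("traces must be time-aligned with equal lengths")
    pred = lat + med
    resid = dual - pred
    amp = float(np.nanmax(np.abs(pred)))
    rms = float(np.sqrt(np.nanmean(resid**2)))
    return {
        "residual": resid,
        "max_abs_residual": float(np.nanmax(np.abs(resid))),
        "residual_rms": rms,
        "residual_fraction": float(np.nanmax(np.abs(resid)) / amp) if amp > 0 else np.nan,
        "residual_rms_fraction": rms / amp if amp > 0 else np.nan,
    }


def swim_probability(
    trials: list[TrialRecord], protocol: ProtocolConfig
) -> dict[float, float]:
    """Per-power fraction of usable trials with >= 1 swim bout in the trap.

    Excluded trials are dropped first.  A power with zero usable trials maps
    to NaN.  Monotonicity with power is reported by the caller, never
    enforced here.
    """
    on, off = protocol.onset_s, protocol.offset_s
    out: dict[float, float] = {}
    powers = sorted({t.power_mw for t in trials})
    for p in powers:
        usable = [t for t in trials if t.power_mw == p and not t.excluded]
        if not usable:
            out[p] = np.nan
            continue
        n_swim = sum(
            any(
                b.classification == "swim"
                and b.onset_s <= off
                and b.offset_s >= on
                for b in t.bouts
            )
            for t in usable
        )
        out[p] = n_swim / len(usable)
    return out


def power_response_fit(
    powers_mw: np.ndarray, responses_deg: np.ndarray
) -> dict:
    """Quadratic fit of mean response vs. power, with per-power SEM.

    ``responses_deg`` has shape (n_larvae, n_powers): one peak response per
    larva per power.  Returns the degree-2 coefficients (highest first, as
    numpy.polyfit), the per-power across-larva means and SEMs, and the
    fitted curve at the input powers.
    """
    p = np.asarray(powers_mw, dtype=float)
    r = np.atleast_2d(np.asarray(responses_deg, dtype=float))
    if np.unique(p).size < 3:
        raise ValueError("need >= 3 distinct powers for a quadratic fit")
    if r.shape[1] != p.size:
        raise ValueError("responses must have one column per power")
    means = np.nanmean(r, axis=0)
    n = np.sum(np.isfinite(r), axis=0)
    sems = np.zeros(p.size)
    multi = n > 1
    if np.any(multi):
        sems[multi] = (
            np.nanstd(r[:, multi], axis=0, ddof=1) / np.sqrt(n[multi])
        )
    coeffs = np.polyfit(p, means, 2)
    return {
        "coefficients": coeffs,
        "mean_deg": means,
        "sem_deg": sems,
        "fitted_deg": np.polyval(coeffs, p),
    }


def paired_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t test on per-larva response pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 paired observations")
    if np.all(x - y == (x - y)[0]) and (x - y)[0] == 0:
        return 0.0, 1.0  # all differences exactly zero: no effect, no evidence
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def summarize_condition(
    trials: list[TrialRecord], protocol: ProtocolConfig
) -> ConditionSummary:
    """Average the usable trials of one (larva, condition, power) cell."""
    used = [t for t in trials if not t.excluded]
    if not used:
        raise ValueError("no usable trials in condition")
    ref = used[0]
    traces = np.vstack(
        [mask_bouts(t.time_s, t.tail_deg, t.bouts) for t in used]
    )
    mean_trace = traces.mean(axis=0)
    onset, offset = onset_offset_response(
        ref.time_s, mean_trace, protocol, bouts=()
    )
    eye = np.nan
    eyes = [
        0.5 * (np.asarray(t.eye_left_deg) + np.asarray(t.eye_right_deg))
        for t in used
        if t.eye_left_deg is not None and t.eye_right_deg is not None
    ]
    if eyes:
        m = np.vstack(eyes).mean(axis=0)
        sel = (ref.time_s >= protocol.onset_s) & (ref.time_s <= protocol.offset_s)
        eye = float(np.nanmax(np.abs(m[sel]))) if np.any(sel) else np.nan
    sel = (ref.time_s >= protocol.onset_s) & (ref.time_s <= protocol.offset_s)
    base = np.nanmean(
        mean_trace[(ref.time_s >= protocol.onset_s - protocol.baseline_window_s)
                   & (ref.time_s < protocol.onset_s)]
    )
    return ConditionSummary(
        larva_id=ref.larva_id,
        condition=ref.condition,
        power_mw=ref.power_mw,
        mean_trace_deg=mean_trace,
        max_deflection_deg=float(np.nanmax(np.abs(mean_trace[sel] - base))),
        onset_response_deg=onset,
        offset_response_deg=offset,
        n_trials_used=len(used),
        max_eye_roll_deg=eye,
    )
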