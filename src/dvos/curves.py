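"""Noiseless hemodynamic response curves for the cuff-occlusion protocol.

During a sub-arterial cuff inflation, venous return is blocked while
arterial inflow continues, so blood pools distally and total hemoglobin
(HbT) rises toward a plateau; after rapid deflation the pooled blood drains
and HbT returns to baseline.  The plateau time (PT) — the interval between
the two points where the HbT curve crosses 90% of its maximum — is the
feature of interest, so the generator is built to place those two crossings
exactly where a requested target PT demands.

Curve family (per inflation trial, relative to baseline):

* pooling onset delay: HbT stays at baseline from inflation onset ``t0``
  until pooling begins at ``ts`` (the cuff ramps up over ~10 s and venous
  capacitance fills before pressure backs up into the optical volume),
* rise, ``ts`` to deflation ``td``: ``A (1 - exp(-(t - ts)/tau_r))`` with a
  short rise constant (default 2 s); peak value ``f A`` at deflation with
  ``f = 1 - exp(-(td - ts)/tau_r)``,
* plateau decline, ``td`` to the target down-crossing ``t2``: a convex
  (cubic-in-time) decline from ``f A`` down to ``0.9 f A`` — the plateau
  holds its level for most of the interval and then gives way, so the
  curve crosses the 90% threshold on a steep slope (saturated trials
  only),
* washout, after ``t2``: decay back toward baseline that starts at the
  decline's end slope (no kink at the crossing, which would bias smoothed
  crossing estimates) and accelerates with a Gaussian factor of time
  scale ``washout_tau_s``.

Because the peak is ``f A``, the 90%-of-maximum threshold is ``0.9 f A``:
the curve sits at or above it exactly on ``[t1, t2]``, so the realized PT
is ``t2 - t1`` by construction.  The onset delay ``ts`` is solved so the
upward crossing lands at ``t1 = t2 - PT``; placing the crossing with the
delay rather than by stretching ``tau_r`` keeps both 90% crossings on
steep flanks, which makes the extracted PT robust to detector noise.
Non-saturated trials (slow arterial inflow, HbT still climbing at
deflation) have no onset delay, use the configured rise constant directly
and skip the plateau segment; their PT is short and emergent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .protocol import ProtocolSchedule, TrialWindow
from .series import ChromophoreSeries

# fraction of the HbT rise attributed to oxyhemoglobin during venous pooling
DEFAULT_HBO2_FRACTION = 0.55
DEFAULT_WASHOUT_TAU_S = 4.0
DEFAULT_RISE_TAU_S = 2.0

_LN10 = float(np.log(10.0))
_MIN_RISE_TAU_S = 0.3
_T1_LATEST_BEFORE_DEFLATION_S = 1.0
_T2_MARGIN_AFTER_DEFLATION_S = 0.5
_T2_PREFERRED_AFTER_DEFLATION_S = 2.0
_T2_MARGIN_BEFORE_END_S = 2.0


class CurveConfigError(ValueError):
    """Requested hemodynamic curve is not realizable under the schedule."""


@dataclass(frozen=True)
class HemodynamicCurveParams:
    """Per-trial hemodynamic response parameters.

    Parameters
    ----------
    baseline_uM:
        Resting HbT offset added to the whole series (micromolar).
    amplitude_uM:
        Asymptotic plateau amplitude of the venous-pooling rise, relative
        to baseline (micromolar).
    rise_tau_s:
        Rise time constant.  Short by default so the 90% crossing sits on
        a steep flank; for saturated trials it is shortened further only
        when a long target PT forces the up-crossing right after
        inflation onset.  Non-saturated trials use it as-is (typically set
        much longer than the hold phase).
    target_pt_s:
        Requested plateau time (seconds); honored exactly (up to sampling)
        when ``saturated`` is true.
    saturated:
        Whether the curve reaches and holds its plateau within the trial.
    washout_tau_s:
        Post-plateau exponential decay constant (seconds).
    """

    baseline_uM: float = 0.0
    amplitude_uM: float = 15.0
    rise_tau_s: float = DEFAULT_RISE_TAU_S
    target_pt_s: float = 30.0
    saturated: bool = True
    washout_tau_s: float = DEFAULT_WASHOUT_TAU_S

    def __post_init__(self) -> None:
        if self.amplitude_uM < 0:
            raise CurveConfigError("plateau amplitude must be non-negative")
        if self.rise_tau_s <= 0 or self.washout_tau_s <= 0:
            raise CurveConfigError("time constants must be positive")
        if self.target_pt_s < 0:
            raise CurveConfigError("target PT must be non-negative")


def _t1_of_onset(ts: float, tau_r: float, td: float) -> float:
    """Up-crossing time of the 90%-of-peak threshold for pooling onset ``ts``.

    With peak ``f A`` at deflation, the rise crosses ``0.9 f A`` where
    ``1 - exp(-(t1 - ts)/tau_r) = 0.9 f``; monotone increasing in ``ts``.
    """
    f = 1.0 - np.exp(-(td - ts) / tau_r)
    return ts - tau_r * np.log(1.0 - 0.9 * f)


def _solve_crossings(
    params: HemodynamicCurveParams, trial: TrialWindow
) -> tuple[float, float, float, float]:
    """Place the two 90% crossings for the target PT.

    Returns ``(t1, t2, pooling_onset, tau_r)``.  The down-crossing is
    preferred shortly after deflation (steep decline); the up-crossing is
    then placed by solving for the pooling-onset delay, shortening the
    rise constant only when the target PT forces the up-crossing right
    after inflation onset.
    """
    t0, td, tend = trial.inflation_onset_s, trial.deflation_s, trial.window_end_s
    pt = params.target_pt_s
    if pt > trial.duration_s:
        raise CurveConfigError(
            f"target PT {pt:g} s exceeds the {trial.duration_s:g} s trial window"
        )
    tau_r = params.rise_tau_s
    t1_latest = td - _T1_LATEST_BEFORE_DEFLATION_S
    t2_min = td + _T2_MARGIN_AFTER_DEFLATION_S
    t2_max = tend - _T2_MARGIN_BEFORE_END_S

    t2 = min(max(td + _T2_PREFERRED_AFTER_DEFLATION_S, t2_min), t2_max)
    t1 = t2 - pt
    if t1 > t1_latest:
        t1 = t1_latest
        t2 = t1 + pt
    t1_earliest = t0 + tau_r * _LN10  # up-crossing with pooling at onset
    if t1 < t1_earliest:
        # long PT: pin the up-crossing right after onset, move t2 out
        t1 = t1_earliest
        t2 = t1 + pt
        if t2 > t2_max:
            # only now steepen the rise to buy the remaining seconds
            tau_r = max(_MIN_RISE_TAU_S, (t2_max - pt - t0) / _LN10)
            t1 = t0 + tau_r * _LN10
            t2 = t1 + pt
    if not (t2_min <= t2 <= t2_max) or t1 <= t0:
        raise CurveConfigError(
            f"target PT {pt:g} s is not realizable within the trial window "
            f"[{t0:g}, {tend:g}] s"
        )
    lo, hi = t0, t1_latest - 1e-9
    if _t1_of_onset(lo, tau_r, td) >= t1:
        ts = lo
    else:
        ts = float(
            brentq(lambda s: _t1_of_onset(s, tau_r, td) - t1, lo, hi,
                   xtol=1e-10, rtol=1e-14)
        )
    return t1, t2, ts, tau_r


def _trial_bump(
    t: np.ndarray, params: HemodynamicCurveParams, trial: TrialWindow
) -> np.ndarray:
    """Baseline-relative HbT contribution of one inflation trial."""
    t0, td = trial.inflation_onset_s, trial.deflation_s
    a = params.amplitude_uM
    out = np.zeros_like(t)
    if a == 0.0:
        return out

    if params.saturated:
        _, t2, ts, tau_r = _solve_crossings(params, trial)
    else:
        ts, tau_r = t0, params.rise_tau_s
        t2 = td  # washout starts right at deflation
    f = 1.0 - np.exp(-(td - ts) / tau_r)
    peak = f * a

    rising = (t >= ts) & (t < td)
    out[rising] = a * (1.0 - np.exp(-(t[rising] - ts) / tau_r))
    if params.saturated and t2 > td:
        plateau = (t >= td) & (t < t2)
        frac = (t[plateau] - td) / (t2 - td)
        out[plateau] = peak - 0.1 * peak * frac**3
        level_at_t2 = 0.9 * peak
        end_slope = 0.3 * peak / (t2 - td)
    else:
        level_at_t2 = peak
        end_slope = level_at_t2 / params.washout_tau_s
    washing = t >= t2
    u = t[washing] - t2
    # slope-continuous at t2, then Gaussian-accelerated decay
    out[washing] = level_at_t2 * np.exp(
        -end_slope / level_at_t2 * u - 0.5 * (u / params.washout_tau_s) ** 2
    )
    return out


def simulate_hbt_curve(
    params: HemodynamicCurveParams | list[HemodynamicCurveParams],
    schedule: ProtocolSchedule,
    frame_rate_hz: float,
    hbo2_fraction: float = DEFAULT_HBO2_FRACTION,
) -> ChromophoreSeries:
    """Simulate a noiseless chromophore time course over the full protocol.

    ``params`` may be a single parameter set applied to both inflation
    trials or one set per trial.  The HbT change is split into oxy- and
    deoxy-hemoglobin by a fixed fraction; their sum reproduces HbT exactly.
    """
    if frame_rate_hz <= 0:
        raise CurveConfigError("frame rate must be positive")
    if not 0.0 <= hbo2_fraction <= 1.0:
        raise CurveConfigError("HbO2 fraction must lie in [0, 1]")
    per_trial = params if isinstance(params, list) else [params] * len(schedule.trials)
    if len(per_trial) != len(schedule.trials):
        raise CurveConfigError("need one parameter set per inflation trial")

    n = int(np.floor(schedule.total_duration_s * frame_rate_hz)) + 1
    t = schedule.phase_bounds_s[0] + np.arange(n) / frame_rate_hz
    hbt = np.full(n, per_trial[0].baseline_uM, dtype=float)
    for p, trial in zip(per_trial, schedule.trials):
        hbt += _trial_bump(t, p, trial)
    dhbt = hbt - per_trial[0].baseline_uM
    dhbo2 = hbo2_fraction * dhbt
    return ChromophoreSeries(
        timestamps_s=t,
        dHbO2_uM=dhbo2 + per_trial[0].baseline_uM * hbo2_fraction,
        dHb_uM=(dhbt - dhbo2) + per_trial[0].baseline_uM * (1.0 - hbo2_fraction),
        provenance={"source": "simulated", "frame_rate_hz": frame_rate_hz},
    )
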