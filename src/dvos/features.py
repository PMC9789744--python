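"""Plateau-time feature extraction and patient-level aggregation.

The plateau time (PT) of one inflation trial is the time between the two
points where the total-hemoglobin curve crosses 90% of its maximum — a
proxy for how long blood pooled in the foot stays at its plateau.  The
threshold is referenced to the curve's level at inflation onset, so PT is
invariant under positive affine rescaling of the curve.  Crossing times are
located by linear interpolation between the bracketing frames.

Per patient and time point the patch PT is the mean over the two cuff
trials (60 and 100 mmHg); the general ("Gen") feature is the mean over all
patches and the localized ("Loc") feature follows the arterial tree around
the ulcer.  Classification uses differences of Gen PT between time points
(Post-Pre, FU1-Pre, FU1-Post).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .protocol import ProtocolSchedule, TrialWindow
from .recording import ANGIOSOMES
from .series import ChromophoreSeries

TIME_POINTS = ("Pre", "Post", "FU1")
DIFFERENCE_PAIRS = {"PostPre": ("Post", "Pre"), "FU1Pre": ("FU1", "Pre"), "FU1Post": ("FU1", "Post")}

PLATEAU_FRACTION = 0.9
SATURATION_MIN_HOLD_S = 5.0
DEFAULT_SMOOTH_FRAMES = 5
BASELINE_LOOKBACK_S = 5.0
LEVEL_WINDOW_S = 4.0  # heavier smoothing used only to read the plateau level


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class TrialFeatures:
    """PT, rise time and peak of one cuff-inflation trial."""

    pressure_mmhg: float
    hbt_max_uM: float
    t_rise_s: float
    pt_s: float
    saturated: bool
    right_censored: bool
    defined: bool = True
    diagnostic: str = ""

    @classmethod
    def undefined(cls, pressure_mmhg: float, diagnostic: str) -> "TrialFeatures":
        return cls(
            pressure_mmhg=pressure_mmhg,
            hbt_max_uM=float("nan"),
            t_rise_s=float("nan"),
            pt_s=float("nan"),
            saturated=False,
            right_censored=False,
            defined=False,
            diagnostic=diagnostic,
        )


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; shrinks toward the edges."""
    if window <= 1:
        return y
    return (
        pd.Series(y).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def _interp_crossing(t0: float, t1: float, y0: float, y1: float, thr: float) -> float:
    if y1 == y0:
        return t0
    return t0 + (thr - y0) / (y1 - y0) * (t1 - t0)


def extract_trial_features(
    series: ChromophoreSeries,
    trial: TrialWindow,
    smooth_frames: int = DEFAULT_SMOOTH_FRAMES,
) -> TrialFeatures:
    """Extract PT/trise/HbTmax from the HbT curve of one trial window.

    The window runs from inflation onset to the end of the post-deflation
    recovery phase.  The curve is pre-smoothed with a centered moving
    average (``smooth_frames`` frames; 1 disables smoothing entirely).
    When smoothing is active, the plateau level HbTmax is read from a more
    heavily smoothed copy of the curve (a ~4 s window): the sample maximum
    of a noisy series is biased upward, and that bias shifts the 90%
    threshold while the plateau itself is flat enough that heavy smoothing
    costs nothing.  Crossing times are always located on the lightly
    smoothed curve.
    """
    t = series.timestamps_s
    mask = (t >= trial.inflation_onset_s) & (t <= trial.window_end_s)
    if mask.sum() < 10:
        raise FeatureError("trial window contains fewer than 10 frames")
    tw = t[mask]
    smoothed = _moving_average(series.dHbT_uM, smooth_frames)
    y = smoothed[mask]
    if smooth_frames > 1:
        dt_est = float(np.median(np.diff(tw)))
        level_frames = max(smooth_frames, int(round(LEVEL_WINDOW_S / dt_est)) | 1)
        y_level = _moving_average(series.dHbT_uM, level_frames)[mask]
    else:
        y_level = y

    # pre-inflation resting level; referencing the threshold to it keeps PT
    # invariant under positive affine rescaling and robust to the curve
    # already rising at the first in-window frame
    pre = (t >= trial.inflation_onset_s - BASELINE_LOOKBACK_S) & (
        t < trial.inflation_onset_s
    )
    y0 = float(np.median(smoothed[pre])) if pre.any() else y[0]
    hbt_max = float(np.max(y_level))
    rise = hbt_max - y0
    if not np.isfinite(rise) or rise <= 0:
        return TrialFeatures.undefined(
            trial.pressure_mmhg, "flat or non-rising curve: HbTmax undefined"
        )
    thr = y0 + PLATEAU_FRACTION * rise
    above = y >= thr

    # first upward crossing
    first = int(np.argmax(above))
    if first == 0:
        t1 = tw[0]
    else:
        t1 = _interp_crossing(tw[first - 1], tw[first], y[first - 1], y[first], thr)

    # last time at or above threshold
    last = len(above) - 1 - int(np.argmax(above[::-1]))
    censored = last == len(above) - 1
    if censored:
        t2 = tw[-1]
    else:
        t2 = _interp_crossing(tw[last], tw[last + 1], y[last], y[last + 1], thr)

    # longest contiguous run at/above threshold, in seconds
    runs = np.diff(np.flatnonzero(np.diff(np.r_[0, above.astype(int), 0])))[::2]
    dt = float(np.median(np.diff(tw)))
    longest_s = (runs.max() - 1) * dt if runs.size else 0.0
    return TrialFeatures(
        pressure_mmhg=trial.pressure_mmhg,
        hbt_max_uM=float(hbt_max),
        t_rise_s=float(t1 - trial.inflation_onset_s),
        pt_s=float(t2 - t1),
        saturated=bool(longest_s >= SATURATION_MIN_HOLD_S),
        right_censored=bool(censored),
    )


def patch_features(
    series: ChromophoreSeries,
    schedule: ProtocolSchedule,
    smooth_frames: int = DEFAULT_SMOOTH_FRAMES,
) -> list[TrialFeatures]:
    """Per-trial features for one patch recording."""
    return [
        extract_trial_features(series, trial, smooth_frames)
        for trial in schedule.trials
    ]


def patch_pt(trials: Sequence[TrialFeatures]) -> float:
    """Patch-level PT: mean of the defined trial PTs.

    If only one trial yields a defined PT that value is used (with a
    warning); if none does, NaN propagates as an explicit missing value.
    """
    values = [tr.pt_s for tr in trials if tr.defined and np.isfinite(tr.pt_s)]
    if not values:
        return float("nan")
    if len(values) < len(trials):
        warnings.warn(
            "patch PT from a single defined trial", stacklevel=2
        )
    return float(np.mean(values))


@dataclass(frozen=True)
class AngiosomeTree:
    """Arterial tree over the foot angiosomes (child -> parent edges)."""

    parent: Mapping[str, str] = field(
        default_factory=lambda: {
            "dorsalis_pedis": "anterior_tibial",
            "medial_plantar": "posterior_tibial",
            "lateral_plantar": "posterior_tibial",
        }
    )

    def __post_init__(self) -> None:
        for child, par in self.parent.items():
            for node in (child, par):
                if node not in ANGIOSOMES:
                    raise FeatureError(f"unknown angiosome {node!r}")
        # acyclicity: walking up from any node must terminate
        for node in self.parent:
            seen = {node}
            while node in self.parent:
                node = self.parent[node]
                if node in seen:
                    raise FeatureError("angiosome tree contains a cycle")
                seen.add(node)

    def children(self, node: str) -> list[str]:
        return [c for c, p in self.parent.items() if p == node]

    def descendants(self, node: str) -> list[str]:
        out: list[str] = []
        stack = self.children(node)
        while stack:
            c = stack.pop()
            out.append(c)
            stack.extend(self.children(c))
        return out


DEFAULT_ANGIOSOME_TREE = AngiosomeTree()


def gen_loc_aggregate(
    patch_pts: Mapping[str, float],
    ulcer_angiosome: str,
    tree: AngiosomeTree = DEFAULT_ANGIOSOME_TREE,
) -> tuple[float, float]:
    """Aggregate patch PTs to the general and localized patient features.

    Gen is the mean over all non-missing patch PTs.  Loc is resolved in
    preferential order: the patch on the ulcer's angiosome, else the mean
    of patches below the affected artery on the tree, else the patch
    directly above; explicit NaN when none applies.
    """
    if ulcer_angiosome not in ANGIOSOMES:
        raise FeatureError(f"unknown ulcer angiosome {ulcer_angiosome!r}")
    present = {a: v for a, v in patch_pts.items() if np.isfinite(v)}
    if not present:
        raise FeatureError("no patch PT available")
    gen = float(np.mean(list(present.values())))

    if ulcer_angiosome in present:
        loc = present[ulcer_angiosome]
    else:
        below = [present[a] for a in tree.descendants(ulcer_angiosome) if a in present]
        if below:
            loc = float(np.mean(below))
        elif tree.parent.get(ulcer_angiosome) in present:
            loc = present[tree.parent[ulcer_angiosome]]
        else:
            loc = float("nan")
    return gen, loc


def difference_features(pt_by_timepoint: Mapping[str, float]) -> dict[str, float]:
    """Later-minus-earlier PT differences across the three time points."""
    out: dict[str, float] = {}
    for name, (late, early) in DIFFERENCE_PAIRS.items():
        a = pt_by_timepoint.get(late, float("nan"))
        b = pt_by_timepoint.get(early, float("nan"))
        out[name] = float(a - b) if np.isfinite(a) and np.isfinite(b) else float("nan")
    return out


@dataclass
class PatientFeatures:
    """Per-patient PT features across the three acquisition time points."""

    patient_id: str
    outcome: int | None
    pt_gen: dict[str, float]
    pt_loc: dict[str, float]
    censored: dict[str, bool] = field(default_factory=dict)

    @property
    def diffs_gen(self) -> dict[str, float]:
        return difference_features(self.pt_gen)

    @property
    def diffs_loc(self) -> dict[str, float]:
        return difference_features(self.pt_loc)


def features_table(patients: Iterable[PatientFeatures]) -> pd.DataFrame:
    """One row per patient: PT levels, difference features, censoring flags."""
    rows = []
    for p in patients:
        row: dict[str, object] = {"patient_id": p.patient_id, "outcome": p.outcome}
        for tp in TIME_POINTS:
            row[f"PT_{tp}_Gen"] = p.pt_gen.get(tp, float("nan"))
        for tp in TIME_POINTS:
            row[f"PT_{tp}_Loc"] = p.pt_loc.get(tp, float("nan"))
        for name, val in p.diffs_gen.items():
            row[f"{name}Gen"] = val
        for name, val in p.diffs_loc.items():
            row[f"{name}Loc"] = val
        for tp in TIME_POINTS:
            row[f"censored_{tp}"] = bool(p.censored.get(tp, False))
        rows.append(row)
    return pd.DataFrame(rows)
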