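"""Seeded synthetic patient cohorts for the cuff-occlusion study design.

A cohort mirrors the clinical study layout: each patient has a binary
wound-healing outcome, 1–4 optical patches on foot angiosomes recorded at
three time points (pre-intervention, post-intervention, first follow-up),
and — for a subset — ankle-brachial-index and duplex-ultrasound ratio
panels.  The classification signal is planted in the FU1-minus-Post
general plateau-time difference: per outcome group it is drawn from a
normal distribution whose defaults are the observed group statistics
(positive 6.7 ± 9.3 s, negative −7.1 ± 4.3 s).

Exactness contract: each patch's per-time-point target PT is the patient's
time-point level plus a patch offset held constant across time points, so
patch and Gen PT differences equal the drawn difference exactly; the curve
generator then places the 90% crossings so the full pipeline recovers them
to within about one frame interval.

Raw voltage recordings are rendered lazily (and deterministically, from
seeds derived per patient/time point/patch) through the Beer–Lambert
forward model, so parameter-level Monte-Carlo studies stay cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .curves import HemodynamicCurveParams, simulate_hbt_curve
from .features import (
    DEFAULT_SMOOTH_FRAMES,
    PatientFeatures,
    features_table,
    gen_loc_aggregate,
    patch_features,
    patch_pt,
)
from .modality import ABI_ARTERIES, ADUS_ARTERIES
from .optics import OpticalModelConfig, forward_optics, reconstruct_recording
from .protocol import ProtocolSchedule, build_protocol
from .recording import ANGIOSOMES, PatchRecording, frame_rate_for_patch_count, write_recording

TIME_POINTS = ("Pre", "Post", "FU1")

# plateau-time band the generator draws from: realizable under the default
# schedule, with enough margin that one trial's washout never contaminates
# the next trial's baseline and that the post-deflation 90% crossing stays
# on a steep flank (see curves.py)
PT_MIN_S = 3.0
PT_MAX_S = 75.0


class CohortSpecError(ValueError):
    pass


@dataclass(frozen=True)
class GroupLevels:
    """Mean/SD of the Gen PT level (seconds) at Pre and Post.

    The FU1 level is Post plus the drawn group difference, so only two
    levels are free.
    """

    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the pilot-study conditions: 9 positive and 5
    negative outcomes, FU1-Post PT differences of 6.7 ± 9.3 s (positive)
    and −7.1 ± 4.3 s (negative), 1–4 patches per patient, 1% multiplicative
    detector noise.
    """

    n_positive: int = 9
    n_negative: int = 5
    diff_mean_pos_s: float = 6.7
    diff_sd_pos_s: float = 9.3
    diff_mean_neg_s: float = -7.1
    diff_sd_neg_s: float = 4.3
    levels_pos: GroupLevels = GroupLevels(20.0, 6.0, 42.0, 6.0)
    levels_neg: GroupLevels = GroupLevels(15.0, 5.0, 47.0, 6.0)
    patch_count: int | None = None  # None: uniform over 1..4 per patient
    patch_offset_sd_s: float = 4.0
    amplitude_mean_uM: float = 15.0
    amplitude_sd_uM: float = 3.0
    noise_rel_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise CohortSpecError("group sizes must be at least 1")
        for sd in (self.diff_sd_pos_s, self.diff_sd_neg_s):
            if sd <= 0:
                raise CohortSpecError("difference SDs must be positive")
        if self.patch_count is not None and self.patch_count not in (1, 2, 3, 4):
            raise CohortSpecError("patch count must be in {1,2,3,4}")
        if self.noise_rel_sd < 0:
            raise CohortSpecError("noise SD must be non-negative")


@dataclass
class SyntheticPatient:
    """One synthetic patient: targets plus lazy recording rendering."""

    patient_id: str
    index: int
    outcome: int
    ulcer_angiosome: str
    patch_angiosomes: list[str]
    frame_rate_hz: float
    drawn_diff_s: float
    level_s: dict[str, float]               # Gen PT target per time point
    patch_offsets_s: list[float]            # constant across time points
    amplitudes_uM: list[float]
    noise_rel_sd: float
    cohort_seed: int
    schedule: ProtocolSchedule

    def target_patch_pt(self, timepoint: str, patch_idx: int) -> float:
        return self.level_s[timepoint] + self.patch_offsets_s[patch_idx]

    def curve_params(self, timepoint: str, patch_idx: int) -> HemodynamicCurveParams:
        return HemodynamicCurveParams(
            amplitude_uM=self.amplitudes_uM[patch_idx],
            target_pt_s=self.target_patch_pt(timepoint, patch_idx),
            saturated=True,
        )

    def recordings(self, timepoint: str) -> list[PatchRecording]:
        """Render the raw voltage recordings of one time point."""
        tp_idx = TIME_POINTS.index(timepoint)
        out = []
        for k, angiosome in enumerate(self.patch_angiosomes):
            series = simulate_hbt_curve(
                self.curve_params(timepoint, k), self.schedule, self.frame_rate_hz
            )
            rng = np.random.default_rng(
                [self.cohort_seed % (2**31), self.index, tp_idx, k]
            )
            out.append(
                forward_optics(
                    series,
                    patch_id=f"{self.patient_id}-{timepoint}-p{k + 1}",
                    angiosome=angiosome,
                    frame_rate_hz=self.frame_rate_hz,
                    schedule=self.schedule,
                    noise_rel_sd=self.noise_rel_sd,
                    rng=rng,
                )
            )
        return out


@dataclass
class Cohort:
    spec: CohortSpec
    schedule: ProtocolSchedule
    patients: list[SyntheticPatient]
    panel: pd.DataFrame  # long: patient_id, timepoint, modality, artery, ratio

    def target_features(self) -> pd.DataFrame:
        """Patient feature table from generator targets (no optics)."""
        rows = []
        for p in self.patients:
            pts = {tp: p.level_s[tp] for tp in TIME_POINTS}
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "outcome": p.outcome,
                    "ulcer_angiosome": p.ulcer_angiosome,
                    **{f"PT_{tp}_Gen": pts[tp] for tp in TIME_POINTS},
                    "PostPreGen": pts["Post"] - pts["Pre"],
                    "FU1PreGen": pts["FU1"] - pts["Pre"],
                    "FU1PostGen": pts["FU1"] - pts["Post"],
                }
            )
        return pd.DataFrame(rows)

    def realized_features(
        self,
        optical_config: OpticalModelConfig | None = None,
        smooth_frames: int = DEFAULT_SMOOTH_FRAMES,
    ) -> pd.DataFrame:
        """Full-pipeline feature table: render, reconstruct, extract, aggregate."""
        optical_config = optical_config or OpticalModelConfig()
        out = []
        for p in self.patients:
            pt_gen: dict[str, float] = {}
            pt_loc: dict[str, float] = {}
            censored: dict[str, bool] = {}
            for tp in TIME_POINTS:
                per_patch: dict[str, float] = {}
                any_censored = False
                for rec in p.recordings(tp):
                    series = reconstruct_recording(rec, optical_config)
                    trials = patch_features(series, self.schedule, smooth_frames)
                    per_patch[rec.angiosome] = patch_pt(trials)
                    any_censored |= any(t.right_censored for t in trials if t.defined)
                gen, loc = gen_loc_aggregate(per_patch, p.ulcer_angiosome)
                pt_gen[tp], pt_loc[tp], censored[tp] = gen, loc, any_censored
            out.append(
                PatientFeatures(
                    patient_id=p.patient_id,
                    outcome=p.outcome,
                    pt_gen=pt_gen,
                    pt_loc=pt_loc,
                    censored=censored,
                )
            )
        table = features_table(out)
        table["ulcer_angiosome"] = [p.ulcer_angiosome for p in self.patients]
        return table

    def write(self, out_dir: str | Path) -> Path:
        """Write all recordings plus a cohort manifest; returns manifest path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest: dict = {
            "seed": self.spec.seed,
            "phase_bounds_s": list(self.schedule.phase_bounds_s),
            "pressures_mmhg": list(self.schedule.pressures_mmhg),
            "ramp_s": self.schedule.ramp_s,
            "patients": [],
        }
        for p in self.patients:
            entry = {
                "patient_id": p.patient_id,
                "outcome": p.outcome,
                "ulcer_angiosome": p.ulcer_angiosome,
                "frame_rate_hz": p.frame_rate_hz,
                "recordings": {},
            }
            for tp in TIME_POINTS:
                files = []
                for rec in p.recordings(tp):
                    path = out_dir / f"{rec.patch_id}.csv"
                    write_recording(rec, path)
                    files.append(path.name)
                entry["recordings"][tp] = files
            manifest["patients"].append(entry)
        self.panel.to_csv(out_dir / "modality_panel.csv", index=False)
        manifest["modality_panel"] = "modality_panel.csv"
        manifest_path = out_dir / "cohort_manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest_path


def _draw_levels(
    rng: np.random.Generator, levels: GroupLevels, diff: float
) -> dict[str, float]:
    """Draw Pre/Post PT levels keeping Post and Post+diff realizable."""
    pre = float(np.clip(rng.normal(levels.pre_mean, levels.pre_sd), PT_MIN_S, PT_MAX_S))
    lo, hi = PT_MIN_S + 0.5, PT_MAX_S - 0.5
    for _ in range(200):
        post = rng.normal(levels.post_mean, levels.post_sd)
        if lo <= post <= hi and lo <= post + diff <= hi:
            break
    else:  # pathological spec: pin to the feasible band center
        post = float(np.clip(-diff / 2 + (lo + hi) / 2, lo, hi))
    return {"Pre": pre, "Post": float(post), "FU1": float(post + diff)}


def _modality_panel(
    rng: np.random.Generator, patients: list[SyntheticPatient]
) -> pd.DataFrame:
    """ABI and duplex ratio panels with study-like availability and only a
    weak outcome association (both modalities performed poorly)."""
    availability = {  # fraction of patients with data, per modality/time point
        ("ABI", "Pre"): 5 / 14, ("ABI", "FU1"): 10 / 14,
        ("ADUS", "Pre"): 9 / 14, ("ADUS", "FU1"): 11 / 14,
    }
    rows = []
    for p in patients:
        for (modality, tp), frac in availability.items():
            if rng.random() > frac:
                continue
            if modality == "ABI":
                center = 0.80 if p.outcome == 1 else 0.72
                for artery in ABI_ARTERIES:
                    rows.append(
                        {
                            "patient_id": p.patient_id,
                            "timepoint": tp,
                            "modality": modality,
                            "artery": artery,
                            "ratio": float(max(0.1, rng.normal(center, 0.25))),
                        }
                    )
            else:
                mu = np.log(2.0) + (-0.10 if p.outcome == 1 else 0.15)
                for artery in ADUS_ARTERIES:
                    rows.append(
                        {
                            "patient_id": p.patient_id,
                            "timepoint": tp,
                            "modality": modality,
                            "artery": artery,
                            "ratio": float(np.exp(rng.normal(mu, 0.5))),
                        }
                    )
    return pd.DataFrame(rows, columns=["patient_id", "timepoint", "modality", "artery", "ratio"])


def generate_cohort(
    spec: CohortSpec | None = None, schedule: ProtocolSchedule | None = None
) -> Cohort:
    """Generate a seeded synthetic cohort.

    The same seed yields a bit-identical cohort, including the lazily
    rendered recordings (their noise streams derive from the cohort seed
    and the patient/time point/patch indices).
    """
    spec = spec or CohortSpec()
    schedule = schedule or build_protocol()
    rng = np.random.default_rng(spec.seed)
    patients: list[SyntheticPatient] = []
    outcomes = [1] * spec.n_positive + [0] * spec.n_negative
    for i, outcome in enumerate(outcomes):
        if outcome == 1:
            diff = float(rng.normal(spec.diff_mean_pos_s, spec.diff_sd_pos_s))
            levels = spec.levels_pos
        else:
            diff = float(rng.normal(spec.diff_mean_neg_s, spec.diff_sd_neg_s))
            levels = spec.levels_neg
        level_s = _draw_levels(rng, levels, diff)
        n_patches = spec.patch_count or int(rng.integers(1, 5))
        ulcer = str(rng.choice(ANGIOSOMES))
        # the ulcer's angiosome is instrumented first, the rest drawn distinct
        others = [a for a in ANGIOSOMES if a != ulcer]
        rng.shuffle(others)
        patch_angiosomes = ([ulcer] + others)[:n_patches]
        lo = PT_MIN_S + 0.25 - min(level_s.values())
        hi = PT_MAX_S - 0.25 - max(level_s.values())
        offsets = [
            float(np.clip(rng.normal(0.0, spec.patch_offset_sd_s), lo, hi))
            for _ in range(n_patches)
        ]
        amplitudes = [
            float(max(5.0, rng.normal(spec.amplitude_mean_uM, spec.amplitude_sd_uM)))
            for _ in range(n_patches)
        ]
        patients.append(
            SyntheticPatient(
                patient_id=f"P{i + 1:02d}",
                index=i,
                outcome=outcome,
                ulcer_angiosome=ulcer,
                patch_angiosomes=patch_angiosomes,
                frame_rate_hz=frame_rate_for_patch_count(n_patches),
                drawn_diff_s=diff,
                level_s=level_s,
                patch_offsets_s=offsets,
                amplitudes_uM=amplitudes,
                noise_rel_sd=spec.noise_rel_sd,
                cohort_seed=spec.seed,
                schedule=schedule,
            )
        )
    panel = _modality_panel(rng, patients)
    return Cohort(spec=spec, schedule=schedule, patients=patients, panel=panel)
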