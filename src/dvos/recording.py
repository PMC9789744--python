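"""Raw multi-wavelength patch recordings and their on-disk format.

A patch carries four laser diodes (670, 780, 808, 850 nm) and two silicon
photodiodes at 1.6 cm ("near") and 2.5 cm ("far") from the sources, so a
recording is eight detector-voltage channels sampled at a common frame
rate.  The frame rate is set by how many patches share the acquisition bus:
1 patch -> 10.24 fps, 2 -> 5.12, 3 -> 3.41, 4 -> 2.56.

On disk a recording is a comma-separated table (``time_s`` plus one
``v<wavelength>_<detector>`` column per channel) preceded by ``#`` header
lines naming the patch, angiosome and frame rate, with a JSON sidecar
holding the cuff-event markers and probe geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .protocol import ProtocolSchedule

WAVELENGTHS_NM = (670, 780, 808, 850)
DETECTOR_DISTANCES_CM = {"near": 1.6, "far": 2.5}
FRAME_RATE_BY_PATCH_COUNT = {1: 10.24, 2: 5.12, 3: 3.41, 4: 2.56}

ANGIOSOMES = (
    "peroneal",
    "posterior_tibial",
    "anterior_tibial",
    "dorsalis_pedis",
    "lateral_plantar",
    "medial_plantar",
)


class RecordingError(ValueError):
    """Malformed patch recording."""


def frame_rate_for_patch_count(n_patches: int) -> float:
    if n_patches not in FRAME_RATE_BY_PATCH_COUNT:
        raise RecordingError(f"patch count must be 1..4, got {n_patches}")
    return FRAME_RATE_BY_PATCH_COUNT[n_patches]


def cuff_events_from_schedule(schedule: ProtocolSchedule) -> list[dict[str, float]]:
    """In-band cuff markers: one entry per inflation trial."""
    return [
        {
            "pressure_mmhg": tr.pressure_mmhg,
            "inflation_start_s": tr.inflation_onset_s,
            "inflation_end_s": tr.inflation_end_s,
            "deflation_s": tr.deflation_s,
            "window_end_s": tr.window_end_s,
        }
        for tr in schedule.trials
    ]


@dataclass
class PatchRecording:
    """Timestamped detector voltages for one patch."""

    patch_id: str
    angiosome: str
    frame_rate_hz: float
    timestamps_s: np.ndarray
    # channel key: (wavelength_nm, detector) e.g. (670, "near")
    voltages: dict[tuple[int, str], np.ndarray]
    cuff_events: list[dict[str, float]] = field(default_factory=list)
    geometry: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.angiosome not in ANGIOSOMES:
            raise RecordingError(f"unknown angiosome {self.angiosome!r}")
        if self.frame_rate_hz not in FRAME_RATE_BY_PATCH_COUNT.values():
            raise RecordingError(
                f"frame rate {self.frame_rate_hz} is not an acquisition rate"
            )
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        n = len(self.timestamps_s)
        if n >= 2 and not np.all(np.diff(self.timestamps_s) > 0):
            raise RecordingError("timestamps must be strictly increasing")
        for key, v in self.voltages.items():
            v = np.asarray(v, dtype=float)
            self.voltages[key] = v
            if v.shape != (n,):
                raise RecordingError(f"channel {key} length mismatch")
            if np.any(v <= 0):
                raise RecordingError(f"channel {key} contains non-positive voltages")
        span = (self.timestamps_s[0], self.timestamps_s[-1]) if n else (0.0, 0.0)
        for ev in self.cuff_events:
            for k in ("inflation_start_s", "deflation_s"):
                if not span[0] <= ev[k] <= span[1]:
                    raise RecordingError("cuff event outside the recording span")

    @property
    def wavelengths_nm(self) -> tuple[int, ...]:
        return tuple(sorted({wl for wl, _ in self.voltages}))

    def channel(self, wavelength_nm: int, detector: str) -> np.ndarray:
        return self.voltages[(wavelength_nm, detector)]


def _channel_name(wavelength_nm: int, detector: str) -> str:
    return f"v{wavelength_nm}_{detector}"


def write_recording(rec: PatchRecording, csv_path: str | Path) -> Path:
    """Write the comma-separated table and its JSON sidecar.

    Returns the sidecar path (``<csv stem>.events.json``).
    """
    csv_path = Path(csv_path)
    cols = {"time_s": rec.timestamps_s}
    for wl in sorted({w for w, _ in rec.voltages}):
        for det in ("near", "far"):
            if (wl, det) in rec.voltages:
                cols[_channel_name(wl, det)] = rec.voltages[(wl, det)]
    header = (
        f"# patch_id={rec.patch_id}\n"
        f"# angiosome={rec.angiosome}\n"
        f"# frame_rate_hz={rec.frame_rate_hz}\n"
    )
    with open(csv_path, "w") as fh:
        fh.write(header)
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.9g")
    sidecar = csv_path.with_suffix(".events.json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "patch_id": rec.patch_id,
                "angiosome": rec.angiosome,
                "frame_rate_hz": rec.frame_rate_hz,
                "cuff_events": rec.cuff_events,
                "geometry": rec.geometry,
            },
            fh,
            indent=2,
        )
    return sidecar


def read_recording(csv_path: str | Path) -> PatchRecording:
    """Read a recording written by :func:`write_recording`."""
    csv_path = Path(csv_path)
    meta: dict[str, str] = {}
    with open(csv_path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh)
    for key in ("patch_id", "angiosome", "frame_rate_hz"):
        if key not in meta:
            raise RecordingError(f"recording header is missing {key!r}")
    voltages: dict[tuple[int, str], np.ndarray] = {}
    for col in table.columns:
        if col == "time_s":
            continue
        if not col.startswith("v") or "_" not in col:
            raise RecordingError(f"unrecognized column {col!r}")
        wl_s, det = col[1:].split("_", 1)
        voltages[(int(wl_s), det)] = table[col].to_numpy()
    cuff_events: list[dict[str, float]] = []
    geometry: dict[str, Any] = {}
    sidecar = csv_path.with_suffix(".events.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            side = json.load(fh)
        cuff_events = side.get("cuff_events", [])
        geometry = side.get("geometry", {})
    return PatchRecording(
        patch_id=meta["patch_id"],
        angiosome=meta["angiosome"],
        frame_rate_hz=float(meta["frame_rate_hz"]),
        timestamps_s=table["time_s"].to_numpy(),
        voltages=voltages,
        cuff_events=cuff_events,
        geometry=geometry,
    )
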