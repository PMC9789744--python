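"""Beer–Lambert forward model and modified Beer–Lambert (MBLL) unmixing.

The forward model maps chromophore concentration changes to detector
voltages through continuous-wave attenuation:

    V(lam, t) = V0(lam) * 10**(-dOD(lam, t)),
    dOD(lam, t) = [eps_HbO2(lam) dHbO2(t) + eps_Hb(lam) dHb(t)] * d * DPF(lam)

with molar extinction coefficients ``eps`` (1/cm/M), source–detector
separation ``d`` (cm) and a differential pathlength factor DPF scaling the
geometric distance to the effective photon path.  Inversion recovers the
per-frame concentration pair by least squares over the four wavelengths —
an overdetermined 4x2 linear system, solved here via the pseudoinverse.

Extinction coefficients default to a standard published compilation of
hemoglobin spectra; they are configuration, not fitted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .recording import (
    DETECTOR_DISTANCES_CM,
    WAVELENGTHS_NM,
    PatchRecording,
    cuff_events_from_schedule,
)
from .protocol import ProtocolSchedule
from .series import ChromophoreSeries

# molar extinction coefficients, 1/(cm M), from a standard compilation of
# oxy-/deoxy-hemoglobin absorption spectra
EXTINCTION_CM_M: dict[int, dict[str, float]] = {
    670: {"HbO2": 294.0, "Hb": 2795.12},
    780: {"HbO2": 710.04, "Hb": 1075.44},
    808: {"HbO2": 851.6, "Hb": 729.36},
    850: {"HbO2": 1058.0, "Hb": 691.32},
}

DEFAULT_DPF = 6.0
DEFAULT_BASELINE_WINDOW_S = (10.0, 50.0)  # central 40 s of the baseline minute
DEFAULT_SOURCE_VOLTAGE = 2.0  # unocculded detector reading, volts

_UM_PER_M = 1e-6  # concentrations are handled in micromolar


class OpticsConfigError(ValueError):
    """Invalid optical model configuration."""


@dataclass(frozen=True)
class OpticalModelConfig:
    """MBLL geometry and spectra.

    ``detector`` selects which photodiode feeds the reconstruction; the far
    detector (2.5 cm) is the default as it samples deeper tissue.  ``dpf``
    may be a scalar (identical across wavelengths) or a per-wavelength map.
    """

    wavelengths_nm: tuple[int, ...] = WAVELENGTHS_NM
    extinction_cm_M: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: EXTINCTION_CM_M
    )
    detector: str = "far"
    dpf: float | Mapping[int, float] = DEFAULT_DPF
    baseline_window_s: tuple[float, float] = DEFAULT_BASELINE_WINDOW_S

    def __post_init__(self) -> None:
        if self.detector not in DETECTOR_DISTANCES_CM:
            raise OpticsConfigError(f"unknown detector {self.detector!r}")
        for wl in self.wavelengths_nm:
            entry = self.extinction_cm_M.get(wl)
            if entry is None or "HbO2" not in entry or "Hb" not in entry:
                raise OpticsConfigError(f"extinction table incomplete at {wl} nm")
        lo, hi = self.baseline_window_s
        if not lo < hi:
            raise OpticsConfigError("baseline window must have positive length")

    @property
    def distance_cm(self) -> float:
        return DETECTOR_DISTANCES_CM[self.detector]

    def dpf_at(self, wavelength_nm: int) -> float:
        if isinstance(self.dpf, Mapping):
            return float(self.dpf[wavelength_nm])
        return float(self.dpf)

    def pathlength_matrix(self) -> np.ndarray:
        """(n_wavelengths, 2) matrix mapping (dHbO2, dHb) in uM to dOD."""
        rows = []
        for wl in self.wavelengths_nm:
            eps = self.extinction_cm_M[wl]
            scale = self.distance_cm * self.dpf_at(wl) * _UM_PER_M
            rows.append([eps["HbO2"] * scale, eps["Hb"] * scale])
        return np.asarray(rows, dtype=float)


def forward_optics(
    series: ChromophoreSeries,
    *,
    patch_id: str = "patch-1",
    angiosome: str = "dorsalis_pedis",
    frame_rate_hz: float = 10.24,
    schedule: ProtocolSchedule | None = None,
    extinction_cm_M: Mapping[int, Mapping[str, float]] | None = None,
    dpf: float | Mapping[int, float] = DEFAULT_DPF,
    source_voltage: float | Mapping[int, float] = DEFAULT_SOURCE_VOLTAGE,
    noise_rel_sd: float = 0.01,
    rng: np.random.Generator | int | None = None,
) -> PatchRecording:
    """Render detector voltages for both photodiodes from a concentration series.

    Multiplicative Gaussian noise of relative standard deviation
    ``noise_rel_sd`` is applied independently per channel and frame.
    """
    extinction = dict(extinction_cm_M) if extinction_cm_M is not None else EXTINCTION_CM_M
    for wl in WAVELENGTHS_NM:
        entry = extinction.get(wl)
        if entry is None or "HbO2" not in entry or "Hb" not in entry:
            raise OpticsConfigError(f"extinction table incomplete at {wl} nm")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    def v0_at(wl: int) -> float:
        if isinstance(source_voltage, Mapping):
            return float(source_voltage[wl])
        return float(source_voltage)

    voltages: dict[tuple[int, str], np.ndarray] = {}
    for wl in WAVELENGTHS_NM:
        eps = extinction[wl]
        dpf_wl = float(dpf[wl]) if isinstance(dpf, Mapping) else float(dpf)
        absorbance = (
            eps["HbO2"] * series.dHbO2_uM + eps["Hb"] * series.dHb_uM
        ) * _UM_PER_M
        for det, dist in DETECTOR_DISTANCES_CM.items():
            clean = v0_at(wl) * 10.0 ** (-absorbance * dist * dpf_wl)
            noisy = clean * (1.0 + noise_rel_sd * rng.standard_normal(len(clean)))
            voltages[(wl, det)] = np.clip(noisy, 1e-12, None)
    events = cuff_events_from_schedule(schedule) if schedule is not None else []
    return PatchRecording(
        patch_id=patch_id,
        angiosome=angiosome,
        frame_rate_hz=frame_rate_hz,
        timestamps_s=series.timestamps_s,
        voltages=voltages,
        cuff_events=events,
        geometry={
            "detector_distances_cm": dict(DETECTOR_DISTANCES_CM),
            "dpf": dpf if not isinstance(dpf, Mapping) else dict(dpf),
            "source_voltage": source_voltage
            if not isinstance(source_voltage, Mapping)
            else dict(source_voltage),
        },
    )


def compute_delta_od(
    recording: PatchRecording, config: OpticalModelConfig | None = None
) -> dict[int, np.ndarray]:
    """Optical-density changes relative to the resting-baseline mean voltage.

    ``dOD(lam, t) = -log10(V(lam, t) / mean_baseline V(lam))`` for the
    configured detector; by construction the mean dOD over the baseline
    window is (up to the log of the mean ratio) zero.
    """
    config = config or OpticalModelConfig()
    t = recording.timestamps_s
    lo, hi = config.baseline_window_s
    if lo < t[0] or hi > t[-1]:
        raise OpticsConfigError("baseline window lies outside the recording")
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise OpticsConfigError("baseline window contains no frames")
    out: dict[int, np.ndarray] = {}
    for wl in config.wavelengths_nm:
        v = recording.channel(wl, config.detector)
        if np.any(v <= 0):
            raise ValueError(f"non-positive voltage at {wl} nm")
        v0 = v[mask].mean()
        out[wl] = -np.log10(v / v0)
    return out


class BeerLambertUnmixer(TransformerMixin, BaseEstimator):
    """Least-squares MBLL unmixing as a scikit-learn transformer.

    ``transform`` maps an ``(n_frames, n_wavelengths)`` array of
    optical-density changes to ``(n_frames, 2)`` concentration changes
    ``(dHbO2, dHb)`` in micromolar, solving the per-frame linear system in
    one pseudoinverse product.

    Parameters
    ----------
    wavelengths_nm : sequence of int, default all four source wavelengths
        Column order of the input dOD array.
    detector : {"far", "near"}, default "far"
        Photodiode whose source–detector distance sets the path length.
    dpf : float or per-wavelength mapping, default 6.0
        Differential pathlength factor.
    """

    def __init__(
        self,
        wavelengths_nm: Sequence[int] = WAVELENGTHS_NM,
        detector: str = "far",
        dpf: float | Mapping[int, float] = DEFAULT_DPF,
        extinction_cm_M: Mapping[int, Mapping[str, float]] | None = None,
    ) -> None:
        self.wavelengths_nm = wavelengths_nm
        self.detector = detector
        self.dpf = dpf
        self.extinction_cm_M = extinction_cm_M

    def _config(self) -> OpticalModelConfig:
        return OpticalModelConfig(
            wavelengths_nm=tuple(self.wavelengths_nm),
            extinction_cm_M=self.extinction_cm_M
            if self.extinction_cm_M is not None
            else EXTINCTION_CM_M,
            detector=self.detector,
            dpf=self.dpf,
        )

    def fit(self, X=None, y=None) -> "BeerLambertUnmixer":
        if len(self.wavelengths_nm) < 2:
            raise OpticsConfigError("unmixing needs at least two wavelengths")
        design = self._config().pathlength_matrix()
        if np.linalg.matrix_rank(design) < 2:
            raise OpticsConfigError("extinction matrix is rank deficient")
        self.design_: np.ndarray = design
        self.pinv_: np.ndarray = np.linalg.pinv(design)
        self.n_features_in_ = len(self.wavelengths_nm)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "pinv_")
        X = check_array(X, ensure_2d=True, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} wavelength columns, got {X.shape[1]}"
            )
        return X @ self.pinv_.T


def unmix(
    delta_od: Mapping[int, np.ndarray],
    config: OpticalModelConfig | None = None,
    timestamps_s: np.ndarray | None = None,
    provenance: dict | None = None,
) -> ChromophoreSeries:
    """Unmix per-wavelength dOD series into chromophore concentrations."""
    config = config or OpticalModelConfig()
    wls = [wl for wl in config.wavelengths_nm if wl in delta_od]
    if len(wls) < 2:
        raise OpticsConfigError("unmixing needs at least two wavelengths")
    sub = OpticalModelConfig(
        wavelengths_nm=tuple(wls),
        extinction_cm_M=config.extinction_cm_M,
        detector=config.detector,
        dpf=config.dpf,
        baseline_window_s=config.baseline_window_s,
    )
    est = BeerLambertUnmixer(
        wavelengths_nm=wls,
        detector=sub.detector,
        dpf=sub.dpf,
        extinction_cm_M=sub.extinction_cm_M,
    ).fit()
    X = np.column_stack([np.asarray(delta_od[wl], dtype=float) for wl in wls])
    conc = est.transform(X)
    n = X.shape[0]
    t = timestamps_s if timestamps_s is not None else np.arange(n, dtype=float)
    return ChromophoreSeries(
        timestamps_s=t,
        dHbO2_uM=conc[:, 0],
        dHb_uM=conc[:, 1],
        provenance=dict(provenance or {}, detector=sub.detector, wavelengths_nm=wls),
    )


def reconstruct_recording(
    recording: PatchRecording, config: OpticalModelConfig | None = None
) -> ChromophoreSeries:
    """Full reconstruction: baseline-referenced dOD then MBLL unmixing."""
    config = config or OpticalModelConfig()
    dod = compute_delta_od(recording, config)
    return unmix(
        dod,
        config,
        timestamps_s=recording.timestamps_s,
        provenance={
            "patch_id": recording.patch_id,
            "angiosome": recording.angiosome,
            "baseline_window_s": list(config.baseline_window_s),
        },
    )
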