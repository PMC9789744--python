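"""Chromophore concentration time courses."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd


@dataclass
class ChromophoreSeries:
    """Oxy-/deoxy-hemoglobin concentration changes over time.

    Concentrations are *changes* relative to a resting baseline, in
    micromolar.  Total hemoglobin ``dHbT`` is the sum of the two components
    at every frame by construction.
    """

    timestamps_s: np.ndarray
    dHbO2_uM: np.ndarray
    dHb_uM: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.dHbO2_uM = np.asarray(self.dHbO2_uM, dtype=float)
        self.dHb_uM = np.asarray(self.dHb_uM, dtype=float)
        n = self.timestamps_s.shape[0]
        if self.dHbO2_uM.shape != (n,) or self.dHb_uM.shape != (n,):
            raise ValueError("timestamps and concentration series must share length")

    @property
    def dHbT_uM(self) -> np.ndarray:
        """Total hemoglobin change: exact frame-wise sum of the components."""
        return self.dHbO2_uM + self.dHb_uM

    def __len__(self) -> int:
        return len(self.timestamps_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.timestamps_s,
                "dHbO_uM": self.dHbO2_uM,
                "dHb_uM": self.dHb_uM,
                "dHbT_uM": self.dHbT_uM,
            }
        )
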