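"""Outcome assignment per modality and the clinical truth table.

Three modalities predict the wound-healing outcome at the first follow-up
(FU1) from a single value and a literature or ROC-derived cutoff:

* optical (DVOS): non-healing predicted when the FU1-minus-postintervention
  plateau-time difference falls below -1.3 s,
* ankle-brachial index: non-healing when the pressure ratio is below 0.9,
* arterial duplex ultrasound: non-healing when the peak-systolic-velocity
  ratio exceeds 2.4.

Assignments are laid out as a truth table against the clinical outcome
(one row per patient; an "X" marks a modality unavailable for that
patient) and each modality column is scored on its available subset.  The
published 14-patient truth table ships with the package as a fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .features import DEFAULT_ANGIOSOME_TREE, AngiosomeTree
from .stats import ConfusionMetrics, confusion_metrics

MODALITY_COLUMNS = ("OO", "ABFG", "ABFL", "ADFG", "ADFL")

ABI_ARTERIES = ("posterior_tibial", "dorsalis_pedis")
ADUS_ARTERIES = ("peroneal", "posterior_tibial", "anterior_tibial")


class ModalityError(ValueError):
    pass


@dataclass(frozen=True)
class CutoffRule:
    """Maps a continuous modality value to a predicted outcome.

    ``predict_negative_when`` names the abnormal side of the cutoff
    (strict inequality): a value there is assigned outcome 0 (non-healing
    predicted), anything else outcome 1.
    """

    modality: str
    cutoff: float
    predict_negative_when: str  # "below" | "above"

    def __post_init__(self) -> None:
        if not np.isfinite(self.cutoff):
            raise ModalityError("cutoff must be finite")
        if self.predict_negative_when not in ("below", "above"):
            raise ModalityError("predict_negative_when must be 'below' or 'above'")


DEFAULT_RULES: dict[str, CutoffRule] = {
    "DVOS": CutoffRule("DVOS", -1.3, "below"),
    "ABI": CutoffRule("ABI", 0.9, "below"),
    "ADUS": CutoffRule("ADUS", 2.4, "above"),
}


def assign_outcome(value, rule: CutoffRule):
    """Apply a cutoff rule; missing values propagate as None."""
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return None
    v = float(value)
    if rule.predict_negative_when == "below":
        return 0 if v < rule.cutoff else 1
    return 0 if v > rule.cutoff else 1


@dataclass
class TruthTable:
    """Per-patient clinical outcome vs modality-assigned outcomes.

    ``table`` has one row per patient with a ``CO`` column (never missing)
    and 0/1/<NA> assignment columns; agreement columns ``CO=<col>`` are
    derived and missing exactly where the assignment is.
    """

    table: pd.DataFrame
    assignment_columns: tuple[str, ...] = MODALITY_COLUMNS

    def __post_init__(self) -> None:
        if self.table["patient"].duplicated().any():
            raise ModalityError("duplicate patient ids in truth table")
        if self.table["CO"].isna().any():
            raise ModalityError("clinical outcome may not be missing")
        for col in self.assignment_columns:
            if col in self.table:
                agree = (self.table[col] == self.table["CO"]).astype("Int64")
                agree[self.table[col].isna()] = pd.NA
                self.table[f"CO={col}"] = agree

    def availability(self, column: str) -> int:
        return int(self.table[column].notna().sum())

    def outcome_counts(self) -> tuple[int, int]:
        """(clinically positive, clinically negative) patient counts."""
        pos = int((self.table["CO"] == 1).sum())
        return pos, len(self.table) - pos

    def score(self, column: str) -> tuple[ConfusionMetrics, int]:
        """Confusion metrics of one assignment column on its available subset."""
        avail = self.table[self.table[column].notna()]
        if avail.empty:
            raise ModalityError(f"no patient has {column} available")
        cm = confusion_metrics(
            avail[column].astype(int).to_numpy(), avail["CO"].astype(int).to_numpy()
        )
        return cm, len(avail)


def score_modalities(table: TruthTable) -> dict[str, dict]:
    """Score every available assignment column of the truth table."""
    out: dict[str, dict] = {}
    for col in table.assignment_columns:
        if col not in table.table or table.table[col].notna().sum() == 0:
            continue
        cm, n = table.score(col)
        out[col] = {
            "n": n,
            "counts": {"TP": cm.tp, "FP": cm.fp, "TN": cm.tn, "FN": cm.fn},
            "rates": cm.as_percentages(),
            "misclassified": cm.misclassified,
        }
    return out


def load_truth_table(path: str | Path | None = None) -> TruthTable:
    """Load a truth-table file; defaults to the packaged published table."""
    if path is None:
        source = resources.files("dvos.data").joinpath("truth_table.csv")
        with resources.as_file(source) as p:
            raw = pd.read_csv(p, dtype=str)
    else:
        raw = pd.read_csv(path, dtype=str)
    expected = {"patient", "CO"}
    if not expected <= set(raw.columns):
        raise ModalityError(f"truth table must contain columns {sorted(expected)}")
    patients = raw["patient"]
    try:
        patients = patients.astype(int)
    except (TypeError, ValueError):
        pass
    df = pd.DataFrame({"patient": patients})
    for col in ["CO", *[c for c in MODALITY_COLUMNS if c in raw.columns]]:
        vals = raw[col].str.strip()
        bad = ~vals.isin(["0", "1", "X"])
        if bad.any():
            line = int(bad.idxmax()) + 2  # header occupies line 1
            raise ModalityError(
                f"malformed entry {vals[bad.idxmax()]!r} in column {col} (line {line})"
            )
        df[col] = vals.replace("X", pd.NA).astype("Int64")
    return TruthTable(table=df)


def _nearest_artery(
    ulcer_angiosome: str,
    arteries: tuple[str, ...],
    tree: AngiosomeTree = DEFAULT_ANGIOSOME_TREE,
) -> list[str]:
    """Arteries "local" to an ulcer: on it, else below it, else above it."""
    if ulcer_angiosome in arteries:
        return [ulcer_angiosome]
    below = [a for a in tree.descendants(ulcer_angiosome) if a in arteries]
    if below:
        return below
    node = ulcer_angiosome
    while node in tree.parent:
        node = tree.parent[node]
        if node in arteries:
            return [node]
    return []


def build_truth_table(
    features: pd.DataFrame,
    panel: pd.DataFrame | None = None,
    rules: Mapping[str, CutoffRule] = DEFAULT_RULES,
    tree: AngiosomeTree = DEFAULT_ANGIOSOME_TREE,
) -> TruthTable:
    """Assemble the FU1 truth table from pipeline features and ratio panels.

    ``features`` needs columns ``patient_id``, ``outcome``, ``FU1PostGen``
    and optionally ``ulcer_angiosome``; ``panel`` is long-format with
    columns ``patient_id, timepoint, modality, artery, ratio`` (missing
    measurements simply absent).  Gen ratios average the per-artery ratios
    at FU1; Loc ratios follow the arterial tree around the ulcer.
    """
    if features["patient_id"].duplicated().any():
        raise ModalityError("duplicate patient ids")
    rows = []
    for _, f in features.iterrows():
        row: dict[str, object] = {
            "patient": f["patient_id"],
            "CO": int(f["outcome"]),
            "OO": assign_outcome(f["FU1PostGen"], rules["DVOS"]),
        }
        for col, modality, arteries in (
            ("ABFG", "ABI", ABI_ARTERIES),
            ("ABFL", "ABI", ABI_ARTERIES),
            ("ADFG", "ADUS", ADUS_ARTERIES),
            ("ADFL", "ADUS", ADUS_ARTERIES),
        ):
            value = None
            if panel is not None:
                sub = panel[
                    (panel["patient_id"] == f["patient_id"])
                    & (panel["timepoint"] == "FU1")
                    & (panel["modality"] == modality)
                ]
                if col.endswith("L"):
                    ulcer = f.get("ulcer_angiosome")
                    if isinstance(ulcer, str):
                        local = _nearest_artery(ulcer, arteries, tree)
                        sub = sub[sub["artery"].isin(local)]
                    else:
                        sub = sub.iloc[0:0]
                if len(sub):
                    value = float(sub["ratio"].mean())
            row[col] = assign_outcome(value, rules[modality])
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in MODALITY_COLUMNS:
        df[col] = df[col].astype("Int64")
    return TruthTable(table=df)
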