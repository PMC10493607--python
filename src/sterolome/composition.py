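"""Per-mille sterol compositions, carbon-family summaries and
internal-standard-based total sterol estimates.

Relative abundance is expressed per mille: each annotated sterol's area is
divided by the sample's total retained signal area and scaled by 1000.
The internal-standard spike is never part of the denominator (it is not a
plant sterol, and its inclusion would distort compositions by loading).
By default the denominator covers every blank-passing retained signal,
annotated or not; ``annotated_only=True`` restricts it to level-1/2
columns, in which case rows sum to exactly 1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import SignalTable
from .registry import parse_label

__all__ = [
    "Composition",
    "InternalStandardSpec",
    "normalize_per_mille",
    "group_by_carbon",
    "dominant_family",
    "total_sterol",
    "CARBON_FAMILIES",
]

CARBON_FAMILIES = ("C27", "C28", "C29", "C30", "C31")


@dataclass
class Composition:
    """Samples x sterols per-mille matrix plus column class labels."""

    values: pd.DataFrame  # rows = samples, columns = sterol labels, unit = permille
    sterol_classes: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < -1e-12).any():
            raise ValueError("per-mille values must be non-negative")

    def save(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")


def _column_label(signal_id: str, row: pd.Series) -> str:
    if row["name"] is not None and not pd.isna(row["name"]):
        return str(row["name"])
    return f"{row['class_label']}@{row['rt']:.2f}"


def normalize_per_mille(
    table: SignalTable,
    sample_ids: list[str] | None = None,
    annotated_only: bool = False,
) -> Composition:
    """Convert annotated signal areas to per-mille compositions.

    Columns are the annotated (level <= 2) signals, keyed by compound name
    (level 1) or class label + RT (level 2); split signals sharing a name
    are summed.  A sample with zero denominator raises, naming the sample.
    """
    signals = table.signals
    passing = signals["blank_pass"].fillna(False).astype(bool)
    is_spike = signals["is_internal_standard"].astype(bool)
    annotated = (signals["level"] <= 2) & ~is_spike

    areas = table.areas
    if sample_ids is not None:
        areas = areas.reindex(columns=sample_ids, fill_value=0.0)

    denom_rows = (annotated if annotated_only else (passing & ~is_spike))
    denominators = areas.loc[signals.index[denom_rows]].sum(axis=0)
    zero = denominators[denominators <= 0]
    if len(zero):
        raise ValueError(
            "zero total retained signal for sample(s): "
            + ", ".join(map(str, zero.index))
        )

    kept = signals.index[annotated & passing]
    labels = [_column_label(sid, signals.loc[sid]) for sid in kept]
    numer = areas.loc[kept].T
    numer.columns = labels
    values = 1000.0 * numer.div(denominators, axis=0)
    values = values.T.groupby(level=0).sum().T  # merge split signals by label

    classes: dict[str, str | None] = {}
    for sid, label in zip(kept, labels):
        classes[label] = signals.loc[sid, "class_label"]
    return Composition(values, classes)


def group_by_carbon(composition: Composition) -> pd.DataFrame:
    """Sum per-mille values into the C27..C31 carbon families.

    A linear, total-conserving map; every column must carry a class.
    """
    unassigned = [
        c for c in composition.values.columns if composition.sterol_classes.get(c) is None
    ]
    if unassigned:
        raise ValueError(f"columns without an assigned sterol class: {unassigned}")
    out = pd.DataFrame(
        0.0, index=composition.values.index, columns=list(CARBON_FAMILIES)
    )
    for col in composition.values.columns:
        family = f"C{parse_label(composition.sterol_classes[col]).carbons}"
        out[family] += composition.values[col]
    return out


def dominant_family(
    carbon_values: pd.DataFrame | pd.Series, threshold: float = 0.60
) -> pd.Series | str | None:
    """Family exceeding ``threshold`` x 1000 permille, else None.

    With threshold 0 this degenerates to the argmax family (any positive
    signal exceeds 0).
    """

    def _one(row: pd.Series):
        top = row.idxmax()
        return top if row[top] > threshold * 1000.0 else None

    if isinstance(carbon_values, pd.Series):
        return _one(carbon_values)
    return carbon_values.apply(_one, axis=1)


@dataclass(frozen=True)
class InternalStandardSpec:
    """The deuterated cholesterol spike added to every pollen sample.

    20 uL of a 0.1 mg/mL methanolic solution = 2 ug; at a monoisotopic
    mass of 393.399 Da (C27H39D7O) that is 5.084 nmol per sample.
    """

    name: str = "d7-cholesterol"
    volume_ul: float = 20.0
    concentration_mg_ml: float = 0.1
    monoisotopic_mass: float = 393.3988

    @property
    def amount_nmol(self) -> float:
        micrograms = self.volume_ul * self.concentration_mg_ml
        return micrograms / self.monoisotopic_mass * 1000.0


def total_sterol(
    analyte_areas: pd.Series,
    analyte_classes: dict[str, str],
    internal_standard_area: float,
    is_spec: InternalStandardSpec | None = None,
    pollen_mass_mg: float = 10.0,
) -> float:
    """Single-point total sterol estimate, mg sterol per kg pollen.

    Assumes an equimolar detector response (response factor 1): total
    nanomoles = spike nanomoles x (sum of analyte areas / spike area).
    Mass-out uses the area-weighted mean molecular mass of the annotated
    classes.  A labelled approximation, not a calibrated quantification.
    """
    if is_spec is None:
        is_spec = InternalStandardSpec()
    if internal_standard_area <= 0:
        raise ValueError(
            "internal standard not detected (area <= 0); "
            "total sterol quantification is unavailable for this sample"
        )
    if pollen_mass_mg <= 0:
        raise ValueError("pollen mass must be positive")
    total_area = float(analyte_areas.sum())
    if total_area == 0:
        return 0.0
    masses = np.array(
        [parse_label(analyte_classes[name]).neutral_mass for name in analyte_areas.index]
    )
    weights = analyte_areas.to_numpy(dtype=float)
    mean_mass = float(np.average(masses, weights=weights))
    amount_nmol = is_spec.amount_nmol * total_area / internal_standard_area
    mass_mg = amount_nmol * 1e-9 * mean_mass * 1e3
    return mass_mg / (pollen_mass_mg * 1e-6)
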