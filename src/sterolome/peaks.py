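"""Peak-table ingestion, signal extraction, cross-sample binning, blank
filtering and level-1/2/3 annotation.

The unit of identity across samples is the *signal*: the combination of
m/z rounded to 3 decimal places and a retention-time cluster (single
linkage, a gap larger than the RT window opens a new cluster).  Every
signal starts at annotation level 3 (raw m/z + RT); a blank-passing signal
whose mass matches a registry class is promoted to level 2, and to level 1
when it additionally elutes at a named standard's reference RT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import Registry, SterolClass

__all__ = [
    "PEAK_COLUMNS",
    "Manifest",
    "SignalTable",
    "read_peak_table",
    "read_manifest",
    "load_study_manifest",
    "summarize_manifest",
    "extract_signals",
    "bin_signals",
    "blank_filter",
    "annotate",
]

PEAK_COLUMNS = ["sample_id", "rt_min", "mz", "area"]

BLANK_ROLES = ("blank_solvent", "blank_extraction")


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited peak table with header sample_id,rt_min,mz,area."""
    peaks = pd.read_csv(path, sep=None, engine="python")
    missing = set(PEAK_COLUMNS) - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table {path} missing columns: {sorted(missing)}")
    peaks = peaks[PEAK_COLUMNS].copy()
    for col in ("rt_min", "mz", "area"):
        peaks[col] = pd.to_numeric(peaks[col])
    if (peaks["rt_min"] < 0).any() or (peaks["area"] < 0).any():
        raise ValueError(f"peak table {path} holds negative rt or area values")
    return peaks


class Manifest:
    """The sample manifest: species, tissue, role and ecological covariates.

    Roles are ``sample`` (leaf or pollen extract), ``blank_solvent``,
    ``blank_extraction`` (internal standard only) and ``qc`` (polyfloral
    pollen loadings).
    """

    REQUIRED = ["sample_id", "species", "tissue", "role", "pollination", "reward"]

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = set(self.REQUIRED) - set(frame.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        frame = frame.copy()
        if "pollinator" not in frame.columns:
            frame["pollinator"] = "NA"
        if "pollen_mass_mg" not in frame.columns:
            frame["pollen_mass_mg"] = np.nan
        if frame["sample_id"].duplicated().any():
            dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_ids in manifest: {dups}")
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def ids_with_role(self, *roles: str) -> list[str]:
        mask = self.frame["role"].isin(roles)
        return self.frame.loc[mask, "sample_id"].tolist()

    @property
    def blank_ids(self) -> list[str]:
        return self.ids_with_role(*BLANK_ROLES)

    @property
    def non_blank_ids(self) -> list[str]:
        mask = ~self.frame["role"].isin(BLANK_ROLES)
        return self.frame.loc[mask, "sample_id"].tolist()

    def column(self, name: str, sample_ids: list[str] | None = None) -> pd.Series:
        series = self.frame.set_index("sample_id")[name]
        return series if sample_ids is None else series.loc[sample_ids]


def read_manifest(path: str | Path) -> Manifest:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=False,
                        na_values=[""])
    return Manifest(frame)


def load_study_manifest() -> Manifest:
    """The packaged manifest of the 40-species leaf/pollen study."""
    from importlib import resources

    ref = resources.files("sterolome.data") / "study_manifest.tsv"
    with resources.as_file(ref) as p:
        return read_manifest(p)


def summarize_manifest(manifest: Manifest) -> dict:
    """Counts of species, paired species and samples per covariate level."""
    df = manifest.frame
    samples = df[df["role"] == "sample"]
    species = samples["species"].unique()
    by_species = samples.groupby("species")["tissue"].agg(lambda t: set(t))
    paired = [sp for sp, tissues in by_species.items() if {"leaf", "pollen"} <= tissues]
    pollination = (
        samples.drop_duplicates("species").groupby("pollination")["species"].count()
    )
    reward = samples.drop_duplicates("species").groupby("reward")["species"].count()
    return {
        "n_species": int(len(species)),
        "n_paired_species": int(len(paired)),
        "paired_species": sorted(paired),
        "n_samples": int(len(samples)),
        "per_pollination": {str(k): int(v) for k, v in pollination.items()},
        "per_reward": {str(k): int(v) for k, v in reward.items()},
    }


# ---------------------------------------------------------------------------
# signal extraction and binning


def extract_signals(
    peaks: pd.DataFrame,
    rt_window: tuple[float, float] = (3.0, 11.0),
    mz_window: tuple[float, float] = (360.0, 442.0),
    area_threshold: float = 500_000.0,
) -> pd.DataFrame:
    """Retain peaks inside the RT and m/z windows with area >= threshold.

    Intervals are closed; the area cut keeps peaks exactly at the
    threshold.  Idempotent by construction.
    """
    if rt_window[0] > rt_window[1] or mz_window[0] > mz_window[1]:
        raise ValueError("windows must be ordered (low, high)")
    mask = (
        peaks["rt_min"].between(*rt_window)
        & peaks["mz"].between(*mz_window)
        & (peaks["area"] >= area_threshold)
    )
    return peaks.loc[mask].reset_index(drop=True)


@dataclass
class SignalTable:
    """Signals x samples areas plus per-signal identity metadata.

    ``signals`` columns: mz_bin, rt, level, class_label, name,
    is_internal_standard, blank_pass (nullable until the blank rule runs).
    ``areas``: one row per signal (same index), one column per sample;
    missing areas are zeros.
    """

    signals: pd.DataFrame
    areas: pd.DataFrame

    def copy(self) -> "SignalTable":
        return SignalTable(self.signals.copy(), self.areas.copy())

    @property
    def n_signals(self) -> int:
        return len(self.signals)

    def passing(self) -> pd.Index:
        if self.signals["blank_pass"].isna().any():
            raise ValueError("blank filter has not been applied")
        return self.signals.index[self.signals["blank_pass"].astype(bool)]

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.signals, self.areas], axis=1)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="signal_id")

    @classmethod
    def load(cls, path: str | Path) -> "SignalTable":
        frame = pd.read_csv(path, sep="\t", index_col="signal_id")
        meta_cols = [
            "mz_bin", "rt", "level", "class_label", "name",
            "is_internal_standard", "blank_pass",
        ]
        signals = frame[meta_cols].copy()
        areas = frame.drop(columns=meta_cols)
        return cls(signals, areas)


def bin_signals(peaks: pd.DataFrame, rt_tol: float = 0.1) -> SignalTable:
    """Establish cross-sample signal identities.

    Two peaks share an identity iff their m/z round equal at 3 d.p. and
    their retention times fall in the same single-linkage cluster (a gap
    > ``rt_tol`` starts a new cluster).  Co-eluting duplicates within one
    sample are summed; the representative RT is the area-weighted mean.
    """
    if peaks.empty:
        signals = pd.DataFrame(
            columns=["mz_bin", "rt", "level", "class_label", "name",
                     "is_internal_standard", "blank_pass"]
        )
        return SignalTable(signals, pd.DataFrame())

    work = peaks.reset_index(drop=True).copy()
    work["mz_bin"] = work["mz"].round(3)

    records = []
    assignments = np.empty(len(work), dtype=object)
    for mz_bin, grp in work.groupby("mz_bin", sort=True):
        order = grp.sort_values("rt_min")
        rts = order["rt_min"].to_numpy()
        cluster_break = np.diff(rts) > rt_tol + 1e-12
        cluster_ids = np.concatenate([[0], np.cumsum(cluster_break)])
        for cid in np.unique(cluster_ids):
            members = order.iloc[cluster_ids == cid]
            weights = members["area"].to_numpy()
            rep_rt = (
                float(np.average(members["rt_min"], weights=weights))
                if weights.sum() > 0
                else float(members["rt_min"].mean())
            )
            signal_id = f"{mz_bin:.3f}@{rep_rt:.3f}"
            records.append((signal_id, mz_bin, rep_rt))
            assignments[members.index.to_numpy()] = signal_id

    work["signal_id"] = assignments
    areas = (
        work.pivot_table(
            index="signal_id", columns="sample_id", values="area", aggfunc="sum"
        )
        .fillna(0.0)
    )
    areas.columns.name = None

    signals = pd.DataFrame.from_records(
        records, columns=["signal_id", "mz_bin", "rt"]
    ).set_index("signal_id")
    signals = signals.loc[areas.index]
    signals["level"] = 3
    signals["class_label"] = None
    signals["name"] = None
    signals["is_internal_standard"] = False
    signals["blank_pass"] = pd.NA
    signals.index.name = None
    return SignalTable(signals, areas)


def blank_filter(
    table: SignalTable, manifest: Manifest, ratio: float = 3.0
) -> SignalTable:
    """Flag signals whose sample mean exceeds ``ratio`` x the blank mean.

    Solvent and extraction blanks are pooled.  Missing (signal, sample)
    areas count as zeros in both means; a signal absent from every blank
    passes whenever its sample mean is positive.  The comparison is strict
    ('higher than').
    """
    blanks = manifest.blank_ids
    if not blanks:
        raise ValueError("manifest holds no blank samples; the blank rule needs >= 1")
    non_blanks = manifest.non_blank_ids

    out = table.copy()
    if out.n_signals == 0:
        return out
    areas = out.areas.reindex(columns=manifest.sample_ids, fill_value=0.0)
    sample_mean = areas[non_blanks].mean(axis=1)
    blank_mean = areas[blanks].mean(axis=1)
    out.signals["blank_pass"] = (sample_mean > ratio * blank_mean).astype(bool)
    return out


def annotate(
    table: SignalTable,
    registry: Registry,
    tol_ppm: float = 5.0,
    rt_tol: float = 0.1,
) -> SignalTable:
    """Assign annotation levels to blank-filtered signals.

    Blank-passing signals whose binned mass matches a registry class get
    level 2 (nearest |delta m/z| on ambiguity); matching a named standard's
    reference RT within ``rt_tol`` as well promotes to level 1 (nearest RT
    on ambiguity).  Blank-failing signals stay level 3 regardless of mass.

    The deuterated internal standard is the one exception to the blank
    gate: the extraction blanks contain it by design, so it is identified
    by its own (deuterated) mass and reference RT irrespective of the
    blank flag, and flagged so compositions can exclude it.
    """
    out = table.copy()
    is_std = registry.internal_standard
    for signal_id, row in out.signals.iterrows():
        mz_bin = float(row["mz_bin"])
        rt = float(row["rt"])

        if is_std is not None and is_std.reference_rt is not None:
            within_mass = (
                abs(mz_bin - is_std.mz_theoretical) / is_std.mz_theoretical
                <= tol_ppm * 1e-6
            )
            if within_mass and abs(rt - is_std.reference_rt) <= rt_tol + 1e-12:
                out.signals.loc[signal_id, ["level", "class_label", "name"]] = (
                    1, is_std.sterol_class.label, is_std.name,
                )
                out.signals.loc[signal_id, "is_internal_standard"] = True
                continue

        if row["blank_pass"] is pd.NA or not bool(row["blank_pass"]):
            continue

        candidates = registry.lookup_by_mz(mz_bin, tol_ppm=tol_ppm)
        if not candidates:
            continue
        best_class = candidates[0]
        named_hits = [
            s
            for s in registry.named_for_class(best_class)
            if s.reference_rt is not None
            and abs(rt - s.reference_rt) <= rt_tol + 1e-12
        ]
        if named_hits:
            named_hits.sort(key=lambda s: abs(rt - s.reference_rt))
            best = named_hits[0]
            out.signals.loc[signal_id, ["level", "class_label", "name"]] = (
                1, best.sterol_class.label, best.name,
            )
        else:
            out.signals.loc[signal_id, ["level", "class_label"]] = (
                2, best_class.label,
            )
    return out
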