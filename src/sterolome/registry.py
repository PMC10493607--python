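"""Sterol mass calculus and the packaged sterol registry.

Plant sterols ionise under APCI almost exclusively as the dehydrated
protonated ion [M-H2O+H]+, so a sterol class is fully described by its
carbon count ``c`` and the number of double-bond equivalents ``d`` beyond
the four canonical rings.  A class is written ``ST(c:d)``; e.g. cholesterol
(C27H46O, one side-chain/ring double bond beyond the ring system) is
``ST(27:1)``.  Cyclopropane-ring sterols of the cycloartenol family carry
their extra ring in ``d`` (cycloartenol C30H50O is ``ST(30:2)``: the 9,19
cyclopropane ring plus the delta-24 double bond).

The registry groups classes into carbon families C27-C31 and carries the
named reference sterols, several of which are isomers sharing one class and
are distinguished chromatographically by retention time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MassConstants",
    "MASS",
    "SterolClass",
    "NamedSterol",
    "Registry",
    "theoretical_mz",
    "parse_label",
    "carbon_group",
    "load_registry",
    "TABLE_CLASSES",
    "AUXILIARY_MASSES",
]


@dataclass(frozen=True)
class MassConstants:
    """Monoisotopic masses (Da) used throughout the m/z calculus.

    The charge carrier is the proton (1.007276 Da), not atomic hydrogen:
    this is what reproduces the reference grid and the deuterated internal
    standard ion at the printed precision.
    """

    carbon: float = 12.0
    hydrogen: float = 1.00782503207
    deuterium: float = 2.01410177785
    oxygen: float = 15.9949146196
    proton: float = 1.00727646688

    @property
    def water(self) -> float:
        return 2.0 * self.hydrogen + self.oxygen


MASS = MassConstants()


class InvalidSterolClassError(ValueError):
    """Raised when a (carbons, dbe) pair implies a negative hydrogen count."""


def theoretical_mz(carbons: int, dbe: int, deuterium_count: int = 0) -> float:
    """m/z of the [M-H2O+H]+ ion of a sterol class, optionally deuterated.

    A sterol CcH(2c-6-2d)O loses water and gains a proton, so

        m/z = 12 c + (2c - 6 - 2d - k) m_H + k m_D + m_O - m_H2O + m_proton

    where ``k`` hydrogens are replaced by deuterium (k = 7 for the
    d7-cholesterol internal standard, giving m/z 376.395).
    """
    if dbe < 0:
        raise InvalidSterolClassError(f"dbe must be >= 0, got {dbe}")
    if deuterium_count < 0:
        raise InvalidSterolClassError(
            f"deuterium_count must be >= 0, got {deuterium_count}"
        )
    hydrogens = 2 * carbons - 6 - 2 * dbe
    if hydrogens < deuterium_count:
        raise InvalidSterolClassError(
            f"ST({carbons}:{dbe}) implies {hydrogens} hydrogens, fewer than "
            f"deuterium_count={deuterium_count}"
        )
    return (
        MASS.carbon * carbons
        + (hydrogens - deuterium_count) * MASS.hydrogen
        + deuterium_count * MASS.deuterium
        + MASS.oxygen
        - MASS.water
        + MASS.proton
    )


@dataclass(frozen=True, order=True)
class SterolClass:
    """A sterol class ST(c:d): carbon count and double-bond equivalents."""

    carbons: int
    dbe: int

    def __post_init__(self) -> None:
        if self.dbe < 0 or 2 * self.carbons - 6 - 2 * self.dbe < 0:
            raise InvalidSterolClassError(
                f"invalid sterol class ({self.carbons}, {self.dbe})"
            )

    @property
    def label(self) -> str:
        return f"ST({self.carbons}:{self.dbe})"

    @property
    def mz_theoretical(self) -> float:
        return theoretical_mz(self.carbons, self.dbe)

    @property
    def neutral_mass(self) -> float:
        """Monoisotopic mass of the neutral sterol CcH(2c-6-2d)O."""
        h = 2 * self.carbons - 6 - 2 * self.dbe
        return MASS.carbon * self.carbons + h * MASS.hydrogen + MASS.oxygen

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


_LABEL_RE = re.compile(r"^ST\((\d+):(\d+)\)$")


def parse_label(label: str) -> SterolClass:
    """Parse an ``ST(c:d)`` label; round-trips with ``SterolClass.label``."""
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"malformed sterol class label: {label!r}")
    return SterolClass(int(m.group(1)), int(m.group(2)))


def carbon_group(sterol_class: SterolClass) -> str:
    """Carbon family of a class: ST(29:1) -> 'C29'."""
    return f"C{sterol_class.carbons}"


@dataclass(frozen=True)
class NamedSterol:
    """A named reference sterol available as an external standard.

    ``reference_rt`` is the retention time (min) at which the standard
    elutes; isomers sharing a class differ in reference RT by more than the
    RT matching window.  ``deuterium_count`` > 0 marks isotopically
    labelled standards (the d7-cholesterol internal spike).
    """

    name: str
    sterol_class: SterolClass
    reference_rt: float | None = None
    is_internal_standard: bool = False
    deuterium_count: int = 0

    @property
    def mz_theoretical(self) -> float:
        return theoretical_mz(
            self.sterol_class.carbons, self.sterol_class.dbe, self.deuterium_count
        )

    @property
    def neutral_mass(self) -> float:
        h = (
            2 * self.sterol_class.carbons
            - 6
            - 2 * self.sterol_class.dbe
            - self.deuterium_count
        )
        return (
            MASS.carbon * self.sterol_class.carbons
            + h * MASS.hydrogen
            + self.deuterium_count * MASS.deuterium
            + MASS.oxygen
        )


#: Every ST(c:d) class whose [M-H2O+H]+ mass appears on the reference grid.
TABLE_CLASSES: tuple[SterolClass, ...] = tuple(
    SterolClass(c, d)
    for c, d in [
        (27, 1), (27, 2),
        (28, 0), (28, 1), (28, 2), (28, 3),
        (29, 0), (29, 1), (29, 2), (29, 3),
        (30, 1), (30, 2), (30, 3),
        (31, 2),
    ]
)

#: Printed reference masses that do not correspond to any ST(c:d)
#: dehydrated-protonated ion.  They form a CH2 homolog series matching, to
#: the printed precision, the protonated (non-dehydrated) [M+H]+ ions of
#: ST(28:2)/ST(29:2)/ST(30:2)/ST(31:2); they are kept as auxiliary masses
#: and are never matched to a class during annotation.
AUXILIARY_MASSES: tuple[float, ...] = (399.362, 413.378, 427.394, 441.409)


class Registry:
    """The collection of sterol classes and named reference sterols."""

    def __init__(
        self,
        classes: Iterable[SterolClass] = TABLE_CLASSES,
        named: Sequence[NamedSterol] = (),
        auxiliary_masses: Sequence[float] = AUXILIARY_MASSES,
    ) -> None:
        self.classes: tuple[SterolClass, ...] = tuple(sorted(set(classes)))
        self.named: tuple[NamedSterol, ...] = tuple(named)
        self.auxiliary_masses: tuple[float, ...] = tuple(auxiliary_masses)
        names = [s.name for s in self.named]
        if len(names) != len(set(names)):
            raise ValueError("named sterol names must be unique")
        missing = {s.sterol_class for s in self.named} - set(self.classes)
        if missing:
            raise ValueError(
                f"named sterols reference classes absent from the registry: {missing}"
            )

    # -- lookups ----------------------------------------------------------

    def lookup_by_mz(self, mz: float, tol_ppm: float = 5.0) -> list[SterolClass]:
        """Classes whose theoretical m/z lies within ``tol_ppm`` of ``mz``.

        Candidates are ordered by |delta m/z|; an empty list means the mass
        is off-grid.  Auxiliary masses are never returned.
        """
        if tol_ppm <= 0:
            raise ValueError("tol_ppm must be > 0")
        hits = [
            (abs(mz - cls.mz_theoretical), cls)
            for cls in self.classes
            if abs(mz - cls.mz_theoretical) / cls.mz_theoretical <= tol_ppm * 1e-6
        ]
        hits.sort(key=lambda t: (t[0], t[1]))
        return [cls for _, cls in hits]

    def named_for_class(self, sterol_class: SterolClass) -> list[NamedSterol]:
        return [
            s
            for s in self.named
            if s.sterol_class == sterol_class and not s.is_internal_standard
        ]

    def get_named(self, name: str) -> NamedSterol:
        for s in self.named:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def internal_standard(self) -> NamedSterol | None:
        for s in self.named:
            if s.is_internal_standard:
                return s
        return None

    @property
    def carbon_groups(self) -> dict[str, list[SterolClass]]:
        """Partition of the class grid by carbon family."""
        groups: dict[str, list[SterolClass]] = {}
        for cls in self.classes:
            groups.setdefault(carbon_group(cls), []).append(cls)
        return groups

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": s.name,
                "carbons": s.sterol_class.carbons,
                "dbe": s.sterol_class.dbe,
                "reference_rt_min": s.reference_rt,
                "internal_standard": int(s.is_internal_standard),
                "deuterium": s.deuterium_count,
            }
            for s in self.named
        ]
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "Registry":
        named = [
            NamedSterol(
                name=str(row["name"]),
                sterol_class=SterolClass(int(row["carbons"]), int(row["dbe"])),
                reference_rt=(
                    None if pd.isna(row["reference_rt_min"]) else float(row["reference_rt_min"])
                ),
                is_internal_standard=bool(int(row["internal_standard"])),
                deuterium_count=int(row.get("deuterium", 0)),
            )
            for _, row in frame.iterrows()
        ]
        return cls(named=named, **kwargs)


def load_registry(path: str | Path | None = None) -> Registry:
    """Load the packaged sterol registry, or a user-supplied TSV override."""
    if path is None:
        ref = resources.files("sterolome.data") / "sterol_registry.tsv"
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p, sep="\t", comment="#")
    else:
        frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "carbons", "dbe", "reference_rt_min", "internal_standard"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"registry file missing columns: {sorted(missing)}")
    return Registry.from_frame(frame)
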