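"""Ground-truthed synthetic sterolomics studies.

The generator emulates the structure of a multi-species leaf/pollen
sterol survey: per-species latent log-abundances evolve by Brownian
motion on a phylogeny, tissue and pollination effects shift the latent
scale, compositions are closed to per mille, and per-sample peak tables
are rendered with multiplicative (lognormal) detector noise, small mass
and retention-time jitter, off-grid decoy signals, blank contamination
and a deuterated internal standard spiked into every pollen sample and
the extraction blanks.

Effects are planted on latent natural-log abundances and then closed to
the simplex, so compositional constraints hold by construction (additive
effects on raw per-mille values could leave the simplex).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .peaks import Manifest
from .phylo import simulate_bm, tree_from_string
from .registry import Registry, load_registry, theoretical_mz

__all__ = ["GeneratorConfig", "GroundTruth", "StudyData", "generate_study", "preset"]


#: Baseline composition (permille) of the default study: C29-dominant, as
#: plant sterolomes generally are.
DEFAULT_BASELINE: dict[str, float] = {
    "beta-sitosterol": 480.0,
    "isofucosterol": 100.0,
    "stigmasterol": 70.0,
    "avenasterol": 40.0,
    "sitostanol": 25.0,
    "schottenol": 15.0,
    "campesterol": 80.0,
    "24-methylenecholesterol": 40.0,
    "episterol": 15.0,
    "brassicasterol": 10.0,
    "ergosterol": 5.0,
    "cholesterol": 30.0,
    "desmosterol": 20.0,
    "cycloartenol": 40.0,
    "obtusifoliol": 10.0,
    "cycloeucalenol": 5.0,
    "cycloartanol": 5.0,
    "24-methylenecycloartanol": 7.0,
    "cyclolaudenol": 3.0,
}

#: Pollen-minus-leaf shifts on the latent log scale: isofucosterol up in
#: pollen, beta-sitosterol up in leaves, with smaller shifts on the other
#: known tissue discriminators.
DEFAULT_TISSUE_EFFECT: dict[str, float] = {
    "beta-sitosterol": -0.45,
    "isofucosterol": 0.90,
    "cycloartenol": 0.35,
    "24-methylenecholesterol": 0.30,
    "desmosterol": 0.25,
    "campesterol": -0.15,
}

#: Animal-minus-wind shifts applied to pollen samples only.
DEFAULT_POLLINATION_EFFECT: dict[str, float] = {
    "cholesterol": 0.60,
    "24-methylenecholesterol": 0.50,
    "beta-sitosterol": -0.20,
}


@dataclass
class GeneratorConfig:
    """Study-level knobs of the synthetic generator.

    Defaults describe the emulated study: 31 species with paired leaf and
    pollen, 6 leaf-only and 3 pollen-only species (40 in total), 7 solvent
    and 3 extraction blanks, triplicate QCs at three pollen loadings, 10%
    multiplicative detector noise, <=2 ppm mass and <=0.03 min RT jitter.
    """

    n_paired_species: int = 31
    n_leaf_only: int = 6
    n_pollen_only: int = 3
    tree_newick: str | None = None  # Yule-simulated when None
    baseline: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    tissue_effect: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_EFFECT)
    )
    pollination_effect: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POLLINATION_EFFECT)
    )
    animal_fraction: float = 0.5
    bm_sigma2: float = 0.15  # log-abundance variance per unit tree depth
    noise_cv: float = 0.10
    n_decoys: int = 12
    n_contaminants: int = 6
    decoy_mz_range: tuple[float, float] = (360.0, 442.0)
    blank_contamination_area: float = 1.2e6
    contaminant_sample_factor: float = 1.5
    area_scale: float = 1.0e8  # total sterol area per sample
    internal_standard_area: float = 5.0e7
    rt_jitter_min: float = 0.03
    mz_jitter_ppm: float = 2.0
    n_solvent_blanks: int = 7
    n_extraction_blanks: int = 3
    qc_loadings: tuple[float, ...] = (2.5, 5.0, 10.0)
    qc_replicates: int = 3
    pollen_mass_mg: float = 10.0
    seed: int = 0

    def validate(self, registry: Registry) -> None:
        total = sum(self.baseline.values())
        if abs(total - 1000.0) > 1e-6:
            raise ValueError(f"baseline composition must sum to 1000, got {total}")
        known = {s.name for s in registry.named}
        for source in (self.baseline, self.tissue_effect, self.pollination_effect):
            unknown = set(source) - known
            if unknown:
                raise ValueError(f"sterols absent from the registry: {sorted(unknown)}")
        for name in set(self.tissue_effect) | set(self.pollination_effect):
            if self.baseline.get(name, 0.0) <= 0:
                raise ValueError(
                    f"effect planted on sterol with zero baseline: {name}"
                )
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.animal_fraction <= 1:
            raise ValueError("animal_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    compositions: pd.DataFrame  # samples x sterols, permille
    tissue_effect_sterols: list[str]
    pollination_effect_sterols: list[str]
    tree_newick: str
    bm_sigma2: float
    peak_identities: pd.Series  # aligned with the peak table rows
    species_pollination: pd.Series


@dataclass
class StudyData:
    manifest: Manifest
    peaks: pd.DataFrame
    truth: GroundTruth
    config: GeneratorConfig


def _yule_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Seeded pure-birth tree, tip edges extended past the final split and
    depth rescaled to 1 so that bm_sigma2 is a per-tree-depth rate."""
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    tree.is_rooted = True
    depth = max(
        lf.distance_from_root() for lf in tree.leaf_node_iter()
    )
    for lf in tree.leaf_node_iter():
        lf.edge.length = (lf.edge.length or 0.0) + 0.1 * max(depth, 1.0)
    depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    return tree


def _species_names(config: GeneratorConfig) -> tuple[list[str], list[str], list[str]]:
    paired = [f"Species_{i + 1:02d}" for i in range(config.n_paired_species)]
    leaf_only = [f"LeafOnly_{i + 1:02d}" for i in range(config.n_leaf_only)]
    pollen_only = [f"PollenOnly_{i + 1:02d}" for i in range(config.n_pollen_only)]
    return paired, leaf_only, pollen_only


def _closed_composition(log_abund: pd.Series) -> pd.Series:
    scaled = np.exp(log_abund - log_abund.max())
    return 1000.0 * scaled / scaled.sum()


def generate_study(
    config: GeneratorConfig, registry: Registry | None = None
) -> StudyData:
    """Generate a manifest, a raw peak table and its ground truth.

    Fully deterministic under ``config.seed``: re-running with the same
    configuration yields byte-identical outputs.
    """
    if registry is None:
        registry = load_registry()
    config.validate(registry)
    rng = np.random.default_rng(config.seed)

    sterols = list(config.baseline)
    paired, leaf_only, pollen_only = _species_names(config)
    all_species = paired + leaf_only + pollen_only

    if config.tree_newick is not None:
        tree = tree_from_string(config.tree_newick)
    else:
        tree = _yule_tree(max(config.n_paired_species, 3), int(rng.integers(2**31)))
    tree_tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if config.tree_newick is None:
        for label, name in zip(tree_tips, paired):
            tip = next(
                lf for lf in tree.leaf_node_iter() if lf.taxon.label == label
            )
            tip.taxon.label = name
        tree_tips = [lf.taxon.label for lf in tree.leaf_node_iter()]

    # latent per-species deviations: BM on the tree for tree species,
    # iid draws of matching marginal variance for off-tree species
    deviations = pd.DataFrame(0.0, index=all_species, columns=sterols)
    for sterol in sterols:
        if config.bm_sigma2 > 0:
            on_tree = simulate_bm(tree, config.bm_sigma2, 0.0, rng)
            for sp in all_species:
                if sp in on_tree.index:
                    deviations.loc[sp, sterol] = on_tree[sp]
                else:
                    deviations.loc[sp, sterol] = rng.normal(
                        0.0, np.sqrt(config.bm_sigma2)
                    )

    pollination = pd.Series(
        np.where(
            rng.random(len(all_species)) < config.animal_fraction, "animal", "wind"
        ),
        index=all_species,
    )
    pollinators = ("bee", "butterfly", "moth", "hummingbird", "generalist")
    rewards = ("nectar", "pollen", "oil")

    log_base = pd.Series(
        {s: np.log(v) if v > 0 else -np.inf for s, v in config.baseline.items()}
    )

    manifest_rows: list[dict] = []
    comp_rows: dict[str, pd.Series] = {}
    animal_counter = 0
    species_meta: dict[str, dict] = {}
    for sp in all_species:
        meta = {"pollination": pollination[sp], "reward": "NA", "pollinator": "NA"}
        if pollination[sp] == "animal":
            meta["reward"] = rewards[animal_counter % len(rewards)]
            meta["pollinator"] = pollinators[animal_counter % len(pollinators)]
            animal_counter += 1
        species_meta[sp] = meta

    def sample_entry(sp: str, tissue: str) -> str:
        sample_id = f"{sp}_{tissue}"
        meta = species_meta[sp]
        manifest_rows.append(
            {
                "sample_id": sample_id,
                "species": sp,
                "tissue": tissue,
                "role": "sample",
                "pollination": meta["pollination"],
                "reward": meta["reward"],
                "pollinator": meta["pollinator"],
                "pollen_mass_mg": config.pollen_mass_mg if tissue == "pollen" else np.nan,
            }
        )
        logs = log_base + deviations.loc[sp]
        if tissue == "pollen":
            for name, shift in config.tissue_effect.items():
                logs[name] += shift
            if meta["pollination"] == "animal":
                for name, shift in config.pollination_effect.items():
                    logs[name] += shift
        comp_rows[sample_id] = _closed_composition(logs)
        return sample_id

    for sp in paired:
        sample_entry(sp, "leaf")
        sample_entry(sp, "pollen")
    for sp in leaf_only:
        sample_entry(sp, "leaf")
    for sp in pollen_only:
        sample_entry(sp, "pollen")

    qc_composition = _closed_composition(log_base)
    for loading in config.qc_loadings:
        for rep in range(1, config.qc_replicates + 1):
            sample_id = f"qc_{loading:g}mg_{rep}"
            manifest_rows.append(
                {
                    "sample_id": sample_id,
                    "species": "polyfloral QC",
                    "tissue": "pollen",
                    "role": "qc",
                    "pollination": "NA",
                    "reward": "NA",
                    "pollinator": "NA",
                    "pollen_mass_mg": loading,
                }
            )
            comp_rows[sample_id] = qc_composition

    for i in range(1, config.n_solvent_blanks + 1):
        manifest_rows.append(
            {
                "sample_id": f"blank_solvent_{i}",
                "species": "NA", "tissue": "NA", "role": "blank_solvent",
                "pollination": "NA", "reward": "NA", "pollinator": "NA",
                "pollen_mass_mg": np.nan,
            }
        )
    for i in range(1, config.n_extraction_blanks + 1):
        manifest_rows.append(
            {
                "sample_id": f"blank_extraction_{i}",
                "species": "NA", "tissue": "NA", "role": "blank_extraction",
                "pollination": "NA", "reward": "NA", "pollinator": "NA",
                "pollen_mass_mg": np.nan,
            }
        )

    manifest = Manifest(pd.DataFrame(manifest_rows))
    compositions = pd.DataFrame(comp_rows).T[sterols]

    # --- peak rendering ---------------------------------------------------
    sterol_info = {name: registry.get_named(name) for name in sterols}
    qc_ids = [r["sample_id"] for r in manifest_rows if r["role"] == "qc"]
    qc_scale = {
        sid: loading / max(config.qc_loadings)
        for sid, loading in zip(
            qc_ids,
            [ld for ld in config.qc_loadings for _ in range(config.qc_replicates)],
        )
    }

    def noisy(base: float) -> float:
        if config.noise_cv <= 0:
            return base
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        return base * float(rng.lognormal(-0.5 * sigma**2, sigma))

    def jitter_mz(mz: float) -> float:
        if config.mz_jitter_ppm <= 0:
            return mz
        return mz * (1.0 + rng.uniform(-1, 1) * config.mz_jitter_ppm * 1e-6)

    def jitter_rt(rt: float) -> float:
        if config.rt_jitter_min <= 0:
            return rt
        return rt + rng.uniform(-1, 1) * config.rt_jitter_min

    peak_rows: list[tuple] = []
    identities: list[str] = []

    def add_peak(sample_id: str, rt: float, mz: float, area: float, identity: str):
        peak_rows.append((sample_id, rt, mz, area))
        identities.append(identity)

    is_std = registry.internal_standard
    for row in manifest_rows:
        sid = row["sample_id"]
        role = row["role"]
        if role in ("sample", "qc"):
            comp = comp_rows[sid]
            scale = config.area_scale * (qc_scale[sid] if role == "qc" else 1.0)
            for name in sterols:
                base_area = comp[name] / 1000.0 * scale
                area = noisy(base_area)
                if area <= 0:
                    continue
                info = sterol_info[name]
                add_peak(
                    sid,
                    jitter_rt(info.reference_rt),
                    jitter_mz(info.mz_theoretical),
                    area,
                    name,
                )
        if is_std is not None and (
            (role in ("sample", "qc") and row["tissue"] == "pollen")
            or role == "blank_extraction"
        ):
            add_peak(
                sid,
                jitter_rt(is_std.reference_rt),
                jitter_mz(is_std.mz_theoretical),
                noisy(config.internal_standard_area),
                is_std.name,
            )

    # decoy and contaminant identities: off-grid masses, clear of every
    # reference RT so they can never steal a level-1 match
    grid = [cls.mz_theoretical for cls in registry.classes]
    if is_std is not None:
        grid.append(is_std.mz_theoretical)
    ref_rts = [
        s.reference_rt for s in registry.named if s.reference_rt is not None
    ]

    def draw_decoy() -> tuple[float, float]:
        while True:
            mz = float(rng.uniform(*config.decoy_mz_range))
            if min(abs(mz - g) for g in grid) < 0.01:
                continue
            rt = float(rng.uniform(3.2, 10.8))
            if min(abs(rt - r) for r in ref_rts) < 0.2:
                continue
            return mz, rt

    non_blank_ids = [
        r["sample_id"] for r in manifest_rows if r["role"] in ("sample", "qc")
    ]
    blank_ids = [
        r["sample_id"] for r in manifest_rows if r["role"].startswith("blank")
    ]
    n_cont = min(config.n_contaminants, config.n_decoys)
    for k in range(config.n_decoys):
        mz, rt = draw_decoy()
        is_contaminant = k < n_cont
        label = f"contaminant_{k}" if is_contaminant else f"decoy_{k}"
        if is_contaminant:
            for sid in non_blank_ids:
                add_peak(
                    sid, jitter_rt(rt), jitter_mz(mz),
                    noisy(
                        config.blank_contamination_area
                        * config.contaminant_sample_factor
                    ),
                    label,
                )
            for sid in blank_ids:
                add_peak(
                    sid, jitter_rt(rt), jitter_mz(mz),
                    noisy(config.blank_contamination_area),
                    label,
                )
        else:
            for sid in non_blank_ids:
                add_peak(
                    sid, jitter_rt(rt), jitter_mz(mz), noisy(2.5e6), label
                )

    peaks = pd.DataFrame(peak_rows, columns=["sample_id", "rt_min", "mz", "area"])
    truth = GroundTruth(
        compositions=compositions,
        tissue_effect_sterols=sorted(
            config.tissue_effect, key=lambda s: -abs(config.tissue_effect[s])
        ),
        pollination_effect_sterols=sorted(
            config.pollination_effect, key=lambda s: -abs(config.pollination_effect[s])
        ),
        tree_newick=tree.as_string(schema="newick"),
        bm_sigma2=config.bm_sigma2,
        peak_identities=pd.Series(identities, name="identity"),
        species_pollination=pollination,
    )
    return StudyData(manifest=manifest, peaks=peaks, truth=truth, config=config)


def preset(name: str) -> GeneratorConfig:
    """Named generator configurations.

    - ``paperlike``: the default emulated study (31 paired + 6 leaf-only +
      3 pollen-only species, C29-dominant baseline, opposite-sign tissue
      shifts on beta-sitosterol and isofucosterol).
    - ``null``: same structure with every planted effect removed.
    - ``noiseless``: no detector noise, jitter, decoys or contamination;
      larger area scale so every planted signal clears the area threshold.
    - ``large-effect``: paperlike with strong (+/-1.5 log-unit) tissue
      shifts on the two marker sterols, for power checks.
    """
    key = name.replace("_", "-").lower()
    if key == "paperlike":
        return GeneratorConfig()
    if key == "null":
        return GeneratorConfig(tissue_effect={}, pollination_effect={})
    if key == "noiseless":
        return GeneratorConfig(
            noise_cv=0.0,
            rt_jitter_min=0.0,
            mz_jitter_ppm=0.0,
            n_decoys=0,
            n_contaminants=0,
            area_scale=1.0e9,
        )
    if key == "large-effect":
        return GeneratorConfig(
            tissue_effect={"beta-sitosterol": -1.5, "isofucosterol": 1.5}
        )
    raise ValueError(f"unknown preset: {name!r}")
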