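"""Synthetic longitudinal study generator.

Emulates the design and signal structure the analysis pipeline assumes: a
handful of homes (intervention + control) sampled biweekly from week -8 to
week +14, five dust strata per home plus an outdoor sampler, soil seeding
events at weeks 0/4/8, and per-sample communities drawn as mixtures of four
source pools (soil, human occupants, outdoor air, resident home background)
with Dirichlet-multinomial read noise.

The soil contribution follows the simplest model consistent with the
qualitative behaviour the pipeline is meant to detect: a per-home deposition
amplitude, multiplicative spatial attenuation per stratum (strongest at the
entrance infant breathing zone, weakest at the living-room adult breathing
zone and floor), and exponential temporal decay from the most recent seeding
event. Background source weights are rescaled to the remaining mass so each
sample's mixing weights sum to one; the generator records those weights as
per-sample ground truth. A seasonal ramp slowly raises the outdoor
contribution late in the study, and a small reagent-contaminant pool plus
blank samples make the decontamination stage exercisable end to end.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    AbundanceTable,
    SampleMetadata,
    Taxonomy,
    write_abundance_table,
    write_metadata,
    write_taxonomy,
)

POOLS = ("soil", "human", "outdoor", "home")

#: stratum name -> (sample_type, location, height, spatial attenuation)
DEFAULT_STRATA: dict[str, tuple[str, str, str, float]] = {
    "entrance_IBZ": ("settled_dust", "entrance", "IBZ", 1.0),
    "entrance_ABZ": ("settled_dust", "entrance", "ABZ", 0.7),
    "LR_IBZ": ("settled_dust", "living_room", "IBZ", 0.45),
    "LR_ABZ": ("settled_dust", "living_room", "ABZ", 0.35),
    "LR_floor": ("floor_dust", "floor", "none", 0.25),
    "outdoor": ("settled_dust", "outdoor", "none", 0.0),
}


@dataclass
class SimulationConfig:
    """Free parameters of the synthetic study; defaults mirror the reference
    design (5 intervention + 1 control home, biweekly weeks -8..14, seedings
    at 0/4/8) with signal magnitudes placed in the regime the pipeline is
    designed for (post-seeding soil-index increases of roughly 1-10
    percentage points near the rug)."""

    n_intervention_homes: int = 5
    n_control_homes: int = 1
    weeks: list[int] = field(default_factory=lambda: list(range(-8, 16, 2)))
    seeding_weeks: list[int] = field(default_factory=lambda: [0, 4, 8])
    strata: dict[str, tuple[str, str, str, float]] = field(
        default_factory=lambda: dict(DEFAULT_STRATA)
    )
    # source pools
    richness: dict[str, int] = field(
        default_factory=lambda: {"soil": 40, "human": 30, "outdoor": 40, "home": 50}
    )
    profile_concentration: dict[str, float] = field(
        default_factory=lambda: {"soil": 0.4, "human": 0.6, "outdoor": 0.5, "home": 0.7}
    )
    soil_outdoor_overlap: float = 0.05
    # deposition and decay
    amplitudes: list[float] = field(
        default_factory=lambda: [0.22, 0.14, 0.12, 0.10, 0.08]
    )
    decay_rate: float = 0.3466  # per week; halves every 2 weeks
    background_weights: dict[str, float] = field(
        default_factory=lambda: {"human": 0.45, "outdoor": 0.15, "home": 0.40}
    )
    outdoor_background_weights: dict[str, float] = field(
        default_factory=lambda: {"human": 0.05, "outdoor": 0.85, "home": 0.10}
    )
    seasonal_start_week: int = 6
    seasonal_slope: float = 0.01  # extra outdoor weight per week past the start
    # read model
    depth_mean: float = 5000.0
    depth_sigma: float = 0.25
    overdispersion: float = 2000.0
    # soil aliquots and QC samples
    n_aliquots_per_event: int = 2
    aliquot_depth_mean: float = 8000.0
    n_blanks: int = 4
    n_contaminants: int = 3
    contaminant_weight: float = 5e-5
    blank_depth_mean: float = 1500.0
    kingdom: str = "bacteria"

    def __post_init__(self) -> None:
        if len(self.amplitudes) != self.n_intervention_homes:
            raise ValueError(
                "amplitudes must list one deposition amplitude per intervention home"
            )
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("deposition amplitudes must be >= 0")
        for name, (_, _, _, att) in self.strata.items():
            if not 0.0 <= att <= 1.0:
                raise ValueError(f"attenuation for {name!r} must be in [0,1]")
        if any(r < 1 for r in self.richness.values()):
            raise ValueError("pool richness must be >= 1")
        if not 0.0 <= self.soil_outdoor_overlap <= 1.0:
            raise ValueError("soil_outdoor_overlap must be a fraction")
        if any(w < 0 for w in self.background_weights.values()):
            raise ValueError("background weights must be >= 0")

    @property
    def intervention_homes(self) -> list[str]:
        return [f"H{i + 1}" for i in range(self.n_intervention_homes)]

    @property
    def control_homes(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_control_homes)]

    @property
    def homes(self) -> list[str]:
        return self.intervention_homes + self.control_homes

    def amplitude_for(self, home: str) -> float:
        if home in self.control_homes:
            return 0.0
        return float(self.amplitudes[self.intervention_homes.index(home)])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "strata" in raw:
            raw["strata"] = {k: tuple(v) for k, v in raw["strata"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["strata"] = {k: list(v) for k, v in payload["strata"].items()}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _stream(seed: int, label: str) -> np.random.Generator:
    """Independent per-label RNG stream derived from the master seed by a
    stable (hash-based) key, so adding samples never perturbs existing ones."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, key]))


@dataclass
class SourceProfiles:
    """Per-pool relative-abundance profiles on a shared feature axis, plus
    the synthetic taxonomy of every feature."""

    profiles: pd.DataFrame  # features x pools (incl. 'contaminant')
    taxonomy: Taxonomy


_HSP_SEED_TAXA = (
    # genus, family — the first human-pool features carry these assignments
    ("Staphylococcus", "Staphylococcaceae"),
    ("Streptococcus", "Streptococcaceae"),
    ("Cutibacterium", "Propionibacteriaceae"),
    ("Corynebacterium", "Corynebacteriaceae"),
    ("Escherichia", "Enterobacteriaceae"),
)


def make_source_profiles(config: SimulationConfig, seed: int) -> SourceProfiles:
    """Draw the four source-pool profiles (plus a tiny contaminant pool).

    Each pool occupies its own block of features and its composition is drawn
    from a symmetric Dirichlet with the pool's concentration parameter (lower
    concentration -> a few dominant taxa, as in a soil community). A
    configurable fraction of soil features is shared with the outdoor pool,
    which raises the pre-seeding floor of any soil signature — the situation
    observed for fungal communities, whose soil taxa also ride in on outdoor
    air.
    """
    rng = _stream(seed, "profiles")
    n_shared = int(round(config.soil_outdoor_overlap * config.richness["soil"]))

    feature_ids: list[str] = []
    pool_features: dict[str, list[int]] = {p: [] for p in POOLS}
    assignments: dict[str, tuple[str, ...]] = {}

    def add_feature(pool: str, genus: str, family: str, order_: str = "") -> int:
        ix = len(feature_ids)
        fid = f"ASV{ix + 1:04d}"
        feature_ids.append(fid)
        domain = "Bacteria" if config.kingdom == "bacteria" else "Fungi"
        assignments[fid] = (
            domain, f"{pool.capitalize()}Phylum", f"{pool.capitalize()}Class",
            order_ or f"{pool.capitalize()}Order", family, genus,
        )
        return ix

    for pool in POOLS:
        n = config.richness[pool]
        if pool == "outdoor":
            # first n_shared outdoor slots reuse soil features
            pool_features[pool].extend(pool_features["soil"][:n_shared])
            n = max(0, n - n_shared)
        for j in range(n):
            prefix = pool.capitalize()
            if pool == "human" and j < len(_HSP_SEED_TAXA):
                genus, family = _HSP_SEED_TAXA[j]
            elif j % 8 == 7:
                # unassigned genus, exercises the "<family>_unclassified" rule
                genus, family = "", f"{prefix}Family{j:02d}"
            elif j % 6 == 5 and j > 0:
                # share the previous feature's genus, exercises rank aggregation
                prev_fid = feature_ids[pool_features[pool][-1]]
                genus = assignments[prev_fid][5] or f"{prefix}_g{j:02d}"
                family = assignments[prev_fid][4]
            else:
                genus, family = f"{prefix}_g{j:02d}", f"{prefix}Family{j // 3:02d}"
            pool_features[pool].append(add_feature(pool, genus, family))

    contaminant_ix = [
        add_feature("home", f"Contam_g{j:02d}", "ContamFamily", order_="ContamOrder")
        for j in range(config.n_contaminants)
    ]

    n_features = len(feature_ids)
    profiles = pd.DataFrame(
        0.0, index=pd.Index(feature_ids), columns=list(POOLS) + ["contaminant"]
    )
    for pool in POOLS:
        ixs = pool_features[pool]
        alpha = np.full(len(ixs), config.profile_concentration[pool])
        if pool == "human":
            alpha[: len(_HSP_SEED_TAXA)] *= 8.0  # occupant signal is HSP-heavy
        weights = rng.dirichlet(alpha)
        profiles.iloc[ixs, profiles.columns.get_loc(pool)] = weights
    if contaminant_ix:
        w = rng.dirichlet(np.full(len(contaminant_ix), 1.0))
        profiles.iloc[contaminant_ix, profiles.columns.get_loc("contaminant")] = w
    return SourceProfiles(profiles=profiles, taxonomy=Taxonomy(assignments))


def soil_weight(week: int, stratum: str, home: str, config: SimulationConfig) -> float:
    """Ground-truth soil mixing weight for a sample.

    w_soil = A_home * attenuation(stratum) * exp(-lambda * dt) with dt the
    weeks since the most recent seeding event *strictly before* the sample
    week (the sample whose window ends at a seeding week was collected before
    deployment, so it sees no soil from that event). Zero before the first
    seeding and for control homes.
    """
    if stratum not in config.strata:
        raise KeyError(f"unknown stratum {stratum!r}")
    amplitude = config.amplitude_for(home)
    att = config.strata[stratum][3]
    past = [s for s in config.seeding_weeks if s < week]
    if not past or amplitude == 0.0 or att == 0.0:
        return 0.0
    dt = week - max(past)
    return float(amplitude * att * math.exp(-config.decay_rate * dt))


def _mixing_weights(
    week: int, stratum: str, home: str, config: SimulationConfig
) -> dict[str, float]:
    w_soil = soil_weight(week, stratum, home, config)
    if stratum == "outdoor":
        base = dict(config.outdoor_background_weights)
    else:
        base = dict(config.background_weights)
    ramp = config.seasonal_slope * max(0, week - config.seasonal_start_week)
    base["outdoor"] = base.get("outdoor", 0.0) + ramp
    total = sum(base.values())
    scale = (1.0 - w_soil) / total
    weights = {pool: base.get(pool, 0.0) * scale for pool in ("human", "outdoor", "home")}
    weights["soil"] = w_soil
    return weights


@dataclass
class StudyBundle:
    """Everything one simulated study produces."""

    table: AbundanceTable
    metadata: SampleMetadata
    truth: pd.DataFrame  # dust samples x (w_soil, w_human, w_outdoor, w_home)
    profiles: SourceProfiles
    config: SimulationConfig

    @property
    def taxonomy(self) -> Taxonomy:
        return self.profiles.taxonomy

    def sample_ids_of_type(self, sample_type: str) -> list[str]:
        sub = self.metadata.frame
        return list(sub.loc[sub["sample_type"] == sample_type, "sample_id"])

    @property
    def aliquot_ids(self) -> list[str]:
        return self.sample_ids_of_type("source_aliquot")

    @property
    def blank_ids(self) -> list[str]:
        return self.sample_ids_of_type("control_blank")

    @property
    def dust_ids(self) -> list[str]:
        sub = self.metadata.frame
        mask = sub["sample_type"].isin(["settled_dust", "floor_dust"])
        return list(sub.loc[mask, "sample_id"])


def _draw_counts(
    rng: np.random.Generator,
    composition: np.ndarray,
    depth_mean: float,
    depth_sigma: float,
    overdispersion: float,
) -> np.ndarray:
    depth = max(1, int(round(rng.lognormal(math.log(depth_mean), depth_sigma))))
    support = np.flatnonzero(composition > 0)
    alpha = overdispersion * composition[support]
    p = rng.dirichlet(alpha)
    counts = np.zeros_like(composition, dtype=np.int64)
    counts[support] = rng.multinomial(depth, p)
    return counts


def simulate_study(config: SimulationConfig, seed: int) -> StudyBundle:
    """Generate one full synthetic study, reproducible from ``seed``.

    Every sample gets its own RNG stream keyed on (home, stratum, week), so
    the draw for a given sample does not depend on how many other samples
    exist. Dust/outdoor samples are Dirichlet-multinomial draws around the
    mixture prescribed by :func:`soil_weight`; soil aliquots are draws from
    the soil pool at each seeding event; blanks are contaminant-dominated.
    """
    profiles = make_source_profiles(config, seed)
    prof = profiles.profiles
    feature_ids = list(prof.index)
    cw = config.contaminant_weight

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    truth_rows: dict[str, dict[str, float]] = {}

    for home in config.homes:
        is_control = home in config.control_homes
        for stratum, (stype, loc, height, _) in config.strata.items():
            for week in config.weeks:
                sid = f"{home}_{stratum}_w{week}"
                weights = _mixing_weights(week, stratum, home, config)
                comp = sum(
                    weights[pool] * prof[pool].to_numpy() for pool in POOLS
                )
                comp = (1.0 - cw) * comp + cw * prof["contaminant"].to_numpy()
                rng = _stream(seed, sid)
                columns[sid] = _draw_counts(
                    rng, comp, config.depth_mean, config.depth_sigma,
                    config.overdispersion,
                )
                meta_rows.append(
                    {
                        "sample_id": sid, "home": home, "sample_type": stype,
                        "location": loc, "height": height, "week": week,
                        "is_control_home": is_control, "kingdom": config.kingdom,
                    }
                )
                truth_rows[sid] = {f"w_{p}": weights[p] for p in POOLS}

    for home in config.intervention_homes:
        for week in config.seeding_weeks:
            for rep in range(config.n_aliquots_per_event):
                sid = f"{home}_soil_w{week}_r{rep + 1}"
                rng = _stream(seed, sid)
                columns[sid] = _draw_counts(
                    rng, prof["soil"].to_numpy(), config.aliquot_depth_mean,
                    config.depth_sigma, config.overdispersion,
                )
                meta_rows.append(
                    {
                        "sample_id": sid, "home": home, "sample_type": "source_aliquot",
                        "location": "source", "height": "none", "week": week,
                        "is_control_home": False, "kingdom": config.kingdom,
                    }
                )

    blank_comp = 0.9 * prof["contaminant"].to_numpy() + 0.1 * prof["home"].to_numpy()
    for i in range(config.n_blanks):
        sid = f"BLANK_{i + 1}"
        rng = _stream(seed, sid)
        columns[sid] = _draw_counts(
            rng, blank_comp, config.blank_depth_mean, config.depth_sigma,
            config.overdispersion,
        )
        meta_rows.append(
            {
                "sample_id": sid, "home": "none", "sample_type": "control_blank",
                "location": "none", "height": "none", "week": config.weeks[0],
                "is_control_home": False, "kingdom": config.kingdom,
            }
        )

    data = pd.DataFrame(columns, index=pd.Index(feature_ids))
    table = AbundanceTable(data, kingdom=config.kingdom, mode="counts")
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    truth = pd.DataFrame.from_dict(truth_rows, orient="index")
    truth.index.name = "sample_id"
    return StudyBundle(
        table=table, metadata=metadata, truth=truth, profiles=profiles, config=config
    )


def write_fixture(bundle: StudyBundle, out_dir: str | Path, force: bool = False) -> None:
    """Write the bundle as the plain-text dialects the pipeline loaders read:
    table.tsv, taxonomy.tsv, metadata.tsv, truth.tsv (+ config.yaml)."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    write_abundance_table(bundle.table, out / "table.tsv")
    write_taxonomy(bundle.taxonomy, out / "taxonomy.tsv")
    write_metadata(bundle.metadata, out / "metadata.tsv")
    truth = bundle.truth.copy()
    truth.to_csv(out / "truth.tsv", sep="\t", float_format="%.10g")
    bundle.config.to_yaml(out / "config.yaml")
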