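import numpy as np
import pandas as pd
import pytest

import soiltrace as st
from soiltrace.pipeline import analyze_bundle

N_REPLICATES = 20


def tiny_config() -> st.SimulationConfig:
    """Scaled-down study used for the committed plain-text fixture:
    2 intervention + 1 control home, one seeding event, 4 strata."""
    strata = {
        k: v
        for k, v in st.synthetic.DEFAULT_STRATA.items()
        if k in ("entrance_IBZ", "entrance_ABZ", "LR_floor", "outdoor")
    }
    return st.SimulationConfig(
        n_intervention_homes=2,
        n_control_homes=1,
        weeks=[-2, 0, 2, 4],
        seeding_weeks=[0],
        strata=strata,
        richness={"soil": 12, "human": 10, "outdoor": 10, "home": 12},
        amplitudes=[0.2, 0.1],
        n_aliquots_per_event=2,
        n_blanks=2,
        n_contaminants=2,
        depth_mean=3000.0,
        aliquot_depth_mean=3000.0,
        blank_depth_mean=800.0,
    )


def run_replicate(seed: int, config: st.SimulationConfig | None = None):
    """One simulated study + full pipeline run."""
    cfg = config if config is not None else st.SimulationConfig()
    bundle = st.simulate_study(cfg, seed=seed)
    result = analyze_bundle(bundle, depth=2000, rarefy_seed=seed + 1)
    return bundle, result


def paired_mean_diffs(bundle, result, comparison: str) -> pd.Series:
    """Per-stratum paired SSI mean difference (fractions) for one comparison."""
    tab = st.intervention_table(
        {"SSI": result.ssi}, bundle.metadata, st.SeedingDesign(), comparisons=[comparison]
    )
    return tab.set_index("stratum")["mean_diff"]


def post_seeding_frame(bundle, result) -> pd.DataFrame:
    """SSI and ground-truth soil weight for post-seeding intervention dust."""
    meta = bundle.metadata.frame.set_index("sample_id")
    ids = [s for s in result.ssi.index if s in bundle.truth.index]
    sub = meta.loc[ids]
    mask = (
        (sub["week"] > 0)
        & (~sub["is_control_home"])
        & (sub["location"] != "outdoor")
        & sub["sample_type"].isin(["settled_dust", "floor_dust"])
    )
    keep = list(sub.index[mask])
    return pd.DataFrame(
        {"ssi": result.ssi.loc[keep], "w_soil": bundle.truth.loc[keep, "w_soil"]}
    )


@pytest.fixture(scope="session")
def default_bundle():
    return st.simulate_study(st.SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def default_result(default_bundle):
    return analyze_bundle(default_bundle, depth=2000, rarefy_seed=12)


@pytest.fixture(scope="session")
def replicate_batch():
    """Independent default-condition study replicates with pipeline output."""
    return [run_replicate(1000 + i) for i in range(N_REPLICATES)]


@pytest.fixture(scope="session")
def null_batch():
    """Replicates with deposition amplitude zero everywhere (no intervention
    signal; homes still labelled as intervention homes)."""
    cfg = st.SimulationConfig(amplitudes=[0.0] * 5)
    return [run_replicate(3000 + i, cfg) for i in range(N_REPLICATES)]


@pytest.fixture
def toy_table():
    data = pd.DataFrame(
        {"S1": [5, 3, 0], "S2": [2, 2, 4]},
        index=["ASV1", "ASV2", "ASV3"],
    )
    return st.AbundanceTable(data, kingdom="bacteria", mode="counts")


@pytest.fixture
def toy_taxonomy():
    return st.Taxonomy(
        {
            "ASV1": ("Bacteria", "Pseudomonadota", "Alpha", "Rhizobiales",
                     "Xanthobacteraceae", "Bradyrhizobium"),
            "ASV2": ("Bacteria", "Pseudomonadota", "Alpha", "Rhizobiales",
                     "Xanthobacteraceae", "Bradyrhizobium"),
            "ASV3": ("Bacteria", "Pseudomonadota", "Alpha", "Rhizobiales",
                     "Xanthobacteraceae", ""),
        }
    )
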