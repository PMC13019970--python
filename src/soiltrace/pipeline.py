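"""End-to-end orchestration of the analysis stages on a study bundle.

This is the canonical stage order: prevalence-based decontamination against
blanks, blank removal, rarefaction to a common depth, genus-level
aggregation, soil-signature construction from the source aliquots, and
per-sample index series (SSI, HSP, optionally FaRMI). The helpers here are
thin glue over the stage modules so scripted analyses, the CLI and tests all
run the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import AbundanceTable, SampleMetadata, Taxonomy, aggregate_to_rank, to_relative
from .preprocess import flag_contaminants_prevalence, rarefy, remove_features
from .signatures import (
    DEFAULT_N_TAXA,
    FarmiModel,
    SourceSignature,
    build_source_signature,
    farmi_score,
    hsp_score,
    score_samples,
)
from .synthetic import StudyBundle


@dataclass
class PipelineResult:
    """Analysis-ready artifacts of one study run."""

    rarefied: AbundanceTable          # ASV level, blanks and contaminants removed
    genus_table: AbundanceTable       # genus-aggregated rarefied counts
    signature: SourceSignature
    ssi: pd.Series                    # fraction, dust + outdoor samples
    hsp: pd.Series                    # fraction
    metadata: SampleMetadata
    dust_ids: list[str]               # settled + floor dust samples that survived QC
    farmi: pd.Series | None = None


def analyze_bundle(
    bundle: StudyBundle,
    depth: int = 2000,
    rarefy_seed: int = 0,
    n_taxa: int | None = None,
    contaminant_threshold: float = 0.5,
    farmi_model: FarmiModel | None = None,
) -> PipelineResult:
    """Run the full pipeline on a (synthetic or loaded) study bundle."""
    table, metadata, taxonomy = bundle.table, bundle.metadata, bundle.taxonomy

    blanks = bundle.blank_ids
    if blanks:
        report = flag_contaminants_prevalence(table, blanks, threshold=contaminant_threshold)
        if report.flagged_ids:
            table = remove_features(table, report.flagged_ids)
        table = table.subset_samples([s for s in table.sample_ids if s not in set(blanks)])

    rarefied, _dropped = rarefy(table, depth=depth, seed=rarefy_seed)
    genus = aggregate_to_rank(rarefied, taxonomy, "genus")

    aliquots = [s for s in bundle.aliquot_ids if s in genus.sample_ids]
    n = n_taxa if n_taxa is not None else DEFAULT_N_TAXA[table.kingdom]
    signature = build_source_signature(genus.subset_samples(aliquots), n_taxa=n)

    non_source = [s for s in genus.sample_ids if s not in set(aliquots)]
    rel_genus = to_relative(genus.subset_samples(non_source))
    ssi = score_samples(rel_genus, signature)
    hsp = hsp_score(to_relative(rarefied.subset_samples(non_source)), taxonomy)
    farmi = farmi_score(rel_genus, farmi_model) if farmi_model is not None else None

    dust_ids = [s for s in bundle.dust_ids if s in genus.sample_ids]
    return PipelineResult(
        rarefied=rarefied,
        genus_table=genus,
        signature=signature,
        ssi=ssi,
        hsp=hsp,
        metadata=metadata,
        dust_ids=dust_ids,
        farmi=farmi,
    )


def synthetic_farmi_model(
    bundle: StudyBundle, n_predictors: int = 12, weight: float = 1.5
) -> FarmiModel:
    """A synthetic stand-in for the published FaRMI coefficient table.

    The published coefficients are external data and are not redistributed;
    this constructs a model of the same shape from the simulation's own
    pools: positive weights on the most abundant soil/outdoor genera,
    negative weights on the human-associated genera, zero intercept. Only for
    simulation-driven tests and demonstrations.
    """
    prof = bundle.profiles.profiles
    taxonomy = bundle.taxonomy
    coefs: dict[str, float] = {}

    def genus_of(fid: str) -> str:
        g = taxonomy.label(fid, "genus")
        if not g:
            _, deepest = taxonomy.deepest_assigned(fid)
            g = f"{deepest}_unclassified"
        return g

    for pool, sign in (("soil", +1.0), ("outdoor", +1.0), ("human", -1.0)):
        top = prof[pool].sort_values(ascending=False).head(n_predictors // 3 + 2)
        for fid in top.index:
            if top[fid] > 0:
                coefs.setdefault(genus_of(fid), sign * weight)
    return FarmiModel(intercept=0.0, coefficients=coefs)
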