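"""Source-tracking indices: the soil source index (SSI), the human source
proxy (HSP), and the farm-home resembling microbiota index (FaRMI).

SSI: the sum, in a dust sample, of the relative abundances of the N most
abundant taxa detected in *every* seeding-soil aliquot (N = 19 bacterial /
28 fungal taxa in the reference configuration). It measures the share of a
community attributable to the covered part of the source signal.

HSP: the summed relative abundance of five human-body-associated groups —
Staphylococcus and Streptococcus at genus rank; Propionibacteriaceae,
Corynebacteriaceae and Enterobacteriaceae at family rank — a proxy for
occupant-shed bacteria.

FaRMI: a logistic-GLM probability that a dust sample comes from a farm-like
home, evaluated from percentile-ranked relative abundances of predictor taxa
(45 in the published model). Coefficients are an external input (CSV); they
are not distributed with this package.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AbundanceTable, RANKS, Taxonomy, to_relative

#: Reference soil-signature sizes: top-N always-present taxa per kingdom.
DEFAULT_N_TAXA = {"bacteria": 19, "fungi": 28}

#: Default human-source proxy taxa as (rank, label) pairs.
HSP_TAXA: tuple[tuple[str, str], ...] = (
    ("genus", "Staphylococcus"),
    ("genus", "Streptococcus"),
    ("family", "Propionibacteriaceae"),
    ("family", "Corynebacteriaceae"),
    ("family", "Enterobacteriaceae"),
)


@dataclass
class SourceSignature:
    """Ordered taxon list defining a source index, with selection provenance.

    ``taxa`` are sorted by descending mean relative abundance across the
    source aliquots (ties broken lexicographically); every listed taxon was
    detected in all aliquots (prevalence 1.0).
    """

    kingdom: str
    taxa: list[str]
    n_requested: int
    selection_stats: pd.DataFrame = field(repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kingdom": self.kingdom,
            "n_requested": self.n_requested,
            "taxa": self.taxa,
            "selection_stats": {
                t: {
                    "mean_abundance": float(self.selection_stats.loc[t, "mean_abundance"]),
                    "prevalence": float(self.selection_stats.loc[t, "prevalence"]),
                }
                for t in self.taxa
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SourceSignature":
        payload = json.loads(Path(path).read_text())
        stats_df = pd.DataFrame.from_dict(payload["selection_stats"], orient="index")
        return cls(
            kingdom=payload["kingdom"],
            taxa=list(payload["taxa"]),
            n_requested=int(payload["n_requested"]),
            selection_stats=stats_df,
        )


def build_source_signature(aliquots: AbundanceTable, n_taxa: int) -> SourceSignature:
    """Build the soil signature from source-aliquot samples.

    Candidates are taxa with nonzero abundance in every aliquot; they are
    ranked by unweighted mean relative abundance across aliquots (descending,
    lexicographic tie-break) and the top ``n_taxa`` are kept. If fewer
    candidates exist than requested, all are returned with a warning.
    """
    if aliquots.n_samples < 2:
        raise ValueError("need at least 2 source aliquot samples")
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rel = aliquots if aliquots.mode == "relative" else to_relative(aliquots)
    present_everywhere = (rel.data > 0).all(axis=1)
    candidates = rel.data.loc[present_everywhere]
    means = candidates.mean(axis=1)
    order = means.to_frame("mean_abundance")
    order["prevalence"] = 1.0
    # descending mean abundance, lexicographic label tie-break
    order = order.iloc[
        np.lexsort((order.index.to_numpy(), -order["mean_abundance"].to_numpy()))
    ]
    taxa = list(order.index[:n_taxa])
    if len(taxa) < n_taxa:
        warnings.warn(
            f"only {len(taxa)} taxa are present in every aliquot "
            f"(requested {n_taxa}); returning all of them",
            stacklevel=2,
        )
    return SourceSignature(
        kingdom=aliquots.kingdom,
        taxa=taxa,
        n_requested=n_taxa,
        selection_stats=order,
    )


def signature_score(sample: pd.Series, signature: SourceSignature) -> float:
    """Sum of a sample's relative abundances over the signature taxa.

    ``sample`` is a relative-abundance vector indexed by taxon label; taxa
    absent from the sample contribute zero.
    """
    present = [t for t in signature.taxa if t in sample.index]
    return float(sample.loc[present].sum()) if present else 0.0


def score_samples(table: AbundanceTable, signature: SourceSignature) -> pd.Series:
    """SSI for every sample of a relative-abundance table (fractions in [0,1])."""
    if table.mode != "relative":
        raise ValueError("signature scoring expects a relative-mode table")
    present = [t for t in signature.taxa if t in table.data.index]
    if not present:
        series = pd.Series(0.0, index=table.sample_ids)
    else:
        series = table.data.loc[present].sum(axis=0)
    series.name = "SSI"
    return series


def source_coverage(
    signature: SourceSignature, aliquots: AbundanceTable
) -> tuple[pd.Series, tuple[float, float]]:
    """Signature score of each source aliquot, plus the (min, max) range.

    This is the fraction of source reads the signature captures (the
    "coverage" of the index).
    """
    rel = aliquots if aliquots.mode == "relative" else to_relative(aliquots)
    per_aliquot = score_samples(rel, signature)
    per_aliquot.name = "coverage"
    return per_aliquot, (float(per_aliquot.min()), float(per_aliquot.max()))


def hsp_score(
    table: AbundanceTable,
    taxonomy: Taxonomy,
    hsp_taxa: Sequence[tuple[str, str]] = HSP_TAXA,
) -> pd.Series:
    """Human source proxy: summed relative abundance of listed taxa.

    The list mixes ranks (genera and families); genus entries are summed at
    genus rank, family entries over the member features of that family. A
    feature already counted under a genus entry is never double-counted under
    a family entry.
    """
    if table.mode != "relative":
        raise ValueError("hsp_score expects a relative-mode table")
    for rank, _ in hsp_taxa:
        if rank not in RANKS:
            raise ValueError(f"unknown rank tag {rank!r}; expected one of {RANKS}")
    missing = [f for f in table.feature_ids if f not in taxonomy]
    if missing:
        raise KeyError(f"features missing from taxonomy: {missing}")

    counted: set[str] = set()
    total = pd.Series(0.0, index=table.sample_ids)
    # genus entries take precedence over family entries
    for rank, label in sorted(hsp_taxa, key=lambda e: RANKS.index(e[0]), reverse=True):
        members = [
            f for f in table.feature_ids
            if f not in counted and taxonomy.label(f, rank) == label
        ]
        if members:
            total = total + table.data.loc[members].sum(axis=0)
            counted.update(members)
    total.name = "HSP"
    return total


@dataclass
class FarmiModel:
    """Intercept + per-taxon coefficients of the FaRMI logistic score."""

    intercept: float
    coefficients: dict[str, float]

    def __post_init__(self) -> None:
        if len(set(self.coefficients)) != len(self.coefficients):
            raise ValueError("duplicate coefficient taxa")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FarmiModel":
        df = pd.read_csv(path, header=0, dtype={0: str})
        if df.shape[1] != 2:
            raise ValueError(f"{path}: expected 2 columns (term, coefficient)")
        terms = df.iloc[:, 0].tolist()
        values = df.iloc[:, 1].astype(float).tolist()
        if "(Intercept)" not in terms:
            raise ValueError(f"{path}: no '(Intercept)' row")
        intercept = values[terms.index("(Intercept)")]
        coefs = {t: v for t, v in zip(terms, values) if t != "(Intercept)"}
        return cls(intercept=intercept, coefficients=coefs)

    def to_csv(self, path: str | Path) -> None:
        rows = [("(Intercept)", self.intercept)] + sorted(self.coefficients.items())
        pd.DataFrame(rows, columns=["term", "coefficient"]).to_csv(path, index=False)


def farmi_score(table: AbundanceTable, model: FarmiModel) -> pd.Series:
    """FaRMI probability score for every sample in the table.

    For each predictor taxon, relative abundances are percentile-ranked
    across the input samples — r = (1-based average rank, ties averaged) / n,
    r in (0, 1] — then eta = intercept + sum coef*r and
    FaRMI = 1/(1+exp(-eta)). The ranking population is exactly the set of
    samples passed in one call, so score at the level you want samples
    ranked together. Predictor taxa absent from the table contribute
    abundance 0 for all samples.
    """
    if table.mode != "relative":
        raise ValueError("farmi_score expects a relative-mode table")
    n = table.n_samples
    if n < 2:
        raise ValueError(
            "FaRMI percentile ranking needs >= 2 samples; pass the full "
            "ranking population in one call"
        )
    eta = np.full(n, model.intercept, dtype=float)
    for taxon, coef in model.coefficients.items():
        if taxon in table.data.index:
            abund = table.data.loc[taxon].to_numpy()
        else:
            abund = np.zeros(n)
        ranks = stats.rankdata(abund, method="average") / n
        eta += coef * ranks
    probs = 1.0 / (1.0 + np.exp(-eta))
    series = pd.Series(probs, index=table.sample_ids, name="FaRMI")
    return series
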