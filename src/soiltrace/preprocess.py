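"""QC stages between the raw ASV table and analysis: prevalence-based
contaminant flagging against negative controls, rarefaction to a common read
depth, and the centered log-ratio (CLR) transform used for Aitchison
distances.

Contaminant flagging follows the prevalence logic of reagent-decontamination
tools: a feature detected more often in sequencing blanks than in real samples
is a contamination candidate. The score here is a one-sided Fisher exact
(hypergeometric) p-value for "more prevalent in controls", which is exact and
direction-explicit at small sample numbers; a feature is flagged when the
score falls below the probability threshold (default 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AbundanceTable, to_relative


@dataclass
class ContaminantReport:
    """Per-feature prevalence comparison between controls and real samples.

    ``table`` columns: prevalence_in_controls, prevalence_in_samples, score,
    flagged — indexed by feature ID. ``flagged`` holds iff score < threshold.
    """

    table: pd.DataFrame
    threshold: float

    @property
    def flagged_ids(self) -> list[str]:
        return list(self.table.index[self.table["flagged"]])


def flag_contaminants_prevalence(
    table: AbundanceTable,
    control_ids: Iterable[str],
    threshold: float = 0.5,
) -> ContaminantReport:
    """Flag features more prevalent in negative controls than in samples.

    For every feature a presence/absence 2x2 table (control vs experimental x
    detected vs not; detection = count > 0) is scored with a one-sided Fisher
    exact test under H1 "more prevalent in controls". Features with
    score < ``threshold`` are flagged.
    """
    if table.mode != "counts":
        raise ValueError("contaminant flagging expects a counts-mode table")
    controls = [str(c) for c in control_ids]
    unknown = set(controls) - set(table.sample_ids)
    if unknown:
        raise KeyError(f"control IDs absent from table: {sorted(unknown)}")
    if not controls:
        raise ValueError("empty control set")
    experimental = [s for s in table.sample_ids if s not in set(controls)]
    if not experimental:
        raise ValueError("no experimental (non-control) samples")

    detected = table.data > 0
    n_ctrl, n_exp = len(controls), len(experimental)
    det_ctrl = detected[controls].sum(axis=1).to_numpy()
    det_exp = detected[experimental].sum(axis=1).to_numpy()

    scores = np.empty(table.n_features)
    for i, (dc, de) in enumerate(zip(det_ctrl, det_exp)):
        # H1: detection more prevalent among controls
        _, scores[i] = stats.fisher_exact(
            [[dc, n_ctrl - dc], [de, n_exp - de]], alternative="greater"
        )
    report = pd.DataFrame(
        {
            "prevalence_in_controls": det_ctrl / n_ctrl,
            "prevalence_in_samples": det_exp / n_exp,
            "score": scores,
            "flagged": scores < threshold,
        },
        index=pd.Index(table.feature_ids),
    )
    return ContaminantReport(report, threshold=threshold)


def remove_features(table: AbundanceTable, feature_ids: Iterable[str]) -> AbundanceTable:
    """Drop the given features; samples left with zero total are dropped too
    (with a warning listing them)."""
    ids = {str(f) for f in feature_ids}
    unknown = ids - set(table.feature_ids)
    if unknown:
        raise KeyError(f"unknown feature IDs: {sorted(unknown)}")
    kept = table.data.drop(index=list(ids))
    sums = kept.sum(axis=0)
    emptied = sums.index[sums == 0].tolist()
    if emptied:
        warnings.warn(
            f"samples emptied by feature removal were dropped: {emptied}",
            stacklevel=2,
        )
        kept = kept.drop(columns=emptied)
    return AbundanceTable(kept, kingdom=table.kingdom, mode=table.mode)


def rarefy(
    table: AbundanceTable, depth: int, seed: int
) -> tuple[AbundanceTable, list[str]]:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped and returned in
    the second element. Sampling is multivariate hypergeometric and
    deterministic given ``seed``.
    """
    if table.mode != "counts":
        raise ValueError("rarefaction expects a counts-mode table")
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    arr = table.data.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("rarefaction requires integer counts")
    arr = np.round(arr).astype(np.int64)
    totals = arr.sum(axis=0)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    rng = np.random.default_rng(seed)
    out = np.zeros((table.n_features, int(keep.sum())), dtype=np.int64)
    j = 0
    for i, k in enumerate(keep):
        if not k:
            continue
        out[:, j] = rng.multivariate_hypergeometric(arr[:, i], depth)
        j += 1
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    data = pd.DataFrame(out, index=table.data.index, columns=kept_ids)
    return AbundanceTable(data, kingdom=table.kingdom, mode="counts"), dropped


def clr_transform(table: AbundanceTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform with a pseudocount for zeros.

    Per sample, x' = counts + pseudocount and clr_i = ln x'_i − mean_j ln x'_j,
    so every sample's CLR values sum to zero. Note the pseudocount breaks the
    scale invariance CLR has on strictly positive compositions: multiplying a
    sample's counts by a constant changes its CLR vector (slightly, for counts
    large relative to the pseudocount).
    """
    if table.mode != "counts":
        raise ValueError("clr_transform expects a counts-mode table")
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    logged = np.log(table.data.to_numpy() + pseudocount)
    clr = logged - logged.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=table.data.index, columns=table.data.columns)
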