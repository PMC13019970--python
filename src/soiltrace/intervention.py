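"""Longitudinal intervention statistics: pairing of pre/post samples around
seeding events, paired tests with a normality gate, cross-location rank
correlations, and unpaired group comparisons.

The design assumptions mirror a repeated soil-on-rug seeding study: samples
are collected on a biweekly grid, seeding events happen at fixed weeks, and a
sample whose 2-week exposure window ends exactly at a seeding week was
collected *before* the rug was (re)deployed — so it is the "pre" member of
the pair for that event. Two comparisons are supported: pre2w-post2w (pre
versus the sample 2 weeks later) and pre2w-post4w (pre versus 4 weeks later).
The 4-weeks-later sample of one event is simultaneously the pre sample of the
next event when events are 4 weeks apart; this overlap is part of the design
and is not corrected for.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .datamodel import SampleMetadata

COMPARISONS = ("pre2w_post2w", "pre2w_post4w")

#: Dust strata analyzed in the paired tables, as (sample_type, location, height).
DUST_STRATA = (
    ("settled_dust", "entrance", "IBZ"),
    ("settled_dust", "entrance", "ABZ"),
    ("settled_dust", "living_room", "IBZ"),
    ("settled_dust", "living_room", "ABZ"),
    ("floor_dust", "floor", "none"),
)


def stratum_label(sample_type: str, location: str, height: str) -> str:
    if sample_type == "floor_dust":
        return "LR_floor"
    loc = {"entrance": "entrance", "living_room": "LR", "outdoor": "outdoor"}[location]
    return f"{loc}_{height}" if height != "none" else loc


@dataclass
class SeedingDesign:
    """Seeding schedule and pairing lags of the intervention design."""

    seeding_weeks: list[int] = field(default_factory=lambda: [0, 4, 8])
    baseline_window: tuple[int, int] = (-8, 0)
    post_lags: dict[str, int] = field(
        default_factory=lambda: {"pre2w_post2w": 2, "pre2w_post4w": 4}
    )

    def __post_init__(self) -> None:
        weeks = list(self.seeding_weeks)
        if weeks != sorted(weeks) or len(set(weeks)) != len(weeks):
            raise ValueError("seeding weeks must be strictly increasing")
        if any(w % 2 for w in weeks):
            raise ValueError("seeding weeks must lie on the biweekly grid")
        self.seeding_weeks = weeks

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SeedingDesign":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "seeding_weeks" in raw:
            kwargs["seeding_weeks"] = [int(w) for w in raw["seeding_weeks"]]
        if "baseline_window" in raw:
            kwargs["baseline_window"] = tuple(int(w) for w in raw["baseline_window"])
        if "post_lags" in raw:
            kwargs["post_lags"] = {k: int(v) for k, v in raw["post_lags"].items()}
        return cls(**kwargs)


def make_pairs(
    metadata: SampleMetadata, design: SeedingDesign, comparison: str
) -> pd.DataFrame:
    """Enumerate (pre, post) sample pairs around each seeding event.

    For every intervention home x dust stratum x seeding week w the pre
    sample is the one at week w and the post sample the one at w+lag. Pairs
    with either member missing are dropped (and reported via a warning);
    control homes are excluded. The output is sorted deterministically and
    independent of metadata row order.
    """
    if comparison not in design.post_lags:
        raise ValueError(
            f"unknown comparison {comparison!r}; expected one of {sorted(design.post_lags)}"
        )
    lag = design.post_lags[comparison]
    df = metadata.frame
    interv = df[~df["is_control_home"]]
    if interv.empty or interv["home"].nunique() == 0:
        raise ValueError("no intervention homes in metadata")

    rows, skipped = [], []
    homes = sorted(interv["home"].astype(str).unique())
    for home in homes:
        sub = interv[interv["home"].astype(str) == home]
        for sample_type, location, height in DUST_STRATA:
            cell = sub[
                (sub["sample_type"] == sample_type)
                & (sub["location"] == location)
                & (sub["height"] == height)
            ]
            if cell.empty:
                continue
            by_week = cell.set_index("week")["sample_id"]
            for w in design.seeding_weeks:
                pre = by_week.get(w)
                post = by_week.get(w + lag)
                if pre is None or post is None:
                    skipped.append((home, stratum_label(sample_type, location, height), w))
                    continue
                rows.append(
                    {
                        "pre_id": pre,
                        "post_id": post,
                        "home": home,
                        "sample_type": sample_type,
                        "location": location,
                        "height": height,
                        "stratum": stratum_label(sample_type, location, height),
                        "event_week": w,
                        "comparison": comparison,
                    }
                )
    if skipped:
        warnings.warn(f"pairs dropped for missing samples: {skipped}", stacklevel=2)
    pairs = pd.DataFrame(
        rows,
        columns=[
            "pre_id", "post_id", "home", "sample_type", "location",
            "height", "stratum", "event_week", "comparison",
        ],
    )
    return pairs.sort_values(["home", "stratum", "event_week"]).reset_index(drop=True)


@dataclass
class PairedResult:
    """One paired pre/post test: positive ``mean_diff`` means the metric
    increased after seeding."""

    metric: str
    stratum: str
    comparison: str
    n_pairs: int
    mean_diff: float
    test_used: str  # 't' or 'wilcoxon'
    p: float


def paired_compare(
    values: pd.Series,
    pairs: pd.DataFrame,
    normality_alpha: float = 0.05,
    metric: str = "metric",
    stratum: str = "all",
) -> PairedResult:
    """Two-sided paired test on post - pre differences with a normality gate.

    Differences are tested for normality with Shapiro-Wilk at
    ``normality_alpha``; normal-looking differences get Student's paired t,
    otherwise a Wilcoxon signed-rank test (zeros dropped, exact distribution
    at small n). All-zero differences degenerate to mean_diff 0, p = 1.
    """
    have = pairs[
        pairs["pre_id"].isin(values.index) & pairs["post_id"].isin(values.index)
    ]
    if len(have) < 2:
        raise ValueError("need at least 2 pairs with both values present")
    d = (
        values.loc[have["post_id"]].to_numpy(dtype=float)
        - values.loc[have["pre_id"]].to_numpy(dtype=float)
    )
    comparison = have["comparison"].iloc[0] if "comparison" in have else "?"
    mean_diff = float(d.mean())
    if np.all(d == 0):
        return PairedResult(metric, stratum, comparison, len(d), 0.0, "wilcoxon", 1.0)

    normal = False
    if len(np.unique(d)) > 1:
        try:
            _, shapiro_p = stats.shapiro(d)
            normal = shapiro_p > normality_alpha
        except ValueError:
            normal = False
    if normal:
        t_res = stats.ttest_1samp(d, 0.0)
        return PairedResult(
            metric, stratum, comparison, len(d), mean_diff, "t", float(t_res.pvalue)
        )
    nz = d[d != 0]
    method = "exact" if len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz) else "approx"
    w_res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return PairedResult(
        metric, stratum, comparison, len(d), mean_diff, "wilcoxon", float(w_res.pvalue)
    )


def intervention_table(
    metrics: Mapping[str, pd.Series],
    metadata: SampleMetadata,
    design: SeedingDesign,
    comparisons: Sequence[str] = COMPARISONS,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired pre/post tests for every metric x dust stratum x comparison —
    the study-style summary table. Control homes are excluded from testing
    (analyze them separately, descriptively)."""
    rows = []
    for comparison in comparisons:
        pairs = make_pairs(metadata, design, comparison)
        for (stype, loc, height) in DUST_STRATA:
            cell = pairs[
                (pairs["sample_type"] == stype)
                & (pairs["location"] == loc)
                & (pairs["height"] == height)
            ]
            if cell.empty:
                continue
            label = stratum_label(stype, loc, height)
            for metric, values in metrics.items():
                try:
                    res = paired_compare(
                        values, cell, normality_alpha, metric=metric, stratum=label
                    )
                except ValueError:
                    continue
                rows.append(
                    {
                        "metric": res.metric,
                        "stratum": res.stratum,
                        "comparison": comparison,
                        "n_pairs": res.n_pairs,
                        "mean_diff": res.mean_diff,
                        "test_used": res.test_used,
                        "p": res.p,
                    }
                )
    return pd.DataFrame(rows)


def spearman(x: pd.Series | Sequence, y: pd.Series | Sequence) -> tuple[float, float]:
    """Spearman rank correlation with an exact permutation p at small n.

    Incomplete pairs (NaN in either series) are dropped; n >= 3 required.
    For n <= 9 the two-sided p-value is computed by full enumeration of rank
    pairings; larger n uses the t-approximation.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        joined = pd.concat([x, y], axis=1, join="inner").dropna()
        xv, yv = joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        keep = ~(np.isnan(xv) | np.isnan(yv))
        xv, yv = xv[keep], yv[keep]
    n = len(xv)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise ValueError("constant input: Spearman rho undefined")
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        obs = abs(np.dot(rx_c, ry_c))
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            stat = abs(np.dot(rx_c, ry_c[list(perm)]))
            if stat >= obs - 1e-12:
                hits += 1
            total += 1
        return rho, hits / total
    t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho ** 2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(1.0, p))


def cross_location_correlations(
    metrics: Mapping[str, pd.Series],
    metadata: SampleMetadata,
    anchor: tuple[str, str] = ("entrance", "IBZ"),
) -> pd.DataFrame:
    """Spearman correlations between the anchor stratum (default entrance
    IBZ, closest to the rug) and every other dust stratum, per metric.

    Samples are matched on home x week; output is tidy:
    (metric, stratum, rho, p, n).
    """
    df = metadata.frame
    anchor_rows = df[
        (df["sample_type"] == "settled_dust")
        & (df["location"] == anchor[0])
        & (df["height"] == anchor[1])
    ]
    if anchor_rows.empty:
        raise ValueError(f"no samples in anchor stratum {anchor}")
    anchor_key = anchor_rows.set_index(["home", "week"])["sample_id"]

    rows = []
    any_overlap = False
    for stype, loc, height in DUST_STRATA:
        other = df[
            (df["sample_type"] == stype)
            & (df["location"] == loc)
            & (df["height"] == height)
        ]
        if other.empty:
            continue
        other_key = other.set_index(["home", "week"])["sample_id"]
        common = anchor_key.index.intersection(other_key.index)
        label = stratum_label(stype, loc, height)
        for metric, values in metrics.items():
            a_ids = anchor_key.loc[common]
            o_ids = other_key.loc[common]
            ok = a_ids.isin(values.index) & o_ids.isin(values.index)
            a_vals = values.loc[a_ids[ok]].to_numpy(float)
            o_vals = values.loc[o_ids[ok]].to_numpy(float)
            n = len(a_vals)
            if n < 3:
                continue
            any_overlap = True
            try:
                rho, p = spearman(a_vals, o_vals)
            except ValueError:
                continue
            rows.append({"metric": metric, "stratum": label, "rho": rho, "p": p, "n": n})
    if not any_overlap:
        raise ValueError("no home x week overlap between anchor and other strata")
    return pd.DataFrame(rows)


@dataclass
class GroupResult:
    test_used: str  # 'ranksum' or 'kruskal'
    statistic: float
    p: float


def group_compare(values: pd.Series | Sequence, groups: Sequence) -> GroupResult:
    """Unpaired comparison of a metric across groups.

    Two groups: two-sided rank-sum (Mann-Whitney). More: Kruskal-Wallis with
    tie correction. Every group must be non-empty.
    """
    vals = np.asarray(values, dtype=float)
    labels = np.asarray(list(groups))
    if len(vals) != len(labels):
        raise ValueError("values and groups must have equal length")
    uniq = pd.unique(labels)
    samples = [vals[labels == g] for g in uniq]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if len(samples) == 2:
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return GroupResult("ranksum", float(res.statistic), float(res.pvalue))
    res = stats.kruskal(*samples)
    return GroupResult("kruskal", float(res.statistic), float(res.pvalue))


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; the default reporting is raw p)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(list(pvalues), method="fdr_bh")[1]
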