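"""Core containers and plain-text I/O for amplicon feature tables, taxonomy
and longitudinal study metadata.

The pipeline works on one kingdom at a time: bacterial (16S) and fungal (ITS)
tables are carried as separate :class:`AbundanceTable` objects and never mixed
in a single matrix. Feature tables are stored features-as-rows,
samples-as-columns, the dominant amplicon-table dialect, with the header cell
``#FeatureID``. Sample weeks live on a biweekly grid; a settled-dust sample's
week is the *end* of its two-week exposure window (the sample whose window
ends at a seeding week was collected before the rug was deployed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

KINGDOMS = ("bacteria", "fungi")
MODES = ("counts", "relative")
SAMPLE_TYPES = ("settled_dust", "floor_dust", "source_aliquot", "outdoor", "control_blank")
LOCATIONS = ("entrance", "living_room", "outdoor", "floor", "source", "none")
HEIGHTS = ("IBZ", "ABZ", "none")

#: Taxonomic ranks carried by :class:`Taxonomy`, shallowest first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")
RANK_PREFIXES = dict(zip(RANKS, ("d__", "p__", "c__", "o__", "f__", "g__")))

FEATURE_HEADER = "#FeatureID"
METADATA_COLUMNS = (
    "sample_id", "home", "sample_type", "location", "height",
    "week", "is_control_home", "kingdom",
)

_REL_TOL = 1e-9


class ParseError(ValueError):
    """Raised when an on-disk table violates the format contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = sorted(seen[seen.duplicated()].unique())
        raise ParseError(f"duplicate {what}: {dupes}")


@dataclass
class AbundanceTable:
    """A feature x sample abundance matrix for one kingdom.

    Parameters
    ----------
    data
        DataFrame with feature IDs as index and sample IDs as columns.
        Values are non-negative counts (``mode='counts'``) or per-sample
        fractions summing to one (``mode='relative'``).
    kingdom
        ``'bacteria'`` or ``'fungi'``.
    mode
        ``'counts'`` or ``'relative'``.
    """

    data: pd.DataFrame
    kingdom: str
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise ValueError(f"kingdom must be one of {KINGDOMS}, got {self.kingdom!r}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        _check_unique(self.data.index, "feature IDs")
        _check_unique(self.data.columns, "sample IDs")
        values = self.data.to_numpy()
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"NaN value at feature {self.data.index[r]!r}, sample {self.data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value {values[r, c]} at feature {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if self.mode == "relative" and self.data.shape[1]:
            sums = values.sum(axis=0)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
            if bad.size:
                raise ValueError(
                    f"relative-mode columns must sum to 1; sample "
                    f"{self.data.columns[bad[0]]!r} sums to {sums[bad[0]]:.6g}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        """One sample's abundance vector indexed by feature ID."""
        return self.data[sample_id]

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        ids = [str(s) for s in sample_ids]
        missing = set(ids) - set(self.data.columns)
        if missing:
            raise KeyError(f"unknown sample IDs: {sorted(missing)}")
        return replace(self, data=self.data[ids])

    def subset_features(self, feature_ids: Iterable[str]) -> "AbundanceTable":
        ids = [str(f) for f in feature_ids]
        missing = set(ids) - set(self.data.index)
        if missing:
            raise KeyError(f"unknown feature IDs: {sorted(missing)}")
        return replace(self, data=self.data.loc[ids])


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert a counts table to per-sample relative abundances.

    Each sample column is divided by its total. Rejects tables already in
    relative mode and tables containing an all-zero sample.
    """
    if table.mode != "counts":
        raise ValueError("to_relative expects a counts-mode table")
    sums = table.data.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample(s) cannot be normalized: {zero}")
    return AbundanceTable(table.data / sums, kingdom=table.kingdom, mode="relative")


def load_abundance_table(path: str | Path, kingdom: str) -> AbundanceTable:
    """Read a feature table TSV (features as rows, ``#FeatureID`` header cell).

    Returns a counts-mode table; duplicate feature/sample IDs, NaNs and
    negative values are rejected with an error naming the offender.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.columns[0] != FEATURE_HEADER:
        raise ParseError(
            f"{path}: first header cell must be {FEATURE_HEADER!r}, got {df.columns[0]!r}"
        )
    df = df.set_index(df.columns[0])
    df.index.name = None
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric abundance value ({exc})") from exc
    try:
        return AbundanceTable(df, kingdom=kingdom, mode="counts")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write a feature table TSV readable by :func:`load_abundance_table`."""
    df = table.data.copy()
    if table.mode == "counts":
        arr = df.to_numpy()
        if np.allclose(arr, np.round(arr)):
            df = df.astype(np.int64)
    df.index.name = FEATURE_HEADER
    df.to_csv(path, sep="\t")


@dataclass
class Taxonomy:
    """Feature ID -> ordered rank labels (domain..genus).

    Missing ranks are empty strings; every mapped feature must have at least
    one assigned rank.
    """

    assignments: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for fid, labels in self.assignments.items():
            labels = tuple(labels) + ("",) * (len(RANKS) - len(labels))
            if len(labels) != len(RANKS):
                raise ValueError(f"{fid}: expected <= {len(RANKS)} rank labels")
            if not any(labels):
                raise ValueError(f"{fid}: no assigned rank at any level")
            clean[str(fid)] = labels
        self.assignments = clean

    def label(self, feature_id: str, rank: str) -> str:
        """Label of ``feature_id`` at ``rank`` ('' when unassigned)."""
        return self.assignments[feature_id][RANKS.index(rank)]

    def deepest_assigned(self, feature_id: str) -> tuple[str, str]:
        """(rank, label) of the deepest assigned rank for a feature."""
        labels = self.assignments[feature_id]
        for i in range(len(RANKS) - 1, -1, -1):
            if labels[i]:
                return RANKS[i], labels[i]
        raise ValueError(f"{feature_id}: no assigned rank")  # unreachable post-init

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.assignments


def load_taxonomy(path: str | Path) -> Taxonomy:
    """Read the 2-column taxonomy TSV (feature_id, 'd__X;p__Y;...')."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str).fillna("")
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, got {df.shape[1]}")
    assignments: dict[str, tuple[str, ...]] = {}
    for fid, lineage in zip(df.iloc[:, 0], df.iloc[:, 1]):
        parts = [p.strip() for p in lineage.split(";")]
        labels = []
        for rank, part in zip(RANKS, parts):
            prefix = RANK_PREFIXES[rank]
            if part and not part.startswith(prefix):
                raise ParseError(f"{path}: {fid}: expected prefix {prefix!r} in {part!r}")
            labels.append(part[len(prefix):] if part else "")
        assignments[fid] = tuple(labels)
    return Taxonomy(assignments)


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    rows = []
    for fid, labels in taxonomy.assignments.items():
        lineage = ";".join(RANK_PREFIXES[r] + lab for r, lab in zip(RANKS, labels))
        rows.append((fid, lineage))
    pd.DataFrame(rows, columns=["feature_id", "taxonomy"]).to_csv(path, sep="\t", index=False)


def aggregate_to_rank(table: AbundanceTable, taxonomy: Taxonomy, rank: str) -> AbundanceTable:
    """Sum features sharing the same label at ``rank``.

    Features unassigned at ``rank`` are kept under
    ``"<deepest assigned label>_unclassified"`` (e.g. an ASV with no genus but
    family Xanthobacteraceae becomes ``Xanthobacteraceae_unclassified``).
    Per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    missing = [f for f in table.feature_ids if f not in taxonomy]
    if missing:
        raise KeyError(f"features missing from taxonomy: {missing}")
    labels = []
    for fid in table.feature_ids:
        lab = taxonomy.label(fid, rank)
        if not lab:
            _, deepest = taxonomy.deepest_assigned(fid)
            lab = f"{deepest}_unclassified"
        labels.append(lab)
    grouped = table.data.groupby(pd.Index(labels, name=None), sort=True).sum()
    grouped.index.name = None
    return AbundanceTable(grouped, kingdom=table.kingdom, mode=table.mode)


@dataclass
class SampleMetadata:
    """Per-sample study-design attributes, backed by a validated DataFrame.

    Columns: sample_id, home, sample_type, location, height, week,
    is_control_home, kingdom. Weeks must be even integers (the biweekly grid).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        df = df[list(METADATA_COLUMNS)]
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"], "sample IDs")
        for col, allowed in (
            ("sample_type", SAMPLE_TYPES), ("location", LOCATIONS),
            ("height", HEIGHTS), ("kingdom", KINGDOMS),
        ):
            bad = sorted(set(df[col]) - set(allowed))
            if bad:
                raise ValueError(f"metadata column {col!r}: invalid values {bad}")
        weeks = df["week"].astype(int)
        if (weeks % 2 != 0).any():
            bad_ids = df.loc[weeks % 2 != 0, "sample_id"].tolist()
            raise ValueError(f"weeks must lie on the biweekly grid; offenders: {bad_ids}")
        df["week"] = weeks
        df["is_control_home"] = df["is_control_home"].astype(bool)
        settled = df[df["sample_type"] == "settled_dust"]
        bad_loc = settled[~settled["location"].isin(["entrance", "living_room", "outdoor"])]
        if len(bad_loc):
            raise ValueError(
                f"settled_dust samples must be at entrance/living_room/outdoor: "
                f"{bad_loc['sample_id'].tolist()}"
            )
        indoor = settled[settled["location"].isin(["entrance", "living_room"])]
        bad_h = indoor[~indoor["height"].isin(["IBZ", "ABZ"])]
        if len(bad_h):
            raise ValueError(
                f"indoor settled_dust samples need height IBZ/ABZ: {bad_h['sample_id'].tolist()}"
            )
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def select(self, **criteria) -> "SampleMetadata":
        """Rows matching every keyword (column=value or column=list-of-values)."""
        df = self.frame
        for col, val in criteria.items():
            if col not in df.columns:
                raise KeyError(f"unknown metadata column {col!r}")
            if isinstance(val, (list, tuple, set, frozenset)):
                df = df[df[col].isin(list(val))]
            else:
                df = df[df[col] == val]
        return SampleMetadata(df)

    def lookup(self, sample_id: str) -> pd.Series:
        rows = self.frame[self.frame["sample_id"] == sample_id]
        if rows.empty:
            raise KeyError(f"unknown sample ID {sample_id!r}")
        return rows.iloc[0]

    def __len__(self) -> int:
        return len(self.frame)


def load_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", header=0)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.frame.to_csv(path, sep="\t", index=False)


def load_distance_matrix(path: str | Path):
    """Read a square distance-matrix TSV into a scikit-bio DistanceMatrix."""
    from skbio.stats.distance import DistanceMatrix

    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: header and index sample IDs disagree")
    return DistanceMatrix(df.to_numpy(), ids=list(df.index))


def write_distance_matrix(dm, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(path, sep="\t")
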