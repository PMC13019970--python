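"""Community-level analysis: Bray-Curtis and Aitchison distances, alpha
diversity (Chao1, Shannon), principal coordinates analysis, convergence of
dust communities toward a per-home source baseline, and permutational
multivariate ANOVA (one-way and marginal).

PERMANOVA here partitions the sums of squares of a Gower-centered distance
matrix and assesses the pseudo-F by free permutation of sample labels. The
permutation p-value includes the identity permutation in both numerator and
denominator, so p >= 1/(n_perm+1) and is never zero; when the number of
distinct label arrangements is no larger than the requested permutation
count, the null distribution is enumerated exhaustively instead.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .datamodel import AbundanceTable, SampleMetadata, to_relative
from .preprocess import clr_transform

__all__ = [
    "bray_curtis", "aitchison_distance", "distance_matrix",
    "source_baseline", "beta_to_baseline", "chao1", "shannon",
    "alpha_diversity", "pcoa", "PCoAResult",
    "permanova", "permanova_marginal", "PermanovaResult",
]


# --------------------------------------------------------------------------
# distances


def bray_curtis(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> float:
    """Bray-Curtis dissimilarity, 1 - 2*sum(min(x,y)) / (sum x + sum y).

    Ranges from 0 (identical communities) to 1 (no shared taxa). Both inputs
    must be non-negative and on the same feature axis.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero; Bray-Curtis undefined")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def aitchison_distance(clr_x: np.ndarray | pd.Series, clr_y: np.ndarray | pd.Series) -> float:
    """Euclidean distance between two CLR-transformed composition vectors."""
    clr_x = np.asarray(clr_x, dtype=float)
    clr_y = np.asarray(clr_y, dtype=float)
    if clr_x.shape != clr_y.shape:
        raise ValueError(f"length mismatch: {clr_x.shape} vs {clr_y.shape}")
    return float(np.linalg.norm(clr_x - clr_y))


def distance_matrix(
    table: AbundanceTable, metric: str, pseudocount: float = 1.0
) -> DistanceMatrix:
    """All-pairs sample distances for a feature table.

    ``metric='bray_curtis'`` applies Bray-Curtis to the stored columns (use
    rarefied counts or relative abundances; no pseudocount is involved).
    ``metric='aitchison'`` CLR-transforms counts internally with the given
    pseudocount and takes Euclidean distances.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    if metric == "bray_curtis":
        X = table.data.to_numpy(dtype=float).T
        sums = X.sum(axis=1)
        if (sums == 0).any():
            bad = [s for s, z in zip(table.sample_ids, sums == 0) if z]
            raise ValueError(f"all-zero sample(s): {bad}")
        mins = np.minimum(X[:, None, :], X[None, :, :]).sum(axis=2)
        mat = 1.0 - 2.0 * mins / (sums[:, None] + sums[None, :])
    elif metric == "aitchison":
        clr = clr_transform(table, pseudocount=pseudocount).to_numpy().T
        diff = clr[:, None, :] - clr[None, :, :]
        mat = np.sqrt((diff ** 2).sum(axis=2))
    else:
        raise ValueError(f"unknown metric {metric!r}; use 'bray_curtis' or 'aitchison'")
    np.fill_diagonal(mat, 0.0)
    mat = (mat + mat.T) / 2.0  # enforce exact symmetry against fp noise
    return DistanceMatrix(mat, ids=table.sample_ids)


# --------------------------------------------------------------------------
# source baseline and convergence


def source_baseline(
    aliquots: AbundanceTable,
    metadata: SampleMetadata,
    homes: Sequence[str] | None = None,
) -> dict[str, pd.Series]:
    """Per-home averaged source profile (mean of the home's aliquots,
    renormalized to sum 1).

    ``homes`` defaults to every home owning at least one aliquot; passing an
    explicit list raises if any requested home has no aliquots.
    """
    rel = aliquots if aliquots.mode == "relative" else to_relative(aliquots)
    by_home: dict[str, list[str]] = {}
    for sid in rel.sample_ids:
        row = metadata.lookup(sid)
        by_home.setdefault(str(row["home"]), []).append(sid)
    if homes is None:
        homes = sorted(by_home)
    missing = [h for h in homes if h not in by_home]
    if missing:
        raise ValueError(f"homes with no source aliquots: {missing}")
    baseline: dict[str, pd.Series] = {}
    for home in homes:
        mean = rel.data[by_home[home]].mean(axis=1)
        baseline[home] = mean / mean.sum()
    return baseline


def beta_to_baseline(
    dust: AbundanceTable,
    metadata: SampleMetadata,
    baseline: Mapping[str, pd.Series],
) -> pd.Series:
    """Bray-Curtis distance of every dust sample to its own home's averaged
    source profile. Lower values = community closer to the source."""
    rel = dust if dust.mode == "relative" else to_relative(dust)
    out = {}
    for sid in rel.sample_ids:
        home = str(metadata.lookup(sid)["home"])
        if home not in baseline:
            raise KeyError(f"sample {sid!r}: home {home!r} has no source baseline")
    for sid in rel.sample_ids:
        home = str(metadata.lookup(sid)["home"])
        ref = baseline[home]
        features = rel.data.index.union(ref.index)
        x = rel.data[sid].reindex(features, fill_value=0.0)
        y = ref.reindex(features, fill_value=0.0)
        out[sid] = bray_curtis(x, y)
    series = pd.Series(out, name="beta_to_source")
    return series


# --------------------------------------------------------------------------
# alpha diversity


def chao1(counts: np.ndarray | pd.Series) -> float:
    """Chao1 richness estimate from integer counts.

    S_obs + F1^2/(2 F2) when doubletons exist; the bias-corrected fallback
    S_obs + F1(F1-1)/2 when F2 = 0 (the classic form is undefined there).
    """
    arr = np.asarray(counts, dtype=float)
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("Chao1 requires integer counts")
    arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def shannon(x: np.ndarray | pd.Series) -> float:
    """Shannon diversity, -sum p ln p over nonzero proportions (natural log)."""
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValueError("abundances must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero vector; Shannon undefined")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Chao1 and Shannon for every sample of a counts table."""
    if table.mode != "counts":
        raise ValueError("alpha diversity is computed on (rarefied) counts")
    rows = {
        sid: {"chao1": chao1(table.data[sid]), "shannon": shannon(table.data[sid])}
        for sid in table.sample_ids
    }
    return pd.DataFrame.from_dict(rows, orient="index")


# --------------------------------------------------------------------------
# ordination


def _gower_center(dm: DistanceMatrix) -> np.ndarray:
    a = -0.5 * dm.data.astype(float) ** 2
    n = a.shape[0]
    c = np.eye(n) - np.ones((n, n)) / n
    return c @ a @ c


@dataclass
class PCoAResult:
    """Principal-coordinates embedding: per-sample coordinates (columns
    PCo1..PCok, scaled by sqrt eigenvalue) plus the full eigenvalue spectrum
    (negatives included, their axes dropped)."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return pos / pos.sum()


def pcoa(dm: DistanceMatrix, k: int = 2) -> PCoAResult:
    """Classical PCoA (Gower double-centering + eigendecomposition).

    Eigenvalues are returned in descending order; axes with non-positive
    eigenvalues are dropped. Axis signs follow the convention that the
    largest-magnitude loading on each axis is positive. Requesting more axes
    than there are positive eigenvalues truncates with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    g = _gower_center(dm)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals[0])) if len(eigvals) else 0.0
    n_pos = int((eigvals > tol).sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        k = n_pos
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    for j in range(k):
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] *= -1
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PCo{i + 1}" for i in range(k)]
    )
    return PCoAResult(coordinates=frame, eigenvalues=eigvals)


# --------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    term: str
    pseudo_f: float
    r2: float
    p: float
    n_permutations: int
    exhaustive: bool = False


def _ss_total(d2: np.ndarray) -> float:
    n = d2.shape[0]
    return float(d2[np.triu_indices(n, 1)].sum() / n)


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        ix = np.flatnonzero(codes == g)
        if len(ix) > 1:
            sub = d2[np.ix_(ix, ix)]
            ss += sub[np.triu_indices(len(ix), 1)].sum() / len(ix)
    return ss


def _multiset_permutations(codes: np.ndarray):
    """Distinct arrangements of a label multiset (lexicographic)."""
    counts = np.bincount(codes)
    n = len(codes)

    def rec(remaining: np.ndarray, prefix: list[int]):
        if len(prefix) == n:
            yield np.array(prefix, dtype=np.int64)
            return
        for g in np.flatnonzero(remaining):
            remaining[g] -= 1
            prefix.append(g)
            yield from rec(remaining, prefix)
            prefix.pop()
            remaining[g] += 1

    yield from rec(counts.copy(), [])


def permanova(
    dm: DistanceMatrix,
    grouping: Sequence | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    term: str = "grouping",
) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against a single factor.

    pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)) from the sums of
    squares of the squared-distance partition. p is estimated by freely
    permuting labels: (1 + #{F_perm >= F_obs}) / (1 + n_perm), or by
    exhaustive enumeration over all distinct label arrangements when there
    are no more of them than ``n_perm``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(grouping, pd.Series):
        grouping = grouping.reindex(list(dm.ids))
        if grouping.isna().any():
            missing = list(grouping.index[grouping.isna()])
            raise ValueError(f"grouping missing for samples: {missing}")
        labels = grouping.to_numpy()
    else:
        labels = np.asarray(list(grouping))
        if len(labels) != len(dm.ids):
            raise ValueError("grouping length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    n = len(codes)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")

    d2 = dm.data.astype(float) ** 2
    ss_t = _ss_total(d2)
    ss_w = _ss_within(d2, codes, a)
    ss_a = ss_t - ss_w
    # ss_w = 0 (perfect separation) legitimately yields an infinite pseudo-F
    with np.errstate(divide="ignore"):
        f_obs = (ss_a / (a - 1)) / (ss_w / (n - a))
    r2 = ss_a / ss_t

    counts = np.bincount(codes)
    n_distinct = math.factorial(n)
    for c in counts:
        n_distinct //= math.factorial(int(c))

    if n_distinct <= n_perm:
        hits = 0
        for perm in _multiset_permutations(codes):
            ss_w_p = _ss_within(d2, perm, a)
            with np.errstate(divide="ignore"):
                f_p = ((ss_t - ss_w_p) / (a - 1)) / (ss_w_p / (n - a))
            if f_p >= f_obs - 1e-12:
                hits += 1
        p = hits / n_distinct
        return PermanovaResult(term, f_obs, r2, p, n_distinct, exhaustive=True)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        ss_w_p = _ss_within(d2, perm, a)
        f_p = ((ss_t - ss_w_p) / (a - 1)) / (ss_w_p / (n - a))
        if f_p >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(term, f_obs, r2, p, n_perm, exhaustive=False)


def _model_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Encode covariates (treatment-coded factors, numerics as-is) plus an
    intercept. Returns the matrix and per-term column indices."""
    n = len(covariates)
    columns = [np.ones(n)]
    term_cols: dict[str, list[int]] = {}
    col_ix = 1
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            columns.append(col.to_numpy(dtype=float))
            term_cols[name] = [col_ix]
            col_ix += 1
        else:
            levels = pd.unique(col.astype(str))
            ixs = []
            for level in sorted(levels)[1:]:  # drop first level (reference)
                columns.append((col.astype(str) == level).to_numpy(dtype=float))
                ixs.append(col_ix)
                col_ix += 1
            term_cols[name] = ixs
    return np.column_stack(columns), term_cols


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def permanova_marginal(
    dm: DistanceMatrix,
    covariates: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> list[PermanovaResult]:
    """Marginal (type-III-style) PERMANOVA: each term's partial sum of
    squares given all other terms, tested against the full-model residual.

    SS_term = SS(full model) - SS(model without the term); pseudo-F uses the
    full-model residual mean square. p-values come from free permutation of
    sample identities, shared across terms. Collinear (aliased) terms are
    rejected with an error naming them.
    """
    ids = list(dm.ids)
    if list(covariates.index) != ids:
        covariates = covariates.reindex(ids)
        if covariates.isna().any().any():
            raise ValueError("covariates missing for some samples in the distance matrix")
    x_full, term_cols = _model_matrix(covariates)
    n, p_full = x_full.shape
    rank = np.linalg.matrix_rank(x_full)
    if rank < p_full:
        aliased = []
        for term, cols in term_cols.items():
            others = [c for c in range(p_full) if c not in cols]
            if np.linalg.matrix_rank(x_full[:, others]) == rank:
                aliased.append(term)
        raise ValueError(f"model matrix is rank deficient; aliased terms: {aliased}")

    g = _gower_center(dm)
    ss_total = float(np.trace(g))
    h_full = _hat(x_full)
    df_resid = n - p_full

    reduced_hats = {}
    for term, cols in term_cols.items():
        keep = [c for c in range(p_full) if c not in cols]
        reduced_hats[term] = _hat(x_full[:, keep])

    def term_stats(gmat: np.ndarray) -> dict[str, float]:
        ss_full = float(np.sum(h_full * gmat))  # tr(H G), H symmetric
        ss_resid = ss_total_g - ss_full
        out = {}
        for term, cols in term_cols.items():
            ss_red = float(np.sum(reduced_hats[term] * gmat))
            ss_term = ss_full - ss_red
            df_term = len(cols)
            out[term] = (ss_term / df_term) / (ss_resid / df_resid)
        return out

    ss_total_g = ss_total
    f_obs = term_stats(g)
    ss_full_obs = float(np.sum(h_full * g))
    ss_resid_obs = ss_total - ss_full_obs

    rng = np.random.default_rng(seed)
    hits = {t: 0 for t in term_cols}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        f_p = term_stats(gp)
        for t in term_cols:
            if f_p[t] >= f_obs[t] - 1e-12:
                hits[t] += 1

    results = []
    for term, cols in term_cols.items():
        ss_red = float(np.sum(reduced_hats[term] * g))
        ss_term = ss_full_obs - ss_red
        results.append(
            PermanovaResult(
                term=term,
                pseudo_f=f_obs[term],
                r2=ss_term / ss_total,
                p=(1 + hits[term]) / (1 + n_perm),
                n_permutations=n_perm,
            )
        )
    return results
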