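"""Similarity between paired biopsies.

Whole-profile correlations per pair, per-gene correlations across pairs, and
adjacency of pair members in an average-linkage dendrogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_model import ExpressionMatrix, SampleSheet
from .errors import InsufficientDataError, ValidationError


@dataclass
class PairCorrelation:
    tumour_id: str
    r_pearson: float
    r_spearman: float
    n_probes: int


@dataclass
class GenePairCorrelation:
    probe_id: str
    r: float
    p: float
    n_pairs: int
    dynamic_range_log2: float


@dataclass
class ClusterConcordance:
    n_pairs_total: int
    n_pairs_adjacent: int

    @property
    def fraction(self) -> float:
        if self.n_pairs_total == 0:
            return float("nan")
        return self.n_pairs_adjacent / self.n_pairs_total


@dataclass
class Dendrogram:
    """Agglomeration tree over samples (scipy linkage matrix + leaf labels)."""

    linkage: np.ndarray
    sample_ids: list[str]

    def sibling_leaf_pairs(self) -> set[frozenset[str]]:
        """Unordered sample pairs whose first merge joins exactly those leaves."""
        n = len(self.sample_ids)
        out = set()
        for a, b, _, _ in self.linkage:
            if a < n and b < n:
                out.add(frozenset((self.sample_ids[int(a)], self.sample_ids[int(b)])))
        return out

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)
        labels = self.sample_ids

        def rec(node, parent_dist):
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{labels[node.id]}:{length:g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def _pair_values(matrix: ExpressionMatrix, s1: str, s2: str) -> tuple[np.ndarray, np.ndarray]:
    x = matrix.values[s1].to_numpy(dtype=float)
    y = matrix.values[s2].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def _safe_corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance vector; correlation undefined", RuntimeWarning)
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "pearson":
            return float(stats.pearsonr(x, y).statistic)
        return float(stats.spearmanr(x, y).statistic)


def profile_correlation(
    matrix: ExpressionMatrix, sheet: SampleSheet
) -> list[PairCorrelation]:
    """Whole-profile Pearson and Spearman correlation for every complete pair.

    Probes with a missing value in either member are excluded from that
    pair's computation; the number actually used is recorded.
    """
    results = []
    for row in sheet.pair_table().itertuples():
        x, y = _pair_values(matrix, row.first, row.second)
        if x.size < 2:
            raise InsufficientDataError(
                f"pair {row.tumour_id!r}: fewer than 2 complete probes"
            )
        results.append(
            PairCorrelation(
                tumour_id=row.tumour_id,
                r_pearson=_safe_corr(x, y, "pearson"),
                r_spearman=_safe_corr(x, y, "spearman"),
                n_probes=int(x.size),
            )
        )
    return results


def gene_pair_correlation(
    matrix: ExpressionMatrix, sheet: SampleSheet, probe_id: str
) -> GenePairCorrelation:
    """Pearson correlation across tumours between first- and second-sample
    expression of one probe, with a two-sided t-distribution p (n - 2 df)."""
    pairs = sheet.pair_table()
    if probe_id not in matrix.values.index:
        raise ValidationError(f"probe {probe_id!r} not in matrix")
    row = matrix.values.loc[probe_id]
    x = row[pairs["first"]].to_numpy(dtype=float)
    y = row[pairs["second"]].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 4:
        raise InsufficientDataError(f"probe {probe_id!r}: only {n} complete pairs (< 4)")
    r = _safe_corr(x, y, "pearson")
    if np.isnan(r):
        p = float("nan")
    elif abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    all_vals = row.to_numpy(dtype=float)
    all_vals = all_vals[np.isfinite(all_vals)]
    rng = float(all_vals.max() - all_vals.min()) if all_vals.size else float("nan")
    return GenePairCorrelation(probe_id=probe_id, r=r, p=p, n_pairs=n, dynamic_range_log2=rng)


def gene_pair_correlation_table(
    matrix: ExpressionMatrix, sheet: SampleSheet, probe_ids: list[str] | None = None
) -> pd.DataFrame:
    """Vectorised :func:`gene_pair_correlation` over many probes.

    Fast path for fully observed probes; rows with missing values fall back
    to the per-probe routine (pairwise exclusion).
    """
    probe_ids = probe_ids if probe_ids is not None else matrix.probe_ids
    pairs = sheet.pair_table()
    n = len(pairs)
    if n < 4:
        raise InsufficientDataError(f"only {n} complete pairs (< 4)")
    sub = matrix.values.loc[probe_ids]
    x = sub[list(pairs["first"])].to_numpy(dtype=float)
    y = sub[list(pairs["second"])].to_numpy(dtype=float)
    complete = np.isfinite(x).all(axis=1) & np.isfinite(y).all(axis=1)

    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc).sum(axis=1) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) >= 1.0] = 0.0

    all_vals = sub.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rng = np.nanmax(all_vals, axis=1) - np.nanmin(all_vals, axis=1)

    out = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "r": r,
            "p": p,
            "n_pairs": n,
            "dynamic_range_log2": rng,
        }
    )
    for i in np.flatnonzero(~complete):
        rec = gene_pair_correlation(matrix, sheet, probe_ids[i])
        out.loc[i, ["r", "p", "n_pairs", "dynamic_range_log2"]] = (
            rec.r, rec.p, rec.n_pairs, rec.dynamic_range_log2,
        )
    return out


def hierarchical_cluster(
    matrix: ExpressionMatrix, metric: str = "euclidean", linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of samples; deterministic given input order."""
    if matrix.n_samples < 2:
        raise InsufficientDataError("clustering needs >= 2 samples")
    data = matrix.values.to_numpy(dtype=float).T
    dists = pdist(data, metric=metric)
    z = hierarchy.linkage(dists, method=linkage)
    return Dendrogram(linkage=z, sample_ids=matrix.sample_ids)


def pair_adjacency_concordance(
    dendrogram: Dendrogram, sheet: SampleSheet
) -> ClusterConcordance:
    """Count complete pairs whose two samples are sibling leaves in the tree."""
    leaves = set(dendrogram.sample_ids)
    pairs = sheet.pair_table()
    for row in pairs.itertuples():
        for s in (row.first, row.second):
            if s not in leaves:
                raise ValidationError(f"sample {s!r} missing from dendrogram")
    siblings = dendrogram.sibling_leaf_pairs()
    adjacent = sum(
        1 for row in pairs.itertuples() if frozenset((row.first, row.second)) in siblings
    )
    return ClusterConcordance(n_pairs_total=len(pairs), n_pairs_adjacent=adjacent)
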