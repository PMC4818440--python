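"""Nearest-centroid intrinsic subtyping with correlation-margin diagnostics.

A sample is assigned the subtype whose centroid profile it correlates with
most strongly (Spearman by default) over the genes shared between matrix and
centroid set, after optional gene-wise median centering across the cohort.
Margins between centroid correlations flag uncertain calls: paired
discordance concentrates where the margin is small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import CentroidSet, ExpressionMatrix, ProbeAnnotation, SampleSheet
from .errors import CoverageError, InsufficientDataError, ValidationError

MARGIN_PAIR_DEFAULT = ("LumA", "LumB")


@dataclass
class SubtypeCall:
    sample_id: str
    assigned: str
    r_by_subtype: dict[str, float]
    margin_pair_diff: float | None  # r(pair[0]) - r(pair[1]), signed
    top_margin: float
    tied: bool = False


@dataclass
class PairedSubtypeConcordance:
    calls: pd.DataFrame  # tumour_id, call_first, call_second, concordant
    contingency: pd.DataFrame  # first calls as rows, second as columns
    discordance_rate: float
    asymmetry_p: float  # exact binomial test of directional shift


def _gene_level_matrix(
    matrix: ExpressionMatrix, annotation: ProbeAnnotation | None
) -> pd.DataFrame:
    """Collapse probes to genes (mean per Entrez id); identity if no annotation."""
    if annotation is None:
        return matrix.values
    ann = annotation.table.set_index("probe_id")["entrez_id"]
    shared = [p for p in matrix.probe_ids if p in ann.index]
    if not shared:
        raise CoverageError("no matrix probes present in annotation")
    sub = matrix.values.loc[shared]
    return sub.groupby(ann.loc[shared].values).mean()


def classify(
    matrix: ExpressionMatrix,
    centroids: CentroidSet,
    annotation: ProbeAnnotation | None = None,
    method: str = "spearman",
    median_center: bool = True,
    margin_pair: tuple[str, str] | None = MARGIN_PAIR_DEFAULT,
) -> list[SubtypeCall]:
    """Assign each sample the subtype of its best-correlated centroid.

    Requires at least half the centroid genes to be present (after probe ->
    gene collapsing); ties broken alphabetically and flagged.
    """
    gene_expr = _gene_level_matrix(matrix, annotation)
    shared = [g for g in centroids.gene_ids if g in gene_expr.index]
    if len(shared) < 0.5 * len(centroids.gene_ids):
        missing = [g for g in centroids.gene_ids if g not in gene_expr.index]
        raise CoverageError(
            f"only {len(shared)}/{len(centroids.gene_ids)} centroid genes matched; "
            f"missing: {missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    expr = gene_expr.loc[shared]
    if median_center:
        expr = expr.sub(expr.median(axis=1), axis=0)
    cent = centroids.table.loc[shared]
    labels = sorted(centroids.subtype_labels)

    if method == "spearman":
        expr_r = expr.rank(axis=0)
        cent_r = cent.rank(axis=0)
    elif method == "pearson":
        expr_r, cent_r = expr, cent
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    e = expr_r.to_numpy(dtype=float)
    c = cent_r.to_numpy(dtype=float)
    e = e - e.mean(axis=0)
    c = c - c.mean(axis=0)
    denom = np.outer(
        np.sqrt((e**2).sum(axis=0)), np.sqrt((c**2).sum(axis=0))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (e.T @ c) / denom  # samples x subtypes
    corr_df = pd.DataFrame(corr, index=matrix.sample_ids, columns=cent.columns)

    mp = margin_pair if margin_pair and all(s in corr_df.columns for s in margin_pair) else None
    calls = []
    for sample in matrix.sample_ids:
        r = corr_df.loc[sample]
        ordered = sorted(labels, key=lambda s: (-r[s], s))
        best = ordered[0]
        tied = len(ordered) > 1 and r[ordered[1]] == r[best]
        top_margin = float(r[best] - r[ordered[1]]) if len(ordered) > 1 else 0.0
        calls.append(
            SubtypeCall(
                sample_id=sample,
                assigned=best,
                r_by_subtype={s: float(r[s]) for s in labels},
                margin_pair_diff=float(r[mp[0]] - r[mp[1]]) if mp else None,
                top_margin=top_margin,
                tied=tied,
            )
        )
    return calls


def paired_concordance(
    calls: list[SubtypeCall], sheet: SampleSheet
) -> PairedSubtypeConcordance:
    """Per-pair call agreement, contingency table, and a symmetry test.

    The symmetry test compares, over discordant pairs, how often the shift
    goes in one label-order direction versus the other (exact two-sided
    binomial against 0.5); a large p means no systematic drift.
    """
    by_sample = {c.sample_id: c for c in calls}
    pairs = sheet.pair_table()
    rows = []
    for row in pairs.itertuples():
        if row.first not in by_sample or row.second not in by_sample:
            raise ValidationError(f"pair {row.tumour_id!r}: missing subtype call")
        a, b = by_sample[row.first].assigned, by_sample[row.second].assigned
        rows.append(
            {"tumour_id": row.tumour_id, "call_first": a, "call_second": b, "concordant": a == b}
        )
    table = pd.DataFrame(rows)
    labels = sorted({c.assigned for c in calls})
    contingency = pd.crosstab(table["call_first"], table["call_second"]).reindex(
        index=labels, columns=labels, fill_value=0
    )
    n_disc = int((~table["concordant"]).sum())
    rate = n_disc / len(table) if len(table) else float("nan")
    forward = int((~table["concordant"] & (table["call_first"] < table["call_second"])).sum())
    if n_disc == 0:
        p = 1.0
    else:
        p = float(stats.binomtest(forward, n_disc, 0.5, alternative="two-sided").pvalue)
    return PairedSubtypeConcordance(
        calls=table, contingency=contingency, discordance_rate=rate, asymmetry_p=p
    )


def median_ci_order_statistic(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Distribution-free CI for the median from order statistics.

    Widest-in symmetric pair of order statistics whose binomial(n, 1/2)
    coverage reaches ``level``; degenerate (min, max) if none does.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise InsufficientDataError("empty group")
    if n == 1:
        return float(x[0]), float(x[0])
    best = (float(x[0]), float(x[-1]))
    for k in range(n // 2, 0, -1):
        # CI (x_(k), x_(n+1-k)) has coverage P(k <= X <= n-k), X ~ Bin(n, 1/2)
        coverage = stats.binom.cdf(n - k, n, 0.5) - stats.binom.cdf(k - 1, n, 0.5)
        if coverage >= level:
            return float(x[k - 1]), float(x[n - k])
    return best


def _bootstrap_median_ci(
    values: np.ndarray, level: float = 0.95, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    meds = np.median(
        rng.choice(values, size=(n_boot, values.size), replace=True), axis=1
    )
    alpha = (1 - level) / 2
    return float(np.quantile(meds, alpha)), float(np.quantile(meds, 1 - alpha))


def margin_summary(
    calls: list[SubtypeCall],
    sheet: SampleSheet,
    timepoint: str = "first",
    level: float = 0.95,
) -> dict[str, dict]:
    """Median |margin| (between the configured subtype pair) with 95 % CI for
    concordant vs discordant pairs.

    ``timepoint`` selects which member of each pair contributes its margin:
    "first", "second", or "both" (pooled). Order-statistic CIs; bootstrap
    fallback below n = 6. Empty groups are omitted with a note.
    """
    conc = paired_concordance(calls, sheet)
    by_sample = {c.sample_id: c for c in calls}
    pairs = sheet.pair_table().set_index("tumour_id")
    cols = {"first": ["first"], "second": ["second"], "both": ["first", "second"]}[timepoint]
    groups: dict[str, list[float]] = {"concordant": [], "discordant": []}
    for row in conc.calls.itertuples():
        for col in cols:
            sample = pairs.loc[row.tumour_id, col]
            margin = by_sample[sample].margin_pair_diff
            if margin is None:
                continue
            groups["concordant" if row.concordant else "discordant"].append(abs(margin))
    out: dict[str, dict] = {}
    for name, vals in groups.items():
        if not vals:
            out[name] = {"note": "empty group; omitted"}
            continue
        arr = np.asarray(vals, dtype=float)
        if arr.size < 6:
            lo, hi = _bootstrap_median_ci(arr, level=level)
            ci_method = "bootstrap"
        else:
            lo, hi = median_ci_order_statistic(arr, level=level)
            ci_method = "order-statistic"
        out[name] = {
            "n": int(arr.size),
            "median": float(np.median(arr)),
            "ci_low": lo,
            "ci_high": hi,
            "ci_method": ci_method,
        }
    return out


def calls_to_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    labels = sorted(calls[0].r_by_subtype) if calls else []
    rows = []
    for c in calls:
        row = {"sample_id": c.sample_id, "assigned": c.assigned, "tied": c.tied,
               "top_margin": c.top_margin, "margin_pair_diff": c.margin_pair_diff}
        for s in labels:
            row[f"r_{s}"] = c.r_by_subtype[s]
        rows.append(row)
    return pd.DataFrame(rows)
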