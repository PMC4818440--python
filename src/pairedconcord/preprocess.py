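"""QC filtering, log transform, quantile normalization, batch centering.

The default recipe is log2(x + 1) -> quantile normalization -> per-batch
gene-mean centering, with sample-level exclusion below a 30 % detected
fraction (strict) applied pairwise, and removal of probes detected in no
sample. Every stage is independently switchable and the report records what
was done.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import ExpressionMatrix, SampleSheet
from .errors import DomainError, InsufficientDataError

log = logging.getLogger(__name__)

DEFAULT_MIN_DETECTED_FRACTION = 0.30


@dataclass
class PreprocessReport:
    """Audit trail of a preprocessing run."""

    excluded_samples: list[dict] = field(default_factory=list)
    removed_probes: int = 0
    normalization: str = "none"
    batches_centered: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        return PreprocessReport(
            excluded_samples=self.excluded_samples + other.excluded_samples,
            removed_probes=self.removed_probes + other.removed_probes,
            normalization=other.normalization if other.normalization != "none" else self.normalization,
            batches_centered=self.batches_centered + other.batches_centered,
            notes=self.notes + other.notes,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def log2_transform(
    matrix: ExpressionMatrix, offset: float = 1.0, already_log2: bool = False
) -> ExpressionMatrix:
    """log2(v + offset) on every cell; detection flags unchanged.

    With ``already_log2`` the matrix is returned untouched (pass-through for
    data deposited on the log scale).
    """
    if already_log2:
        return matrix
    if offset < 0:
        raise DomainError("offset must be >= 0")
    v = matrix.values.to_numpy() + offset
    finite = np.isfinite(matrix.values.to_numpy())
    if (v[finite] <= 0).any():
        raise DomainError("log2 undefined: value + offset <= 0 encountered")
    out = pd.DataFrame(
        np.where(finite, np.log2(np.where(finite & (v > 0), v, 1.0)), np.nan),
        index=matrix.values.index,
        columns=matrix.values.columns,
    )
    return ExpressionMatrix(out, matrix.detected.copy())


def filter_samples_by_detection(
    matrix: ExpressionMatrix,
    sheet: SampleSheet | None = None,
    min_fraction: float = DEFAULT_MIN_DETECTED_FRACTION,
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Drop samples whose detected fraction is strictly below ``min_fraction``.

    When a sample sheet is given the failing sample's pair partner is removed
    too, since all downstream statistics are paired; both removals are listed
    in the report with the triggering fraction.
    """
    frac = matrix.detection_fraction()
    failing = [s for s in matrix.sample_ids if frac[s] < min_fraction]
    report = PreprocessReport()
    to_remove: dict[str, dict] = {}
    for s in failing:
        to_remove[s] = {
            "sample_id": s,
            "reason": f"detected fraction {frac[s]:.4f} < {min_fraction}",
            "detection_fraction": float(frac[s]),
        }
        if sheet is not None:
            partner = sheet.partner_of(s)
            if partner is not None and partner in matrix.sample_ids and partner not in to_remove:
                to_remove[partner] = {
                    "sample_id": partner,
                    "reason": f"pair partner of excluded sample {s}",
                    "detection_fraction": float(frac.get(partner, np.nan)),
                }
    report.excluded_samples = list(to_remove.values())
    keep = [s for s in matrix.sample_ids if s not in to_remove]
    if not keep:
        report.notes.append("all samples excluded by detection filter")
    return matrix.subset(samples=keep), report


def filter_undetected_probes(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Remove probes detected in zero samples."""
    detected_any = matrix.detected.any(axis=1)
    keep = [p for p, ok in detected_any.items() if ok]
    report = PreprocessReport(removed_probes=int((~detected_any).sum()))
    return matrix.subset(probes=keep), report


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the across-sample mean of sorted value vectors.

    Ties within a sample receive the mean of the target values over the tied
    block, which keeps the procedure idempotent and rank-preserving.
    """
    if matrix.n_samples < 2:
        raise InsufficientDataError("quantile normalization needs >= 2 samples")
    x = matrix.values.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(x, order, axis=0)
    target = sorted_vals.mean(axis=1)

    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        col = np.empty(n)
        col[order[:, j]] = target
        # average target over tied blocks of the input column
        xs = x[order[:, j], j]
        block_start = 0
        for k in range(1, n + 1):
            if k == n or xs[k] != xs[block_start]:
                if k - block_start > 1:
                    idx = order[block_start:k, j]
                    col[idx] = target[block_start:k].mean()
                block_start = k
        out[:, j] = col
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(frame, matrix.detected.copy())


def batch_center(matrix: ExpressionMatrix, sheet: SampleSheet) -> ExpressionMatrix:
    """Per gene and batch, subtract the batch mean and add the global gene mean.

    Leaves the global per-gene mean unchanged and zeroes batch main effects.
    Size-1 batches end up centered exactly on the global mean (warned).
    """
    batches = sheet.table.set_index("sample_id")["batch_id"]
    missing = [s for s in matrix.sample_ids if s not in batches.index]
    if missing:
        raise InsufficientDataError(f"samples missing from sheet: {missing[:5]}")
    v = matrix.values
    global_mean = v.mean(axis=1)
    out = v.copy()
    for batch, members in batches.loc[matrix.sample_ids].groupby(batches).groups.items():
        cols = [s for s in members if s in v.columns]
        if len(cols) == 1:
            log.warning("batch %r has a single sample; centered to global mean", batch)
        bmean = v[cols].mean(axis=1)
        out[cols] = v[cols].sub(bmean, axis=0).add(global_mean, axis=0)
    return ExpressionMatrix(out, matrix.detected.copy())


def run_default_recipe(
    matrix: ExpressionMatrix,
    sheet: SampleSheet | None = None,
    *,
    already_log2: bool = True,
    log2_offset: float = 1.0,
    min_detected_fraction: float = DEFAULT_MIN_DETECTED_FRACTION,
    do_quantile: bool = True,
    do_batch_center: bool = False,
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """log2 -> detection filters -> quantile normalization -> batch centering."""
    report = PreprocessReport()
    m = log2_transform(matrix, offset=log2_offset, already_log2=already_log2)
    if not already_log2:
        report.notes.append(f"log2 transform with offset {log2_offset}")
    m, r = filter_samples_by_detection(m, sheet, min_detected_fraction)
    report = report.merge(r)
    m, r = filter_undetected_probes(m)
    report = report.merge(r)
    if do_quantile and m.n_samples >= 2:
        m = quantile_normalize(m)
        report.normalization = "quantile"
    if do_batch_center:
        if sheet is None:
            raise InsufficientDataError("batch centering requires a sample sheet")
        m = batch_center(m, sheet.subset(m.sample_ids))
        report.batches_centered = sorted(
            set(sheet.subset(m.sample_ids).table["batch_id"])
        )
    return m, report
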