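"""Synthetic paired-biopsy cohorts with known ground truth.

The generative model, all on the log2 scale:

    tumour profile  = baseline_g + centroid[g, subtype(t)] + N(0, sigma_between_g)
    biopsy k        = tumour profile + N(0, sigma_within_g)
                      + [k = second] * (delta_g + slope_g * minutes_t)
                      + batch effect
    detection       ~ Bernoulli(logistic((x - dropout_midpoint) / dropout_scale))

so a gene's expected first/second correlation across tumours is the
intraclass correlation sigma_b^2 / (sigma_b^2 + sigma_w^2), systematic
second-sample shifts are injected through ``shift_genes``, and elapsed-time
drift through ``time_slopes``. Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import CentroidSet, ExpressionMatrix, ProbeAnnotation, SampleSheet
from .errors import ConfigError, ValidationError

DEFAULT_SUBTYPE_PROPORTIONS = {
    "LumA": 0.45,
    "LumB": 0.25,
    "Her2": 0.12,
    "Basal": 0.10,
    "Normal": 0.08,
}


@dataclass
class SimulationConfig:
    seed: int
    n_tumours: int = 20
    n_genes: int = 500
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_PROPORTIONS)
    )
    n_subtype_genes: int | None = None  # genes carrying centroid structure; default min(50, n_genes)
    centroid_separation: float = 2.0  # sd of centroid values (log2)
    sigma_between: float | Sequence[float] = 1.0
    sigma_within: float | Sequence[float] = 0.3
    dynamic_range_profile: Sequence[float] | None = None  # multiplies sigma_between
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    shift_genes: Mapping[int, float] = field(default_factory=dict)  # gene index -> delta
    time_slopes: Mapping[int, float] = field(default_factory=dict)  # gene index -> log2/min
    elapsed_range: tuple[float, float] = (20.0, 60.0)
    n_batches: int = 1
    batch_sd: float = 0.0
    split_pairs_across_batches: bool = False
    dropout_midpoint: float = 2.0
    dropout_scale: float = 1.0
    n_degraded_pairs: int = 0  # pairs whose second sample is forced below QC
    degraded_detect_prob: float = 0.15
    study_id: str = "SIM"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"subtype proportions sum to {total}, expected 1")
        for name, arr in (("sigma_between", self.sigma_between), ("sigma_within", self.sigma_within)):
            vals = np.atleast_1d(np.asarray(arr, dtype=float))
            if (vals < 0).any():
                raise ConfigError(f"{name} must be nonnegative")
        if self.n_subtype_genes is None:
            self.n_subtype_genes = min(50, self.n_genes)
        if self.n_subtype_genes > self.n_genes:
            raise ConfigError("n_subtype_genes cannot exceed n_genes")


@dataclass
class GroundTruth:
    subtype_by_tumour: dict[str, str]
    delta: np.ndarray  # per-gene second-sample shift
    sigma_between: np.ndarray
    sigma_within: np.ndarray
    time_slopes: np.ndarray
    gene_ids: list[str]
    elapsed_by_tumour: dict[str, float]

    def to_json(self, path) -> None:
        payload = {
            "subtype_by_tumour": self.subtype_by_tumour,
            "delta": dict(zip(self.gene_ids, self.delta.tolist())),
            "sigma_between": dict(zip(self.gene_ids, self.sigma_between.tolist())),
            "sigma_within": dict(zip(self.gene_ids, self.sigma_within.tolist())),
            "time_slopes": dict(zip(self.gene_ids, self.time_slopes.tolist())),
            "elapsed_by_tumour": self.elapsed_by_tumour,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @property
    def shifted_genes(self) -> list[str]:
        return [g for g, d in zip(self.gene_ids, self.delta) if d != 0]


def _per_gene(value, n_genes: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n_genes, float(arr))
    if arr.shape != (n_genes,):
        raise ConfigError(f"{name} must be scalar or length n_genes")
    return arr


def generate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleSheet, CentroidSet, GroundTruth]:
    """Draw a full paired cohort plus matched ground truth. Deterministic in
    ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    g, t = config.n_genes, config.n_tumours
    gene_ids = [f"g{i:05d}" for i in range(g)]
    tumour_ids = [f"t{i:03d}" for i in range(t)]

    sb = _per_gene(config.sigma_between, g, "sigma_between")
    if config.dynamic_range_profile is not None:
        sb = sb * _per_gene(config.dynamic_range_profile, g, "dynamic_range_profile")
    sw = _per_gene(config.sigma_within, g, "sigma_within")

    labels = list(config.subtype_proportions)
    probs = np.array([config.subtype_proportions[s] for s in labels])
    subtype_idx = rng.choice(len(labels), size=t, p=probs)
    subtypes = [labels[i] for i in subtype_idx]

    baseline = config.baseline_mean + rng.normal(0, config.baseline_sd, size=g)
    centroid = np.zeros((g, len(labels)))
    k = config.n_subtype_genes
    centroid[:k, :] = rng.normal(0, config.centroid_separation, size=(k, len(labels)))

    delta = np.zeros(g)
    for idx, d in config.shift_genes.items():
        delta[int(idx)] = float(d)
    slopes = np.zeros(g)
    for idx, s in config.time_slopes.items():
        slopes[int(idx)] = float(s)

    lo, hi = config.elapsed_range
    minutes = rng.uniform(lo, hi, size=t)

    batch_of_sample: list[str] = []
    batch_effects = rng.normal(0, config.batch_sd, size=(config.n_batches, g))

    tumour_profiles = (
        baseline[:, None] + centroid[:, subtype_idx] + rng.normal(0, 1, size=(g, t)) * sb[:, None]
    )

    values = np.empty((g, 2 * t))
    sample_ids: list[str] = []
    rows = []
    for j, tum in enumerate(tumour_ids):
        if config.split_pairs_across_batches:
            b1, b2 = j % config.n_batches, (j + 1) % config.n_batches
        else:
            b1 = b2 = j % config.n_batches
        for k2, (tp, b) in enumerate((("first", b1), ("second", b2))):
            col = 2 * j + k2
            noise = rng.normal(0, 1, size=g) * sw
            x = tumour_profiles[:, j] + noise + batch_effects[b]
            if tp == "second":
                x = x + delta + slopes * minutes[j]
            values[:, col] = x
            sid = f"{tum}_{1 if tp == 'first' else 2}"
            sample_ids.append(sid)
            batch_of_sample.append(f"b{b}")
            rows.append(
                {
                    "sample_id": sid,
                    "tumour_id": tum,
                    "timepoint": tp,
                    "study_id": config.study_id,
                    "batch_id": f"b{b}",
                    "elapsed_minutes": round(float(minutes[j]), 3),
                }
            )

    # detection dropout: logistic in expression
    prob = 1.0 / (1.0 + np.exp(-(values - config.dropout_midpoint) / config.dropout_scale))
    if config.n_degraded_pairs > 0:
        for j in range(min(config.n_degraded_pairs, t)):
            col = 2 * j + 1  # second sample of pair j
            prob[:, col] = config.degraded_detect_prob
    detected = rng.random(size=values.shape) < prob

    frame = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    det = pd.DataFrame(detected, index=gene_ids, columns=sample_ids)
    matrix = ExpressionMatrix(frame, det)
    sheet = SampleSheet(pd.DataFrame(rows))
    centroid_table = pd.DataFrame(
        baseline[:k, None] + centroid[:k, :], index=gene_ids[:k], columns=labels
    )
    centroids = CentroidSet(centroid_table.sort_index(axis=1))
    truth = GroundTruth(
        subtype_by_tumour=dict(zip(tumour_ids, subtypes)),
        delta=delta,
        sigma_between=sb,
        sigma_within=sw,
        time_slopes=slopes,
        gene_ids=gene_ids,
        elapsed_by_tumour={tum: round(float(m), 3) for tum, m in zip(tumour_ids, minutes)},
    )
    return matrix, sheet, centroids, truth


def identity_annotation(gene_ids: Sequence[str]) -> ProbeAnnotation:
    """Probe == gene annotation for simulated matrices."""
    return ProbeAnnotation(
        pd.DataFrame(
            {"probe_id": list(gene_ids), "entrez_id": list(gene_ids), "symbol": list(gene_ids)}
        )
    )


def truth_recovery_report(
    truth: GroundTruth,
    de_selected: Sequence[str] | None = None,
    subtype_calls=None,
    sheet: SampleSheet | None = None,
    gene_corr: pd.DataFrame | None = None,
    time_table: pd.DataFrame | None = None,
) -> dict:
    """Score analysis outputs against the generating truth.

    Any subset of outputs may be supplied; each contributes its own metrics:
    DE sensitivity/false-discovery proportion, per-sample subtype accuracy,
    mean absolute ICC estimation error, and slope-gene recovery.
    """
    report: dict = {}
    gene_set = set(truth.gene_ids)

    if de_selected is not None:
        unknown = [g for g in de_selected if g not in gene_set]
        if unknown:
            raise ValidationError(f"selected genes not in truth: {unknown[:5]}")
        true_pos = set(truth.shifted_genes)
        sel = set(de_selected)
        tp = len(sel & true_pos)
        report["de"] = {
            "n_selected": len(sel),
            "n_true_shifted": len(true_pos),
            "sensitivity": tp / len(true_pos) if true_pos else float("nan"),
            "fdp": (len(sel) - tp) / len(sel) if sel else 0.0,
        }

    if subtype_calls is not None:
        if sheet is None:
            raise ValidationError("subtype accuracy needs the sample sheet")
        tum_of = sheet.table.set_index("sample_id")["tumour_id"]
        correct = total = 0
        for call in subtype_calls:
            tum = tum_of.get(call.sample_id)
            if tum is None:
                raise ValidationError(f"call for unknown sample {call.sample_id!r}")
            total += 1
            correct += call.assigned == truth.subtype_by_tumour[tum]
        report["subtype"] = {"n_samples": total, "accuracy": correct / total if total else float("nan")}

    if gene_corr is not None:
        icc = truth.sigma_between**2 / (truth.sigma_between**2 + truth.sigma_within**2)
        icc_by_gene = pd.Series(icc, index=truth.gene_ids)
        est = gene_corr.set_index("probe_id")["r"]
        shared = est.index.intersection(icc_by_gene.index)
        if shared.empty:
            raise ValidationError("gene correlation table shares no genes with truth")
        err = (est.loc[shared] - icc_by_gene.loc[shared]).abs()
        report["icc"] = {
            "n_genes": int(shared.size),
            "mean_abs_error": float(err.mean()),
            "mean_estimate": float(est.loc[shared].mean()),
            "mean_true_icc": float(icc_by_gene.loc[shared].mean()),
        }

    if time_table is not None:
        slope_genes = [g for g, s in zip(truth.gene_ids, truth.time_slopes) if s != 0]
        present = [g for g in slope_genes if g in time_table.index]
        if slope_genes and not present:
            raise ValidationError("no slope genes present in time table")
        r_slope = time_table.loc[present, "r_time"] if present else pd.Series(dtype=float)
        report["time"] = {
            "n_slope_genes": len(slope_genes),
            "mean_r_at_slope_genes": float(r_slope.mean()) if present else float("nan"),
        }
    return report
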