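"""Domain types and tab-delimited readers/writers.

All tables are plain TSV. Expression matrices are probe-by-sample with an
optional companion ``<name>.detection.tsv`` holding detection p-values of
identical shape; detection flags are derived at read time by comparing those
p-values against a configurable alpha. Lines starting with ``!`` (GEO
series-matrix headers) are skipped by the expression reader.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

DEFAULT_DETECTION_ALPHA = 0.05

_TIMEPOINT_ALIASES = {
    "first": "first",
    "second": "second",
    "a": "first",
    "b": "second",
    "d": "first",
    "s": "second",
    "baseline": "first",
    "surgery": "second",
}

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "tumour_id",
    "timepoint",
    "study_id",
    "batch_id",
    "elapsed_minutes",
]


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """log2 probe-by-sample expression values plus per-cell detection flags.

    Parameters
    ----------
    values : pandas.DataFrame
        Float matrix, probes as rows, samples as columns.
    detected : pandas.DataFrame
        Boolean matrix of identical shape and labels.
    """

    values: pd.DataFrame
    detected: pd.DataFrame

    def __post_init__(self) -> None:
        v, d = self.values, self.detected
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if v.shape != d.shape or not v.index.equals(d.index) or not v.columns.equals(d.columns):
            raise ValidationError("values and detected must share shape and labels")
        bad = d.to_numpy() & ~np.isfinite(v.to_numpy())
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value flagged detected at probe {v.index[i]!r}, sample {v.columns[j]!r}"
            )

    # -- accessors ----------------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def detection_fraction(self) -> pd.Series:
        """Fraction of detected probes per sample."""
        return self.detected.mean(axis=0)

    def subset(
        self,
        probes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        v, d = self.values, self.detected
        if probes is not None:
            v, d = v.loc[list(probes)], d.loc[list(probes)]
        if samples is not None:
            v, d = v[list(samples)], d[list(samples)]
        return ExpressionMatrix(v.copy(), d.copy())

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.values.equals(other.values) and self.detected.equals(other.detected)

    @classmethod
    def from_values(cls, values: pd.DataFrame) -> "ExpressionMatrix":
        """All finite cells flagged detected."""
        detected = pd.DataFrame(
            np.isfinite(values.to_numpy()), index=values.index, columns=values.columns
        )
        return cls(values.astype(float), detected)


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Maps samples to tumours with timepoint/study/batch/elapsed-time fields.

    ``timepoint`` is normalized to the enumeration {"first", "second"}
    (study I's A/B and study II's D/S map onto it). ``elapsed_minutes`` may be
    missing (NaN); operations that need it must check :meth:`has_elapsed`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in t.columns]
        if missing:
            raise SchemaError(f"sample sheet missing columns: {missing}")
        t = t.copy()
        t["timepoint"] = [
            _normalize_timepoint(x, i) for i, x in enumerate(t["timepoint"])
        ]
        t["elapsed_minutes"] = pd.to_numeric(t["elapsed_minutes"], errors="coerce")
        if (t["elapsed_minutes"].dropna() < 0).any():
            raise ValidationError("elapsed_minutes must be nonnegative")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        dup_tp = t.duplicated(subset=["tumour_id", "timepoint"])
        if dup_tp.any():
            row = t.loc[dup_tp].iloc[0]
            raise ValidationError(
                f"tumour {row['tumour_id']!r} has more than one {row['timepoint']!r} sample"
            )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def complete_pairs(self) -> list[str]:
        """Tumour ids with both timepoints present, in first-seen order."""
        counts = self.table.groupby("tumour_id", sort=False)["timepoint"].nunique()
        return [t for t in counts.index if counts[t] == 2]

    def pair_table(self) -> pd.DataFrame:
        """One row per complete pair: tumour_id, first, second, elapsed_minutes.

        elapsed_minutes is taken from whichever member records it (second
        sample preferred).
        """
        rows = []
        wide = self.table.set_index(["tumour_id", "timepoint"])
        for tum in self.complete_pairs():
            first = wide.loc[(tum, "first")]
            second = wide.loc[(tum, "second")]
            elapsed = second["elapsed_minutes"]
            if pd.isna(elapsed):
                elapsed = first["elapsed_minutes"]
            rows.append(
                {
                    "tumour_id": tum,
                    "first": first["sample_id"],
                    "second": second["sample_id"],
                    "elapsed_minutes": elapsed,
                }
            )
        return pd.DataFrame(rows, columns=["tumour_id", "first", "second", "elapsed_minutes"])

    def has_elapsed(self) -> bool:
        pairs = self.pair_table()
        return len(pairs) > 0 and pairs["elapsed_minutes"].notna().all()

    def partner_of(self, sample_id: str) -> str | None:
        t = self.table
        row = t.loc[t["sample_id"] == sample_id]
        if row.empty:
            return None
        tum = row["tumour_id"].iloc[0]
        others = t.loc[(t["tumour_id"] == tum) & (t["sample_id"] != sample_id), "sample_id"]
        return None if others.empty else others.iloc[0]

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        keep = set(sample_ids)
        return SampleSheet(self.table.loc[self.table["sample_id"].isin(keep)].copy())

    def equals(self, other: "SampleSheet") -> bool:
        return self.table.equals(other.table)


def _normalize_timepoint(value: object, row: int) -> str:
    key = str(value).strip().lower()
    if key not in _TIMEPOINT_ALIASES:
        raise ValidationError(
            f"row {row}: timepoint {value!r} not recognised "
            f"(expected first/second or A/B, D/S)"
        )
    return _TIMEPOINT_ALIASES[key]


# ---------------------------------------------------------------------------
# ProbeAnnotation / GeneSignature / CentroidSet
# ---------------------------------------------------------------------------


@dataclass
class ProbeAnnotation:
    """probe_id -> (entrez_id, symbol); one gene may map to multiple probes."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("probe_id", "entrez_id", "symbol") if c not in self.table.columns]
        if missing:
            raise SchemaError(f"annotation missing columns: {missing}")
        t = self.table.copy()
        t["probe_id"] = t["probe_id"].astype(str)
        t["entrez_id"] = t["entrez_id"].astype(str)
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe_id {dup!r} in annotation")
        self.table = t.reset_index(drop=True)

    def probes_for(self, entrez_id: str) -> list[str]:
        t = self.table
        return list(t.loc[t["entrez_id"] == str(entrez_id), "probe_id"])

    def entrez_for(self, probe_id: str) -> str | None:
        t = self.table
        hit = t.loc[t["probe_id"] == probe_id, "entrez_id"]
        return None if hit.empty else hit.iloc[0]

    def equals(self, other: "ProbeAnnotation") -> bool:
        return self.table.equals(other.table)


@dataclass
class GeneSignature:
    """Named gene set with per-gene weights (Entrez ids)."""

    name: str
    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError(f"signature {self.name!r} has no entries")
        self.entries = [(str(g), float(w)) for g, w in self.entries]
        if not all(math.isfinite(w) for _, w in self.entries):
            raise ValidationError(f"signature {self.name!r} has non-finite weights")

    @property
    def entrez_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CentroidSet:
    """Gene-by-subtype reference profiles for nearest-centroid classification."""

    table: pd.DataFrame  # index: gene ids; columns: subtype labels

    def __post_init__(self) -> None:
        t = self.table
        if t.shape[1] < 2:
            raise ValidationError("centroid set needs >= 2 subtypes")
        if t.index.has_duplicates:
            raise ValidationError("duplicate gene ids in centroid set")
        if t.columns.has_duplicates:
            raise ValidationError("duplicate subtype labels in centroid set")
        if not np.isfinite(t.to_numpy()).all():
            raise ValidationError("centroid set contains missing values")
        self.table = t.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def subtype_labels(self) -> list[str]:
        return list(self.table.columns)

    def equals(self, other: "CentroidSet") -> bool:
        return self.table.equals(other.table)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_rect_tsv(path: str | Path, skip_bang: bool = True) -> tuple[list[str], list[list[str]]]:
    """Strict rectangular TSV reader with row/column-addressed errors."""
    path = Path(path)
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for lineno, rec in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not rec or (skip_bang and rec[0].startswith("!")):
                continue
            if header is None:
                header = rec
                continue
            if len(rec) != len(header):
                raise ParseError(
                    f"{path.name}: line {lineno} has {len(rec)} fields, expected {len(header)}"
                )
            rows.append(rec)
    if header is None:
        raise ParseError(f"{path.name}: empty file")
    return header, rows


def _numeric_frame(
    header: list[str], rows: list[list[str]], path: Path
) -> pd.DataFrame:
    index = [r[0] for r in rows]
    data = np.empty((len(rows), len(header) - 1), dtype=float)
    for i, rec in enumerate(rows):
        for j, cell in enumerate(rec[1:]):
            s = cell.strip()
            if s in ("", "NA", "NaN", "nan"):
                data[i, j] = np.nan
                continue
            try:
                data[i, j] = float(s)
            except ValueError:
                raise ParseError(
                    f"{path.name}: non-numeric value {cell!r} at row {rec[0]!r}, "
                    f"column {header[j + 1]!r}"
                ) from None
    return pd.DataFrame(data, index=index, columns=header[1:])


def detection_companion_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".detection" + path.suffix)


def read_expression_matrix(
    path: str | Path,
    detection_path: str | Path | None = None,
    detection_alpha: float = DEFAULT_DETECTION_ALPHA,
) -> ExpressionMatrix:
    """Read a probe-by-sample TSV, deriving detection flags from p-values.

    If ``detection_path`` is None, a companion ``<name>.detection.tsv`` next
    to ``path`` is used when present; otherwise every finite cell is flagged
    detected. GEO series-matrix ``!`` header lines are skipped.
    """
    path = Path(path)
    header, rows = _read_rect_tsv(path)
    values = _numeric_frame(header, rows, path)
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ParseError(f"{path.name}: duplicate probe row {dup!r}")

    if detection_path is None:
        candidate = detection_companion_path(path)
        detection_path = candidate if candidate.exists() else None
    if detection_path is not None:
        dheader, drows = _read_rect_tsv(Path(detection_path))
        pvals = _numeric_frame(dheader, drows, Path(detection_path))
        if pvals.shape != values.shape:
            raise SchemaError(
                f"detection table shape {pvals.shape} does not match expression {values.shape}"
            )
        pvals = pvals.reindex(index=values.index, columns=values.columns)
        if pvals.isna().to_numpy().all():
            raise SchemaError("detection table labels do not match expression matrix")
        detected = pd.DataFrame(
            pvals.to_numpy() < detection_alpha, index=values.index, columns=values.columns
        )
        return ExpressionMatrix(values, detected)
    return ExpressionMatrix.from_values(values)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, write_detection: bool = True
) -> None:
    """Write values TSV plus a companion detection-p-value TSV.

    Detection flags are encoded as p-values 0.0 (detected) / 1.0 (not), so a
    read at any alpha in (0, 1] round-trips the flags.
    """
    path = Path(path)
    out = matrix.values.copy()
    out.insert(0, "probe_id", out.index)
    out.to_csv(path, sep="\t", index=False)
    if write_detection:
        det = matrix.detected.map(lambda b: 0.0 if b else 1.0)
        det.insert(0, "probe_id", det.index)
        det.to_csv(detection_companion_path(path), sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    return SampleSheet(df[SAMPLE_SHEET_COLUMNS])


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    out = sheet.table.copy()
    out.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> ProbeAnnotation:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("probe_id", "entrez_id", "symbol") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    return ProbeAnnotation(df[["probe_id", "entrez_id", "symbol"]])


def write_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """TSV with columns entrez_id and optional weight (default weight 1.0)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"entrez_id": str})
    if "entrez_id" not in df.columns:
        raise SchemaError(f"{path.name}: missing column 'entrez_id'")
    weights = df["weight"].astype(float) if "weight" in df.columns else [1.0] * len(df)
    entries = list(zip(df["entrez_id"].astype(str), weights))
    return GeneSignature(name or path.stem, entries)


def write_signature(signature: GeneSignature, path: str | Path) -> None:
    df = pd.DataFrame(signature.entries, columns=["entrez_id", "weight"])
    df.to_csv(path, sep="\t", index=False)


def read_centroids(path: str | Path) -> CentroidSet:
    """TSV with first column gene_id and one numeric column per subtype."""
    path = Path(path)
    header, rows = _read_rect_tsv(path)
    if not rows:
        raise SchemaError(f"{path.name}: no centroid rows")
    table = _numeric_frame(header, rows, path)
    return CentroidSet(table)


def write_centroids(centroids: CentroidSet, path: str | Path) -> None:
    out = centroids.table.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False)
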