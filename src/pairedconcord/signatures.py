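"""Gene-set scoring (weighted averages on the log2 scale) and paired tests.

Scores divide by the sum of absolute weights so they stay on the expression
scale. Genes mapping to multiple probes are averaged at the probe level
first, then weighted, so probe multiplicity cannot bias a gene's influence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import ExpressionMatrix, GeneSignature, ProbeAnnotation, SampleSheet
from .errors import InsufficientDataError, NotBundledError, ValidationError


@dataclass
class SignatureScoreTable:
    name: str
    scores: pd.Series  # indexed by sample_id
    n_genes_matched: int
    unmatched_entrez: list[str] = field(default_factory=list)


def score_signature(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    signature: GeneSignature,
    probe_level: bool = False,
) -> SignatureScoreTable:
    """score_s = sum_g w_g x_gs / sum_g |w_g| over matched genes.

    With ``probe_level`` each probe of a gene carries the gene's weight
    instead of being averaged first (alternative convention, off by default).
    """
    weighted = []
    weights = []
    unmatched = []
    probe_index = matrix.values.index
    for entrez, w in signature.entries:
        probes = [p for p in annotation.probes_for(entrez) if p in probe_index]
        if not probes:
            unmatched.append(entrez)
            continue
        if probe_level:
            for p in probes:
                weighted.append(matrix.values.loc[p] * w)
                weights.append(abs(w))
        else:
            gene_expr = matrix.values.loc[probes].mean(axis=0)
            weighted.append(gene_expr * w)
            weights.append(abs(w))
    if not weighted:
        raise ValidationError(
            f"signature {signature.name!r}: zero genes matched in matrix"
        )
    total = sum(weights)
    scores = sum(weighted) / total
    n_matched = len(signature) - len(unmatched)
    return SignatureScoreTable(
        name=signature.name,
        scores=scores,
        n_genes_matched=n_matched,
        unmatched_entrez=unmatched,
    )


def paired_signature_test(
    scores: pd.Series, sheet: SampleSheet, method: str = "wilcoxon"
) -> tuple[float, float]:
    """Two-sided test of the change (second - first) in a per-sample score.

    method 'wilcoxon' is the matched-pairs signed-rank test (exact for small
    n without ties); 'paired_t' the paired t test. All-zero differences give
    p = 1 by convention.
    """
    pairs = sheet.pair_table()
    first = scores[list(pairs["first"])].to_numpy(dtype=float)
    second = scores[list(pairs["second"])].to_numpy(dtype=float)
    diffs = second - first
    if method == "wilcoxon":
        if diffs.size < 5:
            raise InsufficientDataError("wilcoxon needs >= 5 pairs")
        if np.all(diffs == 0):
            return 0.0, 1.0
        res = stats.wilcoxon(second, first, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if method == "paired_t":
        if diffs.size < 3:
            raise InsufficientDataError("paired t needs >= 3 pairs")
        if np.all(diffs == diffs[0]):
            if diffs[0] == 0:
                return 0.0, 1.0
            return float(np.inf * np.sign(diffs[0])), 0.0
        res = stats.ttest_rel(second, first)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Built-in gene sets
# ---------------------------------------------------------------------------

# symbol -> Entrez Gene id for the bundled panels
_ENTREZ = {
    "BAG1": "573",
    "MKI67": "4288",
    "MAPT": "4137",
    "PGR": "5241",
    "SNAI2": "6591",
    "TFF1": "7031",
    "ERBB2": "2064",
    "GPR160": "26996",
    "IGFBP2": "3485",
    "IL6": "3569",
    "CD68": "968",
    "CD14": "929",
    "CD52": "1043",
    "CD44": "960",
    "PPARG": "5468",
    "ADM": "133",
    "VEGFA": "7422",
    "CENPF": "1063",
    "MYC": "4609",
    "CCNB1": "891",
    "MAP1LC3B": "81631",
}

# 13-gene diagnostic-biopsy response panel (a 14th member, SNAI1, is absent
# from the array platform and deliberately not included)
JESELSOHN_SYMBOLS = [
    "IGFBP2",
    "IL6",
    "CD68",
    "CD14",
    "CD52",
    "CD44",
    "PPARG",
    "ADM",
    "VEGFA",
    "CENPF",
    "MYC",
    "CCNB1",
    "MAP1LC3B",
]

# Pre-specified breast-cancer panel; only the published members are bundled,
# so this set is a documented subset of the full 18-gene panel.
PRESELECTED_SYMBOLS = [
    "BAG1",
    "MKI67",
    "MAPT",
    "PGR",
    "SNAI2",
    "TFF1",
    "ERBB2",
    "GPR160",
]

_NOT_BUNDLED = {
    "wound_healing": "wound-healing metagene membership is published elsewhere; supply a signature TSV",
    "immune_response": "immune-response metagene membership is published elsewhere; supply a signature TSV",
}


def entrez_for_symbol(symbol: str) -> str:
    return _ENTREZ[symbol]


def builtin_gene_sets() -> list[GeneSignature]:
    """Bundled unit-weight panels (diagnostic-biopsy response genes and the
    pre-specified breast-cancer genes)."""
    return [
        GeneSignature("jeselsohn_13", [(_ENTREZ[s], 1.0) for s in JESELSOHN_SYMBOLS]),
        GeneSignature("preselected_panel", [(_ENTREZ[s], 1.0) for s in PRESELECTED_SYMBOLS]),
    ]


def builtin_gene_set(name: str) -> GeneSignature:
    if name in _NOT_BUNDLED:
        raise NotBundledError(_NOT_BUNDLED[name])
    for sig in builtin_gene_sets():
        if sig.name == name:
            return sig
    raise KeyError(f"no builtin gene set named {name!r}")


def builtin_symbols(name: str) -> list[str]:
    if name == "jeselsohn_13":
        return list(JESELSOHN_SYMBOLS)
    if name == "preselected_panel":
        return list(PRESELECTED_SYMBOLS)
    if name in _NOT_BUNDLED:
        raise NotBundledError(_NOT_BUNDLED[name])
    raise KeyError(f"no builtin gene set named {name!r}")
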