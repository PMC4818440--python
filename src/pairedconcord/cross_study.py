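"""Compare per-gene pair correlations between two studies (Fisher r-to-z)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError


@dataclass
class CorrelationComparison:
    gene: str
    r1: float
    n1: int
    r2: float
    n2: int
    z_stat: float
    p_two_tail: float

    @property
    def z_rounded(self) -> float:
        """Z at the conventional 2-d.p. reporting precision."""
        return round(self.z_stat, 2)

    @property
    def p_rounded(self) -> float:
        return round(self.p_two_tail, 4)


def fisher_r_to_z_compare(
    r1: float, n1: int, r2: float, n2: int, gene: str = ""
) -> CorrelationComparison:
    """Test equality of two independent correlations.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-tailed
    standard-normal p. Antisymmetric under swapping the studies.
    """
    for label, (r, n) in {"1": (r1, n1), "2": (r2, n2)}.items():
        if n <= 3:
            raise InsufficientDataError(f"study {label}: n must be >= 4, got {n}")
        if abs(r) >= 1:
            raise DomainError(f"study {label}: |r| must be < 1 for the z transform")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2 * stats.norm.sf(abs(z)))
    return CorrelationComparison(
        gene=gene, r1=float(r1), n1=int(n1), r2=float(r2), n2=int(n2),
        z_stat=float(z), p_two_tail=p,
    )


def compare_gene_table(
    study1: pd.DataFrame, study2: pd.DataFrame, genes: list[str] | None = None
) -> pd.DataFrame:
    """Join per-gene (r, n) tables from two studies into one comparison table.

    Inputs need columns ``gene``, ``r``, ``n``. Genes absent from either
    study (or with an undefined r) get an ND row with NaN statistics.
    """
    s1 = study1.set_index("gene")
    s2 = study2.set_index("gene")
    if genes is None:
        genes = list(dict.fromkeys(list(s1.index) + list(s2.index)))
    rows = []
    for g in genes:
        ok1 = g in s1.index and np.isfinite(s1.loc[g, "r"])
        ok2 = g in s2.index and np.isfinite(s2.loc[g, "r"])
        if not (ok1 and ok2):
            rows.append(
                {"gene": g, "r1": np.nan, "n1": np.nan, "r2": np.nan, "n2": np.nan,
                 "z_stat": np.nan, "p_two_tail": np.nan, "status": "ND"}
            )
            continue
        cmp = fisher_r_to_z_compare(
            float(s1.loc[g, "r"]), int(s1.loc[g, "n"]),
            float(s2.loc[g, "r"]), int(s2.loc[g, "n"]), gene=g,
        )
        rows.append(
            {"gene": g, "r1": cmp.r1, "n1": cmp.n1, "r2": cmp.r2, "n2": cmp.n2,
             "z_stat": cmp.z_stat, "p_two_tail": cmp.p_two_tail, "status": "OK"}
        )
    return pd.DataFrame(
        rows, columns=["gene", "r1", "n1", "r2", "n2", "z_stat", "p_two_tail", "status"]
    )
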