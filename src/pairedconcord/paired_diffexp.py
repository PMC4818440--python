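"""Paired differential expression: t statistics, sign-flip permutation
p-values, Benjamini-Hochberg FDR, geometric-mean fold ratios with 95 % CIs,
selection rules, and correlation of within-pair change with elapsed time.

All statistics operate on the genes x pairs matrix of within-pair log2
differences (second - first).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import ExpressionMatrix, SampleSheet
from .errors import InsufficientDataError

DEFAULT_PERMUTATION_SEED = 20160401


def difference_matrix(matrix: ExpressionMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Genes x pairs matrix of second - first log2 values (columns: tumour ids)."""
    pairs = sheet.pair_table()
    if pairs.empty:
        raise InsufficientDataError("no complete pairs in sample sheet")
    first = matrix.values[list(pairs["first"])].to_numpy(dtype=float)
    second = matrix.values[list(pairs["second"])].to_numpy(dtype=float)
    return pd.DataFrame(
        second - first, index=matrix.values.index, columns=list(pairs["tumour_id"])
    )


def _t_from_diffs(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row paired t, two-sided p, and degenerate flag for a diff matrix."""
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    degenerate = sd == 0
    t = np.zeros(d.shape[0])
    nz = ~degenerate
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t), n - 1)
    # zero-variance rows: mean 0 -> no evidence (p=1); mean != 0 -> p -> 0
    p[degenerate & (mean == 0)] = 1.0
    p[degenerate & (mean != 0)] = 0.0
    t[degenerate & (mean != 0)] = np.inf * np.sign(mean[degenerate & (mean != 0)])
    return t, p, degenerate


def paired_t(matrix: ExpressionMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Two-sided paired t test per gene (n - 1 df)."""
    d = difference_matrix(matrix, sheet)
    if d.shape[1] < 3:
        raise InsufficientDataError(f"paired t needs >= 3 pairs, got {d.shape[1]}")
    t, p, degenerate = _t_from_diffs(d.to_numpy())
    return pd.DataFrame(
        {"t_stat": t, "p_parametric": p, "degenerate": degenerate}, index=d.index
    )


def signflip_permutation(
    diffs: pd.DataFrame | np.ndarray,
    n_perm: int = 10_000,
    seed: int = DEFAULT_PERMUTATION_SEED,
    exact: bool = False,
) -> np.ndarray:
    """Per-gene two-sided sign-flip permutation p-values.

    Each permutation flips every pair's difference sign independently; the
    p-value is ``(1 + #{|t*| >= |t|}) / (1 + n_perm)``. With ``exact`` (only
    sensible for small n) all 2^n sign patterns are enumerated and the
    p-value is the exact tail fraction ``#{|t*| >= |t|} / 2^n``.

    Sign flips leave each row's sum of squares unchanged, so t* is computed
    from the permuted means alone.
    """
    d = diffs.to_numpy(dtype=float) if isinstance(diffs, pd.DataFrame) else np.asarray(diffs, float)
    if d.ndim == 1:
        d = d[None, :]
    g, n = d.shape
    ss = (d * d).sum(axis=1)

    def t_from_means(means: np.ndarray) -> np.ndarray:
        # means: genes x k permuted means
        var = (ss[:, None] - n * means**2) / (n - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = means / np.sqrt(var / n)
        t[np.isnan(t)] = 0.0  # all-zero rows
        return t

    t_obs = np.abs(t_from_means(d.mean(axis=1)[:, None]))[:, 0]

    if exact:
        if n > 20:
            raise InsufficientDataError("exact enumeration limited to n <= 20 pairs")
        signs = np.array(list(product((1.0, -1.0), repeat=n)))  # 2^n x n
        means = d @ signs.T / n
        t_star = np.abs(t_from_means(means))
        count = (t_star >= t_obs[:, None] - 1e-12).sum(axis=1)
        return count / signs.shape[0]

    if n_perm < 1:
        raise InsufficientDataError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    count = np.zeros(g, dtype=np.int64)
    chunk = max(1, min(n_perm, int(2e7 // max(g, 1))))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        signs = rng.choice((-1.0, 1.0), size=(n, k))
        means = d @ signs / n
        t_star = np.abs(t_from_means(means))
        count += (t_star >= t_obs[:, None] - 1e-12).sum(axis=1)
        done += k
    return (1 + count) / (1 + n_perm)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def geometric_mean_ratio(diffs: np.ndarray) -> tuple[float, tuple[float, float], bool]:
    """2^(mean d) with 95 % CI 2^(mean d +- t_{0.975, n-1} sd/sqrt(n)).

    Returns (ratio, (lo, hi), degenerate) for one gene's vector of log2
    within-pair differences; NaNs are excluded pairwise.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    n = d.size
    if n < 3:
        raise InsufficientDataError(f"geometric mean ratio needs >= 3 pairs, got {n}")
    mean = d.mean()
    sd = d.std(ddof=1)
    ratio = float(2.0**mean)
    if sd == 0:
        return ratio, (ratio, ratio), True
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return ratio, (float(2.0 ** (mean - half)), float(2.0 ** (mean + half))), False


def paired_diffexp_table(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    n_perm: int = 10_000,
    seed: int = DEFAULT_PERMUTATION_SEED,
    exact: bool = False,
) -> pd.DataFrame:
    """Full per-gene paired analysis.

    Columns: mean_log2_diff, t_stat, p_parametric, p_permutation, q_fdr,
    gm_ratio, gm_ci_low, gm_ci_high, signed_fc, n_pairs, degenerate.
    ``signed_fc`` follows the reporting convention where down-regulation is
    the negative reciprocal (ratio 0.5 -> -2.0).
    """
    d = difference_matrix(matrix, sheet)
    n = d.shape[1]
    if n < 3:
        raise InsufficientDataError(f"paired analysis needs >= 3 pairs, got {n}")
    arr = d.to_numpy()
    t, p_param, degenerate = _t_from_diffs(arr)
    p_perm = signflip_permutation(arr, n_perm=n_perm, seed=seed, exact=exact)
    q = bh_fdr(p_perm)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    ratio = 2.0**mean
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    lo = 2.0 ** (mean - half)
    hi = 2.0 ** (mean + half)
    signed = np.where(ratio >= 1, ratio, -1.0 / ratio)
    return pd.DataFrame(
        {
            "mean_log2_diff": mean,
            "t_stat": t,
            "p_parametric": p_param,
            "p_permutation": p_perm,
            "q_fdr": q,
            "gm_ratio": ratio,
            "gm_ci_low": lo,
            "gm_ci_high": hi,
            "signed_fc": signed,
            "n_pairs": n,
            "degenerate": degenerate,
        },
        index=d.index,
    )


def select_de(
    results: pd.DataFrame,
    fdr_max: float = 0.05,
    fc_min: float = 1.25,
    p_screen: float | None = None,
    fc_strict: bool = True,
) -> list[str]:
    """Genes passing the FDR + fold-change rule.

    Default rule: ``q_fdr <= fdr_max`` and ``max(ratio, 1/ratio) > fc_min``
    (the FDR bound is inclusive so a permissive ``fdr_max=1`` keeps every
    gene). With ``p_screen`` set, the screen uses ``p_parametric < p_screen``
    and a non-strict fold threshold (>=) instead, matching a p-value screen
    at a fixed fold cut.
    """
    fold = np.maximum(results["gm_ratio"], 1.0 / results["gm_ratio"])
    if p_screen is not None:
        mask = (results["p_parametric"] < p_screen) & (fold >= fc_min)
    else:
        fc_ok = fold > fc_min if fc_strict else fold >= fc_min
        mask = (results["q_fdr"] <= fdr_max) & fc_ok
    return list(results.index[mask])


def time_correlation(
    matrix: ExpressionMatrix, sheet: SampleSheet
) -> pd.DataFrame:
    """Per gene, Pearson r between within-pair log2 difference and elapsed
    minutes, with parametric p (t transform, n - 2 df) and BH q."""
    if not sheet.has_elapsed():
        raise InsufficientDataError(
            "elapsed_minutes missing for some pairs; time analysis needs a "
            "sheet with elapsed times recorded (study-I style)"
        )
    d = difference_matrix(matrix, sheet)
    minutes = sheet.pair_table().set_index("tumour_id")["elapsed_minutes"]
    minutes = minutes.loc[d.columns].to_numpy(dtype=float)
    n = minutes.size
    if n < 4:
        raise InsufficientDataError("time correlation needs >= 4 pairs")
    arr = d.to_numpy()
    mc = minutes - minutes.mean()
    dc = arr - arr.mean(axis=1, keepdims=True)
    denom = np.sqrt((dc**2).sum(axis=1) * (mc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (dc @ mc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(tstat), n - 2)
    p[np.isnan(r)] = np.nan
    p[np.abs(r) >= 1.0] = 0.0
    valid = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = bh_fdr(p[valid])
    return pd.DataFrame(
        {"r_time": r, "p": p, "q_adjusted": q, "n_pairs": n}, index=d.index
    )
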