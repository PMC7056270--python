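"""Differential statistics on copy numbers: Welch tests, fold changes,
regulation classes and overlap sets.

Testing is done per protein on log2-transformed copies per cell using the
two-tailed Welch (unequal-variance) t-test with Satterthwaite degrees of
freedom.  Zero copies have no log2 value: only detected (positive)
replicates enter a test, and a condition with fewer than two detected
replicates yields an undefined p-value (``NaN``), never a silent 0 or 1.
Fold changes are ratios of untransformed condition means (zeros included).

Regulation rules (raw p-values, no multiple-testing correction):

* activation ("TCR regulated"): naive-vs-activated p < 0.05, irrespective
  of fold change;
* genotype ("Myc/Slc7a5 regulated"): wild-type-vs-knockout fold change
  > 2 or < 0.5 with p < 0.05.

A Benjamini-Hochberg ``q_value`` column is emitted alongside for modern
reuse but is never consulted by these rules.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import samples_by_condition
from .ruler import CopyNumberResult

__all__ = [
    "welch_test",
    "log2_transform",
    "differential_table",
    "classify_regulation",
    "regulated_overlap",
    "volcano_table",
]

log = logging.getLogger(__name__)


def log2_transform(copies: float) -> float:
    """log2 of a copy number; NaN (undefined) for 0, error for negatives.

    A zero-copy replicate simply does not enter the t-test; the group's
    finite count drops by one.
    """
    if copies < 0:
        raise ValueError("copy numbers cannot be negative")
    return math.log2(copies) if copies > 0 else math.nan


def _welch_arrays(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch test on 2-D arrays with NaN for excluded values.

    Returns ``(t, df, p)`` per row with ``t = (mean_x - mean_y) / se``.
    Degenerate rows: <2 finite values in either group -> all NaN; zero
    pooled variance with equal means -> t=0, p=1; zero pooled variance with
    unequal means -> undefined (NaN) rather than a fabricated infinity.
    """
    nx = np.sum(np.isfinite(x), axis=1).astype(float)
    ny = np.sum(np.isfinite(y), axis=1).astype(float)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mx = np.nanmean(np.where(np.isfinite(x), x, np.nan), axis=1)
        my = np.nanmean(np.where(np.isfinite(y), y, np.nan), axis=1)
    vx = _nanvar1(x, nx, mx)
    vy = _nanvar1(y, ny, my)

    t = np.full(nx.shape, np.nan)
    df = np.full(nx.shape, np.nan)
    p = np.full(nx.shape, np.nan)
    ok = (nx >= 2) & (ny >= 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = vx / nx + vy / ny
        tied = ok & (se2 == 0) & (mx == my)
        t[tied], df[tied], p[tied] = 0.0, (nx + ny)[tied] - 2, 1.0
        good = ok & (se2 > 0)
        t[good] = (mx[good] - my[good]) / np.sqrt(se2[good])
        num = se2[good] ** 2
        den = (vx[good] / nx[good]) ** 2 / (nx[good] - 1) + (vy[good] / ny[good]) ** 2 / (ny[good] - 1)
        df[good] = num / den
        p[good] = 2.0 * stats.t.sf(np.abs(t[good]), df[good])
    return t, df, p


def _nanvar1(a: np.ndarray, n: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Sample variance (ddof=1) ignoring NaN; NaN where n < 2."""
    d = np.where(np.isfinite(a), a - m[:, None], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n >= 2, np.sum(d * d, axis=1) / np.maximum(n - 1, 1), np.nan)


def welch_test(x, y) -> tuple[float, float, float]:
    """Two-tailed Welch t-test between two replicate vectors.

    NaN entries are excluded.  Returns ``(t, df, p)`` with
    ``t = (mean(x) - mean(y)) / sqrt(var(x)/n_x + var(y)/n_y)`` and
    Satterthwaite degrees of freedom; each group needs at least two finite
    values, otherwise every output is NaN (undefined).
    """
    x = np.asarray(x, dtype=float).reshape(1, -1)
    y = np.asarray(y, dtype=float).reshape(1, -1)
    t, df, p = _welch_arrays(x, y)
    return float(t[0]), float(df[0]), float(p[0])


def differential_table(
    result: CopyNumberResult,
    condition_a: str,
    condition_b: str,
    design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-protein differential statistics for one contrast A vs B.

    Columns: ``group_id, gene_name, condition_a, condition_b, mean_a,
    mean_b, fold_change`` (= mean_b / mean_a, untransformed means),
    ``t_stat`` (positive when B is higher), ``df, p_value, q_value`` (BH
    over the defined p-values).
    """
    design = design if design is not None else result.design
    bycond = samples_by_condition(design)
    for cond in (condition_a, condition_b):
        if cond not in bycond:
            raise KeyError(f"condition {cond!r} not present in the design")
    xa = result.copies[bycond[condition_a]].to_numpy(dtype=float)
    xb = result.copies[bycond[condition_b]].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        la = np.where(xa > 0, np.log2(np.where(xa > 0, xa, 1.0)), np.nan)
        lb = np.where(xb > 0, np.log2(np.where(xb > 0, xb, 1.0)), np.nan)
    t, df, p = _welch_arrays(lb, la)  # positive t = up in B

    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_a > 0, mean_b / mean_a, np.inf)
        fc = np.where(mean_b == 0, np.where(mean_a > 0, 0.0, np.nan), fc)

    q = np.full_like(p, np.nan)
    defined = np.isfinite(p)
    if defined.any():
        q[defined] = multipletests(p[defined], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "group_id": result.group_ids,
            "gene_name": result.gene_name.to_numpy(),
            "condition_a": condition_a,
            "condition_b": condition_b,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "q_value": q,
        }
    ).reset_index(drop=True)


def classify_regulation(
    results: pd.DataFrame,
    rule: str,
    p_threshold: float = 0.05,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Attach regulation calls to a differential table.

    ``rule='activation'``: regulated iff p < ``p_threshold`` irrespective of
    fold change.  ``rule='genotype'``: regulated iff p < ``p_threshold`` and
    the fold change exceeds ``fold_threshold`` in either direction
    (FC > 2 or FC < 0.5 at the default).  Adds ``regulated`` (bool) and
    ``direction`` ('up'/'down' relative to condition A, '' when FC is 1 or
    undefined).  Idempotent and order-invariant: calls depend only on each
    row's (fold_change, p_value).
    """
    if rule not in ("activation", "genotype"):
        raise ValueError(f"unknown regulation rule {rule!r}")
    out = results.copy()
    p = out["p_value"].to_numpy(dtype=float)
    fc = out["fold_change"].to_numpy(dtype=float)
    sig = np.isfinite(p) & (p < p_threshold)
    if rule == "activation":
        out["regulated"] = sig
    else:
        with np.errstate(invalid="ignore"):
            big = (fc > fold_threshold) | (fc < 1.0 / fold_threshold)
        out["regulated"] = sig & big
    with np.errstate(invalid="ignore"):
        out["direction"] = np.where(fc > 1, "up", np.where(fc < 1, "down", ""))
    out.loc[~np.isfinite(fc), "direction"] = ""
    return out


def regulated_overlap(set_a, set_b) -> tuple[set, set, set]:
    """Partition two regulated-protein id sets into (only_A, shared, only_B)."""
    a, b = set(set_a), set(set_b)
    only_a, shared, only_b = a - b, a & b, b - a
    log.info("overlap: %d only A, %d shared, %d only B", len(only_a), len(shared), len(only_b))
    return only_a, shared, only_b


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot coordinates: log2 fold change vs -log10 p per protein.

    Rows with undefined p (or non-positive/non-finite fold change) are
    excluded; the excluded count is logged and available as
    ``df.attrs['n_excluded']``.
    """
    p = results["p_value"].to_numpy(dtype=float)
    fc = results["fold_change"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        keep = np.isfinite(p) & np.isfinite(fc) & (fc > 0)
    out = pd.DataFrame(
        {
            "group_id": results["group_id"].to_numpy()[keep],
            "log2_fold_change": np.log2(fc[keep]),
            "neg_log10_p": -np.log10(p[keep]),
        }
    )
    n_excluded = int((~keep).sum())
    out.attrs["n_excluded"] = n_excluded
    if n_excluded:
        log.info("volcano_table: excluded %d rows with undefined p or fold", n_excluded)
    return out
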