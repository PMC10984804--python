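"""Count normalization and gene filtering.

TMM (trimmed mean of M-values) scaling factors, log2CPM conversion, the
average-expression / protein-evidence gene filter, and the cross-dataset
candidate intersection.  Count matrices are gene x sample pandas DataFrames;
normalization factors are a pandas Series indexed by sample.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["tmm_factors", "log2cpm", "filter_genes", "intersect_candidates"]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Unscaled TMM factor of one sample against the reference sample.

    Doubly-trimmed (trim_m on log-ratios M, trim_a on average abundance A)
    weighted mean of M, with inverse approximate binomial variances as
    weights, over genes expressed in both samples.
    """
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise ValueError("no gene is expressed in both the sample and the reference")
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # approximate binomial variance of M; weights are its inverse
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    n = m.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    # rank-based double trim; average ranks keep ties symmetric
    from scipy.stats import rankdata

    rm, ra = rankdata(m), rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose upper-quartile / library-size ratio
    is closest to the mean of that ratio over samples.

    Parameters
    ----------
    counts
        Gene x sample non-negative integer counts.
    trim_m, trim_a
        Two-sided trim fractions applied to the log-ratio (M) and average
        log-abundance (A) distributions.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero library size: {list(zero.index)}")

    mat = counts.to_numpy(dtype=float)
    f75 = np.quantile(mat, 0.75, axis=0) / lib.to_numpy()
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = mat[:, ref_idx]
    lib_ref = float(lib.iloc[ref_idx])

    raw = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        raw[j] = _tmm_pair(mat[:, j], ref, float(lib.iloc[j]), lib_ref, trim_m, trim_a)
    factors = raw / np.exp(np.mean(np.log(raw)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log2cpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes.

    value = log2((count + prior_count) / (libsize * factor) * 1e6).  With
    ``factors=None`` all factors are 1 (plain CPM).
    """
    lib = counts.sum(axis=0).astype(float)
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    missing = [s for s in counts.columns if s not in factors.index]
    if missing:
        raise ValueError(f"missing normalization factors for samples: {missing}")
    eff = lib * factors.reindex(counts.columns)
    vals = np.log2((counts.to_numpy(dtype=float) + prior_count) / eff.to_numpy() * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def filter_genes(
    expr: pd.DataFrame,
    min_avg_log2cpm: float = 4.0,
    protein_evidence: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Keep genes with row-mean log2CPM >= threshold and (optionally) protein evidence.

    Gene order is preserved.  Raises if nothing survives, reporting how many
    genes each filter removed.
    """
    if not np.isfinite(min_avg_log2cpm):
        raise ValueError("min_avg_log2cpm must be finite")
    mean_ok = expr.mean(axis=1) >= min_avg_log2cpm
    if protein_evidence is not None:
        evidence = set(protein_evidence)
        prot_ok = expr.index.to_series().isin(evidence)
    else:
        prot_ok = pd.Series(True, index=expr.index)
    keep = mean_ok & prot_ok
    if not keep.any():
        raise ValueError(
            "no gene passed filtering "
            f"(low expression removed {int((~mean_ok).sum())}, "
            f"no protein evidence removed {int((~prot_ok).sum())})"
        )
    return expr.loc[keep]


def intersect_candidates(matrices: Sequence[pd.DataFrame]) -> list[str]:
    """Genes present in every (already filtered) expression matrix.

    Returned in the gene order of the first matrix.  Raises on an empty
    intersection.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices to intersect")
    common = set(matrices[0].index)
    for m in matrices[1:]:
        common &= set(m.index)
    if not common:
        raise ValueError("candidate gene intersection is empty")
    return [g for g in matrices[0].index if g in common]
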