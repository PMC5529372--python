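"""Replicate-free differential abundance over the time course.

An MA-plot z-test under a random-sampling (binomial) null: for two libraries
with totals ``n1``/``n2`` and one strand's counts ``k1``/``k2``, the log2
proportion difference M is tested with a per-observation binomial variance
approximation.  Labeled "MARS-style" in outputs: a closed-form analog, not a
re-implementation of DEGSeq's smoothed estimator.  Results from a design
without biological replicates carry a warning banner.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .sorting import benjamini_hochberg

logger = logging.getLogger(__name__)

NO_REPLICATES_WARNING = (
    "WARNING: single-library comparisons without biological replicates; "
    "p-values reflect sampling noise only, not biological variability."
)

LN2_SQ = math.log(2.0) ** 2


def mars_test(k1, n1, k2, n2, pseudo: float = 0.5, weighted: bool = False):
    """MA z-test of one strand's proportion between two libraries.

    Returns ``(M, A, z, p)``.  ``M = log2(p1) - log2(p2)`` with the pseudo-count
    applied only to zero counts, ``A`` the mean log2 proportion, and
    ``z = M / sqrt(VarM)`` with ``VarM = (1/ln^2 2) * [(1-p1)/k1 + (1-p2)/k2]``
    under the equal-proportion binomial null; p is the two-sided normal tail.

    Scalar or array inputs; non-integer counts are rejected unless
    ``weighted=True``.
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("library totals must be positive")
    if np.any(k1 < 0) or np.any(k2 < 0):
        raise ValueError("counts must be non-negative")
    if not weighted and (np.any(k1 != np.round(k1)) or np.any(k2 != np.round(k2))):
        raise ValueError("non-integer counts; pass weighted=True for weighted counts")

    a1 = np.where(k1 == 0, pseudo, k1)
    a2 = np.where(k2 == 0, pseudo, k2)
    p1 = a1 / n1
    p2 = a2 / n2
    M = np.log2(p1) - np.log2(p2)
    A = 0.5 * (np.log2(p1) + np.log2(p2))
    var = ((1.0 - p1) / a1 + (1.0 - p2) / a2) / LN2_SQ
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, M / np.sqrt(var), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    if M.ndim == 0:
        return float(M), float(A), float(z), float(p)
    return M, A, z, p


@dataclass
class DEResult:
    strand_id: str
    pool: str
    time_h: int
    M: float
    A: float
    z: float
    p: float
    q: float
    flag4x: str  # 'up', 'down', 'none'


def de_table(raw: pd.DataFrame, design: pd.DataFrame, alpha: float = 0.01,
             fold_cut: float = 4.0, baseline_time: int = 0) -> pd.DataFrame:
    """Per-pool, per-strand MARS-style tests of every post-baseline time point
    against the baseline library.

    ``design`` maps library_id -> (pool, time_h).  BH q-values are computed
    across strands within each (pool, time) comparison.  A strand is flagged
    when |M| >= log2(fold_cut) and q <= alpha; the raw >=fold_cut flag is also
    emitted (``flag4x_raw``).
    """
    logger.warning(NO_REPLICATES_WARNING)
    if not {"pool", "time_h"} <= set(design.columns):
        raise ValueError("design needs 'pool' and 'time_h' columns")
    m_cut = math.log2(fold_cut)
    frames = []
    for pool, sub in design.groupby("pool"):
        base_libs = sub.index[sub["time_h"] == baseline_time]
        if len(base_libs) == 0:
            raise ValueError(f"pool {pool!r}: no baseline library at {baseline_time} h")
        base = base_libs[0]
        n_base = float(raw[base].sum())
        k_base = raw[base].to_numpy(dtype=float)
        for lib in sub.index:
            t = int(sub.loc[lib, "time_h"])
            if t == baseline_time:
                continue
            n_t = float(raw[lib].sum())
            k_t = raw[lib].to_numpy(dtype=float)
            M, A, z, p = mars_test(np.round(k_t), n_t, np.round(k_base), n_base)
            q = benjamini_hochberg(p)
            frames.append(pd.DataFrame({
                "strand_id": raw.index, "pool": pool, "time_h": t,
                "M": M, "A": A, "z": z, "p": p, "q": q,
            }))
    df = pd.concat(frames, ignore_index=True)
    sig = (df["M"].abs() >= m_cut) & (df["q"] <= alpha)
    df["flag4x"] = np.where(sig & (df["M"] > 0), "up",
                            np.where(sig & (df["M"] < 0), "down", "none"))
    raw_flag = df["M"].abs() >= m_cut
    df["flag4x_raw"] = np.where(raw_flag & (df["M"] > 0), "up",
                                np.where(raw_flag & (df["M"] < 0), "down", "none"))
    return df


def log2fc_matrix(de: pd.DataFrame, pool: str) -> pd.DataFrame:
    """Strand x time matrix of M values for one pool."""
    sub = de[de["pool"] == pool]
    return sub.pivot(index="strand_id", columns="time_h", values="M")


def cluster_profiles(log2fc: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Agglomerative clustering (Euclidean, complete linkage) of per-strand
    log2 fold-change profiles; returns labels and dendrogram leaf order."""
    if len(log2fc) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    X = log2fc.fillna(0.0).to_numpy()
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    order = hierarchy.leaves_list(Z)
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(len(order))
    return pd.DataFrame({"cluster": labels, "leaf_order": rank}, index=log2fc.index)


def null_rejection_rate(n_sims: int, count: int, total: int, alpha: float = 0.05,
                        seed: int = 0) -> float:
    """Monte-Carlo type-I error of :func:`mars_test` under the binomial null."""
    rng = np.random.default_rng(seed)
    p_true = count / total
    k1 = rng.binomial(total, p_true, size=n_sims)
    k2 = rng.binomial(total, p_true, size=n_sims)
    _, _, _, p = mars_test(k1, total, k2, total)
    return float(np.mean(p < alpha))


def power_at_fold(n_sims: int, count: int, total: int, fold: float,
                  alpha: float = 0.05, seed: int = 0) -> float:
    """Monte-Carlo power for a true proportion ratio of ``fold``."""
    rng = np.random.default_rng(seed)
    p_base = count / total
    k1 = rng.binomial(total, min(p_base * fold, 1.0), size=n_sims)
    k2 = rng.binomial(total, p_base, size=n_sims)
    _, _, _, p = mars_test(k1, total, k2, total)
    return float(np.mean(p < alpha))
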