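"""Monoallelic / biallelic classification of allele count tables.

A feature (V segment, ATAC peak, promoter) is called monoallelic when an
FDR-corrected exact binomial test against the balanced null (proportion 0.5)
gives q < alpha AND the higher allele has at least ``fold_min`` (default 2)
times the reads of the lower allele; features under a minimum depth are
"insufficient".  For replicated libraries a feature is monoallelic only when
every replicate independently satisfies the full rule on the same allele
(the replicate-consistency criterion used for ATAC peaks); pooled statistics
are reported for the record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CATEGORIES = ("mono_b6", "mono_cast", "biallelic", "insufficient")


@dataclass(frozen=True)
class MonoallelicCall:
    feature_id: str
    category: str
    p_value: float
    q_value: float
    fold: float
    depth: int
    ratio: float


def binomial_p(b6: int, cast: int) -> float:
    """Two-sided exact binomial p-value under the balanced (0.5) null.

    Point-mass-inclusive tail doubling, capped at 1: twice the probability of
    an allele split at least as extreme as observed.  Symmetric in its
    arguments.  Under the symmetric null this equals the minimum-likelihood
    two-sided convention.
    """
    if b6 < 0 or cast < 0:
        raise ValueError("allele counts must be nonnegative")
    n = b6 + cast
    if n == 0:
        raise ValueError("zero total depth: no test possible")
    k = min(b6, cast)
    return float(min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5)))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (same order as input)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_feature(
    b6: int,
    cast: int,
    q: float,
    alpha: float = 0.05,
    fold_min: float = 2.0,
    min_depth: int = 20,
) -> str:
    """Classify one feature given its FDR-adjusted q-value.

    ``insufficient`` below ``min_depth``; ``mono_b6`` when q < alpha and
    b6 >= fold_min * cast; ``mono_cast`` symmetrically; otherwise
    ``biallelic``.
    """
    if b6 + cast < min_depth:
        return "insufficient"
    if q < alpha:
        if b6 >= fold_min * cast:
            return "mono_b6"
        if cast >= fold_min * b6:
            return "mono_cast"
    return "biallelic"


def _fold(b6: float, cast: float) -> float:
    hi, lo = max(b6, cast), min(b6, cast)
    if lo == 0:
        return float("inf") if hi > 0 else 1.0
    return hi / lo


def call_table(
    table: pd.DataFrame,
    alpha: float = 0.05,
    fold_min: float = 2.0,
    min_depth: int = 20,
) -> pd.DataFrame:
    """Call every feature of a single-sample count table (columns feature_id, b6, cast).

    The binomial test is computed for every feature with nonzero depth and BH
    correction is applied across that family before the significance + fold
    rule; features below ``min_depth`` are reported as insufficient.
    """
    t = table.reset_index(drop=True)
    b6 = t["b6"].to_numpy(dtype=int)
    cast = t["cast"].to_numpy(dtype=int)
    depth = b6 + cast
    p = np.full(len(t), np.nan)
    testable = depth > 0
    p[testable] = [binomial_p(int(x), int(y)) for x, y in zip(b6[testable], cast[testable])]
    q = np.full(len(t), np.nan)
    if testable.any():
        q[testable] = bh_fdr(p[testable])
    cats = [
        "insufficient"
        if depth[i] < min_depth
        else call_feature(int(b6[i]), int(cast[i]), float(q[i]), alpha, fold_min, min_depth)
        for i in range(len(t))
    ]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(depth > 0, b6 / np.where(depth > 0, depth, 1), np.nan)
    return pd.DataFrame(
        {
            "feature_id": t["feature_id"],
            "category": cats,
            "p": p,
            "q": q,
            "fold": [_fold(x, y) for x, y in zip(b6, cast)],
            "depth": depth,
            "ratio": ratio,
        }
    )


def call_with_replicates(
    tables: list[pd.DataFrame],
    alpha: float = 0.05,
    fold_min: float = 2.0,
    min_depth: int = 20,
) -> pd.DataFrame:
    """Replicate-consistent monoallelic calls over >=2 biological replicates.

    Each replicate table (columns feature_id, b6, cast; identical feature
    sets) is called independently, with BH correction within the replicate.  A
    feature is mono on an allele only when every replicate calls it mono on
    that same allele; it is insufficient when any replicate is under depth;
    otherwise biallelic.  The reported p/q/fold/ratio come from the pooled
    (summed) counts for the record.
    """
    if len(tables) < 1:
        raise ValueError("need at least one replicate table")
    feats = list(tables[0]["feature_id"])
    for t in tables[1:]:
        if list(t["feature_id"]) != feats:
            raise ValueError("replicate tables must share an identical feature set and order")
    per_rep = [call_table(t, alpha, fold_min, min_depth) for t in tables]
    pooled = tables[0][["feature_id"]].copy()
    pooled["b6"] = sum(t["b6"].to_numpy(dtype=int) for t in tables)
    pooled["cast"] = sum(t["cast"].to_numpy(dtype=int) for t in tables)
    pooled_calls = call_table(pooled, alpha, fold_min, min_depth)
    cats = []
    for i in range(len(feats)):
        rep_cats = [c["category"].iat[i] for c in per_rep]
        if any(c == "insufficient" for c in rep_cats):
            cats.append("insufficient")
        elif all(c == "mono_b6" for c in rep_cats):
            cats.append("mono_b6")
        elif all(c == "mono_cast" for c in rep_cats):
            cats.append("mono_cast")
        else:
            cats.append("biallelic")
    out = pooled_calls.copy()
    out["category"] = cats
    return out


def split_by_sample(table: pd.DataFrame) -> list[pd.DataFrame]:
    """Split a long count table (feature_id, sample, b6, cast) into per-sample
    tables with a common feature order — the shape call_with_replicates expects."""
    order = table["feature_id"].drop_duplicates().tolist()
    out = []
    for _, grp in table.groupby("sample", sort=True):
        g = grp.set_index("feature_id").reindex(order).reset_index()
        if g[["b6", "cast"]].isna().any().any():
            raise ValueError("replicate tables must share an identical feature set")
        g[["b6", "cast"]] = g[["b6", "cast"]].astype(int)
        out.append(g[["feature_id", "b6", "cast"]])
    return out
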