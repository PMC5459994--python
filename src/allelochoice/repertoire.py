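"""Igkappa rearrangement-repertoire quantification and coupling to ncRNA.

Rearranged-fragment counts per V segment are normalised to the total mapped
rearranged fragments of the library (percent contribution), per-V allelic
ratios of rearrangement are computed with the same conventions as the
expression pipeline, repertoire skew toward one allele is summarised, the
repertoire allelic ratio is correlated with the pre-rearrangement ncRNA
allelic ratio (the transcription-instructs-rearrangement readout), and
early/late allele usage is profiled over an induction time course.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .allelic_assignment import allelic_ratio


def normalize_repertoire(counts: pd.DataFrame) -> pd.DataFrame:
    """Percent contribution of each V segment to the rearrangement repertoire.

    ``counts`` has columns ``v_id, allele, count``.  Two views are added:
    ``percent_library`` (count over the total mapped rearranged fragments of
    the whole library) and ``percent`` (within-allele normalisation; the
    per-allele repertoires sum to 100 each).  Raw counts are retained.
    """
    t = counts.copy()
    if (t["count"] < 0).any():
        raise ValueError("rearrangement counts must be nonnegative")
    total = t["count"].sum()
    if total <= 0:
        raise ValueError("library has no mapped rearranged fragments")
    t["percent_library"] = 100.0 * t["count"] / total
    allele_tot = t.groupby("allele")["count"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        t["percent"] = np.where(allele_tot > 0, 100.0 * t["count"] / allele_tot, 0.0)
    return t


def rearrangement_allelic_ratio(table: pd.DataFrame, min_depth: int = 20) -> pd.Series:
    """Per-V B6 fraction of rearranged reads, B6/(B6+Cast), NaN below ``min_depth``.

    Same ratio and missing-data conventions as the expression pipeline so the
    two readouts are directly comparable.
    """
    wide = table.pivot_table(index="v_id", columns="allele", values="count", aggfunc="sum").fillna(0)
    b6 = wide.get("B6", pd.Series(0, index=wide.index)).astype(float)
    cast = wide.get("Cast", pd.Series(0, index=wide.index)).astype(float)
    return pd.Series(
        [allelic_ratio(int(x), int(y), min_depth=min_depth) for x, y in zip(b6, cast)],
        index=wide.index,
        name="ratio",
    )


def ncrna_repertoire_correlation(
    ncrna_ratios: pd.Series, rearr_ratios: pd.Series
) -> tuple[float, float, int]:
    """Pearson correlation between ncRNA and rearrangement allelic ratios.

    Computed over the V segments with a non-missing ratio in both readouts;
    needs at least 3 shared points.  Returns (r, two-sided p, n).
    """
    shared = ncrna_ratios.index.intersection(rearr_ratios.index)
    a = ncrna_ratios.loc[shared].astype(float)
    b = rearr_ratios.loc[shared].astype(float)
    keep = a.notna() & b.notna()
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need at least 3 shared V segments with allelic resolution")
    r, p = stats.pearsonr(a.to_numpy(), b.to_numpy())
    return float(r), float(p), int(len(a))


def skew_fraction(ratios, threshold: float = 0.8) -> float:
    """Fraction of V segments skewed toward one allele (ratio > threshold or
    < 1-threshold), over the non-missing ratios."""
    r = pd.Series(ratios).dropna().to_numpy(dtype=float)
    if r.size == 0:
        raise ValueError("no ratios with allelic resolution")
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0.5, 1]")
    return float(np.mean((r > threshold) | (r < 1.0 - threshold)))


def kinetics_summary(
    time_course: Mapping[float, pd.DataFrame], early_allele: str = "B6"
) -> pd.Series:
    """Early-allele share of rearrangement events per induction timepoint.

    ``time_course`` maps hours to repertoire tables (v_id, allele, count);
    the value per timepoint is the fraction of all rearranged reads on the
    early-replicating allele.  On data generated with increasing elapsed-time
    mixing, this sequence is non-increasing.
    """
    if len(time_course) < 2:
        raise ValueError("a time course needs at least two timepoints")
    if early_allele not in {"B6", "Cast"}:
        raise ValueError("early_allele must be 'B6' or 'Cast'")
    out = {}
    for hours in sorted(time_course):
        table = time_course[hours]
        if set(table["allele"].unique()) - {"B6", "Cast"}:
            raise ValueError("allele column must contain only B6/Cast")
        by_allele = table.groupby("allele")["count"].sum()
        for allele in ("B6", "Cast"):
            if allele not in by_allele.index:
                by_allele[allele] = 0
        total = by_allele.sum()
        if total == 0:
            raise ValueError(f"timepoint {hours}: no rearrangement events")
        out[float(hours)] = float(by_allele[early_allele] / total)
    return pd.Series(out, name="early_allele_fraction").sort_index()
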