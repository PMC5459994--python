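"""Stochastic model of per-allele V-segment activation.

In an F1 hybrid pre-B-cell clone each V segment that has the *potential* to be
activated turns on independently on the B6 allele with probability ``p_b6`` and
on the Cast allele with probability ``p_cast``.  Segments outside the potential
set stay silent on both alleles.  A segment in a clone therefore falls into one
of four categories — silent, mono-B6, mono-Cast or biallelic — with product
probabilities, and the fraction of all functional segments active on at least
one allele has a closed form.  This module provides the analytic category
distribution, the expected activated fraction, closed-form maximum-likelihood
estimation of the per-allele probabilities from observed category counts, and a
chi-square goodness-of-fit test of observed counts against the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("silent", "mono_b6", "mono_cast", "biallelic")


@dataclass(frozen=True)
class ActivationModelParams:
    """Per-allele activation probabilities and segment counts.

    Parameters
    ----------
    p_b6, p_cast:
        Probability that a potential segment is activated on the B6 / Cast
        allele.  The two alleles behave as independent substrates.
    n_potential:
        Number of functional segments with the potential to be activated
        (shared by all clones of a locus).
    n_total:
        Total number of functional segments in the locus.
    """

    p_b6: float
    p_cast: float
    n_potential: int = 60
    n_total: int = 96

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_b6 <= 1.0 and 0.0 <= self.p_cast <= 1.0):
            raise ValueError("activation probabilities must lie in [0, 1]")
        if not (0 <= self.n_potential <= self.n_total):
            raise ValueError("need 0 <= n_potential <= n_total")


@dataclass(frozen=True)
class CategoryCounts:
    """Observed per-clone counts of segments in each activation category."""

    silent: int
    mono_b6: int
    mono_cast: int
    biallelic: int

    def __post_init__(self) -> None:
        for name in CATEGORIES:
            if getattr(self, name) < 0:
                raise ValueError("category counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.silent + self.mono_b6 + self.mono_cast + self.biallelic

    @property
    def n_active(self) -> int:
        return self.mono_b6 + self.mono_cast + self.biallelic

    def as_array(self) -> np.ndarray:
        return np.array([self.silent, self.mono_b6, self.mono_cast, self.biallelic])


def category_probs(params: ActivationModelParams) -> pd.DataFrame:
    """Category probabilities for a potential segment and marginally over all segments.

    Returns a DataFrame indexed by category with two columns:

    ``potential``
        Distribution for a segment inside the potential set:
        biallelic = p_b6*p_cast, mono_b6 = p_b6*(1-p_cast),
        mono_cast = (1-p_b6)*p_cast, silent = (1-p_b6)*(1-p_cast).
    ``marginal``
        Distribution for a segment drawn uniformly from all n_total functional
        segments; the three active categories are scaled by
        n_potential/n_total and the remainder is silent.

    Both columns sum to exactly 1.
    """
    pb, pc = params.p_b6, params.p_cast
    potential = pd.Series(
        {
            "silent": (1 - pb) * (1 - pc),
            "mono_b6": pb * (1 - pc),
            "mono_cast": (1 - pb) * pc,
            "biallelic": pb * pc,
        }
    )
    frac = params.n_potential / params.n_total if params.n_total else 0.0
    marginal = potential * frac
    marginal["silent"] = 1.0 - (marginal["mono_b6"] + marginal["mono_cast"] + marginal["biallelic"])
    out = pd.DataFrame({"potential": potential, "marginal": marginal})
    return out.reindex(list(CATEGORIES))


def expected_active_fraction(params: ActivationModelParams) -> float:
    """Expected fraction of all functional segments active on >=1 allele.

    Closed form ``(1 - (1-p_b6)(1-p_cast)) * n_potential/n_total``.
    """
    p_active = 1.0 - (1.0 - params.p_b6) * (1.0 - params.p_cast)
    return p_active * params.n_potential / params.n_total


@dataclass(frozen=True)
class ParamEstimate:
    """MLE of per-allele activation probabilities with binomial standard errors."""

    params: ActivationModelParams
    se_b6: float
    se_cast: float
    loglik: float


def _multinomial_loglik(counts: np.ndarray, probs: np.ndarray) -> float:
    mask = counts > 0
    if np.any(probs[mask] <= 0):
        return -math.inf
    return float(np.sum(counts[mask] * np.log(probs[mask])))


def estimate_params(
    counts: CategoryCounts,
    n_potential: int | None = 60,
    n_total: int | None = None,
) -> ParamEstimate:
    """Estimate per-allele activation probabilities from one clone's category tally.

    With ``n_potential`` known (the default assumption), ``counts`` must be
    tallied over the potential segments only and the MLE is closed form:
    ``p_b6 = (mono_b6 + biallelic) / n_potential`` and symmetrically for Cast,
    each with a binomial standard error.

    With ``n_potential=None`` the counts are interpreted as a tally over all
    ``n_total`` functional segments and the potential-set size is profiled over
    the grid ``n_active..n_total``, maximising the marginal multinomial
    likelihood at plug-in probability estimates for each candidate size.
    """
    if n_potential is None:
        # counts tallied over ALL n_total segments; profile the potential-set
        # size k on a grid, scoring each k by the marginal multinomial
        # likelihood at the plug-in estimates p = (mono + biallelic)/k.  The
        # size is identified through the biallelic/mono split (the biallelic
        # marginal probability scales as 1/k at fixed active-allele marginals).
        if n_total is None:
            n_total = counts.total
        if counts.total != n_total:
            raise ValueError("profile estimation needs counts over all n_total segments")
        obs = counts.as_array()
        best: ParamEstimate | None = None
        k_min = max(counts.mono_b6 + counts.biallelic, counts.mono_cast + counts.biallelic, 1)
        for k in range(k_min, n_total + 1):
            p_b6 = (counts.mono_b6 + counts.biallelic) / k
            p_cast = (counts.mono_cast + counts.biallelic) / k
            params = ActivationModelParams(p_b6, p_cast, k, n_total)
            ll = _multinomial_loglik(obs, category_probs(params)["marginal"].to_numpy())
            est = ParamEstimate(
                params=params,
                se_b6=math.sqrt(p_b6 * (1 - p_b6) / k),
                se_cast=math.sqrt(p_cast * (1 - p_cast) / k),
                loglik=ll,
            )
            if best is None or ll > best.loglik:
                best = est
        if best is None:
            raise ValueError("no feasible potential-set size on the grid")
        return best

    if counts.n_active > n_potential:
        raise ValueError("active segment count exceeds n_potential")
    if counts.total != n_potential:
        raise ValueError(
            "counts must be tallied over exactly the n_potential potential segments"
        )
    n = n_potential
    p_b6 = (counts.mono_b6 + counts.biallelic) / n
    p_cast = (counts.mono_cast + counts.biallelic) / n
    params = ActivationModelParams(
        p_b6=p_b6,
        p_cast=p_cast,
        n_potential=n,
        n_total=n_total if n_total is not None else n,
    )
    probs = category_probs(params)["potential"].to_numpy()
    return ParamEstimate(
        params=params,
        se_b6=math.sqrt(p_b6 * (1 - p_b6) / n),
        se_cast=math.sqrt(p_cast * (1 - p_cast) / n),
        loglik=_multinomial_loglik(counts.as_array(), probs),
    )


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    p_value: float
    method: str  # "chi-square" or "exact-multinomial" or "monte-carlo"


def _chi_square_stat(observed: np.ndarray, expected: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (observed - expected) ** 2 / expected
    terms = np.where((expected == 0) & (observed == 0), 0.0, terms)
    if np.any((expected == 0) & (observed > 0)):
        return math.inf
    return float(np.sum(terms))


def goodness_of_fit(
    observed: CategoryCounts,
    params: ActivationModelParams,
    n_fitted: int = 0,
    rng: np.random.Generator | None = None,
) -> GofResult:
    """Pearson chi-square test of observed category counts against the model.

    Expected counts are ``category_probs(params).potential * observed.total``;
    ``df = 3 - n_fitted`` (categories minus one minus fitted parameters).  When
    any expected count falls below 1 the chi-square approximation is unreliable
    and an exact multinomial tail probability is computed instead by
    enumerating all outcomes (Monte-Carlo above total 200).
    """
    n = observed.total
    if n == 0:
        raise ValueError("no segments tallied")
    probs = category_probs(params)["potential"].to_numpy()
    expected = probs * n
    obs = observed.as_array()
    stat = _chi_square_stat(obs, expected)
    df = max(len(CATEGORIES) - 1 - n_fitted, 1)

    if np.all(expected >= 1.0) and math.isfinite(stat):
        p = float(stats.chi2.sf(stat, df))
        return GofResult(statistic=stat, df=df, p_value=min(max(p, 0.0), 1.0), method="chi-square")

    # exact multinomial tail: P(chi2(X) >= chi2(obs)) under the model
    if n <= 200:
        grid = np.array(
            [
                (a, b, c, n - a - b - c)
                for a in range(n + 1)
                for b in range(n + 1 - a)
                for c in range(n + 1 - a - b)
            ],
            dtype=float,
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = (grid - expected) ** 2 / expected
        terms = np.where(expected == 0, np.where(grid > 0, np.inf, 0.0), terms)
        stats_all = terms.sum(axis=1)
        from scipy.special import gammaln

        logp = np.where(probs > 0, np.log(np.maximum(probs, 1e-300)), -np.inf)
        # outcomes placing mass on a zero-probability category have pmf 0
        valid = ~np.any((grid > 0) & (probs == 0), axis=1)
        with np.errstate(invalid="ignore"):
            logpmf = (
                gammaln(n + 1)
                - gammaln(grid + 1).sum(axis=1)
                + np.where(grid > 0, grid * logp, 0.0).sum(axis=1)
            )
        pmf = np.where(valid, np.exp(logpmf), 0.0)
        p = float(pmf[stats_all >= stat - 1e-12].sum())
        return GofResult(statistic=stat, df=df, p_value=min(p, 1.0), method="exact-multinomial")

    rng = np.random.default_rng(0) if rng is None else rng
    draws = rng.multinomial(n, probs, size=10_000)
    stats_mc = np.array([_chi_square_stat(x, expected) for x in draws])
    p = float(np.mean(stats_mc >= stat - 1e-12))
    return GofResult(statistic=stat, df=df, p_value=p, method="monte-carlo")


def categories_from_calls(
    calls: pd.DataFrame,
    n_potential: int,
    category_column: str = "category",
) -> CategoryCounts:
    """Tally activation categories over the potential set from monoallelic calls.

    A segment-allele is operationally "active" when the caller classified the
    segment as mono on that allele or biallelic; segments classified
    insufficient (depth below threshold, i.e. leak-level signal only) count as
    silent.  ``silent`` is completed to ``n_potential`` so the tally covers the
    assumed potential set.
    """
    vc = calls[category_column].value_counts()
    mb = int(vc.get("mono_b6", 0))
    mc = int(vc.get("mono_cast", 0))
    bi = int(vc.get("biallelic", 0))
    if mb + mc + bi > n_potential:
        raise ValueError("more active segments than the assumed potential-set size")
    return CategoryCounts(
        silent=n_potential - mb - mc - bi, mono_b6=mb, mono_cast=mc, biallelic=bi
    )
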