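"""Significance machinery: exact binomial tests per codon, step-up FDR
adjustment across all tested codons, intolerant-region calling, and the
validation statistics (rank-sum comparison, low-score enrichment).

The per-codon null model: within a window, the number of observed missense
variants ``x`` among ``n = mis_obs + syn_obs`` observed variants is binomial
with success probability ``p = mis_exp / (mis_exp + syn_exp)``.  The reported
p-value is two-sided by the minimum-likelihood convention (all outcomes no
more probable than the observed one); region calling additionally requires a
depleted score (< 1), so only the missense-depleted direction yields
intolerant regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sp_stats
from scipy.special import gammaln

from .core import MTRProfile
from .errors import InvalidParameterError

#: relative slack when comparing pmf values in the minimum-likelihood tail
_TAIL_RELTOL = 1e-7

DEFAULT_FDR_THRESHOLD = 0.1


@dataclass(slots=True)
class BinomialTest:
    """One per-codon exact test: x successes in n trials under null prob p."""

    n: int
    x: int
    p: float

    @property
    def q(self) -> float:
        return 1.0 - self.p

    def pvalue(self) -> float:
        return binom_exact_test(self.x, self.n, self.p)


def _log_pmf_all(n: int, p: float) -> np.ndarray:
    """log pmf over x = 0..n, computed in log-space (stable to n >= 1e4)."""
    k = np.arange(n + 1)
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )


def binom_pmf(n: int, x: int, p: float) -> float:
    """Exact binomial probability mass P(X = x | n, p)."""
    if n < 0 or not 0 <= x <= n:
        raise InvalidParameterError(f"require 0 <= x <= n, got x={x}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError(f"p={p} outside [0, 1]")
    if p == 0.0:
        return 1.0 if x == 0 else 0.0
    if p == 1.0:
        return 1.0 if x == n else 0.0
    lp = (
        gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
        + x * np.log(p) + (n - x) * np.log1p(-p)
    )
    return float(np.exp(lp))


def binom_exact_test(x: int, n: int, p: float) -> float:
    """Two-sided exact binomial p-value, minimum-likelihood tail.

    Sums the pmf over every outcome whose probability does not exceed that of
    the observed outcome (within a tiny relative slack to absorb round-off).
    ``n = 0`` returns 1 (no data).
    """
    if n < 0 or not 0 <= x <= n:
        raise InvalidParameterError(f"require 0 <= x <= n, got x={x}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError(f"p={p} outside [0, 1]")
    if n == 0:
        return 1.0
    if p == 0.0:
        return 1.0 if x == 0 else 0.0
    if p == 1.0:
        return 1.0 if x == n else 0.0
    pmf = np.exp(_log_pmf_all(n, p))
    tail = pmf[pmf <= pmf[x] * (1.0 + _TAIL_RELTOL)].sum()
    return float(min(1.0, tail))


@lru_cache(maxsize=500_000)
def _cached_exact_test(x: int, n: int, p: float) -> float:
    return binom_exact_test(x, n, p)


def bh_adjust(raw_p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values.

    NaN entries are excluded from the ranking (their q stays NaN); ``m`` is
    the number of non-NaN tests.  Output satisfies q >= p, q <= 1, and is
    monotone in p.
    """
    p = np.asarray(raw_p, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[mask] = out
    return q


def test_profile(profile: MTRProfile) -> MTRProfile:
    """Fill ``raw_p`` per codon from that codon's window tallies (in place).

    Codons whose window has no observed variants keep raw_p = NaN.
    """
    L = profile.n_codons
    raw = np.full(L, np.nan)
    n_arr = profile.mis_obs + profile.syn_obs
    n_exp = profile.mis_exp + profile.syn_exp
    for k in range(L):
        n = int(n_arr[k])
        if n == 0:
            continue
        p_null = float(profile.mis_exp[k] / n_exp[k])
        raw[k] = _cached_exact_test(int(profile.mis_obs[k]), n, p_null)
    profile.raw_p = raw
    return profile


def apply_fdr(
    profiles: Sequence[MTRProfile],
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    scope: str = "joint",
) -> None:
    """Fill ``fdr_q`` and ``significant`` across a set of tested profiles.

    ``scope='joint'`` ranks every non-NaN codon test of every profile in one
    family (exome-wide semantics); ``scope='per_transcript'`` adjusts each
    profile separately.  ``significant`` requires both q below threshold and
    a depleted score (< 1).
    """
    if not 0.0 < fdr_threshold < 1.0:
        raise InvalidParameterError(f"fdr_threshold {fdr_threshold} outside (0,1)")
    if scope == "per_transcript":
        groups = [[p] for p in profiles]
    elif scope == "joint":
        groups = [list(profiles)]
    else:
        raise InvalidParameterError(f"unknown FDR scope {scope!r}")
    for group in groups:
        if not group:
            continue
        joined = np.concatenate([p.raw_p for p in group])
        q = bh_adjust(joined)
        off = 0
        for p in group:
            p.fdr_q = q[off : off + p.n_codons]
            with np.errstate(invalid="ignore"):
                p.significant = (p.fdr_q < fdr_threshold) & (p.mtr < 1.0)
            off += p.n_codons


@dataclass(slots=True)
class IntolerantRegion:
    """A maximal run of consecutive significant, missense-depleted codons."""

    transcript_id: str
    start_codon: int
    end_codon: int  # inclusive
    min_mtr: float
    mean_mtr: float
    min_fdr_q: float
    population: Optional[str] = None

    @property
    def n_codons(self) -> int:
        return self.end_codon - self.start_codon + 1


def call_regions(
    profiles: Sequence[MTRProfile],
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> list[IntolerantRegion]:
    """Maximal runs of codons with fdr_q < threshold and score < 1.

    ``apply_fdr`` must have been run on the profile set first (one joint
    ranking for exome-wide semantics).  Codons significant in the tolerant
    direction (score >= 1) never enter a region.
    """
    regions: list[IntolerantRegion] = []
    for prof in profiles:
        with np.errstate(invalid="ignore"):
            flag = (prof.fdr_q < fdr_threshold) & (prof.mtr < 1.0)
        k = 0
        L = prof.n_codons
        while k < L:
            if not flag[k]:
                k += 1
                continue
            start = k
            while k < L and flag[k]:
                k += 1
            sl = slice(start, k)
            regions.append(
                IntolerantRegion(
                    transcript_id=prof.transcript_id,
                    start_codon=start + 1,
                    end_codon=k,
                    min_mtr=float(np.min(prof.mtr[sl])),
                    mean_mtr=float(np.mean(prof.mtr[sl])),
                    min_fdr_q=float(np.min(prof.fdr_q[sl])),
                    population=prof.population,
                )
            )
    return regions


@dataclass(slots=True)
class RankSumResult:
    u_statistic: float
    pvalue: float


def rank_sum_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    alternative: str = "two-sided",
) -> RankSumResult:
    """Mann–Whitney U comparison of two score distributions.

    Exact enumeration when both groups have <= 12 values and no ties;
    otherwise the tie-corrected normal approximation.  ``alternative='less'``
    tests for lower scores in group a.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("rank_sum_compare requires two non-empty vectors")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 12 and b.size <= 12 and not has_ties) else "asymptotic"
    res = sp_stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return RankSumResult(u_statistic=float(res.statistic), pvalue=float(res.pvalue))


@dataclass(slots=True)
class EnrichmentResult:
    """Enrichment of below-cutoff scores in cases vs controls."""

    cutoff: float
    odds_ratio: float
    pvalue: float
    case_percent: float
    control_percent: float
    table: tuple[int, int, int, int]  # a, b, c, d


def low_mtr_enrichment(
    scores_case: Sequence[float],
    scores_control: Sequence[float],
    cutoffs: Sequence[float] = (0.25, 0.5),
) -> list[EnrichmentResult]:
    """Per-cutoff 2x2 enrichment of low scores in cases versus controls.

    Odds ratio (a*d)/(b*c) with the Haldane 0.5 correction applied to every
    cell when any cell is zero; p-value from the two-sided Fisher exact test
    on the uncorrected table.
    """
    case = np.asarray(scores_case, dtype=float)
    ctrl = np.asarray(scores_control, dtype=float)
    case = case[~np.isnan(case)]
    ctrl = ctrl[~np.isnan(ctrl)]
    if case.size == 0 or ctrl.size == 0:
        raise InvalidParameterError("low_mtr_enrichment requires non-empty vectors")
    out: list[EnrichmentResult] = []
    for cut in cutoffs:
        a = int(np.sum(case < cut))
        b = case.size - a
        c = int(np.sum(ctrl < cut))
        d = ctrl.size - c
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        _, pval = sp_stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        out.append(
            EnrichmentResult(
                cutoff=float(cut),
                odds_ratio=float(orr),
                pvalue=float(pval),
                case_percent=100.0 * a / case.size,
                control_percent=100.0 * c / ctrl.size,
                table=(a, b, c, d),
            )
        )
    return out
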