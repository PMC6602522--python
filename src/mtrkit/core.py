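"""Per-codon missense tolerance ratio profiles.

For each amino-acid position ``i`` of a transcript of length ``L`` codons and
an odd window size ``w``, the window is the codon interval ``[H, J]`` with

    H = max(1, i - (w - 1) / 2)
    J = min(L, i + (w - 1) / 2)

i.e. truncated at the termini.  Observed and expected missense / synonymous
tallies are summed over the window and the score at ``i`` is the ratio of the
observed missense proportion to the expected missense proportion:

    MTR_i = [mis_obs / (mis_obs + syn_obs)] / [mis_exp / (mis_exp + syn_exp)]

Windows with no observed variants have an undefined score (NaN), which is
propagated and excluded from downstream testing.

Counting conventions: observed variants are counted as DISTINCT (cds_pos,
alt) changes (no allele-frequency weighting); expected counts weight every
possible single-nucleotide change equally; only missense and synonymous
changes enter either tally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .cds_model import COUNTED_CONSEQUENCES, Consequence, SiteVariant, Transcript
from .errors import DegenerateWindowError, InvalidParameterError

logger = logging.getLogger(__name__)

#: window sizes published for this score; 31 is the recommended default
WINDOW_SIZES = (21, 31, 41)
DEFAULT_WINDOW = 31

#: defaults for population-stratified profiles
MIN_POPULATION_EXOMES = 15_000
STRATIFIED_WINDOW_SIZES = (31, 41)


@dataclass(slots=True)
class SiteCounts:
    """Observed and expected missense/synonymous tallies at one codon."""

    codon_index: int
    mis_obs: int = 0
    syn_obs: int = 0
    mis_exp: int = 0
    syn_exp: int = 0


@dataclass(slots=True)
class WindowCounts:
    """Window sums centred at codon ``center`` over codons ``[lo, hi]``."""

    center: int
    lo: int
    hi: int
    window_size: int
    mis_obs: int
    syn_obs: int
    mis_exp: int
    syn_exp: int

    @property
    def n_obs(self) -> int:
        return self.mis_obs + self.syn_obs

    @property
    def n_exp(self) -> int:
        return self.mis_exp + self.syn_exp


def window_bounds(i: int, w: int, n_codons: int) -> tuple[int, int]:
    """Truncated window ``[H, J]`` centred at codon ``i``.

    ``w`` must be odd and >= 3; ``i`` must lie in ``1..n_codons``.
    """
    if w < 3 or w % 2 == 0:
        raise InvalidParameterError(f"window size must be odd and >= 3, got {w}")
    if not 1 <= i <= n_codons:
        raise InvalidParameterError(f"codon index {i} outside 1..{n_codons}")
    half = (w - 1) // 2
    return max(1, i - half), min(n_codons, i + half)


def aggregate_window(counts: Sequence[SiteCounts], i: int, w: int) -> WindowCounts:
    """Sum per-codon tallies over the window centred at ``i``.

    ``counts`` must cover codons ``1..L`` in order.
    """
    lo, hi = window_bounds(i, w, len(counts))
    mis_obs = syn_obs = mis_exp = syn_exp = 0
    for c in counts[lo - 1 : hi]:
        mis_obs += c.mis_obs
        syn_obs += c.syn_obs
        mis_exp += c.mis_exp
        syn_exp += c.syn_exp
    return WindowCounts(i, lo, hi, w, mis_obs, syn_obs, mis_exp, syn_exp)


def compute_mtr(wc: WindowCounts) -> float:
    """Score for one window; NaN when the window has no observed variants.

    Raises :class:`DegenerateWindowError` when the expected tallies cannot
    define a proportion (no expected variants, or no expected missense) —
    impossible for a non-empty coding window.
    """
    if wc.n_exp == 0 or wc.mis_exp == 0:
        raise DegenerateWindowError(
            f"window [{wc.lo},{wc.hi}] has degenerate expected counts "
            f"(mis_exp={wc.mis_exp}, syn_exp={wc.syn_exp})"
        )
    if wc.n_obs == 0:
        return float("nan")
    obs_prop = wc.mis_obs / wc.n_obs
    exp_prop = wc.mis_exp / wc.n_exp
    return obs_prop / exp_prop


@dataclass
class MTRProfile:
    """Per-codon window counts, scores and test results for one transcript.

    Arrays are indexed by codon (index 0 is codon 1) and all have length
    ``n_codons``.  ``raw_p``/``fdr_q`` start as NaN and are filled by the
    stats module; ``significant`` marks codons with ``fdr_q`` below the run
    threshold AND a depleted score (< 1).
    """

    transcript_id: str
    window_size: int
    n_codons: int
    population: Optional[str] = None
    mis_obs: np.ndarray = field(default=None)  # type: ignore[assignment]
    syn_obs: np.ndarray = field(default=None)  # type: ignore[assignment]
    mis_exp: np.ndarray = field(default=None)  # type: ignore[assignment]
    syn_exp: np.ndarray = field(default=None)  # type: ignore[assignment]
    mtr: np.ndarray = field(default=None)  # type: ignore[assignment]
    raw_p: np.ndarray = field(default=None)  # type: ignore[assignment]
    fdr_q: np.ndarray = field(default=None)  # type: ignore[assignment]
    significant: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        L = self.n_codons
        for name in ("mis_obs", "syn_obs", "mis_exp", "syn_exp"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(L, dtype=np.int64))
        for name in ("mtr", "raw_p", "fdr_q"):
            if getattr(self, name) is None:
                setattr(self, name, np.full(L, np.nan))
        if self.significant is None:
            self.significant = np.zeros(L, dtype=bool)
        for name in (
            "mis_obs", "syn_obs", "mis_exp", "syn_exp",
            "mtr", "raw_p", "fdr_q", "significant",
        ):
            if len(getattr(self, name)) != L:
                raise InvalidParameterError(f"profile array {name} has wrong length")

    def window(self, i: int) -> WindowCounts:
        """Window counts at codon ``i`` (1-based)."""
        lo, hi = window_bounds(i, self.window_size, self.n_codons)
        k = i - 1
        return WindowCounts(
            i, lo, hi, self.window_size,
            int(self.mis_obs[k]), int(self.syn_obs[k]),
            int(self.mis_exp[k]), int(self.syn_exp[k]),
        )


def _windowed_sums(per_codon: np.ndarray, w: int) -> np.ndarray:
    """Truncated sliding-window sums for all codons at once (O(L))."""
    L = len(per_codon)
    half = (w - 1) // 2
    cum = np.concatenate(([0], np.cumsum(per_codon)))
    idx = np.arange(1, L + 1)
    lo = np.maximum(1, idx - half)
    hi = np.minimum(L, idx + half)
    return cum[hi] - cum[lo - 1]


def _per_codon_counts(
    t: Transcript,
    variants: Iterable[SiteVariant],
    distinct: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """(missense, synonymous) per-codon count arrays of length n_codons."""
    L = t.n_codons
    mis = np.zeros(L, dtype=np.int64)
    syn = np.zeros(L, dtype=np.int64)
    seen: set[tuple[int, str]] = set()
    for v in variants:
        if v.consequence not in COUNTED_CONSEQUENCES:
            continue
        if not 1 <= v.codon_index <= L:
            continue
        if distinct:
            k = v.key()
            if k in seen:
                continue
            seen.add(k)
        if v.consequence is Consequence.MISSENSE:
            mis[v.codon_index - 1] += 1
        else:
            syn[v.codon_index - 1] += 1
    return mis, syn


def site_counts(
    t: Transcript,
    observed: Iterable[SiteVariant],
    possible: Iterable[SiteVariant],
    population: Optional[str] = None,
) -> list[SiteCounts]:
    """Per-codon tallies combining observed (distinct) and possible variants."""
    obs = observed
    if population is not None:
        obs = [v for v in observed if v.population == population]
    mis_o, syn_o = _per_codon_counts(t, obs, distinct=True)
    mis_e, syn_e = _per_codon_counts(t, possible, distinct=False)
    return [
        SiteCounts(i + 1, int(mis_o[i]), int(syn_o[i]), int(mis_e[i]), int(syn_e[i]))
        for i in range(t.n_codons)
    ]


def compute_profile(
    t: Transcript,
    observed: Sequence[SiteVariant],
    possible: Sequence[SiteVariant],
    w: int = DEFAULT_WINDOW,
    population: Optional[str] = None,
) -> MTRProfile:
    """Build the per-codon score profile for one transcript.

    ``possible`` should come from :func:`~mtrkit.cds_model.enumerate_possible_variants`
    on the same transcript; ``observed`` from
    :func:`~mtrkit.cds_model.annotate_observed`.  ``raw_p``/``fdr_q`` are left
    NaN — fill them with :mod:`mtrkit.stats`.
    """
    if w < 3 or w % 2 == 0:
        raise InvalidParameterError(f"window size must be odd and >= 3, got {w}")
    obs: Iterable[SiteVariant] = observed
    if population is not None:
        obs = [v for v in observed if v.population == population]
        if observed and not obs:
            logger.warning(
                "%s: no observed variants labelled population=%r; profile is all-NA",
                t.transcript_id, population,
            )
    mis_o, syn_o = _per_codon_counts(t, obs, distinct=True)
    mis_e, syn_e = _per_codon_counts(t, possible, distinct=False)

    prof = MTRProfile(
        transcript_id=t.transcript_id,
        window_size=w,
        n_codons=t.n_codons,
        population=population,
        mis_obs=_windowed_sums(mis_o, w),
        syn_obs=_windowed_sums(syn_o, w),
        mis_exp=_windowed_sums(mis_e, w),
        syn_exp=_windowed_sums(syn_e, w),
    )
    n_obs = prof.mis_obs + prof.syn_obs
    n_exp = prof.mis_exp + prof.syn_exp
    if np.any((n_exp == 0) | (prof.mis_exp == 0)):
        raise DegenerateWindowError(
            f"{t.transcript_id}: some windows have no expected missense variants"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        mtr = (prof.mis_obs / n_obs) / (prof.mis_exp / n_exp)
    mtr[n_obs == 0] = np.nan
    prof.mtr = mtr
    return prof


def ethnicity_profiles(
    t: Transcript,
    observed: Sequence[SiteVariant],
    possible: Sequence[SiteVariant],
    population_sizes: dict[str, int],
    window_sizes: Sequence[int] = STRATIFIED_WINDOW_SIZES,
    min_exomes: int = MIN_POPULATION_EXOMES,
) -> list[MTRProfile]:
    """Population-stratified profiles.

    One profile per (population, window size), restricted to populations whose
    declared sample size reaches ``min_exomes`` and to the allowed window
    sizes; skipped populations are logged.
    """
    out: list[MTRProfile] = []
    for pop in sorted(population_sizes):
        n = population_sizes[pop]
        if n < min_exomes:
            logger.info(
                "skipping population %s: %d exomes < %d required", pop, n, min_exomes
            )
            continue
        for w in window_sizes:
            out.append(compute_profile(t, observed, possible, w=w, population=pop))
    return out
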