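"""Synthetic transcripts and observed-variant sets with known ground truth.

The observation model is the simplest one consistent with distinct-variant
counting: every possible synonymous change is observed independently with
probability ``pi_obs``; every possible missense change with probability
``pi_obs * rho``, where the missense-retention factor ``rho`` is 1 outside
designated depleted regions and ``rho < 1`` inside them (purifying
selection).  Random streams are split per transcript from the scenario seed,
so per-transcript output is independent of processing order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cds_model import (
    CODON_TO_AA,
    STOP_CODONS,
    Consequence,
    Origin,
    SiteVariant,
    Transcript,
    enumerate_possible_variants,
)
from .errors import ConfigError, InvalidParameterError
from .stats import IntolerantRegion

_NONSTOP_CODONS = tuple(sorted(c for c in CODON_TO_AA if c not in STOP_CODONS))
_STOP_TUPLE = tuple(sorted(STOP_CODONS))


@dataclass(frozen=True)
class DepletedRegion:
    """Ground-truth region [start_codon, end_codon] with missense retention rho."""

    transcript_index: int  # 0-based index into the scenario's transcripts
    start_codon: int
    end_codon: int
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ConfigError(f"rho {self.rho} outside [0, 1]")
        if self.start_codon < 1 or self.end_codon < self.start_codon:
            raise ConfigError(
                f"bad region bounds [{self.start_codon}, {self.end_codon}]"
            )


@dataclass(frozen=True)
class SimulationScenario:
    seed: int
    n_transcripts: int
    length_codons: tuple[int, int]  # inclusive range of amino-acid lengths
    pi_obs: float
    depleted_regions: tuple[DepletedRegion, ...] = ()
    populations: Optional[dict[str, float]] = None  # label -> mixture proportion

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ConfigError("n_transcripts must be >= 1")
        lo, hi = self.length_codons
        if lo < 10 or hi < lo:
            raise ConfigError(f"bad codon-length range {self.length_codons}")
        if not 0.0 < self.pi_obs <= 1.0:
            raise ConfigError(f"pi_obs {self.pi_obs} outside (0, 1]")
        for r in self.depleted_regions:
            if not 0 <= r.transcript_index < self.n_transcripts:
                raise ConfigError(f"region transcript index {r.transcript_index} out of range")
        if self.populations is not None:
            total = sum(self.populations.values())
            if not np.isclose(total, 1.0):
                raise ConfigError(f"population proportions sum to {total}, not 1")

    def regions_for(self, transcript_index: int) -> list[DepletedRegion]:
        return [
            r for r in self.depleted_regions if r.transcript_index == transcript_index
        ]


def scenario_from_dict(d: dict) -> SimulationScenario:
    """Build a scenario from a parsed config mapping (see docs/README)."""
    if not isinstance(d, dict):
        raise ConfigError("scenario config must be a mapping")
    known = {
        "seed", "n_transcripts", "length_codons", "pi_obs",
        "depleted_regions", "populations",
    }
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown scenario keys: {sorted(unknown)}")
    try:
        regions = tuple(
            DepletedRegion(
                transcript_index=int(r["transcript_index"]),
                start_codon=int(r["start_codon"]),
                end_codon=int(r["end_codon"]),
                rho=float(r["rho"]),
            )
            for r in d.get("depleted_regions", [])
        )
        length = d["length_codons"]
        if isinstance(length, int):
            length = (length, length)
        return SimulationScenario(
            seed=int(d["seed"]),
            n_transcripts=int(d["n_transcripts"]),
            length_codons=(int(length[0]), int(length[1])),
            pi_obs=float(d["pi_obs"]),
            depleted_regions=regions,
            populations=(
                {str(k): float(v) for k, v in d["populations"].items()}
                if d.get("populations")
                else None
            ),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"bad scenario config: {exc}") from exc


def generate_transcript(
    length_codons: int,
    seed: int | np.random.SeedSequence | Sequence[int],
) -> Transcript:
    """Random transcript of ``length_codons`` amino acids.

    Starts with ATG, ends with a random stop codon, and contains no internal
    stop codons (codons drawn uniformly from the 61 coding codons).
    Deterministic under ``seed``.
    """
    if length_codons < 10:
        raise InvalidParameterError(f"length_codons {length_codons} < 10")
    rng = np.random.default_rng(seed)
    body = rng.choice(len(_NONSTOP_CODONS), size=length_codons - 1)
    stop = _STOP_TUPLE[rng.integers(len(_STOP_TUPLE))]
    seq = "ATG" + "".join(_NONSTOP_CODONS[i] for i in body) + stop
    sid = f"SYN{int(np.random.default_rng(seed).integers(0, 10**9)):09d}"
    return Transcript(transcript_id=sid, cds_seq=seq)


def _transcript_rng(scenario_seed: int, transcript_index: int, stream: int):
    # independent, order-free streams: one SeedSequence per (transcript, purpose)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=scenario_seed, spawn_key=(transcript_index, stream))
    )


def sample_observed(
    t: Transcript,
    possible: Sequence[SiteVariant],
    scenario: SimulationScenario,
    transcript_index: int,
) -> list[SiteVariant]:
    """Bernoulli draw of observed variants from the possible set.

    Only missense and synonymous possible changes can be observed.  Inside a
    depleted region the missense observation probability is scaled by that
    region's rho.  Deterministic under the scenario seed and transcript index.
    """
    rho = np.ones(t.n_codons)
    for r in scenario.regions_for(transcript_index):
        if r.end_codon > t.n_codons:
            raise ConfigError(
                f"region [{r.start_codon},{r.end_codon}] exceeds transcript "
                f"length {t.n_codons}"
            )
        rho[r.start_codon - 1 : r.end_codon] = r.rho

    candidates = [
        v for v in possible
        if v.consequence in (Consequence.MISSENSE, Consequence.SYNONYMOUS)
    ]
    probs = np.empty(len(candidates))
    for j, v in enumerate(candidates):
        p = scenario.pi_obs
        if v.consequence is Consequence.MISSENSE:
            p *= rho[v.codon_index - 1]
        probs[j] = p

    rng = _transcript_rng(scenario.seed, transcript_index, 0)
    keep = rng.random(len(candidates)) < probs

    pops: Optional[np.ndarray] = None
    if scenario.populations is not None:
        labels = sorted(scenario.populations)
        weights = np.array([scenario.populations[l] for l in labels])
        pop_rng = _transcript_rng(scenario.seed, transcript_index, 1)
        pops = pop_rng.choice(labels, size=len(candidates), p=weights)

    observed: list[SiteVariant] = []
    for j, v in enumerate(candidates):
        if not keep[j]:
            continue
        observed.append(
            dataclasses.replace(
                v,
                origin=Origin.OBSERVED,
                population=None if pops is None else str(pops[j]),
            )
        )
    return observed


@dataclass
class SimulatedDataset:
    scenario: SimulationScenario
    transcripts: list[Transcript]
    possible: dict[str, list[SiteVariant]]  # transcript_id -> possible variants
    observed: dict[str, list[SiteVariant]]  # transcript_id -> observed variants
    truth: list[IntolerantRegion] = field(default_factory=list)


def simulate(scenario: SimulationScenario) -> SimulatedDataset:
    """Generate the full dataset for a scenario (deterministic under seed)."""
    transcripts: list[Transcript] = []
    possible: dict[str, list[SiteVariant]] = {}
    observed: dict[str, list[SiteVariant]] = {}
    lo, hi = scenario.length_codons
    for k in range(scenario.n_transcripts):
        len_rng = _transcript_rng(scenario.seed, k, 2)
        L = int(len_rng.integers(lo, hi + 1))
        t = generate_transcript(
            L, np.random.SeedSequence(entropy=scenario.seed, spawn_key=(k, 3))
        )
        # unique, index-stable ids
        t = Transcript(
            transcript_id=f"SYNT{k:05d}",
            cds_seq=t.cds_seq,
            gene_symbol=f"GENE{k}",
        )
        poss = enumerate_possible_variants(t)
        for v in poss:
            v.transcript_id = t.transcript_id
        obs = sample_observed(t, poss, scenario, k)
        transcripts.append(t)
        possible[t.transcript_id] = poss
        observed[t.transcript_id] = obs
    truth = [
        IntolerantRegion(
            transcript_id=transcripts[r.transcript_index].transcript_id,
            start_codon=r.start_codon,
            end_codon=r.end_codon,
            min_mtr=float("nan"),
            mean_mtr=float("nan"),
            min_fdr_q=float("nan"),
        )
        for r in scenario.depleted_regions
        if r.rho < 1.0
    ]
    return SimulatedDataset(
        scenario=scenario,
        transcripts=transcripts,
        possible=possible,
        observed=observed,
        truth=truth,
    )


@dataclass(slots=True)
class TruthEvaluation:
    tp: int
    fp: int
    fn: int
    tn: int
    jaccard: float


def _codon_set(regions: Sequence[IntolerantRegion]) -> set[tuple[str, int]]:
    out: set[tuple[str, int]] = set()
    for r in regions:
        for c in range(r.start_codon, r.end_codon + 1):
            out.add((r.transcript_id, c))
    return out


def truth_evaluation(
    called: Sequence[IntolerantRegion],
    truth: Sequence[IntolerantRegion],
    transcript_lengths: dict[str, int],
) -> TruthEvaluation:
    """Per-codon confusion counts and region Jaccard against ground truth.

    Jaccard is measured in codon units: |called ∩ true| / |called ∪ true|,
    defined as 1 when both sets are empty.
    """
    called_set = _codon_set(called)
    truth_set = _codon_set(truth)
    total = sum(transcript_lengths.values())
    tp = len(called_set & truth_set)
    fp = len(called_set - truth_set)
    fn = len(truth_set - called_set)
    tn = total - tp - fp - fn
    union = len(called_set | truth_set)
    jaccard = 1.0 if union == 0 else tp / union
    return TruthEvaluation(tp=tp, fp=fp, fn=fn, tn=tn, jaccard=jaccard)
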