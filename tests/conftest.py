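"""Shared fixtures, including the (expensive) simulation harnesses used by
both the synthetic-module property tests and the acceptance suite — built
once per session."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from mtrkit.cds_model import Transcript
from mtrkit.core import compute_profile
from mtrkit.stats import apply_fdr, call_regions, test_profile
from mtrkit.synthetic import (
    DepletedRegion,
    SimulationScenario,
    sample_observed,
    simulate,
    truth_evaluation,
)


@pytest.fixture
def toy2() -> Transcript:
    """Met-Lys-stop: 2 coding codons, terminal stop excluded."""
    return Transcript("TOY2", "ATGAAATAA")


@pytest.fixture
def toy4() -> Transcript:
    """Met-Lys-Trp-Leu, no terminal stop (partial transcript)."""
    return Transcript("TOY4", "ATGAAATGGCTG")


def _score_dataset(ds, w=31, fdr_threshold=0.1):
    """Profiles + tests + joint FDR + regions for a simulated dataset."""
    profiles = []
    for t in ds.transcripts:
        prof = compute_profile(
            t, ds.observed[t.transcript_id], ds.possible[t.transcript_id], w=w
        )
        test_profile(prof)
        profiles.append(prof)
    apply_fdr(profiles, fdr_threshold=fdr_threshold, scope="joint")
    regions = call_regions(profiles, fdr_threshold=fdr_threshold)
    return profiles, regions


NEUTRAL_BASE = SimulationScenario(
    seed=1000, n_transcripts=20, length_codons=(400, 400), pi_obs=0.6
)
N_NEUTRAL_REPLICATES = 50


@pytest.fixture(scope="session")
def neutral_results():
    """50 neutral replicates (20 transcripts x 400 codons, pi_obs=0.6).

    Transcripts are fixed across replicates (observation sampling is the only
    randomness being calibrated); each replicate re-draws observed variants,
    tests and jointly FDR-adjusts.  Returns per-replicate realized FDP among
    q < 0.1 calls and per-replicate fraction of codons with raw_p < 0.05.
    """
    base = simulate(NEUTRAL_BASE)
    fdps = []
    frac_p05 = []
    for rep in range(N_NEUTRAL_REPLICATES):
        scen = dataclasses.replace(NEUTRAL_BASE, seed=2000 + rep)
        profiles = []
        for k, t in enumerate(base.transcripts):
            obs = sample_observed(t, base.possible[t.transcript_id], scen, k)
            prof = compute_profile(t, obs, base.possible[t.transcript_id], w=31)
            test_profile(prof)
            profiles.append(prof)
        apply_fdr(profiles, fdr_threshold=0.1, scope="joint")
        q = np.concatenate([p.fdr_q for p in profiles])
        raw = np.concatenate([p.raw_p for p in profiles])
        n_called = int(np.nansum(q < 0.1))
        # all codons are null: every call is a false discovery
        fdps.append(0.0 if n_called == 0 else 1.0)
        frac_p05.append(float(np.nanmean(raw < 0.05)))
    return {"fdp": fdps, "frac_p05": frac_p05}


def make_recovery_scenario(seed: int) -> SimulationScenario:
    """20 transcripts x 400 codons, one 60-codon depleted region each,
    rho=0.2, pi_obs=0.6."""
    regions = tuple(
        DepletedRegion(transcript_index=k, start_codon=171, end_codon=230, rho=0.2)
        for k in range(20)
    )
    return SimulationScenario(
        seed=seed,
        n_transcripts=20,
        length_codons=(400, 400),
        pi_obs=0.6,
        depleted_regions=regions,
    )


N_RECOVERY_REPLICATES = 20


@pytest.fixture(scope="session")
def recovery_results():
    """20 replicates of the depleted-region scenario, each fully re-simulated;
    per-replicate truth Jaccard and mean within-region vs flank scores."""
    out = []
    for rep in range(N_RECOVERY_REPLICATES):
        scen = make_recovery_scenario(seed=3000 + rep)
        ds = simulate(scen)
        profiles, called = _score_dataset(ds, w=31, fdr_threshold=0.1)
        lengths = {t.transcript_id: t.n_codons for t in ds.transcripts}
        ev = truth_evaluation(called, ds.truth, lengths)
        in_region = []
        flank = []
        for prof in profiles:
            sel = np.zeros(prof.n_codons, dtype=bool)
            sel[170:230] = True  # codons 171..230
            in_region.append(prof.mtr[sel])
            flank.append(prof.mtr[~sel])
        out.append(
            {
                "jaccard": ev.jaccard,
                "region_mean_mtr": float(np.nanmean(np.concatenate(in_region))),
                "flank_mean_mtr": float(np.nanmean(np.concatenate(flank))),
            }
        )
    return out


@pytest.fixture(scope="session")
def depleted_example():
    """One scored depleted-region dataset, for direction/enrichment checks."""
    scen = make_recovery_scenario(seed=4242)
    ds = simulate(scen)
    profiles, called = _score_dataset(ds, w=31, fdr_threshold=0.1)
    return ds, profiles, called
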