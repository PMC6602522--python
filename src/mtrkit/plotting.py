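"""Line-graph rendering of a per-residue score profile."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless
import matplotlib.pyplot as plt
import numpy as np

from .stats import IntolerantRegion

logger = logging.getLogger(__name__)


def plot_profile(
    codon_index: np.ndarray,
    mtr: np.ndarray,
    regions: Sequence[IntolerantRegion] = (),
    transcript_id: str = "",
    out: Optional[str | Path] = None,
    ax: Optional[plt.Axes] = None,
) -> plt.Axes:
    """Score vs codon position, with significant segments highlighted in red
    and the neutral line at 1 marked.  Writes ``out`` when given.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.5))
    finite = np.isfinite(np.asarray(mtr, dtype=float))
    if not finite.any():
        logger.warning("%s: profile is all-NA; plotting empty axes", transcript_id)
    else:
        ax.plot(codon_index, mtr, color="steelblue", lw=1.2, label="MTR")
        for r in regions:
            sel = (codon_index >= r.start_codon) & (codon_index <= r.end_codon)
            ax.plot(
                codon_index[sel], np.asarray(mtr)[sel],
                color="red", lw=2.0,
                label="FDR-significant" if r is regions[0] else None,
            )
    ax.axhline(1.0, color="grey", ls="--", lw=0.8, label="neutral (MTR = 1)")
    ax.set_xlabel("amino-acid position")
    ax.set_ylabel("MTR")
    if transcript_id:
        ax.set_title(transcript_id)
    ax.legend(loc="upper right", fontsize=8)
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
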