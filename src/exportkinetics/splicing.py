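"""Percent-intron (PI) and splicing probability (SP) from junction reads.

For each intron, PI compares reads spanning the two exon-intron boundaries
(EI at the 5' side, IE at the 3' side) with spliced exon-exon reads (EE):

    PI = ((EI + IE)/2) / (EE + (EI + IE)/2)

Treating introns as independently spliced, a gene's splicing probability is
the product over its introns of (1 - PI).  SP uses the mean PI over the two
late timepoints of the stimulation window (where junction coverage is
highest) and is reported missing unless every intron carries more than ten
junction reads.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["percent_intron", "splicing_probability", "gene_splicing_table"]

log = logging.getLogger(__name__)

MIN_JUNCTION_READS = 10  # strict: an intron with exactly 10 reads fails the gate
LATE_TIMEPOINTS = 2  # number of trailing timepoints averaged for SP


def percent_intron(ee, ei, ie):
    """PI in [0, 1]; NaN where all three counts are zero."""
    ee = np.asarray(ee, dtype=float)
    ei = np.asarray(ei, dtype=float)
    ie = np.asarray(ie, dtype=float)
    if np.any(ee < 0) or np.any(ei < 0) or np.any(ie < 0):
        raise ValueError("junction counts must be >= 0")
    half = (ei + ie) / 2.0
    denom = ee + half
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(denom > 0, half / np.where(denom > 0, denom, 1.0), np.nan)
    return pi if pi.ndim else float(pi)


def splicing_probability(
    pis: Sequence[float], junction_totals: Sequence[float] | None = None
) -> float:
    """Product over introns of (1 - PI); NaN when the read gate fails.

    ``junction_totals`` are per-intron total junction reads (EE + EI + IE)
    over the timepoints entering the PI average; any intron at or below
    ten reads makes SP missing.  An intronless gene has SP = 1.
    """
    pis = np.asarray(pis, dtype=float)
    if pis.size == 0:
        log.info("intronless gene: SP = 1")
        return 1.0
    if np.any((pis < 0) | (pis > 1)):
        raise ValueError("PI values must lie in [0, 1]")
    if junction_totals is not None:
        totals = np.asarray(junction_totals, dtype=float)
        if np.any(totals <= MIN_JUNCTION_READS):
            return float("nan")
    return float(np.prod(1.0 - pis))


def gene_splicing_table(
    junctions: pd.DataFrame, mode: str = "mean_pi"
) -> pd.DataFrame:
    """Per-gene SP from a long table (gene_id, intron, time_min, EE, EI, IE).

    PI per intron is averaged over the last two timepoints (``mode=
    "mean_pi"``, the default) or computed from counts pooled across them
    (``mode="pooled"``); the >10-reads gate uses the junction reads summed
    over those timepoints.
    """
    required = {"gene_id", "intron", "time_min", "EE", "EI", "IE"}
    missing = required - set(junctions.columns)
    if missing:
        raise ValueError(f"junction table missing columns {sorted(missing)}")
    if mode not in ("mean_pi", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    for gene, sub in junctions.groupby("gene_id", sort=True):
        late = np.sort(sub["time_min"].unique())[-LATE_TIMEPOINTS:]
        sub = sub[sub["time_min"].isin(late)]
        pis, totals = [], []
        for _, isub in sub.groupby("intron", sort=True):
            totals.append(float((isub["EE"] + isub["EI"] + isub["IE"]).sum()))
            if mode == "mean_pi":
                pi_t = percent_intron(isub["EE"], isub["EI"], isub["IE"])
                pis.append(float(np.nanmean(np.atleast_1d(pi_t))))
            else:
                pis.append(
                    percent_intron(isub["EE"].sum(), isub["EI"].sum(), isub["IE"].sum())
                )
        sp = (
            float("nan")
            if np.any(np.isnan(pis))
            else splicing_probability(pis, totals)
        )
        rows.append(
            dict(gene_id=gene, n_introns=len(pis), splicing_probability=sp)
        )
    return pd.DataFrame(rows)
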