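"""mRNA half-life estimation from actinomycin-D decay time courses.

After transcription arrest the log2 normalized counts of a decaying mRNA
fall linearly with time.  The pipeline: spike-in (ERCC-style) median-ratio
normalization, removal of genes never exceeding 32 raw counts, a
regression-window search (start within the first hour, any later end,
optionally dropping a single interior point) selecting the negative-slope
fit with the highest adjusted R^2, and conversion of the shared slope
(log2/min, fitted with per-replicate intercepts) to a half-life

    HL = -1 / slope   [minutes]

with a 95% CI propagated from the t-based slope confidence interval.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import gmean

from .synthetic import ActDExperiment

__all__ = [
    "HalfLifeEstimate",
    "normalize_spikeins",
    "flag_aberrant_samples",
    "filter_low_count_genes",
    "candidate_start_points",
    "fit_halflife",
    "estimate_halflives",
    "read_actd_table",
]

log = logging.getLogger(__name__)

LOW_COUNT_MAX = 32  # genes with <= this in all samples are dropped
START_WINDOW_MIN = 60.0  # regressions must start within the first hour
DECAY_FRACTION = 0.25  # start-point rule: within 0.25 x max decay/h of the 1st-hour max
PSEUDOCOUNT = 0.5


@dataclass
class HalfLifeEstimate:
    gene_id: str
    slope: float  # log2 counts per minute, < 0
    slope_ci: tuple
    half_life_min: float
    half_life_ci: tuple
    adjusted_r2: float
    window: tuple  # (start offset, end offset), minutes
    removed_point: float | None = None
    flagged_samples: list = field(default_factory=list)


def normalize_spikeins(exp: ActDExperiment) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample normalization factors from the spike-in block.

    factor_s = median over spike-ins i of count_{i,s} / geomean_i, where
    geomean_i is the spike-in's geometric mean across samples; spike-ins
    with a zero anywhere are excluded.  Returns (factors, normalized gene
    counts).
    """
    sp = np.asarray(exp.spikein_counts, dtype=float)
    usable = np.all(sp > 0, axis=1)
    if usable.sum() < 2:
        raise ValueError("need >= 2 spike-ins with nonzero counts in all samples")
    sp = sp[usable]
    ref = gmean(sp, axis=1)
    factors = np.median(sp / ref[:, None], axis=0)
    normalized = np.asarray(exp.gene_counts, dtype=float) / factors[None, :]
    return factors, normalized


def flag_aberrant_samples(
    exp: ActDExperiment, factors: np.ndarray, tolerance: float = 0.10
) -> list[int]:
    """Samples whose normalized library size rises against the decay trend.

    After normalization the total mRNA signal should fall monotonically
    with time post-arrest; a sample whose normalized library size exceeds
    the preceding offset's (within the same replicate) by more than
    ``tolerance`` is flagged.  Returns flagged column indices.
    """
    norm = np.asarray(exp.gene_counts, dtype=float) / np.asarray(factors)[None, :]
    libsize = norm.sum(axis=0)
    flags = []
    for rep in np.unique(exp.replicate_ids):
        cols = np.where(exp.replicate_ids == rep)[0]
        cols = cols[np.argsort(exp.sample_offsets[cols])]
        for prev, cur in zip(cols[:-1], cols[1:]):
            if libsize[cur] > libsize[prev] * (1.0 + tolerance):
                flags.append(int(cur))
    return flags


def filter_low_count_genes(exp: ActDExperiment) -> np.ndarray:
    """Boolean mask of genes with > 32 raw counts in at least one sample."""
    keep = np.asarray(exp.gene_counts).max(axis=1) > LOW_COUNT_MAX
    if not keep.any():
        log.warning("all %d genes fall below the count floor", keep.size)
    return keep


def candidate_start_points(offsets: np.ndarray, log2_counts: np.ndarray) -> np.ndarray:
    """Possible regression start offsets for one gene.

    Offsets t <= 60 min whose log2 normalized count is not lower than the
    first-hour maximum minus 0.25 x the maximum decay per hour, where the
    max decay per hour is the largest drop between consecutive offsets
    rescaled to a 60-minute span.
    """
    offsets = np.asarray(offsets, dtype=float)
    vals = np.asarray(log2_counts, dtype=float)
    if offsets.size < 3:
        raise ValueError("need >= 3 offsets")
    first_hour = offsets <= START_WINDOW_MIN
    max1h = vals[first_hour].max()
    drops = (vals[:-1] - vals[1:]) / (np.diff(offsets) / 60.0)
    max_decay = max(drops.max(), 0.0)
    ok = first_hour & (vals >= max1h - DECAY_FRACTION * max_decay)
    return offsets[ok]


def _shared_slope_fit(times: np.ndarray, values: np.ndarray, reps: np.ndarray):
    """OLS with a common slope and one intercept per replicate."""
    uniq = np.unique(reps)
    X = np.column_stack([times] + [(reps == r).astype(float) for r in uniq])
    model = sm.OLS(values, X)
    res = model.fit()
    return res


def fit_halflife(
    gene_id: str,
    offsets: np.ndarray,
    log2_counts: np.ndarray,  # replicates x offsets
    replicate_ids: Sequence[str] | None = None,
    alpha_level: float = 0.95,
    flagged: Sequence[int] | None = None,
) -> HalfLifeEstimate | None:
    """Window-search regression for one gene; None if no decay is detected.

    Enumerates (start in the candidate set, end, at most one removed
    interior offset) with at least three offsets remaining, fits the
    shared-slope/per-replicate-intercept regression of log2 normalized
    counts on time, and keeps the negative-slope fit with the highest
    adjusted R^2 (ties: more points, then earlier start).
    """
    offsets = np.asarray(offsets, dtype=float)
    vals = np.atleast_2d(np.asarray(log2_counts, dtype=float))
    n_reps = vals.shape[0]
    if replicate_ids is None:
        replicate_ids = [f"rep{i+1}" for i in range(n_reps)]

    mean_series = vals.mean(axis=0)
    starts = candidate_start_points(offsets, mean_series)
    best = None  # (adj_r2, n_points, -start, result-record)
    for start, end in itertools.product(starts, offsets):
        if end <= start:
            continue
        in_win = (offsets >= start) & (offsets <= end)
        win_offsets = offsets[in_win]
        if win_offsets.size < 3:
            continue
        interior = win_offsets[1:-1]
        for removed in itertools.chain([None], interior):
            use = in_win.copy()
            if removed is not None:
                use &= offsets != removed
            if use.sum() < 3:
                continue
            t = np.tile(offsets[use], n_reps)
            y = vals[:, use].ravel()
            reps = np.repeat(np.asarray(replicate_ids), use.sum())
            res = _shared_slope_fit(t, y, reps)
            slope = res.params[0]
            if slope >= 0 or not np.isfinite(res.rsquared_adj):
                continue
            # adjusted R^2 rounded so exact ties break on points/start
            key = (round(res.rsquared_adj, 10), use.sum(), -start)
            if best is None or key > best[0]:
                best = (key, (start, end, removed, res, use.sum()))
    if best is None:
        log.info("%s: no negative-slope regression found", gene_id)
        return None

    start, end, removed, res, _ = best[1]
    slope = float(res.params[0])
    ci = res.conf_int(alpha=1 - alpha_level)
    try:
        lo, hi = float(ci[0, 0]), float(ci[0, 1])
    except (TypeError, IndexError):
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    # HL = -1/slope; a CI upper slope >= 0 means the half-life is unbounded
    hl = -1.0 / slope
    hl_lo = -1.0 / lo if lo < 0 else np.inf
    hl_hi = -1.0 / hi if hi < 0 else np.inf
    return HalfLifeEstimate(
        gene_id=gene_id,
        slope=slope,
        slope_ci=(lo, hi),
        half_life_min=hl,
        half_life_ci=tuple(sorted((hl_lo, hl_hi))),
        adjusted_r2=float(res.rsquared_adj),
        window=(float(start), float(end)),
        removed_point=None if removed is None else float(removed),
        flagged_samples=list(flagged or []),
    )


def estimate_halflives(
    exp: ActDExperiment,
    tolerance: float = 0.10,
    drop_flagged: bool = True,
) -> pd.DataFrame:
    """Run the full pipeline on an experiment; one row per retained gene."""
    factors, normalized = normalize_spikeins(exp)
    flagged = flag_aberrant_samples(exp, factors, tolerance=tolerance)
    keep_genes = filter_low_count_genes(exp)

    cols = np.arange(normalized.shape[1])
    if drop_flagged and flagged:
        cols = np.array([c for c in cols if c not in flagged])
    uniq_reps = list(dict.fromkeys(exp.replicate_ids[cols]))

    rows = []
    for gi in np.where(keep_genes)[0]:
        per_rep = []
        offs_ref = None
        for rep in uniq_reps:
            sel = cols[exp.replicate_ids[cols] == rep]
            order = np.argsort(exp.sample_offsets[sel])
            sel = sel[order]
            offs = exp.sample_offsets[sel]
            if offs_ref is None:
                offs_ref = offs
            elif not np.array_equal(offs, offs_ref):
                raise ValueError("replicates must share arrest offsets after flagging")
            per_rep.append(np.log2(normalized[gi, sel] + PSEUDOCOUNT))
        est = fit_halflife(
            exp.gene_ids[gi], offs_ref, np.vstack(per_rep), uniq_reps, flagged=flagged
        )
        if est is None:
            rows.append(dict(gene_id=exp.gene_ids[gi], half_life_min=np.nan, decay_detected=False))
        else:
            rows.append(
                dict(
                    gene_id=est.gene_id,
                    half_life_min=est.half_life_min,
                    half_life_lo=est.half_life_ci[0],
                    half_life_hi=est.half_life_ci[1],
                    slope=est.slope,
                    adjusted_r2=est.adjusted_r2,
                    window_start=est.window[0],
                    window_end=est.window[1],
                    removed_point=est.removed_point,
                    decay_detected=True,
                )
            )
    return pd.DataFrame(rows)


def read_actd_table(path, spikein_prefix: str = "ERCC-") -> ActDExperiment:
    """Read a TSV of raw ActD counts with a spike-in block.

    Expected columns: ``gene_id`` then one column per sample named
    ``<replicate>_<offset_min>``; rows whose gene_id starts with
    ``spikein_prefix`` form the spike-in block.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing gene_id column")
    sample_cols = [c for c in df.columns if c != "gene_id"]
    reps, offs = [], []
    for c in sample_cols:
        rep, _, off = c.rpartition("_")
        reps.append(rep)
        offs.append(float(off))
    is_spike = df["gene_id"].str.startswith(spikein_prefix)
    genes = df[~is_spike]
    spikes = df[is_spike]
    return ActDExperiment(
        arrest_offsets=np.unique(offs),
        sample_offsets=np.asarray(offs),
        replicate_ids=np.asarray(reps),
        gene_ids=genes["gene_id"].tolist(),
        gene_counts=genes[sample_cols].to_numpy(dtype=float),
        spikein_ids=spikes["gene_id"].tolist(),
        spikein_counts=spikes[sample_cols].to_numpy(dtype=float),
    )
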