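"""Count-table I/O, FPKM computation and inducible-gene selection.

The on-disk dialect is a long-format tab-separated table with columns

    gene_id  fraction  time_min  count  library_size  effective_length_bp

one row per gene, fraction and timepoint.  ``fraction`` is one of
``chromatin``, ``nucleoplasm``, ``cytoplasm``.  FPKM is derived, never
stored: FPKM = count / (effective_length_bp/1000 * library_size/1e6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FRACTIONS",
    "TimeCourse",
    "compute_fpkm",
    "read_count_table",
    "write_count_table",
    "SelectionRules",
    "GeneSelectionReport",
    "select_inducible_genes",
    "run_pipeline",
]

FRACTIONS = ("chromatin", "nucleoplasm", "cytoplasm")

COLUMNS = ["gene_id", "fraction", "time_min", "count", "library_size", "effective_length_bp"]


def compute_fpkm(count, library_size, effective_length_bp):
    """Fragments per kilobase of (effective) transcript per million fragments."""
    count = np.asarray(count, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    length = np.asarray(effective_length_bp, dtype=float)
    if np.any(library_size <= 0):
        raise ValueError("library_size must be positive")
    if np.any(length <= 0):
        raise ValueError("effective_length_bp must be positive")
    return count / (length / 1e3 * library_size / 1e6)


@dataclass
class TimeCourse:
    """Observed counts for one gene in one subcellular fraction over time."""

    gene_id: str
    fraction: str
    times: np.ndarray
    counts: np.ndarray
    library_sizes: np.ndarray
    effective_length_bp: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.fraction not in FRACTIONS:
            raise ValueError(f"unknown fraction {self.fraction!r}")
        if self.times.size != self.counts.size or self.times.size != self.library_sizes.size:
            raise ValueError("times, counts and library_sizes must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.gene_id}/{self.fraction}: times must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.gene_id}/{self.fraction}: negative counts")
        if self.effective_length_bp <= 0:
            raise ValueError("effective_length_bp must be positive")

    @property
    def fpkm(self) -> np.ndarray:
        return compute_fpkm(self.counts, self.library_sizes, self.effective_length_bp)

    @property
    def pseudocount_fpkm(self) -> np.ndarray:
        """0.5 counts expressed in each sample's FPKM units."""
        return compute_fpkm(
            np.full(self.times.size, 0.5), self.library_sizes, self.effective_length_bp
        )

    def log2_fpkm(self) -> np.ndarray:
        """log2(FPKM + pseudocount of 0.5 counts)."""
        return np.log2(self.fpkm + self.pseudocount_fpkm)


def read_count_table(path) -> dict[str, dict[str, TimeCourse]]:
    """Parse a long-format count table into {gene_id: {fraction: TimeCourse}}.

    Malformed rows are rejected with their 1-based line numbers (header is
    line 1).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    lines = df.index.to_numpy() + 2  # 1-based file lines, after the header

    bad = df["fraction"].isin(FRACTIONS) == False  # noqa: E712
    if bad.any():
        raise ValueError(f"{path}: unknown fraction at line(s) {list(lines[bad])}")
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative count at line(s) {list(lines[df['count'] < 0])}")
    dup = df.duplicated(subset=["gene_id", "fraction", "time_min"], keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (gene, fraction, time) at line(s) {list(lines[dup])}"
        )

    out: dict[str, dict[str, TimeCourse]] = {}
    for (gene, fraction), sub in df.groupby(["gene_id", "fraction"], sort=True):
        sub = sub.sort_values("time_min")
        lengths = sub["effective_length_bp"].unique()
        if lengths.size != 1:
            raise ValueError(f"{path}: {gene}/{fraction}: inconsistent effective_length_bp")
        out.setdefault(str(gene), {})[str(fraction)] = TimeCourse(
            gene_id=str(gene),
            fraction=str(fraction),
            times=sub["time_min"].to_numpy(dtype=float),
            counts=sub["count"].to_numpy(dtype=float),
            library_sizes=sub["library_size"].to_numpy(dtype=float),
            effective_length_bp=float(lengths[0]),
        )
    return out


def write_count_table(timecourses: Iterable[TimeCourse], path) -> None:
    rows = []
    for tc in timecourses:
        for t, c, ls in zip(tc.times, tc.counts, tc.library_sizes):
            rows.append(
                dict(
                    gene_id=tc.gene_id,
                    fraction=tc.fraction,
                    time_min=t,
                    count=int(round(c)) if float(c).is_integer() else c,
                    library_size=ls,
                    effective_length_bp=tc.effective_length_bp,
                )
            )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionRules:
    """Thresholds for calling a gene strongly inducible on chromatin.

    A gene passes when (1) at least one sample has > ``min_fragments``
    fragments, (2) at least ``min_expressed_samples`` samples reach
    ``min_fpkm``, and (3) peak chromatin FPKM within the first
    ``induction_window_min`` minutes is >= ``min_fold`` times the basal
    (t = 0) level.
    """

    min_fragments: int = 32
    min_fpkm: float = 1.0
    min_expressed_samples: int = 3
    min_fold: float = 10.0
    induction_window_min: float = 40.0


@dataclass
class GeneSelectionReport:
    gene_id: str
    passed: bool
    reasons: list = field(default_factory=list)


def select_inducible_genes(
    chromatin: Mapping[str, TimeCourse] | Iterable[TimeCourse],
    rules: SelectionRules = SelectionRules(),
) -> list[GeneSelectionReport]:
    """Apply the inducibility filters to chromatin time courses.

    Report-only: every gene gets a :class:`GeneSelectionReport`; ``passed``
    is true iff ``reasons`` is empty.
    """
    if isinstance(chromatin, Mapping):
        tcs = list(chromatin.values())
    else:
        tcs = list(chromatin)
    reports = []
    for tc in tcs:
        reasons = []
        if not np.any(tc.counts >= rules.min_fragments):
            reasons.append(f"all samples < {rules.min_fragments} fragments")
        fpkm = tc.fpkm
        if np.sum(fpkm >= rules.min_fpkm) < rules.min_expressed_samples:
            reasons.append(
                f"fewer than {rules.min_expressed_samples} samples with FPKM >= {rules.min_fpkm}"
            )
        basal = fpkm[np.argmin(tc.times)]
        window = fpkm[tc.times <= rules.induction_window_min]
        peak = window.max() if window.size else 0.0
        if basal <= 0:
            if peak <= 0:
                reasons.append("no expression within the induction window")
        elif peak < rules.min_fold * basal:
            reasons.append(
                f"induction < {rules.min_fold:g}-fold within {rules.induction_window_min:g} min"
            )
        reports.append(GeneSelectionReport(tc.gene_id, passed=not reasons, reasons=reasons))
    return reports


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "n_starts": 50,
    "stages": ["select", "fit", "quality"],
    "profile_params": ["k_cyto_deg", "k2_prime", "effective_transport"],
    "selection": {},
    "synthetic": None,  # e.g. {"n_genes": 10}
    "counts": None,  # path to a count table (alternative to synthetic)
    "outdir": "results",
}


def _validate_config(config: dict) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(config)
    if cfg["counts"] is None and cfg["synthetic"] is None:
        raise ValueError("config needs either 'counts' (path) or 'synthetic' (generator spec)")
    bad = [s for s in cfg["stages"] if s not in ("select", "fit", "profile", "quality")]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    return cfg


def run_pipeline(config: dict | str | Path) -> pd.DataFrame:
    """Run selection / fitting / profiling end to end; returns the gene table.

    ``config`` is a dict or path to a YAML file.  Results are written under
    ``outdir`` (fits.tsv, profiles.tsv, selection.tsv) and the per-gene
    summary table is returned.  One failing gene does not abort the cohort.
    """
    import logging

    from . import inference, synthetic

    log = logging.getLogger("exportkinetics.pipeline")

    if not isinstance(config, dict):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(cfg["seed"])

    if cfg["counts"] is not None:
        genes = read_count_table(cfg["counts"])
    else:
        spec = dict(cfg["synthetic"])
        n_genes = int(spec.pop("n_genes", 10))
        noise = synthetic.NoiseSpec(seed=rng_seed, **spec.pop("noise", {}))
        cohort = synthetic.generate_cohort(n_genes, noise=noise, **spec)
        genes = {g.gene.gene_id: g.timecourses for g in cohort}
        synthetic.write_ground_truth([g.gene for g in cohort], outdir / "ground_truth.json")

    selected = set(genes)
    if "select" in cfg["stages"]:
        reports = select_inducible_genes(
            {gid: tcs["chromatin"] for gid, tcs in genes.items() if "chromatin" in tcs},
            SelectionRules(**cfg["selection"]),
        )
        pd.DataFrame(
            [dict(gene_id=r.gene_id, passed=r.passed, reasons="; ".join(r.reasons)) for r in reports]
        ).to_csv(outdir / "selection.tsv", sep="\t", index=False)
        selected = {r.gene_id for r in reports if r.passed}
        log.info("selection: %d/%d genes pass", len(selected), len(reports))

    rows = []
    profile_rows = []
    if "fit" in cfg["stages"]:
        for i, gid in enumerate(sorted(selected)):
            tcs = genes[gid]
            try:
                fit = inference.fit_gene(
                    tcs, n_starts=int(cfg["n_starts"]), seed=rng_seed + 7919 * i
                )
            except Exception as exc:  # pragma: no cover - defensive
                log.warning("gene %s failed to fit: %s", gid, exc)
                continue
            th = fit.theta_hat
            row = dict(
                gene_id=gid,
                k1_prime=th.k1_prime,
                k2=th.k2,
                k2_prime=th.k2_prime,
                k_cyto_deg=th.k_cyto_deg,
                chromatin_release_efficiency=th.chromatin_release_efficiency,
                export_efficiency=th.export_efficiency,
                effective_transport=th.effective_transport,
                half_life=th.half_life,
                min_cost=fit.min_cost,
                n_converged=fit.n_converged,
            )
            if "quality" in cfg["stages"]:
                row["fit_quality"] = fit.fit_quality
                row["fit_quality_band"] = inference.classify_fit_quality(fit.fit_quality)
            rows.append(row)
            if "profile" in cfg["stages"]:
                for pname in cfg["profile_params"]:
                    prof = inference.profile_likelihood(tcs, fit, pname)
                    profile_rows.append(
                        dict(
                            gene_id=gid,
                            param=pname,
                            estimate=prof.estimate,
                            ci_lower=prof.ci_lower,
                            ci_upper=prof.ci_upper,
                            identifiability=prof.identifiability,
                        )
                    )
            log.info("fitted %s (cost %.2f)", gid, fit.min_cost)

    table = pd.DataFrame(rows)
    if rows:
        table.to_csv(outdir / "fits.tsv", sep="\t", index=False)
    if profile_rows:
        pd.DataFrame(profile_rows).to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    return table
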