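"""Post-calling site-filter cascade.

Raw variant sets are reduced to the analysis SNP set by a fixed-order
cascade: site quality -> biallelic SNP -> mean depth -> call rate -> minor
allele frequency.  The quality step keeps sites with QUAL >= 30, QD >= 5 and
FS <= 200 (removal conditions are strict inequalities, so boundary values
survive).  The call-rate level is expressed directly as the minimum fraction
of genotyped samples per site ("80% missing level" == call rate >= 0.80).
Missing QD/FS/depth annotations pass their sub-criterion unless strict mode
is enabled (GBS VCFs frequently lack FS at some sites).

Each step reports (sites in, removed, out); the report telescopes, and the
cascade is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel, SiteAnnotations

log = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "FilterReport",
    "filter_quality",
    "filter_biallelic",
    "filter_mean_depth",
    "filter_call_rate",
    "filter_maf",
    "run_cascade",
]

_BASES = {"A", "C", "G", "T"}


@dataclass
class FilterConfig:
    """Thresholds for the filter cascade (defaults follow common GBS
    practice: QUAL >= 30, QD >= 5, FS <= 200, biallelic SNPs only,
    mean depth >= 5, call rate >= 0.80, MAF >= 0.05)."""

    min_qual: float = 30.0
    min_qd: float = 5.0
    max_fs: float = 200.0
    require_biallelic: bool = True
    min_mean_dp: float = 5.0
    min_call_rate: float = 0.80
    min_maf: float = 0.05
    strict_missing_info: bool = False

    def __post_init__(self):
        for name in ("min_qual", "min_qd", "min_mean_dp"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if np.isnan(self.max_fs):  # +inf disables the FS bound
            raise ValueError("max_fs must not be NaN")
        for name in ("min_call_rate", "min_maf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class FilterReport:
    """Ordered per-step survivor accounting."""

    steps: list = field(default_factory=list)  # (name, n_in, n_removed, n_out)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        self.steps.append((name, n_in, n_in - n_out, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["step", "sites_in", "sites_removed", "sites_out"]
        )

    def validate(self) -> None:
        for i, (name, n_in, removed, n_out) in enumerate(self.steps):
            assert n_out == n_in - removed, f"step {name}: accounting broken"
            if i:
                assert n_in == self.steps[i - 1][3], f"step {name}: not telescoping"


def _pass_or_missing(values: np.ndarray, ok: np.ndarray, strict: bool) -> np.ndarray:
    missing = np.isnan(values)
    return np.where(missing, not strict, ok)


def filter_quality(ann: SiteAnnotations, cfg: FilterConfig) -> np.ndarray:
    """Mask of sites passing QUAL/QD/FS thresholds (boundary values kept)."""
    df = ann.df
    qual = df["qual"].to_numpy(dtype=float)
    qd = df["qd"].to_numpy(dtype=float)
    fs = df["fs"].to_numpy(dtype=float)
    strict = cfg.strict_missing_info
    ok_qual = _pass_or_missing(qual, qual >= cfg.min_qual, strict)
    ok_qd = _pass_or_missing(qd, qd >= cfg.min_qd, strict)
    ok_fs = _pass_or_missing(fs, fs <= cfg.max_fs, strict)
    return (ok_qual & ok_qd & ok_fs).astype(bool)


def filter_biallelic(ann: SiteAnnotations) -> np.ndarray:
    """Mask keeping exactly-2-allele sites with single-base ref and alt."""
    df = ann.df
    snp = df["ref"].isin(_BASES).to_numpy() & df["alt"].isin(_BASES).to_numpy()
    return snp & (df["n_alleles"].to_numpy() == 2)


def filter_mean_depth(ann: SiteAnnotations, min_mean_dp: float,
                      strict_missing: bool = False) -> np.ndarray:
    """Mask keeping sites with mean per-sample depth >= threshold."""
    dp = ann.df["mean_dp"].to_numpy(dtype=float)
    return _pass_or_missing(dp, dp >= min_mean_dp, strict_missing).astype(bool)


def filter_call_rate(panel: GenotypePanel, level: float) -> np.ndarray:
    """Mask keeping sites genotyped in >= ``level`` fraction of samples."""
    if not (0.0 <= level <= 1.0):
        raise ValueError("call-rate level must be in [0, 1]")
    return panel.call_rate() >= level


def filter_maf(panel: GenotypePanel, min_maf: float) -> np.ndarray:
    """Mask keeping sites with minor-allele frequency >= ``min_maf``,
    computed over called alleles only.  Sites with no called samples are
    removed (with a warning)."""
    alt, m = panel.allele_counts()
    uncallable = m == 0
    if uncallable.any():
        log.warning("%d sites with zero called samples removed", int(uncallable.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(m > 0, alt / np.maximum(m, 1), np.nan)
    maf = np.minimum(f, 1.0 - f)
    return np.where(uncallable, False, maf >= min_maf)


def run_cascade(panel: GenotypePanel, ann: SiteAnnotations, cfg: FilterConfig):
    """Apply the cascade (quality -> biallelic -> mean depth -> call rate ->
    MAF) and return (filtered panel, filtered annotations, FilterReport)."""
    ann.check_aligned(panel)
    report = FilterReport()

    def apply(name: str, mask: np.ndarray, panel, ann):
        n_in = panel.n_sites
        panel = panel.subset_sites(mask)
        ann = ann.subset(mask)
        report.add(name, n_in, panel.n_sites)
        return panel, ann

    panel, ann = apply("quality", filter_quality(ann, cfg), panel, ann)
    if cfg.require_biallelic:
        panel, ann = apply("biallelic", filter_biallelic(ann), panel, ann)
    else:
        report.add("biallelic", panel.n_sites, panel.n_sites)
    panel, ann = apply(
        "mean_depth",
        filter_mean_depth(ann, cfg.min_mean_dp, cfg.strict_missing_info),
        panel,
        ann,
    )
    panel, ann = apply("call_rate", filter_call_rate(panel, cfg.min_call_rate), panel, ann)
    panel, ann = apply("maf", filter_maf(panel, cfg.min_maf), panel, ann)
    report.validate()
    return panel, ann, report
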