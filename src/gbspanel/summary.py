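"""Per-chromosome and per-subgenome SNP summaries.

Counts, density per Mbp, the 12 directional substitution classes (ref -> alt
kept directional, so A/G and G/A are distinct), transition/transversion
percentages and the Ts/Tv ratio.  Subgenome rows aggregate their constituent
chromosomes by summing counts first and computing ratios afterwards; ratios
are computed on unrounded counts and rounded only at presentation (2
decimals).  A ratio with zero transversions is undefined (NaN internally,
"undefined" in exports), never 0 or infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import ChromosomeTable, GenotypePanel, PanelError, SiteAnnotations

__all__ = [
    "SubstitutionClass",
    "TRANSITIONS",
    "CLASS_LABELS",
    "classify_substitution",
    "ts_tv_stats",
    "summarize",
    "format_summary",
]

#: The four directional transition classes (purine<->purine or
#: pyrimidine<->pyrimidine).
TRANSITIONS = frozenset({"A/G", "G/A", "C/T", "T/C"})

#: All 12 directional labels, transitions first, in conventional order.
CLASS_LABELS = [
    "A/G", "C/T", "T/C", "G/A",
    "A/T", "A/C", "T/A", "T/G", "C/A", "C/G", "G/T", "G/C",
]

_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class SubstitutionClass:
    ref: str
    alt: str

    @property
    def label(self) -> str:
        return f"{self.ref}/{self.alt}"

    @property
    def kind(self) -> str:
        return "transition" if self.label in TRANSITIONS else "transversion"


def classify_substitution(ref: str, alt: str) -> SubstitutionClass:
    """Directional substitution class of a biallelic SNP (ref -> alt)."""
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"not unambiguous bases: {ref!r}, {alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    return SubstitutionClass(ref, alt)


def ts_tv_stats(ts: int, tv: int) -> tuple[float, float, float]:
    """(Ts%, Tv%, Ts/Tv) from transition/transversion counts, rounded to 2
    decimals; NaN where undefined (no SNPs, or no transversions)."""
    total = ts + tv
    ts_pct = round(100.0 * ts / total, 2) if total else float("nan")
    tv_pct = round(100.0 * tv / total, 2) if total else float("nan")
    ratio = round(ts / tv, 2) if tv else float("nan")
    return ts_pct, tv_pct, ratio


def _unit_row(unit: str, length_bp: int, class_counts: dict) -> dict:
    n = sum(class_counts.values())
    ts = sum(v for k, v in class_counts.items() if k in TRANSITIONS)
    tv = n - ts
    ts_pct, tv_pct, ratio = ts_tv_stats(ts, tv)
    density = n / (length_bp / 1e6) if length_bp else float("nan")
    return {
        "unit": unit,
        "n_snps": n,
        "length_bp": length_bp,
        "density_per_mbp": density,
        **{k: class_counts.get(k, 0) for k in CLASS_LABELS},
        "ts_count": ts,
        "tv_count": tv,
        "ts_pct": ts_pct,
        "tv_pct": tv_pct,
        "ts_tv_ratio": ratio,
    }


def summarize(
    panel: GenotypePanel | None,
    ann: SiteAnnotations,
    chrom_table: ChromosomeTable,
) -> pd.DataFrame:
    """Summary table with one row per chromosome plus one per subgenome.

    Density is n_snps / (length / 1e6).  Every chromosome seen in the
    annotations must resolve in ``chrom_table`` (hard error otherwise).
    Only biallelic single-base SNP sites are classifiable; the input is
    expected to be the filtered panel.
    """
    if panel is not None:
        ann.check_aligned(panel)
    df = ann.df
    for chrom in sorted(set(df["chrom"])):
        chrom_table.length_bp(chrom)  # raises on absence

    rows = []
    subgenome_counts: dict[str, dict] = {}
    subgenome_len: dict[str, int] = {}
    for chrom in chrom_table.names:
        sub = df.loc[df["chrom"] == chrom]
        counts: dict[str, int] = {}
        for ref, alt in zip(sub["ref"], sub["alt"]):
            label = classify_substitution(ref, alt).label
            counts[label] = counts.get(label, 0) + 1
        length = chrom_table.length_bp(chrom)
        rows.append(_unit_row(chrom, length, counts))
        sg = chrom_table.subgenome(chrom)
        agg = subgenome_counts.setdefault(sg, {})
        for k, v in counts.items():
            agg[k] = agg.get(k, 0) + v
        subgenome_len[sg] = subgenome_len.get(sg, 0) + length
    for sg in sorted(subgenome_counts):
        rows.append(
            _unit_row(f"{sg} genome", subgenome_len[sg], subgenome_counts[sg])
        )
    out = pd.DataFrame(rows)
    if len(out):
        total = out.loc[~out["unit"].str.endswith("genome"), "n_snps"].sum()
        expected = len(df)
        if total != expected:  # conservation check
            raise PanelError(f"class-count conservation broken: {total} != {expected}")
    return out


def format_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Presentation copy: densities/percentages to 2 decimals, undefined
    ratios as the string 'undefined'."""
    out = summary.copy()
    out["density_per_mbp"] = out["density_per_mbp"].round(2)
    for col in ("ts_pct", "tv_pct", "ts_tv_ratio"):
        out[col] = out[col].map(
            lambda v: "undefined" if np.isnan(v) else f"{v:.2f}"
        )
    return out.drop(columns=["length_bp"])
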