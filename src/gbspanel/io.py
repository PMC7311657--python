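"""VCF and metadata-table input/output.

Reading goes through :mod:`cyvcf2`; writing emits VCF 4.2 text directly.
Diploid GT fields map to alternate-allele dosage (0/0 -> 0, 0/1 or 1/0 -> 1,
1/1 -> 2, ./. -> MISSING).  INFO floats are normalised to 6 significant
digits on read so that hand-written annotations (e.g. ``QD=4.9``) survive the
float32 representation used by htslib and round-trip exactly.
"""

from __future__ import annotations

import logging
import math
import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import (
    MISSING,
    ChromosomeTable,
    GenotypePanel,
    PanelError,
    SiteAnnotations,
)

log = logging.getLogger(__name__)


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed; reports the offending record."""


def _norm_float(value) -> float:
    if value is None:
        return math.nan
    try:
        v = float(value)
    except (TypeError, ValueError):
        return math.nan
    if math.isnan(v):
        return v
    # htslib stores INFO floats as float32; 6 significant digits restores
    # the intended decimal value.
    return float(f"{v:.6g}")


def read_vcf(path, keep_duplicate_positions: bool = False):
    """Read a VCF into a (GenotypePanel, SiteAnnotations) pair.

    Sites are sorted by (chrom, pos).  Sites with more than one ALT allele
    are retained and flagged via ``n_alleles`` (the biallelic filter, not the
    reader, drops them); their codes count copies of the first ALT allele
    only.  Duplicate (chrom, pos) records keep the first occurrence unless
    ``keep_duplicate_positions`` is set, in which case a PanelError is raised.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - htslib error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    has_fmt_dp = False
    try:
        for h in vcf.header_iter():
            info = h.info()
            if info.get("HeaderType") == "FORMAT" and info.get("ID") == "DP":
                has_fmt_dp = True
    except Exception:  # pragma: no cover
        has_fmt_dp = True  # fall back to per-record probing
    rows = []
    codes = []
    record_no = 0
    try:
        for var in vcf:
            record_no += 1
            gts = var.genotypes  # [a0, a1, phased] per sample
            site_codes = np.empty(len(samples), dtype=np.int8)
            for i, gt in enumerate(gts):
                a = [x for x in gt[:-1]]
                if len(a) == 0 or a[0] < 0 or (len(a) > 1 and a[1] < 0):
                    site_codes[i] = MISSING
                else:
                    if len(a) == 1:  # haploid call: dosage of allele 1
                        a = [a[0], a[0]]
                    site_codes[i] = int(a[0] == 1) + int(a[1] == 1)
            alt = var.ALT[0] if var.ALT else "."
            n_alleles = 1 + len(var.ALT)
            info_nall = var.INFO.get("NALL")
            if info_nall is not None:
                n_alleles = max(n_alleles, int(info_nall))
            try:
                dp = var.format("DP") if has_fmt_dp else None
            except KeyError:
                dp = None
            if dp is not None:
                dp = np.asarray(dp, dtype=float).ravel()
                dp = dp[dp >= 0]
                mean_dp = float(f"{dp.mean():.6g}") if dp.size else math.nan
            else:
                mean_dp = _norm_float(var.INFO.get("MDP"))
            rows.append(
                {
                    "chrom": var.CHROM,
                    "pos": int(var.POS),
                    "ref": var.REF,
                    "alt": alt,
                    "qual": _norm_float(var.QUAL),
                    "qd": _norm_float(var.INFO.get("QD")),
                    "fs": _norm_float(var.INFO.get("FS")),
                    "mean_dp": mean_dp,
                    "n_alleles": n_alleles,
                }
            )
            codes.append(site_codes)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"malformed VCF {path} at record {record_no + 1}: {exc}"
        ) from exc

    ann = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "qual", "qd", "fs", "mean_dp", "n_alleles"],
    )
    calls = (
        np.stack(codes, axis=1) if codes else np.empty((len(samples), 0), dtype=np.int8)
    )

    order = np.lexsort((ann["pos"].to_numpy(), ann["chrom"].to_numpy())) if len(ann) else []
    ann = ann.iloc[order].reset_index(drop=True) if len(ann) else ann
    calls = calls[:, order] if len(ann) else calls
    dup = ann.duplicated(subset=["chrom", "pos"]) if len(ann) else pd.Series(dtype=bool)
    if len(ann) and dup.any():
        if keep_duplicate_positions:
            raise PanelError(
                f"{int(dup.sum())} duplicate (chrom, pos) records in {path}"
            )
        log.warning("dropping %d duplicate-position records", int(dup.sum()))
        keep = (~dup).to_numpy()
        ann = ann.loc[keep].reset_index(drop=True)
        calls = calls[:, keep]

    panel = GenotypePanel(calls, samples, ann[["chrom", "pos"]].copy())
    return panel, SiteAnnotations(ann)


def _fmt(value, integer: bool = False) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "."
    if integer:
        return str(int(value))
    return f"{float(value):.6g}"


def write_vcf(panel: GenotypePanel, ann: SiteAnnotations, path) -> None:
    """Write a panel + annotations as VCF 4.2 text.

    ``read_vcf(write_vcf(x))`` reproduces genotype codes and annotations.
    Mean depth is carried in INFO:MDP (the panel stores no per-sample
    depths); an allele count above 2 is carried in INFO:NALL.
    """
    ann.check_aligned(panel)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(ann.df["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand score">\n')
        fh.write('##INFO=<ID=MDP,Number=1,Type=Float,Description="Mean sample depth">\n')
        fh.write('##INFO=<ID=NALL,Number=1,Type=Integer,Description="Observed allele count">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for j, row in enumerate(ann.df.itertuples(index=False)):
            info = []
            if not math.isnan(row.qd):
                info.append(f"QD={_fmt(row.qd)}")
            if not math.isnan(row.fs):
                info.append(f"FS={_fmt(row.fs)}")
            if not math.isnan(row.mean_dp):
                info.append(f"MDP={_fmt(row.mean_dp)}")
            if int(row.n_alleles) != 2:
                info.append(f"NALL={int(row.n_alleles)}")
            gts = "\t".join(gt_map[int(c)] for c in panel.calls[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                f"{_fmt(row.qual)}\t.\t{';'.join(info) or '.'}\tGT\t{gts}\n"
            )


def read_taxon_table(path) -> pd.DataFrame:
    """Read an accession -> (species, subspecies[, cluster]) table.

    Tab- or comma-delimited with a header; columns ``accession``, ``species``,
    ``subspecies`` required.  Duplicate accession rows are rejected.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = {"accession", "species", "subspecies"} - set(df.columns)
    if missing:
        raise PanelError(f"taxon table columns missing: {sorted(missing)}")
    if df["accession"].duplicated().any():
        dups = df.loc[df["accession"].duplicated(), "accession"].tolist()
        raise PanelError(f"duplicate accession rows: {dups}")
    return df.set_index("accession", drop=False)


def attach_taxa(panel: GenotypePanel, taxon_map: pd.DataFrame) -> GenotypePanel:
    """Return the panel with the taxon map attached; every VCF sample must be
    present in the table (hard error listing the missing ids)."""
    missing = sorted(set(panel.sample_ids) - set(taxon_map.index))
    if missing:
        raise PanelError("samples absent from taxon table: " + ", ".join(missing))
    return GenotypePanel(panel.calls, panel.sample_ids, panel.sites, taxon_map)


def read_chromosome_table(path) -> ChromosomeTable:
    """Read a chromosome table (columns name, length_bp, subgenome)."""
    df = pd.read_csv(path, sep=None, engine="python")
    return ChromosomeTable(df)
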