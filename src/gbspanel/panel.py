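"""Core data structures for genotype-panel analysis.

The central object is :class:`GenotypePanel`, a samples x sites matrix of
diploid genotype codes counting copies of the alternate allele (0, 1, 2),
with ``MISSING`` (-1) marking uncalled genotypes.  Upstream GBS callers emit
diploid calls regardless of species ploidy, so the same coding is used for
diploid, tetraploid and hexaploid accessions alike.  Per-site quality
annotations live in :class:`SiteAnnotations`, aligned to the panel by
(chromosome, position); chromosome metadata (length, subgenome assignment)
in :class:`ChromosomeTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

#: Sentinel genotype code for an uncalled (missing) genotype.
MISSING: int = -1

#: Admissible genotype codes (alternate-allele dosage or missing).
VALID_CODES = frozenset({0, 1, 2, MISSING})

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "qual", "qd", "fs", "mean_dp", "n_alleles",
]


class PanelError(ValueError):
    """Contract violation in a panel, annotation table or metadata table."""


def _check_sites_sorted_unique(sites: pd.DataFrame) -> None:
    keys = list(zip(sites["chrom"], sites["pos"]))
    if len(set(keys)) != len(keys):
        raise PanelError("site keys (chrom, pos) must be unique")
    if keys != sorted(keys):
        raise PanelError("sites must be sorted by (chrom, pos)")


@dataclass
class GenotypePanel:
    """Samples x sites matrix of alternate-allele dosages.

    Parameters
    ----------
    calls:
        Integer matrix of shape ``(n_samples, n_sites)`` with entries in
        {0, 1, 2, MISSING}.
    sample_ids:
        Unique accession identifiers, one per row.
    sites:
        DataFrame with columns ``chrom`` and ``pos`` (1-based), one row per
        column of ``calls``, sorted by (chrom, pos) with unique keys.
    taxon_map:
        Optional DataFrame indexed by accession with columns ``species`` and
        ``subspecies`` (and optionally ``cluster``) covering every sample.
    """

    calls: np.ndarray
    sample_ids: list[str]
    sites: pd.DataFrame
    taxon_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.calls.ndim != 2:
            raise PanelError("calls must be a 2-D matrix")
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise PanelError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise PanelError("sample_ids must be unique")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise PanelError(
                f"invalid genotype codes: {np.unique(self.calls[bad])!r}"
            )
        self.sites = self.sites.reset_index(drop=True)
        if not {"chrom", "pos"}.issubset(self.sites.columns):
            raise PanelError("sites needs 'chrom' and 'pos' columns")
        _check_sites_sorted_unique(self.sites)
        if self.taxon_map is not None:
            missing = set(self.sample_ids) - set(self.taxon_map.index)
            if missing:
                raise PanelError(
                    "samples absent from taxon map: " + ", ".join(sorted(missing))
                )

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def site_keys(self) -> list[tuple[str, int]]:
        return list(zip(self.sites["chrom"], self.sites["pos"]))

    # -- derived per-site quantities ------------------------------------
    def called_mask(self) -> np.ndarray:
        """Boolean matrix, True where the genotype is called."""
        return self.calls != MISSING

    def call_rate(self) -> np.ndarray:
        """Per-site fraction of samples with a called genotype."""
        return self.called_mask().mean(axis=0)

    def allele_counts(self, sample_mask: np.ndarray | None = None):
        """Per-site (alt allele count, called allele count) over a sample subset."""
        calls = self.calls if sample_mask is None else self.calls[sample_mask]
        called = calls != MISSING
        alt = np.where(called, calls, 0).sum(axis=0)
        m = 2 * called.sum(axis=0)
        return alt.astype(np.int64), m.astype(np.int64)

    def alt_frequency(self) -> np.ndarray:
        """Per-site alternate-allele frequency over called alleles (NaN if none)."""
        alt, m = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(m > 0, alt / np.maximum(m, 1), np.nan)

    def maf(self) -> np.ndarray:
        """Per-site minor-allele frequency (folded alt frequency)."""
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)

    # -- subsetting ------------------------------------------------------
    def subset_sites(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_sites, dtype=bool)
            idx[mask] = True
            mask = idx
        return GenotypePanel(
            self.calls[:, mask],
            list(self.sample_ids),
            self.sites.loc[mask].reset_index(drop=True),
            self.taxon_map,
        )

    def subset_samples(self, which) -> "GenotypePanel":
        """Subset rows by boolean mask or by a list of sample ids."""
        which = np.asarray(which)
        if which.dtype == bool:
            mask = which
        else:
            wanted = set(which.tolist())
            unknown = wanted - set(self.sample_ids)
            if unknown:
                raise PanelError("unknown samples: " + ", ".join(sorted(unknown)))
            mask = np.array([s in wanted for s in self.sample_ids])
        ids = [s for s, keep in zip(self.sample_ids, mask) if keep]
        return GenotypePanel(self.calls[mask], ids, self.sites, self.taxon_map)

    def taxon_labels(self, on: str = "species_subspecies") -> np.ndarray:
        """Per-sample taxon labels: 'species', 'subspecies', 'cluster' or
        the combined 'species_subspecies' ("species:subspecies")."""
        if self.taxon_map is None:
            raise PanelError("panel has no taxon map")
        tm = self.taxon_map.loc[self.sample_ids]
        if on == "species_subspecies":
            return (tm["species"].astype(str) + ":" + tm["subspecies"].astype(str)).to_numpy()
        if on not in tm.columns:
            raise PanelError(f"taxon map has no column {on!r}")
        return tm[on].astype(str).to_numpy()


@dataclass
class SiteAnnotations:
    """Per-site variant-quality annotations aligned with a panel.

    Columns: chrom, pos, ref, alt, qual, qd, fs, mean_dp, n_alleles.  Missing
    INFO annotations are NaN, never zero.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(ANNOTATION_COLUMNS) - set(self.df.columns)
        if missing:
            raise PanelError(f"annotation columns missing: {sorted(missing)}")
        self.df = self.df.reset_index(drop=True)
        if (self.df["pos"] < 1).any():
            raise PanelError("positions must be >= 1")
        for col in ("qual", "mean_dp", "fs"):
            vals = self.df[col]
            if (vals.dropna() < 0).any():
                raise PanelError(f"{col} must be non-negative")
        _check_sites_sorted_unique(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask: np.ndarray) -> "SiteAnnotations":
        return SiteAnnotations(self.df.loc[np.asarray(mask)].reset_index(drop=True))

    def check_aligned(self, panel: GenotypePanel) -> None:
        if len(self) != panel.n_sites or not (
            (self.df["chrom"].to_numpy() == panel.sites["chrom"].to_numpy()).all()
            and (self.df["pos"].to_numpy() == panel.sites["pos"].to_numpy()).all()
        ):
            raise PanelError("annotations are not aligned with the panel sites")


@dataclass
class ChromosomeTable:
    """Chromosome name -> (length in bp, subgenome in {A, B, D, G, other})."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"name", "length_bp", "subgenome"} - set(self.df.columns)
        if missing:
            raise PanelError(f"chromosome table columns missing: {sorted(missing)}")
        if (self.df["length_bp"] <= 0).any():
            raise PanelError("chromosome lengths must be positive")
        if self.df["name"].duplicated().any():
            raise PanelError("duplicate chromosome names")
        self.df = self.df.set_index("name", drop=False)

    def length_bp(self, chrom: str) -> int:
        try:
            return int(self.df.loc[chrom, "length_bp"])
        except KeyError:
            raise PanelError(f"chromosome {chrom!r} not in chromosome table") from None

    def subgenome(self, chrom: str) -> str:
        try:
            return str(self.df.loc[chrom, "subgenome"])
        except KeyError:
            raise PanelError(f"chromosome {chrom!r} not in chromosome table") from None

    @property
    def names(self) -> list[str]:
        return list(self.df["name"])


def load_wheat_chromosomes() -> ChromosomeTable:
    """The packaged 21-chromosome bread-wheat table (IWGSC RefSeq v1.0 names
    and lengths, subgenomes A/B/D)."""
    with resources.files("gbspanel.data").joinpath(
        "iwgsc_refseq_v1_chromosomes.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return ChromosomeTable(df)
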