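"""Synthetic allopolyploid GBS panel generator with planted truth.

The generator emulates a wheat-style genotyping-by-sequencing panel: 21
chromosomes in three subgenomes with heavily skewed SNP allocation (A >> B >>
D), directional substitution classes with a transition excess (Ts/Tv near
1.9), a configurable minor-allele-frequency spectrum, per-call missingness,
and nested sample groups separated by planted allele-frequency differentials
at known "diagnostic" sites.  Samples whose group lacks a subgenome carry
reference-fixed calls at that subgenome's sites, mimicking loci that do not
amplify off an absent homoeologous chromosome set.

Everything is drawn from a single seeded generator in a fixed order (site
allocation -> substitution classes -> frequencies -> diagnostic planting ->
genotypes -> missingness -> annotations) so truth and data never
desynchronise; identical configs and seeds give bit-identical output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import GenotypePanel, MISSING, SiteAnnotations, load_wheat_chromosomes

__all__ = [
    "GroupSpec",
    "Contrast",
    "SimulationConfig",
    "simulate_panel",
    "make_fixture_suite",
    "study_config",
]

#: Directional substitution-class weights (transitions and transversions
#: kept separate; only the within-kind proportions matter, the Ts/Tv target
#: sets the between-kind split).  Shaped like wheat GBS panels: C/T and G/A
#: dominate transitions, G/C and C/G are the commonest transversions.
DEFAULT_TS_WEIGHTS = {"A/G": 1497, "C/T": 3133, "T/C": 1469, "G/A": 3128}
DEFAULT_TV_WEIGHTS = {
    "A/T": 314, "A/C": 367, "T/A": 327, "T/G": 368,
    "C/A": 800, "C/G": 970, "G/T": 829, "G/C": 986,
}


class ConfigError(ValueError):
    """A SimulationConfig invariant is violated."""


@dataclass(frozen=True)
class GroupSpec:
    """One sample group: label, size, and which subgenomes it carries."""

    label: str
    n_samples: int
    subgenomes: frozenset = frozenset({"A", "B", "D"})
    species: str | None = None
    subspecies: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "subgenomes", frozenset(self.subgenomes))
        if self.species is None:
            object.__setattr__(self, "species", self.label)
        if self.subspecies is None:
            object.__setattr__(self, "subspecies", self.label)


@dataclass(frozen=True)
class Contrast:
    """An ordered group-vs-group contrast receiving planted diagnostic sites."""

    id: str
    side_a: tuple
    side_b: tuple
    n_sites: int

    def __post_init__(self):
        object.__setattr__(self, "side_a", tuple(self.side_a))
        object.__setattr__(self, "side_b", tuple(self.side_b))


def _study_groups() -> tuple:
    # Six clusters shaped like a wheat genebank panel: hexaploid bread wheat,
    # durum, einkorn, emmer, timopheevii (G genome) and T. urartu.
    return (
        GroupSpec("cluster1", 182, {"A", "B", "D"}, "T. aestivum", "aestivum"),
        GroupSpec("cluster2", 61, {"A", "B"}, "T. turgidum", "durum"),
        GroupSpec("cluster3", 12, {"A"}, "T. monococcum", "monococcum"),
        GroupSpec("cluster4", 9, {"A", "B"}, "T. turgidum", "dicoccon"),
        GroupSpec("cluster5", 13, {"A", "G"}, "T. timopheevii", "timopheevii"),
        GroupSpec("cluster6", 6, {"A"}, "T. urartu", "urartu"),
    )


@dataclass
class SimulationConfig:
    """Generator settings.  Defaults emulate a wheat genebank GBS panel: 283 accessions
    in six groups, 14,188 sites allocated A:B:D = 10,126:3,721:341, Ts/Tv
    target 1.9, alt-allele frequencies uniform on [0.05, 0.5], 10% missing
    calls, and 340 planted diagnostic sites per one-vs-rest contrast with a
    full (delta = 1) frequency differential."""

    seed: int = 1
    groups: tuple = field(default_factory=_study_groups)
    n_sites: int = 14188
    subgenome_weights: dict = field(
        default_factory=lambda: {"A": 10126, "B": 3721, "D": 341}
    )
    ts_tv_target: float = 1.9
    maf_spectrum: tuple = ("uniform", 0.05, 0.5)
    missing_rate: float = 0.1
    # per-contrast planted diagnostic sites; default matches the per-node
    # diagnostic-panel scale reported for real wheat GBS data (aggregate
    # 2,692 species-specific SNPs over 8 nodes ~ 340 per contrast)
    n_diagnostic: int = 340
    diagnostic_delta: float = 1.0
    contrasts: tuple | None = None  # None -> one one-vs-rest contrast per group
    absent_subgenome_mode: str = "reference"  # or "missing"
    ann_fail_fraction: float = 0.0
    multiallelic_fraction: float = 0.0

    def __post_init__(self):
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0, 1)")
        if not (0 < self.diagnostic_delta <= 1):
            raise ConfigError("diagnostic_delta must be in (0, 1]")
        if self.ts_tv_target <= 0:
            raise ConfigError("ts_tv_target must be positive")
        if self.n_sites <= 0:
            raise ConfigError("n_sites must be positive")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ConfigError("group labels must be unique")
        for g in self.groups:
            if g.n_samples < 2:
                raise ConfigError(f"group {g.label}: need >= 2 samples")
            if not g.subgenomes:
                raise ConfigError(f"group {g.label}: needs >= 1 subgenome")
        if any(w < 0 for w in self.subgenome_weights.values()):
            raise ConfigError("subgenome weights must be non-negative")
        if sum(self.subgenome_weights.values()) <= 0:
            raise ConfigError("subgenome weights must sum to > 0")
        if self.absent_subgenome_mode not in ("reference", "missing"):
            raise ConfigError("absent_subgenome_mode: 'reference' or 'missing'")
        if not (0 <= self.ann_fail_fraction < 1):
            raise ConfigError("ann_fail_fraction must be in [0, 1)")
        if not (0 <= self.multiallelic_fraction < 1):
            raise ConfigError("multiallelic_fraction must be in [0, 1)")
        kind, lo, hi = self.maf_spectrum
        if kind != "uniform" or not (0 <= lo < hi <= 1):
            raise ConfigError("maf_spectrum must be ('uniform', lo, hi), 0<=lo<hi<=1")
        for c in self.resolved_contrasts():
            if not c.side_a or not c.side_b:
                raise ConfigError(f"contrast {c.id}: empty side")
            if set(c.side_a) & set(c.side_b):
                raise ConfigError(f"contrast {c.id}: sides overlap")
            unknown = (set(c.side_a) | set(c.side_b)) - set(labels)
            if unknown:
                raise ConfigError(f"contrast {c.id}: unknown groups {sorted(unknown)}")

    def resolved_contrasts(self) -> tuple:
        if self.contrasts is not None:
            return tuple(self.contrasts)
        labels = [g.label for g in self.groups]
        return tuple(
            Contrast(
                f"{lab}-vs-rest",
                (lab,),
                tuple(l for l in labels if l != lab),
                self.n_diagnostic,
            )
            for lab in labels
        )


def study_config(**overrides) -> SimulationConfig:
    """The default genebank-panel configuration, with optional overrides."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def _draw_positions(rng, n, length) -> np.ndarray:
    """n distinct 1-based positions on a chromosome of the given length."""
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=2 * (n - pos.size))
        pos = np.unique(np.concatenate([pos, extra]))
    if pos.size > n:
        pos = np.sort(rng.choice(pos, size=n, replace=False))
    return pos


def simulate_panel(config: SimulationConfig):
    """Generate (GenotypePanel, SiteAnnotations, truth DataFrame).

    The truth table has one row per site: chrom, pos, subgenome, ref, alt,
    sub_class, is_diagnostic, contrast_id, high_side, per-group generating
    allele frequencies (``freq_<label>``), and planted annotation-failure
    flags (``fail_qual``/``fail_qd``/``fail_fs``/``fail_depth``/
    ``fail_biallelic``).
    """
    rng = np.random.default_rng(config.seed)
    chrom_table = load_wheat_chromosomes()
    n = config.n_sites
    groups = config.groups
    n_groups = len(groups)

    # 1. site allocation: subgenome, chromosome, position
    sg_names = sorted(config.subgenome_weights)
    w = np.array([config.subgenome_weights[s] for s in sg_names], dtype=float)
    site_sg = rng.choice(sg_names, size=n, p=w / w.sum())
    chrom_no = rng.integers(1, 8, size=n)
    chroms = np.array([f"{c}{s}" for c, s in zip(chrom_no, site_sg)])
    pos = np.zeros(n, dtype=np.int64)
    for chrom in sorted(set(chroms)):
        idx = np.where(chroms == chrom)[0]
        try:
            length = chrom_table.length_bp(chrom)
        except Exception:
            length = 600_000_000  # subgenomes without packaged lengths (e.g. G)
        pos[idx] = _draw_positions(rng, idx.size, length)

    # 2. substitution classes
    p_ts = config.ts_tv_target / (1.0 + config.ts_tv_target)
    is_ts = rng.random(n) < p_ts
    ts_labels = list(DEFAULT_TS_WEIGHTS)
    tv_labels = list(DEFAULT_TV_WEIGHTS)
    ts_w = np.array([DEFAULT_TS_WEIGHTS[k] for k in ts_labels], dtype=float)
    tv_w = np.array([DEFAULT_TV_WEIGHTS[k] for k in tv_labels], dtype=float)
    cls = np.empty(n, dtype=object)
    cls[is_ts] = rng.choice(ts_labels, size=int(is_ts.sum()), p=ts_w / ts_w.sum())
    cls[~is_ts] = rng.choice(tv_labels, size=int((~is_ts).sum()), p=tv_w / tv_w.sum())
    ref = np.array([c[0] for c in cls])
    alt = np.array([c[2] for c in cls])

    # 3. base alt-allele frequencies (shared across groups)
    _, lo, hi = config.maf_spectrum
    base_freq = rng.uniform(lo, hi, size=n)
    freqs = np.tile(base_freq, (n_groups, 1))

    # 4. diagnostic planting
    label_to_row = {g.label: i for i, g in enumerate(groups)}
    is_diag = np.zeros(n, dtype=bool)
    contrast_id = np.array([""] * n, dtype=object)
    high_side = np.array([""] * n, dtype=object)
    delta = config.diagnostic_delta
    for contrast in config.resolved_contrasts():
        members = [label_to_row[l] for l in contrast.side_a + contrast.side_b]
        shared = frozenset.intersection(*[groups[i].subgenomes for i in members])
        eligible = np.where(np.isin(site_sg, sorted(shared)) & ~is_diag)[0]
        if eligible.size < contrast.n_sites:
            raise ConfigError(
                f"contrast {contrast.id}: only {eligible.size} eligible sites "
                f"for {contrast.n_sites} requested"
            )
        chosen = rng.choice(eligible, size=contrast.n_sites, replace=False)
        p_low = rng.uniform(0.0, 1.0 - delta, size=contrast.n_sites)
        a_high = rng.random(contrast.n_sites) < 0.5
        is_diag[chosen] = True
        contrast_id[chosen] = contrast.id
        high_side[chosen] = np.where(a_high, "a", "b")
        rows_a = [label_to_row[l] for l in contrast.side_a]
        rows_b = [label_to_row[l] for l in contrast.side_b]
        for k, site in enumerate(chosen):
            pa = p_low[k] + (delta if a_high[k] else 0.0)
            pb = p_low[k] + (0.0 if a_high[k] else delta)
            freqs[rows_a, site] = pa
            freqs[rows_b, site] = pb

    # 5. genotypes (binomial dosage), absent subgenomes reference-fixed
    sample_rows = np.concatenate(
        [np.full(g.n_samples, i, dtype=int) for i, g in enumerate(groups)]
    )
    calls = rng.binomial(2, freqs[sample_rows, :]).astype(np.int8)
    for i, g in enumerate(groups):
        absent = ~np.isin(site_sg, sorted(g.subgenomes))
        if absent.any():
            fill = 0 if config.absent_subgenome_mode == "reference" else MISSING
            calls[np.ix_(sample_rows == i, absent)] = fill

    # 6. missingness
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = MISSING

    # 7. annotations, with planted filter failures
    qual = rng.uniform(50, 1000, size=n)
    qd = rng.uniform(10, 40, size=n)
    fs = np.minimum(rng.exponential(5.0, size=n), 199.0)
    mean_dp = rng.uniform(8, 40, size=n)
    n_alleles = np.full(n, 2, dtype=int)
    fail = {k: np.zeros(n, dtype=bool) for k in ("qual", "qd", "fs", "depth", "biallelic")}
    if config.ann_fail_fraction > 0:
        n_fail = int(round(config.ann_fail_fraction * n))
        chosen = rng.choice(n, size=n_fail, replace=False)
        which = rng.integers(0, 4, size=n_fail)
        for site, crit in zip(chosen, which):
            if crit == 0:
                qual[site] = rng.uniform(0, 29.9)
                fail["qual"][site] = True
            elif crit == 1:
                qd[site] = rng.uniform(0, 4.9)
                fail["qd"][site] = True
            elif crit == 2:
                fs[site] = rng.uniform(200.1, 400.0)
                fail["fs"][site] = True
            else:
                mean_dp[site] = rng.uniform(0, 4.9)
                fail["depth"][site] = True
    if config.multiallelic_fraction > 0:
        n_multi = int(round(config.multiallelic_fraction * n))
        chosen = rng.choice(np.where(~is_diag)[0], size=n_multi, replace=False)
        n_alleles[chosen] = 3
        fail["biallelic"][chosen] = True

    # assemble, sorted by (chrom, pos)
    order = np.lexsort((pos, chroms))
    sites = pd.DataFrame({"chrom": chroms[order], "pos": pos[order]})
    sample_ids = []
    for g in groups:
        sample_ids += [f"{g.label}_{i + 1:03d}" for i in range(g.n_samples)]
    taxon_map = pd.DataFrame(
        {
            "accession": sample_ids,
            "species": np.repeat([g.species for g in groups], [g.n_samples for g in groups]),
            "subspecies": np.repeat(
                [g.subspecies for g in groups], [g.n_samples for g in groups]
            ),
            "cluster": np.repeat([g.label for g in groups], [g.n_samples for g in groups]),
        }
    ).set_index("accession", drop=False)

    panel = GenotypePanel(calls[:, order], sample_ids, sites, taxon_map)
    ann = SiteAnnotations(
        pd.DataFrame(
            {
                "chrom": chroms[order],
                "pos": pos[order],
                "ref": ref[order],
                "alt": alt[order],
                "qual": np.round(qual[order], 4),
                "qd": np.round(qd[order], 4),
                "fs": np.round(fs[order], 4),
                "mean_dp": np.round(mean_dp[order], 4),
                "n_alleles": n_alleles[order],
            }
        )
    )
    truth = pd.DataFrame(
        {
            "chrom": chroms[order],
            "pos": pos[order],
            "subgenome": site_sg[order],
            "ref": ref[order],
            "alt": alt[order],
            "sub_class": cls[order],
            "is_diagnostic": is_diag[order],
            "contrast_id": contrast_id[order],
            "high_side": high_side[order],
            **{f"freq_{g.label}": np.round(freqs[i, order], 6) for i, g in enumerate(groups)},
            **{f"fail_{k}": v[order] for k, v in fail.items()},
        }
    )
    return panel, ann, truth


#: Seed used for the packaged/committed fixture suite.
FIXTURE_SEED = 2020


def fixture_config() -> SimulationConfig:
    """Tiny deterministic configuration behind the committed test fixtures."""
    return SimulationConfig(
        seed=FIXTURE_SEED,
        groups=(
            GroupSpec("grpA", 4, {"A", "B"}, "sp. one", "one"),
            GroupSpec("grpB", 4, {"A", "B"}, "sp. two", "two"),
            GroupSpec("grpC", 3, {"A"}, "sp. three", "three"),
        ),
        n_sites=60,
        subgenome_weights={"A": 7, "B": 3},
        missing_rate=0.1,
        n_diagnostic=5,
        ann_fail_fraction=0.1,
    )


def make_fixture_suite(outdir, config: SimulationConfig | None = None) -> dict:
    """Write a small canonical fixture set (VCF + taxon table + chromosome
    table + truth) into ``outdir``; regenerable bit-for-bit from the packaged
    seed.  Returns the path of each artifact."""
    from .io import write_vcf  # local import to avoid a cycle

    os.makedirs(outdir, exist_ok=True)
    config = config or fixture_config()
    panel, ann, truth = simulate_panel(config)
    paths = {
        "vcf": os.path.join(outdir, "fixture.vcf"),
        "taxa": os.path.join(outdir, "taxa.tsv"),
        "chroms": os.path.join(outdir, "chromosomes.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_vcf(panel, ann, paths["vcf"])
    panel.taxon_map.to_csv(paths["taxa"], sep="\t", index=False)
    chrom_table = load_wheat_chromosomes()
    used = sorted(set(panel.sites["chrom"]))
    chrom_table.df.loc[chrom_table.df["name"].isin(used)].to_csv(
        paths["chroms"], sep="\t", index=False
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
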