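"""End-to-end orchestration: filtering -> summary -> structure -> tree ->
AMOVA -> diagnostic-SNP hierarchy, with a run manifest for reproducibility.

Every artifact is a delimited text file with a header and fixed column
order; the manifest records package/library versions, seeds and the full
parameter echo, so a run can be reproduced from it.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amova import amova, nucleotide_diversity, pairwise_phipt
from .discriminate import DiscriminationTree, load_wheat_tree, run_hierarchy
from .filtering import FilterConfig, run_cascade
from .io import attach_taxa, read_chromosome_table, read_taxon_table, read_vcf, write_vcf
from .panel import load_wheat_chromosomes
from .structure import (
    allele_sharing_distance,
    dapc_cross_validate,
    find_clusters,
    impute_codes,
    nj_tree,
    DAPC,
)
from .summary import format_summary, summarize


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


@dataclass
class RunConfig:
    vcf: str
    taxon_table: str
    out_dir: str
    chromosome_table: str | None = None  # None -> packaged wheat table
    node_tree: str | None = None  # None -> packaged wheat tree
    filter: FilterConfig = field(default_factory=FilterConfig)
    k_max: int = 10
    n_pcs: int = 20
    dapc_n_pcs: int = 30
    n_perm: int = 999
    alpha: float = 0.05
    correction: str = "bonferroni"
    seed: int = 42

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        flt = FilterConfig(**raw.pop("filter", {}))
        return cls(filter=flt, **raw)

    def validate(self) -> None:
        for name in ("vcf", "taxon_table"):
            p = getattr(self, name)
            if not os.path.exists(p):
                raise FileNotFoundError(f"{name}: {p}")
        for name in ("chromosome_table", "node_tree"):
            p = getattr(self, name)
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"{name}: {p}")


def run_all(config: RunConfig) -> str:
    """Run every stage; returns the artifact directory."""
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest = {
        "gbspanel_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "parameters": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }

    stage = "load"
    try:
        panel, ann = read_vcf(config.vcf)
        panel = attach_taxa(panel, read_taxon_table(config.taxon_table))
        chrom_table = (
            read_chromosome_table(config.chromosome_table)
            if config.chromosome_table
            else load_wheat_chromosomes()
        )
        tree = (
            DiscriminationTree.from_yaml(config.node_tree)
            if config.node_tree
            else load_wheat_tree()
        )

        stage = "filter"
        panel, ann, report = run_cascade(panel, ann, config.filter)
        report.to_frame().to_csv(os.path.join(out, "filter_report.tsv"), sep="\t", index=False)
        write_vcf(panel, ann, os.path.join(out, "filtered.vcf"))

        stage = "summarize"
        summary = summarize(panel, ann, chrom_table)
        format_summary(summary).to_csv(os.path.join(out, "snp_summary.tsv"), sep="\t", index=False)

        stage = "structure"
        finder = find_clusters(panel, k_max=config.k_max, n_pcs=config.n_pcs, seed=config.seed)
        finder.bic_.rename_axis("k").to_frame().to_csv(os.path.join(out, "bic.tsv"), sep="\t")
        clusters = pd.DataFrame({"accession": panel.sample_ids, "cluster": finder.labels_})
        clusters.to_csv(os.path.join(out, "clusters.tsv"), sep="\t", index=False)
        X = impute_codes(panel)
        dapc = DAPC(
            n_pcs=min(config.dapc_n_pcs, panel.n_samples - 1), random_state=config.seed
        ).fit(X, finder.labels_)
        coords = dapc.transform(X)
        pd.DataFrame(
            coords, columns=[f"LD{i + 1}" for i in range(coords.shape[1])]
        ).assign(accession=panel.sample_ids, cluster=finder.labels_).to_csv(
            os.path.join(out, "dapc_coords.tsv"), sep="\t", index=False
        )
        xval = dapc_cross_validate(X, finder.labels_, seed=config.seed)
        xval.to_csv(os.path.join(out, "dapc_xval.tsv"), sep="\t", index=False)
        manifest["dapc"] = {
            "k": int(finder.k_),
            "n_pcs": int(dapc.n_pcs),
            "pc_variance_ratio": dapc.pc_variance_ratio_,
            "n_discriminants": int(dapc.n_discriminants_),
        }

        stage = "tree"
        newick = nj_tree(allele_sharing_distance(panel), panel.sample_ids)
        with open(os.path.join(out, "nj_tree.nwk"), "w") as fh:
            fh.write(newick + "\n")

        stage = "amova"
        result = amova(panel, finder.labels_, n_perm=config.n_perm, seed=config.seed)
        result.to_frame().to_csv(os.path.join(out, "amova.tsv"), sep="\t", index=False)
        phi, pval = pairwise_phipt(panel, finder.labels_)
        phi.stack().rename_axis(["group_1", "group_2"]).rename("phi_pt").reset_index().to_csv(
            os.path.join(out, "pairwise_phipt.tsv"), sep="\t", index=False
        )
        nucleotide_diversity(panel, finder.labels_).rename_axis("group").to_frame().to_csv(
            os.path.join(out, "nucleotide_diversity.tsv"), sep="\t"
        )
        manifest["amova"] = {"phi_pt": result.phi_pt, "perm_p": result.perm_p}

        stage = "discriminate"
        panels = run_hierarchy(
            panel, tree, alpha=config.alpha, correction=config.correction,
            ann=ann, verify=True,
        )
        rows = []
        for np_ in panels:
            t = np_.table.copy()
            t.insert(0, "node", np_.node_id)
            rows.append(t)
        markers = (
            pd.concat(rows, ignore_index=True)
            if rows
            else pd.DataFrame(columns=["node", "chrom", "pos"])
        )
        markers.to_csv(os.path.join(out, "diagnostic_snps.tsv"), sep="\t", index=False)
        manifest["discriminate"] = {
            "aggregate_snps": int(sum(p.n_snps for p in panels)),
            "per_node": {p.node_id: int(p.n_snps) for p in panels},
        }
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return out
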