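import os
import textwrap

import numpy as np
import pandas as pd
import pytest

from gbspanel.panel import GenotypePanel, SiteAnnotations
from gbspanel.simulate import SimulationConfig, GroupSpec, simulate_panel

DATA_DIR = os.path.join(os.path.dirname(__file__), "data")

HAND_VCF = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=1A>
    ##contig=<ID=1B>
    ##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
    ##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
    1A\t100\t.\tA\tG\t50\t.\tQD=4.9;FS=201\tGT:DP\t0/0:10\t0/1:12\t1/1:9
    1A\t200\t.\tC\tT\t29\t.\tQD=10;FS=1.2\tGT:DP\t0/0:8\t./.:.\t1/0:7
    1B\t150\t.\tG\tA\t90\t.\t.\tGT:DP\t1/1:15\t0/0:20\t0/1:11
    1B\t300\t.\tT\tA,C\t60\t.\tQD=12;FS=3\tGT:DP\t0/0:9\t0/2:6\t0/1:5
    """
)


@pytest.fixture()
def hand_vcf(tmp_path):
    """Hand-written 3-sample x 4-site VCF with known codes and annotations."""
    path = tmp_path / "hand.vcf"
    path.write_text(HAND_VCF)
    return str(path)


@pytest.fixture()
def hand_taxa(tmp_path):
    path = tmp_path / "taxa.tsv"
    path.write_text(
        "accession\tspecies\tsubspecies\n"
        "S1\tT. aestivum\taestivum\n"
        "S2\tT. aestivum\tcompactum\n"
        "S3\tT. turgidum\tdurum\n"
    )
    return str(path)


def tiny_panel(calls, chroms=None, taxa=None):
    """Build a small panel directly from a call matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    sites = pd.DataFrame(
        {"chrom": chroms or ["1A"] * m, "pos": np.arange(1, m + 1) * 10}
    )
    ids = [f"s{i}" for i in range(n)]
    tm = None
    if taxa is not None:
        tm = pd.DataFrame(
            {"accession": ids, "species": taxa, "subspecies": taxa}
        ).set_index("accession", drop=False)
    return GenotypePanel(calls, ids, sites, tm)


def annotations_for(panel, **overrides):
    """Clean annotations aligned with a panel; columns overridable."""
    m = panel.n_sites
    df = pd.DataFrame(
        {
            "chrom": panel.sites["chrom"],
            "pos": panel.sites["pos"],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "qual": np.full(m, 100.0),
            "qd": np.full(m, 20.0),
            "fs": np.full(m, 1.0),
            "mean_dp": np.full(m, 15.0),
            "n_alleles": np.full(m, 2),
        }
    )
    for key, values in overrides.items():
        df[key] = values
    return SiteAnnotations(df)


@pytest.fixture(scope="session")
def sim_small():
    """Two clearly separated 10-sample groups, 400 sites, planted truth."""
    cfg = SimulationConfig(
        seed=7,
        groups=(
            GroupSpec("left", 10, {"A", "B"}, "sp. left", "l"),
            GroupSpec("right", 10, {"A", "B"}, "sp. right", "r"),
        ),
        n_sites=400,
        subgenome_weights={"A": 3, "B": 1},
        n_diagnostic=25,
        missing_rate=0.05,
    )
    return simulate_panel(cfg)
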