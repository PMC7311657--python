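import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from gbspanel.discriminate import (
    DiagnosticSNPSelector,
    DiscriminationNode,
    DiscriminationTree,
    chi_square_scan,
    discriminant_panel,
    load_wheat_tree,
    run_hierarchy,
    snp_chi_square,
    verify_node_pcoa,
)
from gbspanel.panel import PanelError
from gbspanel.simulate import Contrast, GroupSpec, SimulationConfig, simulate_panel

from conftest import tiny_panel


def panel_from_allele_counts(ref_a, alt_a, ref_b, alt_b):
    """Build a panel realising given per-side allele counts at one site."""
    def genotypes(ref, alt):
        assert (ref + alt) % 2 == 0
        codes = [2] * (alt // 2) + ([1] if alt % 2 else []) + [0] * (ref // 2)
        if (alt % 2) and (ref % 2):
            codes = [2] * (alt // 2) + [1] + [0] * (ref // 2)
        return codes

    a = genotypes(ref_a, alt_a)
    b = genotypes(ref_b, alt_b)
    calls = np.array(a + b, dtype=np.int8)[:, None]
    taxa = ["A"] * len(a) + ["B"] * len(b)
    return tiny_panel(calls, taxa=taxa), np.array([t == "A" for t in taxa])


class TestChiSquare:
    def test_identical_counts_give_zero(self):
        panel, mask_a = panel_from_allele_counts(10, 10, 10, 10)
        stat, p = snp_chi_square(panel, mask_a, ~mask_a, 0)
        assert stat == 0.0 and p == 1.0

    def test_closed_form_fixed_difference(self):
        # alleles x sides table [[10, 0], [0, 10]]: N(ad-bc)^2/products = 20
        panel, mask_a = panel_from_allele_counts(10, 0, 0, 10)
        stat, _ = snp_chi_square(panel, mask_a, ~mask_a, 0)
        assert stat == pytest.approx(20.0)

    def test_matches_scipy_oracle_on_random_tables(self):
        rng = np.random.default_rng(8)
        checked = 0
        while checked < 100:
            ref_a, alt_a, ref_b, alt_b = rng.integers(0, 12, size=4) * 2
            table = np.array([[ref_a, ref_b], [alt_a, alt_b]])
            if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            panel, mask_a = panel_from_allele_counts(ref_a, alt_a, ref_b, alt_b)
            stat, p = snp_chi_square(panel, mask_a, ~mask_a, 0)
            expected = chi2_contingency(table, correction=False)
            assert stat == pytest.approx(expected.statistic, rel=1e-10)
            assert p == pytest.approx(expected.pvalue, rel=1e-8, abs=1e-12)
            checked += 1

    def test_invariant_to_side_and_allele_swap(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(0, 3, size=(20, 30)).astype(np.int8)
        panel = tiny_panel(calls)
        mask = np.arange(20) < 10
        s1, p1, _ = chi_square_scan(panel, mask, ~mask)
        s2, p2, _ = chi_square_scan(panel, ~mask, mask)
        np.testing.assert_allclose(s1, s2)
        flipped = tiny_panel((2 - calls).astype(np.int8))  # swap allele labels
        s3, _, _ = chi_square_scan(flipped, mask, ~mask)
        np.testing.assert_allclose(s1, s3)

    def test_zero_marginal_returns_zero_stat_p_one(self):
        panel, mask_a = panel_from_allele_counts(10, 0, 8, 0)  # no alt anywhere
        stat, p = snp_chi_square(panel, mask_a, ~mask_a, 0)
        assert stat == 0.0 and p == 1.0

    def test_genotype_granularity_agrees_with_scipy(self):
        rng = np.random.default_rng(10)
        calls = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
        panel = tiny_panel(calls)
        mask = np.arange(30) < 15
        stat, p, _ = chi_square_scan(panel, mask, ~mask, granularity="genotype")
        for j in range(20):
            table = np.array(
                [
                    [(calls[mask, j] == g).sum() for g in (0, 1, 2)],
                    [(calls[~mask, j] == g).sum() for g in (0, 1, 2)],
                ]
            ).T
            table = table[table.sum(axis=1) > 0]
            expected = chi2_contingency(table, correction=False)
            assert stat[j] == pytest.approx(expected.statistic, rel=1e-10)


class TestSelector:
    def test_recovers_planted_fixed_differences(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(2, 0.3, size=(40, 200)).astype(np.int8)
        y = np.array(["u"] * 20 + ["v"] * 20)
        X[:20, :10] = 0
        X[20:, :10] = 2  # 10 fixed differences
        sel = DiagnosticSNPSelector(alpha=0.05, correction="bonferroni").fit(X, y)
        assert sel.support_[:10].all()
        assert sel.support_[10:].sum() <= 2
        assert sel.transform(X).shape[1] == sel.support_.sum()

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(2)
        X = rng.binomial(2, 0.4, size=(30, 150)).astype(np.int8)
        y = np.array(["u"] * 15 + ["v"] * 15)
        X[:15, :20] = 0
        strict = DiagnosticSNPSelector(alpha=1e-6).fit(X, y).support_
        loose = DiagnosticSNPSelector(alpha=0.1).fit(X, y).support_
        assert (strict <= loose).all()

    def test_adjusted_p_bounded_by_one(self):
        X = np.zeros((10, 5), dtype=np.int8)
        X[5:] = 1
        sel = DiagnosticSNPSelector().fit(X, np.array(["a"] * 5 + ["b"] * 5))
        assert (sel.pvalues_adjusted_ <= 1.0).all()


def three_level_config(delta=1.0, n_diag=20, seed=31):
    groups = (
        GroupSpec("aest1", 12, {"A", "B"}, "T. aestivum", "aestivum"),
        GroupSpec("aest2", 12, {"A", "B"}, "T. aestivum", "compactum"),
        GroupSpec("dur1", 12, {"A", "B"}, "T. turgidum", "durum"),
        GroupSpec("dur2", 12, {"A", "B"}, "T. turgidum", "polonicum"),
    )
    contrasts = (
        Contrast("species", ("aest1", "aest2"), ("dur1", "dur2"), n_diag),
        Contrast("within_a", ("aest1",), ("aest2",), n_diag),
        Contrast("within_t", ("dur1",), ("dur2",), n_diag),
    )
    return SimulationConfig(
        seed=seed, groups=groups, n_sites=1500, subgenome_weights={"A": 3, "B": 1},
        contrasts=contrasts, diagnostic_delta=delta, missing_rate=0.05,
    )


def nested_tree():
    return DiscriminationTree(
        nodes=[
            DiscriminationNode(
                "1",
                ("T. aestivum:aestivum", "T. aestivum:compactum"),
                ("T. turgidum:durum", "T. turgidum:polonicum"),
            ),
            DiscriminationNode(
                "2A", ("T. aestivum:aestivum",), ("T. aestivum:compactum",), parent="1"
            ),
            DiscriminationNode(
                "2T", ("T. turgidum:durum",), ("T. turgidum:polonicum",), parent="1"
            ),
        ]
    )


class TestTree:
    def test_packaged_wheat_tree_loads_and_nests(self):
        tree = load_wheat_tree()
        ids = [n.id for n in tree.nodes]
        assert ids == ["1", "2A", "2T", "2-2T", "3A", "3T", "4A", "4T"]
        by_id = {n.id: n for n in tree.nodes}
        assert by_id["4T"].scope <= by_id["3T"].scope <= by_id["2T"].scope

    def test_overlapping_sides_rejected(self):
        with pytest.raises(PanelError, match="overlap"):
            DiscriminationNode("x", ("a",), ("a", "b"))

    def test_unnested_child_rejected(self):
        with pytest.raises(PanelError, match="nested"):
            DiscriminationTree(
                nodes=[
                    DiscriminationNode("1", ("a",), ("b",)),
                    DiscriminationNode("2", ("a",), ("c",), parent="1"),
                ]
            )


class TestHierarchy:
    def test_planted_panels_recovered_per_node(self):
        cfg = three_level_config()
        panel, ann, truth = simulate_panel(cfg)
        panels = run_hierarchy(panel, nested_tree(), alpha=0.05, ann=ann)
        by_node = {p.node_id: p for p in panels}
        for node_id, contrast_id in [("1", "species"), ("2A", "within_a"), ("2T", "within_t")]:
            planted = set(
                zip(
                    truth.loc[truth.contrast_id == contrast_id, "chrom"],
                    truth.loc[truth.contrast_id == contrast_id, "pos"],
                )
            )
            found = set(zip(by_node[node_id].table.chrom, by_node[node_id].table.pos))
            assert len(found & planted) / len(planted) >= 0.99, node_id

    def test_alpha_zero_gives_empty_panels(self):
        cfg = three_level_config()
        panel, ann, _ = simulate_panel(cfg)
        node = nested_tree().nodes[0]
        assert discriminant_panel(panel, node, alpha=0.0).n_snps == 0

    def test_single_node_tree_reduces_to_discriminant_panel(self):
        cfg = three_level_config()
        panel, _, _ = simulate_panel(cfg)
        tree = DiscriminationTree(nodes=[nested_tree().nodes[0]])
        [only] = run_hierarchy(panel, tree)
        direct = discriminant_panel(panel, tree.nodes[0])
        pd.testing.assert_frame_equal(only.table, direct.table)

    def test_identical_frequency_subspecies_yield_no_snps(self):
        # two subspecies simulated with identical frequencies everywhere:
        # their node returns an empty panel
        cfg = three_level_config()
        groups = cfg.groups
        contrasts = (cfg.contrasts[0], cfg.contrasts[1])  # nothing planted for 2T
        cfg2 = SimulationConfig(
            seed=cfg.seed, groups=groups, n_sites=1500,
            subgenome_weights={"A": 3, "B": 1}, contrasts=contrasts,
            diagnostic_delta=1.0, missing_rate=0.05,
        )
        panel, _, _ = simulate_panel(cfg2)
        panels = run_hierarchy(panel, nested_tree())
        by_node = {p.node_id: p for p in panels}
        assert by_node["2T"].n_snps == 0

    def test_aggregate_is_sum_of_disjoint_planted_panels(self):
        cfg = three_level_config()
        panel, ann, truth = simulate_panel(cfg)
        panels = run_hierarchy(panel, nested_tree(), ann=ann)
        aggregate = sum(p.n_snps for p in panels)
        # with delta = 1, every node retains at least its planted sites
        assert aggregate >= 3 * 20
        # per-chromosome counts partition each panel
        for p in panels:
            assert p.per_chrom.sum() == p.n_snps

    def test_node_matching_no_samples_is_error(self):
        cfg = three_level_config()
        panel, _, _ = simulate_panel(cfg)
        node = DiscriminationNode("bad", ("no:such",), ("T. aestivum:aestivum",))
        with pytest.raises(PanelError, match="side A"):
            discriminant_panel(panel, node)


class TestVerifyPcoa:
    def test_perfect_panel_separates(self):
        cfg = three_level_config()
        panel, _, truth = simulate_panel(cfg)
        node = nested_tree().nodes[0]
        node_panel = discriminant_panel(panel, node)
        # restrict to the sites planted for this very contrast: a perfectly
        # diagnostic panel with no nested substructure
        planted = truth["contrast_id"].to_numpy() == "species"
        node_panel.table = (
            panel.sites.loc[planted].assign(
                statistic=np.nan, p=np.nan, p_adj=np.nan, low_expected=False
            ).reset_index(drop=True)
        )
        ftpc1, ftpc2, sep = verify_node_pcoa(panel, node_panel, node)
        assert ftpc1 >= ftpc2
        assert sep >= 0.9

    def test_random_nondiagnostic_snps_score_near_zero(self):
        cfg = three_level_config()
        panel, _, truth = simulate_panel(cfg)
        node = nested_tree().nodes[0]
        nondiag = ~truth["is_diagnostic"].to_numpy()
        idx = np.where(nondiag)[0][:40]
        fake = discriminant_panel(panel, node, alpha=1.1, correction="none")
        fake.table = fake.table.iloc[idx].reset_index(drop=True)
        _, _, sep = verify_node_pcoa(panel, fake, node)
        assert sep < 0.35

    def test_tiny_panel_warns_and_undefined(self):
        cfg = three_level_config()
        panel, _, _ = simulate_panel(cfg)
        node = nested_tree().nodes[0]
        empty = discriminant_panel(panel, node, alpha=0.0)
        with pytest.warns(UserWarning, match="< 2 SNPs"):
            out = verify_node_pcoa(panel, empty, node)
        assert out is None and empty.separation is None


class TestChiSquareProperties:
    from hypothesis import given, settings, strategies as st

    counts = st.integers(min_value=0, max_value=15)

    @given(ra=counts, aa=counts, rb=counts, ab=counts)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_swap_invariance_on_generated_tables(self, ra, aa, rb, ab):
        """Statistic unchanged by swapping contrast sides or allele labels."""
        from hypothesis import assume
        assume(ra + aa > 0 and rb + ab > 0)  # each side needs a sample
        panel, mask_a = panel_from_allele_counts(2 * ra, 2 * aa, 2 * rb, 2 * ab)
        stat_ab, _, _ = chi_square_scan(panel, mask_a, ~mask_a)
        stat_ba, _, _ = chi_square_scan(panel, ~mask_a, mask_a)
        assert stat_ab[0] == pytest.approx(stat_ba[0], abs=1e-12)
        flipped = tiny_panel((2 - panel.calls).astype(np.int8))
        stat_flip, _, _ = chi_square_scan(flipped, mask_a, ~mask_a)
        assert stat_ab[0] == pytest.approx(stat_flip[0], abs=1e-9)
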