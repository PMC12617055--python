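import numpy as np
import pandas as pd
import pytest

from sexbias import landscape
from sexbias.io import validate_annotation, validate_sex_systems


@pytest.fixture
def systems():
    return validate_sex_systems(
        pd.DataFrame(
            {
                "species": ["zw", "xy", "mystery"],
                "heterogamety": ["ZW", "XY", "unknown"],
                "sex_linked_chromosomes": ["LG05", "LG05", ""],
            }
        )
    )


@pytest.fixture
def annotation():
    n_lg01, n_lg05, n_lg13 = 100, 10, 20
    rows = []
    for chrom, n in [("LG01", n_lg01), ("LG05", n_lg05), ("LG13", n_lg13),
                     ("MT", 2), ("scaffold_001", 3)]:
        for i in range(n):
            rows.append({"gene_id": f"{chrom}_g{i}", "chromosome": chrom,
                         "start": i * 2000, "end": i * 2000 + 1000})
    return validate_annotation(pd.DataFrame(rows))


def _de(annotation, bias_by_gene):
    genes = annotation["gene_id"]
    bias = genes.map(lambda g: bias_by_gene.get(g, "unbiased"))
    lfc = bias.map({"FBG": -2.0, "MBG": 2.0, "unbiased": 0.05})
    return pd.DataFrame(
        {
            "gene_id": genes,
            "lfc": lfc,
            "pvalue": np.where(bias == "unbiased", 0.5, 1e-6),
            "padj": np.where(bias == "unbiased", 0.8, 1e-5),
            "bias_class": bias,
        }
    )


class TestClassing:
    def test_zw_species_labels(self, annotation, systems):
        c = landscape.classify_chromosomes(annotation, systems, "zw")
        by_chrom = c.groupby(c["chromosome"].astype(str))["chrom_class"].unique()
        assert list(by_chrom["LG05"]) == ["sex_chromosome"]
        assert list(by_chrom["LG13"]) == ["autosome"]
        assert list(by_chrom["MT"]) == ["excluded"]
        assert list(by_chrom["scaffold_001"]) == ["excluded"]

    def test_unknown_system_has_no_sex_labels(self, annotation, systems):
        c = landscape.classify_chromosomes(annotation, systems, "mystery")
        assert (c["chrom_class"] != "sex_chromosome").all()

    def test_missing_sex_chromosome_is_error(self, annotation, systems):
        bad = systems.copy()
        bad.at[0, "sex_linked_chromosomes"] = ["LG99"]
        with pytest.raises(ValueError, match="LG99"):
            landscape.classify_chromosomes(annotation, bad, "zw")


class TestProportions:
    def test_toy_arithmetic(self, annotation, systems):
        bias = {f"LG05_g{i}": "MBG" for i in range(4)}
        bias.update({f"LG01_g{i}": "MBG" for i in range(5)})
        de = _de(annotation, bias)
        c = landscape.classify_chromosomes(annotation, systems, "zw")
        props = landscape.sbg_proportions(de, c, by="MBG").set_index("chromosome")
        assert props.loc["LG05", "proportion"] == pytest.approx(0.40)
        assert props.loc["LG01", "proportion"] == pytest.approx(0.05)

    def test_fbg_and_mbg_sum_to_total(self, annotation, systems):
        rng = np.random.default_rng(0)
        bias = {
            g: rng.choice(["FBG", "MBG", "unbiased"], p=[0.2, 0.2, 0.6])
            for g in annotation["gene_id"]
        }
        de = _de(annotation, bias)
        c = landscape.classify_chromosomes(annotation, systems, "zw")
        total = landscape.sbg_proportions(de, c, by="all").set_index("chromosome")
        f = landscape.sbg_proportions(de, c, by="FBG").set_index("chromosome")
        m = landscape.sbg_proportions(de, c, by="MBG").set_index("chromosome")
        np.testing.assert_allclose(
            total["proportion"], f["proportion"] + m["proportion"]
        )

    def test_all_unbiased_gives_zero(self, annotation, systems):
        de = _de(annotation, {})
        c = landscape.classify_chromosomes(annotation, systems, "zw")
        assert (landscape.sbg_proportions(de, c)["proportion"] == 0).all()


class TestEnrichment:
    def test_matches_hypergeometric_enumeration(self, annotation, systems):
        from math import comb

        bias = {f"LG05_g{i}": "FBG" for i in range(8)}
        bias.update({f"LG01_g{i}": "FBG" for i in range(10)})
        de = _de(annotation, bias)
        c = landscape.classify_chromosomes(annotation, systems, "zw")
        res = landscape.enrichment_fisher(de, c, "LG05")
        # two-sided Fisher by enumeration over the hypergeometric support
        a, b = res.table[0]
        cc, d = res.table[1]
        N, K, n, k = a + b + cc + d, a + cc, a + b, a
        denom = comb(N, n)
        p_obs = comb(K, k) * comb(N - K, n - k) / denom
        p = sum(
            comb(K, i) * comb(N - K, n - i) / denom
            for i in range(max(0, n + K - N), min(n, K) + 1)
            if comb(K, i) * comb(N - K, n - i) / denom <= p_obs * (1 + 1e-9)
        )
        assert res.fisher_p == pytest.approx(p, rel=1e-9)
        assert res.direction == "enriched"

    def test_excluded_genes_never_enter_table(self, annotation, systems):
        bias = {"MT_g0": "FBG", "scaffold_001_g0": "FBG"}
        de = _de(annotation, bias)
        c = landscape.classify_chromosomes(annotation, systems, "zw")
        res = landscape.enrichment_fisher(de, c, "LG05")
        assert res.table.sum() == 130  # 100 + 10 + 20 placed, non-MT genes

    def test_symmetric_toy_is_null(self, annotation, systems):
        bias = {"LG05_g0": "MBG"}
        bias.update({f"LG01_g{i}": "MBG" for i in range(10)})  # 10% both
        de = _de(annotation, bias)
        c = landscape.classify_chromosomes(annotation, systems, "zw")
        res = landscape.enrichment_fisher(de, c, "LG05", exclude_chromosomes=("LG13",))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.fisher_p == pytest.approx(1.0)


class TestSharedSbg:
    def test_identical_species_reduces_to_enrichment(self, annotation, systems):
        bias = {f"LG05_g{i}": "FBG" for i in range(5)}
        bias.update({f"LG01_g{i}": "FBG" for i in range(5)})
        de = _de(annotation, bias)
        c = landscape.classify_chromosomes(annotation, systems, "zw")
        shared = landscape.shared_sbg_fisher(de, de, c, "LG05", bias="FBG")
        direct = landscape.enrichment_fisher(de, c, "LG05", bias="FBG")
        np.testing.assert_array_equal(shared.table, direct.table)
        assert shared.fisher_p == pytest.approx(direct.fisher_p)

    def test_no_sbgs_is_degenerate_p_one(self, annotation, systems):
        de = _de(annotation, {})
        c = landscape.classify_chromosomes(annotation, systems, "zw")
        res = landscape.shared_sbg_fisher(de, de, c, "LG05", bias="FBG")
        assert res.fisher_p == pytest.approx(1.0)

    def test_empty_intersection_is_error(self, annotation, systems):
        de_a = _de(annotation, {}).iloc[:50]
        de_b = _de(annotation, {}).iloc[60:]
        c = landscape.classify_chromosomes(annotation, systems, "zw")
        with pytest.raises(ValueError, match="common"):
            landscape.shared_sbg_fisher(de_a, de_b, c, "LG05")


class TestLfcTests:
    def test_shifted_group_detected(self, annotation, systems):
        rng = np.random.default_rng(1)
        de = _de(annotation, {g: "MBG" for g in annotation["gene_id"]})
        c = landscape.classify_chromosomes(annotation, systems, "zw")
        # autosomal SBG LFCs near 2, sex-chromosome ones near 4
        de["lfc"] = rng.normal(2.0, 0.3, len(de))
        on_sex = de["gene_id"].str.startswith("LG05")
        de.loc[on_sex, "lfc"] += 2.0
        rep = landscape.lfc_distribution_tests(de, c)
        assert rep["pvalue"].iloc[0] < 1e-3
        assert rep["test"].iloc[0] == "wilcoxon_mann_whitney"

    def test_kruskal_used_for_three_groups(self, annotation, systems):
        de = _de(annotation, {g: "MBG" for g in annotation["gene_id"]})
        rng = np.random.default_rng(2)
        de["lfc"] = rng.normal(2, 0.5, len(de))
        c = landscape.classify_chromosomes(annotation, systems, "zw")
        rep = landscape.lfc_distribution_tests(
            de, c, groups={"LG05": ["LG05"], "LG13": ["LG13"], "autosomes": ["LG01"]}
        )
        assert rep["test"].iloc[0] == "kruskal_wallis"
        assert rep["pvalue"].iloc[0] > 0.01  # same distribution everywhere

    def test_kruskal_two_groups_matches_wilcoxon(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(0.5, 1, size=25)
        kw = stats.kruskal(x, y)
        mw = stats.mannwhitneyu(x, y, alternative="two-sided")
        # on tie-free data the chi-square KW p equals the normal-approx MWU p
        z = stats.norm.isf(mw.pvalue / 2)
        assert kw.statistic == pytest.approx(z**2, rel=1e-2)


class TestFeminisation:
    def test_zw_feminised_sex_chromosome(self, annotation, systems):
        rng = np.random.default_rng(4)
        bias = {}
        for i in range(10):  # LG05: 70% FBG
            bias[f"LG05_g{i}"] = "FBG" if i < 7 else "MBG"
        for i in range(40):  # autosomes balanced
            bias[f"LG01_g{i}"] = "FBG" if i % 2 else "MBG"
        de = _de(annotation, bias)
        c = landscape.classify_chromosomes(annotation, systems, "zw")
        fem = landscape.feminisation_summary(de, c).set_index("group")
        assert fem.loc["sex_chromosome", "median_sbg_lfc"] < 0
        assert abs(fem.loc["autosome", "median_sbg_lfc"]) <= 2.0
        assert fem.loc["sex_chromosome", "fbg_mbg_ratio"] == pytest.approx(7 / 3)

    def test_metrics_invariant_to_gene_order(self, annotation, systems):
        rng = np.random.default_rng(5)
        bias = {
            g: rng.choice(["FBG", "MBG", "unbiased"]) for g in annotation["gene_id"]
        }
        de = _de(annotation, bias)
        c = landscape.classify_chromosomes(annotation, systems, "zw")
        a = landscape.feminisation_summary(de, c)
        b = landscape.feminisation_summary(de.sample(frac=1, random_state=0), c)
        pd.testing.assert_frame_equal(a, b)

    def test_no_sbgs_gives_nan_metrics(self, annotation, systems):
        de = _de(annotation, {})
        c = landscape.classify_chromosomes(annotation, systems, "zw")
        fem = landscape.feminisation_summary(de, c).set_index("group")
        assert np.isnan(fem.loc["autosome", "median_sbg_lfc"])
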