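import numpy as np
import pandas as pd
import pytest

from sexbias.simulate import (
    SimConfig,
    default_chromosomes,
    simulate_dataset,
    simulate_species_pair_for_dx,
    species_rng,
)


class TestConfig:
    def test_default_chromosome_layout_sums(self):
        chroms = default_chromosomes(25000)
        assert sum(n for _, n in chroms) == 25000
        names = [c for c, _ in chroms]
        assert names[:22] == [f"LG{i:02d}" for i in range(1, 23)]
        assert "MT" in names
        assert any(n.startswith("scaffold") for n in names)

    def test_chromosome_total_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(n_genes=100, chromosomes=[("LG01", 50)])

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates_per_sex"):
            SimConfig(n_genes=100, chromosomes=[("LG01", 100)], replicates_per_sex=1)

    def test_bad_proportion_rejected(self):
        with pytest.raises(ValueError, match="sbg_fraction"):
            SimConfig(n_genes=100, chromosomes=[("LG01", 100)], sbg_fraction_autosome=1.2)


class TestDataset:
    def test_study_design_sample_count(self):
        """One species, five tissues, three replicates per sex -> 30 samples."""
        cfg = SimConfig(n_genes=500, chromosomes=[("LG01", 450), ("LG05", 50)],
                        species_specs=[("sp", "ZW", ("LG05",))])
        cm, samples, ann, truth = simulate_dataset(cfg)
        assert cm.n_samples == 30
        assert samples.groupby(["tissue", "sex"]).size().eq(3).all()
        assert ann["gene_id"].is_unique and len(ann) == 500

    def test_determinism(self):
        cfg = dict(n_genes=300, chromosomes=[("LG01", 250), ("LG05", 50)],
                   tissues=("gonad",), seed=5)
        a = simulate_dataset(SimConfig(**cfg))
        b = simulate_dataset(SimConfig(**cfg))
        np.testing.assert_array_equal(a[0].counts, b[0].counts)
        pd.testing.assert_frame_equal(a[3].lfc, b[3].lfc)

    def test_null_config_has_no_bias(self):
        cfg = SimConfig(n_genes=300, chromosomes=[("LG01", 250), ("LG05", 50)],
                        sbg_fraction_autosome=0.0, sbg_fraction_sexchrom=0.0)
        _, _, _, truth = simulate_dataset(cfg)
        assert (truth.lfc["true_lfc"] == 0).all()
        assert (truth.lfc["true_bias_class"] == "unbiased").all()

    def test_nb_moment_relation(self):
        """Across replicates of one condition, var ~= mu + alpha*mu^2."""
        alpha = 0.1
        cfg = SimConfig(
            n_genes=2000, chromosomes=[("LG01", 2000)], tissues=("gonad",),
            species_specs=[("sp", "unknown", ())], replicates_per_sex=150,
            dispersion=alpha, library_size_spread=1.0,
            sbg_fraction_autosome=0.0, sbg_fraction_sexchrom=0.0, seed=7,
        )
        cm, samples, _, _ = simulate_dataset(cfg)
        males = samples[samples["sex"] == "male"]["sample_id"]
        sub = cm.subset_samples(males).counts
        mu = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        alpha_hat = (v - mu) / mu**2
        assert np.median(alpha_hat) == pytest.approx(alpha, rel=0.15)

    def test_true_lfc_matches_count_ratio(self):
        """Injected lfc shows up as the male/female mean log-ratio."""
        cfg = SimConfig(
            n_genes=400, chromosomes=[("LG01", 400)], tissues=("gonad",),
            species_specs=[("sp", "unknown", ())], replicates_per_sex=100,
            dispersion=0.05, sbg_fraction_autosome=0.3, library_size_spread=1.0,
            lfc_magnitude_sd=0.0, seed=8,
        )
        cm, samples, _, truth = simulate_dataset(cfg)
        lfc = truth.lfc_for("sp").to_numpy()
        m = cm.subset_samples(samples[samples["sex"] == "male"]["sample_id"]).counts
        f = cm.subset_samples(samples[samples["sex"] == "female"]["sample_id"]).counts
        observed = np.log2(m.mean(axis=1) / f.mean(axis=1))
        biased = lfc != 0
        assert biased.sum() > 50
        assert np.abs(observed[biased] - lfc[biased]).mean() < 0.15

    def test_class_balance_converges_to_config(self):
        cfg = SimConfig(n_genes=8000, chromosomes=[("LG01", 7000), ("LG05", 1000)],
                        tissues=("gonad",), species_specs=[("sp", "ZW", ("LG05",))],
                        sbg_fraction_autosome=0.02, sbg_fraction_sexchrom=0.10, seed=9)
        _, _, ann, truth = simulate_dataset(cfg)
        lfc = truth.lfc_for("sp")
        on_sex = ann.set_index("gene_id")["chromosome"] == "LG05"
        f_sex = (lfc[on_sex.to_numpy()] != 0).mean()
        f_auto = (lfc[~on_sex.to_numpy()] != 0).mean()
        assert f_sex == pytest.approx(0.10, abs=3 * np.sqrt(0.1 * 0.9 / 1000))
        assert f_auto == pytest.approx(0.02, abs=3 * np.sqrt(0.02 * 0.98 / 7000))

    def test_zw_sign_convention(self):
        """~80% of sex-chromosome SBGs of a ZW species are female-biased."""
        cfg = SimConfig(n_genes=6000, chromosomes=[("LG01", 3000), ("LG05", 3000)],
                        tissues=("gonad",), species_specs=[("sp", "ZW", ("LG05",))],
                        sbg_fraction_sexchrom=0.2, female_bias_prob_sexchrom=0.8,
                        seed=10)
        _, _, ann, truth = simulate_dataset(cfg)
        lfc = truth.lfc_for("sp")
        on_sex = (ann.set_index("gene_id")["chromosome"] == "LG05").to_numpy()
        sbg = lfc[on_sex][lfc[on_sex] != 0]
        assert (sbg < 0).mean() == pytest.approx(0.8, abs=0.05)

    def test_adding_species_leaves_existing_untouched(self):
        base = dict(n_genes=300, chromosomes=[("LG01", 250), ("LG05", 50)],
                    tissues=("gonad",), seed=11)
        one = simulate_dataset(
            SimConfig(**base, species_specs=[("alpha", "ZW", ("LG05",))])
        )
        two = simulate_dataset(
            SimConfig(**base, species_specs=[("alpha", "ZW", ("LG05",)),
                                             ("beta", "XY", ("LG05",))])
        )
        cols = list(one[0].sample_ids)
        np.testing.assert_array_equal(
            one[0].counts, two[0].subset_samples(cols).counts
        )

    def test_species_streams_differ(self):
        assert species_rng(0, "a").integers(1 << 30) != species_rng(0, "b").integers(1 << 30)


class TestSpeciesPair:
    def test_no_shift_centres_divergence_at_zero(self):
        cfg = SimConfig(n_genes=500, chromosomes=[("LG01", 500)],
                        species_specs=[("sp", "unknown", ())],
                        outgroup_shift_fraction=0.0, outgroup_shift_fraction_sbg=0.0,
                        seed=12)
        focal, related, truth = simulate_species_pair_for_dx(cfg)
        assert (truth.shift["true_shift"] == 0).all()
        rel_diff = np.log2(focal.mean(axis=1) / related.mean(axis=1))
        assert abs(rel_diff.mean()) < 0.02

    def test_determinism(self):
        cfg = dict(n_genes=200, chromosomes=[("LG01", 200)],
                   species_specs=[("sp", "unknown", ())], seed=13)
        a = simulate_species_pair_for_dx(SimConfig(**cfg))
        b = simulate_species_pair_for_dx(SimConfig(**cfg))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_shift_fractions_differ_by_bias(self):
        cfg = SimConfig(n_genes=20000, chromosomes=[("LG01", 20000)],
                        species_specs=[("sp", "unknown", ())],
                        sbg_fraction_autosome=0.2, outgroup_shift_fraction=0.05,
                        outgroup_shift_fraction_sbg=0.4, seed=14)
        _, _, truth = simulate_species_pair_for_dx(cfg)
        merged = truth.shift.merge(
            truth.lfc.drop_duplicates("gene_id"), on="gene_id"
        )
        sbg = merged["true_bias_class"] != "unbiased"
        assert (merged.loc[sbg, "true_shift"] > 0).mean() == pytest.approx(0.4, abs=0.03)
        assert (merged.loc[~sbg, "true_shift"] > 0).mean() == pytest.approx(0.05, abs=0.01)
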