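import hashlib
import json

import numpy as np
import pandas as pd
import pytest

import circdosage as cd
from circdosage.simulate import ConfigError, _rng


class TestConfigValidation:
    def test_fraction_overflow_rejected(self):
        with pytest.raises(ConfigError):
            cd.SimConfig(frac_par1=0.6, frac_par2=0.5)

    def test_alpha_bounds(self):
        with pytest.raises(ConfigError):
            cd.SimConfig(circ_attenuation=1.5)

    def test_empty_karyotypes_rejected(self):
        with pytest.raises(ConfigError):
            cd.SimConfig(karyotypes=())


class TestGenerateAnnotation:
    def test_zero_par1_fraction_gives_no_par1_genes(self):
        cfg = cd.SimConfig(n_circ=100, frac_par1=0.0, seed=1)
        ann = cd.generate_annotation(cfg)
        assert not any(g.region_class == "PAR1" for g in ann.genes.values())

    def test_par_genes_within_printed_intervals(self):
        cfg = cd.SimConfig(n_circ=200, frac_par1=0.1, frac_par2=0.03, seed=1)
        ann = cd.generate_annotation(cfg)
        for gene in ann.genes.values():
            if gene.region_class in ("PAR1", "PAR2"):
                lo, hi = cd.PAR_REGIONS[gene.region_class]
                assert gene.chrom == "chrX"
                assert gene.start + 1 >= lo and gene.end <= hi

    def test_region_class_counts_match_rounded_fractions(self):
        cfg = cd.SimConfig(n_circ=100, seed=1)
        ann = cd.generate_annotation(cfg)
        hosts = [g for g in ann.genes.values() if g.gene_id.startswith("G")]
        counts = pd.Series([g.region_class for g in hosts]).value_counts()
        assert counts.get("PAR1", 0) == round(cfg.frac_par1 * 100)
        assert counts.get("PAR2", 0) == round(cfg.frac_par2 * 100)
        assert counts.get("chrX_escape", 0) == round(cfg.frac_chrx_escape * 100)
        assert counts.get("chrY", 0) == round(cfg.frac_chry * 100)
        assert len(hosts) == 100


class TestGenerateCohort:
    def test_sample_and_subject_arithmetic(self):
        cfg = cd.SimConfig(n_per_group=3)
        cohort = cd.generate_cohort(cfg)
        assert len(cohort) == 3 * 4 * 3            # subjects x karyotypes x tissues
        assert cohort["subject_id"].nunique() == 12
        # every subject sampled once per tissue (paired design)
        assert (cohort.groupby("subject_id")["tissue"].nunique() == 3).all()

    def test_karyotype_chromosome_counts(self):
        cohort = cd.generate_cohort(cd.SimConfig(n_per_group=1))
        by_kary = cohort.drop_duplicates("karyotype").set_index("karyotype")
        assert tuple(by_kary.loc["47XXY", ["nX", "nY"]]) == (2, 1)
        assert tuple(by_kary.loc["45X", ["nX", "nY"]]) == (1, 0)

    def test_deterministic(self):
        cfg = cd.SimConfig(n_per_group=2, seed=5)
        pd.testing.assert_frame_equal(cd.generate_cohort(cfg), cd.generate_cohort(cfg))


class TestSimulateCounts:
    def test_par_dosage_ratio_converges_at_alpha_one(self):
        # dispersion -> 0, no batch/tissue noise: XXY/XY PAR mean ratio ~ 1.5
        cfg = cd.SimConfig(n_per_group=200, karyotypes=("46XY", "47XXY"),
                           tissues=("blood",), n_circ=60, frac_par1=0.3,
                           dispersion=0.0, batch_sd=0.0, tissue_sd=0.0,
                           lib_size_range=(100_000, 100_000),
                           circ_attenuation=1.0, seed=11)
        truth = cd.simulate_counts(cd.generate_annotation(cfg),
                                   cd.generate_cohort(cfg), cfg)
        cohort = truth.cohort
        par = truth.circ_features.loc[truth.circ_features["region_class"] == "PAR1",
                                      "key"]
        m = truth.true_circ_counts.data
        xy = cohort.loc[cohort["karyotype"] == "46XY", "sample_id"]
        xxy = cohort.loc[cohort["karyotype"] == "47XXY", "sample_id"]
        ratio = (m.loc[par, xxy].mean(axis=1) / m.loc[par, xy].mean(axis=1)).mean()
        assert ratio == pytest.approx(1.5, rel=0.02)
        # group-mean log2 ratio within +-0.05 of log2(3/2)
        assert np.log2(ratio) == pytest.approx(np.log2(1.5), abs=0.05)

    def test_alpha_zero_removes_circ_dosage(self):
        cfg = cd.SimConfig(n_per_group=100, karyotypes=("46XY", "47XXY"),
                           tissues=("blood",), n_circ=60, frac_par1=0.3,
                           dispersion=0.0, batch_sd=0.0, tissue_sd=0.0,
                           lib_size_range=(100_000, 100_000),
                           circ_attenuation=0.0, seed=12)
        truth = cd.simulate_counts(cd.generate_annotation(cfg),
                                   cd.generate_cohort(cfg), cfg)
        cohort = truth.cohort
        par = truth.circ_features.loc[truth.circ_features["region_class"] == "PAR1",
                                      "key"]
        m = truth.true_circ_counts.data
        xy = cohort.loc[cohort["karyotype"] == "46XY", "sample_id"]
        xxy = cohort.loc[cohort["karyotype"] == "47XXY", "sample_id"]
        ratio = (m.loc[par, xxy].mean(axis=1) / m.loc[par, xy].mean(axis=1)).mean()
        assert ratio == pytest.approx(1.0, abs=0.03)

    def test_ctl_target_one_means_zero_linear(self, small_truth):
        keys = small_truth.circ_features.loc[
            small_truth.circ_features["ctl_target"] == 1.0, "key"]
        assert len(keys) > 0
        assert (small_truth.true_linear_counts.loc[keys].to_numpy() == 0).all()

    def test_true_effects_encode_copy_model(self, small_truth):
        eff = small_truth.true_effects
        alpha = small_truth.config.circ_attenuation
        par_circ = eff[(eff["kind"] == "circ") & (eff["region_class"] == "PAR1")]
        assert np.allclose(par_circ["47XXY_vs_46XY"], alpha * np.log2(1.5))
        assert np.allclose(par_circ["45X_vs_46XX"], alpha * np.log2(0.5))
        par_gene = eff[(eff["kind"] == "gene") & (eff["region_class"] == "PAR1")]
        assert np.allclose(par_gene["47XXY_vs_46XY"], np.log2(1.5))
        assert np.allclose(par_gene["45X_vs_46XX"], -1.0)


class TestEmitCallerOutputs:
    def test_zero_noise_tables_equal_truth(self, small_truth):
        co = small_truth.caller_outputs
        detectable = set(small_truth.true_circ_counts.data
                         .loc[lambda d: d.sum(axis=1) > 0].index)
        assert co.primary_keys() == detectable
        for keys in co.secondary_key_sets():
            assert keys == detectable

    def test_primary_counts_conserved(self, small_truth):
        co = small_truth.caller_outputs
        raw = cd.build_count_matrix(co.primary_records(),
                                    keys=small_truth.true_keys)
        want = small_truth.true_circ_counts.data.sum(axis=0)
        got = raw.data.sum(axis=0)
        assert (got.reindex(want.index) == want).all()

    def test_injected_keys_disjoint_from_truth(self, noisy_truth):
        co = noisy_truth.caller_outputs
        for caller, per_sample in co.injected.items():
            for sample, inj in per_sample.items():
                assert inj.isdisjoint(noisy_truth.true_keys)
                assert inj <= co.secondary[caller][sample]

    def test_injection_count_matches_bernoulli_tally(self, noisy_truth):
        cfg = noisy_truth.config
        n_keys = len(noisy_truth.true_circ_counts.data.index)
        samples = list(noisy_truth.true_circ_counts.data.columns)
        co = noisy_truth.caller_outputs
        for c_i, caller in enumerate(co.secondary):
            for s_i, sample in enumerate(samples):
                rng = _rng(cfg, "callers", c_i, s_i)
                present = int((noisy_truth.true_circ_counts.data[sample] > 0).sum())
                rng.random(present)  # the caller's false-negative draw
                expected = int((rng.random(n_keys) < cfg.fp_rate_per_caller).sum())
                assert len(co.injected[caller][sample]) == expected

    def test_full_false_negative_empties_consensus(self):
        cfg = cd.SimConfig(n_per_group=2, tissues=("blood",), n_circ=50,
                           fn_rate_per_caller=1.0, fp_rate_per_caller=0.0, seed=4)
        truth = cd.simulate_study(cfg)
        co = truth.caller_outputs
        assert cd.consensus_filter(co.primary_keys(), co.secondary_key_sets()) == set()


class TestDeterminism:
    def test_identical_seed_reproduces_study(self):
        cfg = cd.SimConfig(n_per_group=2, tissues=("blood",), n_circ=80, seed=77)
        t1, t2 = cd.simulate_study(cfg), cd.simulate_study(cfg)
        pd.testing.assert_frame_equal(t1.true_circ_counts.data, t2.true_circ_counts.data)
        pd.testing.assert_frame_equal(t1.circ_mirna, t2.circ_mirna)
        assert t1.caller_outputs.secondary == t2.caller_outputs.secondary

    def test_written_study_byte_identical(self, tmp_path):
        cfg = cd.SimConfig(n_per_group=2, tissues=("blood",), n_circ=60, seed=13)
        digests = []
        for sub in ("a", "b"):
            paths = cd.write_study(cd.simulate_study(cfg), tmp_path / sub)
            h = hashlib.sha256()
            for p in sorted((tmp_path / sub).rglob("*")):
                if p.is_file():
                    h.update(p.relative_to(tmp_path / sub).as_posix().encode())
                    h.update(p.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]


class TestInteractionTables:
    def test_zero_triplets_gives_empty_recovered_network(self):
        cfg = cd.SimConfig(n_per_group=2, tissues=("blood",), n_circ=100, seed=21,
                           n_triplets=0, n_decoy_triplets=0,
                           n_low_evidence_edges=0, n_noise_edges=0)
        truth = cd.simulate_study(cfg)
        assert len(truth.planted_triplets) == 0
        assert len(truth.circ_mirna) == 0

    def test_experiment_counts_at_least_one(self, small_truth):
        assert (small_truth.circ_mirna["n_clip_experiments"] >= 1).all()

    def test_single_experiment_edges_fail_evidence_filter(self):
        cfg = cd.SimConfig(n_per_group=2, tissues=("blood",), n_circ=100, seed=22,
                           n_triplets=0, n_decoy_triplets=0,
                           n_low_evidence_edges=6, n_noise_edges=0)
        truth = cd.simulate_study(cfg)
        assert (truth.circ_mirna["n_clip_experiments"] == 1).all()
        assert len(cd.filter_circ_mirna(truth.circ_mirna, min_experiments=2)) == 0

    def test_planted_triplets_recorded_with_directions(self, small_truth):
        trip = small_truth.planted_triplets
        assert len(trip) == small_truth.config.n_triplets
        dec = small_truth.dec_directions.set_index("key")["direction"]
        deg = small_truth.deg_directions.set_index("gene_id")["direction"]
        for r in trip.itertuples():
            assert dec[r.key] == r.direction == deg[r.gene_id]
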