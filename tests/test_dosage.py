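import numpy as np
import pandas as pd
import pytest
from scipy import stats

import circdosage as cd


class TestKaryotypeCopies:
    @pytest.mark.parametrize("karyotype,expected", [
        ("45X", (1, 0, 1)), ("46XY", (1, 1, 2)), ("46XX", (2, 0, 2)),
        ("47XXY", (2, 1, 3)), ("45,X", (1, 0, 1)), ("47, XXY", (2, 1, 3)),
    ])
    def test_stoichiometry(self, karyotype, expected):
        assert cd.karyotype_copies(karyotype) == expected

    def test_unknown_karyotype_rejected(self):
        with pytest.raises(ValueError):
            cd.karyotype_copies("48XXXX")


class TestExpectedDosage:
    def test_klinefelter_par_line(self):
        assert cd.expected_dosage_log2fc("47XXY", "46XY", "PAR") == \
            pytest.approx(0.585, abs=5e-4)

    def test_turner_par_line(self):
        assert cd.expected_dosage_log2fc("45X", "46XX", "PAR") == pytest.approx(-1.0)

    def test_equal_copies_give_zero(self):
        assert cd.expected_dosage_log2fc("46XX", "46XY", "PAR") == 0.0

    def test_inactive_and_autosome_expect_zero(self):
        assert cd.expected_dosage_log2fc("45X", "46XX", "chrX_inactive") == 0.0
        assert cd.expected_dosage_log2fc("47XXY", "46XY", "autosome") == 0.0

    def test_escape_uses_x_count(self):
        assert cd.expected_dosage_log2fc("47XXY", "46XY", "chrX_escape") == \
            pytest.approx(1.0)

    def test_zero_copy_control_errors(self):
        with pytest.raises(ValueError):
            cd.expected_dosage_log2fc("46XY", "46XX", "chrY")

    @pytest.mark.parametrize("region", ["PAR", "chrX_escape", "chrX_inactive",
                                        "autosome"])
    @pytest.mark.parametrize("case,control", [("45X", "46XX"), ("47XXY", "46XY"),
                                              ("46XX", "46XY")])
    def test_antisymmetric_under_reversal(self, region, case, control):
        fwd = cd.expected_dosage_log2fc(case, control, region)
        rev = cd.expected_dosage_log2fc(control, case, region)
        assert fwd == pytest.approx(-rev)


class TestOneSampleT:
    def test_closed_form_oracle(self):
        t, p, degenerate = cd.one_sample_t(np.array([1.0, 2.0, 3.0]))
        assert t == pytest.approx(3.464, abs=5e-4)
        assert p == pytest.approx(0.0742, abs=5e-5)
        assert not degenerate

    def test_zero_vector_degenerate(self):
        t, p, degenerate = cd.one_sample_t(np.zeros(5))
        assert degenerate and p == 1.0

    def test_constant_nonzero_degenerate(self):
        t, p, degenerate = cd.one_sample_t(np.full(4, 2.0))
        assert degenerate and p == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            cd.one_sample_t(np.array([1.0]))


class TestCollectivePanShift:
    def _inputs(self, lfcs):
        keys = [f"chrX:{100000+i}-{200000+i}:+" for i in range(len(lfcs))]
        de = pd.DataFrame({"log2fc": lfcs}, index=keys)
        ann = pd.DataFrame({"key": keys, "par": ["PAR1"] * len(keys)})
        return de, ann

    def test_matches_scipy_ttest(self):
        lfcs = [0.3, -0.1, 0.5, 0.2, 0.4]
        de, ann = self._inputs(lfcs)
        shift = cd.collective_par_shift(de, ann, "blood", "45X_vs_46XX")
        ref = stats.ttest_1samp(lfcs, 0.0)
        assert shift.t == pytest.approx(ref.statistic)
        assert shift.p == pytest.approx(ref.pvalue)
        assert shift.n == 5

    def test_too_few_features_error(self):
        de, ann = self._inputs([0.5])
        with pytest.raises(ValueError):
            cd.collective_par_shift(de, ann, "blood", "c")

    def test_significance_stars(self):
        from circdosage.dosage import significance_stars
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.2) == ""

    def test_recovers_attenuated_shift_from_cohort(self):
        # alpha=0.5, true mRNA PAR effect -1 => circRNA shift ~ -0.5.  PAR is a
        # small library share so circCPM compositional compression stays small.
        cfg = cd.SimConfig(n_per_group=50, karyotypes=("45X", "46XX"),
                           tissues=("blood",), n_circ=1000, frac_par1=0.05,
                           sd_log_expression=0.5,
                           dispersion=0.05, batch_sd=0.0, tissue_sd=0.0,
                           circ_attenuation=0.5, n_batches=1, seed=41)
        truth = cd.simulate_counts(cd.generate_annotation(cfg),
                                   cd.generate_cohort(cfg), cfg)
        de = cd.run_de(truth.true_circ_counts.data, truth.cohort,
                       cd.ContrastSpec("45X", "46XX", "blood"))
        ann = cd.annotate_circrnas(truth.circ_features["key"], truth.annotation)
        shift = cd.collective_par_shift(de, ann, "blood", "45X_vs_46XX")
        assert shift.mean_log2fc == pytest.approx(-0.5, abs=0.1)
        assert shift.p < 0.001  # the collective downshift is clearly detected

    def test_permuted_labels_give_uniform_p(self):
        # under label permutation the collective-shift p-value is ~U(0,1)
        rng = np.random.default_rng(99)
        # homogeneous baselines keep the across-feature t-test calibrated
        cfg = cd.SimConfig(n_per_group=8, karyotypes=("45X", "46XX"),
                           tissues=("blood",), n_circ=200, frac_par1=0.1,
                           sd_log_expression=0.0, mean_log_expression=np.log(200),
                           circ_attenuation=0.0, dispersion=0.1, batch_sd=0.0,
                           tissue_sd=0.0, n_batches=1, seed=43)
        truth = cd.simulate_counts(cd.generate_annotation(cfg),
                                   cd.generate_cohort(cfg), cfg)
        par_keys = truth.circ_features.loc[
            truth.circ_features["region_class"] == "PAR1", "key"]
        y = cd.log_cpm_transform(truth.true_circ_counts.data).loc[par_keys]
        n = y.shape[1]
        pvals = []
        for _ in range(200):
            perm = rng.permutation(n)
            g1, g2 = perm[: n // 2], perm[n // 2:]
            lfc = y.iloc[:, g1].mean(axis=1) - y.iloc[:, g2].mean(axis=1)
            _, p, _ = cd.one_sample_t(lfc.to_numpy())
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestStoichiometryProfile:
    def _cohort(self, n=6):
        return cd.generate_cohort(cd.SimConfig(n_per_group=n, tissues=("blood",)))

    def test_flat_profile_rmsd_hand_value(self):
        meta = self._cohort()
        data = pd.DataFrame(100.0, index=["k:0-1:+"], columns=meta["sample_id"])
        prof = cd.stoichiometry_profile(
            cd.CountMatrix(data, scale="circcpm"), meta, "k:0-1:+")
        # flat expression scales to (2,2,2,2); RMSD vs (1,2,2,3) = sqrt(2/4)
        assert prof.attrs["rmsd"] == pytest.approx(np.sqrt(0.5))

    def test_perfect_stoichiometry_rmsd_near_zero(self):
        meta = self._cohort()
        par = dict(zip(("45X", "46XY", "46XX", "47XXY"), (1.0, 2.0, 2.0, 3.0)))
        values = [50.0 * par[k] for k in meta["karyotype"]]
        data = pd.DataFrame([values], index=["k:0-1:+"],
                            columns=meta["sample_id"])
        prof = cd.stoichiometry_profile(
            cd.CountMatrix(data, scale="circcpm"), meta, "k:0-1:+")
        assert prof.attrs["rmsd"] == pytest.approx(0.0, abs=1e-9)

    def test_missing_karyotype_reports_zero_mean(self):
        meta = self._cohort()
        meta = meta[meta["karyotype"] != "45X"]
        data = pd.DataFrame(10.0, index=["k:0-1:+"], columns=meta["sample_id"])
        prof = cd.stoichiometry_profile(
            cd.CountMatrix(data, scale="circcpm"), meta, "k:0-1:+")
        assert prof.set_index("karyotype").loc["45X", "mean_expression"] == 0.0


class TestAttenuation:
    def test_identical_tables_give_unit_slope_and_correlation(self):
        keys = [f"chrX:{100000+i}-{200000+i}:+" for i in range(5)]
        hosts = [f"G{i}" for i in range(5)]
        lfc = [0.1, -0.4, 0.6, 0.3, -0.2]
        circ_de = pd.DataFrame({"log2fc": lfc}, index=keys)
        gene_de = pd.DataFrame({"log2fc": lfc}, index=hosts)
        ann = pd.DataFrame({"key": keys, "host_gene_ids": hosts,
                            "par": ["PAR1"] * 5})
        pairs, r, slope = cd.circ_mrna_attenuation(circ_de, gene_de, ann)
        assert len(pairs) == 5
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_too_few_pairs_error(self):
        ann = pd.DataFrame({"key": ["k:0-1:+"], "host_gene_ids": ["G0"],
                            "par": ["PAR1"]})
        circ_de = pd.DataFrame({"log2fc": [1.0]}, index=["k:0-1:+"])
        gene_de = pd.DataFrame({"log2fc": [1.0]}, index=["G0"])
        with pytest.raises(ValueError):
            cd.circ_mrna_attenuation(circ_de, gene_de, ann)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_slope_recovers_alpha(self, alpha):
        cfg = cd.SimConfig(n_per_group=20, karyotypes=("45X", "46XX"),
                           tissues=("blood",), n_circ=500, frac_par1=0.1,
                           frac_par2=0.0, frac_chrx_escape=0.0,
                           frac_chrx_inactive=0.0, frac_chry=0.0,
                           dispersion=0.05, batch_sd=0.0, tissue_sd=0.0,
                           circ_attenuation=alpha, n_batches=1, seed=7)
        truth = cd.simulate_counts(cd.generate_annotation(cfg),
                                   cd.generate_cohort(cfg), cfg)
        contrast = cd.ContrastSpec("45X", "46XX", "blood")
        circ_de = cd.run_de(truth.true_circ_counts.data, truth.cohort, contrast)
        gene_de = cd.run_de(truth.true_gene_counts, truth.cohort, contrast,
                            feature_kind="gene")
        ann = cd.annotate_circrnas(truth.circ_features["key"], truth.annotation)
        pairs, _, slope = cd.circ_mrna_attenuation(circ_de, gene_de, ann)
        assert len(pairs) == 50
        assert abs(slope - alpha) < 0.1
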