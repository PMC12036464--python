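import numpy as np
import pandas as pd
import pytest

from ncflow import Experiment, ProbeClass, QCConfig
from ncflow.errors import ConfigurationError, ValidationError
from ncflow.qc import (
    _pca_scores,
    background_threshold,
    bio_missingness,
    pca_outliers,
    run_qc,
    std_missingness,
    technical_flags,
)
from ncflow.experiment import LaneAttributes

from conftest import make_experiment


def bio_panel_experiment(below_counts: int, n_bio: int = 11) -> Experiment:
    """One sample; ``below_counts`` of the bio genes sit below background."""
    # negatives (10, 14, 6) -> background threshold 10
    classes = {"NEG_A": ProbeClass.NEGATIVE_SPIKE,
               "NEG_B": ProbeClass.NEGATIVE_SPIKE,
               "NEG_C": ProbeClass.NEGATIVE_SPIKE,
               "GENE1": ProbeClass.ENDOGENOUS,
               "GAPDH": ProbeClass.HOUSEKEEPING}
    counts = {"NEG_A": [10], "NEG_B": [14], "NEG_C": [6],
              "GENE1": [50], "GAPDH": [400]}
    for i in range(n_bio):
        name = f"BIO{i:02d}"
        classes[name] = ProbeClass.BIO_POSITIVE
        counts[name] = [5 if i < below_counts else 50]
    return make_experiment(counts, classes)


class TestBackgroundThreshold:
    def test_mean_of_negatives(self):
        exp = bio_panel_experiment(0)
        assert background_threshold(exp, "S1") == pytest.approx(10.0)

    def test_single_negative(self):
        exp = make_experiment(
            {"NEG_A": [7], "G": [3]},
            {"NEG_A": ProbeClass.NEGATIVE_SPIKE, "G": ProbeClass.ENDOGENOUS},
        )
        assert background_threshold(exp, "S1") == pytest.approx(7.0)

    def test_all_zero_negatives_nothing_below(self):
        exp = make_experiment(
            {"NEG_A": [0], "NEG_B": [0], "B1": [1], "B2": [0]},
            {"NEG_A": ProbeClass.NEGATIVE_SPIKE,
             "NEG_B": ProbeClass.NEGATIVE_SPIKE,
             "B1": ProbeClass.BIO_POSITIVE, "B2": ProbeClass.BIO_POSITIVE},
        )
        assert background_threshold(exp, "S1") == 0.0
        below, _ = bio_missingness(exp, "S1")
        assert below == 0  # nothing is strictly below a zero threshold


class TestTechnicalFlags:
    def test_imaging_flag_below_fov_ratio(self, tiny_experiment):
        lane = LaneAttributes("1", "C1", fov_count=100, fov_counted=70,
                              binding_density=1.0)
        flags = technical_flags(lane, tiny_experiment, "S1")
        assert "IMAGING" in flags

    def test_binding_density_out_of_range(self, tiny_experiment):
        lane = LaneAttributes("1", "C1", 100, 99, binding_density=0.05)
        assert "BINDING" in technical_flags(lane, tiny_experiment, "S1")
        lane = LaneAttributes("1", "C1", 100, 99, binding_density=1.0)
        assert technical_flags(lane, tiny_experiment, "S1") == set()

    def test_lod_uses_half_fm_spike_vs_neg_mean_plus_2sd(self):
        # negatives mean 5, sd 2 -> cutoff 9; POS 0.5 fM at 100 passes, at 8 flags
        classes = {"NEG_A": ProbeClass.NEGATIVE_SPIKE,
                   "NEG_B": ProbeClass.NEGATIVE_SPIKE,
                   "POS_E(0.5)": ProbeClass.POSITIVE_SPIKE,
                   "G": ProbeClass.ENDOGENOUS}
        lane = LaneAttributes("1", "C1", 100, 99, 1.0)
        ok = make_experiment({"NEG_A": [3], "NEG_B": [7], "POS_E(0.5)": [100],
                              "G": [10]}, classes,
                             spike_fm={"POS_E(0.5)": 0.5})
        assert technical_flags(lane, ok, "S1") == set()
        bad = make_experiment({"NEG_A": [3], "NEG_B": [7], "POS_E(0.5)": [8],
                               "G": [10]}, classes,
                              spike_fm={"POS_E(0.5)": 0.5})
        assert technical_flags(lane, bad, "S1") == {"LOD"}

    def test_zero_fov_count_raises(self, tiny_experiment):
        lane = LaneAttributes("1", "C1", 0, 0, 1.0)
        with pytest.raises(ValueError):
            technical_flags(lane, tiny_experiment, "S1")


def pca_oracle(exp: Experiment, cfg: QCConfig) -> set[str]:
    """Explicit covariance eigendecomposition + interpolated quartiles."""
    X = np.log2(exp.biological_counts.to_numpy(float).T + cfg.log_pseudocount)
    Xc = X - X.mean(axis=0)
    gram = Xc @ Xc.T
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1]
    out = set()
    for k in range(min(cfg.pc_axes, len(order))):
        scores = vecs[:, order[k]] * np.sqrt(max(vals[order[k]], 0.0))
        q1, q3 = np.percentile(scores, [25, 75])
        iqr = q3 - q1
        eps = 1e-8 * max(1.0, np.abs(scores).max())
        mask = (scores < q1 - cfg.iqr_multiplier * iqr - eps) | (
            scores > q3 + cfg.iqr_multiplier * iqr + eps
        )
        out.update(np.asarray(exp.samples.index)[mask])
    return out


class TestPcaOutliers:
    def make_cluster_experiment(self, seed=0, n=20, shift_sample=None, factor=50):
        rng = np.random.default_rng(seed)
        classes = {"NEG_A": ProbeClass.NEGATIVE_SPIKE}
        counts = {"NEG_A": list(rng.poisson(10, n))}
        for j in range(12):
            base = rng.uniform(50, 400)
            row = rng.poisson(base, n)
            counts[f"G{j}"] = list(row)
            classes[f"G{j}"] = ProbeClass.ENDOGENOUS
        exp = make_experiment(counts, classes)
        if shift_sample is not None:
            col = exp.counts.columns[shift_sample]
            gene_rows = [p for p in exp.counts.index if p.startswith("G")]
            exp.counts.loc[gene_rows, col] *= factor
        return exp

    def test_planted_global_shift_is_the_only_outlier(self):
        exp = self.make_cluster_experiment(seed=1, shift_sample=3)
        assert pca_outliers(exp) == {"S4"}

    def test_identical_samples_give_no_outliers(self):
        counts = {"NEG_A": [5] * 6, "G1": [100] * 6, "G2": [40] * 6}
        classes = {"NEG_A": ProbeClass.NEGATIVE_SPIKE,
                   "G1": ProbeClass.ENDOGENOUS, "G2": ProbeClass.ENDOGENOUS}
        assert pca_outliers(make_experiment(counts, classes)) == set()

    def test_invariant_to_sample_order(self):
        exp = self.make_cluster_experiment(seed=2, shift_sample=5)
        shuffled = exp.subset_samples(list(exp.samples.index)[::-1])
        out_a = pca_outliers(exp)
        out_b = pca_outliers(shuffled)
        assert out_a == out_b

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_eigendecomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 10, 20
        classes = {"NEG_A": ProbeClass.NEGATIVE_SPIKE}
        counts = {"NEG_A": list(rng.poisson(10, n))}
        for j in range(p):
            counts[f"G{j}"] = list(rng.poisson(rng.uniform(20, 500), n))
            classes[f"G{j}"] = ProbeClass.ENDOGENOUS
        exp = make_experiment(counts, classes)
        cfg = QCConfig()
        assert pca_outliers(exp, cfg) == pca_oracle(exp, cfg)

    def test_too_few_samples_raises(self):
        counts = {"NEG_A": [5, 6], "G1": [10, 12]}
        classes = {"NEG_A": ProbeClass.NEGATIVE_SPIKE,
                   "G1": ProbeClass.ENDOGENOUS}
        with pytest.raises(ValidationError):
            pca_outliers(make_experiment(counts, classes))


class TestBioMissingness:
    @pytest.mark.parametrize("below,expected_flag",
                             [(3, False), (4, True), (11, True), (0, False)])
    def test_flag_boundary(self, below, expected_flag):
        exp = bio_panel_experiment(below)
        count, flag = bio_missingness(exp, "S1")
        assert count == below
        assert flag is expected_flag

    def test_count_rule_equals_fraction_rule_for_all_panel_counts(self):
        cfg = QCConfig()
        for k in range(12):
            count, flag = bio_missingness(bio_panel_experiment(k), "S1", cfg)
            fraction_flag = count / 11 > cfg.bio_missing_fraction
            assert flag == fraction_flag == (k >= 4)

    def test_tie_with_background_counts_as_detected(self):
        # threshold is 10; a probe at exactly 10 is not "below"
        exp = bio_panel_experiment(0)
        exp.counts.loc["BIO00", "S1"] = 10
        count, flag = bio_missingness(exp, "S1")
        assert count == 0 and not flag

    def test_suppressing_more_genes_never_unflags(self):
        flags = [bio_missingness(bio_panel_experiment(k), "S1")[1]
                 for k in range(12)]
        assert flags == sorted(flags)  # False..False then True..True

    def test_requires_bio_probes(self):
        exp = make_experiment(
            {"NEG_A": [5], "G": [50]},
            {"NEG_A": ProbeClass.NEGATIVE_SPIKE, "G": ProbeClass.ENDOGENOUS},
        )
        with pytest.raises(ConfigurationError):
            bio_missingness(exp, "S1")


class TestStdMissingness:
    def build(self, endog_below_frac, hk_below_frac):
        classes, counts = {"NEG_A": ProbeClass.NEGATIVE_SPIKE}, {"NEG_A": [10]}
        for i in range(10):
            classes[f"E{i}"] = ProbeClass.ENDOGENOUS
            counts[f"E{i}"] = [2 if i < endog_below_frac * 10 else 60]
        for i in range(10):
            classes[f"H{i}"] = ProbeClass.HOUSEKEEPING
            counts[f"H{i}"] = [2 if i < hk_below_frac * 10 else 300]
        return make_experiment(counts, classes)

    def test_conjunction_of_both_clauses(self):
        assert std_missingness(self.build(0.4, 0.3), "S1") is True
        assert std_missingness(self.build(0.4, 0.1), "S1") is False
        assert std_missingness(self.build(0.1, 0.4), "S1") is False
        assert std_missingness(self.build(0.0, 0.0), "S1") is False

    def test_or_variant(self):
        cfg = QCConfig(std_rule="or")
        assert std_missingness(self.build(0.4, 0.1), "S1", cfg) is True


class TestRunQc:
    def test_reference_preset_excludes_thirteen(self, study_cohort):
        exp, truth = study_cohort
        report = run_qc(exp)
        assert len(report.excluded) == 13
        assert report.n_retained == 87
        flagged = set(report.excluded)
        assert set(truth.sample.index[truth.sample["degraded"]]) <= flagged
        assert set(truth.sample.index[truth.sample["outlier"]]) <= flagged

    def test_clean_cohort_zero_exclusions(self):
        from ncflow.synthdata import SimConfig, simulate_experiment

        exp, _ = simulate_experiment(SimConfig(seed=4))
        report = run_qc(exp)
        assert report.excluded == {}

    def test_partition_is_exact(self, study_cohort):
        exp, _ = study_cohort
        report = run_qc(exp)
        assert sorted(report.retained + list(report.excluded)) == sorted(
            exp.samples.index
        )
        assert not (set(report.retained) & set(report.excluded))

    def test_degraded_samples_trip_bio_missingness_directly(self, study_cohort):
        exp, truth = study_cohort
        degraded = truth.sample.index[truth.sample["degraded"]]
        clean = truth.sample.index[~(truth.sample["degraded"] | truth.sample["outlier"])]
        for s in degraded:
            _, flag = bio_missingness(exp, s)
            assert flag
        flags = [bio_missingness(exp, s)[1] for s in clean]
        assert not any(flags)

    def test_status_flag_iff_any_component(self, study_cohort):
        exp, _ = study_cohort
        t = run_qc(exp).table
        any_flag = (
            t["fov_flag"] | t["binding_flag"] | t["lod_flag"]
            | t["pca_outlier"] | t["bio_flag"]
        )
        assert ((t["status"] == "FLAG") == any_flag).all()
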