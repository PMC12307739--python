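"""ROC/AUC, DeLong, cutpoints, correlation, kappa, differential channels."""

import numpy as np
import pandas as pd
import pytest

from fdeam.catalog96 import CHANNELS_96, CPG_CT_INDICES, MutationCatalog96, ValidationError
from fdeam.biomarker_eval import (
    candidate_thresholds,
    cohens_kappa,
    delong_paired,
    differential_channels,
    evaluate_at_cutpoint,
    optimize_cutpoint,
    read_signature_matrix,
    roc_auc,
    signature_cgtg_fraction,
    spearman,
)
from fdeam.synthetic_cohort import GeneratorConfig, generate_cohort, profile_with_cpg_mass


def brute_force_auc(scores, labels, direction="higher_predicts_positive"):
    """Pairwise-concordance oracle: ties count 1/2."""
    s = np.asarray(scores, float)
    if direction == "lower_predicts_positive":
        s = -s
    y = np.asarray(labels) == 1
    pos, neg = s[y], s[~y]
    total = sum(
        1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
    )
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 9, 10], [0, 0, 1, 1], "higher_predicts_positive")
        assert r.auc == 1.0

    def test_all_ties(self):
        r = roc_auc([5, 5, 5, 5], [0, 0, 1, 1], "higher_predicts_positive")
        assert r.auc == 0.5

    def test_partial_concordance(self):
        r = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], "higher_predicts_positive")
        assert r.auc == pytest.approx(0.75)

    def test_negative_predictor_orientation(self):
        r = roc_auc([10, 9, 1, 2], [1, 1, 0, 0], "lower_predicts_positive")
        assert r.auc == 0.0  # scores point the wrong way after orientation

    def test_reversal_symmetry(self, rng):
        s = rng.normal(size=30)
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 0, 1
        a = roc_auc(s, y, "higher_predicts_positive").auc
        b = roc_auc(s, y, "lower_predicts_positive").auc
        assert a + b == pytest.approx(1.0)

    def test_na_scores_dropped(self):
        r = roc_auc([np.nan, 1, 2, 9, 10], [1, 0, 0, 1, 1], "higher_predicts_positive")
        assert r.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="both"):
            roc_auc([1, 2], [1, 1], "higher_predicts_positive")

    def test_matches_brute_force_concordance(self, rng):
        for _ in range(25):
            n_pos, n_neg = rng.integers(2, 15, size=2)
            s = np.round(rng.normal(size=n_pos + n_neg), 1)  # rounding makes ties
            y = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
            assert roc_auc(s, y, "higher_predicts_positive").auc == pytest.approx(
                brute_force_auc(s, y), abs=1e-12
            )


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=40)
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        auc_a, auc_b, p = delong_paired(s, s, y)
        assert auc_a == auc_b and p == 1.0

    def test_perfect_vs_random_significant(self, rng):
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        perfect = np.r_[rng.uniform(1, 2, 50), rng.uniform(0, 1, 50)]
        random = rng.normal(size=100)
        _, _, p = delong_paired(perfect, random, y)
        assert p < 0.001

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError, match="identical samples"):
            delong_paired([1, 2], [1, 2, 3], [1, 0])

    def test_matches_proc_reference_implementation(self, rng, tmp_path):
        """Paired DeLong p agrees with R pROC's roc.test to 6 decimals."""
        import subprocess

        y = np.r_[np.ones(25, int), np.zeros(35, int)]
        sa = rng.normal(loc=y * 1.2, scale=1.0)
        sb = rng.normal(loc=y * 0.8, scale=1.0)
        auc_a, auc_b, p = delong_paired(sa, sb, y)

        fix = tmp_path / "fix.tsv"
        np.savetxt(fix, np.c_[sa, sb, y], delimiter="\t")
        script = (
            f'd <- read.table("{fix}"); suppressMessages(library(pROC)); '
            'r1 <- roc(d$V3, d$V1, quiet=TRUE, direction="<"); '
            'r2 <- roc(d$V3, d$V2, quiet=TRUE, direction="<"); '
            't <- roc.test(r1, r2, paired=TRUE, method="delong"); '
            'cat(sprintf("%.10f %.10f %.10f", auc(r1), auc(r2), t$p.value))'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_auc_a, r_auc_b, r_p = map(float, out.stdout.split())
        assert auc_a == pytest.approx(r_auc_a, abs=1e-9)
        assert auc_b == pytest.approx(r_auc_b, abs=1e-9)
        assert p == pytest.approx(r_p, abs=1e-6)

    def test_direction_orients_each_marker(self, rng):
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        s = np.r_[rng.uniform(0, 0.4, 30), rng.uniform(0.6, 1, 30)]  # low = positive
        auc_a, _, _ = delong_paired(s, rng.normal(size=60), y,
                                    direction_a="lower_predicts_positive")
        assert auc_a == 1.0


class TestCutpoints:
    def test_separable_negative_predictor(self):
        r = optimize_cutpoint([5, 8, 20, 30], [1, 1, 0, 0], "lower_predicts_positive")
        assert r.threshold == pytest.approx(14.0)
        assert r.balanced_accuracy == 1.0

    def test_degenerate_all_equal(self):
        r = optimize_cutpoint([7, 7, 7, 7], [1, 1, 0, 0], "lower_predicts_positive")
        assert r.degenerate and r.balanced_accuracy == 0.5

    def test_exhaustive_search_equivalence(self, rng):
        """The optimizer never loses to any candidate threshold."""
        for _ in range(25):
            n = int(rng.integers(6, 30))
            s = np.round(rng.normal(size=n), 1)
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            best = optimize_cutpoint(s, y, "higher_predicts_positive")
            for t in candidate_thresholds(s):
                other = evaluate_at_cutpoint(s, y, t, "higher_predicts_positive")
                assert best.balanced_accuracy >= other.balanced_accuracy - 1e-12

    def test_evaluate_at_cutpoint_separable(self):
        r = evaluate_at_cutpoint([5, 8, 20, 30], [1, 1, 0, 0], 14, "lower_predicts_positive")
        assert (r.sensitivity, r.specificity) == (1.0, 1.0)

    def test_threshold_below_all_scores(self):
        r = evaluate_at_cutpoint([5, 8, 20, 30], [1, 1, 0, 0], 4, "lower_predicts_positive")
        assert (r.sensitivity, r.specificity) == (0.0, 1.0)

    def test_hand_tabulated_confusion(self):
        scores = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        labels = [1, 1, 0, 1, 0, 0, 1, 0, 0, 0]
        # higher_predicts_positive at t=5: predicted positive {5..10}
        # TP: scores 7 -> 1 of 4 positives; TN: 3,4 wait see below
        r = evaluate_at_cutpoint(scores, labels, 5, "higher_predicts_positive")
        # positives have scores 1,2,4,7 -> only 7 >= 5: sens = 1/4
        # negatives have scores 3,5,6,8,9,10 -> below 5: only 3: spec = 1/6
        assert r.sensitivity == pytest.approx(0.25)
        assert r.specificity == pytest.approx(1 / 6)

    def test_infinite_threshold_rejected(self):
        with pytest.raises(ValidationError, match="finite"):
            evaluate_at_cutpoint([1, 2], [1, 0], np.inf, "higher_predicts_positive")


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, -(x ** 3))[0] == pytest.approx(-1.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError, match="3"):
            spearman([1, 2], [2, 1])

    def test_generator_rank_correlation_recovered(self, rng):
        rho = 2 * np.sin(-0.6 * np.pi / 6)  # Gaussian copula for Spearman -0.6
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=300)
        r, _ = spearman(xy[:, 0], xy[:, 1])
        assert abs(r - (-0.6)) < 0.1


class TestKappa:
    def test_identical_calls(self):
        assert cohens_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)

    def test_hand_formula(self):
        # 2x2 table a=40 (1,1), b=10 (1,0), c=10 (0,1), d=40 (0,0)
        a = [1] * 40 + [1] * 10 + [0] * 10 + [0] * 40
        b = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
        assert cohens_kappa(a, b) == pytest.approx(0.6)

    def test_constant_vector_gives_zero(self):
        assert cohens_kappa([1, 1, 1, 1], [1, 0, 1, 0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError, match="length"):
            cohens_kappa([1, 0], [1, 0, 1])


class TestDifferentialChannels:
    @staticmethod
    def _catalogs(rng, n, profile, tmb=150):
        return [
            MutationCatalog96(f"S{i}", rng.multinomial(tmb, profile))
            for i in range(n)
        ]

    def test_depleted_cpg_channels_detected(self, rng):
        pos = self._catalogs(rng, 50, profile_with_cpg_mass(0.08))
        neg = self._catalogs(rng, 50, profile_with_cpg_mass(0.25))
        res = differential_channels(pos, neg).set_index("channel")
        cpg = [CHANNELS_96[i] for i in CPG_CT_INDICES]
        assert res.loc[cpg, "significant"].all()
        assert (res.loc[cpg, "delta"] < 0).all()

    def test_null_mostly_quiet(self, rng):
        p = profile_with_cpg_mass(0.2)
        res = differential_channels(
            self._catalogs(rng, 15, p), self._catalogs(rng, 15, p)
        )
        assert res["significant"].sum() <= 5

    def test_bh_monotone_and_prefix(self, rng):
        pos = self._catalogs(rng, 20, profile_with_cpg_mass(0.10))
        neg = self._catalogs(rng, 20, profile_with_cpg_mass(0.22))
        res = differential_channels(pos, neg).sort_values("p_raw").reset_index()
        assert (res["p_adj"] >= res["p_raw"] - 1e-15).all()
        assert res["p_adj"].is_monotonic_increasing or (
            np.diff(np.minimum.accumulate(res["p_adj"][::-1])[::-1]) >= -1e-15
        ).all()
        sig = res["significant"].to_numpy()
        first_insig = np.argmin(sig) if not sig.all() else len(sig)
        assert not sig[first_insig:].any()

    def test_small_group_rejected(self, rng):
        group = self._catalogs(rng, 3, profile_with_cpg_mass(0.2))
        with pytest.raises(ValidationError, match="at least 2"):
            differential_channels(group, group[:1])


class TestSignatureComposition:
    def test_uniform_vector(self):
        assert signature_cgtg_fraction(np.full(96, 1 / 96)) == pytest.approx(400 / 96)

    def test_all_mass_on_one_cpg_channel(self):
        v = np.zeros(96)
        v[CPG_CT_INDICES[0]] = 1.0
        assert signature_cgtg_fraction(v) == pytest.approx(100.0)

    def test_renormalization_of_unscaled_vector(self):
        v = np.full(96, 2.0)  # sums to 192
        assert signature_cgtg_fraction(v) == pytest.approx(400 / 96)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError, match="96"):
            signature_cgtg_fraction(np.ones(10))

    def test_cosmic_layout_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(
            {"SBSA": rng.dirichlet(np.ones(96)), "SBSB": rng.dirichlet(np.ones(96))},
            index=list(CHANNELS_96),
        )
        shuffled = mat.sample(frac=1, random_state=1)  # COSMIC row order differs
        shuffled.to_csv(tmp_path / "sig.tsv", sep="\t", index_label="Type")
        back = read_signature_matrix(tmp_path / "sig.tsv")
        assert list(back.index) == list(CHANNELS_96)
        assert signature_cgtg_fraction(back["SBSA"]) == pytest.approx(
            100 * mat["SBSA"].to_numpy()[list(CPG_CT_INDICES)].sum()
        )


class TestParameterRecovery:
    def test_cutpoint_between_class_means_and_transfers(self):
        """The optimal f_deam cutpoint learned on one cohort lies between
        the generator class means (8% vs 25%), and its operating point
        agrees with the population values implied by the generator."""
        train = generate_cohort(GeneratorConfig(n_pos=300, n_neg=300, seed=21)).summary()
        opt = optimize_cutpoint(train["f_deam"], train["label"], "lower_predicts_positive")
        assert 8.0 < opt.threshold < 25.0
        # population operating point at the learned threshold
        pop = generate_cohort(GeneratorConfig(n_pos=2000, n_neg=2000, seed=99)).summary()
        held = evaluate_at_cutpoint(
            pop["f_deam"], pop["label"], opt.threshold, "lower_predicts_positive"
        )
        assert abs(held.sensitivity - opt.sensitivity) < 0.05
        assert abs(held.specificity - opt.specificity) < 0.05
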