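import numpy as np
import pytest

from msikit import msi, synthetic_data as sd
from msikit.msi import AlterationRule, MSIStatus
from msikit.panel_io import LengthHistogram, STRLocus, SampleProfile, SampleType

LOCUS16 = STRLocus("L1", "chr1", 0, 16, "A")


def brute_force_prevalence(counts: dict[int, int], ref: int) -> float | None:
    """Independent per-read oracle: expand the histogram and count reads."""
    reads = [length for length, count in counts.items() for _ in range(count)]
    if not reads:
        return None
    altered = [r for r in reads if r <= ref - 2 or r > ref]
    return len(altered) / len(reads)


class TestLocusAlterationPrevalence:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({16: 100}, 0.0),  # all reads at reference
            ({14: 30, 16: 70}, 0.30),  # >=2 bp shortening counts
            ({15: 50, 16: 50}, 0.0),  # 1 bp shortening is stutter, excluded
            ({16: 90, 17: 10}, 0.10),  # any lengthening counts
        ],
    )
    def test_hand_examples(self, counts, expected):
        hist = LengthHistogram("L1", counts)
        assert msi.locus_alteration_prevalence(hist, LOCUS16) == pytest.approx(expected)

    def test_zero_depth_not_evaluable(self):
        assert msi.locus_alteration_prevalence(LengthHistogram("L1", {}), LOCUS16) is None

    def test_matches_per_read_oracle_on_random_histograms(self, rng):
        for _ in range(50):
            ref = int(rng.integers(8, 30))
            locus = STRLocus("L", "chr1", 0, ref, "A")
            lengths = rng.integers(max(1, ref - 6), ref + 4, size=rng.integers(1, 6))
            counts = {int(l): int(rng.integers(0, 40)) for l in np.unique(lengths)}
            hist = LengthHistogram("L", counts)
            expected = brute_force_prevalence(counts, ref)
            got = msi.locus_alteration_prevalence(hist, locus)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=0.0)

    def test_alternative_rules(self):
        hist = LengthHistogram("L1", {13: 10, 14: 20, 16: 60, 17: 10})
        exact2 = AlterationRule(exact_shortening=True)
        assert msi.locus_alteration_prevalence(hist, LOCUS16, exact2) == pytest.approx(0.3)
        no_longer = AlterationRule(count_lengthening=False)
        assert msi.locus_alteration_prevalence(hist, LOCUS16, no_longer) == pytest.approx(0.3)


class TestMSIScore:
    def test_additivity_over_loci(self):
        panel = [LOCUS16, STRLocus("L2", "chr2", 0, 20, "A")]
        profile = SampleProfile(
            "S1",
            SampleType.FFPE,
            {
                "L1": LengthHistogram("L1", {14: 30, 16: 70}),
                "L2": LengthHistogram("L2", {20: 90, 21: 10}),
            },
        )
        result = msi.msi_score(profile, panel)
        assert result.msi_score == pytest.approx(0.4)
        assert result.n_loci_evaluated == 2

    def test_zero_depth_locus_excluded(self):
        panel = [LOCUS16, STRLocus("L2", "chr2", 0, 20, "A")]
        profile = SampleProfile(
            "S1",
            SampleType.FFPE,
            {"L1": LengthHistogram("L1", {14: 100}), "L2": LengthHistogram("L2", {})},
        )
        result = msi.msi_score(profile, panel)
        assert result.n_loci_evaluated == 1
        assert result.msi_score == pytest.approx(1.0)

    def test_null_sample_scores_zero_without_stutter(self, small_panel):
        config = sd.SimulationConfig(seed=11, n_loci=8, n_reference=30,
                                     depth_per_locus=500, stutter_rate=0.0)
        rng = np.random.default_rng(3)
        profile, _ = sd.generate_sample_profile(
            config, small_panel, 0.0, SampleType.FFPE, rng
        )
        assert msi.msi_score(profile, small_panel).msi_score == 0.0

    def test_half_clone_score_matches_binomial_oracle(self, study_config, study_panel):
        """Score at clone fraction 0.5 without stutter is ~ n_loci * 0.5."""
        config = sd.SimulationConfig(seed=21, stutter_rate=0.0)
        rng = np.random.default_rng(8)
        profile, _ = sd.generate_sample_profile(
            config, study_panel, 0.5, SampleType.FFPE, rng
        )
        result = msi.msi_score(profile, study_panel)
        # sum of 39 binomial proportions: SD = sqrt(39 * 0.25 / 5000)
        sd3 = 3 * np.sqrt(39 * 0.25 / config.depth_per_locus)
        assert abs(result.msi_score - 39 * 0.5) < sd3

    def test_mixture_linearity(self):
        """Pooling counts of two profiles mixes prevalences by read weight."""
        h1 = {14: 20, 16: 80}
        h2 = {14: 60, 16: 40}
        pooled = {14: 80, 16: 120}
        p1 = msi.locus_alteration_prevalence(LengthHistogram("L1", h1), LOCUS16)
        p2 = msi.locus_alteration_prevalence(LengthHistogram("L1", h2), LOCUS16)
        pm = msi.locus_alteration_prevalence(LengthHistogram("L1", pooled), LOCUS16)
        assert pm == pytest.approx(0.5 * p1 + 0.5 * p2)


class TestThresholdCalibration:
    def _profiles_with_scores(self, scores):
        # one-locus profiles engineered to given alteration prevalences
        profiles = []
        for i, s in enumerate(scores):
            counts = {14: int(round(1000 * s)), 16: 1000 - int(round(1000 * s))}
            profiles.append(
                SampleProfile(
                    f"R{i}", SampleType.REFERENCE, {"L1": LengthHistogram("L1", counts)}
                )
            )
        return profiles

    def test_zero_variance_returns_common_score(self):
        profiles = self._profiles_with_scores([0.2] * 25)
        panel = [LOCUS16]
        assert msi.calibrate_threshold(profiles, panel) == pytest.approx(0.2)

    def test_mean_plus_three_sd(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(0.8, 0.1, size=200).clip(0, 1)
        profiles = self._profiles_with_scores(scores)
        got = msi.calibrate_threshold(profiles, [LOCUS16])
        realized = np.array([round(1000 * s) / 1000 for s in scores])
        assert got == pytest.approx(realized.mean() + 3 * realized.std(ddof=1))

    def test_percentile_rule_is_order_statistic(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 0.5, size=400)
        profiles = self._profiles_with_scores(scores)
        got = msi.calibrate_threshold(
            profiles, [LOCUS16], threshold_rule="percentile", percentile=99
        )
        realized = np.sort([round(1000 * s) / 1000 for s in scores])
        assert got == pytest.approx(np.percentile(realized, 99))

    def test_too_few_references_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            msi.calibrate_threshold(self._profiles_with_scores([0.1] * 5), [LOCUS16])


class TestCallMSI:
    def _profile(self, prevalence):
        counts = {14: int(1000 * prevalence), 16: 1000 - int(1000 * prevalence)}
        return SampleProfile("S", SampleType.FFPE, {"L1": LengthHistogram("L1", counts)})

    def test_below_threshold_is_mss(self):
        result = msi.call_msi(self._profile(0.0), [LOCUS16], threshold=1.1, min_loci=1)
        assert result.status == MSIStatus.MSS

    def test_above_threshold_is_positive(self):
        result = msi.call_msi(self._profile(0.5), [LOCUS16], threshold=0.3, min_loci=1)
        assert result.status == MSIStatus.MSI_POSITIVE

    def test_tie_at_threshold_is_mss(self):
        result = msi.call_msi(self._profile(0.5), [LOCUS16], threshold=0.5, min_loci=1)
        assert result.status == MSIStatus.MSS

    def test_too_few_loci_is_indeterminate(self):
        result = msi.call_msi(self._profile(0.5), [LOCUS16], threshold=0.3, min_loci=10)
        assert result.status == MSIStatus.INDETERMINATE


class TestOperatingCharacteristics:
    def test_sensitivity_and_specificity_at_study_depth(
        self, study_config, study_panel, study_threshold
    ):
        """>= 99% sensitivity at clone fraction 0.2 and >= 99% specificity."""
        rng = np.random.default_rng(606)
        positive = 0
        for i in range(200):
            profile, _ = sd.generate_sample_profile(
                study_config, study_panel, 0.2, SampleType.FFPE, rng, f"POS{i}"
            )
            res = msi.call_msi(profile, study_panel, study_threshold)
            positive += res.status == MSIStatus.MSI_POSITIVE
        assert positive >= 198

        fresh = sd.generate_reference_profiles(
            sd.SimulationConfig(seed=607, n_reference=200), study_panel, prefix="NEG"
        )
        negative = sum(
            msi.call_msi(p, study_panel, study_threshold).status == MSIStatus.MSS
            for p in fresh
        )
        assert negative >= 198


class TestScoreMonotonicity:
    def test_expected_score_nondecreasing_in_clone_fraction(self, small_panel):
        config = sd.SimulationConfig(seed=42, n_loci=8, n_reference=30, depth_per_locus=2000)
        means = []
        for f in np.arange(0.0, 1.01, 0.2):
            rng = np.random.default_rng(1234)  # paired seeds across fractions
            scores = []
            for _ in range(10):
                profile, _ = sd.generate_sample_profile(
                    config, small_panel, float(f), SampleType.FFPE, rng
                )
                scores.append(msi.msi_score(profile, small_panel).msi_score)
            means.append(np.mean(scores))
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))
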