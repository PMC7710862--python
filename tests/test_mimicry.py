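"""Monte-Carlo confusion analysis: frequency classes, distance samples,
and the discrimination report."""

import numpy as np
import pytest

from mimicolor.color_pdf import BivariatePDF, CopulaModel, MarginalModel
from mimicolor.discrimination import threshold_distance
from mimicolor.mimicry import (
    class_pair_distances,
    classify_frequency,
    cross_species_distances,
    discrimination_report,
)


@pytest.fixture(scope="module")
def round_normal_pdf():
    """Circular bivariate normal: density is monotone in the radius."""
    return BivariatePDF(
        MarginalModel("normal", (0.0, 1.0)),
        MarginalModel("normal", (0.0, 1.0)),
        CopulaModel("independence"),
    )


class TestClassifyFrequency:
    def test_band_sizes_are_ten_percent(self, pdfs):
        classed = classify_frequency(pdfs["wc_petal"], n=20_000, seed=0)
        frac = classed.data["freq_class"].value_counts(normalize=True)
        for cls in ("typical", "less_frequent", "rare"):
            assert frac[cls] == pytest.approx(0.10, abs=0.01)

    def test_radius_ordering_for_circular_normal(self, round_normal_pdf):
        classed = classify_frequency(round_normal_pdf, n=20_000, seed=1)
        r = np.hypot(classed.data["x"], classed.data["y"])
        by = classed.data["freq_class"]
        assert r[by == "typical"].max() < r[by == "rare"].min()
        assert r[by == "typical"].max() < r[by == "less_frequent"].min()

    def test_deterministic_under_seed(self, pdfs):
        a = classify_frequency(pdfs["ez_labellum"], n=10_000, seed=3)
        b = classify_frequency(pdfs["ez_labellum"], n=10_000, seed=3)
        assert a.data.equals(b.data)

    def test_minimum_sample_size(self, pdfs):
        with pytest.raises(ValueError, match="10,000"):
            classify_frequency(pdfs["wc_petal"], n=500)

    def test_density_bands_ordered(self, pdfs):
        classed = classify_frequency(pdfs["wc_petal"], n=20_000, seed=4)
        b = classed.density_bands
        assert b["rare"][0] < b["less_frequent"][0] < b["typical"][0]


class TestClassPairDistances:
    def test_published_within_species_means(self, pdfs):
        """Typical-vs-less-frequent and typical-vs-rare mean distances for
        the orchid lateral petal match the published table values."""
        classed = classify_frequency(pdfs["ez_lateral_petal"], n=100_000, seed=5)
        m_lfq, bands = class_pair_distances(classed, ("typical", "less_frequent"), seed=6)
        m_rar, _ = class_pair_distances(classed, ("typical", "rare"), seed=7)
        assert m_lfq == pytest.approx(0.025, abs=0.005)
        assert m_rar == pytest.approx(0.035, abs=0.005)
        assert set(bands) == {"typical", "less_frequent"}

    def test_collapsed_support_gives_zero_distance(self):
        tiny = BivariatePDF(
            MarginalModel("normal", (0.761, 0.027e-6)),
            MarginalModel("normal", (1.08, 0.012e-6)),
            CopulaModel("independence"),
        )
        classed = classify_frequency(tiny, n=10_000, seed=8)
        mean_dc, _ = class_pair_distances(classed, ("typical", "rare"), seed=9)
        assert mean_dc < 1e-4

    def test_unknown_class_errors(self, pdfs):
        classed = classify_frequency(pdfs["wc_petal"], n=10_000, seed=10)
        with pytest.raises(ValueError, match="empty"):
            class_pair_distances(classed, ("typical", "nonexistent"))


class TestCrossSpeciesDistances:
    def test_identical_pdf_same_seed_gives_zero(self, pdfs):
        p = pdfs["wc_petal"]
        a = p.sample(10_000, seed=11)
        b = p.sample(10_000, seed=11)
        assert np.allclose(a, b)

    def test_petal_pair_median(self, pdfs):
        d = cross_species_distances(pdfs["ez_lateral_petal"], pdfs["wc_petal"],
                                    n_pairs=100_000, seed=12)
        assert np.median(d) == pytest.approx(0.053, abs=0.005)

    def test_labellum_pollen_median(self, pdfs):
        d = cross_species_distances(pdfs["ez_labellum"], pdfs["wc_pollen"],
                                    n_pairs=100_000, seed=13)
        assert np.median(d) == pytest.approx(0.110, abs=0.01)

    def test_median_stable_when_doubling_n(self, pdfs):
        d1 = cross_species_distances(pdfs["ez_lateral_petal"], pdfs["wc_petal"],
                                     n_pairs=50_000, seed=14)
        d2 = cross_species_distances(pdfs["ez_lateral_petal"], pdfs["wc_petal"],
                                     n_pairs=100_000, seed=14)
        # MC standard error of the median ~ 1.25 sd/sqrt(n)
        se = 1.25 * d1.std() / np.sqrt(d1.size)
        assert abs(np.median(d1) - np.median(d2)) < 2 * se

    def test_translation_invariance_of_report(self, pdfs, disc_fns):
        p = pdfs["ez_lateral_petal"]
        q = pdfs["wc_petal"]
        shift = 3.7
        p2 = BivariatePDF(
            MarginalModel("normal", (p.margin_x.params[0] + shift, p.margin_x.params[1])),
            MarginalModel("normal", (p.margin_y.params[0], p.margin_y.params[1])),
            p.copula,
        )
        # shifting both species' x' margins by the same offset leaves the
        # distance distribution unchanged (gamma margins cannot be shifted
        # in-family, so test with the normal-margin species against itself)
        d0 = cross_species_distances(p, p, n_pairs=20_000, seed=15)
        p3 = BivariatePDF(p2.margin_x, p.margin_y, p.copula)
        d1 = cross_species_distances(p3, p3, n_pairs=20_000, seed=15)
        assert np.allclose(np.median(d0), np.median(d1), atol=1e-12)


class TestDiscriminationReport:
    def test_threshold_equivalence(self, pdfs, disc_fns):
        """Percent with pi < 0.75 equals percent with distance below the
        pi75 threshold distance — exact, by monotonicity."""
        d = cross_species_distances(pdfs["ez_lateral_petal"], pdfs["wc_petal"],
                                    n_pairs=20_000, seed=16)
        rep = discrimination_report(d, {"abs": disc_fns["absolute"]})
        thr = threshold_distance(disc_fns["absolute"], 0.75)
        by_pi = 100.0 * np.mean(disc_fns["absolute"](d, clamp=False) < 0.75)
        assert rep.conditions["abs"][3] == pytest.approx(by_pi, abs=1e-9)
        assert rep.conditions["abs"][3] == pytest.approx(100 * np.mean(d < thr), abs=1e-9)

    def test_experience_ordering(self, pdfs, disc_fns):
        d = cross_species_distances(pdfs["ez_labellum"], pdfs["wc_pollen"],
                                    n_pairs=20_000, seed=17)
        rep = discrimination_report(
            d, {"abs": disc_fns["absolute"], "succ": disc_fns["successive_blue"]})
        assert rep.conditions["abs"][3] >= rep.conditions["succ"][3]

    def test_zero_distances_are_fully_confusable(self, disc_fns):
        rep = discrimination_report(
            np.zeros(100), {"abs": disc_fns["absolute"], "succ": disc_fns["successive_blue"]})
        assert rep.conditions["abs"][3] == 100.0
        assert rep.conditions["succ"][3] == 100.0
        assert rep.conditions["abs"][0] == 0.5  # clamped at chance

    def test_unreachable_threshold_flagged(self, disc_fns):
        from mimicolor.discrimination import DiscriminationFunction

        weak = DiscriminationFunction("logistic3", {"K": 0.70, "r": 50.0, "Mo": 0.52})
        rep = discrimination_report(np.full(50, 0.2), {"weak": weak}, threshold=0.75)
        assert rep.conditions["weak"][3] == 100.0
        assert "weak" in rep.flags

    def test_report_frame_layout(self, pdfs, disc_fns):
        d = np.array([0.01, 0.05, 0.1, 0.2])
        rep = discrimination_report(
            d, {"abs": disc_fns["absolute"], "succ": disc_fns["successive_blue"]},
            pair="lateral petal/petal")
        row = rep.to_frame().iloc[0]
        assert row["pair"] == "lateral petal/petal"
        assert row["min_dc"] <= row["median_dc"] <= row["max_dc"]
        for cond in ("abs", "succ"):
            assert 0.5 <= row[f"pi_{cond}"] <= 1.0
            assert 0.0 <= row[f"pct_below_{cond}"] <= 100.0
        assert "pi_simul" not in row.index  # only emitted when supplied
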