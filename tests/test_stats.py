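"""Spearman correlation, Bland-Altman agreement, category split."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from ushisto import (
    PairedMeasurement,
    agreement_report,
    bland_altman,
    spearman_correlation,
    split_categories,
)
from ushisto.margins import MeasurementRecord
from ushisto.stats import bland_altman_from_diffs, pair_measurements


def make_pair(us, wsi, region="deep", slide="s1", source="US_M"):
    return PairedMeasurement(slide_id=slide, region=region, wsi_mm=wsi, us_mm=us, us_source=source)


class TestSpearman:
    def test_monotone_relation_gives_unit_rho(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        assert spearman_correlation(x, np.exp(0.3 * x)).rho == pytest.approx(1.0)
        assert spearman_correlation(x, -x[::-1] * 0 + x[::-1]).rho == pytest.approx(-1.0)

    def test_rho_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=20)
            y = rng.normal(size=20) + 0.5 * x
            ours = spearman_correlation(x, y)
            ref_rho, ref_p = sps.spearmanr(x, y)
            assert ours.rho == pytest.approx(ref_rho, abs=1e-12)
            assert ours.p_value == pytest.approx(ref_p, abs=1e-9)

    def test_rho_with_ties_matches_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 9.0, 10.0, 11.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 5.0, 8.0, 8.0, 12.0, 11.0])
        brute = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert spearman_correlation(x, y).rho == pytest.approx(brute, abs=1e-12)

    def test_exact_permutation_p_at_n7_matches_enumeration(self):
        """Full 7! enumeration with an independent per-permutation statistic."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        ours = spearman_correlation(x, y)
        obs = abs(sps.spearmanr(x, y).statistic)
        count = sum(
            1
            for perm in itertools.permutations(y)
            if abs(sps.spearmanr(x, perm).statistic) >= obs - 1e-12
        )
        assert ours.p_value == pytest.approx(count / math.factorial(7), abs=1e-12)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            spearman_correlation([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_equal_diffs_give_zero_width(self):
        pairs = [make_pair(5.0 + d, 5.0) for d in [1.5] * 4]
        ba = bland_altman(pairs)
        assert ba.mean_diff_mm == pytest.approx(1.5)
        assert ba.loa_upper_mm == ba.loa_lower_mm == pytest.approx(1.5)

    def test_symmetric_diffs_closed_form(self):
        ba = bland_altman_from_diffs([-1.0, 1.0])
        assert ba.mean_diff_mm == 0.0
        assert ba.sd_diff_mm == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert ba.loa_upper_mm == pytest.approx(1.96 * np.sqrt(2.0), abs=1e-12)

    def test_matches_direct_formulas_on_random_data(self):
        rng = np.random.default_rng(1)
        d = rng.normal(2.0, 3.0, 40)
        ba = bland_altman_from_diffs(d)
        assert ba.mean_diff_mm == pytest.approx(d.mean(), abs=1e-12)
        assert ba.sd_diff_mm == pytest.approx(d.std(ddof=1), abs=1e-12)
        assert ba.loa_lower_mm == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-12)

    def test_reported_limits_consistent_with_196_sd_convention(self):
        """Mean 2.14 with SD 2.495 must reproduce limits (-2.75; 7.03)."""
        mean, sd = 2.14, 4.89 / 1.96
        n = 200
        base = sps.norm.ppf((np.arange(n) + 0.5) / n)  # exact-moment normal scores
        d = base / base.std(ddof=1) * sd + mean
        ba = bland_altman_from_diffs(d)
        assert round(ba.loa_lower_mm, 2) == -2.75
        assert round(ba.loa_upper_mm, 2) == 7.03

    def test_single_pair_raises(self):
        with pytest.raises(ValueError):
            bland_altman_from_diffs([1.0])


class TestCategories:
    def test_boundaries_left_closed(self):
        pairs = [
            make_pair(4.9, 4.9),  # mean 4.9 -> <5
            make_pair(5.0, 5.0),  # mean 5.0 -> 5<10
            make_pair(10.0, 10.0),  # mean 10.0 -> >10
        ]
        cats = split_categories(pairs)
        assert [len(cats[c]) for c in ("<5", "5<10", ">10")] == [1, 1, 1]
        assert pairs[0].category == "<5"
        assert pairs[1].category == "5<10"
        assert pairs[2].category == ">10"

    def test_empty_input_gives_three_empty_lists(self):
        cats = split_categories([])
        assert set(cats) == {"<5", "5<10", ">10"}
        assert all(len(v) == 0 for v in cats.values())

    def test_partition_matches_brute_force_filter(self):
        rng = np.random.default_rng(2)
        pairs = [make_pair(u, w) for u, w in rng.uniform(0, 16, (60, 2))]
        cats = split_categories(pairs)
        means = np.array([p.mean_mm for p in pairs])
        assert len(cats["<5"]) == int((means < 5).sum())
        assert len(cats["5<10"]) == int(((means >= 5) & (means < 10)).sum())
        assert len(cats[">10"]) == int((means >= 10).sum())
        assert sum(len(v) for v in cats.values()) == len(pairs)

    def test_negative_mean_raises(self):
        with pytest.raises(ValueError, match="negative"):
            split_categories([make_pair(-3.0, -4.0)])


class TestAgreementReport:
    @staticmethod
    def _records(rng, n_slides=20, us_noise=0.0, scale=1.0):
        records = []
        for i in range(n_slides):
            for region in ("cranial", "deep", "caudal", "thickness"):
                true = rng.uniform(1.0, 14.0)
                records.append(MeasurementRecord("WSI", region, scale * true, f"s{i}"))
                records.append(
                    MeasurementRecord(
                        "US_M", region, max(true + rng.normal(0, us_noise + 1e-9), 0.0), f"s{i}"
                    )
                )
                records.append(
                    MeasurementRecord("US_Reg", region, max(true + rng.normal(0, 0.05), 0.0), f"s{i}")
                )
        return records

    def test_identical_sources_give_perfect_agreement(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(12):
            v = rng.uniform(1, 12)
            for src in ("WSI", "US_M", "US_Reg"):
                records.append(MeasurementRecord(src, "deep", v, f"s{i}"))
        report = agreement_report(records).set_index(["us_source", "stratum"])
        for src in ("US_M", "US_Reg"):
            row = report.loc[(src, "All")]
            assert row["rho"] == pytest.approx(1.0)
            assert row["mean_diff_mm"] == pytest.approx(0.0, abs=1e-12)

    def test_noisier_source_has_wider_limits_and_lower_rho(self):
        rng = np.random.default_rng(1)
        records = self._records(rng, us_noise=1.0, scale=0.9)
        report = agreement_report(records).set_index(["us_source", "stratum"])
        m, r = report.loc[("US_M", "All")], report.loc[("US_Reg", "All")]
        assert (r["loa_upper_mm"] - r["loa_lower_mm"]) < (m["loa_upper_mm"] - m["loa_lower_mm"])
        assert r["rho"] > m["rho"]

    def test_proportional_bias_increases_mean_diff_across_categories(self):
        rng = np.random.default_rng(2)
        records = self._records(rng, us_noise=0.0, scale=0.9)
        report = agreement_report(records).set_index(["us_source", "stratum"])
        diffs = [report.loc[("US_Reg", c), "mean_diff_mm"] for c in ("<5", "5<10", ">10")]
        assert diffs[0] < diffs[1] < diffs[2]

    def test_small_strata_flagged_not_computed(self):
        rng = np.random.default_rng(3)
        records = []
        for i in range(5):
            v = rng.uniform(1, 3)  # everything lands in <5
            records.append(MeasurementRecord("WSI", "deep", v, f"s{i}"))
            records.append(MeasurementRecord("US_M", "deep", v + 0.1, f"s{i}"))
        report = agreement_report(records, us_sources=("US_M",)).set_index(["us_source", "stratum"])
        assert not report.loc[("US_M", ">10"), "computed"]
        assert report.loc[("US_M", "<5"), "computed"]

    def test_order_independence(self):
        rng = np.random.default_rng(4)
        records = self._records(rng, n_slides=8, us_noise=0.5)
        a = agreement_report(records)
        b = agreement_report(list(reversed(records)))
        assert a.equals(b)

    def test_no_wsi_measurements_raise(self):
        with pytest.raises(ValueError, match="WSI"):
            agreement_report([MeasurementRecord("US_M", "deep", 1.0, "s")])

    def test_pairing_joins_on_slide_and_region(self):
        records = [
            MeasurementRecord("WSI", "deep", 4.0, "a"),
            MeasurementRecord("US_M", "deep", 5.0, "a"),
            MeasurementRecord("US_M", "cranial", 9.0, "a"),  # no WSI partner
        ]
        pairs = pair_measurements(records, "US_M")
        assert len(pairs) == 1
        assert pairs[0].diff_mm == pytest.approx(1.0)
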