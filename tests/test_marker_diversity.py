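"""Allele statistics, genetic distances and single-marker association."""

import numpy as np
import pandas as pd
import pytest

from agt_screen.errors import ValidationError
from agt_screen.marker_diversity import (
    allele_stats, expected_heterozygosity, genetic_distance, pic_botstein,
    single_marker_analysis, stats_frame,
)
from agt_screen.synthetic_data import simulate_markers
from agt_screen.trial_io import MarkerDataset


class TestPic:
    def test_biallelic_closed_form(self):
        # 1 - (0.61^2 + 0.39^2) - 2 * 0.61^2 * 0.39^2 = 0.36260718
        assert pic_botstein([0.61, 0.39]) == pytest.approx(0.3626072, abs=1e-6)

    def test_four_equifrequent_alleles(self):
        assert pic_botstein([0.25] * 4) == pytest.approx(0.703125)

    def test_monomorphic(self):
        assert pic_botstein([1.0]) == pytest.approx(0.0)

    def test_pic_below_heterozygosity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 6)
            p = rng.dirichlet(np.ones(k))
            assert pic_botstein(p) < expected_heterozygosity(p)

    def test_pic_maximized_at_equal_frequencies(self):
        # grid search over biallelic..tetra-allelic simplexes
        for k in (2, 3, 4):
            best = pic_botstein([1.0 / k] * k)
            grid = np.linspace(0.02, 0.98, 25)
            for p1 in grid:
                rest = (1 - p1) / (k - 1)
                freqs = [p1] + [rest] * (k - 1)
                assert pic_botstein(freqs) <= best + 1e-12

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            pic_botstein([0.5, 0.3])


class TestAlleleStats:
    def test_counting_and_flags(self):
        calls = pd.DataFrame(
            {"L1": ["A", "B", "A"], "L2": ["A", "A", "A"]},
            index=["g1", "g2", "g3"],
        )
        stats = allele_stats(MarkerDataset(calls))
        frame = stats_frame(stats).set_index("locus")
        assert frame.loc["L1", "Na"] == 2
        assert frame.loc["L2", "Na"] == 1
        assert frame.loc["L2", "MAF"] == 1.0
        assert frame.loc["L2", "PIC"] == 0.0
        assert bool(frame.loc["L2", "monomorphic"])

    def test_frequencies_over_nonmissing(self):
        calls = pd.DataFrame({"L1": ["A", "B", None, "A"]},
                             index=list("wxyz"))
        (s,) = allele_stats(MarkerDataset(calls))
        assert s.maf == pytest.approx(2 / 3)
        assert s.missing_fraction == pytest.approx(0.25)

    def test_simulated_maf_recovery(self):
        ds = simulate_markers({"L1": (0.61, 0.39)}, n=5000, seed=12)
        (s,) = allele_stats(ds)
        assert s.maf == pytest.approx(0.61, abs=0.02)

    def test_all_missing_excluded(self):
        calls = pd.DataFrame({"L1": [None, None], "L2": ["A", "B"]},
                             index=["g1", "g2"])
        with pytest.warns(UserWarning, match="L1"):
            stats = allele_stats(MarkerDataset(calls))
        assert [s.locus for s in stats] == ["L2"]


class TestGeneticDistance:
    def test_identical_genotypes_zero_everywhere(self):
        calls = pd.DataFrame({"L1": ["A", "A"], "L2": ["B", "B"]},
                             index=["g1", "g2"])
        ds = MarkerDataset(calls)
        for metric in ("nei_li", "shared_allele", "mismatch"):
            assert genetic_distance(ds, metric)[("g1", "g2")] == 0.0

    def test_no_shared_bands(self):
        calls = pd.DataFrame({"L1": ["A", "B"], "L2": ["C", "D"]},
                             index=["g1", "g2"])
        d = genetic_distance(MarkerDataset(calls), "nei_li")
        assert d[("g1", "g2")] == pytest.approx(1.0)

    def test_mismatch_count_and_band_oracle(self):
        calls = pd.DataFrame(
            {
                "L1": ["A", "A"], "L2": ["B", "C"], "L3": ["D", "E"],
                "L4": ["F", "F"], "L5": ["G", "H"],
            },
            index=["g1", "g2"],
        )
        ds = MarkerDataset(calls)
        assert genetic_distance(ds, "mismatch")[("g1", "g2")] == 3.0
        # brute-force band counting: 5 bands each, 2 shared
        shared, nx, ny = 2, 5, 5
        assert genetic_distance(ds, "nei_li")[("g1", "g2")] == pytest.approx(
            1 - 2 * shared / (nx + ny)
        )
        assert genetic_distance(ds, "shared_allele")[("g1", "g2")] == (
            pytest.approx(3 / 5)
        )

    def test_missing_calls_use_coscored_loci(self):
        calls = pd.DataFrame({"L1": ["A", None], "L2": ["B", "B"]},
                             index=["g1", "g2"])
        d = genetic_distance(MarkerDataset(calls), "shared_allele")
        assert d[("g1", "g2")] == 0.0


def brute_force_anova(groups):
    pooled = np.concatenate(groups)
    grand = pooled.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    sst = ((pooled - grand) ** 2).sum()
    ssw = sst - ssb
    dfb, dfw = len(groups) - 1, len(pooled) - len(groups)
    from scipy.stats import f as fdist
    F = (ssb / dfb) / (ssw / dfw)
    return 100 * ssb / sst, float(fdist.sf(F, dfb, dfw))


class TestSingleMarkerAnalysis:
    def _dataset(self, calls_by_genotype):
        calls = pd.DataFrame({"M1": list(calls_by_genotype.values())},
                             index=list(calls_by_genotype))
        return MarkerDataset(calls)

    def test_two_class_toy_matches_oracle(self):
        genos = [f"g{i}" for i in range(6)]
        markers = self._dataset(dict(zip(genos, ["A"] * 3 + ["B"] * 3)))
        records = pd.DataFrame({"SL": [1.0, 2, 3, 5, 6, 7]}, index=genos)
        out = single_marker_analysis(markers, records, ["SL"])
        row = out[out["skipped"].isna()].iloc[0]
        r2, p = brute_force_anova(
            [np.array([1.0, 2, 3]), np.array([5.0, 6, 7])]
        )
        assert row["R2"] == pytest.approx(r2)
        assert row["p"] == pytest.approx(p)

    def test_biallelic_r2_equals_squared_correlation(self):
        rng = np.random.default_rng(2)
        genos = [f"g{i}" for i in range(40)]
        alleles = ["A"] * 22 + ["B"] * 18
        markers = self._dataset(dict(zip(genos, alleles)))
        x = np.array([0.0 if a == "A" else 1.0 for a in alleles])
        y = 2 * x + rng.normal(0, 1, 40)
        records = pd.DataFrame({"SL": y}, index=genos)
        out = single_marker_analysis(markers, records, ["SL"])
        row = out[out["skipped"].isna()].iloc[0]
        assert row["R2"] == pytest.approx(100 * np.corrcoef(x, y)[0, 1] ** 2)

    def test_perfectly_explaining_marker(self):
        genos = [f"g{i}" for i in range(8)]
        markers = self._dataset(dict(zip(genos, ["A"] * 4 + ["B"] * 4)))
        records = pd.DataFrame({"SL": [1.0] * 4 + [9.0] * 4}, index=genos)
        out = single_marker_analysis(markers, records, ["SL"])
        row = out[out["skipped"].isna()].iloc[0]
        assert row["R2"] == pytest.approx(100.0)
        assert row["p"] < 1e-10

    def test_constant_trait_skipped(self):
        genos = [f"g{i}" for i in range(6)]
        markers = self._dataset(dict(zip(genos, ["A"] * 3 + ["B"] * 3)))
        records = pd.DataFrame({"SL": [4.0] * 6}, index=genos)
        out = single_marker_analysis(markers, records, ["SL"])
        assert (out["skipped"] == "constant trait").any()

    def test_single_class_marker_skipped_with_reason(self):
        genos = [f"g{i}" for i in range(6)]
        markers = self._dataset(dict(zip(genos, ["A"] * 6)))
        records = pd.DataFrame({"SL": np.arange(6.0)}, index=genos)
        out = single_marker_analysis(markers, records, ["SL"])
        assert out["skipped"].notna().all()
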