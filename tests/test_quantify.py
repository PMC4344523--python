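"""Per-nucleus metrics and group statistics."""

import math

import numpy as np
import pytest

import halofish as hf
from halofish.foci import FocusRecord
from halofish.quantify import (
    NucleusMetrics,
    assign_cell_cycle_bin,
    cell_cycle_fold_changes,
    compare_groups,
    group_summary,
    length_distribution_stats,
    metrics_to_dataframe,
    regress_content_vs_centromeres,
    summarize_nucleus,
)


def _rec(channel, compartment, bp=10_000.0, intensity=None, pos=(0, 0, 0),
         passes=True):
    return FocusRecord(
        nucleus_id="n", channel=channel, centroid_um=tuple(pos),
        voxel_count=5,
        integrated_intensity=float(intensity if intensity is not None else bp),
        compartment=compartment, estimated_bp=float(bp),
        passes_threshold=passes,
    )


def _foci_dict(g_halo=0, c_halo=0, g_core=0, c_core=0, cen_core=0,
               bp=10_000.0):
    rng = np.random.default_rng(0)

    def recs(ch, comp, n):
        return [_rec(ch, comp, bp=bp, pos=tuple(rng.random(3) * 10))
                for _ in range(n)]

    return {
        "TelG": recs("TelG", "halo", g_halo) + recs("TelG", "core", g_core),
        "TelC": recs("TelC", "halo", c_halo) + recs("TelC", "core", c_core),
        "CEN": recs("CEN", "core", cen_core),
    }


class TestSummarizeNucleus:
    def test_counts_and_number_bias(self):
        m = summarize_nucleus(None, _foci_dict(g_halo=10, c_halo=0))
        assert m.halo_count_G == 10 and m.halo_count_C == 0
        assert m.number_bias == pytest.approx(200.0)

    def test_ectr_fraction_half_when_contents_equal(self):
        m = summarize_nucleus(None, _foci_dict(g_halo=5, g_core=5))
        assert m.ectr_fraction_G == pytest.approx(50.0)

    def test_tel_cen_ratio_diploid_core(self):
        """92 core telomere foci per strand over 46 centromeres gives 2.0."""
        m = summarize_nucleus(
            None, _foci_dict(g_core=92, c_core=92, cen_core=46)
        )
        assert m.tel_cen_ratio_G == pytest.approx(2.0)
        assert m.tel_cen_ratio_C == pytest.approx(2.0)

    def test_ratio_flagged_nan_without_centromeres(self):
        m = summarize_nucleus(None, _foci_dict(g_core=10))
        assert math.isnan(m.tel_cen_ratio_G)

    def test_content_conservation(self):
        foci = _foci_dict(g_halo=7, g_core=3, bp=2_000.0)
        m = summarize_nucleus(None, foci)
        total = sum(f.estimated_bp for f in foci["TelG"]
                    if f.passes_threshold) / 1000.0
        assert m.halo_content_kb_G + m.core_content_kb_G \
            == pytest.approx(total)

    def test_channel_swap_antisymmetry(self):
        foci = _foci_dict(g_halo=12, c_halo=5, g_core=4, c_core=9,
                          cen_core=40)
        m = summarize_nucleus(None, foci)
        swapped = dict(foci)
        swapped["TelG"], swapped["TelC"] = foci["TelC"], foci["TelG"]
        ms = summarize_nucleus(None, swapped)
        assert ms.number_bias == pytest.approx(-m.number_bias)
        assert ms.content_bias == pytest.approx(-m.content_bias)
        assert ms.coloc_fraction_halo == pytest.approx(m.coloc_fraction_halo)

    def test_missing_channel_yields_nulls(self):
        m = summarize_nucleus(None, {"TelG": _foci_dict(g_halo=3)["TelG"]})
        assert m.halo_count_C == 0
        assert math.isnan(m.tel_cen_ratio_G)
        assert m.centromere_count_core == 0

    def test_sub_threshold_foci_not_counted(self):
        foci = {"TelG": [_rec("TelG", "halo", passes=False)]}
        m = summarize_nucleus(None, foci)
        assert m.halo_count_G == 0


class TestCellCycleBinning:
    @pytest.mark.parametrize("count,expected",
                             [(46, "G1"), (57, "G1"), (58, "S"), (69, "S"),
                              (80, "S"), (81, "G2"), (92, "G2")])
    def test_binning_rule(self, count, expected):
        assert assign_cell_cycle_bin(count, 46) == expected

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            assign_cell_cycle_bin(0, 46)
        with pytest.raises(ValueError):
            assign_cell_cycle_bin(46, 0)


class TestLengthStats:
    def test_degenerate_sample(self):
        s = length_distribution_stats([10.0, 10.0, 10.0])
        assert s.mean_kb == s.median_kb == 10.0
        assert s.mean_median_ratio == pytest.approx(1.0)
        assert s.pct_below_50 == 100.0 and s.pct_above_200 == 0.0

    def test_exponential_mean_median_ratio(self):
        """Exponential control: mean/median = 1/ln 2 within 1% at n=1e5."""
        rng = np.random.default_rng(0)
        s = length_distribution_stats(rng.exponential(30.0, 100_000))
        assert abs(s.mean_median_ratio - 1 / math.log(2)) \
            < 0.01 / math.log(2)

    def test_empty_gives_nans(self):
        s = length_distribution_stats([])
        assert math.isnan(s.mean_kb) and math.isnan(s.median_kb)


class TestCompareGroups:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        r = compare_groups(a, a)
        assert r.t_statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_swap_negates_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(10, 2, 30), rng.normal(12, 2, 30)
        r1, r2 = compare_groups(a, b), compare_groups(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_separated_groups_significant(self):
        """N(100,10) vs N(200,10), n=60: overwhelming significance."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            r = compare_groups(rng.normal(100, 10, 60), rng.normal(200, 10, 60))
            assert r.p_value < 1e-6

    def test_degenerate_zero_variance(self):
        with pytest.raises(ValueError):
            compare_groups([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])

    def test_median_iqr_reported(self):
        r = compare_groups([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r.median_a == 3 and r.median_b == 30
        assert r.iqr_a[0] <= r.median_a <= r.iqr_a[1]


def _metrics(nucleus_id="n", cen=46, g_halo=50, c_halo=40, content_g=500.0,
             content_c=400.0, phase=None, med_g=10.0, med_c=10.0):
    m = NucleusMetrics(nucleus_id=nucleus_id)
    m.centromere_count_core = cen
    m.halo_count_G, m.halo_count_C = g_halo, c_halo
    m.halo_content_kb_G, m.halo_content_kb_C = content_g, content_c
    m.cell_cycle_bin = phase
    m.length_stats_G.median_kb = med_g
    m.length_stats_C.median_kb = med_c
    return m


class TestRegression:
    def test_exact_linear_relation(self):
        ms = [_metrics(cen=c, content_g=10.0 * c, content_c=0.0)
              for c in (40, 50, 60, 70, 80, 92)]
        r = regress_content_vs_centromeres(ms)
        assert r.slope == pytest.approx(10.0)
        assert r.intercept == pytest.approx(0.0, abs=1e-8)
        assert r.slope_ci95[1] - r.slope_ci95[0] == pytest.approx(0.0,
                                                                  abs=1e-8)

    def test_doubling_content_through_cycle_gives_positive_slope(self):
        rng = np.random.default_rng(1)
        ms = []
        for i in range(60):
            cen = int(rng.integers(46, 93))
            content = 5.0 * cen * rng.lognormal(0, 0.3)
            ms.append(_metrics(nucleus_id=str(i), cen=cen,
                               content_g=content / 2, content_c=content / 2))
        r = regress_content_vs_centromeres(ms)
        assert r.slope > 0
        assert r.slope_ci95[0] > 0

    def test_permutation_null_ci_covers_zero(self):
        """CI should cover 0 in about 95% of permuted (null) datasets."""
        rng = np.random.default_rng(2)
        cens = np.array([int(rng.integers(46, 93)) for _ in range(60)])
        contents = 5.0 * cens * rng.lognormal(0, 0.3, 60)
        covered = 0
        n_perm = 60
        for _ in range(n_perm):
            perm = rng.permutation(contents)
            ms = [_metrics(nucleus_id=str(i), cen=int(c), content_g=p,
                           content_c=0.0)
                  for i, (c, p) in enumerate(zip(cens, perm))]
            r = regress_content_vs_centromeres(ms)
            covered += r.slope_ci95[0] <= 0 <= r.slope_ci95[1]
        assert covered / n_perm >= 0.85

    def test_constant_predictor_raises(self):
        ms = [_metrics(nucleus_id=str(i), cen=46) for i in range(5)]
        with pytest.raises(ValueError):
            regress_content_vs_centromeres(ms)


class TestCellCycleFoldChanges:
    def test_exact_threefold_counts_lengths_unchanged(self):
        ms = [_metrics(nucleus_id=f"g1-{i}", g_halo=30, c_halo=30,
                       phase="G1") for i in range(10)]
        ms += [_metrics(nucleus_id=f"g2-{i}", g_halo=90, c_halo=90,
                        phase="G2") for i in range(10)]
        out = cell_cycle_fold_changes(ms)
        assert out["count_fold_g2_g1"] == pytest.approx(3.0)
        assert out["length_fold_g2_g1"] == pytest.approx(1.0)

    def test_generator_recovery(self):
        """Sampled counts with a 3x G2 rate recover the fold within noise."""
        base = hf.GM847
        import dataclasses
        preset = dataclasses.replace(base, ectr_count_g2_fold=3.0,
                                     ectr_length_g2_fold=1.0)
        from halofish.simdata import _phase_factors, sample_ectr_population

        ms = []
        for phase, n in (("G1", 60), ("G2", 60)):
            cf, lf = _phase_factors(preset, phase)
            pops = sample_ectr_population(preset.scaled(cf, lf), n,
                                          seed=7 if phase == "G1" else 8)
            for i, pop in enumerate(pops):
                lens = [m.repeat_length_bp / 1000 for m in pop]
                med = float(np.median(lens)) if lens else float("nan")
                ms.append(_metrics(
                    nucleus_id=f"{phase}{i}",
                    g_halo=sum(m.strand == "G" for m in pop),
                    c_halo=sum(m.strand == "C" for m in pop),
                    phase=phase, med_g=med, med_c=med,
                ))
        out = cell_cycle_fold_changes(ms)
        assert 2.5 <= out["count_fold_g2_g1"] <= 3.5
        assert 0.95 <= out["length_fold_g2_g1"] <= 1.05

    def test_single_bin_gives_nulls(self):
        ms = [_metrics(phase="G1") for _ in range(4)]
        out = cell_cycle_fold_changes(ms)
        assert math.isnan(out["count_fold_g2_g1"])


class TestGroupSummary:
    def test_median_and_iqr_ordering(self):
        ms = [_metrics(nucleus_id=str(i), g_halo=i * 10) for i in range(1, 8)]
        df = metrics_to_dataframe(ms)
        df["group"] = "all"
        s = group_summary(df, "group")
        row = s.iloc[0]
        assert row["n_nuclei"] == 7
        assert (row["halo_count_G_iqr_low"] <= row["halo_count_G_median"]
                <= row["halo_count_G_iqr_high"])
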