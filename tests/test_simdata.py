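"""Simulator: sampling laws, truth construction, rendering physics."""

import numpy as np
import pytest

import halofish as hf
from halofish.simdata import (
    BP_PER_REPEAT,
    CAMERA_OFFSET_ADU,
    GroundTruth,
    Molecule,
    build_nucleus_truth,
    default_geometry,
    sample_ectr_population,
    simulate_calibration_slide,
)


class TestEctrSampling:
    def test_zero_rate_preset_yields_empty_nuclei(self):
        preset = hf.null_preset()
        pops = sample_ectr_population(preset, 50, seed=0)
        assert all(len(p) == 0 for p in pops)

    def test_sample_mean_matches_configured_mean(self):
        """Law of large numbers: 10,000 nuclei recover the preset count means."""
        pops = sample_ectr_population(hf.GM847, 10_000, seed=1)
        g = np.array([sum(1 for m in p if m.strand == "G") for p in pops])
        c = np.array([sum(1 for m in p if m.strand == "C") for p in pops])
        for counts, mean in ((g, hf.GM847.ectr_count_mean_G),
                             (c, hf.GM847.ectr_count_mean_C)):
            se = counts.std(ddof=1) / np.sqrt(len(counts))
            assert abs(counts.mean() - mean) < 3 * se

    def test_count_variance_matches_negative_binomial(self):
        pops = sample_ectr_population(hf.GM847, 10_000, seed=2)
        totals = np.array([len(p) for p in pops])
        m = hf.GM847.ectr_count_mean_G + hf.GM847.ectr_count_mean_C
        r = hf.GM847.ectr_count_dispersion
        expected_var = m + m * m / r
        assert abs(totals.var(ddof=1) / expected_var - 1) < 0.15

    def test_count_spread_covers_reported_range(self):
        """Strong ALT nuclei should range from <20 to >300 molecules."""
        pops = sample_ectr_population(hf.GM847, 2_000, seed=3)
        g = np.array([sum(1 for m in p if m.strand == "G") for p in pops])
        assert g.min() < 20
        assert g.max() > 300

    @pytest.mark.parametrize("preset", [hf.GM847, hf.VA13, hf.U2OS],
                             ids=lambda p: p.name)
    def test_length_skew_mean_median_ratio(self, preset):
        """ALT length distributions: mean 2-2.5x the median, reproducibly."""
        ratios = []
        for seed in (0, 1):
            pops = sample_ectr_population(preset, 400, seed=seed)
            lengths = np.array(
                [m.repeat_length_bp for p in pops for m in p]
            )
            assert lengths.mean() > np.median(lengths)  # strict positive skew
            ratios.append(lengths.mean() / np.median(lengths))
        assert 2.0 <= np.mean(ratios) <= 2.5
        assert abs(ratios[0] / ratios[1] - 1) < 0.05

    def test_invalid_preset_rejected(self):
        with pytest.raises(ValueError):
            hf.CellLinePreset(name="bad", ectr_count_mean_G=float("nan"),
                              ectr_count_mean_C=1.0)
        with pytest.raises(ValueError):
            hf.CellLinePreset(name="bad", ectr_count_mean_G=-1.0,
                              ectr_count_mean_C=1.0)
        with pytest.raises(ValueError):
            sample_ectr_population(hf.GM847, 0, seed=0)


class TestNucleusTruth:
    @pytest.mark.parametrize("phase,n_cen", [("G1", 46), ("G2", 92)])
    def test_centromere_counts_by_phase(self, default_config, phase, n_cen):
        geom = default_geometry(default_config)
        truth = build_nucleus_truth(
            hf.GM847, [], phase, geom, default_config, seed=0
        )
        assert len(truth.centromere_positions_um) == n_cen
        # core telomeres: 2 foci per strand per chromosome copy
        per_strand = sum(
            1 for m in truth.molecules
            if m.strand == "G" and m.compartment_truth == "core"
        )
        assert per_strand == 2 * n_cen

    def test_s_phase_counts_intermediate(self, default_config):
        geom = default_geometry(default_config)
        truth = build_nucleus_truth(
            hf.GM847, [], "S", geom, default_config, seed=5
        )
        assert 46 < len(truth.centromere_positions_um) < 92

    def test_halo_molecules_outside_core(self, default_config):
        geom = default_geometry(default_config)
        mols = [Molecule("G", 5000.0) for _ in range(1000)]
        truth = build_nucleus_truth(
            hf.GM847, mols, "G1", geom, default_config, seed=1
        )
        halo = truth.ectr_molecules()
        assert len(halo) == 1000
        center = np.asarray(truth.core_center_um)
        for m in halo:
            assert m.compartment_truth == "halo"
            assert np.linalg.norm(np.asarray(m.position_um) - center) \
                > truth.core_radius_um

    def test_placement_fails_when_field_too_small(self, default_config):
        geom = default_geometry(default_config)
        geom.halo_offset_um = 50.0  # forces every draw out of the field
        with pytest.raises(RuntimeError):
            build_nucleus_truth(
                hf.GM847, [Molecule("G", 5000.0)], "G1", geom,
                default_config, seed=0,
            )

    def test_truth_json_round_trip(self, default_config):
        geom = default_geometry(default_config)
        truth = build_nucleus_truth(
            hf.GM847, [Molecule("C", 1234.0)], "G1", geom, default_config,
            seed=2,
        )
        back = GroundTruth.from_dict(truth.to_dict())
        assert back.nucleus_id == truth.nucleus_id
        assert len(back.molecules) == len(truth.molecules)
        assert back.molecules[-1].repeat_length_bp == pytest.approx(1234.0)


def _single_molecule_truth(config, bp, pos=None, strand="G"):
    if pos is None:
        pos = tuple(s / 2 for s in config.field_size_um())
    return GroundTruth(
        nucleus_id="t", core_center_um=None, core_radius_um=0.0,
        molecules=[Molecule(strand, float(bp), pos, "halo")],
    )


class TestRendering:
    def test_flux_conservation_single_molecule(self, small_config):
        """Summed signal of one 810-bp molecule = photons_per_bp x 810."""
        truth = _single_molecule_truth(small_config, 810)
        stack = hf.render_stack(truth, small_config, noise=False)
        tel = stack.channel("TelG").astype(np.float64)
        total = float(
            tel.sum()
            - tel.size * (CAMERA_OFFSET_ADU + small_config.background_level)
        )
        expected = small_config.photons_per_bp * 810
        assert abs(total / expected - 1) < 1e-3

    def test_rendering_linear_in_length(self, small_config):
        """Two molecules of 810 and 1620 bp integrate at ratio 2.0."""
        fz, fy, fx = small_config.field_size_um()
        t1 = _single_molecule_truth(small_config, 810, (fz / 2, fy / 2, fx / 4))
        t2 = _single_molecule_truth(small_config, 1620,
                                    (fz / 2, fy / 2, 3 * fx / 4))
        base = small_config.background_level + CAMERA_OFFSET_ADU
        s1 = hf.render_stack(t1, small_config, noise=False)
        s2 = hf.render_stack(t2, small_config, noise=False)
        a1 = s1.channel("TelG").astype(np.float64)
        a2 = s2.channel("TelG").astype(np.float64)
        i1 = float(a1.sum() - a1.size * base)
        i2 = float(a2.sum() - a2.size * base)
        assert abs(i2 / i1 - 2.0) < 0.01

    def test_empty_truth_mean_is_background_plus_offset(self, small_config):
        truth = GroundTruth("null", None, 0.0, [])
        stack = hf.render_stack(truth, small_config,
                                rng=np.random.default_rng(0), noise=True)
        mean = float(stack.channel("TelC").mean())
        expected = small_config.background_level + CAMERA_OFFSET_ADU
        assert abs(mean - expected) < 0.5

    def test_rendering_reproducible_with_seed(self, small_config):
        truth = _single_molecule_truth(small_config, 50_000)
        a = hf.render_stack(truth, small_config, rng=np.random.default_rng(7))
        b = hf.render_stack(truth, small_config, rng=np.random.default_rng(7))
        assert np.array_equal(a.voxels, b.voxels)

    def test_quantization_and_clipping(self, small_config):
        truth = _single_molecule_truth(small_config, 10_000_000)  # saturates
        stack = hf.render_stack(truth, small_config,
                                rng=np.random.default_rng(0), noise=True)
        tel = stack.channel("TelG")
        assert tel.max() == small_config.max_adu
        assert np.allclose(tel, np.rint(tel))

    def test_duplex_emits_in_both_telomere_channels(self, small_config):
        truth = _single_molecule_truth(small_config, 5000)
        truth.molecules[0].strand = "duplex"
        stack = hf.render_stack(truth, small_config, noise=False)
        base = small_config.background_level + CAMERA_OFFSET_ADU
        for ch in ("TelG", "TelC"):
            assert float(stack.channel(ch).max()) > base + 5

    def test_dapi_core_bright_with_faint_halo(self, default_config):
        geom = default_geometry(default_config)
        truth = build_nucleus_truth(hf.GM847, [], "G1", geom, default_config,
                                    seed=0)
        stack = hf.render_stack(truth, default_config, noise=False)
        dapi = stack.channel("DAPI")
        center_vox = tuple(
            int(c / v) for c, v in zip(truth.core_center_um,
                                       default_config.voxel_size_um)
        )
        assert dapi[center_vox] > 500 + CAMERA_OFFSET_ADU
        assert dapi[2, 2, 2] < 50 + CAMERA_OFFSET_ADU


class TestCalibrationSlide:
    @pytest.mark.parametrize("repeats,bp", [(135, 810.0), (270, 1620.0)])
    def test_insert_repeat_lengths(self, small_config, repeats, bp):
        _, truth = simulate_calibration_slide(repeats, 10, small_config, seed=0)
        assert all(m.repeat_length_bp == bp for m in truth.molecules)
        assert all(m.strand == "duplex" for m in truth.molecules)
        assert bp == BP_PER_REPEAT * repeats

    def test_zero_foci_gives_pure_background(self, small_config):
        stack, truth = simulate_calibration_slide(135, 0, small_config, seed=0,
                                                  noise=False)
        assert truth.molecules == []
        base = small_config.background_level + CAMERA_OFFSET_ADU
        assert np.allclose(stack.channel("TelG"), base, atol=1e-4)

    def test_minimum_separation_enforced(self, small_config):
        _, truth = simulate_calibration_slide(135, 12, small_config, seed=1)
        pos = np.array([m.position_um for m in truth.molecules])
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2.0

    def test_overcrowded_slide_raises(self, small_config):
        with pytest.raises(RuntimeError):
            simulate_calibration_slide(135, 10_000, small_config, seed=0)

    def test_invalid_repeats_rejected(self, small_config):
        with pytest.raises(ValueError):
            simulate_calibration_slide(0, 5, small_config, seed=0)
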