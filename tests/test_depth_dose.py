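"""Depth-dose curve I/O, characterization, extraction and prediction."""

import warnings

import numpy as np
import pytest

import ebfkit as ek


def simple_curve(doses, spacing=1.0):
    depths = (np.arange(len(doses)) + 0.5) * spacing
    return ek.DepthDoseCurve(depths, np.asarray(doses, float), voxel_size=spacing)


class TestCurveIO:
    def test_round_trip_preserves_values(self, tmp_path):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            curve = ek.synth_reference_pdd(
                ek.SyntheticConfig(preset="15", noise_relative_sd=0.002, seed=3)
            )
        path = tmp_path / "pdd.csv"
        ek.write_curve(curve, path)
        back = ek.read_curve(path)
        assert np.array_equal(back.depths, curve.depths)
        assert np.array_equal(back.doses, curve.doses)

    def test_two_row_file(self, tmp_path):
        path = tmp_path / "tiny.csv"
        path.write_text("depth_mm,dose\n0,85.2\n1,87.0\n")
        curve = ek.read_curve(path)
        assert len(curve) == 2
        assert curve.doses[1] == pytest.approx(87.0)

    @pytest.mark.parametrize(
        "body",
        [
            "depth_mm,intensity\n0,1\n1,2\n",  # missing dose column
            "depth_mm,dose\n0,1\n0,2\n",  # non-monotone depths
            "depth_mm,dose\n0,1\n1,-2\n",  # negative dose
        ],
    )
    def test_malformed_files_rejected(self, tmp_path, body):
        path = tmp_path / "bad.csv"
        path.write_text(body)
        with pytest.raises(ek.FormatError):
            ek.read_curve(path)


class TestNormalization:
    @pytest.mark.parametrize(
        "doses,expected",
        [
            ((50.0, 100.0, 25.0), (50.0, 100.0, 25.0)),
            ((1.0, 2.0, 0.5), (50.0, 100.0, 25.0)),
            ((5.0, 5.0, 5.0), (100.0, 100.0, 100.0)),
        ],
    )
    def test_scaling(self, doses, expected):
        out = ek.normalize_to_dmax(simple_curve(doses))
        assert np.allclose(out.doses, expected)
        assert out.doses.max() == 100.0

    def test_idempotent(self):
        c = simple_curve((1.0, 3.0, 2.0))
        once = ek.normalize_to_dmax(c)
        twice = ek.normalize_to_dmax(once)
        assert np.array_equal(once.doses, twice.doses)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ek.normalize_to_dmax(simple_curve((0.0, 0.0, 0.0)))


class TestBeamQuality:
    @pytest.mark.parametrize("name", ["6", "9", "12", "15"])
    def test_recovers_preset_parameters_within_half_voxel(self, name):
        preset = ek.get_preset(name)
        cfg = ek.SyntheticConfig(preset=name, noise_relative_sd=0.0)
        curve = ek.synth_reference_pdd(cfg)
        bq = ek.beam_quality(curve)
        assert abs(bq.r50_mm - preset.r50_mm) <= 0.5 * cfg.voxel_size
        assert abs(bq.rp_mm - preset.rp_mm) <= 0.5 * cfg.voxel_size
        assert bq.e0_mev == pytest.approx(ek.e0_from_r50(bq.r50_mm))
        assert bq.r50_mm < bq.rp_mm

    def test_truncated_curve_rejected(self):
        cfg = ek.SyntheticConfig(preset="9", noise_relative_sd=0.0)
        curve = ek.synth_reference_pdd(cfg)
        keep = curve.doses / curve.doses.max() * 100 > 80
        short = ek.DepthDoseCurve(curve.depths[keep], curve.doses[keep])
        with pytest.raises(ValueError):
            ek.beam_quality(short)


class TestExtraction:
    def setup_method(self):
        self.cfg = ek.SyntheticConfig(preset="12", noise_relative_sd=0.0)
        self.ref = ek.synth_reference_pdd(self.cfg)
        self.beam = self.cfg.beam_preset.beam

    def test_ratio_identity_for_constructed_pair(self):
        # multiply the reference by a known profile and recover it exactly
        interface = ek.LeadInterface(depth=30.0)
        profile = 1.0 + 0.4 * np.exp(-0.3 * (interface.depth - self.ref.depths))
        doses = np.where(
            self.ref.depths < interface.depth, self.ref.doses * profile, 0.0
        )
        pb = ek.DepthDoseCurve(self.ref.depths, doses, voxel_size=1.0)
        obs = ek.extract_backscatter(pb, self.ref, interface, self.beam)
        expected = {
            round(interface.depth - d, 9): p
            for d, p in zip(self.ref.depths, profile)
            if d < interface.depth
        }
        for o in obs:
            assert o.ebf == pytest.approx(expected[round(o.t_mm, 9)], abs=1e-12)
        assert obs[0].is_interface and obs[0].t_mm == pytest.approx(0.5)
        assert sum(o.is_interface for o in obs) == 1

    def test_grid_mismatch_requires_resample(self):
        coarser = ek.DepthDoseCurve(self.ref.depths[::2], self.ref.doses[::2])
        interface = ek.LeadInterface(depth=30.0)
        with pytest.raises(ValueError, match="resample"):
            ek.extract_backscatter(self.ref, coarser, interface, self.beam)
        obs = ek.extract_backscatter(
            self.ref, coarser, interface, self.beam, resample=True
        )
        assert len(obs) == np.sum(self.ref.depths < interface.depth)

    def test_interface_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            ek.extract_backscatter(
                self.ref, self.ref, ek.LeadInterface(depth=1000.0), self.beam
            )

    def test_shared_interface_energy(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            pb, ref = ek.synth_pb_pair(self.cfg, ek.LeadInterface(depth=30.0))
            obs = ek.extract_backscatter(pb, ref, ek.LeadInterface(depth=30.0), self.beam)
        assert len({o.em_mev for o in obs}) == 1
        assert obs[0].em_mev == pytest.approx(
            ek.mean_energy_at_depth(self.beam, 30.0)
        )


class TestRangeScaling:
    def test_identity_and_measured_factor(self):
        c = ek.DepthDoseCurve(np.array([10.0, 20.0]), np.array([1.0, 2.0]))
        assert np.array_equal(ek.apply_range_scaling(c, 1.0).depths, c.depths)
        scaled = ek.apply_range_scaling(c, 1.02)
        assert np.allclose(scaled.depths, [10.2, 20.4])
        assert np.array_equal(scaled.doses, c.doses)

    def test_composition(self):
        c = simple_curve((1.0, 2.0, 3.0))
        a = ek.apply_range_scaling(ek.apply_range_scaling(c, 1.1), 1.2)
        b = ek.apply_range_scaling(c, 1.1 * 1.2)
        assert np.allclose(a.depths, b.depths)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            ek.apply_range_scaling(simple_curve((1.0, 2.0)), 0.0)


class TestPrediction:
    def setup_method(self):
        self.cfg = ek.SyntheticConfig(preset="9", noise_relative_sd=0.0)
        self.ref = ek.synth_reference_pdd(self.cfg)
        self.beam = self.cfg.beam_preset.beam
        self.coeffs = ek.EBFCoefficients.default()

    def test_voxel_ratios_follow_the_model(self):
        interface = ek.LeadInterface(depth=20.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            out = ek.predict_perturbed_pdd(self.ref, interface, self.beam, self.coeffs)
            em = ek.mean_energy_at_depth(self.beam, interface.depth)
            upstream = self.ref.depths < interface.depth
            t = interface.depth - self.ref.depths[upstream]
            expected = ek.ebf_upstream(em, t, self.coeffs)
            expected[-1] = ek.ebf_at_interface(em, self.coeffs)  # t=0 attribution
        ratio = out.doses[upstream] / self.ref.doses[upstream]
        assert np.allclose(ratio, expected, rtol=0, atol=1e-12)
        assert np.all(out.doses[~upstream] == 0.0)

    def test_interface_voxel_matches_half_range_energy(self):
        # Pb at half the practical range puts the interface at Em = E0/2
        interface = ek.LeadInterface(depth=self.beam.rp_mm / 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            out = ek.predict_perturbed_pdd(self.ref, interface, self.beam, self.coeffs)
            expected = ek.ebf_at_interface(self.beam.e0_mev / 2, self.coeffs)
        first = np.nonzero(self.ref.depths < interface.depth)[0][-1]
        assert out.doses[first] / self.ref.doses[first] == pytest.approx(
            expected, abs=1e-9
        )

    def test_interface_beyond_practical_range(self):
        interface = ek.LeadInterface(depth=self.beam.rp_mm + 10.0)
        with pytest.warns(UserWarning, match="practical range"):
            out = ek.predict_perturbed_pdd(self.ref, interface, self.beam, self.coeffs)
        upstream = self.ref.depths < interface.depth
        assert np.array_equal(out.doses[upstream], self.ref.doses[upstream])
        assert np.all(out.doses[~upstream] == 0.0)

    def test_extraction_inverts_prediction(self):
        interface = ek.LeadInterface(depth=24.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            out = ek.predict_perturbed_pdd(self.ref, interface, self.beam, self.coeffs)
            obs = ek.extract_backscatter(out, self.ref, interface, self.beam)
            em = ek.mean_energy_at_depth(self.beam, interface.depth)
            for o in obs:
                t_eff = 0.0 if o.is_interface else o.t_mm
                assert o.ebf == pytest.approx(
                    ek.ebf_upstream(em, t_eff, self.coeffs), abs=1e-12
                )
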