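"""Layer thicknesses, band widths, fovea localization, and flattening."""

import numpy as np
import pytest

from hovmap import (
    BScan,
    band_width,
    flatten,
    layer_profiles,
    locate_fovea,
    structural_biomarkers,
    thickness_summaries,
)
from hovmap.bscan import FoveaUndefinedError, SegmentationError
from hovmap.synthetic import LayerSpec, TruthSurface, simulate_bscan_pair


def make_scan(n=601, extent=4.5, inl=None, onl=90.0, isg=25.0, osg=35.0,
              ez_mask=None, **kw):
    """Flat-layer scan builder; thicknesses in um, half-extent in mm."""
    u = np.linspace(-extent, extent, n)
    inl = np.full(n, 100.0) if inl is None else inl
    elm = inl + onl
    ez = elm + isg
    prpe = ez + osg
    if ez_mask is not None:
        ez = np.where(ez_mask(u), ez, np.nan)
    return BScan(orientation="H", lateral_mm=u,
                 boundaries={"INL": inl, "ELM": elm, "EZ": ez, "pRPE": prpe}, **kw)


class TestLayerProfiles:
    def test_parallel_flat_boundaries(self):
        p = layer_profiles(make_scan(onl=100.0, isg=25.0, osg=35.0))
        np.testing.assert_allclose(p["ONL"], 100.0)
        np.testing.assert_allclose(p["REC"], 160.0)

    def test_additivity_per_column(self):
        """OS+ + ONL+ + (EZ-ELM band) must equal REC at every column."""
        rng = np.random.default_rng(1)
        n = 301
        scan = make_scan(n=n, inl=100 + rng.uniform(-5, 5, n),
                         onl=90 + rng.uniform(0, 10),
                         isg=25 + rng.uniform(0, 5), osg=35.0)
        p = layer_profiles(scan)
        ez_elm = scan.boundaries["EZ"] - scan.boundaries["ELM"]
        np.testing.assert_allclose(p["OS"] + p["ONL"] + ez_elm, p["REC"])
        np.testing.assert_allclose(p["ISOS"] + p["ONL"], p["REC"])

    def test_ez_gap_propagates_to_os_not_rec(self):
        scan = make_scan(ez_mask=lambda u: np.abs(u) <= 1.75)
        p = layer_profiles(scan)
        far = np.abs(scan.lateral_mm) > 1.75
        assert np.isnan(p["OS"][far]).all()
        assert np.isfinite(p["REC"]).all()

    def test_ordering_violation_reports_column(self):
        n = 50
        inl = np.full(n, 100.0)
        elm = inl + 90
        ez = elm + 25
        prpe = ez + 35
        ez[17] = prpe[17] + 10  # EZ below pRPE
        with pytest.raises(SegmentationError, match="column 17"):
            BScan(orientation="H", lateral_mm=np.linspace(-3, 3, n),
                  boundaries={"INL": inl, "ELM": elm, "EZ": ez, "pRPE": prpe})


class TestThicknessSummaries:
    def test_constant_profile(self):
        scan = make_scan(onl=90, isg=25, osg=35)
        s = thickness_summaries(layer_profiles(scan), scan.lateral_mm, 0.0)
        assert s["REC"] == {"AVG": 150.0, "FOV": 150.0, "MAX": 150.0}

    def test_linear_profile_mean(self):
        """Thickness ramping 100 -> 200 um has mean 150 um."""
        n = 1001
        u = np.linspace(-4.5, 4.5, n)
        ramp = np.linspace(100, 200, n)
        scan = BScan(orientation="H", lateral_mm=u,
                     boundaries={"INL": np.zeros(n), "ELM": ramp * 0.5,
                                 "EZ": ramp * 0.75, "pRPE": ramp})
        s = thickness_summaries(layer_profiles(scan), u, 0.0)
        assert s["REC"]["AVG"] == pytest.approx(150.0)
        assert s["REC"]["MAX"] == pytest.approx(200.0)

    def test_foveal_pit_fov_below_avg(self):
        n = 601
        u = np.linspace(-4.5, 4.5, n)
        pit = 40 * np.exp(-(u**2) / (2 * 0.3**2))
        inl = 100 + pit
        elm = np.full(n, 190.0)  # ELM flat: ONL+ thins by the pit depth
        scan = BScan(orientation="H", lateral_mm=u,
                     boundaries={"INL": inl, "ELM": elm, "EZ": elm + 25,
                                 "pRPE": elm + 60})
        s = thickness_summaries(layer_profiles(scan), u, 0.0)
        assert s["ONL"]["FOV"] == pytest.approx(50.0, abs=0.5)
        assert s["ONL"]["AVG"] > s["ONL"]["FOV"]

    def test_fovea_outside_scan_rejected(self):
        scan = make_scan()
        with pytest.raises(ValueError):
            thickness_summaries(layer_profiles(scan), scan.lateral_mm, 99.0)


class TestBandWidth:
    def test_flat_band_width(self):
        scan = make_scan(ez_mask=lambda u: np.abs(u) <= 1.75)
        w, truncated = band_width(scan, "EZ")
        assert w == pytest.approx(3.5, abs=0.02)
        assert not truncated

    def test_axial_offset_pythagoras(self):
        """Endpoints 3.5 mm apart laterally and 300 um axially give
        sqrt(3.5^2 + 0.3^2) mm."""
        n = 701
        u = np.linspace(-3.5, 3.5, n)
        ez = np.full(n, 150.0)
        ez[np.abs(u + 1.75) < 0.004] = 150.0
        mask = np.abs(u) <= 1.75 + 1e-9
        ez = np.where(mask, 150.0, np.nan)
        i_right = np.flatnonzero(mask)[-1]
        ez[i_right] += 300.0  # axial offset at the right edge only
        inl = np.zeros(n)
        scan = BScan(orientation="H", lateral_mm=u,
                     boundaries={"INL": inl, "ELM": inl + 50,
                                 "EZ": ez, "pRPE": inl + 500})
        w, _ = band_width(scan, "EZ")
        assert w == pytest.approx(np.hypot(3.5, 0.3), abs=0.02)

    def test_full_span_band_truncated(self):
        scan = make_scan()
        _, truncated = band_width(scan, "EZ")
        assert truncated

    def test_reversal_invariance(self):
        scan = make_scan(ez_mask=lambda u: (u > -1.0) & (u < 2.0))
        rev = BScan(orientation="H", lateral_mm=-scan.lateral_mm[::-1],
                    boundaries={k: v[::-1] for k, v in scan.boundaries.items()})
        assert band_width(scan, "EZ")[0] == pytest.approx(
            band_width(rev, "EZ")[0], rel=1e-12
        )

    def test_undefined_band_rejected(self):
        scan = make_scan(ez_mask=lambda u: u > 99)
        with pytest.raises(ValueError, match="nowhere defined"):
            band_width(scan, "EZ")


class TestFovea:
    @pytest.mark.parametrize("pos", [0.0, 0.4, -0.8])
    def test_pit_position_recovered(self, pos):
        t = TruthSurface()
        h, _ = simulate_bscan_pair(t, fovea_mm=pos, seed=0)
        assert locate_fovea(h) == pytest.approx(pos, abs=0.012)

    def test_flat_trace_rejected(self):
        with pytest.raises(FoveaUndefinedError):
            locate_fovea(make_scan())

    def test_hint_fallback(self):
        scan = make_scan(fovea_hint_mm=0.25)
        from hovmap.bscan import fovea_or_hint

        assert fovea_or_hint(scan) == 0.25


class TestFlatten:
    def fuzz_scan(self, rng):
        n = int(rng.integers(200, 500))
        extent = rng.uniform(3.0, 5.0)
        u = np.linspace(-extent, extent, n)
        curve = rng.uniform(-5, 5) * u**2 + rng.uniform(-2, 2) * u**3
        pit = rng.uniform(20, 60) * np.exp(-(u**2) / (2 * 0.35**2))
        inl = 100 + curve + pit
        onl = np.maximum(90 - pit + rng.normal(0, 1, n), 1.0)
        elm = inl + onl
        ez = elm + 25 + rng.normal(0, 1, n)
        prpe = ez + 35 + rng.normal(0, 1, n).clip(-30, None)
        hw = rng.uniform(1.0, extent * 0.9)
        ez = np.where(np.abs(u) <= hw, ez, np.nan)
        return BScan(orientation="H", lateral_mm=u,
                     boundaries={"INL": inl, "ELM": elm, "EZ": ez, "pRPE": prpe})

    def test_already_flat_is_identity(self):
        scan = make_scan()
        f = flatten(scan)
        for name in scan.boundaries:
            np.testing.assert_allclose(f.depth(name), scan.depth(name), atol=1e-9)

    def test_cubic_curvature_removed(self):
        n = 601
        u = np.linspace(-3, 3, n)
        curve = 10 * u**3
        scan = make_scan(n=n, extent=3.0, inl=100 + curve)
        f = flatten(scan)
        assert np.ptp(f.depth("pRPE")) < 1e-6
        for layer, p in layer_profiles(scan).items():
            np.testing.assert_array_equal(p, layer_profiles(f)[layer])

    def test_thickness_bitwise_invariant_on_fuzzed_scans(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            scan = self.fuzz_scan(rng)
            f = flatten(scan)
            for layer, p in layer_profiles(scan).items():
                assert np.array_equal(p, layer_profiles(f)[layer], equal_nan=True)

    def test_band_width_nearly_invariant(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            scan = self.fuzz_scan(rng)
            w0, _ = band_width(scan, "EZ")
            w1, _ = band_width(flatten(scan), "EZ")
            assert abs(w1 - w0) / w0 < 0.005


class TestGroundTruthRecovery:
    def test_zero_noise_biomarkers_match_generator(self):
        layers = LayerSpec()
        h, v = simulate_bscan_pair(
            TruthSurface(), ez_halfwidth_mm=1.75, layers=layers,
            axial_noise_sd=0.0, seed=5,
        )
        for scan in (h, v):
            b = structural_biomarkers(scan)
            assert b["W_EZ"] == pytest.approx(3.5, abs=0.012)
            assert not b["ez_truncated"]
            assert b["T_OS_AVG"] == pytest.approx(layers.os_um, abs=0.01)
            assert b["T_REC_MAX"] == pytest.approx(layers.rec_um, abs=0.01)
            # the pit displaces INL posteriorly: REC thins at the fovea
            assert b["T_REC_FOV"] == pytest.approx(
                layers.rec_um - layers.pit_depth_um, abs=1.0
            )
            assert abs(b["fovea_mm"]) < 0.012

    def test_determinism(self):
        t = TruthSurface()
        a = simulate_bscan_pair(t, axial_noise_sd=2.0, seed=9)
        b = simulate_bscan_pair(t, axial_noise_sd=2.0, seed=9)
        for s1, s2 in zip(a, b):
            for k in s1.boundaries:
                assert np.array_equal(s1.boundaries[k], s2.boundaries[k],
                                      equal_nan=True)
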