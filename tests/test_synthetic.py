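"""Synthetic delivery generator: plan, production, emission, transport, detector."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from fragmon.config import EmissionConfig, PhantomConfig, PlanConfig, SyntheticConfig
from fragmon.synthetic import (
    detector_response,
    direction_window_mass,
    generate_plan,
    ion_range_mm,
    path_density_integral,
    production_profile,
    sample_emission_direction,
    sample_vertex_depth,
    simulate_fraction,
    sphere_diameter_mm,
    transport_fragment,
)

EM = EmissionConfig()
PH = PhantomConfig()


class TestPlan:
    def test_single_spot_plan(self):
        plan = generate_plan(PlanConfig(n_layers=1, spots_per_layer=1))
        assert len(plan) == 1
        assert plan.iloc[0]["t_start_ns"] < plan.iloc[0]["t_end_ns"]

    def test_energies_linearly_spaced_within_span(self):
        plan = generate_plan(PlanConfig(n_layers=25, spots_per_layer=4))
        e = np.unique(plan["energy_mev_u"])
        assert len(e) == 25
        np.testing.assert_allclose(e, np.linspace(153.0, 250.0, 25))

    def test_deterministic(self):
        p1 = generate_plan(PlanConfig(), seed=5)
        p2 = generate_plan(PlanConfig(), seed=5)
        pd.testing.assert_frame_equal(p1, p2)

    def test_spot_intervals_disjoint_and_ordered(self):
        plan = generate_plan(PlanConfig(n_layers=2, spots_per_layer=10))
        assert (plan["t_start_ns"].to_numpy()[1:] > plan["t_end_ns"].to_numpy()[:-1]).all()

    def test_ptv_sphere_diameter_rounds_to_46mm(self):
        assert round(sphere_diameter_mm(50.0)) == 46

    def test_carbon_range_scale(self):
        # Bragg-Kleeman defaults: ~128 mm at 250 MeV/u, monotone in energy
        assert ion_range_mm(250.0, EM) == pytest.approx(128.0, rel=0.02)
        assert ion_range_mm(153.0, EM) < ion_range_mm(250.0, EM)


class TestVertexDepth:
    def test_uniform_density_long_attenuation_gives_uniform_depths(self, rng):
        em = EmissionConfig(lambda_primary_mm=1e9)
        prof = production_profile(250.0, PH, em)
        z = sample_vertex_depth(prof, rng, 10_000)
        lo, hi = PH.entry_z_mm, PH.entry_z_mm + ion_range_mm(250.0, em)
        assert stats.kstest(z, stats.uniform(loc=lo, scale=hi - lo).cdf).pvalue > 0.01

    def test_insert_doubles_local_production_before_survival(self):
        """The added silicone density (~1) doubles the production rate in the
        insert interval relative to the unit-density reference."""
        em = EmissionConfig(lambda_primary_mm=1e9)  # disable survival weighting
        p_ref = production_profile(250.0, PH, em, insert_on=False)
        p_ins = production_profile(250.0, PH, em, insert_on=True)
        zc = 0.5 * (p_ref.z_edges[:-1] + p_ref.z_edges[1:])
        in_ins = (zc >= PH.insert_z_mm[0]) & (zc < PH.insert_z_mm[1])
        ratio = p_ins.weights[in_ins].sum() / p_ref.weights[in_ins].sum()
        assert ratio == pytest.approx(1.0 + PH.insert_delta_density, rel=1e-6)

    def test_production_beyond_insert_strictly_lower(self):
        p_ref = production_profile(250.0, PH, EM, insert_on=False)
        p_ins = production_profile(250.0, PH, EM, insert_on=True)
        zc = 0.5 * (p_ref.z_edges[:-1] + p_ref.z_edges[1:])
        beyond = (zc > PH.insert_z_mm[1]) & (p_ref.weights > 0)
        assert (p_ins.weights[beyond] < p_ref.weights[beyond]).all()

    def test_truncation_at_primary_range(self, rng):
        prof = production_profile(153.0, PH, EM)
        z = sample_vertex_depth(prof, rng, 5000)
        assert z.max() <= PH.entry_z_mm + ion_range_mm(153.0, EM) + 0.5


class TestEmissionDirections:
    def test_small_theta0_collimates_along_beam(self, rng):
        em = EmissionConfig(theta0_rad=1e-4)
        d = sample_emission_direction(em, rng, 1000)
        assert np.arccos(d[:, 2]).max() < 1e-3

    def test_mean_polar_angle_matches_truncated_exponential(self, rng):
        d = sample_emission_direction(EM, rng, 100_000)
        theta = np.arccos(np.clip(d[:, 2], -1, 1))
        t0 = EM.theta0_rad
        z_norm = quad(lambda t: np.exp(-t / t0), 0, np.pi / 2)[0]
        mean_exact = quad(lambda t: t * np.exp(-t / t0), 0, np.pi / 2)[0] / z_norm
        se = theta.std() / np.sqrt(len(theta))
        assert abs(theta.mean() - mean_exact) < 3 * se

    def test_wider_theta0_raises_mass_near_thirty_degrees(self, rng):
        band = (np.radians(25), np.radians(35))
        fracs = []
        for t0 in (0.1, 0.5):
            d = sample_emission_direction(EmissionConfig(theta0_rad=t0), rng, 50_000)
            th = np.arccos(np.clip(d[:, 2], -1, 1))
            fracs.append(((th >= band[0]) & (th < band[1])).mean())
        assert fracs[1] > fracs[0]

    def test_windowed_sampling_stays_in_window_with_correct_mass(self, rng):
        tw, pw = (0.3, 0.8), (1.0, 2.0)
        d = sample_emission_direction(EM, rng, 20_000, tw, pw)
        th = np.arccos(np.clip(d[:, 2], -1, 1))
        ph = np.arctan2(d[:, 1], d[:, 0])
        assert th.min() >= tw[0] - 1e-9 and th.max() <= tw[1] + 1e-9
        assert ph.min() >= pw[0] - 1e-9 and ph.max() <= pw[1] + 1e-9
        # window mass consistent with full-sphere sampling frequency
        full = sample_emission_direction(EM, rng, 200_000)
        th_f = np.arccos(np.clip(full[:, 2], -1, 1))
        ph_f = np.arctan2(full[:, 1], full[:, 0])
        hit = ((th_f >= tw[0]) & (th_f <= tw[1]) & (ph_f >= pw[0]) & (ph_f <= pw[1])).mean()
        mass = direction_window_mass(EM, tw, pw)
        assert hit == pytest.approx(mass, abs=4 * np.sqrt(mass / 200_000))


class TestTransport:
    def test_no_attenuation_no_scatter_is_identity(self, rng):
        em = EmissionConfig(lambda_fragment_mm=1e12, mcs_sigma_rad=0.0)
        dirs = np.tile([[0.0, np.sin(0.5), np.cos(0.5)]], (100, 1))
        verts = np.tile([[0.0, 0.0, 0.0]], (100, 1))
        surv, out = transport_fragment(verts, dirs, PH, em, rng)
        assert surv.all()
        np.testing.assert_array_equal(out, dirs)

    def test_insert_column_density_closed_form(self):
        """A vertical ray crossing the full 10 mm insert picks up exactly
        delta_rho * 10 mm of extra water-equivalent path."""
        verts = np.array([[0.0, 0.0, -40.0]])
        dirs = np.array([[0.0, 0.0, 1.0]])
        i_off = path_density_integral(verts, dirs, PH, insert_on=False)
        i_on = path_density_integral(verts, dirs, PH, insert_on=True)
        extra = PH.insert_delta_density * (PH.insert_z_mm[1] - PH.insert_z_mm[0])
        assert i_on[0] - i_off[0] == pytest.approx(extra, abs=1e-9)
        # survival factor exp(-extra/lambda)
        ratio = np.exp(-i_on[0] / EM.lambda_fragment_mm) / np.exp(
            -i_off[0] / EM.lambda_fragment_mm
        )
        assert ratio == pytest.approx(np.exp(-extra / EM.lambda_fragment_mm))

    def test_ray_missing_insert_laterally_unaffected(self):
        verts = np.array([[40.0, 0.0, -40.0]])  # outside the 25 mm lateral box
        dirs = np.array([[0.0, 0.0, 1.0]])
        i_off = path_density_integral(verts, dirs, PH, insert_on=False)
        i_on = path_density_integral(verts, dirs, PH, insert_on=True)
        assert i_on[0] == pytest.approx(i_off[0], abs=1e-12)

    def test_upstream_fragments_toward_tracker_lose_detections(self, rng):
        """Fragments emitted upstream of the silicone toward the tracker
        traverse it and are absorbed more often than without the insert."""
        n = 40_000
        verts = np.tile([[0.0, 0.0, -25.0]], (n, 1))
        d = np.array([0.0, np.sin(np.radians(30)), np.cos(np.radians(30))])
        dirs = np.tile(d, (n, 1))
        s_off, _ = transport_fragment(verts, dirs, PH, EM, np.random.default_rng(3))
        s_on, _ = transport_fragment(
            verts, dirs, PH, EM, np.random.default_rng(3), insert_on=True
        )
        assert s_on.sum() < s_off.sum()
        ratio = s_on.sum() / s_off.sum()
        L = (PH.insert_z_mm[1] - PH.insert_z_mm[0]) / np.cos(np.radians(30))
        expect = np.exp(-PH.insert_delta_density * L / EM.lambda_fragment_mm)
        assert ratio == pytest.approx(expect, abs=0.01)


class TestDetector:
    def test_central_ray_hits_both_layer_centers(self, geom, rng):
        resp = detector_response(
            np.zeros((1, 3)), geom.focus_direction[None, :], np.array([0.0]), geom, EM, rng
        )
        assert resp["detected"][0]
        nc, nr = geom.pixels_per_layer
        for layer in ("front", "back"):
            h = resp[layer]
            e_tot = h["energy_kev"].sum()
            cc = (h["col"] * h["energy_kev"]).sum() / e_tot
            cr = (h["row"] * h["energy_kev"]).sum() / e_tot
            assert abs(cc - (nc - 1) / 2) < 0.5
            assert abs(cr - (nr - 1) / 2) < 0.5

    def test_subthreshold_deposit_leaves_no_hits(self, geom, rng):
        em = EmissionConfig(edep_median_kev=2.0, edep_sigma_log=0.0)
        resp = detector_response(
            np.zeros((1, 3)), geom.focus_direction[None, :], np.array([0.0]), geom, em, rng
        )
        assert not resp["detected"][0]
        assert len(resp["front"]["col"]) == 0

    def test_ray_missing_back_layer_is_undetected(self, geom, rng):
        # aim at a front-layer corner along the focus direction: the parallax
        # from the isocenter pushes the back-layer intersection off the sensor
        corner = geom.layer_corners("front")[0] - 0.2 * (
            geom.layer_corners("front")[0] - geom.layer_center("front")
        ) / np.linalg.norm(geom.layer_corners("front")[0] - geom.layer_center("front"))
        d = corner / np.linalg.norm(corner)
        resp = detector_response(np.zeros((1, 3)), d[None, :], np.array([0.0]), geom, EM, rng)
        assert not resp["detected"][0]

    def test_toa_on_timestamp_grid(self, geom, rng):
        resp = detector_response(
            np.zeros((5, 3)),
            np.tile(geom.focus_direction, (5, 1)),
            np.full(5, 1e6),
            geom,
            EM,
            rng,
        )
        toa = resp["front"]["toa_ns"]
        np.testing.assert_allclose(np.round(toa / 1.5625) * 1.5625, toa, atol=1e-9)


class TestSimulateFraction:
    def small(self, **kw):
        synth = SyntheticConfig(**kw)
        synth.plan.n_layers = 2
        synth.plan.spots_per_layer = 9
        synth.plan.n_primaries = 20_000
        synth.n_repetitions = 2
        return synth

    def test_bit_identical_for_same_seed(self, geom):
        s1 = simulate_fraction(self.small(), geom, seed=9)
        s2 = simulate_fraction(self.small(), geom, seed=9)
        for a, b in zip(s1.hits_front, s2.hits_front):
            pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(s1.truth, s2.truth)
        assert s1.provenance == s2.provenance

    def test_detected_count_linear_in_primaries(self, geom):
        n1 = simulate_fraction(self.small(), geom, seed=1).provenance["n_detected"]
        big = self.small()
        big.plan.n_primaries *= 2
        n2 = simulate_fraction(big, geom, seed=2).provenance["n_detected"]
        assert abs(n2 - 2 * n1) < 3 * np.sqrt(n2 + 4 * n1)

    def test_detected_fraction_small_and_grows_with_theta0(self, geom):
        lo = self.small()
        lo.emission.theta0_rad = 0.15
        hi = self.small()
        hi.emission.theta0_rad = 0.5
        p_lo = simulate_fraction(lo, geom, seed=3).provenance
        p_hi = simulate_fraction(hi, geom, seed=3).provenance
        f_lo = p_lo["n_detected"] / p_lo["n_produced"]
        f_hi = p_hi["n_detected"] / p_hi["n_produced"]
        assert f_hi < 0.01  # acceptance at 30 degrees is a tiny fraction
        assert f_hi > f_lo  # wider emission reaches the tracker more often

    def test_importance_sampling_matches_full_sphere(self, geom):
        """Thinning by the direction-envelope mass leaves the detected-event
        rate unchanged (the envelope provably contains all detectable
        directions)."""
        a = self.small(importance_sampling=True)
        b = self.small(importance_sampling=False)
        na = simulate_fraction(a, geom, seed=4).provenance["n_detected"]
        nb = simulate_fraction(b, geom, seed=5).provenance["n_detected"]
        assert abs(na - nb) < 4 * np.sqrt(na + nb + 1)

    def test_truth_matches_hits_bookkeeping(self, geom):
        sim = simulate_fraction(self.small(), geom, seed=6)
        assert len(sim.truth) == sim.provenance["n_detected"]
        assert sim.truth["detected"].all()
        assert sim.truth["t_track_ns"].notna().all()

    def test_insert_on_reduces_total_detections(self, geom):
        synth = self.small()
        synth.plan.n_primaries = 60_000
        off = simulate_fraction(synth, geom, insert_on=False, seed=8)
        on = simulate_fraction(synth, geom, insert_on=True, seed=8)
        n_off = off.provenance["n_detected"]
        n_on = on.provenance["n_detected"]
        # net effect: in-insert gain < downstream loss + upstream absorption
        assert n_on < n_off + 3 * np.sqrt(n_on + n_off)

    def test_miss_distance_grows_with_spot_width(self, geom):
        from fragmon.config import RunConfig
        from fragmon.pipeline import run_reconstruction_multi

        med = []
        for sigma in (0.0, 1.0, 2.0, 4.0):
            cfg = RunConfig()
            cfg.synthetic = self.small()
            cfg.synthetic.emission.beam_sigma_mm = sigma
            sim = simulate_fraction(cfg.synthetic, geom, seed=10)
            v, _ = run_reconstruction_multi(cfg, sim.hits_front, sim.hits_back, sim.beam_log)
            med.append(v["miss_mm"].median())
        assert med == sorted(med)
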