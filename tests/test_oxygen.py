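"""Oxygen reaction–diffusion solver: closed-form oracles and invariants."""

import numpy as np
import pytest

from slicequant import oxygen as ox

#: zeroth-order consumption (km = 0) for which the slab has a closed form
ZEROTH = ox.KineticsSpec(r_max=0.03, km=0.0, shutoff_below_threshold=False)
P0 = 150.0
K_TISSUE = ox.TISSUE.permeability_K


def _slab_profile_parabola(z, L, r_max, k):
    """p(z) = p0 + (r/2K)(z^2 - Lz): both faces clamped at p0."""
    return P0 + r_max / (2.0 * k) * (z**2 - L * z)


class TestSteadyStateSlab:
    def test_matches_parabolic_profile_at_64_intervals(self):
        lay = ox.build_slab(120.0, nz=65, p_top=P0, p_bottom=P0)
        f = ox.steady_state(lay, ZEROTH)
        expect = _slab_profile_parabola(lay.z, 120e-6, ZEROTH.r_max, K_TISSUE)
        assert np.allclose(f.po2[:, 1], expect, rtol=5e-3)
        # midplane drop r*L^2/(8K) = 22.5 mmHg
        assert f.po2[lay.core_index] == pytest.approx(127.5, rel=5e-3)

    def test_insulated_face_half_slab(self):
        # one face insulated: drop at that face is r*L^2/(2K) = 90 mmHg
        lay = ox.build_slab(120.0, nz=65, p_top=P0, p_bottom=None)
        f = ox.steady_state(lay, ZEROTH)
        assert f.po2[0, 1] == pytest.approx(60.0, rel=5e-3)

    def test_zero_consumption_is_uniform(self):
        lay = ox.build_slab(120.0, nz=17, p_top=P0, p_bottom=P0)
        f = ox.steady_state(lay, ox.KineticsSpec(r_max=0.0))
        assert np.allclose(f.po2, P0, atol=1e-8)

    def test_mesh_convergence_is_second_order(self):
        # Michaelis–Menten slab (no closed form): Richardson against a fine
        # reference; halving h should cut the error ~4x.
        kin = ox.KineticsSpec(r_max=0.05, km=20.0, shutoff_below_threshold=False)
        thickness, p_faces = 200.0, 60.0

        def solve(nz):
            lay = ox.build_slab(thickness, nz=nz, p_top=p_faces, p_bottom=p_faces)
            return ox.steady_state(lay, kin).po2[:, 1]

        ref = solve(257)
        errors = []
        for nz in (9, 17, 33):
            p = solve(nz)
            stride = 256 // (nz - 1)
            errors.append(np.max(np.abs(p - ref[::stride])))
        assert errors[0] > 1e-8  # genuinely resolvable error
        for coarse, fine in zip(errors, errors[1:]):
            assert 2.5 < coarse / fine < 6.0


class TestBuildDomain:
    def test_transwell_boundaries(self):
        lay = ox.build_domain(ox.CultureConfiguration("transwell"))
        assert lay.dirichlet_mask[-1].all()  # free medium surface
        assert not lay.dirichlet_mask[0].any()  # impermeable dish bottom
        # membrane is a continuity interface: tissue exists strictly inside
        assert lay.tissue_mask.any()
        assert not lay.tissue_mask[0].any() and not lay.tissue_mask[-1].any()

    def test_pfc_boundaries(self):
        lay = ox.build_domain(ox.CultureConfiguration("pfc"))
        assert lay.dirichlet_mask[0].all() and lay.dirichlet_mask[-1].all()
        assert np.allclose(lay.dirichlet_value[0], ox.ATMOSPHERIC_GAS_PO2)

    def test_lateral_margin_surrounds_tissue_with_medium(self):
        cfg = ox.CultureConfiguration("transwell", slice_width_mm=4.0, lateral_margin_mm=2.0)
        lay = ox.build_domain(cfg, resolution=ox.GridResolution(nx=17))
        tissue_cols = lay.cell_is_tissue.any(axis=0)
        assert not tissue_cols[0] and not tissue_cols[-1] and tissue_cols.any()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"slice_thickness_um": 0.0},
            {"slice_thickness_um": -5.0},
            {"medium_depth_above_mm": 0.0},
            {"lateral_margin_mm": -1.0},
            {"mode": "dish"},
        ],
    )
    def test_degenerate_geometry_rejected(self, kwargs):
        base = {"mode": "transwell"}
        base.update(kwargs)
        with pytest.raises(ValueError):
            ox.CultureConfiguration(**base)

    def test_missing_phase_rejected(self):
        with pytest.raises(ValueError, match="tissue"):
            ox.build_domain(
                ox.CultureConfiguration("pfc"), phases={"medium": ox.MEDIUM}
            )

    def test_too_coarse_resolution_rejected(self):
        with pytest.raises(ValueError, match="3 nodes"):
            ox.GridResolution(nz_tissue=2)


SMALL = ox.GridResolution(nx=4, nz_tissue=9, nz_medium_above=9, nz_medium_below=9)


class TestTransient:
    def test_equilibrium_without_consumption(self):
        lay = ox.build_slab(120.0, nz=9, p_top=P0, p_bottom=P0)
        res = ox.simulate(lay, ox.KineticsSpec(r_max=0.0), duration_h=0.5, dt_s=60.0)
        assert np.allclose(res.core_po2, P0, atol=1e-8)
        assert np.all(res.anoxic_fraction == 0.0)

    @pytest.mark.parametrize("mode", ["transwell", "pfc"])
    def test_discrete_mass_balance(self, mode):
        lay = ox.build_domain(ox.CultureConfiguration(mode), resolution=SMALL)
        res = ox.simulate(lay, ox.KineticsSpec(), duration_h=2.0, dt_s=60.0)
        assert res.mass_balance_max_rel_error <= 1e-4

    def test_maximum_principle(self):
        lay = ox.build_domain(ox.CultureConfiguration("transwell"), resolution=SMALL)
        res = ox.simulate(
            lay, ox.KineticsSpec(), duration_h=1.0, dt_s=60.0, store_fields=True
        )
        for f in res.fields:
            assert f.po2.min() >= 0.0
            assert f.po2.max() <= ox.ATMOSPHERIC_GAS_PO2 * (1 + 1e-12)

    def test_core_monotone_from_saturated_start(self):
        # constant boundaries, initial >= steady state: the core can only fall
        lay = ox.build_domain(ox.CultureConfiguration("pfc"), resolution=SMALL)
        res = ox.simulate(lay, ox.KineticsSpec(), duration_h=2.0, dt_s=60.0)
        assert np.all(np.diff(res.core_po2) <= 1e-9)

    def test_terminal_anoxia_monotone_in_medium_depth_above(self):
        fracs = []
        for depth in (0.5, 1.0, 2.0):
            cfg = ox.CultureConfiguration("transwell", medium_depth_above_mm=depth)
            lay = ox.build_domain(cfg, resolution=SMALL)
            res = ox.simulate(lay, ox.KineticsSpec(), duration_h=2.0, dt_s=120.0)
            fracs.append(res.anoxic_fraction[-1])
        assert fracs == sorted(fracs)

    def test_invalid_durations_rejected(self):
        lay = ox.build_slab(120.0, nz=9)
        with pytest.raises(ValueError):
            ox.simulate(lay, ZEROTH, duration_h=0.0)
        with pytest.raises(ValueError):
            ox.simulate(lay, ZEROTH, duration_h=1.0, dt_s=-1.0)


class TestAnoxiaStatistics:
    def test_anoxic_fraction_brute_force(self):
        po2 = np.array([0.05, 0.2, 0.09, 5.0])
        vol = np.ones(4)
        assert ox.anoxic_fraction(po2, vol, threshold=0.1) == pytest.approx(0.5)

    def test_anoxic_fraction_extremes(self):
        vol = np.ones(5)
        assert ox.anoxic_fraction(np.full(5, 150.0), vol) == 0.0
        assert ox.anoxic_fraction(np.full(5, 0.05), vol) == 1.0

    def test_empty_tissue_rejected(self):
        with pytest.raises(ValueError, match="empty tissue"):
            ox.anoxic_fraction(np.array([1.0]), np.array([0.0]))

    def _result(self, times, minp):
        return ox.SimulationResult(
            times_h=np.asarray(times, float),
            core_po2=np.asarray(minp, float),
            anoxic_fraction=np.zeros(len(times)),
            min_tissue_po2=np.asarray(minp, float),
            mass_balance_max_rel_error=0.0,
        )

    def test_onset_first_crossing(self):
        res = self._result([0.0, 8.0, 16.0], [10.0, 1.0, 0.05])
        assert ox.anoxia_onset(res, threshold=0.1) == 16.0

    def test_onset_none_when_never_anoxic(self):
        res = self._result([0.0, 8.0], [10.0, 5.0])
        assert ox.anoxia_onset(res, threshold=0.1) is None

    def test_onset_needs_two_snapshots(self):
        with pytest.raises(ValueError):
            ox.anoxia_onset(self._result([0.0], [10.0]))


@pytest.fixture(scope="module")
def sweep():
    configs = [
        ox.CultureConfiguration("transwell"),
        ox.CultureConfiguration("pfc"),
    ]
    return ox.ocr_sweep(
        configs,
        [0.01, 0.03, 0.05],
        duration_h=2.0,
        resolution=SMALL,
        dt_s=120.0,
    )


class TestOcrSweep:
    def test_table_shape(self, sweep):
        assert len(sweep) == 6
        assert set(sweep["mode"]) == {"transwell", "pfc"}

    def test_fraction_monotone_in_ocr(self, sweep):
        for _, grp in sweep.groupby("mode"):
            vals = grp.sort_values("ocr")["anoxic_fraction"].to_numpy()
            assert np.all(np.diff(vals) >= -1e-12)

    def test_pfc_never_worse_than_transwell(self, sweep):
        piv = sweep.pivot(index="ocr", columns="mode", values="anoxic_fraction")
        assert np.all(piv["pfc"].to_numpy() <= piv["transwell"].to_numpy() + 1e-12)

    def test_unsorted_ocr_rejected(self):
        with pytest.raises(ValueError):
            ox.ocr_sweep([ox.CultureConfiguration("pfc")], [0.05, 0.01], 1.0)


class TestValidation:
    def test_phase_positivity(self):
        with pytest.raises(ValueError):
            ox.TransportPhase("bad", solubility_alpha=-1.0, permeability_K=1e-12)

    def test_kinetics_bounds(self):
        with pytest.raises(ValueError):
            ox.KineticsSpec(r_max=2.0)
        with pytest.raises(ValueError):
            ox.KineticsSpec(km=-0.1)

    def test_oxygen_field_rejects_negative(self):
        with pytest.raises(ValueError):
            ox.OxygenField(po2=np.array([[-1.0]]), time_s=0.0)
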