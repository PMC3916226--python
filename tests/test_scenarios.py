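"""Scenario catalog, multiplicative application, and plausibility verdicts."""

import json
from importlib import resources

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nfkbsim.model import PARAMETER_NAMES, UnknownParameterError
from nfkbsim.readouts import observable, peak
from nfkbsim.scenarios import Scenario, apply_scenario, build_catalog, evaluate_scenario

REQUIRED_ENTRIES = {
    "nominal": ({}, {}),
    "Fig6A_combined": ({"kiA20": 10.0, "kc2a": 1 / 6}, {"NFkB_pool": 0.70}),
    "Fig4A_c2a_30th": ({"c2a": 1 / 30}, {}),
    "Fig5A_pool70": ({}, {"NFkB_pool": 0.70}),
    "Fig5B_pool70_IKKn5p5": ({}, {"NFkB_pool": 0.70, "IKKn_pool": 0.055}),
    "FigS4B_IKKn8th_kc2a5th": ({"kc2a": 0.2}, {"IKKn_pool": 0.125}),
    "FigS4C_pool70_kc2a10th": ({"kc2a": 0.1}, {"NFkB_pool": 0.70}),
    "FigS5_pool70_kiA20x10": ({"kiA20": 10.0}, {"NFkB_pool": 0.70}),
    "FigS6A_ka_16th": ({"ka": 1 / 16}, {}),
    "FigS6B_kc2a_32nd": ({"kc2a": 1 / 32}, {}),
    "FigS7B_IKKn18th_pool70": ({}, {"NFkB_pool": 0.70, "IKKn_pool": 1 / 18}),
}


class TestCatalog:
    def test_required_entries_and_factors(self, catalog):
        for name, (rates, pool) in REQUIRED_ENTRIES.items():
            assert name in catalog, name
            assert catalog[name].rate_factors == rates
            assert catalog[name].pool_factors == pool

    def test_published_scan_factors_present(self, catalog):
        ka_factors = sorted(s.rate_factors["ka"] for s in catalog.values()
                            if set(s.rate_factors) == {"ka"})
        for f in (1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0):
            assert any(np.isclose(f, g) for g in ka_factors)
        kc2a_factors = [s.rate_factors["kc2a"] for s in catalog.values()
                        if set(s.rate_factors) == {"kc2a"}]
        for f in (0.2, 1 / 6, 0.1, 1 / 32):
            assert any(np.isclose(f, g) for g in kc2a_factors)
        for rate in ("kp", "kua1", "kuc1", "kupd"):
            assert any(set(s.rate_factors) == {rate} and
                       all(f < 1 for f in s.rate_factors.values())
                       for s in catalog.values()), rate
        for rate in ("ki", "kiA20"):
            assert any(set(s.rate_factors) == {rate} and
                       all(f > 1 for f in s.rate_factors.values())
                       for s in catalog.values()), rate
        ikk_factors = [s.pool_factors["IKKn_pool"] for s in catalog.values()
                       if set(s.pool_factors) == {"IKKn_pool"}]
        for f in (0.055, 0.125, 1 / 18):
            assert any(np.isclose(f, g) for g in ikk_factors)

    def test_every_entry_cites_provenance_and_is_valid(self, catalog, params, pools):
        for name, s in catalog.items():
            if name != "nominal":
                assert s.provenance
            p2, q2 = s.apply(params, pools)
            assert all(v >= 0 for v in p2.values())

    def test_nominal_entry_is_identity(self, catalog, params, pools):
        s = catalog["nominal"]
        assert s.is_nominal
        p2, q2 = s.apply(params, pools)
        assert p2 == params and q2 == pools

    def test_shipped_json_matches_code(self, catalog):
        with resources.files("nfkbsim.data").joinpath("catalog.json").open() as fh:
            shipped = {d["name"]: Scenario.from_dict(d) for d in json.load(fh)}
        assert shipped == catalog


class TestApplyScenario:
    def test_single_rate_scaled_all_else_unchanged(self, params, pools):
        s = Scenario("ka16", rate_factors={"ka": 1 / 16})
        p2, q2 = apply_scenario(params, pools, s)
        assert p2.ka == params.ka / 16
        assert all(p2[k] == params[k] for k in PARAMETER_NAMES if k != "ka")
        assert q2 == pools

    def test_factor_one_bit_identical(self, params, pools):
        s = Scenario("noop", rate_factors={"kc2a": 1.0})
        p2, _ = apply_scenario(params, pools, s)
        assert p2 == params

    def test_unknown_name_rejected_with_listing(self, params, pools):
        s = Scenario("bad", rate_factors={"kq9": 2.0})
        with pytest.raises(UnknownParameterError, match="kiA20"):
            apply_scenario(params, pools, s)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            Scenario("bad", rate_factors={"ka": 0.0})

    @given(f_rate=st.floats(0.01, 100.0), f_pool=st.floats(0.01, 100.0))
    def test_apply_then_inverse_restores_nominal(self, f_rate, f_pool):
        from nfkbsim import nominal_parameters, nominal_pools

        params, pools = nominal_parameters(), nominal_pools()
        s = Scenario("x", rate_factors={"kc2a": f_rate, "ka": f_rate},
                     pool_factors={"NFkB_pool": f_pool})
        p1, q1 = s.apply(params, pools)
        p2, q2 = s.inverse().apply(p1, q1)
        for k in PARAMETER_NAMES:
            assert p2[k] == pytest.approx(params[k], rel=1e-15)
        assert q2.nfkb_total == pytest.approx(pools.nfkb_total, rel=1e-15)


class TestVerdicts:
    def test_nominal_vs_itself_all_reductions_false(self, catalog, nominal_traj):
        v = evaluate_scenario(catalog["nominal"], nominal_traj, nominal_traj)
        assert not v.reduces_basal_total_IkBa
        assert not v.reduces_peak_IKKa
        assert not v.reduces_peak_nuclear_NFkB
        assert v.preserves_basal_NFkB_activity
        assert not v.plausible

    def test_ikk_pool_reduction_alone_cannot_lower_basal_ikba(
            self, catalog, nominal_traj, scenario_run):
        """Without basal IKK activity the resting state is independent of
        the IKK pool, so reducing IKK alone cannot reduce basal IκBα."""
        v = evaluate_scenario(catalog["FigS4A_IKKn_8th"], nominal_traj,
                              scenario_run("FigS4A_IKKn_8th"))
        assert not v.plausible
        assert "reduces_basal_total_IkBa" in v.failed_criteria
        assert v.basal_total_IkBa_ratio == pytest.approx(1.0, abs=1e-6)

    def test_downstream_only_plus_pool_cannot_reduce_ikk(
            self, catalog, nominal_traj, scenario_run):
        v = evaluate_scenario(catalog["FigS4C_pool70_kc2a10th"], nominal_traj,
                              scenario_run("FigS4C_pool70_kc2a10th"))
        assert not v.plausible
        assert "reduces_peak_IKKa" in v.failed_criteria

    @pytest.mark.parametrize("name", ["Fig6A_combined", "Fig5B_pool70_IKKn5p5"])
    def test_combined_scenarios_are_plausible(self, catalog, nominal_traj,
                                              scenario_run, name):
        v = evaluate_scenario(catalog[name], nominal_traj, scenario_run(name))
        assert v.plausible, v.failed_criteria

    def test_mismatched_grids_rejected(self, catalog, nominal_traj, params,
                                       nominal_eq):
        from nfkbsim.simulate import run_stimulus

        other = run_stimulus(params, nominal_eq, grid=np.linspace(0, 150, 7))
        with pytest.raises(ValueError, match="grid"):
            evaluate_scenario(catalog["nominal"], nominal_traj, other)


class TestStructuralProperties:
    def test_nfkb_pool_scenario_leaves_ikka_unchanged(self, nominal_traj,
                                                      scenario_run):
        """The NF-κB pool feeds back on IKK only through A20, whose early
        influence is small: IKKa deviates < 1% over the first 30 min."""
        run = scenario_run("Fig5A_pool70")
        mask = nominal_traj.t <= 30.0
        nom = observable(nominal_traj, "ikk_active").values[mask]
        sce = observable(run, "ikk_active").values[mask]
        assert np.max(np.abs(sce - nom)) < 0.01 * nom.max()

    def test_c2a_30th_signature(self, nominal_traj, scenario_run):
        """Suppressing IκBα translation lowers resting IκBα but elevates
        basal and late nuclear NF-κB — the feedback cannot terminate the
        response."""
        run = scenario_run("Fig4A_c2a_30th")
        nom_ikba = observable(nominal_traj, "total_ikba")
        sce_ikba = observable(run, "total_ikba")
        assert sce_ikba.values[0] < 0.9 * nom_ikba.values[0]
        nom_nfkb = observable(nominal_traj, "nuclear_nfkb")
        sce_nfkb = observable(run, "nuclear_nfkb")
        assert sce_nfkb.values[0] > nom_nfkb.values[0]
        i120 = np.flatnonzero(np.isclose(nominal_traj.t, 120.0))[0]
        assert sce_nfkb.values[i120] > nom_nfkb.values[i120]

    def test_monotone_ka_scan(self, catalog, nominal_traj, scenario_run):
        peaks_ikk, peaks_nfkb = [], []
        for f in ("1", "0.5", "0.25", "0.125", "0.0625"):
            run = nominal_traj if f == "1" else scenario_run(f"Fig3A_ka_x{f}")
            peaks_ikk.append(peak(observable(run, "ikk_active"))[0])
            peaks_nfkb.append(peak(observable(run, "nuclear_nfkb"))[0])
        assert np.all(np.diff(peaks_ikk) <= 0)
        assert np.all(np.diff(peaks_nfkb) <= 0)

    @pytest.mark.parametrize("rate", ["kc2a", "kua1", "kuc1", "kupd"])
    def test_downstream_scenarios_cannot_touch_early_ikk(
            self, params, pools, nominal_traj, rate):
        """Initial IKK activation is structurally insulated from everything
        downstream of IKK: only A20 feeds back, and it needs transcription
        and translation time."""
        from nfkbsim import simulate_scenario_run

        s = Scenario(f"ds_{rate}", rate_factors={rate: 0.2})
        run = simulate_scenario_run(params, pools, s)
        mask = nominal_traj.t <= 5.0
        nom = observable(nominal_traj, "ikk_active").values[mask]
        sce = observable(run, "ikk_active").values[mask]
        assert np.max(np.abs(sce - nom)) < 0.01 * nom.max()
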