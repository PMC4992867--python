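import copy

import numpy as np
import pytest

from nucleoflux.correction import correct_plate
from nucleoflux.kinetics import promoter_activity
from nucleoflux.simulate import (Grid, GrowthParams, IntermediateLag,
                                 NoiseParams, PositionEffect, PromoterProgram,
                                 ScenarioConfig, WellSpec, render_plate,
                                 scenario_from_dict, scenario_to_dict,
                                 simulate_growth, simulate_reporter)

GRID = Grid(t_end_min=1380.0, dt_min=10.0)


def test_zero_growth_rate_constant_od():
    curve = simulate_growth(GrowthParams(mu_max=0.0), GRID)
    np.testing.assert_allclose(curve.od, curve.od[0])


def test_logistic_growth_saturates_at_capacity():
    g = GrowthParams(lag_min=60.0, mu_max=0.03, od_capacity=0.5)
    curve = simulate_growth(g, GRID)
    assert curve.od_at(np.array([1380.0]))[0] == pytest.approx(0.5, rel=1e-3)
    assert curve.od[0] == pytest.approx(0.5 / 200.0)  # 1:200 inoculum
    assert np.all(np.diff(curve.od) >= 0)


def test_intermediate_lag_delays_half_capacity_by_its_duration():
    g0 = GrowthParams(lag_min=60.0, mu_max=0.02, od_capacity=0.5)
    g1 = copy.deepcopy(g0)
    g1.intermediate_lag = IntermediateLag(start_od=0.05, duration_min=200.0)
    grid = Grid(t_end_min=1380.0, dt_min=1.0)
    t_half = []
    for g in (g0, g1):
        curve = simulate_growth(g, grid)
        t_half.append(curve.t[np.argmax(curve.od >= 0.25)])
    assert t_half[1] - t_half[0] == pytest.approx(200.0, abs=1.0)


def _curve(mu_max=0.02):
    return simulate_growth(GrowthParams(mu_max=mu_max), GRID), mu_max


def test_zero_base_rate_no_reporter():
    curve, mu_max = _curve()
    rt = simulate_reporter(curve, PromoterProgram(base_rate=0.0),
                           PositionEffect(), mu_max)
    np.testing.assert_allclose(rt.f_true, 0.0)


def test_constitutive_reporter_on_constant_od_is_linear():
    curve, mu_max = _curve(mu_max=0.0)
    prog = PromoterProgram(archetype="piecewise", base_rate=8.0,
                           segments=[[0.0, 1.0]])
    rt = simulate_reporter(curve, prog, PositionEffect(dosage_coeff=0.0), 0.0)
    slope = 8.0 * curve.od[0]
    np.testing.assert_allclose(rt.f_true, slope * curve.t, rtol=1e-9)


def test_origin_proximal_exceeds_terminus_in_exponential_phase():
    curve, mu_max = _curve()
    prog = PromoterProgram(archetype="hns", base_rate=10.0)
    f = {}
    for x in (0.0, 0.5, 1.0):
        eff = PositionEffect(rel_position=x, dosage_coeff=1.0)
        f[x] = simulate_reporter(curve, prog, eff, mu_max).f_at(
            np.array([300.0]))[0]
    # monotone dosage along the origin->terminus axis
    assert f[0.0] > f[0.5] > f[1.0]


def test_dosage_vanishes_in_stationary_phase():
    curve, mu_max = _curve()
    prog = PromoterProgram(archetype="dps", base_rate=10.0)
    a_or = simulate_reporter(curve, prog,
                             PositionEffect(rel_position=0.1), mu_max)
    a_tr = simulate_reporter(curve, prog,
                             PositionEffect(rel_position=0.9), mu_max)
    late = curve.t > 1200.0
    # residual growth rate in deep stationary phase is ~1e-8 of mu_max
    np.testing.assert_allclose(a_or.activity[late], a_tr.activity[late],
                               rtol=1e-6)


def _mini_cfg(seed=0, **noise_kw):
    return ScenarioConfig(
        growth=GrowthParams(),
        noise=NoiseParams(**noise_kw) if noise_kw else NoiseParams(),
        grid=GRID, seed=seed,
        wells=[WellSpec("A1", role="blank", genotype="none", module="none"),
               WellSpec("A3", role="background", module="none"),
               WellSpec("B1", program=PromoterProgram(archetype="hns",
                                                      base_rate=10.0),
                        effect=PositionEffect(), position="ML")])


def test_same_seed_renders_bit_identical_plates():
    w1, _, _ = render_plate(_mini_cfg(seed=123))
    w2, _, _ = render_plate(_mini_cfg(seed=123))
    for wid in w1:
        np.testing.assert_array_equal(w1[wid].od_raw, w2[wid].od_raw)
        np.testing.assert_array_equal(w1[wid].fluor_raw, w2[wid].fluor_raw)
    w3, _, _ = render_plate(_mini_cfg(seed=124))
    assert not np.array_equal(w1["B1"].fluor_raw, w3["B1"].fluor_raw)


def test_zero_noise_corrections_are_identities():
    cfg = _mini_cfg(od_sd=0.0, f_sd=0.0, autofluor_per_od=0.0, f_offset=0.0)
    cfg.growth.od_blank_offset = 0.0
    wells, layout, truth = render_plate(cfg)
    np.testing.assert_allclose(wells["B1"].od_raw, truth["B1"]["od_true"],
                               atol=1e-12)
    np.testing.assert_allclose(wells["B1"].fluor_raw, truth["B1"]["f_true"],
                               atol=1e-9)


def test_od_noise_calibration():
    """Empirical OD noise over a plate matches the configured sd within 10%."""
    cfg = _mini_cfg(seed=7)
    cfg.grid = Grid(t_end_min=1380.0, dt_min=1.0)  # >1000 points per well
    wells, _, truth = render_plate(cfg)
    resid = np.concatenate([
        wells[w].od_raw - truth[w]["od_true"] - cfg.growth.od_blank_offset
        for w in wells])
    assert resid.size >= 1000
    assert abs(resid.std() / cfg.noise.od_sd - 1) < 0.10


def test_zero_noise_constitutive_well_has_constant_discrete_activity(
        noiseless_constitutive_plate):
    wells, layout, _ = noiseless_constitutive_plate
    expr = correct_plate(wells, layout)["B1"]
    prof = promoter_activity(expr)
    # with constant biomass (stationary phase) a constitutive promoter gives
    # d(F/OD) = a*dt exactly; during growth the term is diluted by mu
    sel = prof.mask & (prof.time_min > 1300.0)
    vals = prof.d_fod_raw[sel]
    assert vals.size > 10
    np.testing.assert_allclose(vals, 40.0 * 1.0, rtol=1e-6)


def test_scenario_yaml_dict_roundtrip(scenarios):
    cfg = scenarios["hup_fis_pair"]
    back = scenario_from_dict(scenario_to_dict(cfg))
    assert back == cfg


def test_packaged_scenarios_encode_study_structure(scenarios):
    assert len(scenarios) >= 8
    for name, cfg in scenarios.items():
        cvs = [w.effect.replicate_cv for w in cfg.wells
               if w.role == "sample" and w.effect is not None]
        if name.startswith("hup"):
            assert all(cv > 0 for cv in cvs), name
        else:
            assert all(cv == 0 for cv in cvs), name
    # fis pair truth ratio fixed at 2.5 (midpoint of the observed 2-3x)
    pair = {w.position: w for w in scenarios["hup_fis_pair"].wells
            if w.role == "sample"}
    assert pair["MLup"].effect.genotype_multiplier / \
        pair["ML"].effect.genotype_multiplier == pytest.approx(2.5)
    # arabinose coupling halves the module in the mutant only
    hup = {(w.position, w.upstream_active): w
           for w in scenarios["hup_ara"].wells if w.role == "sample"}
    assert hup[("ara", True)].effect.upstream_coupling == pytest.approx(0.5)
    wt = {(w.position, w.upstream_active): w
          for w in scenarios["wt_ara"].wells if w.role == "sample"}
    assert wt[("ara", True)].effect.upstream_coupling == pytest.approx(1.0)
    # media variants encode the 2.5x dps rate ratio
    rate = {n: scenarios[n].wells[-1].program.base_rate
            for n in ("wt_dps_casamino", "wt_dps_minimal")}
    assert rate["wt_dps_casamino"] / rate["wt_dps_minimal"] == \
        pytest.approx(2.5)


def test_hup_fis_pair_truth_activity_ratio(scenarios):
    cfg = scenarios["hup_fis_pair"].replace(seed=3)
    _, _, truth = render_plate(cfg)
    layout_pos = {w.well_id: w.position for w in cfg.wells if w.role == "sample"}
    by_pos = {layout_pos[wid]: truth[wid] for wid in layout_pos}
    t = cfg.grid.times
    expo = (t > 100) & (t < 200)  # onset of exponential growth
    a_ml = by_pos["ML"]["activity"][expo] / by_pos["ML"]["rep_multiplier"]
    a_up = by_pos["MLup"]["activity"][expo] / by_pos["MLup"]["rep_multiplier"]
    np.testing.assert_allclose(a_up / a_ml, 2.5, rtol=1e-9)
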