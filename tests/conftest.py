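import numpy as np
import pytest

from nucleoflux.correction import ExpressionSeries
from nucleoflux.plate_io import WellSeries
from nucleoflux.simulate import (Grid, GrowthParams, NoiseParams,
                                 PositionEffect, PromoterProgram,
                                 ScenarioConfig, WellSpec,
                                 build_study_scenarios, render_plate)


def make_expression(time, fod, well_id="B1", od=0.3):
    """ExpressionSeries with a given F/OD trace and constant corrected OD."""
    time = np.asarray(time, dtype=float)
    fod = np.asarray(fod, dtype=float)
    od_corr = np.full_like(time, od)
    mask = np.isfinite(fod) & (od_corr >= 0.01)
    return ExpressionSeries(well_id, time, od_corr, fod * od, fod, mask)


@pytest.fixture(scope="session")
def scenarios():
    return build_study_scenarios()


def noiseless_scenario(program, t_end=1380.0, dt=1.0, dosage_coeff=0.0,
                       **growth_kw):
    """Single-sample zero-noise scenario (blank + background + one well)."""
    eff = PositionEffect(dosage_coeff=dosage_coeff)
    return ScenarioConfig(
        growth=GrowthParams(**growth_kw),
        noise=NoiseParams(od_sd=0.0, f_sd=0.0, autofluor_per_od=0.0,
                          f_offset=0.0),
        grid=Grid(t_end_min=t_end, dt_min=dt),
        wells=[
            WellSpec("A1", role="blank", genotype="none", module="none"),
            WellSpec("A3", role="background", module="none"),
            WellSpec("B1", program=program, effect=eff, position="native"),
        ],
        seed=0,
    )


@pytest.fixture(scope="session")
def noiseless_piecewise_plate():
    """Zero-noise 1-min-grid plate with piecewise-constant activity.

    True per-biomass activity: 40 until 400 min, 80 until 800 min, 20 after.
    """
    prog = PromoterProgram(archetype="piecewise", base_rate=40.0,
                           segments=[[0.0, 1.0], [400.0, 2.0], [800.0, 0.5]])
    cfg = noiseless_scenario(prog)
    wells, layout, truth = render_plate(cfg)
    return wells, layout, truth


@pytest.fixture(scope="session")
def noiseless_constitutive_plate():
    """Zero-noise 1-min-grid plate with constant activity 40."""
    prog = PromoterProgram(archetype="piecewise", base_rate=40.0,
                           segments=[[0.0, 1.0]])
    cfg = noiseless_scenario(prog)
    return render_plate(cfg)


@pytest.fixture(scope="session")
def rendered_wt_dps(scenarios):
    return render_plate(scenarios["wt_dps"].replace(seed=11))
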