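"""Recover a known piecewise-constant promoter activity with the spline
synthesis-rate estimator.

A zero-noise well is simulated on a 1-min grid whose true per-biomass
synthesis rate steps 40 -> 80 -> 20 fluorescence units per OD per minute.
The estimator fits least-squares cubic splines (Schoenberg–Whitney knot
selection) to corrected F and OD and evaluates q(t) = F'(t)/OD(t).
"""

import numpy as np

from nucleoflux.correction import correct_plate
from nucleoflux.kinetics import synthesis_rate
from nucleoflux.simulate import (Grid, GrowthParams, NoiseParams,
                                 PositionEffect, PromoterProgram,
                                 ScenarioConfig, WellSpec, render_plate)

prog = PromoterProgram(archetype="piecewise", base_rate=40.0,
                       segments=[[0.0, 1.0], [400.0, 2.0], [800.0, 0.5]])
cfg = ScenarioConfig(
    growth=GrowthParams(),
    noise=NoiseParams(od_sd=0.0, f_sd=0.0, autofluor_per_od=0.0, f_offset=0.0),
    grid=Grid(t_end_min=1380.0, dt_min=1.0),
    wells=[WellSpec("A1", role="blank", genotype="none", module="none"),
           WellSpec("A3", role="background", module="none"),
           WellSpec("B1", program=prog, position="native",
                    effect=PositionEffect(dosage_coeff=0.0))],
    seed=0)

wells, layout, truth = render_plate(cfg)
expr = correct_plate(wells, layout)["B1"]
prof = synthesis_rate(expr)

print(f"fitted {len(prof.knots) - 8} interior knots on "
      f"{int(expr.mask.sum())} unmasked points")
for lo, hi, a_true in [(200, 350, 40.0), (450, 750, 80.0), (850, 1300, 20.0)]:
    sel = (prof.eval_times >= lo) & (prof.eval_times <= hi)
    q = prof.q[sel]
    print(f"plateau t in [{lo}, {hi}] min: true rate {a_true:5.1f}, "
          f"estimated {q.mean():6.2f} (max deviation "
          f"{100 * np.abs(q / a_true - 1).max():.2f}%)")
print()
print("The estimated rate q(t) sits on each true plateau to within a few")
print("percent; the discrete d(F/OD) statistic would instead be diluted by")
print("growth (d(F/OD)/dt = q - mu*F/OD).")
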