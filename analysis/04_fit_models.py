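#!/usr/bin/env python
"""Mixed models of trip statistics and within-trip speed.

Fits the trip-level models (distance traveled, maximum distance to the
start/end waterhole, mean speed ~ trip type * duration, random intercept
and slopes by individual) and the four within-trip speed candidates
(distance-to-water vs progression, linear vs quadratic), ranks the
candidates by AIC, and attaches 95% parametric-bootstrap confidence
intervals to the winning and trip-level models.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from watertrips import models, pipeline

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
n_boot = int(sys.argv[2]) if len(sys.argv) > 2 else 500

stats = pd.read_csv("results/trip_stats.csv")
steps = pd.read_csv("results/steps.csv")

fits, boots = {}, {}
for resp in models.TRIP_RESPONSES:
    fit = models.fit_trip_model(stats, resp)
    fits[f"trip_{resp}"] = fit
    boots[f"trip_{resp}"] = models.parametric_bootstrap(fit, n_boot, seed=seed)

speed_fits = models.fit_speed_models(steps)
print("AIC ranking of within-trip speed models:")
for f in speed_fits:
    print(f"  {f.spec.name:<16s} AIC {f.aic:9.1f}  (converged={f.converged})")
best = speed_fits[0]
fits[f"speed_{best.spec.name}"] = best
boots[f"speed_{best.spec.name}"] = models.parametric_bootstrap(best, n_boot, seed=seed + 1)

tables_json, tables_txt = pipeline.render_tables(fits, boots)
Path("results/model_tables.json").write_text(json.dumps(tables_json, indent=2) + "\n")
Path("results/model_tables.txt").write_text(tables_txt + "\n")
Path("results/aic_ranking.json").write_text(
    json.dumps(
        [{"model": f.spec.name, "aic": f.aic, "converged": f.converged} for f in speed_fits],
        indent=2,
    )
    + "\n"
)
print()
print(tables_txt)
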