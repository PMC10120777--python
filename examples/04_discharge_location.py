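"""Fit the baseline-category discharge-location models (reference: home)
and the follow-up binary models for the sub-locations inside "other".
"""

import numpy as np

import genderdx as gx
from genderdx.discharge import DISCHARGE_CONTROLS

cohort, _, truth = gx.simulate_cohort(gx.SimConfig(n_persons=50_000, seed=3))
cohort["gender_score"] = truth.bayes_optimal_score

dataset = gx.build_discharge_set(cohort)
print(f"discharge analysis set: {len(dataset)} acute-care survivors")

models = gx.run_discharge_models(dataset)
res = models["model2"].result
for category in ("rehab", "ltc", "other"):
    est = np.exp(res.params[(category, "gender_score")])
    true = np.exp(truth.true_discharge_coefficients.get(
        category, {"score": np.nan}).get("score", np.nan))
    line = f"Model 2 {category} vs home, per unit gender score: OR {est:.2f}"
    if np.isfinite(true):
        line += f" (simulated truth {true:.2f})"
    print(line)
# OR < 1: more female-like code patterns lower the odds of that
# destination relative to going home.

sub_fits = gx.fit_other_sublocation_models(dataset, ["gender_score"] + DISCHARGE_CONTROLS)
for sub, ctx in sorted(sub_fits.items()):
    est = np.exp(ctx.result.params["gender_score"])
    true = np.exp(truth.true_discharge_coefficients[sub]["score"])
    print(f"  '{sub}' vs home: OR {est:.2f} (truth {true:.2f}, n={ctx.result.n})")
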