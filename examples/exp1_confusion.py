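"""Experiment-1 pipeline for the explaining-away observer, all cue conditions.

The Bayesian observer infers the size-change rate from a noisy image cue
plus whatever auxiliary distance cues the condition provides (binocular
and/or haptic, trust-weighted).  More auxiliary information explains away
more of the distance confound, so the fitted confusion ratio should fall
from 1 (H-/B-) toward 0 as cues are added; the closed-form model
prediction is printed alongside the Monte-Carlo pipeline estimate.
"""

import sizechange as sc

params = sc.ObserverParams()  # sigma_B = sigma_H = 13 mm/s, trust_H = 0.3
k_img = sc.default_k_img()

print("condition   pipeline   predicted   (95% CI)")
for i, condition in enumerate(sc.CueCondition.all_conditions()):
    grid = sc.build_exp1_grid(repeats=50, conditions=[condition], seed=10 + i)
    records = sc.simulate_exp1(grid, params, seed=20 + i)
    result = sc.analyze_condition(records, condition, B=200, seed=30 + i)
    predicted = sc.predicted_confusion(params, condition, k_img)
    print(
        f"{condition.label:>8s}   {result.confusion:8.3f}   {predicted:9.3f}"
        f"   [{result.ci_low:.3f}, {result.ci_high:.3f}]"
    )

print(
    "\nThe binocular cue (full trust) removes most of the confusion; the "
    "haptic cue (trust\n0.3) removes less despite equal reliability -- the "
    "asymmetry is carried by trust alone."
)
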