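"""Experiment-2 pipeline: 2IFC speed discrimination -> single-cue noise.

Simulates the two-interval speed-discrimination design (2 standards x 7
comparison offsets x 14 repeats, the desk-scale session size) for each
single-cue condition, fits psychometric functions over the signed speed
difference, converts the mean JND to the cue noise via sigma = JND/sqrt(2),
and runs the bootstrap test of "binocular noise < haptic noise".
"""

import sizechange as sc

params = sc.ObserverParams(sigma_binocular=13.0, sigma_haptic=13.0)

estimates = {}
for i, condition in enumerate(
    [sc.CueCondition(True, False), sc.CueCondition(False, True)]
):
    design = sc.build_exp2_design(repeats=14, condition=condition, seed=40 + i)
    records = sc.simulate_exp2(design, params, seed=50 + i)
    est = sc.estimate_noise(records, condition, B=500, seed=60 + i)
    estimates[condition.label] = est
    cue = "haptic" if condition.haptic else "binocular"
    print(
        f"{condition.label} ({cue:>9s}): sigma = {est.sigma:5.2f} "
        f"+/- {est.madc_se:.2f} mm/s (true 13.00); per-standard JNDs "
        f"{est.per_standard_jnds[0]:.2f}, {est.per_standard_jnds[1]:.2f} mm/s"
    )

p = sc.bootstrap_noise_test(estimates["H-/B+"], estimates["H+/B-"])
print(f"\nbootstrap test of sigma_B < sigma_H: one-sided p = {p:.3f}")
print(
    "With equal generating noise the test should not reject (p > 0.05): "
    "matched reliabilities\ncannot explain a binocular/haptic asymmetry in "
    "confusion -- that points to unequal trust.\n(A single 196-trial "
    "session per cue gives wide error bars; the MADC bars above show it.)"
)
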