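"""Recovering a known spot size from noisy synthetic measurements.

Generates a measured FOF grid at a known (ESSx, ESSy), perturbs it with
the field-size-dependent measurement noise, and runs the two-step
sequential procedure followed by the joint cross-check.
"""

from smallfield import (
    ESSPair,
    NoiseModel,
    SyntheticEvaluator,
    add_measurement_noise,
    optimize_joint,
    optimize_sequential,
    simulate_fof_grid,
)

truth = ESSPair(0.7, 0.8)
print(f"truth: ESSx = {truth.essx_mm} mm, ESSy = {truth.essy_mm} mm")

calc = simulate_fof_grid(truth)
measured = add_measurement_noise(calc, NoiseModel(seed=12345))

engine = SyntheticEvaluator(measured)
seq = optimize_sequential(engine)
print(
    f"sequential: ESSx' in {seq.essx_mm} mm, ESSy' in {seq.essy_mm} mm; "
    f"residuals {seq.residual_4x05_pct:+.2f}% (4 x 0.5), "
    f"{seq.residual_05x4_pct:+.2f}% (0.5 x 4)"
)

joint = optimize_joint(engine, objective="max_abs")
print(f"joint cross-check: ESSx' in {joint.essx_mm} mm, ESSy' in {joint.essy_mm} mm")
# With 1.8% noise on the 0.5 cm extreme fields the recovered values can
# land one or two candidates away from the truth (here they do): a single
# noisy grid constrains each spot size to roughly +/- 0.2 mm.  The
# residuals show how much extreme-field disagreement the optimum leaves.
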