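"""Forge synthetic predictor outputs and audit their plausibility.

Three models of the same kind of repeat sequence: a clean β-solenoid, one
with an uncompensated buried glutamate stack at high confidence (the
"problematic" signature), and one with the stack compensated by a lysine on
the neighbouring core position.  The audit should flag exactly the middle
one.
"""

import numpy as np

from repeataudit import (
    FeatureInjection, ScoreTable3D1D, SolenoidSpec, audit_model,
    build_solenoid, make_unit, tandem,
)

unit = make_unit(12, "beta", seed=4)
specs = {
    "clean": [],
    "uncompensated_stack": [FeatureInjection("charged_stack", 0, "E")],
    "compensated_stack": [FeatureInjection("charged_stack", 0, "E"),
                          FeatureInjection("compensating_counter_charge", 2, "K")],
}

table = ScoreTable3D1D.default()
for name, injections in specs.items():
    spec = SolenoidSpec(sequence=tandem(unit, 10),
                        plddt_profile=np.full(120, 85.0),
                        injections=injections)
    report = audit_model(build_solenoid(spec), unit_length=12, seq_id=name,
                         table=table)
    print(f"{name:22s} fold={report.fold_class:13s} "
          f"pLDDT={report.mean_plddt:5.1f} 3D/1D={report.mean_3d1d:+.3f} "
          f"stacks={report.n_stacks} (uncompensated={report.n_uncompensated_stacks}) "
          f"problematic={report.problematic}")

print()
print("'problematic' = confident (pLDDT > 70) yet carrying an uncompensated")
print("buried charged stack or a mean 3D/1D score below 0.1.")
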