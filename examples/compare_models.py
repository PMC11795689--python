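"""Compare alternative models of one repeat sequence.

The same sequence folded three ways — β-solenoid, long ideal α-helix, and a
disordered coil — mirroring how different structure predictors can disagree.
RMSD is the single-pass CA superposition (no outlier rejection); TM > 0.5 is
the conventional same-fold call.
"""

from repeataudit import (
    SolenoidSpec, build_coil, build_helix, build_solenoid, classify_fold,
    is_significant_match, make_unit, rank_model_rmsd, tandem, tm_score,
)

seq = tandem(make_unit(12, "beta", seed=2), 10)
models = {
    "solenoid": build_solenoid(SolenoidSpec(sequence=seq)),
    "helix": build_helix(seq.full),
    "coil": build_coil(seq.full, seed=2),
}

for name, model in models.items():
    print(f"{name:9s} classified as {classify_fold(model, 12)}")
print()

ref = models["solenoid"]
for name in ("helix", "coil"):
    res = rank_model_rmsd(ref, models[name], id_a="solenoid", id_b=name)
    tm = tm_score(ref, models[name])
    verdict = "same fold" if is_significant_match(tm) else "different fold"
    print(f"solenoid vs {name:6s} rmsd={res.rmsd:6.2f} Å  TM={tm:.3f}  ({verdict})")
print(f"solenoid vs itself TM={tm_score(ref, ref):.3f}")
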