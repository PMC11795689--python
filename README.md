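# repeataudit

Tools for probing how protein structure predictors behave on **perfect tandem
repeat sequences** — sequences of the form `u × k`, a random unit repeated
exactly — and for auditing the resulting models for features that real,
stable proteins essentially never show.

Deep-learning predictors can emit highly confident β-solenoid models for
biologically meaningless repeat sequences, models that on inspection carry
buried stacks of like-charged residues, hydrophobic side chains strewn over
the surface, or steric clashes, all under a reassuring pLDDT. This package
implements the desk-scale half of that investigation, for structural
bioinformaticians who want to generate the sequence cohorts, ingest predictor
outputs (or forge stand-ins), and run the plausibility audit end to end:

* **`repeatgen`** — propensity-pool sequence design. The 20 amino acids are
  grouped by secondary-structure preference into β (C F I T V W Y),
  α (A E K M Q R L) and neutral (G N D P H S) pools; units of length 5–30 are
  drawn from single pools or unions and concatenated 10×. Ships the expanded
  26 × 3 = 78-sequence design, the preliminary 50-entry design
  (31 random 20-mers + 19 alanine-mutant slots), per-sequence mean
  Chou–Fasman propensities, and a repeat-perfection score with the
  score/unit-length > 7.0 "near-perfect" convention.
* **`solenoid_forge`** — synthetic structures with ground truth: parametric
  β-solenoids (constant 4.8 Å rise per rung, configurable cross-section and
  handedness), ideal α-helix and self-avoiding-coil decoys, pLDDT annotation
  in both the AF2 residue-level and AF3 atomic B-factor dialects, and
  injectable implausible features (buried charged stacks, compensating
  counter-charges, protruding surface hydrophobics, clashes).
* **`structure_io`** — PDB/mmCIF reading and writing via gemmi, pLDDT
  extraction for the residue-level and atomic dialects, and 0–1 → 0–100
  scale normalisation (RFAA-style files).
* **`plausibility_audit`** — Shrake–Rupley SASA with side-chain burial,
  CA-only secondary structure, a 3D/1D environment-compatibility profile
  (18 environment classes, 21-residue smoothing, categorical fail when
  < 80 % of residues score ≥ 0.1), buried charged-stack detection with
  compensation, exposed-hydrophobic and clash counting, geometric fold
  classification, disorder-probability flagging (mean ≥ 0.5), and the
  **problematic** rule: mean pLDDT > 70 yet mean 3D/1D < 0.1 or an
  uncompensated internal charged stack.
* **`model_compare`** — Kabsch superposition RMSD (single pass, no outlier
  rejection) and TM-score with the standard
  d0 = max(1.24·(L−15)^⅓ − 1.8, 0.5) normalisation; TM > 0.5 is the
  same-fold call.
* **`cohort_cli`** — a thin `repeataudit` command with `generate`, `forge`,
  `audit`, `compare` and `summarize` subcommands over the library.

Running the predictors themselves (AF2/AF3/ESMFold/RFAA), molecular
dynamics, and database searches are out of scope; predictor outputs are
ingested as files, and the forge stands in for them during testing.

## A worked example

`examples/forge_and_audit.py` forges three 120-residue solenoid models of
one β-pool sequence and audits them:

```
clean                  fold=beta_solenoid pLDDT= 85.0 3D/1D=+0.225 stacks=0 (uncompensated=0) problematic=False
uncompensated_stack    fold=beta_solenoid pLDDT= 85.0 3D/1D=+0.195 stacks=1 (uncompensated=1) problematic=True
compensated_stack      fold=beta_solenoid pLDDT= 85.0 3D/1D=+0.168 stacks=2 (uncompensated=0) problematic=False
```

All three are confidently "predicted" (pLDDT 85) β-solenoids with decent
mean 3D/1D scores — but only the middle one buries a stack of glutamates
with no counter-charge in reach, and only it is flagged problematic. That is
the point of the rule: averaged validation scores can hide a locally
disqualifying feature. The other example scripts cover cohort design
(`design_cohort.py`), model-to-model comparison (`compare_models.py`, where
a solenoid and a helix of the same sequence score TM ≈ 0.05), and profile
validation (`profile_validation.py`).

The same pipeline from a shell:

```bash
repeataudit generate --seed 1 --out-fasta cohort.fasta --out-manifest manifest.tsv
repeataudit forge --seed 1 --outdir forged/
repeataudit audit --structures forged/ --manifest forged/manifest.tsv --out-report report.tsv
repeataudit summarize --report report.tsv
```

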