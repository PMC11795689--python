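# Methods

This note records the models, parameter choices and numerical conventions
behind `repeataudit`, and what the synthetic data can and cannot certify.

## Sequence design

Units are drawn uniformly with replacement from the union of the selected
propensity pools (β = C F I T V W Y, α = A E K M Q R L, neutral =
G N D P H S). Uniformity over the union, rather than pool-weighted
sampling, is the simplest reading of "randomly selected from the
categories" and is what the character-frequency test certifies. A single
cohort seed derives per-sequence seeds as `seed + index`, so a cohort is
reproducible from one integer, and any sequence can be regenerated in
isolation.

Mean α/β propensities use the Chou–Fasman scale by default (shipped as
`data/chou_fasman.tsv`, swappable for any 20-row TSV with positive values).
On this scale 1.0 is indifferent; β-pool units average ≈ 1.3–1.4 in sheet
propensity. The mean is over the full concatenated sequence, so it depends
only on unit composition — a property test rotates the unit and checks
invariance.

Repeat perfection is the mean column-wise identity over unit positions
(each column's identity = highest residue frequency / number of copies):
1.0 for a perfect tandem, 1/k when all k copies disagree. It is a native
stand-in for dynamic-programming repeat scores; the familiar
score-per-unit-length > 7.0 threshold is kept for the normalised form.
Alanine mutants replace an aromatic or charged residue (histidine counts as
charged) at one unit position in **every** copy; the 19 mutant slots of the
preliminary design are abstract because the choice of parent and position
is an experimental decision, so the API requires it explicitly.

## The forge

Forged β-solenoids put CA atoms at equal angular steps on a gently
triangular perturbed circle, r(θ) = R(1 + 0.02·cos 3θ), climbing linearly
at 4.8 Å per rung; R is solved numerically so the mean consecutive CA
distance is 3.8 Å. This yields consecutive CA distances within ±0.08 Å and
exact rung periodicity across unit lengths 5–30. Side chains are reduced to
CB plus one terminal pseudo-atom (`SCP`) whose element matches the
residue's chemistry (O for D/E/N/Q/S/T, N for K/R/H, S for C/M, C
otherwise) — enough for SASA, charge-stack and clash auditing without
rotamer chemistry. Core-facing ("inward") positions are evenly spaced
(every 2nd position up to unit length 20, every 3rd beyond); their
pseudo-atoms are drawn toward a packed core ring whose radius is the
smallest that keeps neighbours ≥ 3.4 Å apart.

Injections and their margins against the default detector thresholds,
measured on the default grid:

| injection | realisation | margin |
|---|---|---|
| `charged_stack` | charged residue at one unit position, inward in every rung | buried members' side-chain rel-SASA ≤ 0.09 for unit lengths ≤ 14 vs the 0.15 threshold |
| `compensating_counter_charge` | opposite charge on an adjacent core position | centre distance ≈ 3.4 Å vs the 4.5 Å compensation radius |
| `surface_hydrophobic` | side chain protruding 7.5 Å from CA | rel-SASA ≥ 0.70 vs the 0.5 threshold; non-protruding wall residues ≤ 0.44 |
| `clash` | one pseudo-atom moved to 2.0 Å from the next rung's | 1.0 Å inside the C–C contact limit |

Beyond unit length 14 the generic circular cross-section leaves the lumen
open (measured buried rel-SASA 0.2–0.4), so the forge **refuses** a stack
injection there rather than emit a spec it cannot realise — real wide
solenoids flatten their cross-sections to pack the core, which this
geometry does not emulate. Chain termini are genuinely more exposed (no
neighbouring rung on one side), so a 10-rung stack is detected with 9
buried members; tests assert ≥ rungs − 1.

Helix decoys are ideal α-helices (1.5 Å rise, 100° twist, radius 2.3 Å).
Coil decoys are self-avoiding CA walks (step 3.8 Å, turning angle uniform
in 60–105°, all non-adjacent pairs ≥ 4.5 Å, whole-walk restart on dead
ends) — a disordered *trace*, deliberately without side chains. pLDDT
annotation writes the profile per-residue (AF2 dialect) or perturbs atoms
uniformly ±2 and re-centres per residue (AF3 dialect), so the
atom-to-residue average recovers the profile exactly while individual atoms
differ; RFAA's 0–1 scale is handled by multiplying by 100 whenever every
value is ≤ 1.

What the forge does *not* emulate: hydrogen bonding, rotamer chemistry,
realistic cross-section diversity, or predictor error statistics. Passing
the forged-truth tests certifies the **audit machinery** — that each
detector fires exactly on its target feature — not audit performance on
real predictor outputs.

## The audit

**SASA** is Shrake–Rupley with a deterministic golden-spiral point set
(960 points, probe 1.4 Å) over the shipped van der Waals radii; it agrees
with biotite's implementation to < 1 % on shared fixtures. Two relative
measures are reported: whole-residue SASA over a max-exposure total
reference (an isolated residue scores ≈ 1), and side-chain SASA over an
isolated-side-chain reference. Burial-dependent diagnostics use the
side-chain measure, because backbone area — similar for buried and exposed
residues in a solenoid wall — washes out the contrast. References are
per-representation: computed once for the reduced atom layout
(`data/max_sasa_reduced.tsv`, regenerable from the package itself) and
literature-derived theoretical maxima for full-atom files
(`data/max_sasa_fullatom.tsv`, total values with a constant backbone
contribution subtracted for the side-chain column — adequate for
thresholding, not for quantitative exposure work).

**Secondary structure** is assigned from CA geometry alone (so CA-only
traces audit cleanly), in the spirit of P-SEA: helix requires
d(i,i+2) ≈ 5.4, d(i,i+3) ≈ 5.1, d(i,i+4) ≈ 6.2 Å over a 5-residue run;
strand requires sustained extension (d(i,i+2) ≥ 6.0 over three consecutive
windows, d(i,i+3) ≥ 6.3 over two). Both require the virtual torsion to
drift by ≤ 35° across consecutive windows — the key guard that keeps
random coils (measured max strand fraction 0.13 over 600 walks) well below
the 0.25 fraction that fold classification uses. The windows are wider on
the strand side than crystallographic pleated strands would need, because
solenoid strands curve smoothly around the cross-section.

**Environment classes** cross six burial/polarity classes (buried ≤ 0.09
side-chain rel-SASA, partial ≤ 0.40, else exposed; buried split at
surrounding polar-atom fractions 0.45/0.58, partial at 0.67) with
helix/sheet/other, giving the 18 classes of the 3D/1D scheme. The shipped
default score table (`data/score_3d1d_default.tsv`) is implementer-derived:
a smooth surface over hydropathy–burial match, polarity match and
Chou–Fasman SS preference, scaled to the familiar raw-score range
(≈ −0.2 to 0.5). It is a *plausible stand-in*, not a reproduction of any
server's statistics — which is why every test whose outcome depends on
score values injects its own table (usually a constant one) and why the
table is a load-path parameter everywhere. Raw scores are smoothed by a
centred moving average (window 21, truncated at termini); the categorical
fail fires when < 80 % of residues have a smoothed score ≥ 0.1, and the
headline mean is the mean of smoothed scores (the natural reading of
averaging per-residue averaged scores).

**Charged stacks**: ≥ 3 same-sign charged residues (D/E negative, K/R
positive, His positive by default and configurable) at the same unit
position in consecutive rungs, each buried (side-chain rel-SASA ≤ 0.15)
with consecutive charge-centre distances ≤ 7.0 Å; compensated iff any
member has an opposite-sign charge centre within 4.5 Å. Charge centres use
the real side-chain atoms when present (carboxylate midpoints, NZ, CZ,
imidazole midpoint), else the pseudo-atom, CB, CA. The 7.0 Å link
comfortably covers the 4.8 Å rung rise; 4.5 Å is a generous salt-bridge
radius; 0.15 is a conventional "buried" cutoff. All four are parameters.

**Clashes** count atom pairs closer than r₁ + r₂ − 0.4 Å: all pairs for
residues ≥ 2 apart, side-chain/side-chain pairs only for adjacent residues
(their backbones are covalently coupled), nothing intra-residue.

**Fold classification** is geometric: β-solenoid iff the CA trace repeats
at the unit period (median |CA_i − CA_{i+L}| in 4–7 Å, coefficient of
variation < 0.25) with ≥ 25 % strand; long helix iff ≥ 60 % helix with a
radius of gyration ≥ 60 % of the equivalent straight rod's; "none"
(disordered) iff no SS class reaches 25 % and the rung test fails; else
"other". It replaces library-matching classifiers with a coordinate-only
criterion, so it is invariant under rigid motion (property-tested) but
blind to folds outside this three-way vocabulary.

**Problematic** = mean pLDDT > 70 **and** (mean 3D/1D < 0.1 **or** an
uncompensated stack). Strict inequalities; monotone in the evidence at
fixed confidence. Disorder flagging is the cohort-mean ≥ 0.5 rule over an
ingested per-residue probability TSV.

## Comparison

Kabsch superposition (SVD, proper rotation enforced, degenerate point sets
rejected) is validated against Horn's quaternion method to 1e-8 on random
50-point pairs. Comparisons are CA-only with identity correspondence —
sequences are identical by construction, and a guard raises on mismatch
instead of aligning. TM-score seeds superpositions on sliding fragments of
lengths L, L/2, L/4 and refines each by re-superposing on the residues
within a distance cutoff until membership stabilises (≤ 20 iterations),
keeping the best score; d0 = max(1.24·(L−15)^⅓ − 1.8, 0.5). The search can
only improve on the single global superposition (asserted as a property).

## Cohort sizes and determinism

The default truth cohort is 50 models (10 clean solenoids across unit
lengths 5–30, 8 uncompensated-stack models at pLDDT 85, 4 at pLDDT 60, 3
compensated, 5 surface-hydrophobic, 4 clash, 8 helices, 8 coils), sized so
a full forge + audit runs in about a minute on one CPU while covering every
injection type and both decoys; solenoid sequences come from the β pool so
no charged residue lands on a core position by chance and every
ground-truth stack is an injection. Audit reports are written with fixed
float formatting and sorted rows, so repeated seeded runs are byte-identical
(asserted). All randomness flows from explicit integer seeds through
numpy Generators; no global state.

## Known limitations

* The forge's cross-section is a perturbed circle; real β-solenoids are
  triangular/rectangular with packed cores, which is why deep burial is
  only guaranteed for unit lengths ≤ 14.
* The default 3D/1D table is a constructed preference surface; absolute
  mean scores from it are not comparable to any published server's, only
  the machinery (environments, smoothing, thresholds) is.
* The full-atom side-chain SASA references subtract a constant backbone
  area from theoretical totals — a thresholding convenience.
* Fold classification knows three folds plus "other"; α-solenoids, for
  instance, land in "other".
* CA-only RMSD will differ from all-atom alignment tools on the same pair
  of models; the dialect independence (forged and real files alike) was
  judged worth the divergence.
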