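"""Parametric β-solenoid, ideal-helix and coil decoy structures.

Structure predictors are deliberately out of scope here; this module forges
their outputs so that every audit stage can be exercised against known ground
truth.  A forged solenoid is a CA trace on a gently triangular cross-section
(perturbed circle) climbing at a constant rise per rung, decorated with a
reduced side-chain representation: backbone N/CA/C/O, a CB, and a single
side-chain terminal pseudo-atom (named SCP) placed at the charge centre
(D/E/K/R/H), ring centroid (F/W/Y) or distal-atom position of the residue.

Implausible features can be injected and are recorded as ground truth:

* ``charged_stack`` — a charged residue at one unit position, pointing into
  the lumen in every rung, producing a buried same-charge stack.
* ``compensating_counter_charge`` — an opposite-charge residue on the
  adjacent inward position, close enough to compensate the stack.
* ``surface_hydrophobic`` — a hydrophobic residue protruding from the outer
  wall far enough to count as solvent-exposed.
* ``clash`` — one side-chain pseudo-atom displaced onto the next rung's,
  creating a steric clash.

The generic circular cross-section leaves the lumen of very wide solenoids
open, so buried charged stacks can only be realised for unit lengths up to
``MAX_STACK_UNIT_LENGTH`` (14); the forge raises rather than emitting a spec
it cannot honour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .repeatgen import RepeatSequence
from .structure_io import Atom, Residue, StructureModel, write_structure

#: Element of the side-chain terminal pseudo-atom, by residue type.
SC_ELEMENT = {
    "D": "O", "E": "O", "N": "O", "Q": "O", "S": "O", "T": "O",
    "K": "N", "R": "N", "H": "N",
    "C": "S", "M": "S",
}
#: Default distance CA -> side-chain pseudo-atom on the outer wall, Å.
OUTWARD_SC_DIST = 4.0
#: CA -> pseudo-atom distance for a protruding (injected) surface residue, Å.
PROTRUDING_SC_DIST = 7.5
CB_DIST = 1.5
CA_SPACING = 3.8
#: Largest unit length at which an injected charged stack is genuinely buried.
MAX_STACK_UNIT_LENGTH = 14

InjectionKind = Literal["charged_stack", "surface_hydrophobic", "clash",
                        "compensating_counter_charge"]


@dataclass(frozen=True)
class FeatureInjection:
    """A deliberately implausible feature to build into a forged solenoid."""

    kind: InjectionKind
    unit_position: int
    residue_code: str = ""

    def __post_init__(self) -> None:
        kinds = ("charged_stack", "surface_hydrophobic", "clash",
                 "compensating_counter_charge")
        if self.kind not in kinds:
            raise ValueError(f"unknown injection kind {self.kind!r}")
        if self.kind == "charged_stack" and self.residue_code not in set("DEKRH"):
            raise ValueError("charged_stack needs a charged residue_code (D/E/K/R/H)")
        if self.kind == "compensating_counter_charge" and self.residue_code not in set("DEKRH"):
            raise ValueError("compensating_counter_charge needs a charged residue_code")
        if self.kind == "surface_hydrophobic" and self.residue_code not in set("AVLIMFWYC"):
            raise ValueError("surface_hydrophobic needs a hydrophobic residue_code")


@dataclass
class SolenoidSpec:
    """Everything needed to forge one β-solenoid model."""

    sequence: RepeatSequence
    rise_per_rung: float = 4.8
    n_sides: int = 3
    handedness: Literal["left", "right"] = "left"
    inward_positions: frozenset[int] | None = None
    plddt_profile: np.ndarray | None = None
    injections: list[FeatureInjection] = field(default_factory=list)
    triangularity: float = 0.02

    def __post_init__(self) -> None:
        L = self.sequence.unit_length
        if L < self.n_sides:
            raise ValueError(f"unit length {L} < n_sides {self.n_sides}")
        if self.rise_per_rung <= 0:
            raise ValueError("rise_per_rung must be positive")
        if self.inward_positions is not None:
            bad = [p for p in self.inward_positions if not 0 <= p < L]
            if bad:
                raise ValueError(f"inward positions out of range: {bad}")
        for inj in self.injections:
            if not 0 <= inj.unit_position < L:
                raise ValueError(f"injection position {inj.unit_position} out of "
                                 f"range for unit length {L}")
            if inj.kind == "charged_stack" and L > MAX_STACK_UNIT_LENGTH:
                raise ValueError(
                    f"charged_stack injection cannot be realised (buried) at unit "
                    f"length {L} > {MAX_STACK_UNIT_LENGTH} with the generic "
                    f"cross-section")


def default_inward_positions(unit_length: int) -> frozenset[int]:
    """Evenly spaced inward (core-facing) unit positions.

    Every other position up to length 20, every third beyond, so the packed
    core ring never brings side chains within clash distance.
    """
    step = 2 if unit_length <= 20 else 3
    m = max(2, unit_length // step)
    return frozenset(int(round(j * unit_length / m)) % unit_length for j in range(m))


def _solve_radius(L: int, a: float, n_sides: int, rise: float) -> float:
    """Radius of the perturbed circle giving mean consecutive CA 3.8 Å."""
    dz = rise / L

    def mean_dev(R: float) -> float:
        i = np.arange(2 * L)
        th = 2 * np.pi * i / L
        r = R * (1 + a * np.cos(n_sides * th))
        ca = np.stack([r * np.cos(th), r * np.sin(th), i * dz], axis=1)
        return float(np.linalg.norm(np.diff(ca, axis=0), axis=1).mean()) - CA_SPACING

    return brentq(mean_dev, 0.3, 80.0)


def _ca_trace(spec: SolenoidSpec) -> tuple[np.ndarray, float]:
    L = spec.sequence.unit_length
    n = len(spec.sequence)
    R = _solve_radius(L, spec.triangularity, spec.n_sides, spec.rise_per_rung)
    sign = -1.0 if spec.handedness == "left" else 1.0
    i = np.arange(n)
    th = sign * 2 * np.pi * i / L
    r = R * (1 + spec.triangularity * np.cos(spec.n_sides * th))
    ca = np.stack([r * np.cos(th), r * np.sin(th), i * spec.rise_per_rung / L], axis=1)
    return ca, R


def _core_radius(L: int, inward: Sequence[int]) -> float:
    """Radius of the packed inward ring keeping side chains clash-free."""
    inw = sorted(inward)
    if len(inw) < 2:
        return 2.2
    gaps = [(inw[(k + 1) % len(inw)] - inw[k]) % L for k in range(len(inw))]
    gmin = min(g for g in gaps if g > 0)
    if gmin >= L / 2:
        return 2.2
    return max(2.2, 1.7 / np.sin(np.pi * gmin / L))


def _sc_element(code: str) -> str:
    return SC_ELEMENT.get(code, "C")


def build_solenoid(spec: SolenoidSpec) -> StructureModel:
    """Forge a β-solenoid model from a spec.

    One residue per sequence position, with N/CA/C/O backbone, CB, and a
    side-chain pseudo-atom (SCP); Gly gets no side chain, Ala only a CB.
    """
    seq = spec.sequence.full
    L = spec.sequence.unit_length
    n = len(seq)
    if n < 2 * L:
        raise ValueError("need at least two rungs of sequence")
    inward = (spec.inward_positions if spec.inward_positions is not None
              else default_inward_positions(L))

    # realize injections on the sequence and side-chain layout
    seq_list = list(seq)
    protruding: set[int] = set()
    clash_positions: set[int] = set()
    inward = set(inward)
    for inj in spec.injections:
        p = inj.unit_position
        if inj.kind in ("charged_stack", "compensating_counter_charge"):
            for k in range(p, n, L):
                seq_list[k] = inj.residue_code
            inward.add(p)
        elif inj.kind == "surface_hydrophobic":
            for k in range(p, n, L):
                seq_list[k] = inj.residue_code
            inward.discard(p)
            protruding.add(p)
        elif inj.kind == "clash":
            clash_positions.add(p)
    seq = "".join(seq_list)

    ca, _R = _ca_trace(spec)
    r_core = _core_radius(L, sorted(inward))
    zhat = np.array([0.0, 0.0, 1.0])
    residues: list[Residue] = []
    for k in range(n):
        p = k % L
        code = seq[k]
        t = ca[min(k + 1, n - 1)] - ca[max(k - 1, 0)]
        t = t / np.linalg.norm(t)
        outward_dir = np.array([ca[k, 0], ca[k, 1], 0.0])
        outward_dir = outward_dir / np.linalg.norm(outward_dir)
        atoms = [
            Atom("N", "N", ca[k] - 0.6 * t + 0.35 * zhat),
            Atom("CA", "C", ca[k].copy()),
            Atom("C", "C", ca[k] + 0.6 * t + 0.35 * zhat),
            Atom("O", "O", ca[k] + 0.6 * t + 1.35 * zhat),
        ]
        if code != "G":
            if p in inward:
                rad = float(np.linalg.norm(ca[k, :2]))
                sc_d = max(1.0, rad - r_core)
                cb_d = min(CB_DIST, max(0.8, sc_d - 1.0))
                d = -outward_dir
            elif p in protruding:
                sc_d = PROTRUDING_SC_DIST
                cb_d = CB_DIST
                d = outward_dir
            else:
                sc_d = OUTWARD_SC_DIST
                cb_d = CB_DIST
                d = outward_dir
            atoms.append(Atom("CB", "C", ca[k] + cb_d * d))
            if code != "A":
                atoms.append(Atom("SCP", _sc_element(code), ca[k] + sc_d * d))
        residues.append(Residue(seqid=k + 1, code=code, atoms=atoms))

    # clash injection: drop the pseudo-atom of rung 0 at the given unit
    # position to 2.0 Å below the same atom one rung up
    for p in clash_positions:
        donor = residues[p].atom("SCP") or residues[p].atom("CB") or residues[p].atom("CA")
        accept = (residues[p + L].atom("SCP") or residues[p + L].atom("CB")
                  or residues[p + L].atom("CA"))
        direction = donor.position - accept.position
        direction = direction / np.linalg.norm(direction)
        donor.position = accept.position + 2.0 * direction

    model = StructureModel(chain_id="A", residues=residues, source="forge:solenoid")
    if spec.plddt_profile is not None:
        model = annotate_plddt(model, spec.plddt_profile, "residue_bfactor")
    return model


def build_helix(seq: str, plddt_profile: np.ndarray | None = None) -> StructureModel:
    """Ideal α-helix decoy: 1.5 Å rise and 100° twist per residue."""
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    i = np.arange(n)
    th = np.deg2rad(100.0) * i
    ca = np.stack([2.3 * np.cos(th), 2.3 * np.sin(th), 1.5 * i], axis=1)
    zhat = np.array([0.0, 0.0, 1.0])
    residues = []
    for k in range(n):
        t = ca[min(k + 1, n - 1)] - ca[max(k - 1, 0)]
        norm = np.linalg.norm(t)
        t = t / norm if norm > 0 else zhat  # single-residue degenerate case
        out = np.array([ca[k, 0], ca[k, 1], 0.0])
        out = out / (np.linalg.norm(out) or 1.0)
        code = seq[k]
        atoms = [
            Atom("N", "N", ca[k] - 0.6 * t + 0.35 * zhat),
            Atom("CA", "C", ca[k].copy()),
            Atom("C", "C", ca[k] + 0.6 * t + 0.35 * zhat),
            Atom("O", "O", ca[k] + 0.6 * t + 1.35 * zhat),
        ]
        if code != "G":
            atoms.append(Atom("CB", "C", ca[k] + CB_DIST * out))
            if code != "A":
                atoms.append(Atom("SCP", _sc_element(code), ca[k] + OUTWARD_SC_DIST * out))
        residues.append(Residue(seqid=k + 1, code=code, atoms=atoms))
    model = StructureModel(chain_id="A", residues=residues, source="forge:helix")
    if plddt_profile is not None:
        model = annotate_plddt(model, plddt_profile, "residue_bfactor")
    return model


def build_coil(seq: str, seed: int = 0, plddt_profile: np.ndarray | None = None,
               max_retries: int = 500) -> StructureModel:
    """Disordered-coil decoy: self-avoiding CA walk, step 3.8 Å.

    Turning angles are drawn in [60°, 105°] so consecutive-but-one residues
    stay at least 4.5 Å apart; every placement is rejection-sampled against
    all previous CAs.  CA-only residues (a trace, as disordered predictions
    effectively are).
    """
    if not seq:
        raise ValueError("empty sequence")
    pts: list[np.ndarray] = []
    for attempt in range(50):
        rng = np.random.default_rng((seed + attempt * 100_003) % 2**31)
        pts = [np.zeros(3), np.array([CA_SPACING, 0.0, 0.0])]
        stuck = False
        while len(pts) < len(seq) and not stuck:
            placed = False
            for _ in range(max_retries):
                gamma = np.deg2rad(rng.uniform(60.0, 105.0))
                phi = rng.uniform(0.0, 2 * np.pi)
                prev = pts[-1] - pts[-2]
                prev = prev / np.linalg.norm(prev)
                ref = (np.array([0.0, 0.0, 1.0]) if abs(prev[2]) < 0.9
                       else np.array([1.0, 0.0, 0.0]))
                u = np.cross(prev, ref)
                u = u / np.linalg.norm(u)
                v = np.cross(prev, u)
                step = CA_SPACING * (np.cos(gamma) * prev
                                     + np.sin(gamma) * (np.cos(phi) * u + np.sin(phi) * v))
                cand = pts[-1] + step
                others = np.asarray(pts[:-1])
                if np.linalg.norm(others - cand, axis=1).min() >= 4.5:
                    pts.append(cand)
                    placed = True
                    break
            stuck = not placed  # dead end: restart the whole walk, new substream
        if len(pts) == len(seq):
            break
    else:
        raise RuntimeError("coil walk failed to place all residues after 50 restarts")
    residues = [Residue(seqid=k + 1, code=c, atoms=[Atom("CA", "C", pts[k])])
                for k, c in enumerate(seq[:len(pts)])]
    model = StructureModel(chain_id="A", residues=residues, source="forge:coil")
    if plddt_profile is not None:
        model = annotate_plddt(model, plddt_profile, "residue_bfactor")
    return model


def annotate_plddt(model: StructureModel, profile: Sequence[float] | np.ndarray,
                   dialect: str = "residue_bfactor", seed: int = 0) -> StructureModel:
    """Write a pLDDT profile into the B-factor column.

    ``residue_bfactor`` writes one value per residue to all its atoms (AF2
    style).  ``atomic_bfactor`` perturbs per-atom values uniformly within ±2
    around the residue value, mean-centred per residue so the atom average
    recovers the profile exactly (AF3 style), seeded for determinism.
    Returns an annotated copy; the input model is left untouched.
    """
    import copy

    model = copy.deepcopy(model)
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (len(model),):
        raise ValueError(f"profile length {profile.size} != residue count {len(model)}")
    if profile.size and (profile.min() < 0 or profile.max() > 100):
        raise ValueError("pLDDT values must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    for i, res in enumerate(model.residues):
        if dialect == "residue_bfactor":
            for a in res.atoms:
                a.bfactor = float(profile[i])
        elif dialect == "atomic_bfactor":
            noise = rng.uniform(-2.0, 2.0, size=len(res.atoms))
            noise -= noise.mean()
            for a, dv in zip(res.atoms, noise):
                a.bfactor = float(np.clip(profile[i] + dv, 0.0, 100.0))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    model.dialect = dialect  # type: ignore[assignment]
    return model


@dataclass
class DecoySpec:
    """A non-solenoid decoy: ideal helix or random coil."""

    sequence: RepeatSequence
    kind: Literal["ideal_helix", "random_coil"]
    plddt_profile: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ideal_helix", "random_coil"):
            raise ValueError(f"unknown decoy kind {self.kind!r}")


def build_decoy(spec: DecoySpec) -> StructureModel:
    if spec.kind == "ideal_helix":
        return build_helix(spec.sequence.full, spec.plddt_profile)
    return build_coil(spec.sequence.full, spec.seed, spec.plddt_profile)


def forge_truth_cohort(specs: Sequence[SolenoidSpec | DecoySpec],
                       outdir: str | Path, seed: int = 0,
                       format: str = "pdb") -> list[dict]:
    """Forge a cohort of models with ground-truth labels.

    Writes one structure file per spec plus ``truth.json`` recording, for
    acceptance against the audit: fold class, injected features, and the mean
    of the pLDDT profile.  Returns the truth records.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".cif" if format == "mmcif" else ".pdb"
    truth: list[dict] = []
    for i, spec in enumerate(specs):
        sid = spec.sequence.seq_id or f"model{i:03d}"
        if isinstance(spec, SolenoidSpec):
            model = build_solenoid(spec)
            fold = "beta_solenoid"
            injections = [
                {"kind": inj.kind, "unit_position": inj.unit_position,
                 "residue_code": inj.residue_code}
                for inj in spec.injections
            ]
        else:
            model = build_decoy(spec)
            fold = "alpha_helical" if spec.kind == "ideal_helix" else "none"
            injections = []
        profile = spec.plddt_profile
        mean_p = float(np.mean(profile)) if profile is not None else 0.0
        path = write_structure(model, outdir / f"{sid}{ext}", format=format)
        kinds = {inj["kind"] for inj in injections}
        truth.append({
            "seq_id": sid,
            "file": path.name,
            "fold_class": fold,
            "unit_length": spec.sequence.unit_length,
            "n_copies": spec.sequence.n_copies,
            "mean_plddt": mean_p,
            "injections": injections,
            "has_uncompensated_stack": ("charged_stack" in kinds
                                        and "compensating_counter_charge" not in kinds),
            "problematic": (mean_p > 70.0
                            and "charged_stack" in kinds
                            and "compensating_counter_charge" not in kinds),
        })
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("seq_id\tfile\tunit_length\tn_copies\n")
        for t in truth:
            fh.write(f"{t['seq_id']}\t{t['file']}\t{t['unit_length']}\t"
                     f"{t['n_copies']}\n")
    return truth


def default_truth_specs(seed: int = 0) -> list[SolenoidSpec | DecoySpec]:
    """The default 50-model truth cohort.

    Solenoid sequences are drawn from the β pool (no charged residues), so
    every ground-truth charged stack comes from an injection: 10 clean
    solenoids, 8 with an uncompensated charged stack at confident pLDDT
    (problematic by construction), 4 stacked but low-confidence, 3 with a
    compensated stack, 5 with protruding surface hydrophobics, 4 with steric
    clashes, plus 8 ideal helices and 8 random coils.  Per-model seeds are
    seed + index.
    """
    from .repeatgen import make_unit, tandem

    specs: list[SolenoidSpec | DecoySpec] = []
    idx = 0

    def solenoid(unit_length: int, plddt: float, injections: list[FeatureInjection],
                 tag: str) -> SolenoidSpec:
        nonlocal idx
        sub = seed + idx
        unit = make_unit(unit_length, "beta", seed=sub)
        seq = tandem(unit, 10, scheme="beta", seed=sub,
                     seq_id=f"m{idx:03d}_{tag}")
        idx += 1
        return SolenoidSpec(sequence=seq,
                            plddt_profile=np.full(len(seq), plddt),
                            injections=injections)

    def decoy(kind: str, unit_length: int, n_copies: int, plddt: float,
              tag: str) -> DecoySpec:
        nonlocal idx
        sub = seed + idx
        pool = "alpha" if kind == "ideal_helix" else "all"
        unit = make_unit(unit_length, pool, seed=sub)
        seq = tandem(unit, n_copies, scheme=pool, seed=sub,
                     seq_id=f"m{idx:03d}_{tag}")
        idx += 1
        return DecoySpec(sequence=seq, kind=kind,  # type: ignore[arg-type]
                         plddt_profile=np.full(len(seq), plddt), seed=sub)

    clean_lengths = [5, 8, 10, 12, 14, 16, 20, 25, 30, 12]
    for L in clean_lengths:
        specs.append(solenoid(L, 85.0, [], "clean"))
    stack_lengths = [5, 8, 10, 12, 14, 6, 9, 13]
    stack_residues = ["E", "D", "E", "K", "D", "E", "R", "D"]
    for L, res in zip(stack_lengths, stack_residues):
        specs.append(solenoid(L, 85.0, [FeatureInjection("charged_stack", 0, res)],
                              "stack_hi"))
    for L, res in zip([5, 10, 12, 14], ["E", "D", "K", "E"]):
        specs.append(solenoid(L, 60.0, [FeatureInjection("charged_stack", 0, res)],
                              "stack_lo"))
    for L in [12, 13, 14]:
        comp_pos = 2
        specs.append(solenoid(L, 85.0,
                              [FeatureInjection("charged_stack", 0, "E"),
                               FeatureInjection("compensating_counter_charge",
                                                comp_pos, "K")],
                              "stack_comp"))
    for L in [8, 10, 12, 16, 20]:
        specs.append(solenoid(L, 80.0,
                              [FeatureInjection("surface_hydrophobic", 1, "F")],
                              "surf"))
    for L in [8, 12, 16, 20]:
        specs.append(solenoid(L, 75.0, [FeatureInjection("clash", 1)], "clash"))
    for L, nc in [(10, 6), (10, 8), (8, 10), (12, 8), (10, 10), (8, 8), (12, 6), (10, 7)]:
        specs.append(decoy("ideal_helix", L, nc, 87.0, "helix"))
    for _ in range(8):
        specs.append(decoy("random_coil", 10, 6, 35.0, "coil"))
    return specs
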