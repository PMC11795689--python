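"""Model-plausibility diagnostics for (predicted or forged) repeat structures.

A high-confidence prediction is not necessarily a plausible protein.  This
module implements the red flags that betray an unrealistic model:

* solvent accessibility (Shrake-Rupley) and side-chain burial;
* CA-geometry secondary structure (distance/torsion criteria in the spirit
  of P-SEA, so it works on CA-only traces);
* a 3D/1D environment-compatibility profile with window smoothing, the
  categorical-fail rule (fewer than 80 % of residues scoring >= 0.1), and the
  mean profile score;
* buried same-charge stacks running down the solenoid axis, with
  counter-charge compensation detection;
* solvent-exposed hydrophobic residues;
* steric clash counting against van der Waals radii;
* geometric fold classification (β-solenoid / long helix / disordered);
* the "problematic" rule: confident (pLDDT > 70) yet scoring < 0.1 on the
  3D/1D profile or carrying an uncompensated internal charged stack.

Burial here is side-chain relative SASA: the residue's side-chain SASA in
context divided by a maximum-exposure reference (shipped for both full-atom
and reduced pseudo-atom representations).  Backbone area would dilute the
contrast that charged-stack and exposed-hydrophobic detection rely on.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import StructureModel, mean_plddt as _mean_plddt

NEGATIVE = frozenset("DE")
POSITIVE_WITH_HIS = frozenset("KRH")
POSITIVE_NO_HIS = frozenset("KR")
HYDROPHOBIC = frozenset("AVLIMFWYC")
BACKBONE_NAMES = frozenset(("N", "CA", "C", "O"))
POLAR_ELEMENTS = frozenset(("N", "O"))

BURIAL_CLASSES = ("E", "P1", "P2", "B1", "B2", "B3")
SS_CLASSES = ("helix", "sheet", "other")


def _load_tsv_map(name: str, key: str, value: str) -> dict[str, float]:
    ref = resources.files("repeataudit.data") / name
    out: dict[str, float] = {}
    with ref.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row[key]] = float(row[value])
    return out


def vdw_radii() -> dict[str, float]:
    """Van der Waals radii (Å) by element symbol, from the shipped table."""
    return _load_tsv_map("vdw_radii.tsv", "element", "radius")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere point set (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def _atom_areas(coords: np.ndarray, elements: Sequence[str],
                probe_radius: float, n_points: int) -> np.ndarray:
    radii_map = vdw_radii()
    try:
        radii = np.array([radii_map[e] for e in elements]) + probe_radius
    except KeyError as exc:
        raise KeyError(f"unknown element {exc.args[0]!r}: no van der Waals radius") from None
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], radii[i] + rmax):
            if j == i:
                continue
            accessible &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
        areas[i] = 4 * np.pi * radii[i] ** 2 * accessible.mean()
    return areas


def _is_reduced(model: StructureModel) -> bool:
    allowed = BACKBONE_NAMES | {"CB", "SCP"}
    return all(a.name in allowed for r in model.residues for a in r.atoms)


def _sasa_references(model: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    """(max total, max side-chain) references, picked per representation."""
    table_name = ("max_sasa_reduced.tsv" if _is_reduced(model)
                  else "max_sasa_fullatom.tsv")
    total_map = _load_tsv_map(table_name, "residue", "max_total_sasa")
    side_map = _load_tsv_map(table_name, "residue", "max_sidechain_sasa")
    total = np.array([total_map[r.code] for r in model.residues])
    side = np.array([side_map[r.code] for r in model.residues])
    return total, side


@dataclass
class SasaResult:
    """Per-residue absolute and relative solvent accessibility.

    ``relative`` is the whole residue against a max-exposure total reference
    (an isolated residue scores ~1).  ``rel_sidechain`` is the side chain
    against an isolated-side-chain reference; burial-dependent diagnostics
    (charged stacks, exposed hydrophobics, environment classes) use it, since
    backbone area dilutes the buried/exposed contrast.
    """

    absolute: np.ndarray        # total residue SASA, Å²
    relative: np.ndarray        # total / max-exposure total reference
    rel_sidechain: np.ndarray   # side-chain SASA / side-chain reference
    atom_areas: np.ndarray      # flat per-atom areas, model order


def sasa(model: StructureModel, probe_radius: float = 1.4,
         n_points: int = 960) -> SasaResult:
    """Shrake-Rupley SASA with a deterministic golden-spiral point set.

    CA stands in for the side chain of glycine and of CA-only traces;
    reference tables are picked automatically for the full-atom or reduced
    pseudo-atom representation.
    """
    flat = model.all_atoms()
    coords = np.array([a.position for _, a in flat])
    elements = [a.element for _, a in flat]
    areas = _atom_areas(coords, elements, probe_radius, n_points)
    n = len(model)
    absolute = np.zeros(n)
    side = np.zeros(n)
    bare = {i for i, res in enumerate(model.residues) if not res.sidechain_atoms()}
    for (i, atom), area in zip(flat, areas):
        absolute[i] += area
        if atom.name not in BACKBONE_NAMES:
            side[i] += area
        elif i in bare and atom.name == "CA":
            # Gly and CA-only traces: CA stands in for the side chain
            side[i] += area
    total_ref, side_ref = _sasa_references(model)
    return SasaResult(absolute=absolute, relative=absolute / total_ref,
                      rel_sidechain=side / side_ref, atom_areas=areas)


# ---------------------------------------------------------------------------
# secondary structure from CA geometry

def _virtual_torsions(ca: np.ndarray) -> np.ndarray:
    b1 = ca[1:-2] - ca[:-3]
    b2 = ca[2:-1] - ca[1:-2]
    b3 = ca[3:] - ca[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = (n1 * n2).sum(axis=1)
    y = (m1 * n2).sum(axis=1)
    return np.degrees(np.arctan2(y, x))


def _wrap_angle(d: np.ndarray | float) -> np.ndarray | float:
    return (d + 180.0) % 360.0 - 180.0


def assign_ss(model: StructureModel | np.ndarray) -> np.ndarray:
    """Per-residue secondary structure (H/E/C) from CA distances and torsions.

    Distance windows follow the CA-geometry approach of P-SEA: helix needs
    d(i,i+2) ≈ 5.4, d(i,i+3) ≈ 5.1, d(i,i+4) ≈ 6.2 Å over a 5-residue run;
    strand needs sustained extended geometry (d(i,i+2) >= 6.0, d(i,i+3) >= 6.3)
    over a 5-residue run.  Both additionally require the virtual torsion to
    vary slowly (within 35° across two consecutive windows), which random
    coils fail.  Fewer than 5 residues are all coil.
    """
    ca = model if isinstance(model, np.ndarray) else model.ca_coords()
    n = len(ca)
    ss = np.full(n, "C", dtype="<U1")
    if n < 5:
        return ss
    d2 = np.linalg.norm(ca[2:] - ca[:-2], axis=1)
    d3 = np.linalg.norm(ca[3:] - ca[:-3], axis=1)
    d4 = np.linalg.norm(ca[4:] - ca[:-4], axis=1)
    tau = _virtual_torsions(ca)
    regular = np.zeros(n, dtype=bool)
    dtau = np.abs(_wrap_angle(np.diff(tau)))
    regular[:len(dtau)] = dtau <= 35.0
    is_h = np.zeros(n, dtype=bool)
    is_e = np.zeros(n, dtype=bool)
    for i in range(n - 5):
        if (4.9 <= d2[i] <= 5.9 and 4.5 <= d3[i] <= 5.9
                and 5.5 <= d4[i] <= 6.9 and regular[i] and regular[i + 1]):
            is_h[i:i + 5] = True
    for i in range(n - 4):
        if (d2[i] >= 6.0 and d2[i + 1] >= 6.0 and d2[i + 2] >= 6.0
                and d3[i] >= 6.3 and d3[i + 1] >= 6.3
                and regular[i] and regular[i + 1]):
            is_e[i:i + 5] = True
    ss[is_e] = "E"
    ss[is_h] = "H"  # helix wins where both fire
    return ss


# ---------------------------------------------------------------------------
# environment classes and the 3D/1D profile

@dataclass(frozen=True)
class EnvironmentClass:
    """Burial/polarity class crossed with secondary structure (18 combos)."""

    burial: str  # E, P1, P2, B1, B2, B3
    ss: str      # helix, sheet, other

    def __post_init__(self) -> None:
        if self.burial not in BURIAL_CLASSES:
            raise ValueError(f"unknown burial class {self.burial!r}")
        if self.ss not in SS_CLASSES:
            raise ValueError(f"unknown ss class {self.ss!r}")

    @property
    def label(self) -> str:
        return f"{self.burial}_{self.ss}"


ALL_ENVIRONMENT_CLASSES = tuple(EnvironmentClass(b, s)
                                for b in BURIAL_CLASSES for s in SS_CLASSES)

#: Burial / polarity thresholds for environment assignment (config defaults):
#: buried if side-chain rel-SASA <= 0.09, partial if <= 0.40, else exposed;
#: buried split by surrounding polar-atom fraction at 0.45 / 0.58, partial
#: split at 0.67.
ENV_THRESHOLDS = {
    "buried_max": 0.09,
    "partial_max": 0.40,
    "b1_polar_max": 0.45,
    "b2_polar_max": 0.58,
    "p1_polar_max": 0.67,
}


def assign_environment(rel_sasa: float, polar_fraction: float, ss: str,
                       thresholds: dict | None = None) -> EnvironmentClass:
    """Map burial, surrounding polarity and SS to one of 18 environments."""
    th = thresholds or ENV_THRESHOLDS
    if rel_sasa < 0 or not math.isfinite(rel_sasa):
        raise ValueError(f"relative SASA out of range: {rel_sasa}")
    if not 0.0 <= polar_fraction <= 1.0:
        raise ValueError(f"polar fraction out of range: {polar_fraction}")
    if rel_sasa <= th["buried_max"]:
        if polar_fraction <= th["b1_polar_max"]:
            burial = "B1"
        elif polar_fraction <= th["b2_polar_max"]:
            burial = "B2"
        else:
            burial = "B3"
    elif rel_sasa <= th["partial_max"]:
        burial = "P1" if polar_fraction <= th["p1_polar_max"] else "P2"
    else:
        burial = "E"
    ss_name = {"H": "helix", "E": "sheet"}.get(ss, "other")
    return EnvironmentClass(burial, ss_name)


def polar_fractions(model: StructureModel, radius: float = 6.5) -> np.ndarray:
    """Fraction of polar (N/O) atoms among other residues' atoms near each
    residue's side-chain centroid."""
    flat = model.all_atoms()
    coords = np.array([a.position for _, a in flat])
    owners = np.array([i for i, _ in flat])
    polar = np.array([a.element in POLAR_ELEMENTS for _, a in flat])
    tree = cKDTree(coords)
    out = np.zeros(len(model))
    for i, res in enumerate(model.residues):
        side = res.sidechain_atoms()
        center = (np.mean([a.position for a in side], axis=0) if side
                  else (res.ca or res.atoms[0]).position)
        idx = [j for j in tree.query_ball_point(center, radius) if owners[j] != i]
        out[i] = polar[idx].mean() if idx else 0.0
    return out


class ScoreTable3D1D:
    """20 residues × 18 environment classes of compatibility scores."""

    def __init__(self, frame: pd.DataFrame):
        from .repeatgen import AMINO_ACIDS

        labels = [c.label for c in ALL_ENVIRONMENT_CLASSES]
        missing_rows = set(AMINO_ACIDS) - set(frame.index)
        missing_cols = set(labels) - set(frame.columns)
        if missing_rows or missing_cols:
            raise ValueError(f"incomplete 3D/1D table: missing residues "
                             f"{sorted(missing_rows)}, classes {sorted(missing_cols)}")
        if frame.loc[list(AMINO_ACIDS), labels].isna().any().any():
            raise ValueError("3D/1D table has missing cells")
        self.frame = frame.loc[list(AMINO_ACIDS), labels].astype(float)

    def score(self, residue: str, env: EnvironmentClass) -> float:
        try:
            return float(self.frame.at[residue, env.label])
        except KeyError:
            raise KeyError(f"no 3D/1D score for residue {residue!r}") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreTable3D1D":
        return cls(pd.read_csv(path, sep="\t", index_col="residue"))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.rename_axis("residue").to_csv(path, sep="\t")

    @classmethod
    def default(cls) -> "ScoreTable3D1D":
        """The shipped default table (implementer-derived; see docs/methods)."""
        ref = resources.files("repeataudit.data") / "score_3d1d_default.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    @classmethod
    def constant(cls, value: float) -> "ScoreTable3D1D":
        """A flat table (every cell = value); useful for table-independent tests."""
        from .repeatgen import AMINO_ACIDS

        labels = [c.label for c in ALL_ENVIRONMENT_CLASSES]
        frame = pd.DataFrame(value, index=list(AMINO_ACIDS), columns=labels)
        return cls(frame)


def smooth_profile(raw: np.ndarray, window: int = 21) -> np.ndarray:
    """Centered moving average, truncated at the termini."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    raw = np.asarray(raw, dtype=float)
    half = window // 2
    out = np.empty_like(raw)
    for i in range(len(raw)):
        lo = max(0, i - half)
        hi = min(len(raw), i + half + 1)
        out[i] = raw[lo:hi].mean()
    return out


@dataclass
class EnvironmentProfile:
    """Per-residue environments, raw and smoothed 3D/1D scores, and the
    categorical pass/fail assessment."""

    environments: list[EnvironmentClass]
    raw_scores: np.ndarray
    smoothed_scores: np.ndarray
    mean_3d1d: float
    frac_ge_threshold: float
    categorical_fail: bool
    score_threshold: float = 0.1
    min_fraction: float = 0.8


def assess_scores(raw: np.ndarray, window: int = 21, score_threshold: float = 0.1,
                  min_fraction: float = 0.8,
                  environments: list[EnvironmentClass] | None = None) -> EnvironmentProfile:
    """Smooth raw per-residue scores and apply the categorical-fail rule.

    The model fails categorically when fewer than ``min_fraction`` (80 %) of
    residues have a smoothed score >= ``score_threshold`` (0.1); the headline
    number is the mean of the smoothed per-residue scores.
    """
    raw = np.asarray(raw, dtype=float)
    smoothed = smooth_profile(raw, window)
    frac = float(np.mean(smoothed >= score_threshold)) if raw.size else 0.0
    return EnvironmentProfile(
        environments=environments or [],
        raw_scores=raw,
        smoothed_scores=smoothed,
        mean_3d1d=float(smoothed.mean()) if raw.size else 0.0,
        frac_ge_threshold=frac,
        categorical_fail=frac < min_fraction,
        score_threshold=score_threshold,
        min_fraction=min_fraction,
    )


def profile_3d1d(model: StructureModel, table: ScoreTable3D1D | None = None,
                 window: int = 21, sasa_result: SasaResult | None = None,
                 ss: np.ndarray | None = None) -> EnvironmentProfile:
    """Compute the 3D/1D environment-compatibility profile of a model."""
    table = table or ScoreTable3D1D.default()
    sasa_result = sasa_result or sasa(model)
    ss = ss if ss is not None else assign_ss(model)
    pf = polar_fractions(model)
    envs = [assign_environment(min(float(r), 1.0), float(p), s)
            for r, p, s in zip(sasa_result.rel_sidechain, pf, ss)]
    raw = np.array([table.score(res.code, env)
                    for res, env in zip(model.residues, envs)])
    return assess_scores(raw, window=window, environments=envs)


# ---------------------------------------------------------------------------
# charged stacks, exposed hydrophobics, clashes

#: Side-chain charge-centre atom names for full-atom structures, searched in
#: order; the forge's SCP pseudo-atom, then CB, then CA serve as fallbacks.
CHARGE_CENTER_ATOMS = {
    "D": (("OD1", "OD2"), ("CG",)),
    "E": (("OE1", "OE2"), ("CD",)),
    "K": (("NZ",),),
    "R": (("NH1", "NH2"), ("CZ",)),
    "H": (("ND1", "NE2"),),
}


def charge_center(residue) -> np.ndarray:
    """Charge-centre position of a residue's side chain."""
    for group in CHARGE_CENTER_ATOMS.get(residue.code, ()):
        atoms = [residue.atom(name) for name in group]
        atoms = [a for a in atoms if a is not None]
        if atoms:
            return np.mean([a.position for a in atoms], axis=0)
    for name in ("SCP", "CB", "CA"):
        a = residue.atom(name)
        if a is not None:
            return a.position
    return residue.atoms[0].position


@dataclass
class ChargedStack:
    """A buried same-charge stack down consecutive rungs of a solenoid."""

    unit_position: int
    member_indices: list[int]     # 0-based residue indices, one per rung
    sign: str                     # "negative" | "positive"
    compensated: bool
    min_member_distance: float    # min consecutive charge-centre distance, Å

    def __len__(self) -> int:
        return len(self.member_indices)


def detect_charged_stacks(model: StructureModel, unit_length: int,
                          stack_min: int = 3, link_dist: float = 7.0,
                          burial_max_relsasa: float = 0.15,
                          compensation_dist: float = 4.5,
                          his_positive: bool = True,
                          sasa_result: SasaResult | None = None) -> list[ChargedStack]:
    """Find buried same-charge stacks at a fixed unit position.

    A stack is >= ``stack_min`` same-sign charged residues (D/E negative,
    K/R and optionally H positive) occupying the same unit position in
    consecutive rungs, each buried (side-chain rel-SASA <=
    ``burial_max_relsasa``) with consecutive charge-centre distances <=
    ``link_dist``.  A stack is compensated when any member has an
    opposite-sign charge centre within ``compensation_dist``.
    """
    if unit_length <= 0:
        raise ValueError(f"unit_length must be positive, got {unit_length}")
    positive = POSITIVE_WITH_HIS if his_positive else POSITIVE_NO_HIS
    sasa_result = sasa_result or sasa(model)
    rel = sasa_result.rel_sidechain
    n = len(model)
    centers = {i: charge_center(r) for i, r in enumerate(model.residues)
               if r.code in NEGATIVE | positive}
    stacks: list[ChargedStack] = []
    for sign_name, charge_set in (("negative", NEGATIVE), ("positive", positive)):
        opposite = positive if sign_name == "negative" else NEGATIVE
        opp_centers = [centers[i] for i in centers
                       if model.residues[i].code in opposite]
        for p in range(unit_length):
            eligible = [k for k in range(p, n, unit_length)
                        if model.residues[k].code in charge_set
                        and rel[k] <= burial_max_relsasa]
            run: list[int] = []
            runs: list[list[int]] = []
            for k in eligible:
                if run and k - run[-1] == unit_length and \
                        np.linalg.norm(centers[k] - centers[run[-1]]) <= link_dist:
                    run.append(k)
                else:
                    if len(run) >= stack_min:
                        runs.append(run)
                    run = [k]
            if len(run) >= stack_min:
                runs.append(run)
            for members in runs:
                pos = [centers[k] for k in members]
                dmin = float(min(np.linalg.norm(b - a)
                                 for a, b in zip(pos, pos[1:])))
                compensated = any(
                    np.linalg.norm(oc - mc) <= compensation_dist
                    for mc in pos for oc in opp_centers)
                stacks.append(ChargedStack(
                    unit_position=p, member_indices=members, sign=sign_name,
                    compensated=compensated, min_member_distance=dmin))
    return stacks


def detect_exposed_hydrophobics(model: StructureModel, relsasa_min: float = 0.5,
                                hydrophobic_set: frozenset[str] = HYDROPHOBIC,
                                sasa_result: SasaResult | None = None) -> list[int]:
    """0-based indices of hydrophobic residues with rel-SASA >= threshold."""
    if not hydrophobic_set:
        return []
    sasa_result = sasa_result or sasa(model)
    return [i for i, r in enumerate(model.residues)
            if r.code in hydrophobic_set and sasa_result.rel_sidechain[i] >= relsasa_min]


def count_clashes(model: StructureModel, tolerance: float = 0.4) -> int:
    """Count non-bonded atom pairs closer than the vdW contact minus tolerance.

    All pairs from residues >= 2 apart are checked; for adjacent residues only
    side-chain/side-chain pairs (backbone atoms of neighbours are covalently
    coupled); intra-residue pairs are skipped.
    """
    radii_map = vdw_radii()
    flat = model.all_atoms()
    coords = np.array([a.position for _, a in flat])
    try:
        radii = np.array([radii_map[a.element] for _, a in flat])
    except KeyError as exc:
        raise KeyError(f"unknown element {exc.args[0]!r}: no van der Waals radius") from None
    owners = np.array([i for i, _ in flat])
    is_side = np.array([a.name not in BACKBONE_NAMES for _, a in flat])
    tree = cKDTree(coords)
    cutoff = 2 * radii.max() - tolerance
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if not len(pairs):
        return 0
    sep = np.abs(owners[pairs[:, 0]] - owners[pairs[:, 1]])
    dist = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    limit = radii[pairs[:, 0]] + radii[pairs[:, 1]] - tolerance
    close = dist < limit
    far_pairs = (sep >= 2) & close
    adj_pairs = (sep == 1) & close & is_side[pairs[:, 0]] & is_side[pairs[:, 1]]
    return int(far_pairs.sum() + adj_pairs.sum())


# ---------------------------------------------------------------------------
# fold classification and the problematic rule

FoldClass = Literal["beta_solenoid", "alpha_helical", "none", "other"]


def classify_fold(model: StructureModel, unit_length: int,
                  ss: np.ndarray | None = None) -> str:
    """Geometric fold classification.

    β-solenoid: the CA trace repeats with a rung spacing of 4-7 Å at the unit
    period (median |CA_i − CA_(i+L)| in [4, 7] Å, coefficient of variation
    < 0.25) and at least a quarter of residues in strand state.  Long helix:
    >= 60 % helix and a radius of gyration close to the extended-rod value.
    "none" (disordered): no secondary-structure class reaches 25 % and the
    rung test fails.  Anything else: "other".
    """
    n = len(model)
    if unit_length >= n:
        raise ValueError(f"unit_length {unit_length} >= residue count {n}")
    ca = model.ca_coords()
    ss = ss if ss is not None else assign_ss(model)
    frac_h = float(np.mean(ss == "H"))
    frac_e = float(np.mean(ss == "E"))
    rungs = np.linalg.norm(ca[unit_length:] - ca[:-unit_length], axis=1)
    med = float(np.median(rungs))
    cv = float(rungs.std() / rungs.mean()) if rungs.mean() > 0 else np.inf
    rung_ok = 4.0 <= med <= 7.0 and cv < 0.25
    if rung_ok and frac_e >= 0.25:
        return "beta_solenoid"
    centred = ca - ca.mean(axis=0)
    rg = float(np.sqrt((centred ** 2).sum(axis=1).mean()))
    rod_rg = 1.5 * (n - 1) / math.sqrt(12.0)
    if frac_h >= 0.6 and rg >= 0.6 * rod_rg:
        return "alpha_helical"
    if max(frac_h, frac_e) < 0.25 and not rung_ok:
        return "none"
    return "other"


def flag_problematic(mean_plddt: float, mean_3d1d: float,
                     stacks: Sequence[ChargedStack]) -> bool:
    """Confident but implausible: pLDDT > 70 and (3D/1D mean < 0.1 or an
    uncompensated charged stack)."""
    if mean_plddt <= 70.0:
        return False
    return mean_3d1d < 0.1 or any(not s.compensated for s in stacks)


def disorder_flag(probabilities: Sequence[float] | np.ndarray,
                  threshold: float = 0.5) -> tuple[float, bool]:
    """Mean per-residue disorder probability and the >= 0.5 cohort flag."""
    arr = np.asarray(probabilities, dtype=float)
    if arr.size == 0:
        raise ValueError("empty disorder profile")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("disorder probabilities must lie in [0, 1]")
    mean = float(arr.mean())
    return mean, mean >= threshold


def read_disorder_tsv(path: str | Path) -> np.ndarray:
    """Read a per-residue disorder TSV (columns residue_index, probability)."""
    frame = pd.read_csv(path, sep="\t")
    frame = frame.sort_values("residue_index")
    return frame["probability"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# whole-model audit

@dataclass
class AuditReport:
    """All plausibility diagnostics for one model, kept separately; the
    'problematic' verdict is derived, never stored over the facts."""

    seq_id: str
    mean_plddt: float
    mean_3d1d: float
    frac_ge_threshold: float
    categorical_fail: bool
    charged_stacks: list[ChargedStack]
    n_exposed_hydrophobics: int
    clash_count: int
    fold_class: str
    disorder_mean: float | None = None
    disorder_flagged: bool | None = None
    raw_scores: np.ndarray | None = None
    smoothed_scores: np.ndarray | None = None

    @property
    def n_stacks(self) -> int:
        return len(self.charged_stacks)

    @property
    def n_uncompensated_stacks(self) -> int:
        return sum(1 for s in self.charged_stacks if not s.compensated)

    @property
    def problematic(self) -> bool:
        return flag_problematic(self.mean_plddt, self.mean_3d1d, self.charged_stacks)

    def to_dict(self) -> dict:
        return {
            "seq_id": self.seq_id,
            "mean_plddt": round(self.mean_plddt, 4),
            "mean_3d1d": round(self.mean_3d1d, 4),
            "frac_ge_threshold": round(self.frac_ge_threshold, 4),
            "categorical_fail": self.categorical_fail,
            "n_stacks": self.n_stacks,
            "n_uncompensated_stacks": self.n_uncompensated_stacks,
            "stacks": [
                {"unit_position": s.unit_position, "n_members": len(s),
                 "sign": s.sign, "compensated": s.compensated,
                 "min_member_distance": round(s.min_member_distance, 3)}
                for s in self.charged_stacks
            ],
            "n_exposed_hydrophobics": self.n_exposed_hydrophobics,
            "clash_count": self.clash_count,
            "fold_class": self.fold_class,
            "disorder_mean": (round(self.disorder_mean, 4)
                              if self.disorder_mean is not None else None),
            "disorder_flagged": self.disorder_flagged,
            "problematic": self.problematic,
        }


def audit_model(model: StructureModel, unit_length: int, seq_id: str = "",
                table: ScoreTable3D1D | None = None, window: int = 21,
                disorder: np.ndarray | None = None,
                stack_params: dict | None = None,
                relsasa_min: float = 0.5,
                clash_tolerance: float = 0.4) -> AuditReport:
    """Run the full plausibility audit on one model."""
    sasa_result = sasa(model)
    ss = assign_ss(model)
    profile = profile_3d1d(model, table=table, window=window,
                           sasa_result=sasa_result, ss=ss)
    stacks = detect_charged_stacks(model, unit_length,
                                   sasa_result=sasa_result,
                                   **(stack_params or {}))
    exposed = detect_exposed_hydrophobics(model, relsasa_min=relsasa_min,
                                          sasa_result=sasa_result)
    clashes = count_clashes(model, tolerance=clash_tolerance)
    fold = classify_fold(model, unit_length, ss=ss)
    d_mean = d_flag = None
    if disorder is not None:
        d_mean, d_flag = disorder_flag(disorder)
    return AuditReport(
        seq_id=seq_id or model.source,
        mean_plddt=_mean_plddt(model),
        mean_3d1d=profile.mean_3d1d,
        frac_ge_threshold=profile.frac_ge_threshold,
        categorical_fail=profile.categorical_fail,
        charged_stacks=stacks,
        n_exposed_hydrophobics=len(exposed),
        clash_count=clashes,
        fold_class=fold,
        disorder_mean=d_mean,
        disorder_flagged=d_flag,
        raw_scores=profile.raw_scores,
        smoothed_scores=profile.smoothed_scores,
    )
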