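"""Design of perfect tandem-repeat sequences from secondary-structure pools.

The protocol groups the 20 amino acids into three pools by secondary-structure
propensity — β-favouring (C, F, I, T, V, W, Y), α-favouring (A, E, K, M, Q, R,
L) and neutral (G, N, D, P, H, S) — draws a random repeat unit from one pool
or a union of pools, and concatenates it (10× by default) into a perfect
repeat protein.  Two cohort designs are provided: the preliminary 50-entry
design (20-residue units, 31 random sequences + 19 alanine-mutant slots) and
the expanded design covering unit lengths 5-30 across three pool schemes
(26 × 3 = 78 sequences).

Sequence-level summary statistics are the mean α and β propensities (Chou-
Fasman by default) and a repeat-perfection score (mean column-wise identity
across copies), whose normalised form uses the convention of dividing a raw
repeat score by the unit length with "near-perfect" meaning > 7.0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues eligible for alanine substitution: aromatic or charged.
AROMATIC_OR_CHARGED = set("FWYHDEKR")


@dataclass(frozen=True)
class AminoPools:
    """The three propensity pools.  Pairwise disjoint, union = 20 residues."""

    beta: frozenset[str] = frozenset("CFITVWY")
    alpha: frozenset[str] = frozenset("AEKMQRL")
    neutral: frozenset[str] = frozenset("GNDPHS")

    def __post_init__(self) -> None:
        union = self.beta | self.alpha | self.neutral
        if len(union) != 20 or union != set(AMINO_ACIDS):
            raise ValueError("pools must cover exactly the 20 standard residues")
        if (self.beta & self.alpha) or (self.beta & self.neutral) or (self.alpha & self.neutral):
            raise ValueError("pools must be pairwise disjoint")

    def for_scheme(self, scheme: str) -> str:
        """Sorted residue string for a pool scheme label."""
        parts = {
            "alpha": self.alpha,
            "beta": self.beta,
            "neutral": self.neutral,
            "alpha+beta": self.alpha | self.beta,
            "alpha+neutral": self.alpha | self.neutral,
            "beta+neutral": self.beta | self.neutral,
            "all": self.alpha | self.beta | self.neutral,
        }
        if scheme not in parts:
            raise ValueError(f"unknown pool scheme {scheme!r}; expected one of {sorted(parts)}")
        return "".join(sorted(parts[scheme]))


SCHEMES = ("alpha", "beta", "neutral", "alpha+beta", "alpha+neutral",
           "beta+neutral", "all")


@dataclass(frozen=True)
class RepeatSequence:
    """A repeat unit, its copy count, and the concatenated full sequence."""

    unit: str
    n_copies: int
    scheme: str = "all"
    seed: int | None = None
    seq_id: str = ""

    def __post_init__(self) -> None:
        if not self.unit:
            raise ValueError("repeat unit must be non-empty")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")

    @property
    def full(self) -> str:
        return self.unit * self.n_copies

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    def __len__(self) -> int:
        return len(self.unit) * self.n_copies


class PropensityTable:
    """Per-residue (p_alpha, p_beta) propensities for the 20 standard codes."""

    def __init__(self, values: dict[str, tuple[float, float]]):
        if set(values) != set(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - set(values)
            extra = set(values) - set(AMINO_ACIDS)
            raise ValueError(f"table must cover exactly 20 codes (missing {sorted(missing)}, "
                             f"extra {sorted(extra)})")
        if any(a <= 0 or b <= 0 for a, b in values.values()):
            raise ValueError("propensities must be positive")
        self.values = dict(values)

    def p_alpha(self, code: str) -> float:
        return self._get(code)[0]

    def p_beta(self, code: str) -> float:
        return self._get(code)[1]

    def _get(self, code: str) -> tuple[float, float]:
        try:
            return self.values[code]
        except KeyError:
            raise KeyError(f"residue {code!r} not in propensity table") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropensityTable":
        values: dict[str, tuple[float, float]] = {}
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                values[row["residue"]] = (float(row["p_alpha"]), float(row["p_beta"]))
        return cls(values)

    @classmethod
    def default(cls) -> "PropensityTable":
        """Chou-Fasman helix/sheet propensities (shipped TSV)."""
        ref = resources.files("repeataudit.data") / "chou_fasman.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def make_unit(length: int, scheme: str = "all", seed: int | None = None,
              pools: AminoPools | None = None) -> str:
    """Draw a random repeat unit, uniform with replacement over the scheme's pool."""
    if length < 1:
        raise ValueError(f"unit length must be >= 1, got {length}")
    alphabet = (pools or AminoPools()).for_scheme(scheme)
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(alphabet), size=length))


def tandem(unit: str, n_copies: int, scheme: str = "all",
           seed: int | None = None, seq_id: str = "") -> RepeatSequence:
    """Concatenate a unit into a perfect tandem repeat."""
    return RepeatSequence(unit=unit, n_copies=n_copies, scheme=scheme,
                          seed=seed, seq_id=seq_id)


DEFAULT_LENGTHS = range(5, 31)
DEFAULT_SCHEMES = ("beta", "alpha+beta", "all")


def generate_expanded_cohort(lengths: Iterable[int] = DEFAULT_LENGTHS,
                             schemes: Sequence[str] = DEFAULT_SCHEMES,
                             n_copies: int = 10,
                             seed: int = 0,
                             pools: AminoPools | None = None) -> list[RepeatSequence]:
    """One sequence per (unit length, scheme): the expanded 78-sequence design.

    Per-sequence seeds are derived deterministically as ``seed + index`` so a
    single cohort seed reproduces the whole set.
    """
    out: list[RepeatSequence] = []
    idx = 0
    for length in lengths:
        for scheme in schemes:
            sub = seed + idx
            unit = make_unit(length, scheme, seed=sub, pools=pools)
            out.append(tandem(unit, n_copies, scheme=scheme, seed=sub,
                              seq_id=f"rep{length:02d}_{scheme}"))
            idx += 1
    return out


@dataclass(frozen=True)
class DesignEntry:
    kind: str           # "random" or "mutant"
    scheme: str         # pool scheme for random entries; "" for mutants
    unit_length: int


@dataclass
class CohortDesign:
    """An expandable list of design slots (random draws and mutant slots)."""

    entries: list[DesignEntry] = field(default_factory=list)
    seed: int = 0

    @property
    def n_random(self) -> int:
        return sum(1 for e in self.entries if e.kind == "random")

    @property
    def n_mutants(self) -> int:
        return sum(1 for e in self.entries if e.kind == "mutant")

    def __len__(self) -> int:
        return len(self.entries)


#: (scheme, count) composition of the 31 random entries in the preliminary design.
PRELIMINARY_COMPOSITION = (
    ("alpha", 2), ("beta", 3), ("neutral", 2),
    ("alpha+neutral", 3), ("beta+neutral", 3), ("alpha+beta", 3),
    ("all", 15),
)
PRELIMINARY_N_MUTANTS = 19


def enumerate_preliminary_design(seed: int = 0, unit_length: int = 20) -> CohortDesign:
    """The preliminary 50-entry design: 31 random 20-mers plus 19 mutant slots.

    Mutant slots are abstract here — which parent sequence and unit position
    each mutant derives from is an explicit user choice (see
    :func:`alanine_mutant`).
    """
    entries = [DesignEntry("random", scheme, unit_length)
               for scheme, count in PRELIMINARY_COMPOSITION for _ in range(count)]
    entries += [DesignEntry("mutant", "", unit_length)
                for _ in range(PRELIMINARY_N_MUTANTS)]
    return CohortDesign(entries=entries, seed=seed)


def realize_random_entries(design: CohortDesign, n_copies: int = 10,
                           pools: AminoPools | None = None) -> list[RepeatSequence]:
    """Draw the random entries of a design into concrete sequences."""
    out = []
    for i, entry in enumerate(e for e in design.entries if e.kind == "random"):
        sub = design.seed + i
        unit = make_unit(entry.unit_length, entry.scheme, seed=sub, pools=pools)
        out.append(tandem(unit, n_copies, scheme=entry.scheme, seed=sub,
                          seq_id=f"pre{i:02d}_{entry.scheme}"))
    return out


def alanine_mutant(seq: RepeatSequence, unit_position: int) -> RepeatSequence:
    """Replace the residue at ``unit_position`` of every copy with alanine.

    Only aromatic or charged residues (F, W, Y, H, D, E, K, R) are eligible;
    histidine counts as charged.
    """
    if not 0 <= unit_position < seq.unit_length:
        raise IndexError(f"unit position {unit_position} out of range for "
                         f"unit of length {seq.unit_length}")
    residue = seq.unit[unit_position]
    if residue not in AROMATIC_OR_CHARGED:
        raise ValueError(f"residue {residue!r} at unit position {unit_position} "
                         f"is not aromatic or charged")
    new_unit = seq.unit[:unit_position] + "A" + seq.unit[unit_position + 1:]
    return RepeatSequence(unit=new_unit, n_copies=seq.n_copies, scheme=seq.scheme,
                          seed=seq.seed,
                          seq_id=(seq.seq_id + f"_A{unit_position}") if seq.seq_id else "")


def propensity_means(seq: RepeatSequence | str,
                     table: PropensityTable | None = None) -> tuple[float, float]:
    """Arithmetic mean α and β propensity over the full sequence."""
    table = table or PropensityTable.default()
    full = seq if isinstance(seq, str) else seq.full
    if not full:
        raise ValueError("empty sequence")
    alphas = []
    betas = []
    for code in full:
        pa, pb = table._get(code)
        alphas.append(pa)
        betas.append(pb)
    return float(np.mean(alphas)), float(np.mean(betas))


def normalize_repeat_score(raw_score: float, unit_length: int) -> float:
    """Normalise a raw repeat score by the repeat unit length."""
    if unit_length < 1:
        raise ValueError(f"unit_length must be >= 1, got {unit_length}")
    return raw_score / unit_length


def is_near_perfect(raw_score: float, unit_length: int, threshold: float = 7.0) -> bool:
    """True when the length-normalised repeat score is strictly above 7.0."""
    return normalize_repeat_score(raw_score, unit_length) > threshold


def repeat_perfection(full: str, unit_length: int) -> float:
    """Mean column-wise identity of a sequence read as stacked unit copies.

    Each unit position is a column over the (floor) copies; a column's
    identity is the frequency of its most common residue.  1.0 for a perfect
    tandem repeat; 1/n_copies when every copy disagrees everywhere.
    """
    if unit_length < 1:
        raise ValueError("unit_length must be >= 1")
    n_copies = len(full) // unit_length
    if n_copies < 2:
        raise ValueError("sequence must contain at least two full copies")
    columns = [full[p::unit_length][:n_copies] for p in range(unit_length)]
    idents = []
    for col in columns:
        counts = {c: col.count(c) for c in set(col)}
        idents.append(max(counts.values()) / n_copies)
    return float(np.mean(idents))


def write_fasta(seqs: Sequence[RepeatSequence], path: str | Path,
                width: int = 60) -> Path:
    """Write sequences as FASTA; headers carry unit length, scheme, and seed."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            sid = s.seq_id or f"seq{i:03d}"
            fh.write(f">{sid} unit_length={s.unit_length} n_copies={s.n_copies} "
                     f"scheme={s.scheme} seed={s.seed}\n")
            full = s.full
            for j in range(0, len(full), width):
                fh.write(full[j:j + width] + "\n")
    return path


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Minimal FASTA read-back: list of (header, sequence)."""
    records: list[tuple[str, str]] = []
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:]
                chunks = []
            elif line:
                chunks.append(line)
    if header is not None:
        records.append((header, "".join(chunks)))
    return records


def cohort_manifest(seqs: Sequence[RepeatSequence],
                    table: PropensityTable | None = None) -> "pandas.DataFrame":
    """Summary table: id, unit, lengths, scheme, seed, propensity means, perfection."""
    import pandas as pd

    table = table or PropensityTable.default()
    rows = []
    for i, s in enumerate(seqs):
        ma, mb = propensity_means(s, table)
        rows.append({
            "seq_id": s.seq_id or f"seq{i:03d}",
            "unit": s.unit,
            "unit_length": s.unit_length,
            "n_copies": s.n_copies,
            "scheme": s.scheme,
            "seed": s.seed,
            "mean_alpha": round(ma, 4),
            "mean_beta": round(mb, 4),
            "repeat_perfection": (repeat_perfection(s.full, s.unit_length)
                                  if s.n_copies >= 2 else float("nan")),
        })
    return pd.DataFrame(rows)
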