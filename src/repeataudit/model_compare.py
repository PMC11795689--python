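"""Comparing alternative models of the same sequence.

Two use cases: rank-to-rank RMSD within one predictor's set of five models
(single-pass least-squares superposition, no outlier-rejection cycles, the
inputs never moved), and method-to-method TM-scores, where 0.5 is the
conventional same-fold significance threshold.  Comparisons are CA-only with
identity residue correspondence — the sequences are identical by
construction, and a guard rejects mismatches rather than silently aligning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .structure_io import StructureModel, mean_plddt

TM_SIGNIFICANT = 0.5


@dataclass
class ComparisonResult:
    """Superposition RMSD and/or TM-score between two models."""

    id_a: str
    id_b: str
    n_matched: int
    rmsd: float | None = None
    tm: float | None = None
    plddt_a: float | None = None
    plddt_b: float | None = None


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares superposition of A onto B (Kabsch, via SVD).

    Returns (rotation, translation, rmsd) with a proper rotation
    (det = +1); applying ``coords_a @ rotation.T + translation`` moves A onto
    B.  Inputs are not modified.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"point sets must both be (n, 3); got {a.shape} and {b.shape}")
    if len(a) < 3:
        raise ValueError(f"need at least 3 points, got {len(a)}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("coordinates must be finite")
    ca = a - a.mean(axis=0)
    cb = b - b.mean(axis=0)
    h = ca.T @ cb
    u, s, vt = np.linalg.svd(h)
    # degenerate (e.g. collinear) point sets leave the rotation underdetermined
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate point set: superposition underdetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = b.mean(axis=0) - rot @ a.mean(axis=0)
    moved = ca @ rot.T
    rmsd = float(np.sqrt(((moved - cb) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def _check_same_sequence(model_a: StructureModel, model_b: StructureModel) -> None:
    if model_a.sequence != model_b.sequence:
        raise ValueError("models have different sequences; rank/method comparison "
                         "requires identical sequences")


def rank_model_rmsd(model_a: StructureModel, model_b: StructureModel,
                    id_a: str = "rank1", id_b: str = "rankK") -> ComparisonResult:
    """CA-only superposed RMSD between two models of the same sequence."""
    _check_same_sequence(model_a, model_b)
    ca_a = model_a.ca_coords()
    ca_b = model_b.ca_coords()
    _, _, rmsd = kabsch_superpose(ca_a, ca_b)
    return ComparisonResult(id_a=id_a, id_b=id_b, n_matched=len(ca_a), rmsd=rmsd,
                            plddt_a=_safe_plddt(model_a), plddt_b=_safe_plddt(model_b))


def _safe_plddt(model: StructureModel) -> float | None:
    try:
        return mean_plddt(model)
    except Exception:
        return None


def tm_d0(l_norm: int) -> float:
    """TM-score distance scale d0(L) = 1.24 (L − 15)^{1/3} − 1.8, floored at 0.5 Å."""
    if l_norm < 3:
        raise ValueError(f"normalization length must be >= 3, got {l_norm}")
    if l_norm <= 15:
        return 0.5
    return max(1.24 * (l_norm - 15) ** (1.0 / 3.0) - 1.8, 0.5)


def _tm_from_superposition(a: np.ndarray, b: np.ndarray, subset: np.ndarray,
                           d0: float, l_norm: int) -> tuple[float, np.ndarray]:
    """Score all residues after superposing on a subset; returns (TM, distances)."""
    rot, trans, _ = kabsch_superpose(a[subset], b[subset])
    moved = a @ rot.T + trans
    d = np.linalg.norm(moved - b, axis=1)
    tm = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)
    return tm, d


def tm_score(model_a: StructureModel | np.ndarray,
             model_b: StructureModel | np.ndarray,
             normalize_by: Literal["a", "b", "shorter"] = "shorter",
             max_iter: int = 20) -> float:
    """TM-score between two models of the same sequence (identity alignment).

    Superpositions are seeded on sliding fragments of length L, L/2 and L/4,
    each refined by iterating Kabsch superposition on the residues within a
    distance cutoff until membership is stable (TM-align's heuristic); the
    best score over all seeds and refinement stages is returned.
    """
    if isinstance(model_a, StructureModel) and isinstance(model_b, StructureModel):
        _check_same_sequence(model_a, model_b)
        a = model_a.ca_coords()
        b = model_b.ca_coords()
    else:
        a = np.asarray(model_a, dtype=float)
        b = np.asarray(model_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("identity alignment requires equal lengths")
    n = len(a)
    l_norm = {"a": n, "b": n, "shorter": n}[normalize_by]  # identical lengths here
    d0 = tm_d0(l_norm)
    best = 0.0
    fragment_lengths = sorted({n, max(n // 2, 4), max(n // 4, 4)}, reverse=True)
    for frag in fragment_lengths:
        stride = max(1, (n - frag) // 8) if frag < n else 1
        for start in range(0, n - frag + 1, stride):
            subset = np.arange(start, start + frag)
            if len(subset) < 3:
                continue
            try:
                tm, d = _tm_from_superposition(a, b, subset, d0, l_norm)
            except ValueError:
                continue  # degenerate fragment
            best = max(best, tm)
            # iterative distance-cutoff refinement
            cutoff = max(d0 + 1.0, 3.5)
            prev: np.ndarray | None = None
            for _ in range(max_iter):
                sel = np.where(d < cutoff)[0]
                if len(sel) < 3:
                    cutoff += 0.5
                    continue
                if prev is not None and len(sel) == len(prev) and np.array_equal(sel, prev):
                    break
                prev = sel
                try:
                    tm, d = _tm_from_superposition(a, b, sel, d0, l_norm)
                except ValueError:
                    break
                best = max(best, tm)
    return best


def is_significant_match(tm: float, threshold: float = TM_SIGNIFICANT) -> bool:
    """Same-fold call at the conventional TM > 0.5 threshold."""
    return tm > threshold


def divergence_table(models_by_method: Mapping[str, StructureModel],
                     reference: str = "AF2",
                     problematic: bool | None = None) -> pd.DataFrame:
    """Pairwise TM-scores of each method's model against a reference method.

    One row per non-reference method with the TM-score to the reference and
    both mean pLDDTs; an optional 'problematic' audit flag is joined in.
    """
    if reference not in models_by_method:
        raise KeyError(f"reference method {reference!r} not among "
                       f"{sorted(models_by_method)}")
    if len(models_by_method) < 2:
        raise ValueError("need at least two methods to compare")
    ref_model = models_by_method[reference]
    rows = []
    for method, model in models_by_method.items():
        if method == reference:
            continue
        tm = tm_score(ref_model, model)
        rows.append({
            "method": method,
            "reference": reference,
            "tm_vs_reference": round(tm, 4),
            "significant": is_significant_match(tm),
            "plddt_reference": _safe_plddt(ref_model),
            "plddt_method": _safe_plddt(model),
            "problematic": problematic,
        })
    return pd.DataFrame(rows)
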