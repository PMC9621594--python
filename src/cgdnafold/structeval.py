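"""Structure evaluation: base-pair detection, CG-RMSD, ensemble statistics.

RMSD is computed over CG beads matched by (strand, residue, kind) after
optimal rigid-body superposition (Kabsch; rotation + translation, no
scaling).  Beads missing from the native structure (e.g. 5'-terminal
phosphates in crystal structures) are excluded from both sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .forcefield import ForceFieldParams, base_pairing_energy, default_params
from .topology import CGSystem

__all__ = ["Pair", "RmsdReport", "detect_pairs", "cg_rmsd", "ensemble_stats"]


class Pair(NamedTuple):
    strand_i: int
    res_i: int          # residue index within strand_i
    strand_j: int
    res_j: int
    kind: str           # "GC" or "AT"


@dataclass
class RmsdReport:
    per_structure: np.ndarray
    mean: float
    minimum: float
    argmin: int
    matched_beads: int


def detect_pairs(system: CGSystem,
                 params: ForceFieldParams | None = None) -> list[Pair]:
    """Base pairs whose pairing energy is below the detection threshold
    (a configured fraction of the single-pair minimum -eps_bp)."""
    params = params or default_params()
    thresh = params.pairing.detect_threshold
    _, matched = base_pairing_energy(system, params)
    starts = system.strand_res_start
    strand = system.strand_of_res
    bases = "".join(system.sequences)
    out = []
    for i, j, e in matched:
        if e >= thresh:
            continue
        si, sj = int(strand[i]), int(strand[j])
        kind = "".join(sorted((bases[i], bases[j])))
        kind = {"CG": "GC", "AT": "AT"}[kind]
        out.append(Pair(si, i - int(starts[si]), sj, j - int(starts[sj]), kind))
    return sorted(out)


def _matched_coords(predicted: CGSystem, native: CGSystem):
    if predicted.sequences != native.sequences:
        for s, (a, b) in enumerate(zip(predicted.sequences, native.sequences)):
            for r, (x, y) in enumerate(zip(a, b)):
                if x != y:
                    raise ValueError(
                        f"sequence mismatch at strand {s} residue {r}: "
                        f"{x!r} vs {y!r}")
        raise ValueError("sequence mismatch: different strand counts/lengths")
    keep = predicted.present & native.present
    return predicted.positions[keep], native.positions[keep], int(keep.sum())


def _kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD after optimal rotation+translation of p onto q (SVD Kabsch)."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = pc @ rot - qc
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def cg_rmsd(predicted: CGSystem, native: CGSystem,
            superpose: bool = True) -> float:
    """CG-bead RMSD between two systems of identical sequence.

    With ``superpose`` (default) an optimal rigid-body superposition is
    applied first, making the measure invariant to global rotation and
    translation of either argument.
    """
    p, q, n = _matched_coords(predicted, native)
    if n == 0:
        raise ValueError("no common beads to compare")
    if superpose:
        return _kabsch_rmsd(p, q)
    diff = p - q
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def ensemble_stats(ensemble, native: CGSystem,
                   superpose: bool = True) -> RmsdReport:
    """Mean and minimum CG-RMSD of a structure ensemble vs the native.

    ``ensemble`` is an iterable of CGSystem or of coordinate arrays
    shaped like ``native.positions`` (sharing the native's topology).
    """
    vals = []
    for item in ensemble:
        if isinstance(item, CGSystem):
            sys_ = item
        else:
            sys_ = native.copy()
            sys_.positions = np.asarray(item, dtype=float)
            sys_.present = np.ones(len(sys_.positions), dtype=bool)
        vals.append(cg_rmsd(sys_, native, superpose=superpose))
    if not vals:
        raise ValueError("empty ensemble")
    arr = np.array(vals)
    _, _, matched = _matched_coords(native, native)
    return RmsdReport(
        per_structure=arr,
        mean=float(arr.mean()),
        minimum=float(arr.min()),
        argmin=int(arr.argmin()),
        matched_beads=matched,
    )
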