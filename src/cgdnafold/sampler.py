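"""Metropolis Monte Carlo simulated annealing for CG DNA.

Folding protocol: start from a random chain (or boxed pair of chains) at
high temperature (default 120 C) and cool along a temperature ladder to
the target, sampling with pivot moves (and rigid chain translations for
dsDNA) under the Para_nonhelical bonded parameters.  The last
conformation at the target temperature is the initial structure
prediction, which `refine` then polishes with Para_helical parameters on
the consecutively base-paired regions.

A sweep is one attempted move per bead.  Move amplitudes adapt toward
30-50% acceptance during a short burn-in at each ladder temperature and
are frozen afterwards so production sampling obeys detailed balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _mc_kernel as K
from .forcefield import (
    COULOMB,
    KB,
    ForceFieldParams,
    default_params,
    electro_params,
    pair_combos,
    stacking_table,
    total_energy,
)
from .topology import CGSystem, bonded_terms

__all__ = [
    "AnnealSchedule",
    "MoveSet",
    "Trajectory",
    "anneal",
    "refine",
    "metropolis_accept",
    "metropolis_step",
    "pivot_move",
    "translation_move",
    "majority_partners",
    "kernel_full_energy",
]

_BOND_NAMES = ["PC", "CP", "CN"]
_ANGLE_NAMES = ["PCP", "CPC", "NCP5", "NCP3"]
_DIHEDRAL_NAMES = ["PCPC", "CPCP", "NCPC"]


@dataclass
class MoveSet:
    """Move mixture and (initial) amplitudes; amplitudes adapt per block."""

    p_translation: float = 0.2       # used only for two-chain systems
    max_pivot_angle: float = 0.6     # radians
    max_translation: float = 4.0     # Angstrom

    def __post_init__(self):
        if not 0.0 <= self.p_translation < 1.0:
            raise ValueError("p_translation must be in [0, 1)")


@dataclass
class AnnealSchedule:
    """Cooling schedule: strictly decreasing ladder from t_start to t_target."""

    t_target: float
    t_start: float = 120.0
    t_step: float = 5.0
    sweeps_per_t: int | None = None      # default: 2e5 for <=30 nt, linear in n
    refine_steps: int = 100_000
    thin: int = 25
    adapt_fraction: float = 0.1
    explicit_ladder: tuple | None = None

    def ladder(self) -> np.ndarray:
        if self.explicit_ladder is not None:
            lad = np.asarray(self.explicit_ladder, dtype=float)
            d = np.diff(lad)
            # explicit ladders may run either way (heating branches of
            # melting protocols) but must be strictly monotone
            if len(lad) > 1 and not (np.all(d < 0) or np.all(d > 0)):
                raise ValueError("ladder must be strictly monotone")
            return lad
        if self.t_start < self.t_target:
            raise ValueError("t_start must exceed t_target")
        lad = list(np.arange(self.t_start, self.t_target, -abs(self.t_step)))
        if not lad or lad[-1] != self.t_target:
            lad.append(self.t_target)
        return np.array(lad)

    def sweeps_for(self, n_residues: int) -> int:
        if self.sweeps_per_t is not None:
            return int(self.sweeps_per_t)
        return int(200_000 * max(1.0, n_residues / 30.0))


@dataclass
class Trajectory:
    """Thinned MC frames: per-frame energies, pair counts and pairings."""

    frames: pd.DataFrame                 # block, sweep, temperature_c, U_*, n_pairs
    partners: np.ndarray                 # (n_frames, n_res) int16, -1 = unpaired
    seed: int
    final_system: CGSystem
    coords: np.ndarray | None = None     # (n_coord_frames, n_beads, 3)
    acceptance: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Kernel plumbing


def _kernel_static(system: CGSystem, params: ForceFieldParams):
    terms = bonded_terms(system)
    starts = system.strand_res_start
    counts = np.array([len(s) for s in system.sequences], dtype=np.int64)
    slices = np.empty((len(counts), 6), dtype=np.int64)
    for c in range(len(counts)):
        lo, hi = starts[c], starts[c] + counts[c]
        slices[c, 0:2] = np.searchsorted(terms["bond_res"][:, 0], [lo, hi])
        slices[c, 2:4] = np.searchsorted(terms["angle_res"][:, 0], [lo, hi])
        slices[c, 4:6] = np.searchsorted(terms["dihedral_res"][:, 0], [lo, hi])
    eq = params.bonded.equilibrium
    radii = np.array([params.bead_radii[k] for k in ("P", "C", "N")])
    return {
        "terms": terms,
        "slices": slices,
        "starts": starts.astype(np.int64),
        "counts": counts,
        "bond_r0": np.array([eq[n] for n in _BOND_NAMES]),
        "angle_t0": np.array([eq[n] for n in _ANGLE_NAMES]),
        "dih_p0": np.array([eq[n] for n in _DIHEDRAL_NAMES]),
        "radsum2": (radii[:, None] + radii[None, :]) ** 2,
        "strand_of_bead": system.strand_of_res[
            np.arange(3 * system.n_residues) // 3].astype(np.int64),
        "res_of_bead": (np.arange(3 * system.n_residues) // 3).astype(np.int64),
        "combos": pair_combos(system, params),
    }


def _pack_prm(system: CGSystem, params: ForceFieldParams, t_celsius: float,
              move_set: MoveSet) -> np.ndarray:
    t_k = t_celsius + 273.15
    ep = electro_params(system.ion_condition, t_k, params)
    prm = np.zeros(K.N_PRM)
    bp = params.bonded
    prm[K.P_KBOND] = bp.k_bond
    prm[K.P_KANG] = bp.k_angle
    prm[K.P_KDIH] = bp.k_dihedral
    prm[K.P_NHFAC] = bp.nonhelical_factor
    prm[K.P_EPSEXC] = params.eps_exc
    prm[K.P_EXCCAP] = params.exc_cap
    pp = params.pairing
    prm[K.P_EPSBP] = pp.eps_bp
    prm[K.P_R0NN] = pp.r0_nn
    prm[K.P_D0X] = pp.d0_cross
    prm[K.P_ALPHAR] = pp.alpha_r
    prm[K.P_ALPHAD] = pp.alpha_d
    prm[K.P_WINDOW] = pp.window
    prm[K.P_DETECT] = pp.detect_threshold
    prm[K.P_SIGST] = params.stacking.sigma_st
    prm[K.P_STCUT] = params.stacking.cutoff
    prm[K.P_ELPREF] = COULOMB * ep.Q**2 / ep.eps_rel
    prm[K.P_LDEBYE] = ep.l_debye
    prm[K.P_BOX] = system.box_side if system.box_side else 0.0
    prm[K.P_KT] = KB * t_k
    prm[K.P_PTRANS] = move_set.p_translation if system.n_strands == 2 else 0.0
    prm[K.P_COAXCUT] = params.stacking.sigma_st + 2.0
    return prm


def kernel_full_energy(system: CGSystem, t_celsius: float | None = None,
                       params: ForceFieldParams | None = None,
                       helical_mask: np.ndarray | None = None):
    """Eight energy components as the compiled kernel computes them.

    Exposed so tests can assert agreement with the reference
    :func:`cgdnafold.forcefield.total_energy`.
    """
    params = params or default_params()
    t_c = system.temperature_c if t_celsius is None else t_celsius
    st = _kernel_static(system, params)
    hel = (helical_mask if helical_mask is not None
           else np.zeros(system.n_residues)).astype(np.uint8)
    prm = _pack_prm(system, params, t_c, MoveSet())
    gabs = np.abs(stacking_table(t_c + 273.15, params))
    u, partner, n_pairs = K.full_energy(
        system.positions.astype(float), system.base_of_res.astype(np.int64),
        system.strand_of_res.astype(np.int64), st["strand_of_bead"],
        st["res_of_bead"], st["combos"], gabs, st["radsum2"], prm,
        st["terms"]["bonds"], st["terms"]["angles"], st["terms"]["dihedrals"],
        st["terms"]["bond_res"], st["terms"]["angle_res"],
        st["terms"]["dihedral_res"],
        st["bond_r0"], st["angle_t0"], st["dih_p0"], hel, st["slices"])
    return u, partner, n_pairs


def _run_block(system, params, st, t_c, sweeps, schedule, move_set, amps,
               helical, seed, record_coords=False, coords_thin=None):
    prm = _pack_prm(system, params, t_c, move_set)
    gabs = np.abs(stacking_table(t_c + 273.15, params))
    n_frames = sweeps // schedule.thin + 1
    frame_e = np.zeros((n_frames, 8))
    frame_np = np.zeros(n_frames, dtype=np.int64)
    frame_partner = np.full((n_frames, system.n_residues), -1, dtype=np.int16)
    if record_coords:
        ct = coords_thin or schedule.thin
        coords_out = np.zeros((sweeps // ct + 1, len(system.positions), 3))
    else:
        ct = sweeps + 1
        coords_out = np.zeros((1, 1, 3))
    adapt = max(1, int(schedule.adapt_fraction * sweeps))
    n_acc, n_att, u, nf, nc = K.run_block(
        system.positions, system.base_of_res.astype(np.int64),
        system.strand_of_res.astype(np.int64), st["strand_of_bead"],
        st["res_of_bead"],
        st["starts"], st["counts"], st["combos"], gabs, st["radsum2"], prm,
        st["terms"]["bonds"], st["terms"]["angles"], st["terms"]["dihedrals"],
        st["terms"]["bond_res"], st["terms"]["angle_res"],
        st["terms"]["dihedral_res"],
        st["bond_r0"], st["angle_t0"], st["dih_p0"], helical, st["slices"],
        sweeps, adapt, schedule.thin, seed, amps,
        frame_e, frame_np, frame_partner, coords_out, ct,
        record_coords)
    return (frame_e[:nf], frame_np[:nf], frame_partner[:nf],
            coords_out[:nc] if record_coords else None, n_acc, n_att, u)


def _block_seed(seed: int, block: int) -> int:
    return int((seed * 1_000_003 + 7919 * block + 1) % (2**31 - 1))


def anneal(system: CGSystem, schedule: AnnealSchedule,
           params: ForceFieldParams | None = None, seed: int = 0,
           move_set: MoveSet | None = None) -> Trajectory:
    """Simulated annealing along the schedule's cooling ladder.

    Uses Para_nonhelical bonded parameters throughout.  The input system
    is not modified; the trajectory's ``final_system`` holds the last
    conformation at the target temperature (the initial structure
    prediction).
    """
    params = params or default_params()
    move_set = move_set or MoveSet()
    sys_ = system.copy()
    if not np.all(sys_.present):
        raise ValueError("simulation requires all beads present (3 per residue)")
    st = _kernel_static(sys_, params)
    helical = np.zeros(sys_.n_residues, dtype=np.uint8)
    amps = np.array([move_set.max_pivot_angle, move_set.max_translation])
    sweeps = schedule.sweeps_for(sys_.n_residues)

    rows, partners, acc = [], [], []
    step0 = 0
    for bi, t_c in enumerate(schedule.ladder()):
        fe, fn, fp, _, n_acc, n_att, _ = _run_block(
            sys_, params, st, float(t_c), sweeps, schedule, move_set, amps,
            helical, _block_seed(seed, bi))
        for k in range(len(fe)):
            rows.append((bi, step0 + k * schedule.thin, float(t_c), *fe[k],
                         fe[k].sum(), fn[k]))
        partners.append(fp)
        acc.append(n_acc / max(n_att, 1))
        step0 += sweeps
    frames = pd.DataFrame(
        rows,
        columns=["block", "sweep", "temperature_c",
                 "U_b", "U_a", "U_d", "U_exc", "U_bp", "U_bs", "U_cs", "U_el",
                 "U_total", "n_pairs"],
    )
    sys_.temperature_c = float(schedule.ladder()[-1])
    return Trajectory(frames=frames, partners=np.concatenate(partners),
                      seed=seed, final_system=sys_, acceptance=acc)


def majority_partners(partners: np.ndarray, last_fraction: float = 0.1) -> np.ndarray:
    """Majority pairing over the trailing fraction of frames.

    A residue keeps the partner it holds in more than half of those
    frames, else -1.  Robust against single-snapshot fluctuations.
    """
    n = len(partners)
    tail = partners[int(math.floor(n * (1.0 - last_fraction))):]
    if len(tail) == 0:
        tail = partners[-1:]
    n_res = partners.shape[1]
    out = np.full(n_res, -1, dtype=np.int16)
    for r in range(n_res):
        vals, counts = np.unique(tail[:, r], return_counts=True)
        best = vals[np.argmax(counts)]
        if best >= 0 and counts.max() > len(tail) / 2:
            out[r] = best
    # enforce symmetry
    for r in range(n_res):
        p = out[r]
        if p >= 0 and out[p] != r:
            out[r] = -1
    return out


def refine(system: CGSystem, reference_partner: np.ndarray,
           params: ForceFieldParams | None = None,
           refine_steps: int = 100_000, seed: int = 1,
           thin: int = 100, move_set: MoveSet | None = None):
    """Fixed-temperature refinement with Para_helical on paired regions.

    Residues paired in ``reference_partner`` switch to the full-strength
    helical bonded parameters; all other residues stay nonhelical.  If no
    pairs were detected the run degenerates to continued folding (a
    warning is emitted).  Returns ``(ensemble, trajectory)`` where
    ``ensemble`` is the (n_frames, n_beads, 3) array of sampled
    structures (refine_steps/thin frames).
    """
    import warnings

    params = params or default_params()
    move_set = move_set or MoveSet()
    sys_ = system.copy()
    helical = (np.asarray(reference_partner) >= 0).astype(np.uint8)
    if helical.sum() == 0:
        warnings.warn("no paired residues: refinement continues folding")
    st = _kernel_static(sys_, params)
    amps = np.array([move_set.max_pivot_angle, move_set.max_translation])
    schedule = AnnealSchedule(t_target=sys_.temperature_c, thin=thin)
    fe, fn, fp, coords, n_acc, n_att, _ = _run_block(
        sys_, params, st, sys_.temperature_c, int(refine_steps), schedule,
        move_set, amps, helical, _block_seed(seed, 9999),
        record_coords=True, coords_thin=thin)
    rows = [(0, k * thin, sys_.temperature_c, *fe[k], fe[k].sum(), fn[k])
            for k in range(len(fe))]
    frames = pd.DataFrame(
        rows,
        columns=["block", "sweep", "temperature_c",
                 "U_b", "U_a", "U_d", "U_exc", "U_bp", "U_bs", "U_cs", "U_el",
                 "U_total", "n_pairs"],
    )
    traj = Trajectory(frames=frames, partners=fp, seed=seed,
                      final_system=sys_, coords=coords,
                      acceptance=[n_acc / max(n_att, 1)])
    return coords, traj


# ---------------------------------------------------------------------------
# Python-level moves (reference implementations used in unit tests)


def pivot_move(system: CGSystem, rng: np.random.Generator,
               max_angle: float = 0.6) -> CGSystem:
    """Rotate a random chain segment rigidly about a random axis through a
    random backbone bead; the proposal density is symmetric."""
    if system.n_residues < 2:
        raise ValueError("pivot requires at least 2 residues")
    sys_ = system.copy()
    chain = int(rng.integers(system.n_strands))
    first = int(system.strand_res_start[chain])
    count = len(system.sequences[chain])
    res = first + int(rng.integers(count))
    piv = 3 * res + int(rng.integers(2))
    lo, hi = ((3 * first, piv) if rng.random() < 0.5
              else (piv + 1, 3 * (first + count)))
    if lo >= hi:
        return sys_
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = float(rng.uniform(-max_angle, max_angle))
    c, s = math.cos(angle), math.sin(angle)
    seg = sys_.positions[lo:hi] - sys_.positions[piv]
    rot = (seg * c + np.cross(axis, seg) * s
           + np.outer(seg @ axis, axis) * (1.0 - c))
    sys_.positions[lo:hi] = rot + sys_.positions[piv]
    return sys_


def translation_move(system: CGSystem, rng: np.random.Generator,
                     max_disp: float = 4.0) -> CGSystem:
    """Rigidly translate one whole chain (two-chain systems).

    Returns the proposal; the caller rejects it if any bead left the box.
    """
    if system.n_strands != 2:
        raise ValueError("translation moves apply to two-chain systems")
    sys_ = system.copy()
    chain = int(rng.integers(2))
    first = int(system.strand_res_start[chain])
    count = len(system.sequences[chain])
    delta = rng.uniform(-max_disp, max_disp, size=3)
    sys_.positions[3 * first:3 * (first + count)] += delta
    return sys_


def metropolis_accept(delta_u: float, t_kelvin: float,
                      rng: np.random.Generator) -> bool:
    """Standard Metropolis rule: accept with min(1, exp(-dU/kT))."""
    if delta_u <= 0.0:
        return True
    return rng.random() < math.exp(-delta_u / (KB * t_kelvin))


def metropolis_step(system: CGSystem, t_celsius: float,
                    params: ForceFieldParams | None = None,
                    rng: np.random.Generator | None = None,
                    move_set: MoveSet | None = None):
    """One full-recompute Metropolis step (reference path, small systems)."""
    params = params or default_params()
    rng = rng or np.random.default_rng()
    move_set = move_set or MoveSet()
    if system.n_strands == 2 and rng.random() < move_set.p_translation:
        prop = translation_move(system, rng, move_set.max_translation)
        if system.box_side and (np.any(prop.positions < 0)
                                or np.any(prop.positions > system.box_side)):
            return system, False
    else:
        prop = pivot_move(system, rng, move_set.max_pivot_angle)
        if system.box_side and (np.any(prop.positions < 0)
                                or np.any(prop.positions > system.box_side)):
            return system, False
    du = (total_energy(prop, t_celsius, params).U_total
          - total_energy(system, t_celsius, params).U_total)
    if metropolis_accept(du, t_celsius + 273.15, rng):
        return prop, True
    return system, False
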