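"""The eight-term CG DNA energy function.

U = U_b + U_a + U_d + U_exc + U_bp + U_bs + U_cs + U_el

* bonded: harmonic virtual bonds and angles, periodic dihedrals, with two
  parameter regimes -- Para_helical for base-paired stems during
  refinement and Para_nonhelical (half strength, same equilibria) for
  free chains and loops during folding;
* excluded volume: purely repulsive truncated Lennard-Jones;
* base pairing: orientation-dependent Watson-Crick (G-C, A-T) attraction
  between glycosidic N beads, modulated by two auxiliary C-N cross
  distances, with one-to-one best-energy matching;
* base stacking: sequence-dependent attraction between neighbouring base
  pairs with strength G(T) = dH - T(dS - dS_c) from experimental dimer
  thermodynamics, dS_c being the conformational-entropy share already
  paid by the explicit chain degrees of freedom in the MC sampling;
* coaxial stacking: the same functional form applied across the interface
  of two discontiguous helices;
* electrostatics: Debye-Hueckel screened Coulomb repulsion between
  phosphate beads carrying a Manning-reduced charge Q(Na+, Mg2+, T).

This module is the plain-numpy reference implementation; the Monte Carlo
sampler uses an equivalent compiled kernel that is checked against it.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml
from scipy.constants import Avogadro, Boltzmann, elementary_charge, epsilon_0

from .topology import BASES, CGSystem, bonded_terms

__all__ = [
    "KB",
    "COULOMB",
    "BondedParams",
    "PairParams",
    "StackParams",
    "ElectroParams",
    "ForceFieldParams",
    "EnergyBreakdown",
    "default_params",
    "load_params",
    "dielectric",
    "bjerrum_length",
    "debye_length",
    "reduced_charge",
    "electro_params",
    "stacking_strength",
    "stacking_table",
    "bonded_energy",
    "excluded_volume",
    "base_pairing_energy",
    "base_stacking_energy",
    "coaxial_stacking_energy",
    "find_helices",
    "electrostatic_energy",
    "total_energy",
    "pair_combos",
    "estimate_stack_entropy",
]

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872041
#: e^2 / (4 pi eps0), kcal*A/mol (unit relative permittivity)
COULOMB = 332.06371
_COMPLEMENT_CODE = {0: 1, 1: 0, 2: 3, 3: 2}   # A<->T, G<->C
_BASE = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass(frozen=True)
class BondedParams:
    """Equilibria (A / radians) and per-class strengths for both regimes."""

    equilibrium: dict          # type name -> value (angles in radians)
    k_bond: float              # helical strengths
    k_angle: float
    k_dihedral: float
    nonhelical_factor: float = 0.5

    def strength(self, term_class: str, helical: bool) -> float:
        k = {"bond": self.k_bond, "angle": self.k_angle,
             "dihedral": self.k_dihedral}[term_class]
        return k if helical else k * self.nonhelical_factor


@dataclass(frozen=True)
class PairParams:
    eps_bp: float
    r0_nn: float
    d0_cross: float
    alpha_r: float
    alpha_d: float
    window: float
    min_loop: int
    detect_fraction: float

    @property
    def detect_threshold(self) -> float:
        """Energy below which a matched candidate counts as a formed pair."""
        return -self.detect_fraction * self.eps_bp


@dataclass(frozen=True)
class StackParams:
    sigma_st: float
    cutoff: float
    ds_c: float                       # cal/mol/K
    thermo: dict                      # "XY" -> (dH kcal/mol, dS cal/mol/K)


@dataclass(frozen=True)
class ElectroParams:
    """Condition-resolved electrostatic parameters (see electro_params)."""

    Q: float                  # reduced charge fraction per phosphate
    l_debye: float            # A
    eps_rel: float            # relative dielectric at T
    ion_condition: tuple      # ([Na+], [Mg2+]) molar
    cap: float = 1000.0


@dataclass(frozen=True)
class ForceFieldParams:
    bonded: BondedParams
    pairing: PairParams
    stacking: StackParams
    eps_exc: float
    exc_cap: float
    bead_radii: dict
    b_charge_spacing: float
    mg_competition: float
    exclude_bonded_elec: bool
    version: int = 1
    checksum: str = ""
    raw: dict = field(default_factory=dict, repr=False)


def load_params(path=None) -> ForceFieldParams:
    """Load a force-field parameter file (YAML); default is the packaged set."""
    if path is None:
        ref = resources.files("cgdnafold") / "parameters" / "default.yaml"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    checksum = hashlib.sha256(text.encode()).hexdigest()
    eq = dict(raw["bonded"]["equilibrium"])
    for key in ("PCP", "CPC", "NCP5", "NCP3", "PCPC", "CPCP", "NCPC"):
        eq[key] = math.radians(eq[key])
    sh = raw["bonded"]["strength_helical"]
    thermo = {k: tuple(v) for k, v in raw["thermo_table"].items()}
    return ForceFieldParams(
        bonded=BondedParams(
            equilibrium=eq,
            k_bond=sh["bond"], k_angle=sh["angle"], k_dihedral=sh["dihedral"],
            nonhelical_factor=raw["bonded"]["nonhelical_factor"],
        ),
        pairing=PairParams(**raw["pairing"]),
        stacking=StackParams(
            sigma_st=raw["stacking"]["sigma_st"],
            cutoff=raw["stacking"]["cutoff"],
            ds_c=raw["stacking"]["ds_c"],
            thermo=thermo,
        ),
        eps_exc=raw["excluded_volume"]["epsilon"],
        exc_cap=raw["excluded_volume"]["cap"],
        bead_radii=dict(raw["bead_radii"]),
        b_charge_spacing=raw["electrostatics"]["b_charge_spacing"],
        mg_competition=raw["electrostatics"]["mg_competition"],
        exclude_bonded_elec=raw["electrostatics"]["exclude_bonded"],
        version=raw["version"],
        checksum=checksum,
        raw=raw,
    )


@lru_cache(maxsize=1)
def default_params() -> ForceFieldParams:
    return load_params()


# ---------------------------------------------------------------------------
# Solvent / salt


def dielectric(t_celsius: float) -> float:
    """Temperature-dependent relative dielectric constant of water."""
    t = t_celsius
    return 87.740 - 0.4008 * t + 9.398e-4 * t * t - 1.41e-6 * t**3


def bjerrum_length(t_kelvin: float) -> float:
    """Bjerrum length (A) at temperature T."""
    return COULOMB / (dielectric(t_kelvin - 273.15) * KB * t_kelvin)


def debye_length(ion_condition, t_kelvin: float) -> float:
    """Debye screening length (A) at charge-weighted ionic strength
    I = [Na+] + 3 [Mg2+]."""
    na, mg = ion_condition
    ionic = na + 3.0 * mg
    if ionic <= 0:
        raise ValueError("undefined ionic strength: both ion concentrations zero")
    eps_r = dielectric(t_kelvin - 273.15)
    # SI: l_D = sqrt(eps0*eps_r*kB*T / (2*e^2*NA*I)), I in mol/m^3
    l_m = math.sqrt(
        epsilon_0 * eps_r * Boltzmann * t_kelvin
        / (2.0 * elementary_charge**2 * Avogadro * ionic * 1e3)
    )
    return l_m * 1e10


def reduced_charge(ion_condition, t_kelvin: float,
                   params: ForceFieldParams | None = None) -> float:
    """Reduced phosphate charge fraction Q from counterion condensation.

    Na+-only limit is the Manning fraction Q = b/l_B (b the contour
    charge spacing); Mg2+ condensation is folded in through an empirical
    competition weight, approaching the divalent plateau b/(2 l_B) at
    high [Mg2+].  Q is clipped to (0, 1].
    """
    params = params or default_params()
    na, mg = ion_condition
    if na < 0 or mg < 0 or (na == 0 and mg == 0):
        raise ValueError("need non-negative [Na+], [Mg2+], not both zero")
    q_na = min(1.0, params.b_charge_spacing / bjerrum_length(t_kelvin))
    w = params.mg_competition * mg
    x = w / (w + na) if (w + na) > 0 else 0.0
    return q_na * (1.0 - 0.5 * x)


def electro_params(ion_condition, t_kelvin: float,
                   params: ForceFieldParams | None = None) -> ElectroParams:
    params = params or default_params()
    return ElectroParams(
        Q=reduced_charge(ion_condition, t_kelvin, params),
        l_debye=debye_length(ion_condition, t_kelvin),
        eps_rel=dielectric(t_kelvin - 273.15),
        ion_condition=tuple(ion_condition),
        cap=params.exc_cap,
    )


# ---------------------------------------------------------------------------
# Stacking strengths


def _revcomp_step(dimer: str) -> str:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    return comp[dimer[1]] + comp[dimer[0]]


def stacking_strength(dimer: str, t_kelvin: float,
                      params: ForceFieldParams | None = None) -> float:
    """G(T) = dH - T*(dS - dS_c) for a 5'->3' nearest-neighbour step
    (kcal/mol); unknown steps raise KeyError."""
    params = params or default_params()
    table = params.stacking.thermo
    dimer = dimer.upper()
    if dimer in table:
        dh, ds = table[dimer]
    elif _revcomp_step(dimer) in table:
        dh, ds = table[_revcomp_step(dimer)]
    else:
        raise KeyError(f"unknown nearest-neighbour dimer {dimer!r}")
    return dh - t_kelvin * (ds - params.stacking.ds_c) / 1000.0


def stacking_table(t_kelvin: float,
                   params: ForceFieldParams | None = None) -> np.ndarray:
    """(4,4) array of G(T) for all steps, indexed by base codes (ATGC)."""
    params = params or default_params()
    out = np.empty((4, 4))
    for i, a in enumerate(BASES):
        for j, b in enumerate(BASES):
            out[i, j] = stacking_strength(a + b, t_kelvin, params)
    return out


# ---------------------------------------------------------------------------
# Energy terms (reference implementation)


@dataclass(frozen=True)
class EnergyBreakdown:
    U_b: float
    U_a: float
    U_d: float
    U_exc: float
    U_bp: float
    U_bs: float
    U_cs: float
    U_el: float

    @property
    def U_total(self) -> float:
        return (self.U_b + self.U_a + self.U_d + self.U_exc
                + self.U_bp + self.U_bs + self.U_cs + self.U_el)

    def as_array(self) -> np.ndarray:
        return np.array([self.U_b, self.U_a, self.U_d, self.U_exc,
                         self.U_bp, self.U_bs, self.U_cs, self.U_el])


_BOND_NAMES = ["PC", "CP", "CN"]
_ANGLE_NAMES = ["PCP", "CPC", "NCP5", "NCP3"]
_DIHEDRAL_NAMES = ["PCPC", "CPCP", "NCPC"]


def _angles(pos, ijk):
    u = pos[ijk[:, 0]] - pos[ijk[:, 1]]
    v = pos[ijk[:, 2]] - pos[ijk[:, 1]]
    cosang = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _dihedrals(pos, ijkl):
    b1 = pos[ijkl[:, 1]] - pos[ijkl[:, 0]]
    b2 = pos[ijkl[:, 2]] - pos[ijkl[:, 1]]
    b3 = pos[ijkl[:, 3]] - pos[ijkl[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1)[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(y, x)


def bonded_energy(system: CGSystem, params: ForceFieldParams | None = None,
                  regime_mask: np.ndarray | None = None):
    """(U_b, U_a, U_d) summed over all intra-strand bonded terms.

    ``regime_mask`` flags helical residues (full strength); a term uses
    Para_helical only when every residue it spans is helical.
    """
    params = params or default_params()
    bp = params.bonded
    if regime_mask is None:
        regime_mask = np.zeros(system.n_residues, dtype=bool)
    terms = bonded_terms(system)
    pos = system.positions
    eq = bp.equilibrium

    def factors(res_span):
        hel = regime_mask[res_span[:, 0]] & regime_mask[res_span[:, 1]]
        return np.where(hel, 1.0, bp.nonhelical_factor)

    b = terms["bonds"]
    r = np.linalg.norm(pos[b[:, 0]] - pos[b[:, 1]], axis=1)
    r0 = np.array([eq[_BOND_NAMES[t]] for t in b[:, 2]])
    u_b = float(np.sum(bp.k_bond * factors(terms["bond_res"]) * (r - r0) ** 2))

    a = terms["angles"]
    th = _angles(pos, a)
    th0 = np.array([eq[_ANGLE_NAMES[t]] for t in a[:, 3]])
    u_a = float(np.sum(bp.k_angle * factors(terms["angle_res"]) * (th - th0) ** 2))

    d = terms["dihedrals"]
    ph = _dihedrals(pos, d)
    ph0 = np.array([eq[_DIHEDRAL_NAMES[t]] for t in d[:, 4]])
    u_d = float(np.sum(
        bp.k_dihedral * factors(terms["dihedral_res"]) * (1.0 - np.cos(ph - ph0))
    ))
    return u_b, u_a, u_d


def excluded_volume(system: CGSystem, params: ForceFieldParams | None = None) -> float:
    """Purely repulsive truncated LJ over all non-bonded bead pairs.

    Pairs within the same or sequence-adjacent residue of one strand are
    governed by bonded terms and skipped.  Zero at and beyond contact
    (sum of radii); coincident beads contribute the documented cap.
    """
    params = params or default_params()
    pos, kinds = system.positions, system.kinds
    present = system.present
    res = np.arange(system.n_residues).repeat(3)
    strand = system.strand_of_res[res]
    radii = np.array([params.bead_radii[k] for k in ("P", "C", "N")])
    n = len(pos)
    ii, jj = np.triu_indices(n, k=1)
    keep = present[ii] & present[jj]
    same_strand = strand[ii] == strand[jj]
    near = np.abs(res[ii] - res[jj]) <= 1
    keep &= ~(same_strand & near)
    ii, jj = ii[keep], jj[keep]
    d = np.linalg.norm(pos[ii] - pos[jj], axis=1)
    sigma = radii[kinds[ii]] + radii[kinds[jj]]
    mask = d < sigma
    if not np.any(mask):
        return 0.0
    x = (sigma[mask] / np.maximum(d[mask], 1e-6)) ** 6
    e = params.eps_exc * (x * x - 2.0 * x + 1.0)
    return float(np.sum(np.minimum(e, params.exc_cap)))


def pair_combos(system: CGSystem, params: ForceFieldParams | None = None) -> np.ndarray:
    """(k,2) global residue pairs allowed to form Watson-Crick pairs.

    Complementary bases only (G-C, A-T); intra-strand partners must be
    separated by more than ``min_loop`` residues (minimum hairpin loop).
    """
    params = params or default_params()
    min_loop = params.pairing.min_loop
    base = system.base_of_res
    strand = system.strand_of_res
    out = []
    n = system.n_residues
    for i in range(n):
        for j in range(i + 1, n):
            if base[j] != _COMPLEMENT_CODE[int(base[i])]:
                continue
            if strand[i] == strand[j] and (j - i) <= min_loop:
                continue
            out.append((i, j))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _pair_energy(system, i, j, pp: PairParams):
    pos = system.positions
    Ni, Nj = pos[3 * i + 2], pos[3 * j + 2]
    r = float(np.linalg.norm(Ni - Nj))
    if abs(r - pp.r0_nn) > pp.window:
        return 0.0
    Ci, Cj = pos[3 * i + 1], pos[3 * j + 1]
    d1 = float(np.linalg.norm(Ci - Nj))
    d2 = float(np.linalg.norm(Ni - Cj))
    return -pp.eps_bp * math.exp(
        -pp.alpha_r * (r - pp.r0_nn) ** 2
        - pp.alpha_d * ((d1 - pp.d0_cross) ** 2 + (d2 - pp.d0_cross) ** 2)
    )


def base_pairing_energy(system: CGSystem, params: ForceFieldParams | None = None):
    """Orientation-dependent WC pairing energy with one-to-one matching.

    Returns ``(energy, matched)`` where ``matched`` is a list of
    ``(res_i, res_j, energy)`` with i<j, each residue in at most one pair,
    chosen greedily by lowest pair energy (ties by lexicographic (i, j)).
    """
    params = params or default_params()
    pp = params.pairing
    combos = pair_combos(system, params)
    cands = []
    for i, j in combos:
        e = _pair_energy(system, int(i), int(j), pp)
        if e < 0.0:
            cands.append((e, int(i), int(j)))
    cands.sort()
    used = set()
    matched, total = [], 0.0
    for e, i, j in cands:
        if i in used or j in used:
            continue
        used.update((i, j))
        matched.append((i, j, e))
        total += e
    return total, matched


def _bracket(r: float, sigma: float, cutoff: float) -> float:
    """5(s/r)^12 - 6(s/r)^10; equals -1 at r=sigma, 0 beyond the cutoff."""
    if r >= cutoff:
        return 0.0
    x = sigma / max(r, 0.05 * sigma)
    x10 = x**10
    return min(5.0 * x10 * x * x - 6.0 * x10, 1e3)


def _partner_array(system: CGSystem, pairs) -> np.ndarray:
    partner = np.full(system.n_residues, -1, dtype=np.int64)
    for i, j, *_ in pairs:
        partner[i] = j
        partner[j] = i
    return partner


def base_stacking_energy(system: CGSystem, pairs, t_kelvin: float,
                         params: ForceFieldParams | None = None) -> float:
    """Sequence-dependent stacking between neighbouring base pairs (the
    1/2 |G| [5-12/6-10 + 5-12/6-10] form over both strand-side N-N gaps)."""
    params = params or default_params()
    sp = params.stacking
    g = stacking_table(t_kelvin, params)
    base = system.base_of_res
    strand = system.strand_of_res
    partner = _partner_array(system, pairs)
    pos = system.positions
    total = 0.0
    for r in range(system.n_residues - 1):
        if strand[r] != strand[r + 1]:
            continue
        p, q = partner[r], partner[r + 1]
        if p < 0 or q < 0 or q != p - 1:
            continue
        if r >= q:          # count each stack once (from its left-most side)
            continue
        gij = abs(g[base[r], base[r + 1]])
        b1 = _bracket(float(np.linalg.norm(pos[3 * r + 2] - pos[3 * (r + 1) + 2])),
                      sp.sigma_st, sp.cutoff)
        b2 = _bracket(float(np.linalg.norm(pos[3 * p + 2] - pos[3 * q + 2])),
                      sp.sigma_st, sp.cutoff)
        total += 0.5 * gij * (b1 + b2)
    return total


def find_helices(system: CGSystem, pairs) -> list[tuple[int, int]]:
    """Maximal runs of consecutively stacked base pairs.

    Returns a list of (first_res, last_res) on the lower-index side; the
    partner side follows from the pair list.
    """
    partner = _partner_array(system, pairs)
    strand = system.strand_of_res
    helices = []
    n = system.n_residues
    r = 0
    while r < n:
        p = partner[r]
        if p <= r:
            r += 1
            continue
        start = r
        while (r + 1 < n and strand[r + 1] == strand[r]
               and partner[r + 1] == partner[r] - 1 and partner[r] - 1 > r + 1):
            r += 1
        helices.append((start, r))
        r += 1
    return helices


def coaxial_stacking_energy(system: CGSystem, pairs, t_kelvin: float,
                            params: ForceFieldParams | None = None,
                            helices: list | None = None) -> float:
    """Stacking across the interfaced terminal base pairs of two helices.

    Uses the same 5-12/6-10 functional form and dimer-specific |G| as
    base stacking; zero when no interface is within the stacking cutoff.
    An interface whose two stack contacts are both sequence-adjacent is
    regular (intra-helix) stacking territory and is excluded, and each
    helix end joins at most one interface (best energy first) — together
    these keep mis-registered pair ladders from collecting spurious
    coaxial energy.
    """
    params = params or default_params()
    sp = params.stacking
    if helices is None:
        helices = find_helices(system, pairs)
    if len(helices) < 2:
        return 0.0
    g = stacking_table(t_kelvin, params)
    partner = _partner_array(system, pairs)
    base = system.base_of_res
    strand = system.strand_of_res
    pos = system.positions
    Npos = lambda r: pos[3 * r + 2]
    coax_cut = sp.sigma_st + 2.0

    def adjacent(r1, r2):
        return strand[r1] == strand[r2] and abs(int(r1) - int(r2)) == 1

    # candidate interfaces between helix ends, best register each
    cands = []   # (energy, end_id_a, end_id_b)
    for a in range(len(helices)):
        ends_a = sorted({helices[a][0], helices[a][1]})
        for b in range(a + 1, len(helices)):
            ends_b = sorted({helices[b][0], helices[b][1]})
            for ea in ends_a:
                for eb in ends_b:
                    i, j = ea, int(partner[ea])
                    k, l = eb, int(partner[eb])
                    best = 0.0
                    for (c1, c2, c3, c4) in ((i, k, j, l), (i, l, j, k)):
                        if adjacent(c1, c2) and adjacent(c3, c4):
                            continue
                        r1 = float(np.linalg.norm(Npos(c1) - Npos(c2)))
                        r2 = float(np.linalg.norm(Npos(c3) - Npos(c4)))
                        if r1 < coax_cut and r2 < coax_cut:
                            gij = abs(g[base[c1], base[c2]])
                            e = 0.5 * gij * (
                                _bracket(r1, sp.sigma_st, sp.cutoff)
                                + _bracket(r2, sp.sigma_st, sp.cutoff))
                            if e < best:
                                best = e
                    if best < 0.0:
                        cands.append((best, (a, ea), (b, eb)))
    cands.sort()
    used = set()
    total = 0.0
    for e, ia, ib in cands:
        if ia in used or ib in used:
            continue
        used.update((ia, ib))
        total += e
    return total


def electrostatic_energy(system: CGSystem,
                         eparams: ElectroParams | None = None,
                         params: ForceFieldParams | None = None) -> float:
    """Screened Coulomb repulsion between all distinct P-bead pairs."""
    params = params or default_params()
    if eparams is None:
        eparams = electro_params(
            system.ion_condition, system.temperature_c + 273.15, params)
    mask = (system.kinds == 0) & system.present
    p = system.positions[mask]
    if len(p) < 2:
        return 0.0
    ii, jj = np.triu_indices(len(p), k=1)
    d = np.linalg.norm(p[ii] - p[jj], axis=1)
    d = d[d < 10.0 * eparams.l_debye]      # truncate far, fully screened pairs
    pref = COULOMB * eparams.Q**2 / eparams.eps_rel
    e = pref * np.exp(-d / eparams.l_debye) / np.maximum(d, 1e-6)
    return float(np.sum(np.minimum(e, eparams.cap)))


def total_energy(system: CGSystem, t_celsius: float | None = None,
                 params: ForceFieldParams | None = None,
                 regime_mask: np.ndarray | None = None) -> EnergyBreakdown:
    """All eight energy components recomputed from scratch."""
    params = params or default_params()
    t_c = system.temperature_c if t_celsius is None else t_celsius
    t_k = t_c + 273.15
    u_b, u_a, u_d = bonded_energy(system, params, regime_mask)
    u_exc = excluded_volume(system, params)
    u_bp, pairs = base_pairing_energy(system, params)
    u_bs = base_stacking_energy(system, pairs, t_k, params)
    u_cs = coaxial_stacking_energy(system, pairs, t_k, params)
    u_el = electrostatic_energy(
        system, electro_params(system.ion_condition, t_k, params), params)
    return EnergyBreakdown(u_b, u_a, u_d, u_exc, u_bp, u_bs, u_cs, u_el)


# ---------------------------------------------------------------------------
# Conformational entropy of one stack (dS_c estimation)


def estimate_stack_entropy(params: ForceFieldParams | None = None,
                           seed: int = 0, t_celsius: float = 37.0,
                           n_sweeps: int = 20000, burnin: int = 2000) -> float:
    """MC estimate of the conformational entropy change of closing one stack.

    Runs Metropolis MC (single-bead Gaussian displacements) on a free
    dinucleotide with bonded + excluded-volume terms only, and measures
    the probability that the neighbour N-N distance sits inside the
    stacking well (bracket < -1/2).  dS_c = R ln p, in cal/mol/K.
    """
    from .topology import chain_from_sequence

    params = params or default_params()
    sp = params.stacking
    sys_ = chain_from_sequence("GC", seed=seed)
    rng = np.random.default_rng(seed + 1)
    pos = sys_.positions
    t_k = t_celsius + 273.15
    beta = 1.0 / (KB * t_k)

    def energy():
        u_b, u_a, u_d = bonded_energy(sys_, params)
        return u_b + u_a + u_d + excluded_volume(sys_, params)

    e = energy()
    inside = 0
    count = 0
    # well bounds: bracket(r) <= -0.5
    rgrid = np.linspace(0.6 * sp.sigma_st, 2.0 * sp.sigma_st, 2000)
    br = np.array([_bracket(float(r), sp.sigma_st, sp.cutoff) for r in rgrid])
    well = rgrid[br <= -0.5]
    r_lo, r_hi = float(well.min()), float(well.max())
    for sweep in range(n_sweeps):
        for b in range(len(pos)):
            old = pos[b].copy()
            pos[b] = old + 0.35 * rng.standard_normal(3)
            e_new = energy()
            if e_new - e <= 0 or rng.random() < math.exp(-beta * (e_new - e)):
                e = e_new
            else:
                pos[b] = old
        if sweep >= burnin:
            r = float(np.linalg.norm(pos[2] - pos[5]))
            count += 1
            inside += int(r_lo <= r <= r_hi)
    p = max(inside / max(count, 1), 1.0 / max(count, 1))
    return 1.9872041 * math.log(p)
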