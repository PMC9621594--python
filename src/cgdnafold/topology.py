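"""Coarse-grained DNA topology: chains, beads, and structure builders.

Each deoxynucleotide is reduced to three beads placed at the positions of
real atoms: P (phosphate phosphorus), C (sugar C4'), and N (glycosidic
nitrogen, N1 for pyrimidines C/T and N9 for purines A/G).  Beads are van
der Waals spheres of radius 1.9 / 1.7 / 2.2 Angstrom respectively, and one
unit negative charge sits on every P bead.

This module builds :class:`CGSystem` objects from sequence (self-avoiding
random coils, boxed duplex starting states), from experimental PDB files,
and from an ideal B-form helical template used as a geometric reference
and test fixture.  Coordinates are Cartesian Angstrom, residues are
0-based and ordered 5'->3' within each strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.constants import Avogadro

__all__ = [
    "BASES",
    "COMPLEMENT",
    "BEAD_KINDS",
    "BEAD_RADII",
    "SequenceError",
    "PlacementError",
    "UnsupportedMoleculeError",
    "CGSystem",
    "validate_sequence",
    "complement",
    "chain_from_sequence",
    "duplex_box_from_sequences",
    "box_side_for_concentration",
    "ideal_bform_strand",
    "ideal_bform_duplex",
    "ideal_hairpin",
    "cg_from_pdb",
    "write_cg_pdb",
    "bonded_terms",
]

BASES = "ATGC"
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
#: bead kind codes used throughout (arrays store uint8 codes)
BEAD_KINDS = ("P", "C", "N")
BEAD_RADII = {"P": 1.9, "C": 1.7, "N": 2.2}
BEAD_CHARGE = {"P": -1.0, "C": 0.0, "N": 0.0}
_PURINES = {"A", "G"}
_BASE_CODE = {b: i for i, b in enumerate(BASES)}

# ---------------------------------------------------------------------------
# Ideal B-form CG template (cylindrical construction).
#
# The template reproduces standard B-DNA CG distances: P-C4' 3.9 A, C4'-P
# 3.7 A, C4'-N 3.4 A, paired N-N 8.9 A, rise 3.38 A, twist 36 deg.  The
# in-residue angular/axial offsets below were solved once from those
# constraints; all bonded equilibrium values in the default force-field
# parameter file are measured from this template.
TEMPLATE = {
    "rise": 3.38,
    "twist_deg": 36.0,
    "r_p": 8.9,
    "r_c": 7.3,
    "r_n": 4.8,
    "dphi_p_deg": -25.3275778662,
    "dz_p": -0.3996805209,
    "dphi_n_deg": 22.2540557463,
    "dz_n": -0.300,
    # angular phase between a residue and its pairing partner about the
    # helix axis; fixes the paired N-N distance at 8.9 A
    "duplex_pair_phase_deg": 180.1629609568,
}


class SequenceError(ValueError):
    """Invalid base character; carries the 0-based offending position."""

    def __init__(self, seq: str, position: int):
        self.position = position
        super().__init__(
            f"invalid base {seq[position]!r} at position {position} "
            f"(alphabet is A/T/G/C)"
        )


class PlacementError(RuntimeError):
    """Self-avoiding chain or box placement failed after bounded retries."""


class UnsupportedMoleculeError(ValueError):
    """PDB chain contains polymer residues that are not standard DNA."""


def validate_sequence(seq: str) -> str:
    """Uppercase and validate a DNA sequence, raising :class:`SequenceError`."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in COMPLEMENT:
            raise SequenceError(seq, i)
    return seq


def complement(seq: str) -> str:
    """Watson-Crick complement, 5'->3' (i.e. reverse complement)."""
    return "".join(COMPLEMENT[b] for b in reversed(validate_sequence(seq)))


@dataclass
class CGSystem:
    """A CG DNA system: one (ssDNA) or two (dsDNA) chains of P/C/N beads.

    Beads are stored flat; residue ``r`` (global index across strands)
    owns beads ``3r .. 3r+2`` in the order P, C, N.  Systems imported from
    PDB files may lack 5'-terminal phosphates: those beads are kept in the
    arrays with ``present`` False so the 3-beads-per-residue indexing
    stays valid.
    """

    positions: np.ndarray            # (n_beads, 3) float64, Angstrom
    kinds: np.ndarray                # (n_beads,) uint8: 0=P 1=C 2=N
    present: np.ndarray              # (n_beads,) bool, False for missing P
    sequences: list[str]             # per-strand base strings, 5'->3'
    strand_of_res: np.ndarray        # (n_res,) int32
    box_side: float | None = None    # Angstrom; dsDNA only
    temperature_c: float = 25.0
    ion_condition: tuple[float, float] = (1.0, 0.0)   # ([Na+], [Mg2+]) molar
    strand_concentration: float | None = None          # molar
    metadata: dict = field(default_factory=dict)

    # -- derived -----------------------------------------------------------
    @property
    def n_strands(self) -> int:
        return len(self.sequences)

    @property
    def n_residues(self) -> int:
        return sum(len(s) for s in self.sequences)

    @property
    def n_beads(self) -> int:
        return int(self.present.sum())

    @property
    def base_of_res(self) -> np.ndarray:
        """(n_res,) uint8 base codes (A=0 T=1 G=2 C=3)."""
        return np.array(
            [_BASE_CODE[b] for s in self.sequences for b in s], dtype=np.uint8
        )

    @property
    def strand_res_start(self) -> np.ndarray:
        starts, acc = [], 0
        for s in self.sequences:
            starts.append(acc)
            acc += len(s)
        return np.array(starts, dtype=np.int64)

    @property
    def total_charge(self) -> float:
        """Total charge in elementary charges (-1 per present P bead)."""
        return -float(np.sum(self.present & (self.kinds == 0)))

    def bead_index(self, strand: int, residue: int, kind: str) -> int:
        r = int(self.strand_res_start[strand]) + residue
        return 3 * r + BEAD_KINDS.index(kind)

    def residue_range(self, strand: int) -> range:
        start = int(self.strand_res_start[strand])
        return range(start, start + len(self.sequences[strand]))

    def copy(self) -> "CGSystem":
        return replace(
            self,
            positions=self.positions.copy(),
            kinds=self.kinds.copy(),
            present=self.present.copy(),
            sequences=list(self.sequences),
            strand_of_res=self.strand_of_res.copy(),
            metadata=dict(self.metadata),
        )

    def validate(self) -> None:
        n_res = self.n_residues
        if self.positions.shape != (3 * n_res, 3):
            raise ValueError("positions shape inconsistent with sequences")
        if self.n_strands == 2 and (self.box_side is None or self.box_side <= 0):
            raise ValueError("two-chain systems require box_side > 0")
        if self.n_strands not in (1, 2):
            raise ValueError("only ssDNA (1 chain) and dsDNA (2 chains) supported")


def _assemble(strand_arrays: list[np.ndarray], sequences: list[str], **kw) -> CGSystem:
    pos = np.concatenate(strand_arrays, axis=0)
    n_res = sum(len(s) for s in sequences)
    kinds = np.tile(np.arange(3, dtype=np.uint8), n_res)
    strand_of_res = np.concatenate(
        [np.full(len(s), i, dtype=np.int32) for i, s in enumerate(sequences)]
    )
    sys_ = CGSystem(
        positions=pos,
        kinds=kinds,
        present=np.ones(3 * n_res, dtype=bool),
        sequences=list(sequences),
        strand_of_res=strand_of_res,
        **kw,
    )
    sys_.validate()
    return sys_


# ---------------------------------------------------------------------------
# Ideal B-form builders


def _template_strand(seq: str) -> np.ndarray:
    """(3n,3) bead coordinates of one B-form strand along +z."""
    t = TEMPLATE
    tw = math.radians(t["twist_deg"])
    out = np.empty((3 * len(seq), 3))
    offsets = [
        (t["r_p"], math.radians(t["dphi_p_deg"]), t["dz_p"]),
        (t["r_c"], 0.0, 0.0),
        (t["r_n"], math.radians(t["dphi_n_deg"]), t["dz_n"]),
    ]
    for i in range(len(seq)):
        for k, (r, dphi, dz) in enumerate(offsets):
            a = i * tw + dphi
            out[3 * i + k] = (r * math.cos(a), r * math.sin(a), i * t["rise"] + dz)
    return out


def ideal_bform_strand(seq: str) -> CGSystem:
    """Single strand laid out on the ideal B-form helical template."""
    seq = validate_sequence(seq)
    return _assemble([_template_strand(seq)], [seq])


def ideal_bform_duplex(seq: str, seq_b: str | None = None) -> CGSystem:
    """Ideal B-form duplex of ``seq`` and its complement (or ``seq_b``).

    Strand B is the template rotated 180 deg about x (antiparallel, same
    handedness), shifted so residue ``k`` of B pairs residue ``n-1-k`` of A,
    then phased so the paired N-N distance equals the template value 8.9 A.
    """
    seq = validate_sequence(seq)
    if seq_b is None:
        seq_b = complement(seq)
    else:
        seq_b = validate_sequence(seq_b)
        if len(seq_b) != len(seq):
            raise ValueError("duplex strands must have equal length")
    n = len(seq)
    a = _template_strand(seq)
    b = _template_strand(seq_b).copy()
    b[:, 1] *= -1.0
    b[:, 2] = -b[:, 2] + (n - 1) * TEMPLATE["rise"]
    phi0 = math.radians(
        (n - 1) * TEMPLATE["twist_deg"] - TEMPLATE["duplex_pair_phase_deg"]
    )
    c, s = math.cos(phi0), math.sin(phi0)
    b[:, :2] = b[:, :2] @ np.array([[c, s], [-s, c]])
    sys_ = _assemble([a, b], [seq, seq_b], box_side=_default_box(n))
    # centre in the box; remember where the helix axis (z-direction) lands
    shift = sys_.box_side / 2.0 - sys_.positions.mean(axis=0)
    sys_.positions += shift
    sys_.metadata["helix_axis_xy"] = (float(shift[0]), float(shift[1]))
    return sys_


def _default_box(n: int) -> float:
    return max(3.0 * TEMPLATE["rise"] * n, 60.0)


def ideal_hairpin(seq: str, stem_len: int) -> CGSystem:
    """Hairpin fixture: ideal B-form stem plus a smooth, strain-free loop.

    The first and last ``stem_len`` residues take the ideal duplex
    geometry; the loop backbone is solved by least squares so that every
    virtual bond sits exactly at its equilibrium length (the pivot move
    set cannot relax bond strain, so fixtures must not carry any).
    """
    from scipy.optimize import least_squares

    from .forcefield import default_params

    seq = validate_sequence(seq)
    n = len(seq)
    loop_len = n - 2 * stem_len
    if stem_len < 2 or loop_len < 3:
        raise ValueError("need stem_len >= 2 and a loop of >= 3 residues")
    for a, b in zip(seq[:stem_len], reversed(seq[-stem_len:])):
        if COMPLEMENT[a] != b:
            raise ValueError("stem halves are not complementary")
    dup = ideal_bform_duplex(seq[:stem_len], seq[n - stem_len:])
    pos = np.zeros((3 * n, 3))
    pos[: 3 * stem_len] = dup.positions[: 3 * stem_len]
    pos[3 * (n - stem_len):] = dup.positions[3 * stem_len:]

    eq = default_params().bonded.equilibrium
    anchor_a = pos[3 * (stem_len - 1) + 1]          # C of last 5' stem residue
    anchor_b = pos[3 * (n - stem_len)]              # P of first 3' stem residue
    # backbone chain: anchor_a -(CP)- P_i -(PC)- C_i - ... -(CP)- anchor_b
    bond_seq = []
    for _ in range(loop_len):
        bond_seq.extend([eq["CP"], eq["PC"]])
    bond_seq.append(eq["CP"])
    m = 2 * loop_len                                # free backbone points
    mid = 0.5 * (anchor_a + anchor_b)
    bulge = mid + np.array([0.0, 0.0, 6.0 + 3.3 * loop_len])
    ts = np.linspace(0.0, 1.0, m + 2)[1:-1]
    x0 = np.concatenate([
        (1 - t) ** 2 * anchor_a + 2 * (1 - t) * t * bulge + t**2 * anchor_b
        for t in ts
    ])
    stem_beads = np.concatenate(
        [pos[: 3 * stem_len], pos[3 * (n - stem_len):]])

    def residuals(x):
        pts = np.vstack([anchor_a, x.reshape(m, 3), anchor_b])
        bonds = np.linalg.norm(np.diff(pts, axis=0), axis=1) - np.array(bond_seq)
        d = np.linalg.norm(
            pts[1:-1, None, :] - stem_beads[None, :, :], axis=2)
        clash = np.clip(5.0 - d, 0.0, None).ravel()
        return np.concatenate([bonds * 10.0, 0.3 * clash])

    sol = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12)
    pts = sol.x.reshape(m, 3)
    for k in range(loop_len):
        i = stem_len + k
        pos[3 * i] = pts[2 * k]
        pos[3 * i + 1] = pts[2 * k + 1]
        # N bead at exact bond length off the sugar
        nxt = pts[2 * k + 2] if k + 1 < loop_len else anchor_b
        pos[3 * i + 2] = _nerf(nxt, pos[3 * i], pos[3 * i + 1],
                               eq["CN"], eq["NCP5"], math.pi / 2.0)
    return _assemble([pos], [seq])


# ---------------------------------------------------------------------------
# Random self-avoiding chains

#: bond lengths are set exactly at equilibrium: the pivot/translation move
#: set never changes them, so generated strain would be frozen in forever
_CLASH_TOL = 0.35      # fractional reduction of contact distance when testing
_ANGLE_NOISE = math.radians(14.0)


def _nerf(a, b, c, bond, theta, phi):
    """Place a bead bonded to ``c`` with angle ``theta`` (b-c-new) and
    dihedral ``phi`` (a-b-c-new). Natural extension reference frame."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:   # colinear fallback: any perpendicular
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        nn = np.linalg.norm(n)
        if nn < 1e-10:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
            nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(phi),
            bond * math.sin(theta) * math.sin(phi),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _clashes(pos_done: np.ndarray, kinds_done: np.ndarray, p: np.ndarray,
             kind: int, skip_from: int) -> bool:
    """True if bead ``p`` overlaps any earlier bead outside the bonded
    neighbourhood (beads with flat index < skip_from are tested)."""
    if skip_from <= 0:
        return False
    radii = np.array([1.9, 1.7, 2.2])
    d = np.linalg.norm(pos_done[:skip_from] - p, axis=1)
    cut = (radii[kinds_done[:skip_from]] + radii[kind]) * (1.0 - _CLASH_TOL)
    return bool(np.any(d < cut))


def _grow_chain(seq: str, rng: np.random.Generator, max_restarts: int = 60) -> np.ndarray:
    """Self-avoiding random coil grown residue-by-residue.

    Backbone beads are appended with bonded geometry drawn around the
    nonhelical equilibrium values (Gaussian bond/angle noise, uniform
    backbone dihedrals), N beads hang off each sugar; clashing proposals
    are re-drawn a bounded number of times.
    """
    n = len(seq)
    from .forcefield import default_params   # local import avoids a cycle

    eq = default_params().bonded.equilibrium
    for _ in range(max_restarts):
        pos = np.zeros((3 * n, 3))
        kinds = np.tile(np.arange(3), n)
        ok = True
        for i in range(n):
            placed = False
            for _attempt in range(60):
                trial = {}
                bl = lambda key: eq[key]
                if i == 0:
                    trial[0] = np.zeros(3)
                    v = rng.standard_normal(3)
                    trial[1] = trial[0] + bl("PC") * v / np.linalg.norm(v)
                else:
                    pPrev, cPrev = pos[3 * (i - 1)], pos[3 * (i - 1) + 1]
                    ref = pos[3 * (i - 2) + 1] if i >= 2 else pos[3 * (i - 1) + 2]
                    trial[0] = _nerf(  # P_i from C_{i-1}
                        ref, pPrev, cPrev, bl("CP"),
                        eq["PCP"] + _ANGLE_NOISE * rng.standard_normal(),
                        rng.uniform(-math.pi, math.pi),
                    )
                    trial[1] = _nerf(  # C_i
                        pPrev, cPrev, trial[0], bl("PC"),
                        eq["CPC"] + _ANGLE_NOISE * rng.standard_normal(),
                        rng.uniform(-math.pi, math.pi),
                    )
                # N_i off the sugar
                if i == 0:
                    v = rng.standard_normal(3)
                    v -= v.dot(trial[1] - trial[0]) * (trial[1] - trial[0]) / max(
                        np.linalg.norm(trial[1] - trial[0]) ** 2, 1e-12)
                    trial[2] = trial[1] + bl("CN") * v / np.linalg.norm(v)
                else:
                    trial[2] = _nerf(
                        pos[3 * (i - 1) + 1], trial[0], trial[1], bl("CN"),
                        eq["NCP5"] + _ANGLE_NOISE * rng.standard_normal(),
                        rng.uniform(-math.pi, math.pi),
                    )
                bad = False
                for k in (0, 1, 2):
                    if _clashes(pos, kinds, trial[k], k, 3 * i):
                        bad = True
                        break
                if not bad:
                    for k in (0, 1, 2):
                        pos[3 * i + k] = trial[k]
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return pos
    raise PlacementError(f"could not grow self-avoiding chain for {seq!r}")


def chain_from_sequence(
    seq: str,
    seed: int,
    temperature_c: float = 25.0,
    ion_condition: tuple[float, float] = (1.0, 0.0),
) -> CGSystem:
    """Self-avoiding random CG chain for a single strand (3 beads/residue).

    Deterministic for a fixed ``seed``.
    """
    seq = validate_sequence(seq)
    rng = np.random.default_rng(seed)
    pos = _grow_chain(seq, rng)
    return _assemble(
        [pos], [seq], temperature_c=temperature_c, ion_condition=ion_condition
    )


def box_side_for_concentration(strand_conc: float) -> float:
    """Cubic box side (A) holding the two strands of a duplex at total
    single-strand concentration ``strand_conc`` (mol/L): (2/(N_A c))^(1/3).

    1 mM gives 149.2 A.
    """
    if strand_conc <= 0:
        raise ValueError("strand concentration must be positive")
    vol_l = 2.0 / (Avogadro * strand_conc)       # litres
    return (vol_l * 1e27) ** (1.0 / 3.0)         # 1 L = 1e27 A^3


def duplex_box_from_sequences(
    seq_a: str,
    seq_b: str,
    strand_conc: float,
    seed: int,
    temperature_c: float = 25.0,
    ion_condition: tuple[float, float] = (1.0, 0.0),
    max_tries: int = 200,
) -> CGSystem:
    """Two random coils placed without overlap in a concentration-set box.

    Each chain is independently grown, randomly oriented, and translated
    to a uniform position inside the box; placement is retried a bounded
    number of times if the chains overlap or poke outside the walls.
    """
    seq_a, seq_b = validate_sequence(seq_a), validate_sequence(seq_b)
    side = box_side_for_concentration(strand_conc)
    rng = np.random.default_rng(seed)
    a = _grow_chain(seq_a, rng)
    b = _grow_chain(seq_b, rng)
    radii = np.array([1.9, 1.7, 2.2])
    kinds_a = np.tile(np.arange(3), len(seq_a))
    kinds_b = np.tile(np.arange(3), len(seq_b))

    def _place(arr, rnd):
        arr = arr - arr.mean(axis=0)
        from scipy.spatial.transform import Rotation

        arr = arr @ Rotation.random(random_state=rnd).as_matrix().T
        ext_lo, ext_hi = arr.min(axis=0), arr.max(axis=0)
        lo, hi = -ext_lo, side - ext_hi
        if np.any(hi <= lo):
            return None
        return arr + rng.uniform(lo, hi)

    rnd = np.random.RandomState(int(rng.integers(2**31 - 1)))
    for _ in range(max_tries):
        pa = _place(a, rnd)
        pb = _place(b, rnd)
        if pa is None or pb is None:
            continue
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        cut = radii[kinds_a][:, None] + radii[kinds_b][None, :]
        if np.all(d > cut):
            return _assemble(
                [pa, pb],
                [seq_a, seq_b],
                box_side=side,
                temperature_c=temperature_c,
                ion_condition=ion_condition,
                strand_concentration=strand_conc,
            )
    raise PlacementError("could not place two chains in the box without overlap")


# ---------------------------------------------------------------------------
# PDB import / export

_DNA_RESNAMES = {"DA": "A", "DT": "T", "DG": "G", "DC": "C",
                 "A": "A", "T": "T", "G": "G", "C": "C"}
_SOLVENT = {"HOH", "WAT", "NA", "MG", "CL", "K", "MN", "SPM", "CA"}


def cg_from_pdb(source) -> CGSystem:
    """Map an experimental PDB structure to CG beads.

    ``source`` is a path to a PDB file or an already-parsed Bio.PDB entity.
    Bead positions are copied from the P, C4' and N1 (pyrimidine) / N9
    (purine) atoms.  A missing 5'-terminal phosphate is tolerated and
    flagged (bead marked absent, total charge renormalised); any residue
    missing C4' or its glycosidic nitrogen is rejected.  Chains containing
    non-DNA polymer residues raise :class:`UnsupportedMoleculeError`.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Entity import Entity

    if isinstance(source, Entity):
        structure = source
    else:
        structure = PDBParser(QUIET=True).get_structure("cg", str(source))
    model = next(structure.get_models()) if hasattr(structure, "get_models") else structure

    sequences: list[str] = []
    strand_pos: list[np.ndarray] = []
    strand_present: list[np.ndarray] = []
    missing: list[tuple[int, int]] = []
    author_numbers: list[list] = []

    for chain in model.get_chains():
        seq, coords, present, numbers = [], [], [], []
        for res in chain:
            name = res.get_resname().strip()
            if name in _SOLVENT or res.id[0] != " ":
                continue
            if name not in _DNA_RESNAMES:
                raise UnsupportedMoleculeError(
                    f"chain {chain.id!r} residue {name!r} is not standard DNA"
                )
            base = _DNA_RESNAMES[name]
            n_name = "N9" if base in _PURINES else "N1"
            if "C4'" not in res or n_name not in res:
                raise ValueError(
                    f"residue {name} {res.id[1]} missing C4' or {n_name}"
                )
            i = len(seq)
            if "P" in res:
                p_xyz = np.asarray(res["P"].get_coord(), dtype=float)
                p_ok = True
            elif i == 0:
                p_xyz = np.zeros(3)
                p_ok = False
                missing.append((len(sequences), 0))
            else:
                raise ValueError(
                    f"internal residue {name} {res.id[1]} missing P"
                )
            seq.append(base)
            numbers.append(res.id[1])
            coords.append(
                np.stack([
                    p_xyz,
                    np.asarray(res["C4'"].get_coord(), dtype=float),
                    np.asarray(res[n_name].get_coord(), dtype=float),
                ])
            )
            present.extend([p_ok, True, True])
        if seq:
            sequences.append("".join(seq))
            strand_pos.append(np.concatenate(coords, axis=0))
            strand_present.append(np.array(present, dtype=bool))
            author_numbers.append(numbers)

    if not sequences:
        raise UnsupportedMoleculeError("no DNA residues found")
    if len(sequences) > 2:
        raise UnsupportedMoleculeError(
            f"{len(sequences)} DNA chains found; only 1 or 2 supported"
        )
    n_res = sum(len(s) for s in sequences)
    sys_ = CGSystem(
        positions=np.concatenate(strand_pos, axis=0),
        kinds=np.tile(np.arange(3, dtype=np.uint8), n_res),
        present=np.concatenate(strand_present),
        sequences=sequences,
        strand_of_res=np.concatenate(
            [np.full(len(s), i, dtype=np.int32) for i, s in enumerate(sequences)]
        ),
        box_side=_default_box(max(len(s) for s in sequences)) if len(sequences) == 2 else None,
        metadata={"missing_p": missing, "author_residue_numbers": author_numbers},
    )
    if len(sequences) == 2:
        # roomy box centred on the imported coordinates
        sys_.positions -= sys_.positions.min(axis=0) - 10.0
        sys_.box_side = float(sys_.positions.max() + 10.0)
    sys_.validate()
    return sys_


def write_cg_pdb(system: CGSystem, path, model_sets: list[np.ndarray] | None = None) -> None:
    """Write CG beads as minimal PDB ATOM records (viewable in PyMOL).

    Atom names follow the source-atom convention (P, C4', N1/N9) so that
    the written files round-trip through :func:`cg_from_pdb`.  Passing
    ``model_sets`` writes a multi-model file (e.g. a refined ensemble).
    """
    frames = model_sets if model_sets is not None else [system.positions]
    chain_ids = "AB"
    resname = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}
    with open(path, "w") as fh:
        for imodel, pos in enumerate(frames, start=1):
            if len(frames) > 1:
                fh.write(f"MODEL {imodel:8d}\n")
            serial = 1
            r = 0
            for s, seq in enumerate(system.sequences):
                for i, base in enumerate(seq):
                    n_name = "N9" if base in _PURINES else "N1"
                    for k, name in enumerate(["P", "C4'", n_name]):
                        b = 3 * r + k
                        if not system.present[b]:
                            continue
                        x, y, z = pos[b]
                        element = name[0]
                        # fixed-column PDB ATOM record (name cols 13-16,
                        # resname 18-20, chain 22, resseq 23-26)
                        fh.write(
                            f"ATOM  {serial:5d} {name:<4s} {resname[base]:>3s}"
                            f" {chain_ids[s]}{i + 1:4d}    "
                            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                            f"          {element:>2s}\n"
                        )
                        serial += 1
                    r += 1
                fh.write("TER\n")
            if len(frames) > 1:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Bonded term lists (shared by the force field and the MC kernel)


def bonded_terms(system: CGSystem):
    """Enumerate bonded interactions of every strand.

    Returns dict with integer arrays:
      ``bonds``     (m,3): bead_i, bead_j, type  (0=PC 1=CP 2=CN)
      ``angles``    (m,4): i, j, k, type         (0=PCP 1=CPC 2=NCP5 3=NCP3)
      ``dihedrals`` (m,5): i, j, k, l, type      (0=PCPC 1=CPCP 2=NCPC)
    plus ``term_res`` arrays giving the residue span (lo, hi) of each term,
    used to resolve the helical/nonhelical regime per term.
    """
    bonds, angles, dihedrals = [], [], []
    b_res, a_res, d_res = [], [], []
    start = 0
    for seq in system.sequences:
        n = len(seq)
        P = lambda i: 3 * (start + i)
        C = lambda i: 3 * (start + i) + 1
        N = lambda i: 3 * (start + i) + 2
        for i in range(n):
            g = start + i
            bonds.append((P(i), C(i), 0)); b_res.append((g, g))
            bonds.append((C(i), N(i), 2)); b_res.append((g, g))
            angles.append((N(i), C(i), P(i), 2)); a_res.append((g, g))
            if i + 1 < n:
                bonds.append((C(i), P(i + 1), 1)); b_res.append((g, g + 1))
                angles.append((P(i), C(i), P(i + 1), 0)); a_res.append((g, g + 1))
                angles.append((N(i), C(i), P(i + 1), 3)); a_res.append((g, g + 1))
                angles.append((C(i), P(i + 1), C(i + 1), 1)); a_res.append((g, g + 1))
                dihedrals.append((P(i), C(i), P(i + 1), C(i + 1), 0)); d_res.append((g, g + 1))
                dihedrals.append((N(i), C(i), P(i + 1), C(i + 1), 2)); d_res.append((g, g + 1))
            if i + 2 < n:
                dihedrals.append((C(i), P(i + 1), C(i + 1), P(i + 2), 1)); d_res.append((g, g + 2))
        start += n
    as_arr = lambda x, w: np.array(x, dtype=np.int64).reshape(-1, w)
    return {
        "bonds": as_arr(bonds, 3),
        "angles": as_arr(angles, 4),
        "dihedrals": as_arr(dihedrals, 5),
        "bond_res": as_arr(b_res, 2),
        "angle_res": as_arr(a_res, 2),
        "dihedral_res": as_arr(d_res, 2),
    }
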