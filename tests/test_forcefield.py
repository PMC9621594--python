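"""Closed forms and invariants of the eight-term energy function."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from cgdnafold import (
    chain_from_sequence,
    default_params,
    ideal_bform_duplex,
    ideal_bform_strand,
    total_energy,
)
from cgdnafold.forcefield import (
    COULOMB,
    KB,
    _bracket,
    base_pairing_energy,
    base_stacking_energy,
    bjerrum_length,
    bonded_energy,
    coaxial_stacking_energy,
    debye_length,
    dielectric,
    electro_params,
    electrostatic_energy,
    excluded_volume,
    reduced_charge,
    stacking_strength,
    stacking_table,
)
from cgdnafold.sampler import kernel_full_energy
from cgdnafold.topology import BASES


class TestBonded:
    def test_zero_at_template_equilibrium(self):
        s = ideal_bform_strand("GCGCGC")
        ub, ua, ud = bonded_energy(s)
        assert ub + ua + ud == pytest.approx(0.0, abs=1e-6)

    def test_half_strength_rule(self, params):
        s = ideal_bform_strand("GCG")
        pos = s.positions.copy()
        # stretch the first P-C bond along its axis
        v = pos[1] - pos[0]
        pos[0] -= 0.3 * v / np.linalg.norm(v)
        s2 = s.copy()
        s2.positions = pos
        hel = np.ones(3, dtype=bool)
        nonhel = np.zeros(3, dtype=bool)
        ub_h, ua_h, ud_h = bonded_energy(s2, regime_mask=hel)
        ub_n, ua_n, ud_n = bonded_energy(s2, regime_mask=nonhel)
        assert ub_n == pytest.approx(0.5 * ub_h, rel=1e-12)
        assert ub_h == pytest.approx(params.bonded.k_bond * 0.3**2, rel=1e-6)

    def test_matches_independent_summation(self, coil13, params):
        """Oracle: term-by-term loop over explicit geometry formulas."""
        from cgdnafold.topology import bonded_terms

        terms = bonded_terms(coil13)
        pos = coil13.positions
        eq = params.bonded.equilibrium
        names_b = ["PC", "CP", "CN"]
        names_a = ["PCP", "CPC", "NCP5", "NCP3"]
        names_d = ["PCPC", "CPCP", "NCPC"]
        f = params.bonded.nonhelical_factor
        exp_b = sum(
            f * params.bonded.k_bond
            * (np.linalg.norm(pos[i] - pos[j]) - eq[names_b[t]]) ** 2
            for i, j, t in terms["bonds"])
        exp_a = 0.0
        for i, j, k, t in terms["angles"]:
            u, v = pos[i] - pos[j], pos[k] - pos[j]
            th = math.acos(np.clip(
                u.dot(v) / np.linalg.norm(u) / np.linalg.norm(v), -1, 1))
            exp_a += f * params.bonded.k_angle * (th - eq[names_a[t]]) ** 2
        exp_d = 0.0
        for i, j, k, l, t in terms["dihedrals"]:
            b1, b2, b3 = pos[j] - pos[i], pos[k] - pos[j], pos[l] - pos[k]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            m1 = np.cross(n1, b2 / np.linalg.norm(b2))
            ph = math.atan2(m1.dot(n2), n1.dot(n2))
            exp_d += f * params.bonded.k_dihedral * (
                1.0 - math.cos(ph - eq[names_d[t]]))
        ub, ua, ud = bonded_energy(coil13)
        assert ub == pytest.approx(exp_b, rel=1e-10, abs=1e-12)
        assert ua == pytest.approx(exp_a, rel=1e-10)
        assert ud == pytest.approx(exp_d, rel=1e-10)


class TestExcludedVolume:
    def _two_p_beads(self, r):
        """3-residue chain with only the P beads of residues 0 and 2
        (non-adjacent, so not excluded) at distance r."""
        from cgdnafold.topology import _assemble

        pos = np.zeros((9, 3))
        pos[0] = [0, 0, 0]           # P0
        pos[1] = [60, 0, 0]
        pos[2] = [60, 5, 0]
        pos[3] = [120, 0, 0]         # residue 1 far away
        pos[4] = [120, 5, 0]
        pos[5] = [120, 10, 0]
        pos[6] = [r, 0, 0]           # P2 approaches P0
        pos[7] = [-60, 50, 0]
        pos[8] = [-60, 55, 0]
        s = _assemble([pos], ["GCG"])
        return s

    def test_zero_beyond_contact(self):
        # adjacent-residue exclusion means we need a 3-residue chain
        s = ideal_bform_strand("GCG")
        assert excluded_volume(s) == pytest.approx(0.0)

    def test_zero_at_exact_contact_38(self):
        s = self._two_p_beads(3.8)
        assert excluded_volume(s) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_increase_on_approach(self):
        vals = [excluded_volume(self._two_p_beads(r))
                for r in np.linspace(3.6, 2.0, 12)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(v >= 0 for v in vals)
        # below that the cap takes over
        assert excluded_volume(self._two_p_beads(1.0)) == 1000.0

    def test_coincident_beads_capped(self, params):
        s = self._two_p_beads(0.0)
        assert excluded_volume(s) == pytest.approx(params.exc_cap)


class TestStackingStrength:
    def test_root_of_linear_form(self, params):
        dh, ds = params.stacking.thermo["GC"]
        t_root = dh / ((ds - params.stacking.ds_c) / 1000.0)
        assert stacking_strength("GC", t_root) == pytest.approx(0.0, abs=1e-9)

    def test_linear_in_temperature(self, params):
        dh, ds = params.stacking.thermo["AT"]
        slope = -(ds - params.stacking.ds_c) / 1000.0
        g1 = stacking_strength("AT", 300.0)
        g2 = stacking_strength("AT", 350.0)
        assert (g2 - g1) / 50.0 == pytest.approx(slope, rel=1e-12)

    @pytest.mark.parametrize("dimer", ["AA", "AT", "TA", "CA", "GT", "CT",
                                       "GA", "CG", "GC", "GG"])
    def test_hand_evaluation_at_310(self, dimer, params):
        dh, ds = params.stacking.thermo[dimer]
        expected = dh - 310.0 * (ds - params.stacking.ds_c) / 1000.0
        assert stacking_strength(dimer, 310.0) == pytest.approx(expected)

    def test_unknown_dimer_raises(self):
        with pytest.raises(KeyError):
            stacking_strength("AX", 300.0)

    def test_reverse_complement_symmetry(self):
        # the 6 steps absent from the table resolve via their complements
        assert stacking_strength("TT", 310.0) == stacking_strength("AA", 310.0)
        assert stacking_strength("TG", 310.0) == stacking_strength("CA", 310.0)

    def test_all_16_steps_defined(self):
        table = stacking_table(310.0)
        assert table.shape == (4, 4)
        assert np.all(np.isfinite(table))


class TestStackingBracket:
    def test_minus_one_at_sigma(self, params):
        sig = params.stacking.sigma_st
        assert _bracket(sig, sig, 9.0) == pytest.approx(-1.0)

    def test_decay_to_zero(self, params):
        sig = params.stacking.sigma_st
        assert abs(_bracket(8.99, sig, 9.0)) < 0.01
        assert _bracket(9.01, sig, 9.0) == 0.0

    def test_minimum_location_and_depth_numerically(self, params):
        sig = params.stacking.sigma_st
        res = minimize_scalar(lambda r: _bracket(r, sig, 20.0),
                              bounds=(0.7 * sig, 1.8 * sig), method="bounded")
        assert res.x == pytest.approx(sig, rel=1e-4)
        assert res.fun == pytest.approx(-1.0, rel=1e-6)

    def test_stack_energy_equals_minus_g_at_optimum(self, duplex_gcgc, params):
        _, pairs = base_pairing_energy(duplex_gcgc)
        t_k = 298.15
        u_bs = base_stacking_energy(duplex_gcgc, pairs, t_k)
        g = sum(abs(stacking_strength(d, t_k)) for d in ("GC", "CG", "GC"))
        # template stack distance deviates from sigma_st by <0.01 A
        assert u_bs == pytest.approx(-g, rel=5e-3)


class TestBasePairing:
    def test_ideal_duplex_four_pairs(self, duplex_gcgc, params):
        e, pairs = base_pairing_energy(duplex_gcgc)
        assert len(pairs) == 4
        assert e <= -4 * params.pairing.eps_bp * 0.99

    def test_extended_strand_no_pairs(self, strand_extended):
        e, pairs = base_pairing_energy(strand_extended)
        assert e == 0.0 and pairs == []

    def test_non_wc_opposition_no_pair(self):
        s = ideal_bform_duplex("AAAA", "GGGG")   # A opposite G at optimum
        e, pairs = base_pairing_energy(s)
        assert pairs == []

    def test_one_partner_per_residue(self, hairpin13):
        _, pairs = base_pairing_energy(hairpin13)
        seen = [r for p in pairs for r in p[:2]]
        assert len(seen) == len(set(seen))


class TestCoaxialStacking:
    def test_single_helix_zero(self, duplex_gcgc):
        _, pairs = base_pairing_energy(duplex_gcgc)
        assert coaxial_stacking_energy(duplex_gcgc, pairs, 298.15) == 0.0

    def test_two_far_hairpins_zero(self, hairpin13):
        from cgdnafold.topology import _assemble

        a = hairpin13
        b = hairpin13.copy()
        # same chain, far apart: two distinct helices beyond any cutoff
        pos = np.concatenate([a.positions, b.positions + 500.0])
        s = _assemble([pos[:len(a.positions)]], [a.sequences[0]])
        two = _assemble(
            [pos], [a.sequences[0] + b.sequences[0]])
        _, pairs = base_pairing_energy(two)
        assert len(pairs) >= 8
        assert coaxial_stacking_energy(two, pairs, 298.15) == 0.0

    def test_abutting_stems_attractive(self, params):
        """A bulge-loop geometry: the downstream helix screwed one step
        toward the upstream one scores a near-full stack interface."""
        import math

        dup = ideal_bform_duplex("GCGCGC")
        pos = dup.positions.copy()
        ax, ay = dup.metadata["helix_axis_xy"]
        rise = 3.38
        tw = math.radians(-36.0)
        c, s = math.cos(tw), math.sin(tw)
        # residue A2 is 'bulged out': slide A3-5 and their partners B6-8
        # (global residues 6,7,8) down one helical step
        movers = [b for r in (3, 4, 5, 6, 7, 8) for b in range(3 * r, 3 * r + 3)]
        xy = pos[movers, :2] - [ax, ay]
        pos[movers, 0] = ax + xy[:, 0] * c - xy[:, 1] * s
        pos[movers, 1] = ay + xy[:, 0] * s + xy[:, 1] * c
        pos[movers, 2] -= rise
        moved = dup.copy()
        moved.positions = pos
        # helix1: pairs (0,11),(1,10); helix2: pairs (3,8),(4,7),(5,6)
        pairs = [(0, 11, -1.0), (1, 10, -1.0),
                 (3, 8, -1.0), (4, 7, -1.0), (5, 6, -1.0)]
        u = coaxial_stacking_energy(moved, pairs, 298.15)
        assert u < -0.8 * abs(stacking_strength("GC", 298.15))


class TestElectrostatics:
    def test_dielectric_decreasing(self):
        ts = np.linspace(0, 120, 25)
        eps = [dielectric(t) for t in ts]
        assert all(b < a for a, b in zip(eps, eps[1:]))
        assert dielectric(25.0) == pytest.approx(78.3, abs=0.2)

    def test_debye_length_value(self):
        # 0.1 M 1:1 salt at 25 C: ~9.6 A
        assert debye_length((0.1, 0.0), 298.15) == pytest.approx(9.6, abs=0.15)

    def test_manning_limit_na_only(self, params):
        t_k = 298.15
        q = reduced_charge((1.0, 0.0), t_k)
        assert q == pytest.approx(
            params.b_charge_spacing / bjerrum_length(t_k), rel=1e-12)

    def test_q_bounds_and_mg_monotone(self):
        t_k = 310.15
        qs = [reduced_charge((0.1, mg), t_k)
              for mg in (0.0, 1e-4, 1e-3, 1e-2, 0.1, 1.0)]
        assert all(0 < q <= 1 for q in qs)
        assert all(b <= a for a, b in zip(qs, qs[1:]))
        # divalent plateau strictly below the Na-only value
        assert qs[-1] < qs[0]
        assert qs[-1] > 0.4 * qs[0]

    def test_q_continuous_in_concentrations(self):
        t_k = 298.15
        base = reduced_charge((0.1, 1e-3), t_k)
        near = reduced_charge((0.1 + 1e-9, 1e-3 + 1e-12), t_k)
        assert near == pytest.approx(base, rel=1e-6)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            reduced_charge((0.0, 0.0), 298.15)
        with pytest.raises(ValueError):
            debye_length((0.0, 0.0), 298.15)

    def test_single_p_bead_zero(self):
        from cgdnafold.topology import _assemble

        s = _assemble([np.arange(9, dtype=float).reshape(3, 3) * 10], ["G"])
        assert electrostatic_energy(s) == 0.0

    def test_closed_form_two_beads_at_debye_length(self):
        """DH pair energy at r = l_D equals (Qe)^2 e^-1 / (4 pi e0 e(T) l_D)."""
        from cgdnafold.topology import _assemble

        t_k = 298.15
        ep = electro_params((0.15, 0.0), t_k)
        pos = np.zeros((6, 3))
        pos[1] = [2000, 0, 0]
        pos[2] = [2000, 5, 0]
        pos[3] = [ep.l_debye, 0, 0]
        pos[4] = [-2000, 0, 0]
        pos[5] = [-2000, 5, 0]
        s = _assemble([pos], ["GC"])
        s.temperature_c = 25.0
        s.ion_condition = (0.15, 0.0)
        expected = COULOMB * ep.Q**2 / ep.eps_rel * math.exp(-1.0) / ep.l_debye
        assert electrostatic_energy(s, ep) == pytest.approx(expected, rel=1e-12)

    def test_screening_monotone_in_debye_length(self):
        from cgdnafold.topology import _assemble
        from dataclasses import replace

        pos = np.zeros((6, 3))
        pos[1] = [1000, 0, 0]; pos[2] = [1000, 5, 0]
        pos[3] = [7.0, 0, 0]; pos[4] = [-1000, 0, 0]; pos[5] = [-1000, 5, 0]
        s = _assemble([pos], ["GC"])
        ep = electro_params((0.1, 0.0), 298.15)
        e1 = electrostatic_energy(s, ep)
        e2 = electrostatic_energy(s, replace(ep, l_debye=2 * ep.l_debye))
        assert e2 > e1 > 0


class TestTotalEnergy:
    def test_component_additivity(self, hairpin13):
        e = total_energy(hairpin13, 25.0)
        assert e.U_total == pytest.approx(e.as_array().sum(), rel=1e-12)

    def test_separated_strands_no_contact_terms(self, strand_extended):
        e = total_energy(strand_extended, 25.0)
        assert e.U_bp == 0.0 and e.U_bs == 0.0 and e.U_cs == 0.0
        assert e.U_exc >= 0.0 and e.U_el >= 0.0

    def test_signs(self, hairpin13):
        e = total_energy(hairpin13, 25.0)
        assert e.U_exc >= 0.0
        assert e.U_el >= 0.0
        assert e.U_bp <= 0.0
        assert e.U_bs <= 0.0

    def test_matches_kernel_recompute(self, hairpin13, coil13, duplex_gcgc):
        for s in (hairpin13, coil13, duplex_gcgc):
            ref = total_energy(s, 37.0).as_array()
            u, _, _ = kernel_full_energy(s, 37.0)
            np.testing.assert_allclose(u, ref, rtol=1e-8, atol=1e-10)

    def test_rigid_motion_invariance(self, hairpin13):
        from scipy.spatial.transform import Rotation

        e0 = total_energy(hairpin13, 25.0).as_array()
        s = hairpin13.copy()
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        s.positions = hairpin13.positions @ rot.T + np.array([5.0, -3.0, 11.0])
        e1 = total_energy(s, 25.0).as_array()
        np.testing.assert_allclose(e1, e0, rtol=1e-9, atol=1e-9)

    def test_stacking_stronger_cold(self, duplex_gcgc):
        e25 = total_energy(duplex_gcgc, 25.0)
        e120 = total_energy(duplex_gcgc, 120.0)
        assert abs(e25.U_bs) > abs(e120.U_bs)
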