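"""Pair energy terms, OBC-II Born radii and IEM assembly."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from conftest import brute_force_pair_components, mc_descreen_integral
from iem import (
    ObcParameters,
    SolventModel,
    assign_parameters,
    born_radii_obc2,
    build_iem,
    electrostatic_pair_energy,
    gb_pair_energy,
    hct_descreen_term,
    lj_pair_energy,
    residue_pair_ie,
    total_ies,
)
from iem.errors import DegenerateGeometryError, ParameterizationError, UsageError
from iem.fixtures import FixtureSpec, make_toy_structure

VACUUM = SolventModel("vacuum")
DDDC = SolventModel("dddc")
GB = SolventModel("gb")


def parameterized(fixture):
    return assign_parameters(fixture.structure, fixture.parameter_set)


class TestLennardJones:
    def test_zero_at_sigma(self):
        assert lj_pair_energy(3.4, 0.1, 3.4) == pytest.approx(0.0)

    def test_minimum_at_r_min(self):
        r_min = 2 ** (1 / 6) * 3.4
        assert lj_pair_energy(3.4, 0.1, r_min) == pytest.approx(-0.1)

    def test_worked_value(self):
        # independent high-precision evaluation of 4ε[(σ/r)^12 − (σ/r)^6]
        assert lj_pair_energy(3.4, 0.1, 3.8) == pytest.approx(-0.0999317, abs=1e-6)

    def test_clash_raises(self):
        with pytest.raises(DegenerateGeometryError):
            lj_pair_energy(3.4, 0.1, 0.0)


class TestElectrostatics:
    @pytest.mark.parametrize("model", [VACUUM, DDDC])
    def test_zero_charge(self, model):
        assert electrostatic_pair_energy(0.0, 1.0, 3.0, model) == 0.0

    def test_vacuum_worked_value(self):
        # k/r with k = 332.0636 and r chosen to give exactly +100 kcal/mol
        assert electrostatic_pair_energy(1, 1, 3.320636, VACUUM) == pytest.approx(100.0)

    def test_dddc_worked_value(self):
        # k/r² evaluated by hand: 332.0636 / 3.320636² = 30.1147
        assert electrostatic_pair_energy(1, 1, 3.320636, DDDC) == pytest.approx(
            30.1147, abs=1e-4
        )

    def test_dddc_equals_vacuum_at_unit_distance(self):
        assert electrostatic_pair_energy(0.5, -0.5, 1.0, DDDC) == pytest.approx(
            electrostatic_pair_energy(0.5, -0.5, 1.0, VACUUM)
        )

    def test_gb_kind_rejected(self):
        with pytest.raises(UsageError):
            electrostatic_pair_energy(1, 1, 3.0, GB)


class TestGbPairEnergy:
    def test_reduces_to_vacuum_when_dielectrics_match(self):
        model = SolventModel("gb", eps_in=1.0, eps_out=1.0)
        e = gb_pair_energy(1, -1, 3.0, 1.5, 1.7, model)
        assert e == pytest.approx(electrostatic_pair_energy(1, -1, 3.0, VACUUM))

    def test_worked_value(self):
        # f_GB = sqrt(9 + 2.25 e^{-1}) ≈ 3.1349
        assert gb_pair_energy(1, -1, 3.0, 1.5, 1.5, GB) == pytest.approx(
            -6.1131, abs=1e-3
        )

    def test_screened_coulomb_at_large_separation(self):
        r = 40.0  # > 20 × max Born radius
        e = gb_pair_energy(1, 1, r, 1.5, 2.0, GB)
        screened = 332.0636 / (GB.eps_out * r)
        assert e == pytest.approx(screened, rel=0.01)

    def test_degenerate_distance(self):
        with pytest.raises(DegenerateGeometryError):
            gb_pair_energy(1, 1, 0.0, 1.5, 1.5, GB)


class TestHctDescreening:
    def test_vanishes_at_infinity(self):
        assert hct_descreen_term(1.41, 1.5, 0.8, 1e6) < 1e-15

    def test_engulfed_sphere_contributes_nothing(self):
        assert hct_descreen_term(3.0, 1.5, 0.8, 1.0) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            hct_descreen_term(-1.0, 1.5, 0.8, 2.0)

    @pytest.mark.parametrize(
        "rt,rho,scale,r",
        [
            (1.41, 1.5, 0.8, 4.0),   # non-overlapping
            (1.41, 1.5, 0.8, 2.0),   # partial overlap
            (1.2, 2.0, 0.9, 0.5),    # atom i inside descreening sphere
            (1.0, 2.5, 1.0, 0.8),    # deep overlap
        ],
    )
    def test_matches_numerical_quadrature(self, rt, rho, scale, r):
        """High-precision 1D quadrature of the shell-fraction integral."""
        s = scale * rho
        lo, hi = max(rt, abs(r - s)), r + s

        def shell_fraction(x):
            c = (x * x + r * r - s * s) / (2 * x * r)
            return (1 - min(1.0, max(-1.0, c))) / 2

        expected, _ = quad(lambda x: x**-2 * shell_fraction(x), lo, hi, limit=200)
        if r < s - rt:
            expected += 1 / rt - 1 / lo
        assert hct_descreen_term(rt, rho, scale, r) == pytest.approx(
            expected, rel=1e-8
        )

    def test_matches_monte_carlo_volume_integral(self):
        # the r'⁻⁴ volume integral sampled at 10⁷ points, fixed seed
        value = hct_descreen_term(1.41, 1.5, 0.8, 4.0)
        mc = mc_descreen_integral(1.41, 1.5, 0.8, 4.0, n_samples=10_000_000)
        assert value == pytest.approx(mc, rel=0.01)


class TestBornRadii:
    def test_isolated_atom_closed_form(self):
        fx = make_toy_structure(
            FixtureSpec("two_sphere", params={"r": 1e6, "gb_rho": 1.5})
        )
        br = born_radii_obc2(parameterized(fx))
        assert br.radii == pytest.approx([1.41, 1.41], abs=1e-9)

    def test_neighbors_only_grow_radii(self):
        fx2 = make_toy_structure(FixtureSpec("two_sphere"))
        br2 = born_radii_obc2(parameterized(fx2))
        assert (br2.radii >= 1.41 - 1e-12).all()
        # adding a third residue must not shrink anyone's radius
        fx3 = make_toy_structure(FixtureSpec("helix", params={"n": 3}))
        fx2h = make_toy_structure(FixtureSpec("helix", params={"n": 2}))
        r3 = born_radii_obc2(parameterized(fx3))
        r2 = born_radii_obc2(parameterized(fx2h))
        n = len(r2.radii)
        assert (r3.radii[:n] >= r2.radii - 1e-12).all()

    def test_two_sphere_matches_scalar_recomputation(self):
        fx = make_toy_structure(FixtureSpec("two_sphere"))
        br = born_radii_obc2(parameterized(fx))
        integral = hct_descreen_term(1.5 - 0.09, 1.5, 0.8, 3.0)
        psi = integral * (1.5 - 0.09)
        expected = 1.0 / (
            1.0 / (1.5 - 0.09)
            - (1.0 / 1.5) * math.tanh(psi - 0.8 * psi**2 + 4.85 * psi**3)
        )
        assert br.radii == pytest.approx([expected, expected], rel=1e-12)

    def test_over_descreened_radii_clamped_with_warning(self):
        """A huge-radius atom buried in many scaled spheres hits the cap."""
        from iem.forcefield import AtomParameters, ParameterizedStructure
        from iem.structure_io import Atom, Chain, Residue, ResidueKey, Structure

        centers = [np.zeros(3)] + [
            1.2 * np.array(v)
            for v in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                      (0, 0, 1), (0, 0, -1), (0.7, 0.7, 0), (-0.7, -0.7, 0)]
        ]
        chain = Chain(chain_id="A")
        params = {}
        for i, pos in enumerate(centers):
            key = ResidueKey("A", i + 1, "", "SPH")
            chain.residues.append(
                Residue(key=key, atoms=[Atom("Q1", "C", pos, 12.0, i + 1)])
            )
            params[key] = [AtomParameters(0.0, 3.4, 0.0, 5.0, 1.5)]
        ps = ParameterizedStructure(
            structure=Structure(chains=[chain]), parameters=params
        )
        with pytest.warns(UserWarning, match="clamped"):
            br = born_radii_obc2(ps)
        assert (br.radii <= 100.0).all()


class TestIemAssembly:
    @pytest.mark.parametrize("model", [VACUUM, DDDC, GB], ids=lambda m: m.kind)
    def test_symmetry_and_zero_diagonal(self, helix5, model):
        iem = build_iem(parameterized(helix5), model)
        for comp in (iem.electrostatic, iem.lennard_jones):
            assert np.allclose(comp, comp.T)
        assert np.diag(iem.total) == pytest.approx(np.zeros(5))

    @pytest.mark.parametrize("model", [VACUUM, GB], ids=lambda m: m.kind)
    def test_matches_brute_force_double_loop(self, helix5, model):
        ps = parameterized(helix5)
        born = born_radii_obc2(ps) if model.kind == "gb" else None
        iem = build_iem(ps, model)
        residues = list(ps.structure.residues())
        for a, b in [(0, 1), (0, 4), (2, 3)]:
            el, lj = brute_force_pair_components(
                ps, residues[a], residues[b], model, born
            )
            assert iem.electrostatic[a, b] == pytest.approx(el, rel=1e-10)
            assert iem.lennard_jones[a, b] == pytest.approx(lj, rel=1e-10)

    def test_two_residue_matrix_equals_pair_energy(self, dipeptide):
        ps = parameterized(dipeptide)
        iem = build_iem(ps, VACUUM)
        keys = iem.residue_keys
        pair = residue_pair_ie(ps, keys[0], keys[1], VACUUM)
        assert iem.total[0, 1] == pytest.approx(pair.total)
        assert pair.total == pytest.approx(pair.electrostatic + pair.lennard_jones)

    def test_pair_energy_symmetric_in_arguments(self, dipeptide):
        ps = parameterized(dipeptide)
        keys = list(ps.parameters)
        ab = residue_pair_ie(ps, keys[0], keys[1], VACUUM)
        ba = residue_pair_ie(ps, keys[1], keys[0], VACUUM)
        assert ab.electrostatic == pytest.approx(ba.electrostatic, rel=1e-12)
        assert ab.lennard_jones == pytest.approx(ba.lennard_jones, rel=1e-12)

    def test_permutation_equivariance(self, helix5):
        ps = parameterized(helix5)
        iem = build_iem(ps, VACUUM)
        # permute residues by rotating the chain list
        chain = ps.structure.chains[0]
        chain.residues = chain.residues[2:] + chain.residues[:2]
        iem_p = build_iem(ps, VACUUM)
        perm = [iem.residue_keys.index(k) for k in iem_p.residue_keys]
        assert np.allclose(iem_p.total, iem.total[np.ix_(perm, perm)])

    @pytest.mark.parametrize("model", [VACUUM, GB], ids=lambda m: m.kind)
    def test_rigid_motion_invariance(self, helix5, model):
        ps = parameterized(helix5)
        ref = build_iem(ps, model).total
        rng = np.random.default_rng(7)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = 1.1
        kmat = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        rot = np.eye(3) + np.sin(angle) * kmat + (1 - np.cos(angle)) * kmat @ kmat
        shift = np.array([11.0, -7.0, 3.0])
        fx = make_toy_structure(FixtureSpec("helix", params={"n": 5}))
        for res in fx.structure.residues():
            res.atoms = [
                type(a)(a.name, a.element, rot @ a.position + shift, a.mass, a.serial)
                for a in res.atoms
            ]
        moved = build_iem(parameterized(fx), model).total
        assert np.abs(moved - ref).max() <= 1e-8 * np.abs(ref).max()

    def test_total_ies_are_row_sums(self, helix5):
        iem = build_iem(parameterized(helix5), VACUUM)
        totals = total_ies(iem)
        assert totals["total"] == pytest.approx(iem.total.sum(axis=1))
        # double-counting identity
        assert totals["total"].sum() == pytest.approx(
            2 * np.triu(iem.total).sum()
        )

    def test_two_residue_totals_equal_the_single_pair(self, dipeptide):
        iem = build_iem(parameterized(dipeptide), VACUUM)
        totals = total_ies(iem)["total"]
        assert totals[0] == pytest.approx(iem.total[0, 1])
        assert totals[1] == pytest.approx(iem.total[0, 1])

    def test_unassigned_atom_in_scope_raises(self, write_text):
        from iem import builtin_parameter_set, parse_pdb

        pdb = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00"
            "           N\n"
            "ATOM      2  XQ1 ALA A   1       1.500   0.000   0.000  1.00  0.00"
            "           C\n"
            "ATOM      3  N   ALA A   2       5.000   0.000   0.000  1.00  0.00"
            "           N\nEND\n"
        )
        ps = assign_parameters(
            parse_pdb(write_text("bad.pdb", pdb)), builtin_parameter_set()
        )
        with pytest.raises(ParameterizationError, match="XQ1"):
            build_iem(ps, VACUUM)

    def test_zero_parameters_give_zero_energy(self):
        fx = make_toy_structure(
            FixtureSpec("two_atom", params={"q1": 0.0, "q2": 0.0, "epsilon": 0.0})
        )
        iem = build_iem(parameterized(fx), VACUUM)
        assert iem.total[0, 1] == 0.0


class TestModelRelations:
    def test_gb_with_matching_dielectrics_equals_vacuum(self, helix5):
        ps = parameterized(helix5)
        gb_flat = build_iem(ps, SolventModel("gb", eps_in=1.0, eps_out=1.0))
        vac = build_iem(ps, VACUUM)
        assert np.allclose(gb_flat.total, vac.total, rtol=1e-12, atol=1e-12)

    def test_global_geometry_affects_gb_but_not_vacuum(self):
        """A third residue changes a pair's GB energy via the Born radii."""
        fx2 = make_toy_structure(FixtureSpec("helix", params={"n": 2}))
        fx3 = make_toy_structure(FixtureSpec("helix", params={"n": 3}))
        ps2, ps3 = parameterized(fx2), parameterized(fx3)
        vac2 = build_iem(ps2, VACUUM).total[0, 1]
        vac3 = build_iem(ps3, VACUUM).total[0, 1]
        assert vac2 == pytest.approx(vac3, rel=1e-12)
        gb2 = build_iem(ps2, GB).total[0, 1]
        gb3 = build_iem(ps3, GB).total[0, 1]
        assert abs(gb2 - gb3) > 1e-6


class TestExclusionsAndCutoff:
    def test_ff_policy_removes_bonded_contacts(self, dipeptide):
        ps = parameterized(dipeptide)
        plain = build_iem(ps, VACUUM).total[0, 1]
        excl = build_iem(ps, VACUUM, exclusions="ff").total[0, 1]
        # the 1-2/1-3 steric terms dominate the unexcluded sum
        assert abs(excl) < abs(plain) / 100

    def test_subgroup_restriction_changes_energy(self, dipeptide):
        ps = parameterized(dipeptide)
        full = build_iem(ps, VACUUM).total[0, 1]
        bb = build_iem(ps, VACUUM, subgroup="backbone").total[0, 1]
        sc = build_iem(ps, VACUUM, subgroup="sidechain").total[0, 1]
        assert bb != pytest.approx(full)
        assert sc != pytest.approx(full)

    def test_cutoff_zeroes_distant_pairs(self):
        fx = make_toy_structure(FixtureSpec("helix", params={"n": 4}))
        ps = parameterized(fx)
        iem = build_iem(ps, VACUUM, cutoff=5.0)
        # residues 0 and 3 are ~10 Å apart: every atom pair beyond cutoff
        assert iem.total[0, 3] == 0.0
        assert iem.total[0, 1] != 0.0
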