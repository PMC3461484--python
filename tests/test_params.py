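"""Conversion-engine behaviour: units, torsion forms, pairs, boxes, water."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topoconv import constants as C
from topoconv.errors import (
    MissingParameterError,
    NetChargeError,
    StructuralError,
)
from topoconv.fixtures import generate_toy_system
from topoconv.model import (
    AtomRecord,
    BondTerm,
    BoxSpec,
    LJType,
    MolecularSystem,
    ParameterSource,
    TorsionTerm,
)
from topoconv.params import (
    build_pairs_exclusions,
    classify_torsions,
    convert_box,
    convert_harmonic,
    convert_torsion_f9,
    fourier_to_rb,
    fourier_value,
    guess_net_charge,
    lj_ab_to_sigma_eps,
    recognize_water,
    resolve_parameters,
    sigma_eps_to_ab,
    validate_geometry,
)

GRID = np.linspace(0.0, 2.0 * math.pi, 360, endpoint=False)


class TestConvertHarmonic:
    def test_bond_units_and_half_convention(self):
        # k 100 kcal/A^2 -> 2 * 4.184 * 100 * 100 kJ/nm^2
        assert convert_harmonic(100.0, 1.0, "bond") == pytest.approx((0.1, 83680.0))

    def test_zero_force_constant(self):
        b0, kb = convert_harmonic(0.0, 1.5, "bond")
        assert kb == 0.0 and b0 == pytest.approx(0.15)

    def test_angle_units(self):
        th0, ka = convert_harmonic(63.0, 1.9111, "angle")
        assert th0 == pytest.approx(math.degrees(1.9111), abs=1e-6)
        assert th0 == pytest.approx(109.49, abs=0.01)
        assert ka == pytest.approx(527.184)

    def test_negative_force_constant_rejected(self):
        with pytest.raises(ValueError):
            convert_harmonic(-1.0, 1.0, "bond")

    @pytest.mark.parametrize("kind,eq", [("bond", 1.2), ("angle", 1.9)])
    def test_linearity_in_force_constant(self, kind, eq):
        _, k1 = convert_harmonic(7.0, eq, kind)
        _, k2 = convert_harmonic(14.0, eq, kind)
        assert k2 == pytest.approx(2.0 * k1)


class TestConvertTorsionF9:
    def test_units_and_phase(self):
        term = TorsionTerm((1, 2, 3, 4), barrier_half=1.4, periodicity=2, phase=math.pi)
        assert convert_torsion_f9(term) == pytest.approx((180.0, 5.8576, 2))

    def test_zero_barrier_retained(self):
        term = TorsionTerm((1, 2, 3, 4), barrier_half=0.0, periodicity=3, phase=0.0)
        phase, k, n = convert_torsion_f9(term)
        assert k == 0.0 and n == 3

    def test_linearity(self):
        t1 = TorsionTerm((1, 2, 3, 4), 1.0, 2, 0.0)
        t2 = TorsionTerm((1, 2, 3, 4), 3.0, 2, 0.0)
        assert convert_torsion_f9(t2)[1] == pytest.approx(3 * convert_torsion_f9(t1)[1])


class TestFourierToRB:
    def test_f1_only(self):
        rb = fourier_to_rb([(2.0, 0.0, 1)])
        assert rb.C[0] == pytest.approx(1.0 * C.KCAL_TO_KJ)
        assert rb.C[1] == pytest.approx(-1.0 * C.KCAL_TO_KJ)
        assert rb.C[2:] == pytest.approx((0.0, 0.0, 0.0, 0.0))
        # dense-grid oracle: V(phi) = 1 + cos(phi) kcal/mol
        expected = (1.0 + np.cos(GRID)) * C.KCAL_TO_KJ
        assert np.max(np.abs(rb.value(GRID) - expected)) < 1e-9

    def test_all_zero(self):
        rb = fourier_to_rb([(0.0, 0.0, n) for n in (1, 2, 3, 4)])
        assert rb.C == pytest.approx((0.0,) * 6)

    def test_f3_only(self):
        f3 = 5.0
        rb = fourier_to_rb([(f3, 0.0, 3)])
        assert rb.C[0] == pytest.approx(f3 / 2 * C.KCAL_TO_KJ)
        assert rb.C[1] == pytest.approx(1.5 * f3 * C.KCAL_TO_KJ)
        assert rb.C[3] == pytest.approx(-2.0 * f3 * C.KCAL_TO_KJ)
        expected = fourier_value([(f3, 0.0, 3)], GRID)
        assert np.max(np.abs(rb.value(GRID) - expected)) < 1e-9

    def test_rejects_general_phase(self):
        with pytest.raises(ValueError, match="function-9"):
            fourier_to_rb([(1.0, math.pi / 3, 2)])

    def test_random_series_grid_equivalence(self):
        """100 random Fourier series match their RB form on a 360-point grid."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            series = [
                (float(rng.uniform(0, 20)), float(rng.choice([0.0, math.pi])), n)
                for n in (1, 2, 3, 4)
            ]
            rb = fourier_to_rb(series)
            diff = np.max(np.abs(rb.value(GRID) - fourier_value(series, GRID)))
            worst = max(worst, float(diff))
        assert worst <= 1e-9  # kJ/mol


class TestClassifyTorsions:
    K, N, P = [1.5], [2.0], [math.pi]

    def _one(self, entry):
        return classify_torsions([entry], self.K, self.N, self.P)[0]

    def test_negative_fourth_is_improper(self):
        term = self._one([3, 6, 9, -12, 1])
        assert term.kind == "improper" and not term.generates_14
        assert term.atoms == (2, 3, 4, 5)

    def test_negative_third_suppresses_14(self):
        term = self._one([3, 6, -9, 12, 1])
        assert term.kind == "proper" and not term.generates_14

    def test_plain_entry_generates_14(self):
        term = self._one([3, 6, 9, 12, 1])
        assert term.kind == "proper" and term.generates_14

    def test_negative_first_position_rejected(self):
        with pytest.raises(StructuralError):
            self._one([-3, 6, 9, 12, 1])

    def test_propers_before_impropers(self):
        raw = [[0, 3, 6, -9, 1], [0, 3, 6, 9, 1]]
        terms = classify_torsions(raw, self.K, self.N, self.P)
        assert [t.kind for t in terms] == ["proper", "improper"]


def _bare_system(n, edges, torsion_quartets):
    atoms = [AtomRecord(i, f"C{i}", "c3", 0.0, 12.01, "C") for i in range(1, n + 1)]
    bonds = [BondTerm((i, j), 300.0, 1.5) for i, j in edges]
    torsions = [
        TorsionTerm(q, 0.5, 3, 0.0, "proper", True) for q in torsion_quartets
    ]
    return MolecularSystem(atoms=atoms, bonds=bonds, torsions=torsions,
                           lj_types=[LJType("c3", 1000.0, 30.0)])


def _brute_force_distance3(n, edges):
    """Independent oracle: BFS over the bond graph, no networkx."""
    adj = {i: set() for i in range(1, n + 1)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    pairs = set()
    for start in range(1, n + 1):
        dist = {start: 0}
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for j, d in dist.items():
            if d == 3 and start < j:
                pairs.add((start, j))
    return pairs


class TestPairs14:
    def test_chain4_single_pair(self, chain4):
        pairs, _ = build_pairs_exclusions(chain4)
        assert pairs == [(1, 4)]

    def test_four_ring_has_no_pairs(self):
        edges = [(1, 2), (2, 3), (3, 4), (4, 1)]
        quartets = [(1, 2, 3, 4), (2, 3, 4, 1), (3, 4, 1, 2), (4, 1, 2, 3)]
        system = _bare_system(4, edges, quartets)
        pairs, _ = build_pairs_exclusions(system)
        assert pairs == []
        assert _brute_force_distance3(4, edges) == set()

    def test_ring6_deduplicates_to_para_pairs(self, ring6):
        pairs, _ = build_pairs_exclusions(ring6)
        assert len(pairs) == 3
        assert set(pairs) == {(1, 4), (2, 5), (3, 6)}

    @pytest.mark.parametrize("name", ["water_tip3p", "methane", "chain4", "ring6"])
    def test_equals_brute_force_graph_distance_oracle(self, toy_systems, name):
        system, _ = toy_systems[name]
        pairs, _ = build_pairs_exclusions(system)
        edges = [b.atoms for b in system.bonds]
        assert set(pairs) == _brute_force_distance3(system.n_atoms, edges)

    def test_exclusions_symmetric_and_complete(self, chain4):
        _, excl = build_pairs_exclusions(chain4)
        for i, lst in enumerate(excl, start=1):
            for j in lst:
                assert i in excl[j - 1]
        # chain of 4: everything within 3 bonds of everything else
        assert excl[0] == [2, 3, 4]


class TestLJConversion:
    def test_zero_lj_hydrogen(self):
        assert lj_ab_to_sigma_eps(LJType("ho", 0.0, 0.0)) == (0.0, 0.0)
        assert sigma_eps_to_ab(0.0, 0.0) == (0.0, 0.0)

    def test_a_equals_b_symmetry_case(self):
        sigma, eps = lj_ab_to_sigma_eps(LJType("q", 7.5, 7.5))
        assert sigma == pytest.approx(0.1)
        assert eps == pytest.approx(7.5 * C.KCAL_TO_KJ / 4.0)

    def test_tip3p_oxygen_scale(self):
        sigma, eps = lj_ab_to_sigma_eps(LJType("OW", 582000.0, 595.0))
        assert sigma == pytest.approx(0.3151, abs=2e-4)
        assert eps == pytest.approx(0.636, abs=1e-3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lj_ab_to_sigma_eps((-1.0, 1.0))

    @settings(max_examples=200, derandomize=True)
    @given(
        sigma=st.floats(0.05, 1.0),
        eps=st.floats(1e-6, 10.0),
    )
    def test_round_trip_identity(self, sigma, eps):
        a, b = sigma_eps_to_ab(sigma, eps)
        sigma2, eps2 = lj_ab_to_sigma_eps((a, b))
        assert sigma2 == pytest.approx(sigma, rel=1e-10)
        assert eps2 == pytest.approx(eps, rel=1e-10)


class TestConvertBox:
    def test_truncated_octahedron_norms_and_angles(self):
        box = BoxSpec.from_lengths_angles(
            (20.0, 20.0, 20.0), (109.471219, 109.471219, 109.471219)
        )
        v = convert_box(box)
        for row in v:
            assert np.linalg.norm(row) == pytest.approx(2.0, abs=1e-9)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            cosang = np.dot(v[i], v[j]) / (np.linalg.norm(v[i]) * np.linalg.norm(v[j]))
            assert math.acos(cosang) == pytest.approx(math.acos(-1.0 / 3.0), abs=1e-9)
        # GROMACS-compatible orientation: a along x, off-diagonals negative
        assert v[1][0] < 0 and v[2][0] < 0 and v[2][1] < 0

    def test_orthorhombic_diagonal(self):
        box = BoxSpec("orthorhombic", (10.0, 10.0, 10.0), (90.0, 90.0, 90.0))
        assert convert_box(box) == pytest.approx(np.diag([1.0, 1.0, 1.0]))

    def test_no_box_uses_extent_plus_clearance(self):
        coords = np.array([[0.0, 0.0, 0.0], [10.0, 10.0, 10.0]])  # 1 nm span
        v = convert_box(BoxSpec(), coords, clearance=1.0)
        assert v == pytest.approx(np.diag([3.0, 3.0, 3.0]))


class TestWaterRecognition:
    def test_tip3p(self, water):
        assert recognize_water(water) == "TIP3P"

    def test_spce(self):
        from topoconv.params import load_water_models, sigma_eps_to_ab as to_ab

        model = next(m for m in load_water_models() if m.name == "SPCE")
        a, b = to_ab(model.sigma_o, model.eps_o)
        system = MolecularSystem(
            atoms=[
                AtomRecord(1, "O", "OW", model.q_o, 16.0, "O", "SOL", 1),
                AtomRecord(2, "H1", "HW", model.q_h, 1.008, "H", "SOL", 1),
                AtomRecord(3, "H2", "HW", model.q_h, 1.008, "H", "SOL", 1),
            ],
            lj_types=[LJType("OW", a, b), LJType("HW", 0.0, 0.0)],
        )
        assert recognize_water(system) == "SPCE"

    def test_methane_is_not_water(self, methane):
        assert recognize_water(methane) is None


class TestNetCharge:
    def test_near_integer_rounds(self):
        assert guess_net_charge([-0.5001, -0.5001]) == -1

    def test_empty_list(self):
        assert guess_net_charge([]) == 0

    def test_far_from_integer_errors(self):
        with pytest.raises(NetChargeError):
            guess_net_charge([0.4])

    def test_warning_band(self):
        with pytest.warns(UserWarning, match="rounding"):
            assert guess_net_charge([0.03]) == 0


class TestGeometryFilter:
    def _two_atoms_at(self, d):
        atoms = [
            AtomRecord(1, "C1", "c3", 0.0, 12.01, "C"),
            AtomRecord(2, "H1", "hc", 0.0, 1.008, "H"),
        ]
        return MolecularSystem(
            atoms=atoms,
            bonds=[BondTerm((1, 2), 300.0, 1.1)],
            coordinates=np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]),
        )

    def test_normal_bond_passes(self):
        report = validate_geometry(self._two_atoms_at(1.09))
        assert report.passed and not report.violations

    def test_too_short_flags_min_rule(self):
        report = validate_geometry(self._two_atoms_at(0.3))
        assert not report.passed
        assert report.violations[0][2] == "min_0.5"

    def test_too_long_flags_max_rule(self):
        report = validate_geometry(self._two_atoms_at(3.5))
        assert not report.passed
        assert report.violations[0][2] == "max_3.0"

    def test_requires_coordinates(self, methane):
        import copy

        bare = copy.deepcopy(methane)
        bare.coordinates = None
        with pytest.raises(StructuralError):
            validate_geometry(bare)


def _source(label, with_bond=True):
    src = ParameterSource(label=label)
    src.mass_table = {"c3": (12.01, "C"), "hc": (1.008, "H")}
    if with_bond:
        src.bond_table[("c3", "hc")] = (337.3, 1.093)
    src.angle_table[("hc", "c3", "hc")] = (39.43, math.radians(108.35))
    src.lj_table = {"c3": (1.908, 0.1094), "hc": (1.487, 0.0157)}
    return src


def _methane_connectivity():
    atoms = [AtomRecord(1, "C1", "c3", -0.1048, 12.01, "C")] + [
        AtomRecord(i, f"H{i-1}", "hc", 0.0262, 1.008, "H") for i in range(2, 6)
    ]
    return MolecularSystem(
        atoms=atoms, bond_orders=[(1, i, "1") for i in range(2, 6)]
    )


class TestParameterFallback:
    def test_first_source_wins(self):
        system = _methane_connectivity()
        prov = resolve_parameters(system, [_source("primary"), _source("fallback")])
        assert prov["bond:c3-hc"] == "primary"

    def test_falls_back_when_primary_lacks_key(self):
        system = _methane_connectivity()
        prov = resolve_parameters(
            system, [_source("primary", with_bond=False), _source("fallback")]
        )
        assert prov["bond:c3-hc"] == "fallback"
        assert prov["angle:hc-c3-hc"] == "primary"

    def test_missing_everywhere_names_the_tuple(self):
        system = _methane_connectivity()
        primary = _source("primary", with_bond=False)
        fallback = _source("fallback", with_bond=False)
        with pytest.raises(MissingParameterError, match="c3.*hc"):
            resolve_parameters(system, [primary, fallback])

    def test_wildcard_after_exact(self):
        src = ParameterSource(label="s")
        src.mass_table = {"c3": (12.01, "C")}
        src.bond_table[("c3", "c3")] = (303.1, 1.535)
        src.angle_table[("c3", "c3", "c3")] = (63.21, math.radians(110.63))
        src.lj_table = {"c3": (1.908, 0.1094)}
        exact_key = ("c3", "c3", "c3", "c3")
        src.torsion_table[ParameterSource.torsion_key(*exact_key)] = [(0.9, 0.0, 3)]
        src.torsion_table[ParameterSource.torsion_key("X", "c3", "c3", "X")] = [
            (0.1, 0.0, 3)
        ]
        atoms = [AtomRecord(i, f"C{i}", "c3", 0.0, 12.01, "C") for i in range(1, 5)]
        system = MolecularSystem(
            atoms=atoms, bond_orders=[(1, 2, "1"), (2, 3, "1"), (3, 4, "1")]
        )
        resolve_parameters(system, [src])
        assert system.torsions[0].barrier_half == pytest.approx(0.9)
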