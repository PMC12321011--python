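"""Lattice math and allowed-reflection tables.

The extinction-rule tables are cross-checked against gemmi's space-group
machinery (an independent crystallographic implementation) and against
brute-force Miller-index enumeration.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesosaxs.phases import (
    LatticeEstimate,
    MesophaseModel,
    Phase,
    Reflection,
    lattice_from_assignments,
    reflection_positions,
)

TAU = 2 * math.pi


class TestReflectionTables:
    @pytest.mark.parametrize("name, expected_m2", [
        ("lamellar", [1, 4, 9, 16, 25, 36]),
        ("Pn3m", [2, 3, 4, 6, 8, 9]),
        ("Im3m", [2, 4, 6, 8, 10, 12]),
        ("hexagonal", [1, 3, 4, 7, 9, 12]),
    ])
    def test_ratio_sequences(self, name, expected_m2):
        model = MesophaseModel.create(name)
        assert np.allclose(model.ratios**2, expected_m2)

    def test_pn3m_omits_forbidden_classes(self):
        m2 = set(np.round(MesophaseModel.create("Pn3m", 12).ratios ** 2).astype(int))
        assert not {1, 5, 7} & m2

    def test_im3m_body_centring(self):
        for refl in MesophaseModel.create("Im3m", 10).reflections:
            assert (refl.h + refl.k + refl.l) % 2 == 0

    @pytest.mark.parametrize("sg_name, phase", [("P n -3 m", "Pn3m"),
                                                ("I m -3 m", "Im3m")])
    def test_cubic_tables_match_gemmi(self, sg_name, phase):
        """Independent oracle: gemmi systematic-absence machinery."""
        gemmi = pytest.importorskip("gemmi")
        ops = gemmi.SpaceGroup(sg_name).operations()
        allowed_m2 = set()
        for h in range(0, 7):
            for k in range(0, 7):
                for l in range(0, 7):
                    if h == k == l == 0:
                        continue
                    if not ops.is_systematically_absent([h, k, l]):
                        allowed_m2.add(h * h + k * k + l * l)
        expected = sorted(allowed_m2)[:6]
        got = list(np.round(MesophaseModel.create(phase).ratios ** 2).astype(int))
        assert got == expected

    def test_reflections_strictly_ascending(self):
        for name in Phase:
            ms = MesophaseModel.create(name, 8).ratios
            assert np.all(np.diff(ms) > 0)


class TestReflectionPositions:
    def test_lamellar_unit_repeat(self):
        # d = 2*pi makes q_n = n exactly
        model = MesophaseModel.create("lamellar")
        got = reflection_positions(model, TAU, (0.5, 3.5))
        assert [round(q, 12) for _, q in got] == [1.0, 2.0, 3.0]
        assert [r.h for r, _ in got] == [1, 2, 3]

    def test_pn3m_ratio_values(self):
        model = MesophaseModel.create("Pn3m")
        got = [q for _, q in reflection_positions(model, TAU, (1.0, 2.1))]
        assert np.allclose(got, [math.sqrt(2), math.sqrt(3), 2.0])

    def test_im3m_matches_brute_force_enumeration(self):
        """Oracle: enumerate all hkl with h+k+l even, dedupe by m^2."""
        a = 12.7
        m2s = set()
        for h in range(0, 8):
            for k in range(0, 8):
                for l in range(0, 8):
                    if (h, k, l) != (0, 0, 0) and (h + k + l) % 2 == 0:
                        m2s.add(h * h + k * k + l * l)
        expected = sorted(TAU * math.sqrt(m2) / a for m2 in m2s)
        expected = [q for q in expected if 0.5 <= q <= 4.5][:6]
        model = MesophaseModel.create("Im3m")
        got = [q for _, q in reflection_positions(model, a, (0.5, 4.5))]
        assert np.allclose(got, expected[:len(got)])
        assert len(got) == len(expected)

    def test_invalid_lattice_rejected(self):
        model = MesophaseModel.create("lamellar")
        with pytest.raises(ValueError):
            reflection_positions(model, -1.0)
        with pytest.raises(ValueError):
            reflection_positions(model, 6.0, (2.0, 1.0))

    @pytest.mark.parametrize("phase, hkl_hi, hkl_lo, ratio", [
        ("Pn3m", (1, 1, 1), (1, 1, 0), math.sqrt(3 / 2)),
        ("Im3m", (2, 0, 0), (1, 1, 0), math.sqrt(2)),
        ("lamellar", (2, 0, 0), (1, 0, 0), 2.0),
    ])
    def test_ratio_invariance(self, phase, hkl_hi, hkl_lo, ratio):
        model = MesophaseModel.create(phase)
        for a in (6.34, 11.6, 29.1):
            qs = {(r.h, r.k, r.l): q
                  for r, q in reflection_positions(model, a, (1e-6, 1e6))}
            assert qs[hkl_hi] / qs[hkl_lo] == pytest.approx(ratio, rel=1e-14)


class TestLatticeRegression:
    def test_noiseless_pn3m_consistency(self):
        a = 11.6
        assigned = [
            (TAU * math.sqrt(2) / a, Reflection.cubic(1, 1, 0)),
            (TAU * math.sqrt(3) / a, Reflection.cubic(1, 1, 1)),
            (TAU * 2 / a, Reflection.cubic(2, 0, 0)),
        ]
        est = lattice_from_assignments(assigned)
        assert est.a == pytest.approx(a, rel=1e-12)
        assert est.residual_rms == pytest.approx(0.0, abs=1e-12)
        assert est.n_peaks == 3

    def test_two_peak_closed_form(self):
        # oracle: unweighted through-origin regression slope
        # s = sum(m*q)/sum(m^2) computed by hand
        q1, q2 = 0.99, 2.01
        s = (1 * q1 + 2 * q2) / (1 + 4)
        expected_a = TAU / s
        est = lattice_from_assignments([
            (q1, Reflection.lamellar(1)), (q2, Reflection.lamellar(2))])
        assert est.a == pytest.approx(expected_a, rel=1e-12)

    def test_single_peak_error_propagation(self):
        est = lattice_from_assignments([((1.000, 0.010), Reflection.lamellar(1))])
        assert est.a == pytest.approx(TAU, rel=1e-12)
        assert est.sigma_a == pytest.approx(TAU * 0.010 / 1.000, rel=1e-9)

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            lattice_from_assignments([])
        with pytest.raises(ValueError):
            lattice_from_assignments([(-1.0, Reflection.lamellar(1))])
        with pytest.raises(ValueError):
            Reflection(1, 0, 0, m=-2.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=st.floats(min_value=1.0, max_value=50.0),
           phase=st.sampled_from(["lamellar", "Pn3m", "Im3m", "hexagonal"]))
    def test_round_trip_property(self, a, phase):
        model = MesophaseModel.create(phase)
        positions = reflection_positions(model, a, (1e-9, 1e9))
        est = lattice_from_assignments([(q, r) for r, q in positions])
        assert est.a == pytest.approx(a, rel=1e-12)

    def test_scale_equivariance(self):
        model = MesophaseModel.create("Pn3m")
        positions = reflection_positions(model, 11.6, (0.5, 4.5))
        base = lattice_from_assignments([(q, r) for r, q in positions]).a
        c = 1.7
        scaled = lattice_from_assignments([(q * c, r) for r, q in positions]).a
        assert scaled == pytest.approx(base / c, rel=1e-12)

    def test_sigma_reported_nonnegative(self):
        est = lattice_from_assignments([
            ((1.0, 0.01), Reflection.lamellar(1)),
            ((2.003, 0.01), Reflection.lamellar(2)),
        ])
        assert est.sigma_a > 0

    def test_lattice_estimate_invariants(self):
        with pytest.raises(ValueError):
            LatticeEstimate(a=-1.0, sigma_a=0.1, residual_rms=0, n_peaks=1)
        with pytest.raises(ValueError):
            LatticeEstimate(a=1.0, sigma_a=-0.1, residual_rms=0, n_peaks=1)
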