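"""Coulomb surrogate, barrier differences, probe laws, and the Eyring link."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsscan.constants import COULOMB_CONSTANT, KB_OVER_H
from tsscan.energetics import (
    ClashError,
    EnergyModel,
    coulomb_interaction,
    dg_from_rate,
    rate_from_dg,
    scan,
    state_barrier,
)
from tsscan.mutagenesis import (
    ALA_PLUS_PROBE,
    NULL_PERTURBATION,
    Perturbation,
    apply_mutation,
    MutantSpec,
)
from tsscan.structures import REACT, TS1, AtomRecord, StateStructure, pair_states
from tsscan.synthetic import naive_coulomb


def _dipole_pair(env_spec):
    """Two QM sites 4 Å apart; site A gains −0.5 e, site B +0.5 e at TS."""
    def build(label):
        delta = 0.5 if label == TS1 else 0.0
        qm = [
            AtomRecord("A1", "O", "QMX", "X", 1, (0.0, 0.0, 0.0),
                       -0.2 - delta, region="QM"),
            AtomRecord("B1", "S", "QMX", "X", 1, (4.0, 0.0, 0.0),
                       0.2 + delta, region="QM"),
        ]
        env = [AtomRecord(name, "C", "ENV", "A", 10 + i, coords, q)
               for i, (name, coords, q) in enumerate(env_spec)]
        return StateStructure(label, qm + env,
                              qm_selection=frozenset(a.key for a in qm))
    return pair_states(build(REACT), build(TS1), "X:1:A1", "X:1:B1")


class TestCoulombInteraction:
    def test_unit_charges_one_angstrom(self):
        e = coulomb_interaction([(0, 0, 0)], [1.0], [(1, 0, 0)], [1.0])
        assert e == pytest.approx(COULOMB_CONSTANT, abs=1e-12)

    def test_empty_set_gives_zero(self):
        assert coulomb_interaction([(0, 0, 0)], [1.0],
                                   np.empty((0, 3)), []) == 0.0

    def test_clash_guard(self):
        with pytest.raises(ClashError):
            coulomb_interaction([(0, 0, 0)], [1.0], [(0.01, 0, 0)], [1.0])

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(1, 30, size=2)
        pos_a = rng.uniform(-10, 10, (na, 3))
        pos_b = rng.uniform(11, 30, (nb, 3))
        q_a = rng.uniform(-1, 1, na)
        q_b = rng.uniform(-1, 1, nb)
        fast = coulomb_interaction(pos_a, q_a, pos_b, q_b)
        slow = naive_coulomb(zip(pos_a.tolist(), q_a.tolist()),
                             zip(pos_b.tolist(), q_b.tolist()))
        assert fast == pytest.approx(slow, abs=1e-9)


class TestStateBarrier:
    def test_null_perturbation_gives_zero_exactly(self, toy_pair):
        result = state_barrier(toy_pair, (NULL_PERTURBATION,
                                          NULL_PERTURBATION))
        assert result.ddE == 0.0

    def test_removing_zero_charges_gives_zero(self):
        pair = _dipole_pair([("C1", (2.0, 3.0, 0.0), 0.0),
                             ("C2", (1.0, -2.0, 1.0), 0.0)])
        pert = Perturbation(removed_atom_keys=frozenset({("A", 10, "C1")}))
        assert state_barrier(pair, (pert, pert)).ddE == pytest.approx(0.0)

    def test_deleting_stabilizing_charge_raises_barrier(self):
        """+1 e at 3 Å from the site turning negative, 5 Å from the other:
        deleting it raises the barrier by 332.0637·(0.5/3 − 0.5/5)."""
        pos = (0.0, 3.0, 0.0)  # 3 Å from A1, 5 Å from B1 (3-4-5 triangle)
        pair = _dipole_pair([("P1", pos, 1.0)])
        pert = Perturbation(removed_atom_keys=frozenset({("A", 10, "P1")}))
        expected = -COULOMB_CONSTANT * (-0.5 / 3.0 + 0.5 / 5.0)
        result = state_barrier(pair, (pert, pert))
        assert result.ddE == pytest.approx(expected, abs=1e-9)
        assert result.ddE == pytest.approx(22.1376, abs=1e-3)

    @given(st.floats(-2.0, 2.0))
    @settings(max_examples=30, deadline=None)
    def test_probe_linearity_in_charge(self, q):
        pair = _dipole_pair([("C1", (2.0, 3.0, 0.0), 0.1)])
        pos = (1.3, 2.7, 0.4)
        unit = state_barrier(pair, tuple(
            Perturbation(probe=(pos, 1.0)) for _ in range(2))).ddE
        scaled = state_barrier(pair, tuple(
            Perturbation(probe=(pos, q)) for _ in range(2))).ddE
        assert scaled == pytest.approx(q * unit, abs=1e-9)

    def test_probe_antisymmetry(self, toy_pair):
        pos = (2.0, 4.0, 1.0)
        plus = state_barrier(toy_pair, tuple(
            Perturbation(probe=(pos, 1.0)) for _ in range(2))).ddE
        minus = state_barrier(toy_pair, tuple(
            Perturbation(probe=(pos, -1.0)) for _ in range(2))).ddE
        assert plus == pytest.approx(-minus, abs=1e-12)

    def test_equidistant_probe_is_null(self):
        pair = _dipole_pair([("C1", (2.0, 6.0, 0.0), 0.3)])
        pos = (2.0, 3.3, 1.7)  # on the bisecting plane x = 2
        ddE = state_barrier(pair, tuple(
            Perturbation(probe=(pos, 1.0)) for _ in range(2))).ddE
        assert abs(ddE) <= 1e-9

    def test_include_env_env_cancels_for_shared_environment(self):
        """Environment self-terms are state-independent here, so ΔΔE‡ is
        unchanged when they are included."""
        pair = _dipole_pair([("C1", (2.0, 3.0, 0.0), 0.4),
                             ("C2", (2.0, -3.0, 0.0), -0.3)])
        pert = Perturbation(removed_atom_keys=frozenset({("A", 10, "C1")}))
        base = state_barrier(pair, (pert, pert)).ddE
        full = state_barrier(pair, (pert, pert),
                             EnergyModel(include_env_env=True)).ddE
        assert full == pytest.approx(base, abs=1e-9)


class TestScan:
    def test_records_match_individual_state_barriers(self, toy_pair,
                                                     toy_answers):
        residues = sorted(toy_answers.per_residue)
        records = scan(toy_pair, residues)
        assert [r.residue_id for r in records] == residues
        for rec in records[:3]:
            spec = MutantSpec(rec.residue_id, scheme=ALA_PLUS_PROBE,
                              probe_charge=+1.0)
            direct = state_barrier(toy_pair, apply_mutation(toy_pair, spec))
            assert rec.ddE_probe_pos == pytest.approx(direct.ddE, abs=1e-12)

    def test_planted_signs_and_order_recovered(self, toy_pair, toy_answers):
        records = scan(toy_pair, sorted(toy_answers.per_residue))
        by_id = {r.residue_id: r for r in records}
        for rid, answer in toy_answers.per_residue.items():
            assert by_id[rid].ddE_ala == pytest.approx(answer["ALA"],
                                                       abs=1e-9)
        # the Asp planted near O_p is the best alanine candidate
        best = min(records, key=lambda r: r.ddE_ala)
        assert by_id[best.residue_id].residue_name == "ASP"

    def test_failures_are_quarantined(self, toy_pair):
        records = scan(toy_pair, [("A", 101), ("A", 999)])
        by_id = {r.residue_id: r for r in records}
        assert by_id[("A", 999)].error is not None
        assert by_id[("A", 101)].error is None
        assert math.isfinite(by_id[("A", 101)].ddE_ala)


class TestEyring:
    def test_experimental_turnover_reproduces_barrier(self):
        """k_cat = 1.6 min⁻¹ at 310 K corresponds to ΔG‡ = 20.4 kcal/mol."""
        assert dg_from_rate(1.6 / 60.0, 310.0) == pytest.approx(20.4,
                                                                abs=0.05)

    def test_prefactor_rate_gives_zero_barrier(self):
        T = 298.15
        assert dg_from_rate(KB_OVER_H * T, T) == pytest.approx(0.0,
                                                               abs=1e-12)

    @given(st.floats(1e-6, 1e6), st.floats(200.0, 400.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_exact(self, rate, temperature):
        back = rate_from_dg(dg_from_rate(rate, temperature), temperature)
        assert back == pytest.approx(rate, rel=1e-10)

    @pytest.mark.parametrize("rate,temp", [(-1.0, 300.0), (0.0, 300.0),
                                           (1.0, 0.0), (1.0, -5.0)])
    def test_nonpositive_inputs_rejected(self, rate, temp):
        with pytest.raises(ValueError):
            dg_from_rate(rate, temp)
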