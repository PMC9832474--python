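"""Electrostatic-embedding barrier surrogate and transition-state-theory link.

The activation energy of the frozen pair is modelled by the Coulomb
interaction between the QM-region charges (which differ between REACT and
TS1, encoding the charge flow of the reaction) and the environment point
charges:

    E_int(state) = k_C · Σ_i Σ_j  q_i(state) q_j / r_ij
    ΔE‡          = E_int(TS1) − E_int(REACT)
    ΔΔE‡         = ΔE‡(mutant) − ΔE‡(wild type)

With frozen geometries and state-independent environment charges, only the
QM charge *shift* couples to the perturbation — exactly the macrodipole
picture: a point charge closer to the site that gains electron density at
the TS stabilizes (or destabilizes) the barrier according to its sign.

The Eyring relation converts between turnover rates and Gibbs activation
energies with unit transmission coefficient:

    ΔG‡ = R·T·ln(k_B·T / (h·k))
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .constants import (
    COULOMB_CONSTANT,
    DEFAULT_MIN_DISTANCE_GUARD,
    GAS_CONSTANT,
    KB_OVER_H,
)
from .mutagenesis import (
    ALA_PLUS_PROBE,
    ALA_TRUNCATE,
    MutantSpec,
    NULL_PERTURBATION,
    Perturbation,
    apply_mutation,
)
from .structures import StatePair, StateStructure

MODE_ALA = "ALA"
MODE_PROBE_POS = "PROBE_POS"
MODE_PROBE_NEG = "PROBE_NEG"
ALL_MODES = (MODE_ALA, MODE_PROBE_POS, MODE_PROBE_NEG)


class ClashError(ValueError):
    """A pair of point charges is closer than the minimum-distance guard."""


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the Coulomb surrogate.

    ``include_env_env`` adds the environment-internal terms touched by a
    perturbation (they cancel from ΔΔE‡ whenever the environment charges are
    state-independent, which is the default setup).  ``min_distance_guard``
    rejects unphysically close charge pairs, e.g. a probe clashing with an
    atom.
    """

    coulomb_constant: float = COULOMB_CONSTANT
    include_env_env: bool = False
    min_distance_guard: float = DEFAULT_MIN_DISTANCE_GUARD

    def __post_init__(self) -> None:
        if self.min_distance_guard <= 0:
            raise ValueError("min_distance_guard must be positive")


@dataclass(frozen=True)
class BarrierResult:
    """Wild-type and mutant activation energies and their difference.

    ``ddE`` is the primary quantity, computed directly from the
    perturbation's interaction terms (so probe antisymmetry and linearity
    are exact in floating point); the mutant barrier is derived from it.
    """

    dE_act_wt: float
    ddE: float

    @property
    def dE_act_mut(self) -> float:
        return self.dE_act_wt + self.ddE


def coulomb_interaction(pos_a: np.ndarray, q_a: np.ndarray,
                        pos_b: np.ndarray, q_b: np.ndarray,
                        model: EnergyModel = EnergyModel()) -> float:
    """Exact Coulomb interaction between two disjoint charge sets (kcal·mol⁻¹).

    No cutoffs, no dielectric: ε = 1 vacuum point-charge embedding.
    """
    pos_a = np.atleast_2d(np.asarray(pos_a, dtype=float))
    pos_b = np.atleast_2d(np.asarray(pos_b, dtype=float))
    q_a = np.atleast_1d(np.asarray(q_a, dtype=float))
    q_b = np.atleast_1d(np.asarray(q_b, dtype=float))
    if q_a.size == 0 or q_b.size == 0:
        return 0.0
    dist = cdist(pos_a, pos_b)
    dmin = dist.min()
    if dmin < model.min_distance_guard:
        raise ClashError(
            f"charge pair at {dmin:.4f} Å, below the "
            f"{model.min_distance_guard} Å guard"
        )
    return float(model.coulomb_constant * q_a @ (1.0 / dist) @ q_b)


def _environment_after(state: StateStructure, pert: Perturbation,
                       shared_keys: set | None) -> tuple[np.ndarray, np.ndarray]:
    """Environment positions/charges of one state after a perturbation.

    Atoms present in only one state (orphans of the pairing) are excluded so
    that REACT and TS1 sums run over corresponding charge sets.
    """
    pos, q = [], []
    for a in state.env_atoms():
        if shared_keys is not None and a.key not in shared_keys:
            continue
        if a.key in pert.removed_atom_keys:
            continue
        pos.append(a.coords)
        q.append(pert.charge_edits.get(a.key, a.charge))
    for p, charge in pert.added_charges:
        pos.append(p)
        q.append(charge)
    return np.array(pos, dtype=float).reshape(-1, 3), np.array(q, dtype=float)


def _touched_env_delta(state: StateStructure, pert: Perturbation,
                       shared_keys: set | None, model: EnergyModel) -> float:
    """Change in environment-internal energy caused by the perturbation.

    Only pairs with at least one touched charge (removed, re-charged, added,
    or the probe) can change, so the sum is restricted to those.
    """
    touched = set(pert.removed_atom_keys) | set(pert.charge_edits)
    untouched_pos, untouched_q = [], []
    before_pos, before_q, after_q = [], [], []
    for a in state.env_atoms():
        if shared_keys is not None and a.key not in shared_keys:
            continue
        if a.key in touched:
            before_pos.append(a.coords)
            before_q.append(a.charge)
            after_q.append(0.0 if a.key in pert.removed_atom_keys
                           else pert.charge_edits.get(a.key, a.charge))
        else:
            untouched_pos.append(a.coords)
            untouched_q.append(a.charge)
    new_pos = [p for p, _ in pert.added_charges]
    new_q = [c for _, c in pert.added_charges]
    if pert.probe is not None:
        new_pos.append(pert.probe[0])
        new_q.append(pert.probe[1])

    def pairwise(pos, q):
        pos = np.asarray(pos, float).reshape(-1, 3)
        q = np.asarray(q, float)
        if len(q) < 2:
            return 0.0
        dist = cdist(pos, pos)
        iu = np.triu_indices(len(q), k=1)
        d = dist[iu]
        if d.min() < model.min_distance_guard:
            raise ClashError("internal charge pair below distance guard")
        return float(model.coulomb_constant * np.sum(
            q[iu[0]] * q[iu[1]] / d))

    def cross(pa, qa, pb, qb):
        if len(qa) == 0 or len(qb) == 0:
            return 0.0
        return coulomb_interaction(pa, qa, pb, qb, model)

    e_before = (pairwise(before_pos, before_q)
                + cross(before_pos, before_q, untouched_pos, untouched_q))
    after_pos = before_pos + new_pos
    after_all_q = after_q + new_q
    e_after = (pairwise(after_pos, after_all_q)
               + cross(after_pos, after_all_q, untouched_pos, untouched_q))
    return e_after - e_before


def _state_interaction(state: StateStructure, pert: Perturbation,
                       shared_keys: set | None, model: EnergyModel) -> float:
    """Full QM↔environment interaction of one (possibly perturbed) state."""
    qm = state.qm_atoms()
    qm_pos = np.array([a.coords for a in qm], dtype=float)
    qm_q = np.array([a.charge for a in qm], dtype=float)
    env_pos, env_q = _environment_after(state, pert, shared_keys)
    e = coulomb_interaction(qm_pos, qm_q, env_pos, env_q, model)
    if pert.probe is not None:
        pos, q = pert.probe
        e += coulomb_interaction(qm_pos, qm_q, [pos], [q], model)
    if model.include_env_env:
        e += _touched_env_delta(state, pert, shared_keys, model)
    return e


def _perturbation_delta(state: StateStructure, pert: Perturbation,
                        shared_keys: set | None, model: EnergyModel) -> float:
    """E_int(perturbed) − E_int(wild type) for one state, term by term.

    Only the charges the perturbation touches enter the sum, so the
    wild-type contribution cancels *structurally* rather than numerically:
    a probe of charge −q contributes exactly the negative of a +q probe,
    and a null perturbation contributes exactly zero.
    """
    qm = state.qm_atoms()
    qm_pos = np.array([a.coords for a in qm], dtype=float)
    qm_q = np.array([a.charge for a in qm], dtype=float)
    delta = 0.0
    if pert.removed_atom_keys or pert.charge_edits:
        pos, dq = [], []
        for key in sorted(pert.removed_atom_keys):
            atom = state.atom(key)
            pos.append(atom.coords)
            dq.append(-atom.charge)
        for key in sorted(pert.charge_edits):
            if key in pert.removed_atom_keys:
                continue
            atom = state.atom(key)
            pos.append(atom.coords)
            dq.append(pert.charge_edits[key] - atom.charge)
        delta += coulomb_interaction(qm_pos, qm_q, pos, dq, model)
    if pert.added_charges:
        pos = [p for p, _ in pert.added_charges]
        q = [c for _, c in pert.added_charges]
        delta += coulomb_interaction(qm_pos, qm_q, pos, q, model)
    if pert.probe is not None:
        pos, q = pert.probe
        env = [a for a in state.env_atoms()
               if (shared_keys is None or a.key in shared_keys)
               and a.key not in pert.removed_atom_keys]
        if env:
            env_pos = np.array([a.coords for a in env], dtype=float)
            if cdist(env_pos, [pos]).min() < model.min_distance_guard:
                raise ClashError("probe clashes with an environment atom")
        delta += coulomb_interaction(qm_pos, qm_q, [pos], [q], model)
    if model.include_env_env:
        delta += _touched_env_delta(state, pert, shared_keys, model)
    return delta


def state_barrier(pair: StatePair,
                  perturbation_pair: tuple[Perturbation, Perturbation],
                  model: EnergyModel = EnergyModel()) -> BarrierResult:
    """Activation energy of the perturbed pair relative to the wild type.

    ΔΔE‡ is assembled from the perturbation's own interaction terms in the
    two states; the wild-type barrier is reported alongside it.
    """
    pert_react, pert_ts = perturbation_pair
    shared = set(pair.correspondence)
    e_wt_react = _state_interaction(pair.react, NULL_PERTURBATION, shared, model)
    e_wt_ts = _state_interaction(pair.ts, NULL_PERTURBATION, shared, model)
    d_react = _perturbation_delta(pair.react, pert_react, shared, model)
    d_ts = _perturbation_delta(pair.ts, pert_ts, shared, model)
    return BarrierResult(dE_act_wt=e_wt_ts - e_wt_react, ddE=d_ts - d_react)


@dataclass
class ScanEnergies:
    """Per-residue ΔΔE‡ values from one scan (NaN where a mode failed)."""

    residue_id: tuple[str, int]
    residue_name: str
    ddE_ala: float = math.nan
    ddE_probe_pos: float = math.nan
    ddE_probe_neg: float = math.nan
    error: str | None = None


def scan(pair: StatePair, shell, model: EnergyModel = EnergyModel(),
         modes: tuple[str, ...] = ALL_MODES,
         truncation_mode: str = "ZERO_SIDECHAIN",
         n_jobs: int = 1) -> list[ScanEnergies]:
    """Run the alanine / ±1e probe scan over every shell residue.

    Residues are processed in deterministic (chain, number) order;
    per-residue computations are independent, so ``n_jobs > 1`` runs them in
    a thread pool with results identical to serial execution.  A failure on
    one residue is recorded on its record and the scan continues.
    """
    bad = set(modes) - set(ALL_MODES)
    if bad:
        raise ValueError(f"unknown scan modes: {sorted(bad)}")

    residues = sorted(shell)

    def one(residue_id) -> ScanEnergies:
        rec = ScanEnergies(residue_id=residue_id, residue_name="???")
        try:
            rec.residue_name = pair.react.residue_name(residue_id)
            specs: list[tuple[str, MutantSpec]] = []
            if MODE_ALA in modes:
                specs.append(("ddE_ala", MutantSpec(
                    residue_id, scheme=ALA_TRUNCATE,
                    truncation_mode=truncation_mode)))
            if MODE_PROBE_POS in modes:
                specs.append(("ddE_probe_pos", MutantSpec(
                    residue_id, scheme=ALA_PLUS_PROBE, probe_charge=+1.0,
                    truncation_mode=truncation_mode)))
            if MODE_PROBE_NEG in modes:
                specs.append(("ddE_probe_neg", MutantSpec(
                    residue_id, scheme=ALA_PLUS_PROBE, probe_charge=-1.0,
                    truncation_mode=truncation_mode)))
            for attr, spec in specs:
                perts = apply_mutation(pair, spec)
                result = state_barrier(pair, perts, model)
                setattr(rec, attr, result.ddE)
        except Exception as exc:  # quarantine, keep scanning
            rec.error = f"{type(exc).__name__}: {exc}"
        return rec

    if n_jobs > 1:
        with ThreadPoolExecutor(max_workers=n_jobs) as pool:
            return list(pool.map(one, residues))
    return [one(r) for r in residues]


# ---------------------------------------------------------------------------
# transition-state theory
# ---------------------------------------------------------------------------

def dg_from_rate(rate: float, temperature: float) -> float:
    """Gibbs activation energy (kcal·mol⁻¹) from a rate constant (s⁻¹).

    Eyring with transmission coefficient 1:  ΔG‡ = R·T·ln(k_B·T/(h·k)).
    """
    if rate <= 0 or temperature <= 0:
        raise ValueError("rate and temperature must be positive")
    return GAS_CONSTANT * temperature * math.log(
        KB_OVER_H * temperature / rate)


def rate_from_dg(dg_act: float, temperature: float) -> float:
    """Rate constant (s⁻¹) from a Gibbs activation energy (kcal·mol⁻¹)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return KB_OVER_H * temperature * math.exp(
        -dg_act / (GAS_CONSTANT * temperature))
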