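"""Analytically solvable synthetic fixtures.

Everything the other modules consume can be generated here without any
external data: a toy active site whose reactant→TS charge shift forms a
dipole (electron density moving onto an O_p-like oxygen and off an S-like
sulfur), shells of residues of every chemical class placed at *exact*
prescribed distances from the two sites, and toy multiple sequence
alignments with controlled column conservation.

Every toy pair ships with an answer sheet of exact ΔΔE‡ values computed by a
deliberately naive double-loop Coulomb summation — an oracle written
independently of the vectorized energetics code so the two can cross-check
each other.  Residue geometry is idealized (zig-zag side chains, planar-ish
backbone); realistic stereochemistry is out of scope and unnecessary for the
electrostatics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import (
    AA3_TO_1,
    ATOMIC_WEIGHTS,
    CHARGED_GROUP_ATOMS,
    COULOMB_CONSTANT,
)
from .structures import (
    REACT,
    TS1,
    AtomRecord,
    ResidueId,
    StatePair,
    StateStructure,
    pair_states,
)

MIN_PLACEMENT_SEPARATION = 1.5  # Å, between atoms of different residues


class ClashingLayoutError(ValueError):
    """Residue placement puts atoms closer than the allowed separation."""


class InfeasibleLayoutError(ValueError):
    """No point can be at the two requested distances from the sites."""


# ---------------------------------------------------------------------------
# residue template library (idealized geometry, fixture charges)
# ---------------------------------------------------------------------------

# Backbone heavy atoms: local coordinates (CA at origin) and fixture charges
# that sum to exactly zero.
_BACKBONE = [
    ("N", "N", (-1.20, 0.85, 0.00), -0.25),
    ("CA", "C", (0.00, 0.00, 0.00), 0.25),
    ("C", "C", (1.35, 0.75, 0.00), 0.45),
    ("O", "O", (1.45, 1.95, 0.20), -0.45),
]

# Side-chain topology: (atom, element, parent, placement) where placement is
# "chain" (extend away from the backbone) or "branch±" (fork sideways).
_SIDE_TOPOLOGY: dict[str, list[tuple[str, str, str, str]]] = {
    # Gly/Ala/Pro exist for shell-rule fixtures; they are never mutable.
    "GLY": [],
    "ALA": [("CB", "C", "CA", "chain")],
    "PRO": [("CB", "C", "CA", "chain"), ("CG", "C", "CB", "chain"),
            ("CD", "C", "CG", "chain")],
    "SER": [("CB", "C", "CA", "chain"), ("OG", "O", "CB", "chain")],
    "THR": [("CB", "C", "CA", "chain"), ("OG1", "O", "CB", "branch+"),
            ("CG2", "C", "CB", "branch-")],
    "CYS": [("CB", "C", "CA", "chain"), ("SG", "S", "CB", "chain")],
    "VAL": [("CB", "C", "CA", "chain"), ("CG1", "C", "CB", "branch+"),
            ("CG2", "C", "CB", "branch-")],
    "LEU": [("CB", "C", "CA", "chain"), ("CG", "C", "CB", "chain"),
            ("CD1", "C", "CG", "branch+"), ("CD2", "C", "CG", "branch-")],
    "ILE": [("CB", "C", "CA", "chain"), ("CG1", "C", "CB", "branch+"),
            ("CG2", "C", "CB", "branch-"), ("CD1", "C", "CG1", "chain")],
    "MET": [("CB", "C", "CA", "chain"), ("CG", "C", "CB", "chain"),
            ("SD", "S", "CG", "chain"), ("CE", "C", "SD", "chain")],
    "PHE": [("CB", "C", "CA", "chain"), ("CG", "C", "CB", "chain"),
            ("CD1", "C", "CG", "branch+"), ("CD2", "C", "CG", "branch-"),
            ("CE1", "C", "CD1", "chain"), ("CE2", "C", "CD2", "chain"),
            ("CZ", "C", "CE1", "branch-")],
    "TYR": [("CB", "C", "CA", "chain"), ("CG", "C", "CB", "chain"),
            ("CD1", "C", "CG", "branch+"), ("CD2", "C", "CG", "branch-"),
            ("CE1", "C", "CD1", "chain"), ("CE2", "C", "CD2", "chain"),
            ("CZ", "C", "CE1", "branch-"), ("OH", "O", "CZ", "chain")],
    "TRP": [("CB", "C", "CA", "chain"), ("CG", "C", "CB", "chain"),
            ("CD1", "C", "CG", "branch+"), ("CD2", "C", "CG", "branch-"),
            ("NE1", "N", "CD1", "chain"), ("CE2", "C", "CD2", "chain"),
            ("CE3", "C", "CD2", "branch-"), ("CZ2", "C", "CE2", "chain"),
            ("CZ3", "C", "CE3", "chain"), ("CH2", "C", "CZ2", "branch-")],
    "ASN": [("CB", "C", "CA", "chain"), ("CG", "C", "CB", "chain"),
            ("OD1", "O", "CG", "branch+"), ("ND2", "N", "CG", "branch-")],
    "GLN": [("CB", "C", "CA", "chain"), ("CG", "C", "CB", "chain"),
            ("CD", "C", "CG", "chain"), ("OE1", "O", "CD", "branch+"),
            ("NE2", "N", "CD", "branch-")],
    "ASP": [("CB", "C", "CA", "chain"), ("CG", "C", "CB", "chain"),
            ("OD1", "O", "CG", "branch+"), ("OD2", "O", "CG", "branch-")],
    "GLU": [("CB", "C", "CA", "chain"), ("CG", "C", "CB", "chain"),
            ("CD", "C", "CG", "chain"), ("OE1", "O", "CD", "branch+"),
            ("OE2", "O", "CD", "branch-")],
    "LYS": [("CB", "C", "CA", "chain"), ("CG", "C", "CB", "chain"),
            ("CD", "C", "CG", "chain"), ("CE", "C", "CD", "chain"),
            ("NZ", "N", "CE", "chain")],
    "ARG": [("CB", "C", "CA", "chain"), ("CG", "C", "CB", "chain"),
            ("CD", "C", "CG", "chain"), ("NE", "N", "CD", "chain"),
            ("CZ", "C", "NE", "chain"), ("NH1", "N", "CZ", "branch+"),
            ("NH2", "N", "CZ", "branch-")],
    "HIS": [("CB", "C", "CA", "chain"), ("CG", "C", "CB", "chain"),
            ("ND1", "N", "CG", "branch+"), ("CD2", "C", "CG", "branch-"),
            ("CE1", "C", "ND1", "chain"), ("NE2", "N", "CD2", "chain")],
}

# Fixture side-chain charges; each pattern sums exactly to the formal charge
# (−1 for Asp/Glu, +1 for Lys/Arg, 0 otherwise).
_SIDE_CHARGES: dict[str, dict[str, float]] = {
    "GLY": {},
    "ALA": {"CB": 0.0},
    "PRO": {"CB": 0.0, "CG": 0.0, "CD": 0.0},
    "SER": {"CB": 0.20, "OG": -0.20},
    "THR": {"CB": 0.15, "OG1": -0.25, "CG2": 0.10},
    "CYS": {"CB": 0.12, "SG": -0.12},
    "VAL": {"CB": 0.0, "CG1": 0.0, "CG2": 0.0},
    "LEU": {"CB": 0.0, "CG": 0.0, "CD1": 0.0, "CD2": 0.0},
    "ILE": {"CB": 0.0, "CG1": 0.0, "CG2": 0.0, "CD1": 0.0},
    "MET": {"CB": 0.0, "CG": 0.05, "SD": -0.10, "CE": 0.05},
    "PHE": {n: 0.0 for n in ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ")},
    "TYR": {"CB": 0.0, "CG": 0.0, "CD1": 0.0, "CD2": 0.0, "CE1": 0.0,
            "CE2": 0.0, "CZ": 0.25, "OH": -0.25},
    "TRP": {"CB": 0.0, "CG": 0.0, "CD1": 0.10, "CD2": 0.0, "NE1": -0.30,
            "CE2": 0.20, "CE3": 0.0, "CZ2": 0.0, "CZ3": 0.0, "CH2": 0.0},
    "ASN": {"CB": 0.0, "CG": 0.55, "OD1": -0.55, "ND2": 0.0},
    "GLN": {"CB": 0.0, "CG": 0.0, "CD": 0.55, "OE1": -0.55, "NE2": 0.0},
    "ASP": {"CB": 0.0, "CG": 0.40, "OD1": -0.70, "OD2": -0.70},
    "GLU": {"CB": 0.0, "CG": 0.0, "CD": 0.40, "OE1": -0.70, "OE2": -0.70},
    "LYS": {"CB": 0.0, "CG": 0.0, "CD": 0.0, "CE": 0.25, "NZ": 0.75},
    "ARG": {"CB": 0.0, "CG": 0.0, "CD": 0.10, "NE": -0.10, "CZ": 0.50,
            "NH1": 0.25, "NH2": 0.25},
    "HIS": {"CB": 0.0, "CG": 0.10, "ND1": -0.30, "CD2": 0.10, "CE1": 0.30,
            "NE2": -0.20},
}

_CHAIN_STEPS = (np.array([0.45, -1.30, 0.35]), np.array([-0.45, -1.30, -0.35]))
_BRANCH_STEPS = {"branch+": np.array([1.15, -0.55, 0.55]),
                 "branch-": np.array([-1.15, -0.55, -0.55])}
_BOND_LENGTH = 1.52


def residue_template(name: str) -> list[tuple[str, str, np.ndarray, float]]:
    """Idealized heavy-atom template: (atom, element, local coords, charge)."""
    name = name.upper()
    if name not in _SIDE_TOPOLOGY:
        raise ValueError(f"no template for residue {name!r}")
    coords = {n: np.array(c, dtype=float) for n, _, c, _ in _BACKBONE}
    depth = {"CA": 0}
    atoms = [(n, e, coords[n], q) for n, e, c, q in _BACKBONE]
    for atom, element, parent, placement in _SIDE_TOPOLOGY[name]:
        d = depth[parent] + 1
        if placement == "chain":
            step = _CHAIN_STEPS[d % 2]
        else:
            step = _BRANCH_STEPS[placement]
        step = step / np.linalg.norm(step) * _BOND_LENGTH
        coords[atom] = coords[parent] + step
        depth[atom] = d
        atoms.append((atom, element, coords[atom],
                      _SIDE_CHARGES[name][atom]))
    return atoms


def _template_reference(name: str,
                        atoms: Sequence[tuple[str, str, np.ndarray, float]]
                        ) -> np.ndarray:
    """Reference point of a template: charged-group or side-chain mass COM.

    Mirrors the convention used on parsed structures so a residue placed
    "at (d1, d2)" really has its analysis coordinate at those distances.
    """
    name = name.upper()
    if name in CHARGED_GROUP_ATOMS:
        wanted = set(CHARGED_GROUP_ATOMS[name])
        group = [(e, c) for n, e, c, _ in atoms if n in wanted]
    else:
        backbone = {n for n, *_ in _BACKBONE}
        group = [(e, c) for n, e, c, _ in atoms if n not in backbone]
    if not group:  # glycine: fall back to the alpha carbon
        group = [(e, c) for n, e, c, _ in atoms if n == "CA"]
    masses = np.array([ATOMIC_WEIGHTS[e] for e, _ in group])
    coords = np.array([c for _, c in group])
    return masses @ coords / masses.sum()


# ---------------------------------------------------------------------------
# toy active-site pair
# ---------------------------------------------------------------------------

#: QM core of the toy: a flavin-like fragment carrying the proximal (OP) and
#: distal (OD) oxygens, and a substrate fragment carrying the sulfur (SD).
_QM_CORE = [
    # (atom, element, residue_name, residue_number, coords, react charge)
    ("C4A", "C", "FLV", 900, (-1.40, -0.80, 0.00), 0.20),
    ("OP", "O", "FLV", 900, (0.00, 0.00, 0.00), -0.35),
    ("OD", "O", "FLV", 900, (0.70, 1.15, 0.00), -0.25),
    ("SD", "S", "DBT", 901, (None, 0.00, 0.00), 0.10),  # x = site_separation
    ("C1", "C", "DBT", 901, (None, 0.85, 0.00), -0.10),  # x = sep + 1.55
]

QM_CHAIN = "X"
O_P_SELECTOR = f"{QM_CHAIN}:900:OP"
O_D_SELECTOR = f"{QM_CHAIN}:900:OD"
S_DBT_SELECTOR = f"{QM_CHAIN}:901:SD"

DEFAULT_LAYOUT: tuple[tuple[str, float, float], ...] = (
    ("ASP", 4.0, 6.5),
    ("LYS", 4.5, 7.0),
    ("SER", 6.0, 6.0),
    ("LEU", 3.0, 5.0),
    ("PHE", 7.0, 4.0),
    ("GLU", 8.0, 5.5),
    ("ARG", 5.5, 8.0),
    ("THR", 6.5, 5.0),
)


@dataclass(frozen=True)
class ToySystemSpec:
    """Specification of a synthetic active-site pair.

    ``delta_q`` is the magnitude of the reactant→TS charge shift: the
    O_p-like oxygen gains ``delta_q`` electrons (charge −delta_q) and the
    S-like sulfur loses as many.  ``shell_layout`` places one residue per
    entry with its reference point at exactly (distance to O_p, distance to
    S) Å.
    """

    delta_q: float = 0.5
    site_separation: float = 4.6
    shell_layout: tuple[tuple[str, float, float], ...] = DEFAULT_LAYOUT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_q <= 0:
            raise ValueError("delta_q must be positive")
        if self.site_separation <= 0:
            raise ValueError("site_separation must be positive")


@dataclass
class ToyAnswers:
    """Exact ΔΔE‡ answer sheet, from the naive double-loop oracle.

    Keys per residue: ``ALA`` (zero-side-chain truncation), ``PROBE_POS`` /
    ``PROBE_NEG`` (truncation plus ±1e probe), ``PROBE_ONLY_POS`` /
    ``PROBE_ONLY_NEG`` (bare probe, no truncation).
    """

    per_residue: dict[ResidueId, dict[str, float]]
    probe_points: dict[ResidueId, tuple[float, float, float]]


def site_point(spec: ToySystemSpec, d_op: float, d_sdbt: float,
               angle: float = 0.0) -> np.ndarray:
    """A point at exactly ``d_op`` from O_p and ``d_sdbt`` from the sulfur.

    The locus is a circle around the O_p→S axis; ``angle`` picks the point.
    """
    s = spec.site_separation
    x = (d_op ** 2 - d_sdbt ** 2 + s ** 2) / (2 * s)
    r_sq = d_op ** 2 - x ** 2
    if r_sq < 0:
        raise InfeasibleLayoutError(
            f"no point at {d_op} Å from O_p and {d_sdbt} Å from S "
            f"with site separation {s} Å"
        )
    r = math.sqrt(r_sq)
    return np.array([x, r * math.cos(angle), r * math.sin(angle)])


def _rotation(angle_x: float, angle_y: float) -> np.ndarray:
    cx, sx = math.cos(angle_x), math.sin(angle_x)
    cy, sy = math.cos(angle_y), math.sin(angle_y)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    return rx @ ry


def _qm_atoms(spec: ToySystemSpec, state: str) -> list[AtomRecord]:
    atoms = []
    for atom, element, res_name, res_num, coords, q_react in _QM_CORE:
        x, y, z = coords
        if x is None:
            x = spec.site_separation + (0.0 if atom == "SD" else 1.55)
        q = q_react
        if state == TS1:
            if atom == "OP":
                q -= spec.delta_q
            elif atom == "SD":
                q += spec.delta_q
        atoms.append(AtomRecord(
            atom_name=atom, element=element, residue_name=res_name,
            chain=QM_CHAIN, residue_number=res_num,
            coords=(float(x), float(y), float(z)), charge=q))
    return atoms


def _place_residue(spec: ToySystemSpec, name: str, d_op: float,
                   d_sdbt: float, chain: str, res_num: int, angle: float,
                   tilt: float = 0.0) -> list[AtomRecord]:
    template = residue_template(name)
    ref = _template_reference(name, template)
    target = site_point(spec, d_op, d_sdbt, angle)
    rot = _rotation(angle, tilt)
    atoms = []
    for atom, element, local, charge in template:
        pos = target + rot @ (np.asarray(local) - ref)
        atoms.append(AtomRecord(
            atom_name=atom, element=element, residue_name=name.upper(),
            chain=chain, residue_number=res_num,
            coords=tuple(float(v) for v in pos), charge=charge))
    return atoms


def _check_clashes(groups: Sequence[Sequence[AtomRecord]]) -> None:
    from scipy.spatial.distance import cdist

    coords = [np.array([a.coords for a in g]) for g in groups]
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if cdist(coords[i], coords[j]).min() < MIN_PLACEMENT_SEPARATION:
                raise ClashingLayoutError(
                    f"atoms of groups {i} and {j} closer than "
                    f"{MIN_PLACEMENT_SEPARATION} Å"
                )


def make_toy_pair(spec: ToySystemSpec = ToySystemSpec(),
                  resolve_clashes: bool = False
                  ) -> tuple[StatePair, ToyAnswers]:
    """Build the toy REACT/TS1 pair and its exact answer sheet.

    Both states share geometry; only the QM charges on the O_p-like and
    S-like atoms differ.  Residues are placed around the inter-site axis at
    exactly their prescribed distances, deterministically from the seed.
    With ``resolve_clashes`` the placement angle is re-drawn (distances
    untouched) until no two residues approach within the minimum
    separation; otherwise a clashing layout is an error.
    """
    rng = np.random.default_rng(spec.seed)
    react_qm = _qm_atoms(spec, REACT)
    ts_qm = _qm_atoms(spec, TS1)
    qm_coords = np.array([a.coords for a in react_qm])

    n = len(spec.shell_layout)
    groups: list[list[AtomRecord]] = []
    placed_coords: list[np.ndarray] = [qm_coords]
    residue_ids: list[ResidueId] = []
    for k, (name, d_op, d_sdbt) in enumerate(spec.shell_layout):
        res_num = 101 + k
        attempts = 400 if resolve_clashes else 1
        group = None
        for _ in range(attempts):
            angle = float(rng.uniform(0, 2 * math.pi)) if resolve_clashes \
                else 2 * math.pi * k / max(n, 1) + float(rng.uniform(0, 0.3))
            tilt = float(rng.uniform(-0.4, 0.4))
            candidate = _place_residue(spec, name, d_op, d_sdbt, "A",
                                       res_num, angle, tilt)
            coords = np.array([a.coords for a in candidate])
            from scipy.spatial.distance import cdist as _cdist
            if all(_cdist(coords, other).min() >= MIN_PLACEMENT_SEPARATION
                   for other in placed_coords):
                group = candidate
                break
        if group is None:
            raise ClashingLayoutError(
                f"could not place {name} #{res_num} at "
                f"({d_op}, {d_sdbt}) Å without clashes"
            )
        groups.append(group)
        placed_coords.append(np.array([a.coords for a in group]))
        residue_ids.append(("A", res_num))

    _check_clashes([react_qm] + groups)

    env_atoms = [a for g in groups for a in g]
    qm_keys = [a.key for a in react_qm]
    react = StateStructure(REACT, react_qm + env_atoms,
                           qm_selection=frozenset(qm_keys))
    ts = StateStructure(TS1, ts_qm + env_atoms,
                        qm_selection=frozenset(qm_keys))
    pair = pair_states(react, ts, O_P_SELECTOR, S_DBT_SELECTOR, O_D_SELECTOR)
    answers = _answer_sheet(react_qm, ts_qm, groups, residue_ids)
    return pair, answers


# ---------------------------------------------------------------------------
# the naive oracle
# ---------------------------------------------------------------------------

def naive_coulomb(set_a: Iterable[tuple[Sequence[float], float]],
                  set_b: Iterable[tuple[Sequence[float], float]]) -> float:
    """Deliberately naive O(N²) Coulomb double loop (independent oracle)."""
    total = 0.0
    set_b = list(set_b)
    for (xa, ya, za), qa in set_a:
        for (xb, yb, zb), qb in set_b:
            r = math.sqrt((xa - xb) ** 2 + (ya - yb) ** 2 + (za - zb) ** 2)
            total += COULOMB_CONSTANT * qa * qb / r
    return total


def _oracle_ddE(qm_react, qm_ts, env_wt, env_mut) -> float:
    d_wt = naive_coulomb(qm_ts, env_wt) - naive_coulomb(qm_react, env_wt)
    d_mut = naive_coulomb(qm_ts, env_mut) - naive_coulomb(qm_react, env_mut)
    return d_mut - d_wt


def _answer_sheet(react_qm: Sequence[AtomRecord], ts_qm: Sequence[AtomRecord],
                  groups: Sequence[Sequence[AtomRecord]],
                  residue_ids: Sequence[ResidueId]) -> ToyAnswers:
    backbone_names = {n for n, *_ in _BACKBONE}
    qm_r = [(a.coords, a.charge) for a in react_qm]
    qm_t = [(a.coords, a.charge) for a in ts_qm]
    env_all = [a for g in groups for a in g]
    env_wt = [(a.coords, a.charge) for a in env_all]

    per_residue: dict[ResidueId, dict[str, float]] = {}
    probe_points: dict[ResidueId, tuple[float, float, float]] = {}
    for rid, group in zip(residue_ids, groups):
        removed = {a.key for a in group
                   if a.atom_name not in backbone_names
                   and a.atom_name != "CB"}
        heavy_side = [a for a in group
                      if a.atom_name not in backbone_names]
        env_ala = [(a.coords, a.charge) for a in env_all
                   if a.key not in removed]
        answers = {"ALA": _oracle_ddE(qm_r, qm_t, env_wt, env_ala)}
        if heavy_side:  # Gly has nowhere to center a probe
            centroid = tuple(
                float(v) for v in
                np.mean([a.coords for a in heavy_side], axis=0))
            probe_points[rid] = centroid
            for tag, q in (("POS", +1.0), ("NEG", -1.0)):
                answers[f"PROBE_{tag}"] = _oracle_ddE(
                    qm_r, qm_t, env_wt, env_ala + [(centroid, q)])
                answers[f"PROBE_ONLY_{tag}"] = _oracle_ddE(
                    qm_r, qm_t, env_wt, env_wt + [(centroid, q)])
        per_residue[rid] = answers
    return ToyAnswers(per_residue=per_residue, probe_points=probe_points)


# ---------------------------------------------------------------------------
# toy alignments
# ---------------------------------------------------------------------------

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

_REGIMES = ("high", "mid", "low")


def _sample_column(regime: str, n_seqs: int, rng: np.random.Generator,
                   consensus: str = "L",
                   alternatives: Sequence[str] = ("I", "V")) -> str:
    """One alignment column under a conservation regime.

    ``high`` columns are fully conserved; ``mid`` columns mix the consensus
    with two alternatives; ``low`` columns are uniform over all residues.
    Sampling is rejected until the empirical composition matches the regime,
    keeping the regimes' entropies strictly ordered.
    """
    if regime == "high":
        return consensus * n_seqs
    for _ in range(200):
        if regime == "mid":
            pool = [consensus] + list(alternatives)
            probs = np.array([0.6] + [0.4 / len(alternatives)]
                             * len(alternatives))
            col = "".join(rng.choice(pool, size=n_seqs, p=probs))
            counts = {c: col.count(c) for c in set(col)}
            if 2 <= len(counts) <= 1 + len(alternatives) and \
                    counts.get(consensus, 0) >= 0.45 * n_seqs:
                return col
        elif regime == "low":
            col = "".join(rng.choice(list(_AA20), size=n_seqs))
            if len(set(col)) >= min(8, n_seqs):
                return col
        else:
            raise ValueError(f"unknown conservation regime {regime!r}")
    raise RuntimeError(f"could not sample a {regime!r} column")


def make_toy_msa(n_seqs: int, column_plan: Sequence[str], seed: int = 0,
                 path: str | Path | None = None) -> MultipleSeqAlignment:
    """Toy aligned FASTA with per-column conservation regimes.

    ``column_plan`` assigns each column ``"high"``, ``"mid"`` or ``"low"``;
    the first row (id ``query``) is the query sequence.  Optionally written
    to ``path`` in the exact format :func:`tsscan.conservation.read_msa`
    consumes.
    """
    if n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    unknown = set(column_plan) - set(_REGIMES)
    if unknown:
        raise ValueError(f"unknown regimes in plan: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    columns = [_sample_column(regime, n_seqs, rng) for regime in column_plan]
    rows = ["".join(col[i] for col in columns) for i in range(n_seqs)]
    records = [
        SeqRecord(Seq(row), id="query" if i == 0 else f"homolog_{i:03d}",
                  description="")
        for i, row in enumerate(rows)
    ]
    aln = MultipleSeqAlignment(records)
    if path is not None:
        write_msa(aln, path)
    return aln


def write_msa(alignment: MultipleSeqAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in alignment:
            fh.write(f">{rec.id}\n{str(rec.seq)}\n")


# ---------------------------------------------------------------------------
# full end-to-end case
# ---------------------------------------------------------------------------

# Residues planted with a strong, sign-known effect in one scan mode.
# Acidic residues near the O_p-like site destabilize the TS (their deletion
# lowers the barrier); apolar residues near one site respond strongly to a
# probe of the matching sign while their deletion does nothing.
_CASE_PLANTED_ALA = (("ASP", 4.2, 7.8), ("GLU", 4.8, 8.5), ("ASP", 5.0, 8.8))
_CASE_DETRIMENTAL = (("LYS", 4.3, 7.9), ("ARG", 5.3, 8.7))
_CASE_PLANTED_PPOS = (("PHE", 4.0, 8.0), ("LEU", 3.6, 7.4))
_CASE_PLANTED_PNEG = (("PHE", 8.0, 4.0), ("ILE", 7.8, 3.9))
_CASE_NEUTRAL = (("VAL", 6.5, 6.5), ("LEU", 7.2, 7.2), ("PHE", 8.2, 8.2),
                 ("ILE", 7.7, 7.7))
_CASE_POLAR_FILLERS = (("SER", 6.0, 7.0), ("THR", 7.0, 6.2),
                       ("ASN", 6.8, 7.6), ("GLN", 7.4, 6.6),
                       ("TYR", 8.6, 7.2), ("TRP", 8.1, 8.8),
                       ("CYS", 6.3, 5.6), ("HIS", 8.6, 7.5))

_FILLER_NAMES = ("LEU", "VAL", "ILE", "MET", "PHE", "SER", "THR", "ASN",
                 "GLN", "TYR")

# Non-charged replacement residues observed at planted acidic positions in
# the synthetic homologues (what real homologue variability would offer).
_CASE_MSA_ALTERNATIVES = {"ASP": ("N", "S"), "GLU": ("Q", "N")}

MODE_ALA = "ALA"
MODE_PROBE_POS = "PROBE_POS"
MODE_PROBE_NEG = "PROBE_NEG"


@dataclass
class ToyCase:
    """End-to-end synthetic input bundle with its planted ground truth."""

    spec: ToySystemSpec
    pair: StatePair
    answers: ToyAnswers
    planted: dict[str, list[ResidueId]]
    neutral: list[ResidueId]
    alignment: MultipleSeqAlignment
    position_offset: int
    files: dict[str, Path] = field(default_factory=dict)


def make_dszc_like_case(seed: int = 0, n_fillers: int = 8,
                        outdir: str | Path | None = None) -> ToyCase:
    """A full pipeline exercise: toy pair, shell of every class, MSA.

    The layout plants residues with strong known effects in each scan mode
    (acidic residues near the O_p-like site for the alanine scan; apolar
    residues near one site for each probe sign) alongside residues that are
    exactly neutral, plus polar/apolar fillers.  The generator verifies the
    planted margins on the oracle answer sheet before returning.  With
    ``outdir`` the bundle is also written to disk (PDBs, PQR charge tables,
    aligned FASTA, YAML config) in the formats the readers consume.
    """
    rng = np.random.default_rng(seed)
    layout: list[tuple[str, float, float]] = []
    roles: list[str] = []
    for entries, role in (
            (_CASE_PLANTED_ALA, MODE_ALA),
            (_CASE_DETRIMENTAL, "detrimental"),
            (_CASE_PLANTED_PPOS, MODE_PROBE_POS),
            (_CASE_PLANTED_PNEG, MODE_PROBE_NEG),
            (_CASE_NEUTRAL, "neutral"),
            (_CASE_POLAR_FILLERS, "filler")):
        for entry in entries:
            layout.append(entry)
            roles.append(role)
    for _ in range(n_fillers):
        name = str(rng.choice(_FILLER_NAMES))
        d_op = float(rng.uniform(6.0, 10.5))
        d_sdbt = float(np.clip(d_op + rng.uniform(-2.5, 2.5), 5.5, 10.5))
        layout.append((name, round(d_op, 2), round(d_sdbt, 2)))
        roles.append("filler")

    spec = ToySystemSpec(shell_layout=tuple(layout), seed=seed)
    pair, answers = make_toy_pair(spec, resolve_clashes=True)

    residue_ids = [("A", 101 + k) for k in range(len(layout))]
    planted: dict[str, list[ResidueId]] = {
        MODE_ALA: [], MODE_PROBE_POS: [], MODE_PROBE_NEG: []}
    neutral: list[ResidueId] = []
    for rid, role in zip(residue_ids, roles):
        if role in planted:
            planted[role].append(rid)
        elif role == "neutral":
            neutral.append(rid)

    _verify_margins(answers, planted, neutral)
    alignment = _case_msa(pair, residue_ids, rng)

    case = ToyCase(spec=spec, pair=pair, answers=answers, planted=planted,
                   neutral=neutral, alignment=alignment, position_offset=100)
    if outdir is not None:
        case.files = _write_case(case, Path(outdir))
    return case


def _verify_margins(answers: ToyAnswers, planted: dict, neutral: list,
                    strong: float = 1.0, weak: float = 0.1) -> None:
    """Construction self-check: planted effects strong, neutral ones tiny."""
    key = {MODE_ALA: "ALA", MODE_PROBE_POS: "PROBE_POS",
           MODE_PROBE_NEG: "PROBE_NEG"}
    for mode, rids in planted.items():
        for rid in rids:
            value = answers.per_residue[rid][key[mode]]
            if not value < -strong:
                raise RuntimeError(
                    f"planted residue {rid} has {mode} effect {value:.3f}, "
                    f"not below -{strong}")
    for rid in neutral:
        for k in ("ALA", "PROBE_POS", "PROBE_NEG"):
            if abs(answers.per_residue[rid][k]) > weak:
                raise RuntimeError(
                    f"neutral residue {rid} has |{k}| = "
                    f"{answers.per_residue[rid][k]:.3f} > {weak}")


def _case_msa(pair: StatePair, residue_ids: Sequence[ResidueId],
              rng: np.random.Generator, n_seqs: int = 30
              ) -> MultipleSeqAlignment:
    """Alignment whose query mirrors the structure (position = resid − 100).

    Acidic positions vary into non-charged alternatives in the homologues;
    everything else is fully conserved, so probe-mode suggestions at
    apolar/polar positions are correctly flagged risky.
    """
    by_number = {rid[1]: pair.react.residue_name(rid) for rid in residue_ids}
    length = max(by_number) - 100
    columns = []
    for pos in range(1, length + 1):
        res3 = by_number.get(pos + 100, "ALA")
        consensus = AA3_TO_1[res3]
        if res3 in _CASE_MSA_ALTERNATIVES:
            col = _sample_column("mid", n_seqs, rng, consensus=consensus,
                                 alternatives=_CASE_MSA_ALTERNATIVES[res3])
        else:
            col = _sample_column("high", n_seqs, rng, consensus=consensus)
        columns.append(col)
    rows = ["".join(col[i] for col in columns) for i in range(n_seqs)]
    records = [
        SeqRecord(Seq(row), id="query" if i == 0 else f"homolog_{i:03d}",
                  description="")
        for i, row in enumerate(rows)
    ]
    return MultipleSeqAlignment(records)


def _write_case(case: ToyCase, outdir: Path) -> dict[str, Path]:
    import yaml

    from .structures import write_pdb, write_pqr

    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "react_pdb": outdir / "react.pdb",
        "ts_pdb": outdir / "ts1.pdb",
        "react_charges": outdir / "react.pqr",
        "ts_charges": outdir / "ts1.pqr",
        "msa": outdir / "homologs.fasta",
        "config": outdir / "config.yaml",
    }
    write_pdb(case.pair.react.atoms, files["react_pdb"])
    write_pdb(case.pair.ts.atoms, files["ts_pdb"])
    write_pqr(case.pair.react.atoms, files["react_charges"])
    write_pqr(case.pair.ts.atoms, files["ts_charges"])
    write_msa(case.alignment, files["msa"])
    config = {
        "react_pdb": str(files["react_pdb"]),
        "ts_pdb": str(files["ts_pdb"]),
        "react_charges": str(files["react_charges"]),
        "ts_charges": str(files["ts_charges"]),
        "qm_selection": [f"{QM_CHAIN}:900", f"{QM_CHAIN}:901"],
        "o_p": O_P_SELECTOR,
        "s_dbt": S_DBT_SELECTOR,
        "o_d": O_D_SELECTOR,
        "cutoff": 10.0,
        "excluded_names": [],
        "msa": str(files["msa"]),
        "query_id": "query",
        "position_offset": case.position_offset,
        "scan_modes": ["ALA", "PROBE_POS", "PROBE_NEG"],
        "label_threshold": 1.0,
        "output_dir": str(outdir / "results"),
        "seed": case.spec.seed,
    }
    files["config"].write_text(yaml.safe_dump(config, sort_keys=False))
    return files
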