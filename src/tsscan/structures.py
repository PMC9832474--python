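"""Stationary-point structures, per-state charges, and mutable-shell selection.

A scan works on a *pair* of frozen geometries of the same enzyme:substrate
system — the reactant (``REACT``) and the rate-limiting transition state
(``TS1``) — each carrying per-atom partial charges.  The atoms are
partitioned into a QM region (the reacting core, whose charges differ
between the two states and encode the electron-density shift of the
reaction) and a point-charge environment.  Coordinates come from PDB files;
charges come from a PQR twin or a plain whitespace table aligned to atom
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import cdist

from .constants import (
    AA3_VARIANTS,
    ION_NAMES,
    SHELL_EXCLUDED_NAMES,
    STANDARD_AA3,
    WATER_NAMES,
    DEFAULT_SHELL_CUTOFF,
)

#: Atom key: (chain id, residue number, atom name).  Unique within a state.
AtomKey = tuple[str, int, str]

#: Residue id: (chain id, residue number).
ResidueId = tuple[str, int]

MAX_ABS_CHARGE = 2.5  # e; larger values signal a corrupt charge table

REACT = "REACT"
TS1 = "TS1"

QM = "QM"
ENV = "ENV"


class StructureError(ValueError):
    """Raised for unreadable, inconsistent, or mispaired structure inputs."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a stationary-point structure."""

    atom_name: str
    element: str
    residue_name: str
    chain: str
    residue_number: int
    coords: tuple[float, float, float]
    charge: float
    region: str = ENV  # QM | ENV

    @property
    def key(self) -> AtomKey:
        return (self.chain, self.residue_number, self.atom_name)

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain, self.residue_number)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom {self.key}")
        if abs(self.charge) > MAX_ABS_CHARGE:
            raise StructureError(
                f"charge {self.charge:+.3f} e on {self.key} exceeds "
                f"|{MAX_ABS_CHARGE}| e — charge table misaligned?"
            )
        if self.region not in (QM, ENV):
            raise StructureError(f"unknown region {self.region!r}")


def canonical_residue_name(name: str) -> str:
    """Map protonation-variant names (HIP, GLH, ...) to the parent residue."""
    name = name.strip().upper()
    return AA3_VARIANTS.get(name, name)


def infer_element(atom_name: str, element_hint: str = "") -> str:
    """Best-effort element from the PDB element column or the atom name."""
    hint = element_hint.strip().upper()
    if hint and hint in ("H", "C", "N", "O", "S", "P", "SE", "FE", "ZN", "MG",
                         "NA", "CL", "K", "CA", "MN", "CU", "BR", "I"):
        return hint
    name = atom_name.strip().upper()
    # two-letter elements that appear as full atom names (ions, metals)
    if name in ("FE", "ZN", "MG", "NA", "CL", "MN", "CU", "BR", "SE"):
        return name
    stripped = name.lstrip("0123456789")
    return stripped[0] if stripped else "C"


@dataclass
class StateStructure:
    """One stationary point: atoms with per-state charges and a QM selection."""

    label: str  # REACT | TS1
    atoms: list[AtomRecord]
    qm_selection: frozenset[AtomKey] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set[AtomKey] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))
            raise StructureError(f"duplicate atom key {dup}")
        key_set = set(keys)
        if self.qm_selection:
            missing = set(self.qm_selection) - key_set
            if missing:
                raise StructureError(
                    f"QM selection names atoms absent from structure: "
                    f"{sorted(missing)[:5]}"
                )
            self.atoms = [
                replace(a, region=QM if a.key in self.qm_selection else ENV)
                for a in self.atoms
            ]
        self._index = {a.key: i for i, a in enumerate(self.atoms)}

    # -- lookups -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def __contains__(self, key: AtomKey) -> bool:
        return key in self._index

    def atom(self, key: AtomKey) -> AtomRecord:
        try:
            return self.atoms[self._index[key]]
        except KeyError:
            raise StructureError(f"atom {key} not in {self.label}") from None

    def coords_of(self, keys: Iterable[AtomKey]) -> np.ndarray:
        return np.array([self.atom(k).coords for k in keys], dtype=float)

    @property
    def keys(self) -> list[AtomKey]:
        return [a.key for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def qm_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.region == QM]

    def env_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.region == ENV]

    def residue_ids(self) -> list[ResidueId]:
        seen: dict[ResidueId, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)

    def residue_atoms(self, residue_id: ResidueId) -> list[AtomRecord]:
        out = [a for a in self.atoms if a.residue_id == residue_id]
        if not out:
            raise StructureError(f"residue {residue_id} not in {self.label}")
        return out

    def residue_name(self, residue_id: ResidueId) -> str:
        return self.residue_atoms(residue_id)[0].residue_name

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StateStructure":
        """Rigid-body copy: x -> R x + t (charges and regions untouched)."""
        rot = np.asarray(rotation, float)
        tr = np.asarray(translation, float)
        atoms = [
            replace(a, coords=tuple(rot @ np.asarray(a.coords) + tr))
            for a in self.atoms
        ]
        return StateStructure(self.label, atoms, self.qm_selection)


@dataclass
class StatePair:
    """Matched REACT/TS1 structures plus the two distance-reference atoms.

    ``o_p_key`` and ``s_dbt_key`` name the atoms with the largest
    reactant→TS electron-density change (gain and loss respectively); the
    asymmetry of a residue's position with respect to them is the geometric
    coordinate of the whole analysis.  ``o_d_key`` (the transferred atom) is
    carried for reference only.
    """

    react: StateStructure
    ts: StateStructure
    correspondence: dict[AtomKey, AtomKey]
    o_p_key: AtomKey
    s_dbt_key: AtomKey
    o_d_key: AtomKey | None = None
    react_only: frozenset[AtomKey] = field(default_factory=frozenset)
    ts_only: frozenset[AtomKey] = field(default_factory=frozenset)


def parse_atom_selector(selector: str | Sequence) -> tuple:
    """Parse ``"chain:resid"`` / ``"chain:resid:atom"`` (or tuple forms).

    Returns a 2-tuple residue selector or a 3-tuple atom key.
    """
    if isinstance(selector, str):
        parts = selector.split(":")
    else:
        parts = list(selector)
    if len(parts) == 2:
        return (str(parts[0]), int(parts[1]))
    if len(parts) == 3:
        return (str(parts[0]), int(parts[1]), str(parts[2]))
    raise StructureError(f"bad atom selector {selector!r}")


def resolve_selection(atoms: Sequence[AtomRecord],
                      selectors: Iterable) -> frozenset[AtomKey]:
    """Expand residue- and atom-level selectors into a set of atom keys."""
    by_res: dict[ResidueId, list[AtomKey]] = {}
    keys = set()
    for a in atoms:
        by_res.setdefault(a.residue_id, []).append(a.key)
        keys.add(a.key)
    out: set[AtomKey] = set()
    for sel in selectors:
        parsed = parse_atom_selector(sel)
        if len(parsed) == 2:
            if parsed not in by_res:
                raise StructureError(f"selector {sel!r}: residue not found")
            out.update(by_res[parsed])
        else:
            if parsed not in keys:
                raise StructureError(f"selector {sel!r}: atom not found")
            out.add(parsed)
    return frozenset(out)


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def _read_pdb_atoms(path: Path) -> list[dict]:
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    rows = []
    for i in range(arr.array_length()):
        rows.append({
            "atom_name": str(arr.atom_name[i]),
            "residue_name": str(arr.res_name[i]),
            "chain": str(arr.chain_id[i]) or "A",
            "residue_number": int(arr.res_id[i]),
            "coords": tuple(float(x) for x in arr.coord[i]),
            "element": infer_element(str(arr.atom_name[i]),
                                     str(arr.element[i])),
        })
    return rows


def read_charge_table(path: Path) -> list[dict]:
    """Read charges from a PQR file or a plain whitespace table.

    Accepted dialects (detected per file):

    * PQR: ``ATOM/HETATM serial name resName [chain] resSeq x y z q r``
      (whitespace-delimited; charge is the second-to-last field);
    * ``x y z q`` — four floats per row, aligned to atom order;
    * ``chain resid atomname q`` — identifying columns plus the charge.
    """
    rows: list[dict] = []
    text = Path(path).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "REMARK", "COMMENT")):
            continue
        fields = line.split()
        if fields[0] in ("ATOM", "HETATM"):
            if len(fields) < 10:
                raise StructureError(f"malformed PQR row: {line!r}")
            rows.append({
                "atom_name": fields[2],
                "charge": float(fields[-2]),
            })
        elif fields[0] in ("TER", "END", "ENDMDL"):
            continue
        elif len(fields) == 4:
            try:
                x = float(fields[0])
            except ValueError:
                rows.append({
                    "chain": fields[0],
                    "residue_number": int(fields[1]),
                    "atom_name": fields[2],
                    "charge": float(fields[3]),
                })
            else:
                rows.append({
                    "coords": (x, float(fields[1]), float(fields[2])),
                    "charge": float(fields[3]),
                })
        else:
            raise StructureError(f"unrecognized charge-table row: {line!r}")
    if not rows:
        raise StructureError(f"empty charge table: {path}")
    return rows


def read_structure(path: str | Path, charge_source: str | Path, label: str,
                   qm_selection: Iterable = ()) -> StateStructure:
    """Read one stationary point: a PDB file plus its charge table.

    Charges are matched to atoms by file order, with a cross-check against
    whatever identifying columns the table carries (atom names for PQR and
    keyed tables, coordinates for ``x y z q`` tables).
    """
    path, charge_source = Path(path), Path(charge_source)
    if not path.exists():
        raise StructureError(f"structure file not found: {path}")
    if not charge_source.exists():
        raise StructureError(f"charge file not found: {charge_source}")
    pdb_rows = _read_pdb_atoms(path)
    charge_rows = read_charge_table(charge_source)
    if len(pdb_rows) != len(charge_rows):
        raise StructureError(
            f"charge table mismatch: {len(pdb_rows)} atoms in {path.name} vs "
            f"{len(charge_rows)} charge rows in {charge_source.name}"
        )
    atoms = []
    for i, (p, c) in enumerate(zip(pdb_rows, charge_rows)):
        if "atom_name" in c and c["atom_name"] != p["atom_name"]:
            raise StructureError(
                f"charge table mismatch at row {i}: atom name "
                f"{c['atom_name']!r} vs PDB {p['atom_name']!r}"
            )
        if "coords" in c:
            if not np.allclose(c["coords"], p["coords"], atol=0.01):
                raise StructureError(
                    f"charge table mismatch at row {i}: coordinates disagree"
                )
        atoms.append(AtomRecord(
            atom_name=p["atom_name"],
            element=p["element"],
            residue_name=p["residue_name"],
            chain=c.get("chain", p["chain"]),
            residue_number=p["residue_number"],
            coords=p["coords"],
            charge=c["charge"],
        ))
    selection = resolve_selection(atoms, qm_selection) if qm_selection else frozenset()
    return StateStructure(label=label, atoms=atoms, qm_selection=selection)


def write_pdb(atoms: Sequence[AtomRecord], path: str | Path) -> None:
    """Write atoms as a single-model PDB file (occupancy/B left at defaults)."""
    n = len(atoms)
    arr = struc.AtomArray(n)
    arr.coord = np.array([a.coords for a in atoms], dtype=np.float32)
    arr.chain_id = np.array([a.chain for a in atoms])
    arr.res_id = np.array([a.residue_number for a in atoms])
    arr.res_name = np.array([a.residue_name for a in atoms])
    arr.atom_name = np.array([a.atom_name for a in atoms])
    arr.element = np.array([a.element for a in atoms])
    arr.hetero = np.array([a.residue_name in WATER_NAMES | ION_NAMES
                           for a in atoms])
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_pqr(atoms: Sequence[AtomRecord], path: str | Path,
              radius: float = 1.5) -> None:
    """Write a whitespace-dialect PQR twin of the structure."""
    with open(path, "w") as fh:
        for i, a in enumerate(atoms, start=1):
            x, y, z = a.coords
            fh.write(
                f"ATOM {i} {a.atom_name} {a.residue_name} {a.chain} "
                f"{a.residue_number} {x:.4f} {y:.4f} {z:.4f} "
                f"{a.charge:.6f} {radius:.3f}\n"
            )


def write_charge_table(atoms: Sequence[AtomRecord], path: str | Path) -> None:
    """Write the keyed plain charge table ``chain resid atomname q``."""
    with open(path, "w") as fh:
        for a in atoms:
            fh.write(f"{a.chain} {a.residue_number} {a.atom_name} "
                     f"{a.charge:.6f}\n")


# ---------------------------------------------------------------------------
# pairing and shell selection
# ---------------------------------------------------------------------------

def pair_states(react: StateStructure, ts: StateStructure,
                o_p: str | Sequence, s_dbt: str | Sequence,
                o_d: str | Sequence | None = None) -> StatePair:
    """Match REACT and TS1 atoms by (chain, residue, atom name).

    Atoms present in only one state (e.g. a transferred hydrogen renamed to
    its new host) are recorded as orphans and excluded from perturbation
    bookkeeping.  Fewer than half of the environment atoms matching signals
    mispaired inputs and is an error.
    """
    if react.label != REACT or ts.label != TS1:
        raise StructureError(
            f"expected labels {REACT}/{TS1}, got {react.label}/{ts.label}"
        )
    react_keys = set(react.keys)
    ts_keys = set(ts.keys)
    shared = react_keys & ts_keys
    correspondence = {k: k for k in react.keys if k in shared}

    refs = []
    for sel in (o_p, s_dbt) + ((o_d,) if o_d is not None else ()):
        key = parse_atom_selector(sel)
        if len(key) != 3:
            raise StructureError(f"reference atom selector must name an atom: {sel!r}")
        if key not in react_keys or key not in ts_keys:
            raise StructureError(f"reference atom {key} absent from one state")
        refs.append(key)
    o_p_key, s_dbt_key = refs[0], refs[1]
    o_d_key = refs[2] if o_d is not None else None

    env_react = {a.key for a in react.env_atoms()}
    env_ts = {a.key for a in ts.env_atoms()}
    for label, env in ((REACT, env_react), (TS1, env_ts)):
        if env and len(env & shared) < 0.5 * len(env):
            raise StructureError(
                f"fewer than 50% of {label} environment atoms matched — "
                "mispaired inputs?"
            )
    return StatePair(
        react=react, ts=ts, correspondence=correspondence,
        o_p_key=o_p_key, s_dbt_key=s_dbt_key, o_d_key=o_d_key,
        react_only=frozenset(react_keys - shared),
        ts_only=frozenset(ts_keys - shared),
    )


@dataclass(frozen=True)
class ShellSelection:
    """Mutable residues within ``cutoff`` Å of the active site."""

    residues: tuple[ResidueId, ...]
    cutoff: float
    excluded_names: frozenset[str]

    def __iter__(self):
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def select_shell(pair: StatePair, active_site: Iterable[AtomKey] | None = None,
                 cutoff: float = DEFAULT_SHELL_CUTOFF,
                 excluded_names: Iterable[str] = ()) -> ShellSelection:
    """Select mutable residues around the active site in the REACT geometry.

    A residue enters the shell iff at least one of its atoms lies within
    ``cutoff`` Å of any active-site atom, it is a standard amino acid other
    than Gly/Ala/Pro (or any extra ``excluded_names``), and it contributes no
    atom to the QM selection.  Waters and ions are never included.
    """
    if cutoff <= 0:
        raise StructureError("cutoff must be positive")
    react = pair.react
    if active_site is None:
        site_keys = set(react.qm_selection)
    else:
        site_keys = set(active_site)
    if not site_keys:
        raise StructureError("active-site selection is empty")
    site_coords = react.coords_of(site_keys)

    excluded = SHELL_EXCLUDED_NAMES | {n.upper() for n in excluded_names}
    qm_residues = {k[:2] for k in react.qm_selection}

    selected: list[ResidueId] = []
    for rid in react.residue_ids():
        atoms = react.residue_atoms(rid)
        name = canonical_residue_name(atoms[0].residue_name)
        if name not in STANDARD_AA3 or name in excluded:
            continue
        if name in WATER_NAMES or name in ION_NAMES:
            continue
        if rid in qm_residues:
            continue
        coords = np.array([a.coords for a in atoms])
        if cdist(coords, site_coords).min() <= cutoff:
            selected.append(rid)
    if not selected:
        warnings.warn("shell selection is empty", stacklevel=2)
    selected.sort()
    return ShellSelection(tuple(selected), float(cutoff),
                          frozenset(excluded))
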