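"""Frozen-geometry perturbations: alanine truncation and ±1e probe charges.

Every perturbation is purely electrostatic bookkeeping on fixed coordinates:
side-chain atoms beyond Cβ are deleted (their charges with them), retained
atoms may be re-charged from an alanine library, and an optional unit point
charge is placed at the geometric center of the wild-type side chain.  No
atom ever moves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .constants import (
    ALANINE_LIBRARY_CHARGES,
    BACKBONE_ATOMS,
    SHELL_EXCLUDED_NAMES,
    STANDARD_AA3,
)
from .structures import (
    AtomKey,
    AtomRecord,
    ResidueId,
    StatePair,
    StateStructure,
    StructureError,
    canonical_residue_name,
    write_pdb,
)

ALA_TRUNCATE = "ALA_TRUNCATE"
PROBE_ONLY = "PROBE_ONLY"
ALA_PLUS_PROBE = "ALA_PLUS_PROBE"

ZERO_SIDECHAIN = "ZERO_SIDECHAIN"
ALA_LIBRARY = "ALA_LIBRARY"


class MutationError(ValueError):
    """Raised for invalid mutation specifications."""


@dataclass(frozen=True)
class MutantSpec:
    """One requested perturbation of a shell residue."""

    residue_id: ResidueId
    scheme: str = ALA_TRUNCATE
    probe_charge: float = 0.0
    truncation_mode: str = ZERO_SIDECHAIN

    def __post_init__(self) -> None:
        if self.scheme not in (ALA_TRUNCATE, PROBE_ONLY, ALA_PLUS_PROBE):
            raise MutationError(f"unknown scheme {self.scheme!r}")
        if self.truncation_mode not in (ZERO_SIDECHAIN, ALA_LIBRARY):
            raise MutationError(f"unknown truncation mode {self.truncation_mode!r}")
        if self.scheme == ALA_TRUNCATE and self.probe_charge != 0.0:
            raise MutationError("ALA_TRUNCATE carries no probe charge")
        if self.scheme != ALA_TRUNCATE and self.probe_charge == 0.0:
            raise MutationError(f"{self.scheme} requires a non-zero probe charge")


@dataclass(frozen=True)
class Perturbation:
    """Electrostatic edit of one state: removals, re-charges, optional probe.

    ``added_charges`` carries extra fixed point charges that are part of the
    mutant itself (the ALA_LIBRARY capping hydrogen), as opposed to the
    diagnostic ``probe``.
    """

    removed_atom_keys: frozenset[AtomKey] = field(default_factory=frozenset)
    charge_edits: dict[AtomKey, float] = field(default_factory=dict)
    probe: tuple[tuple[float, float, float], float] | None = None
    added_charges: tuple[tuple[tuple[float, float, float], float], ...] = ()

    def __post_init__(self) -> None:
        if self.probe is not None:
            pos, q = self.probe
            if not np.all(np.isfinite(pos)):
                raise MutationError("probe position must be finite")


NULL_PERTURBATION = Perturbation()


def _sidechain_atoms(state: StateStructure, residue_id: ResidueId) -> list[AtomRecord]:
    """All atoms of the residue that are not backbone (Cβ included)."""
    return [a for a in state.residue_atoms(residue_id)
            if a.atom_name not in BACKBONE_ATOMS]


def _beyond_cbeta(state: StateStructure, residue_id: ResidueId) -> list[AtomRecord]:
    """Side-chain atoms removed by alanine truncation: everything except Cβ
    and its hydrogens."""
    side = _sidechain_atoms(state, residue_id)
    return [a for a in side
            if a.atom_name != "CB" and not a.atom_name.startswith("HB")]


def sidechain_heavy_atoms(state: StateStructure,
                          residue_id: ResidueId) -> list[AtomRecord]:
    """Heavy (non-H) side-chain atoms, Cβ and beyond."""
    return [a for a in _sidechain_atoms(state, residue_id)
            if not a.is_hydrogen]


def _check_mutable(state: StateStructure, residue_id: ResidueId) -> str:
    name = canonical_residue_name(state.residue_name(residue_id))
    if name not in STANDARD_AA3:
        raise MutationError(f"{residue_id}: {name} is not a standard amino acid")
    if name in SHELL_EXCLUDED_NAMES:
        raise MutationError(f"{residue_id}: {name} is never truncated")
    return name


def alanine_truncate(state: StateStructure, residue_id: ResidueId,
                     mode: str = ZERO_SIDECHAIN) -> Perturbation:
    """Truncate one residue's side chain to alanine (methyl), frozen geometry.

    ``ZERO_SIDECHAIN`` deletes atoms beyond Cβ together with their charges
    and changes nothing else, so the net-charge change is exactly minus the
    summed charge of the removed atoms.  ``ALA_LIBRARY`` additionally
    re-charges the retained backbone + Cβ atoms from a standard alanine
    library and caps Cβ with a third hydrogen 1.09 Å along the former
    Cβ→Cγ direction.
    """
    _check_mutable(state, residue_id)
    atoms = state.residue_atoms(residue_id)
    names = {a.atom_name for a in atoms}
    if "CB" not in names:
        raise MutationError(f"{residue_id}: residue lacks CB")
    removed = _beyond_cbeta(state, residue_id)
    removed_keys = frozenset(a.key for a in removed)
    if mode == ZERO_SIDECHAIN:
        return Perturbation(removed_atom_keys=removed_keys)

    edits: dict[AtomKey, float] = {}
    for a in atoms:
        if a.key in removed_keys:
            continue
        lib_name = "HB2" if a.atom_name == "HB" else a.atom_name
        if lib_name in ALANINE_LIBRARY_CHARGES:
            edits[a.key] = ALANINE_LIBRARY_CHARGES[lib_name]
    cb = next(a for a in atoms if a.atom_name == "CB")
    gamma = [a for a in removed
             if not a.is_hydrogen and a.atom_name in
             ("CG", "CG1", "OG", "OG1", "SG")]
    added: tuple = ()
    if gamma:
        direction = np.asarray(gamma[0].coords) - np.asarray(cb.coords)
        norm = np.linalg.norm(direction)
        if norm > 0:
            hb_pos = np.asarray(cb.coords) + 1.09 * direction / norm
            added = ((tuple(float(x) for x in hb_pos),
                      ALANINE_LIBRARY_CHARGES["HB1"]),)
    return Perturbation(removed_atom_keys=removed_keys, charge_edits=edits,
                        added_charges=added)


def probe_position(state: StateStructure, residue_id: ResidueId) -> np.ndarray:
    """Unweighted geometric center of the wild-type side chain's heavy atoms.

    The geometric center stands in for the center of mass: side chains are
    built almost entirely from C, N and O, whose masses are similar.
    """
    heavy = sidechain_heavy_atoms(state, residue_id)
    if not heavy:
        raise MutationError(
            f"{residue_id}: no side-chain heavy atoms to center a probe on"
        )
    return np.mean([a.coords for a in heavy], axis=0)


def apply_mutation(pair: StatePair, spec: MutantSpec,
                   probe_from: str = "wild-type"
                   ) -> tuple[Perturbation, Perturbation]:
    """Build the REACT and TS1 perturbations for one mutant spec.

    The probe (if any) sits at the geometric center of the *wild-type*
    side chain, computed from the REACT geometry and reused identically in
    both states; frozen geometries make the TS1 position the same by
    construction.
    """
    perturbations = []
    probe = None
    if spec.scheme in (PROBE_ONLY, ALA_PLUS_PROBE):
        pos = probe_position(pair.react, spec.residue_id)
        probe = (tuple(float(x) for x in pos), float(spec.probe_charge))
    for state in (pair.react, pair.ts):
        if spec.scheme == PROBE_ONLY:
            pert = Perturbation(probe=probe)
        else:
            pert = alanine_truncate(state, spec.residue_id,
                                    spec.truncation_mode)
            if probe is not None:
                pert = Perturbation(
                    removed_atom_keys=pert.removed_atom_keys,
                    charge_edits=pert.charge_edits, probe=probe,
                    added_charges=pert.added_charges,
                )
        perturbations.append(pert)
    return perturbations[0], perturbations[1]


# ---------------------------------------------------------------------------
# QM/MM export
# ---------------------------------------------------------------------------

def _apply_to_atoms(state: StateStructure,
                    pert: Perturbation) -> tuple[list[AtomRecord], list[tuple]]:
    """Materialize a perturbation: surviving atoms and (x, y, z, q) rows."""
    from dataclasses import replace as _replace
    kept = []
    for a in state.atoms:
        if a.key in pert.removed_atom_keys:
            continue
        if a.key in pert.charge_edits:
            a = _replace(a, charge=pert.charge_edits[a.key])
        kept.append(a)
    rows = [(*a.coords, a.charge) for a in kept]
    for pos, q in pert.added_charges:
        rows.append((*pos, q))
    if pert.probe is not None:
        pos, q = pert.probe
        rows.append((*pos, q))
    return kept, rows


def write_qmmm_manifest(pair: StatePair, spec: MutantSpec,
                        outdir: str | Path) -> dict[str, Path]:
    """Write per-state mutant PDBs and point-charge tables for external QM/MM.

    Emits, for each state, ``<state>_mutant.pdb`` and ``<state>_charges.txt``
    (free-format ``x y z q`` rows, the probe appended as an extra record),
    plus a JSON sidecar recording the spec, removed atoms and charge edits.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pert_react, pert_ts = apply_mutation(pair, spec)
    files: dict[str, Path] = {}
    sidecar: dict = {
        "spec": {
            "residue_id": list(spec.residue_id),
            "scheme": spec.scheme,
            "probe_charge": spec.probe_charge,
            "truncation_mode": spec.truncation_mode,
        },
        "states": {},
    }
    for state, pert in ((pair.react, pert_react), (pair.ts, pert_ts)):
        stem = state.label.lower()
        kept, rows = _apply_to_atoms(state, pert)
        pdb_path = outdir / f"{stem}_mutant.pdb"
        write_pdb(kept, pdb_path)
        chg_path = outdir / f"{stem}_charges.txt"
        with open(chg_path, "w") as fh:
            for x, y, z, q in rows:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f} {q:.6f}\n")
        files[f"{stem}_pdb"] = pdb_path
        files[f"{stem}_charges"] = chg_path
        sidecar["states"][state.label] = {
            "removed_atom_keys": sorted(list(k) for k in pert.removed_atom_keys),
            "charge_edits": [[*k, q] for k, q in sorted(pert.charge_edits.items())],
            "probe": None if pert.probe is None
                     else {"position": list(pert.probe[0]),
                           "charge": pert.probe[1]},
            "added_charges": [{"position": list(pos), "charge": q}
                              for pos, q in pert.added_charges],
        }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(sidecar, indent=2))
    files["manifest"] = manifest_path
    return files


def read_manifest(outdir: str | Path) -> tuple[MutantSpec, dict[str, Perturbation]]:
    """Load a manifest back into its spec and per-state perturbations."""
    data = json.loads((Path(outdir) / "manifest.json").read_text())
    s = data["spec"]
    spec = MutantSpec(residue_id=tuple(s["residue_id"]), scheme=s["scheme"],
                      probe_charge=s["probe_charge"],
                      truncation_mode=s["truncation_mode"])
    perts = {}
    for label, rec in data["states"].items():
        probe = rec["probe"]
        perts[label] = Perturbation(
            removed_atom_keys=frozenset(
                (c, int(r), n) for c, r, n in rec["removed_atom_keys"]),
            charge_edits={(c, int(r), n): q
                          for c, r, n, q in rec["charge_edits"]},
            probe=None if probe is None
                  else (tuple(probe["position"]), probe["charge"]),
            added_charges=tuple(
                (tuple(a["position"]), a["charge"])
                for a in rec.get("added_charges", ())),
        )
    return spec, perts
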