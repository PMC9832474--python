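"""Distance-asymmetry coordinates, chemical classes, ranking, and plot data.

Each scanned residue is reduced to a point — the center of mass of its
charged group for Asp/Glu/Lys/Arg, of all side-chain heavy atoms otherwise —
and located by its distances to the two atoms with the largest reactant→TS
electron-density change (``d_Op``, ``d_SDBT``).  The signed asymmetry
``delta_d = d_Op − d_SDBT`` is the x-coordinate of the scan scatter: the
equidistant locus ``delta_d = 0`` is where the effect of a charge on the
transition-state macrodipole changes sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import (
    ATOMIC_WEIGHTS,
    CHARGED_GROUP_ATOMS,
    CLASS_COLORS,
    CLASS_POSITIVE,
    DEFAULT_LABEL_THRESHOLD,
    RESIDUE_CLASS,
)
from .energetics import MODE_ALA, MODE_PROBE_NEG, MODE_PROBE_POS, ScanEnergies
from .mutagenesis import sidechain_heavy_atoms
from .structures import (
    ResidueId,
    StatePair,
    StateStructure,
    StructureError,
    canonical_residue_name,
)

MODE_TO_ATTR = {
    MODE_ALA: "ddE_ala",
    MODE_PROBE_POS: "ddE_probe_pos",
    MODE_PROBE_NEG: "ddE_probe_neg",
}


@dataclass
class ScanRecord:
    """One residue's scan result joined with its geometric coordinates."""

    residue_id: ResidueId
    residue_name: str
    chem_class: str
    d_Op: float
    d_SDBT: float
    bulk: int
    ddE_ala: float = float("nan")
    ddE_probe_pos: float = float("nan")
    ddE_probe_neg: float = float("nan")
    labeled: bool = False
    error: str | None = None

    @property
    def delta_d(self) -> float:
        return self.d_Op - self.d_SDBT

    @property
    def label(self) -> str:
        return f"{self.residue_name.capitalize()}{self.residue_id[1]}"


def residue_reference_point(state: StateStructure,
                            residue_id: ResidueId) -> np.ndarray:
    """Center of mass of the residue's charged group or full side chain.

    Asp/Glu use the carboxyl heavy atoms, Lys the terminal amine nitrogen,
    Arg the guanidinium group; every other residue uses all side-chain heavy
    atoms.  Masses are standard atomic weights.
    """
    name = canonical_residue_name(state.residue_name(residue_id))
    if name in CHARGED_GROUP_ATOMS:
        wanted = CHARGED_GROUP_ATOMS[name]
        atoms = [a for a in state.residue_atoms(residue_id)
                 if a.atom_name in wanted]
        if len(atoms) != len(wanted):
            found = {a.atom_name for a in atoms}
            raise StructureError(
                f"{residue_id} ({name}): charged-group atoms missing: "
                f"{sorted(set(wanted) - found)}"
            )
    else:
        atoms = sidechain_heavy_atoms(state, residue_id)
        if not atoms:
            raise StructureError(f"{residue_id}: no side-chain heavy atoms")
    masses = np.array([ATOMIC_WEIGHTS[a.element] for a in atoms])
    coords = np.array([a.coords for a in atoms])
    return masses @ coords / masses.sum()


def distance_coordinates(pair: StatePair, residue_id: ResidueId,
                         state: str = "REACT") -> tuple[float, float, float]:
    """(d_Op, d_SDBT, delta_d) of one residue, by default on REACT geometry."""
    struct = pair.react if state == "REACT" else pair.ts
    ref = residue_reference_point(struct, residue_id)
    o_p = np.asarray(struct.atom(pair.o_p_key).coords)
    s_dbt = np.asarray(struct.atom(pair.s_dbt_key).coords)
    d_op = float(np.linalg.norm(ref - o_p))
    d_s = float(np.linalg.norm(ref - s_dbt))
    return d_op, d_s, d_op - d_s


def classify_residue(residue_name: str,
                     protonation_hints: Iterable[str] = ()) -> str:
    """Chemical class: POSITIVE / NEGATIVE / POLAR / APOLAR.

    His counts as POSITIVE only when a protonated-imidazolium hint (HIP/HSP)
    is given, either as the residue name itself or in ``protonation_hints``.
    """
    raw = residue_name.strip().upper()
    hints = {h.strip().upper() for h in protonation_hints}
    name = canonical_residue_name(raw)
    if name == "HIS" and (raw in ("HIP", "HSP") or hints & {"HIP", "HSP"}):
        return CLASS_POSITIVE
    try:
        return RESIDUE_CLASS[name]
    except KeyError:
        raise ValueError(f"unknown residue code {residue_name!r}") from None


def build_records(pair: StatePair, energies: Sequence[ScanEnergies],
                  threshold: float = DEFAULT_LABEL_THRESHOLD,
                  distance_state: str = "REACT") -> list[ScanRecord]:
    """Join scan energies with distances, classes, and bulkiness."""
    struct = pair.react if distance_state == "REACT" else pair.ts
    records = []
    for e in energies:
        if e.error is not None:
            try:
                chem = classify_residue(e.residue_name)
            except ValueError:
                chem = "APOLAR"
            records.append(ScanRecord(
                residue_id=e.residue_id, residue_name=e.residue_name,
                chem_class=chem,
                d_Op=float("nan"), d_SDBT=float("nan"), bulk=0,
                error=e.error))
            continue
        d_op, d_s, _ = distance_coordinates(pair, e.residue_id, distance_state)
        bulk = len(sidechain_heavy_atoms(struct, e.residue_id))
        records.append(ScanRecord(
            residue_id=e.residue_id, residue_name=e.residue_name,
            chem_class=classify_residue(e.residue_name),
            d_Op=d_op, d_SDBT=d_s, bulk=bulk,
            ddE_ala=e.ddE_ala, ddE_probe_pos=e.ddE_probe_pos,
            ddE_probe_neg=e.ddE_probe_neg))
    apply_labels(records, threshold)
    return records


def apply_labels(records: Sequence[ScanRecord],
                 threshold: float = DEFAULT_LABEL_THRESHOLD) -> None:
    """Set ``labeled`` on records whose largest |ΔΔE‡| exceeds the threshold."""
    if threshold <= 0:
        raise ValueError("label threshold must be positive")
    for r in records:
        values = [abs(v) for v in (r.ddE_ala, r.ddE_probe_pos, r.ddE_probe_neg)
                  if not np.isnan(v)]
        r.labeled = bool(values and max(values) > threshold)


def rank_and_label(records: Sequence[ScanRecord], mode: str = MODE_ALA,
                   threshold: float = DEFAULT_LABEL_THRESHOLD
                   ) -> list[ScanRecord]:
    """Order records most barrier-lowering first for one scan mode.

    Ascending in the mode's ΔΔE‡ (negative values — predicted faster mutants
    — first); NaNs sink to the end; ties break on (chain, residue number).
    Also refreshes the ``labeled`` flags at the given threshold.
    """
    attr = MODE_TO_ATTR[mode]
    recs = list(records)
    apply_labels(recs, threshold)

    def sort_key(r: ScanRecord):
        v = getattr(r, attr)
        return (np.isnan(v), v if not np.isnan(v) else 0.0, r.residue_id)

    return sorted(recs, key=sort_key)


def records_to_frame(records: Sequence[ScanRecord]):
    """Scan records as a tidy pandas DataFrame (plot-ready)."""
    import pandas as pd

    return pd.DataFrame([{
        "chain": r.residue_id[0],
        "resid": r.residue_id[1],
        "residue": r.residue_name,
        "class": r.chem_class,
        "ddE_ala": r.ddE_ala,
        "ddE_probe_pos": r.ddE_probe_pos,
        "ddE_probe_neg": r.ddE_probe_neg,
        "d_Op": r.d_Op,
        "d_SDBT": r.d_SDBT,
        "delta_d": r.delta_d,
        "bulk": r.bulk,
        "labeled": r.labeled,
        "error": r.error if r.error else "",
    } for r in records])


def export_figure_data(records: Sequence[ScanRecord], outpath: str | Path,
                       render: str | Path | None = None,
                       mode: str = MODE_ALA) -> Path:
    """Write the plot-ready TSV and optionally render the scan scatter.

    The scatter shows ΔΔE‡ against the distance asymmetry ``delta_d``:
    marker area grows with side-chain heavy-atom count, colors follow the
    chemical class (blue positive, red negative, green polar, gray apolar),
    and residues past the label threshold are annotated.
    """
    outpath = Path(outpath)
    df = records_to_frame(records)
    df.to_csv(outpath, sep="\t", index=False, float_format="%.6f")
    if render is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        attr = MODE_TO_ATTR[mode]
        fig, ax = plt.subplots(figsize=(6, 4.5))
        for r in records:
            y = getattr(r, attr)
            if np.isnan(y):
                continue
            ax.scatter(r.delta_d, y, s=20 + 12 * r.bulk,
                       color=CLASS_COLORS[r.chem_class], alpha=0.8,
                       edgecolors="black", linewidths=0.4)
            if r.labeled:
                ax.annotate(r.label, (r.delta_d, y), fontsize=7,
                            xytext=(3, 3), textcoords="offset points")
        ax.axvline(0.0, color="gray", linestyle="--", linewidth=0.8)
        ax.axhline(0.0, color="black", linewidth=0.6)
        ax.set_xlabel(r"$d_{O_p} - d_{S}$ (Å)")
        ax.set_ylabel(r"$\Delta\Delta E^{\ddag}$ (kcal·mol$^{-1}$)")
        ax.set_title(f"scan mode {mode}")
        fig.tight_layout()
        fig.savefig(render, dpi=150)
        plt.close(fig)
    return outpath
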