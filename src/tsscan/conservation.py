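"""Positional conservation grading, ConSurf-export parsing, and candidate
filtering by evolutionary plausibility.

Conservation is graded per query position on the ConSurf-style 1–9 scale
(9 = most conserved).  Here the score behind the grade is the Jensen–Shannon
divergence of the column's residue-frequency distribution (gaps excluded,
sequences weighted by the Henikoff position-based scheme) from a background
amino-acid distribution; scores are ranked and binned into nine
equal-population grades.  True ConSurf grade exports are accepted as an
alternative input.

Candidate filtering implements the engineering logic of the scan: residues
whose alanine truncation lowers the barrier should be replaced by
*non-charged* residues observed at the position in homologues or with a good
BLOSUM62 score; residues where a ±1e probe lowers the barrier suggest a
charged replacement of that sign, flagged risky when homologues never show
one.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment, substitution_matrices
from scipy.spatial.distance import jensenshannon

from .constants import (
    AA1_TO_3,
    AA3_TO_1,
    BLOSUM62_BACKGROUND,
    CLASS_NEGATIVE,
    CLASS_POSITIVE,
    DEFAULT_LABEL_THRESHOLD,
    RESIDUE_CLASS,
)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = set("-.")


class AlignmentError(ValueError):
    """Raised for unreadable or malformed alignments / grade files."""


@dataclass
class ConservationRecord:
    """One query position's conservation grade and observed variability."""

    position: int  # 1-based in the query sequence
    grade: int  # 1 (variable) .. 9 (conserved)
    variability: list[tuple[str, float | None]]  # (1-letter aa, frequency)
    n_effective: int  # non-gap homologue residues at the column
    query_residue: str | None = None
    grade_range: tuple[int, int] | None = None
    score: float | None = None  # raw divergence score, when computed here

    def variant_residues(self) -> set[str]:
        return {aa for aa, _ in self.variability}


# ---------------------------------------------------------------------------
# MSA input and column bookkeeping
# ---------------------------------------------------------------------------

def read_msa(path: str | Path) -> MultipleSeqAlignment:
    """Read an aligned FASTA file (equal row lengths enforced)."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise AlignmentError(f"empty or missing alignment: {path}")
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise AlignmentError(f"bad alignment {path}: {exc}") from exc
    return aln


def map_columns(alignment: MultipleSeqAlignment,
                query_id: str | None = None) -> dict[int, int]:
    """Map 1-based alignment columns to 1-based query positions.

    Columns where the query carries a gap are unmapped; the mapping is
    strictly increasing by construction.
    """
    query = _query_row(alignment, query_id)
    mapping: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(str(query.seq), start=1):
        if ch not in GAP_CHARS:
            pos += 1
            mapping[col] = pos
    return mapping


def _query_row(alignment: MultipleSeqAlignment, query_id: str | None):
    if query_id is None:
        return alignment[0]
    for rec in alignment:
        if rec.id == query_id:
            return rec
    raise AlignmentError(f"query {query_id!r} not in alignment")


def henikoff_weights(alignment: MultipleSeqAlignment) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff), summing to 1.

    Gaps are treated as an ordinary symbol type for weighting purposes, so
    duplicated sequences share — rather than multiply — their weight.
    """
    rows = [str(rec.seq).upper() for rec in alignment]
    n, L = len(rows), len(rows[0])
    w = np.zeros(n)
    for col in range(L):
        symbols = [row[col] for row in rows]
        counts: dict[str, int] = {}
        for s in symbols:
            counts[s] = counts.get(s, 0) + 1
        r = len(counts)
        for i, s in enumerate(symbols):
            w[i] += 1.0 / (r * counts[s])
    total = w.sum()
    if total == 0:
        raise AlignmentError("degenerate alignment: zero total weight")
    return w / total


# ---------------------------------------------------------------------------
# grading
# ---------------------------------------------------------------------------

def _column_distribution(column: Sequence[str], weights: np.ndarray
                         ) -> tuple[np.ndarray, int]:
    """Weighted residue-frequency vector over the 20 amino acids (gaps out)."""
    freq = np.zeros(len(AA_ORDER))
    n_obs = 0
    for ch, w in zip(column, weights):
        ch = ch.upper()
        if ch in GAP_CHARS:
            continue
        idx = AA_ORDER.find(ch)
        if idx < 0:  # X / nonstandard: ignored for the distribution
            continue
        freq[idx] += w
        n_obs += 1
    return freq, n_obs


def _background_vector(background: dict[str, float] | None) -> np.ndarray:
    bg = background or BLOSUM62_BACKGROUND
    vec = np.array([bg[aa] for aa in AA_ORDER], dtype=float)
    return vec / vec.sum()


def grades_from_scores(scores: Sequence[float]) -> list[int]:
    """Bin scores into nine equal-population grades, 9 = highest score.

    Grade boundaries are the 1/9 … 8/9 score quantiles; a score equal to a
    boundary falls in the upper bin, so tied scores always share a grade
    (an alignment of identical columns grades 9 everywhere).
    """
    scores = np.asarray(scores, dtype=float)
    cuts = np.quantile(scores, np.arange(1, 9) / 9.0)
    return [int(1 + np.sum(s >= cuts)) for s in scores]


def conservation_grades(alignment: MultipleSeqAlignment,
                        query_id: str | None = None,
                        background: dict[str, float] | None = None,
                        freq_floor: float = 0.02
                        ) -> list[ConservationRecord]:
    """Grade every query position of the alignment on the 1–9 scale.

    The per-column score is the Jensen–Shannon divergence (base-2) between
    the Henikoff-weighted residue distribution and the background; a column
    drifting far from background composition — ultimately a point mass — is
    conserved.  Scores are binned into nine equal-population grades.
    """
    query = _query_row(alignment, query_id)
    n_others = len(alignment) - 1
    if n_others < 5:
        warnings.warn(
            f"only {n_others} non-query sequences; grades will be noisy",
            stacklevel=2)
    weights = henikoff_weights(alignment)
    mapping = map_columns(alignment, query_id)
    bg = _background_vector(background)
    query_idx = list(alignment).index(query)

    scores: list[float] = []
    meta: list[tuple[int, str, list[tuple[str, float]], int]] = []
    for col, pos in mapping.items():
        column = [str(rec.seq)[col - 1] for rec in alignment]
        freq, _ = _column_distribution(column, weights)
        if freq.sum() == 0:
            raise AlignmentError(f"column {col} has no usable residues")
        p = freq / freq.sum()
        score = float(jensenshannon(p, bg, base=2) ** 2)
        query_aa = column[query_idx].upper()
        non_query = [c.upper() for i, c in enumerate(column)
                     if i != query_idx and c.upper() not in GAP_CHARS]
        n_eff = len(non_query)
        variability = [
            (AA_ORDER[i], float(p[i]))
            for i in np.argsort(-p)
            if p[i] >= freq_floor and AA_ORDER[i] != query_aa
        ]
        scores.append(score)
        meta.append((pos, query_aa, variability, n_eff))

    grades = grades_from_scores(scores)
    return [
        ConservationRecord(position=pos, grade=g, variability=var,
                           n_effective=n_eff, query_residue=q, score=s)
        for (pos, q, var, n_eff), g, s in zip(meta, grades, scores)
    ]


# ---------------------------------------------------------------------------
# ConSurf exports
# ---------------------------------------------------------------------------

_CONSURF_ROW = re.compile(
    r"^\s*(?P<res>[A-Za-z]{3})\s*(?P<pos>\d+)\*?\s+"
    r"(?P<lo>\d)\s*(?:[-–—]\s*(?P<hi>\d))?\s*(?P<var>.*)$"
)


def parse_consurf(path: str | Path) -> list[ConservationRecord]:
    """Parse a ConSurf-style grades text export.

    Expected rows look like ``Asp87  9  Glu`` or ``Asp214  8–9  Val, Gly,
    Ala, Glu, Ser`` (grade ranges kept as min/max; emphasis markers and
    trailing asterisks tolerated).  Variant frequencies are not reported by
    ConSurf and are stored as ``None``.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise AlignmentError(f"empty or missing grades file: {path}")
    records: list[ConservationRecord] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.replace("**", "").strip()
        if not line or line.startswith("#") or line.upper().startswith(
                ("RESIDUE", "SCORE", "MUTATION")):
            continue
        m = _CONSURF_ROW.match(line)
        if not m:
            raise AlignmentError(f"{path}:{lineno}: malformed row {line!r}")
        res3 = m.group("res").upper()
        if res3 not in AA3_TO_1:
            raise AlignmentError(f"{path}:{lineno}: unknown residue {res3}")
        lo = int(m.group("lo"))
        hi = int(m.group("hi")) if m.group("hi") else lo
        variants = []
        for token in re.split(r"[,\s]+", m.group("var")):
            token = token.strip("*,").capitalize()
            if not token:
                continue
            if token.upper() not in AA3_TO_1:
                raise AlignmentError(
                    f"{path}:{lineno}: unknown variant residue {token!r}")
            variants.append((AA3_TO_1[token.upper()], None))
        records.append(ConservationRecord(
            position=int(m.group("pos")), grade=hi, grade_range=(lo, hi),
            variability=variants, n_effective=0,
            query_residue=AA3_TO_1[res3]))
    if not records:
        raise AlignmentError(f"no grade rows found in {path}")
    return records


# ---------------------------------------------------------------------------
# candidate filtering
# ---------------------------------------------------------------------------

MODE_ALA_SCAN = "ALA_SCAN"
MODE_PROBE = "PROBE"

_NEVER_PROPOSED = {"G", "P"}  # glycine/proline insertions disturb the backbone


def _is_charged(aa1: str) -> bool:
    cls = RESIDUE_CLASS[AA1_TO_3[aa1]]
    return cls in (CLASS_POSITIVE, CLASS_NEGATIVE)


@dataclass(frozen=True)
class SubstitutionFilter:
    """BLOSUM62 compatibility filter for replacement residues."""

    min_score: int = 0
    matrix: object = field(default_factory=lambda:
                           substitution_matrices.load("BLOSUM62"))

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[a, b])

    def compatible(self, wt: str, candidate: str) -> bool:
        return self.score(wt, candidate) >= self.min_score


@dataclass(frozen=True)
class MutationCandidate:
    """One proposed replacement with its provenance and driving ΔΔE‡."""

    residue_id: tuple[str, int]
    wild_type: str  # 1-letter
    replacement: str  # 1-letter
    provenance: str  # variability | blosum | risky
    ddE: float
    mode: str
    grade: int | None = None


def suggest_mutations(scan_records, conservation_records:
                      Sequence[ConservationRecord] | None,
                      subst_filter: SubstitutionFilter | None = None,
                      mode: str = MODE_ALA_SCAN,
                      threshold: float = DEFAULT_LABEL_THRESHOLD,
                      exclude_positions: Iterable[tuple[str, int]] = (),
                      position_offset: int = 0) -> list[MutationCandidate]:
    """Propose replacements for residues whose perturbation lowers the barrier.

    ``ALA_SCAN`` mode: residues with ΔΔE‡(Ala) < −threshold get non-charged
    replacements drawn from the position's homologue variability, else from
    BLOSUM62-compatible residues.  ``PROBE`` mode: residues where a ±1e probe
    lowers the barrier get charged replacements of that sign, flagged
    ``risky`` unless homologues actually show such a residue there.
    Catalytic/QM positions (``exclude_positions``) and Gly/Pro insertions are
    never proposed.
    """
    if mode not in (MODE_ALA_SCAN, MODE_PROBE):
        raise ValueError(f"unknown suggestion mode {mode!r}")
    subst_filter = subst_filter or SubstitutionFilter()
    by_pos: dict[int, ConservationRecord] = {}
    for rec in conservation_records or ():
        by_pos[rec.position] = rec
    excluded = set(exclude_positions)

    candidates: list[MutationCandidate] = []
    for r in scan_records:
        if r.residue_id in excluded or r.error:
            continue
        wt3 = r.residue_name.upper()
        if wt3 not in AA3_TO_1:
            continue
        wt1 = AA3_TO_1[wt3]
        cons = by_pos.get(r.residue_id[1] - position_offset)
        variants = cons.variant_residues() if cons else set()
        grade = cons.grade if cons else None

        if mode == MODE_ALA_SCAN:
            if not (r.ddE_ala < -threshold):
                continue
            seen: set[str] = set()
            for aa, _ in (cons.variability if cons else []):
                if aa in _NEVER_PROPOSED or aa == wt1 or _is_charged(aa):
                    continue
                seen.add(aa)
                candidates.append(MutationCandidate(
                    r.residue_id, wt1, aa, "variability", r.ddE_ala, mode,
                    grade))
            for aa in AA_ORDER:
                if (aa in seen or aa in _NEVER_PROPOSED or aa == wt1
                        or _is_charged(aa)):
                    continue
                if subst_filter.compatible(wt1, aa):
                    candidates.append(MutationCandidate(
                        r.residue_id, wt1, aa, "blosum", r.ddE_ala, mode,
                        grade))
        else:  # PROBE
            for ddE, pool in ((r.ddE_probe_pos, ("K", "R")),
                              (r.ddE_probe_neg, ("D", "E"))):
                if not (ddE < -threshold):
                    continue
                for aa in pool:
                    if aa == wt1:
                        continue
                    provenance = "variability" if aa in variants else "risky"
                    candidates.append(MutationCandidate(
                        r.residue_id, wt1, aa, provenance, ddE, mode, grade))

    candidates.sort(key=lambda c: (c.ddE, c.residue_id, c.replacement))
    return candidates


def candidates_to_frame(candidates: Sequence[MutationCandidate]):
    """Candidate list as a tidy pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame([{
        "chain": c.residue_id[0],
        "resid": c.residue_id[1],
        "wild_type": c.wild_type,
        "replacement": c.replacement,
        "mutation": f"{c.wild_type}{c.residue_id[1]}{c.replacement}",
        "mode": c.mode,
        "provenance": c.provenance,
        "ddE": c.ddE,
        "grade": c.grade if c.grade is not None else "",
    } for c in candidates])
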