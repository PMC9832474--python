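"""One-command orchestration: config in, ranked candidate report out.

Runs the full chain — structure pairing, shell selection, alanine/probe
scanning, distance-asymmetry analysis, conservation filtering — and writes
deterministic TSV/JSON reports plus a log of every threshold that shaped
them.  Per-residue computations are independent; ``n_jobs`` simply splits
them over threads with results identical to serial execution.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .constants import (
    DEFAULT_LABEL_THRESHOLD,
    DEFAULT_SHELL_CUTOFF,
)
from .conservation import (
    MODE_ALA_SCAN,
    MODE_PROBE,
    MutationCandidate,
    SubstitutionFilter,
    candidates_to_frame,
    conservation_grades,
    parse_consurf,
    read_msa,
    suggest_mutations,
)
from .energetics import ALL_MODES, EnergyModel, scan as energy_scan
from .geometry_analysis import (
    ScanRecord,
    build_records,
    export_figure_data,
    rank_and_label,
    records_to_frame,
)
from .mutagenesis import ALA_PLUS_PROBE, ALA_TRUNCATE, MutantSpec, write_qmmm_manifest
from .structures import (
    REACT,
    TS1,
    StatePair,
    pair_states,
    read_structure,
    select_shell,
)

logger = logging.getLogger("tsscan")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Everything a scan run needs; mirrors the YAML config file keys."""

    react_pdb: str = ""
    ts_pdb: str = ""
    react_charges: str = ""
    ts_charges: str = ""
    qm_selection: list = field(default_factory=list)
    o_p: str = ""
    s_dbt: str = ""
    o_d: str | None = None
    active_site: list | None = None
    cutoff: float = DEFAULT_SHELL_CUTOFF
    excluded_names: list = field(default_factory=list)
    scan_modes: list = field(default_factory=lambda: list(ALL_MODES))
    truncation_mode: str = "ZERO_SIDECHAIN"
    label_threshold: float = DEFAULT_LABEL_THRESHOLD
    min_blosum_score: int = 0
    include_env_env: bool = False
    distance_state: str = "REACT"
    msa: str | None = None
    query_id: str | None = None
    consurf: str | None = None
    position_offset: int = 0
    output_dir: str = "tsscan_out"
    seed: int = 0
    n_jobs: int = 1
    write_manifests: bool = False
    render_figures: bool = False

    def validate(self) -> None:
        for key in ("react_pdb", "ts_pdb", "react_charges", "ts_charges"):
            value = getattr(self, key)
            if not value:
                raise ConfigError(f"config key {key!r} is required")
            if not Path(value).exists():
                raise ConfigError(f"{key}: file not found: {value}")
        for key in ("msa", "consurf"):
            value = getattr(self, key)
            if value and not Path(value).exists():
                raise ConfigError(f"{key}: file not found: {value}")
        if not self.qm_selection:
            raise ConfigError("qm_selection must not be empty")
        if not self.o_p or not self.s_dbt:
            raise ConfigError("o_p and s_dbt reference atoms are required")
        if not self.scan_modes:
            raise ConfigError("scan_modes must not be empty")
        bad = set(self.scan_modes) - set(ALL_MODES)
        if bad:
            raise ConfigError(f"unknown scan modes: {sorted(bad)}")
        if self.label_threshold <= 0:
            raise ConfigError("label_threshold must be positive")
        if self.cutoff <= 0:
            raise ConfigError("cutoff must be positive")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config file into a validated RunConfig."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    config = RunConfig(**data)
    config.validate()
    return config


@dataclass
class ScanReport:
    """Everything a run produced, in memory plus on disk."""

    pair: StatePair
    shell: Sequence
    records: list[ScanRecord]
    rankings: dict[str, list[ScanRecord]]
    candidates: list[MutationCandidate]
    conservation: list | None
    outputs: dict[str, Path]


def _setup_logging(output_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(output_dir / "scan.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler)
               and h.stream is sys.stderr for h in logger.handlers):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(stream)
    return handler


def run_scan(config: RunConfig) -> ScanReport:
    """Execute the full screening pipeline for one configuration."""
    config.validate()
    output_dir = Path(config.output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    log_handler = _setup_logging(output_dir)
    try:
        return _run_scan(config, output_dir)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _run_scan(config: RunConfig, output_dir: Path) -> ScanReport:
    logger.info("tsscan %s, seed %d", __version__, config.seed)
    logger.info(
        "thresholds: cutoff=%.2f Å, label=%.2f kcal/mol, probe=±1.0 e, "
        "truncation=%s, blosum_min=%d",
        config.cutoff, config.label_threshold, config.truncation_mode,
        config.min_blosum_score)

    react = read_structure(config.react_pdb, config.react_charges, REACT,
                           qm_selection=config.qm_selection)
    ts = read_structure(config.ts_pdb, config.ts_charges, TS1,
                        qm_selection=config.qm_selection)
    pair = pair_states(react, ts, config.o_p, config.s_dbt, config.o_d)
    logger.info("paired %d/%d atoms (%d orphans)", len(pair.correspondence),
                len(react), len(pair.react_only) + len(pair.ts_only))

    active_site = None
    if config.active_site:
        from .structures import resolve_selection
        active_site = resolve_selection(react.atoms, config.active_site)
    shell = select_shell(pair, active_site=active_site, cutoff=config.cutoff,
                         excluded_names=config.excluded_names)
    logger.info("shell: %d residues within %.1f Å", len(shell), config.cutoff)

    model = EnergyModel(include_env_env=config.include_env_env)
    energies = energy_scan(pair, shell, model=model,
                           modes=tuple(config.scan_modes),
                           truncation_mode=config.truncation_mode,
                           n_jobs=config.n_jobs)
    failed = [e for e in energies if e.error]
    for e in failed:
        logger.warning("residue %s quarantined: %s", e.residue_id, e.error)

    records = build_records(pair, energies, threshold=config.label_threshold,
                            distance_state=config.distance_state)
    rankings = {mode: rank_and_label(records, mode=mode,
                                     threshold=config.label_threshold)
                for mode in config.scan_modes}

    conservation = None
    if config.consurf:
        conservation = parse_consurf(config.consurf)
        logger.info("conservation: %d graded positions (ConSurf export)",
                    len(conservation))
    elif config.msa:
        alignment = read_msa(config.msa)
        conservation = conservation_grades(alignment,
                                           query_id=config.query_id)
        logger.info("conservation: %d graded positions (MSA, %d sequences)",
                    len(conservation), len(alignment))
    else:
        logger.warning("no MSA or ConSurf input: candidate report will lack "
                       "conservation filtering")

    qm_positions = {k[:2] for k in pair.react.qm_selection}
    subst = SubstitutionFilter(min_score=config.min_blosum_score)
    candidates: list[MutationCandidate] = []
    if "ALA" in config.scan_modes:
        candidates += suggest_mutations(
            records, conservation, subst, mode=MODE_ALA_SCAN,
            threshold=config.label_threshold,
            exclude_positions=qm_positions,
            position_offset=config.position_offset)
    if {"PROBE_POS", "PROBE_NEG"} & set(config.scan_modes):
        candidates += suggest_mutations(
            records, conservation, subst, mode=MODE_PROBE,
            threshold=config.label_threshold,
            exclude_positions=qm_positions,
            position_offset=config.position_offset)
    logger.info("%d candidate mutations", len(candidates))

    outputs = _write_outputs(config, output_dir, records, rankings,
                             candidates)
    if config.write_manifests:
        outputs.update(_write_manifests(config, pair, shell, output_dir))
    return ScanReport(pair=pair, shell=shell, records=records,
                      rankings=rankings, candidates=candidates,
                      conservation=conservation, outputs=outputs)


def _write_outputs(config: RunConfig, output_dir: Path, records, rankings,
                   candidates) -> dict[str, Path]:
    outputs: dict[str, Path] = {}
    scan_path = output_dir / "scan.tsv"
    records_to_frame(records).to_csv(scan_path, sep="\t", index=False,
                                     float_format="%.6f")
    outputs["scan"] = scan_path

    cand_path = output_dir / "candidates.tsv"
    candidates_to_frame(candidates).to_csv(cand_path, sep="\t", index=False,
                                           float_format="%.6f")
    outputs["candidates"] = cand_path

    for mode, ranked in rankings.items():
        fig_path = output_dir / f"figure_{mode.lower()}.tsv"
        render = (output_dir / f"figure_{mode.lower()}.png"
                  if config.render_figures else None)
        export_figure_data(ranked, fig_path, render=render, mode=mode)
        outputs[f"figure_{mode}"] = fig_path

    summary = {
        "version": __version__,
        "seed": config.seed,
        "cutoff": config.cutoff,
        "label_threshold": config.label_threshold,
        "scan_modes": list(config.scan_modes),
        "n_shell": len(records),
        "n_candidates": len(candidates),
    }
    summary_path = output_dir / "run.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs["summary"] = summary_path
    return outputs


def _write_manifests(config: RunConfig, pair: StatePair, shell,
                     output_dir: Path) -> dict[str, Path]:
    outputs: dict[str, Path] = {}
    manifest_root = output_dir / "qmmm"
    for residue_id in shell:
        specs = []
        if "ALA" in config.scan_modes:
            specs.append(MutantSpec(residue_id, scheme=ALA_TRUNCATE,
                                    truncation_mode=config.truncation_mode))
        for mode, q in (("PROBE_POS", +1.0), ("PROBE_NEG", -1.0)):
            if mode in config.scan_modes:
                specs.append(MutantSpec(
                    residue_id, scheme=ALA_PLUS_PROBE, probe_charge=q,
                    truncation_mode=config.truncation_mode))
        for spec in specs:
            tag = spec.scheme.lower()
            if spec.probe_charge:
                tag += "_pos" if spec.probe_charge > 0 else "_neg"
            subdir = manifest_root / f"{residue_id[0]}{residue_id[1]}_{tag}"
            write_qmmm_manifest(pair, spec, subdir)
            outputs[f"manifest_{residue_id[0]}{residue_id[1]}_{tag}"] = subdir
    return outputs
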