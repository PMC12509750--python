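"""End-to-end orchestration: simulate -> search -> screen -> quant.

Each stage is a plain function taking a :class:`PipelineConfig` and an
output directory, reading the previous stage's artifacts from disk and
writing its own (FASTA/MGF/TSV plus a run log), so stages can be run
separately or chained with :func:`run_all`.  Every run is reproducible
from its logged configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from . import chem, digest as dg, quant as qt, screen as sc, search as se
from .spectra import NoiseConfig, read_mgf, write_mgf
from .synthetic_data import (
    SimConfig,
    simulate_proteome,
    simulate_quant,
    simulate_spectra,
    write_fasta,
    write_locations,
)

__all__ = [
    "PipelineConfig",
    "load_config",
    "run_simulate",
    "run_search",
    "run_screen",
    "run_quant",
    "run_all",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage configurations plus the global seed.

    Defaults are the search and screening settings used throughout:
    10 ppm / 0.02 Da tolerances, 1% PSM FDR, 2 missed cleavages,
    charge-specific XCorr reliability thresholds {2: 2.2, 3: 3.75},
    and differential-expression thresholds FC > 1.5 or < 0.67 at
    FDR < 0.05.
    """

    seed: int = 1
    digest: dg.DigestConfig = field(default_factory=dg.DigestConfig)
    search: se.SearchConfig = field(default_factory=se.SearchConfig)
    screen: sc.ScreenCriteria = field(default_factory=sc.ScreenCriteria)
    sim: SimConfig = field(default_factory=SimConfig)


def _build_section(cls, section: str, values: dict):
    try:
        return cls(**values)
    except TypeError as exc:
        raise ValueError(f"config section {section!r}: {exc}") from exc
    except ValueError as exc:
        raise ValueError(f"config section {section!r}: {exc}") from exc


def load_config(path: Union[str, Path, None] = None) -> PipelineConfig:
    """Load a YAML pipeline configuration; missing keys take defaults.

    Raises ``ValueError`` naming the offending section/field on invalid
    input.
    """
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known = {"seed", "digest", "search", "screen", "sim"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    screen_raw = dict(raw.get("screen", {}))
    if "xcorr_thresholds" in screen_raw:
        screen_raw["xcorr_thresholds"] = {
            int(k): float(v) for k, v in screen_raw["xcorr_thresholds"].items()
        }
    if "phenotype_terms" in screen_raw:
        screen_raw["phenotype_terms"] = tuple(screen_raw["phenotype_terms"])
    sim_raw = dict(raw.get("sim", {}))
    if "noise" in sim_raw:
        sim_raw["noise"] = _build_section(NoiseConfig, "sim.noise", sim_raw["noise"])
    for key in ("segments_per_protein", "segment_length"):
        if key in sim_raw:
            sim_raw[key] = tuple(sim_raw[key])
    search_raw = dict(raw.get("search", {}))
    if "charges" in search_raw:
        search_raw["charges"] = tuple(search_raw["charges"])
    return PipelineConfig(
        seed=int(raw.get("seed", 1)),
        digest=_build_section(dg.DigestConfig, "digest", raw.get("digest", {})),
        search=_build_section(se.SearchConfig, "search", search_raw),
        screen=_build_section(sc.ScreenCriteria, "screen", screen_raw),
        sim=_build_section(SimConfig, "sim", sim_raw),
    )


def _log_run(outdir: Path, stage: str, cfg: PipelineConfig, **counts) -> None:
    entry = {
        "stage": stage,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        **counts,
    }
    with open(outdir / f"{stage}.log.json", "w") as fh:
        json.dump(entry, fh, indent=1, default=str)


def run_simulate(cfg: PipelineConfig, outdir: Union[str, Path]) -> dict:
    """Generate proteome FASTA, localization sidecar, per-group MGF files,
    the TMT matrix, a term-set GMT, and a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome = simulate_proteome(cfg.sim, cfg.seed)
    write_fasta(proteome, outdir / "proteome.fasta")
    write_locations(proteome, outdir / "locations.tsv")
    spectra = simulate_spectra(cfg.sim, proteome, cfg.seed + 1)
    for group, specs in spectra.items():
        write_mgf(specs, outdir / f"{group}.mgf")
    qm, truth = simulate_quant(cfg.sim, cfg.seed + 2)
    qm.to_tsv(outdir / "quant.tsv")
    # term sets for enrichment: the planted mitochondrial subset plus
    # random location-themed sets of similar size
    rng = np.random.default_rng(cfg.seed + 3)
    proteins = list(qm.data.index)
    sets = {}
    if truth["mito"]:
        sets["mitochondrion"] = truth["mito"]
    for name in ("nucleus", "cytoplasm", "membrane"):
        size = max(len(truth["mito"]), 20)
        sets[name] = [proteins[i] for i in rng.choice(len(proteins), size, replace=False)]
    qt.write_gmt(sets, outdir / "terms.gmt")
    truth_all = {
        "planted_protein": proteome.planted_protein,
        "planted_peptide": proteome.planted_peptide.sequence,
        "planted_peptide_start": proteome.planted_peptide.start,
        "planted_cys_site": proteome.planted_cys_site,
        "quant": truth,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_all, fh, indent=1)
    _log_run(
        outdir, "simulate", cfg,
        n_proteins=len(proteome.sequences),
        n_spectra={g: len(s) for g, s in spectra.items()},
        n_quant_proteins=len(qm.data),
    )
    return truth_all


def build_database(
    sequences: dict[str, str],
    cfg: PipelineConfig,
    mode: str = "target-id",
) -> list[chem.Peptidoform]:
    """Digest targets plus reversed-sequence decoys and enumerate
    peptidoforms.

    ``target-id`` mode searches carbamidomethyl, the covalent adduct,
    oxidation and protein-N-terminal acetyl as variable modifications;
    ``quant`` mode applies TMT and carbamidomethyl statically with
    oxidation/acetyl variable.
    """
    reg = chem.default_registry()
    if mode == "target-id":
        variable = [reg["carbamidomethyl"], reg["JB"], reg["oxidation"], reg["acetyl"]]
        static = []
    elif mode == "quant":
        variable = [reg["oxidation"], reg["acetyl"]]
        static = [reg["TMT6"], reg["carbamidomethyl"]]
    else:
        raise ValueError(f"unknown database mode {mode!r}")
    all_seqs = dict(sequences)
    all_seqs.update(se.build_decoys(sequences))
    db: list[chem.Peptidoform] = []
    for acc, seq in all_seqs.items():
        is_decoy = acc.startswith("DECOY_")
        for pep in dg.digest(seq, cfg.digest):
            db.extend(
                dg.enumerate_peptidoforms(
                    pep, variable, cfg.digest, protein_id=acc,
                    static_mods=static, is_decoy=is_decoy,
                )
            )
    return db


def run_search(cfg: PipelineConfig, outdir: Union[str, Path]) -> list[se.PSM]:
    """Search both groups' MGF files against the FASTA (+decoys), assign
    target-decoy q-values, write the PSM table."""
    outdir = Path(outdir)
    fasta = outdir / "proteome.fasta"
    if not fasta.exists():
        raise FileNotFoundError(f"missing input: {fasta}")
    sequences, _ = dg.read_fasta(fasta)
    db = build_database(sequences, cfg)
    spectra = []
    for group in ("control", "treated"):
        path = outdir / f"{group}.mgf"
        if not path.exists():
            raise FileNotFoundError(f"missing input: {path}")
        spectra.extend(read_mgf(path))
    psms = se.search(spectra, db, cfg.search)
    psms = se.assign_fdr(psms)
    se.write_psm_table(psms, outdir / "psms.tsv")
    _log_run(
        outdir, "search", cfg,
        n_spectra=len(spectra), n_candidates=len(db), n_psms=len(psms),
        n_accepted=len(se.filter_psms(psms, cfg.search.fdr_cutoff)),
    )
    return psms


def run_screen(cfg: PipelineConfig, outdir: Union[str, Path]) -> list[sc.CandidateRecord]:
    """FDR-filter the PSM table and run the screening funnel; write the
    ranked candidate table."""
    outdir = Path(outdir)
    reg = chem.default_registry()
    psm_path = outdir / "psms.tsv"
    if not psm_path.exists():
        raise FileNotFoundError(f"missing input: {psm_path}")
    psms = se.read_psm_table(psm_path, reg)
    accepted = se.filter_psms(psms, cfg.search.fdr_cutoff)
    locations = {}
    loc_path = outdir / "locations.tsv"
    if loc_path.exists():
        with open(loc_path) as fh:
            fh.readline()
            for line in fh:
                acc, loc = line.rstrip("\n").split("\t")
                locations[acc] = loc
    jb = reg["JB"]
    records = sc.collect_modified_proteins(accepted, jb, locations)
    both = sc.identified_both(accepted, jb)
    records = [
        dataclasses.replace(r, identified_both=both.get(r.protein, False))
        for r in records
    ]
    records = sc.reliability_filter(records, cfg.screen)
    records = sc.prioritize(records, cfg.screen)
    sc.write_candidate_table(records, outdir / "candidates.tsv")
    _log_run(outdir, "screen", cfg, n_candidates=len(records))
    return records


def run_quant(cfg: PipelineConfig, outdir: Union[str, Path]):
    """Normalize the TMT matrix, call DEPs, and run ORA of the down-called
    set against the term sets (if a GMT is present)."""
    outdir = Path(outdir)
    qpath = outdir / "quant.tsv"
    if not qpath.exists():
        raise FileNotFoundError(f"missing input: {qpath}")
    qm = qt.QuantMatrix.from_tsv(qpath)
    qm = qt.normalize_channels(qm)
    dep = qt.differential(qm)
    dep.index.name = "protein"
    dep.to_csv(outdir / "dep.tsv", sep="\t")
    enr = None
    gmt = outdir / "terms.gmt"
    if gmt.exists():
        sets = qt.read_gmt(gmt)
        down = list(dep.index[dep["call"] == "down"])
        enr = qt.ora_enrichment(down, sets, list(dep.index))
        enr.to_csv(outdir / "enrichment.tsv", sep="\t")
    _log_run(
        outdir, "quant", cfg,
        n_proteins=len(dep),
        n_up=int((dep["call"] == "up").sum()),
        n_down=int((dep["call"] == "down").sum()),
    )
    return dep, enr


def run_all(cfg: PipelineConfig, outdir: Union[str, Path]) -> dict:
    """simulate -> search -> screen -> quant; write a summary naming the
    top-ranked covalent-target candidate."""
    outdir = Path(outdir)
    truth = run_simulate(cfg, outdir)
    run_search(cfg, outdir)
    records = run_screen(cfg, outdir)
    dep, enr = run_quant(cfg, outdir)
    top = records[0] if records else None
    summary = {
        "top_candidate": top.protein if top else None,
        "top_candidate_xcorr": round(top.xcorr, 4) if top else None,
        "top_candidate_location": top.location if top else None,
        "n_candidates": len(records),
        "n_dep_up": int((dep["call"] == "up").sum()),
        "n_dep_down": int((dep["call"] == "down").sum()),
        "planted_protein": truth["planted_protein"],
        "seed": cfg.seed,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    lines = [
        f"top-ranked covalent-target candidate: {summary['top_candidate']}"
        f" (XCorr {summary['top_candidate_xcorr']},"
        f" {summary['top_candidate_location']})",
        f"candidates screened: {summary['n_candidates']}",
        f"differential proteins: {summary['n_dep_up']} up,"
        f" {summary['n_dep_down']} down",
    ]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary
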