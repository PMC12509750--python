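"""Synthetic inputs with the statistical structure the pipeline assumes.

Real chemoproteomics acquisitions are large and instrument-specific, so
every stage here can instead be exercised on generated data: a random
tryptic proteome with one planted covalent-target protein (a cysteine
inside a clean tryptic peptide, annotated mitochondrial), MS/MS spectra
for two experimental arms (the planted site carbamidomethylated in
controls, adduct-bearing in a configurable fraction of treated spectra
— which creates the identified-both ground truth), and a 6-channel TMT
intensity matrix with planted fold changes, including a down-regulated
mitochondrial subset in mitochondrial-provenance mode.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .chem import Peptidoform, default_registry
from .digest import DigestConfig, Peptide, digest
from .screen import CandidateRecord
from .spectra import NoiseConfig, Spectrum, render_synthetic
from .quant import QuantMatrix

__all__ = [
    "SimConfig",
    "SimulatedProteome",
    "simulate_proteome",
    "simulate_spectra",
    "simulate_quant",
    "reference_candidates",
    "write_fasta",
    "write_locations",
]

# residues allowed inside a tryptic segment (no internal K/R); P additionally
# excluded from segment starts so cleavage after the preceding K/R is never blocked
_SEGMENT_ALPHABET = np.array(list("ACDEFGHILMNPQSTVWY"))
_START_ALPHABET = np.array(list("ACDEFGHILMNQSTVWY"))

_LOCATIONS = (
    "Cytoplasm", "Nucleus", "Cell membrane", "Secreted protein",
    "Golgi apparatus", "Endoplasmic reticulum",
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment.

    The spectra arm mirrors a two-group target-identification run: one
    mitochondrial protein carries the covalent adduct on a known
    cysteine, half of the treated-group spectra of that peptide bear the
    adduct (``adduct_fraction``), and the rest of both groups is
    background peptides with carbamidomethylated cysteines.  The quant
    arm mirrors a 3 + 3 TMT experiment with planted fold changes.
    """

    n_proteins: int = 20
    segments_per_protein: tuple[int, int] = (8, 16)
    segment_length: tuple[int, int] = (5, 11)
    planted_protein: str = "TARGET01"
    adduct_fraction: float = 0.5
    planted_spectra_per_group: int = 10
    n_spectra_per_group: int = 150
    noise: NoiseConfig = field(
        default_factory=lambda: NoiseConfig(
            peak_fraction=0.9, intensity_cv=0.2, n_noise_peaks=30,
            mz_jitter_sd=0.004,
        )
    )
    # TMT arm
    n_quant_proteins: int = 500
    n_up: int = 20
    n_down: int = 20
    fold_up: float = 2.0
    fold_down: float = 0.5
    intensity_cv: float = 0.10
    mito_subset_size: int = 30
    mito_fold: float = 0.5
    provenance: str = "whole-cell"

    def __post_init__(self) -> None:
        if not 0.0 <= self.adduct_fraction <= 1.0:
            raise ValueError("adduct_fraction must be in [0, 1]")
        if self.n_proteins < 2:
            raise ValueError("need at least 2 proteins")


@dataclass
class SimulatedProteome:
    sequences: dict[str, str]
    locations: dict[str, str]
    planted_protein: str
    planted_peptide: Peptide      # position within the planted protein
    planted_cys_site: int         # 1-based within the peptide


def _random_segment(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    chars = [str(rng.choice(_START_ALPHABET))]
    chars += list(rng.choice(_SEGMENT_ALPHABET, size=n - 1))
    return "".join(chars) + str(rng.choice(np.array(["K", "R"])))


def simulate_proteome(cfg: SimConfig, seed: int) -> SimulatedProteome:
    """Random tryptic proteome with one planted covalent-target protein.

    Segment construction guarantees every protein yields tryptic
    peptides in the 6-40 residue range.  The planted protein contains a
    unique, non-palindromic cysteine peptide and is annotated
    mitochondrial in the localization sidecar.
    """
    rng = np.random.default_rng(seed)
    lo_s, hi_s = cfg.segments_per_protein
    lo_l, hi_l = cfg.segment_length
    sequences: dict[str, str] = {}
    locations: dict[str, str] = {}

    planted_seg = None
    for attempt in range(1000):
        seg = _random_segment(rng, max(lo_l, 8), hi_l)
        core = list(seg[:-1])
        pos = int(rng.integers(2, len(core)))  # keep Cys off the first residue
        core[pos] = "C"
        seg = "".join(core) + seg[-1]
        if seg != seg[::-1] and seg.count("C") == 1:
            planted_seg = seg
            planted_site = pos + 1
            break
    if planted_seg is None:
        raise RuntimeError("could not construct a planted cysteine peptide")

    ids = [cfg.planted_protein] + [
        f"P{i:04d}" for i in range(1, cfg.n_proteins)
    ]
    for idx, acc in enumerate(ids):
        n_seg = int(rng.integers(lo_s, hi_s + 1))
        segs = [_random_segment(rng, lo_l, hi_l) for _ in range(n_seg)]
        if acc == cfg.planted_protein:
            insert_at = n_seg // 2
            segs[insert_at] = planted_seg
        seq = "".join(segs)
        sequences[acc] = seq
        if acc == cfg.planted_protein:
            locations[acc] = "Mitochondrion outer membrane"
            start = sum(len(s) for s in segs[:insert_at]) + 1
            planted_peptide = Peptide(planted_seg, start)
        else:
            locations[acc] = str(rng.choice(np.array(_LOCATIONS)))

    # the planted peptide must be a real digestion product in range
    dcfg = DigestConfig()
    assert any(
        p.sequence == planted_peptide.sequence and p.start == planted_peptide.start
        for p in digest(sequences[cfg.planted_protein], dcfg)
    ), "planted peptide not recovered by digestion"

    return SimulatedProteome(
        sequences, locations, cfg.planted_protein, planted_peptide,
        planted_cys_site=planted_site,
    )


def _charge_for(peptide: str) -> int:
    return 2 if len(peptide) <= 14 else 3


def simulate_spectra(
    cfg: SimConfig, proteome: SimulatedProteome, seed: int
) -> dict[str, list[Spectrum]]:
    """Two-group MS/MS spectra.

    Control: the planted site is always carbamidomethylated.  Treated:
    each planted-peptide spectrum carries the adduct with probability
    ``cfg.adduct_fraction`` and carbamidomethyl otherwise.  Background
    spectra come from other tryptic peptides (cysteines alkylated).
    """
    rng = np.random.default_rng(seed)
    reg = default_registry()
    jb, cam = reg["JB"], reg["carbamidomethyl"]
    dcfg = DigestConfig(max_missed_cleavages=0)

    background: list[Peptidoform] = []
    for acc, seq in proteome.sequences.items():
        for pep in digest(seq, dcfg):
            if (
                acc == proteome.planted_protein
                and pep.sequence == proteome.planted_peptide.sequence
            ):
                continue
            mods = {
                i: cam for i, aa in enumerate(pep.sequence, 1) if aa == "C"
            }
            background.append(Peptidoform(pep.sequence, mods, acc, pep.start))
    if not background:
        raise ValueError("proteome produced no background peptides")

    planted = proteome.planted_peptide
    site = proteome.planted_cys_site
    pf_cam = Peptidoform(
        planted.sequence, {site: cam}, proteome.planted_protein, planted.start
    )
    pf_jb = Peptidoform(
        planted.sequence, {site: jb}, proteome.planted_protein, planted.start
    )

    out: dict[str, list[Spectrum]] = {}
    for group in ("control", "treated"):
        spectra: list[Spectrum] = []
        for k in range(cfg.planted_spectra_per_group):
            if group == "treated" and rng.random() < cfg.adduct_fraction:
                pf = pf_jb
            else:
                pf = pf_cam
            spectra.append(
                render_synthetic(
                    pf, _charge_for(pf.sequence), cfg.noise, rng,
                    spectrum_id=f"{group}_planted_{k}", group=group,
                )
            )
        n_bg = max(cfg.n_spectra_per_group - cfg.planted_spectra_per_group, 0)
        picks = rng.integers(0, len(background), size=n_bg)
        for k, j in enumerate(picks):
            pf = background[int(j)]
            spectra.append(
                render_synthetic(
                    pf, _charge_for(pf.sequence), cfg.noise, rng,
                    spectrum_id=f"{group}_bg_{k}", group=group,
                )
            )
        out[group] = spectra
    return out


def simulate_quant(cfg: SimConfig, seed: int) -> tuple[QuantMatrix, dict[str, list[str]]]:
    """6-channel TMT matrix (3 control + 3 treated) with planted effects.

    Returns the matrix and the ground truth: ``{"up": [...], "down":
    [...], "mito": [...]}``.  Base abundances are log-normal; replicate
    noise has the configured CV; in mitochondrial-provenance mode a
    mitochondrial subset is additionally down-regulated, emulating loss
    of respiratory-chain subunits.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_quant_proteins
    proteins = [f"Q{i:05d}" for i in range(n)]
    base_log2 = rng.normal(20.0, 1.5, n)

    fold = np.ones(n)
    idx = rng.permutation(n)
    up = idx[: cfg.n_up]
    down = idx[cfg.n_up: cfg.n_up + cfg.n_down]
    fold[up] = cfg.fold_up
    fold[down] = cfg.fold_down
    mito: np.ndarray = np.array([], dtype=int)
    if cfg.provenance == "mitochondrial" and cfg.mito_subset_size > 0:
        mito = idx[cfg.n_up + cfg.n_down: cfg.n_up + cfg.n_down + cfg.mito_subset_size]
        fold[mito] = fold[mito] * cfg.mito_fold

    sigma = np.sqrt(np.log1p(cfg.intensity_cv**2)) / np.log(2)  # CV on linear scale
    cols = {}
    for c in range(3):
        cols[f"C{c + 1}"] = np.power(
            2.0, base_log2 + rng.normal(0.0, sigma, n)
        )
    for c in range(3):
        cols[f"T{c + 1}"] = np.power(
            2.0, base_log2 + np.log2(fold) + rng.normal(0.0, sigma, n)
        )
    data = pd.DataFrame(cols, index=proteins)
    groups = {f"C{c}": "control" for c in (1, 2, 3)}
    groups |= {f"T{c}": "treated" for c in (1, 2, 3)}
    truth = {
        "up": [proteins[i] for i in up],
        "down": [proteins[i] for i in down],
        "mito": [proteins[i] for i in mito],
    }
    return QuantMatrix(data, groups, cfg.provenance), truth


def reference_candidates() -> list[CandidateRecord]:
    """The packaged 13-candidate screening table (the worked example the
    funnel is validated against): protein, charge, XCorr, identified-both
    flag and subcellular location for each adduct-bearing protein."""
    path = importlib.resources.files("adductscreen").joinpath(
        "data/screening_candidates.tsv"
    )
    records = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header == ["protein", "charge", "xcorr", "identified_both", "location"]
        for line in fh:
            prot, charge, xc, both, loc = line.rstrip("\n").split("\t")
            records.append(
                CandidateRecord(
                    protein=prot,
                    charge=int(charge),
                    xcorr=float(xc),
                    identified_both=(both == "Yes"),
                    location=loc,
                )
            )
    return records


def write_fasta(proteome: SimulatedProteome, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for acc, seq in proteome.sequences.items():
            loc = proteome.locations.get(acc, "")
            fh.write(f">{acc} location={loc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def write_locations(proteome: SimulatedProteome, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tlocation\n")
        for acc, loc in proteome.locations.items():
            fh.write(f"{acc}\t{loc}\n")
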