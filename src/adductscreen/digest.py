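"""In-silico tryptic digestion, peptidoform enumeration and b/y fragments.

The search database is built here: proteins are cleaved with the full
trypsin rule (after K/R, never before P), each peptide is expanded into
every assignment of variable modifications up to a per-peptide cap, and
each peptidoform yields its theoretical b/y ion series.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

from Bio import SeqIO
from pyteomics import parser as _pparser

from .chem import (
    CTERM,
    NTERM,
    PROTEIN_NTERM,
    PROTON,
    RESIDUE_MASS,
    WATER,
    Modification,
    Peptidoform,
)

__all__ = [
    "DigestConfig",
    "Peptide",
    "Fragment",
    "digest",
    "enumerate_peptidoforms",
    "fragment",
    "read_fasta",
    "TRYPSIN_RULE",
]

# Full trypsin: cleave C-terminal to K or R unless the next residue is P.
TRYPSIN_RULE = r"[KR](?!P)"


@dataclass(frozen=True)
class DigestConfig:
    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 40
    max_variable_mods: int = 4

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")
        if self.enzyme != "trypsin":
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")


@dataclass(frozen=True)
class Peptide:
    """A digestion product with its 1-based position in the parent protein."""

    sequence: str
    start: int
    missed_cleavages: int = 0


def digest(sequence: str, cfg: DigestConfig = DigestConfig()) -> list[Peptide]:
    """All tryptic peptides of ``sequence`` within the configured length
    range and missed-cleavage budget, with 1-based start positions."""
    if not sequence:
        raise ValueError("empty protein sequence")
    out = []
    seen = set()
    for start0, pep in _pparser.icleave(
        sequence,
        TRYPSIN_RULE,
        missed_cleavages=cfg.max_missed_cleavages,
        min_length=1,
        regex=True,
    ):
        if not (cfg.min_length <= len(pep) <= cfg.max_length):
            continue
        key = (pep, start0)
        if key in seen:
            continue
        seen.add(key)
        mc = sum(
            1
            for i in range(len(pep) - 1)
            if pep[i] in "KR" and pep[i + 1] != "P"
        )
        out.append(Peptide(pep, start0 + 1, mc))
    out.sort(key=lambda p: (p.start, len(p.sequence)))
    return out


def enumerate_peptidoforms(
    peptide: Union[Peptide, str],
    variable_mods: Sequence[Modification],
    cfg: DigestConfig = DigestConfig(),
    protein_id: str = "",
    static_mods: Sequence[Modification] = (),
    protein_nterm: bool | None = None,
    is_decoy: bool = False,
) -> list[Peptidoform]:
    """Every assignment of <= ``cfg.max_variable_mods`` variable
    modifications to eligible sites (one mod per site), including the
    unmodified form.  Static modifications are applied at every eligible
    site unconditionally and do not count against the cap.

    ``protein_nterm`` controls eligibility of protein-N-terminal mods;
    by default it is inferred from the peptide's start position.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide, 1)
    seq = peptide.sequence
    if protein_nterm is None:
        protein_nterm = peptide.start == 1

    static: dict[Union[int, str], Modification] = {}
    for mod in static_mods:
        if NTERM in mod.targets:
            static[NTERM] = mod
        if PROTEIN_NTERM in mod.targets and protein_nterm:
            static.setdefault(NTERM, mod)
        for i, aa in enumerate(seq, start=1):
            if aa in mod.targets:
                static[i] = mod

    # Per site, the variable mods that may sit there (site untouched by statics).
    site_options: list[tuple[Union[int, str], list[Modification]]] = []
    term_sites = [(NTERM, NTERM), (CTERM, CTERM)]
    if protein_nterm:
        term_sites.append((NTERM, PROTEIN_NTERM))
    for site, token in term_sites:
        if site in static:
            continue
        opts = [m for m in variable_mods if token in m.targets]
        if opts:
            prev = dict(site_options).get(site)
            if prev:
                prev.extend(o for o in opts if o not in prev)
            else:
                site_options.append((site, opts))
    for i, aa in enumerate(seq, start=1):
        if i in static:
            continue
        opts = [m for m in variable_mods if aa in m.targets]
        if opts:
            site_options.append((i, opts))

    forms: list[Peptidoform] = []
    sites = [s for s, _ in site_options]
    choice_lists = [[None] + opts for _, opts in site_options]
    for combo in itertools.product(*choice_lists):
        n_assigned = sum(1 for c in combo if c is not None)
        if n_assigned > cfg.max_variable_mods:
            continue
        mods = dict(static)
        for site, mod in zip(sites, combo):
            if mod is not None:
                mods[site] = mod
        forms.append(
            Peptidoform(seq, mods, protein_id, peptide.start, is_decoy=is_decoy)
        )
    return forms


@dataclass(frozen=True)
class Fragment:
    ion_type: str  # "b" or "y"
    index: int
    charge: int
    mz: float


def fragment(p: Peptidoform, max_frag_charge: int = 1) -> list[Fragment]:
    """Theoretical b/y ions of ``p`` at charges 1..``max_frag_charge``.

    Modification deltas are carried by every prefix (b) or suffix (y)
    fragment containing the modified site; N-terminal mods ride with b
    ions, C-terminal mods with y ions.
    """
    n = len(p.sequence)
    if n < 2:
        raise ValueError("peptide must have >= 2 residues to fragment")
    site_delta = [0.0] * (n + 1)  # 1-based residue deltas
    nterm_delta = 0.0
    cterm_delta = 0.0
    for site, mod in p.mods.items():
        if site == NTERM:
            nterm_delta += mod.delta
        elif site == CTERM:
            cterm_delta += mod.delta
        else:
            site_delta[site] += mod.delta

    prefix = [0.0] * (n + 1)
    for i, aa in enumerate(p.sequence, start=1):
        prefix[i] = prefix[i - 1] + RESIDUE_MASS[aa] + site_delta[i]
    total = prefix[n]

    frags: list[Fragment] = []
    for i in range(1, n):
        b_neutral = prefix[i] + nterm_delta          # b ion: prefix, no water
        y_neutral = total - prefix[i] + WATER + cterm_delta
        for z in range(1, max_frag_charge + 1):
            frags.append(Fragment("b", i, z, (b_neutral + z * PROTON) / z))
            frags.append(Fragment("y", n - i, z, (y_neutral + z * PROTON) / z))
    frags.sort(key=lambda f: (f.ion_type, f.index, f.charge))
    return frags


def read_fasta(path: Union[str, Path]) -> tuple[dict[str, str], dict[str, str]]:
    """Read a protein FASTA.

    Returns ``(sequences, locations)`` keyed by accession (first token of
    the description line).  A subcellular-localization tag of the form
    ``location=...`` in the description is parsed into ``locations``;
    the value runs to the end of the line so multi-word compartments
    survive round-tripping.
    """
    seqs: dict[str, str] = {}
    locs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
        desc = rec.description
        if "location=" in desc:
            locs[rec.id] = desc.split("location=", 1)[1].strip()
    return seqs, locs
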