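"""Mass arithmetic for peptides and covalent modifications.

Everything downstream of this module (fragment m/z values, precursor
matching, parent-ion mass shifts) is sums of the monoisotopic masses
defined here.  Average masses are never used: the covalent adduct of
interest weighs 330.183 Da only in monoisotopic terms (intact addition
of a C20H26O4 molecule to a cysteine thiol after epoxide ring opening),
and the 10 ppm precursor tolerances in play are far below the
monoisotopic/average gap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

from pyteomics import mass as _pmass

__all__ = [
    "MONOISOTOPIC",
    "RESIDUE_MASS",
    "PROTON",
    "WATER",
    "Modification",
    "Peptidoform",
    "monoisotopic_mass",
    "peptide_neutral_mass",
    "precursor_mz",
    "neutral_from_mz",
    "delta_vs_carbamidomethyl",
    "ppm_within",
    "default_registry",
    "load_registry",
    "dump_registry",
    "NTERM",
    "CTERM",
    "PROTEIN_NTERM",
]

#: Monoisotopic element masses (Da). Carbon is exactly 12 by definition.
MONOISOTOPIC: dict[str, float] = {
    el: iso[0][0]
    for el, iso in _pmass.nist_mass.items()
    if not el[-1].isdigit() and el not in ("e*",)
}

#: Monoisotopic residue masses (Da) for the 20 canonical amino acids.
RESIDUE_MASS: dict[str, float] = {
    aa: m for aa, m in _pmass.std_aa_mass.items() if len(aa) == 1 and aa.isupper()
}

PROTON = 1.00727646688  # mass of H+, for m/z <-> neutral-mass conversion
WATER = MONOISOTOPIC["H"] * 2 + MONOISOTOPIC["O"]

# Terminus tokens used as modification sites, distinct from residue indices.
NTERM = "N-term"
CTERM = "C-term"
PROTEIN_NTERM = "protein-N-term"
_TERMINUS_TOKENS = frozenset({NTERM, CTERM, PROTEIN_NTERM})

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
    return counts


def monoisotopic_mass(formula: Union[str, Mapping[str, int]]) -> float:
    """Monoisotopic mass (Da) of an elemental composition.

    ``formula`` is either a Hill-style string (``"C20H26O4"``) or a
    mapping ``{element: count}``.  Unknown element symbols raise
    ``KeyError`` naming the symbol; negative counts raise ``ValueError``.
    """
    counts = _parse_formula(formula) if isinstance(formula, str) else dict(formula)
    total = 0.0
    for el, n in counts.items():
        if el not in MONOISOTOPIC:
            raise KeyError(f"unknown element symbol: {el!r}")
        if n < 0:
            raise ValueError(f"negative count for element {el}: {n}")
        total += MONOISOTOPIC[el] * n
    return total


@dataclass(frozen=True)
class Modification:
    """A named mass delta with site specificity.

    ``targets`` holds one-letter residue codes and/or terminus tokens
    (:data:`NTERM`, :data:`CTERM`, :data:`PROTEIN_NTERM`).  If an
    elemental ``formula`` is given, its monoisotopic mass must agree
    with ``delta`` to within 1 mDa.
    """

    name: str
    delta: float
    targets: frozenset[str] = field(default_factory=frozenset)
    formula: str | None = None

    def __post_init__(self) -> None:
        if not (self.delta == self.delta and abs(self.delta) != float("inf")):
            raise ValueError(f"non-finite delta for modification {self.name}")
        object.__setattr__(self, "targets", frozenset(self.targets))
        for t in self.targets:
            if t not in _TERMINUS_TOKENS and t not in RESIDUE_MASS:
                raise ValueError(f"invalid modification target {t!r}")
        if self.formula is not None:
            fm = monoisotopic_mass(self.formula)
            if abs(fm - self.delta) > 1e-3:
                raise ValueError(
                    f"modification {self.name}: formula mass {fm:.4f} "
                    f"disagrees with delta {self.delta:.4f}"
                )

    def applies_to(self, site: Union[int, str], residue: str | None = None) -> bool:
        if isinstance(site, str):
            return site in self.targets
        return residue in self.targets


def default_registry() -> dict[str, Modification]:
    """The modifications this pipeline searches, keyed by name.

    Deltas are stored to 4 decimals.  ``JB`` is the cysteine-reactive
    epoxide adduct (intact C20H26O4 addition); ``carbamidomethyl`` the
    iodoacetamide alkylation that marks the control state of the same
    cysteine; TMT6 is applied statically in quantification mode.
    """
    mods = [
        Modification("JB", 330.1831, frozenset("C"), "C20H26O4"),
        Modification("carbamidomethyl", 57.0215, frozenset("C"), "C2H3NO"),
        Modification("oxidation", 15.9949, frozenset("M"), "O"),
        Modification("acetyl", 42.0106, frozenset({PROTEIN_NTERM}), "C2H2O"),
        Modification("TMT6", 229.1629, frozenset({"K", NTERM})),
    ]
    return {m.name: m for m in mods}


def load_registry(path: Union[str, Path]) -> dict[str, Modification]:
    """Read a registry from flat TSV (name, delta, targets, formula)."""
    mods: dict[str, Modification] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["name", "delta", "targets", "formula"]:
            raise ValueError(f"unexpected registry header: {header}")
        for line in fh:
            if not line.strip():
                continue
            name, delta, targets, formula = line.rstrip("\n").split("\t")[:4]
            mods[name] = Modification(
                name,
                float(delta),
                frozenset(targets.split(",")) if targets else frozenset(),
                formula or None,
            )
    return mods


def dump_registry(mods: Mapping[str, Modification], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("name\tdelta\ttargets\tformula\n")
        for m in mods.values():
            fh.write(
                f"{m.name}\t{m.delta:.4f}\t{','.join(sorted(m.targets))}\t"
                f"{m.formula or ''}\n"
            )


@dataclass(frozen=True)
class Peptidoform:
    """A peptide sequence with localized modifications.

    ``mods`` maps 1-based site indices within the peptide (or terminus
    tokens) to a single :class:`Modification` each.  ``start`` is the
    peptide's 1-based position within ``protein_id``, so the protein
    coordinate of residue site ``i`` is ``start + i - 1``.
    """

    sequence: str
    mods: Mapping[Union[int, str], Modification] = field(default_factory=dict)
    protein_id: str = ""
    start: int = 1
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for aa in self.sequence:
            if aa not in RESIDUE_MASS:
                raise ValueError(f"non-canonical residue {aa!r} in {self.sequence}")
        object.__setattr__(self, "mods", dict(self.mods))
        for site, mod in self.mods.items():
            if isinstance(site, int):
                if not 1 <= site <= len(self.sequence):
                    raise ValueError(
                        f"mod site {site} outside peptide of length {len(self.sequence)}"
                    )
                res = self.sequence[site - 1]
                if not mod.applies_to(site, res):
                    raise ValueError(
                        f"{mod.name} does not target residue {res} at site {site}"
                    )
            elif site not in _TERMINUS_TOKENS:
                raise ValueError(f"invalid modification site {site!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_mods(self) -> int:
        return len(self.mods)

    def mods_notation(self) -> str:
        """Human-readable site list, e.g. ``"C4 (JB); C7 (carbamidomethyl)"``."""
        parts = []
        for site in sorted(self.mods, key=lambda s: (isinstance(s, str), s if isinstance(s, str) else s)):
            mod = self.mods[site]
            if isinstance(site, int):
                parts.append(f"{self.sequence[site - 1]}{site} ({mod.name})")
            else:
                parts.append(f"{site} ({mod.name})")
        return "; ".join(parts)

    def key(self) -> str:
        """Canonical string, used for deterministic tie-breaking."""
        return f"{self.sequence}|{self.mods_notation()}|{self.protein_id}|{self.start}"


def peptide_neutral_mass(p: Peptidoform) -> float:
    """Neutral monoisotopic mass: residues + water + modification deltas."""
    m = WATER + sum(RESIDUE_MASS[aa] for aa in p.sequence)
    m += sum(mod.delta for mod in p.mods.values())
    return m


def precursor_mz(neutral_mass: float, charge: int) -> float:
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON) / charge


def neutral_from_mz(mz: float, charge: int) -> float:
    return mz * charge - charge * PROTON


def delta_vs_carbamidomethyl(m: Modification) -> float:
    """Expected parent-ion mass shift between a peptide carrying ``m`` on a
    cysteine and the same peptide carbamidomethylated at that site."""
    cam = default_registry()["carbamidomethyl"]
    return m.delta - cam.delta


def ppm_within(observed: float, theoretical: float, tol_ppm: float) -> bool:
    """True iff |observed - theoretical| / theoretical * 1e6 <= tol_ppm."""
    if theoretical <= 0:
        raise ValueError(f"theoretical mass must be positive, got {theoretical}")
    return abs(observed - theoretical) / theoretical * 1e6 <= tol_ppm
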