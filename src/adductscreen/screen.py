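"""The forward/reverse screening funnel for covalent-target candidates.

Reverse arm: proteins carrying the adduct are collected from
FDR-filtered PSMs, filtered on charge-specific XCorr reliability
thresholds, and on the "identified both" criterion — the same cysteine
site observed carbamidomethylated in the control group and
adduct-modified in the treated group.  The forward (phenotype) arm
contributes a localization keyword (e.g. "mitochond") that the
prioritization uses to rank candidates.  Verification utilities check
the parent-ion mass shift between the alkylated and adducted forms and
the b/y spectral similarity of paired spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .chem import (
    Modification,
    delta_vs_carbamidomethyl,
    neutral_from_mz,
)
from .search import PSM, fragment_coverage
from .spectra import Spectrum

__all__ = [
    "CandidateRecord",
    "ScreenCriteria",
    "collect_modified_proteins",
    "reliability_filter",
    "identified_both",
    "prioritize",
    "apply_funnel",
    "spectral_similarity",
    "verify_mass_shift",
    "write_candidate_table",
]


@dataclass
class CandidateRecord:
    """One row of the screening table: a protein observed with the adduct."""

    protein: str
    peptide: str = ""
    modifications: str = ""
    charge: int = 0
    xcorr: float = 0.0
    identified_both: bool = False
    location: str = ""
    passes_reliability: bool | None = None
    priority_rank: int | None = None


@dataclass(frozen=True)
class ScreenCriteria:
    """Reliability thresholds are strict (score must exceed them) and
    charges without a stated threshold fail closed."""

    xcorr_thresholds: Mapping[int, float] = field(
        default_factory=lambda: {2: 2.2, 3: 3.75}
    )
    phenotype_terms: tuple[str, ...] = ("mitochond",)
    require_identified_both: bool = True

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.xcorr_thresholds.values()):
            raise ValueError("xcorr thresholds must be positive")


def collect_modified_proteins(
    psms: Sequence[PSM],
    adduct: Modification,
    locations: Mapping[str, str] | None = None,
    spectra_by_id: Mapping[str, Spectrum] | None = None,
    min_fragment_coverage: float | None = None,
    fragment_tol_da: float = 0.02,
) -> list[CandidateRecord]:
    """One record per protein with >= 1 accepted PSM bearing the adduct;
    the highest-scoring adduct PSM defines the record's peptide, charge
    and XCorr.

    ``min_fragment_coverage`` (with ``spectra_by_id``) optionally drops
    adduct PSMs whose spectra match fewer than that fraction of
    theoretical b/y ions — a stand-in for manual spectra-quality curation.
    """
    best: dict[str, PSM] = {}
    for psm in psms:
        if psm.is_decoy:
            continue
        if not any(m is adduct or m.name == adduct.name
                   for m in psm.peptidoform.mods.values()):
            continue
        if min_fragment_coverage is not None and spectra_by_id is not None:
            spec = spectra_by_id.get(psm.spectrum_id)
            if spec is not None and fragment_coverage(
                spec, psm.peptidoform, fragment_tol_da
            ) < min_fragment_coverage:
                continue
        cur = best.get(psm.protein)
        if cur is None or psm.xcorr > cur.xcorr:
            best[psm.protein] = psm
    records = []
    for prot in sorted(best):
        psm = best[prot]
        records.append(
            CandidateRecord(
                protein=prot,
                peptide=psm.peptidoform.sequence,
                modifications=psm.peptidoform.mods_notation(),
                charge=psm.charge,
                xcorr=psm.xcorr,
                location=(locations or {}).get(prot, ""),
            )
        )
    return records


def reliability_filter(
    records: Iterable[CandidateRecord], criteria: ScreenCriteria = ScreenCriteria()
) -> list[CandidateRecord]:
    """Set ``passes_reliability``: XCorr strictly above the threshold for
    the record's charge; charges without a threshold fail."""
    out = []
    for r in records:
        thr = criteria.xcorr_thresholds.get(r.charge)
        out.append(replace(r, passes_reliability=thr is not None and r.xcorr > thr))
    return out


def _adduct_sites(psm: PSM, adduct_name: str) -> set[tuple[str, str, int]]:
    sites = set()
    pf = psm.peptidoform
    for site, mod in pf.mods.items():
        if isinstance(site, int) and mod.name == adduct_name:
            sites.add((pf.protein_id, pf.sequence, pf.start + site - 1))
    return sites


def identified_both(
    psms: Sequence[PSM],
    adduct: Modification,
    control_mod_name: str = "carbamidomethyl",
    control_group: str = "control",
    treated_group: str = "treated",
) -> dict[str, bool]:
    """Per protein: is some cysteine site adduct-modified in treated-group
    PSMs *and* carbamidomethylated at the same site (same peptide) in
    control-group PSMs?

    Keyed on (protein, peptide sequence, residue position in protein) so
    the criterion is site-level, not merely protein-level.
    """
    cam_sites: set[tuple[str, str, int]] = set()
    adduct_sites: set[tuple[str, str, int]] = set()
    proteins: set[str] = set()
    for psm in psms:
        if psm.is_decoy:
            continue
        pf = psm.peptidoform
        proteins.add(pf.protein_id)
        for site, mod in pf.mods.items():
            if not isinstance(site, int):
                continue
            key = (pf.protein_id, pf.sequence, pf.start + site - 1)
            if psm.group == control_group and mod.name == control_mod_name:
                cam_sites.add(key)
            elif psm.group == treated_group and mod.name == adduct.name:
                adduct_sites.add(key)
    both_keys = cam_sites & adduct_sites
    both_proteins = {k[0] for k in both_keys}
    return {prot: prot in both_proteins for prot in sorted(proteins)}


def prioritize(
    records: Sequence[CandidateRecord],
    criteria: ScreenCriteria = ScreenCriteria(),
    phenotype_terms: Sequence[str] | None = None,
) -> list[CandidateRecord]:
    """Rank candidates by (passes reliability, identified both, localization
    matches a phenotype term, XCorr descending); ties broken by protein
    name so the ranking is independent of input order."""
    terms = tuple(phenotype_terms) if phenotype_terms is not None else criteria.phenotype_terms

    def loc_match(r: CandidateRecord) -> bool:
        loc = r.location.lower()
        return any(t.lower() in loc for t in terms)

    def sort_key(r: CandidateRecord):
        return (
            not bool(r.passes_reliability),
            not r.identified_both,
            not loc_match(r),
            -r.xcorr,
            r.protein,
        )

    ranked = sorted(records, key=sort_key)
    return [replace(r, priority_rank=i + 1) for i, r in enumerate(ranked)]


def apply_funnel(
    records: Sequence[CandidateRecord],
    criteria: ScreenCriteria = ScreenCriteria(),
) -> list[CandidateRecord]:
    """Candidates surviving all three screens: reliability, identified-both
    (if required), and phenotype-localization match."""
    ranked = prioritize(reliability_filter(records, criteria), criteria)
    out = []
    for r in ranked:
        if not r.passes_reliability:
            continue
        if criteria.require_identified_both and not r.identified_both:
            continue
        loc = r.location.lower()
        if not any(t.lower() in loc for t in criteria.phenotype_terms):
            continue
        out.append(r)
    return out


def spectral_similarity(
    a: np.ndarray, b: np.ndarray, align_tol: float = 0.25
) -> float:
    """Cosine similarity of two relative-intensity peak lists.

    Peaks are aligned greedily within ``align_tol`` m/z (closest pairs
    first, each peak used once); unmatched peaks are paired with zero
    intensity.  Symmetric and scale-invariant; result in [0, 1].
    """
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    if a.size == 0 or b.size == 0:
        raise ValueError("spectral_similarity requires non-empty peak lists")
    pairs = []
    for i in range(len(a)):
        d = np.abs(b[:, 0] - a[i, 0])
        for j in np.nonzero(d <= align_tol)[0]:
            pairs.append((d[j], i, int(j)))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    va, vb = [], []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        va.append(a[i, 1])
        vb.append(b[j, 1])
    for i in range(len(a)):
        if i not in used_a:
            va.append(a[i, 1])
            vb.append(0.0)
    for j in range(len(b)):
        if j not in used_b:
            va.append(0.0)
            vb.append(b[j, 1])
    va = np.asarray(va)
    vb = np.asarray(vb)
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    if denom == 0:
        return 0.0
    return float(np.clip(va @ vb / denom, 0.0, 1.0))


def verify_mass_shift(
    alkylated: PSM,
    adducted: PSM,
    adduct: Modification,
    tol_ppm: float = 10.0,
) -> tuple[float, float, bool]:
    """Observed vs theoretical parent-ion mass shift for a peptide pair.

    Both PSMs must share the peptide sequence and modified site.  The
    observed shift comes from the measured precursor neutral masses; the
    theoretical shift is the adduct-minus-carbamidomethyl delta.  The
    pair is ``within_tol`` if the discrepancy is below ``tol_ppm`` of
    the heavier precursor.
    """
    if alkylated.peptidoform.sequence != adducted.peptidoform.sequence:
        raise ValueError("mass-shift verification requires the same peptide sequence")
    site_a = {s for s, m in alkylated.peptidoform.mods.items() if isinstance(s, int)}
    site_b = {s for s, m in adducted.peptidoform.mods.items()
              if isinstance(s, int) and m.name == adduct.name}
    if site_b and not (site_b & site_a):
        raise ValueError("adduct site not alkylated in the paired control PSM")
    m_alk = neutral_from_mz(alkylated.precursor_mz, alkylated.charge)
    m_add = neutral_from_mz(adducted.precursor_mz, adducted.charge)
    observed = m_add - m_alk
    theoretical = delta_vs_carbamidomethyl(adduct)
    tol = max(m_alk, m_add) * tol_ppm * 1e-6
    return observed, theoretical, abs(observed - theoretical) <= tol


_CAND_COLUMNS = [
    "protein", "peptide", "modifications", "charge", "xcorr",
    "identified_both", "location", "passes_reliability", "priority_rank",
]


def write_candidate_table(
    records: Sequence[CandidateRecord], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CAND_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join([
                    r.protein, r.peptide, r.modifications, str(r.charge),
                    f"{r.xcorr:.4f}",
                    "Yes" if r.identified_both else "No",
                    r.location,
                    "" if r.passes_reliability is None else str(r.passes_reliability),
                    "" if r.priority_rank is None else str(r.priority_rank),
                ]) + "\n"
            )
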