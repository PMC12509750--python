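"""Adduct-aware database search: XCorr scoring and target-decoy FDR.

The score is a cross-correlation in the SEQUEST family, in the fast
single-pass formulation: the binned experimental spectrum is replaced by
its mean-subtracted version (mean over +/-75 bin offsets, offset 0
excluded), so the dot product with the theoretical spectrum equals the
correlation at lag 0 minus the average correlation over the offset
window.  Preprocessing follows the published recipe: square-root
intensities, the m/z range split into 10 regions, each region's maximum
normalized to 50.  Absolute comparability with any commercial engine's
XCorr is not a goal; the statistic is used with charge-specific
reliability thresholds downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .chem import Peptidoform, neutral_from_mz, peptide_neutral_mass
from .digest import fragment
from .spectra import Spectrum

__all__ = [
    "SearchConfig",
    "PSM",
    "xcorr",
    "search",
    "assign_fdr",
    "filter_psms",
    "fragment_coverage",
    "build_decoys",
    "write_psm_table",
    "read_psm_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.02
    fdr_cutoff: float = 0.01
    charges: tuple[int, ...] = (2, 3, 4)
    n_regions: int = 10           # intensity-normalization windows
    region_norm: float = 50.0     # per-region max after normalization
    background_window: int = 75   # +/- bins for the mean-correlation term
    theoretical_intensity: float = 50.0

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")
        if not 0.0 < self.fdr_cutoff < 1.0:
            raise ValueError("fdr_cutoff must be in (0, 1)")


@dataclass
class PSM:
    """A scored peptidoform-spectrum match."""

    spectrum_id: str
    peptidoform: Peptidoform
    charge: int
    xcorr: float
    is_decoy: bool = False
    group: str | None = None
    precursor_mz: float = 0.0
    q_value: float | None = None

    @property
    def protein(self) -> str:
        return self.peptidoform.protein_id


def _bin_index(mz: np.ndarray, bin_width: float) -> np.ndarray:
    return np.asarray(np.floor(mz / bin_width + 0.5), dtype=np.int64)


def _preprocess(s: Spectrum, cfg: SearchConfig):
    """Square-root + regional normalization, binned at the fragment tolerance.

    Returns (sorted unique bins, processed intensities, cumulative sums)
    for O(log n) windowed sums during scoring.
    """
    if s.peaks.size == 0:
        return None
    mz = s.mz
    inten = np.sqrt(s.intensity)
    lo, hi = mz.min(), mz.max()
    width = max((hi - lo) / cfg.n_regions, 1e-9)
    region = np.minimum(((mz - lo) / width).astype(int), cfg.n_regions - 1)
    out = np.zeros_like(inten)
    for r in range(cfg.n_regions):
        m = region == r
        if m.any():
            top = inten[m].max()
            if top > 0:
                out[m] = inten[m] * (cfg.region_norm / top)
    bins = _bin_index(mz, cfg.fragment_tol_da)
    # keep the max intensity per bin
    order = np.lexsort((-out, bins))
    bins, out = bins[order], out[order]
    keep = np.ones(len(bins), dtype=bool)
    keep[1:] = bins[1:] != bins[:-1]
    bins, out = bins[keep], out[keep]
    csum = np.concatenate([[0.0], np.cumsum(out)])
    return bins, out, csum


def _score_bins(theo_bins: np.ndarray, prep, cfg: SearchConfig) -> float:
    bins, vals, csum = prep
    w = cfg.background_window
    # y(b)
    idx = np.searchsorted(bins, theo_bins)
    hit = (idx < len(bins)) & (bins[np.minimum(idx, len(bins) - 1)] == theo_bins)
    y0 = np.where(hit, vals[np.minimum(idx, len(bins) - 1)], 0.0)
    # windowed sum over [b - w, b + w]
    left = np.searchsorted(bins, theo_bins - w, side="left")
    right = np.searchsorted(bins, theo_bins + w, side="right")
    wsum = csum[right] - csum[left]
    y_prime = y0 - (wsum - y0) / (2 * w)
    return float(np.sum(y_prime) * cfg.theoretical_intensity / 1e4)


def _theoretical_bins(p: Peptidoform, cfg: SearchConfig) -> np.ndarray:
    mz = np.array([f.mz for f in fragment(p, max_frag_charge=1)])
    return np.unique(_bin_index(mz, cfg.fragment_tol_da))


def xcorr(s: Spectrum, p: Peptidoform, cfg: SearchConfig = SearchConfig()) -> float:
    """Cross-correlation score of spectrum ``s`` against peptidoform ``p``.

    Higher is better; an empty spectrum scores 0.  Invariant to uniform
    intensity scaling of the spectrum (regional normalization).
    """
    prep = _preprocess(s, cfg)
    if prep is None:
        return 0.0
    return _score_bins(_theoretical_bins(p, cfg), prep, cfg)


def build_decoys(sequences: dict[str, str], prefix: str = "DECOY_") -> dict[str, str]:
    """Decoy database by full protein sequence reversal."""
    return {prefix + acc: seq[::-1] for acc, seq in sequences.items()}


def _tie_key(score: float, p: Peptidoform):
    # higher xcorr, then fewer modifications, then lexicographic string
    return (-score, p.n_mods, p.key())


def search(
    spectra: Iterable[Spectrum],
    peptidoforms: Sequence[Peptidoform],
    cfg: SearchConfig = SearchConfig(),
) -> list[PSM]:
    """Score each spectrum against all candidates within the precursor
    tolerance at its charge; keep the best PSM per spectrum.

    Candidates (targets and decoys together) compete for each spectrum.
    Spectra with no candidate in tolerance are logged and skipped.
    Results are independent of database ordering (deterministic ties).
    """
    masses = np.array([peptide_neutral_mass(p) for p in peptidoforms])
    order = np.argsort(masses, kind="stable")
    masses = masses[order]
    cands = [peptidoforms[i] for i in order]
    theo_cache: dict[str, np.ndarray] = {}

    psms: list[PSM] = []
    unmatched = 0
    for s in spectra:
        neutral = neutral_from_mz(s.precursor_mz, s.precursor_charge)
        tol = neutral * cfg.precursor_tol_ppm * 1e-6
        lo = np.searchsorted(masses, neutral - tol, side="left")
        hi = np.searchsorted(masses, neutral + tol, side="right")
        if hi <= lo:
            unmatched += 1
            continue
        prep = _preprocess(s, cfg)
        best = None
        for p in cands[lo:hi]:
            k = p.key()
            tb = theo_cache.get(k)
            if tb is None:
                tb = _theoretical_bins(p, cfg)
                theo_cache[k] = tb
            score = _score_bins(tb, prep, cfg) if prep is not None else 0.0
            key = _tie_key(score, p)
            if best is None or key < best[0]:
                best = (key, p, score)
        _, p, score = best
        psms.append(
            PSM(
                spectrum_id=s.id,
                peptidoform=p,
                charge=s.precursor_charge,
                xcorr=score,
                is_decoy=p.is_decoy,
                group=s.group,
                precursor_mz=s.precursor_mz,
            )
        )
    if unmatched:
        logger.info("search: %d spectra had no candidate within tolerance", unmatched)
    return psms


def assign_fdr(psms: Sequence[PSM]) -> list[PSM]:
    """Target-decoy q-values.

    PSMs are ranked by descending score; at each score threshold the FDR
    estimate is #decoys / #targets among PSMs at or above it, and the
    q-value is the minimum estimate over all thresholds at or below the
    PSM's score (so q is non-increasing in score).
    """
    if not psms:
        return []
    if not any(not p.is_decoy for p in psms):
        raise ValueError("no target PSMs: cannot estimate FDR")
    order = sorted(range(len(psms)), key=lambda i: -psms[i].xcorr)
    n_t = n_d = 0
    raw = np.empty(len(psms))
    for rank, i in enumerate(order):
        if psms[i].is_decoy:
            n_d += 1
        else:
            n_t += 1
        raw[rank] = n_d / max(n_t, 1)
    q = np.minimum.accumulate(raw[::-1])[::-1]
    out = list(psms)
    for rank, i in enumerate(order):
        p = out[i]
        out[i] = PSM(
            p.spectrum_id, p.peptidoform, p.charge, p.xcorr,
            p.is_decoy, p.group, p.precursor_mz, q_value=float(min(q[rank], 1.0)),
        )
    return out


def filter_psms(psms: Sequence[PSM], fdr_cutoff: float = 0.01) -> list[PSM]:
    """Target PSMs accepted at the q-value cutoff."""
    return [
        p for p in psms
        if not p.is_decoy and p.q_value is not None and p.q_value <= fdr_cutoff
    ]


def fragment_coverage(
    s: Spectrum, p: Peptidoform, tol_da: float = 0.02
) -> float:
    """Fraction of theoretical b/y ions with an observed peak within
    ``tol_da`` — the spectra-quality statistic used for curation."""
    frags = fragment(p, max_frag_charge=1)
    if s.peaks.size == 0:
        return 0.0
    mz = s.mz
    hit = 0
    for f in frags:
        i = np.searchsorted(mz, f.mz)
        near = []
        if i < len(mz):
            near.append(abs(mz[i] - f.mz))
        if i > 0:
            near.append(abs(mz[i - 1] - f.mz))
        if near and min(near) <= tol_da:
            hit += 1
    return hit / len(frags)


_PSM_COLUMNS = [
    "spectrum_id", "protein", "start", "peptide", "modifications",
    "charge", "xcorr", "q_value", "group", "is_decoy", "precursor_mz",
]


def write_psm_table(psms: Sequence[PSM], path: Union[str, Path]) -> None:
    """PSM table as TSV with site-annotated modification notation."""
    with open(path, "w") as fh:
        fh.write("\t".join(_PSM_COLUMNS) + "\n")
        for p in psms:
            fh.write(
                "\t".join([
                    p.spectrum_id,
                    p.peptidoform.protein_id,
                    str(p.peptidoform.start),
                    p.peptidoform.sequence,
                    p.peptidoform.mods_notation(),
                    str(p.charge),
                    f"{p.xcorr:.4f}",
                    "" if p.q_value is None else f"{p.q_value:.6f}",
                    p.group or "",
                    str(int(p.is_decoy)),
                    f"{p.precursor_mz:.5f}",
                ]) + "\n"
            )


def _parse_mods_notation(
    notation: str, registry: dict[str, "object"]
) -> dict:
    """Inverse of ``Peptidoform.mods_notation`` given a registry by name."""
    mods = {}
    if not notation:
        return mods
    for part in notation.split("; "):
        site_txt, name = part.split(" (", 1)
        name = name.rstrip(")")
        mod = registry[name]
        if site_txt in ("N-term", "C-term", "protein-N-term"):
            mods[site_txt] = mod
        else:
            mods[int(site_txt[1:])] = mod
    return mods


def read_psm_table(
    path: Union[str, Path], registry: dict[str, "object"]
) -> list[PSM]:
    psms = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PSM_COLUMNS:
            raise ValueError(f"unexpected PSM table header: {header}")
        for line in fh:
            f = dict(zip(_PSM_COLUMNS, line.rstrip("\n").split("\t")))
            pf = Peptidoform(
                f["peptide"],
                _parse_mods_notation(f["modifications"], registry),
                f["protein"],
                int(f["start"]),
                is_decoy=bool(int(f["is_decoy"])),
            )
            psms.append(
                PSM(
                    f["spectrum_id"], pf, int(f["charge"]), float(f["xcorr"]),
                    pf.is_decoy, f["group"] or None, float(f["precursor_mz"]),
                    q_value=float(f["q_value"]) if f["q_value"] else None,
                )
            )
    return psms
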