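"""Centroided spectrum model, MGF I/O and synthetic spectrum rendering.

MGF is the interchange format throughout: centroided peak lists are all
the scoring needs, and the text format round-trips exactly.  m/z values
are written with 5 decimals and intensities with 2; charge as ``N+``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
from pyteomics import mgf as _pmgf

from .chem import Peptidoform, peptide_neutral_mass, precursor_mz
from .digest import fragment

__all__ = [
    "Spectrum",
    "NoiseConfig",
    "read_mgf",
    "write_mgf",
    "normalize_relative",
    "render_synthetic",
]

_GROUP_RE = re.compile(r"group=(\w+)")


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum.

    ``peaks`` is an (n, 2) float array of (m/z, intensity), kept sorted
    by m/z.  ``group`` labels the experimental arm (control / treated).
    """

    id: str
    precursor_mz: float
    precursor_charge: int
    peaks: np.ndarray
    group: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if self.peaks.size:
            order = np.argsort(self.peaks[:, 0], kind="stable")
            self.peaks = self.peaks[order]
            if (self.peaks[:, 1] < 0).any():
                raise ValueError("negative peak intensity")
        if self.precursor_charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.precursor_charge}")

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]


def read_mgf(path: Union[str, Path]) -> list[Spectrum]:
    """Read an MGF file into :class:`Spectrum` objects.

    TITLE becomes the spectrum id; a ``group=<label>`` token in the
    title (or a GROUP header) is parsed into ``Spectrum.group``.
    Malformed blocks are rejected with the block index named.
    """
    spectra: list[Spectrum] = []
    with _pmgf.read(str(path), use_index=False, convert_arrays=1) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            try:
                title = str(params.get("title", f"spectrum_{i}"))
                pepmass = params["pepmass"][0]
                charge = int(params["charge"][0])
            except (KeyError, IndexError, TypeError, ValueError) as exc:
                raise ValueError(f"malformed MGF block {i}: {exc}") from exc
            group = params.get("group")
            if group is None:
                m = _GROUP_RE.search(title)
                group = m.group(1) if m else None
            peaks = np.column_stack(
                [entry["m/z array"], entry["intensity array"]]
            ) if len(entry["m/z array"]) else np.empty((0, 2))
            spectra.append(Spectrum(title, float(pepmass), charge, peaks, group))
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: Union[str, Path]) -> None:
    """Write spectra as MGF; the group label is embedded in the TITLE."""
    with open(path, "w") as fh:
        for s in spectra:
            title = s.id
            if s.group and f"group={s.group}" not in title:
                title = f"{title} group={s.group}"
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={title}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.5f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.5f} {inten:.2f}\n")
            fh.write("END IONS\n")


def normalize_relative(s: Spectrum) -> np.ndarray:
    """Peaks rescaled so the base peak has relative intensity 100.

    Returns an (n, 2) array of (m/z, relative intensity in [0, 100]).
    """
    if s.peaks.size == 0:
        raise ValueError("cannot normalize an empty spectrum")
    top = s.intensity.max()
    if top <= 0:
        raise ValueError("cannot normalize all-zero intensities")
    return np.column_stack([s.mz, s.intensity * 100.0 / top])


@dataclass(frozen=True)
class NoiseConfig:
    """How far a synthetic spectrum departs from its theoretical ions.

    ``peak_fraction``: probability each theoretical b/y ion is observed.
    ``intensity_cv``: coefficient of variation of peak intensities.
    ``n_noise_peaks``: uniform chemical-noise peaks over [100, precursor m/z].
    ``mz_jitter_sd``: Gaussian m/z error (Da); keep <= fragment tol / 3.
    """

    peak_fraction: float = 1.0
    intensity_cv: float = 0.0
    n_noise_peaks: int = 0
    mz_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.peak_fraction <= 1.0:
            raise ValueError("peak_fraction must be in [0, 1]")
        if self.intensity_cv < 0 or self.mz_jitter_sd < 0 or self.n_noise_peaks < 0:
            raise ValueError("noise parameters must be non-negative")


def render_synthetic(
    p: Peptidoform,
    charge: int,
    noise_cfg: NoiseConfig = NoiseConfig(),
    seed: int | np.random.Generator = 0,
    spectrum_id: str | None = None,
    group: str | None = None,
    base_intensity: float = 1000.0,
) -> Spectrum:
    """Render the theoretical b/y spectrum of ``p`` with controlled noise.

    Deterministic given the seed.  With noise off (defaults) the peak
    list is exactly the theoretical fragment m/z values.
    """
    if charge < 1:
        raise ValueError(f"invalid precursor charge {charge}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frags = fragment(p, max_frag_charge=1)
    mz = np.array([f.mz for f in frags])
    # y ions tend to dominate HCD spectra of tryptic peptides
    inten = np.array(
        [base_intensity * (1.0 if f.ion_type == "y" else 0.6) for f in frags]
    )
    if noise_cfg.peak_fraction < 1.0:
        keep = rng.random(len(mz)) < noise_cfg.peak_fraction
        if not keep.any():
            keep[rng.integers(len(mz))] = True
        mz, inten = mz[keep], inten[keep]
    if noise_cfg.intensity_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cfg.intensity_cv**2))
        inten = inten * rng.lognormal(-sigma**2 / 2, sigma, len(inten))
    if noise_cfg.mz_jitter_sd > 0:
        mz = mz + rng.normal(0.0, noise_cfg.mz_jitter_sd, len(mz))

    neutral = peptide_neutral_mass(p)
    pmz = precursor_mz(neutral, charge)
    if noise_cfg.n_noise_peaks > 0:
        noise_mz = rng.uniform(100.0, pmz, noise_cfg.n_noise_peaks)
        noise_int = rng.uniform(0.01, 0.2, noise_cfg.n_noise_peaks) * base_intensity
        mz = np.concatenate([mz, noise_mz])
        inten = np.concatenate([inten, noise_int])

    sid = spectrum_id or f"syn|{p.protein_id}|{p.sequence}|z{charge}"
    return Spectrum(
        sid,
        pmz,
        charge,
        np.column_stack([mz, inten]),
        group=group,
        metadata={
            "peptide": p.sequence,
            "mods": p.mods_notation(),
            "protein": p.protein_id,
        },
    )
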