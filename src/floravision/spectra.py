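"""Reading, preprocessing and characterisation of floral reflectance spectra.

A reflectance spectrum is the proportion of incident light a surface reflects
at each wavelength; here the working range is 300–700 nm (the part of the
spectrum visible to bee and hummingbird pollinators), resampled to a 1 nm
grid. This module provides replicate averaging, the field-standard rolling
average smoothing, integral normalisation (so that clustering compares
pigment *combinations*, not pigment concentration), brightness (area under
the curve, a proxy for pigment concentration), and inference of chlorophyll
in petal tissue from its in vivo absorption minimum near 675 nm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STANDARD_GRID",
    "Spectrum",
    "TaxonRecord",
    "ChlorophyllCall",
    "read_spectra",
    "write_spectra",
    "read_metadata",
    "resample",
    "average_replicates",
    "smooth",
    "brightness",
    "normalize_integral",
    "detect_chlorophyll",
    "mask_artefact",
]

#: Standard wavelength grid: 300..700 nm inclusive, 1 nm step (401 points).
STANDARD_GRID = np.arange(300.0, 701.0, 1.0)


class SpectrumError(ValueError):
    """Raised for malformed or out-of-contract spectral data."""


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed reflectance curve with accession metadata.

    Parameters
    ----------
    wavelengths_nm:
        Strictly increasing wavelength grid in nanometres.
    reflectance:
        Reflectance fraction per wavelength. Must be non-negative; values may
        slightly exceed 1 for glossy surfaces.
    accession_id, taxon, morph:
        Identification metadata; ``morph`` distinguishes colour morphs of a
        single accession (e.g. white vs. pink flowers of one species).
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    accession_id: str = ""
    taxon: str = ""
    morph: str | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        rf = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or rf.ndim != 1 or wl.size != rf.size:
            raise SpectrumError("wavelengths and reflectance must be 1-D and equal length")
        if wl.size < 2:
            raise SpectrumError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise SpectrumError("non-monotone grid: wavelengths must be strictly increasing")
        if np.any(rf < 0):
            raise SpectrumError("negative reflectance values are not physical")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "reflectance", rf)

    @property
    def on_standard_grid(self) -> bool:
        return self.wavelengths_nm.size == STANDARD_GRID.size and np.array_equal(
            self.wavelengths_nm, STANDARD_GRID
        )

    def with_values(self, reflectance: np.ndarray) -> "Spectrum":
        return replace(self, reflectance=np.asarray(reflectance, dtype=float))


@dataclass(frozen=True)
class TaxonRecord:
    """Role of a taxon in the hybridisation network.

    ``role`` is one of ``diploid``, ``polyploid`` (allopolyploid) or
    ``homoploid`` (hybrid without genome doubling). Hybrids carry their
    maternal and paternal progenitor taxa, unless the progenitors are known
    only to section level (``progenitor_section_level``), in which case the
    expected states come from ancestral-state reconstruction instead.
    """

    taxon: str
    role: str
    maternal_progenitor: str | None = None
    paternal_progenitor: str | None = None
    progenitor_section_level: bool = False

    def __post_init__(self) -> None:
        if self.role not in {"diploid", "polyploid", "homoploid"}:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "diploid":
            if self.maternal_progenitor or self.paternal_progenitor:
                raise ValueError(f"diploid {self.taxon!r} cannot have progenitors")
        else:
            both = self.maternal_progenitor and self.paternal_progenitor
            if not (both or self.progenitor_section_level):
                raise ValueError(
                    f"hybrid {self.taxon!r} needs both progenitors or section-level flag"
                )


@dataclass(frozen=True)
class ChlorophyllCall:
    """Inference of chlorophyll in petal tissue from the 675 nm minimum."""

    present: bool
    minimum_wavelength_nm: float = float("nan")
    prominence: float = 0.0

    @property
    def state(self) -> str:
        """Categorical state: 'C' (chlorophyll) or 'N' (none)."""
        return "C" if self.present else "N"


# ---------------------------------------------------------------------------
# I/O


def read_metadata(path: str | Path) -> dict[str, TaxonRecord]:
    """Read an accession metadata CSV (accession_id, taxon, role, maternal, paternal)."""
    df = pd.read_csv(path)
    records: dict[str, TaxonRecord] = {}
    for _, row in df.iterrows():
        maternal = row.get("maternal")
        paternal = row.get("paternal")
        maternal = None if pd.isna(maternal) else str(maternal)
        paternal = None if pd.isna(paternal) else str(paternal)
        section = bool(row.get("section_level", False)) if "section_level" in df.columns else False
        records[str(row["accession_id"])] = TaxonRecord(
            taxon=str(row["taxon"]),
            role=str(row["role"]),
            maternal_progenitor=maternal,
            paternal_progenitor=paternal,
            progenitor_section_level=section,
        )
    return records


def read_spectra(
    path: str | Path,
    format: str = "two_column",
    metadata: dict[str, TaxonRecord] | None = None,
    resample_to_grid: bool = True,
) -> list[Spectrum]:
    """Read reflectance spectra from a two-column file or a wide table.

    ``two_column``: one accession per file, rows of (wavelength_nm,
    reflectance); the accession id defaults to the file stem. ``wide_table``:
    first column is the wavelength, every further column one accession.
    Non-monotone grids and negative reflectances are rejected; missing
    metadata produces a warning, not an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "two_column":
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
        if df.shape[1] < 2:
            raise SpectrumError(f"{path}: expected two columns")
        if not np.issubdtype(np.asarray(df.iloc[0]).dtype, np.number):
            df = df.iloc[1:].astype(float)  # tolerate a header row
        spectra = [_build(path.stem, df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float), metadata)]
    elif format == "wide_table":
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        wl = df.iloc[:, 0].to_numpy(float)
        spectra = [
            _build(str(col), wl, df[col].to_numpy(float), metadata) for col in df.columns[1:]
        ]
    else:
        raise ValueError(f"unknown format {format!r}")
    if resample_to_grid:
        spectra = [resample(s) for s in spectra]
    return spectra


def _build(
    accession: str,
    wl: np.ndarray,
    rf: np.ndarray,
    metadata: dict[str, TaxonRecord] | None,
) -> Spectrum:
    taxon = ""
    if metadata is not None:
        rec = metadata.get(accession)
        if rec is None:
            warnings.warn(f"no metadata for accession {accession!r}; keeping spectrum")
        else:
            taxon = rec.taxon
    return Spectrum(wl, rf, accession_id=accession, taxon=taxon)


def write_spectra(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra sharing a grid as a wide CSV (6 significant digits)."""
    if not spectra:
        raise ValueError("nothing to write")
    wl = spectra[0].wavelengths_nm
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths_nm, wl):
            raise SpectrumError("spectra must share a grid to be written as a wide table")
    df = pd.DataFrame({"wavelength_nm": wl})
    for s in spectra:
        df[s.accession_id or s.taxon or "spectrum"] = s.reflectance
    df.to_csv(path, index=False, float_format="%.6g")


def write_chlorophyll_calls(calls: dict[str, ChlorophyllCall], path: str | Path) -> None:
    payload = {
        acc: {
            "present": bool(c.present),
            "minimum_wavelength_nm": None if np.isnan(c.minimum_wavelength_nm) else c.minimum_wavelength_nm,
            "prominence": c.prominence,
        }
        for acc, c in calls.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Preprocessing


def resample(s: Spectrum, grid: np.ndarray = STANDARD_GRID, edge_tolerance_nm: float = 2.0) -> Spectrum:
    """Linearly interpolate onto the standard 1 nm grid.

    The source spectrum must cover the grid; a coverage gap greater than
    ``edge_tolerance_nm`` at either end is an error (extrapolation is
    forbidden; gaps within tolerance hold the edge value).
    """
    wl, rf = s.wavelengths_nm, s.reflectance
    if wl[0] > grid[0] + edge_tolerance_nm or wl[-1] < grid[-1] - edge_tolerance_nm:
        raise SpectrumError(
            f"spectrum covers {wl[0]:g}-{wl[-1]:g} nm; cannot resample to "
            f"{grid[0]:g}-{grid[-1]:g} nm (gap exceeds {edge_tolerance_nm:g} nm)"
        )
    values = np.interp(grid, wl, rf)
    return replace(s, wavelengths_nm=grid.copy(), reflectance=values)


def average_replicates(spectra: Sequence[Spectrum], pool: bool = False) -> Spectrum:
    """Pointwise mean of replicate measurements of one accession.

    Mixed accessions are an error unless ``pool=True`` (used where several
    accessions of one taxon are deliberately pooled).
    """
    if not spectra:
        raise ValueError("no spectra to average")
    wl = spectra[0].wavelengths_nm
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths_nm, wl):
            raise SpectrumError("replicates must share a common grid")
    accessions = {s.accession_id for s in spectra}
    if len(accessions) > 1 and not pool:
        raise SpectrumError(f"mixed accessions {sorted(accessions)}; pass pool=True to pool them")
    mean = np.mean([s.reflectance for s in spectra], axis=0)
    first = spectra[0]
    accession = first.accession_id if len(accessions) == 1 else "+".join(sorted(accessions))
    return Spectrum(wl.copy(), mean, accession_id=accession, taxon=first.taxon, morph=first.morph)


def smooth(s: Spectrum, window_nm: int = 9, passes: int = 3) -> Spectrum:
    """Centred rolling average of width ``window_nm``, applied ``passes`` times.

    Requires a 1 nm grid and an odd window. At the boundaries the window
    shrinks symmetrically to the available points, so the output grid equals
    the input grid and no padding artefacts are introduced at the 300/700 nm
    ends (which drive the UV receptor).
    """
    if window_nm % 2 == 0:
        raise ValueError("window must be odd")
    if not np.allclose(np.diff(s.wavelengths_nm), 1.0):
        raise SpectrumError("smoothing expects a 1 nm grid; resample first")
    n = s.reflectance.size
    if window_nm > n:
        raise SpectrumError("window larger than spectrum")
    half = window_nm // 2
    values = s.reflectance
    for _ in range(passes):
        out = np.empty_like(values)
        csum = np.concatenate(([0.0], np.cumsum(values)))
        for i in range(n):
            h = min(half, i, n - 1 - i)
            out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
        values = out
    return s.with_values(values)


def brightness(s: Spectrum) -> float:
    """Area under the reflectance curve (reflectance·nm); a pigment-concentration proxy."""
    return float(np.trapezoid(s.reflectance, s.wavelengths_nm))


def normalize_integral(s: Spectrum, target: float = 100.0) -> Spectrum:
    """Scale so the area under the curve equals ``target`` (default 100).

    Removes pigment-concentration differences so clustering compares the
    combination of pigments only; the choice of target does not affect
    clustering (Euclidean distances scale uniformly).
    """
    area = brightness(s)
    if area <= 0:
        raise SpectrumError("cannot normalize a zero-area spectrum")
    return s.with_values(s.reflectance * (target / area))


def detect_chlorophyll(
    s: Spectrum,
    window_nm: tuple[float, float] = (660.0, 690.0),
    min_prominence: float = 0.02,
) -> ChlorophyllCall:
    """Infer chlorophyll from a reflectance minimum near 675 nm.

    Chlorophyll absorbs at 675 nm in vivo, producing a local reflectance
    minimum. The call is positive iff the deepest interior local minimum in
    the detection window sits at least ``min_prominence`` below the lower of
    the window's two flanking shoulder values.
    """
    wl, rf = s.wavelengths_nm, s.reflectance
    lo, hi = window_nm
    mask = (wl >= lo) & (wl <= hi)
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        raise SpectrumError("detection window contains too few samples")
    shoulder = min(rf[idx[0]], rf[idx[-1]])
    interior = idx[1:-1]
    is_min = (rf[interior] <= rf[interior - 1]) & (rf[interior] <= rf[interior + 1])
    candidates = interior[is_min]
    if candidates.size == 0:
        return ChlorophyllCall(False)
    best = candidates[np.argmin(rf[candidates])]
    prominence = float(shoulder - rf[best])
    present = prominence >= min_prominence
    return ChlorophyllCall(present, float(wl[best]) if present else float("nan"), max(prominence, 0.0))


def mask_artefact(s: Spectrum, interval_nm: tuple[float, float]) -> Spectrum:
    """Interpolate across a stated interval to remove a measurement artefact.

    Used for anomalous reflectance minima (e.g. 475–500 nm) that trace to the
    instrument rather than the flower; off by default in all pipelines.
    """
    lo, hi = interval_nm
    wl, rf = s.wavelengths_nm, s.reflectance.copy()
    inside = (wl > lo) & (wl < hi)
    keep = ~inside
    rf[inside] = np.interp(wl[inside], wl[keep], rf[keep])
    return s.with_values(rf)
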