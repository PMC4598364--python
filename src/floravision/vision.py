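"""Photoreceptor excitation and pollinator colour spaces.

Models how a trichromatic bee (UV/blue/green receptors) and a tetrachromatic
hummingbird (UV/blue/blue-green/yellow receptors, the last extending into the
red) perceive a reflectance spectrum. The chain is:

1. quantum catch  Q_i = ∫ R(λ) I(λ) S_i(λ) dλ  over 300–700 nm,
2. von Kries adaptation  P_i = Q_i / Q_i(background)  against an average
   leaf background under sunlight (D65), modelling colour constancy,
3. hyperbolic transform  E_i = P_i / (P_i + 1)  mapping to excitation in
   [0, 1), with E = 0.5 exactly at the adaptation point,
4. projection to a chromaticity locus: the 2-D bee colour hexagon
   (hue = angle, spectral purity = distance from the achromatic origin) or
   the 3-D opponent hummingbird colour space.

Receptor sensitivity curves default to the Govardovskii A1 visual-pigment
nomogram at the published peak wavelengths (bee 350/440/530 nm; hummingbird
370/440/508/560 nm); measured curves can be loaded from file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import STANDARD_GRID, Spectrum, SpectrumError

__all__ = [
    "ReceptorSensitivity",
    "VisualSystem",
    "ReceptorExcitations",
    "ColourLocus",
    "build_sensitivity",
    "load_sensitivity",
    "d65_illuminant",
    "bee_visual_system",
    "hummingbird_visual_system",
    "quantum_catch",
    "excitations",
    "hexagon_locus",
    "bird_locus",
    "project_library",
    "HEXAGON_X_COEFF",
    "BIRD_COEFFICIENTS",
    "BEE_LAMBDA_MAX",
    "HUMMINGBIRD_LAMBDA_MAX",
]

#: Peak sensitivities (nm) of the honeybee photoreceptor classes.
BEE_LAMBDA_MAX = {"UV": 350.0, "B": 440.0, "G": 530.0}

#: Peak sensitivities (nm) of the hummingbird single-cone classes
#: (the 560 nm "yellow" receptor's sensitivity extends into the red).
HUMMINGBIRD_LAMBDA_MAX = {"UV": 370.0, "B": 440.0, "G": 508.0, "R": 560.0}

#: Hexagon x-coefficient. The canonical geometry (maximal-excitation states at
#: the vertices of a regular unit hexagon) requires √3/2; 3/2 is available as
#: an as-printed variant of the published equations.
HEXAGON_X_COEFF = math.sqrt(3.0) / 2.0

#: Opponent coefficients of the 3-D hummingbird colour space, rows (x, y, z)
#: applied to excitations ordered (UV, B, G, R):
#:   x = 3/4·E_B − 1/12·(E_UV + E_G + E_R)
#:   y = 2/3·E_G − 1/6·(E_UV + E_R)
#:   z = 1/2·(E_UV − E_R)
BIRD_COEFFICIENTS = np.array(
    [
        [-1.0 / 12.0, 3.0 / 4.0, -1.0 / 12.0, -1.0 / 12.0],
        [-1.0 / 6.0, 0.0, 2.0 / 3.0, -1.0 / 6.0],
        [1.0 / 2.0, 0.0, 0.0, -1.0 / 2.0],
    ]
)


@dataclass(frozen=True)
class ReceptorSensitivity:
    """A peak-normalised spectral sensitivity curve on the standard grid."""

    name: str
    lambda_max_nm: float
    template: str
    curve: np.ndarray

    def __post_init__(self) -> None:
        curve = np.asarray(self.curve, dtype=float)
        if curve.shape != STANDARD_GRID.shape:
            raise ValueError("sensitivity curve must live on the standard grid")
        if np.any(curve < 0):
            raise ValueError("sensitivity must be non-negative")
        object.__setattr__(self, "curve", curve)


def _govardovskii_a1(lambda_max: float, grid: np.ndarray) -> np.ndarray:
    """Govardovskii A1 visual-pigment nomogram (alpha + beta bands)."""
    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x)) + np.exp(-14.9 * (1.104 - x)) + 0.674
    )
    lam_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((grid - lam_beta) / b_beta) ** 2))
    return alpha + beta


def build_sensitivity(
    lambda_max_nm: float,
    template: str = "govardovskii_a1",
    name: str = "",
    sigma_nm: float = 50.0,
) -> ReceptorSensitivity:
    """Build a peak-normalised receptor sensitivity on the standard grid.

    ``govardovskii_a1`` uses the A1 pigment nomogram (alpha + beta bands);
    ``gaussian`` a Gaussian of width ``sigma_nm`` (default 50 nm).
    """
    if not (300.0 <= lambda_max_nm <= 650.0):
        raise ValueError(f"lambda_max {lambda_max_nm} nm outside the supported range")
    if template == "govardovskii_a1":
        curve = _govardovskii_a1(lambda_max_nm, STANDARD_GRID)
    elif template == "gaussian":
        curve = np.exp(-0.5 * ((STANDARD_GRID - lambda_max_nm) / sigma_nm) ** 2)
    else:
        raise ValueError(f"unknown template {template!r}")
    curve = curve / curve.max()
    return ReceptorSensitivity(name or f"lmax{lambda_max_nm:g}", lambda_max_nm, template, curve)


def load_sensitivity(path: str | Path, name: str = "") -> ReceptorSensitivity:
    """Load a measured sensitivity curve (two-column: wavelength, sensitivity)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    wl = df.iloc[:, 0].to_numpy(float)
    sv = df.iloc[:, 1].to_numpy(float)
    curve = np.interp(STANDARD_GRID, wl, sv, left=0.0, right=0.0)
    curve = curve / curve.max()
    lmax = float(STANDARD_GRID[np.argmax(curve)])
    return ReceptorSensitivity(name or Path(path).stem, lmax, "measured", curve)


def d65_illuminant() -> np.ndarray:
    """CIE D65 relative spectral power on the standard grid (sunlight)."""
    with resources.files("floravision.data").joinpath("cie_d65_300_700_10nm.csv").open() as fh:
        table = pd.read_csv(fh)
    return np.interp(STANDARD_GRID, table["wavelength_nm"], table["relative_power"])


@dataclass(frozen=True)
class VisualSystem:
    """Receptors + illuminant + adapting background defining a colour space.

    ``space`` is ``hexagon`` (exactly three receptors, ordered UV, B, G) or
    ``bird3d`` (exactly four, ordered UV, B, G, R).
    """

    receptors: tuple[ReceptorSensitivity, ...]
    illuminant: np.ndarray
    background: Spectrum
    space: str
    coefficient_matrix: np.ndarray = field(default_factory=lambda: BIRD_COEFFICIENTS.copy())
    hexagon_x_coeff: float = HEXAGON_X_COEFF
    centre_on_background: bool = False

    def __post_init__(self) -> None:
        if self.space == "hexagon" and len(self.receptors) != 3:
            raise ValueError("the colour hexagon needs exactly 3 receptors (UV, B, G)")
        if self.space == "bird3d" and len(self.receptors) != 4:
            raise ValueError("the 3-D bird space needs exactly 4 receptors (UV, B, G, R)")
        if self.space not in {"hexagon", "bird3d"}:
            raise ValueError(f"unknown space {self.space!r}")
        mat = np.asarray(self.coefficient_matrix, dtype=float)
        if self.space == "bird3d" and mat.shape != (3, 4):
            raise ValueError("bird3d coefficient matrix must be 3x4")
        object.__setattr__(self, "coefficient_matrix", mat)
        if not self.background.on_standard_grid:
            raise SpectrumError("background spectrum must be on the standard grid")

    @property
    def receptor_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.receptors)


def bee_visual_system(
    background: Spectrum,
    illuminant: np.ndarray | None = None,
    template: str = "govardovskii_a1",
    hexagon_x_coeff: float = HEXAGON_X_COEFF,
) -> VisualSystem:
    """Honeybee trichromatic system (also a fair proxy for bumblebees and hawkmoths)."""
    receptors = tuple(
        build_sensitivity(lmax, template, name) for name, lmax in BEE_LAMBDA_MAX.items()
    )
    return VisualSystem(
        receptors,
        d65_illuminant() if illuminant is None else illuminant,
        background,
        "hexagon",
        hexagon_x_coeff=hexagon_x_coeff,
    )


def hummingbird_visual_system(
    background: Spectrum,
    illuminant: np.ndarray | None = None,
    template: str = "govardovskii_a1",
    coefficient_matrix: np.ndarray | None = None,
    centre_on_background: bool = False,
) -> VisualSystem:
    """Tetrachromatic hummingbird system (green-backed firecrown receptor peaks)."""
    receptors = tuple(
        build_sensitivity(lmax, template, name) for name, lmax in HUMMINGBIRD_LAMBDA_MAX.items()
    )
    return VisualSystem(
        receptors,
        d65_illuminant() if illuminant is None else illuminant,
        background,
        "bird3d",
        coefficient_matrix=BIRD_COEFFICIENTS.copy() if coefficient_matrix is None else coefficient_matrix,
        centre_on_background=centre_on_background,
    )


@dataclass(frozen=True)
class ReceptorExcitations:
    """Per-receptor quantum catches, adapted catches P, and excitations E.

    E_i = P_i / (P_i + 1) lies in [0, 1) and equals 0.5 exactly when the
    stimulus matches the adapting background (P = 1).
    """

    names: tuple[str, ...]
    quantum_catch: np.ndarray
    adapted_P: np.ndarray
    E: np.ndarray

    def __getitem__(self, name: str) -> float:
        return float(self.E[self.names.index(name)])


@dataclass(frozen=True)
class ColourLocus:
    """A point in a pollinator colour space.

    ``coords`` is (x, y) for the hexagon, (x, y, z) for the bird space;
    ``purity`` is the distance from the origin (saturation) and
    ``hue_angle`` the angular position in degrees (hexagon only).
    """

    coords: tuple[float, ...]
    purity: float
    hue_angle: float | None = None

    @property
    def x(self) -> float:
        return self.coords[0]

    @property
    def y(self) -> float:
        return self.coords[1]

    @property
    def z(self) -> float:
        if len(self.coords) < 3:
            raise AttributeError("2-D locus has no z")
        return self.coords[2]


def quantum_catch(s: Spectrum, receptor: ReceptorSensitivity, illuminant: np.ndarray) -> float:
    """Trapezoidal integral of reflectance x illuminant x sensitivity over 300-700 nm."""
    if not s.on_standard_grid:
        raise SpectrumError("spectrum must be resampled to the standard grid")
    illuminant = np.asarray(illuminant, dtype=float)
    if illuminant.shape != STANDARD_GRID.shape:
        raise SpectrumError("illuminant must live on the standard grid")
    return float(np.trapezoid(s.reflectance * illuminant * receptor.curve, STANDARD_GRID))


def excitations(s: Spectrum, vs: VisualSystem) -> ReceptorExcitations:
    """von Kries-adapted receptor excitations of a stimulus under a visual system."""
    catches = np.array([quantum_catch(s, r, vs.illuminant) for r in vs.receptors])
    background = np.array([quantum_catch(vs.background, r, vs.illuminant) for r in vs.receptors])
    for name, b in zip(vs.receptor_names, background):
        if b <= 0:
            raise SpectrumError(f"background quantum catch is zero for receptor {name}")
    P = catches / background
    E = P / (P + 1.0)
    return ReceptorExcitations(vs.receptor_names, catches, P, E)


def hexagon_locus(e: ReceptorExcitations | Sequence[float], x_coeff: float = HEXAGON_X_COEFF) -> ColourLocus:
    """Bee colour hexagon locus from excitations ordered (UV, B, G).

    x = c·(E_G − E_UV), y = E_B − ½·(E_UV + E_G) with c = √3/2 by default
    (vertices of the hexagon then lie at unit distance); c = 3/2 reproduces
    the equations exactly as printed in some sources.
    """
    euv, eb, eg = (e.E if isinstance(e, ReceptorExcitations) else np.asarray(e, dtype=float))
    x = x_coeff * (eg - euv)
    y = eb - 0.5 * (euv + eg)
    purity = math.hypot(x, y)
    hue = math.degrees(math.atan2(y, x)) % 360.0
    return ColourLocus((float(x), float(y)), purity, hue)


def bird_locus(
    e: ReceptorExcitations | Sequence[float],
    coefficient_matrix: np.ndarray = BIRD_COEFFICIENTS,
    background_locus: Sequence[float] | None = None,
) -> ColourLocus:
    """Hummingbird 3-D colour-space locus from excitations ordered (UV, B, G, R).

    Coordinates are the coefficient matrix applied to the excitation vector;
    if ``background_locus`` is given it is subtracted (background-centred
    variant). z is antisymmetric under swapping the UV and R excitations, so
    stimuli with E_UV = E_R lie in the z = 0 plane.
    """
    E = np.asarray(e.E if isinstance(e, ReceptorExcitations) else e, dtype=float)
    mat = np.asarray(coefficient_matrix, dtype=float)
    if mat.shape != (3, 4):
        raise ValueError("coefficient matrix must be 3x4")
    coords = mat @ E
    if background_locus is not None:
        coords = coords - np.asarray(background_locus, dtype=float)
    purity = float(np.linalg.norm(coords))
    return ColourLocus(tuple(float(c) for c in coords), purity)


def project_library(library: Sequence[Spectrum], vs: VisualSystem) -> pd.DataFrame:
    """Project a spectral library into a colour space; one row per accession.

    Columns: accession, taxon, x, y, (z,) purity, (hue_angle,) and the
    receptor excitations. This table is the clustering input for the
    perceptual colour categories.
    """
    rows = []
    background_locus = None
    if vs.space == "bird3d" and vs.centre_on_background:
        bg_e = excitations(vs.background, vs)
        background_locus = bird_locus(bg_e, vs.coefficient_matrix).coords
    for s in library:
        try:
            e = excitations(s, vs)
        except SpectrumError as err:
            raise SpectrumError(f"accession {s.accession_id!r}: {err}") from err
        if vs.space == "hexagon":
            locus = hexagon_locus(e, vs.hexagon_x_coeff)
            row = {
                "accession": s.accession_id,
                "taxon": s.taxon,
                "x": locus.x,
                "y": locus.y,
                "purity": locus.purity,
                "hue_angle": locus.hue_angle,
            }
        else:
            locus = bird_locus(e, vs.coefficient_matrix, background_locus)
            row = {
                "accession": s.accession_id,
                "taxon": s.taxon,
                "x": locus.x,
                "y": locus.y,
                "z": locus.z,
                "purity": locus.purity,
            }
        for name in vs.receptor_names:
            row[f"E_{name}"] = e[name]
        rows.append(row)
    columns = (
        ["accession", "taxon", "x", "y", "purity", "hue_angle", "E_UV", "E_B", "E_G"]
        if vs.space == "hexagon"
        else ["accession", "taxon", "x", "y", "z", "purity", "E_UV", "E_B", "E_G", "E_R"]
    )
    return pd.DataFrame(rows, columns=columns)
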