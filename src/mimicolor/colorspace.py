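"""Hexagon colour space for trichromatic hymenopteran vision.

Converts reflectance spectra into receptor quantum catches and hexagon
colour loci for a honeybee-like visual system (UV / blue / green receptor
classes), following the colour-opponent hexagon model: after von Kries
adaptation to a background, the quantum catch ``P`` of each receptor is
transduced to an excitation ``E = P / (P + 1)`` and the three excitations
are projected onto a 2-D chromaticity plane.  Distances in that plane
("hexagon units", Hu) are the perceptual colour differences used by the
discrimination functions elsewhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "DEFAULT_GRID",
    "Spectrum",
    "VisualSystem",
    "ExcitationTriplet",
    "ColorLocus",
    "resample_spectrum",
    "receptor_excitations",
    "hexagon_locus",
    "color_distance",
    "translate_locus",
    "spectrum_to_locus",
    "read_spectra_csv",
    "read_loci_csv",
    "write_loci_csv",
]

#: 10 nm wavelength grid covering the bee-visible range.
DEFAULT_GRID = np.arange(300.0, 651.0, 10.0)


@dataclass(frozen=True)
class Spectrum:
    """A sampled function of wavelength (reflectance or photon flux).

    Parameters
    ----------
    wavelengths : array-like of float
        Strictly increasing wavelength grid in nm.
    values : array-like of float
        Non-negative spectral values (reflectance as a fraction, or
        relative photon flux for illuminants).
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.shape != wl.shape:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(vals < 0):
            raise ValueError("spectral values must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def resample(self, grid: np.ndarray | None = None) -> "Spectrum":
        return resample_spectrum(self, grid)


def resample_spectrum(spectrum: Spectrum, grid: np.ndarray | None = None) -> Spectrum:
    """Resample onto ``grid`` (default 300:10:650 nm) with a shape-preserving
    piecewise cubic Hermite interpolant (PCHIP).

    PCHIP keeps monotone input segments monotone and never overshoots local
    extrema, which matters for smooth floral reflectance curves measured with
    uneven spectrometer grids.

    Raises
    ------
    ValueError
        If ``grid`` extends beyond the measured wavelength range
        (extrapolation is refused).
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    wl = spectrum.wavelengths
    if grid.min() < wl[0] or grid.max() > wl[-1]:
        raise ValueError(
            f"requested grid [{grid.min()}, {grid.max()}] nm extends beyond the "
            f"measured range [{wl[0]}, {wl[-1]}] nm; refusing to extrapolate"
        )
    interp = PchipInterpolator(wl, spectrum.values, extrapolate=False)
    vals = interp(grid)
    # interpolation of non-negative data can brush zero from below by rounding
    return Spectrum(grid, np.clip(vals, 0.0, None))


# ---------------------------------------------------------------------------
# Visual system
# ---------------------------------------------------------------------------

# CIE D65 relative spectral power distribution, 300-650 nm at 10 nm, energy
# units.  Absolute scale is irrelevant: von Kries adaptation cancels it.
_D65_ENERGY = np.array([
    0.03, 3.29, 20.24, 37.05, 39.95, 44.91, 46.64, 52.09, 49.98, 54.65,
    82.75, 91.49, 93.43, 86.68, 104.86, 117.01, 117.81, 114.86, 115.92,
    108.81, 109.35, 107.80, 104.79, 107.69, 104.41, 104.05, 100.00, 96.33,
    95.79, 88.69, 90.01, 89.60, 87.70, 83.29, 83.70, 80.03,
])


def _rhodopsin_template(grid: np.ndarray, lambda_max: float) -> np.ndarray:
    """A1 visual-pigment absorbance template (Govardovskii et al. 2000),
    alpha band plus the small beta band."""
    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lam_beta = 189.0 + 0.315 * lambda_max
    bw = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((grid - lam_beta) / bw) ** 2))
    s = alpha + beta
    return s / s.max()


def _green_leaf_reflectance(grid: np.ndarray) -> np.ndarray:
    """Smooth synthetic foliage reflectance: ~5% in the UV, ~15% peak at
    550 nm, falling back to ~5% at 650 nm."""
    return 0.05 + 0.10 * np.exp(-(((grid - 550.0) / 42.0) ** 2))


@dataclass(frozen=True)
class VisualSystem:
    """Receptor sensitivities plus the viewing context (illuminant and
    chromatic-adaptation background).

    Exactly three receptor classes are supported (UV, blue, green), the
    trichromatic complement conserved across bees.
    """

    sensitivities: tuple[Spectrum, Spectrum, Spectrum]
    illuminant: Spectrum
    background: Spectrum

    def __post_init__(self) -> None:
        if len(self.sensitivities) != 3:
            raise ValueError("exactly three receptor classes required")

    @classmethod
    def honeybee(cls, grid: np.ndarray | None = None) -> "VisualSystem":
        """Default honeybee-like system on the 10 nm grid.

        Sensitivities are rhodopsin-template curves at lambda_max = 344,
        436 and 544 nm (UV, blue, green).  The illuminant is a standard
        daylight (D65-like) distribution converted to relative photon flux
        and normalised to 1 at 540 nm; the adaptation background is a
        synthetic average green leaf.
        """
        grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
        sens = tuple(
            Spectrum(grid, _rhodopsin_template(grid, lm)) for lm in (344.0, 436.0, 544.0)
        )
        d65 = Spectrum(DEFAULT_GRID, _D65_ENERGY).resample(grid)
        photon = d65.values * grid  # photon flux ~ energy * lambda
        photon = photon / np.interp(540.0, grid, photon)
        illum = Spectrum(grid, photon)
        background = Spectrum(grid, _green_leaf_reflectance(grid))
        return cls(sens, illum, background)


@dataclass(frozen=True)
class ExcitationTriplet:
    """Adapted quantum catches P and receptor excitations E = P/(P+1)."""

    P: tuple[float, float, float]
    E: tuple[float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        P = tuple(float(p) for p in self.P)
        if any(p < 0 for p in P):
            raise ValueError("quantum catches must be non-negative")
        E = tuple(p / (p + 1.0) for p in P)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "E", E)


@dataclass(frozen=True)
class ColorLocus:
    """A point in the hexagon chromaticity plane (coordinates in Hu)."""

    x: float
    y: float
    excitations: ExcitationTriplet | None = None


def receptor_excitations(reflectance: Spectrum, vs: VisualSystem) -> ExcitationTriplet:
    """Quantum catches and excitations of a stimulus under von Kries
    adaptation.

    For receptor class *i* with sensitivity :math:`S_i`, illuminant
    :math:`D` and background reflectance :math:`I_B`,

    .. math:: P_i = R_i \\sum_\\lambda I_S(\\lambda) S_i(\\lambda) D(\\lambda),
              \\qquad R_i = 1 / \\sum_\\lambda I_B(\\lambda) S_i(\\lambda) D(\\lambda)

    (left-rectangle sums on the common 10 nm grid; the constant bin width
    cancels), then :math:`E_i = P_i/(P_i+1)`.  A stimulus identical to the
    background therefore yields P = 1 and E = 0.5 in every receptor.
    """
    grid = vs.illuminant.wavelengths
    stim = reflectance.resample(grid) if not np.array_equal(reflectance.wavelengths, grid) else reflectance
    P = []
    for sens in vs.sensitivities:
        if not np.array_equal(sens.wavelengths, grid):
            sens = sens.resample(grid)
        weight = sens.values * vs.illuminant.values
        denom = float(np.sum(vs.background.values * weight))
        if denom <= 0.0:
            raise ZeroDivisionError(
                "adaptation background has zero overlap with a receptor sensitivity"
            )
        P.append(float(np.sum(stim.values * weight)) / denom)
    return ExcitationTriplet(P=tuple(P))


def hexagon_locus(e: ExcitationTriplet) -> ColorLocus:
    """Project excitations (E_UV, E_B, E_G) onto the hexagon plane:

    .. math:: x = \\tfrac{\\sqrt{3}}{2}(E_G - E_{UV}), \\qquad
              y = E_B - (E_{UV} + E_G)/2
    """
    e_uv, e_b, e_g = e.E
    x = (np.sqrt(3.0) / 2.0) * (e_g - e_uv)
    y = e_b - (e_uv + e_g) / 2.0
    return ColorLocus(float(x), float(y), excitations=e)


def color_distance(a: ColorLocus, b: ColorLocus) -> float:
    """Euclidean distance between two loci in hexagon units (Hu)."""
    return float(np.hypot(a.x - b.x, a.y - b.y))


def translate_locus(locus: ColorLocus, dx: float, dy: float) -> ColorLocus:
    """Shift a locus by a constant offset (e.g. into an all-positive x'y'
    frame); pairwise distances are unaffected."""
    return ColorLocus(locus.x + dx, locus.y + dy, excitations=locus.excitations)


def spectrum_to_locus(reflectance: Spectrum, vs: VisualSystem | None = None) -> ColorLocus:
    """Convenience composition: reflectance -> excitations -> hexagon locus."""
    vs = VisualSystem.honeybee() if vs is None else vs
    return hexagon_locus(receptor_excitations(reflectance, vs))


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_spectra_csv(path) -> dict[str, Spectrum]:
    """Read spectra from CSV: column ``wavelength_nm`` plus one column per
    sample (sample IDs as headers)."""
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ValueError("spectra CSV must have a 'wavelength_nm' column")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength_nm must be strictly increasing")
    return {
        str(col): Spectrum(wl, df[col].to_numpy(dtype=float))
        for col in df.columns
        if col != "wavelength_nm"
    }


def read_loci_csv(path) -> dict[str, ColorLocus]:
    """Read loci from CSV with columns ``sample_id,x,y``."""
    df = pd.read_csv(path)
    for col in ("sample_id", "x", "y"):
        if col not in df.columns:
            raise ValueError("loci CSV must have columns sample_id,x,y")
    return {
        str(r.sample_id): ColorLocus(float(r.x), float(r.y))
        for r in df.itertuples(index=False)
    }


def write_loci_csv(loci: dict[str, ColorLocus], path) -> None:
    pd.DataFrame(
        {
            "sample_id": list(loci),
            "x": [l.x for l in loci.values()],
            "y": [l.y for l in loci.values()],
        }
    ).to_csv(path, index=False)
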