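"""Tissue optics: forward simulation of diffuse reflectance and the camera twin.

The forward model maps a physiological/optical parameter vector (oxygen
saturation StO2, blood volume fraction VHb, reduced scattering, water
content, ...) to a diffuse-reflectance spectrum on a fine simulation
wavelength grid, then resamples it through a digital twin of a 100-band
visible/NIR camera (500-995 nm, 5 nm pitch).

Reflectance is computed with a closed-form semi-infinite
diffusion-approximation model

    R_d = a' / (1 + 2k(1-a') + (1 + 2k/3) sqrt(3(1-a')))

where ``a' = mus'/(mua + mus')`` is the transport albedo and ``k`` is an
internal-reflection factor derived from the tissue refractive index
(Egan-Hilgeman style empirical fit). This preserves the dependencies the
retrieval pipeline exploits (mua down -> R up, mus' up -> R up, n through
boundary reflection) while staying deterministic and desk-scale.

Absorption is a linear chromophore mix:

    mua(lam) = vhb * C_hb * ln(10) * (sto2 * eps_HbO2 + (1-sto2) * eps_Hb)
               + w_water * mua_water(lam)

with C_hb the whole-blood hemoglobin molarity (150 g/L / 64500 g/mol), so
``vhb`` reads directly as a blood volume fraction.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

__all__ = [
    "C_HB_MOLAR",
    "PARAM_FIELDS",
    "PARAM_RANGES",
    "WavelengthGrid",
    "TissueParams",
    "ChromophoreTable",
    "ReflectanceSpectrum",
    "CameraModel",
    "simulation_grid",
    "camera_grid",
    "params_to_array",
    "absorption_coefficient",
    "reduced_scattering",
    "diffuse_reflectance",
    "diffuse_reflectance_batch",
    "resample_to_camera",
    "resample_batch",
    "l1_normalize",
    "isosbestic_wavelengths",
]

#: Whole-blood hemoglobin molarity [mol/L]: 150 g/L at 64500 g/mol.
C_HB_MOLAR = 150.0 / 64500.0

_LN10 = np.log(10.0)

#: Canonical ordering of the tissue parameter vector.
PARAM_FIELDS = ("sto2", "vhb", "mus500", "b_mie", "g", "n_refr", "d_cm", "w_water")

#: Admissible range per parameter (closed intervals).
PARAM_RANGES = {
    "sto2": (0.0, 1.0),
    "vhb": (0.0, 0.3),
    "mus500": (5.0, 50.0),
    "b_mie": (0.3, 3.0),
    "g": (0.8, 0.95),
    "n_refr": (1.33, 1.54),
    "d_cm": (0.002, 0.2),
    "w_water": (0.8, 0.9),
}


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing, uniformly spaced wavelength axis in nm."""

    wavelengths_nm: np.ndarray
    spacing_nm: float

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        if w.ndim != 1 or w.size < 2:
            raise DataError("wavelength grid needs at least two points")
        d = np.diff(w)
        if not np.all(d > 0):
            raise DataError("wavelengths must be strictly increasing")
        if not np.allclose(d, self.spacing_nm, rtol=0, atol=1e-9):
            raise DataError("wavelength spacing is not uniform")

    def __len__(self) -> int:
        return self.wavelengths_nm.size


def simulation_grid() -> WavelengthGrid:
    """Default fine grid for forward simulation: 300-1000 nm, 2 nm (351 points)."""
    return WavelengthGrid(np.arange(300.0, 1001.0, 2.0), 2.0)


def camera_grid() -> WavelengthGrid:
    """Default camera band-center grid: 500-995 nm, 5 nm (100 bands)."""
    return WavelengthGrid(np.arange(500.0, 996.0, 5.0), 5.0)


@dataclass(frozen=True)
class TissueParams:
    """Single tissue parameter vector; every field validated against PARAM_RANGES.

    ``g`` (anisotropy) and ``d_cm`` (layer thickness) are carried for
    fidelity to the full simulation parameter set but are not consumed by
    the semi-infinite diffusion model (scattering enters already reduced,
    the layer is treated as optically thick).
    """

    sto2: float
    vhb: float
    mus500: float
    b_mie: float
    g: float = 0.9
    n_refr: float = 1.4
    d_cm: float = 0.05
    w_water: float = 0.85

    def __post_init__(self):
        for name in PARAM_FIELDS:
            lo, hi = PARAM_RANGES[name]
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < lo or v > hi:
                raise DataError(
                    f"TissueParams.{name}={v!r} outside admissible range [{lo}, {hi}]"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_FIELDS], dtype=float)


def params_to_array(params) -> np.ndarray:
    """Coerce TissueParams / sequence of them / (N,8) array to a validated (N,8) array."""
    if isinstance(params, TissueParams):
        arr = params.as_array()[None, :]
    elif isinstance(params, np.ndarray):
        arr = np.atleast_2d(np.asarray(params, dtype=float))
    else:
        arr = np.stack([p.as_array() for p in params])
    if arr.ndim != 2 or arr.shape[1] != len(PARAM_FIELDS):
        raise DataError(f"parameter array must be (N, {len(PARAM_FIELDS)})")
    for j, name in enumerate(PARAM_FIELDS):
        lo, hi = PARAM_RANGES[name]
        col = arr[:, j]
        if not np.all(np.isfinite(col)) or col.min() < lo or col.max() > hi:
            raise DataError(f"parameter column {name!r} outside [{lo}, {hi}]")
    return arr


@dataclass(frozen=True)
class ChromophoreTable:
    """Per-wavelength chromophore basis: HbO2/Hb molar extinction and water absorption.

    The bundled default is a synthetic stand-in for digitized literature
    extinction curves (see data/chromophores_synthetic.tsv): smooth
    Gaussian-band constructions with the qualitative spectral features of
    the real chromophores and exact isosbestic crossings on the grid.
    """

    wavelengths_nm: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray
    mua_water: np.ndarray

    def __post_init__(self):
        for name in ("wavelengths_nm", "eps_hbo2", "eps_hb", "mua_water"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.wavelengths_nm.size
        if not all(a.shape == (n,) for a in (self.eps_hbo2, self.eps_hb, self.mua_water)):
            raise DataError("chromophore table columns have inconsistent lengths")
        if np.any(self.eps_hbo2 < 0) or np.any(self.eps_hb < 0) or np.any(self.mua_water < 0):
            raise DataError("chromophore table contains negative values")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise DataError("chromophore table wavelengths must be increasing")

    @classmethod
    def from_tsv(cls, path) -> "ChromophoreTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            df["wavelength_nm"].to_numpy(),
            df["eps_hbo2"].to_numpy(),
            df["eps_hb"].to_numpy(),
            df["mua_water"].to_numpy(),
        )

    @classmethod
    def default(cls) -> "ChromophoreTable":
        global _DEFAULT_TABLE
        if _DEFAULT_TABLE is None:
            ref = importlib.resources.files("hsi_tta.data") / "chromophores_synthetic.tsv"
            with importlib.resources.as_file(ref) as p:
                _DEFAULT_TABLE = cls.from_tsv(p)
        return _DEFAULT_TABLE

    def interpolate(self, grid: WavelengthGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Columns evaluated on ``grid``; wavelengths outside coverage are an error."""
        w = grid.wavelengths_nm
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        bad = (w < lo) | (w > hi)
        if np.any(bad):
            raise DataError(
                f"wavelength {w[bad][0]:g} nm outside chromophore table "
                f"coverage [{lo:g}, {hi:g}] nm"
            )
        return (
            np.interp(w, self.wavelengths_nm, self.eps_hbo2),
            np.interp(w, self.wavelengths_nm, self.eps_hb),
            np.interp(w, self.wavelengths_nm, self.mua_water),
        )


_DEFAULT_TABLE = None


def isosbestic_wavelengths(
    table: ChromophoreTable, lo: float = 500.0, hi: float = 995.0
) -> np.ndarray:
    """Grid wavelengths in [lo, hi] where eps_HbO2 equals eps_Hb exactly."""
    w = table.wavelengths_nm
    m = (w >= lo) & (w <= hi) & (table.eps_hbo2 == table.eps_hb)
    return w[m]


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Reflectance values on an explicit wavelength grid."""

    values: np.ndarray
    grid: WavelengthGrid
    normalized: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.grid),):
            raise DataError("spectrum length does not match its wavelength grid")
        if not np.all(np.isfinite(v)):
            raise DataError("spectrum contains non-finite values")
        if self.normalized:
            if abs(np.abs(v).sum() - 1.0) > 1e-9:
                raise DataError("normalized flag set but |values| do not sum to 1")
        elif v.min() < 0 or v.max() > 1:
            raise DataError("un-normalized reflectance must lie in [0, 1]")


@dataclass(frozen=True)
class CameraModel:
    """Digital twin of the 100-band camera: band centers plus a spectral response."""

    band_centers_nm: np.ndarray = field(default_factory=lambda: np.arange(500.0, 996.0, 5.0))
    band_width_nm: float = 5.0
    srf_kind: str = "boxcar"

    def __post_init__(self):
        c = np.asarray(self.band_centers_nm, dtype=float)
        object.__setattr__(self, "band_centers_nm", c)
        if c.size != 100:
            raise DataError(f"camera must have 100 bands, got {c.size}")
        if not np.allclose(np.diff(c), 5.0):
            raise DataError("camera band centers must be uniform at 5 nm")
        if self.srf_kind not in ("boxcar", "gaussian"):
            raise DataError(f"unknown spectral response kind {self.srf_kind!r}")

    def response_matrix(self, grid: WavelengthGrid) -> np.ndarray:
        """(100, L) row-normalized band weights on the simulation grid.

        Boxcar: uniform weights over centers +- width/2. Gaussian: FWHM equal
        to the band width, evaluated out to 3 sigma but truncated at the grid
        edge. Raises if the grid does not cover a band's central half-width.
        """
        lam = grid.wavelengths_nm
        half = self.band_width_nm / 2.0
        W = np.zeros((self.band_centers_nm.size, lam.size))
        for i, c in enumerate(self.band_centers_nm):
            if lam[0] > c - half or lam[-1] < c + half:
                raise DataError(
                    f"simulation grid does not cover camera band at {c:g} nm"
                )
            if self.srf_kind == "boxcar":
                W[i, np.abs(lam - c) <= half] = 1.0
            else:
                sigma = self.band_width_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
                m = np.abs(lam - c) <= 3.0 * sigma
                W[i, m] = np.exp(-((lam[m] - c) ** 2) / (2.0 * sigma**2))
            W[i] /= W[i].sum()
        return W

    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(self.band_centers_nm, 5.0)


# ---------------------------------------------------------------------------
# forward model

def absorption_coefficient(params, grid: WavelengthGrid, table: ChromophoreTable) -> np.ndarray:
    """Absorption coefficient mua [1/cm]; (L,) for one record, (N, L) for a batch."""
    arr = params_to_array(params)
    eps_o, eps_d, mw = table.interpolate(grid)
    sto2, vhb, w = arr[:, 0:1], arr[:, 1:2], arr[:, 7:8]
    mua = vhb * C_HB_MOLAR * _LN10 * (sto2 * eps_o + (1 - sto2) * eps_d) + w * mw
    return mua[0] if isinstance(params, TissueParams) else mua


def reduced_scattering(params, grid: WavelengthGrid) -> np.ndarray:
    """Reduced scattering mus' [1/cm] from the Mie power law anchored at 500 nm."""
    arr = params_to_array(params)
    lam = grid.wavelengths_nm
    musp = arr[:, 2:3] * (lam / 500.0) ** (-arr[:, 3:4])
    return musp[0] if isinstance(params, TissueParams) else musp


def _rd_from_albedo(albedo: np.ndarray, n_refr: np.ndarray) -> np.ndarray:
    r_id = -1.440 / n_refr**2 + 0.710 / n_refr + 0.668 + 0.0636 * n_refr
    k = (1.0 + r_id) / (1.0 - r_id)
    one_m = 1.0 - albedo
    return albedo / (1.0 + 2.0 * k * one_m + (1.0 + 2.0 * k / 3.0) * np.sqrt(3.0 * one_m))


def diffuse_reflectance_batch(
    params_arr: np.ndarray,
    grid: WavelengthGrid,
    table: ChromophoreTable,
    mua_override: np.ndarray | None = None,
) -> np.ndarray:
    """(N, L) diffuse reflectance for an (N, 8) parameter array.

    ``mua_override`` substitutes the absorption coefficient (same shape as
    the computed mua); used for opacity-limit checks and model probing.
    """
    arr = params_to_array(params_arr)
    mua = mua_override if mua_override is not None else absorption_coefficient(arr, grid, table)
    musp = reduced_scattering(arr, grid)
    albedo = musp / (mua + musp)
    rd = _rd_from_albedo(albedo, arr[:, 5:6])
    if not np.all(np.isfinite(rd)):
        raise DataError("diffuse reflectance produced non-finite values")
    return rd


def diffuse_reflectance(
    params: TissueParams,
    grid: WavelengthGrid | None = None,
    table: ChromophoreTable | None = None,
    mua_override: np.ndarray | None = None,
) -> ReflectanceSpectrum:
    """Un-normalized diffuse reflectance for a single tissue parameter vector."""
    grid = grid or simulation_grid()
    table = table or ChromophoreTable.default()
    ov = None if mua_override is None else np.atleast_2d(mua_override)
    rd = diffuse_reflectance_batch(params.as_array()[None, :], grid, table, mua_override=ov)
    return ReflectanceSpectrum(rd[0], grid, normalized=False)


def resample_batch(values: np.ndarray, grid: WavelengthGrid, cam: CameraModel) -> np.ndarray:
    """Resample (N, L) simulation-grid spectra to (N, 100) camera bands."""
    W = cam.response_matrix(grid)
    return np.atleast_2d(values) @ W.T


def resample_to_camera(spec: ReflectanceSpectrum, cam: CameraModel) -> ReflectanceSpectrum:
    """Weighted band-averaging of a simulation-grid spectrum through the camera twin."""
    out = resample_batch(spec.values[None, :], spec.grid, cam)[0]
    return ReflectanceSpectrum(out, cam.grid(), normalized=False)


def l1_normalize(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Scale spectra so absolute values sum to one along ``axis``."""
    v = np.asarray(values, dtype=float)
    s = np.abs(v).sum(axis=axis, keepdims=True)
    if np.any(s == 0):
        raise DataError("cannot L1-normalize an all-zero spectrum")
    return v / s
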