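"""Detection-volume (PSF) models.

The effective detection volume (EDV) of a confocal microscope is represented
here as a peak-normalized intensity field: the probability that a photon
emitted by a molecule at position ``r`` is detected is proportional to the
field value at ``r``.  Two models are supported:

* :class:`GaussianPSF` — the separable 3D Gaussian approximation,
  ``exp(-x²/2σx²) · exp(-y²/2σy²) · exp(-z²/2σz²)``, with lateral standard
  deviations σx = σy = 180 nm and axial σz = 880 nm by default.
* :class:`TabulatedPSF` — an arbitrary non-negative intensity field sampled
  on a regular 3D grid (e.g. the product of numerically computed excitation
  and detection profiles), evaluated by trilinear interpolation and zero
  outside the grid's support.

All positions handled by this module are in nanometres; the diffusion and
photon modules convert from micrometres at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "GaussianPSF",
    "TabulatedPSF",
    "load_tabulated_psf",
    "save_tabulated_psf",
    "make_squared_gaussian_grid",
    "psf_energy",
    "rescale_to_energy",
]


def _check_position(position: np.ndarray) -> np.ndarray:
    pos = np.asarray(position, dtype=float)
    if pos.shape[-1] != 3:
        raise ValueError("position must have 3 components on the last axis")
    if not np.all(np.isfinite(pos)):
        raise ValueError("position must be finite")
    return pos


@dataclass(frozen=True)
class GaussianPSF:
    """Separable Gaussian detection profile, peak-normalized to 1 at the origin.

    Parameters are standard deviations in nm along x, y, z.
    """

    sigma_x_nm: float = 180.0
    sigma_y_nm: float = 180.0
    sigma_z_nm: float = 880.0

    kind = "gaussian"

    def __post_init__(self) -> None:
        if min(self.sigma_x_nm, self.sigma_y_nm, self.sigma_z_nm) <= 0:
            raise ValueError("PSF standard deviations must be positive")

    @property
    def sigmas_nm(self) -> np.ndarray:
        return np.array([self.sigma_x_nm, self.sigma_y_nm, self.sigma_z_nm])

    def evaluate(self, position_nm) -> np.ndarray:
        """Intensity in [0, 1] at ``position_nm`` (…, 3 array, nm)."""
        pos = _check_position(position_nm)
        q = 0.5 * np.sum((pos / self.sigmas_nm) ** 2, axis=-1)
        return np.exp(-q)


@dataclass(frozen=True)
class TabulatedPSF:
    """Detection profile sampled on a regular grid; trilinear interpolation.

    ``grid`` is a 3D array of non-negative intensities (rescaled so the
    maximum is 1), ``spacing_nm`` the (dx, dy, dz) node spacings and
    ``origin_nm`` the position of node ``grid[0, 0, 0]``.  Evaluation
    outside the grid support returns 0.
    """

    grid: np.ndarray
    spacing_nm: tuple[float, float, float]
    origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    _interp: RegularGridInterpolator = field(init=False, repr=False, compare=False)

    kind = "tabulated"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 3:
            raise ValueError("tabulated PSF grid must be 3D")
        if np.any(grid < 0):
            raise ValueError("tabulated PSF grid must be non-negative")
        peak = grid.max()
        if peak <= 0:
            raise ValueError("tabulated PSF grid is identically zero")
        object.__setattr__(self, "grid", grid / peak)
        axes = [
            self.origin_nm[i] + self.spacing_nm[i] * np.arange(grid.shape[i])
            for i in range(3)
        ]
        interp = RegularGridInterpolator(
            axes, self.grid, method="linear", bounds_error=False, fill_value=0.0
        )
        object.__setattr__(self, "_interp", interp)

    def evaluate(self, position_nm) -> np.ndarray:
        pos = _check_position(position_nm)
        out = self._interp(pos)
        if pos.ndim == 1:
            return float(out[0])
        return out


def make_squared_gaussian_grid(
    sigma_x_nm: float = 180.0,
    sigma_y_nm: float = 180.0,
    sigma_z_nm: float = 880.0,
    extent_xy_nm: float = 2000.0,
    extent_z_nm: float = 6000.0,
    n_xy: int = 81,
    n_z: int = 81,
) -> TabulatedPSF:
    """Surrogate "narrower-than-Gaussian" numerical PSF.

    The square of a Gaussian profile (the product of identical excitation and
    detection Gaussians) tabulated on a regular grid: an analytically known
    field that is narrower than its Gaussian parent, used to exercise the
    tabulated-PSF code path and the wide-vs-narrow EDV comparisons.
    """
    x = np.linspace(-extent_xy_nm, extent_xy_nm, n_xy)
    y = np.linspace(-extent_xy_nm, extent_xy_nm, n_xy)
    z = np.linspace(-extent_z_nm, extent_z_nm, n_z)
    gx = np.exp(-0.5 * (x / sigma_x_nm) ** 2)
    gy = np.exp(-0.5 * (y / sigma_y_nm) ** 2)
    gz = np.exp(-0.5 * (z / sigma_z_nm) ** 2)
    grid = (gx[:, None, None] * gy[None, :, None] * gz[None, None, :]) ** 2
    return TabulatedPSF(
        grid=grid,
        spacing_nm=(x[1] - x[0], y[1] - y[0], z[1] - z[0]),
        origin_nm=(x[0], y[0], z[0]),
    )


def load_tabulated_psf(path) -> TabulatedPSF:
    """Read a tabulated PSF from HDF5 (datasets ``psf/data``, ``psf/spacing_nm``,
    ``psf/origin_nm``); intensities are rescaled so the maximum is 1."""
    with h5py.File(path, "r") as f:
        if "psf" not in f or "data" not in f["psf"]:
            raise ValueError(f"{path}: missing psf/data dataset")
        data = f["psf/data"][()]
        if "spacing_nm" not in f["psf"]:
            raise ValueError(f"{path}: missing psf/spacing_nm dataset")
        spacing = f["psf/spacing_nm"][()]
        origin = f["psf/origin_nm"][()] if "origin_nm" in f["psf"] else np.zeros(3)
    if np.ndim(data) != 3:
        raise ValueError(f"{path}: psf/data must be a 3D array")
    if np.any(np.asarray(data) < 0):
        raise ValueError(f"{path}: psf/data has negative intensities")
    if np.shape(spacing) != (3,):
        raise ValueError(f"{path}: psf/spacing_nm must hold 3 values")
    return TabulatedPSF(grid=data, spacing_nm=tuple(spacing), origin_nm=tuple(origin))


def save_tabulated_psf(psf: TabulatedPSF, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("psf/data", data=psf.grid)
        f.create_dataset("psf/spacing_nm", data=np.asarray(psf.spacing_nm, float))
        f.create_dataset("psf/origin_nm", data=np.asarray(psf.origin_nm, float))


def psf_energy(psf) -> float:
    """Volume integral of the peak-normalized intensity field, in nm³.

    For the Gaussian model the closed form is (2π)^{3/2} σx σy σz; tabulated
    grids are integrated by a Riemann sum over the nodes.
    """
    if psf.kind == "gaussian":
        return float((2 * np.pi) ** 1.5 * psf.sigma_x_nm * psf.sigma_y_nm * psf.sigma_z_nm)
    voxel = float(np.prod(psf.spacing_nm))
    return float(psf.grid.sum() * voxel)


def rescale_to_energy(psf, target_energy_nm3: float):
    """Brightness multiplier making ``psf`` deliver ``target_energy_nm3``.

    Detection-volume models are compared at equal energies rather than equal
    widths: the peak-normalized field is kept as-is and the molecular
    brightness is scaled by ``target_energy / psf_energy`` so a uniformly
    distributed emitter population yields the same total detected photon flux
    under either model.  Returns ``(psf, multiplier)``.
    """
    if target_energy_nm3 <= 0:
        raise ValueError("target energy must be positive")
    own = psf_energy(psf)
    if own <= 0:
        raise ValueError("degenerate PSF model with zero energy")
    return psf, target_energy_nm3 / own
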