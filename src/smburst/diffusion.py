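"""3D Brownian dynamics of point molecules in a periodic box.

The simulation backbone: ``n`` molecules perform free diffusion in a
rectangular box with periodic boundary conditions, advanced in fixed time
steps (200 ns by default).  The box volume encodes the molar concentration
(``V = n / (c · N_A)``), so a 15-molecule simulation at 62 pM runs in a
~402 μm³ box.  Trajectories are produced as a stream of fixed-size chunks so
long runs never materialize the full position history (a 60 s run at 200 ns
holds ~4.5 × 10⁹ positions).

Periodic boundaries preserve the uniform stationary distribution, i.e. a
constant concentration, without depletion at walls.  The default box aspect
is (1, 1, 2): elongated along the optical (z) axis so that every box
dimension is large compared to the corresponding extent of the detection
volume (σz = 880 nm ≫ σx).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from ._kernels import brownian_chunk, unwrap_chunk
from ._rng import substream

__all__ = [
    "AVOGADRO",
    "SimulationConfig",
    "TrajectoryChunk",
    "box_from_concentration",
    "simulate",
    "estimate_diffusion_coeff",
    "dump_trajectories",
]

AVOGADRO = 6.02214076e23  # 1/mol

#: μm³ per litre
_UM3_PER_L = 1e15


def box_from_concentration(
    n_molecules: int,
    concentration_pM: float,
    aspect: Sequence[float] = (1.0, 1.0, 2.0),
) -> np.ndarray:
    """Box edge lengths (μm) holding ``n_molecules`` at ``concentration_pM``.

    The volume ``V = n / (c · N_A)`` is distributed over the axes in the given
    aspect ratios: ``L_i = aspect_i · (V / Πaspect)^(1/3)``.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if concentration_pM <= 0:
        raise ValueError("concentration must be positive")
    aspect = np.asarray(aspect, dtype=float)
    if aspect.shape != (3,) or np.any(aspect <= 0):
        raise ValueError("aspect must be 3 positive ratios")
    volume_um3 = n_molecules / (concentration_pM * 1e-12 * AVOGADRO) * _UM3_PER_L
    unit = (volume_um3 / np.prod(aspect)) ** (1.0 / 3.0)
    return aspect * unit


@dataclass
class SimulationConfig:
    """Parameters of one diffusion/photon simulation.

    ``diffusion_um2_s`` may be a scalar or one value per molecule.
    ``bg_rate_khz`` is a single rate for one-channel simulations or a
    (donor, acceptor) pair for smFRET ones.  If ``box_um`` is None the box
    is derived from the concentration and aspect ratios.
    """

    n_molecules: int = 15
    concentration_pM: float = 62.0
    diffusion_um2_s: float | Sequence[float] = 90.0
    timestep_ns: float = 200.0
    duration_s: float = 5.0
    brightness_khz: float = 200.0
    bg_rate_khz: float | tuple[float, float] = 2.3
    seed: int = 0
    box_um: np.ndarray | None = None
    aspect: tuple[float, float, float] = (1.0, 1.0, 2.0)
    chunk_steps: int = 300_000

    def __post_init__(self) -> None:
        if self.timestep_ns <= 0 or self.duration_s <= 0:
            raise ValueError("timestep and duration must be positive")
        if np.any(np.asarray(self.diffusion_um2_s) < 0):
            raise ValueError("diffusion coefficient must be >= 0")
        if np.any(np.asarray(self.bg_rate_khz) < 0) or self.brightness_khz < 0:
            raise ValueError("rates must be >= 0")
        if self.box_um is None:
            self.box_um = box_from_concentration(
                self.n_molecules, self.concentration_pM, self.aspect
            )
        else:
            self.box_um = np.asarray(self.box_um, dtype=float)
            if self.box_um.shape != (3,) or np.any(self.box_um <= 0):
                raise ValueError("box_um must be 3 positive lengths")
            implied_pM = (
                self.n_molecules
                / (np.prod(self.box_um) / _UM3_PER_L)
                / AVOGADRO
                / 1e-12
            )
            if abs(implied_pM - self.concentration_pM) / self.concentration_pM > 1e-3:
                self.concentration_pM = implied_pM

    @property
    def timestep_s(self) -> float:
        return self.timestep_ns * 1e-9

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_s / self.timestep_s))

    @property
    def diffusion_per_molecule(self) -> np.ndarray:
        d = np.broadcast_to(
            np.asarray(self.diffusion_um2_s, dtype=float), (self.n_molecules,)
        )
        return np.array(d)


@dataclass
class TrajectoryChunk:
    """Positions of all molecules over a contiguous span of steps.

    ``positions[i, s, a]`` is molecule ``i`` at global step
    ``start_step + s``, axis ``a``, wrapped into the box (μm).
    """

    positions: np.ndarray
    start_step: int
    timestep_ns: float

    @property
    def n_steps(self) -> int:
        return self.positions.shape[1]


def simulate(config: SimulationConfig) -> Iterator[TrajectoryChunk]:
    """Stream Brownian trajectory chunks for ``config``.

    Per axis and step, displacements are N(0, 2·D·dt); initial positions are
    uniform in the box; positions are wrapped periodically.  Given the same
    config (including seed), the stream is bit-identical between runs.
    """
    rng = substream(config.seed, "diffusion")
    box = config.box_um
    box_half = box / 2.0
    d_mol = config.diffusion_per_molecule
    step_sd = np.sqrt(2.0 * d_mol * config.timestep_s)  # (n_mol,), μm
    if np.any(step_sd > box.min() / 4.0):
        warnings.warn(
            "per-step displacement exceeds a quarter box length; "
            "PSF sampling along trajectories will be too coarse",
            stacklevel=2,
        )
    current = rng.uniform(-box_half, box_half, size=(config.n_molecules, 3))
    n_total = config.n_steps
    start = 0
    while start < n_total:
        n = min(config.chunk_steps, n_total - start)
        if step_sd.max() > 0:
            steps = rng.standard_normal(
                (config.n_molecules, n, 3), dtype=np.float32
            )
            steps *= step_sd[:, None, None].astype(np.float32)
        else:
            steps = np.zeros((config.n_molecules, n, 3), dtype=np.float32)
        out = np.empty_like(steps)
        brownian_chunk(steps, current, box_half, out)
        yield TrajectoryChunk(out, start, config.timestep_ns)
        start += n


def estimate_diffusion_coeff(
    chunks: Iterator[TrajectoryChunk],
    box_um: np.ndarray,
    max_lag: int = 8,
    stride: int = 50,
) -> tuple[float, float]:
    """MSD-based diffusion-coefficient estimate with standard error (μm²/s).

    Trajectories are unwrapped across periodic crossings, the per-axis mean
    squared displacement is accumulated at lags 1..max_lag steps (window
    starts thinned by ``stride`` for speed), and MSD(t) = 2·D·t is fitted
    through the origin per molecule and axis.  The estimate is the mean over
    molecule × axis slopes; the error is their standard error.
    """
    box_len = np.asarray(box_um, dtype=float)
    sums = None
    counts = None
    prev = None
    timestep_s = None
    total_steps = 0
    for chunk in chunks:
        timestep_s = chunk.timestep_ns * 1e-9
        n_mol, n_steps = chunk.positions.shape[0], chunk.n_steps
        if prev is None:
            prev = chunk.positions[:, 0, :].astype(np.float64)
            sums = np.zeros((n_mol, 3, max_lag))
            counts = np.zeros(max_lag, dtype=np.int64)
        unwrapped = np.empty((n_mol, n_steps, 3), dtype=np.float64)
        unwrap_chunk(chunk.positions, prev, box_len, unwrapped)
        total_steps += n_steps
        for lag in range(1, max_lag + 1):
            if n_steps <= lag:
                continue
            idx = np.arange(0, n_steps - lag, stride)
            d = unwrapped[:, idx + lag, :] - unwrapped[:, idx, :]
            sums[:, :, lag - 1] += np.sum(d * d, axis=1)
            counts[lag - 1] += len(idx)
    if prev is None or total_steps < 1000:
        raise ValueError("need at least 1000 simulated steps to estimate D")
    msd = sums / counts[None, None, :]  # (n_mol, 3, lag)
    t = np.arange(1, max_lag + 1) * timestep_s
    # least-squares slope through origin of MSD(t) = 2 D t
    slopes = np.tensordot(msd, t, axes=([2], [0])) / np.sum(t * t)
    d_values = slopes.ravel() / 2.0
    d_hat = float(np.mean(d_values))
    d_se = float(np.std(d_values, ddof=1) / np.sqrt(d_values.size))
    return d_hat, d_se


def dump_trajectories(chunks: Iterator[TrajectoryChunk], path) -> int:
    """Optional trajectory archive: HDF5 ``trajectories/positions`` (float32,
    μm, chunked+gzip) and ``trajectories/timestep_ns``.  Returns the number
    of steps written.  Off by default in the pipeline — a 60 s record at
    200 ns is tens of GB."""
    import h5py

    written = 0
    with h5py.File(path, "w") as f:
        dset = None
        for chunk in chunks:
            n_mol, n_steps = chunk.positions.shape[0], chunk.n_steps
            if dset is None:
                dset = f.create_dataset(
                    "trajectories/positions",
                    shape=(n_mol, 0, 3),
                    maxshape=(n_mol, None, 3),
                    chunks=(n_mol, min(n_steps, 65536), 3),
                    dtype=np.float32,
                    compression="gzip",
                    compression_opts=1,
                )
                f.create_dataset("trajectories/timestep_ns", data=chunk.timestep_ns)
            dset.resize(written + n_steps, axis=1)
            dset[:, written : written + n_steps, :] = chunk.positions
            written += n_steps
    return written
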