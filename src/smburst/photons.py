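"""Photon generation: PSF-weighted emission, background, channel splitting.

A trajectory stream is converted into labeled photon records by Bernoulli
thinning of the inhomogeneous Poisson emission process: at each 200 ns step a
molecule emits with probability ``brightness · PSF(r) · dt`` (at the default
200 kHz peak brightness this is at most 0.04, so the one-photon-per-step
approximation is accurate to O(p²)).  Timestamps are integer step indices —
exact arithmetic, bit-stable sorting — with the step duration carried as
metadata, mirroring photon-counting hardware conventions.

Every photon carries its ground-truth molecule id and emission position;
background photons (an added homogeneous Poisson process) carry id −1 and a
NaN position.  For smFRET simulations each signal photon is routed to the
acceptor channel with probability E(molecule) and to the donor channel
otherwise, after which channel-specific backgrounds are added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from ._kernels import gaussian_emission
from ._rng import substream
from .diffusion import SimulationConfig, TrajectoryChunk, simulate
from .psf import GaussianPSF

__all__ = [
    "CHANNEL_SINGLE",
    "CHANNEL_DONOR",
    "CHANNEL_ACCEPTOR",
    "PhotonStream",
    "FRETConfig",
    "emission_rate",
    "draw_photons",
    "add_background",
    "split_channels",
    "simulate_photons",
]

CHANNEL_SINGLE = 0
CHANNEL_DONOR = 1
CHANNEL_ACCEPTOR = 2

BACKGROUND_ID = -1
#: molecule id used by readers when a file carries no ground-truth labels
UNKNOWN_ID = -2


@dataclass
class PhotonStream:
    """Time-ordered photon records with ground-truth labels.

    timestamps   : int64 step indices (one step = ``timestep_ns``)
    molecule_id  : int32, −1 for background
    channel      : uint8, one of the CHANNEL_* constants
    position_um  : (n, 3) float32 emission positions, NaN for background
    """

    timestamps: np.ndarray
    molecule_id: np.ndarray
    channel: np.ndarray
    position_um: np.ndarray
    timestep_ns: float
    duration_s: float
    n_molecules: int

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def times_s(self) -> np.ndarray:
        return self.timestamps * (self.timestep_ns * 1e-9)

    @property
    def is_background(self) -> np.ndarray:
        return self.molecule_id == BACKGROUND_ID

    def validate(self) -> None:
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("photon timestamps are not sorted")
        signal = ~self.is_background
        if signal.any() and not np.all(np.isfinite(self.position_um[signal])):
            raise ValueError("signal photons must carry finite positions")

    def sorted(self) -> "PhotonStream":
        """Time-sorted copy with ties ordered by molecule id (stable)."""
        order = np.lexsort((self.molecule_id, self.timestamps))
        return replace(
            self,
            timestamps=self.timestamps[order],
            molecule_id=self.molecule_id[order],
            channel=self.channel[order],
            position_um=self.position_um[order],
        )


def _empty_stream(timestep_ns: float, duration_s: float, n_molecules: int) -> PhotonStream:
    return PhotonStream(
        timestamps=np.empty(0, np.int64),
        molecule_id=np.empty(0, np.int32),
        channel=np.empty(0, np.uint8),
        position_um=np.empty((0, 3), np.float32),
        timestep_ns=timestep_ns,
        duration_s=duration_s,
        n_molecules=n_molecules,
    )


def _merge(a: PhotonStream, b: PhotonStream) -> PhotonStream:
    merged = replace(
        a,
        timestamps=np.concatenate([a.timestamps, b.timestamps]),
        molecule_id=np.concatenate([a.molecule_id, b.molecule_id]),
        channel=np.concatenate([a.channel, b.channel]),
        position_um=np.concatenate([a.position_um, b.position_um]),
    )
    return merged.sorted()


@dataclass(frozen=True)
class FRETConfig:
    """Per-molecule FRET efficiencies for an smFRET simulation."""

    efficiencies: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.efficiencies, dtype=float)
        if np.any((e < 0) | (e > 1)):
            raise ValueError("FRET efficiencies must lie in [0, 1]")
        object.__setattr__(self, "efficiencies", e)

    @classmethod
    def two_populations(
        cls, n_high: int = 10, e_high: float = 0.75, n_low: int = 5, e_low: float = 0.5
    ) -> "FRETConfig":
        """The default two-species mixture: 10 molecules at E = 0.75 and 5 at 0.50."""
        return cls(np.array([e_high] * n_high + [e_low] * n_low))

    @property
    def n_molecules(self) -> int:
        return len(self.efficiencies)


def emission_rate(psf, position_nm, brightness_khz: float) -> np.ndarray:
    """Instantaneous emission rate (kHz) at a position: brightness · PSF(r)."""
    if brightness_khz < 0:
        raise ValueError("brightness must be >= 0")
    return brightness_khz * psf.evaluate(position_nm)


def draw_photons(
    chunks: Iterable[TrajectoryChunk],
    psf,
    brightness_khz: float,
    seed: int,
    duration_s: float,
    n_molecules: int,
    brightness_multiplier: float = 1.0,
) -> PhotonStream:
    """Emit photons along a trajectory stream (no background).

    ``brightness_multiplier`` rescales the peak brightness, e.g. the
    equal-energy factor from :func:`smburst.psf.rescale_to_energy`.
    """
    rng = substream(seed, "emission")
    ts_parts: list[np.ndarray] = []
    mol_parts: list[np.ndarray] = []
    pos_parts: list[np.ndarray] = []
    timestep_ns = None
    gaussian = isinstance(psf, GaussianPSF)
    if gaussian:
        sig_um = psf.sigmas_nm / 1000.0
        inv_2s2 = 1.0 / (2.0 * sig_um**2)
    for chunk in chunks:
        timestep_ns = chunk.timestep_ns
        dt_s = timestep_ns * 1e-9
        p_peak = brightness_khz * 1e3 * brightness_multiplier * dt_s
        if p_peak > 0.1:
            warnings.warn(
                f"peak per-step emission probability {p_peak:.2f} > 0.1; "
                "Bernoulli thinning becomes a poor Poisson approximation",
                stacklevel=2,
            )
        n_mol, n_steps = chunk.positions.shape[0], chunk.n_steps
        u = rng.random((n_mol, n_steps), dtype=np.float32)
        if gaussian:
            cap = max(1024, int(4 * p_peak * n_mol * n_steps))
            out_mol = np.empty(cap, np.int32)
            out_step = np.empty(cap, np.int64)
            k = gaussian_emission(chunk.positions, inv_2s2, p_peak, u, out_mol, out_step)
            mol, step = out_mol[:k], out_step[:k]
        else:
            pos_nm = chunk.positions * np.float32(1000.0)
            # only interpolate inside the grid's support; outside is 0
            lo = np.asarray(psf.origin_nm, np.float32)
            hi = lo + np.asarray(psf.spacing_nm, np.float32) * (
                np.array(psf.grid.shape, np.float32) - 1
            )
            inside = np.all((pos_nm >= lo) & (pos_nm <= hi), axis=-1)
            p = np.zeros(pos_nm.shape[:2], dtype=float)
            if inside.any():
                p[inside] = p_peak * psf.evaluate(pos_nm[inside])
            mol, step = np.nonzero(u < p)
        if len(mol) == 0:
            continue
        order = np.lexsort((mol, step))
        mol, step = mol[order], step[order]
        ts_parts.append(step + chunk.start_step)
        mol_parts.append(mol.astype(np.int32))
        pos_parts.append(chunk.positions[mol, step, :])
    if timestep_ns is None:
        raise ValueError("empty trajectory stream")
    if not ts_parts:
        return _empty_stream(timestep_ns, duration_s, n_molecules)
    return PhotonStream(
        timestamps=np.concatenate(ts_parts).astype(np.int64),
        molecule_id=np.concatenate(mol_parts),
        channel=np.zeros(sum(map(len, ts_parts)), np.uint8),
        position_um=np.concatenate(pos_parts),
        timestep_ns=timestep_ns,
        duration_s=duration_s,
        n_molecules=n_molecules,
    )


def _poisson_timestamps(
    rate_khz: float, duration_s: float, timestep_ns: float, rng: np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson arrivals as sorted integer step indices."""
    n_steps = int(round(duration_s / (timestep_ns * 1e-9)))
    count = rng.poisson(rate_khz * 1e3 * duration_s)
    ts = rng.integers(0, max(n_steps, 1), size=count, dtype=np.int64)
    ts.sort()
    return ts


def add_background(
    stream: PhotonStream,
    bg_rate_khz: float,
    seed: int,
    channel: int = CHANNEL_SINGLE,
) -> PhotonStream:
    """Merge homogeneous Poisson background (molecule id −1, NaN position)."""
    if bg_rate_khz < 0:
        raise ValueError("background rate must be >= 0")
    if bg_rate_khz == 0:
        return stream
    rng = substream(seed, "background")
    ts = _poisson_timestamps(bg_rate_khz, stream.duration_s, stream.timestep_ns, rng)
    bg = PhotonStream(
        timestamps=ts,
        molecule_id=np.full(len(ts), BACKGROUND_ID, np.int32),
        channel=np.full(len(ts), channel, np.uint8),
        position_um=np.full((len(ts), 3), np.nan, np.float32),
        timestep_ns=stream.timestep_ns,
        duration_s=stream.duration_s,
        n_molecules=stream.n_molecules,
    )
    return _merge(stream, bg)


def split_channels(
    stream: PhotonStream,
    fret: FRETConfig,
    bg_donor_khz: float = 1.5,
    bg_acceptor_khz: float = 0.8,
    seed: int = 0,
) -> PhotonStream:
    """Assign donor/acceptor channels by per-molecule E; add channel backgrounds.

    Each signal photon goes to the acceptor channel with probability
    E(molecule), independently; the input stream must not contain background
    yet (the two channel backgrounds are drawn here, at their own rates).
    """
    if stream.is_background.any():
        raise ValueError("split_channels expects a background-free stream")
    if fret.n_molecules != stream.n_molecules:
        raise ValueError("FRETConfig must define E for every molecule")
    rng = substream(seed, "channels")
    e_per_photon = fret.efficiencies[stream.molecule_id]
    acceptor = rng.random(len(stream)) < e_per_photon
    channel = np.where(acceptor, CHANNEL_ACCEPTOR, CHANNEL_DONOR).astype(np.uint8)
    out = replace(stream, channel=channel)
    for rate, chan, tag in (
        (bg_donor_khz, CHANNEL_DONOR, 0),
        (bg_acceptor_khz, CHANNEL_ACCEPTOR, 1),
    ):
        if rate < 0:
            raise ValueError("background rate must be >= 0")
        if rate == 0:
            continue
        ts = _poisson_timestamps(rate, stream.duration_s, stream.timestep_ns, rng)
        bg = PhotonStream(
            timestamps=ts,
            molecule_id=np.full(len(ts), BACKGROUND_ID, np.int32),
            channel=np.full(len(ts), chan, np.uint8),
            position_um=np.full((len(ts), 3), np.nan, np.float32),
            timestep_ns=stream.timestep_ns,
            duration_s=stream.duration_s,
            n_molecules=stream.n_molecules,
        )
        out = _merge(out, bg)
    return out


def simulate_photons(
    config: SimulationConfig,
    psf=None,
    fret: FRETConfig | None = None,
    brightness_multiplier: float = 1.0,
) -> PhotonStream:
    """End-to-end convenience: diffusion → emission → background/channels.

    With ``fret`` given, ``config.bg_rate_khz`` must be a (donor, acceptor)
    pair; otherwise a single-channel background is added.
    """
    if psf is None:
        psf = GaussianPSF()
    chunks = simulate(config)
    stream = draw_photons(
        chunks,
        psf,
        config.brightness_khz,
        config.seed,
        config.duration_s,
        config.n_molecules,
        brightness_multiplier=brightness_multiplier,
    )
    if fret is not None:
        bg = config.bg_rate_khz
        if np.ndim(bg) != 1 or len(bg) != 2:
            raise ValueError("smFRET simulations need (donor, acceptor) bg rates")
        return split_channels(stream, fret, bg[0], bg[1], seed=config.seed)
    if np.ndim(config.bg_rate_khz) != 0:
        raise ValueError("single-channel simulations need a scalar bg rate")
    return add_background(stream, float(config.bg_rate_khz), seed=config.seed)
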