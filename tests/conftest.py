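import numpy as np
import pytest

import smburst as sb


@pytest.fixture(scope="session")
def short_stream():
    """A 0.5 s default-condition photon stream with background (seed 42)."""
    cfg = sb.SimulationConfig(duration_s=0.5, seed=42)
    return sb.simulate_photons(cfg)


@pytest.fixture(scope="session")
def fret_stream():
    """A 2 s two-population smFRET stream (10× E=0.75, 5× E=0.50, seed 7)."""
    cfg = sb.SimulationConfig(duration_s=2.0, bg_rate_khz=(1.5, 0.8), seed=7)
    return sb.simulate_photons(cfg, fret=sb.FRETConfig.two_populations())


def make_burst(molecule_ids, channels=None, times_s=None, positions_um=None):
    """Handmade Burst for unit tests of the purity/FRET statistics."""
    ids = np.asarray(molecule_ids, dtype=np.int32)
    n = len(ids)
    if times_s is None:
        times_s = np.arange(n, dtype=float) * 1e-4
    if channels is None:
        channels = np.zeros(n, dtype=np.uint8)
    if positions_um is None:
        positions_um = np.zeros((n, 3), dtype=np.float32)
        positions_um[ids == sb.photons.BACKGROUND_ID] = np.nan
    return sb.Burst(
        first=0,
        last=n - 1,
        times_s=np.asarray(times_s, float),
        peak_rate_khz=0.0,
        molecule_id=ids,
        channel=np.asarray(channels, np.uint8),
        position_um=np.asarray(positions_um, np.float32),
    )
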