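import numpy as np
import pytest

import smburst as sb
from smburst.diffusion import TrajectoryChunk
from smburst.photons import BACKGROUND_ID, CHANNEL_ACCEPTOR, CHANNEL_DONOR


def pinned_chunks(n_mol, n_steps, position=(0.0, 0.0, 0.0), chunk=200_000):
    """Trajectory stream with every molecule fixed at one position."""
    start = 0
    while start < n_steps:
        n = min(chunk, n_steps - start)
        pos = np.tile(np.asarray(position, np.float32), (n_mol, n, 1))
        yield TrajectoryChunk(pos, start, 200.0)
        start += n


class TestEmissionRate:
    def test_peak_rate_equals_brightness(self):
        assert sb.emission_rate(sb.GaussianPSF(), [0, 0, 0], 200.0) == 200.0

    def test_one_sigma_rate(self):
        r = sb.emission_rate(sb.GaussianPSF(), [180.0, 0, 0], 200.0)
        assert r == pytest.approx(200 * np.exp(-0.5))

    def test_far_away_rate_zero(self):
        r = sb.emission_rate(sb.GaussianPSF(), [5e6, 0, 0], 200.0)
        assert r == pytest.approx(0.0, abs=1e-12)


class TestDrawPhotons:
    def test_zero_brightness_empty(self):
        stream = sb.draw_photons(pinned_chunks(1, 1000), sb.GaussianPSF(), 0.0,
                                 seed=1, duration_s=2e-4, n_molecules=1)
        assert len(stream) == 0

    def test_pinned_molecule_poisson_count(self):
        # molecule at the PSF peak, brightness r, duration T: count ~ Poisson(rT)
        T, r = 1.0, 200.0
        n_steps = int(T / 200e-9)
        stream = sb.draw_photons(pinned_chunks(1, n_steps), sb.GaussianPSF(), r,
                                 seed=2, duration_s=T, n_molecules=1)
        expected = r * 1e3 * T
        assert abs(len(stream) - expected) < 3 * np.sqrt(expected)
        stream.validate()

    def test_two_pinned_molecules_exchangeable_and_sorted(self):
        T = 0.5
        n_steps = int(T / 200e-9)
        stream = sb.draw_photons(pinned_chunks(2, n_steps), sb.GaussianPSF(), 200.0,
                                 seed=3, duration_s=T, n_molecules=2)
        counts = np.bincount(stream.molecule_id, minlength=2)
        diff = abs(int(counts[0]) - int(counts[1]))
        assert diff < 4 * np.sqrt(counts.sum())
        assert np.all(np.diff(stream.timestamps) >= 0)

    def test_positions_recorded_at_emission(self):
        stream = sb.draw_photons(
            pinned_chunks(1, 50_000, position=(0.1, 0.0, 0.2)),
            sb.GaussianPSF(), 200.0, seed=4, duration_s=0.01, n_molecules=1,
        )
        assert len(stream) > 0
        np.testing.assert_allclose(stream.position_um[:, 0], 0.1, atol=1e-6)
        np.testing.assert_allclose(stream.position_um[:, 2], 0.2, atol=1e-6)

    def test_high_probability_warns(self):
        with pytest.warns(UserWarning, match="0.1"):
            sb.draw_photons(pinned_chunks(1, 1000), sb.GaussianPSF(), 1e6,
                            seed=5, duration_s=2e-4, n_molecules=1)


class TestBackground:
    def test_zero_rate_unchanged(self, short_stream):
        out = sb.add_background(short_stream, 0.0, seed=1)
        assert out is short_stream

    def test_background_count_poisson(self):
        empty = sb.draw_photons(pinned_chunks(1, 1000), sb.GaussianPSF(), 0.0,
                                seed=1, duration_s=30.0, n_molecules=1)
        out = sb.add_background(empty, 2.3, seed=6)
        expected = 2.3e3 * 30.0
        assert abs(len(out) - expected) < 3 * np.sqrt(expected)
        assert np.all(out.molecule_id == BACKGROUND_ID)
        assert np.all(np.isnan(out.position_um))

    def test_merge_only_adds_records(self, short_stream):
        n_sig = int((~short_stream.is_background).sum())
        again = sb.add_background(short_stream, 1.0, seed=7)
        assert int((~again.is_background).sum()) == n_sig
        assert np.all(np.diff(again.timestamps) >= 0)


class TestSplitChannels:
    def _signal(self, seed=8, T=0.5, n_mol=2):
        n_steps = int(T / 200e-9)
        return sb.draw_photons(pinned_chunks(n_mol, n_steps), sb.GaussianPSF(),
                               100.0, seed=seed, duration_s=T, n_molecules=n_mol)

    def test_e_one_all_acceptor(self):
        stream = self._signal()
        out = sb.split_channels(stream, sb.FRETConfig([1.0, 1.0]), 0.0, 0.0, seed=1)
        assert np.all(out.channel == CHANNEL_ACCEPTOR)

    def test_binomial_fraction_at_half(self):
        stream = self._signal()
        out = sb.split_channels(stream, sb.FRETConfig([0.5, 0.5]), 0.0, 0.0, seed=2)
        n = len(out)
        frac = np.mean(out.channel == CHANNEL_ACCEPTOR)
        assert n > 5000
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_channel_background_rates(self):
        stream = self._signal(T=2.0)
        out = sb.split_channels(stream, sb.FRETConfig([0.5, 0.5]), 1.5, 0.8, seed=3)
        bg = out.is_background
        n_d = int(np.sum(bg & (out.channel == CHANNEL_DONOR)))
        n_a = int(np.sum(bg & (out.channel == CHANNEL_ACCEPTOR)))
        assert abs(n_d - 1.5e3 * 2.0) < 4 * np.sqrt(1.5e3 * 2.0)
        assert abs(n_a - 0.8e3 * 2.0) < 4 * np.sqrt(0.8e3 * 2.0)

    def test_photon_conservation_and_order(self):
        stream = self._signal()
        out = sb.split_channels(stream, sb.FRETConfig([0.3, 0.9]), 1.5, 0.8, seed=4)
        assert int((~out.is_background).sum()) == len(stream)
        assert np.all(np.diff(out.timestamps) >= 0)

    def test_rejects_stream_with_background(self, short_stream):
        e = sb.FRETConfig(np.full(short_stream.n_molecules, 0.5))
        with pytest.raises(ValueError, match="background-free"):
            sb.split_channels(short_stream, e, 1.5, 0.8, seed=5)

    def test_rejects_bad_efficiency(self):
        with pytest.raises(ValueError):
            sb.FRETConfig([0.5, 1.2])
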