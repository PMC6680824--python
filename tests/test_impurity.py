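import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import smburst as sb
from conftest import make_burst

BG = sb.photons.BACKGROUND_ID


class TestBurstImpurity:
    def test_modal_fraction_with_background_discarded(self):
        b = make_burst([0] * 8 + [1] * 2 + [BG] * 3)
        assert sb.burst_impurity(b) == pytest.approx(0.2)

    def test_single_molecule_burst_pure(self):
        assert sb.burst_impurity(make_burst([3] * 12)) == 0.0

    def test_even_tie(self):
        assert sb.burst_impurity(make_burst([0] * 5 + [1] * 5)) == pytest.approx(0.5)

    def test_background_only_burst_undefined(self):
        assert np.isnan(sb.burst_impurity(make_burst([BG] * 4)))


class TestSummarize:
    def test_all_pure(self):
        s = sb.summarize_impurity([make_burst([0] * 10), make_burst([1] * 10)])
        assert s.fraction_impure == 0.0
        assert s.mean_burst_impurity == 0.0
        assert s.photon_impurity_fraction == 0.0

    def test_direct_arithmetic(self):
        bursts = [make_burst([0] * 8 + [1] * 2), make_burst([2] * 10)]
        s = sb.summarize_impurity(bursts)
        assert s.fraction_impure == pytest.approx(0.5)
        assert s.mean_burst_impurity == pytest.approx(0.1)
        assert s.photon_impurity_fraction == pytest.approx(2 / 20)
        lo, hi = s.fraction_impure_ci95
        assert 0.0 <= lo <= 0.5 <= hi <= 1.0

    def test_empty_input_sentinel(self):
        assert sb.summarize_impurity([]) is None

    def test_background_only_bursts_excluded_but_counted(self):
        bursts = [make_burst([0] * 10), make_burst([BG] * 5)]
        s = sb.summarize_impurity(bursts)
        assert s.n_bursts == 1
        assert s.n_background_only_bursts == 1

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_independent_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        bursts = []
        for _ in range(rng.integers(2, 12)):
            ids = rng.integers(0, 4, size=rng.integers(2, 30))
            bursts.append(make_burst(ids))
        s = sb.summarize_impurity(bursts)
        # independent recomputation from the raw label arrays
        imps, non_modal, total = [], 0, 0
        for b in bursts:
            counts = np.bincount(b.molecule_id)
            imps.append(1 - counts.max() / counts.sum())
            non_modal += counts.sum() - counts.max()
            total += counts.sum()
        assert s.mean_burst_impurity == pytest.approx(np.mean(imps))
        assert s.fraction_impure == pytest.approx(np.mean(np.array(imps) > 0))
        assert s.photon_impurity_fraction == pytest.approx(non_modal / total)
        # algebraic identity: photon fraction is the size-weighted mean impurity
        sizes = np.array([len(b.molecule_id) for b in bursts])
        assert s.photon_impurity_fraction == pytest.approx(
            np.average(imps, weights=sizes)
        )
        # each impure burst contributes at most 1 to the impure fraction
        assert s.mean_burst_impurity <= s.fraction_impure + 1e-12


class TestDispersion:
    def test_point_mass_zero_sd(self):
        b = make_burst([0] * 10, positions_um=np.ones((10, 3), np.float32))
        d = sb.position_dispersion([b])
        assert np.all(d.sd_nm == 0.0)

    def test_gaussian_sample_recovers_sigma(self):
        rng = np.random.default_rng(4)
        n = 10_000
        pos = np.zeros((n, 3), np.float32)
        pos[:, 0] = rng.normal(0.0, 0.180, size=n)  # 180 nm in um
        d = sb.position_dispersion([make_burst([0] * n, positions_um=pos)])
        assert abs(d.sd_x_nm - 180.0) < 3 * d.sd_uncertainty_nm[0]

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        pos = rng.normal(0, 0.2, size=(500, 3)).astype(np.float32)
        d0 = sb.position_dispersion([make_burst([0] * 500, positions_um=pos)])
        d1 = sb.position_dispersion([make_burst([0] * 500, positions_um=pos + 5.0)])
        np.testing.assert_allclose(d0.sd_nm, d1.sd_nm, rtol=1e-4)

    def test_background_positions_excluded(self):
        pos = np.zeros((4, 3), np.float32)
        pos[2:] = np.nan
        b = make_burst([0, 0, BG, BG], positions_um=pos)
        d = sb.position_dispersion([b])
        assert d.n_photons == 2
        assert np.all(np.isfinite(d.sd_nm))

    def test_too_few_photons_rejected(self):
        with pytest.raises(ValueError):
            sb.position_dispersion([make_burst([0])])


class TestClassifyPhotons:
    def test_all_pure_no_impure_class(self):
        classes = sb.classify_photons([make_burst([0] * 10), make_burst([1] * 7)])
        assert len(classes["impure"]) == 0
        assert len(classes["pure_burst"]) == 17
        assert len(classes["impure_burst"]) == 0

    def test_mixed_burst_counts(self):
        classes = sb.classify_photons([make_burst([0] * 8 + [1] * 2)])
        assert len(classes["impure"]) == 2
        assert len(classes["impure_burst"]) == 10
        assert len(classes["all"]) == 10

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_class_counts_conserve_photons(self, seed):
        rng = np.random.default_rng(seed)
        bursts = [
            make_burst(rng.integers(0, 3, size=rng.integers(2, 20)))
            for _ in range(rng.integers(1, 8))
        ]
        classes = sb.classify_photons(bursts)
        total = sum(len(b.molecule_id) for b in bursts)
        assert len(classes["all"]) == total
        assert len(classes["pure_burst"]) + len(classes["impure_burst"]) == total

    def test_modal_tie_breaks_to_lower_id(self):
        from smburst.impurity import modal_molecule

        assert modal_molecule(make_burst([1] * 5 + [0] * 5)) == 0

    def test_histograms_normalized(self):
        rng = np.random.default_rng(6)
        pos = rng.normal(0, 0.5, size=(400, 3)).astype(np.float32)
        classes = sb.classify_photons([make_burst([0] * 400, positions_um=pos)])
        from smburst.impurity import position_histograms

        hists = position_histograms(classes, axis=2)
        h = hists["all"]
        width = h["edges"][1] - h["edges"][0]
        assert h["density"].sum() * width == pytest.approx(1.0)
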