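# smburst

Brownian-dynamics simulation and burst-purity analysis of confocal-based
single-molecule fluorescence detection (SMFD).

## The problem

In diffusion-based SMFD, fluorophores at pM concentration wander through the
~1 fL effective detection volume (EDV) of a confocal microscope and emit
photon bursts against a Poisson background.  Burst analysis — a sliding
window of *m* consecutive photons whose instantaneous rate must exceed *F*
times the background rate, followed by selection on burst size *sz* and
width *w* — turns the photon stream into per-molecule observations.  But the
parameter choices are largely conventional, and an experiment cannot tell
whether a given burst really came from a single molecule.  A simulation can:
every photon generated here carries the identity and position of its
emitting molecule, so the package measures exactly

- **burst impurity** — for each burst, `f = 1 − (photons from the modal
  molecule)/(all signal photons)`, plus the fraction of impure bursts and
  the pooled photon-level impurity;
- **molecular position dispersion** — per-axis sd of the emission positions
  of accepted photons, i.e. the sub-volume of the EDV the analysis accepts;
- an **FCS surrogate**: the burst-photon autocorrelation fitted with
  `G(τ) = ⟨N⟩⁻¹ (1+τ/τ_D)⁻¹ (1+τ/(κ²τ_D))^(−1/2)` (κ = 7), whose ⟨N⟩ gives
  the Poisson multi-occupancy probability `P(N>1) = 1 − e⁻ᴺ − Ne⁻ᴺ`;
- the effect of impurity on **smFRET accuracy**: a two-population mixture
  (10 molecules at E = 0.75, 5 at E = 0.50) whose burst proximity-ratio
  histogram is fitted with a sum of two Gaussians.

The model: 15 point molecules diffusing (D = 90 μm²/s, 200 ns steps) in a
periodic box whose volume sets the concentration (62 pM default), photon
emission as PSF-weighted Poisson thinning (Gaussian EDV with
σxy = 180 nm, σz = 880 nm, or any tabulated 3D grid; 200 kHz peak
brightness), plus Poisson background (2.3 kHz single-channel, 1.5/0.8 kHz
donor/acceptor).  See `docs/methods.md` for the full model description.

## Worked example

```python
import smburst as sb

grid = sb.ExperimentGrid(duration_s=3.0, seeds=[0], known_bg=True)
df = sb.run_grid(grid)
cols = ["m", "F", "sz", "n_bursts", "mean_burst_impurity", "sd_z_nm"]
print(df[df.m == 10][cols].head(5).to_string(index=False))
```

```
  m     F  sz  n_bursts  mean_burst_impurity     sd_z_nm
 10   6.0  10       171             0.055206  733.808935
 10   3.0  10       159             0.081014  758.540511
 10  11.0  10       181             0.037066  702.894390
 10  16.0  10       198             0.033988  679.090738
 10  21.0  10       202             0.030227  655.884922
```

Reading the rows: raising the rate threshold from F = 3 to F = 21 cuts the
mean burst impurity from 8.1% to 3.0% and shrinks the axial position
dispersion from 759 nm to 656 nm — more stringent rate thresholds accept
photons from purer bursts emitted closer to the EDV centre.  Sweeps over
*m* and *sz* (also in `df`) show the opposite: larger windows and size
thresholds select *more* impure bursts.

The same machinery drives the smFRET demonstration
(`sb.run_fret_condition(seed=1, duration_s=10.0)`), where the fitted means
of the two FRET populations move toward the simulated 0.75/0.50 truth as F
grows.

A thin CLI wraps the library:
`smburst simulate --duration-s 5 --out photons.h5`,
`smburst search photons.h5 --m 10 --F 6`, `smburst grid`,
`smburst analyze`, `smburst report`.

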