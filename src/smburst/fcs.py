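"""Photon-timestamp autocorrelation and 3D-diffusion FCS fitting.

The fluctuation autocorrelation of a stationary photon stream on [0, T] is
estimated on log-spaced lag bins from pair counts:

    G(bin) = C(bin) / E[C(bin) | Poisson] − 1,

where ``C`` counts ordered photon pairs with separation inside the bin and
the Poisson expectation ``λ²·[T·Δτ − (e₂²−e₁²)/2]`` includes the exact
finite-record edge correction.  Under this normalization an uncorrelated
Poisson stream gives G ≈ 0 and a dilute diffusing emitter gives
G(τ→0) → 1/⟨N⟩.

Fitting uses the standard single-component 3D diffusion model for a
Gaussian detection volume with axial-to-lateral ratio κ (fixed at 7):

    G(τ) = ⟨N⟩⁻¹ · (1 + τ/τ_D)⁻¹ · (1 + τ/(κ²·τ_D))⁻¹ᐟ²

⟨N⟩ is the mean occupancy of the detection volume; since the occupancy is
Poisson distributed, the probability that more than one molecule is present
is 1 − e^(−N) − N·e^(−N), and conditioned on at least one molecule present
(the situation inside a burst) it is that quantity divided by 1 − e^(−N).
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

__all__ = [
    "CorrelationCurve",
    "FCSFit",
    "autocorrelate",
    "fcs_model",
    "fit_fcs",
    "p_more_than_one",
    "p_burst_more_than_one",
    "write_correlation_curve",
]


@dataclass(frozen=True)
class CorrelationCurve:
    """G(τ) on log-spaced lag bins; ``lag_s`` are geometric bin centres."""

    lag_s: np.ndarray
    g: np.ndarray
    pair_counts: np.ndarray
    duration_s: float
    n_photons: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lag_s) <= 0) or np.any(self.lag_s <= 0):
            raise ValueError("lags must be positive and strictly increasing")


def _pairs_below(t: np.ndarray, edge: float) -> int:
    """Number of ordered pairs (i<j) with t_j − t_i <= edge."""
    n = len(t)
    idx = np.searchsorted(t, t + edge, side="right")
    return int(idx.sum() - n * (n + 1) // 2)


def autocorrelate(
    times_s: np.ndarray,
    lag_min_s: float = 2e-6,
    lag_max_s: float = 0.1,
    n_bins: int = 48,
    duration_s: float | None = None,
) -> CorrelationCurve:
    """Normalized fluctuation autocorrelation of a timestamp stream."""
    t = np.asarray(times_s, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be sorted")
    if duration_s is None:
        duration_s = float(t[-1] - t[0]) if len(t) else 0.0
    if duration_s <= 0 or len(t) < 2:
        raise ValueError("need a positive-duration stream with >= 2 photons")
    edges = np.geomspace(lag_min_s, lag_max_s, n_bins + 1)
    cum = np.array([_pairs_below(t, e) for e in edges], dtype=float)
    counts = np.diff(cum)
    lam = len(t) / duration_s
    expected = lam * lam * (
        duration_s * np.diff(edges) - 0.5 * np.diff(edges**2)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        g = counts / expected - 1.0
    centers = np.sqrt(edges[:-1] * edges[1:])
    return CorrelationCurve(
        lag_s=centers,
        g=g,
        pair_counts=counts,
        duration_s=duration_s,
        n_photons=len(t),
    )


def fcs_model(tau_s, n_mean: float, tau_d_s: float, kappa: float = 7.0):
    """Single-component 3D diffusion autocorrelation for a Gaussian volume."""
    tau_s = np.asarray(tau_s, dtype=float)
    return (
        1.0
        / n_mean
        / (1.0 + tau_s / tau_d_s)
        / np.sqrt(1.0 + tau_s / (kappa**2 * tau_d_s))
    )


@dataclass(frozen=True)
class FCSFit:
    n_mean: float
    n_mean_err: float
    tau_d_s: float
    tau_d_err_s: float
    kappa: float
    p_gt1: float
    p_burst_gt1: float
    redchi: float
    result: lmfit.model.ModelResult

    def summary(self) -> str:
        return (
            f"FCS fit: <N> = {self.n_mean:.4g} ± {self.n_mean_err:.2g}, "
            f"tau_D = {self.tau_d_s*1e3:.4g} ± {self.tau_d_err_s*1e3:.2g} ms "
            f"(kappa fixed at {self.kappa:g}); "
            f"P(N>1) = {self.p_gt1:.4g}, P_burst(N>1) = {self.p_burst_gt1:.4g}"
        )


def fit_fcs(
    curve: CorrelationCurve,
    kappa: float = 7.0,
    weights: np.ndarray | None = None,
) -> FCSFit:
    """Least-squares fit of the 3D diffusion model; ⟨N⟩ and τ_D free, κ fixed.

    Initial guesses: ⟨N⟩ from the small-lag amplitude, τ_D from the lag at
    half amplitude.  ``weights`` (1/σ per lag) enable weighted fitting;
    the default is unweighted.
    """
    good = np.isfinite(curve.g)
    tau, g = curve.lag_s[good], curve.g[good]
    if len(tau) < 4:
        raise ValueError("too few finite correlation points to fit")
    g0 = max(np.mean(g[: max(3, len(g) // 10)]), 1e-6)
    half = g0 / 2.0
    below = np.nonzero(g < half)[0]
    tau_d0 = tau[below[0]] if len(below) else tau[len(tau) // 2]
    model = lmfit.Model(fcs_model, independent_vars=["tau_s"])
    params = model.make_params(
        n_mean=dict(value=1.0 / g0, min=1e-6),
        tau_d_s=dict(value=float(tau_d0), min=1e-9),
        kappa=dict(value=kappa, vary=False),
    )
    result = model.fit(
        g, params, tau_s=tau, weights=weights[good] if weights is not None else None
    )
    if not result.success:
        raise RuntimeError(f"FCS fit failed: {result.message}")
    n_hat = result.params["n_mean"].value
    n_err = result.params["n_mean"].stderr or np.nan
    td = result.params["tau_d_s"].value
    td_err = result.params["tau_d_s"].stderr or np.nan
    return FCSFit(
        n_mean=n_hat,
        n_mean_err=n_err,
        tau_d_s=td,
        tau_d_err_s=td_err,
        kappa=kappa,
        p_gt1=p_more_than_one(n_hat),
        p_burst_gt1=p_burst_more_than_one(n_hat),
        redchi=result.redchi,
        result=result,
    )


def write_correlation_curve(curve: CorrelationCurve, path) -> None:
    """Two-column text export: lag (s) and G."""
    np.savetxt(path, np.column_stack([curve.lag_s, curve.g]),
               header="lag_s\tG", delimiter="\t")


def p_more_than_one(n_mean: float) -> float:
    """P(N > 1) for Poisson occupancy with mean ``n_mean``."""
    if n_mean <= 0:
        raise ValueError("n_mean must be positive")
    return float(1.0 - np.exp(-n_mean) - n_mean * np.exp(-n_mean))


def p_burst_more_than_one(n_mean: float) -> float:
    """P(N > 1 | N >= 1): multi-occupancy given at least one molecule present."""
    if n_mean <= 0:
        raise ValueError("n_mean must be positive")
    denom = 1.0 - np.exp(-n_mean)
    return float(p_more_than_one(n_mean) / denom)
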