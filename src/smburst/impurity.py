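"""Ground-truth burst purity and molecular position dispersion.

A burst is *impure* when it contains signal photons from more than one
molecule.  The impurity of a burst is

    f = 1 − (photons from the modal molecule) / (all signal photons),

background photons being discarded from both counts.  Three aggregates
summarize a burst set: the fraction of impure bursts (f > 0) with a Wilson
95% confidence interval, the mean per-burst impurity with its standard
error, and the photon-level impurity — all non-modal signal photons over all
signal photons, a single pooled number carrying no error bar.

The *molecular position dispersion* is the per-axis standard deviation of
the emission positions of all signal photons pooled across the selected
bursts; it proxies the sub-volume of the detection volume from which
accepted photons originate.  Its uncertainty uses the Gaussian sampling
approximation s/√(2(n−1)), which understates the error when photons of one
molecule crossing are correlated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .bursts import Burst
from .photons import BACKGROUND_ID, UNKNOWN_ID

__all__ = [
    "ImpuritySummary",
    "DispersionSummary",
    "burst_impurity",
    "summarize_impurity",
    "position_dispersion",
    "classify_photons",
]


@dataclass(frozen=True)
class ImpuritySummary:
    fraction_impure: float
    fraction_impure_ci95: tuple[float, float]
    mean_burst_impurity: float
    mean_burst_impurity_se: float
    photon_impurity_fraction: float
    n_bursts: int
    n_burst_photons: int
    n_background_only_bursts: int = 0


@dataclass(frozen=True)
class DispersionSummary:
    sd_nm: np.ndarray          # (3,) per-axis standard deviation
    sd_uncertainty_nm: np.ndarray
    n_photons: int

    @property
    def sd_x_nm(self) -> float:
        return float(self.sd_nm[0])

    @property
    def sd_y_nm(self) -> float:
        return float(self.sd_nm[1])

    @property
    def sd_z_nm(self) -> float:
        return float(self.sd_nm[2])


def _signal_counts(burst: Burst) -> tuple[np.ndarray, np.ndarray]:
    if burst.molecule_id is None:
        raise ValueError("burst carries no ground-truth molecule labels")
    if np.any(burst.molecule_id == UNKNOWN_ID):
        raise ValueError(
            "photon stream has no ground-truth labels; purity analysis unavailable"
        )
    ids = burst.molecule_id[burst.molecule_id != BACKGROUND_ID]
    if len(ids) == 0:
        return np.empty(0, np.int32), np.empty(0, np.int64)
    return np.unique(ids, return_counts=True)


def burst_impurity(burst: Burst) -> float:
    """Fraction of signal photons not from the modal molecule; NaN if the
    burst holds only background photons."""
    uniq, counts = _signal_counts(burst)
    if len(uniq) == 0:
        return float("nan")
    return float(1.0 - counts.max() / counts.sum())


def modal_molecule(burst: Burst) -> int:
    """Most frequent signal molecule; ties break toward the lower id."""
    uniq, counts = _signal_counts(burst)
    if len(uniq) == 0:
        return BACKGROUND_ID
    return int(uniq[np.argmax(counts)])


def summarize_impurity(bursts: Sequence[Burst]) -> ImpuritySummary | None:
    """Aggregate impurity over a burst set; None for an empty set.

    Bursts consisting solely of background photons have undefined impurity
    and are excluded from all three aggregates (their count is reported).
    """
    impurities = []
    non_modal = 0
    signal_total = 0
    n_bg_only = 0
    for b in bursts:
        uniq, counts = _signal_counts(b)
        if len(uniq) == 0:
            n_bg_only += 1
            continue
        impurities.append(1.0 - counts.max() / counts.sum())
        non_modal += counts.sum() - counts.max()
        signal_total += counts.sum()
    if not impurities:
        return None
    imp = np.asarray(impurities)
    n = len(imp)
    n_impure = int(np.sum(imp > 0))
    lo, hi = proportion_confint(n_impure, n, alpha=0.05, method="wilson")
    se = imp.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
    return ImpuritySummary(
        fraction_impure=n_impure / n,
        fraction_impure_ci95=(float(lo), float(hi)),
        mean_burst_impurity=float(imp.mean()),
        mean_burst_impurity_se=float(se),
        photon_impurity_fraction=float(non_modal / signal_total),
        n_bursts=n,
        n_burst_photons=int(signal_total),
        n_background_only_bursts=n_bg_only,
    )


def _pooled_positions(bursts: Sequence[Burst]) -> np.ndarray:
    parts = []
    for b in bursts:
        if b.position_um is None or b.molecule_id is None:
            raise ValueError("bursts carry no emission positions")
        sig = b.molecule_id != BACKGROUND_ID
        parts.append(b.position_um[sig])
    if not parts:
        return np.empty((0, 3), np.float32)
    return np.concatenate(parts)


def position_dispersion(bursts: Sequence[Burst]) -> DispersionSummary:
    """Per-axis sd (nm) of all pooled signal-photon emission positions."""
    pos = _pooled_positions(bursts)
    n = len(pos)
    if n < 2:
        raise ValueError("need at least 2 signal photons for a dispersion")
    sd_um = pos.std(axis=0, ddof=1).astype(float)
    unc_um = sd_um / np.sqrt(2.0 * (n - 1))
    return DispersionSummary(sd_nm=sd_um * 1e3, sd_uncertainty_nm=unc_um * 1e3, n_photons=n)


def classify_photons(bursts: Sequence[Burst]) -> dict:
    """Per-photon purity classes and their pooled positions.

    Classes over signal photons of all bursts:
      ``impure``       — photons whose molecule differs from the burst's
                          modal molecule,
      ``impure_burst`` — all photons of bursts with impurity > 0,
      ``pure_burst``   — all photons of pure bursts,
      ``all``          — all signal photons of all bursts.

    Returns a dict mapping class name → (k, 3) array of positions (μm).
    """
    out = {"impure": [], "impure_burst": [], "pure_burst": [], "all": []}
    for b in bursts:
        uniq, counts = _signal_counts(b)
        if len(uniq) == 0:
            continue
        modal = uniq[np.argmax(counts)]
        sig = b.molecule_id != BACKGROUND_ID
        pos = b.position_um[sig]
        ids = b.molecule_id[sig]
        out["all"].append(pos)
        if counts.max() < counts.sum():  # impure burst
            out["impure_burst"].append(pos)
            out["impure"].append(pos[ids != modal])
        else:
            out["pure_burst"].append(pos)
    return {
        k: (np.concatenate(v) if v else np.empty((0, 3), np.float32))
        for k, v in out.items()
    }


def position_histograms(
    class_positions: dict, axis: int = 2, n_bins: int = 50
) -> dict:
    """Raw-count and unit-area histograms of class positions along one axis.

    Bin range spans ±3 pooled standard deviations of the ``all`` class.
    """
    ref = class_positions["all"][:, axis]
    if len(ref) == 0:
        raise ValueError("no burst photons to histogram")
    span = 3.0 * ref.std()
    edges = np.linspace(-span, span, n_bins + 1)
    out = {}
    for name, pos in class_positions.items():
        counts, _ = np.histogram(pos[:, axis], bins=edges)
        width = edges[1] - edges[0]
        total = counts.sum()
        density = counts / (total * width) if total else np.zeros_like(counts, float)
        out[name] = {"edges": edges, "counts": counts, "density": density}
    return out
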