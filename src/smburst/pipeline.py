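"""Parameter-grid orchestration and reporting.

One *condition* is a (PSF model, concentration, diffusion coefficient, seed)
tuple; the expensive diffusion/photon simulation runs once per condition and
the cheap burst search/selection is repeated across every burst-parameter
set on the same photon stream.  Results land in a long-format pandas table,
one row per condition × parameter set, the machine-readable analogue of a
per-condition summary appendix.

Default parameter sets mirror the study design: m ∈ {5, 10, 15, 20} at
F = 6; F ∈ {3, 6, 11, 16, 21} at m = 10; size thresholds sz ∈ {10, 20, 40,
80} and width thresholds w ∈ {0, 0.5, 1.0} ms at m = 10, F = 6.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import fcs as fcs_mod
from .bursts import (
    BurstSearchParams,
    BurstSelectionParams,
    burst_metrics,
    search_stream,
    select_bursts,
)
from .diffusion import SimulationConfig
from .fret import accuracy_report, fit_two_gaussians, proximity_ratios
from .impurity import position_dispersion, summarize_impurity
from .photons import FRETConfig, simulate_photons
from .psf import GaussianPSF, make_squared_gaussian_grid, psf_energy, rescale_to_energy

logger = logging.getLogger("smburst")

__all__ = [
    "ParameterSet",
    "ExperimentGrid",
    "default_parameter_sets",
    "run_condition",
    "run_grid",
    "render_report",
]


@dataclass(frozen=True)
class ParameterSet:
    m: int = 10
    F: float = 6.0
    sz: int = 10
    w_ms: float = 0.0

    @property
    def search(self) -> BurstSearchParams:
        return BurstSearchParams(m=self.m, F=self.F)

    @property
    def selection(self) -> BurstSelectionParams:
        return BurstSelectionParams(min_size=max(self.sz, self.m), min_width_ms=self.w_ms)


def default_parameter_sets() -> list[ParameterSet]:
    """The four sweeps of the study design, without duplicates."""
    sets: list[ParameterSet] = []
    for m in (5, 10, 15, 20):
        sets.append(ParameterSet(m=m, F=6.0, sz=m, w_ms=0.0))
    for F in (3.0, 6.0, 11.0, 16.0, 21.0):
        if F != 6.0:
            sets.append(ParameterSet(m=10, F=F, sz=10, w_ms=0.0))
    for sz in (20, 40, 80):
        sets.append(ParameterSet(m=10, F=6.0, sz=sz, w_ms=0.0))
    for w in (0.5, 1.0):
        sets.append(ParameterSet(m=10, F=6.0, sz=10, w_ms=w))
    return sets


@dataclass
class ExperimentGrid:
    """Full experiment: conditions × burst-parameter sets.

    ``psf_models`` entries are either "gaussian" or a TabulatedPSF instance.
    """

    psf_models: Sequence = ("gaussian",)
    concentrations_pM: Sequence[float] = (62.0,)
    diffusion_um2_s: Sequence[float] = (90.0,)
    parameter_sets: Sequence[ParameterSet] = field(default_factory=default_parameter_sets)
    duration_s: float = 5.0
    seeds: Sequence[int] = (0,)
    n_molecules: int = 15
    brightness_khz: float = 200.0
    bg_rate_khz: float = 2.3
    known_bg: bool = False
    with_fcs: bool = False

    def config_hash(self) -> str:
        payload = {
            "psf_models": [getattr(p, "kind", p) for p in self.psf_models],
            "concentrations_pM": list(self.concentrations_pM),
            "diffusion_um2_s": list(self.diffusion_um2_s),
            "parameter_sets": [
                (p.m, p.F, p.sz, p.w_ms) for p in self.parameter_sets
            ],
            "duration_s": self.duration_s,
            "seeds": list(self.seeds),
            "n_molecules": self.n_molecules,
            "brightness_khz": self.brightness_khz,
            "bg_rate_khz": self.bg_rate_khz,
            "known_bg": self.known_bg,
            "with_fcs": self.with_fcs,
        }
        text = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _resolve_psf(spec):
    if spec == "gaussian" or isinstance(spec, GaussianPSF):
        psf = GaussianPSF() if spec == "gaussian" else spec
        return psf, 1.0, "gaussian"
    if spec == "tabulated":
        spec = make_squared_gaussian_grid()
    # equal-energy convention: narrow numerical models get brighter peaks
    reference = psf_energy(GaussianPSF())
    _, mult = rescale_to_energy(spec, reference)
    return spec, mult, "tabulated"


def run_condition(
    psf_spec,
    concentration_pM: float,
    diffusion_um2_s: float,
    seed: int,
    parameter_sets: Sequence[ParameterSet],
    duration_s: float = 5.0,
    n_molecules: int = 15,
    brightness_khz: float = 200.0,
    bg_rate_khz: float = 2.3,
    known_bg: bool = False,
    with_fcs: bool = False,
) -> list[dict]:
    """Simulate one condition and analyze it under every parameter set."""
    psf, mult, psf_name = _resolve_psf(psf_spec)
    config = SimulationConfig(
        n_molecules=n_molecules,
        concentration_pM=concentration_pM,
        diffusion_um2_s=diffusion_um2_s,
        duration_s=duration_s,
        brightness_khz=brightness_khz,
        bg_rate_khz=bg_rate_khz,
        seed=seed,
    )
    logger.info(
        "condition psf=%s c=%g pM D=%g um2/s seed=%d: simulating %g s",
        psf_name, concentration_pM, diffusion_um2_s, seed, duration_s,
    )
    stream = simulate_photons(config, psf, brightness_multiplier=mult)
    logger.info("  %d photons", len(stream))
    bg = bg_rate_khz if known_bg else None
    rows = []
    for ps in parameter_sets:
        found = search_stream(stream, ps.search, bg_rate_khz=bg)
        selected = select_bursts(found, ps.selection)
        row = {
            "psf_model": psf_name,
            "concentration_pM": concentration_pM,
            "D_um2_s": diffusion_um2_s,
            "seed": seed,
            "duration_s": duration_s,
            "m": ps.m,
            "F": ps.F,
            "sz": ps.sz,
            "w_ms": ps.w_ms,
            "n_bursts": len(selected),
        }
        metrics = burst_metrics(selected)
        row["mean_width_ms"] = metrics["mean_width_s"] * 1e3
        row["mean_width_se_ms"] = metrics["mean_width_se_s"] * 1e3
        summary = summarize_impurity(selected) if selected else None
        if summary is not None:
            row.update(
                fraction_impure=summary.fraction_impure,
                fraction_impure_ci_lo=summary.fraction_impure_ci95[0],
                fraction_impure_ci_hi=summary.fraction_impure_ci95[1],
                mean_burst_impurity=summary.mean_burst_impurity,
                mean_burst_impurity_se=summary.mean_burst_impurity_se,
                photon_impurity_fraction=summary.photon_impurity_fraction,
                n_burst_photons=summary.n_burst_photons,
            )
            disp = position_dispersion(selected)
            row.update(
                sd_x_nm=disp.sd_x_nm,
                sd_y_nm=disp.sd_y_nm,
                sd_z_nm=disp.sd_z_nm,
                sd_x_unc_nm=float(disp.sd_uncertainty_nm[0]),
                sd_z_unc_nm=float(disp.sd_uncertainty_nm[2]),
            )
        if with_fcs and selected:
            t_burst = np.concatenate([b.times_s for b in selected])
            try:
                fit = fcs_mod.fit_fcs(fcs_mod.autocorrelate(t_burst))
                row.update(
                    fcs_n_mean=fit.n_mean,
                    fcs_n_mean_err=fit.n_mean_err,
                    fcs_tau_d_ms=fit.tau_d_s * 1e3,
                    fcs_p_gt1=fit.p_gt1,
                    fcs_p_burst_gt1=fit.p_burst_gt1,
                )
            except (RuntimeError, ValueError) as exc:
                logger.warning("  FCS fit skipped: %s", exc)
        rows.append(row)
    return rows


def run_grid(grid: ExperimentGrid) -> pd.DataFrame:
    """Run every condition of the grid; returns the long-format results table.

    Failed conditions are logged and skipped; the surviving rows carry the
    grid's config hash for provenance.
    """
    all_rows: list[dict] = []
    for psf_spec in grid.psf_models:
        for conc in grid.concentrations_pM:
            for d in grid.diffusion_um2_s:
                for seed in grid.seeds:
                    try:
                        all_rows.extend(
                            run_condition(
                                psf_spec, conc, d, seed,
                                grid.parameter_sets,
                                duration_s=grid.duration_s,
                                n_molecules=grid.n_molecules,
                                brightness_khz=grid.brightness_khz,
                                bg_rate_khz=grid.bg_rate_khz,
                                known_bg=grid.known_bg,
                                with_fcs=grid.with_fcs,
                            )
                        )
                    except Exception:
                        logger.exception(
                            "condition failed (psf=%s c=%g D=%g seed=%d); skipped",
                            psf_spec, conc, d, seed,
                        )
    df = pd.DataFrame(all_rows)
    df.attrs["config_hash"] = grid.config_hash()
    return df


def run_fret_condition(
    seed: int,
    f_values: Sequence[float] = (6.0, 11.0, 21.0),
    m: int = 10,
    duration_s: float = 5.0,
    psf_spec="gaussian",
    fret: FRETConfig | None = None,
    fixed_fraction: float | None = None,
    known_bg: bool = False,
) -> pd.DataFrame:
    """Two-population smFRET simulation analyzed over an F sweep.

    Simulates the 10× E=0.75 / 5× E=0.50 mixture once (donor/acceptor
    backgrounds 1.5/0.8 kHz), runs the channel-blind burst search per F and
    fits each proximity-ratio histogram with a sum of two Gaussians.
    """
    if fret is None:
        fret = FRETConfig.two_populations()
    psf, mult, psf_name = _resolve_psf(psf_spec)
    config = SimulationConfig(
        n_molecules=fret.n_molecules,
        duration_s=duration_s,
        bg_rate_khz=(1.5, 0.8),
        seed=seed,
    )
    stream = simulate_photons(config, psf, fret=fret, brightness_multiplier=mult)
    bg_total = 1.5 + 0.8
    rows = []
    for F in f_values:
        bursts = search_stream(
            stream,
            BurstSearchParams(m=m, F=F),
            bg_rate_khz=bg_total if known_bg else None,
        )
        e_values = proximity_ratios(bursts)
        row = {"psf_model": psf_name, "seed": seed, "m": m, "F": F,
               "n_bursts": len(e_values)}
        try:
            fit = fit_two_gaussians(e_values, fixed_fraction=fixed_fraction)
            rep = accuracy_report(fit, fret)
            row.update(
                mu1=fit.mu1, mu1_err=fit.mu1_err,
                mu2=fit.mu2, mu2_err=fit.mu2_err,
                fraction=fit.fraction, fraction_err=fit.fraction_err,
                mu1_dev=rep["mu1_dev"], mu2_dev=rep["mu2_dev"],
                fraction_dev=rep["fraction_dev"],
            )
        except RuntimeError as exc:
            logger.warning("FRET fit failed at F=%g: %s", F, exc)
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(results: pd.DataFrame, out_dir, fret_results: pd.DataFrame | None = None,
                  class_histograms: dict | None = None) -> list:
    """Write the standard figure set from a results table.

    One figure per archetype: dispersion vs parameter, impurity vs
    parameter, impurity-vs-dispersion scatter, per-class position
    histograms (if provided), FRET histograms with fits (if provided).
    Deterministic file naming; returns the written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if results.empty:
        raise ValueError("empty results table")

    sweeps = [("F", results[results.m == 10]), ("m", results[results.F == 6.0])]

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, (par, sub) in zip(axes, sweeps):
        for key, g in sub.groupby(["psf_model", "concentration_pM", "D_um2_s"]):
            g = g.sort_values(par)
            ax.errorbar(g[par], g.get("sd_z_nm"), yerr=g.get("sd_z_unc_nm"),
                        marker="o", label=str(key))
        ax.set_xlabel(par)
        ax.set_ylabel("sd z (nm)")
    axes[0].legend(fontsize=6)
    fig.tight_layout()
    p = out / "dispersion_vs_parameter.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, (par, sub) in zip(axes, sweeps):
        for key, g in sub.groupby(["psf_model", "concentration_pM", "D_um2_s"]):
            g = g.sort_values(par)
            ax.errorbar(g[par], g.get("mean_burst_impurity"),
                        yerr=g.get("mean_burst_impurity_se"), marker="o",
                        label=str(key))
        ax.set_xlabel(par)
        ax.set_ylabel("mean burst impurity")
    fig.tight_layout()
    p = out / "impurity_vs_parameter.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.errorbar(results.get("sd_z_nm"), results.get("mean_burst_impurity"),
                xerr=results.get("sd_z_unc_nm"),
                yerr=results.get("mean_burst_impurity_se"), fmt="o", ms=3)
    ax.set_xlabel("sd z (nm)")
    ax.set_ylabel("mean burst impurity")
    fig.tight_layout()
    p = out / "impurity_vs_dispersion.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    if class_histograms is not None:
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        colors = {"impure": "red", "impure_burst": "gold",
                  "pure_burst": "green", "all": "black"}
        for name, h in class_histograms.items():
            centers = 0.5 * (h["edges"][:-1] + h["edges"][1:])
            axes[0].step(centers, h["counts"], color=colors.get(name), label=name)
            axes[1].step(centers, h["density"], color=colors.get(name), label=name)
        axes[0].set_ylabel("photons")
        axes[1].set_ylabel("density")
        for ax in axes:
            ax.set_xlabel("z (μm)")
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        p = out / "position_histograms.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        logger.info("no class histograms supplied; position figure skipped")

    if fret_results is not None and not fret_results.empty:
        fig, ax = plt.subplots(figsize=(4.5, 4))
        for seed, g in fret_results.groupby("seed"):
            g = g.sort_values("F")
            ax.errorbar(g.F, g.mu1, yerr=g.mu1_err, marker="o", label=f"mu1 seed {seed}")
            ax.errorbar(g.F, g.mu2, yerr=g.mu2_err, marker="s", label=f"mu2 seed {seed}")
        ax.axhline(0.75, ls="--", c="r")
        ax.axhline(0.50, ls="--", c="g")
        ax.set_xlabel("F")
        ax.set_ylabel("fitted mean FRET efficiency")
        ax.legend(fontsize=6)
        fig.tight_layout()
        p = out / "fret_recovery.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        logger.info("no FRET results supplied; FRET figure skipped")
    return written
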