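"""End-to-end pipeline: synth -> traits -> fit -> demography -> harvest.

Every stage reads the previous stage's serialized output, so each can also
run standalone.  A run writes its resolved configuration, a log with the
seed and library versions, and CSV/JSON artifacts for every stage into one
output directory; reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demography, harvest, models, reference, synth, traits

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("turtleharvest")

ZONES = ("temperate", "tropical")


@dataclass
class PipelineConfig:
    """Configuration of a pipeline run.

    Either ``input_csv`` points at an existing report table or the synth
    stage generates one.  ``zone_inputs`` short-circuits the trait stages:
    when given (zone -> {adult_survival, age_maturity, fecundity}), the
    demography and harvest stages run directly from it.
    """

    outdir: str = "turtleharvest_out"
    seed: int = 0
    input_csv: str | None = None
    zone_inputs: dict | None = None
    synth: synth.SynthConfig | None = None
    survival_arcsine: str = "sqrt"
    conventions: demography.ConventionFlags = field(
        default_factory=demography.ConventionFlags
    )
    sweep_points: int = 200
    jackknife_iterations: int = 500
    run_jackknife: bool = True
    make_plots: bool = False
    confidence_level: float = 0.95

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(outdir / "run.log", mode="w"),
    ):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def _zone_observed_inputs(species: pd.DataFrame) -> dict:
    """Zone-level observed matrix inputs from species medians."""
    out = {}
    for zone in ZONES:
        sub = species[species["zone"] == zone]
        if sub.empty:
            warnings.warn(f"no species in {zone} zone; zone skipped")
            continue
        vals = {
            "adult_survival": sub["adult_survival"].median(),
            "age_maturity": sub["age_maturity_yr"].median(),
            "fecundity": sub["fecundity"].median(),
        }
        if any(pd.isna(v) for v in vals.values()):
            warnings.warn(
                f"{zone} zone lacks data for some demographic inputs; "
                "zone skipped"
            )
            continue
        out[zone] = {k: float(v) for k, v in vals.items()}
    return out


def _zone_predicted_inputs(pred: pd.DataFrame) -> dict:
    out = {}
    for zone in ZONES:
        sub = pred[pred["zone"] == zone]
        if sub.empty:
            continue
        out[zone] = {
            "adult_survival": float(sub["pred_adult_survival"].median()),
            "age_maturity": float(sub["pred_age_maturity"].median()),
            "fecundity": float(sub["pred_fecundity"].median()),
        }
    return out


def _demography_tables(zone_inputs: dict, conv: demography.ConventionFlags):
    """Matrix, eigen-structure and elasticities per zone."""
    eigen_rows, elast_rows = [], []
    params_by_zone = {}
    for zone, inp in zone_inputs.items():
        params = demography.DemographicParams.from_traits(
            p_adult=inp["adult_survival"],
            age_maturity=inp["age_maturity"],
            fecundity=inp["fecundity"],
            conventions=conv,
        )
        params_by_zone[zone] = params
        A = demography.build_matrix(params, conv)
        es = demography.eigen_analysis(A)
        el = demography.elasticities(A)
        eigen_rows.append(
            {
                "zone": zone,
                "lambda": es.lam,
                "r": es.r,
                "w_egg": es.w[0],
                "w_juvenile": es.w[1],
                "w_adult": es.w[2],
                "v_egg": es.v[0],
                "v_juvenile": es.v[1],
                "v_adult": es.v[2],
                "F": A.F,
                "G1": A.G1,
                "P1": A.P1,
                "G2": A.G2,
                "P2": A.P2,
            }
        )
        for label, value in el.as_dict().items():
            elast_rows.append({"zone": zone, "parameter": label,
                               "elasticity": value})
    return params_by_zone, pd.DataFrame(eigen_rows), pd.DataFrame(elast_rows)


def _harvest_tables(
    params_by_zone: dict,
    species: pd.DataFrame | None,
    cfg: PipelineConfig,
):
    """Sweeps, thresholds, margins and (optionally) jackknife bands."""
    conv = cfg.conventions
    margin_rows, sweep_frames = [], []
    for zone, params in params_by_zone.items():
        hm = harvest.zone_margins(params, conv)
        for focal in harvest.FOCAL_PARAMETERS:
            margin_rows.append(
                {
                    "zone": zone,
                    "parameter": focal,
                    "predicted": hm.predicted[focal],
                    "r_min": hm.threshold[focal],
                    "margin_percent": hm.margin_percent[focal],
                }
            )
        for focal in harvest.FOCAL_PARAMETERS:
            grid = harvest.default_grid(params, focal, cfg.sweep_points)
            if cfg.run_jackknife and species is not None:
                sub = species[species["zone"] == zone]
                values = {
                    "fecundity": sub["fecundity"].dropna().to_numpy(),
                    "adult_survival": sub["adult_survival"]
                    .dropna()
                    .to_numpy(),
                }
                try:
                    res = harvest.jackknife_bands(
                        values,
                        params,
                        focal,
                        grid=grid,
                        n_iter=cfg.jackknife_iterations,
                        seed=np.random.default_rng(
                            (
                                cfg.seed,
                                harvest.FOCAL_PARAMETERS.index(focal),
                                ZONES.index(zone),
                            )
                        ),
                        conventions=conv,
                    )
                except ValueError as exc:
                    log.warning("jackknife skipped for %s/%s: %s",
                                zone, focal, exc)
                    res = harvest.sweep(params, focal, grid, conv)
            else:
                res = harvest.sweep(params, focal, grid, conv)
            frame = pd.DataFrame(
                {"zone": zone, "parameter": focal, "value": res.grid,
                 "r": res.r}
            )
            for name in ("band_lo", "band_hi", "ci_lo", "ci_hi"):
                arr = getattr(res, name)
                if arr is not None:
                    frame[name] = arr
            sweep_frames.append(frame)
    return pd.DataFrame(margin_rows), pd.concat(sweep_frames,
                                                ignore_index=True)


def _plot_sweeps(sweeps: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharey=True)
    for ax, focal in zip(axes.ravel(), harvest.FOCAL_PARAMETERS):
        for zone, color in (("temperate", "tab:orange"),
                            ("tropical", "tab:blue")):
            sub = sweeps[(sweeps["parameter"] == focal)
                         & (sweeps["zone"] == zone)]
            if sub.empty:
                continue
            ax.plot(sub["value"], sub["r"], color=color, label=zone)
            if "band_lo" in sub:
                ax.fill_between(sub["value"], sub["band_lo"],
                                sub["band_hi"], color=color, alpha=0.2)
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel(focal.replace("_", " "))
        ax.set_ylabel("intrinsic rate r")
    axes[0, 0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns a dict of the main in-memory results."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    log.info("seed=%d numpy=%s pandas=%s", cfg.seed, np.__version__,
             pd.__version__)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(cfg.resolved(), sort_keys=True)
    )
    results: dict = {}

    species = None
    fits_by_trait = None
    if cfg.zone_inputs is not None:
        log.info("demography-only mode: zone inputs supplied directly")
        zone_obs = None
        zone_pred = {z: dict(v) for z, v in cfg.zone_inputs.items()}
    else:
        if cfg.input_csv is not None:
            reports = pd.read_csv(cfg.input_csv)
            missing = set(traits.REPORT_COLUMNS) - set(reports.columns)
            if missing:
                raise ValueError(
                    f"input table lacks required columns: {sorted(missing)}"
                )
        else:
            scfg = cfg.synth or synth.SynthConfig(seed=cfg.seed)
            reports, truth = synth.generate_reports(scfg)
            synth.write_reports(reports, outdir / "reports.csv")
            truth.to_json(outdir / "ground_truth.json")
            log.info("generated %d reports for %d species", len(reports),
                     reports["species"].nunique())

        species = traits.aggregate_species(reports)
        species.to_csv(outdir / "species.csv", index=False,
                       lineterminator="\n")
        summary = traits.zone_summary(species)
        summary.to_csv(outdir / "zone_summary.csv", index=False,
                       lineterminator="\n")
        results["species"] = species
        results["zone_summary"] = summary

        fits_by_trait = {
            t: models.fit_trait_models(species, t, cfg.survival_arcsine)
            for t in models.TRAIT_COLUMNS
        }
        model_table = models.model_summary_table(fits_by_trait)
        model_table.to_csv(outdir / "model_selection.csv", index=False,
                           lineterminator="\n")
        coef_rows = [
            {"trait": t, "model": f.spec.focal, "term": term,
             "estimate": f.coef[term], "se": f.se[term],
             "p": f.pvalue[term]}
            for t, fits in fits_by_trait.items()
            for f in fits
            for term in f.term_names
        ]
        pd.DataFrame(coef_rows).to_csv(
            outdir / "coefficients.csv", index=False, lineterminator="\n"
        )
        results["model_selection"] = model_table
        results["fits_by_trait"] = fits_by_trait

        pred = models.predict_traits(
            species, fits_by_trait, cfg.confidence_level,
            cfg.survival_arcsine,
        )
        pred.to_csv(outdir / "species_predicted.csv", index=False,
                    lineterminator="\n")
        zone_obs = _zone_observed_inputs(species)
        zone_pred = _zone_predicted_inputs(pred)
        results["species_predicted"] = pred

    conv = cfg.conventions
    demo_rows = []
    for label, zone_inputs in (("observed", zone_obs),
                               ("predicted", zone_pred)):
        if not zone_inputs:
            continue
        params_by_zone, eigen_df, elast_df = _demography_tables(
            zone_inputs, conv
        )
        eigen_df.insert(0, "inputs", label)
        elast_df.insert(0, "inputs", label)
        demo_rows.append((label, params_by_zone, eigen_df, elast_df))
    if not demo_rows:
        raise ValueError("no zone has sufficient demographic inputs")

    pd.concat([e for _, _, e, _ in demo_rows], ignore_index=True).to_csv(
        outdir / "eigen_analysis.csv", index=False, lineterminator="\n"
    )
    elast_all = pd.concat([x for _, _, _, x in demo_rows],
                          ignore_index=True)
    elast_all.to_csv(outdir / "elasticities.csv", index=False,
                     lineterminator="\n")
    results["elasticities"] = elast_all

    # Harvest analysis runs on the predicted inputs (falling back to the
    # observed ones in observed-only runs).
    label, params_by_zone, _, _ = demo_rows[-1]
    log.info("harvest analysis on %s inputs", label)
    margins_df, sweeps_df = _harvest_tables(params_by_zone, species, cfg)
    margins_df.to_csv(outdir / "harvest_margins.csv", index=False,
                      lineterminator="\n")
    sweeps_df.to_csv(outdir / "sweeps.csv", index=False,
                     lineterminator="\n", float_format="%.8g")
    results["harvest_margins"] = margins_df
    results["sweeps"] = sweeps_df

    diagnostic = harvest.convention_search(
        reference.reference_zone_inputs("predicted"),
        reference.reference_targets(),
    )
    (outdir / "convention_diagnostic.json").write_text(
        json.dumps(diagnostic, indent=2)
    )
    results["convention_diagnostic"] = diagnostic

    if cfg.make_plots:
        _plot_sweeps(sweeps_df, outdir / "sweeps.png")

    log.info("pipeline complete: outputs in %s", outdir)
    return results
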