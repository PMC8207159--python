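"""End-to-end orchestration: filter -> state-space -> phylogeny -> models -> report.

Stages communicate through plain CSV files in the run directory, so any
stage can be inspected or re-run in isolation. A JSON run manifest
records the configuration snapshot, seeds, SHA-256 digests of every file
a stage read or wrote, and wall-clock time per stage, making run-to-run
differences auditable.

The default configuration mirrors the study setup (4 chains, 10,000
iterations with 1,000 warm-up, 80/90/95% credible levels, the seven
selection criteria); every value is an overridable named key.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import egss, lpd
from .bayes import (
    PosteriorSummary,
    SamplerConfig,
    compute_raw_growth_rates,
    fit_growth_model,
    fit_residual_stage1,
    fit_residual_stage2,
    fit_yte_model,
    phylo_signal,
)
from .loo import compare_yte_models
from .phylo import grafen_lengths, phylo_correlation, read_newick, resolve_polytomies
from .simulate import VortexGeneratorConfig, generate_study

__all__ = [
    "RunManifest",
    "default_config",
    "run_pipeline",
    "build_series_tables",
    "write_report",
    "PipelineError",
]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def default_config() -> dict:
    return {
        "seed": 1,
        "out_dir": "results/run",
        "filter": {"keep_rejected": True},
        "egss": {"n_starts": 6},
        "models": {
            "chains": 4,
            "iterations": 10_000,
            "warmup": 1_000,
            "force": False,
        },
        "report": {"ci_levels": [80, 90, 95]},
    }


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, seconds: float, inputs: dict, outputs: dict,
               info: dict | None = None) -> None:
        self.stages[stage] = {
            "wall_clock_s": round(seconds, 3),
            "inputs": inputs,
            "outputs": outputs,
            "info": info or {},
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "seed": self.seed, "stages": self.stages},
            indent=2, sort_keys=True, default=str) + "\n")


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _digests(paths: dict) -> dict:
    return {str(k): _digest(p) for k, p in paths.items() if Path(p).exists()}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def build_series_tables(
    accepted: list[lpd.FilteredSeries],
    n_starts: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-series state-space fits and the derived analysis rows.

    Returns (fits, smoothed, growth_raw): the ML parameter estimates per
    series, the smoothed log-abundance path with corrected abundance and
    annual growth rates, and the raw geometric growth rates used by the
    variability analysis.
    """
    fit_rows, smooth_rows, raw_rows = [], [], []
    for k, fs in enumerate(accepted):
        logs = {
            y: float(np.log(v))
            for y, v in fs.scaled_abundance.items()
            if v > 0 and fs.yte[y] >= 0
        }
        fit = egss.fit_egss(logs, n_starts=n_starts, seed=seed + k)
        fit_rows.append(
            {
                "series_id": fs.base.series_id,
                "species": fs.base.species_binomial,
                "mu": fit.mu,
                "sigma2": fit.sigma2,
                "tau2": fit.tau2,
                "loglik": fit.loglik,
                "converged": fit.converged,
                "boundary": "|".join(sorted(fit.boundary_flags)),
            }
        )
        sm = egss.kalman_smooth(fit, logs)
        for i, year in enumerate(sm.years):
            year = int(year)
            smooth_rows.append(
                {
                    "series_id": fs.base.series_id,
                    "species": fs.base.species_binomial,
                    "year": year,
                    "yte": fs.extinction_year - year,
                    "observed": bool(sm.observed[i]),
                    "smoothed_log_abundance": float(sm.state_mean[i]),
                    "y_corrected": float(np.exp(sm.state_mean[i])),
                    "gamma": sm.gamma.get(year, np.nan),
                }
            )
        for year, r in compute_raw_growth_rates(fs).items():
            raw_rows.append(
                {
                    "series_id": fs.base.series_id,
                    "species": fs.base.species_binomial,
                    "year": year,
                    "yte": fs.yte[year],
                    "r": r,
                }
            )
    return (
        pd.DataFrame(fit_rows),
        pd.DataFrame(smooth_rows),
        pd.DataFrame(raw_rows),
    )


def _load_masses(path) -> pd.DataFrame:
    masses = pd.read_csv(path)
    if not {"species", "mass_kg"} <= set(masses.columns):
        raise ValueError(f"{path}: need columns species, mass_kg")
    masses = masses.copy()
    masses["log10_mass"] = np.log10(masses["mass_kg"].astype(float))
    return masses[["species", "log10_mass"]]


def run_pipeline(config: dict | str | Path):
    """Execute the full analysis; returns (manifest, results dict).

    ``config`` is a YAML path or a dict; unknown keys are rejected by the
    stages that consume them. With a ``simulate`` block the inputs are
    generated first; otherwise ``inputs`` must name the abundance CSV,
    Newick tree, and body-mass CSV.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = _merge(default_config(), config)
    seed = int(cfg["seed"])
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed)
    manifest_path = out / "manifest.json"
    results: dict = {}

    # ---- simulate (optional) ----
    if "simulate" in cfg:
        t0 = time.time()
        sim_cfg = dict(cfg["simulate"] or {})
        sim_cfg.setdefault("seed", seed)
        if "series_length" in sim_cfg:
            sim_cfg["series_length"] = tuple(sim_cfg["series_length"])
        study = generate_study(VortexGeneratorConfig(**sim_cfg))
        sim_paths = study.to_dir(out / "sim")
        cfg["inputs"] = {
            "abundance": str(sim_paths["abundance"]),
            "tree": str(sim_paths["tree"]),
            "masses": str(sim_paths["masses"]),
        }
        manifest.record(
            "simulate", time.time() - t0, {}, _digests(sim_paths),
            {"acceptance_rate": study.acceptance_rate},
        )
    if "inputs" not in cfg:
        raise PipelineError("inputs", "no input files and no simulate block")
    inputs = cfg["inputs"]
    for key in ("abundance", "tree", "masses"):
        if key not in inputs or not Path(inputs[key]).exists():
            stage = "phylo" if key == "tree" else "filter" if key == "abundance" else "models"
            raise PipelineError(stage, f"missing input file for {key!r}")

    # ---- filter ----
    t0 = time.time()
    long_csv = out / "long.csv"
    rejected_csv = out / "rejections.csv"
    try:
        series = lpd.parse_lpd_table(inputs["abundance"])
        accepted, reports = lpd.filter_table(series)
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc
    if not accepted:
        raise PipelineError("filter", "no series passed the selection criteria")
    lpd.to_long_frame(accepted).to_csv(long_csv, index=False)
    pd.DataFrame(
        [
            {
                "series_id": r.series_id,
                "accepted": r.accepted,
                "failed_criteria": "|".join(r.failed_criteria),
            }
            for r in reports
            if cfg["filter"]["keep_rejected"] or r.accepted
        ]
    ).to_csv(rejected_csv, index=False)
    manifest.record(
        "filter", time.time() - t0, _digests({"abundance": inputs["abundance"]}),
        _digests({"long": long_csv, "rejections": rejected_csv}),
        {"n_in": len(series), "n_accepted": len(accepted)},
    )

    # ---- state-space fits ----
    t0 = time.time()
    fits_csv = out / "egss_fits.csv"
    smooth_csv = out / "smoothed.csv"
    raw_csv = out / "raw_growth.csv"
    try:
        fits, smoothed, raw_growth = build_series_tables(
            accepted, n_starts=int(cfg["egss"]["n_starts"]), seed=seed
        )
    except Exception as exc:
        raise PipelineError("fit-ssm", str(exc)) from exc
    fits.to_csv(fits_csv, index=False)
    smoothed.to_csv(smooth_csv, index=False)
    raw_growth.to_csv(raw_csv, index=False)
    manifest.record(
        "fit-ssm", time.time() - t0, _digests({"long": long_csv}),
        _digests({"fits": fits_csv, "smoothed": smooth_csv, "raw_growth": raw_csv}),
        {"n_series": len(fits)},
    )

    # ---- phylogeny ----
    t0 = time.time()
    phylo_csv = out / "phylo_correlation.csv"
    study_species = sorted({fs.base.species_binomial for fs in accepted})
    try:
        tree = read_newick(inputs["tree"])
        tree = grafen_lengths(resolve_polytomies(tree, seed=seed))
        corr = phylo_correlation(tree, species=study_species)
    except Exception as exc:
        raise PipelineError("phylo", str(exc)) from exc
    pd.DataFrame(corr.matrix, index=corr.species, columns=corr.species).to_csv(phylo_csv)
    manifest.record(
        "phylo", time.time() - t0, _digests({"tree": inputs["tree"]}),
        _digests({"correlation": phylo_csv}), {"n_species": len(corr.species)},
    )

    # ---- hierarchical models ----
    t0 = time.time()
    masses = _load_masses(inputs["masses"])
    mcfg = cfg["models"]
    sampler_cfg = SamplerConfig(
        chains=int(mcfg["chains"]),
        iterations=int(mcfg["iterations"]),
        warmup=int(mcfg["warmup"]),
        seed=seed,
    )
    force = bool(mcfg.get("force", False))

    obs = smoothed[smoothed["observed"]]
    yte_table = (
        obs[obs["yte"] >= 1][["series_id", "species", "year", "yte", "y_corrected"]]
        .merge(masses, on="species", how="left")
    )
    growth_table = (
        obs.dropna(subset=["gamma"])[["series_id", "species", "year", "yte", "gamma"]]
        .merge(masses, on="species", how="left")
    )
    resid_table = raw_growth.merge(masses, on="species", how="left")
    for name, table in (("yte", yte_table), ("growth", growth_table),
                        ("residual", resid_table)):
        if table["log10_mass"].isna().any():
            missing = sorted(table[table["log10_mass"].isna()]["species"].unique())
            raise PipelineError("fit-models", f"{name}: species without mass: {missing}")

    try:
        summaries: dict[str, PosteriorSummary] = {}
        summaries["yte_raw"] = fit_yte_model(
            yte_table, corr, log_abundance=False, config=sampler_cfg, force=force
        )
        summaries["yte_logged"] = fit_yte_model(
            yte_table, corr, log_abundance=True, config=sampler_cfg, force=force
        )
        summaries["growth"] = fit_growth_model(
            growth_table, corr, config=sampler_cfg, force=force
        )
        stage1, resid_out = fit_residual_stage1(
            resid_table, corr, config=sampler_cfg, force=force
        )
        summaries["resid_stage1"] = stage1
        summaries["resid_stage2"] = fit_residual_stage2(
            resid_out, corr, config=sampler_cfg, force=force
        )
        comparison = compare_yte_models(summaries["yte_raw"], summaries["yte_logged"])
    except Exception as exc:
        raise PipelineError("fit-models", str(exc)) from exc

    summary_csv = out / "posterior_summaries.csv"
    signal_csv = out / "phylo_signal.csv"
    compare_csv = out / "elpd_comparison.csv"
    pd.concat([s.table for s in summaries.values()], ignore_index=True).to_csv(
        summary_csv, index=False
    )
    pd.DataFrame(
        [{"model": name, **phylo_signal(s)} for name, s in summaries.items()]
    ).to_csv(signal_csv, index=False)
    comparison.table.to_csv(compare_csv, index=False)
    manifest.record(
        "fit-models", time.time() - t0,
        _digests({"smoothed": smooth_csv, "raw_growth": raw_csv,
                  "masses": inputs["masses"], "correlation": phylo_csv}),
        _digests({"summaries": summary_csv, "signal": signal_csv,
                  "comparison": compare_csv}),
        {"models": list(summaries), "best_yte_model": comparison.best_model},
    )

    # ---- report ----
    t0 = time.time()
    report_paths = write_report(summaries, comparison, out / "report")
    manifest.record(
        "report", time.time() - t0, _digests({"summaries": summary_csv}),
        _digests(report_paths), {},
    )

    manifest.save(manifest_path)
    results.update(
        summaries=summaries, comparison=comparison, manifest=manifest,
        accepted=accepted, fits=fits, smoothed=smoothed, raw_growth=raw_growth,
        correlation=corr,
    )
    return manifest, results


def write_report(
    summaries: dict[str, PosteriorSummary], comparison, out_dir
) -> dict[str, Path]:
    """Coefficient tables, dot-interval plots, and the phylogenetic-signal
    table for the three analyses."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not summaries:
        raise ValueError("nothing to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    analyses = {
        "years_to_extinction": summaries.get("yte_logged") or summaries.get("yte_raw"),
        "growth_rate": summaries.get("growth"),
        "residual_variability": summaries.get("resid_stage2"),
    }
    analyses = {k: v for k, v in analyses.items() if v is not None}
    if not analyses:
        raise ValueError("nothing to report")
    for name, summary in analyses.items():
        fixed = summary.table[
            ~summary.table["parameter"].str.startswith(("b[", "sigma", "shape"))
        ]
        table_path = out / f"{name}_coefficients.csv"
        fixed.to_csv(table_path, index=False)
        paths[f"{name}_table"] = table_path

        fig, ax = plt.subplots(figsize=(6, 0.7 * len(fixed) + 1.2))
        ypos = np.arange(len(fixed))[::-1]
        for lw, level in ((1.0, 95), (2.2, 90), (3.6, 80)):
            ax.hlines(
                ypos, fixed[f"ci{level}_lo"], fixed[f"ci{level}_hi"],
                lw=lw, color="steelblue",
            )
        ax.plot(fixed["median"], ypos, "o", color="k", ms=5)
        ax.axvline(0.0, ls="--", color="grey", lw=0.8)
        ax.set_yticks(ypos)
        ax.set_yticklabels(fixed["parameter"])
        ax.set_xlabel("posterior estimate (80/90/95% CI)")
        ax.set_title(name.replace("_", " "))
        fig.tight_layout()
        plot_path = out / f"{name}_coefficients.png"
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        paths[f"{name}_plot"] = plot_path

    signal_path = out / "phylo_signal.csv"
    pd.DataFrame(
        [{"model": name, **phylo_signal(s)} for name, s in summaries.items()]
    ).to_csv(signal_path, index=False)
    paths["phylo_signal"] = signal_path
    if comparison is not None:
        cmp_path = out / "elpd_comparison.csv"
        comparison.table.to_csv(cmp_path, index=False)
        paths["elpd_comparison"] = cmp_path
    return paths
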