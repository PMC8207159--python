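"""Bayesian hierarchical analyses of extinction-vortex dynamics.

Three analyses share one skeleton: a response modelled with fixed effects
(standardized covariates plus their interaction), a phylogenetically
correlated species intercept, and an independent species intercept.

1. *Years to extinction* (negative binomial, log link): YTE regressed on
   the state-space-corrected scaled abundance Y_t (raw or log10), log10
   body mass, and their interaction. The final (extinction) year of each
   series is excluded.
2. *Population growth rate* (Gaussian): Kalman-smoothed annual growth
   rates gamma_t regressed on YTE, log10 body mass, and their
   interaction. A positive YTE coefficient means growth deteriorates as
   extinction approaches.
3. *Residual variability* (Gaussian, two stages): raw geometric growth
   rates r = ln(N_t / N_{t-1}) are regressed on YTE alone; the squared
   conditional residuals are then regressed on YTE, log10 body mass, and
   their interaction. A negative YTE coefficient in stage 2 means growth
   variability inflates near extinction.

Fixed effects are judged by where their 95/90/80% credible intervals sit
relative to zero (strong/moderate/weak/none evidence). Phylogenetic
signal is summarized by the posterior of the phylogenetic intercept scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import PhyloCovariance
from .sampler import (
    GaussianMixedModel,
    MixedModelData,
    NegBinMixedModel,
    SamplerConfig,
    run_hmc,
)

__all__ = [
    "PosteriorSummary",
    "ConvergenceError",
    "standardize_covariates",
    "credible_interval",
    "evidence_class",
    "rhat",
    "phylo_signal",
    "compute_raw_growth_rates",
    "fit_yte_model",
    "fit_growth_model",
    "fit_residual_stage1",
    "fit_residual_stage2",
]

RHAT_LIMIT = 1.05
RHAT_FAIL_FRACTION = 0.10


class ConvergenceError(RuntimeError):
    pass


def standardize_covariates(
    table: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Center and scale columns to mean 0, sample SD 1 (n-1 denominator).

    Returns the transformed copy and a {column: (mean, sd)} record for
    back-transformation. Constant columns are an error.
    """
    out = table.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        m = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(f"column {col!r} is constant; cannot standardize")
        out[col] = (x - m) / sd
        scaling[col] = (m, sd)
    return out, scaling


def credible_interval(draws, level: int) -> tuple[float, float]:
    """Equal-tailed interval from empirical quantiles (linear interpolation)."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 100:
        raise ValueError(f"need >=100 draws for a credible interval, got {draws.size}")
    if level not in (80, 90, 95):
        raise ValueError("level must be one of 80, 90, 95")
    tail = (100 - level) / 2.0
    lo, hi = np.percentile(draws, [tail, 100 - tail], method="linear")
    return float(lo), float(hi)


def evidence_class(
    ci80: tuple[float, float], ci90: tuple[float, float], ci95: tuple[float, float]
) -> str:
    """Strong/moderate/weak/none by the widest interval excluding zero."""
    for inner, outer in ((ci80, ci90), (ci90, ci95)):
        if inner[0] < outer[0] - 1e-12 or inner[1] > outer[1] + 1e-12:
            raise ValueError("credible intervals are not nested")
    for ci, label in ((ci95, "strong"), (ci90, "moderate"), (ci80, "weak")):
        if ci[0] > 0.0 or ci[1] < 0.0:
            return label
    return "none"


def rhat(chains) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` is (m, n): m >= 2 chains of equal length. Identical
    constant chains report exactly 1 (zero-variance guard).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("rhat needs >=2 chains of equal length")
    n = chains.shape[1] // 2
    if n < 2:
        raise ValueError("chains too short for split-Rhat")
    if np.ptp(chains) == 0.0:
        return 1.0  # identical constant chains: no variance to compare
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    within = np.mean(np.var(halves, axis=1, ddof=1))
    between = n * np.var(np.mean(halves, axis=1), ddof=1)
    if within == 0.0:
        return 1.0
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def _ess(chains: np.ndarray) -> float:
    import warnings

    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(chains[None, :, :].reshape(chains.shape[0], -1)))


@dataclass
class PosteriorSummary:
    """Per-parameter posterior summaries plus a draws handle.

    ``table`` has one row per parameter (median, the three nested CIs,
    Rhat, ESS, evidence class). ``draws`` maps parameter name to its
    flattened posterior draws; fitted designs are retained privately so
    pointwise log-likelihoods and conditional residuals can be formed.
    """

    model_name: str
    family: str
    table: pd.DataFrame
    draws: dict[str, np.ndarray]
    scaling: dict[str, tuple[float, float]]
    data: MixedModelData = field(repr=False, default=None)
    theta_draws: np.ndarray = field(repr=False, default=None)
    run: object = field(repr=False, default=None)
    n_dropped_rows: int = 0

    def median(self, parameter: str) -> float:
        row = self.table.set_index("parameter").loc[parameter]
        return float(row["median"])

    def ci(self, parameter: str, level: int) -> tuple[float, float]:
        row = self.table.set_index("parameter").loc[parameter]
        return (float(row[f"ci{level}_lo"]), float(row[f"ci{level}_hi"]))

    def evidence(self, parameter: str) -> str:
        return str(self.table.set_index("parameter").loc[parameter]["evidence"])


def phylo_signal(fit: PosteriorSummary) -> dict[str, float]:
    """Posterior mean +/- sd of the phylogenetic random-intercept scale.

    The variance and the proportion of the combined intercept variance are
    reported alongside the SD, since "signal" can be read either way.
    """
    if "sigma_phylo" not in fit.draws:
        raise ValueError("fit has no phylogenetic random effect")
    sp = fit.draws["sigma_phylo"]
    ss = fit.draws.get("sigma_species", np.zeros_like(sp))
    prop = sp**2 / np.maximum(sp**2 + ss**2, 1e-300)
    return {
        "sd_mean": float(np.mean(sp)),
        "sd_sd": float(np.std(sp, ddof=1)),
        "var_mean": float(np.mean(sp**2)),
        "var_sd": float(np.std(sp**2, ddof=1)),
        "proportion_mean": float(np.mean(prop)),
        "proportion_sd": float(np.std(prop, ddof=1)),
    }


def compute_raw_growth_rates(series) -> dict[int, float]:
    """Geometric growth rates r_t = ln(N_t / N_{t-1}) on raw abundances.

    Defined only for calendar-consecutive observed years with nonzero
    abundance in both; the transition into the first zero year is dropped
    (log 0 is not resolvable).
    """
    obs = series.base.observations if hasattr(series, "base") else series.observations
    out: dict[int, float] = {}
    for year, value in obs.items():
        prev = obs.get(year - 1)
        if prev is None or prev <= 0 or value <= 0:
            continue
        out[year] = float(np.log(value / prev))
    return out


def _summarize(run, model, config: SamplerConfig, model_name: str, family: str,
               scaling, force: bool, n_dropped: int = 0) -> PosteriorSummary:
    names = run.param_names
    flat = run.flat(max_draws=config.max_kept_draws, seed=config.seed + 1)
    rows = []
    rhats = []
    for j, name in enumerate(names):
        draws_j = flat[:, j]
        is_scale = name.startswith("sigma") or name == "shape"
        if is_scale:
            draws_j = np.exp(draws_j)
        wc = run.per_chain(j)
        r = rhat(wc)
        rhats.append(r)
        ci80 = credible_interval(draws_j, 80)
        ci90 = credible_interval(draws_j, 90)
        ci95 = credible_interval(draws_j, 95)
        rows.append(
            {
                "model": model_name,
                "parameter": name,
                "median": float(np.median(draws_j)),
                "ci80_lo": ci80[0],
                "ci80_hi": ci80[1],
                "ci90_lo": ci90[0],
                "ci90_hi": ci90[1],
                "ci95_lo": ci95[0],
                "ci95_hi": ci95[1],
                "rhat": r,
                "ess": _ess(wc),
                "evidence": evidence_class(ci80, ci90, ci95),
            }
        )
    frac_bad = float(np.mean(np.array(rhats) > RHAT_LIMIT))
    if frac_bad > RHAT_FAIL_FRACTION and not force:
        raise ConvergenceError(
            f"{model_name}: Rhat > {RHAT_LIMIT} on {frac_bad:.0%} of parameters; "
            "increase iterations or pass force=True"
        )
    draws = {}
    for j, name in enumerate(names):
        d = flat[:, j]
        draws[name] = np.exp(d) if (name.startswith("sigma") or name == "shape") else d
    return PosteriorSummary(
        model_name=model_name,
        family=family,
        table=pd.DataFrame(rows),
        draws=draws,
        scaling=scaling,
        data=model.data,
        theta_draws=flat,
        run=run,
        n_dropped_rows=n_dropped,
    )


def _build_data(
    frame: pd.DataFrame,
    response: str,
    covariates: list[str],
    phylo: PhyloCovariance,
    interaction: bool = True,
) -> tuple[MixedModelData, dict]:
    species = sorted(frame["species"].unique())
    cov = phylo.reorder(species)
    std, scaling = standardize_covariates(frame, covariates)
    cols = [np.ones(len(std))]
    names = ["intercept"]
    for c in covariates:
        cols.append(std[c].to_numpy(dtype=float))
        names.append(c)
    if interaction and len(covariates) == 2:
        cols.append(cols[1] * cols[2])
        names.append(f"{covariates[0]}:{covariates[1]}")
    X = np.column_stack(cols)
    sp_index = {sp: i for i, sp in enumerate(species)}
    data = MixedModelData(
        X=X,
        y=std[response].to_numpy(dtype=float),
        species_idx=np.array([sp_index[sp] for sp in std["species"]]),
        A=cov.matrix,
        species=species,
        fixed_names=names,
    )
    return data, scaling


def fit_yte_model(
    data: pd.DataFrame,
    phylo: PhyloCovariance,
    log_abundance: bool = True,
    config: SamplerConfig | None = None,
    force: bool = False,
) -> PosteriorSummary:
    """Years-to-extinction model (negative binomial, log link).

    ``data`` needs columns ``species``, ``yte``, ``y_corrected`` (the
    state-space-corrected scaled abundance) and ``log10_mass``. Rows with
    ``yte <= 0`` (the extinction year itself) are excluded, as are rows
    whose corrected abundance is nonpositive when the log10 transform is
    requested (their count is recorded on the summary).
    """
    config = config or SamplerConfig()
    frame = data.copy()
    n0 = len(frame)
    frame = frame[frame["yte"] >= 1]
    abundance_col = "log10_Yt" if log_abundance else "Yt"
    if log_abundance:
        frame = frame[frame["y_corrected"] > 0]
        frame[abundance_col] = np.log10(frame["y_corrected"])
    else:
        frame[abundance_col] = frame["y_corrected"]
    dropped = n0 - len(frame)
    mdata, scaling = _build_data(
        frame, "yte", [abundance_col, "log10_mass"], phylo
    )
    # response is the raw count, not standardized
    mdata.y = frame["yte"].to_numpy(dtype=float)
    model = NegBinMixedModel(mdata)
    run = run_hmc(model, config)
    name = "yte_logged_abundance" if log_abundance else "yte_raw_abundance"
    return _summarize(run, model, config, name, "negative_binomial", scaling,
                      force, n_dropped=dropped)


def _fit_gaussian(frame, response, covariates, phylo, config, name, force,
                  interaction=True) -> PosteriorSummary:
    config = config or SamplerConfig()
    mdata, scaling = _build_data(frame, response, covariates, phylo, interaction)
    mdata.y = frame[response].to_numpy(dtype=float)
    model = GaussianMixedModel(mdata)
    run = run_hmc(model, config)
    return _summarize(run, model, config, name, "gaussian", scaling, force)


def fit_growth_model(
    data: pd.DataFrame,
    phylo: PhyloCovariance,
    config: SamplerConfig | None = None,
    force: bool = False,
) -> PosteriorSummary:
    """Smoothed growth-rate model: gamma ~ yte * log10(body mass) + phylo/species."""
    return _fit_gaussian(
        data.copy(), "gamma", ["yte", "log10_mass"], phylo, config, "growth", force
    )


def fit_residual_stage1(
    data: pd.DataFrame,
    phylo: PhyloCovariance,
    config: SamplerConfig | None = None,
    force: bool = False,
) -> tuple[PosteriorSummary, pd.DataFrame]:
    """Stage 1 of the variability analysis: r ~ yte + random intercepts.

    Residuals are conditional: observed r minus the posterior-mean linear
    predictor including the species effects.
    """
    frame = data.copy().reset_index(drop=True)
    fit = _fit_gaussian(frame, "r", ["yte"], phylo, config, "resid_stage1",
                        force, interaction=False)
    mdata = fit.data
    theta = fit.theta_draws
    sub = theta[:: max(1, len(theta) // 500)]
    model = GaussianMixedModel(mdata)
    eta = model.linear_predictor(sub)
    resid = mdata.y - eta.mean(axis=0)
    out = frame.copy()
    out["residual"] = resid
    out["residual2"] = resid**2
    return fit, out


def fit_residual_stage2(
    residuals: pd.DataFrame,
    phylo: PhyloCovariance,
    config: SamplerConfig | None = None,
    force: bool = False,
) -> PosteriorSummary:
    """Stage 2: squared stage-1 residuals ~ yte * log10(body mass)."""
    return _fit_gaussian(
        residuals.copy(), "residual2", ["yte", "log10_mass"], phylo, config,
        "resid_stage2", force
    )
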