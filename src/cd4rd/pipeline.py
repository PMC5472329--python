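"""End-to-end pipeline: cohort -> fits -> policy table -> figures.

One configuration object drives a full reproducible run: obtain a cohort
(from a file or the synthetic generator), apply the sample filters, fit
the global and local discontinuity models, simulate both threshold-change
scenarios, and write delimited-text reports plus a run manifest. All
randomness flows from a single root seed, split per stage; rerunning the
same configuration is bit-identical for every deterministic output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    apply_filters,
    binned_uptake,
    cohort_from_frame,
    estimate_cd4_distribution,
    read_cohort,
    summarize,
)
from .global_rd import confidence_band, constant_uptake_bound, fit_global_rd
from .local_rd import fit_local_rd, ik_bandwidth
from .policy import (
    DEFAULT_N_NATIONAL_INITIATORS,
    DEFAULT_N_NATIONAL_ON_ART,
    PolicyScenario,
    national_projection,
    propagate_uncertainty,
    sensitivity_scenario,
    simulate_policy,
)
from .synthetic import default_params, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "make_figures"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``input_path`` (a cohort file) or ``n_patients`` (the
    synthetic generator) must be set.
    """

    input_path: str | None = None
    n_patients: int | None = None
    seed: int = 1
    threshold: int = 350
    window_start: date = date(2011, 8, 12)
    window_end: date = date(2013, 6, 30)
    dist_year_start: date = date(2013, 1, 1)
    dist_year_end: date = date(2013, 12, 31)
    scenarios: tuple[str, ...] = ("raise_to_500", "eliminate_threshold")
    n_draws: int = 10_000
    n_national_initiators: int = DEFAULT_N_NATIONAL_INITIATORS
    n_national_on_art: int = DEFAULT_N_NATIONAL_ON_ART
    out_dir: str = "cd4rd_run"
    make_plots: bool = False

    def validate(self) -> None:
        if (self.input_path is None) == (self.n_patients is None):
            raise ValueError(
                "config must set exactly one of input_path (read a cohort file) "
                "or n_patients (generate a synthetic cohort)"
            )
        if self.n_draws >= 1 and self.seed is None:
            raise ValueError("a seed is required whenever a stochastic stage runs")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("window_start", "window_end", "dist_year_start", "dist_year_end"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = date.fromisoformat(raw[key])
        if "scenarios" in raw:
            raw["scenarios"] = tuple(raw["scenarios"])
        return cls(**raw)

    def digest(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


_SCENARIOS = {
    "raise_to_500": PolicyScenario.raise_to_500,
    "eliminate_threshold": PolicyScenario.eliminate_threshold,
}


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write reports; returns the artifacts.

    Artifacts: the cohort and regression sample, CD4 distribution, binned
    uptake, global and local fits, uptake curves, per-scenario impact
    tables with intervals, national projections, and the manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    gen_seed, draw_seed = (int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2))

    with _stage("cohort"):
        if config.input_path is not None:
            cohort = read_cohort(config.input_path)
        else:
            cohort = cohort_from_frame(
                generate_cohort(default_params(config.n_patients, seed=gen_seed)),
                provenance=f"generator(seed={gen_seed})",
            )

    with _stage("filter"):
        sample = apply_filters(cohort, config.window_start, config.window_end)
        summary_full = summarize(cohort)
        summary_sample = summarize(sample)

    with _stage("cd4_distribution"):
        fcd4 = estimate_cd4_distribution(
            cohort, config.dist_year_start, config.dist_year_end
        )
        bins = binned_uptake(sample)

    with _stage("global_fit"):
        fit = fit_global_rd(sample, threshold=config.threshold)
        curve_elig = confidence_band(fit, eligible=True)
        curve_inelig = confidence_band(fit, eligible=False)
        curve_bound = constant_uptake_bound(fit)

    with _stage("local_fit"):
        h = ik_bandwidth(sample, config.threshold)
        local = fit_local_rd(sample, config.threshold, bandwidth=h)

    with _stage("policy"):
        df = cohort.records
        in_year = (df["first_cd4_date"] >= pd.Timestamp(config.dist_year_start)) & (
            df["first_cd4_date"] <= pd.Timestamp(config.dist_year_end)
        )
        n_presenters_ref = int(in_year.sum())
        n_initiators_ref = int(df.loc[in_year, "initiated_6mo"].sum())
        impacts, nationals, sens = {}, {}, {}
        for name in config.scenarios:
            scenario = _SCENARIOS[name]()
            impact = simulate_policy(
                fcd4, curve_elig, curve_inelig, scenario, n_presenters_ref, n_initiators_ref
            )
            impact.intervals = propagate_uncertainty(
                fit, fcd4, scenario, n_presenters_ref, n_initiators_ref,
                n_draws=config.n_draws, seed=draw_seed,
            )
            impacts[name] = impact
            nationals[name] = national_projection(
                impact.pct_increase_in_initiators,
                config.n_national_initiators,
                config.n_national_on_art,
            )
            sens[name] = sensitivity_scenario(
                fit, fcd4, scenario, n_presenters_ref, n_initiators_ref
            )

    artifacts = {
        "config": config,
        "cohort": cohort,
        "sample": sample,
        "summary_full": summary_full,
        "summary_sample": summary_sample,
        "fcd4": fcd4,
        "binned": bins,
        "global_fit": fit,
        "curves": {
            "if_eligible": curve_elig,
            "if_ineligible": curve_inelig,
            "constant_bound": curve_bound,
        },
        "local_fit": local,
        "impacts": impacts,
        "nationals": nationals,
        "sensitivity": sens,
        "refs": {"n_presenters": n_presenters_ref, "n_initiators": n_initiators_ref},
    }

    with _stage("reports"):
        _write_reports(artifacts, out)
    if config.make_plots:
        with _stage("figures"):
            make_figures(artifacts, out)
    return artifacts


def _impact_rows(impact, nat) -> dict:
    iv = impact.intervals

    def pair(name):
        return iv.get(name, (np.nan, np.nan))

    return {
        "pct_of_presenters": impact.pct_of_presenters,
        "pct_initiate_old_regime": impact.pct_initiate_old_regime,
        "pct_initiate_expanded": impact.pct_initiate_expanded,
        "pct_initiate_expanded_lo": pair("pct_initiate_expanded")[0],
        "pct_initiate_expanded_hi": pair("pct_initiate_expanded")[1],
        "pct_new_initiators": impact.pct_new_initiators,
        "pct_new_initiators_lo": pair("pct_new_initiators")[0],
        "pct_new_initiators_hi": pair("pct_new_initiators")[1],
        "pct_not_initiating": impact.pct_not_initiating,
        "pct_increase_in_initiators": impact.pct_increase_in_initiators,
        "national_additional_initiators": nat.additional_initiators_rounded if nat else np.nan,
        "national_pct_increase_on_art": nat.pct_increase_on_art if nat else np.nan,
    }


def _write_reports(artifacts: dict, out: Path) -> None:
    config: RunConfig = artifacts["config"]
    fit = artifacts["global_fit"]
    local = artifacts["local_fit"]

    table2 = pd.DataFrame(
        {
            name: _impact_rows(artifacts["impacts"][name], artifacts["nationals"][name])
            for name in config.scenarios
        }
    )
    table2.to_csv(out / "policy_table.csv")

    sens = pd.DataFrame(
        {name: _impact_rows(artifacts["sensitivity"][name], None) for name in config.scenarios}
    )
    sens.to_csv(out / "policy_table_sensitivity.csv")

    for label, curve in artifacts["curves"].items():
        pd.DataFrame(
            {"cd4": curve.grid, "p": curve.p, "lo95": curve.lo95, "hi95": curve.hi95}
        ).to_csv(out / f"curve_{label}.csv", index=False)

    bins = artifacts["binned"]
    pd.DataFrame(
        {"bin_left": bins.bin_edges, "mean_uptake": bins.bin_mean_uptake, "n": bins.bin_n}
    ).to_csv(out / "binned_uptake.csv", index=False)

    fcd4 = artifacts["fcd4"]
    pd.DataFrame({"cd4": np.arange(fcd4.pmf.size), "pmf": fcd4.pmf}).to_csv(
        out / "cd4_pmf.csv", index=False
    )

    fit_report = {
        "threshold": fit.threshold,
        "coef": dict(zip(("alpha", "gamma", "beta_below", "beta_above"), fit.coef.tolist())),
        "se": dict(zip(("alpha", "gamma", "beta_below", "beta_above"), fit.se.tolist())),
        "vcov": fit.vcov.tolist(),
        "loglik": fit.loglik,
        "n_obs": fit.n_obs,
        "local": {
            "bandwidth": local.bandwidth,
            "kernel": local.kernel,
            "gap": local.gap,
            "se_gap": local.se_gap,
            "n_in_window": local.n_in_window,
        },
    }
    (out / "fit_report.json").write_text(json.dumps(fit_report, indent=2, sort_keys=True))

    manifest = {
        "package_version": __version__,
        "config": {k: str(v) for k, v in asdict(config).items()},
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_cohort": len(artifacts["cohort"]),
        "n_sample": len(artifacts["sample"]),
        "exclusions": artifacts["sample"].n_excluded_by_rule,
        "refs": artifacts["refs"],
        "outputs": sorted(p.name for p in out.glob("*.csv")) + ["fit_report.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def make_figures(artifacts: dict, out_dir) -> list[Path]:
    """Histogram of first CD4 counts and the uptake-discontinuity figure.

    Every numeric series drawn here comes straight from the artifact
    objects (no recomputation), so the exported plot-data files written by
    the report stage match the figures exactly.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fcd4 = artifacts["fcd4"]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(np.arange(fcd4.pmf.size), fcd4.pmf, width=1.0, color="#4477aa")
    for x in (350, 500):
        ax.axvline(x, color="k", ls="--", lw=0.8)
    ax.set_xlabel("first CD4 count (cells/mm$^3$)")
    ax.set_ylabel("probability mass")
    ax.set_title(f"Distribution of first CD4 counts (n = {fcd4.n})")
    fig.tight_layout()
    p1 = out / "fig_cd4_distribution.png"
    fig.savefig(p1, dpi=150)
    plt.close(fig)
    written.append(p1)

    bins = artifacts["binned"]
    curves = artifacts["curves"]
    fit = artifacts["global_fit"]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    centers = bins.bin_edges + bins.bin_width / 2
    ok = bins.bin_n > 0
    ax.scatter(centers[ok], bins.bin_mean_uptake[ok], s=14, color="0.35", zorder=3)
    ce, ci, cb = curves["if_eligible"], curves["if_ineligible"], curves["constant_bound"]
    below = ce.grid < fit.threshold
    ax.plot(ce.grid[below], ce.p[below], color="crimson", lw=1.6, label="fitted (eligible)")
    ax.plot(ci.grid[~below], ci.p[~below], color="crimson", lw=1.6, ls="-",
            label="fitted (ineligible)")
    ax.plot(ce.grid[~below], ce.p[~below], color="darkorange", lw=1.6, ls="--",
            label="extrapolated if eligible")
    ax.fill_between(ce.grid[~below], ce.lo95[~below], ce.hi95[~below],
                    color="darkorange", alpha=0.2, lw=0)
    ax.plot(cb.grid[~below], cb.p[~below], color="0.2", ls=":", lw=1.2,
            label="constant-uptake bound")
    ax.axvline(fit.threshold, color="k", lw=0.8)
    ax.set_ylim(0, 1)
    ax.set_xlabel("first CD4 count (cells/mm$^3$)")
    ax.set_ylabel("P(start ART within 6 months)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    p2 = out / "fig_uptake_discontinuity.png"
    fig.savefig(p2, dpi=150)
    plt.close(fig)
    written.append(p2)
    return written
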