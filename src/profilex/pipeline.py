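"""End-to-end orchestration: simulate -> LPA -> univariate -> selection.

One configuration and one master seed drive the full analysis in the
standard order — profile indicators, class enumeration, assignment and
labeling, univariate screen, sparse-cell exclusion, bootstrap stability
selection, final report. Stage seeds are derived by hashing the stage
name with the master seed, so adding a stage never perturbs the random
streams of earlier stages, and outputs are byte-identical across runs
with the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .cohort import CohortConfig, default_config, generate_cohort, read_cohort
from .lpa import assign_and_label, enumerate_profiles, posterior, standardize
from .selection import bootstrap_relaxed_lasso, build_design, final_report
from .univariate import profile_crosstabs, screen_sparse, univariate_report


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"stage {stage!r} failed: {msg}")
        self.stage = stage


class ConfigError(ValueError):
    pass


class RunConfig(BaseModel):
    """Validated configuration of a full pipeline run."""

    model_config = ConfigDict(extra="forbid")

    input: Optional[str] = None
    synthetic: Optional[CohortConfig] = None
    k_max: int = Field(default=5, gt=1)
    blrt_reps: int = Field(default=100, ge=19)
    bootstrap_reps: int = Field(default=1000, gt=0)
    threshold: float = Field(default=0.5, gt=0.0, le=1.0)
    folds: int = Field(default=10, gt=1)
    lpa_starts: int = Field(default=50, gt=0)
    sparse_threshold: int = Field(default=10, ge=0)
    seed: int = 0
    outdir: str = "profilex_out"
    make_figures: bool = True

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "RunConfig":
        if (self.input is None) == (self.synthetic is None):
            raise ValueError("exactly one of 'input' and 'synthetic' must be set")
        return self


class _DupKeyLoader(yaml.SafeLoader):
    pass


def _no_dup_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise ConfigError(f"duplicate key {key!r} in configuration")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_DupKeyLoader.add_constructor(yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _no_dup_mapping)


def validate_config(path) -> RunConfig:
    """Parse and range-check a YAML run configuration (typos rejected)."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"configuration file not found: {p}")
    with open(p, "r", encoding="utf-8") as fh:
        data = yaml.load(fh, Loader=_DupKeyLoader)
    if data is None:
        data = {}
    if "synthetic" in data and data["synthetic"] is None:
        # a bare "synthetic:" key means "use the default synthetic cohort"
        data["synthetic"] = default_config().model_dump(mode="json")
    elif "input" not in data and "synthetic" not in data:
        # no data source at all defaults to the default synthetic cohort
        data["synthetic"] = default_config().model_dump(mode="json")
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:  # pydantic formats field-level messages
        raise ConfigError(str(exc)) from exc


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed from the master seed and stage name."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written).

    Emits, under ``config.outdir``: the (possibly simulated) cohort, the
    class-enumeration table, per-profile medians, the univariate report,
    the sparse-screen decision, the stability-selection report and
    per-replicate log, optional figures, a markdown summary and the JSON
    manifest itself.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "seeds": {},
        "files": [],
        "timings": {},
        "warnings": [],
    }
    results: dict = {}

    def _stage(name):
        s = stage_seed(config.seed, name)
        manifest["seeds"][name] = s
        return s, time.perf_counter()

    def _done(name, t0):
        manifest["timings"][name] = round(time.perf_counter() - t0, 3)

    def _write(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, index=False)
        manifest["files"].append(name)

    # --- cohort -----------------------------------------------------------
    seed, t0 = _stage("cohort")
    try:
        if config.synthetic is not None:
            cohort = generate_cohort(config.synthetic, seed=seed)
            _write(cohort, "cohort.csv")
        else:
            cohort = read_cohort(config.input)
    except Exception as exc:
        raise PipelineError("cohort", str(exc)) from exc
    _done("cohort", t0)

    # --- LPA enumeration and assignment ----------------------------------
    seed, t0 = _stage("lpa")
    try:
        ind = standardize(cohort)
        enum = enumerate_profiles(
            ind, K_max=config.k_max, B=config.blrt_reps, seed=seed, n_starts=config.lpa_starts
        )
        _write(enum.table, "enumeration.csv")
        fit2 = enum.fits[2]
        post = posterior(fit2, ind)
        labeled, medians = assign_and_label(fit2, post, cohort)
        _write(labeled, "labeled_cohort.csv")
        medians.reset_index().to_csv(outdir / "profile_medians.csv", index=False)
        manifest["files"].append("profile_medians.csv")
        if enum.chosen_k != 2:
            manifest["warnings"].append(
                f"enumeration chose K={enum.chosen_k}; downstream stages use the 2-class solution"
            )
    except Exception as exc:
        raise PipelineError("lpa", str(exc)) from exc
    _done("lpa", t0)
    results["enumeration"] = enum
    results["labeled"] = labeled
    results["medians"] = medians

    # --- univariate screen and sparse exclusion ---------------------------
    seed, t0 = _stage("univariate")
    try:
        skip = {"true_class", "aps", "gps", "uwes"}  # indicators define the profiles
        categorical = [
            c
            for c in cohort.columns
            if c not in skip and cohort[c].nunique() <= 2 and c not in _SCALES
        ]
        continuous = [c for c in cohort.columns if c not in categorical and c not in skip]
        report = univariate_report(labeled, categorical, continuous, seed=seed)
        _write(report, "univariate.csv")
        counts = profile_crosstabs(labeled, categorical)
        kept, excluded = screen_sparse(counts, continuous, threshold=config.sparse_threshold)
        with open(outdir / "screen.json", "w", encoding="utf-8") as fh:
            json.dump({"kept": kept, "excluded": excluded}, fh, indent=2)
        manifest["files"].append("screen.json")
    except Exception as exc:
        raise PipelineError("univariate", str(exc)) from exc
    _done("univariate", t0)
    results["kept"], results["excluded"] = kept, excluded

    # --- stability selection ----------------------------------------------
    seed, t0 = _stage("selection")
    try:
        design, y = build_design(labeled, kept)
        summary = bootstrap_relaxed_lasso(
            design,
            y,
            B=config.bootstrap_reps,
            threshold=config.threshold,
            folds=config.folds,
            seed=seed,
        )
        table5 = final_report(summary)
        _write(table5, "stability.csv")
        rep_rows = [
            {
                "replicate": r.replicate,
                "lambda": r.lam,
                "selected": ";".join(r.selected),
                "separated": r.separated,
                **{f"coef_{k}": v for k, v in r.coef_raw.items()},
            }
            for r in summary.replicates
        ]
        _write(pd.DataFrame(rep_rows), "replicates.csv")
    except Exception as exc:
        raise PipelineError("selection", str(exc)) from exc
    _done("selection", t0)
    results["stability"] = summary

    if config.make_figures:
        t0 = time.perf_counter()
        _figures(outdir, manifest, design, y, summary, stage_seed(config.seed, "figures"))
        _done("figures", t0)

    _summary_md(outdir, manifest, enum, medians, table5)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["results"] = results
    return manifest


_SCALES = ("fas", "gses", "psss", "aps", "gps", "uwes")


def _figures(outdir: Path, manifest: dict, design, y, summary, seed: int) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .selection import cv_choose_lambda, lambda_grid, lasso_logistic

    # selection-frequency bars
    t = summary.table
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.barh(t["predictor"], 100 * t["frequency"], color="#4878a8")
    ax.axvline(100 * summary.threshold, color="crimson", linestyle="--", label="vote threshold")
    ax.set_xlabel("selection frequency (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "selection_frequency.svg")
    plt.close(fig)
    manifest["files"].append("selection_frequency.svg")

    # coefficient paths and CV curve on the full sample
    grid = lambda_grid(design.X, y)
    betas = []
    warm = None
    for lam in grid:
        fit = lasso_logistic(design.X, y, lam, warm=warm)
        warm = (fit.intercept, fit.beta)
        betas.append(fit.beta.copy())
    betas = np.array(betas)
    lam_star = cv_choose_lambda(design.X, y, grid=grid, seed=seed)
    fig, ax = plt.subplots(figsize=(6, 4))
    for j, name in enumerate(design.columns):
        ax.plot(np.log(grid), betas[:, j], label=name)
    ax.axvline(np.log(lam_star), color="k", linestyle=":")
    ax.set_xlabel(r"log($\lambda$)")
    ax.set_ylabel("coefficient (fitting scale)")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(outdir / "coefficient_paths.svg")
    plt.close(fig)
    manifest["files"].append("coefficient_paths.svg")


def _summary_md(outdir: Path, manifest: dict, enum, medians, table5) -> None:
    lines = [
        "# Pipeline summary",
        "",
        f"Chosen number of profiles: **{enum.chosen_k}** ({enum.rationale})",
        "",
        "## Class enumeration",
        "```",
        enum.table.round(3).to_string(index=False),
        "```",
        "",
        "## Per-profile medians (raw scale)",
        "```",
        medians.round(1).to_string(),
        "```",
        "",
        "## Stability selection",
        "```",
        table5.to_string(index=False),
        "```",
        "",
    ]
    (outdir / "summary.md").write_text("\n".join(lines), encoding="utf-8")
    manifest["files"].append("summary.md")
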