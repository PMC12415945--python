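"""End-to-end pipeline: filter -> select -> train -> evaluate (-> enrich,
validate), with a YAML config, presets and a reproducibility manifest.

Two presets mirror the two clock-building flows:

* ``post_fledging`` — merge complementary dinucleotides first, then coverage-
  filter; universal sites are the exact intersection over all samples
  (adult ageing clock, ages in years).
* ``pre_fledging`` — coverage-filter per-strand records first, then merge;
  the common panel comes from the age-stratified random subset search
  (developmental clock, ages in days).

Every stage writes its output as TSV into the run directory, so stages can be
re-run individually, and ``manifest.json`` records the package version, the
resolved config, the master seed and SHA-256 digests of all inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .clock import (
    ClockHyperparams,
    alpha_sweep,
    loocv_evaluate,
    plot_predictions,
    save_model,
    train_clock,
)
from .enrichment import chromosome_enrichment
from .io import (
    FilterConfig,
    FilterOrder,
    apply_sample_filters,
    build_ratio_matrix,
    filter_variability,
    read_calls,
    site_ids,
    write_matrix,
)
from .selection import (
    SubsetSearchConfig,
    sample_qc,
    stratified_subset_search,
    universal_sites,
)
from .synthetic import summarize_site_counts
from .validation import fit_treatment_model, plot_group_means

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "PRESETS"]

logger = logging.getLogger(__name__)

PRESETS: dict[str, dict[str, Any]] = {
    # adult ageing clock: merge first, plain intersection
    "post_fledging": {"filter_order": "merge_first", "subset_search": False},
    # developmental clock: per-strand filter first, subset search on
    "pre_fledging": {"filter_order": "filter_first", "subset_search": True},
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    calls_dir: str
    metadata: str
    out_dir: str
    preset: str = "post_fledging"
    seed: int = 0
    qc_min_sites: float = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    subset: SubsetSearchConfig = field(default_factory=SubsetSearchConfig)
    clock: ClockHyperparams = field(default_factory=ClockHyperparams)
    run_sweep: bool = False
    run_enrichment: bool = True
    run_validation: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; use one of {list(PRESETS)}")
        order = FilterOrder(PRESETS[self.preset]["filter_order"])
        if self.filter.order is not order:
            self.filter = dataclasses.replace(self.filter, order=order)

    @property
    def use_subset_search(self) -> bool:
        return bool(PRESETS[self.preset]["subset_search"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        for key in ("calls_dir", "metadata", "out_dir", "preset", "seed",
                    "qc_min_sites", "run_sweep", "run_enrichment",
                    "run_validation", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "filter" in raw:
            kwargs["filter"] = FilterConfig(**raw["filter"])
        if "subset_search" in raw and isinstance(raw["subset_search"], dict):
            kwargs["subset"] = SubsetSearchConfig(**raw["subset_search"])
        if "clock" in raw:
            kwargs["clock"] = ClockHyperparams(**{
                k: (tuple(v) if k == "sweep_alphas" else v)
                for k, v in raw["clock"].items()
            })
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all configured stages; returns the run directory.

    A stage failure raises :class:`PipelineError` naming the stage; outputs
    of completed stages are left in place.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    calls_dir = Path(config.calls_dir)
    metadata = pd.read_csv(config.metadata, sep="\t").set_index("sample")
    call_paths = sorted(calls_dir.glob("*.calls.tsv"))
    if not call_paths:
        raise PipelineError("load", FileNotFoundError(f"no *.calls.tsv in {calls_dir}"))

    manifest: dict[str, Any] = {
        "package": "methclock",
        "version": __version__,
        "seed": config.seed,
        "preset": config.preset,
        "config": _config_dict(config),
        "inputs": {str(p): _sha256(p) for p in [*call_paths, Path(config.metadata)]},
        "outputs": [],
    }

    @_stage("filter")
    def stage_filter():
        calls = {p.name.removesuffix(".calls.tsv"): read_calls(p) for p in call_paths}
        counts = summarize_site_counts(calls)
        retained = sample_qc(counts, config.qc_min_sites)
        counts.rename_axis("sample").to_frame().assign(
            retained=counts.index.isin(retained)
        ).to_csv(out / "site_counts.tsv", sep="\t")
        sites = {
            s: apply_sample_filters(calls[s], config.filter) for s in retained
        }
        return sites

    sites = stage_filter()

    @_stage("select")
    def stage_select():
        idsets = {s: set(site_ids(t)) for s, t in sites.items()}
        if config.use_subset_search:
            ages = metadata.loc[list(idsets), "age"]
            result = stratified_subset_search(ages, idsets, config.subset)
            pd.DataFrame(
                {"sample": result.samples}
            ).to_csv(out / "subset_samples.tsv", sep="\t", index=False)
            chosen, panel = result.samples, result.sites
        else:
            chosen, panel = list(idsets), universal_sites(idsets)
        matrix = build_ratio_matrix(
            {s: sites[s] for s in chosen}, sorted(panel)
        )
        keep = filter_variability(
            matrix, config.filter.mean_low, config.filter.mean_high,
            config.filter.min_sd,
        )
        matrix = matrix.loc[keep]
        write_matrix(matrix, out / "matrix.tsv")
        return matrix

    matrix = stage_select()

    @_stage("train")
    def stage_train():
        X = matrix.T
        y = metadata.loc[X.index, "age"]
        unit = str(metadata.loc[X.index, "age_unit"].iloc[0]) \
            if "age_unit" in metadata.columns else "years"
        if config.run_sweep:
            sweep = alpha_sweep(X, y, config.clock)
            sweep.to_csv(out / "alpha_sweep.tsv", sep="\t", index=False)
        model = train_clock(
            X, y, alpha=config.clock.alpha, cv_folds=config.clock.cv_folds,
            seed=config.seed, n_lambda=config.clock.n_lambda, age_unit=unit,
        )
        save_model(model, out / "clock.tsv")
        return model, X, y, unit

    model, X, y, unit = stage_train()

    @_stage("evaluate")
    def stage_evaluate():
        report = loocv_evaluate(
            X, y, alpha=config.clock.alpha, cv_folds=config.clock.cv_folds,
            seed=config.seed, fixed_lambda=config.clock.lam,
            n_lambda=config.clock.n_lambda, age_unit=unit,
        )
        report.predictions.rename_axis("sample").to_csv(
            out / "loocv_predictions.tsv", sep="\t"
        )
        pd.DataFrame(
            [{
                "n": len(report.predictions),
                "pearson_r": report.pearson_r,
                "r_ci_low": report.r_ci_low,
                "r_ci_high": report.r_ci_high,
                "mad": report.mad,
                "age_unit": report.age_unit,
                "n_clock_cpgs": len(model.coef),
            }]
        ).to_csv(out / "metrics.tsv", sep="\t", index=False)
        plot_predictions(report, out / "loocv_scatter.png")
        return report

    stage_evaluate()

    if config.run_enrichment:
        @_stage("enrich")
        def stage_enrich():
            background = list(matrix.index)
            chrom_map = {s: s.split(":", 1)[0] for s in background}
            table = chromosome_enrichment(model.sites, background, chrom_map)
            table.to_csv(out / "enrichment.tsv", sep="\t", index=False)

        stage_enrich()

    if config.run_validation:
        @_stage("validate")
        def stage_validate():
            needed = {"treatment", "brood"}
            if not needed <= set(metadata.columns):
                raise ValueError("metadata lacks treatment/brood columns")
            preds = model.predict(X)
            frame = metadata.loc[X.index].assign(epi_age=preds).reset_index()
            analysis = fit_treatment_model(frame)
            analysis.fixed_effects.to_csv(out / "treatment_fixed_effects.tsv",
                                          sep="\t", index=False)
            analysis.emmeans.to_csv(out / "treatment_emmeans.tsv", sep="\t",
                                    index=False)
            analysis.contrasts.to_csv(out / "treatment_contrasts.tsv", sep="\t",
                                      index=False)
            plot_group_means(analysis, frame, out / "treatment_means.png")

        stage_validate()

    manifest["outputs"] = sorted(p.name for p in out.iterdir())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _config_dict(config: PipelineConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["filter"]["order"] = config.filter.order.value
    return d
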