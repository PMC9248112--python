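"""End-to-end pipeline: preprocess → exchange → specificity → trajectories → clock."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .clock import MANDATORY_COVARIATES, build_clock
from .errors import ConfigurationError, VaprotError
from .exchange import median_normalize, paired_exchange_test, venoarterial_diffs
from .io import config_hash, read_expression_table, write_json
from .longitudinal import cluster_mean_curves, evaluate_mean_curves, fit_all_curves
from .preprocess import detect_atypical_samples, protein_columns, winsorize_high_abundance
from .specificity import classify_specific, specificity_contrast

log = logging.getLogger("vaprot")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; every output records its hash and seed."""

    four_vessel_path: str = ""
    longitudinal_path: str = ""
    out_dir: str = "vaprot_out"
    alpha: float = 0.05
    winsor_q: float = 0.98
    mad_threshold: float = 5.0
    spline_df: int = 3
    k_min: int = 2
    k_max: int = 8
    pi: float = 0.6
    n_subsamples: int = 100
    train_fraction: float = 2.0 / 3.0
    normalization: str = "median"
    seed: int = 17

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.winsor_q < 1.0:
            raise ConfigurationError(f"winsor_q must be in (0, 1), got {self.winsor_q}")
        if not 2 <= self.k_min <= self.k_max:
            raise ConfigurationError(f"need 2 <= k_min <= k_max, got {self.k_min}..{self.k_max}")
        if not 0.5 < self.pi <= 1.0:
            raise ConfigurationError(f"pi must be in (0.5, 1], got {self.pi}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.normalization not in ("median", "none"):
            raise ConfigurationError(f"normalization must be 'median' or 'none', got {self.normalization!r}")

    def hash(self) -> str:
        return config_hash(asdict(self))


def _screen(table, vein, artery, config):
    diffs = venoarterial_diffs(table, vein, artery)
    if config.normalization == "median":
        diffs = median_normalize(diffs)
    else:
        diffs.normalized = True  # declared bias-free by configuration
    return diffs, paired_exchange_test(diffs, alpha=config.alpha)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the configured input tables; returns the manifest.

    Stage order: preprocess (winsorize longitudinal panel, drop atypical
    samples) → venoarterial screens UV−RA and AV−RA → placenta-specificity →
    gestational trajectories of the specific proteins (spline mixed models,
    correlation clustering) → proteomic clock trained on the released
    proteins. All stage outputs are written under ``config.out_dir`` along
    with a run manifest (versions, seed, config hash, per-stage counts).
    A stage failure aborts the run with the stage name and cause.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.hash(),
        "stages": {},
    }

    stage = "read"
    try:
        four = read_expression_table(config.four_vessel_path, kind="four_vessel")
        longi = read_expression_table(config.longitudinal_path, kind="longitudinal")

        stage = "preprocess"
        flagged = detect_atypical_samples(four, mad_threshold=config.mad_threshold)
        if flagged:
            log.warning("excluding %d atypical four-vessel sample(s)", len(flagged))
            four = four.drop(index=flagged)
        longi = winsorize_high_abundance(longi, q=config.winsor_q)
        manifest["stages"]["preprocess"] = {
            "atypical_samples_excluded": len(flagged),
            "n_proteins": len(protein_columns(four)),
            "n_four_vessel_rows": len(four),
            "n_longitudinal_rows": len(longi),
        }

        stage = "exchange"
        uv_diffs, uv_result = _screen(four, "UV", "RA", config)
        av_diffs, av_result = _screen(four, "AV", "RA", config)
        uv_result.table.to_csv(out / "exchange_uv_ra.tsv", sep="\t")
        av_result.table.to_csv(out / "exchange_av_ra.tsv", sep="\t")
        manifest["stages"]["exchange"] = {
            "n_released": int(len(uv_result.released)),
            "n_uptake": int(len(uv_result.uptake)),
            "n_arm_significant": int((av_result.table["exchange_class"] != "none").sum()),
        }

        stage = "specificity"
        contrast = specificity_contrast(uv_diffs, av_diffs)
        spec = classify_specific(uv_result, av_result, contrast, alpha=config.alpha)
        spec.table.to_csv(out / "specificity.tsv", sep="\t")
        specific = [p for p in spec.specific if p in longi.columns]
        manifest["stages"]["specificity"] = {
            "n_specific": int(len(spec.specific)),
            "n_specific_in_longitudinal": len(specific),
        }

        stage = "longitudinal"
        cluster_counts = {}
        if specific:
            fits = fit_all_curves(longi, specific, spline_df=config.spline_df)
            curves = evaluate_mean_curves(fits)
            curves.to_csv(out / "mean_curves.tsv", sep="\t")
            k_max = min(config.k_max, len(curves) - 1)
            if k_max >= config.k_min:
                clusters = cluster_mean_curves(curves, k_candidates=range(config.k_min, k_max + 1))
                clusters.assignment.to_csv(out / "clusters.tsv", sep="\t")
                clusters.mean_silhouette.rename("mean_silhouette").to_csv(
                    out / "silhouette.tsv", sep="\t")
                cluster_counts = {"chosen_k": clusters.chosen_k,
                                  "n_curves": int(len(curves))}
            else:
                log.warning("too few curves (%d) to cluster", len(curves))
        manifest["stages"]["longitudinal"] = {
            "n_specific_modeled": len(specific), **cluster_counts}

        stage = "clock"
        candidates = [p for p in uv_result.released if p in longi.columns]
        clock_counts = {}
        if len(candidates) >= 1 and longi["participant_id"].nunique() >= 15:
            result = build_clock(longi, candidates, covariates=list(MANDATORY_COVARIATES),
                                 pi=config.pi, n_subsamples=config.n_subsamples,
                                 train_fraction=config.train_fraction, seed=config.seed)
            write_json({
                "selected_proteins": result.model.selected_proteins,
                "protein_coefficients": result.model.protein_coefficients,
                "covariate_coefficients": result.model.covariate_coefficients,
                "intercept": result.model.intercept,
                "pi": result.model.stability_threshold,
                "selection_frequency": result.model.selection_frequency,
                "performance": result.model.performance,
                "seed": config.seed,
                "config_hash": config.hash(),
            }, out / "clock_model.json")
            clock_counts = {"n_candidates": len(candidates),
                            "n_selected": len(result.model.selected_proteins),
                            **{k: (None if pd.isna(v) else round(float(v), 4))
                               for k, v in result.model.performance.items()}}
        else:
            log.warning("clock stage skipped: %d candidates, %d participants",
                        len(candidates), longi["participant_id"].nunique())
        manifest["stages"]["clock"] = clock_counts or {"skipped": True}
    except VaprotError as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        write_json(manifest, out / "manifest.json")
        raise VaprotError(f"pipeline aborted in stage {stage!r}: {exc}") from exc

    manifest["complete"] = True
    write_json(manifest, out / "manifest.json")
    return manifest
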