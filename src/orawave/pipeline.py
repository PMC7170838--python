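"""End-to-end orchestration: simulate/ingest -> quality filter -> replicate
averaging -> VAE train + denoise -> features (Monot1-2 + descriptors) ->
Lasso screen -> exhaustive AICc search -> nested with/without-Monot1-2
ANOVA -> report + latent-traversal animation.

Also hosts the validation harness: the planted-coefficient recovery
experiment, the denoising experiment, and the null calibration of the
nested ANOVA — the computations behind this package's quantitative claims.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import io as wio
from . import selection as sel
from . import synthetic as syn
from . import vae as vae_mod
from .errors import ConfigError, PipelineError

logger = logging.getLogger("orawave")

__all__ = [
    "RunConfig", "ReportBundle", "run_pipeline", "recovery_experiment",
    "denoising_experiment", "null_anova_calibration",
]

_SEED_MOD = 2 ** 31


@dataclass
class RunConfig:
    """One-file configuration for a full pipeline run."""

    mode: str = "simulate"                  # "simulate" or "ingest"
    seed: int = 0
    outdir: str = "orawave_run"
    sim: syn.SimConfig = field(default_factory=syn.SimConfig)
    waveform_table: Optional[str] = None    # ingest mode
    covariate_table: Optional[str] = None   # ingest mode
    quality_threshold: float = wio.QUALITY_THRESHOLD
    average_mode: str = "trace"             # "trace" or "parameters"
    feature_source: str = "raw"             # "raw" or "reconstructed"
    include_keratometry: bool = False
    vae_epochs: int = 500
    vae_batch_size: int = 16
    vae_learning_rate: float = 1e-3
    vae_beta: float = 1.0
    vae_recon_sigma: float = vae_mod.DEFAULT_RECON_SIGMA
    screen_k: int = sel.DEFAULT_SCREEN_K
    top_k: int = 20
    animate: bool = True
    n_frames: int = 21
    span: Optional[float] = None            # default: 2 sd of projected latents
    write_outputs: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ConfigError("mode must be 'simulate' or 'ingest'")
        if self.mode == "ingest" and not (self.waveform_table
                                          and self.covariate_table):
            raise ConfigError("ingest mode needs waveform_table and "
                              "covariate_table")
        if self.average_mode not in ("trace", "parameters"):
            raise ConfigError("average_mode must be 'trace' or 'parameters'")
        if self.feature_source not in ("reconstructed", "raw"):
            raise ConfigError("feature_source must be 'reconstructed' or 'raw'")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["sim"]["covariates"] = {k: list(v) for k, v in
                                  d["sim"]["covariates"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim_d = d.pop("sim", {})
        if "covariates" in sim_d:
            sim_d["covariates"] = {k: tuple(v) for k, v in
                                   sim_d["covariates"].items()}
        return cls(sim=syn.SimConfig(**sim_d), **d)


@dataclass(eq=False)
class ReportBundle:
    """Everything a run produces, in memory."""

    counts: Dict[str, int]
    univariate: pd.DataFrame
    selection: sel.SelectionResult
    best: sel.OLSFit
    ablated: sel.OLSFit                      # the no-Monot1-2 counterpart
    delta_aicc: float                        # ablated.aicc - best-with-monot.aicc
    anova_p: float
    animation_path: Optional[str]
    manifest: Dict[str, object]
    model: Optional[vae_mod.VAEModel] = None
    design: Optional[feat.DesignMatrix] = None


def _derive_seed(base: int, offset: int) -> int:
    return (int(base) + 1013 * offset) % _SEED_MOD


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every stage in order and (optionally) write the report.

    A rerun with the same configuration is bit-identical.  Stage failures
    propagate as :class:`PipelineError` naming the stage, and any partial
    output files are removed.
    """
    outdir = Path(config.outdir)
    written: List[Path] = []
    try:
        return _run_pipeline_inner(config, outdir, written)
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as e:  # pragma: no cover - defensive
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"unexpected failure: {e}") from e


def _run_pipeline_inner(config: RunConfig, outdir: Path,
                        written: List[Path]) -> ReportBundle:
    def stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage: %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return _Ctx()

    counts: Dict[str, int] = {}

    with stage("ingest"):
        if config.mode == "simulate":
            sim_cfg = replace(config.sim, seed=_derive_seed(config.seed, 0))
            bundle = syn.simulate_cohort(sim_cfg)
            records, covariates = bundle.records, bundle.covariates
        else:
            records = wio.read_waveform_table(config.waveform_table)
            covariates = wio.read_covariates_table(config.covariate_table)
        all_eyes = [c.eye_id for c in covariates]
        counts["records"] = len(records)

    with stage("quality_filter"):
        filtered = wio.filter_by_quality(records, config.quality_threshold)
        counts["after_quality_filter"] = len(filtered)
        if not filtered:
            raise ValueError("no records survive the quality filter")

    with stage("average_replicates"):
        averaged, dropped = wio.average_replicates(filtered, all_eyes)
        counts["eyes_averaged"] = len(averaged)

    with stage("vae"):
        traces = np.vstack([r.trace for r in averaged])
        arch = vae_mod.VAEArch(input_dim=traces.shape[1])
        model = vae_mod.init_vae(arch, seed=_derive_seed(config.seed, 1))
        vae_mod.train_vae(model, traces, epochs=config.vae_epochs,
                          batch_size=config.vae_batch_size,
                          learning_rate=config.vae_learning_rate,
                          seed=_derive_seed(config.seed, 2),
                          beta=config.vae_beta,
                          recon_sigma=config.vae_recon_sigma)
        codes = vae_mod.encode_traces(model, traces)

    with stage("features"):
        eye_feats: Dict[str, Dict[str, float]] = {}
        if config.average_mode == "trace":
            for rec in averaged:
                trace = (vae_mod.reconstruct(model, rec.trace)
                         if config.feature_source == "reconstructed"
                         else rec.trace)
                eye_feats[rec.eye_id] = feat.compute_features(trace)
        else:  # average the per-replicate parameter values instead
            per_eye: Dict[str, List[Dict[str, float]]] = {}
            for rec in filtered:
                trace = (vae_mod.reconstruct(model, rec.trace)
                         if config.feature_source == "reconstructed"
                         else rec.trace)
                per_eye.setdefault(rec.eye_id, []).append(
                    feat.compute_features(trace))
            for eye, fs in per_eye.items():
                eye_feats[eye] = {k: float(np.mean([f[k] for f in fs]))
                                  for k in fs[0]}

    with stage("design_matrix"):
        cov_in = [c for c in covariates if c.eye_id in eye_feats]
        design = feat.assemble_design_matrix(
            eye_feats, cov_in, include_keratometry=config.include_keratometry)
        counts["eyes_in_design"] = design.X.shape[0]

    with stage("univariate_scan"):
        univariate = sel.univariate_scan(design.X, design.y)

    with stage("lasso_screen"):
        candidates = sel.lasso_screen(design.X, design.y, k=config.screen_k)

    with stage("exhaustive_search"):
        result = sel.exhaustive_aicc_search(design.X, design.y, candidates,
                                            top_k=config.top_k)
        best = result.best

    with stage("monot12_ablation"):
        # Headline comparison: the optimal model against the same model with
        # Monot1-2 removed (or, if the search excluded it, added back in).
        if "monot12" in best.subset:
            with_m = best
            without_m = sel.ols_fit(design.X, design.y,
                                    [c for c in best.subset if c != "monot12"])
        else:
            without_m = best
            with_m = sel.ols_fit(design.X, design.y,
                                 list(best.subset) + ["monot12"])
        anova_p = sel.anova_nested(without_m, with_m)
        delta_aicc = without_m.aicc - with_m.aicc

    animation_path: Optional[str] = None
    frames = None
    with stage("latent_traversal"):
        if config.animate:
            praa = [design.y.loc[rec.eye_id] for rec in averaged
                    if rec.eye_id in design.y.index]
            used_codes = [c for rec, c in zip(averaged, codes)
                          if rec.eye_id in design.y.index]
            axis = vae_mod.fit_praa_axis(used_codes, praa)
            span = config.span
            if span is None:
                proj = np.vstack([c.mu for c in used_codes]) @ axis.direction
                span = 2.0 * float(np.std(proj))
            frames = vae_mod.traverse(model, axis, span, config.n_frames)

    manifest = {
        "seed": int(config.seed),
        "mode": config.mode,
        "n_eyes_requested": int(config.sim.n_eyes) if config.mode == "simulate"
        else None,
        "quality_threshold": config.quality_threshold,
        "feature_source": config.feature_source,
        "screen_k": int(config.screen_k),
        "vae_epochs": int(config.vae_epochs),
        "dropped_eyes": list(dropped),
    }

    bundle_out = ReportBundle(
        counts=counts, univariate=univariate, selection=result, best=best,
        ablated=without_m, delta_aicc=float(delta_aicc),
        anova_p=float(anova_p), animation_path=None, manifest=manifest,
        model=model, design=design,
    )

    if config.write_outputs:
        with stage("write_report"):
            outdir.mkdir(parents=True, exist_ok=True)
            if config.mode == "simulate":
                wf = outdir / "waveforms.csv"
                cv = outdir / "covariates.csv"
                wio.write_waveform_table(records, wf)
                wio.write_covariates_table(covariates, cv)
                written += [wf, cv]
            fpath = outdir / "features.csv"
            pd.DataFrame(eye_feats).T.rename_axis("eye_id").to_csv(fpath)
            written.append(fpath)
            ckpt = outdir / "vae_checkpoint.npz"
            vae_mod.save_model(model, ckpt)
            written += [ckpt, Path(str(ckpt) + ".json")]
            if frames is not None:
                gif = outdir / "traversal.gif"
                vae_mod.export_animation(frames, gif)
                written += [gif, Path(str(gif) + ".frames.csv")]
                animation_path = str(gif)
                bundle_out.animation_path = animation_path
            rpath = outdir / "report.json"
            with open(rpath, "w") as fh:
                json.dump(_report_dict(bundle_out), fh, indent=1)
            written.append(rpath)
            mpath = outdir / "report.md"
            mpath.write_text(_report_markdown(bundle_out))
            written.append(mpath)

    return bundle_out


def _report_dict(b: ReportBundle) -> Dict[str, object]:
    return {
        "counts": b.counts,
        "manifest": b.manifest,
        "candidates": list(b.selection.candidates),
        "n_models_evaluated": int(b.selection.n_models_evaluated),
        "best_subset": list(b.best.subset),
        "best_coefficients": b.best.coefficients,
        "best_std_errors": b.best.std_errors,
        "best_p_values": b.best.p_values,
        "best_aicc": b.best.aicc,
        "ablated_subset": list(b.ablated.subset),
        "ablated_aicc": b.ablated.aicc,
        "delta_aicc_without_monot12": b.delta_aicc,
        "anova_p_with_vs_without_monot12": b.anova_p,
        "univariate": b.univariate.to_dict(orient="records"),
        "animation": b.animation_path,
    }


def _report_markdown(b: ReportBundle) -> str:
    lines = ["# PRAA waveform-model report", ""]
    lines.append("## Stage counts")
    for k, v in b.counts.items():
        lines.append(f"- {k}: {v}")
    lines.append("")
    lines.append(f"## Optimal model (AICc = {b.best.aicc:.1f}, "
                 f"{b.selection.n_models_evaluated} subsets evaluated)")
    lines.append("")
    lines.append("| term | coefficient | SE | p |")
    lines.append("|---|---|---|---|")
    for name in ("intercept",) + b.best.subset:
        lines.append(f"| {name} | {b.best.coefficients[name]:.4g} | "
                     f"{b.best.std_errors[name]:.3g} | "
                     f"{b.best.p_values[name]:.3g} |")
    lines.append("")
    lines.append(f"Without Monot1-2: AICc = {b.ablated.aicc:.1f} "
                 f"(Delta = {b.delta_aicc:+.2f}); "
                 f"ANOVA with vs without Monot1-2: p = {b.anova_p:.4g}")
    if b.animation_path:
        lines.append("")
        lines.append(f"Latent traversal animation: {b.animation_path}")
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Validation harness
# ---------------------------------------------------------------------------

def recovery_experiment(config: RunConfig, n_seeds: int) -> pd.DataFrame:
    """Repeat the pipeline over seeds; score selection of planted predictors.

    Returns one row per design column: how often it entered the optimal
    subset, its mean coefficient when selected, the planted value, and the
    mean relative bias for planted predictors.
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    planted = dict(config.sim.praa_coefs)
    freq: Dict[str, int] = {}
    coefs: Dict[str, List[float]] = {}
    for i in range(n_seeds):
        cfg = replace(config, seed=_derive_seed(config.seed, 100 + i),
                      animate=False, write_outputs=False)
        b = run_pipeline(cfg)
        for name in b.best.subset:
            freq[name] = freq.get(name, 0) + 1
            coefs.setdefault(name, []).append(b.best.coefficients[name])
    rows = []
    names = sorted(set(freq) | set(planted))
    for name in names:
        truth = planted.get(name, 0.0)
        mean_coef = float(np.mean(coefs[name])) if name in coefs else np.nan
        rows.append({
            "variable": name,
            "selection_frequency": freq.get(name, 0) / n_seeds,
            "mean_coefficient": mean_coef,
            "planted_coefficient": truth,
            "relative_bias": ((mean_coef - truth) / abs(truth)
                              if truth != 0 and name in coefs else np.nan),
        })
    return pd.DataFrame(rows)


def denoising_experiment(seed: int = 0, n_train: int = 500, n_test: int = 100,
                         noise_frac: float = 0.04, epochs: int = 500,
                         batch_size: int = 16,
                         recon_sigma: float = vae_mod.DEFAULT_RECON_SIGMA
                         ) -> Dict[str, float]:
    """Train on noisy traces; measure denoising on a held-out set.

    Noise sd is ``noise_frac`` of the mean first-peak height.  Returns the
    mean L2 distance to the clean truth of (a) the raw noisy inputs and
    (b) their reconstructions, plus the ratio b/a (< 1 means the VAE
    moved traces toward the truth).
    """
    cfg = syn.SimConfig(n_eyes=n_train + n_test, n_replicates=1,
                        noise_sd=noise_frac * 611.54,
                        seed=_derive_seed(seed, 7))
    bundle = syn.simulate_cohort(cfg)
    noisy = np.vstack([r.trace for r in bundle.records])
    clean = bundle.truth.clean_traces
    model = vae_mod.init_vae(vae_mod.VAEArch(), seed=_derive_seed(seed, 8))
    vae_mod.train_vae(model, noisy[:n_train], epochs=epochs,
                      batch_size=batch_size, seed=_derive_seed(seed, 9),
                      recon_sigma=recon_sigma)
    recon = vae_mod.reconstruct(model, noisy[n_train:])
    l2_noisy = float(np.mean(np.linalg.norm(noisy[n_train:] - clean[n_train:],
                                            axis=1)))
    l2_recon = float(np.mean(np.linalg.norm(recon - clean[n_train:], axis=1)))
    return {"l2_noisy": l2_noisy, "l2_recon": l2_recon,
            "ratio": l2_recon / l2_noisy, "n_test": n_test}


def null_anova_calibration(seed: int = 0, n_sims: int = 2000, n: int = 60,
                           alpha: float = 0.05) -> Dict[str, float]:
    """Type-I error of the nested F-test when the added variable is noise."""
    rng = np.random.default_rng(_derive_seed(seed, 13))
    rejections = 0
    for _ in range(n_sims):
        X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        y = pd.Series(1.5 * X["x1"].to_numpy() + rng.normal(size=n))
        small = sel.ols_fit(X, y, ["x1"])
        large = sel.ols_fit(X, y, ["x1", "x2"])
        if sel.anova_nested(small, large) < alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims,
            "alpha": alpha}
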