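"""End-to-end orchestration: simulate -> QC -> deconvolve -> delta-beta ->
sweep/train -> score -> evaluate -> variance decomposition -> contamination.

A single global seed is expanded into per-stage seeds (seed + stage index) so
stages can be rerun in isolation; rerunning with the same config reproduces
all numeric outputs exactly.  When an output directory is given every stage
artefact is written alongside a manifest (file hashes, per-stage seeds,
package version).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .contamination import contamination_shift_curve
from .deconv import build_reference_panel, correct_tumour_fraction, estimate_fractions
from .dmp import estimate_delta_betas, rank_cpgs
from .index import IndexModel, finalize_index, sweep_index_size
from .mixture import BetaMixtureDecomposer
from .qc import qc_filter_impute, split_discovery
from .simulate import EffectSpec, UniformICFractions, generate_cohort, generate_profiles, generate_reference_samples
from .stats import quartile_odds_table, roc_auc_ci

_STAGES = ("simulate", "qc", "deconv", "delta", "sweep", "score", "evaluate", "decompose", "contaminate")

__all__ = ["PipelineConfig", "run_end_to_end"]


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run, validated before any stage."""

    seed: int = 1
    # cohort
    n_cases: int = 150
    n_controls: int = 450
    n_cpgs: int = 10_000
    n_informative: int = 500
    epithelial_delta: float = 0.1
    ic_low: float = 0.0
    ic_high: float = 0.8
    noise_sd: float = 0.02
    detection_fail_rate: float = 1e-5
    markers_per_type: int | None = None
    n_ref_per_type: int = 12
    # qc
    p_thresh: float = 0.01
    sample_fail_frac: float = 0.10
    probe_fail_frac: float = 0.10
    knn_k: int = 10
    # deconvolution panel
    panel_p_adj_max: float = 0.01
    panel_delta_min: float = 0.4
    panel_target_count: int | None = None
    loess_span: float = 0.75
    # split and classifier
    train_frac: float = 2 / 3
    rank_mode: str = "epithelial"
    n_grid: tuple = (100, 500, 1500, 3000)
    penalty: str = "ridge"
    folds: int = 5
    n_lambdas: int = 20
    lambda_min_ratio: float = 1e-3
    # variance decomposition
    decompose_top: int = 100
    variance_ratio: float = 2.0
    # contamination
    rho_grid: tuple = tuple(np.round(np.arange(0, 1.0001, 0.05), 3))
    target_shift_sd: float = 1.25
    contamination_ic_max: float = 0.5
    # stage toggles for the optional tails
    run_decompose: bool = True
    run_contaminate: bool = True

    def validate(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie strictly between 0 and 1")
        if self.n_cpgs < 10:
            raise ValueError("n_cpgs must be at least 10")
        if self.n_cases + self.n_controls < 3:
            raise ValueError("cohort too small to split")
        if not 0 <= self.detection_fail_rate <= 1:
            raise ValueError("detection_fail_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.p_thresh < 1:
            raise ValueError("p_thresh must lie in (0, 1)")
        if self.penalty not in ("ridge", "lasso"):
            raise ValueError("penalty must be 'ridge' or 'lasso'")
        if len(self.n_grid) == 0:
            raise ValueError("n_grid is empty")
        if max(self.n_grid) > self.n_cpgs:
            raise ValueError("n_grid exceeds the number of CpGs")
        if self.n_informative > self.n_cpgs:
            raise ValueError("more informative CpGs than CpGs")
        if any(r < 0 or r > 1 for r in self.rho_grid):
            raise ValueError("rho grid must lie in [0, 1]")

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + _STAGES.index(stage)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("n_grid", "rho_grid"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["n_grid"] = list(self.n_grid)
        d["rho_grid"] = [float(r) for r in self.rho_grid]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_end_to_end(config: PipelineConfig, outdir=None) -> dict:
    """Run every stage on one synthetic cohort; returns the results bundle.

    The returned dict carries the in-memory artefacts (beta matrix, sample
    sheet, fractions, delta-beta records, sweep table, index models, scores,
    evaluation summary, variance fits, contamination curve).  With ``outdir``
    set, stage outputs, a summary.json and a manifest.json are also written.
    """
    config.validate()
    out: dict = {"config": asdict(config)}

    # --- simulate ------------------------------------------------------
    sim_seed = config.stage_seed("simulate")
    profiles, annotation = generate_profiles(
        config.n_cpgs, seed=sim_seed, markers_per_type=config.markers_per_type
    )
    rng = np.random.default_rng(sim_seed)
    effect = None
    if config.n_informative > 0 and config.epithelial_delta != 0:
        from .simulate import feasible_effect_cpgs

        marker_ids = set(profiles.loc[profiles["is_marker"], "cpg_id"])
        feasible = [
            c
            for c in feasible_effect_cpgs(profiles, config.epithelial_delta)
            if c not in marker_ids
        ]
        informative = tuple(
            sorted(rng.choice(feasible, size=config.n_informative, replace=False))
        )
        effect = EffectSpec(informative, config.epithelial_delta, "epithelial")
    beta, sheet, detection_p, truth = generate_cohort(
        profiles,
        n_cases=config.n_cases,
        n_controls=config.n_controls,
        effect=effect,
        fraction_model=UniformICFractions(config.ic_low, config.ic_high),
        noise_sd=config.noise_sd,
        detection_fail_rate=config.detection_fail_rate,
        p_thresh=config.p_thresh,
        seed=sim_seed,
    )
    ref_beta, ref_labels = generate_reference_samples(
        profiles, n_per_type=config.n_ref_per_type, seed=sim_seed + 1000
    )
    out.update(annotation=annotation, sheet=sheet, truth=truth)

    # --- qc ------------------------------------------------------------
    beta, qc_report = qc_filter_impute(
        beta, detection_p, p_thresh=config.p_thresh,
        sample_fail_frac=config.sample_fail_frac,
        probe_fail_frac=config.probe_fail_frac, k=config.knn_k,
    )
    sheet = sheet[sheet["sample_id"].isin(beta.columns)].reset_index(drop=True)
    out.update(beta=beta, qc_report=qc_report)

    # --- deconvolution -------------------------------------------------
    panel = build_reference_panel(
        ref_beta, ref_labels, p_adj_max=config.panel_p_adj_max,
        delta_min=config.panel_delta_min, target_count_per_type=config.panel_target_count,
    )
    fractions = estimate_fractions(beta, panel)
    fractions = correct_tumour_fraction(
        fractions, sheet.loc[sheet["type"] == "control", "sample_id"], span=config.loess_span
    )
    out.update(panel=panel, fractions=fractions)

    # --- split + delta-beta -------------------------------------------
    train_ids, val_ids = split_discovery(sheet, config.train_frac, seed=config.stage_seed("delta"))
    labels = sheet.set_index("sample_id")["type"]
    ic = fractions["ic"]
    records = estimate_delta_betas(beta[train_ids], ic[train_ids], labels[train_ids])
    ranked = rank_cpgs(records, mode=config.rank_mode)
    out.update(train_ids=train_ids, val_ids=val_ids, records=records, ranked_cpgs=ranked)

    # --- sweep ---------------------------------------------------------
    sweep_seed = config.stage_seed("sweep")
    sweep_table, optimal_n, fit_opt = sweep_index_size(
        beta[train_ids], labels[train_ids], beta[val_ids], labels[val_ids],
        ranked, config.n_grid, penalty=config.penalty, folds=config.folds,
        seed=sweep_seed, n_lambdas=config.n_lambdas, lambda_min_ratio=config.lambda_min_ratio,
    )
    out.update(sweep_table=sweep_table, optimal_n=optimal_n)

    # internal model: trained on the training set only, scaled on training scores
    Xtr = beta[train_ids].loc[fit_opt["cpgs"]].to_numpy().T
    s_tr = Xtr @ fit_opt["weights"]
    model_internal = IndexModel(
        cpgs=fit_opt["cpgs"], weights=list(map(float, fit_opt["weights"])),
        mu=float(s_tr.mean()), sigma=float(s_tr.std(ddof=1)), n=optimal_n,
        penalty=config.penalty, lambda_=fit_opt["lambda_"], seed=sweep_seed,
        training_means=Xtr.mean(axis=0).tolist(), intercept=fit_opt["intercept"],
    )
    # final model: refit on the whole discovery set with lambda fixed
    model_final = finalize_index(
        beta, labels, ranked, optimal_n, config.penalty, fit_opt["lambda_"], seed=sweep_seed
    )
    out.update(model_internal=model_internal, model_final=model_final)

    # --- score + evaluate ---------------------------------------------
    from .index import compute_index

    scores_val = compute_index(model_internal, beta[val_ids])
    scores_all = compute_index(model_final, beta)
    y_val = labels[val_ids]
    auc, auc_ci = roc_auc_ci(scores_val.to_numpy(), (y_val == "case").to_numpy().astype(int))
    ref_scores = scores_val[y_val[y_val == "control"].index].to_numpy()
    quartiles = quartile_odds_table(scores_val.to_numpy(), (y_val == "case").to_numpy().astype(int), ref_scores)
    out.update(scores_validation=scores_val, scores_all=scores_all)
    summary = {
        "n_samples": int(beta.shape[1]),
        "n_cpgs_after_qc": int(beta.shape[0]),
        "optimal_n": int(optimal_n),
        "lambda": float(fit_opt["lambda_"]),
        "auc_validation": float(sweep_table["auc_validation"].max()),
        "auc_validation_ci": [float(auc_ci[0]), float(auc_ci[1])],
        "sweep": sweep_table.to_dict(orient="list"),
        "quartile_control_counts": quartiles.control_counts.tolist(),
        "quartile_case_counts": quartiles.case_counts.tolist(),
        "quartile_odds_ratios": [float(v) for v in quartiles.odds_ratios],
    }
    out["quartiles"] = quartiles

    # --- decompose -----------------------------------------------------
    if config.run_decompose:
        order = np.argsort(-np.abs(np.asarray(model_final.weights)), kind="stable")
        top = [model_final.cpgs[i] for i in order[: config.decompose_top]]
        dec = BetaMixtureDecomposer(ratio=config.variance_ratio).fit(beta.loc[top], ic)
        out["variance_fits"] = dec.fits_
        cls = dec.fits_["origin_class"].value_counts(normalize=True, dropna=True)
        summary["origin_class_fractions"] = {k: float(v) for k, v in cls.items()}

    # --- contaminate ---------------------------------------------------
    if config.run_contaminate:
        ctrl_val = [s for s in val_ids if labels[s] == "control" and ic[s] < config.contamination_ic_max]
        tumour_profile = ref_beta.loc[:, (ref_labels == "tumour").to_numpy()].mean(axis=1)
        curve, rho_star = contamination_shift_curve(
            model_final, beta[ctrl_val], tumour_profile.reindex(beta.index),
            config.rho_grid, target_shift_sd=config.target_shift_sd,
        )
        out["contamination_curve"] = curve
        summary["rho_star"] = None if rho_star is None else float(rho_star)
        summary["contamination_shift_at_1"] = float(curve["mean_shift_sd"].iloc[-1])

    out["summary"] = summary
    if outdir is not None:
        _write_run(Path(outdir), config, out)
    return out


def _write_run(outdir: Path, config: PipelineConfig, out: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    mio.write_beta_tsv(out["beta"], outdir / "beta_qc.tsv")
    mio.write_sheet_csv(out["sheet"], outdir / "sample_sheet.csv")
    mio.write_fractions_csv(out["fractions"], outdir / "fractions.csv")
    mio.write_panel_tsv(out["panel"], outdir / "reference_panel.tsv")
    mio.write_records_tsv(out["records"], outdir / "delta_beta.tsv")
    out["sweep_table"].to_csv(outdir / "sweep.csv", index=False)
    out["model_final"].to_json(outdir / "index_model.json")
    out["scores_all"].rename_axis("sample_id").to_csv(outdir / "index_scores.csv")
    mio.write_json(out["qc_report"].to_dict(), outdir / "qc_report.json")
    mio.write_json({"train": list(out["train_ids"]), "validation": list(out["val_ids"])},
                   outdir / "split.json")
    if "variance_fits" in out:
        mio.write_records_tsv(out["variance_fits"], outdir / "variance_fits.tsv")
    if "contamination_curve" in out:
        out["contamination_curve"].to_csv(outdir / "contamination_curve.csv", index=False)
    mio.write_json(out["summary"], outdir / "summary.json")

    manifest = {
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in _STAGES},
        "version": _version(),
        "files": {p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.name != "manifest.json"},
    }
    mio.write_json(manifest, outdir / "manifest.json")


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("methrisk")
    except Exception:  # pragma: no cover
        return "unknown"
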