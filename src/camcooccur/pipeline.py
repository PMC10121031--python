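"""End-to-end orchestration: records -> histories -> models -> overlap report.

The model set mirrors the staged strategy used in sparse two-species felid
studies: occupancy covariates are screened one at a time per species, the
best occupancy structure then carries detection-covariate candidates, and
finally co-occurrence (f12) covariates, the f12 = 0 independence null and
the all-constant null join the candidate set.  Covariate pairs flagged by
the Spearman collinearity screen are barred from co-occurring in one model.
All fitted models are ranked by AIC with Akaike weights.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity as act
from . import cooccurrence as co
from .detections import (
    DetectionData,
    SurveyDesign,
    build_detection_data,
    filter_independent_records,
    summarize_effort,
)

logger = logging.getLogger(__name__)

OCC_COVARIATES = ("tree_cover", "water_dist", "plantation_dist")
DET_COVARIATES = ("effort", "water_dist")


def build_model_set(
    data: DetectionData,
    occ_covariates=OCC_COVARIATES,
    det_covariates=DET_COVARIATES,
    barred: set | None = None,
    seed: int | None = None,
    n_starts: int = 3,
) -> tuple[list, pd.DataFrame]:
    """Fit the staged candidate set; returns (fitted models, skipped table)."""
    barred = barred or set()
    fitted: list[co.TwoSpeciesModel] = []
    skipped = []

    def try_fit(spec: co.ModelSpec):
        if any(m.spec.label == spec.label for m in fitted):
            return None
        if spec.violates(barred):
            skipped.append((spec.label, "collinear covariate pair barred"))
            logger.info("skipping %s: collinear covariates", spec.label)
            return None
        model = co.fit(spec, data, n_starts=n_starts, seed=seed)
        if not model.converged:
            skipped.append((spec.label, "did not converge"))
            return None
        fitted.append(model)
        return model

    def spec_of(f1, f2, f12, p1, p2, fix=False):
        s = co.ModelSpec("tmp", f1, f2, f12, fix, p1, p2)
        return co.ModelSpec(co.default_label(s), f1, f2, f12, fix, p1, p2)

    # stage 1: one occupancy covariate at a time per species
    occ_options = [()] + [(c,) for c in occ_covariates]
    stage1 = {}
    for o1, o2 in itertools.product(occ_options, occ_options):
        m = try_fit(spec_of(o1, o2, (), (), ()))
        if m is not None:
            stage1[(o1, o2)] = m.aic
    best_f1, best_f2 = min(stage1, key=stage1.get) if stage1 else ((), ())

    # stage 2: detection covariates on the best occupancy structure
    det_options = [()] + [(c,) for c in det_covariates]
    stage2 = {}
    for d1, d2 in itertools.product(det_options, det_options):
        if (d1, d2) == ((), ()):
            continue  # already fitted in stage 1
        m = try_fit(spec_of(best_f1, best_f2, (), d1, d2))
        if m is not None:
            stage2[(d1, d2)] = m.aic
    stage2[((), ())] = stage1.get((best_f1, best_f2), np.inf)
    best_p1, best_p2 = min(stage2, key=stage2.get)

    # stage 3: co-occurrence covariates, the independence null, the full null
    for c in occ_covariates:
        try_fit(spec_of(best_f1, best_f2, (c,), best_p1, best_p2))
    try_fit(spec_of(best_f1, best_f2, (), best_p1, best_p2, fix=True))
    try_fit(spec_of((), (), (), (), (), fix=True))

    skipped_df = pd.DataFrame(skipped, columns=["model", "reason"])
    return fitted, skipped_df


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    species_pair: tuple[str, str]
    design: SurveyDesign
    outdir: str
    seed: int = 0
    records: pd.DataFrame | None = None
    deployments: pd.DataFrame | None = None
    covariates: pd.DataFrame | None = None
    window_minutes: float = 60.0
    occ_covariates: tuple = OCC_COVARIATES
    det_covariates: tuple = DET_COVARIATES
    activity_pairs: list = field(default_factory=list)
    n_boot: int = 10000
    n_iter: int = 10000
    collinearity_threshold: float = 0.7
    n_starts: int = 3


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute detections -> co-occurrence -> activity and write the bundle.

    Returns a dict of the in-memory results; CSV/JSON outputs land in
    ``cfg.outdir``.  Any stage failure is re-raised naming the stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"seed": cfg.seed}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # pragma: no cover - error path
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return deco

    # -- detections ---------------------------------------------------------
    @stage("detections")
    def _detections():
        rec = filter_independent_records(cfg.records, cfg.window_minutes, cfg.deployments)
        trap_nights, effort_table = summarize_effort(rec, cfg.deployments)
        data = build_detection_data(rec, cfg.deployments, cfg.design, cfg.species_pair, None)
        return rec, trap_nights, effort_table, data

    rec, trap_nights, effort_table, data = _detections
    effort_table.to_csv(outdir / "effort_summary.csv", index=False)
    results.update(trap_nights=trap_nights, effort_table=effort_table, records=rec)

    # -- covariates ---------------------------------------------------------
    @stage("covariates")
    def _covariates():
        cov = co.standardize_covariates(
            cfg.covariates, columns=[c for c in cfg.occ_covariates if c in cfg.covariates.columns]
        )
        screen = co.screen_collinearity(cov, cfg.collinearity_threshold)
        return cov, screen, co.barred_pairs(screen)

    cov, screen, barred = _covariates
    screen.to_csv(outdir / "collinearity_screen.csv", index=False)
    data = build_detection_data(rec, cfg.deployments, cfg.design, cfg.species_pair, cov.data)
    results["screen"] = screen

    # -- co-occurrence ------------------------------------------------------
    @stage("cooccurrence")
    def _models():
        fitted, skipped = build_model_set(
            data,
            [c for c in cfg.occ_covariates if c in cov.data.columns],
            cfg.det_covariates,
            barred,
            seed=cfg.seed,
            n_starts=cfg.n_starts,
        )
        table = co.model_table(fitted)
        return fitted, skipped, table

    fitted, skipped, table = _models
    table.to_csv(outdir / "model_table.csv", index=False)
    skipped.to_csv(outdir / "models_skipped.csv", index=False)
    best = {m.spec.label: m for m in fitted}[table["model"].iloc[0]]
    best.coef_table().to_csv(outdir / "best_model_coefficients.csv", index=False)
    coef_json = {
        r.parameter: {
            "estimate": r.estimate,
            "se": r.se,
            "ci": [r.ci_lower, r.ci_upper],
            "important": bool(r.important),
        }
        for r in best.coef_table().itertuples()
    }
    (outdir / "best_model_coefficients.json").write_text(json.dumps(coef_json, indent=2))
    results.update(models=fitted, model_table=table, best_model=best, skipped=skipped)

    # -- occupancy prediction ----------------------------------------------
    @stage("prediction")
    def _predict():
        preds = co.predict_occupancy(best, data.site_covariates)
        curves = {}
        for c in set(best.spec.f1) | set(best.spec.f2) | set(best.spec.f12):
            grid = pd.DataFrame({c: np.linspace(-2, 2, 41)})
            for other in set(best.spec.covariates_used()) - {c, "effort"}:
                grid[other] = 0.0
            curve = co.predict_occupancy(best, grid)
            curve[f"{c}_original"] = cov.original(c, grid[c].to_numpy())
            curves[c] = curve
            curve.to_csv(outdir / f"occupancy_curve_{c}.csv", index=False)
        return preds, curves

    preds, curves = _predict
    preds.to_csv(outdir / "site_occupancy.csv", index=False)
    results.update(site_occupancy=preds, curves=curves)

    # -- activity overlap ---------------------------------------------------
    @stage("activity")
    def _activity():
        rows = []
        rng_seed = np.random.SeedSequence(cfg.seed).generate_state(1)[0] % (2**31)
        for i, (sp_a, sp_b) in enumerate(cfg.activity_pairs):
            s1 = act.CircularSample.from_records(rec, sp_a)
            s2 = act.CircularSample.from_records(rec, sp_b)
            ov = act.bootstrap_ci(s1, s2, n_boot=cfg.n_boot, seed=int(rng_seed + 3 * i))
            a1 = act.activity_level(s1, seed=int(rng_seed + 3 * i + 1))
            a2 = act.activity_level(s2, seed=int(rng_seed + 3 * i + 2))
            wald = act.wald_activity_test(a1, a2)
            rand = act.randomization_test(s1, s2, n_iter=cfg.n_iter, seed=int(rng_seed + 3 * i))
            rows.append(
                {
                    "pair": f"{sp_a}-{sp_b}",
                    "n1": s1.n,
                    "n2": s2.n,
                    "estimator": ov.estimator,
                    "delta_hat": round(ov.delta_hat, 2),
                    "ci_lower": round(ov.ci[0], 2),
                    "ci_upper": round(ov.ci[1], 2),
                    "wald_W": round(wald.statistic, 2),
                    "wald_P": round(wald.p_value, 2),
                    "null_mean": round(rand.null_summary, 2),
                    "randomization_P": round(rand.p_value, 4),
                }
            )
        return pd.DataFrame(rows)

    overlap_table = _activity
    overlap_table.to_csv(outdir / "overlap_table.csv", index=False)
    results["overlap_table"] = overlap_table

    log = {
        "seed": cfg.seed,
        "n_sites": data.n_sites,
        "trap_nights": trap_nights,
        "n_boot": cfg.n_boot,
        "n_iter": cfg.n_iter,
        "models_fitted": [m.spec.label for m in fitted],
        "models_converged": {m.spec.label: bool(m.converged) for m in fitted},
        "models_skipped": skipped.to_dict(orient="records"),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return results
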