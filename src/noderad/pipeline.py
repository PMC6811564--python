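"""End-to-end orchestration: synthesize/ingest -> preprocess -> extract ->
select -> fit -> evaluate -> stratify.

A run is fully described by one :class:`PipelineConfig` (loadable from
YAML) and a global seed; per-stage seeds are derived by hashing the stage
name so stages can be rerun independently yet reproducibly.  Outputs land
in a run directory: feature CSVs, selection-rate CSVs, model JSONs, an
evaluation report, Kaplan-Meier plots and a manifest recording the config
hash, seed and per-stage dimensions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import VolumeWithMasks, derive_seed
from .features import cohort_feature_matrix, feature_group
from .lnpt import LNPT_NAMES
from .manifest import DEFAULT_MANIFEST, FeatureManifest
from .modeling import (
    FittedModel,
    LassoConfig,
    ModelBuildError,
    StratificationError,
    bootstrap_resamples,
    build_cox_model,
    build_lc_rad_score,
    build_mixed_model,
    compare_models,
    evaluate,
    fit_stratification_threshold,
    stratify,
)
from .preprocess import PreprocessConfig, preprocess_patient
from .selection import SelectionConfig, bootstrap_mrmr
from .synthetic import GroundTruth, PhantomSpec, generate_cohort, simulate_outcomes

log = logging.getLogger(__name__)

N_STAGE_ORDINAL = {"N1": 1, "N2a": 2, "N2b": 3, "N2c": 4, "N3": 5}


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    images_dir: str | None = None
    masks_dir: str | None = None
    clinical_csv: str | None = None
    synth: PhantomSpec | None = None
    truth: GroundTruth | None = None
    train_fraction: float = 0.6
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    manifest: FeatureManifest = field(default_factory=lambda: DEFAULT_MANIFEST)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    lasso: LassoConfig = field(default_factory=LassoConfig)
    n_eval_boot: int = 100
    horizon: float = 18.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("out_dir", "images_dir", "masks_dir", "clinical_csv",
                    "train_fraction", "n_eval_boot", "horizon", "seed"):
            if key in d:
                kwargs[key] = d[key]
        if "synth" in d and d["synth"] is not None:
            s = dict(d["synth"])
            for tup in ("grid_shape", "spacing", "pt_radius_range",
                        "n_ln_range", "ln_radius_range"):
                if tup in s:
                    s[tup] = tuple(s[tup])
            kwargs["synth"] = PhantomSpec(**s)
        if "truth" in d and d["truth"] is not None:
            t = dict(d["truth"])
            for k in ("planted_lc", "planted_regional"):
                if k in t:
                    t[k] = tuple((str(n), float(b)) for n, b in t[k])
            kwargs["truth"] = GroundTruth(**t)
        for key, klass in (("preprocess", PreprocessConfig),
                           ("selection", SelectionConfig), ("lasso", LassoConfig)):
            if key in d and d[key] is not None:
                sub = dict(d[key])
                if key == "preprocess" and "hu_window" in sub:
                    sub["hu_window"] = tuple(sub["hu_window"])
                kwargs[key] = klass(**sub)
        return cls(**kwargs)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, (tuple, list, frozenset)):
                return [enc(x) for x in o]
            return o

        blob = json.dumps(enc(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_cohort(cfg: PipelineConfig) -> list[VolumeWithMasks]:
    """Read NIfTI images + PT/LN masks from the configured directories."""
    import nibabel as nib

    images = sorted(Path(cfg.images_dir).glob("*.nii*"))
    out = []
    for img_path in images:
        pid = img_path.name.split(".nii")[0]
        img = nib.load(img_path)
        spacing_xyz = img.header.get_zooms()[:3]
        data = np.asarray(img.dataobj).T  # disk (x, y, z) -> memory (z, y, x)
        masks = {}
        for roi in ("pt", "ln"):
            mp = Path(cfg.masks_dir) / f"{pid}_{roi}.nii.gz"
            if not mp.exists():
                mp = Path(cfg.masks_dir) / f"{pid}_{roi}.nii"
            masks[roi] = np.asarray(nib.load(mp).dataobj).T > 0.5
        out.append(
            VolumeWithMasks(
                patient_id=pid,
                image=data,
                spacing=tuple(float(s) for s in spacing_xyz[::-1]),
                pt_mask=masks["pt"],
                ln_mask=masks["ln"],
            )
        )
    return out


def validate_inputs(features: pd.DataFrame, clinical: pd.DataFrame) -> list[dict]:
    """Per-patient consistency report (no modelling is run).

    Checks that every patient with features has outcomes, that LC/LRC
    columns are complete, that N stages are known levels, and that the
    composite endpoint dominates the local one (an LRC failure can never
    come after the LC failure it contains).
    """
    problems = []
    for pid in features.index:
        if pid not in clinical.index:
            problems.append({"patient_id": pid, "problem": "no clinical record"})
    required = ("lc_time", "lc_event", "lrc_time", "lrc_event")
    for pid, row in clinical.iterrows():
        for col in required:
            if col not in clinical.columns or pd.isna(row.get(col)):
                problems.append({"patient_id": pid, "problem": f"missing {col}"})
        if "n_stage" in clinical.columns and row.get("n_stage") not in N_STAGE_ORDINAL:
            problems.append(
                {"patient_id": pid, "problem": f"unknown N stage {row.get('n_stage')!r}"}
            )
        if all(c in clinical.columns for c in required):
            if bool(row["lc_event"]) and (
                not bool(row["lrc_event"]) or row["lrc_time"] > row["lc_time"] + 1e-9
            ):
                problems.append(
                    {"patient_id": pid,
                     "problem": "inconsistent composite endpoint (LC failure "
                                "without dominating LRC failure)"}
                )
    return problems


def _prepare_cohort(cfg: PipelineConfig):
    """Stage 1-2: obtain volumes, preprocess, extract, attach outcomes."""
    if cfg.synth is not None:
        spec = dataclasses.replace(cfg.synth, seed=derive_seed(cfg.seed, "synth"))
        cohort = generate_cohort(spec)
    else:
        cohort = load_cohort(cfg)
    prepared = []
    for v in cohort:
        try:
            p = preprocess_patient(v, cfg.preprocess)
        except Exception as exc:
            raise RuntimeError(f"preprocessing failed for {v.patient_id}: {exc}") from exc
        if p.eligible:
            prepared.append(p)
        else:
            log.info("%s excluded: artifact volume above the eligibility limit",
                     v.patient_id)
    features = cohort_feature_matrix(prepared, cfg.manifest)
    if cfg.synth is not None:
        truth = cfg.truth or GroundTruth()
        clinical = simulate_outcomes(features, truth, derive_seed(cfg.seed, "outcomes"))
        n_train = int(round(cfg.train_fraction * len(clinical)))
        clinical["cohort"] = ["training"] * n_train + ["validation"] * (
            len(clinical) - n_train
        )
    else:
        clinical = pd.read_csv(cfg.clinical_csv, index_col="patient_id")
        clinical = clinical.loc[features.index]
    return features, clinical


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full workflow; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "models").mkdir(exist_ok=True)

    features, clinical = _prepare_cohort(cfg)
    features.to_csv(out / "features.csv")
    clinical.to_csv(out / "clinical.csv")
    problems = validate_inputs(features, clinical)
    if problems:
        raise RuntimeError(f"input validation failed: {problems[:3]}")

    is_train = clinical["cohort"] == "training"
    Xtr, Xva = features[is_train], features[~is_train]
    ytr, yva = clinical[is_train], clinical[~is_train]

    # --- preselection, separately per feature group and endpoint ---------
    sel_seed = derive_seed(cfg.seed, "mrmr")
    sel_cfg = dataclasses.replace(cfg.selection, rng_seed=sel_seed)
    selections = {}
    tasks = [
        ("PT", "LC"), ("PT", "LRC"), ("LN", "LRC"), ("LNPT", "LRC"),
    ]
    for group, endpoint in tasks:
        Xg = feature_group(Xtr, group)
        Xg = Xg.loc[:, Xg.std(ddof=0) > 0]
        t = ytr[f"{endpoint.lower()}_time"].to_numpy()
        e = ytr[f"{endpoint.lower()}_event"].to_numpy()
        selections[(group, endpoint)] = bootstrap_mrmr(
            Xg, t, e, sel_cfg, group=group
        )
    pd.concat(
        [s.to_frame().assign(endpoint=ep) for (g, ep), s in selections.items()]
    ).to_csv(out / "selection_rates.csv")

    # --- model building --------------------------------------------------
    lasso_cfg = dataclasses.replace(cfg.lasso, rng_seed=derive_seed(cfg.seed, "lasso"))
    t_lc, e_lc = ytr["lc_time"].to_numpy(), ytr["lc_event"].to_numpy()
    t_lrc, e_lrc = ytr["lrc_time"].to_numpy(), ytr["lrc_event"].to_numpy()

    models: dict[str, FittedModel] = {}
    failures: dict[str, str] = {}

    def attempt(name, fn):
        try:
            m = fn()
            models[name] = m
            if not m.successful:
                failures[name] = "reduced to the forced covariate"
        except ModelBuildError as exc:
            failures[name] = str(exc)
            log.warning("model %s unsuccessful: %s", name, exc)

    sel_pt_lc = selections[("PT", "LC")].selected
    attempt("lc_model", lambda: build_lc_rad_score(
        Xtr[sel_pt_lc], t_lc, e_lc, lasso_cfg))

    sel_pt_lrc = selections[("PT", "LRC")].selected
    attempt("pt_model", lambda: build_cox_model(
        Xtr[sel_pt_lrc], t_lrc, e_lrc, lasso_cfg, endpoint="LRC"))

    sel_ln = selections[("LN", "LRC")].selected
    attempt("ln_model", lambda: build_cox_model(
        Xtr[sel_ln], t_lrc, e_lrc, lasso_cfg, endpoint="LRC"))

    if "lc_model" in models:
        rad_tr = models["lc_model"].rad_score(Xtr)
        attempt("mixed_model", lambda: build_mixed_model(
            rad_tr, Xtr[sel_ln], t_lrc, e_lrc, lasso_cfg))
        sel_lnpt = selections[("LNPT", "LRC")].selected
        attempt("lnpt_mixed_model", lambda: build_mixed_model(
            rad_tr, Xtr[sel_lnpt], t_lrc, e_lrc, lasso_cfg))
        if "n_stage" in clinical.columns:
            n_ord = ytr["n_stage"].map(N_STAGE_ORDINAL).to_numpy(float)
            attempt("nstage_model", lambda: build_mixed_model(
                rad_tr, pd.DataFrame({"n_stage": n_ord}, index=Xtr.index),
                t_lrc, e_lrc, lasso_cfg))

    for name, m in models.items():
        m.to_json(out / "models" / f"{name}.json")

    # --- validation ------------------------------------------------------
    # Mixed models that carry only their forced covariate score exactly like
    # the LC model; they are reported as unsuccessful and not evaluated.
    eval_seed = derive_seed(cfg.seed, "evaluate")
    tv_lrc = yva["lrc_time"].to_numpy()
    ev_lrc = yva["lrc_event"].to_numpy()
    resamples = bootstrap_resamples(len(Xva), cfg.n_eval_boot, tv_lrc, ev_lrc, eval_seed)
    report: dict = {"models": {}, "failures": failures,
                    "comparisons": {}, "stratification": {}}
    evaluable = {
        n: m for n, m in models.items() if m.endpoint == "LRC" and m.successful
    }
    dists = {}
    for name, m in evaluable.items():
        # mixed models need the rad-score column materialised for validation
        Xv = Xva.copy()
        if "lc_rad_score" in m.features:
            Xv["lc_rad_score"] = models["lc_model"].rad_score(Xva)
        if "n_stage" in m.features:
            Xv["n_stage"] = yva["n_stage"].map(N_STAGE_ORDINAL).to_numpy(float)
        res = evaluate(m, Xv, tv_lrc, ev_lrc, resamples=resamples)
        dists[name] = res["cindex"]
        report["models"][name] = {
            "features": m.features,
            "coefficients": dict(zip(m.features, m.coefficients.tolist())),
            "train_cindex": m.train_cindex,
            "validation_cindex_mean": res["mean"],
            "validation_cindex_ci": res["ci"],
        }
        # risk stratification: threshold frozen on training
        Xt = Xtr.copy()
        if "lc_rad_score" in m.features:
            Xt["lc_rad_score"] = models["lc_model"].rad_score(Xtr)
        if "n_stage" in m.features:
            Xt["n_stage"] = ytr["n_stage"].map(N_STAGE_ORDINAL).to_numpy(float)
        try:
            thr = fit_stratification_threshold(
                m.rad_score(Xt), t_lrc, e_lrc, cfg.horizon)
            strat = stratify(m, Xv, tv_lrc, ev_lrc, cfg.horizon, threshold=thr)
            report["stratification"][name] = {
                "threshold": strat["threshold"],
                "logrank_p": strat["logrank_p"],
                "n_high": strat["n_high"],
                "n_low": strat["n_low"],
            }
            _km_plot(out / f"km_{name}.png", m.rad_score(Xv) > thr,
                     tv_lrc, ev_lrc, name)
        except StratificationError as exc:
            report["stratification"][name] = {"failed": str(exc)}
            log.warning("stratification failed for %s: %s", name, exc)

    for a, b in (("mixed_model", "pt_model"), ("mixed_model", "ln_model")):
        if a in dists and b in dists:
            report["comparisons"][f"{a}_vs_{b}"] = compare_models(dists[a], dists[b])

    with open(out / "evaluation.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_patients": int(len(features)),
        "n_train": int(is_train.sum()),
        "n_validation": int((~is_train).sum()),
        "n_features": int(features.shape[1]),
        "n_lnpt_features": len(LNPT_NAMES),
        "models_built": sorted(models),
        "models_failed": failures,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def _km_plot(path, high_risk, time, event, title):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    fig, ax = plt.subplots(figsize=(5, 4))
    for mask, label in ((~high_risk, "low risk"), (high_risk, "high risk")):
        if mask.any():
            KaplanMeierFitter().fit(
                time[mask], event[mask], label=label
            ).plot_survival_function(ax=ax)
    ax.set_xlabel("months")
    ax.set_ylabel("loco-regional control")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
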