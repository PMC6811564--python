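"""Bootstrap LASSO-Cox model building, validation and risk stratification.

Model building repeats an L1-penalised Cox fit on bootstrap resamples of
the training cohort (default 100), choosing the penalty on each resample by
5-fold cross-validated partial likelihood; features with a non-zero
coefficient in at least 60% of resamples form the final set, which is then
refit as an ordinary (unpenalised) multivariate Cox model.  The model's
linear predictor is its "rad score".

A local-control (LC) rad score is built from primary-tumour features, and
the mixed model feeds that score together with lymph-node features into the
same procedure against the loco-regional endpoint.  Validation uses
Harrell's c-index on bootstrap resamples of the validation cohort (default
100, shared across models so distributions are paired), a paired two-sided
Wilcoxon signed-rank test between models, and Kaplan-Meier risk groups cut
at the training-cohort threshold maximising Youden's J for failure by 18
months.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy.stats import rankdata, wilcoxon
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._survstats import cox_partial_loglik, harrell_cindex

log = logging.getLogger(__name__)


class ModelBuildError(RuntimeError):
    """Raised when the LASSO stage discards every candidate feature."""


class StratificationError(RuntimeError):
    """Raised when a risk-group split leaves one group empty."""


@dataclass(frozen=True)
class LassoConfig:
    n_bootstrap: int = 100
    cv_folds: int = 5
    selection_rate_threshold: float = 0.60
    lambda_rule: str = "min"          # or "1se"
    n_alphas: int = 30
    rng_seed: int = 0

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not (0 < self.selection_rate_threshold <= 1):
            raise ValueError("selection_rate_threshold must be in (0, 1]")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")


@dataclass
class FittedModel:
    """An unpenalised multivariate Cox model over a selected feature set.

    Stores the frozen training standardisation so the rad score can be
    applied to validation data without touching validation statistics.
    """

    endpoint: str                      # "LC" or "LRC"
    features: list[str]
    coefficients: np.ndarray           # log hazard ratios, per z-scored unit
    mean: np.ndarray
    scale: np.ndarray
    train_cindex: float = 0.5
    selection_rates: dict[str, float] = field(default_factory=dict)
    threshold: float | None = None
    successful: bool = True

    def rad_score(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.features].to_numpy(dtype=float) - self.mean) / self.scale
        return Z @ self.coefficients

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "endpoint": self.endpoint,
                    "features": self.features,
                    "coefficients": self.coefficients.tolist(),
                    "mean": self.mean.tolist(),
                    "scale": self.scale.tolist(),
                    "train_cindex": self.train_cindex,
                    "selection_rates": self.selection_rates,
                    "threshold": self.threshold,
                    "successful": self.successful,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            endpoint=d["endpoint"],
            features=d["features"],
            coefficients=np.asarray(d["coefficients"]),
            mean=np.asarray(d["mean"]),
            scale=np.asarray(d["scale"]),
            train_cindex=d["train_cindex"],
            selection_rates=d["selection_rates"],
            threshold=d["threshold"],
            successful=d["successful"],
        )


def _standardize_fit(X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean().to_numpy()
    scale = X.std(ddof=0).to_numpy()
    scale[scale == 0] = 1.0
    return mean, scale


def _drop_duplicate_columns(X: pd.DataFrame) -> pd.DataFrame:
    """Drop candidates rank-identical (|Spearman rho| = 1) to an earlier one."""
    keep: list[str] = []
    ranks = {}
    for c in X.columns:
        r = rankdata(X[c].to_numpy())
        dup = None
        for k in keep:
            rho = np.corrcoef(r, ranks[k])[0, 1]
            if np.isclose(abs(rho), 1.0):
                dup = k
                break
        if dup is None:
            keep.append(c)
            ranks[c] = r
        else:
            log.info("dropping %s: perfectly rank-correlated with %s", c, dup)
    return X[keep]


def _cv_alpha(
    Z: np.ndarray, time: np.ndarray, event: np.ndarray, cfg: LassoConfig, seed: int
) -> tuple[float, np.ndarray, np.ndarray]:
    """Pick the L1 penalty by K-fold cross-validated partial likelihood."""
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=cfg.n_alphas, alpha_min_ratio=0.05, normalize=False
    )
    path.fit(Z, y)
    alphas = np.asarray(path.alphas_)
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=seed % (2**31 - 1))
    scores = np.zeros((cfg.cv_folds, len(alphas)))
    for f, (tr, te) in enumerate(kf.split(Z)):
        if event[tr].sum() == 0 or event[te].sum() == 0:
            scores[f] = np.nan
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, normalize=False)
        with warnings.catch_warnings():
            # fully-shrunk path ends are expected while scanning the grid
            warnings.simplefilter("ignore")
            m.fit(Z[tr], y[tr])
        fitted = np.asarray(m.alphas_)
        coefs = np.asarray(m.coef_)
        for a_i, alpha in enumerate(alphas):
            j = np.argmin(np.abs(fitted - alpha))
            lp = Z[te] @ coefs[:, j]
            scores[f, a_i] = cox_partial_loglik(lp, time[te], event[te])
    mean = np.nanmean(scores, axis=0)
    if np.all(np.isnan(mean)):
        raise ArithmeticError("cross-validation failed on every fold")
    best = int(np.nanargmax(mean))
    if cfg.lambda_rule == "1se":
        se = np.nanstd(scores, axis=0) / np.sqrt(cfg.cv_folds)
        ok = mean >= mean[best] - se[best]
        best = int(np.flatnonzero(ok)[0])  # alphas are sorted descending
    coef = np.asarray(path.coef_)[:, best]
    return float(alphas[best]), coef, alphas


def bootstrap_lasso_cox(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    cfg: LassoConfig = LassoConfig(),
) -> tuple[pd.Series, list[str]]:
    """Bootstrap selection rates of an L1 Cox fit and the >= 60% final set.

    ``X`` should already be restricted to the MRMR-selected candidates
    (plus any forced covariates such as the LC rad score).  Returns the
    per-feature selection rates and the surviving set; raises
    ``ModelBuildError`` if nothing reaches the threshold.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    if X.shape[1] == 0:
        raise ModelBuildError("empty candidate feature set (nothing preselected)")
    X = _drop_duplicate_columns(X)
    mean, scale = _standardize_fit(X)
    Zfull = (X.to_numpy(dtype=float) - mean) / scale
    n = len(X)
    rng = np.random.default_rng(cfg.rng_seed)
    counts = pd.Series(0.0, index=X.columns)
    done = failures = 0
    while done < cfg.n_bootstrap:
        idx = rng.integers(0, n, size=n)
        if event[idx].sum() < 2:
            continue
        try:
            _, coef, _ = _cv_alpha(
                Zfull[idx], time[idx], event[idx], cfg, seed=int(rng.integers(2**31 - 1))
            )
        except (ArithmeticError, ValueError) as exc:
            failures += 1
            log.debug("resample refit failed (%s); redrawn", exc)
            if failures > 5 * cfg.n_bootstrap:
                raise ModelBuildError("bootstrap LASSO failed on most resamples")
            continue
        counts[np.abs(coef) > 1e-10] += 1.0
        done += 1
    rates = counts / cfg.n_bootstrap
    final = sorted(rates.index[rates >= cfg.selection_rate_threshold],
                   key=lambda f: (-rates[f], f))
    if not final:
        raise ModelBuildError(
            "no feature reached the selection-rate threshold; model training unsuccessful"
        )
    return rates, list(final)


def _refit_cox(
    Z: pd.DataFrame, time: np.ndarray, event: np.ndarray
) -> np.ndarray:
    df = Z.copy()
    df["__time"] = time
    df["__event"] = event.astype(int)
    cph = CoxPHFitter(penalizer=0.0)
    try:
        cph.fit(df, duration_col="__time", event_col="__event")
    except ConvergenceError:
        log.warning("unpenalised Cox refit did not converge; ridge 0.1 applied")
        cph = CoxPHFitter(penalizer=0.1, l1_ratio=0.0)
        cph.fit(df, duration_col="__time", event_col="__event")
    return cph.params_[Z.columns].to_numpy()


def build_cox_model(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    cfg: LassoConfig = LassoConfig(),
    endpoint: str = "LRC",
    required_beyond: str | None = None,
) -> FittedModel:
    """Full model-building stage: bootstrap LASSO selection + Cox refit.

    ``required_beyond`` names a forced covariate (e.g. the LC rad score);
    if the final set contains nothing besides it, the model is flagged
    unsuccessful (it adds no information beyond the forced input).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    rates, final = bootstrap_lasso_cox(X, time, event, cfg)
    Xf = X[final]
    mean, scale = _standardize_fit(Xf)
    Z = (Xf - mean) / scale
    coef = _refit_cox(Z, time, event)
    model = FittedModel(
        endpoint=endpoint,
        features=list(final),
        coefficients=coef,
        mean=mean,
        scale=scale,
        selection_rates={f: float(rates[f]) for f in rates.index},
    )
    model.train_cindex = harrell_cindex(model.rad_score(X), time, event)
    if required_beyond is not None and final == [required_beyond]:
        model.successful = False
        log.warning("model training unsuccessful: only %s survived the LASSO "
                    "selection", required_beyond)
    return model


def build_lc_rad_score(
    X_pt: pd.DataFrame,
    lc_time: np.ndarray,
    lc_event: np.ndarray,
    cfg: LassoConfig = LassoConfig(),
) -> FittedModel:
    """Local-control model on preselected PT features; its linear predictor
    is the LC rad score used as a covariate by the mixed models."""
    return build_cox_model(X_pt, lc_time, lc_event, cfg, endpoint="LC")


def build_mixed_model(
    rad_score: np.ndarray,
    X_other: pd.DataFrame,
    lrc_time: np.ndarray,
    lrc_event: np.ndarray,
    cfg: LassoConfig = LassoConfig(),
    score_name: str = "lc_rad_score",
) -> FittedModel:
    """Loco-regional model combining the LC rad score with other features.

    The rad score enters the LASSO as an ordinary candidate covariate.
    The returned model is flagged unsuccessful when nothing but the rad
    score survives selection.
    """
    X = X_other.copy()
    X.insert(0, score_name, np.asarray(rad_score, float))
    return build_cox_model(
        X, lrc_time, lrc_event, cfg, endpoint="LRC", required_beyond=score_name
    )


def bootstrap_resamples(n: int, n_boot: int, time, event, seed: int) -> np.ndarray:
    """Shared validation resamples: each row has >= 1 comparable pair.

    The redraw rule depends only on follow-up times and events, never on
    any model's score, so the same resamples can be reused to pair c-index
    distributions across models.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    rng = np.random.default_rng(seed)
    rows = []
    while len(rows) < n_boot:
        idx = rng.integers(0, n, size=n)
        comparable = (time[idx][:, None] < time[idx][None, :]) & event[idx][:, None]
        if not comparable.any():
            log.debug("validation resample without comparable pairs redrawn")
            continue
        rows.append(idx)
    return np.asarray(rows)


def evaluate(
    model: FittedModel,
    X_val: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    n_boot: int = 100,
    seed: int = 0,
    resamples: np.ndarray | None = None,
) -> dict:
    """Bootstrap c-index distribution of the rad score on a validation set.

    Pass the same ``resamples`` (or the same seed) for every model under
    comparison so the distributions are paired.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    if resamples is None:
        resamples = bootstrap_resamples(len(X_val), n_boot, time, event, seed)
    score = model.rad_score(X_val)
    cis = np.array(
        [harrell_cindex(score[idx], time[idx], event[idx]) for idx in resamples]
    )
    return {
        "cindex": cis,
        "mean": float(cis.mean()),
        "ci": (float(np.percentile(cis, 2.5)), float(np.percentile(cis, 97.5))),
    }


def compare_models(a: np.ndarray, b: np.ndarray) -> float:
    """Paired two-sided Wilcoxon signed-rank p-value on c-index values."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired distributions must have equal length")
    if np.allclose(a, b):
        log.info("identical c-index distributions; p-value 1 by convention")
        return 1.0
    return float(wilcoxon(a, b, alternative="two-sided").pvalue)


def fit_stratification_threshold(
    score: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float = 18.0,
    censored_as_controls: bool = False,
) -> float:
    """Training-cohort score cut maximising Youden's J at the horizon.

    Patients with an event by ``horizon`` months are cases; patients
    followed event-free beyond it are controls; patients censored
    event-free before the horizon are excluded (landmark treatment) unless
    ``censored_as_controls``.
    """
    score = np.asarray(score, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    case = event & (time <= horizon)
    ctrl = time >= horizon if not censored_as_controls else ~case
    use = case | ctrl
    if case.sum() == 0 or ctrl.sum() == 0:
        raise StratificationError("no cases or no controls at the horizon")
    s, y = score[use], case[use]
    cuts = np.unique(s)
    cuts = (cuts[:-1] + cuts[1:]) / 2 if len(cuts) > 1 else cuts
    best_j, best_c = -np.inf, float(np.median(s))
    for c in cuts:
        sens = (y & (s > c)).sum() / y.sum()
        spec = (~y & (s <= c)).sum() / (~y).sum()
        j = sens + spec - 1
        if j > best_j:
            best_j, best_c = j, float(c)
    return best_c


def stratify(
    model: FittedModel,
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float = 18.0,
    threshold: float | None = None,
) -> dict:
    """Split a cohort into risk groups and test separation by log-rank.

    If ``threshold`` is None it is fitted on this cohort (training use);
    pass the frozen training threshold for validation.  Raises
    ``StratificationError`` if a group is empty.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    score = model.rad_score(X)
    if threshold is None:
        threshold = fit_stratification_threshold(score, time, event, horizon)
    high = score > threshold
    if high.all() or not high.any():
        raise StratificationError(
            "threshold fails to stratify: one risk group is empty"
        )
    lr = logrank_test(time[high], time[~high], event[high], event[~high])
    return {
        "threshold": float(threshold),
        "high_risk": high,
        "logrank_p": float(lr.p_value),
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
    }
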