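"""Bootstrap MRMR feature preselection for survival endpoints.

The preselection stage sizes the per-run feature count k by principal-
component analysis (smallest number of components explaining 95% of the
variance of the standardised training matrix), then repeats maximum-
relevance-minimum-redundancy selection on bootstrap resamples of the
training cohort.  Features chosen in at least 60% of resamples survive.

MRMR uses the difference scheme: the next feature maximises
relevance(f) - mean_{s in S} |Spearman rho(f, s)|, where relevance is the
distance of the feature's univariate Harrell c-index from 0.5 (a Cox model
with a single covariate ranks patients exactly by that covariate, so the
index can be computed directly from the feature).  Selection runs
separately per feature group (PT, LN, LNPT); no cross-group redundancy is
ever computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from ._survstats import columnwise_cindex

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    n_bootstrap: int = 1000
    selection_rate_threshold: float = 0.60
    variance_explained: float = 0.95
    relevance_metric: str = "cindex"
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.selection_rate_threshold <= 1):
            raise ValueError("selection_rate_threshold must be in (0, 1]")
        if not (0 < self.variance_explained < 1):
            raise ValueError("variance_explained must be in (0, 1)")
        if self.relevance_metric != "cindex":
            raise ValueError("only the 'cindex' relevance metric is implemented")


@dataclass
class SelectionResult:
    group: str
    k: int
    rates: pd.Series           # feature -> selection rate in [0, 1]
    selected: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "rate": self.rates,
                "selected": [f in set(self.selected) for f in self.rates.index],
            }
        )


class Standardizer:
    """Z-score transform frozen on the training cohort."""

    def __init__(self):
        self.mean_: pd.Series | None = None
        self.scale_: pd.Series | None = None

    def fit(self, X: pd.DataFrame) -> "Standardizer":
        self.mean_ = X.mean()
        scale = X.std(ddof=0)
        self.scale_ = scale.replace(0.0, 1.0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X[self.mean_.index] - self.mean_) / self.scale_

    def fit_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).transform(X)


def pca_feature_count(X: pd.DataFrame, cfg: SelectionConfig = SelectionConfig()) -> int:
    """Smallest k whose principal components explain >= 95% of variance.

    Features are z-scored first; constant columns are dropped with a log
    entry (they carry no variance and would break standardisation).
    """
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA sizing needs at least 2 samples and 2 features")
    const = X.columns[X.std(ddof=0) == 0]
    if len(const):
        log.info("dropping %d constant feature(s) before PCA: %s",
                 len(const), list(const[:5]))
        X = X.drop(columns=const)
    Z = Standardizer().fit_transform(X)
    pca = PCA().fit(Z.to_numpy())
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, cfg.variance_explained) + 1)
    return min(k, X.shape[1])


def mrmr_rank(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    k: int,
    relevance: np.ndarray | None = None,
) -> list[str]:
    """Greedy MRMR ranking of k features (deterministic).

    Ties in the greedy score are broken by lexicographic feature name,
    which is logged at debug level.
    """
    cols = list(X.columns)
    if k > len(cols):
        raise ValueError("k cannot exceed the number of features")
    Xv = X.to_numpy(dtype=float)
    if relevance is None:
        relevance = np.abs(columnwise_cindex(Xv, time, event) - 0.5)
    ranks = np.apply_along_axis(rankdata, 0, Xv)
    with np.errstate(invalid="ignore"):
        rho = np.abs(np.corrcoef(ranks, rowvar=False))
    rho = np.nan_to_num(rho, nan=0.0)

    chosen: list[int] = []
    remaining = set(range(len(cols)))
    while len(chosen) < k:
        if chosen:
            red = rho[np.ix_(sorted(remaining), chosen)].mean(axis=1)
            cand = np.array(sorted(remaining))
            scores = relevance[cand] - red
        else:
            cand = np.array(sorted(remaining))
            scores = relevance[cand]
        best = scores.max()
        tied = cand[np.isclose(scores, best, rtol=0, atol=1e-12)]
        if len(tied) > 1:
            tied = sorted(tied, key=lambda idx: cols[idx])
            log.debug("MRMR tie broken lexicographically: %s", cols[tied[0]])
        pick = int(tied[0])
        chosen.append(pick)
        remaining.discard(pick)
    return [cols[i] for i in chosen]


def bootstrap_mrmr(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    cfg: SelectionConfig = SelectionConfig(),
    k: int | None = None,
    group: str = "PT",
) -> SelectionResult:
    """Bootstrap-stabilised MRMR with the 60% selection-rate rule.

    k defaults to the PCA 95%-variance count computed on the full training
    matrix.  Each resample draws n patients with replacement; resamples
    without any event are redrawn (and logged).  Reproducible from
    ``cfg.rng_seed``.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    if k is None:
        k = pca_feature_count(X, cfg)
    rng = np.random.default_rng(cfg.rng_seed)
    n = len(X)
    counts = pd.Series(0.0, index=X.columns)
    done = 0
    while done < cfg.n_bootstrap:
        idx = rng.integers(0, n, size=n)
        if event[idx].sum() == 0:
            log.debug("bootstrap resample without events redrawn")
            continue
        top = mrmr_rank(X.iloc[idx], time[idx], event[idx], k)
        counts[top] += 1.0
        done += 1
    rates = counts / cfg.n_bootstrap
    selected = sorted(
        rates.index[rates >= cfg.selection_rate_threshold],
        key=lambda f: (-rates[f], f),
    )
    log.info("group %s: k=%d, %d/%d features selected (threshold %.2f)",
             group, k, len(selected), X.shape[1], cfg.selection_rate_threshold)
    return SelectionResult(group=group, k=k, rates=rates, selected=list(selected))
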