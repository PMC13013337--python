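"""Cross-series correlation diagnostics and shared-covariate augmentation.

Day-to-day *changes* in the group census series are often correlated —
residents reclassified from one acuity group to another show up as paired
opposite-sign moves, common admission waves as same-sign moves.  The "_S"
model variants exploit this: groups are clustered on the correlation of
their first differences, and each series' regression vector is augmented
with a lagged, standardized summary of the other members of its cluster,
whose time-varying effect is learned online like any other state entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .state import RegressionVector

__all__ = [
    "SharedInfoConfig",
    "change_correlation_matrix",
    "cluster_groups",
    "augment_regression",
    "shared_covariate",
]


@dataclass(frozen=True)
class SharedInfoConfig:
    """Partition of series labels into correlated clusters.

    ``lag`` is how many days back the shared covariate looks (default 1, so
    only attained data enters the information set); ``standardize`` rescales
    the covariate by its own running history.
    """

    clusters: tuple[tuple[str, ...], ...]
    lag: int = 1
    standardize: bool = True

    def __post_init__(self) -> None:
        clusters = tuple(tuple(c) for c in self.clusters)
        labels = [lab for c in clusters for lab in c]
        if len(labels) != len(set(labels)):
            raise ValueError("clusters must not overlap")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        object.__setattr__(self, "clusters", clusters)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for c in self.clusters for lab in c)

    def cluster_of(self, label: str) -> tuple[str, ...]:
        for c in self.clusters:
            if label in c:
                return c
        raise KeyError(f"label {label!r} not covered by the cluster partition")

    def partners_of(self, label: str) -> tuple[str, ...]:
        return tuple(lab for lab in self.cluster_of(label) if lab != label)


def change_correlation_matrix(series: dict[str, np.ndarray] | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of first differences across aligned series.

    Constant series (zero-variance differences) get correlation 0 off the
    diagonal, with a warning.
    """
    df = pd.DataFrame(dict(series)) if not isinstance(series, pd.DataFrame) else series
    if df.shape[1] < 2:
        raise ValueError("need at least two series")
    diffs = df.astype(float).diff().iloc[1:]
    sd = diffs.std(ddof=1)
    constant = sd[sd == 0.0].index.tolist()
    if constant:
        warnings.warn(
            f"constant series {constant}: correlations set to 0", stacklevel=2
        )
    corr = diffs.corr()
    for lab in constant:
        corr.loc[lab, :] = 0.0
        corr.loc[:, lab] = 0.0
    np.fill_diagonal(corr.values, 1.0)
    return corr


def cluster_groups(corr: pd.DataFrame, threshold: float = 0.5) -> SharedInfoConfig:
    """Average-linkage hierarchical clustering on distance 1 - rho.

    The dendrogram is cut at distance 1 - threshold: pairs more correlated
    than ``threshold`` tend to share a cluster.  Deterministic given input.
    """
    labels = list(corr.columns)
    dist = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    if len(labels) == 1:
        return SharedInfoConfig(((labels[0],),))
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    cut = 1.0 - threshold
    if cut < 0.0:
        assignments = np.arange(1, len(labels) + 1)  # threshold > 1: singletons
    else:
        assignments = hierarchy.fcluster(Z, t=cut, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for lab, k in zip(labels, assignments):
        clusters.setdefault(int(k), []).append(lab)
    ordered = tuple(tuple(clusters[k]) for k in sorted(clusters))
    return SharedInfoConfig(ordered)


def shared_covariate(
    own_label: str, cfg: SharedInfoConfig, history: pd.DataFrame
) -> float:
    """Value of the shared covariate for ``own_label`` at the next day.

    The covariate is the lagged sum of the other cluster members' values:
    forecasting day t it reads their observations at t - lag, i.e. the last
    attained row of ``history`` when lag=1.  With ``standardize`` on, the
    value is centred and scaled by the running mean/sd of that summed series
    over the attained history (sd floor 1 while fewer than 2 days or sd 0).
    """
    partners = cfg.partners_of(own_label)
    if not partners:
        return 0.0
    summed = history[list(partners)].sum(axis=1).to_numpy(dtype=float)
    if summed.size < cfg.lag:
        return 0.0
    value = summed[summed.size - cfg.lag]
    if not cfg.standardize:
        return float(value)
    past = summed[: summed.size - cfg.lag + 1]
    centre = past.mean()
    scale = past.std(ddof=1) if past.size >= 2 else 0.0
    if not scale > 0.0:
        scale = 1.0
    return float((value - centre) / scale)


def augment_regression(
    base_F: RegressionVector,
    own_label: str,
    cfg: SharedInfoConfig,
    history: pd.DataFrame,
) -> RegressionVector:
    """Append the shared covariate to a base regression vector.

    Singleton clusters return ``base_F`` unchanged (no partners, no extra
    state).  The intercept entry is never touched.  The paired latent-state
    block must have been created one entry larger (diffuse prior on the
    shared effect) — see the models' ``n_extra`` initialization argument.
    """
    partners = cfg.partners_of(own_label)
    if not partners:
        return base_F
    value = shared_covariate(own_label, cfg, history)
    return RegressionVector(
        np.r_[base_F.values, value],
        base_F.names + (f"shared({'+'.join(partners)})",),
    )
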