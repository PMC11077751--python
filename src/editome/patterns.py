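"""Temporal pattern discovery over editing-level trajectories.

Site trajectories (EL per time point) are row-standardised, the fuzzifier m
is set by the empirical formula of Schwämmle & Jensen (2010) from the
matrix dimensions, and soft clusters are found with fuzzy c-means at c = 6.
Clusters are renumbered by the time point at which their centre peaks, so
cluster 1 always peaks earliest in development.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def standardize_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score; rows with missing values or zero variance dropped."""
    complete = profiles.dropna(axis=0)
    n_dropped = len(profiles) - len(complete)
    if n_dropped:
        logger.info("standardize_profiles: %d incomplete rows dropped", n_dropped)
    sd = complete.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        logger.info("standardize_profiles: %d zero-variance rows dropped",
                    int(flat.sum()))
    complete = complete.loc[~flat]
    if complete.empty:
        raise ValueError("no clusterable profiles after standardization")
    mean = complete.mean(axis=1)
    sd = complete.std(axis=1, ddof=0)
    return complete.sub(mean, axis=0).div(sd, axis=0)


def estimate_fuzzifier(n_rows: int, n_cols: int) -> float:
    """Empirical fuzzifier m(N, D) of Schwämmle & Jensen (2010).

    m = 1 + (1418/N + 22.05) D^-2
          + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("matrix dimensions must be positive")
    N, D = float(n_rows), float(n_cols)
    m = (
        1.0
        + (1418.0 / N + 22.05) * D ** -2.0
        + (12.33 / N + 0.243) * D ** (-0.0406 * np.log(N) - 0.1134)
    )
    return float(m)


@dataclass
class FuzzyClustering:
    c: int
    m: float
    centers: np.ndarray              # c x D
    membership: pd.DataFrame         # sites x c, rows sum to 1
    objective_trace: list[float] = field(default_factory=list)
    columns: list[str] = field(default_factory=list)

    @property
    def labels(self) -> pd.Series:
        """Hard assignment: argmax membership, clusters numbered from 1."""
        return pd.Series(
            self.membership.to_numpy().argmax(axis=1) + 1,
            index=self.membership.index,
        )

    def to_frame(self) -> pd.DataFrame:
        lab = self.membership.values.argmax(axis=1)
        return pd.DataFrame(
            {
                "cluster": lab + 1,
                "membership": self.membership.values[
                    np.arange(len(self.membership)), lab
                ],
            },
            index=self.membership.index,
        )


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int = 6,
    m: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
    n_init: int = 8,
) -> FuzzyClustering:
    """Fuzzy c-means on standardized profiles.

    Alternates centre and membership updates minimising
    sum_ij u_ij^m ||x_i - v_j||^2 with u_ij ∝ ||x_i - v_j||^(-2/(m-1))
    normalised per site.  Centres are initialised with k-means++ seeding;
    ``n_init`` restarts (seeds derived from ``seed``) are run and the
    solution with the lowest objective kept, since single runs can stall in
    poor local minima.  A site coincident with a centre takes membership 1
    there (the limit rule).  The objective is asserted non-increasing.
    """
    X = profiles.to_numpy(dtype=float)
    n, d = X.shape
    if c > n:
        raise ValueError(f"c={c} exceeds the number of profiles ({n})")
    if m is None:
        m = estimate_fuzzifier(n, d)
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")

    best: FuzzyClustering | None = None
    for i in range(n_init):
        run = _fuzzy_cmeans_once(profiles, X, c, float(m), tol, max_iter,
                                 seed + 7919 * i)
        if best is None or run.objective_trace[-1] < best.objective_trace[-1]:
            best = run
    return best


def _fuzzy_cmeans_once(profiles: pd.DataFrame, X: np.ndarray, c: int,
                       m: float, tol: float, max_iter: int,
                       seed: int) -> FuzzyClustering:
    from sklearn.cluster import kmeans_plusplus

    centers, _ = kmeans_plusplus(X, n_clusters=c, random_state=seed)
    trace: list[float] = []
    U = None
    for it in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
        U = np.where(zero.any(axis=1, keepdims=True),
                     zero.astype(float), inv)
        U = U / U.sum(axis=1, keepdims=True)
        obj = float((U ** m * d2).sum())
        if trace and obj > trace[-1] + 1e-9 * max(1.0, abs(trace[-1])):
            raise AssertionError(
                f"fuzzy c-means objective increased at iteration {it}: "
                f"{trace[-1]} -> {obj}"
            )
        converged = trace and abs(trace[-1] - obj) < tol
        trace.append(obj)
        if converged:
            break
        W = U ** m
        centers = (W.T @ X) / W.sum(axis=0)[:, None]
    membership = pd.DataFrame(
        U, index=profiles.index, columns=[f"c{j + 1}" for j in range(c)]
    )
    return FuzzyClustering(
        c=c, m=float(m), centers=centers, membership=membership,
        objective_trace=trace, columns=list(profiles.columns),
    )


def reorder_by_peak(clustering: FuzzyClustering,
                    time_order: list[str] | None = None) -> FuzzyClustering:
    """Renumber clusters by ascending time index of each centre's maximum.

    Ties are broken by the earlier secondary peak, then by original index;
    applying the reordering twice is idempotent.
    """
    centers = clustering.centers
    keys = []
    for j in range(clustering.c):
        order = np.argsort(-centers[j])  # time indices by descending value
        primary = int(order[0])
        secondary = int(order[1]) if len(order) > 1 else primary
        keys.append((primary, secondary, j))
    perm = [j for _, _, j in sorted(keys)]
    new_centers = centers[perm]
    new_membership = clustering.membership.iloc[:, perm]
    new_membership.columns = [f"c{j + 1}" for j in range(clustering.c)]
    return FuzzyClustering(
        c=clustering.c, m=clustering.m, centers=new_centers,
        membership=new_membership, objective_trace=list(clustering.objective_trace),
        columns=list(clustering.columns),
    )


@dataclass
class PrevalenceGroups:
    counts: pd.Series        # per site: number of time points present
    labels: pd.Series        # per site: "f1".."f5"

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def group_by_prevalence(presence: pd.DataFrame) -> PrevalenceGroups:
    """Group sites by the number of time points at which they survived.

    ``presence`` is the boolean site x timepoint survival matrix from the
    filter cascade; f1 marks sites seen at exactly one time point, f5 sites
    shared by all five.  Sites present nowhere are excluded with a warning.
    """
    counts = presence.sum(axis=1).astype(int)
    absent = counts == 0
    if absent.any():
        logger.warning("group_by_prevalence: %d sites present nowhere excluded",
                       int(absent.sum()))
    counts = counts[~absent]
    labels = "f" + counts.astype(str)
    return PrevalenceGroups(counts=counts, labels=labels)


def build_profiles(
    el_by_tp: pd.DataFrame,
    presence: pd.DataFrame | None = None,
    min_defined: int = 2,
    fill_zero: bool = True,
) -> pd.DataFrame:
    """Assemble the clustering input matrix from per-time-point ELs.

    ``el_by_tp`` rows are sites, columns time points; entries are missing
    where pooled coverage was insufficient.  With ``fill_zero`` (default) a
    covered-but-unedited time point keeps its measured EL (possibly 0):
    absence of editing is a measurement, not missingness.  Rows with fewer
    than ``min_defined`` defined entries are dropped.
    """
    prof = el_by_tp.copy()
    if presence is not None:
        prof = prof.loc[prof.index.intersection(presence.index)]
    defined = prof.notna().sum(axis=1)
    prof = prof.loc[defined >= min_defined]
    if fill_zero:
        pass  # measured zeros are already in el_by_tp; only true gaps stay NaN
    return prof
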