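"""Fuzzy c-means clustering of standardized temporal expression profiles.

Each gene's profile is its per-timepoint mean of log2 abundance,
z-standardized across timepoints (sample standard deviation, n-1).
Clustering uses the classic fuzzy c-means alternating updates with
fuzzifier m and Euclidean distance, seeded initialization from data
points for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SampleDesign, ValidationError

__all__ = ["TemporalProfiles", "FuzzyClustering", "build_profiles", "fuzzy_cmeans", "assign_clusters"]


@dataclass(frozen=True)
class TemporalProfiles:
    """Genes x timepoints standardized mean profiles; constant genes dropped."""

    values: pd.DataFrame
    dropped: tuple[str, ...]  # genes excluded for zero temporal variance


@dataclass(frozen=True)
class FuzzyClustering:
    membership: pd.DataFrame  # genes x clusters, rows sum to 1
    centers: pd.DataFrame  # clusters x timepoints
    fuzzifier: float
    n_iter: int
    objective: tuple[float, ...]  # per-iteration objective values

    @property
    def hard_labels(self) -> pd.Series:
        """Argmax membership; ties broken toward the lowest cluster index."""
        return self.membership.idxmax(axis=1)


def build_profiles(
    log_matrix: pd.DataFrame, design: SampleDesign, deg_set: set[str] | list[str]
) -> TemporalProfiles:
    """Average replicates per timepoint, then z-standardize each gene.

    Genes with zero variance across timepoint means are excluded (their
    standardized profile is undefined) and reported in ``dropped``.
    """
    genes = [g for g in log_matrix.index if g in set(deg_set)]
    means = pd.DataFrame(
        {tp: log_matrix.loc[genes, design.samples_at(tp)].mean(axis=1) for tp in design.timepoints}
    )
    sd = means.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropped {int(constant.sum())} constant-profile genes: "
            f"{sorted(means.index[constant])[:10]}",
            stacklevel=2,
        )
    kept = means[~constant]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[~constant], axis=0)
    return TemporalProfiles(values=z, dropped=tuple(sorted(means.index[constant])))


def fuzzy_cmeans(
    profiles: TemporalProfiles | pd.DataFrame,
    c: int = 4,
    m: float = 1.25,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> FuzzyClustering:
    """Fuzzy c-means on profile rows.

    Memberships follow u_ij = 1 / sum_k (d_ij / d_kj)^(2/(m-1)); centers are
    the u^m-weighted means.  A zero distance to a center assigns full
    membership there.  Initial centers are c distinct profiles sampled with
    the given seed, so runs are deterministic.
    """
    x = profiles.values if isinstance(profiles, TemporalProfiles) else profiles
    data = x.to_numpy(dtype=float)
    n, _ = data.shape
    if c < 1:
        raise ValidationError("c must be >= 1")
    if not m > 1:
        raise ValidationError("fuzzifier m must be > 1")
    if n < c:
        raise ValidationError(f"cannot fit {c} clusters to {n} profiles")
    rng = np.random.default_rng(seed)
    # k-means++-style seeding from data points: spread initial centers out
    idx = [int(rng.integers(n))]
    for _ in range(1, c):
        d2min = np.min(
            ((data[:, None, :] - data[idx][None, :, :]) ** 2).sum(axis=2), axis=1
        )
        total = d2min.sum()
        if total <= 0:
            # all remaining points coincide with a center; take any unused point
            unused = [i for i in range(n) if i not in idx]
            idx.append(unused[0])
            continue
        idx.append(int(rng.choice(n, p=d2min / total)))
    centers = data[idx].copy()

    exp = 2.0 / (m - 1.0)
    u = np.zeros((n, c))
    objective: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        u_new = np.zeros_like(d2)
        zero = d2 <= 0
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore"):
            ratio = d2 ** (-exp / 2.0)  # (1/d)^exp
        u_new[~any_zero] = ratio[~any_zero] / ratio[~any_zero].sum(axis=1, keepdims=True)
        # degenerate rule: coincident with a center -> crisp membership there
        for i in np.flatnonzero(any_zero):
            u_new[i] = 0.0
            u_new[i, np.argmax(zero[i])] = 1.0
        objective.append(float(((u_new**m) * d2).sum()))
        delta = np.abs(u_new - u).max() if n_iter > 1 else np.inf
        u = u_new
        if delta < tol:
            break
        um = u**m
        centers = (um.T @ data) / um.sum(axis=0)[:, None]

    index = x.index
    cluster_ids = [f"C{i + 1}" for i in range(c)]
    return FuzzyClustering(
        membership=pd.DataFrame(u, index=index, columns=cluster_ids),
        centers=pd.DataFrame(centers, index=cluster_ids, columns=x.columns),
        fuzzifier=m,
        n_iter=n_iter,
        objective=tuple(objective),
    )


def assign_clusters(
    clustering: FuzzyClustering, min_membership: float = 0.3
) -> pd.Series:
    """Hard labels by argmax membership; below-threshold genes 'unassigned'.

    Ties go to the lowest cluster index (pandas idxmax convention).
    """
    u = clustering.membership
    labels = u.idxmax(axis=1)
    labels[u.max(axis=1) < min_membership] = "unassigned"
    return labels
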