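"""OPLS-DA / VIP screening of targeted-metabolomics concentration tables.

The two-class model is fitted NIPALS-style on autoscaled (mean-centered,
unit-variance) concentrations with a +/-1 class vector: the predictive
weight is the X-y covariance direction; orthogonal components (variation
uncorrelated with class) are estimated and removed n_orth times, then a
single predictive component is refitted on the filtered matrix.

VIP_j = sqrt(p * sum_a(SSY_a * w_aj^2) / sum_a SSY_a) over predictive
components; with one unit-norm predictive weight vector this reduces to
sqrt(p) * |w_j| and always satisfies sum_j VIP_j^2 = p.

Differentially regulated metabolites (DRMs): pairwise rule
FC >= high or FC <= low (raw-concentration group-mean ratio, boundaries
inclusive) AND VIP > 1 (strict); multi-group rule one-way ANOVA p < 0.05
AND VIP > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import MetaboliteTable, SampleDesign, ValidationError

__all__ = [
    "OplsModel",
    "MetaboliteScreen",
    "fit_oplsda",
    "vip_scores",
    "cross_val_q2",
    "pairwise_drm",
    "multigroup_drm",
    "drm_sets",
]


@dataclass(frozen=True)
class OplsModel:
    variables: tuple[str, ...]
    weights: np.ndarray  # predictive weight vector, unit norm
    scores: np.ndarray  # predictive scores t
    loadings: np.ndarray  # predictive loadings p
    y_loading: float  # q: regression of y on t
    orth_weights: np.ndarray  # n_orth x p
    orth_scores: np.ndarray  # n x n_orth
    orth_loadings: np.ndarray  # n_orth x p
    center: np.ndarray
    scale: np.ndarray
    classes: np.ndarray  # +/-1 per sample
    group_a: str
    group_b: str

    @property
    def n_orth(self) -> int:
        return self.orth_weights.shape[0]


def _autoscale(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    keep = scale > 0
    return (x[:, keep] - center[keep]) / scale[keep], center, scale, keep


def _opls_core(x: np.ndarray, y: np.ndarray, n_orth: int):
    """NIPALS OPLS on preprocessed data; returns predictive and orthogonal parts."""
    xw = x.copy()
    orth_w, orth_t, orth_p = [], [], []
    for _ in range(n_orth):
        w = xw.T @ y / (y @ y)
        w /= np.linalg.norm(w)
        t = xw @ w
        p = xw.T @ t / (t @ t)
        wo = p - (w @ p) * w
        norm = np.linalg.norm(wo)
        if norm < 1e-12:
            break  # no orthogonal variation left
        wo /= norm
        to = xw @ wo
        po = xw.T @ to / (to @ to)
        xw = xw - np.outer(to, po)
        orth_w.append(wo)
        orth_t.append(to)
        orth_p.append(po)
    w = xw.T @ y / (y @ y)
    w /= np.linalg.norm(w)
    t = xw @ w
    p = xw.T @ t / (t @ t)
    q = float(y @ t / (t @ t))
    nv = x.shape[1]
    ow = np.array(orth_w) if orth_w else np.zeros((0, nv))
    ot = np.array(orth_t).T if orth_t else np.zeros((x.shape[0], 0))
    op_ = np.array(orth_p) if orth_p else np.zeros((0, nv))
    return w, t, p, q, ow, ot, op_


def fit_oplsda(
    table: MetaboliteTable,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    n_orth: int = 1,
) -> OplsModel:
    """Two-class OPLS-DA of group_b (+1) against group_a (-1)."""
    sa = design.samples_at(group_a)
    sb = design.samples_at(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValidationError("each group needs >= 2 samples for OPLS-DA")
    samples = sa + sb
    x = table.values[samples].to_numpy(dtype=float).T  # samples x variables
    y = np.array([-1.0] * len(sa) + [1.0] * len(sb))
    y = y - y.mean()
    xs, center, scale, keep = _autoscale(x)
    if not keep.any():
        raise ValidationError("all variables are constant; nothing to fit")
    if not keep.all():
        dropped = [m for m, k in zip(table.metabolite_ids, keep) if not k]
        warnings.warn(f"dropped constant variable(s): {dropped[:5]}", stacklevel=2)
    w, t, p, q, ow, ot, op_ = _opls_core(xs, y, n_orth)
    return OplsModel(
        variables=tuple(m for m, k in zip(table.metabolite_ids, keep) if k),
        weights=w,
        scores=t,
        loadings=p,
        y_loading=q,
        orth_weights=ow,
        orth_scores=ot,
        orth_loadings=op_,
        center=center,
        scale=scale,
        classes=np.array([-1.0] * len(sa) + [1.0] * len(sb)),
        group_a=group_a,
        group_b=group_b,
    )


def vip_scores(model: OplsModel) -> pd.Series:
    """Variable importance in projection over the predictive component(s).

    With one unit-norm predictive weight vector, VIP_j = sqrt(p) |w_j|
    and sum VIP^2 = p identically.
    """
    w = model.weights
    p = w.size
    ssy = (model.y_loading**2) * float(model.scores @ model.scores)
    vip = np.sqrt(p * (ssy * w**2) / ssy)
    return pd.Series(vip, index=model.variables, name="vip")


def cross_val_q2(
    table: MetaboliteTable,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    n_orth: int = 1,
    n_folds: int = 7,
    seed: int = 0,
) -> float:
    """K-fold cross-validated Q2 of the OPLS-DA class prediction.

    Q2 = 1 - PRESS / SS around the class mean; <= 0 means no predictive
    power (the expected outcome under permuted labels).
    """
    sa = design.samples_at(group_a)
    sb = design.samples_at(group_b)
    samples = sa + sb
    x = table.values[samples].to_numpy(dtype=float).T
    y = np.array([-1.0] * len(sa) + [1.0] * len(sb))
    n = len(samples)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, min(n_folds, n))
    press = 0.0
    for test in folds:
        train = np.setdiff1d(perm, test)
        ytr = y[train] - y[train].mean()
        xs, center, scale, keep = _autoscale(x[train])
        w, t, p, q, ow, ot, op_ = _opls_core(xs, ytr, n_orth)
        xte = (x[test][:, keep] - center[keep]) / scale[keep]
        for wo, po in zip(ow, op_):
            xte = xte - np.outer(xte @ wo, po)
        yhat = (xte @ w) * q + y[train].mean()
        press += float(((y[test] - yhat) ** 2).sum())
    ss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss


@dataclass(frozen=True)
class MetaboliteScreen:
    table: pd.DataFrame  # index metabolite; fold_change, vip, [anova_p], drm_flag, direction
    comparison: str
    fc_low: float
    fc_high: float

    @property
    def drms(self) -> set[str]:
        return set(self.table.index[self.table["drm_flag"]])


def _group_means(table: MetaboliteTable, design: SampleDesign, tp: str) -> pd.Series:
    return table.values[design.samples_at(tp)].mean(axis=1)


def pairwise_drm(
    table: MetaboliteTable,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    model: OplsModel | None = None,
    fc_low: float = 0.5,
    fc_high: float = 2.0,
    n_orth: int = 1,
) -> MetaboliteScreen:
    """Pairwise DRM screen: (FC >= high or FC <= low) AND VIP > 1.

    Fold-change is the raw-concentration group-mean ratio (B over A),
    boundaries inclusive; VIP strictly greater than 1.  ``model`` defaults
    to an OPLS-DA of the same pair.
    """
    if model is None:
        model = fit_oplsda(table, design, group_a, group_b, n_orth=n_orth)
    vip = vip_scores(model)
    mean_a = _group_means(table, design, group_a)
    mean_b = _group_means(table, design, group_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_b / mean_a
    out = pd.DataFrame({"fold_change": fc, "vip": vip.reindex(fc.index)})
    out["drm_flag"] = (
        ((out["fold_change"] >= fc_high) | (out["fold_change"] <= fc_low))
        & (out["vip"] > 1.0)
    ).fillna(False)
    out["direction"] = np.where(out["fold_change"] >= 1.0, "increased", "decreased")
    return MetaboliteScreen(
        table=out,
        comparison=f"{group_b}_vs_{group_a}",
        fc_low=fc_low,
        fc_high=fc_high,
    )


def multigroup_drm(
    table: MetaboliteTable,
    design: SampleDesign,
    model: OplsModel | None = None,
    p_max: float = 0.05,
    n_orth: int = 1,
) -> MetaboliteScreen:
    """Multi-group DRM screen: one-way ANOVA p < 0.05 AND VIP > 1.

    The VIP comes from an OPLS-DA of the first against the last timepoint
    unless a model is supplied.  Direction is the last-vs-first group-mean
    fold-change.
    """
    tps = design.timepoints
    if len(tps) < 2:
        raise ValidationError("multi-group screen needs >= 2 timepoints")
    if model is None:
        model = fit_oplsda(table, design, tps[0], tps[-1], n_orth=n_orth)
    vip = vip_scores(model)
    groups = [table.values[design.samples_at(tp)].to_numpy(dtype=float) for tp in tps]
    pvals = np.array(
        [stats.f_oneway(*[g[i] for g in groups]).pvalue for i in range(len(table.metabolite_ids))]
    )
    pvals = np.nan_to_num(pvals, nan=1.0)  # constant metabolite: no evidence
    mean_first = _group_means(table, design, tps[0])
    mean_last = _group_means(table, design, tps[-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_last / mean_first
    out = pd.DataFrame(
        {
            "fold_change": fc,
            "vip": vip.reindex(fc.index),
            "anova_p": pvals,
        },
        index=table.values.index,
    )
    out["drm_flag"] = ((out["anova_p"] < p_max) & (out["vip"] > 1.0)).fillna(False)
    out["direction"] = np.where(out["fold_change"] >= 1.0, "increased", "decreased")
    return MetaboliteScreen(
        table=out,
        comparison=f"{tps[-1]}_vs_{tps[0]}_multigroup",
        fc_low=np.nan,
        fc_high=np.nan,
    )


def drm_sets(screens: dict[str, MetaboliteScreen]) -> dict:
    """UpSet-style accounting over per-comparison DRM sets.

    Returns exclusive intersection sizes per membership pattern, the
    metabolites called DRM-increased in every baseline comparison
    (comparisons ending in the same earliest group), and the fraction of
    all DRM calls that are increases.
    """
    names = list(screens)
    sets = {name: screens[name].drms for name in names}
    universe = set().union(*sets.values()) if sets else set()
    regions: dict[tuple[str, ...], int] = {}
    for met in universe:
        pattern = tuple(name for name in names if met in sets[name])
        regions[pattern] = regions.get(pattern, 0) + 1
    # consistent direction vs the shared baseline (e.g. *_vs_D0 comparisons)
    baselines: dict[str, list[str]] = {}
    for name in names:
        if "_vs_" in name:
            baselines.setdefault(name.split("_vs_")[1], []).append(name)
    consistent_up: dict[str, list[str]] = {}
    for base, comps in baselines.items():
        if len(comps) < 2:
            continue
        up = None
        for c in comps:
            t = screens[c].table
            s = set(t.index[t["drm_flag"] & (t["direction"] == "increased")])
            up = s if up is None else up & s
        consistent_up[base] = sorted(up or [])
    n_calls = sum(int(screens[n].table["drm_flag"].sum()) for n in names)
    n_up = sum(
        int((screens[n].table["drm_flag"] & (screens[n].table["direction"] == "increased")).sum())
        for n in names
    )
    return {
        "exclusive_regions": {" & ".join(k): v for k, v in sorted(regions.items())},
        "consistent_increased": consistent_up,
        "fraction_increased": (n_up / n_calls) if n_calls else float("nan"),
        "n_drm_calls": n_calls,
    }


def all_pairwise_screens(
    table: MetaboliteTable,
    design: SampleDesign,
    fc_low: float = 0.5,
    fc_high: float = 2.0,
    n_orth: int = 1,
) -> dict[str, MetaboliteScreen]:
    """Pairwise DRM screens for every ordered timepoint pair."""
    out: dict[str, MetaboliteScreen] = {}
    for a, b in combinations(design.timepoints, 2):
        s = pairwise_drm(table, design, a, b, fc_low=fc_low, fc_high=fc_high, n_orth=n_orth)
        out[s.comparison] = s
    return out
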