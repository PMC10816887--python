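"""Pairwise differential expression with empirical-Bayes variance moderation.

The test is a two-group contrast on log2 abundances in which gene-wise
residual variances are shrunk toward a common prior.  The prior
(scale ``s0^2`` and degrees of freedom ``d0``) is estimated by a
method-of-moments fit of a scaled inverse-chi-square to the observed
variances on the log scale: if ``s_g^2 ~ s0^2 * chi2_{d0} / d0`` marginally,
then ``log s_g^2`` has known digamma/trigamma moments, which are matched
and inverted.  ``d0 = 0`` recovers the ordinary pooled-variance t test
exactly; ``d0 = inf`` pools all genes to a single variance.

The differentially-expressed-gene (DEG) filter defaults to raw p < 0.05
and |log2 fold-change| >= 1; Benjamini-Hochberg adjusted p values are
always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, SampleDesign, ValidationError

__all__ = [
    "DiffResult",
    "log_transform",
    "moderated_ttest",
    "filter_degs",
    "union_degs",
    "ddct_relative_expression",
    "all_pairwise",
]


@dataclass(frozen=True)
class DiffResult:
    """Per-gene statistics for one two-group comparison (B over A)."""

    table: pd.DataFrame  # columns: log2_fc, t_mod, p_raw, p_adj, mean_a, mean_b
    comparison: str
    group_a: str
    group_b: str
    prior_df: float
    prior_var: float

    def __post_init__(self) -> None:
        t = self.table
        for col in ("log2_fc", "t_mod", "p_raw", "p_adj", "mean_a", "mean_b"):
            if col not in t.columns:
                raise ValidationError(f"DiffResult missing column {col!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(value + pseudocount); pseudocount must be positive."""
    if not pseudocount > 0:
        raise ValidationError(f"pseudocount must be > 0, got {pseudocount}")
    return np.log2(matrix.values + pseudocount)


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting point: trigamma(y) ~ 1/y + 1/(2y^2)
    for _ in range(60):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y - dif
        if np.all(np.abs(dif) < 1e-12 * np.maximum(y, 1.0)):
            break
    return y


def fit_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log variances.

    Returns (prior_df, prior_var).  Genes with zero variance are excluded
    from the fit.  If the observed spread of log variances is no larger
    than sampling noise alone, prior_df = inf and prior_var is the
    pooled-scale estimate.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return 0.0, float(s2.mean()) if s2.size else 0.0
    z = np.log(s2)
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    ebar = e.mean()
    evar = np.var(e, ddof=1) - special.polygamma(1, df_resid / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * float(_trigamma_inverse(evar))
    s0sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def moderated_ttest(
    log_matrix: pd.DataFrame,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    prior_df: float | None = None,
) -> DiffResult:
    """Two-group moderated t test on a log2 matrix (genes x samples).

    ``group_a`` / ``group_b`` are timepoint labels; fold-changes are B over
    A.  ``prior_df`` overrides the estimated prior degrees of freedom
    (0 gives the classic pooled t; inf pools variances fully).
    """
    sa = design.samples_at(group_a)
    sb = design.samples_at(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValidationError("each group needs >= 2 samples for the moderated t test")
    xa = log_matrix[sa].to_numpy(dtype=float)
    xb = log_matrix[sb].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    lfc = mean_b - mean_a
    df_resid = na + nb - 2
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0sq = fit_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0sq = fit_variance_prior(s2, df_resid) if d0 > 0 else (0.0, 0.0)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    elif d0 > 0:
        s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    else:
        s2_post = s2
        df_total = df_resid

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    # degenerate genes: no variance anywhere and no difference -> null result
    flat = (s2_post == 0) & (lfc == 0)
    t[flat] = 0.0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p[flat] = 1.0
    # zero posterior variance with a real difference: infinitely significant
    blown = np.isinf(t)
    p[blown] = 0.0
    p_adj = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "log2_fc": lfc,
            "t_mod": t,
            "p_raw": p,
            "p_adj": p_adj,
            "mean_a": mean_a,
            "mean_b": mean_b,
        },
        index=log_matrix.index,
    )
    return DiffResult(
        table=table,
        comparison=f"{group_b}_vs_{group_a}",
        group_a=group_a,
        group_b=group_b,
        prior_df=float(d0),
        prior_var=float(s0sq),
    )


def filter_degs(
    result: DiffResult,
    lfc_min: float = 1.0,
    p_max: float = 0.05,
    use_adjusted: bool = False,
) -> set[str]:
    """Genes with |log2FC| >= lfc_min AND p < p_max.

    The fold-change boundary is inclusive (|log2FC| exactly 1 passes); the
    p boundary is exclusive (p exactly 0.05 fails).  ``use_adjusted``
    switches the p filter to Benjamini-Hochberg adjusted values.
    """
    t = result.table
    pcol = t["p_adj"] if use_adjusted else t["p_raw"]
    mask = (t["log2_fc"].abs() >= lfc_min) & (pcol < p_max)
    return set(t.index[mask])


def union_degs(deg_sets: list[set[str]] | dict[str, set[str]]) -> list[str]:
    """Stable-sorted union of DEG sets over comparisons."""
    sets = deg_sets.values() if isinstance(deg_sets, dict) else deg_sets
    out: set[str] = set()
    for s in sets:
        out |= s
    return sorted(out)


def ddct_relative_expression(
    ct_target: float,
    ct_reference: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Relative qPCR quantity by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) - (Ct_target_cal - Ct_reference_cal);
    returns 2^-ddCt.
    """
    cts = (ct_target, ct_reference, ct_target_calibrator, ct_reference_calibrator)
    if not all(np.isfinite(c) for c in cts):
        raise ValidationError(f"non-finite Ct value in {cts}")
    ddct = (ct_target - ct_reference) - (ct_target_calibrator - ct_reference_calibrator)
    return float(2.0 ** (-ddct))


def all_pairwise(
    log_matrix: pd.DataFrame, design: SampleDesign, prior_df: float | None = None
) -> dict[str, DiffResult]:
    """Moderated t for every ordered timepoint pair (later vs earlier)."""
    tps = design.timepoints
    out: dict[str, DiffResult] = {}
    for i, a in enumerate(tps):
        for b in tps[i + 1 :]:
            res = moderated_ttest(log_matrix, design, a, b, prior_df=prior_df)
            out[res.comparison] = res
    return out
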