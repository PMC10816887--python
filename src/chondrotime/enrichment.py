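"""Gene-set over-representation and per-sample enrichment scoring.

`ora` is an upper-tail hypergeometric test of a query gene list against
each set of a collection, BH-adjusted across sets.  `sample_scores` is a
rank-based single-sample enrichment score: within each sample, genes are
ranked by expression and a weighted Kolmogorov-Smirnov random walk is
taken over the ranked list (in-set steps weighted by rank^tau, out-of-set
steps -1/(N-K)); the score is the maximum-magnitude deviation, signed.
Being rank-based, scores are invariant to any strictly monotone transform
of a sample's values.  `score_significance` reuses the moderated t test
on the score matrix across timepoint groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GeneSetCollection, SampleDesign, ValidationError
from .diffexpr import moderated_ttest

__all__ = ["OraResult", "bh_adjust", "ora", "sample_scores", "score_significance"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class OraResult:
    table: pd.DataFrame  # index set id; columns k, K, n, N, p_hyper, p_adj, overlap
    universe_size: int


def ora(
    query: set[str] | list[str],
    collection: GeneSetCollection,
    universe: set[str] | list[str],
    min_size: int = 3,
    max_size: int = 500,
) -> OraResult:
    """Hypergeometric over-representation of `query` in each gene set.

    Sets are intersected with the universe; those with fewer than
    ``min_size`` (or more than ``max_size``) members in the universe are
    skipped.  Query genes outside the universe are dropped with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    query = set(query)
    stray = query - universe
    if stray:
        warnings.warn(
            f"{len(stray)} query gene(s) outside the universe dropped: "
            f"{sorted(stray)[:5]}",
            stacklevel=2,
        )
        query &= universe
    N = len(universe)
    n = len(query)
    rows = []
    for sid in collection:
        members = set(collection.members(sid)) & universe
        K = len(members)
        if K < min_size or K > max_size:
            continue
        overlap = members & query
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((sid, k, K, n, N, p, ",".join(sorted(overlap))))
    df = pd.DataFrame(rows, columns=["set_id", "k", "K", "n", "N", "p_hyper", "overlap"])
    df["p_adj"] = bh_adjust(df["p_hyper"].to_numpy()) if len(df) else []
    return OraResult(table=df.set_index("set_id"), universe_size=N)


def _walk_score(order: np.ndarray, in_set: np.ndarray, tau: float) -> float:
    """Signed max deviation of the weighted KS walk for one sample.

    `order` is gene positions sorted by descending expression; `in_set`
    flags set membership per gene (in original gene order).
    """
    N = order.size
    member = in_set[order]
    K = int(member.sum())
    ranks = np.arange(N, 0, -1, dtype=float)  # top gene gets rank N
    w = np.where(member, ranks**tau, 0.0)
    inside_total = w.sum()
    steps = np.where(member, w / inside_total, -1.0 / (N - K))
    walk = np.cumsum(steps)
    i = int(np.abs(walk).argmax())
    return float(walk[i])


def sample_scores(
    log_matrix: pd.DataFrame,
    collection: GeneSetCollection,
    tau: float = 0.25,
) -> pd.DataFrame:
    """Per-sample enrichment scores (sets x samples).

    Sets are intersected with the matrix genes; sets with fewer than 2
    matrix genes, or spanning every gene (undefined outside step), are
    skipped with a warning.
    """
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    genes = list(log_matrix.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)
    x = log_matrix.to_numpy(dtype=float)
    # descending stable order per sample; ties broken by gene order
    orders = np.argsort(-x, axis=0, kind="stable")
    masks: dict[str, np.ndarray] = {}
    for sid in collection:
        members = [g for g in collection.members(sid) if g in gene_pos]
        if len(members) < 2:
            warnings.warn(f"set {sid!r}: fewer than 2 matrix genes; skipped", stacklevel=2)
            continue
        if len(members) >= N:
            warnings.warn(f"set {sid!r} covers every gene; skipped", stacklevel=2)
            continue
        mask = np.zeros(N, dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        masks[sid] = mask
    scores = np.empty((len(masks), x.shape[1]))
    for j in range(x.shape[1]):
        order = orders[:, j]
        for i, mask in enumerate(masks.values()):
            scores[i, j] = _walk_score(order, mask, tau)
    return pd.DataFrame(scores, index=list(masks), columns=log_matrix.columns)


def score_significance(
    score_matrix: pd.DataFrame,
    design: SampleDesign,
    contrasts: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moderated t on enrichment scores across timepoint groups.

    `contrasts` is a list of (earlier, later) timepoint pairs; default is
    every later timepoint against the first.  Returns a long table with
    one row per (set, contrast) and a `significant` flag at BH-adjusted
    p <= alpha (boundary inclusive).
    """
    tps = design.timepoints
    if contrasts is None:
        contrasts = [(tps[0], tp) for tp in tps[1:]]
    frames = []
    for a, b in contrasts:
        res = moderated_ttest(score_matrix, design, a, b)
        t = res.table[["log2_fc", "t_mod", "p_raw", "p_adj"]].rename(
            columns={"log2_fc": "delta"}
        )
        t = t.assign(contrast=res.comparison, set_id=t.index)
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = out["p_adj"] <= alpha
    return out[["set_id", "contrast", "delta", "t_mod", "p_raw", "p_adj", "significant"]]
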