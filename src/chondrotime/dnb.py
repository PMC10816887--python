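"""Dynamic network biomarker (DNB) analysis.

A DNB is a gene module whose members, approaching a critical transition,
fluctuate more (rising within-module standard deviation, SDin), become
strongly mutually correlated (rising mean absolute Pearson correlation,
PCCin), and decouple from the rest of the transcriptome (falling mean
absolute correlation to non-members, PCCout).  The criticality index

    CI = SDin * PCCin / max(PCCout, epsilon)

summarises the three conditions; the timepoint at which the best module's
CI peaks is the tipping point.

Candidate modules per timepoint come from average-linkage hierarchical
clustering on the distance 1 - |r| between replicate profiles, with the
tree cut at a grid of heights.  All correlations are computed across
replicates within one timepoint, using the sample (n-1) standard
deviation convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import InteractionNetwork, SampleDesign, ValidationError

__all__ = [
    "DnbModuleStats",
    "DnbResult",
    "candidate_modules",
    "module_stats",
    "criticality_curve",
    "dnb_neighborhood",
]

DEFAULT_CUT_HEIGHTS = (0.2, 0.4, 0.6, 0.8)


@dataclass(frozen=True)
class DnbModuleStats:
    timepoint: str
    members: tuple[str, ...]
    sd_in: float
    pcc_in: float
    pcc_out: float
    ci: float


@dataclass(frozen=True)
class DnbResult:
    ci_curve: pd.Series  # timepoint -> best module CI, in temporal order
    best_modules: dict[str, DnbModuleStats]
    tipping_timepoint: str
    members: tuple[str, ...]  # best module at the tip


def _abs_corr(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(|r| matrix, per-gene sample sd) across replicates at one timepoint.

    Zero-variance genes get correlation 0 to everything (flagged upstream).
    """
    sd = values.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return np.abs(r), sd


def candidate_modules(
    log_matrix: pd.DataFrame,
    design: SampleDesign,
    timepoint: str,
    min_size: int = 5,
    max_size: int = 100,
    cut_heights: tuple[float, ...] = DEFAULT_CUT_HEIGHTS,
) -> list[tuple[str, ...]]:
    """Co-fluctuation candidate modules at one timepoint.

    Average-linkage hierarchical clustering on 1 - |r| over replicate
    values, cut at each height in `cut_heights`; clusters within the size
    band are returned, deduplicated, in a deterministic order.
    """
    samples = design.samples_at(timepoint)
    if len(samples) < 3:
        raise ValidationError(
            f"timepoint {timepoint!r}: need >= 3 replicates for correlation-based search"
        )
    genes = list(log_matrix.index)
    if len(genes) < min_size:
        raise ValidationError(
            f"only {len(genes)} analyzable genes; min module size is {min_size}"
        )
    values = log_matrix[samples].to_numpy(dtype=float)
    absr, sd = _abs_corr(values)
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} zero-variance gene(s) at {timepoint}; "
            "their correlations set to 0",
            stacklevel=2,
        )
    dist = 1.0 - absr
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    seen: set[tuple[str, ...]] = set()
    modules: list[tuple[str, ...]] = []

    def collect(labels: np.ndarray) -> None:
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            if min_size <= idx.size <= max_size:
                module = tuple(sorted(genes[i] for i in idx))
                if module not in seen:
                    seen.add(module)
                    modules.append(module)

    for h in cut_heights:
        collect(fcluster(z, t=h, criterion="distance"))
    if not modules:
        # noisy small-replicate correlations can merge everything below the
        # coarsest height; fall back to fixed cluster counts on the same tree
        k = 2
        while k <= max(2, len(genes) // min_size):
            collect(fcluster(z, t=k, criterion="maxclust"))
            k *= 2
    return modules


def module_stats(
    module: tuple[str, ...] | list[str],
    log_matrix: pd.DataFrame,
    design: SampleDesign,
    timepoint: str,
    epsilon: float = 0.05,
    _precomputed: tuple[np.ndarray, np.ndarray] | None = None,
) -> DnbModuleStats:
    """SDin / PCCin / PCCout / CI for one module at one timepoint.

    SDin: mean across members of the replicate-wise sample sd.
    PCCin: mean |r| over all member pairs.  PCCout: mean |r| over all
    member x non-member pairs within the analyzed matrix.  CI divides by
    max(PCCout, epsilon).
    """
    module = tuple(module)
    if len(module) < 2:
        raise ValidationError("module needs >= 2 members")
    genes = list(log_matrix.index)
    pos = {g: i for i, g in enumerate(genes)}
    missing = [g for g in module if g not in pos]
    if missing:
        raise ValidationError(f"module gene {missing[0]!r} absent from matrix")
    if _precomputed is not None:
        absr, sd = _precomputed
    else:
        samples = design.samples_at(timepoint)
        absr, sd = _abs_corr(log_matrix[samples].to_numpy(dtype=float))
    midx = np.array([pos[g] for g in module])
    out_mask = np.ones(len(genes), dtype=bool)
    out_mask[midx] = False
    sd_in = float(sd[midx].mean())
    sub = absr[np.ix_(midx, midx)]
    iu = np.triu_indices(len(midx), k=1)
    pcc_in = float(sub[iu].mean())
    if out_mask.any():
        pcc_out = float(absr[np.ix_(midx, out_mask)].mean())
    else:
        pcc_out = 0.0
    ci = sd_in * pcc_in / max(pcc_out, epsilon)
    return DnbModuleStats(
        timepoint=timepoint,
        members=module,
        sd_in=sd_in,
        pcc_in=pcc_in,
        pcc_out=pcc_out,
        ci=float(ci),
    )


def criticality_curve(
    log_matrix: pd.DataFrame,
    design: SampleDesign,
    min_size: int = 5,
    max_size: int = 100,
    epsilon: float = 0.05,
    cut_heights: tuple[float, ...] = DEFAULT_CUT_HEIGHTS,
) -> DnbResult:
    """Best-module CI per timepoint and the tipping point (CI argmax).

    Per timepoint the best module maximises CI, ties broken toward the
    larger module and then the lexicographically smallest member list.
    If every timepoint's best CI is equal the earliest is chosen, with a
    warning.
    """
    best: dict[str, DnbModuleStats] = {}
    for tp in design.timepoints:
        samples = design.samples_at(tp)
        absr, sd = _abs_corr(log_matrix[samples].to_numpy(dtype=float))
        modules = candidate_modules(
            log_matrix, design, tp, min_size=min_size, max_size=max_size, cut_heights=cut_heights
        )
        stats_tp = [
            module_stats(
                m, log_matrix, design, tp, epsilon=epsilon, _precomputed=(absr, sd)
            )
            for m in modules
        ]
        if not stats_tp:
            raise ValidationError(f"no candidate module at timepoint {tp!r}")
        top_ci = max(s.ci for s in stats_tp)
        contenders = [s for s in stats_tp if s.ci == top_ci]
        # ties: larger module first, then lexicographically smallest member list
        contenders.sort(key=lambda s: (-len(s.members), s.members))
        best[tp] = contenders[0]
    curve = pd.Series({tp: best[tp].ci for tp in design.timepoints}, name="ci")
    if curve.nunique() == 1 and len(curve) > 1:
        warnings.warn("all timepoints have equal CI; earliest chosen as tip", stacklevel=2)
    tip = str(curve.idxmax())  # idxmax returns the first maximum in order
    return DnbResult(
        ci_curve=curve,
        best_modules=best,
        tipping_timepoint=tip,
        members=best[tip].members,
    )


def dnb_neighborhood(
    members: tuple[str, ...] | list[str],
    network: InteractionNetwork,
    deg_set: set[str],
) -> tuple[list[str], list[tuple[str, str]]]:
    """Members plus their first-neighbor DEGs, with the induced edges.

    Members absent from the interaction network stay as isolated nodes.
    Returns (nodes, edges) sorted deterministically.
    """
    members = list(dict.fromkeys(members))
    neighbors: set[str] = set()
    for m in members:
        neighbors |= network.neighbors(m) & set(deg_set)
    nodes = sorted(set(members) | neighbors)
    present = [n for n in nodes if n in network.graph]
    sub = network.graph.subgraph(present)
    edges = sorted(tuple(sorted(e)) for e in sub.edges())
    return nodes, edges
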