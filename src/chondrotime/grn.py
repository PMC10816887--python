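"""Per-state transcriptional regulatory networks.

A transcriptional state is one timepoint-pair comparison with its DEG set
split by direction.  The stages here: TF-family over-representation
(cumulative hypergeometric + Fisher's exact, BH across families), PWM
scanning of 1 kb promoters with exact p-values from a dynamic-programming
null score distribution, directional TF -> target edge assembly
(activation when TF and target move the same way, inhibition otherwise),
and pair counting per state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BASES, PromoterSet, PwmLibrary, TfAnnotation, ValidationError
from .enrichment import bh_adjust

__all__ = [
    "TranscriptionalState",
    "MotifHit",
    "RegulatoryEdge",
    "tf_family_enrichment",
    "pwm_scan",
    "build_state_network",
    "count_pairs",
]

_BASE_CODE = {b: i for i, b in enumerate(BASES)}
_BASE_CODE["N"] = 4
_SCORE_BIN = 1e-3  # discretization bin for log-odds scores (in bits)
_PROB_FLOOR = 1e-4  # pseudo-frequency floor before log-odds


@dataclass(frozen=True)
class TranscriptionalState:
    """One comparison's DEGs with directions and its differentially expressed TFs."""

    label: str  # e.g. "state1"
    comparison: str  # e.g. "D4_vs_D0" (later vs earlier)
    direction: dict[str, str]  # DEG -> "up" | "down"
    tfs: frozenset[str]

    def __post_init__(self) -> None:
        bad = set(self.tfs) - set(self.direction)
        if bad:
            raise ValidationError(
                f"state {self.label}: TF {sorted(bad)[0]!r} not in the DEG set"
            )
        wrong = {d for d in self.direction.values() if d not in ("up", "down")}
        if wrong:
            raise ValidationError(f"state {self.label}: invalid direction {wrong}")


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    gene_id: str
    offset: int  # 0-based window start on the forward sequence
    strand: str  # '+' or '-'
    score: float  # log2 odds vs background
    p_value: float


@dataclass(frozen=True)
class RegulatoryEdge:
    tf_gene_id: str
    target_gene_id: str
    state: str
    sign: str  # "activation" | "inhibition"
    hit: MotifHit


def tf_family_enrichment(
    tf_subset: set[str], annotation: TfAnnotation, universe: set[str]
) -> pd.DataFrame:
    """Family over-representation of a TF list against the annotated universe.

    For each family: upper-tail cumulative hypergeometric P(X >= k) with
    N = |universe|, K = family size in the universe, n = |subset|,
    k = observed overlap; plus Fisher's exact two-sided p on the same 2x2
    table and BH adjustment of the hypergeometric p across families.
    """
    universe = set(universe)
    subset = set(tf_subset) & universe
    n = len(subset)
    N = len(universe)
    rows = []
    for family, members in sorted(annotation.families.items()):
        K = len(members & universe)
        if K == 0:
            continue
        k = len(members & subset)
        p_hyper = float(stats.hypergeom.sf(k - 1, N, K, n))
        table = [[k, n - k], [K - k, N - K - (n - k)]]
        p_fisher = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append((family, K, k, p_hyper, p_fisher))
    df = pd.DataFrame(rows, columns=["family", "family_size", "count", "p_hyper", "p_fisher"])
    df["p_adj"] = bh_adjust(df["p_hyper"].to_numpy()) if len(df) else []
    return df.set_index("family")


def _floored_logodds(pwm: np.ndarray, background: np.ndarray) -> np.ndarray:
    """4 x width log2-odds matrix with probability floor applied and
    a fifth all-zero row for N bases."""
    p = np.maximum(np.asarray(pwm, dtype=float), _PROB_FLOOR)
    p = p / p.sum(axis=0)
    lo = np.log2(p / np.asarray(background)[:, None])
    return np.vstack([lo, np.zeros((1, lo.shape[1]))])


def _revcomp_matrix(score5: np.ndarray) -> np.ndarray:
    """Score matrix for matches on the reverse strand (RC of the motif)."""
    rc = score5[[3, 2, 1, 0], ::-1].copy()  # swap A<->T, C<->G; reverse positions
    return np.vstack([rc, np.zeros((1, rc.shape[1]))])


def _null_tail(score_int: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact null distribution of the integer window score under background.

    Returns (tail, min_score): tail[s - min_score] = P(score >= s).
    Computed by position-wise convolution of the 4-point per-column score
    distributions (dynamic programming over positions).
    """
    w = score_int.shape[1]
    lo = int(score_int[:4].min(axis=0).sum())
    hi = int(score_int[:4].max(axis=0).sum())
    size = hi - lo + 1
    dist = np.zeros(size)
    dist[-lo] = 1.0  # P(score 0) = 1 before any position; index s - lo
    for j in range(w):
        new = np.zeros(size)
        for b in range(4):
            shift = int(score_int[b, j])
            if shift >= 0:
                new[shift:] += background[b] * dist[: size - shift] if shift else background[b] * dist
            else:
                new[: size + shift] += background[b] * dist[-shift:]
        dist = new
    tail = np.cumsum(dist[::-1])[::-1]
    return tail, lo


def pwm_scan(
    promoters: PromoterSet,
    pwm_library: PwmLibrary,
    p_threshold: float = 1e-4,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan promoters with every motif; report windows with exact p <= threshold.

    Scores are log2 odds against the library background with a 1e-4
    probability floor; N bases contribute 0 (background probability).
    Per-score p-values come from the exact null distribution of the window
    score under the background model, computed by dynamic programming on
    scores discretized to 1e-3 bits; the reverse strand is scored with the
    reverse-complement matrix and its own null.
    """
    bg = np.asarray(pwm_library.background, dtype=float)
    hits: list[MotifHit] = []
    encoded = {
        gid: np.array([_BASE_CODE[ch] for ch in seq.upper()], dtype=np.int64)
        for gid, seq in promoters.sequences.items()
    }
    for motif_id, pwm in pwm_library.motifs.items():
        w = np.asarray(pwm).shape[1]
        mats = [("+", _floored_logodds(pwm, bg))]
        if both_strands:
            mats.append(("-", _revcomp_matrix(mats[0][1][:4])))
        per_strand = []
        for strand, mat in mats:
            mat_int = np.round(mat / _SCORE_BIN).astype(np.int64)
            tail, lo = _null_tail(mat_int, bg)
            per_strand.append((strand, mat, mat_int, tail, lo))
        too_wide = [g for g, codes in encoded.items() if codes.size < w]
        if too_wide:
            warnings.warn(
                f"motif {motif_id} (width {w}) wider than {len(too_wide)} promoter(s); skipped there",
                stacklevel=2,
            )
        for gid, codes in encoded.items():
            if codes.size < w:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(codes, w)
            pos_idx = np.arange(w)
            for strand, mat, mat_int, tail, lo in per_strand:
                iscores = mat_int[windows, pos_idx].sum(axis=1)
                idx = np.clip(iscores - lo, 0, tail.size - 1)
                pvals = tail[idx]
                pvals = np.where(iscores - lo < 0, 1.0, pvals)
                sig = np.flatnonzero(pvals <= p_threshold)
                scores = None
                if sig.size:
                    scores = mat[windows[sig], pos_idx].sum(axis=1)
                for rank, off in enumerate(sig):
                    hits.append(
                        MotifHit(
                            motif_id=motif_id,
                            gene_id=gid,
                            offset=int(off),
                            strand=strand,
                            score=float(scores[rank]),
                            p_value=float(pvals[off]),
                        )
                    )
    return hits


def build_state_network(
    state: TranscriptionalState,
    motif_hits: list[MotifHit],
    tf_to_motifs: dict[str, list[str] | tuple[str, ...]],
) -> list[RegulatoryEdge]:
    """TF -> target edges for one state.

    An edge requires a differentially expressed TF, a target in the state's
    DEG set, and a motif hit for one of the TF's motifs in the target's
    promoter.  Sign: activation when the TF and target DEG directions
    agree in the comparison, inhibition otherwise.  TFs with no mapped
    motif contribute no edges.
    """
    hits_by_motif_gene: dict[tuple[str, str], MotifHit] = {}
    for h in motif_hits:
        key = (h.motif_id, h.gene_id)
        prev = hits_by_motif_gene.get(key)
        if prev is None or h.p_value < prev.p_value:
            hits_by_motif_gene[key] = h
    edges: list[RegulatoryEdge] = []
    for tf in sorted(state.tfs):
        motifs = tf_to_motifs.get(tf, ())
        for target in sorted(state.direction):
            if target == tf:
                continue
            best: MotifHit | None = None
            for m in motifs:
                h = hits_by_motif_gene.get((m, target))
                if h is not None and (best is None or h.p_value < best.p_value):
                    best = h
            if best is None:
                continue
            sign = (
                "activation"
                if state.direction[tf] == state.direction[target]
                else "inhibition"
            )
            edges.append(
                RegulatoryEdge(
                    tf_gene_id=tf,
                    target_gene_id=target,
                    state=state.label,
                    sign=sign,
                    hit=best,
                )
            )
    return edges


def count_pairs(edges: list[RegulatoryEdge]) -> tuple[pd.DataFrame, list[str]]:
    """Per-state activation/inhibition counts and TFs active in > 1 state."""
    counts: dict[str, dict[str, int]] = {}
    tf_states: dict[str, set[str]] = {}
    for e in edges:
        counts.setdefault(e.state, {"activation": 0, "inhibition": 0})[e.sign] += 1
        tf_states.setdefault(e.tf_gene_id, set()).add(e.state)
    df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    if df.empty:
        df = pd.DataFrame(columns=["activation", "inhibition"]).astype(int)
    multi = sorted(tf for tf, states in tf_states.items() if len(states) > 1)
    return df, multi


def edges_to_frame(edges: list[RegulatoryEdge]) -> pd.DataFrame:
    """Flat TSV-ready view of a regulatory edge list."""
    return pd.DataFrame(
        [
            {
                "tf": e.tf_gene_id,
                "target": e.target_gene_id,
                "state": e.state,
                "sign": e.sign,
                "motif": e.hit.motif_id,
                "offset": e.hit.offset,
                "strand": e.hit.strand,
                "score": e.hit.score,
                "p_value": e.hit.p_value,
            }
            for e in edges
        ],
        columns=["tf", "target", "state", "sign", "motif", "offset", "strand", "score", "p_value"],
    )
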