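"""Synthetic time-course generators with planted ground truth.

The generators emulate the statistical structure the downstream analysis
assumes: a 4-timepoint (D0/D4/D8/D12), 3-replicate expression design with
four temporal archetype clusters; one planted DNB module whose
within-module correlation and standard deviation spike at a chosen
tipping timepoint while its coupling to the rest of the transcriptome
stays low; promoters with planted consensus motif instances for chosen
TF -> target pairs; and a targeted metabolite panel with planted
per-timepoint fold-changes.

Noise model: multivariate normal on the log2 scale, exponentiated
(log-normal abundances).  The DNB correlation structure is imposed by a
single shared factor per timepoint: members load sqrt(rho_in), outside
genes load rho_out / sqrt(rho_in), which yields exactly the requested
member-member and member-outside correlations and is positive
semi-definite by construction.  All generators are pure functions of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    BASES,
    ExpressionMatrix,
    MetaboliteTable,
    PromoterSet,
    PwmLibrary,
    SampleDesign,
    TfAnnotation,
    ValidationError,
)

__all__ = [
    "ClusterSpec",
    "DnbSpec",
    "TfSpec",
    "MetSpec",
    "SimulationConfig",
    "PromoterTruth",
    "simulate_timecourse",
    "simulate_promoters",
    "simulate_metabolome",
    "default_config",
]

DEFAULT_TIMEPOINTS = ("D0", "D4", "D8", "D12")
# four temporal archetypes mirroring a dip-recover / rise / fall / pulse design
DEFAULT_ARCHETYPES: tuple[tuple[str, tuple[float, ...]], ...] = (
    ("down_up", (0.0, -2.0, -1.0, 1.0)),
    ("monotone_up", (-1.5, -0.5, 0.5, 1.5)),
    ("monotone_down", (1.5, 0.5, -0.5, -1.5)),
    ("up_down", (-1.0, 1.5, 0.5, -1.0)),
)


@dataclass(frozen=True)
class ClusterSpec:
    """One temporal archetype: mean log2 offsets per timepoint + iid noise."""

    name: str
    profile: tuple[float, ...]  # log2 offsets, one per timepoint
    n_genes: int = 100
    noise_sd: float = 0.3  # log2 scale


@dataclass(frozen=True)
class DnbSpec:
    """Planted DNB module: correlation/variance spike at one timepoint."""

    module_size: int = 20
    tipping_index: int = 1
    rho_in_pre: float = 0.2
    rho_in_at_tip: float = 0.9
    rho_out: float = 0.1
    sd_multiplier_at_tip: float = 3.0
    base_sd: float = 0.5  # log2 scale


@dataclass(frozen=True)
class TfSpec:
    """Planted promoter motifs for TF -> target pairs."""

    n_tfs: int = 5
    targets_per_tf: int = 10
    motif_width: int = 8
    promoter_length: int = 1000
    insertion_rate: float = 1.0
    background: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    consensus_prob: float = 0.97  # PWM probability on the consensus base


@dataclass(frozen=True)
class MetSpec:
    """Metabolite panel with planted per-timepoint log2 offsets."""

    n_metabolites: int = 50
    n_planted_up: int = 14
    n_planted_down: int = 2
    planted_log2fc: float = 2.0
    cv: float = 0.1  # coefficient of variation on the raw scale
    n_per_group: int = 5


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    baseline_log2: float = 6.0
    cluster_spec: tuple[ClusterSpec, ...] = tuple(
        ClusterSpec(name, profile) for name, profile in DEFAULT_ARCHETYPES
    )
    n_null_genes: int = 100  # flat, uncorrelated background genes
    dnb_spec: DnbSpec = field(default_factory=DnbSpec)
    tf_spec: TfSpec = field(default_factory=TfSpec)
    met_spec: MetSpec = field(default_factory=MetSpec)

    def __post_init__(self) -> None:
        d = self.dnb_spec
        if not (0.0 <= d.rho_out < d.rho_in_at_tip <= 1.0):
            raise ValidationError("need 0 <= rho_out < rho_in_at_tip <= 1")
        if not 0.0 < d.rho_in_pre <= 1.0:
            raise ValidationError("rho_in_pre must be in (0, 1]")
        for rho_in in (d.rho_in_pre, d.rho_in_at_tip):
            if d.rho_out / np.sqrt(rho_in) > 1.0:
                raise ValidationError(
                    "DNB block not positive semi-definite: outside factor loading "
                    f"rho_out/sqrt(rho_in) = {d.rho_out / np.sqrt(rho_in):.3f} > 1"
                )
        if not 0 <= d.tipping_index < len(self.timepoints):
            raise ValidationError("tipping_index outside the timepoint range")
        if d.module_size < 2 or self.n_replicates < 2:
            raise ValidationError("module_size and n_replicates must be >= 2")
        for cs in self.cluster_spec:
            if len(cs.profile) != len(self.timepoints):
                raise ValidationError(
                    f"cluster {cs.name!r}: profile length != number of timepoints"
                )
            if cs.n_genes < 1 or cs.noise_sd < 0:
                raise ValidationError(f"cluster {cs.name!r}: invalid counts")


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    return SimulationConfig(seed=seed, **overrides)


def _design_frame(timepoints: tuple[str, ...], n_replicates: int) -> SampleDesign:
    rows = []
    for tp in timepoints:
        for r in range(1, n_replicates + 1):
            rows.append((f"{tp}_r{r}", tp, r))
    df = pd.DataFrame(rows, columns=["sample", "timepoint", "replicate"]).set_index("sample")
    return SampleDesign(df)


def simulate_timecourse(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, dict[str, str], list[str]]:
    """Expression matrix + (gene -> archetype label) truth + DNB member list.

    Cluster genes follow their archetype mean profile with independent
    log2 noise; DNB members are flat in mean but share a per-timepoint
    factor giving correlation rho_in_pre (rho_in_at_tip at the tip) and a
    base_sd scaled by sd_multiplier_at_tip there; null genes are flat and
    independent.  Identical config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    tps = config.timepoints
    n_rep = config.n_replicates
    d = config.dnb_spec

    gene_ids: list[str] = []
    truth: dict[str, str] = {}
    profiles: list[np.ndarray] = []
    noise_sds: list[float] = []
    for cs in config.cluster_spec:
        for i in range(cs.n_genes):
            gid = f"{cs.name}_{i + 1:04d}"
            gene_ids.append(gid)
            truth[gid] = cs.name
            profiles.append(np.asarray(cs.profile, dtype=float))
            noise_sds.append(cs.noise_sd)
    dnb_members = [f"DNB_{i + 1:03d}" for i in range(d.module_size)]
    for gid in dnb_members:
        gene_ids.append(gid)
        truth[gid] = "dnb"
        profiles.append(np.zeros(len(tps)))
        noise_sds.append(d.base_sd)
    for i in range(config.n_null_genes):
        gid = f"null_{i + 1:04d}"
        gene_ids.append(gid)
        truth[gid] = "null"
        profiles.append(np.zeros(len(tps)))
        noise_sds.append(0.3)

    n_genes = len(gene_ids)
    prof = np.vstack(profiles)  # genes x timepoints
    sds = np.asarray(noise_sds)
    is_dnb = np.array([g.startswith("DNB_") for g in gene_ids])

    cols: dict[str, np.ndarray] = {}
    for t_idx, tp in enumerate(tps):
        at_tip = t_idx == d.tipping_index
        rho_in = d.rho_in_at_tip if at_tip else d.rho_in_pre
        a = np.sqrt(rho_in)  # member factor loading
        b = d.rho_out / a  # outside factor loading
        member_sd = d.base_sd * (d.sd_multiplier_at_tip if at_tip else 1.0)
        for r in range(1, n_rep + 1):
            f = rng.standard_normal()  # shared factor, one draw per sample
            e = rng.standard_normal(n_genes)
            z = np.where(
                is_dnb,
                member_sd * (a * f + np.sqrt(1.0 - a * a) * e),
                sds * (b * f + np.sqrt(1.0 - b * b) * e),
            )
            cols[f"{tp}_r{r}"] = config.baseline_log2 + prof[:, t_idx] + z
    log2_values = pd.DataFrame(cols, index=gene_ids)
    values = (2.0**log2_values).astype(float)
    design = _design_frame(tps, n_rep)
    return ExpressionMatrix(values, design), truth, dnb_members


@dataclass(frozen=True)
class PromoterTruth:
    """Planted motif instances: (tf, motif_id, target, offset) records."""

    hits: tuple[tuple[str, str, str, int], ...]
    tf_to_motifs: dict[str, tuple[str, ...]]
    consensus: dict[str, str]  # motif id -> consensus sequence


def simulate_promoters(
    config: SimulationConfig,
    tf_targets: dict[str, list[str] | tuple[str, ...]],
) -> tuple[PromoterSet, PwmLibrary, PromoterTruth]:
    """Background promoters with exact-consensus motif instances planted.

    One motif per TF (random consensus of the configured width, PWM
    concentrated on the consensus).  Every promoter in the union of all
    target lists is generated i.i.d. from the background; for each
    TF -> target pair a consensus copy is inserted at a recorded uniform
    offset with probability ``insertion_rate``.
    """
    spec = config.tf_spec
    if spec.motif_width > spec.promoter_length:
        raise ValidationError("motif wider than the promoter length")
    rng = np.random.default_rng(config.seed + 1)
    bg = np.asarray(spec.background, dtype=float)
    bg = bg / bg.sum()
    off_prob = (1.0 - spec.consensus_prob) / 3.0

    motifs: dict[str, np.ndarray] = {}
    consensus: dict[str, str] = {}
    tf_to_motifs: dict[str, tuple[str, ...]] = {}
    for tf in tf_targets:
        motif_id = f"M_{tf}"
        cons_idx = rng.integers(0, 4, size=spec.motif_width)
        mat = np.full((4, spec.motif_width), off_prob)
        mat[cons_idx, np.arange(spec.motif_width)] = spec.consensus_prob
        motifs[motif_id] = mat
        consensus[motif_id] = "".join(BASES[i] for i in cons_idx)
        tf_to_motifs[tf] = (motif_id,)

    all_targets: list[str] = []
    for targets in tf_targets.values():
        for t in targets:
            if t not in all_targets:
                all_targets.append(t)
    seqs = {
        t: "".join(rng.choice(list(BASES), size=spec.promoter_length, p=bg))
        for t in all_targets
    }
    hits: list[tuple[str, str, str, int]] = []
    for tf, targets in tf_targets.items():
        motif_id = tf_to_motifs[tf][0]
        cons = consensus[motif_id]
        for t in targets:
            if rng.random() >= spec.insertion_rate:
                continue
            off = int(rng.integers(0, spec.promoter_length - spec.motif_width + 1))
            s = seqs[t]
            seqs[t] = s[:off] + cons + s[off + spec.motif_width :]
            hits.append((tf, motif_id, t, off))
    return (
        PromoterSet(seqs),
        PwmLibrary(motifs, bg),
        PromoterTruth(hits=tuple(hits), tf_to_motifs=tf_to_motifs, consensus=consensus),
    )


def simulate_tf_annotation(
    tf_targets: dict[str, list[str] | tuple[str, ...]],
    families: tuple[str, ...] = ("zf-C2H2", "Homeobox", "TF_bZIP", "RHD", "bHLH"),
) -> TfAnnotation:
    """Round-robin family assignment for the simulated TFs."""
    return TfAnnotation(
        {tf: families[i % len(families)] for i, tf in enumerate(tf_targets)}
    )


def simulate_metabolome(
    config: SimulationConfig,
) -> tuple[MetaboliteTable, dict[str, set[str]]]:
    """Metabolite panel + truth DRM sets per pairwise comparison.

    Planted metabolites shift their group means by the configured log2
    fold-change from the second timepoint onward (up for ``n_planted_up``,
    down at 3/4 strength for ``n_planted_down``); the rest are flat.
    Truth records, per comparison ``B_vs_A``, every metabolite whose
    planted |log2FC| between the two timepoints is >= 1.  Concentrations
    are log-normal with the configured raw-scale coefficient of variation.
    """
    spec = config.met_spec
    tps = config.timepoints
    n_planted = spec.n_planted_up + spec.n_planted_down
    if n_planted > spec.n_metabolites:
        raise ValidationError("more planted metabolites than panel size")
    rng = np.random.default_rng(config.seed + 2)

    offsets = np.zeros((spec.n_metabolites, len(tps)))
    names = []
    for i in range(spec.n_metabolites):
        if i < spec.n_planted_up:
            names.append(f"met_up_{i + 1:02d}")
            offsets[i, 1:] = spec.planted_log2fc
        elif i < n_planted:
            names.append(f"met_down_{i - spec.n_planted_up + 1:02d}")
            offsets[i, 1:] = -0.75 * spec.planted_log2fc
        else:
            names.append(f"met_null_{i - n_planted + 1:02d}")

    sigma_log2 = np.sqrt(np.log(1.0 + spec.cv**2)) / np.log(2.0)
    base = rng.uniform(3.0, 8.0, size=spec.n_metabolites)  # log2 baseline level
    cols: dict[str, np.ndarray] = {}
    rows = []
    for t_idx, tp in enumerate(tps):
        for r in range(1, spec.n_per_group + 1):
            noise = rng.standard_normal(spec.n_metabolites) * sigma_log2
            cols[f"{tp}_r{r}"] = 2.0 ** (base + offsets[:, t_idx] + noise)
            rows.append((f"{tp}_r{r}", tp, r))
    design = SampleDesign(
        pd.DataFrame(rows, columns=["sample", "timepoint", "replicate"]).set_index("sample")
    )
    table = MetaboliteTable(pd.DataFrame(cols, index=names), design)

    truth: dict[str, set[str]] = {}
    for i_a, a in enumerate(tps):
        for b in tps[i_a + 1 :]:
            j_a, j_b = tps.index(a), tps.index(b)
            delta = offsets[:, j_b] - offsets[:, j_a]
            truth[f"{b}_vs_{a}"] = {names[i] for i in range(len(names)) if abs(delta[i]) >= 1.0}
    return table, truth
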