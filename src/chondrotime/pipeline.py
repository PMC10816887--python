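"""End-to-end orchestration: simulate inputs, run all stages, write a manifest.

`run_pipeline` executes differential expression -> temporal clustering ->
regulatory network -> DNB -> enrichment -> metabolomics -> integration on
files referenced by a `RunConfig`, writing per-stage TSV outputs, a JSON
run manifest (parameters, seed, per-output SHA-256 checksums) and a log.
Stages are skippable; a failing stage aborts with its name while keeping
the upstream outputs on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, dnb, enrichment, grn, integration, io, metabolomics, timeclust
from .core import ValidationError
from .simulate import (
    SimulationConfig,
    simulate_metabolome,
    simulate_promoters,
    simulate_tf_annotation,
    simulate_timecourse,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "write_simulation"]

log = logging.getLogger("chondrotime")

STAGES = (
    "diffexpr",
    "timeclust",
    "grn",
    "dnb",
    "enrichment",
    "metabolomics",
    "integration",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    expression: str
    design: str
    out_dir: str
    metabolites: str | None = None
    met_design: str | None = None
    promoters: str | None = None
    motifs: str | None = None
    tf_annotation: str | None = None
    tf_motif_map: str | None = None
    network: str | None = None
    gene_sets: str | None = None
    pathway_map: str | None = None
    seed: int = 0
    lfc_min: float = 1.0
    p_max: float = 0.05
    n_clusters: int = 4
    fuzzifier: float = 1.25
    min_membership: float = 0.3
    pwm_p_threshold: float = 1e-4
    dnb_min_size: int = 5
    dnb_max_size: int = 100
    dnb_epsilon: float = 0.05
    gsva_tau: float = 0.25
    fc_low: float = 0.5
    fc_high: float = 2.0
    n_orth: int = 1
    alpha: float = 0.05
    skip: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "skip" in data:
            data["skip"] = tuple(data["skip"])
        return cls(**data)

    def validate(self) -> None:
        enabled = [s for s in STAGES if s not in self.skip]
        required: list[tuple[str, str | None]] = [
            ("expression", self.expression),
            ("design", self.design),
        ]
        if "grn" in enabled:
            required += [
                ("promoters", self.promoters),
                ("motifs", self.motifs),
                ("tf_annotation", self.tf_annotation),
                ("tf_motif_map", self.tf_motif_map),
            ]
        if "dnb" in enabled:
            required += [("network", self.network)]
        if "enrichment" in enabled:
            required += [("gene_sets", self.gene_sets)]
        if "metabolomics" in enabled:
            required += [("metabolites", self.metabolites), ("met_design", self.met_design)]
        if "integration" in enabled:
            required += [("pathway_map", self.pathway_map)]
        for name, path in required:
            if path is None:
                raise ValidationError(f"config field {name!r} is required but unset")
            if not Path(path).exists():
                raise ValidationError(f"config field {name!r}: file not found: {path}")
        for bound, value in (
            ("lfc_min", self.lfc_min),
            ("p_max", self.p_max),
            ("alpha", self.alpha),
        ):
            if value < 0:
                raise ValidationError(f"{bound} must be non-negative")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages and return the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(filename=out / "run.log", level=logging.INFO, force=True)
    manifest: dict = {
        "package": "chondrotime",
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if not isinstance(v, (dict,))
        },
        "stages": [],
        "outputs": {},
    }
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame, index: bool = True) -> None:
        path = out / name
        _write_tsv(df, path, index=index)
        written.append(path)

    matrix = io.read_expression(config.expression, config.design)
    design = matrix.design
    logm = diffexpr.log_transform(matrix)
    stage = ""
    results: dict[str, diffexpr.DiffResult] = {}
    deg_sets: dict[str, set[str]] = {}
    union: list[str] = []
    try:
        if "diffexpr" not in config.skip:
            stage = "diffexpr"
            log.info("stage diffexpr")
            results = diffexpr.all_pairwise(logm, design)
            for comp, res in results.items():
                deg_sets[comp] = diffexpr.filter_degs(res, config.lfc_min, config.p_max)
                t = res.table.copy()
                t["deg_flag"] = t.index.isin(deg_sets[comp])
                emit(f"diffexpr_{comp}.tsv", t)
            union = diffexpr.union_degs(deg_sets)
            emit("degs_union.tsv", pd.DataFrame({"gene": union}), index=False)
            manifest["stages"].append(stage)

        if "timeclust" not in config.skip:
            stage = "timeclust"
            log.info("stage timeclust")
            profiles = timeclust.build_profiles(logm, design, set(union))
            fc = timeclust.fuzzy_cmeans(
                profiles, c=config.n_clusters, m=config.fuzzifier, seed=config.seed
            )
            labels = timeclust.assign_clusters(fc, config.min_membership)
            emit("cluster_membership.tsv", fc.membership)
            emit("cluster_centers.tsv", fc.centers)
            emit("cluster_labels.tsv", labels.rename("cluster").to_frame())
            manifest["stages"].append(stage)

        if "grn" not in config.skip:
            stage = "grn"
            log.info("stage grn")
            promoters = io.read_fasta(config.promoters)
            pwms = io.read_pwm(config.motifs)
            annot = io.read_tf_annotation(config.tf_annotation)
            tf_map_df = pd.read_csv(config.tf_motif_map, sep="\t", dtype=str)
            tf_to_motifs: dict[str, list[str]] = {}
            for _, row in tf_map_df.iterrows():
                tf_to_motifs.setdefault(row["tf"], []).append(row["motif"])
            hits = grn.pwm_scan(promoters, pwms, p_threshold=config.pwm_p_threshold)
            # consecutive-stage comparisons define the transcriptional states
            tps = design.timepoints
            edges: list[grn.RegulatoryEdge] = []
            enrich_frames = []
            for i in range(len(tps) - 1):
                a, b = tps[i], tps[i + 1]
                comp = f"{b}_vs_{a}"
                res = results.get(comp)
                if res is None:
                    res = diffexpr.moderated_ttest(logm, design, a, b)
                degs = diffexpr.filter_degs(res, config.lfc_min, config.p_max)
                direction = {
                    g: "up" if res.table.loc[g, "log2_fc"] > 0 else "down" for g in degs
                }
                tfs = frozenset(g for g in degs if annot.is_tf(g))
                state = grn.TranscriptionalState(
                    label=f"state{i + 1}", comparison=comp, direction=direction, tfs=tfs
                )
                edges += grn.build_state_network(state, hits, tf_to_motifs)
                fam = grn.tf_family_enrichment(set(tfs), annot, set(annot.family_of))
                enrich_frames.append(fam.assign(state=state.label))
            emit("grn_edges.tsv", grn.edges_to_frame(edges), index=False)
            counts, multi = grn.count_pairs(edges)
            emit("grn_pair_counts.tsv", counts)
            emit(
                "grn_multistate_tfs.tsv",
                pd.DataFrame({"tf": multi}),
                index=False,
            )
            emit("grn_family_enrichment.tsv", pd.concat(enrich_frames))
            manifest["stages"].append(stage)

        if "dnb" not in config.skip:
            stage = "dnb"
            log.info("stage dnb")
            network = io.read_edges(config.network)
            analyzed = logm.loc[[g for g in logm.index if g in set(union)]] if union else logm
            if len(analyzed) < config.dnb_min_size:
                analyzed = logm
            result = dnb.criticality_curve(
                analyzed,
                design,
                min_size=config.dnb_min_size,
                max_size=config.dnb_max_size,
                epsilon=config.dnb_epsilon,
            )
            emit("dnb_ci_curve.tsv", result.ci_curve.rename("ci").to_frame())
            emit(
                "dnb_members.tsv",
                pd.DataFrame({"gene": list(result.members)}),
                index=False,
            )
            nodes, nedges = dnb.dnb_neighborhood(result.members, network, set(union))
            dropped = len([m for m in result.members if m not in network.graph])
            emit(
                "dnb_neighborhood_edges.tsv",
                pd.DataFrame(nedges, columns=["a", "b"]),
                index=False,
            )
            manifest["dnb_tipping_timepoint"] = result.tipping_timepoint
            manifest["dnb_members_outside_network"] = dropped
            manifest["stages"].append(stage)

        if "enrichment" not in config.skip:
            stage = "enrichment"
            log.info("stage enrichment")
            sets = io.read_gmt(config.gene_sets)
            ora_res = enrichment.ora(set(union), sets, set(matrix.gene_ids))
            emit("ora.tsv", ora_res.table)
            scores = enrichment.sample_scores(logm, sets, tau=config.gsva_tau)
            emit("sample_scores.tsv", scores)
            sig = enrichment.score_significance(scores, design, alpha=config.alpha)
            emit("score_significance.tsv", sig, index=False)
            manifest["stages"].append(stage)

        screens: dict[str, metabolomics.MetaboliteScreen] = {}
        if "metabolomics" not in config.skip:
            stage = "metabolomics"
            log.info("stage metabolomics")
            met = io.read_metabolites(config.metabolites, config.met_design)
            screens = metabolomics.all_pairwise_screens(
                met, met.design, fc_low=config.fc_low, fc_high=config.fc_high, n_orth=config.n_orth
            )
            for comp, scr in screens.items():
                emit(f"metab_screen_{comp}.tsv", scr.table)
            multi = metabolomics.multigroup_drm(met, met.design, n_orth=config.n_orth)
            emit("metab_screen_multigroup.tsv", multi.table)
            summary = metabolomics.drm_sets(screens)
            (out / "metab_set_summary.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True)
            )
            written.append(out / "metab_set_summary.json")
            manifest["fraction_increased"] = summary["fraction_increased"]
            manifest["stages"].append(stage)

        if "integration" not in config.skip:
            stage = "integration"
            log.info("stage integration")
            pmap = io.read_pathway_map(config.pathway_map)
            met = io.read_metabolites(config.metabolites, config.met_design)
            drm_union: set[str] = set()
            for scr in screens.values():
                drm_union |= scr.drms
            joint = integration.joint_enrichment(
                set(union),
                drm_union,
                pmap,
                set(matrix.gene_ids),
                set(met.metabolite_ids),
                alpha=config.alpha,
            )
            emit("joint_pathways.tsv", joint)
            frames = [
                integration.pathway_projection_table(results, screens, pmap, pid)
                for pid in pmap.pathways
            ]
            emit("pathway_projection.tsv", pd.concat(frames, ignore_index=True), index=False)
            manifest["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        raise PipelineError(stage or "setup", str(exc)) from exc

    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(written)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def write_simulation(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Generate every pipeline input from one simulation config.

    Writes expression/design/metabolite TSVs, promoter FASTA, MEME motif
    file, TF annotation and TF->motif map, an interaction edge list over
    the DNB members and cluster genes, gene sets, a pathway map, and
    truth.json with every planted ground-truth record.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth_clusters, dnb_members = simulate_timecourse(config)
    io.write_expression(matrix, out / "expression.tsv")
    io.write_design(matrix.design, out / "design.tsv")

    # TFs and their targets are archetype genes, so both sides can be DEGs
    genes = matrix.gene_ids
    spec = config.tf_spec
    pool = [g for g in genes if not g.startswith(("DNB_", "null_"))]
    rng = np.random.default_rng(config.seed + 3)
    picked = rng.choice(len(pool), size=spec.n_tfs, replace=False)
    tfs = [pool[j] for j in picked]
    target_pool = [g for g in pool if g not in set(tfs)]
    tf_targets = {
        tf: [
            target_pool[j]
            for j in rng.choice(len(target_pool), size=spec.targets_per_tf, replace=False)
        ]
        for tf in tfs
    }
    promoters, pwms, ptruth = simulate_promoters(config, tf_targets)
    io.write_fasta(promoters, out / "promoters.fasta")
    io.write_pwm(pwms, out / "motifs.meme")
    annot = simulate_tf_annotation(tf_targets)
    io.write_tf_annotation(annot, out / "tf_annotation.tsv")
    pd.DataFrame(
        [(tf, m) for tf, motifs in ptruth.tf_to_motifs.items() for m in motifs],
        columns=["tf", "motif"],
    ).to_csv(out / "tf_motif_map.tsv", sep="\t", index=False)

    # interaction network: a chain through the DNB members plus random pairs
    edges = [(dnb_members[i], dnb_members[i + 1]) for i in range(len(dnb_members) - 1)]
    for _ in range(len(pool)):
        i, j = rng.choice(len(pool), size=2, replace=False)
        if pool[i] != pool[j]:
            edges.append((pool[i], pool[j]))
    seen = set()
    lines = []
    for a, b in edges:
        key = tuple(sorted((a, b)))
        if key not in seen:
            seen.add(key)
            lines.append(f"{a}\t{b}")
    (out / "network.tsv").write_text("\n".join(lines) + "\n")

    # gene sets: one per archetype plus a random set
    gmt_lines = []
    for cs in config.cluster_spec:
        members = [g for g, lab in truth_clusters.items() if lab == cs.name]
        gmt_lines.append("\t".join([f"set_{cs.name}", cs.name, *members]))
    rand = [genes[j] for j in rng.choice(len(genes), size=30, replace=False)]
    gmt_lines.append("\t".join(["set_random", "random", *dict.fromkeys(rand)]))
    (out / "gene_sets.gmt").write_text("\n".join(gmt_lines) + "\n")

    met_table, met_truth = simulate_metabolome(config)
    io.write_metabolites(met_table, out / "metabolites.tsv")
    io.write_design(met_table.design, out / "met_design.tsv")

    # pathway map: planted pathway joins up-shifted metabolites with the
    # first archetype's genes; a null pathway holds null members
    first = config.cluster_spec[0].name
    p_genes = [g for g, lab in truth_clusters.items() if lab == first][:30]
    p_mets = [m for m in met_table.metabolite_ids if m.startswith("met_up")]
    n_genes = [g for g in genes if g.startswith("null_")][:30]
    n_mets = [m for m in met_table.metabolite_ids if m.startswith("met_null")][:10]
    rows = (
        [("pw_planted", g, "gene") for g in p_genes]
        + [("pw_planted", m, "metabolite") for m in p_mets]
        + [("pw_null", g, "gene") for g in n_genes]
        + [("pw_null", m, "metabolite") for m in n_mets]
    )
    pd.DataFrame(rows, columns=["pathway", "member", "kind"]).to_csv(
        out / "pathway_map.tsv", sep="\t", index=False
    )

    truth = {
        "clusters": truth_clusters,
        "dnb_members": dnb_members,
        "dnb_tipping_timepoint": config.timepoints[config.dnb_spec.tipping_index],
        "planted_motif_hits": [list(h) for h in ptruth.hits],
        "motif_consensus": ptruth.consensus,
        "drm_truth": {k: sorted(v) for k, v in met_truth.items()},
        "seed": config.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth

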