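"""Joint projection of DEGs and DRMs onto shared pathways.

Each pathway's gene side and metabolite side are tested separately for
over-representation (hypergeometric upper tail, BH within each side);
a pathway is flagged *joint* when both sides pass the adjusted-p
threshold.  A Fisher combination chi2 = -2(ln p_gene + ln p_met) with
4 degrees of freedom is reported as an optional summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneSetCollection, PathwayMap, ValidationError
from .diffexpr import DiffResult
from .enrichment import bh_adjust, ora
from .metabolomics import MetaboliteScreen

__all__ = ["joint_enrichment", "pathway_projection_table", "sign_concordance"]


def _side_ora(
    query: set[str], members_of: dict[str, tuple[str, ...]], universe: set[str]
) -> pd.DataFrame:
    collection = GeneSetCollection(
        {pid: ("", tuple(m)) for pid, m in members_of.items() if m}
    )
    if not len(collection):
        return pd.DataFrame(columns=["k", "p_hyper", "overlap"])
    res = ora(query, collection, universe, min_size=1, max_size=10**9)
    return res.table


def joint_enrichment(
    deg_set: set[str],
    drm_set: set[str],
    pathway_map: PathwayMap,
    gene_universe: set[str],
    met_universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-pathway two-sided over-representation of DEGs and DRMs.

    A pathway with an empty side gets p = 1 on that side and can never be
    joint.  Columns: per-side overlap, raw and BH-adjusted p, the joint
    flag (both adjusted p <= alpha) and the Fisher-combined p.
    """
    if not gene_universe or not met_universe:
        raise ValidationError("gene and metabolite universes must be non-empty")
    pids = list(pathway_map.pathways)
    gene_side = _side_ora(
        set(deg_set), {pid: pathway_map.genes(pid) for pid in pids}, set(gene_universe)
    )
    met_side = _side_ora(
        set(drm_set),
        {pid: pathway_map.metabolites(pid) for pid in pids},
        set(met_universe),
    )
    rows = []
    for pid in pids:
        pg = float(gene_side["p_hyper"].get(pid, 1.0))
        pm = float(met_side["p_hyper"].get(pid, 1.0))
        rows.append(
            {
                "pathway": pid,
                "gene_overlap": gene_side["overlap"].get(pid, ""),
                "gene_k": int(gene_side["k"].get(pid, 0)),
                "p_gene": pg,
                "met_overlap": met_side["overlap"].get(pid, ""),
                "met_k": int(met_side["k"].get(pid, 0)),
                "p_met": pm,
            }
        )
    df = pd.DataFrame(rows).set_index("pathway")
    df["p_gene_adj"] = bh_adjust(df["p_gene"].to_numpy())
    df["p_met_adj"] = bh_adjust(df["p_met"].to_numpy())
    df["joint"] = (df["p_gene_adj"] <= alpha) & (df["p_met_adj"] <= alpha)
    chi2 = -2.0 * (np.log(df["p_gene"]) + np.log(df["p_met"]))
    df["fisher_chi2"] = chi2
    df["p_combined"] = stats.chi2.sf(chi2, df=4)
    return df


def pathway_projection_table(
    deg_results: dict[str, DiffResult],
    met_screens: dict[str, MetaboliteScreen],
    pathway_map: PathwayMap,
    pathway_id: str,
    missing_marker: str = "NA",
) -> pd.DataFrame:
    """Long-format per-member, per-comparison change table for one pathway.

    One row per (member, comparison): genes carry their log2 fold-change,
    metabolites their fold-change and direction; members absent from the
    data get the missing marker.
    """
    genes = pathway_map.genes(pathway_id)
    mets = pathway_map.metabolites(pathway_id)
    rows = []
    for comp, res in deg_results.items():
        for g in genes:
            if g in res.table.index:
                val = f"{res.table.loc[g, 'log2_fc']:.6g}"
            else:
                val = missing_marker
            rows.append((pathway_id, comp, g, "gene", val, missing_marker))
    for comp, scr in met_screens.items():
        for m in mets:
            if m in scr.table.index:
                val = f"{scr.table.loc[m, 'fold_change']:.6g}"
                direction = str(scr.table.loc[m, "direction"])
            else:
                val, direction = missing_marker, missing_marker
            rows.append((pathway_id, comp, m, "metabolite", val, direction))
    return pd.DataFrame(
        rows, columns=["pathway", "comparison", "member", "kind", "change", "direction"]
    )


def sign_concordance(
    deg_result: DiffResult,
    met_screen: MetaboliteScreen,
    pathway_map: PathwayMap,
    pathway_id: str,
) -> float:
    """Fraction of (gene, metabolite) pairs in a pathway moving the same way.

    A simple summary of gene-metabolite coupling defined by this package
    (not a literature statistic): gene sign from log2FC, metabolite sign
    from FC vs 1, averaged over all present pairs.  NaN when no pair is
    observable.
    """
    genes = [g for g in pathway_map.genes(pathway_id) if g in deg_result.table.index]
    mets = [m for m in pathway_map.metabolites(pathway_id) if m in met_screen.table.index]
    if not genes or not mets:
        return float("nan")
    gsign = np.sign(deg_result.table.loc[genes, "log2_fc"].to_numpy())
    msign = np.sign(np.log(met_screen.table.loc[mets, "fold_change"].to_numpy()))
    agree = (gsign[:, None] * msign[None, :]) > 0
    return float(agree.mean())
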