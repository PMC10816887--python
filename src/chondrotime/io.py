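"""Readers and writers for the pipeline's plain-text interchange formats.

Formats: TSV (expression, design, metabolites, edges, TF annotation,
pathway map), GMT (gene sets), FASTA (promoters, via Biopython), and
MEME-minimal motif text.  Every reader validates through the `core`
containers; every writer is the reader's inverse on valid data.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    BASES,
    ExpressionMatrix,
    GeneSetCollection,
    InteractionNetwork,
    MetaboliteTable,
    PathwayMap,
    PromoterSet,
    PwmLibrary,
    SampleDesign,
    TfAnnotation,
    ValidationError,
)

__all__ = [
    "read_design",
    "write_design",
    "read_expression",
    "write_expression",
    "read_metabolites",
    "write_metabolites",
    "read_gmt",
    "write_gmt",
    "read_pwm",
    "write_pwm",
    "read_edges",
    "write_edges",
    "read_fasta",
    "write_fasta",
    "read_tf_annotation",
    "write_tf_annotation",
    "read_pathway_map",
    "write_pathway_map",
]


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "timepoint": str})
    for col in ("sample", "timepoint", "replicate"):
        if col not in df.columns:
            raise ValidationError(f"design file {path}: missing column {col!r}")
    df = df.set_index("sample")[["timepoint", "replicate"]]
    df["replicate"] = df["replicate"].astype(int)
    return SampleDesign(df)


def write_design(design: SampleDesign, path: str | Path) -> None:
    out = design.table.reset_index(names="sample")
    out.to_csv(path, sep="\t", index=False)


def _read_grid(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate {what} id: {dup!r}")
    return df


def read_expression(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Load a genes x samples TSV (first column gene ids, header sample ids)
    together with its sample design table."""
    return ExpressionMatrix(_read_grid(path, "gene"), read_design(design_path))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.rename_axis("gene").to_csv(path, sep="\t")


def read_metabolites(path: str | Path, design_path: str | Path) -> MetaboliteTable:
    return MetaboliteTable(_read_grid(path, "metabolite"), read_design(design_path))


def write_metabolites(table: MetaboliteTable, path: str | Path) -> None:
    table.values.rename_axis("metabolite").to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs id, description and >=1 member"
                )
            sid, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if sid in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set id {sid!r}")
            # tolerate repeated members within a line; dedupe preserving order
            members = list(dict.fromkeys(members))
            sets[sid] = (desc, tuple(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, (desc, members) in collection.sets.items():
            fh.write("\t".join([sid, desc, *members]) + "\n")


def read_pwm(path: str | Path) -> PwmLibrary:
    """Parse a MEME-minimal motif file (letter-probability matrices)."""
    motifs: dict[str, np.ndarray] = {}
    background = np.full(4, 0.25)
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freq[b] for b in BASES])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            # seek the letter-probability header
            while i < len(lines) and "letter-probability" not in lines[i]:
                if lines[i].strip().startswith("MOTIF"):
                    raise ValidationError(
                        f"{path}: motif {name!r} has no letter-probability matrix"
                    )
                i += 1
            if i >= len(lines):
                raise ValidationError(
                    f"{path}: motif {name!r} has no letter-probability matrix"
                )
            rows = []
            i += 1
            while i < len(lines):
                stripped = lines[i].strip()
                if not stripped or not stripped[0].isdigit() and stripped[0] != ".":
                    break
                rows.append([float(x) for x in stripped.split()])
                i += 1
            if not rows:
                raise ValidationError(f"{path}: motif {name!r}: empty matrix")
            mat = np.array(rows).T  # file rows are positions; we store 4 x width
            if mat.shape[0] != 4:
                raise ValidationError(
                    f"{path}: motif {name!r}: expected 4 columns (A C G T), got {mat.shape[0]}"
                )
            colsums = mat.sum(axis=0)
            if np.abs(colsums - 1).max() > 1e-3:
                j = int(np.abs(colsums - 1).argmax())
                raise ValidationError(
                    f"{path}: motif {name!r}: position {j} probabilities sum to "
                    f"{colsums[j]:.4f}, not 1"
                )
            mat = mat / colsums  # renormalise printing round-off
            motifs[name] = mat
            continue
        i += 1
    return PwmLibrary(motifs, background)


def write_pwm(library: PwmLibrary, path: str | Path) -> None:
    buf = _io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\n")
    buf.write("Background letter frequencies\n")
    buf.write(
        " ".join(f"{b} {f:.6f}" for b, f in zip(BASES, library.background)) + "\n\n"
    )
    for name, mat in library.motifs.items():
        mat = np.asarray(mat)
        w = mat.shape[1]
        buf.write(f"MOTIF {name}\n")
        buf.write(f"letter-probability matrix: alength= 4 w= {w}\n")
        for j in range(w):
            buf.write(" ".join(f"{mat[i, j]:.6f}" for i in range(4)) + "\n")
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


def read_edges(path: str | Path) -> InteractionNetwork:
    """Two- or three-column TSV edge list; undirected, deduplicated."""
    edges: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: edge line needs two node ids")
            if len(parts) >= 3:
                edges.append((parts[0], parts[1], float(parts[2])))
            else:
                edges.append((parts[0], parts[1]))
    return InteractionNetwork.from_edges(edges)


def write_edges(network: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(network.graph.edges(data=True)):
            if "weight" in data:
                fh.write(f"{a}\t{b}\t{data['weight']}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_fasta(path: str | Path) -> PromoterSet:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"{path}: duplicate promoter id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValidationError(f"{path}: empty sequence for {rec.id!r}")
        seqs[rec.id] = seq
    return PromoterSet(seqs)


def write_fasta(promoters: PromoterSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gid, description="")
        for gid, seq in promoters.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_tf_annotation(path: str | Path) -> TfAnnotation:
    """TSV with columns gene, family; one family per gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene" not in df.columns or "family" not in df.columns:
        raise ValidationError(f"{path}: TF annotation needs columns gene, family")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: gene {dup!r} mapped to more than one family")
    return TfAnnotation(dict(zip(df["gene"], df["family"])))


def write_tf_annotation(annotation: TfAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        {"gene": list(annotation.family_of), "family": list(annotation.family_of.values())}
    ).to_csv(path, sep="\t", index=False)


def read_pathway_map(path: str | Path) -> PathwayMap:
    """Long-format TSV with columns pathway, member, kind (gene|metabolite)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("pathway", "member", "kind"):
        if col not in df.columns:
            raise ValidationError(f"{path}: pathway map needs columns pathway, member, kind")
    bad = ~df["kind"].isin(["gene", "metabolite"])
    if bad.any():
        raise ValidationError(
            f"{path}: unknown member kind {df['kind'][bad].iloc[0]!r}"
        )
    pathways: dict[str, tuple[list[str], list[str]]] = {}
    for _, row in df.iterrows():
        genes, mets = pathways.setdefault(row["pathway"], ([], []))
        (genes if row["kind"] == "gene" else mets).append(row["member"])
    return PathwayMap(
        {pid: (tuple(dict.fromkeys(g)), tuple(dict.fromkeys(m))) for pid, (g, m) in pathways.items()}
    )


def write_pathway_map(pmap: PathwayMap, path: str | Path) -> None:
    rows: list[tuple[str, str, str]] = []
    for pid, (genes, mets) in pmap.pathways.items():
        rows += [(pid, g, "gene") for g in genes]
        rows += [(pid, m, "metabolite") for m in mets]
    pd.DataFrame(rows, columns=["pathway", "member", "kind"]).to_csv(
        path, sep="\t", index=False
    )
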