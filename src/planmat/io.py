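"""Readers and writers for the dialects the pipeline consumes and produces.

Tabular evidence arrives as InterProScan TSV, BLAST tabular (outfmt 6) and
headered predictor summary TSVs; expression data as MatrixMarket sparse
counts with gene/barcode lists; gene sets as GMT. All writers round-trip
losslessly through the matching reader. Malformed rows raise with the
offending line number.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .annotate import EvidenceBundle
from .types import (
    BlastHit,
    CellAnnotation,
    DomainCatalog,
    DomainHit,
    ExpressionMatrix,
    GeneSet,
    HumanMatrisomeMap,
    MatrisomeCall,
    ProteinRecord,
    to_dataframe,
)

# ---------------------------------------------------------------- catalogs


def load_domain_catalog(path: Optional[Path] = None) -> DomainCatalog:
    """Load the matrisome-defining/excluding domain dictionary.

    Defaults to the catalog packaged with the library. TSV columns:
    domain_id, role (defining|excluding), categories (one category for
    defining rows; comma list or ``all`` for excluding rows), keep_list
    (0/1), description.
    """
    if path is None:
        src = resources.files("planmat").joinpath("data/domain_catalog.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    defining: dict[str, str] = {}
    excluding: dict[str, set[str]] = {}
    keep: set[str] = set()
    all_cats = {"core", "affiliated", "regulator", "secreted"}
    for i, row in df.iterrows():
        role = row["role"]
        if role == "defining":
            defining[row["domain_id"]] = row["categories"]
        elif role == "excluding":
            cats = all_cats if row["categories"] == "all" else set(
                row["categories"].split(",")
            )
            excluding.setdefault(row["domain_id"], set()).update(cats)
        else:
            raise ValueError(f"line {i + 2}: unknown role {role!r}")
        if str(row.get("keep_list", "0")) == "1":
            keep.add(row["domain_id"])
    return DomainCatalog(
        defining=defining, excluding=excluding, keep_list_domains=frozenset(keep)
    )


def read_human_map(path: Path) -> HumanMatrisomeMap:
    """Headered TSV: accession, category."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return HumanMatrisomeMap(zip(df["accession"], df["category"]))


def write_human_map(mapping: dict[str, str], path: Path) -> None:
    pd.DataFrame(
        {"accession": list(mapping), "category": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------- InterProScan domains

_IPS_COLUMNS = [
    "protein_accession", "md5", "length", "analysis", "signature_accession",
    "description", "start", "stop", "score", "status", "date",
    "interpro_accession", "interpro_description",
]


def read_interpro_tsv(path: Path) -> dict[str, list[DomainHit]]:
    """InterProScan 13-column TSV (no header); rows without an InterPro
    accession are skipped."""
    hits: dict[str, list[DomainHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_IPS_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(_IPS_COLUMNS)} columns, "
                    f"got {len(parts)}"
                )
            ipr = parts[11]
            if not ipr or ipr == "-":
                continue
            try:
                hit = DomainHit(
                    contig_id=parts[0],
                    domain_id=ipr,
                    description=parts[12],
                    evalue=float(parts[8]),
                    start=int(parts[6]),
                    end=int(parts[7]),
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.setdefault(parts[0], []).append(hit)
    return hits


def write_interpro_tsv(hits: dict[str, list[DomainHit]], path: Path) -> None:
    with open(path, "w") as fh:
        for contig in sorted(hits):
            for h in hits[contig]:
                row = [
                    h.contig_id, "-", "0", "SYNTH", h.domain_id, h.description,
                    str(h.start), str(h.end), repr(h.evalue), "T", "-",
                    h.domain_id, h.description,
                ]
                fh.write("\t".join(row) + "\n")


# ----------------------------------------------------------- BLAST outfmt 6

_BLAST6_NCOL = 12


def read_blast6(path: Path, direction: str) -> list[BlastHit]:
    """BLAST tabular outfmt 6 (qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore)."""
    out: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != _BLAST6_NCOL:
                raise ValueError(
                    f"{path}:{lineno}: expected {_BLAST6_NCOL} columns, got {len(parts)}"
                )
            try:
                out.append(
                    BlastHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                        direction=direction,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_blast6(hits: list[BlastHit], path: Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            row = [
                h.query_id, h.subject_id, "90.0", "100", "10", "0", "1", "100",
                "1", "100", repr(h.evalue), repr(h.bitscore),
            ]
            fh.write("\t".join(row) + "\n")


# ------------------------------------------------------- predictor summaries


def read_signalp(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _need(df, path, ["contig_id", "sp_flag", "cleavage_pos"])
    return df


def read_tmhmm(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _need(df, path, ["contig_id", "tm_start", "tm_end"])
    return df


def read_gpi(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _need(df, path, ["contig_id", "gpi_flag"])
    return df


def read_proteins(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _need(df, path, ["contig_id", "protein_length", "avg_read_count"])
    return df


def _need(df: pd.DataFrame, path: Path, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


# ------------------------------------------------------- evidence bundle dir

_BUNDLE_FILES = {
    "interpro": "interpro.tsv",
    "blastx": "blastx_fwd.tsv",
    "tblastn": "tblastn_rev.tsv",
    "signalp": "signalp.tsv",
    "tmhmm": "tmhmm.tsv",
    "gpi": "gpi.tsv",
    "proteins": "proteins.tsv",
}


def write_evidence_bundle(bundle: EvidenceBundle, outdir: Path) -> None:
    """Write a bundle as the per-tool files the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_interpro_tsv(bundle.domain_hits, outdir / _BUNDLE_FILES["interpro"])
    fwd = [h for hs in bundle.blast_forward.values() for h in hs]
    write_blast6(fwd, outdir / _BUNDLE_FILES["blastx"])
    write_blast6(bundle.blast_reverse, outdir / _BUNDLE_FILES["tblastn"])
    recs = sorted(bundle.records.values(), key=lambda r: r.contig_id)
    pd.DataFrame(
        {
            "contig_id": [r.contig_id for r in recs],
            "sp_flag": [int(r.signal_peptide) for r in recs],
            "cleavage_pos": [r.sp_cleavage_pos if r.sp_cleavage_pos else "" for r in recs],
        }
    ).to_csv(outdir / _BUNDLE_FILES["signalp"], sep="\t", index=False)
    tm_rows = [
        {"contig_id": r.contig_id, "tm_start": s, "tm_end": e}
        for r in recs for s, e in r.tm_segments
    ]
    pd.DataFrame(tm_rows, columns=["contig_id", "tm_start", "tm_end"]).to_csv(
        outdir / _BUNDLE_FILES["tmhmm"], sep="\t", index=False
    )
    pd.DataFrame(
        {"contig_id": [r.contig_id for r in recs],
         "gpi_flag": [int(r.gpi_anchor) for r in recs]}
    ).to_csv(outdir / _BUNDLE_FILES["gpi"], sep="\t", index=False)
    pd.DataFrame(
        {
            "contig_id": [r.contig_id for r in recs],
            "protein_length": [r.protein_length for r in recs],
            "avg_read_count": [r.avg_read_count for r in recs],
            "orf_group_id": [r.orf_group_id or "" for r in recs],
        }
    ).to_csv(outdir / _BUNDLE_FILES["proteins"], sep="\t", index=False)


def read_evidence_bundle(indir: Path) -> EvidenceBundle:
    indir = Path(indir)
    for key, fname in _BUNDLE_FILES.items():
        if not (indir / fname).exists():
            raise FileNotFoundError(f"missing evidence table {key!r}: {indir / fname}")
    bundle = EvidenceBundle()
    bundle.domain_hits = read_interpro_tsv(indir / _BUNDLE_FILES["interpro"])
    for h in read_blast6(indir / _BUNDLE_FILES["blastx"], "blastx"):
        bundle.blast_forward.setdefault(h.query_id, []).append(h)
    bundle.blast_reverse = read_blast6(indir / _BUNDLE_FILES["tblastn"], "tblastn")

    prot = read_proteins(indir / _BUNDLE_FILES["proteins"]).set_index("contig_id")
    sp = read_signalp(indir / _BUNDLE_FILES["signalp"]).set_index("contig_id")
    gpi = read_gpi(indir / _BUNDLE_FILES["gpi"]).set_index("contig_id")
    tm = read_tmhmm(indir / _BUNDLE_FILES["tmhmm"])
    tm_by: dict[str, list[tuple[int, int]]] = {}
    for _, row in tm.iterrows():
        tm_by.setdefault(str(row["contig_id"]), []).append(
            (int(row["tm_start"]), int(row["tm_end"]))
        )
    for contig, row in prot.iterrows():
        contig = str(contig)
        sp_flag = bool(int(sp.loc[contig, "sp_flag"])) if contig in sp.index else False
        cleave = None
        if sp_flag and contig in sp.index:
            raw = sp.loc[contig, "cleavage_pos"]
            if pd.notna(raw) and str(raw) != "":
                cleave = int(float(raw))
        raw_group = row.get("orf_group_id", "")
        group = "" if pd.isna(raw_group) else str(raw_group)
        bundle.records[contig] = ProteinRecord(
            contig_id=contig,
            protein_length=int(row["protein_length"]),
            signal_peptide=sp_flag,
            sp_cleavage_pos=cleave,
            tm_segments=tm_by.get(contig, []),
            gpi_anchor=bool(int(gpi.loc[contig, "gpi_flag"]))
            if contig in gpi.index else False,
            avg_read_count=float(row["avg_read_count"]),
            orf_group_id=group if group else None,
        )
    return bundle


# --------------------------------------------------------------- expression


def read_mtx(mtx_path: Path, genes_path: Path, barcodes_path: Path) -> ExpressionMatrix:
    """MatrixMarket counts (genes x cells) with one-column gene/barcode lists."""
    counts = sparse.csr_matrix(spio.mmread(mtx_path))
    genes = [l.split("\t")[0] for l in Path(genes_path).read_text().splitlines() if l]
    cells = [l.split("\t")[0] for l in Path(barcodes_path).read_text().splitlines() if l]
    if counts.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix {counts.shape} does not match {len(genes)} genes x "
            f"{len(cells)} barcodes"
        )
    return ExpressionMatrix(counts=counts, gene_ids=genes, cell_ids=cells)


def write_mtx(matrix: ExpressionMatrix, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(matrix.counts))
    Path(outdir / "genes.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
    Path(outdir / "barcodes.tsv").write_text("\n".join(matrix.cell_ids) + "\n")


def read_cell_annotation(path: Path) -> CellAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _need(df, path, ["cell_id", "type_label"])
    return CellAnnotation(
        cell_ids=list(df["cell_id"]),
        type_labels=list(df["type_label"]),
        cluster_ids=list(df["cluster_id"]) if "cluster_id" in df.columns else None,
    )


def write_cell_annotation(annot: CellAnnotation, path: Path) -> None:
    df = pd.DataFrame({"cell_id": annot.cell_ids, "type_label": annot.type_labels})
    if annot.cluster_ids is not None:
        df["cluster_id"] = annot.cluster_ids
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- GMT


def read_gmt(path: Path) -> list[GeneSet]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ... Duplicate genes
    within a set are deduplicated (the set container enforces it)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need >= 3 columns")
            genes = [g for g in parts[2:] if g]
            if len(genes) != len(set(genes)):
                import logging
                logging.getLogger(__name__).warning(
                    "%s:%d: duplicate genes in set %s deduplicated",
                    path, lineno, parts[0],
                )
            sets.append(GeneSet(name=parts[0], members=frozenset(genes)))
    return sets


def write_gmt(sets: list[GeneSet], path: Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.members)]) + "\n")


# ------------------------------------------------------------------ outputs


def write_matrisome_table(
    calls: list[MatrisomeCall],
    path: Path,
    bundle: Optional[EvidenceBundle] = None,
    names: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Final matrisome table: one row per contig with category, confidence,
    provenance, flags, domain content and best human hit."""
    df = to_dataframe(calls)
    df.insert(1, "name", [
        (names or {}).get(c, "") for c in df["contig_id"]
    ])
    if bundle is not None:
        domains, best_hits = [], []
        for contig in df["contig_id"]:
            hs = bundle.domain_hits.get(contig, [])
            domains.append(";".join(sorted({h.domain_id for h in hs})))
            bh = sorted(
                bundle.blast_forward.get(contig, []),
                key=lambda h: (h.evalue, -h.bitscore),
            )
            best_hits.append(bh[0].subject_id if bh else "")
        df["domains"] = domains
        df["best_human_hit"] = best_hits
    df.to_csv(path, sep="\t", index=False)
    return df


def write_report(path: Path, stage: str, config: dict, seed: Optional[int],
                 summary: dict, inputs: Optional[dict] = None) -> dict:
    """JSON run report; validated against the packaged schema."""
    import platform

    from . import __version__

    report = {
        "stage": stage,
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": config,
        "inputs": inputs or {},
        "summary": summary,
    }
    validate_report(report)
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default) + "\n")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_report_schema() -> dict:
    src = resources.files("planmat").joinpath("data/report_schema.json")
    return json.loads(src.read_text())


def validate_report(report: dict) -> None:
    """Minimal structural validation against the packaged schema (required
    keys and primitive types)."""
    schema = load_report_schema()
    for key, typ in schema["required"].items():
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
        expected = {
            "string": str, "object": dict, "integer_or_null": (int, type(None)),
        }[typ]
        if not isinstance(report[key], expected):
            raise ValueError(f"report key {key!r} has wrong type")
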