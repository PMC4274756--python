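"""Readers and writers for the external file formats.

Gene models come in as GFF3 (coordinates taken as-is) or BED4+ (0-based
half-open, converted to 1-based inclusive on read).  QTL regions, gene->term
annotations, gene lists, SNP hits and all result tables are tab-separated
text with a header row; annotations may alternatively be a GAF 2.x subset
(DB object id, GO id, aspect).  Every reader logs how many records were read,
retained and discarded so no input is lost silently.
"""

from __future__ import annotations

import logging
import os
from collections.abc import Iterable

import gffutils
import pandas as pd

from .model import (
    FunctionAnnotation,
    Gene,
    GenomeGeneSet,
    IdMapping,
    QTLCompendium,
    QTLRegion,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_gene_models",
    "read_qtl_regions",
    "read_annotations",
    "read_gene_list",
    "read_tf_catalog",
    "read_snp_hits",
    "read_id_mapping",
    "apply_id_mapping",
    "write_tsv",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line or row."""


def _require(path: str | os.PathLike) -> str:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return path


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | os.PathLike, format: str = "gff3") -> GenomeGeneSet:
    """Read gene models from a GFF3 or BED file into a :class:`GenomeGeneSet`.

    Parameters
    ----------
    path
        Input file.
    format
        ``"gff3"`` (gene-level features, 1-based inclusive, taken as-is) or
        ``"bed"`` (BED4+, 0-based half-open; converted to 1-based inclusive
        via ``start + 1``, ``end``).
    """
    path = _require(path)
    if format == "gff3":
        genes = _read_gff3_genes(path)
    elif format == "bed":
        genes = _read_bed_genes(path)
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    genome = GenomeGeneSet(genes)
    logger.info("read %d gene models from %s (%s)", genome.size, path, format)
    return genome


def _read_gff3_genes(path: str) -> list[Gene]:
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises heterogeneous error types
        raise ParseError(f"{path}: failed to parse GFF3 ({exc})") from exc
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        strand = feat.strand if feat.strand in {"+", "-"} else "."
        genes.append(Gene(feat.id, feat.seqid, feat.start, feat.end, strand))
    return genes


def _read_bed_genes(path: str) -> list[Gene]:
    genes = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: BED needs >=4 fields")
            chrom, start, end, name = fields[:4]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in {"+", "-"} else "."
            # BED is 0-based half-open; internal convention is 1-based closed.
            genes.append(Gene(name, chrom, start_i + 1, end_i, strand))
    return genes


# ---------------------------------------------------------------------------
# QTL compendium


def read_qtl_regions(path: str | os.PathLike) -> QTLCompendium:
    """Read a trait -> interval table (TSV: trait, chrom, start, end[, region_id]).

    ``region_id`` is auto-generated as ``<trait>#<ordinal>`` when the column
    is absent.  Rows with ``start > end`` are rejected with their row index.
    """
    path = _require(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"trait", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ParseError(f"{path}: no QTL regions")
    regions = []
    counters: dict[str, int] = {}
    for idx, row in df.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError as exc:
            raise ParseError(f"{path}: row {idx}: non-integer coordinates") from exc
        if start > end:
            raise ParseError(f"{path}: row {idx}: start {start} > end {end}")
        trait = str(row["trait"])
        if "region_id" in df.columns and pd.notna(row["region_id"]):
            region_id = str(row["region_id"])
        else:
            counters[trait] = counters.get(trait, 0) + 1
            region_id = f"{trait}#{counters[trait]}"
        regions.append(QTLRegion(region_id, trait, str(row["chrom"]), start, end))
    compendium = QTLCompendium(regions)
    logger.info(
        "read %d QTL regions for %d traits from %s",
        len(compendium),
        len(compendium.traits),
        path,
    )
    return compendium


# ---------------------------------------------------------------------------
# functional annotation


def read_annotations(
    path: str | os.PathLike,
    universe: GenomeGeneSet,
    format: str = "tsv2col",
) -> FunctionAnnotation:
    """Read gene -> BP-term annotations restricted to the gene universe.

    ``tsv2col`` is a two-column TSV (header ``gene_id``, ``term_id``); ``gaf``
    is a GAF 2.x subset where only aspect-``P`` (biological process) rows are
    used.  Pairs whose gene is not in *universe* are discarded and counted;
    an empty surviving set is an error because the enrichment background
    would be undefined.
    """
    path = _require(path)
    if format == "tsv2col":
        pairs = _read_pairs_tsv(path)
    elif format == "gaf":
        pairs = _read_pairs_gaf(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if not pairs:
        raise ParseError(f"{path}: no usable annotation rows")
    annotation, discarded = FunctionAnnotation.from_pairs(pairs, universe)
    logger.info(
        "read %d annotation pairs from %s: retained %d, discarded %d out-of-universe",
        len(pairs),
        path,
        annotation.n_pairs,
        discarded,
    )
    return annotation


def _read_pairs_tsv(path: str) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"} <= set(df.columns):
        raise ParseError(f"{path}: need columns gene_id, term_id")
    return list(zip(df["gene_id"], df["term_id"]))


def _read_pairs_gaf(path: str) -> list[tuple[str, str]]:
    # GAF 2.x: column 2 = DB object id, 5 = GO id, 9 = aspect (P/F/C).
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: GAF row has <9 columns")
            if fields[8] == "P":
                pairs.append((fields[1], fields[4]))
    return pairs


# ---------------------------------------------------------------------------
# auxiliary gene lists


def read_gene_list(path: str | os.PathLike) -> set[str]:
    """Read a one-gene-per-line list (a ``gene_id`` header row is allowed)."""
    path = _require(path)
    ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip().split("\t")[0]
            if token and token != "gene_id" and not token.startswith("#"):
                ids.add(token)
    logger.info("read %d gene ids from %s", len(ids), path)
    return ids


def read_tf_catalog(path: str | os.PathLike) -> dict[str, str]:
    """Read a transcription-factor catalog: gene_id [tab family].

    Returns gene_id -> family; family is ``""`` when absent.
    """
    path = _require(path)
    catalog: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "gene_id":
                continue
            catalog[fields[0]] = fields[1] if len(fields) > 1 else ""
    logger.info("read %d transcription factors from %s", len(catalog), path)
    return catalog


def read_snp_hits(path: str | os.PathLike) -> pd.DataFrame:
    """Read GWAS SNP hits (TSV: trait, chrom, pos). Empty files are valid."""
    path = _require(path)
    df = pd.read_csv(path, sep="\t", dtype={"trait": str, "chrom": str})
    missing = {"trait", "chrom", "pos"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df["pos"] = df["pos"].astype(int)
    logger.info("read %d SNP hits from %s", len(df), path)
    return df[["trait", "chrom", "pos"]]


def read_id_mapping(path: str | os.PathLike) -> IdMapping:
    """Read an (external_id, canonical_gene_id) two-column TSV."""
    path = _require(path)
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: id mapping needs two columns")
    return IdMapping(zip(df.iloc[:, 0], df.iloc[:, 1]))


def apply_id_mapping(
    ids: Iterable[str], mapping: IdMapping
) -> tuple[set[str], list[str]]:
    """Map external ids to canonical ids; unmapped ids are returned, not dropped."""
    mapped, unmapped = mapping.apply(ids)
    if unmapped:
        logger.warning(
            "%d of %d ids had no mapping and are excluded from the analysis set",
            len(unmapped),
            len(unmapped) + len(mapped),
        )
    return mapped, unmapped


# ---------------------------------------------------------------------------
# output


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a result table as UTF-8 TSV with header, no index."""
    os.makedirs(os.path.dirname(os.fspath(path)) or ".", exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
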