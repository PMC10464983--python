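"""Gene annotation handling for the ageing-expression pipeline.

Reads GFF3 gene annotation into a flat table, injects the four custom
strand-specific probes covering the rDNA intergenic spacers (IGS1/IGS2),
applies the study's gene-inclusion rules, and classifies genes into
chromosome-arm groups (in particular ChrXIIr, the region of chromosome XII
between the rDNA and the right telomere).

Coordinates are 1-based inclusive throughout; BED interchange converts to
0-based half-open at the boundary only (see :mod:`repliage.cnv`).
"""

from __future__ import annotations

import io
import logging
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Biotypes retained by :func:`filter_genes`.
INCLUDED_BIOTYPES = ("protein_coding", "transposable_element", "rDNA_intergenic")

#: Chromosome names treated as mitochondrial.
MITO_CHROMS = frozenset({"Mito", "MT", "chrM", "chrMito", "mitochondrion"})

#: rDNA exclusion zone on chromosome XII (1-based inclusive).
RDNA_REGION = ("XII", 450000, 491000)

#: Default ChrXIIr boundary: right edge of the rDNA exclusion zone.  Genes
#: with start strictly greater than this on XII belong to ChrXIIr (~0.6 Mb
#: to the right telomere).
CHRXIIR_BOUNDARY = 491000

# Strand-specific probes for the Pol II ncRNAs of the rDNA intergenic
# spacers, quoted with their printed coordinates.  IGS2-1S is printed with
# start > end; coordinates are normalised to start <= end on load while the
# printed strand is kept, and the printed text is retained for provenance.
IGS_PROBES = (
    {"gene_id": "IGS2-1S", "chrom": "XII", "start": 485433, "end": 459675,
     "strand": "-", "printed": "XII: 485433-459675, - strand"},
    {"gene_id": "IGS2-1AS", "chrom": "XII", "start": 458433, "end": 459675,
     "strand": "+", "printed": "XII: 458433-459675, + strand"},
    {"gene_id": "IGS1-2S", "chrom": "XII", "start": 459797, "end": 460711,
     "strand": "-", "printed": "XII: 459797-460711, - strand"},
    {"gene_id": "IGS1-2AS", "chrom": "XII", "start": 459797, "end": 460711,
     "strand": "+", "printed": "XII: 459797-460711, + strand"},
)

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype",
                "is_chrxiir", "printed_coords"]


class AnnotationError(ValueError):
    """Malformed annotation input or violated gene-table invariant."""


def _empty_gene_table() -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": pd.Series(dtype=str),
        "chrom": pd.Series(dtype=str),
        "start": pd.Series(dtype=int),
        "end": pd.Series(dtype=int),
        "strand": pd.Series(dtype=str),
        "biotype": pd.Series(dtype=str),
        "is_chrxiir": pd.Series(dtype=bool),
        "printed_coords": pd.Series(dtype=str),
    })


def _finalize(records: list[dict], rdna_region=RDNA_REGION) -> pd.DataFrame:
    table = pd.DataFrame(records, columns=GENE_COLUMNS) if records else _empty_gene_table()
    if len(table):
        dup = table["gene_id"][table["gene_id"].duplicated()]
        if len(dup):
            raise AnnotationError(
                f"duplicate gene_id(s): {sorted(set(dup))[:5]}")
        swapped = table["start"] > table["end"]
        if swapped.any():
            s = table.loc[swapped, "start"].copy()
            table.loc[swapped, "start"] = table.loc[swapped, "end"]
            table.loc[swapped, "end"] = s
        if (table["start"] < 1).any():
            raise AnnotationError("gene start positions must be >= 1")
    table = table.reset_index(drop=True)
    table.attrs["rdna_region"] = tuple(rdna_region)
    return table


def _parse_attributes(field: str) -> dict:
    attrs = {}
    for part in field.strip().strip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:  # GFF3 style
            key, _, val = part.partition("=")
        else:  # GTF style: key "value"
            key, _, val = part.partition(" ")
            val = val.strip().strip('"')
        attrs[key.strip()] = val.strip()
    return attrs


def load_annotation(
    gff: str | io.TextIOBase,
    add_igs_probes: bool = True,
    biotype_key: str = "gene_biotype",
    feature_types: Sequence[str] = ("gene",),
    rdna_region: tuple = RDNA_REGION,
) -> pd.DataFrame:
    """Parse gene features from GFF3/GTF text into a gene table.

    Parameters
    ----------
    gff
        Path to a GFF3/GTF file, or an open text stream.
    add_igs_probes
        Append the four custom rDNA-intergenic probes (IGS2-1S, IGS2-1AS,
        IGS1-2S, IGS1-2AS) with biotype ``rDNA_intergenic``.
    biotype_key
        Attribute key carrying the gene biotype (``biotype`` also accepted
        as a fallback).  Biotypes outside :data:`INCLUDED_BIOTYPES` are
        stored as ``other``.
    feature_types
        GFF feature types treated as genes.

    Returns
    -------
    pandas.DataFrame
        Gene table with columns ``gene_id, chrom, start, end, strand,
        biotype, is_chrxiir, printed_coords`` and the rDNA region recorded
        in ``.attrs["rdna_region"]``.
    """
    if isinstance(gff, str):
        with open(gff) as handle:
            lines = handle.readlines()
    else:
        lines = gff.readlines()

    records: list[dict] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationError(
                f"malformed GFF line {lineno}: expected 9 tab-separated "
                f"fields, got {len(fields)}")
        chrom, _source, ftype, start, end, _score, strand, _frame, attr_field = fields
        if ftype not in feature_types:
            continue
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise AnnotationError(
                f"malformed GFF line {lineno}: non-integer coordinates") from exc
        attrs = _parse_attributes(attr_field)
        gene_id = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
        if gene_id is None:
            raise AnnotationError(
                f"malformed GFF line {lineno}: no ID/gene_id attribute")
        raw_biotype = attrs.get(biotype_key) or attrs.get("biotype") or "other"
        biotype = raw_biotype if raw_biotype in INCLUDED_BIOTYPES else "other"
        records.append({
            "gene_id": gene_id, "chrom": chrom, "start": start_i,
            "end": end_i, "strand": strand if strand in "+-" else "+",
            "biotype": biotype, "is_chrxiir": False, "printed_coords": "",
        })

    if add_igs_probes:
        records.extend(igs_probe_records())
    return _finalize(records, rdna_region)


def igs_probe_records() -> list[dict]:
    """The four rDNA-intergenic probe records (coordinates as printed)."""
    out = []
    for probe in IGS_PROBES:
        out.append({
            "gene_id": probe["gene_id"], "chrom": probe["chrom"],
            "start": probe["start"], "end": probe["end"],
            "strand": probe["strand"], "biotype": "rDNA_intergenic",
            "is_chrxiir": False, "printed_coords": probe["printed"],
        })
    return out


def load_probes_tsv(path: str) -> list[dict]:
    """Read custom probe definitions (name, chrom, start, end, strand)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append({
            "gene_id": row.name if hasattr(row, "name") else row[0],
            "chrom": row.chrom, "start": int(row.start), "end": int(row.end),
            "strand": row.strand, "biotype": "rDNA_intergenic",
            "is_chrxiir": False, "printed_coords": "",
        })
    return out


def filter_genes(genes: pd.DataFrame, mito_chroms: Iterable[str] = MITO_CHROMS) -> pd.DataFrame:
    """Apply the study's gene-inclusion rules.

    Retains only biotypes ``protein_coding``, ``transposable_element`` and
    ``rDNA_intergenic``; removes mitochondrially encoded genes; removes
    genes whose start or end falls within the rDNA exclusion zone
    (default XII:450000-491000) unless their biotype is ``rDNA_intergenic``.
    Idempotent.
    """
    rdna = genes.attrs.get("rdna_region", RDNA_REGION)
    mito = set(mito_chroms)
    keep_biotype = genes["biotype"].isin(INCLUDED_BIOTYPES)
    n_other = int((~keep_biotype).sum())
    if n_other:
        logger.info("filter_genes: dropping %d genes with excluded biotypes (%s)",
                    n_other,
                    dict(genes.loc[~keep_biotype, "biotype"].value_counts()))
    not_mito = ~genes["chrom"].isin(mito)
    chrom, lo, hi = rdna
    in_zone = (genes["chrom"] == chrom) & (
        genes["start"].between(lo, hi) | genes["end"].between(lo, hi))
    keep_zone = ~in_zone | (genes["biotype"] == "rDNA_intergenic")
    out = genes[keep_biotype & not_mito & keep_zone].reset_index(drop=True)
    out.attrs["rdna_region"] = tuple(rdna)
    return out


def flag_chrxiir(genes: pd.DataFrame, boundary: int = CHRXIIR_BOUNDARY) -> pd.DataFrame:
    """Set ``is_chrxiir`` for genes on XII with start strictly beyond *boundary*."""
    out = genes.copy()
    out["is_chrxiir"] = (out["chrom"] == "XII") & (out["start"] > boundary)
    out.attrs["rdna_region"] = tuple(genes.attrs.get("rdna_region", RDNA_REGION))
    return out


def write_gene_table(genes: pd.DataFrame, path: str) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_gene_table(path: str, rdna_region: tuple = RDNA_REGION) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "printed_coords" in genes.columns:
        genes["printed_coords"] = genes["printed_coords"].fillna("")
    genes.attrs["rdna_region"] = tuple(rdna_region)
    return genes
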