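"""Readers and writers for the standard formats the pipeline touches.

Supported formats
-----------------
* GFF3 genome annotations (1-based, converted to internal 0-based midpoints),
  parsed with :mod:`gffutils`;
* bedGraph-style coverage tracks (4-column TSV, 0-based half-open);
* gene-level count tables (TSV: gene_id, length, one column per sample,
  sample names ``<CONDITION>_<replicate>``);
* proteinortho v6 ortholog tables;
* species metadata and gene-category TSVs.

All writers emit TSV with a header line; ``#``-prefixed lines are treated as
comments by every reader, and writers may include them as provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gffutils
import numpy as np
import pandas as pd

from .chromosome import CircularChromosome, GeneRecord
from .errors import FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageTrack",
    "CountTable",
    "OrthologTable",
    "SpeciesMeta",
    "read_gff3",
    "write_gff3",
    "read_coverage",
    "write_coverage",
    "read_counts",
    "write_counts",
    "read_proteinortho",
    "write_proteinortho",
    "read_species_meta",
    "read_categories",
    "merge_categories",
]


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Piecewise-constant read depth over one chromosome.

    Intervals are 0-based, half-open, sorted and non-overlapping; depth may
    be fractional (pre-normalized tracks are accepted).
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.depths = np.asarray(self.depths, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.depths)):
            raise FormatError("coverage arrays must have equal length")
        order = np.argsort(self.starts, kind="stable")
        self.starts = self.starts[order]
        self.ends = self.ends[order]
        self.depths = self.depths[order]
        if np.any(self.ends <= self.starts):
            raise FormatError("coverage intervals must satisfy start < end")
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise FormatError("coverage intervals overlap")
        if np.any(self.depths < 0):
            raise FormatError("coverage depth must be >= 0")

    def __len__(self) -> int:
        return len(self.starts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.starts, "end": self.ends,
             "depth": self.depths}
        )


def read_coverage(path) -> CoverageTrack:
    """Read a bedGraph-style 4-column TSV (chrom, start, end, value)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "depth"])
    if df.empty:
        raise FormatError(f"{path}: empty coverage file")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise FormatError(f"{path}: expected a single chromosome, got {list(chroms)}")
    return CoverageTrack(str(chroms[0]), df["start"].to_numpy(),
                         df["end"].to_numpy(), df["depth"].to_numpy())


def write_coverage(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write("# bedGraph: chrom\tstart\tend\tdepth\n")
        for s, e, d in zip(track.starts, track.ends, track.depths):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{float(d)!r}\n")


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def _split_sample(name: str) -> Tuple[str, str]:
    """Split 'EXP_1' into ('EXP', '1'); a name without '_' is its own condition."""
    if "_" in name:
        cond, rep = name.rsplit("_", 1)
        return cond, rep
    return name, "1"


@dataclass
class CountTable:
    """Gene-level counts: genes x samples plus per-gene lengths.

    ``counts`` is a DataFrame indexed by gene_id with one column per sample;
    sample names encode condition and replicate as ``COND_rep``.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        self.lengths = self.lengths.astype(np.int64).reindex(self.counts.index)
        if self.counts.columns.duplicated().any():
            raise FormatError("duplicate sample names")
        if self.counts.index.duplicated().any():
            raise FormatError("duplicate gene ids")
        if self.lengths.isna().any():
            raise FormatError("every gene needs a length")
        if (self.lengths <= 0).any():
            raise FormatError("gene lengths must be > 0")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("counts must be >= 0")

    @property
    def genes(self) -> List[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    def condition_of(self, sample: str) -> str:
        return _split_sample(sample)[0]

    def samples_of(self, condition: str) -> List[str]:
        return [s for s in self.samples if self.condition_of(s) == condition]

    @property
    def conditions(self) -> List[str]:
        seen: List[str] = []
        for s in self.samples:
            c = self.condition_of(s)
            if c not in seen:
                seen.append(c)
        return seen


def read_counts(path) -> CountTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "length"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: count table needs columns {sorted(required)}")
    df = df.set_index("gene_id")
    lengths = df.pop("length")
    return CountTable(df, lengths)


def write_counts(table: CountTable, path) -> None:
    out = table.counts.copy()
    out.insert(0, "length", table.lengths)
    out.index.name = "gene_id"
    with open(path, "w") as fh:
        fh.write("# gene-level counts; samples named CONDITION_replicate\n")
        out.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# GFF3 annotations
# ---------------------------------------------------------------------------

def _gene_id_of(feature) -> str:
    for key in ("locus_tag", "ID", "Name", "gene"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return f"{feature.featuretype}:{feature.seqid}:{feature.start}"


def _midpoint_0based(start_1based: int, end_1based: int) -> int:
    # midpoint of the 0-based inclusive interval [start-1, end-1]
    return (start_1based - 1 + end_1based - 1) // 2


def read_gff3(path, *, length: Optional[int] = None, oriC: Optional[int] = None,
              gene_types: Sequence[str] = ("gene", "CDS"),
              ) -> Tuple[CircularChromosome, List[GeneRecord], List[dict]]:
    """Read a GFF3 annotation into (chromosome, genes, rRNA features).

    Gene features are taken from the first feature type in ``gene_types``
    that is present (genes preferred, CDS as fallback so minimal annotations
    work).  GFF3 1-based coordinates are converted to 0-based midpoints.
    The chromosome length comes from the ``##sequence-region`` directive
    unless overridden; oriC may be supplied or annotated as a feature whose
    ID/Name contains 'oriC' (e.g. type rep_origin), else defaults to 0.

    rRNA features are returned as dicts (seqid, start, end, strand, product)
    so 16S genes can be counted downstream.
    """
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    seq_lengths: Dict[str, int] = {}
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            parts = directive.split()
            if len(parts) >= 4:
                seq_lengths[parts[1]] = int(parts[3])

    seqids = sorted({f.seqid for f in db.all_features()})
    if len(seqids) != 1:
        raise FormatError(
            f"{path}: expected one chromosome per annotation, got {seqids}")
    seqid = seqids[0]
    if length is None:
        length = seq_lengths.get(seqid)
    if length is None:
        raise FormatError(
            f"{path}: no ##sequence-region length for {seqid}; pass length=")

    if oriC is None:
        for f in db.all_features():
            names = f.attributes.get("ID", []) + f.attributes.get("Name", [])
            if f.featuretype in ("rep_origin", "origin_of_replication") or any(
                    "oric" in n.lower() for n in names):
                oriC = _midpoint_0based(f.start, f.end)
                break
    chrom = CircularChromosome(seqid, length, oriC if oriC is not None else 0)

    genes: List[GeneRecord] = []
    for ftype in gene_types:
        feats = list(db.features_of_type(ftype))
        if feats:
            for f in feats:
                mid = _midpoint_0based(f.start, f.end)
                if not 0 <= mid < length:
                    raise FormatError(
                        f"{path}: feature {_gene_id_of(f)} midpoint outside chromosome")
                genes.append(GeneRecord(_gene_id_of(f), mid,
                                        f.strand if f.strand in "+-" else "+",
                                        f.end - f.start + 1))
            break

    rrna: List[dict] = []
    for f in db.features_of_type("rRNA"):
        product = f.attributes.get("product", [""])[0]
        rrna.append({"seqid": f.seqid, "start": f.start - 1, "end": f.end,
                     "strand": f.strand, "product": product,
                     "name": f.attributes.get("Name", [""])[0]})
    return chrom, genes, rrna


def write_gff3(chrom: CircularChromosome, genes: Sequence[GeneRecord], path,
               rrna: Sequence[dict] = ()) -> None:
    """Write genes (and optional rRNA features) as a minimal GFF3 file.

    Genes are written as ``gene`` features centred on their midpoint with
    their annotated length, which round-trips the midpoint convention of
    :func:`read_gff3` exactly.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {chrom.name} 1 {chrom.length}\n")
        fh.write(f"{chrom.name}\tdosagescope\trep_origin\t{chrom.oriC + 1}\t"
                 f"{chrom.oriC + 1}\t.\t+\t.\tID=oriC;Name=oriC\n")
        for g in genes:
            # choose a 1-based interval whose 0-based inclusive midpoint is g.midpoint
            half = (g.length - 1) // 2
            start0 = g.midpoint - half
            end0 = start0 + g.length - 1
            if start0 < 0 or end0 >= chrom.length:  # keep toy features on-sequence
                start0 = max(0, min(start0, chrom.length - g.length))
                end0 = start0 + g.length - 1
            attrs = f"ID={g.gene_id};locus_tag={g.gene_id}"
            if g.category:
                attrs += f";category={g.category}"
            fh.write(f"{chrom.name}\tdosagescope\tgene\t{start0 + 1}\t{end0 + 1}\t"
                     f".\t{g.strand}\t.\t{attrs}\n")
        for r in rrna:
            fh.write(f"{chrom.name}\tdosagescope\trRNA\t{r['start'] + 1}\t{r['end']}\t"
                     f".\t{r.get('strand', '+')}\t.\t"
                     f"ID={r.get('name', 'rrna')};product={r.get('product', '')}\n")


# ---------------------------------------------------------------------------
# proteinortho tables
# ---------------------------------------------------------------------------

@dataclass
class OrthologTable:
    """Single-copy ortholog pairs between two species.

    Only rows where both species columns contain exactly one gene survive
    parsing, so every pair is single-copy by construction and no gene
    appears in two pairs.
    """

    species_a: str
    species_b: str
    pairs: List[Tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise FormatError("a gene appears in two single-copy pairs")

    def __len__(self) -> int:
        return len(self.pairs)


def read_proteinortho(path, species_a: Optional[str] = None,
                      species_b: Optional[str] = None) -> OrthologTable:
    """Parse a proteinortho v6 TSV into single-copy ortholog pairs.

    The first three columns (species count, gene count, connectivity) are
    ignored; species columns hold comma-separated gene lists with ``*`` for
    absent.  Rows with anything but exactly one gene per selected species
    are dropped, per the single-copy (no paralog) rule.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0].startswith("#"):
        df = df.rename(columns={df.columns[0]: df.columns[0].lstrip("# ")})
    species_cols = list(df.columns[3:])
    if len(species_cols) < 2:
        raise FormatError(f"{path}: proteinortho table needs >= 2 species columns")
    species_a = species_a or species_cols[0]
    species_b = species_b or species_cols[1]
    for sp in (species_a, species_b):
        if sp not in species_cols:
            raise FormatError(f"{path}: species column {sp!r} not found")

    pairs: List[Tuple[str, str]] = []
    for _, row in df.iterrows():
        a, b = str(row[species_a]), str(row[species_b])
        if "," in a or "," in b or a == "*" or b == "*" or not a or not b:
            continue
        pairs.append((a, b))
    return OrthologTable(species_a, species_b, pairs)


def write_proteinortho(table: OrthologTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# Species\tGenes\tAlg.-Conn.\t{table.species_a}\t{table.species_b}\n")
        for a, b in table.pairs:
            fh.write(f"2\t2\t1\t{a}\t{b}\n")


# ---------------------------------------------------------------------------
# species metadata and functional categories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesMeta:
    """One species in the comparative screen."""

    species: str
    family: str
    taxon_class: str
    n_16S: int
    chromosome_length: int

    def __post_init__(self) -> None:
        if self.n_16S < 0:
            raise FormatError(f"{self.species}: n_16S must be >= 0")


def read_species_meta(path) -> List[SpeciesMeta]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"species", "family", "class", "n_16S", "chromosome_length"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        SpeciesMeta(str(r["species"]), str(r["family"]), str(r["class"]),
                    int(r["n_16S"]), int(r["chromosome_length"]))
        for _, r in df.iterrows()
    ]


def read_categories(path) -> Dict[str, str]:
    """Read a 2-column (gene_id, category) TSV; extra labels per gene dropped."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: category table needs 2 columns")
    gene_col, cat_col = df.columns[:2]
    out: Dict[str, str] = {}
    dropped = 0
    for _, row in df.iterrows():
        gid = str(row[gene_col])
        if gid in out:
            dropped += 1
            continue
        out[gid] = str(row[cat_col])
    if dropped:
        logger.warning("%s: %d extra category labels dropped (one per gene kept)",
                       path, dropped)
    return out


def merge_categories(genes: Sequence[GeneRecord],
                     categories: Dict[str, str]) -> List[GeneRecord]:
    """Return new GeneRecords with categories merged on by gene id."""
    return [
        GeneRecord(g.gene_id, g.midpoint, g.strand, g.length,
                   categories.get(g.gene_id, g.category))
        for g in genes
    ]
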