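"""Input/output for the pipeline's external formats.

Reads FASTA (nucleotide and protein), GFF3 gene models and MetaBAT-style
contig depth tables into the domain types used downstream, and writes
tabular reports as TSV. No science happens here.

Coordinate convention: 1-based inclusive (GFF3 native) throughout the
package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import gffutils
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Habitat",
    "ContigSeq",
    "GenomeRecord",
    "GeneModel",
    "ProteinSeq",
    "read_fasta",
    "read_genome_fasta",
    "read_protein_fasta",
    "read_gff3",
    "read_depth_table",
    "read_labels",
    "write_tsv",
]

# IUPAC nucleotide codes (unambiguous + ambiguity + N)
NT_LETTERS = frozenset("ACGTU" "RYSWKMBDHVN")
AA_STANDARD = "ACDEFGHIKLMNPQRSTVWY"
# extended letters tolerated in predicted proteomes
AA_LETTERS = frozenset(AA_STANDARD + "XBZUJ*")


class Habitat(str, enum.Enum):
    """Source-environment label of a genome."""

    thermal = "thermal"
    non_thermal = "non_thermal"
    unknown = "unknown"


@dataclass(frozen=True)
class ContigSeq:
    """A single assembled contig (upper-case nucleotides)."""

    contig_id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomeRecord:
    """A named set of contigs (one MAG) plus its habitat label."""

    genome_id: str
    contigs: list[ContigSeq]
    habitat: Habitat = Habitat.unknown
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError(f"genome {self.genome_id!r} has no contigs")
        ids = [c.contig_id for c in self.contigs]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(
                f"genome {self.genome_id!r}: duplicate contig id {dup!r}"
            )

    def contig_lengths(self) -> dict[str, int]:
        return {c.contig_id: len(c) for c in self.contigs}


@dataclass(frozen=True)
class GeneModel:
    """A coding gene: 1-based inclusive coordinates on a contig.

    ``coding_len`` is the summed length of the CDS segments that were
    merged into this model; for a single-segment gene it equals
    ``end - start + 1``.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    type: str = "CDS"
    coding_len: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid coordinates "
                f"{self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )
        if self.coding_len == 0:
            object.__setattr__(self, "coding_len", self.end - self.start + 1)


@dataclass(frozen=True)
class ProteinSeq:
    """One predicted protein; terminal stop ('*') already stripped."""

    protein_id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


def _validate_letters(seq: str, allowed: frozenset, rec_id: str, path) -> None:
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise ValueError(
                f"{path}: record {rec_id!r} has illegal character "
                f"{ch!r} at position {pos}"
            )


def read_fasta(path, alphabet: Literal["nt", "aa"]) -> list[ContigSeq] | list[ProteinSeq]:
    """Read a FASTA file into contig or protein records.

    Sequences are upper-cased and record order is preserved. For the
    ``aa`` alphabet a single terminal ``*`` (stop codon marker emitted by
    gene callers) is stripped. Raises on an empty file, a duplicate
    record id, or a character outside the alphabet.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    seen: set[str] = set()
    out: list = []
    allowed = NT_LETTERS if alphabet == "nt" else AA_LETTERS
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        desc = rec.description[len(rec.id):].strip()
        if alphabet == "aa" and seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} is empty")
        _validate_letters(seq, allowed, rec.id, path)
        if alphabet == "nt":
            out.append(ContigSeq(rec.id, seq, desc))
        else:
            out.append(ProteinSeq(rec.id, seq, desc))
    return out


def read_genome_fasta(path, genome_id: str | None = None,
                      habitat: Habitat = Habitat.unknown) -> GenomeRecord:
    """Read one genome assembly FASTA into a :class:`GenomeRecord`.

    ``genome_id`` defaults to the file stem.
    """
    path = Path(path)
    contigs = read_fasta(path, "nt")
    return GenomeRecord(genome_id or path.stem, contigs, habitat=habitat)


def read_protein_fasta(path) -> list[ProteinSeq]:
    """Read a predicted proteome (protein FASTA)."""
    return read_fasta(path, "aa")


def read_gff3(path) -> list[GeneModel]:
    """Read CDS features from a GFF3 file.

    CDS segments sharing an ``ID`` attribute are merged into a single
    :class:`GeneModel` spanning min(start)..max(end) whose ``coding_len``
    is the sum of the segment lengths. Features of other types are
    ignored. Raises on start > end or an unknown strand symbol.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    merged: dict[str, dict] = {}
    order: list[str] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype != "CDS":
            continue
        if feat.start > feat.end:
            raise ValueError(
                f"{path}: CDS with start > end ({feat.start} > {feat.end})"
            )
        if feat.strand not in ("+", "-"):
            raise ValueError(
                f"{path}: unknown strand {feat.strand!r} for CDS at "
                f"{feat.seqid}:{feat.start}"
            )
        raw_ids = feat.attributes.get("ID") or [feat.id]
        # gffutils uniquifies repeated IDs as 'x_1'; merge on the raw ID
        gene_id = raw_ids[0]
        seg_len = feat.end - feat.start + 1
        if gene_id not in merged:
            merged[gene_id] = {
                "contig": feat.seqid, "start": feat.start, "end": feat.end,
                "strand": feat.strand, "len": seg_len,
            }
            order.append(gene_id)
        else:
            m = merged[gene_id]
            m["start"] = min(m["start"], feat.start)
            m["end"] = max(m["end"], feat.end)
            m["len"] += seg_len
    return [
        GeneModel(g, m["contig"], m["start"], m["end"], m["strand"],
                  "CDS", coding_len=m["len"])
        for g, m in ((g, merged[g]) for g in order)
    ]


def read_depth_table(path):
    """Read a MetaBAT ``jgi_summarize_bam_contig_depths`` TSV.

    Expects header columns ``contigName``, ``contigLen``,
    ``totalAvgDepth`` followed by one mean-depth column per sample;
    ``*-var`` variance columns, if present, are ignored. Returns a
    :class:`thermotrait.community.CoverageTable`.
    """
    from .community import CoverageTable

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["contigName", "contigLen", "totalAvgDepth"]
    if list(df.columns[:3]) != required:
        raise ValueError(
            f"{path}: expected leading columns {required}, "
            f"got {list(df.columns[:3])}"
        )
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged or missing values in depth table")
    sample_cols = [
        c for c in df.columns[3:] if not c.endswith("-var")
    ]
    depth = {}
    for col in sample_cols:
        vals = df[col]
        if (vals < 0).any():
            bad = df.loc[vals < 0, "contigName"].iloc[0]
            raise ValueError(
                f"{path}: negative depth for contig {bad!r} in sample {col!r}"
            )
        depth[col] = dict(zip(df["contigName"], vals.astype(float)))
    contig_len = dict(zip(df["contigName"], df["contigLen"].astype(int)))
    return CoverageTable(samples=sample_cols, depth=depth,
                         contig_len=contig_len)


def read_labels(path) -> dict[str, Habitat]:
    """Read a two-column TSV ``genome_id<TAB>habitat`` into a label map."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    gcol, hcol = df.columns[0], df.columns[1]
    return {str(r[gcol]): Habitat(r[hcol]) for _, r in df.iterrows()}


def write_tsv(df: pd.DataFrame, path, float_decimals: int = 4) -> None:
    """Write a report DataFrame as TSV with fixed float precision.

    Column order is the DataFrame's order (deterministic by
    construction in all report builders).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False,
              float_format=f"%.{float_decimals}f")


def write_fasta(records: Iterable[ContigSeq | ProteinSeq], path,
                width: int = 70) -> None:
    """Write contig or protein records as FASTA (fixed line width)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in records:
            rec_id = getattr(rec, "contig_id", None) or getattr(
                rec, "protein_id"
            )
            header = rec_id if not rec.description else (
                f"{rec_id} {rec.description}"
            )
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")
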