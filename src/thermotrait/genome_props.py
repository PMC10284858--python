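"""Per-genome assembly and gene-structure properties.

Computes the per-MAG summary statistics used throughout comparative
genomics of metagenome-assembled genomes: assembly size, GC content,
N50, contig count, gene count, average coding-gene length and coding
density.

Conventions (documented because deposited-genome summaries vary):

* genome size counts every residue, including N (assembly length as
  deposited);
* the GC denominator excludes N and ambiguity codes, so gappy MAGs are
  not deflated;
* coding density sums CDS lengths without overlap deduplication by
  default (matching typical annotation-pipeline summaries); pass
  ``overlap_dedup=True`` for union length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .seqio import GeneModel, GenomeRecord

__all__ = [
    "GenomeProperties",
    "gc_content",
    "n50",
    "genome_size",
    "gene_stats",
    "coding_density",
    "genome_properties",
    "properties_table",
]

_UNAMBIG = set("ACGT")


@dataclass(frozen=True)
class GenomeProperties:
    genome_id: str
    size_bp: int
    gc_pct: float
    n50_bp: int
    n_contigs: int
    gene_count: int | None = None
    avg_gene_len_bp: float | None = None
    coding_density_pct: float | None = None


def gc_content(genome: GenomeRecord) -> float:
    """GC content in percent: 100·(G+C)/(A+C+G+T).

    N and IUPAC ambiguity codes are excluded from numerator and
    denominator. Raises if the genome contains no unambiguous base.
    """
    gc = at = 0
    for contig in genome.contigs:
        seq = contig.seq
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError(
            f"genome {genome.genome_id!r}: no unambiguous bases"
        )
    return 100.0 * gc / (gc + at)


def n50(genome: GenomeRecord) -> int:
    """N50: smallest contig length L such that contigs ≥ L cover half
    the assembly."""
    lengths = sorted((len(c) for c in genome.contigs), reverse=True)
    half = sum(lengths) / 2.0
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def genome_size(genome: GenomeRecord) -> int:
    """Total assembly length in bp (all residues, N included)."""
    return sum(len(c) for c in genome.contigs)


def gene_stats(genes: list[GeneModel]) -> tuple[int, float | None]:
    """(gene_count, average coding length in bp).

    The average uses CDS (coding) length, not genomic span. With no
    genes the average is None (reported as a missing value).
    """
    if not genes:
        return 0, None
    total = sum(g.coding_len for g in genes)
    return len(genes), total / len(genes)


def coding_density(genes: list[GeneModel], genome: GenomeRecord,
                   overlap_dedup: bool = False) -> float:
    """Percent of the assembly covered by coding sequence.

    Default sums gene coding lengths (overlaps counted once per gene),
    so values above 100 are possible and flagged by the caller rather
    than clamped. With ``overlap_dedup=True`` overlapping gene spans are
    merged per contig before summing (union length).
    """
    known = set(genome.contig_lengths())
    for g in genes:
        if g.contig_id not in known:
            raise ValueError(
                f"gene {g.gene_id!r} references unknown contig "
                f"{g.contig_id!r} in genome {genome.genome_id!r}"
            )
    size = genome_size(genome)
    if not overlap_dedup:
        total = sum(g.coding_len for g in genes)
    else:
        total = 0
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for g in genes:
            by_contig.setdefault(g.contig_id, []).append((g.start, g.end))
        for spans in by_contig.values():
            spans.sort()
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s <= cur_e + 1:
                    cur_e = max(cur_e, e)
                else:
                    total += cur_e - cur_s + 1
                    cur_s, cur_e = s, e
            total += cur_e - cur_s + 1
    return 100.0 * total / size


def genome_properties(genome: GenomeRecord,
                      genes: list[GeneModel] | None = None) -> GenomeProperties:
    """All assembly (and, if gene models are given, gene) properties."""
    props = dict(
        genome_id=genome.genome_id,
        size_bp=genome_size(genome),
        gc_pct=gc_content(genome),
        n50_bp=n50(genome),
        n_contigs=len(genome.contigs),
    )
    if genes is not None:
        count, avg = gene_stats(genes)
        props.update(
            gene_count=count,
            avg_gene_len_bp=avg,
            coding_density_pct=(coding_density(genes, genome)
                                if genes else 0.0),
        )
    return GenomeProperties(**props)


def properties_table(props: list[GenomeProperties]) -> pd.DataFrame:
    """Assemble per-genome properties into a report table.

    Column order is fixed; missing gene statistics appear as NaN.
    """
    cols = ["genome_id", "size_bp", "gc_pct", "n50_bp", "n_contigs",
            "gene_count", "avg_gene_len_bp", "coding_density_pct"]
    rows = []
    for p in props:
        rows.append({c: getattr(p, c) for c in cols})
    df = pd.DataFrame(rows, columns=cols)
    if df["avg_gene_len_bp"].isna().all() and df["gene_count"].isna().all():
        df = df.drop(columns=["gene_count", "avg_gene_len_bp",
                              "coding_density_pct"])
    return df
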