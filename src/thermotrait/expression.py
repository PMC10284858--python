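"""FPKM quantification and expression summaries.

Per-gene fragment counts arrive as tables (read counting is upstream);
this module converts them to FPKM —

    FPKM(g) = counts(g) · 10^9 / (gene_len(g) · total_mapped)

— where ``total_mapped`` defaults to the per-sample sum of counts over
the reference gene set (fragments mapped onto the selected reference
genomes), and provides per-genome detected-gene fractions and
pathway-level transcript shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CountTable",
    "fpkm",
    "fpkm_matrix",
    "expressed_fraction",
    "pathway_share",
]


@dataclass
class CountTable:
    """Fragment counts for one sample over a fixed gene set."""

    sample_id: str
    counts: dict[str, int]
    gene_len: dict[str, int]
    total_mapped: int | None = None

    def __post_init__(self) -> None:
        missing = [g for g in self.counts if g not in self.gene_len]
        if missing:
            raise ValueError(
                f"gene {missing[0]!r} has no length in sample "
                f"{self.sample_id!r}"
            )
        for g, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for gene {g!r}")
        for g, l in self.gene_len.items():
            if l < 1:
                raise ValueError(f"gene {g!r} has length {l} < 1")
        if self.total_mapped is None:
            self.total_mapped = sum(self.counts.values())
        if self.total_mapped < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: total mapped fragments "
                f"{self.total_mapped} < 1"
            )
        if sum(self.counts.values()) > self.total_mapped:
            raise ValueError(
                f"sample {self.sample_id!r}: counts exceed total_mapped"
            )


def fpkm(counts: CountTable) -> pd.Series:
    """FPKM for every gene of one sample."""
    vals = {
        g: n * 1.0e9 / (counts.gene_len[g] * counts.total_mapped)
        for g, n in counts.counts.items()
    }
    s = pd.Series(vals, name=counts.sample_id)
    s.index.name = "gene_id"
    return s


def fpkm_matrix(tables: list[CountTable]) -> pd.DataFrame:
    """Gene × sample FPKM matrix from per-sample count tables.

    Genes absent from a sample's table get FPKM 0 in that column.
    """
    if not tables:
        raise ValueError("no count tables given")
    cols = [fpkm(t) for t in tables]
    df = pd.concat(cols, axis=1).fillna(0.0)
    df.index.name = "gene_id"
    return df


def expressed_fraction(matrix: pd.DataFrame,
                       genome_of: dict[str, str],
                       threshold: float = 0.0) -> pd.DataFrame:
    """Per-genome detected-gene counts and percentage.

    A gene counts as expressed if its FPKM exceeds ``threshold`` in at
    least one sample. Percentages are rounded to one decimal, the
    precision such fractions are conventionally reported at.
    """
    missing = [g for g in matrix.index if g not in genome_of]
    if missing:
        raise ValueError(
            f"gene {missing[0]!r} has no genome assignment"
        )
    expressed = (matrix > threshold).any(axis=1)
    df = pd.DataFrame({
        "genome_id": [genome_of[g] for g in matrix.index],
        "expressed": expressed.values,
    })
    grouped = df.groupby("genome_id", sort=True)["expressed"]
    out = pd.DataFrame({
        "n_expressed": grouped.sum().astype(int),
        "n_total": grouped.count().astype(int),
    })
    out["pct_expressed"] = (100.0 * out["n_expressed"]
                            / out["n_total"]).round(1)
    return out.reset_index()


def overall_expressed_fraction(matrix: pd.DataFrame,
                               threshold: float = 0.0,
                               ) -> tuple[int, int, float]:
    """Detected-gene count over the whole matrix:
    (n_expressed, n_total, pct rounded to 1 decimal)."""
    expressed = int((matrix > threshold).any(axis=1).sum())
    total = int(matrix.shape[0])
    return expressed, total, round(100.0 * expressed / total, 1)


def pathway_share(matrix: pd.DataFrame,
                  gene_tags: dict[str, str],
                  tag_set: set[str],
                  genome_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Percentage of summed FPKM carried by tagged genes.

    Per (genome, sample) — or overall per sample if ``genome_of`` is
    None. The share is NaN where a genome-sample has zero total FPKM.
    """
    genome_of = genome_of or {g: "all" for g in matrix.index}
    df = matrix.copy()
    df["_genome"] = [genome_of[g] for g in df.index]
    df["_tagged"] = [gene_tags.get(g) in tag_set for g in df.index]
    rows = []
    for genome, sub in df.groupby("_genome", sort=True):
        for sample in matrix.columns:
            total = sub[sample].sum()
            tagged = sub.loc[sub["_tagged"], sample].sum()
            rows.append({
                "genome_id": genome, "sample": sample,
                "share_pct": (100.0 * tagged / total
                              if total > 0 else float("nan")),
            })
    return pd.DataFrame(rows)
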