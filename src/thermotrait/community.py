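"""Coverage-based relative abundance of genome bins (MAGs).

The relative abundance of a MAG in a sample is the sum of mean read
depths over its contigs divided by the summed depth of *all* contigs in
the assembly, × 100. Contigs not assigned to any bin are pooled into a
pseudo-bin ``"unbinned"`` so per-sample abundances always close to 100.

Two modes:

* ``sum_cov`` (default): sums per-contig mean depths directly. This is
  the conventional depth-table formula but is biased toward bins with
  many short contigs.
* ``len_weighted``: weights each contig's depth by its length in both
  numerator and denominator (i.e. sums mapped bases), removing the
  contig-count bias. The two agree exactly when all contigs have equal
  length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CoverageTable",
    "BinAssignment",
    "UNBINNED",
    "relative_abundance",
    "dominance_report",
]

UNBINNED = "unbinned"

GUILDS = ("comammox", "AOB", "AOA", "NOB", "anammox", "other")
# guilds capable of ammonia oxidation, for dominance calls
AMMONIA_OXIDIZERS = ("comammox", "AOB", "AOA")


@dataclass
class CoverageTable:
    """Per-sample per-contig mean depth plus contig lengths."""

    samples: list[str]
    depth: dict[str, dict[str, float]]  # sample -> contig -> mean depth
    contig_len: dict[str, int]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("coverage table has no samples")
        for sample in self.samples:
            for contig, d in self.depth[sample].items():
                if d < 0:
                    raise ValueError(
                        f"negative depth for contig {contig!r} "
                        f"in sample {sample!r}"
                    )

    @property
    def contigs(self) -> list[str]:
        return list(self.contig_len)


@dataclass
class BinAssignment:
    """contig → bin membership; unmapped contigs are unbinned."""

    bin_of: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path) -> "BinAssignment":
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected contig and bin columns")
        c, b = df.columns[0], df.columns[1]
        if df[c].duplicated().any():
            dup = df.loc[df[c].duplicated(), c].iloc[0]
            raise ValueError(
                f"{path}: contig {dup!r} assigned to more than one bin"
            )
        return cls(dict(zip(df[c].astype(str), df[b].astype(str))))

    def bins(self) -> list[str]:
        return sorted(set(self.bin_of.values()))


def relative_abundance(cov: CoverageTable, bins: BinAssignment,
                       mode: str = "sum_cov") -> pd.DataFrame:
    """Relative abundance (%) of each bin per sample.

    Returns a DataFrame with bins (plus ``"unbinned"``) as rows and
    samples as columns; each column sums to 100. Raises if a binned
    contig is missing from the coverage table or a sample has zero
    total coverage.
    """
    if mode not in ("sum_cov", "len_weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    known = set(cov.contig_len)
    missing = [c for c in bins.bin_of if c not in known]
    if missing:
        raise ValueError(
            f"binned contig {missing[0]!r} absent from the coverage table"
        )
    bin_ids = bins.bins() + [UNBINNED]
    out = pd.DataFrame(0.0, index=bin_ids, columns=cov.samples)
    for sample in cov.samples:
        depths = cov.depth[sample]
        totals = {b: 0.0 for b in bin_ids}
        grand = 0.0
        for contig, d in depths.items():
            w = d if mode == "sum_cov" else d * cov.contig_len[contig]
            totals[bins.bin_of.get(contig, UNBINNED)] += w
            grand += w
        if grand == 0.0:
            raise ValueError(f"total coverage is zero in sample {sample!r}")
        for b in bin_ids:
            out.loc[b, sample] = 100.0 * totals[b] / grand
    out.index.name = "bin_id"
    return out


def dominance_report(abundance: pd.DataFrame,
                     guild_labels: dict[str, str]) -> pd.DataFrame:
    """Per-sample summed abundance per guild plus the dominant
    ammonia-oxidizer guild.

    ``guild_labels`` maps bin ids to functional guilds (comammox, AOB,
    AOA, NOB, anammox); unlabeled bins (and the unbinned pool) default
    to "other". Ties for the top ammonia-oxidizing guild are reported
    as a '|'-joined tie.
    """
    bad = {g for g in guild_labels.values() if g not in GUILDS}
    if bad:
        raise ValueError(f"unknown guild labels: {sorted(bad)}")
    rows = []
    for sample in abundance.columns:
        sums = {g: 0.0 for g in GUILDS}
        for bin_id, ra in abundance[sample].items():
            sums[guild_labels.get(bin_id, "other")] += ra
        ao = {g: sums[g] for g in AMMONIA_OXIDIZERS}
        top = max(ao.values())
        winners = sorted(g for g, v in ao.items() if v == top)
        rows.append({
            "sample": sample, **sums,
            "dominant_ammonia_oxidizer": "|".join(winners),
            "is_tie": len(winners) > 1,
        })
    return pd.DataFrame(rows)
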