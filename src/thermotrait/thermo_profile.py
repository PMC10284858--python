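"""Proteome-composition thermostability analytics.

Thermophilic prokaryotes bias their proteomes toward charged and
non-polar residues at the expense of polar ones; the IVYWREL fraction
(Ile, Val, Tyr, Trp, Arg, Glu, Leu) tracks optimal growth temperature
(OGT) closely enough that a linear regression on it predicts OGT from a
genome alone. This module computes, per genome:

* pooled amino-acid usage (20-letter frequency vector),
* class fractions under a configurable polar / non-polar / charged
  partition,
* the IVYWREL fraction, and
* predicted OGT under a configurable linear model (default:
  OGT = 937·f − 335 °C, the regression published with the index).

Counts are pooled over all proteins of a genome; ambiguous letters
(X, B, Z, U, J, *) are excluded from every numerator and denominator,
so every reported quantity is a fraction of identified residues.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .seqio import AA_STANDARD, Habitat, ProteinSeq

__all__ = [
    "AAClassMap",
    "AAProfile",
    "OGTModel",
    "DEFAULT_CLASS_MAP",
    "DEFAULT_OGT_MODEL",
    "IVYWREL_LETTERS",
    "aa_usage",
    "ivywrel",
    "predict_ogt",
    "profile_cohort",
    "profiles_table",
]

IVYWREL_LETTERS = frozenset("IVYWREL")

CLASS_NAMES = ("polar", "nonpolar", "charged")


@dataclass(frozen=True)
class AAClassMap:
    """Partition of the 20 standard letters into polar / non-polar /
    charged classes. Must cover the 20 letters exactly once."""

    class_of: dict[str, str]

    def __post_init__(self) -> None:
        letters = sorted(self.class_of)
        if letters != sorted(AA_STANDARD):
            raise ValueError(
                "class map must cover exactly the 20 standard letters"
            )
        bad = {c for c in self.class_of.values() if c not in CLASS_NAMES}
        if bad:
            raise ValueError(f"unknown class names: {sorted(bad)}")

    def members(self, cls: str) -> frozenset:
        return frozenset(
            l for l, c in self.class_of.items() if c == cls
        )


# Standard biochemistry partition; user-overridable, and reports echo
# the map in use.
DEFAULT_CLASS_MAP = AAClassMap({
    **{l: "nonpolar" for l in "AVLIPFMWG"},
    **{l: "polar" for l in "STCYNQ"},
    **{l: "charged" for l in "DEKRH"},
})


@dataclass(frozen=True)
class OGTModel:
    """Linear OGT regression on the IVYWREL fraction: OGT = a·f + b."""

    a: float = 937.0
    b: float = -335.0


DEFAULT_OGT_MODEL = OGTModel()


@dataclass
class AAProfile:
    """Pooled composition profile of one genome's proteome."""

    genome_id: str
    freq: dict[str, float]
    class_frac: dict[str, float]
    ivywrel: float
    ogt_pred_c: float
    n_residues: int
    habitat: Habitat = Habitat.unknown


def _pooled_counts(proteome: list[ProteinSeq]) -> Counter:
    counts: Counter = Counter()
    for p in proteome:
        counts.update(p.seq)
    return Counter({l: counts[l] for l in AA_STANDARD})


def aa_usage(proteome: list[ProteinSeq],
             classes: AAClassMap = DEFAULT_CLASS_MAP,
             ) -> tuple[dict[str, float], dict[str, float], int]:
    """Pooled letter frequencies and class fractions of a proteome.

    Returns ``(freq, class_frac, n_residues)`` where ``n_residues``
    counts only the 20 standard letters. Raises if the proteome has no
    standard residue.
    """
    counts = _pooled_counts(proteome)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("proteome contains no standard amino-acid residue")
    freq = {l: counts[l] / n for l in AA_STANDARD}
    class_frac = {c: 0.0 for c in CLASS_NAMES}
    for l, f in freq.items():
        class_frac[classes.class_of[l]] += f
    return freq, class_frac, n


def ivywrel(proteome: list[ProteinSeq]) -> float:
    """Fraction of identified residues that are I, V, Y, W, R, E or L,
    pooled across the proteome."""
    counts = _pooled_counts(proteome)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("proteome contains no standard amino-acid residue")
    return sum(counts[l] for l in IVYWREL_LETTERS) / n


def predict_ogt(ivywrel_fraction: float,
                model: OGTModel = DEFAULT_OGT_MODEL) -> float:
    """Predicted optimal growth temperature (°C) from the IVYWREL
    fraction under a linear model."""
    if not 0.0 <= ivywrel_fraction <= 1.0:
        raise ValueError(
            f"IVYWREL fraction {ivywrel_fraction} outside [0, 1]"
        )
    return model.a * ivywrel_fraction + model.b


def profile_genome(genome_id: str, proteome: list[ProteinSeq],
                   classes: AAClassMap = DEFAULT_CLASS_MAP,
                   model: OGTModel = DEFAULT_OGT_MODEL,
                   habitat: Habitat = Habitat.unknown) -> AAProfile:
    """Full composition profile (usage, classes, IVYWREL, OGT) of one
    genome."""
    freq, class_frac, n = aa_usage(proteome, classes)
    f = sum(freq[l] for l in IVYWREL_LETTERS)
    return AAProfile(
        genome_id=genome_id, freq=freq, class_frac=class_frac,
        ivywrel=f, ogt_pred_c=predict_ogt(f, model), n_residues=n,
        habitat=habitat,
    )


def profile_cohort(proteomes: dict[str, list[ProteinSeq]],
                   labels: dict[str, Habitat] | None = None,
                   classes: AAClassMap = DEFAULT_CLASS_MAP,
                   model: OGTModel = DEFAULT_OGT_MODEL) -> list[AAProfile]:
    """Profile every genome of a cohort, attaching habitat labels for
    downstream group comparison. Per-genome errors are re-raised with
    the genome id attached."""
    labels = labels or {}
    out = []
    for gid, proteome in proteomes.items():
        try:
            out.append(profile_genome(
                gid, proteome, classes, model,
                habitat=labels.get(gid, Habitat.unknown),
            ))
        except ValueError as exc:
            raise ValueError(f"genome {gid!r}: {exc}") from exc
    return out


def profiles_table(profiles: list[AAProfile]) -> pd.DataFrame:
    """Report table: one row per genome.

    IVYWREL is reported both as a fraction and ×100 (index style,
    matching the conventional printed range of ~40 for mesophiles).
    """
    rows = []
    for p in profiles:
        row = {
            "genome_id": p.genome_id,
            "habitat": p.habitat.value,
            "n_residues": p.n_residues,
            "polar": p.class_frac["polar"],
            "nonpolar": p.class_frac["nonpolar"],
            "charged": p.class_frac["charged"],
            "ivywrel": p.ivywrel,
            "ivywrel_index": 100.0 * p.ivywrel,
            "ogt_pred_c": p.ogt_pred_c,
        }
        row.update({f"freq_{l}": p.freq[l] for l in AA_STANDARD})
        rows.append(row)
    return pd.DataFrame(rows)
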