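"""Protein isoelectric points from Henderson–Hasselbalch net charge.

The net charge of a protein at a given pH is modelled as the sum of
independent titratable groups: the N-terminus, Lys, Arg and His
contribute positive charge ``1/(1+10^(pH−pKa))``; the C-terminus, Asp,
Glu, Cys and Tyr contribute negative charge ``−1/(1+10^(pKa−pH))``.
The isoelectric point (pI) is the unique pH where the net charge is
zero — unique because every term, hence the sum, is strictly
decreasing in pH — and is found by bisection on [0, 14].

Computed pI values depend on the pKa set; the default is the public
EMBOSS set. X/B/Z/U/J are treated as non-ionizable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .seqio import ProteinSeq

__all__ = [
    "PKaSet",
    "PIResult",
    "EMBOSS_PKA",
    "net_charge",
    "isoelectric_point",
    "proteome_pi_table",
    "pi_summary",
]

_POSITIVE = "KRH"
_NEGATIVE = "DECY"


@dataclass(frozen=True)
class PKaSet:
    """Acid-dissociation constants for the ionizable groups."""

    name: str
    nterm: float
    cterm: float
    sidechain: dict[str, float]  # keys among D,E,C,Y,H,K,R

    def __post_init__(self) -> None:
        vals = [self.nterm, self.cterm, *self.sidechain.values()]
        if not all(0.0 < v < 14.0 for v in vals):
            raise ValueError(f"pKa set {self.name!r}: values outside (0,14)")


EMBOSS_PKA = PKaSet(
    name="emboss",
    nterm=8.6, cterm=3.6,
    sidechain={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
               "H": 6.5, "K": 10.8, "R": 12.5},
)

PKA_SETS = {"emboss": EMBOSS_PKA}


@dataclass(frozen=True)
class PIResult:
    protein_id: str
    pi: float
    n_ionizable: int


def net_charge(seq: ProteinSeq | str, ph: float,
               pkas: PKaSet = EMBOSS_PKA) -> float:
    """Net charge (elementary charges) of a protein at a given pH."""
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH {ph} outside [0, 14]")
    s = seq.seq if isinstance(seq, ProteinSeq) else seq
    charge = 1.0 / (1.0 + 10.0 ** (ph - pkas.nterm))
    charge -= 1.0 / (1.0 + 10.0 ** (pkas.cterm - ph))
    for letter in _POSITIVE:
        k = pkas.sidechain.get(letter)
        if k is not None:
            charge += s.count(letter) / (1.0 + 10.0 ** (ph - k))
    for letter in _NEGATIVE:
        k = pkas.sidechain.get(letter)
        if k is not None:
            charge -= s.count(letter) / (1.0 + 10.0 ** (k - ph))
    return charge


def isoelectric_point(seq: ProteinSeq, pkas: PKaSet = EMBOSS_PKA,
                      tol: float = 1e-4) -> PIResult:
    """pI by bisection on [0, 14] to |net charge| ≤ tol.

    The termini always provide one positive and one negative group, so
    the charge runs from positive at pH 0 to negative at pH 14 and the
    bracket is valid by construction.
    """
    lo, hi = 0.0, 14.0
    c_lo = net_charge(seq, lo, pkas)
    c_hi = net_charge(seq, hi, pkas)
    if not (c_lo > 0 > c_hi):  # pragma: no cover - impossible with termini
        raise RuntimeError("net-charge bracket is not sign-changing")
    mid = 7.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = net_charge(seq, mid, pkas)
        if abs(c) <= tol:
            break
        if c > 0:
            lo = mid
        else:
            hi = mid
    n_ion = 2 + sum(
        seq.seq.count(l) for l in pkas.sidechain
    )
    return PIResult(seq.protein_id, pi=round(mid, 2), n_ionizable=n_ion)


def proteome_pi_table(proteome: list[ProteinSeq],
                      pkas: PKaSet = EMBOSS_PKA) -> pd.DataFrame:
    """Per-protein pI report for one proteome."""
    rows = [
        {"protein_id": r.protein_id, "pi": r.pi,
         "n_ionizable": r.n_ionizable}
        for r in (isoelectric_point(p, pkas) for p in proteome)
    ]
    return pd.DataFrame(rows, columns=["protein_id", "pi", "n_ionizable"])


def pi_summary(pi_table: pd.DataFrame) -> dict[str, float]:
    """Per-genome summary: median pI and fraction of acidic (pI < 7)
    proteins."""
    return {
        "median_pi": float(pi_table["pi"].median()),
        "frac_acidic": float((pi_table["pi"] < 7.0).mean()),
    }
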