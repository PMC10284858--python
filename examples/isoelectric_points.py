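"""Isoelectric points by net-charge bisection.

Computes the pI of a few peptides under the EMBOSS pKa set: the pH at
which the Henderson–Hasselbalch net charge over all ionizable groups
(termini, D/E/C/Y negative, K/R/H positive) crosses zero.
"""

from thermotrait import isoelectric_point, net_charge
from thermotrait.protein_pi import proteome_pi_table, pi_summary
from thermotrait.seqio import ProteinSeq

peptides = [ProteinSeq("acidic", "DDEEGG"),
            ProteinSeq("basic", "KKRRGG"),
            ProteinSeq("mixed", "MKDAERH")]

table = proteome_pi_table(peptides)
print(table.to_string(index=False))
print("\nnet charge of 'mixed' at pH 7:",
      round(net_charge(peptides[2], 7.0), 3))
print("summary:", pi_summary(table))
print("\nAcid-rich peptides sit below pH 7, basic ones above; the "
      "summary gives the median pI and acidic fraction used as the "
      "per-genome report.")
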