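# Methods

## Scope and model

`thermotrait` quantifies thermal-adaptation signals in genome bins
(MAGs) and compares them between habitat groups. The underlying model
is compositional: a genome's pooled proteome is treated as a bag of
residues drawn from a 20-letter frequency vector, and thermophily
manifests as (i) a shift of that vector toward charged and non-polar
classes and away from polar ones, (ii) a higher IVYWREL fraction
*f* = (I+V+Y+W+R+E+L)/N, and (iii) a smaller assembly. Group contrasts
are tested non-parametrically; no phylogenetic correction is applied
(group membership is treated as exchangeable), which is a known
limitation of this design.

## Per-genome quantities

**GC content** is 100·(G+C)/(A+C+G+T); N and IUPAC ambiguity codes are
excluded from numerator *and* denominator so gappy assemblies are not
deflated. **Genome size** counts every residue including N (assembly
length as deposited). **N50** is the smallest contig length L such that
contigs ≥ L cover half the assembly. **Coding density** sums CDS
lengths over assembly length without overlap deduplication (matching
common annotation-pipeline summaries; values > 100% are possible with
heavily overlapping models and are reported, not clamped); a
union-length mode (`overlap_dedup=True`) is available. **Average gene
length** uses coding (CDS) length, not genomic span; CDS segments
sharing a GFF3 `ID` are merged with summed length. Coordinates are
1-based inclusive (GFF3 native) everywhere.

**Amino-acid usage** is pooled over all proteins of a genome (an
alternative per-protein mean is deliberately not the default: pooling
weights proteins by length, matching the residue-level model).
Ambiguous letters (X, B, Z, U, J, *) are excluded from every numerator
and denominator. The default class partition is the standard
biochemistry one — non-polar {A,V,L,I,P,F,M,W,G}, polar {S,T,C,Y,N,Q},
charged {D,E,K,R,H} — and is user-configurable; reports echo the map
used.

**OGT** is predicted as a·f + b with configurable coefficients. The
default (a = 937 °C, b = −335 °C) is the published linear regression of
optimal growth temperature on the IVYWREL fraction. Because OGT methods
differ between tools, the module guarantees only the configured model's
arithmetic; coefficients used are recorded in every report.

**Isoelectric points** solve Σ charges(pH) = 0 where positive groups
(N-terminus, K, R, H) contribute 1/(1+10^(pH−pKa)) and negative groups
(C-terminus, D, E, C, Y) contribute −1/(1+10^(pKa−pH)). The sum is
strictly decreasing in pH and the termini guarantee a sign change on
[0, 14], so bisection converges to the unique root; iteration stops at
|charge| ≤ 1e-4 (default) and pI is reported to 2 decimals. The default
pKa set is the public EMBOSS set; published pI values depend strongly
on the pKa model, so cross-tool comparisons should fix the set. The
per-genome summary is the median pI and the fraction of acidic (pI < 7)
proteins.

## Community and expression

**Relative abundance** of a bin in a sample is 100 × (summed mean depth
of its contigs) / (summed mean depth of all contigs). Unbinned contigs
stay in the denominator and are reported as a pseudo-bin so columns
close to 100. The default `sum_cov` mode follows this formula verbatim
even though it over-weights fragmented bins; `len_weighted` mode uses
depth×length (mapped bases) in both sums and is the recommended
alternative when contig length distributions differ between bins.
Guild dominance (which ammonia-oxidizer guild tops each sample) takes
guild labels as an input table; marker-gene annotation is out of scope.

**FPKM** is counts·10⁹/(gene length · total mapped fragments), with
`total_mapped` defaulting to the per-sample sum of counts over the
reference gene set — i.e., the mapping-restricted library, computed
jointly over all reference genomes rather than per genome. A gene is
"detected" when FPKM > 0 (threshold configurable) in at least one
sample; detected percentages are reported to one decimal. Counts are
taken as given; multi-mapping resolution is upstream.

## Group statistics

The Wilcoxon rank-sum test reports the group-1 rank sum W and a
two-sided p = min(1, 2·min(P(W ≤ w), P(W ≥ w))). For tie-free pooled
samples with n₁+n₂ ≤ 20 the p-value is exact: the null distribution of
W is computed by the subset-sum count recursion (equivalent to
enumerating all C(N, n₁) rank assignments) and cached per (n₁, n₂).
Larger or tied samples use the normal approximation with tie-corrected
variance and a 0.5 continuity correction; `method="exact"` can force
the exact distribution for any tie-free sample sizes. No
multiple-testing correction is applied by default (per-property raw
p-values are reported); Holm step-down adjustment is available.
Correlations are Pearson (product-moment) or Spearman (Pearson on
average ranks), both with t-transform p-values.

## Synthetic data

The generator emulates the study conditions the pipeline is designed
for, and its defaults are those conditions:

* **Cohort**: 12 thermal vs 18 non-thermal genomes. Base amino-acid
  frequencies are the Swiss-Prot average composition (IVYWREL ≈ 0.388,
  i.e. a mesophile under the default OGT model). The thermal group's
  class fractions are shifted by (+0.02 charged, +0.02 non-polar,
  −0.04 polar) by default — shifts are applied multiplicatively within
  classes and renormalization is exact because they sum to zero, so all
  20 letters stay present. Residues per proteome default to 50,000
  (the scale at which letter frequencies are recovered within 3
  binomial standard errors), split into 100 proteins at uniform random
  breakpoints. Genome sizes are Normal(2.88 Mbp, 0.25) for thermal and
  Normal(3.74 Mbp, 0.45) for non-thermal (the midpoints and spreads of
  the ranges typical for thermal vs mesophilic clade-A comammox
  assemblies); GC is Normal(58%, 1.2) vs Normal(56%, 1.5).
* **Community**: bins of log-normal per-sample depth with ±20% uniform
  per-contig jitter, contig lengths Normal(20 kb, 10 kb) truncated at
  2.5 kb, and a configurable unbinned fraction (default 20% of the
  binned contig count). The generator returns the constructed per-bin
  depth sums, so abundance recovery is an arithmetic identity.
* **Expression**: exactly round(fraction·n) genes are expressed;
  expressed genes draw 1 + NB(mean−1, dispersion) fragments per sample
  (a shifted negative binomial, guaranteeing ≥ 1 fragment so the
  detected fraction recovers the specification exactly at threshold 0),
  all other genes are structural zeros. Negative-binomial rather than
  Poisson counts provide realistic overdispersion for power studies.

All draws flow through one `numpy.random.Generator` passed explicitly;
fixed seeds give bit-identical outputs, and generated files round-trip
through the readers losslessly.

What the generator does **not** emulate: phylogenetic correlation
between genomes, codon/GC coupling between the nucleotide and protein
models, read-level noise, multi-mapping artifacts, or between-genome
overdispersion of composition beyond multinomial sampling. Passing
tests therefore demonstrate correctness of the computations and
calibration of the statistics under exchangeable sampling — not that
real habitat groups differ, which is an empirical question for real
data.

## Experiment sizes

The statistical validation experiments run at these problem sizes,
chosen so the full suite completes in seconds while keeping Monte-Carlo
error small relative to the quantities checked: null calibration uses
2,000 replicate 12-vs-18 cohorts at 5,000 residues per genome
(rank-sum calibration does not depend on the residue count), drawing
per-genome class counts directly from the multinomial model rather than
materializing sequences; the power grid uses 400 replicates per effect
size at 2,000 residues; frequency and shift recovery use the full
50,000-residue proteomes; the detected-gene computation uses the full
19,142-gene, 3-sample matrix.

## Degenerate inputs and tie-breaks

Empty FASTA files, duplicate record ids, illegal characters, all-N
genomes, negative depths, zero-coverage samples, zero-length genes and
proteomes without standard residues are rejected with named errors.
Identical pooled samples give p = 1 with direction "none" (no signal,
not an error). Genomes with no gene models report gene count 0,
missing average gene length and density 0. Dominance ties are reported
as ties, not broken. Per-genome failures in a cohort run are logged
and skipped; the run exits with a "partial" status code (3).
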