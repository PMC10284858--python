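# thermotrait

Comparative thermophily profiling of metagenome-assembled genomes
(MAGs), built for microbial ecologists studying nitrifier communities —
in particular complete ammonia oxidizers (comammox *Nitrospira*) — along
temperature gradients such as hot springs.

Thermophilic prokaryotes leave a compositional fingerprint in their
genomes: proteomes enriched in charged and non-polar amino acids at the
expense of polar ones, and reduced genome sizes. `thermotrait` turns
those signals into a tested, reusable pipeline:

* **Genome properties** — assembly size, GC content (N-excluded
  denominator), N50, gene count, average CDS length, coding density.
* **Composition profiling** — pooled amino-acid usage, class fractions
  under a configurable polar / non-polar / charged partition, and the
  **IVYWREL fraction** *f* (Ile, Val, Tyr, Trp, Arg, Glu, Leu), from
  which optimal growth temperature is predicted by a linear model,
  default `OGT = 937·f − 335 °C`.
* **Isoelectric points** — per-protein pI by bisection on the
  Henderson–Hasselbalch net-charge function (EMBOSS pKa set by
  default).
* **Community abundance** — MAG relative abundance per sample as
  `100 · Σ depth(contigs of bin) / Σ depth(all contigs)` from
  MetaBAT-style depth tables, plus nitrifier-guild dominance calls.
* **Expression** — FPKM (`counts · 10⁹ / (length · library size)`),
  detected-gene fractions and pathway transcript shares.
* **Group statistics** — two-sided Wilcoxon rank-sum comparisons of
  every property between thermal and non-thermal genomes (exact
  p-values by rank enumeration for small tie-free samples), and
  Pearson/Spearman correlation for genome size vs predicted OGT.
* **Synthetic cohorts** — a seeded generator for proteomes, genomes,
  depth and count tables with known ground truth, used for the
  calibration, power and parameter-recovery experiments in the test
  suite.

## Worked example

```python
from thermotrait import CohortSpec, profile_cohort, simulate_cohort

spec = CohortSpec(n_thermal=3, n_nonthermal=3,
                  residues_per_genome=10_000, seed=42)
proteomes, labels = simulate_cohort(spec)
for p in profile_cohort(proteomes, labels):
    print(p.genome_id, p.habitat.value, round(p.class_frac["charged"], 4),
          round(p.ivywrel, 4), round(p.ogt_pred_c, 1))
```

prints

```
thermal_01 thermal     0.2792 0.4022 41.9
thermal_02 thermal     0.2762 0.4001 39.9
thermal_03 thermal     0.2787 0.3949 35.0
meso_01 non_thermal    0.2576 0.3908 31.2
meso_02 non_thermal    0.2539 0.3896 30.1
meso_03 non_thermal    0.2611 0.3970 37.0
```

Thermal genomes carry ~2 percentage points more charged residues, and
their higher IVYWREL fraction maps to predicted optimal growth
temperatures in the high 30s–low 40s °C, versus ~30 °C for the
non-thermal group. The `examples/` directory holds one short script per
capability (profiling, group comparison, abundance, FPKM, pI).

## Command line

```bash
thermotrait demo --seed 1 --out-dir demo_out        # simulate + full chain
thermotrait profile --proteomes DIR --labels labels.tsv --out-dir out
thermotrait abundance --depth depth.tsv --bins bins.tsv --out ra.tsv
thermotrait expression --counts counts.tsv --out fpkm.tsv
thermotrait pi --proteome p.faa --out pi.tsv
thermotrait simulate cohort --seed 3 --out-dir sim
```

All outputs are TSV plus a JSON run manifest; identical config and seed
give byte-identical outputs.

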