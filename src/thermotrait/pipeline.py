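"""End-to-end runs: profile → compare, abundance, expression, demo.

Thin orchestration over the library modules: resolves inputs, applies
configuration, writes deterministic TSV reports plus a JSON run
manifest. The CLI in :mod:`thermotrait.cli` is a shell wrapper around
these functions.

Exit-status convention (surfaced by the CLI): 0 clean, 3 partial
(some genomes failed and were skipped), 1 fatal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import seqio
from .genome_props import genome_properties, properties_table
from .group_stats import compare_cohort, comparisons_table, correlate
from .protein_pi import PKA_SETS, EMBOSS_PKA, pi_summary, proteome_pi_table
from .seqio import Habitat, write_tsv
from .synthetic_data import CohortSpec, simulate_cohort
from .thermo_profile import (
    AAClassMap, DEFAULT_CLASS_MAP, DEFAULT_OGT_MODEL, OGTModel,
    profile_cohort, profiles_table,
)

logger = logging.getLogger(__name__)

EXIT_OK, EXIT_FATAL, EXIT_PARTIAL = 0, 1, 3


@dataclass
class RunConfig:
    """Validated run configuration; flags override config-file values."""

    genomes_dir: Path | None = None
    gff_dir: Path | None = None
    proteomes_dir: Path | None = None
    labels_path: Path | None = None
    out_dir: Path = Path("thermotrait_out")
    class_map: AAClassMap = field(default_factory=lambda: DEFAULT_CLASS_MAP)
    ogt_model: OGTModel = field(default_factory=lambda: DEFAULT_OGT_MODEL)
    pka_set: str = "emboss"
    abundance_mode: str = "sum_cov"
    fpkm_threshold: float = 0.0
    compute_pi: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pka_set not in PKA_SETS:
            raise ValueError(f"unknown pKa set {self.pka_set!r}")
        if self.abundance_mode not in ("sum_cov", "len_weighted"):
            raise ValueError(
                f"unknown abundance mode {self.abundance_mode!r}"
            )

    @classmethod
    def from_toml(cls, path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs: dict = {}
        for key in ("genomes_dir", "gff_dir", "proteomes_dir",
                    "labels_path", "out_dir"):
            if key in raw:
                kwargs[key] = Path(raw[key])
        if "class_map" in raw:
            kwargs["class_map"] = AAClassMap(raw["class_map"])
        if "ogt_model" in raw:
            kwargs["ogt_model"] = OGTModel(**raw["ogt_model"])
        for key in ("pka_set", "abundance_mode", "fpkm_threshold",
                    "compute_pi", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)


def _manifest(config: RunConfig, inputs: dict) -> dict:
    cfg = {k: str(v) for k, v in dataclasses.asdict(config).items()}
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    return {"version": __version__, "config": cfg,
            "config_hash": digest, "inputs": inputs}


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_profile(config: RunConfig) -> int:
    """Per-genome properties, composition profiles and (optionally)
    pI summaries, written under ``config.out_dir``.

    Per-genome failures are logged and skipped; the return code is 3
    when any genome failed, 0 otherwise.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = (seqio.read_labels(config.labels_path)
              if config.labels_path else {})
    failed: list[str] = []
    inputs: dict = {}

    props = []
    if config.genomes_dir:
        fastas = sorted(Path(config.genomes_dir).glob("*.f*a")) + \
            sorted(Path(config.genomes_dir).glob("*.fasta"))
        fastas = sorted(set(fastas))
        inputs["genomes"] = [str(p) for p in fastas]
        for fasta in fastas:
            gid = fasta.stem
            try:
                genome = seqio.read_genome_fasta(
                    fasta, habitat=labels.get(gid, Habitat.unknown))
                genes = None
                if config.gff_dir:
                    gff = Path(config.gff_dir) / f"{gid}.gff3"
                    if not gff.exists():
                        gff = Path(config.gff_dir) / f"{gid}.gff"
                    if gff.exists():
                        genes = seqio.read_gff3(gff)
                    else:
                        logger.warning(
                            "genome %s: no GFF found; gene columns "
                            "will be missing", gid)
                props.append(genome_properties(genome, genes))
            except (ValueError, OSError) as exc:
                logger.error("genome %s: %s", gid, exc)
                failed.append(gid)
        if props:
            write_tsv(properties_table(props), out / "props.tsv")

    if config.proteomes_dir:
        faas = sorted(Path(config.proteomes_dir).glob("*.faa"))
        inputs["proteomes"] = [str(p) for p in faas]
        proteomes = {}
        for faa in faas:
            gid = faa.stem
            try:
                proteomes[gid] = seqio.read_protein_fasta(faa)
            except (ValueError, OSError) as exc:
                logger.error("proteome %s: %s", gid, exc)
                failed.append(gid)
        if proteomes:
            profiles = profile_cohort(
                proteomes, labels, config.class_map, config.ogt_model)
            write_tsv(profiles_table(profiles), out / "aa_profiles.tsv")
            if config.compute_pi:
                rows = []
                for gid, proteome in sorted(proteomes.items()):
                    table = proteome_pi_table(
                        proteome, PKA_SETS[config.pka_set])
                    rows.append({"genome_id": gid, **pi_summary(table)})
                write_tsv(pd.DataFrame(rows), out / "pi.tsv")

    _write_manifest(out, _manifest(config, inputs))
    return EXIT_PARTIAL if failed else EXIT_OK


def run_compare(profiles_tsv, out_dir, props_tsv=None) -> int:
    """Group comparison from a written profile (and optional property)
    table; writes comparisons.tsv."""
    out = Path(out_dir)
    table = pd.read_csv(profiles_tsv, sep="\t")
    if props_tsv is not None:
        props = pd.read_csv(props_tsv, sep="\t")
        table = table.merge(props, on="genome_id", how="left")
    comparisons = compare_cohort(table)
    write_tsv(comparisons_table(comparisons), out / "comparisons.tsv")
    return EXIT_OK


def run_demo(seed: int, out_dir, residues_per_genome: int = 20_000) -> int:
    """Simulate a 12 vs 18 cohort with thermal-style composition and
    size contrasts, profile it, compare the groups, and write the full
    report chain plus a plain-text summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(seed=seed, residues_per_genome=residues_per_genome)
    proteomes, labels = simulate_cohort(spec)
    profiles = profile_cohort(proteomes, labels)
    prof_df = profiles_table(profiles)
    # genome sizes drawn from the group distributions, attached so the
    # size comparison runs without simulating full assemblies
    import numpy as np
    rng = np.random.default_rng(spec.seed + 1)
    sizes = []
    for gid in prof_df["genome_id"]:
        thermal = labels[gid] is Habitat.thermal
        mu = spec.size_mean_thermal if thermal else spec.size_mean_nonthermal
        sd = spec.size_sd_thermal if thermal else spec.size_sd_nonthermal
        sizes.append(float(rng.normal(mu, sd)))
    prof_df["size_bp"] = sizes
    write_tsv(prof_df, out / "aa_profiles.tsv")
    comparisons = compare_cohort(prof_df)
    comp_df = comparisons_table(comparisons)
    write_tsv(comp_df, out / "comparisons.tsv")
    corr = correlate(prof_df["size_bp"], prof_df["ogt_pred_c"], "pearson")
    lines = ["demo cohort: 12 thermal vs 18 non-thermal simulated genomes",
             ""]
    for c in comparisons:
        verdict = "separates" if c.p_two_sided < 0.05 else "does not separate"
        lines.append(
            f"{c.property_name}: p={c.p_two_sided:.4g} ({c.method}) "
            f"{verdict} the groups; direction {c.direction}"
        )
    lines.append("")
    lines.append(
        f"size vs predicted OGT: pearson r={corr.r:.3f} "
        f"(n={corr.n}, p={corr.p_two_sided:.3g})"
    )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    config = RunConfig(out_dir=out, seed=seed)
    _write_manifest(out, _manifest(config, {"mode": "demo"}))
    return EXIT_OK
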