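"""Run orchestration: configuration, file formats, stage functions.

Ties the stages together into reproducible runs::

    simulate  ->  strain genomes, FASTQ reads, annotation + phenotype TSVs
    quantify  ->  junction reports, variant catalogs, dosage matrix
    associate ->  strain filter, association ledgers, model-fit JSON

A single global seed fans out to per-stage seeds by a fixed derivation,
so each stage is independently reproducible; every stage writes a
manifest with a config echo and SHA-256 checksums of its outputs. All
user-facing coordinates are 1-based inclusive; TSVs carry header rows.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from ._util import sha256_file, spawn_seed
from .consensus_align import (
    AlignParams,
    ConsensusAligner,
    ConsensusIndex,
    UNALIGNED,
    compute_depth,
    estimate_genome_depth,
    left_align_junction,
)
from .dosage import (
    DosageProfile,
    annotation_copy_numbers,
    assembly_copy_numbers,
    build_dosage_matrix,
    estimator_correlations,
    fp_kp_ratio,
    load_annotation_table,
)
from .synthetic_data import (
    KP_JUNCTION,
    PhenotypeSimConfig,
    ReadPairs,
    StrainSimConfig,
    TECopySpec,
    TEConsensus,
    build_strain_haplotypes,
    default_variants,
    simulate_annotation_table,
    simulate_phenotypes,
    simulate_reads,
    synthetic_consensus,
    write_fastq_pair,
)
from .variant_model import (
    FULL_LENGTH,
    KP,
    VariantCatalog,
    classify_variant,
    collect_junctions,
    enumerate_variants,
    estimate_abundances,
    filter_variants,
)
from . import assoc as assoc_mod

__all__ = [
    "QuantifyParams",
    "RunConfig",
    "StrainQuantification",
    "quantify_strain_reads",
    "covariates_from_matrix",
    "run_simulate",
    "run_quantify",
    "run_associate",
    "read_fasta",
    "read_fastq_pair",
]


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


@dataclass(frozen=True)
class QuantifyParams:
    """Alignment, junction and filtering parameters for quantification."""

    k: int = 15
    min_overhang: int = 12
    max_mismatch_rate: float = 0.04
    min_support: int = 2
    min_frac: float = 0.01
    kp_junction: tuple[int, int] = KP_JUNCTION
    kp_tolerance_bp: int = 0

    def align_params(self) -> AlignParams:
        return AlignParams(self.k, self.min_overhang, self.max_mismatch_rate)


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    seed: int = 0
    outdir: str = "tedosage_run"
    simulate: dict = field(default_factory=dict)
    quantify: QuantifyParams = field(default_factory=QuantifyParams)
    associate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _check_keys(raw, {"seed", "outdir", "simulate", "quantify", "associate"}, "run config")
        sim = dict(raw.get("simulate") or {})
        _check_keys(
            sim,
            {
                "background_length", "depth", "read_length", "insert_mean", "insert_sd",
                "error_rate", "annotation_jitter", "strains", "phenotypes",
            },
            "simulate",
        )
        for strain in sim.get("strains", []):
            _check_keys(strain, {"id", "copies"}, f"simulate.strains[{strain.get('id')}]")
            for copy in strain.get("copies", []):
                _check_keys(copy, {"family", "variant", "count", "frequency"}, "copies entry")
        if "phenotypes" in sim and sim["phenotypes"] is not None:
            _check_keys(
                dict(sim["phenotypes"]),
                {
                    "beta0", "beta_P", "beta_H", "sigma_block", "sigma_strain",
                    "n_blocks", "blocks_per_strain", "females_per_strain_block",
                },
                "simulate.phenotypes",
            )
        q = dict(raw.get("quantify") or {})
        _check_keys(
            q,
            {"k", "min_overhang", "max_mismatch_rate", "min_support", "min_frac",
             "kp_junction", "kp_tolerance_bp"},
            "quantify",
        )
        if "kp_junction" in q:
            q["kp_junction"] = tuple(q["kp_junction"])
        ass = dict(raw.get("associate") or {})
        _check_keys(
            ass,
            {"focal", "baseline", "exclude", "min_females", "min_blocks", "per_block",
             "random_strain"},
            "associate",
        )
        return cls(
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "tedosage_run")),
            simulate=sim,
            quantify=QuantifyParams(**q),
            associate=ass,
        )


# ----------------------------------------------------------------------
# formats
# ----------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, entries: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in entries.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fastq_pair(path1, path2) -> ReadPairs:
    recs1 = list(SeqIO.parse(str(path1), "fastq"))
    recs2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(recs1) != len(recs2):
        raise ValueError(f"mate files {path1} and {path2} differ in read count")
    names = [r.id.rsplit("/", 1)[0] for r in recs1]
    return ReadPairs(names, [str(r.seq) for r in recs1], [str(r.seq) for r in recs2])


def _write_manifest(outdir: Path, stage: str, config_echo: dict, outputs: list[Path], t0: float) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "config": config_echo,
        "checksums": {p.name: sha256_file(p) for p in sorted(outputs)},
        "wall_clock_s": round(time.monotonic() - t0, 3),
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


# ----------------------------------------------------------------------
# quantification core (in-memory; file stages wrap this)
# ----------------------------------------------------------------------

@dataclass
class StrainQuantification:
    strain_id: str
    genome_mean_depth: float
    catalogs: dict[str, VariantCatalog]
    profiles: list[DosageProfile]
    junction_tables: dict[str, pd.DataFrame]


def quantify_strain_reads(
    strain_id: str,
    reads: ReadPairs,
    consensi: list[TEConsensus],
    background: str,
    params: QuantifyParams = QuantifyParams(),
) -> StrainQuantification:
    """Full per-strain quantification from reads held in memory.

    Two-pass alignment per family: novel junction discovery first, then
    realignment of unplaced reads with all retained junctions supplied
    as guided, so junction-spanning reads with short anchors are
    recovered. Genome mean depth comes from reads placed on the
    background reference.
    """
    aparams = params.align_params()
    bg_index = ConsensusIndex(background, params.k)
    genome_depth = estimate_genome_depth(reads.all_reads(), bg_index, aparams)

    catalogs: dict[str, VariantCatalog] = {}
    profiles: list[DosageProfile] = []
    junction_tables: dict[str, pd.DataFrame] = {}

    for consensus in consensi:
        family = consensus.family_name
        guided = (
            (left_align_junction(params.kp_junction, consensus),) if family == "P" else ()
        )
        aligner = ConsensusAligner(consensus, aparams, guided_junctions=guided)
        aligned, unplaced = [], []
        for read_id, seq in reads.all_reads():
            aln = aligner.align(read_id, seq)
            (aligned if aln.status != UNALIGNED else unplaced).append((aln, seq))
        evidence = collect_junctions((a for a, _ in aligned), guided, params.min_support)

        # second pass: rescue short-anchor junction reads with discovered
        # junctions supplied as guided references
        retained_junctions = tuple(e.junction for e in evidence)
        if retained_junctions:
            rescue = ConsensusAligner(consensus, aparams, guided_junctions=retained_junctions)
            still = []
            for aln, seq in unplaced:
                aln2 = rescue.align(aln.read_id, seq)
                if aln2.status != UNALIGNED:
                    aligned.append((aln2, seq))
                else:
                    still.append((aln, seq))
            evidence = collect_junctions((a for a, _ in aligned), guided, params.min_support)

        alignments = [a for a, _ in aligned]
        candidates = enumerate_variants(evidence, consensus)
        estimate_abundances(
            candidates, alignments, consensus.length,
            junction_margin=params.min_overhang - 1,
        )
        catalog = filter_variants(candidates, family, consensus.length, params.min_frac)
        kp_ref = left_align_junction(params.kp_junction, consensus) if family == "P" else None
        for v in catalog.retained:
            v.variant_class = classify_variant(v, kp_ref, params.kp_tolerance_bp)
        for v, _ in catalog.filtered:
            v.variant_class = classify_variant(v, kp_ref, params.kp_tolerance_bp)
        catalogs[family] = catalog

        junction_tables[family] = pd.DataFrame(
            [
                {
                    "family": family,
                    "donor": e.junction[0],
                    "acceptor": e.junction[1],
                    "support": e.support,
                    "guided": e.guided,
                }
                for e in evidence
            ],
            columns=["family", "donor", "acceptor", "support", "guided"],
        )

        profile = DosageProfile(strain=strain_id, family=family)
        if genome_depth > 0:
            total_cn, fl_cn, _, proportions = assembly_copy_numbers(catalog, genome_depth)
            depth_vec = compute_depth(alignments, consensus.length)
            profile.normalized_coverage = depth_vec.mean / genome_depth
            profile.assembly_total_cn = total_cn
            profile.full_length_cn = fl_cn
            profile.proportions = proportions
            if family == "P":
                profile.fp_kp_ratio = fp_kp_ratio(
                    catalog.class_abundance(FULL_LENGTH), catalog.class_abundance(KP)
                )
        profiles.append(profile)

    return StrainQuantification(strain_id, genome_depth, catalogs, profiles, junction_tables)


def covariates_from_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-strain covariate table: columns ``{family}_{estimator}``."""
    wide = matrix.pivot(index="strain", columns="family")
    wide.columns = [f"{family}_{estimator}" for estimator, family in wide.columns]
    return wide


# ----------------------------------------------------------------------
# file-based stages
# ----------------------------------------------------------------------

def _build_variant_library(config: RunConfig):
    consensi = [synthetic_consensus("P"), synthetic_consensus("hobo")]
    variants = {c.family_name: default_variants(c, config.quantify.kp_junction) for c in consensi}
    return consensi, variants


def run_simulate(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Generate genomes, reads, annotation, phenotypes and truth tables."""
    t0 = time.monotonic()
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulate
    consensi, variants = _build_variant_library(config)
    write_fasta(out / "consensi.fasta", {c.family_name: c.sequence for c in consensi})

    strain_entries = sim.get("strains", [])
    if not strain_entries:
        raise ValueError("simulate.strains is empty")
    outputs = [out / "consensi.fasta"]
    truth_rows, junction_rows, annotation_frames = [], [], []
    dosages = {}
    jitter = float(sim.get("annotation_jitter", 0.0))

    for entry in strain_entries:
        strain_id = str(entry["id"])
        copies = [TECopySpec(**c) for c in entry.get("copies", [])]
        cfg = StrainSimConfig(
            strain_id=strain_id,
            te_copies=copies,
            background_length=int(sim.get("background_length", 50_000)),
            depth=float(sim.get("depth", 30.0)),
            read_length=int(sim.get("read_length", 100)),
            insert_mean=float(sim.get("insert_mean", 300.0)),
            insert_sd=float(sim.get("insert_sd", 30.0)),
            error_rate=float(sim.get("error_rate", 0.002)),
            seed=spawn_seed(config.seed, "simulate", strain_id),
        )
        haps, truth = build_strain_haplotypes(cfg, consensi, variants)
        reads = simulate_reads(haps, cfg)
        write_fasta(out / f"{strain_id}_background.fasta", {"background": haps.background})
        write_fastq_pair(reads, out / f"{strain_id}_1.fastq", out / f"{strain_id}_2.fastq")
        outputs += [
            out / f"{strain_id}_background.fasta",
            out / f"{strain_id}_1.fastq",
            out / f"{strain_id}_2.fastq",
        ]
        annotation_frames.append(
            simulate_annotation_table(truth, jitter, seed=spawn_seed(config.seed, "annot", strain_id))
        )
        for family in ("P", "hobo"):
            truth_rows.append(
                {
                    "strain": strain_id,
                    "family": family,
                    "haploid_cn": truth.haploid_cn(family),
                    "realized_cn": truth.realized_cn(family),
                    "weighted_cn": truth.weighted_cn(family),
                    "proportions": json.dumps(truth.variant_proportions(family)),
                }
            )
            for donor, acceptor in truth.junctions(family):
                junction_rows.append(
                    {"strain": strain_id, "family": family, "donor": donor, "acceptor": acceptor}
                )
        dosages[strain_id] = (truth.weighted_cn("P"), truth.weighted_cn("hobo"))

    nonempty = [f for f in annotation_frames if not f.empty]
    annotation = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else pd.DataFrame(columns=["strain", "insertion_id", "family", "frequency"])
    )
    annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "truth_dosage.tsv", sep="\t", index=False)
    pd.DataFrame(junction_rows, columns=["strain", "family", "donor", "acceptor"]).to_csv(
        out / "truth_junctions.tsv", sep="\t", index=False
    )
    outputs += [out / "annotation.tsv", out / "truth_dosage.tsv", out / "truth_junctions.tsv"]

    pheno_cfg = sim.get("phenotypes")
    if pheno_cfg is not None:
        pcfg = PhenotypeSimConfig(**dict(pheno_cfg), seed=spawn_seed(config.seed, "phenotypes"))
        table, _ = simulate_phenotypes(pcfg, dosages)
        table.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
        outputs.append(out / "phenotypes.tsv")

    _write_manifest(out, "simulate", {"seed": config.seed, "simulate": sim}, outputs, t0)
    return out


def run_quantify(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Quantify every strain's FASTQ pair into the dosage matrix."""
    t0 = time.monotonic()
    out = Path(outdir if outdir is not None else config.outdir)
    consensi_seqs = read_fasta(out / "consensi.fasta")
    consensi = [TEConsensus(name, seq) for name, seq in consensi_seqs.items()]

    annotation = None
    if (out / "annotation.tsv").exists():
        annotation = load_annotation_table(out / "annotation.tsv")

    profiles, junction_frames, catalog_rows = [], [], []
    for fq1 in sorted(out.glob("*_1.fastq")):
        strain_id = fq1.name[: -len("_1.fastq")]
        fq2 = out / f"{strain_id}_2.fastq"
        if not fq2.exists():
            raise FileNotFoundError(f"missing mate file for {strain_id}: expected {fq2.name}")
        reads = read_fastq_pair(fq1, fq2)
        background = read_fasta(out / f"{strain_id}_background.fasta")["background"]
        result = quantify_strain_reads(strain_id, reads, consensi, background, config.quantify)
        for family, table in result.junction_tables.items():
            table = table.copy()
            table.insert(0, "strain", strain_id)
            junction_frames.append(table)
        for family, catalog in result.catalogs.items():
            for v in catalog.retained:
                catalog_rows.append(_catalog_row(strain_id, family, v, True, ""))
            for v, reason in catalog.filtered:
                catalog_rows.append(_catalog_row(strain_id, family, v, False, reason))
        for profile in result.profiles:
            if annotation is not None:
                total, weighted = annotation_copy_numbers(annotation, strain_id, profile.family)
                profile.annotation_total = total
                profile.annotation_weighted = weighted
            profiles.append(profile)

    matrix = build_dosage_matrix(profiles)
    matrix.to_csv(out / "dosage_matrix.tsv", sep="\t", index=False)
    junctions = (
        pd.concat(junction_frames, ignore_index=True)
        if junction_frames
        else pd.DataFrame(columns=["strain", "family", "donor", "acceptor", "support", "guided"])
    )
    junctions.to_csv(out / "junctions.tsv", sep="\t", index=False)
    pd.DataFrame(
        catalog_rows,
        columns=["strain", "family", "variant", "donor", "acceptor", "class", "abundance", "retained", "filter_reason"],
    ).to_csv(out / "variant_catalog.tsv", sep="\t", index=False)
    for family in matrix["family"].unique():
        estimator_correlations(matrix, family).to_csv(out / f"correlations_{family}.tsv", sep="\t")
    outputs = [out / "dosage_matrix.tsv", out / "junctions.tsv", out / "variant_catalog.tsv"] + [
        out / f"correlations_{family}.tsv" for family in matrix["family"].unique()
    ]
    _write_manifest(out, "quantify", {"seed": config.seed, "quantify": asdict(config.quantify)}, outputs, t0)
    return out


def _catalog_row(strain_id, family, v, retained, reason):
    donor, acceptor = v.junctions[0] if v.junctions else (None, None)
    return {
        "strain": strain_id,
        "family": family,
        "variant": v.name,
        "donor": donor,
        "acceptor": acceptor,
        "class": v.variant_class,
        "abundance": v.abundance,
        "retained": retained,
        "filter_reason": reason,
    }


def run_associate(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Strain filter, heritability comparison and association ledgers."""
    t0 = time.monotonic()
    out = Path(outdir if outdir is not None else config.outdir)
    records = pd.read_csv(out / "phenotypes.tsv", sep="\t")
    matrix = pd.read_csv(out / "dosage_matrix.tsv", sep="\t")
    covariates = covariates_from_matrix(matrix)

    missing = sorted(set(records["strain"]) - set(covariates.index))
    if missing:
        raise ValueError(f"phenotype strains absent from dosage matrix: {missing}")

    ass = config.associate
    retained, filtered = assoc_mod.strain_filter(
        records,
        min_females=int(ass.get("min_females", 20)),
        min_blocks=int(ass.get("min_blocks", 2)),
        per_block=bool(ass.get("per_block", True)),
    )

    focal = list(ass.get("focal") or [c for c in covariates.columns if c.startswith("P_")])
    baseline = tuple(ass.get("baseline") or ())
    exclude = tuple(ass.get("exclude") or ())
    random_strain = bool(ass.get("random_strain", False))

    ledger_full = assoc_mod.association_scan(
        filtered, covariates, focal, baseline, random_strain=random_strain
    )
    ledger_excl = assoc_mod.association_scan(
        filtered, covariates, focal, baseline, exclude_strains=exclude, random_strain=random_strain
    )
    ledger = ledger_full.merge(ledger_excl, on="estimator", suffixes=("", "_excluded"))
    ledger.to_csv(out / "association_ledger.tsv", sep="\t", index=False)

    null_fit, alt_fit, herit = assoc_mod.heritability_comparison(filtered)
    report = {
        "n_records": int(len(filtered)),
        "n_strains_retained": len(retained),
        "heritability": {
            "chi2": herit.chi2,
            "df": herit.df,
            "p": herit.p,
            "delta_aic": herit.delta_aic,
            "null_aic": null_fit.aic,
            "strain_fixed_aic": alt_fit.aic,
            "strain_fixed_loglik": alt_fit.log_likelihood,
        },
        "fits": {
            "null": _fit_json(null_fit),
            "strain_fixed": _fit_json(alt_fit),
        },
    }
    with open(out / "model_fits.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _write_manifest(
        out, "associate", {"seed": config.seed, "associate": ass},
        [out / "association_ledger.tsv", out / "model_fits.json"], t0,
    )
    return out


def _fit_json(fit) -> dict:
    return {
        "log_likelihood": fit.log_likelihood,
        "aic": fit.aic,
        "n_params": fit.n_params,
        "coefficients": fit.coefficients,
        "standard_errors": fit.standard_errors,
        "variance_components": fit.variance_components,
        "converged": fit.converged,
        "n_obs": fit.n_obs,
    }
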