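"""Per-species orchestration and cross-species aggregation.

Runs the stages in dependency order (k-mer fit first, since the TE subsample
needs the fitted haploid genome size; palindrome and HGT screens are
independent and require only the assembly annotation), records every output in
a machine-readable report, and aggregates reports into the cross-species
feature table grouped by hybrid origin and cellular mechanism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import hgt as hgt_mod
from . import io, kmer_profile, palindromes, te_load


@dataclass
class SpeciesConfig:
    species: str
    reads: str | None = None
    assembly: str | None = None
    gff: str | None = None
    proteins: str | None = None
    te_library: str | None = None
    hgt_db: str | None = None
    hgt_labels: str | None = None
    ploidy: int = 2
    topology: str = "AB"
    hybrid_origin: str = "unknown"  # hybrid | intraspecific | unknown
    mechanism: str = "unknown"
    k: int = 21
    genome_size_override: float | None = None
    hgt_threshold: float = 30.0
    seeds: dict[str, int] = field(default_factory=lambda: {"te_subsample": 0})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpeciesConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        if self.ploidy != len(self.topology):
            raise ValueError("ploidy/topology mismatch")
        for attr in ("reads", "assembly", "gff", "proteins", "te_library",
                     "hgt_db", "hgt_labels"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{attr}: {path}")


ABSENT = "absent"


@dataclass
class FeatureReport:
    """Per-species genome features; missing stages are recorded, never zeroed."""

    species: str
    hybrid_origin: str
    mechanism: str
    ploidy: int
    topology: str
    heterozygosity: dict | str = ABSENT  # per-layer %, composite %, lambda, G...
    structure: dict | str = ABSENT
    te: dict | str = ABSENT
    palindromes: dict | str = ABSENT
    hgt: dict | str = ABSENT
    warnings: list[str] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)  # field -> source file

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str, sort_keys=True)

    def flat_row(self) -> dict:
        row = dict(species=self.species, hybrid_origin=self.hybrid_origin,
                   mechanism=self.mechanism, ploidy=self.ploidy,
                   topology=self.topology)
        het = self.heterozygosity if isinstance(self.heterozygosity, dict) else {}
        row["het_composite_pct"] = het.get("het_composite_pct")
        te = self.te if isinstance(self.te, dict) else {}
        row["te_load_pct"] = te.get("te_load_percent")
        for cls in io.TE_CLASSES:
            row[f"te_{cls}_pct"] = (te.get("per_class_percent") or {}).get(cls)
        pal = self.palindromes if isinstance(self.palindromes, dict) else {}
        row["palindromes"] = pal.get("n_palindromes")
        row["palindrome_genes"] = pal.get("n_genes_affected")
        row["palindrome_gene_pct"] = pal.get("percent_genes")
        hgt = self.hgt if isinstance(self.hgt, dict) else {}
        row["hgt_c_pct"] = hgt.get("hgt_c_percent")
        return row


def run_species(config: SpeciesConfig, outdir: str | Path) -> FeatureReport:
    """Run every stage the config provides inputs for; failures never abort.

    Each stage writes its intermediate outputs under ``outdir`` and the report
    records, per feature, which file it came from. With fixed seeds the report
    is bit-identical across reruns.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = FeatureReport(species=config.species, hybrid_origin=config.hybrid_origin,
                           mechanism=config.mechanism, ploidy=config.ploidy,
                           topology=config.topology)

    reads = None
    fitted_G = None
    if config.reads is not None:
        try:
            reads = io.read_fastq(config.reads)
            table = kmer_profile.count_kmers(reads, k=config.k, keep_table=True)
            spectrum = table.spectrum()
            spectrum.to_tsv(outdir / "kmer_spectrum.tsv")
            fit = kmer_profile.fit_spectrum(spectrum, config.ploidy, config.topology)
            fitted_G = fit.genome_size_G
            report.heterozygosity = fit.to_dict()
            report.warnings.extend(fit.warnings)
            with open(outdir / "spectrum_fit.json", "w") as fh:
                json.dump(fit.to_dict(), fh, indent=2, default=str)
            report.provenance["heterozygosity"] = str(outdir / "spectrum_fit.json")
            if config.ploidy > 2:
                fams = kmer_profile.extract_het_families(
                    table, fit.error_cutoff, fit.lambda_cov, config.ploidy,
                    rho=max(fit.rho, 0.5))
                summary = kmer_profile.classify_structures(
                    fams, fit.lambda_cov, config.ploidy)
                report.structure = dict(fractions=summary.fractions,
                                        n_families=summary.n_families,
                                        n_classified=summary.n_classified)
                with open(outdir / "structure_summary.json", "w") as fh:
                    json.dump(report.structure, fh, indent=2)
                report.provenance["structure"] = str(outdir / "structure_summary.json")
        except Exception as exc:  # keep remaining stages running
            report.errors["kmer_profile"] = f"{type(exc).__name__}: {exc}"

    if reads is not None and config.te_library is not None:
        try:
            G = config.genome_size_override or fitted_G
            if G is None:
                raise ValueError("no genome size: k-mer fit failed and no override")
            lib = io.read_te_library(config.te_library)
            result = te_load.estimate_te_load(
                reads, G, lib, seed=config.seeds.get("te_subsample", 0))
            report.te = dict(sampled_nt=result.sampled_nt,
                             per_class_nt=result.per_class_nt,
                             unknown_repeat_nt=result.unknown_repeat_nt,
                             te_load_percent=result.te_load_percent,
                             per_class_percent=result.per_class_percent())
            result.long_table().to_csv(outdir / "te_classes.tsv", sep="\t", index=False)
            report.provenance["te"] = str(outdir / "te_classes.tsv")
        except Exception as exc:
            report.errors["te_load"] = f"{type(exc).__name__}: {exc}"

    genes = proteins = None
    if config.gff is not None and config.proteins is not None:
        try:
            genes = io.read_gff3_genes(config.gff)
            proteins = io.read_protein_fasta(config.proteins)
        except Exception as exc:
            report.errors["annotation"] = f"{type(exc).__name__}: {exc}"

    if genes is not None and proteins is not None:
        try:
            screen = palindromes.find_palindromes(proteins, genes)
            n, n_genes, pct = palindromes.summarize_palindromes(
                screen.palindromes, len(genes))
            report.palindromes = dict(n_palindromes=n, n_genes_affected=n_genes,
                                      percent_genes=pct)
            rows = [dict(scaffold=p.block.scaffold_a, n_genes=p.n_genes,
                         n_anchor_pairs=p.block.n_pairs,
                         genes=";".join(p.gene_ids))
                    for p in screen.palindromes]
            pd.DataFrame(rows, columns=["scaffold", "n_genes", "n_anchor_pairs",
                                        "genes"]).to_csv(
                outdir / "palindromes.tsv", sep="\t", index=False)
            report.provenance["palindromes"] = str(outdir / "palindromes.tsv")
        except Exception as exc:
            report.errors["palindromes"] = f"{type(exc).__name__}: {exc}"

        if config.hgt_db is not None and config.hgt_labels is not None:
            try:
                db = io.load_reference_db(config.hgt_db, config.hgt_labels)
                rep = hgt_mod.call_hgt(proteins, genes, db,
                                       threshold=config.hgt_threshold)
                report.hgt = dict(n_genes_total=rep.n_genes_total,
                                  n_candidates_prefilter=rep.n_candidates_prefilter,
                                  n_candidates_linked=rep.n_candidates_linked,
                                  hgt_c_percent=rep.hgt_c_percent)
                pd.DataFrame(
                    [dict(gene_id=s.gene_id, B_in=s.best_metazoan_score,
                          B_out=s.best_nonmetazoan_score, hU=s.hU, call=s.call)
                     for s in rep.scores]
                ).to_csv(outdir / "hgt_scores.tsv", sep="\t", index=False)
                report.provenance["hgt"] = str(outdir / "hgt_scores.tsv")
            except Exception as exc:
                report.errors["hgt"] = f"{type(exc).__name__}: {exc}"

    report.to_json(outdir / "feature_report.json")
    return report


def aggregate_reports(reports: list[FeatureReport]):
    """Cross-species feature table plus group summaries.

    Returns (table, group_summary): the table has one row per species; the
    summary reports median/min/max composite heterozygosity and TE load per
    (hybrid_origin, mechanism) group, the groupings behind the study's
    headline heterozygosity contrast.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    table = pd.DataFrame([r.flat_row() for r in reports])
    stats = (
        table.groupby(["hybrid_origin", "mechanism"], dropna=False)
        .agg(n=("species", "count"),
             het_median=("het_composite_pct", "median"),
             het_min=("het_composite_pct", "min"),
             het_max=("het_composite_pct", "max"),
             te_median=("te_load_pct", "median"))
        .reset_index()
    )
    return table, stats


def run_manifest(manifest_path: str | Path, outdir: str | Path):
    """Run every species listed in a YAML manifest and write the feature table."""
    outdir = Path(outdir)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    reports = []
    for entry in manifest["species"]:
        cfg = (SpeciesConfig.from_yaml(entry) if isinstance(entry, str)
               else SpeciesConfig(**entry))
        reports.append(run_species(cfg, outdir / cfg.species))
    table, stats = aggregate_reports(reports)
    table.to_csv(outdir / "feature_table.tsv", sep="\t", index=False)
    stats.to_csv(outdir / "group_summary.tsv", sep="\t", index=False)
    return table, stats
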