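"""Synthetic genomes with known truth.

Emulates the study system end to end: multi-haplotype genomes with a prescribed
divergence topology (AB, AAB, AAAB, AABB, ABC, ABCD), TE insertions at a target
load, reverse-complementary duplicated gene cassettes (palindromes), foreign
gene cassettes on host scaffolds (HGT) plus contaminant-only scaffolds, and
single-end shotgun reads with a uniform substitution-error model. Every implant
is recorded in a truth table so each analysis stage can be scored exactly.

Variant sites are substitutions only: the k-mer window algebra used by the
spectrum fit is exact for substitutions, and indels are out of scope. Genes are
ORF-like random sequences; downstream stages need only coordinates, strands and
homology signal, not biological realism.

Internal coordinates are 0-based half-open; GFF3 output is 1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import dna

# topology -> haplotype letters; identical letters are byte-identical copies
TOPOLOGIES = {
    "AB": "AB",
    "AAB": "AAB",
    "AAAB": "AAAB",
    "AABB": "AABB",
    "ABC": "ABC",
    "ABCD": "ABCD",
}

#: recognised het_rates keys per topology (first entry is the primary layer)
LAYER_KEYS = {
    "AB": ("allelic",),
    "AAB": ("homoeolog", "homolog"),
    "AAAB": ("homoeolog",),
    "AABB": ("homoeolog",),
    "ABC": ("branch", "branch_B", "branch_C"),
    "ABCD": ("pairwise",),
}

MAX_RATE = 0.35


@dataclass
class GenomeSpec:
    """Parameters of a simulated multi-haplotype genome.

    het_rates maps divergence layers to per-site substitution probabilities,
    e.g. ``{"homoeolog": 0.02}`` for an AAB triploid whose B copy diverged 2%
    from the two near-identical A copies.
    """

    ancestral_length: int
    ploidy: int
    topology: str
    het_rates: dict[str, float] = field(default_factory=dict)
    gc_content: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        letters = TOPOLOGIES[self.topology]
        if self.ploidy != len(letters):
            raise ValueError(
                f"ploidy {self.ploidy} does not match topology {self.topology} "
                f"({len(letters)} haplotypes)"
            )
        allowed = set(LAYER_KEYS[self.topology])
        for layer, rate in self.het_rates.items():
            if layer not in allowed:
                raise ValueError(
                    f"layer {layer!r} not valid for topology {self.topology}; "
                    f"expected one of {sorted(allowed)}"
                )
            if not 0.0 <= rate <= MAX_RATE:
                raise ValueError(f"het rate {layer}={rate} outside [0, {MAX_RATE}]")
        if self.ancestral_length < 10 * 31:
            raise ValueError("ancestral_length too short for downstream k-mer sizes")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")


@dataclass
class HaplotypeSet:
    """One sequence per haplotype copy plus the per-site truth table."""

    spec: GenomeSpec
    letters: str  # e.g. "AAB"; copies[i] belongs to letters[i]
    copies: list[np.ndarray]
    truth_sites: pd.DataFrame  # columns: position, layer, alleles, n_alleles

    @property
    def length(self) -> int:
        return len(self.copies[0])

    def copy_strings(self) -> list[str]:
        return [dna.decode(c) for c in self.copies]

    def het_window_positions(self, k: int, max_variants: int | None = None) -> np.ndarray:
        """Start positions of k-windows containing >=1 (or exactly n) variant sites.

        Truth oracle for het k-mer family counts: a window yields a detectable
        family only when its copies differ; ``max_variants=1`` restricts to
        windows with a single variant site (clean one-substitution families).
        """
        L = self.length
        hits = np.zeros(L, dtype=np.int32)
        hits[self.truth_sites["position"].to_numpy()] = 1
        cs = np.concatenate([[0], np.cumsum(hits)])
        per_window = cs[k:] - cs[: L - k + 1]
        if max_variants is None:
            keep = per_window >= 1
        else:
            keep = (per_window >= 1) & (per_window <= max_variants)
        return np.nonzero(keep)[0]


def _solve_abcd_branch_rate(pairwise: float) -> float:
    # pairwise divergence of two copies each mutated at q from a hidden
    # ancestor: 2q(1-q) + (2/3)q^2 ; solve for q
    if pairwise == 0:
        return 0.0
    a, b, c = 4.0 / 3.0, -2.0, pairwise
    return (-b - math.sqrt(b * b - 4 * a * c)) / (2 * a)


def simulate_haplotypes(spec: GenomeSpec) -> HaplotypeSet:
    """Simulate one sequence per haplotype letter under the topology's layers.

    Identical letters share byte-identical sequences (unless an explicit
    homolog layer is requested for AAB). Distinct letters differ by independent
    per-site substitutions at the layer's rate; the truth table lists every
    variant site with the allele carried by each copy.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.ancestral_length
    anc = dna.random_codes(rng, L, spec.gc_content)
    rates = spec.het_rates
    topo = spec.topology

    def draw_sites(rate: float) -> np.ndarray:
        return np.nonzero(rng.random(L) < rate)[0]

    events: list[tuple[str, np.ndarray]] = []  # (layer, positions) for bookkeeping
    copies: list[np.ndarray]

    if topo == "AB":
        pos = draw_sites(rates.get("allelic", 0.0))
        b = dna.mutate_codes(rng, anc, pos)
        copies = [anc, b]
        events.append(("allelic", pos))
    elif topo in ("AAB", "AAAB", "AABB"):
        pos = draw_sites(rates.get("homoeolog", 0.0))
        b = dna.mutate_codes(rng, anc, pos)
        events.append(("homoeolog", pos))
        if topo == "AAB":
            a2 = anc
            hom = rates.get("homolog", 0.0)
            if hom > 0:
                pos2 = draw_sites(hom)
                a2 = dna.mutate_codes(rng, anc, pos2)
                events.append(("homolog", pos2))
            copies = [anc, a2, b]
        elif topo == "AAAB":
            copies = [anc, anc, anc, b]
        else:  # AABB
            copies = [anc, anc, b, b]
    elif topo == "ABC":
        shared = rates.get("branch", None)
        rb = rates.get("branch_B", shared if shared is not None else 0.0)
        rc = rates.get("branch_C", shared if shared is not None else 0.0)
        pos_b = draw_sites(rb)
        pos_c = draw_sites(rc)
        b = dna.mutate_codes(rng, anc, pos_b)
        c = dna.mutate_codes(rng, anc, pos_c)
        copies = [anc, b, c]
        events.append(("branch_B", pos_b))
        events.append(("branch_C", pos_c))
    elif topo == "ABCD":
        q = _solve_abcd_branch_rate(rates.get("pairwise", 0.0))
        copies = []
        for i in range(4):
            pos = draw_sites(q)
            copies.append(dna.mutate_codes(rng, anc, pos))
            events.append((f"branch_{'ABCD'[i]}", pos))
    else:  # pragma: no cover
        raise AssertionError(topo)

    # truth table: any site where copies disagree
    all_pos = np.unique(np.concatenate([p for _, p in events])) if events else np.array([], int)
    records = []
    if len(all_pos):
        stack = np.stack([c[all_pos] for c in copies])  # (ploidy, nsites)
        differs = (stack != stack[0]).any(axis=0)
        layer_of: dict[int, str] = {}
        for layer, pos in events:
            for p in pos:
                p = int(p)
                layer_of[p] = layer if p not in layer_of else layer_of[p] + "+" + layer
        for j in np.nonzero(differs)[0]:
            p = int(all_pos[j])
            alleles = "".join(dna.BASES[c] for c in stack[:, j])
            records.append((p, layer_of[p], alleles, len(set(alleles))))
    truth = pd.DataFrame(records, columns=["position", "layer", "alleles", "n_alleles"])
    return HaplotypeSet(spec=spec, letters=TOPOLOGIES[topo], copies=copies, truth_sites=truth)


# --- feature implants --------------------------------------------------------


@dataclass
class TERecord:
    name: str
    te_class: str  # DNA, LINE, SINE, LTR, Helitron, or other
    family: str
    seq: str

    @property
    def header(self) -> str:
        return f"{self.name}#{self.te_class}/{self.family}"


@dataclass
class RefRecord:
    id: str
    label: str  # "metazoan" | "non-metazoan"
    seq: str


TE_CLASS_LENGTHS = {
    "DNA": 2200,
    "LINE": 3200,
    "SINE": 320,
    "LTR": 4200,
    "Helitron": 2800,
}


def default_te_library(seed: int = 0, families_per_class: int = 2) -> list[TERecord]:
    """A small synthetic consensus library with RepeatMasker-style labels."""
    rng = np.random.default_rng(seed)
    lib = []
    for cls, length in TE_CLASS_LENGTHS.items():
        for j in range(families_per_class):
            name = f"{cls.lower()}_fam{j + 1}"
            seq = dna.decode(dna.random_codes(rng, length))
            lib.append(TERecord(name=name, te_class=cls, family=f"Fam{j + 1}", seq=seq))
    return lib


@dataclass
class FeatureImplantPlan:
    """What to implant into the collapsed assembly, all recorded as truth."""

    te_library: list[TERecord] | None = None
    te_target_fraction: float = 0.0
    te_max_divergence: float = 0.10
    te_min_length_fraction: float = 0.5
    n_genes: int = 0
    gene_length: int = 900
    palindrome_implants: list[tuple[int, int]] = field(default_factory=list)
    palindrome_copy_divergence: float = 0.01
    hgt_implants: int = 0
    contaminant_scaffolds: int = 0
    n_scaffolds: int = 1  # scaffolds per homoeolog group
    n_decoy_refs: int = 20

    def validate(self) -> None:
        if not 0.0 <= self.te_target_fraction <= 0.6:
            raise ValueError("te_target_fraction outside [0, 0.6]")
        if self.te_target_fraction > 0 and not self.te_library:
            raise ValueError("te_target_fraction > 0 requires a te_library")
        if self.hgt_implants > 0 and self.n_genes < 1:
            raise ValueError("HGT implants require at least one host gene for linkage")
        if self.gene_length % 3 != 0:
            raise ValueError("gene_length must be a codon multiple")


@dataclass
class AssemblyBundle:
    """Collapsed assembly + annotation + proteins + reference sets + truth."""

    scaffolds: dict[str, str]
    genes: pd.DataFrame  # gene_id scaffold start end strand origin palindrome_id source_ref
    proteins: dict[str, str]
    te_truth: pd.DataFrame  # scaffold start end te_class family divergence strand
    palindrome_truth: pd.DataFrame  # palindrome_id scaffold arm1_genes arm2_genes n_genes
    reference_db: list[RefRecord]
    te_library: list[TERecord]
    letter_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())

    def read_templates(self) -> dict[str, str]:
        """Scaffolds expanded to genome copy number for read simulation.

        A scaffold of a homoeolog group present n times in the topology (the
        two A copies of AAB, say) appears n times, so shotgun coverage per
        haplotype copy is correct; contaminant scaffolds appear once.
        """
        out: dict[str, str] = {}
        for name, seq in self.scaffolds.items():
            n = self.letter_counts.get(name.split("_", 1)[0], 1)
            for i in range(n):
                out[f"{name}|copy{i + 1}"] = seq
        return out

    def te_fraction_truth(self) -> float:
        if self.te_truth.empty:
            return 0.0
        return float((self.te_truth["end"] - self.te_truth["start"]).sum()) / self.total_bp

    def hgt_fraction_truth(self) -> float:
        """Fraction of non-contaminant genes that are implanted foreign genes."""
        g = self.genes[self.genes["origin"] != "contaminant"]
        return float((g["origin"] == "hgt").sum()) / len(g)

    # -- writers (plain-text standard formats) --------------------------------

    def write_assembly(self, path: str | Path, width: int = 80) -> None:
        _write_fasta(path, self.scaffolds.items(), width)

    def write_proteins(self, path: str | Path) -> None:
        _write_fasta(path, self.proteins.items())

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for row in self.genes.itertuples():
                fh.write(
                    f"{row.scaffold}\tparthenoscan\tgene\t{row.start + 1}\t{row.end}\t.\t"
                    f"{row.strand}\t.\tID={row.gene_id}\n"
                )

    def write_te_library(self, path: str | Path) -> None:
        _write_fasta(path, ((r.header, r.seq) for r in self.te_library))

    def write_reference_db(self, fasta: str | Path, labels: str | Path) -> None:
        _write_fasta(fasta, ((r.id, r.seq) for r in self.reference_db))
        with open(labels, "w") as fh:
            for r in self.reference_db:
                fh.write(f"{r.id}\t{r.label}\n")

    def write_truth(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(outdir / "genes_truth.tsv", sep="\t", index=False)
        self.te_truth.to_csv(outdir / "te_truth.tsv", sep="\t", index=False)
        self.palindrome_truth.to_csv(outdir / "palindrome_truth.tsv", sep="\t", index=False)


def _write_fasta(path, items, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


class _Placer:
    """Non-overlapping random interval placement on a set of scaffolds."""

    def __init__(self, rng, scaffolds: dict[str, np.ndarray], margin: int = 100):
        self.rng = rng
        self.scaffolds = scaffolds
        self.names = list(scaffolds)
        self.trees = {n: IntervalTree() for n in scaffolds}
        self.margin = margin

    def place(self, length: int, scaffold: str | None = None, retries: int = 300):
        names = [scaffold] if scaffold is not None else self.names
        for _ in range(retries):
            name = names[self.rng.integers(len(names))]
            seq = self.scaffolds[name]
            lo, hi = self.margin, len(seq) - length - self.margin
            if hi <= lo:
                continue
            start = int(self.rng.integers(lo, hi))
            if not self.trees[name].overlap(start, start + length):
                self.trees[name].addi(start, start + length)
                return name, start
        raise RuntimeError(
            f"could not place an interval of {length} bp after {retries} retries; "
            "genome too crowded for the requested implants"
        )


def implant_features(
    haplotypes: HaplotypeSet, plan: FeatureImplantPlan, seed: int = 0
) -> AssemblyBundle:
    """Build a collapsed assembly from the haplotypes and implant features.

    The assembly carries one scaffold set per homoeolog group (unique topology
    letter), mimicking published collapsed assemblies. Host genes, palindromic
    gene cassettes, foreign (HGT) genes, contaminant scaffolds and TE copies
    are written into the sequence and recorded in truth tables.
    """
    plan.validate()
    rng = np.random.default_rng(seed)

    # collapsed assembly: one copy per unique letter, split into scaffolds
    scaffolds: dict[str, np.ndarray] = {}
    seen: set[str] = set()
    for letter, codes in zip(haplotypes.letters, haplotypes.copies):
        if letter in seen:
            continue
        seen.add(letter)
        chunks = np.array_split(codes.copy(), plan.n_scaffolds)
        for i, chunk in enumerate(chunks):
            scaffolds[f"{letter}_scf{i + 1}"] = chunk

    placer = _Placer(rng, scaffolds)
    gene_rows: list[dict] = []
    proteins: dict[str, str] = {}
    n_gene_counter = 0

    def add_gene(seq_nt: str, scaffold: str, start: int, strand: str, origin: str,
                 palindrome_id: str = "", source_ref: str = "") -> str:
        nonlocal n_gene_counter
        gid = f"g{n_gene_counter:05d}"
        n_gene_counter += 1
        arr = scaffolds[scaffold]
        placed = seq_nt if strand == "+" else dna.revcomp(seq_nt)
        arr[start : start + len(seq_nt)] = dna.encode(placed)
        gene_rows.append(
            dict(gene_id=gid, scaffold=scaffold, start=start, end=start + len(seq_nt),
                 strand=strand, origin=origin, palindrome_id=palindrome_id,
                 source_ref=source_ref)
        )
        proteins[gid] = dna.translate(seq_nt)
        return gid

    # host genes
    for _ in range(plan.n_genes):
        seq_nt = dna.random_orf(rng, plan.gene_length)
        scaf, start = placer.place(plan.gene_length)
        add_gene(seq_nt, scaf, start, "+", "host")

    # palindrome implants: arm1 genes (+), spacer host gene, arm2 = reverse
    # complement of arm1 (order-reversed, '-' strand, slight divergence)
    pal_rows = []
    scaffold_names = list(scaffolds)
    spacer = 150
    for p_idx, (m, scf_idx) in enumerate(plan.palindrome_implants):
        pid = f"pal{p_idx + 1}"
        scaf = scaffold_names[scf_idx % len(scaffold_names)]
        gl = plan.gene_length
        block_len = (2 * m + 1) * (gl + spacer) + spacer
        _, start = placer.place(block_len, scaffold=scaf)
        arm_seqs = [dna.random_orf(rng, gl) for _ in range(m)]
        arm1_ids, arm2_ids = [], []
        offset = start
        for s in arm_seqs:
            arm1_ids.append(add_gene(s, scaf, offset, "+", "palindrome", pid))
            offset += gl + spacer
        # spacer host gene between the arms (keeps the innermost anchor pair
        # from being rank-adjacent, i.e. distinguishable from a tandem artifact)
        add_gene(dna.random_orf(rng, gl), scaf, offset, "+", "host")
        offset += gl + spacer
        for s in reversed(arm_seqs):
            div_pos = np.nonzero(rng.random(gl) < plan.palindrome_copy_divergence)[0]
            seq2 = dna.decode(dna.mutate_codes(rng, dna.encode(s), div_pos))
            arm2_ids.append(add_gene(seq2, scaf, offset, "-", "palindrome", pid))
            offset += gl + spacer
        pal_rows.append(
            dict(palindrome_id=pid, scaffold=scaf, arm1_genes=";".join(arm1_ids),
                 arm2_genes=";".join(arm2_ids), n_genes=2 * m)
        )

    # non-metazoan reference pool (HGT donors + decoys)
    prot_len = plan.gene_length // 3 - 1
    pool = [
        RefRecord(id=f"nonmet_{i:04d}", label="non-metazoan",
                  seq=dna.random_protein(rng, prot_len))
        for i in range(plan.hgt_implants + plan.n_decoy_refs)
    ]

    # HGT implants: foreign genes on scaffolds that also carry host genes
    host_scaffolds = sorted({r["scaffold"] for r in gene_rows if r["origin"] == "host"})
    for i in range(plan.hgt_implants):
        donor = pool[i]
        seq_nt = dna.reverse_translate(rng, donor.seq)
        scaf = host_scaffolds[int(rng.integers(len(host_scaffolds)))]
        _, start = placer.place(len(seq_nt), scaffold=scaf)
        add_gene(seq_nt, scaf, start, "+", "hgt", source_ref=donor.id)

    # contaminant scaffolds: only foreign genes, no host linkage
    contam_pool = pool[plan.hgt_implants :] or pool
    for i in range(plan.contaminant_scaffolds):
        name = f"contam_scf{i + 1}"
        length = 3 * (plan.gene_length + 400) + 400
        scaffolds[name] = dna.random_codes(rng, length)
        placer.scaffolds[name] = scaffolds[name]
        placer.names.append(name)
        placer.trees[name] = IntervalTree()
        for j in range(2):
            donor = contam_pool[int(rng.integers(len(contam_pool)))]
            seq_nt = dna.reverse_translate(rng, donor.seq)
            _, start = placer.place(len(seq_nt), scaffold=name)
            add_gene(seq_nt, name, start, "+", "contaminant", source_ref=donor.id)

    # TE implants, until the target fraction of genome bp is reached
    te_rows = []
    if plan.te_target_fraction > 0:
        lib = plan.te_library or []
        total_bp = sum(len(s) for s in scaffolds.values())
        target_bp = plan.te_target_fraction * total_bp
        te_bp = 0
        while te_bp < target_bp:
            rec = lib[int(rng.integers(len(lib)))]
            frac = rng.uniform(plan.te_min_length_fraction, 1.0)
            length = max(100, int(len(rec.seq) * frac))
            copy = dna.encode(rec.seq[:length])
            div = rng.uniform(0.0, plan.te_max_divergence)
            pos = np.nonzero(rng.random(length) < div)[0]
            copy = dna.mutate_codes(rng, copy, pos)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                copy = dna.revcomp_codes(copy)
            scaf, start = placer.place(length)
            scaffolds[scaf][start : start + length] = copy
            te_rows.append(
                dict(scaffold=scaf, start=start, end=start + length,
                     te_class=rec.te_class, family=rec.name, divergence=round(div, 4),
                     strand=strand)
            )
            te_bp += length

    # metazoan partition: every non-foreign gene's protein is a database record
    ref_db = [
        RefRecord(id=f"met_{r['gene_id']}", label="metazoan", seq=proteins[r["gene_id"]])
        for r in gene_rows
        if r["origin"] in ("host", "palindrome")
    ] + pool

    gene_cols = ["gene_id", "scaffold", "start", "end", "strand", "origin",
                 "palindrome_id", "source_ref"]
    genes = pd.DataFrame(gene_rows, columns=gene_cols)
    te_truth = pd.DataFrame(
        te_rows, columns=["scaffold", "start", "end", "te_class", "family",
                          "divergence", "strand"])
    pal_truth = pd.DataFrame(
        pal_rows, columns=["palindrome_id", "scaffold", "arm1_genes", "arm2_genes",
                           "n_genes"])
    letter_counts = {letter: haplotypes.letters.count(letter)
                     for letter in set(haplotypes.letters)}
    return AssemblyBundle(
        scaffolds={n: dna.decode(a) for n, a in scaffolds.items()},
        genes=genes, proteins=proteins, te_truth=te_truth, palindrome_truth=pal_truth,
        reference_db=ref_db, te_library=list(plan.te_library or []),
        letter_counts=letter_counts,
    )


# --- read simulation ---------------------------------------------------------


@dataclass
class ReadSimSpec:
    coverage_per_haplotype: float
    read_length: int = 100
    error_rate: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        if self.coverage_per_haplotype <= 0:
            raise ValueError("coverage_per_haplotype must be > 0")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate outside [0, 0.05]")
        if self.read_length < 21:
            raise ValueError("read_length too short")


@dataclass
class ReadSet:
    """Single-end reads with recorded provenance (source, position, strand)."""

    names: list[str]
    seqs: list[str]
    sources: list[str]
    positions: np.ndarray
    strands: np.ndarray  # '+' stored as 0, '-' as 1

    def __len__(self) -> int:
        return len(self.seqs)

    @property
    def total_bases(self) -> int:
        return sum(len(s) for s in self.seqs)

    def subset(self, indices: np.ndarray) -> "ReadSet":
        return ReadSet(
            names=[self.names[i] for i in indices],
            seqs=[self.seqs[i] for i in indices],
            sources=[self.sources[i] for i in indices],
            positions=self.positions[indices],
            strands=self.strands[indices],
        )

    def to_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.names, self.seqs):
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_reads(
    sequences: dict[str, str] | list[str] | HaplotypeSet, sim: ReadSimSpec
) -> ReadSet:
    """Uniform single-end shotgun reads with i.i.d. substitution errors.

    Reads are drawn uniformly across the source sequences at
    ``coverage_per_haplotype`` fold per sequence (total bases within one read
    of coverage x total length); half are reverse-complemented. Deterministic
    for a fixed seed.
    """
    sim.validate()
    if isinstance(sequences, HaplotypeSet):
        named = [(f"hap{i}_{l}", dna.decode(c))
                 for i, (l, c) in enumerate(zip(sequences.letters, sequences.copies))]
    elif isinstance(sequences, dict):
        named = list(sequences.items())
    else:
        named = [(f"seq{i}", s) for i, s in enumerate(sequences)]

    rl = sim.read_length
    lengths = np.array([len(s) for _, s in named])
    if rl > lengths.min():
        raise ValueError("read_length exceeds the shortest source sequence")
    total = lengths.sum()
    n_reads = int(round(sim.coverage_per_haplotype * total / rl))
    rng = np.random.default_rng(sim.seed)
    src = rng.choice(len(named), size=n_reads, p=lengths / total)

    names: list[str] = [""] * n_reads
    seqs: list[str] = [""] * n_reads
    sources: list[str] = [""] * n_reads
    positions = np.zeros(n_reads, dtype=np.int64)
    strands = np.zeros(n_reads, dtype=np.uint8)

    for s_idx, (sname, sseq) in enumerate(named):
        idx = np.nonzero(src == s_idx)[0]
        if not len(idx):
            continue
        codes = dna.encode(sseq)
        pos = rng.integers(0, len(sseq) - rl + 1, size=len(idx))
        mat = codes[pos[:, None] + np.arange(rl)]
        if sim.error_rate > 0:
            err = rng.random(mat.shape) < sim.error_rate
            n_err = int(err.sum())
            if n_err:
                mat[err] = (mat[err] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
        rc = rng.random(len(idx)) < 0.5
        mat[rc] = 3 - mat[rc, ::-1]
        raw = dna.DECODE_LUT[mat].tobytes()
        for row, i in enumerate(idx):
            seqs[i] = raw[row * rl : (row + 1) * rl].decode("ascii")
            strand = "-" if rc[row] else "+"
            names[i] = f"r{i}|{sname}|{pos[row]}|{strand}"
            sources[i] = sname
            positions[i] = pos[row]
            strands[i] = 1 if rc[row] else 0
    return ReadSet(names=names, seqs=seqs, sources=sources, positions=positions,
                   strands=strands)
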