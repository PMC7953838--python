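"""Generator correctness: realized divergence, truth conservation, determinism."""

import itertools

import numpy as np
import pytest

from parthenoscan import dna
from parthenoscan import simulate as sim


def binomial_3sd(rate: float, n: int) -> float:
    return 3.0 * np.sqrt(max(rate * (1 - rate), 1e-12) / n)


class TestSimulateHaplotypes:
    def test_zero_divergence_gives_identical_copies_and_empty_truth(self):
        spec = sim.GenomeSpec(50_000, 2, "AB", {"allelic": 0.0}, seed=1)
        h = sim.simulate_haplotypes(spec)
        assert np.array_equal(h.copies[0], h.copies[1])
        assert h.truth_sites.empty

    def test_identical_letters_are_byte_identical(self):
        spec = sim.GenomeSpec(50_000, 3, "AAB", {"homoeolog": 0.05}, seed=2)
        h = sim.simulate_haplotypes(spec)
        assert np.array_equal(h.copies[0], h.copies[1])
        assert not np.array_equal(h.copies[0], h.copies[2])

    def test_aab_divergence_matches_requested_rate(self):
        r, L = 0.02, 1_000_000
        spec = sim.GenomeSpec(L, 3, "AAB", {"homoeolog": r}, seed=3)
        h = sim.simulate_haplotypes(spec)
        observed = float((h.copies[0] != h.copies[2]).mean())
        assert abs(observed - r) <= binomial_3sd(r, L)

    def test_abcd_all_pairwise_divergences_match(self):
        r, L = 0.01, 400_000
        spec = sim.GenomeSpec(L, 4, "ABCD", {"pairwise": r}, seed=4)
        h = sim.simulate_haplotypes(spec)
        for i, j in itertools.combinations(range(4), 2):
            observed = float((h.copies[i] != h.copies[j]).mean())
            assert abs(observed - r) <= binomial_3sd(r, L), (i, j, observed)

    def test_truth_table_matches_sequence_differences(self):
        spec = sim.GenomeSpec(80_000, 3, "ABC", {"branch": 0.01}, seed=5)
        h = sim.simulate_haplotypes(spec)
        stack = np.stack(h.copies)
        diff_pos = np.nonzero((stack != stack[0]).any(axis=0))[0]
        assert sorted(h.truth_sites["position"]) == sorted(diff_pos)
        for row in h.truth_sites.itertuples():
            alleles = "".join(dna.BASES[c] for c in stack[:, row.position])
            assert alleles == row.alleles

    def test_topology_ploidy_mismatch_rejected(self):
        with pytest.raises(ValueError, match="ploidy"):
            sim.GenomeSpec(50_000, 2, "AAB", {"homoeolog": 0.01}).validate()

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="het rate"):
            sim.GenomeSpec(50_000, 2, "AB", {"allelic": 0.5}).validate()

    def test_determinism(self):
        spec = sim.GenomeSpec(40_000, 2, "AB", {"allelic": 0.01}, seed=7)
        h1 = sim.simulate_haplotypes(spec)
        h2 = sim.simulate_haplotypes(spec)
        assert all(np.array_equal(a, b) for a, b in zip(h1.copies, h2.copies))


class TestImplantFeatures:
    def test_empty_plan_preserves_haplotype_sequence(self):
        spec = sim.GenomeSpec(60_000, 2, "AB", {"allelic": 0.01}, seed=8)
        h = sim.simulate_haplotypes(spec)
        bundle = sim.implant_features(h, sim.FeatureImplantPlan(), seed=9)
        assert bundle.scaffolds["A_scf1"] == dna.decode(h.copies[0])
        assert bundle.scaffolds["B_scf1"] == dna.decode(h.copies[1])
        assert bundle.te_truth.empty

    def test_palindrome_implant_structure(self, annotated_bundle):
        truth = annotated_bundle.palindrome_truth.iloc[0]
        genes = annotated_bundle.genes.set_index("gene_id")
        arm1 = truth.arm1_genes.split(";")
        arm2 = truth.arm2_genes.split(";")
        assert truth.n_genes == 6
        # same scaffold, arm2 strand-flipped and order-reversed
        scafs = {genes.loc[g, "scaffold"] for g in arm1 + arm2}
        assert scafs == {truth.scaffold}
        assert all(genes.loc[g, "strand"] == "+" for g in arm1)
        assert all(genes.loc[g, "strand"] == "-" for g in arm2)
        starts1 = [genes.loc[g, "start"] for g in arm1]
        starts2 = [genes.loc[g, "start"] for g in arm2]
        assert starts1 == sorted(starts1) and starts2 == sorted(starts2)
        # order-reversed copy: arm2[i] is the (diverged) copy of arm1[m-1-i]
        p1 = annotated_bundle.proteins[arm1[-1]]
        p2 = annotated_bundle.proteins[arm2[0]]
        same = sum(a == b for a, b in zip(p1, p2)) / len(p1)
        assert same > 0.9

    def test_hgt_truth_fraction_arithmetic(self, annotated_bundle):
        g = annotated_bundle.genes
        non_contam = g[g.origin != "contaminant"]
        expected = (non_contam.origin == "hgt").sum() / len(non_contam)
        assert annotated_bundle.hgt_fraction_truth() == pytest.approx(expected)
        assert (g.origin == "hgt").sum() == 5

    def test_te_fraction_reaches_target(self, annotated_bundle):
        assert 0.05 <= annotated_bundle.te_fraction_truth() <= 0.065

    def test_truth_tables_describe_emitted_sequence(self, annotated_bundle):
        """Conservation: every truth record can be re-parsed from the FASTA."""
        genes = annotated_bundle.genes
        for row in genes.sample(10, random_state=0).itertuples():
            sub = annotated_bundle.scaffolds[row.scaffold][row.start:row.end]
            if row.strand == "-":
                sub = dna.revcomp(sub)
            assert dna.translate(sub) == annotated_bundle.proteins[row.gene_id]
        for row in annotated_bundle.te_truth.head(5).itertuples():
            copy = annotated_bundle.scaffolds[row.scaffold][row.start:row.end]
            lib = {r.name: r.seq for r in annotated_bundle.te_library}
            consensus = lib[row.family]
            if row.strand == "-":
                copy = dna.revcomp(copy)
            matches = sum(a == b for a, b in zip(copy, consensus))
            assert matches / len(copy) >= 1 - row.divergence - 0.02

    def test_contaminant_scaffolds_carry_only_foreign_genes(self, annotated_bundle):
        g = annotated_bundle.genes
        contam_scafs = {s for s in annotated_bundle.scaffolds if s.startswith("contam")}
        assert len(contam_scafs) == 2
        on_contam = g[g.scaffold.isin(contam_scafs)]
        assert set(on_contam.origin) == {"contaminant"}

    def test_unreachable_te_fraction_fails(self, te_library):
        spec = sim.GenomeSpec(4_000, 2, "AB", {"allelic": 0.0}, seed=10)
        h = sim.simulate_haplotypes(spec)
        plan = sim.FeatureImplantPlan(te_library=te_library, te_target_fraction=0.6)
        with pytest.raises(RuntimeError, match="could not place"):
            sim.implant_features(h, plan, seed=11)


class TestSimulateReads:
    def test_total_bases_match_requested_coverage(self):
        spec = sim.GenomeSpec(500_000, 2, "AB", {"allelic": 0.0}, seed=12)
        h = sim.simulate_haplotypes(spec)
        rs = sim.simulate_reads(h, sim.ReadSimSpec(10, 100, 0.0, seed=13))
        assert abs(rs.total_bases - 10 * 2 * 500_000) <= 100

    def test_same_seed_identical_fastq(self, tmp_path):
        spec = sim.GenomeSpec(50_000, 2, "AB", {"allelic": 0.01}, seed=14)
        h = sim.simulate_haplotypes(spec)
        s = sim.ReadSimSpec(5, 100, 0.01, seed=15)
        f1, f2 = tmp_path / "a.fq", tmp_path / "b.fq"
        sim.simulate_reads(h, s).to_fastq(f1)
        sim.simulate_reads(h, s).to_fastq(f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_error_rate_realized_in_reads(self):
        """Realign reads to their recorded source positions and count mismatches."""
        e = 0.01
        spec = sim.GenomeSpec(100_000, 2, "AB", {"allelic": 0.0}, seed=16)
        h = sim.simulate_haplotypes(spec)
        rs = sim.simulate_reads(h, sim.ReadSimSpec(5, 100, e, seed=17))
        sources = {f"hap{i}_{l}": dna.decode(c)
                   for i, (l, c) in enumerate(zip(h.letters, h.copies))}
        mism = total = 0
        for i in range(len(rs)):
            ref = sources[rs.sources[i]][rs.positions[i] : rs.positions[i] + 100]
            read = rs.seqs[i] if rs.strands[i] == 0 else dna.revcomp(rs.seqs[i])
            mism += sum(a != b for a, b in zip(read, ref))
            total += 100
        observed = mism / total
        assert abs(observed - e) <= 3 * np.sqrt(e * (1 - e) / total)

    def test_read_length_longer_than_scaffold_rejected(self):
        with pytest.raises(ValueError, match="read_length"):
            sim.simulate_reads({"s": "ACGT" * 20}, sim.ReadSimSpec(5, 100, 0.0, 1))
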