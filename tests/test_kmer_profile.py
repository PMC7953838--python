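"""Spectrum counting, mixture weights, fitting and het-family machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parthenoscan import dna
from parthenoscan import kmer_profile as kp
from parthenoscan import simulate as sim


def naive_canonical_counts(seqs, k):
    """Dict-based oracle for canonical k-mer counting."""
    counts = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) - set("ACGT"):
                continue
            c = min(w, dna.revcomp(w))
            counts[c] = counts.get(c, 0) + 1
    return counts


class TestCountKmers:
    def test_single_read_all_kmers_distinct(self):
        rng = np.random.default_rng(0)
        read = dna.decode(dna.random_codes(rng, 25))
        sp = kp.count_kmers([read], k=21)
        assert sp.total_distinct == 5 and sp.bins[1] == 5

    def test_read_plus_revcomp_doubles_coverage(self):
        rng = np.random.default_rng(1)
        read = dna.decode(dna.random_codes(rng, 25))
        sp = kp.count_kmers([read, dna.revcomp(read)], k=21)
        assert sp.bins[2] == 5 and sp.bins[1] == 0

    def test_n_containing_windows_skipped(self):
        read = "A" * 30 + "N" + "C" * 30
        sp = kp.count_kmers([read], k=21)
        assert sp.total_kmers == 2 * (30 - 21 + 1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGTN", min_size=11, max_size=60),
                    min_size=1, max_size=8))
    def test_matches_naive_oracle(self, seqs):
        oracle = naive_canonical_counts(seqs, 11)
        if not oracle:
            return
        table = kp.count_kmers(seqs, k=11, keep_table=True)
        got = {kp.decode_kmer(int(c), 11): int(n)
               for c, n in zip(table.kmers, table.counts)}
        assert got == oracle

    def test_mass_conservation(self):
        """Sum of bins[c]*c equals the k-mers streamed from the reads."""
        spec = sim.GenomeSpec(30_000, 2, "AB", {"allelic": 0.01}, seed=20)
        h = sim.simulate_haplotypes(spec)
        rs = sim.simulate_reads(h, sim.ReadSimSpec(4, 80, 0.0, seed=21))
        sp = kp.count_kmers(rs, k=21)
        assert sp.total_kmers == len(rs) * (80 - 21 + 1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kp.count_kmers([], k=21)

    def test_k_longer_than_reads_rejected(self):
        with pytest.raises(ValueError):
            kp.count_kmers(["ACGTACGTACGT"], k=21)

    def test_error_free_homozygous_diploid_peaks_at_two_lambda(self):
        spec = sim.GenomeSpec(100_000, 2, "AB", {"allelic": 0.0}, seed=22)
        h = sim.simulate_haplotypes(spec)
        rs = sim.simulate_reads(h, sim.ReadSimSpec(10, 100, 0.0, seed=23))
        sp = kp.count_kmers(rs, 21)
        lam = 10 * (100 - 21 + 1) / 100  # per-copy k-mer coverage
        mode = int(np.argmax(sp.bins))
        assert abs(mode - 2 * lam) <= 2


class TestTopologyWeights:
    def test_zero_rate_single_peak_everywhere(self):
        for topo in kp.FIT_TOPOLOGIES:
            key = {"AB": "allelic", "ABC": "branch"}.get(topo, "homoeolog")
            w = kp.topology_weights(topo, {key: 0.0}, 21)
            assert w == {len(topo): 1.0} or w[len(topo)] == pytest.approx(1.0)

    def test_ab_closed_form(self):
        r, k = 0.01, 21
        a = 1 - (1 - r) ** k
        w = kp.topology_weights("AB", {"allelic": r}, k)
        total = sum(w.values())
        assert w[1] / total == pytest.approx(2 * a / (1 + a))
        assert total == pytest.approx(1 + a)

    def test_aab_has_mid_peak_but_pure_abc_does_not(self):
        w_aab = kp.topology_weights("AAB", {"homoeolog": 0.02}, 21)
        assert w_aab[2] > 0
        # ABC with a single fully-divergent pair of branches: a2 mass only
        w_abc = kp.topology_weights("ABC", {"branch_B": 0.02, "branch_C": 0.0}, 21)
        a = 1 - 0.98**21
        assert w_abc[2] == pytest.approx(a)
        assert w_abc[1] == pytest.approx(a)

    def test_unknown_topology_rejected(self):
        with pytest.raises(ValueError):
            kp.topology_weights("AABC", {"homoeolog": 0.01}, 21)

    @pytest.mark.parametrize("topo,rates", [
        ("AB", {"allelic": 0.01}),
        ("AAB", {"homoeolog": 0.02}),
        ("AABB", {"homoeolog": 0.015}),
        ("ABC", {"branch": 0.01}),
    ])
    def test_weights_match_window_enumeration(self, topo, rates):
        """Oracle: enumerate every k-window of a small simulation and count
        distinct k-mers by copy multiplicity; compare against the algebra."""
        k, L = 21, 60_000
        spec = sim.GenomeSpec(L, len(topo), topo, rates, seed=30)
        h = sim.simulate_haplotypes(spec)
        copies = [dna.decode(c) for c in h.copies]
        by_mult = {}
        for pos in range(L - k + 1):
            windows = {}
            for c in copies:
                w = c[pos : pos + k]
                windows[w] = windows.get(w, 0) + 1
            for mult in windows.values():
                by_mult[mult] = by_mult.get(mult, 0) + 1
        n_windows = L - k + 1
        expected = kp.topology_weights(topo, rates, k)
        for mult, w in expected.items():
            observed = by_mult.get(mult, 0) / n_windows
            # binomial noise on window classes
            tol = 3 * np.sqrt(max(w * 1.0, 0.05) / n_windows) + 0.003
            assert observed == pytest.approx(w, abs=tol), (mult, observed, w)


class TestFitSpectrum:
    @staticmethod
    def model_spectrum(topology, lam, rho, rate, G, k=21, cmax=200):
        key = {"AB": "allelic", "ABC": "branch"}.get(topology, "homoeolog")
        w = kp.topology_weights(topology, {key: rate}, k)
        cs = np.arange(cmax + 1)
        y = kp._model_counts(cs, lam, rho, w, G)
        bins = np.rint(y).astype(np.int64)
        bins[0] = 0
        return kp.KmerSpectrum(k=k, bins=bins)

    def test_self_consistency_on_model_generated_spectrum(self):
        sp = self.model_spectrum("AB", lam=20, rho=2.0, rate=0.01, G=1_000_000)
        fit = kp.fit_spectrum(sp, 2, "AB")
        assert fit.lambda_cov == pytest.approx(20, rel=0.01)
        assert fit.rho == pytest.approx(2.0, rel=0.05)
        assert fit.het_composite_pct == pytest.approx(1.0, rel=0.01)
        assert fit.genome_size_G == pytest.approx(1_000_000, rel=0.01)

    def test_monotonicity_in_true_rate(self):
        """Estimated r strictly increases with true r on model spectra."""
        estimates = []
        for r in (0.005, 0.01, 0.02, 0.04):
            sp = self.model_spectrum("AAB", lam=15, rho=1.0, rate=r, G=300_000)
            fit = kp.fit_spectrum(sp, 3, "AAB")
            estimates.append(fit.het_composite_pct)
        assert all(b > a for a, b in zip(estimates, estimates[1:]))

    def test_zero_rate_limit_is_single_component(self):
        sp = self.model_spectrum("AABB", lam=12, rho=1.5, rate=0.0, G=200_000)
        fit = kp.fit_spectrum(sp, 4, "AABB")
        assert fit.het_composite_pct < 0.02
        assert fit.lambda_cov * 4 == pytest.approx(48, rel=0.02)

    def test_reads_with_errors_recover_rate(self):
        """2% heterozygosity, 15x per copy, 0.2% sequencing error."""
        spec = sim.GenomeSpec(300_000, 2, "AB", {"allelic": 0.02}, seed=33)
        h = sim.simulate_haplotypes(spec)
        rs = sim.simulate_reads(h, sim.ReadSimSpec(15, 100, 0.002, seed=34))
        sp = kp.count_kmers(rs, 21)
        assert sp.error_cutoff() > 1  # error k-mers excluded
        fit = kp.fit_spectrum(sp, 2, "AB")
        assert fit.het_composite_pct == pytest.approx(2.0, abs=0.2)

    def test_degenerate_spectrum_rejected(self):
        sp = kp.KmerSpectrum(k=21, bins=np.array([0, 5, 0, 0]))
        with pytest.raises(ValueError, match="degenerate"):
            kp.fit_spectrum(sp, 2, "AB")


class TestHetFamilies:
    def test_homozygous_simulation_yields_no_families(self):
        spec = sim.GenomeSpec(80_000, 2, "AB", {"allelic": 0.0}, seed=40)
        h = sim.simulate_haplotypes(spec)
        rs = sim.simulate_reads(h, sim.ReadSimSpec(15, 100, 0.0, seed=41))
        table = kp.count_kmers(rs, 21, keep_table=True)
        fams = kp.extract_het_families(table, 3, 12.0, 2)
        assert fams == []

    def test_family_count_tracks_het_window_truth(self):
        """AB at 20x, r=1%: families within 15% of single-variant windows."""
        spec = sim.GenomeSpec(150_000, 2, "AB", {"allelic": 0.01}, seed=42)
        h = sim.simulate_haplotypes(spec)
        rs = sim.simulate_reads(h, sim.ReadSimSpec(20, 100, 0.0, seed=43))
        table = kp.count_kmers(rs, 21, keep_table=True)
        fit = kp.fit_spectrum(table.spectrum(), 2, "AB")
        fams = kp.extract_het_families(table, fit.error_cutoff, fit.lambda_cov, 2,
                                       rho=max(fit.rho, 0.5))
        truth = len(h.het_window_positions(21, max_variants=1))
        assert abs(len(fams) - truth) / truth <= 0.15

    def test_two_substitutions_apart_not_a_family(self):
        base = "ACGTACGTACGTACGTACGTA"
        other = "AAGTACGTACGTACGTACGTC"  # differs at positions 1 and 20
        codes = np.sort(np.array(
            [kp.encode_kmer(min(s, dna.revcomp(s))) for s in (base, other)],
            dtype=np.uint64))
        table = kp.KmerCountTable(k=21, kmers=codes,
                                  counts=np.array([20, 20], dtype=np.int64))
        assert kp.extract_het_families(table, 3, 20.0, 2) == []

    def test_one_substitution_apart_is_a_family_in_either_orientation(self):
        base = "ACGTACGTACGTACGTACGTA"
        var = base[:10] + "C" + base[11:]
        codes = np.sort(np.array(
            [kp.encode_kmer(min(base, dna.revcomp(base))),
             kp.encode_kmer(min(dna.revcomp(var), var))], dtype=np.uint64))
        table = kp.KmerCountTable(k=21, kmers=codes,
                                  counts=np.array([20, 40], dtype=np.int64))
        fams = kp.extract_het_families(table, 3, 20.0, 3)
        assert len(fams) == 1 and fams[0].size == 2

    def test_missing_table_instructs_rerun(self):
        spectrum = kp.KmerSpectrum(k=21, bins=np.zeros(10, dtype=np.int64))
        with pytest.raises(TypeError, match="keep_table"):
            kp.extract_het_families(spectrum, 3, 10.0, 2)


class TestClassifyStructures:
    def make_family(self, coverages):
        n = len(coverages)
        return kp.HetKmerFamily(members=np.arange(n, dtype=np.uint64),
                                coverages=np.array(coverages, dtype=np.int64))

    def test_exact_template_matches(self):
        lam = 20.0
        assert kp.classify_family(self.make_family([20, 40]), lam) == "AAB"
        assert kp.classify_family(self.make_family([20, 20]), lam) == "AB"
        assert kp.classify_family(self.make_family([40, 40]), lam) == "AABB"
        assert kp.classify_family(self.make_family([20, 60]), lam) == "AAAB"

    def test_three_members_multiallelic(self):
        assert kp.classify_family(self.make_family([20, 20, 20]), 20.0) == "MULTI"

    def test_far_off_coverages_ambiguous(self):
        assert kp.classify_family(self.make_family([5, 90]), 20.0) == "AMBIGUOUS"

    def test_ploidy_aware_category_mapping(self):
        """An AB-like pair in a triploid marks a multiallelic locus."""
        fams = [self.make_family([20, 20])]
        summary = kp.classify_structures(fams, 20.0, ploidy=3)
        assert summary.fractions[kp.CAT_MULTI] == 1.0
        summary2 = kp.classify_structures(fams, 20.0, ploidy=2)
        assert summary2.fractions[kp.CAT_DIPLOID] == 1.0

    def test_super_ploidy_template_is_ambiguous(self):
        fams = [self.make_family([40, 40])]  # AABB pattern in a diploid
        summary = kp.classify_structures(fams, 20.0, ploidy=2)
        assert summary.n_classified == 0

    def test_empty_family_list(self):
        summary = kp.classify_structures([], 20.0, ploidy=3)
        assert summary.n_families == 0 and not summary.defined
        assert summary.fractions == {}

    def test_fractions_sum_to_one(self):
        fams = [self.make_family(c) for c in ([20, 40], [20, 40], [20, 20],
                                              [15, 15, 15])]
        summary = kp.classify_structures(fams, 20.0, ploidy=3)
        assert sum(summary.fractions.values()) == pytest.approx(1.0)
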