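# Methods

`parthenoscan` re-implements, as one standardized toolkit, the four read- and
assembly-based genome screens used to compare parthenogenetic animal genomes:
intragenomic heterozygosity from the k-mer spectrum (with allele-structure
decomposition in polyploids), transposable-element load from a low-coverage
read subsample, palindromic gene arrangements from gene collinearity, and
horizontally-transferred gene candidates with a contamination control. A
synthetic-data generator produces genomes for which the truth of every one of
these quantities is known by construction; all validation in `tests/` and
`scripts/acceptance.py` runs against that truth.

## Heterozygosity from the k-mer spectrum

**Model.** Reads are decomposed into canonical k-mers (lexicographic minimum
of a k-mer and its reverse complement, k = 21 by default) and histogrammed by
coverage. For a genome of ploidy P with haploid per-copy k-mer coverage λ, a
k-mer shared by i of the P copies has coverage ~ NB(mean = iλ), giving a
mixture of evenly spaced negative binomial components. The NB is parameterized
with size μ/ρ so the variance is μ(1 + ρ); ρ → 0 is the Poisson limit reached
by uniform error-free reads, and the fit bounds ρ > 0 accordingly.

Heterozygosity enters through the window term: a k-long window containing at
least one variant site splits its k-mer across copies. With
a = 1 − (1 − r)^k for a layer of per-site rate r, the expected distinct-k-mer
mass per ancestral window is, by peak multiplicity:

| topology | λ | 2λ | 3λ | 4λ |
|---|---|---|---|---|
| AB   | 2a      | 1−a |     |     |
| AAB  | a       | a   | 1−a |     |
| AAAB | a       |     | a   | 1−a |
| AABB |         | 2a  |     | 1−a |
| ABC  | a2+3a3  | a2  | 1−a2−a3 | |

For ABC the two non-reference copies diverge independently from the ancestor;
with per-branch window probabilities ab, ac this gives a2 = ab(1−ac)+ac(1−ab)
(exactly one copy diverged in the window) and a3 = ab·ac (all three distinct).
The default fit ties the two branch rates (a2 = 2a(1−a), a3 = a²): with free
rates only ab+ac is well constrained at low divergence, so the tied model is
the identifiable default. This algebra is exact for substitution-only
divergence, which is why the simulator implants substitutions only (no
indels). The table is validated against exhaustive window enumeration on
small simulated haplotype sets in the test suite.

**Fitting.** Trust-region least squares (scipy) on √counts (variance
stabilization) of G · Σᵢ wᵢ · NB(c; iλ, ρ) over bins above the error cutoff,
with parameters (λ, ρ, a, log G). The error cutoff is the first local minimum
of the histogram walking up from coverage 1 (degenerating to 1 on error-free
spectra); it is overridable. Multi-start over λ ∈ {mode/P, …, mode} crossed
with three initial rates; ties break by lowest residual, then lowest rate. r
is reported per site in percent, r = 1 − (1 − a)^{1/k}; composite
heterozygosity is the sum over layers (for diploids the allelic and homoeolog
layers are indistinguishable and the single rate is flagged composite). G is
the fitted number of ancestral windows, i.e. haploid genome size in distinct
k-mer units. Peaks are modelled up to i = P; k-mer mass further right is
summed into a repeat fraction, and a range-exceeded warning fires above 30%
(homoeolog divergence beyond what k = 21 can separate — e.g. bdelloid-like
genomes — is explicitly out of range).

**Accuracy.** On 400 kb simulated genomes at 15× per copy, error-free, the
acceptance tests recover r within ±10% relative (measured ≤ 3%) for r ∈
{0.5%, 2%, 5%} across all five topologies, and G within 5% (measured ≤ 0.5%).

## Allele structure in polyploids

Heterozygous loci are recovered directly from the k-mer count table: k-mers
within one substitution of each other (same flanks, orientation-aware) are
grouped by masking each position in turn; families are connected components of
this one-substitution graph, so a triallelic locus whose B- and C-variants
differ from the reference k-mer at different sites still forms one family.
Only k-mers with coverage in [error cutoff, Pλ + 4√(Pλρ)] participate;
components larger than 6 members are discarded as repeat-induced.

A two-member family with coverages (c_low, c_high) is matched to the nearest
biallelic template in (total coverage, minor-allele fraction) coordinates —
AB = (2λ, 1/2), AAB = (3λ, 1/3), AABB = (4λ, 1/2), AAAB = (4λ, 1/4) — by
summed relative deviation; a deviation above 35% on either coordinate marks
the family ambiguous. Category assignment is ploidy-aware: a template whose
total copy multiplicity falls short of the ploidy leaves genome copies
unaccounted, which is itself evidence of further alleles — a (λ, λ) pair in a
triploid covers two of three copies, so the third copy carries a third allele
and the locus is multiallelic. Templates exceeding the ploidy (repeat-like
signal) are ambiguous. Families of 3+ members are multiallelic directly.

**Noise floor.** The per-family decision is coverage-limited. For a true
AABB family at 20× per copy (λ = 16), pure Poisson counting noise alone sends
~4.6% of families across the (λ, 2λ) boundary — essentially the whole 5%
multiallelic budget the AABB validation allows. The AABB structure check
therefore runs at 30× per copy, where the same Monte-Carlo calculation puts
the floor at ~1.8%; the AAB and ABC checks run at 20×. These coverages are
validation conditions, not method parameters.

## TE load from a 0.5× subsample

Reads are uniformly subsampled without replacement to 0.5× of the haploid
genome size (from the spectrum fit's G or a user override). The subsample is
assembled with a greedy exact suffix–prefix overlap assembler (min overlap
31 bp, strand-aware, duplicates collapsed, longest overlaps merged first);
repeat regions retain enough local depth to assemble while single-copy
regions mostly do not. Contigs supported by ≥ 2 reads and the leftover reads
are annotated against a TE library (`name#Class/Family` headers) by seeded
local alignment (shared 13-mer shortlist, then match/mismatch 2/−3 with
affine gaps), keeping hits with ≥ 70% identity over ≥ 80 aligned bp.

Accounting stays on the sampled-nucleotide scale the load is defined on: a
contig contributes (aligned fraction) × (read nucleotides it assembled) to
its best hit's class; an unassembled read contributes its aligned length.
TE load = Σ class nt / sampled nt, over the classes DNA, LINE, SINE, LTR,
Helitron. Repeat contigs without a hit — and hits to non-TE classes such as
satellites — are reported as "unknown" and never enter the load.

Two honest caveats. First, at 0.5× with 100 bp reads the expected number of
exact-overlap partners per read is ≈ 2·(100−31)/100 · 0.5 ≈ 0.7 regardless of
genome size, so a third to a half of single-copy reads pair into small chance
contigs; these inflate the "unknown" bucket but cannot enter the TE load
(they do not align to the library). Second, copies truncated or diverged near
the 70%/80 bp thresholds lose their boundary reads, biasing the load down by
up to ~1.5 points at 20% load; the ±2-point validation band absorbs both
effects. Recovery measured on implanted loads of 5/10/20%: within ±2 points,
monotone, with a 5-seed subsampling SD below 1.5 points.

## Palindromic gene arrangements

All-vs-all protein homology (BLOSUM62 local alignment on pairs shortlisted by
≥ 2 shared 5-mers; hits kept at e-value ≤ 1e−5, identity ≥ 50%, aligned
length ≥ 100 aa) provides anchor pairs. Anchors are chained per scaffold pair
and orientation by dynamic programming over gene ranks: a chain extends while
both rank gaps are ≤ 25 and the subject side moves in the chain's direction;
score = anchors − 0.1 per skipped rank; the best non-overlapping chains are
extracted greedily. When a gene has several hits in a context only its best
anchor is kept, so no gene repeats within a block. On small instances the DP
is verified against exhaustive enumeration of all monotone anchor
subsequences.

A palindrome is a reverse-oriented block on a single scaffold whose anchor
genes sit on opposite strands and whose two sides do not overlap. Anchors
whose genes are within one rank of each other are excluded first: an
immediately adjacent inverted copy is indistinguishable from a tail-to-tail
tandem (or scaffolding) artifact. Single-gene palindromic arrangements count
by default; `--mcscanx-strict` requires blocks of ≥ 5 gene pairs, the
classical synteny-block convention. Gene counting uses set semantics
(a gene in two palindromes counts once), and a gene-order permutation null
(gene identities shuffled across slots, coordinates and strands staying with
the slots) is available as an empirical misassembly guard; its expected count
is not exactly zero in general — a shuffled homolog pair can land inverted on
one scaffold — so it is reported alongside results rather than assumed away.

## HGT candidates with contamination control

Each annotated protein is aligned (same seeded BLOSUM62 machinery) against a
reference database carrying binary metazoan / non-metazoan labels. With best
scores B_in (metazoan) and B_out (non-metazoan), hU = B_out − B_in; a gene is
an HGT candidate when hU ≥ H, of unambiguous metazoan origin when hU ≤ −H,
ambiguous in between (H = 30 score units by default, configurable — database
and threshold conventions vary between studies, so real-data percentages are
comparable only within one configuration). A candidate is retained only if
its scaffold also carries at least one unambiguously metazoan gene; an
all-foreign scaffold is indistinguishable from assembly contamination and
contributes nothing. On synthetic genomes where implanted foreign genes are
exact copies of database records, linked-candidate precision and recall are
both 1.0, and adding contaminant-only scaffolds changes the linked count by
exactly zero.

## The synthetic-data generator

`simulate_haplotypes` draws a uniform-random ancestor (GC content 0.5 by
default — no claim of matching any real base composition) and applies
substitution layers per topology: AB/AAB/AAAB/AABB mutate the B letter at the
homoeolog rate (identical letters stay byte-identical); ABC mutates B and C
independently at their branch rates; ABCD mutates all four letters at a rate
solved so the realized pairwise divergence equals the requested value. Every
variant site is recorded with its allele-to-copy assignment.

`implant_features` collapses the haplotypes to one scaffold set per homoeolog
group (mimicking published collapsed assemblies), then writes features into
the sequence: ORF-like host genes (900 bp, forward strand), palindrome
implants (a gene cassette, a host spacer gene, then the reverse-complement
copy, order-reversed on the minus strand with ~1% copy divergence), foreign
genes back-translated from a generated non-metazoan protein pool and placed
on host-gene scaffolds, contaminant-only scaffolds, and TE copies drawn from
a labelled consensus library with per-copy truncation (uniform ≥ 50% of
length) and divergence (uniform up to 10%) until the target fraction is
reached. The reference database pairs every host protein (metazoan partition)
with the non-metazoan pool. All coordinates are non-overlapping and recorded
in truth tables that exactly describe the emitted FASTA/GFF3.

`simulate_reads` draws single-end reads uniformly at a per-copy coverage
(scaffolds expanded to genome copy number), applies i.i.d. substitution
errors, reverse-complements half, and is a pure function of its seed.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: indels and structural variation beyond the implants,
non-uniform coverage and quality profiles, paired ends, real repeat-family
age structure, real codon usage and protein families, and database
incompleteness (real HGT reference databases are neither exhaustive nor
exact). Implanted features are letter-specific, so heavily implanted genomes
carry presence/absence (hemizygous) variation that legitimately inflates
apparent heterozygosity; the heterozygosity validations therefore run on
implant-free genomes, and the end-to-end test documents the inflation.

## Numerical choices and degenerate inputs

Canonical k-mers use A<C<G<T; k must be odd (no self-reverse-complement
k-mers) and within [11, 31] (2-bit packing in uint64). k-mers containing N
are skipped. Empty read sets, k longer than every read, spectra with fewer
than two occupied bins, empty protein sets, single-partition HGT databases
and unreachable TE targets all raise immediately with instructive messages;
fit non-convergence is flagged in the report, never silently zeroed. Implant
placement retries 300 times before failing. All randomness flows through
numpy Generators seeded explicitly; stage seeds are spawned via SeedSequence
so no two generators share a stream (reusing one integer across generators
would duplicate sequence content verbatim). Problem sizes in the validation
suite (400 kb fit genomes, 500 kb TE genomes, 1.2 Mb palindrome genomes) were
chosen so binomial sampling noise is small against each stated tolerance.

## Known limitations

- Homoeolog divergence beyond the k-mer-detectable range (≳ 15–20% at k=21)
  only triggers the range-exceeded warning; assembly-based divergence
  estimation is out of scope.
- Ploidy and topology are user-supplied, not inferred; the fit quantifies a
  given model rather than selecting one.
- The greedy overlap assembler is a deliberately simple stand-in for a
  coverage-aware assembler: exact overlaps make it brittle to sequencing
  error inside repeats, which the read-level annotation path compensates for.
- Real-data HGT and TE values depend on database versions and are only
  qualitatively comparable between studies.
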