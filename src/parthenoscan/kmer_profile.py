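"""Stage 1: heterozygosity, coverage and genome size from the k-mer spectrum.

The spectrum of canonical k-mer coverages is fitted with a mixture of evenly
spaced negative binomial components: a genome with per-copy (haploid) k-mer
coverage lambda places a k-mer shared by i haplotype copies at mean coverage
i*lambda. Heterozygous k-length windows split their k-mers across lower
multiplicities, so the relative peak weights encode the per-site
heterozygosity r through the window probability a = 1 - (1 - r)^k.

For polyploids, the per-locus allele structure (AAB vs AABB vs multiallelic)
is read from het k-mer families: sets of k-mers one substitution apart whose
coverages reveal how many genome copies carry each allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import nbinom

from . import dna
from .simulate import ReadSet

FIT_TOPOLOGIES = ("AB", "AAB", "AAAB", "AABB", "ABC")

#: summary categories for polyploid heterozygosity structure
CAT_SINGLE = "biallelic_single_copy"  # AAB / AAAB: alternative allele on one copy
CAT_BALANCED = "biallelic_balanced"  # AABB: both alleles on two copies
CAT_MULTI = "multiallelic"  # three or more alleles at the locus
CAT_DIPLOID = "diploid_AB"


@dataclass
class KmerSpectrum:
    """Histogram of distinct canonical k-mers by integer coverage."""

    k: int
    bins: np.ndarray  # bins[c] = number of distinct canonical k-mers seen c times

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.int64)

    @property
    def total_kmers(self) -> int:
        """Total k-mers streamed (sum over distinct k-mers of their coverage)."""
        return int((self.bins * np.arange(len(self.bins))).sum())

    @property
    def total_distinct(self) -> int:
        return int(self.bins.sum())

    def error_cutoff(self) -> int:
        """First local minimum of the histogram between coverage 1 and the mode.

        Low-coverage k-mers below the cutoff are treated as sequencing errors.
        On error-free spectra the histogram rises from coverage 1 and the
        cutoff degenerates to 1 (nothing is excluded).
        """
        b = self.bins
        if len(b) < 4:
            return 1
        c = 1
        while c + 1 < len(b) and b[c] > b[c + 1]:
            c += 1
        if c + 2 >= len(b):  # monotone decay, no second mode: nothing to exclude
            return 1
        return c

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c in range(1, len(self.bins)):
                if self.bins[c]:
                    fh.write(f"{c}\t{self.bins[c]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, k: int) -> "KmerSpectrum":
        cov, cnt = [], []
        with open(path) as fh:
            for line in fh:
                a, b = line.split()
                cov.append(int(a))
                cnt.append(int(b))
        bins = np.zeros(max(cov) + 1, dtype=np.int64)
        bins[np.array(cov)] = cnt
        return cls(k=k, bins=bins)


@dataclass
class KmerCountTable:
    """Distinct canonical k-mers (2-bit packed uint64) with their coverages."""

    k: int
    kmers: np.ndarray  # uint64, sorted
    counts: np.ndarray  # int64

    def spectrum(self) -> KmerSpectrum:
        return KmerSpectrum(k=self.k, bins=np.bincount(self.counts))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for code, cnt in zip(self.kmers, self.counts):
                fh.write(f"{decode_kmer(int(code), self.k)}\t{cnt}\n")


def decode_kmer(code: int, k: int) -> str:
    return "".join(dna.BASES[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))


def encode_kmer(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = (code << 2) | int(dna.CODE_LUT[ord(b)])
    return code


def _revcomp_codes_packed(codes: np.ndarray, k: int) -> np.ndarray:
    rc = np.zeros_like(codes)
    three = np.uint64(3)
    for j in range(k):
        base = (codes >> np.uint64(2 * (k - 1 - j))) & three
        rc |= (three ^ base) << np.uint64(2 * j)
    return rc


def _canonical_kmers_of_block(block: np.ndarray, k: int) -> np.ndarray:
    """Canonical packed k-mers of a uint8 code block; windows with code 4 dropped."""
    n = len(block) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    invalid = (block >= 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(invalid)])
    ok = (cs[k:] - cs[:n]) == 0
    bb = np.where(block < 4, block, 0).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        fwd |= bb[j : j + n] << np.uint64(2 * (k - 1 - j))
        rev |= (three ^ bb[j : j + n]) << np.uint64(2 * j)
    return np.minimum(fwd, rev)[ok]


def _iter_sequences(reads) -> "list[str]":
    if isinstance(reads, ReadSet):
        return reads.seqs
    if isinstance(reads, (str, Path)):
        from .io import read_fastq

        return read_fastq(reads).seqs
    return list(reads)


def count_kmers(
    reads, k: int = 21, keep_table: bool = False, chunk_bases: int = 8_000_000
):
    """Count canonical k-mers of a read set and histogram their coverages.

    Canonical k-mer = lexicographic minimum (A<C<G<T) of the k-mer and its
    reverse complement. k-mers containing non-ACGT characters are skipped.
    Returns a KmerSpectrum, or a KmerCountTable when ``keep_table`` (needed by
    het-family extraction).
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError("k must be odd and within [11, 31]")
    seqs = _iter_sequences(reads)
    if not seqs:
        raise ValueError("no reads supplied")
    if max(len(s) for s in seqs) < k:
        raise ValueError("k exceeds every read length")

    chunks: list[np.ndarray] = []
    buf: list[str] = []
    buf_len = 0
    for s in seqs:
        buf.append(s)
        buf_len += len(s) + 1
        if buf_len >= chunk_bases:
            block = dna.encode("N".join(buf))
            chunks.append(_canonical_kmers_of_block(block, k))
            buf, buf_len = [], 0
    if buf:
        block = dna.encode("N".join(buf))
        chunks.append(_canonical_kmers_of_block(block, k))
    allk = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
    kmers, counts = np.unique(allk, return_counts=True)
    table = KmerCountTable(k=k, kmers=kmers, counts=counts.astype(np.int64))
    return table if keep_table else table.spectrum()


# --- mixture weights ---------------------------------------------------------


def window_het_prob(r: float, k: int) -> float:
    """Probability a k-length window contains at least one variant site."""
    return 1.0 - (1.0 - r) ** k


def rate_from_window_prob(a: float, k: int) -> float:
    return 1.0 - (1.0 - min(max(a, 0.0), 1.0 - 1e-12)) ** (1.0 / k)


def topology_weights(topology: str, rates: dict[str, float], k: int) -> dict[int, float]:
    """Expected distinct-k-mer mass per ancestral window, by peak multiplicity.

    Peak i collects k-mers shared by i haplotype copies (mean coverage
    i*lambda). With a = 1-(1-r)^k per layer, a heterozygous window splits one
    shared k-mer into copy-specific ones; the weights below follow directly
    from how each topology partitions its copies. Weights sum to the expected
    number of distinct k-mers per window (>= 1).
    """
    if topology == "AB":
        a = window_het_prob(_one_rate(rates, ("allelic", "het", "composite")), k)
        return {1: 2 * a, 2: 1 - a}
    if topology == "AAB":
        a = window_het_prob(_one_rate(rates, ("homoeolog",)), k)
        return {1: a, 2: a, 3: 1 - a}
    if topology == "AAAB":
        a = window_het_prob(_one_rate(rates, ("homoeolog",)), k)
        return {1: a, 3: a, 4: 1 - a}
    if topology == "AABB":
        a = window_het_prob(_one_rate(rates, ("homoeolog",)), k)
        return {2: 2 * a, 4: 1 - a}
    if topology == "ABC":
        if "branch" in rates:
            ab = ac = window_het_prob(rates["branch"], k)
        else:
            ab = window_het_prob(rates["branch_B"], k)
            ac = window_het_prob(rates["branch_C"], k)
        a2 = ab * (1 - ac) + ac * (1 - ab)  # exactly one copy diverged in the window
        a3 = ab * ac  # all three mutually distinct
        return {1: a2 + 3 * a3, 2: a2, 3: 1 - a2 - a3}
    raise ValueError(f"unsupported topology for fitting: {topology!r}")


def _one_rate(rates: dict[str, float], keys: tuple[str, ...]) -> float:
    for key in keys:
        if key in rates:
            return rates[key]
    if len(rates) == 1:
        return next(iter(rates.values()))
    raise ValueError(f"expected one of {keys} in het_rates, got {sorted(rates)}")


# --- spectrum fit ------------------------------------------------------------


@dataclass
class SpectrumFit:
    """Fitted mixture parameters of a k-mer spectrum."""

    topology: str
    ploidy: int
    k: int
    lambda_cov: float  # haploid per-copy k-mer coverage
    rho: float  # overdispersion; NB variance = mu * (1 + rho)
    het_rates: dict[str, float]  # per-site rates, percent
    composite: bool  # True when layers cannot be separated
    genome_size_G: float  # haploid genome size, distinct k-mer (window) units
    error_cutoff: int
    residual: float  # relative sum of squared residuals over the fitted bins
    repeat_fraction: float  # k-mer mass above the modelled peaks
    converged: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def het_composite_pct(self) -> float:
        """Composite heterozygosity: the sum of the layer rates, percent."""
        return float(sum(self.het_rates.values()))

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["het_composite_pct"] = self.het_composite_pct
        return d


def _model_counts(cs, lam, rho, weights, scale):
    """Expected histogram counts at coverages cs for peak weights {i: w}."""
    out = np.zeros_like(cs, dtype=float)
    p = 1.0 / (1.0 + rho)
    for i, w in weights.items():
        if w <= 0:
            continue
        mu = i * lam
        size = mu / rho
        out += w * nbinom.pmf(cs, size, p)
    return scale * out


def _rates_from_params(topology: str, avec: np.ndarray, k: int) -> dict[str, float]:
    if topology == "AB":
        return {"composite": rate_from_window_prob(avec[0], k)}
    if topology in ("AAB", "AAAB", "AABB"):
        return {"homoeolog": rate_from_window_prob(avec[0], k)}
    if topology == "ABC":
        return {"branch": rate_from_window_prob(avec[0], k)}
    raise AssertionError(topology)


def _weights_from_params(topology: str, avec: np.ndarray, k: int) -> dict[int, float]:
    rates = _rates_from_params(topology, avec, k)
    return topology_weights(topology, rates, k)


def fit_spectrum(
    spectrum: KmerSpectrum,
    ploidy: int,
    topology: str,
    error_cutoff: int | None = None,
    max_rho: float = 30.0,
) -> SpectrumFit:
    """Weighted nonlinear least squares of the NB mixture against the spectrum.

    Residuals are taken on sqrt(counts) (variance stabilization); multi-start
    over lambda in {mode/ploidy, ..., mode} and several initial rates, ties
    broken by lowest residual then lowest heterozygosity. Peaks are modelled up
    to i = ploidy; k-mer mass further right is reported as repeat fraction.
    """
    if topology not in FIT_TOPOLOGIES:
        raise ValueError(f"unsupported topology {topology!r}; use one of {FIT_TOPOLOGIES}")
    if ploidy != len(topology):
        raise ValueError("ploidy does not match topology")
    k = spectrum.k
    cutoff = spectrum.error_cutoff() if error_cutoff is None else error_cutoff
    b = spectrum.bins
    occupied = np.nonzero(b[cutoff:])[0]
    if len(occupied) < 2:
        raise ValueError("degenerate spectrum: fewer than 2 occupied bins above cutoff")
    mode = int(np.argmax(b[cutoff:]) + cutoff)
    cmax = min(len(b) - 1, int(mode * (ploidy + 1) * 1.5) + 20)
    cs = np.arange(cutoff, cmax + 1)
    y = b[cutoff : cmax + 1].astype(float)
    sqrt_y = np.sqrt(y)
    mass_total = float((b[cutoff:] * np.arange(cutoff, len(b))).sum())

    def residuals(x):
        lam, rho, a, logG = x
        w = _weights_from_params(topology, np.array([a]), k)
        return np.sqrt(_model_counts(cs, lam, rho, w, np.exp(logG))) - sqrt_y

    logG0 = np.log(max(b[cutoff:].sum(), 10))
    best = None
    for i in range(1, ploidy + 1):
        lam0 = mode / i
        if lam0 <= cutoff / 2 or lam0 < 1:
            continue
        for a0 in (0.05, 0.3, 0.7):
            x0 = np.array([lam0, 0.5, a0, logG0])
            try:
                sol = least_squares(
                    residuals, x0,
                    bounds=([max(1.0, cutoff / 2), 1e-6, 1e-9, logG0 - 8],
                            [cmax, max_rho, 0.9999, logG0 + 8]),
                    xtol=1e-10, ftol=1e-10, max_nfev=400,
                )
            except Exception:
                continue
            model = _model_counts(
                cs, sol.x[0], sol.x[1],
                _weights_from_params(topology, sol.x[2:3], k), np.exp(sol.x[3]))
            rel = float(((y - model) ** 2).sum() / (y**2).sum())
            rate = sum(_rates_from_params(topology, sol.x[2:3], k).values())
            key = (round(rel, 12), rate)
            if best is None or key < best[0]:
                best = (key, sol, rel)
    if best is None:
        raise RuntimeError("spectrum fit failed to converge from every start")
    _, sol, rel = best
    lam, rho, a, logG = sol.x
    weights = _weights_from_params(topology, np.array([a]), k)
    rates_frac = _rates_from_params(topology, np.array([a]), k)
    het_rates = {layer: 100.0 * r for layer, r in rates_frac.items()}
    wsum = sum(weights.values())
    G = np.exp(logG)  # scale = number of ancestral windows

    top = ploidy * lam
    hi = int(top + 4 * np.sqrt(top * (1 + rho)))
    if hi < len(b):
        mass_hi = float((b[hi:] * np.arange(hi, len(b))).sum())
    else:
        mass_hi = 0.0
    repeat_fraction = mass_hi / mass_total if mass_total else 0.0

    warnings = []
    if repeat_fraction > 0.30:
        warnings.append(
            "range-exceeded: >30% of k-mer mass above the modelled peaks; divergence "
            "or repeat structure outside the quantifiable range"
        )
    if not sol.success:
        warnings.append("optimizer reported non-convergence; treat parameters as suspect")
    if rel > 0.05:
        warnings.append(f"poor fit: relative squared residual {rel:.3g}")

    return SpectrumFit(
        topology=topology, ploidy=ploidy, k=k, lambda_cov=float(lam), rho=float(rho),
        het_rates=het_rates, composite=(topology == "AB"),
        genome_size_G=float(G), error_cutoff=int(cutoff), residual=rel,
        repeat_fraction=float(repeat_fraction), converged=bool(sol.success),
        warnings=warnings,
    )


# --- het k-mer families ------------------------------------------------------


@dataclass
class HetKmerFamily:
    """Canonical k-mers one substitution apart, with their coverages."""

    members: np.ndarray  # packed uint64 codes
    coverages: np.ndarray
    classification: str = ""

    @property
    def size(self) -> int:
        return len(self.members)


def extract_het_families(
    table: KmerCountTable,
    error_cutoff: int,
    lambda_cov: float,
    ploidy: int,
    rho: float = 2.0,
    max_members: int = 6,
) -> list[HetKmerFamily]:
    """Group k-mers that differ at a single position into het families.

    Only k-mers with coverage in [error_cutoff, ploidy*lambda +
    4*sqrt(ploidy*lambda*rho)] participate. Families are connected components
    of the one-substitution graph (a locus with three alleles links its three
    k-mers through shared single-substitution neighbours); components larger
    than ``max_members`` are discarded as repeat-induced.
    """
    if not isinstance(table, KmerCountTable):
        raise TypeError(
            "extract_het_families needs the k-mer count table; rerun count_kmers "
            "with keep_table=True"
        )
    k = table.k
    hi = ploidy * lambda_cov + 4.0 * np.sqrt(ploidy * lambda_cov * rho)
    keep = (table.counts >= error_cutoff) & (table.counts <= hi)
    kmers = table.kmers[keep]
    counts = table.counts[keep]
    n = len(kmers)
    if n == 0:
        return []
    rc = _revcomp_codes_packed(kmers, k)

    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    three = np.uint64(3)
    for p in range(k):
        m_f = ~(three << np.uint64(2 * (k - 1 - p)))
        m_r = ~(three << np.uint64(2 * p))
        keys = np.minimum(kmers & m_f, rc & m_r)
        order = np.argsort(keys, kind="stable")
        sk = keys[order]
        boundaries = np.nonzero(np.diff(sk))[0] + 1
        start = 0
        for end in list(boundaries) + [n]:
            if end - start >= 2:
                base = order[start]
                for t in order[start + 1 : end]:
                    union(base, t)
            start = end

    groups: dict[int, list[int]] = {}
    for i in range(n):
        root = find(i)
        groups.setdefault(root, []).append(i)
    families = []
    for members in groups.values():
        if 2 <= len(members) <= max_members:
            idx = np.array(members)
            families.append(HetKmerFamily(members=kmers[idx], coverages=counts[idx]))
    return families


# --- structure classification ------------------------------------------------

# templates in (total coverage multiple of lambda, minor allele fraction)
_TEMPLATES = {
    "AB": (2.0, 0.5),
    "AAB": (3.0, 1.0 / 3.0),
    "AABB": (4.0, 0.5),
    "AAAB": (4.0, 0.25),
}

_CATEGORY_OF = {"AB": CAT_DIPLOID, "AAB": CAT_SINGLE, "AAAB": CAT_SINGLE,
                "AABB": CAT_BALANCED}

#: total copy multiplicity implied by each biallelic template
_TEMPLATE_COPIES = {"AB": 2, "AAB": 3, "AABB": 4, "AAAB": 4}


@dataclass
class StructureSummary:
    fractions: dict[str, float]  # over classified families; empty if none
    n_families: int
    n_classified: int

    @property
    def defined(self) -> bool:
        return self.n_classified > 0


def classify_family(family: HetKmerFamily, lambda_cov: float,
                    max_deviation: float = 0.35) -> str:
    """Assign a biallelic family to its nearest coverage configuration.

    Biallelic templates live in (total coverage, minor-allele fraction) space:
    AB=(2L, 1/2), AAB=(3L, 1/3), AABB=(4L, 1/2), AAAB=(4L, 1/4). Families with
    3+ members are multiallelic; a relative deviation above ``max_deviation``
    on either coordinate marks the family AMBIGUOUS.
    """
    if family.size >= 3:
        return "MULTI"
    c_low, c_high = sorted(float(c) for c in family.coverages)
    t = (c_low + c_high) / lambda_cov
    f = c_low / (c_low + c_high)
    best_name, best_dev = None, np.inf
    for name, (t0, f0) in _TEMPLATES.items():
        dev = abs(t - t0) / t0 + abs(f - f0) / f0
        if dev < best_dev:
            best_name, best_dev = name, dev
    t0, f0 = _TEMPLATES[best_name]
    if abs(t - t0) / t0 > max_deviation or abs(f - f0) / f0 > max_deviation:
        return "AMBIGUOUS"
    return best_name


def classify_structures(
    families: list[HetKmerFamily],
    lambda_cov: float,
    ploidy: int = 2,
    max_deviation: float = 0.35,
) -> StructureSummary:
    """Classify families and summarize the relative heterozygosity structure.

    Category assignment is ploidy-aware. A biallelic template accounts for a
    total copy multiplicity M (AB: 2, AAB: 3, AABB/AAAB: 4). In a genome of
    ploidy P, a family whose template leaves copies unaccounted (M < P) is
    evidence of a locus with additional alleles: e.g. a (lambda, lambda) pair
    in a triploid covers only two of three copies, so the third copy carries a
    third allele and the locus is multiallelic. Templates exceeding the ploidy
    (M > P) imply more copies than the genome has (repeat-like signal) and are
    treated as AMBIGUOUS.
    """
    if lambda_cov <= 0:
        raise ValueError("lambda_cov must be positive")
    tallies = {CAT_SINGLE: 0, CAT_BALANCED: 0, CAT_MULTI: 0, CAT_DIPLOID: 0}
    n_classified = 0
    for fam in families:
        label = classify_family(fam, lambda_cov, max_deviation)
        if label not in ("MULTI", "AMBIGUOUS") and _TEMPLATE_COPIES[label] > ploidy:
            label = "AMBIGUOUS"
        fam.classification = label
        if label == "AMBIGUOUS":
            continue
        if label == "MULTI" or _TEMPLATE_COPIES[label] < ploidy:
            cat = CAT_MULTI
        else:
            cat = _CATEGORY_OF[label]
        tallies[cat] += 1
        n_classified += 1
    fractions = (
        {cat: cnt / n_classified for cat, cnt in tallies.items()} if n_classified else {}
    )
    return StructureSummary(fractions=fractions, n_families=len(families),
                            n_classified=n_classified)
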