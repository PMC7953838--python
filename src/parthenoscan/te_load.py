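"""Stage 2: TE load from a low-coverage read subsample.

The estimator mirrors read-based repeat quantification: subsample reads to
0.5x of the haploid genome size, assemble them with a greedy exact
suffix-prefix overlap assembler (single-copy regions mostly fail to assemble
at such low coverage while repeats retain enough local depth), annotate the
assembled contigs and the leftover reads against a TE reference library by
local alignment, and report annotated nucleotides as a fraction of all sampled
nucleotides. Repetitive sequence without a library hit is reported separately
as "unknown" and never counted into the TE load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dna
from .io import TE_CLASSES
from .simulate import ReadSet, TERecord


def subsample_reads(
    reads: ReadSet, haploid_genome_size: float, target_cov: float = 0.5, seed: int = 0
) -> ReadSet:
    """Uniform sample without replacement until target_cov x genome size bases.

    Deterministic per seed. Raises if the read set cannot reach the target,
    reporting the achievable coverage.
    """
    if haploid_genome_size <= 0:
        raise ValueError("haploid_genome_size must be positive")
    target = target_cov * haploid_genome_size
    if reads.total_bases < target:
        raise ValueError(
            f"insufficient reads: achievable coverage is "
            f"{reads.total_bases / haploid_genome_size:.3f}x, requested {target_cov}x"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    lengths = np.array([len(reads.seqs[i]) for i in order])
    n_take = int(np.searchsorted(np.cumsum(lengths), target) + 1)
    return reads.subset(order[:n_take])


# --- greedy overlap assembly -------------------------------------------------


@dataclass
class Contig:
    seq: str
    n_reads: int
    read_nt: int


@dataclass
class AssemblyResult:
    contigs: list[Contig]
    unassembled: list[str]  # read sequences left out of any >=min_reads contig


def assemble_repeats(
    subsample: ReadSet | list[str], min_overlap: int = 31, min_reads: int = 2
) -> AssemblyResult:
    """Greedy exact suffix-prefix overlap assembly, strand-aware.

    Identical reads (or reverse complements) are collapsed first; overlaps of
    at least ``min_overlap`` exact bases are chained longest-first, each
    sequence end used at most once. Paths supported by >= min_reads reads
    become repeat-candidate contigs; everything else is returned unassembled.
    """
    seqs = subsample.seqs if isinstance(subsample, ReadSet) else list(subsample)
    if not seqs:
        return AssemblyResult(contigs=[], unassembled=[])

    # collapse duplicates up to reverse complement
    mult: dict[str, int] = {}
    for s in seqs:
        canon = min(s, dna.revcomp(s))
        mult[canon] = mult.get(canon, 0) + 1
    nodes = list(mult)  # canonical orientation strings
    multiplicity = [mult[s] for s in nodes]
    n = len(nodes)

    # index prefixes of both orientations: word -> list of (node, orient)
    prefix_index: dict[str, list[tuple[int, int]]] = {}
    oriented = [(nodes[i], dna.revcomp(nodes[i])) for i in range(n)]
    for i in range(n):
        for o in (0, 1):
            prefix_index.setdefault(oriented[i][o][:min_overlap], []).append((i, o))

    # candidate overlaps (suffix of u-orient matches prefix of v-orient)
    candidates: list[tuple[int, int, int, int, int]] = []  # olen, u, uo, v, vo
    for u in range(n):
        for uo in (0, 1):
            s = oriented[u][uo]
            for p in range(1, len(s) - min_overlap + 1):
                for v, vo in prefix_index.get(s[p : p + min_overlap], ()):
                    if v == u:
                        continue
                    olen = len(s) - p
                    t = oriented[v][vo]
                    if olen <= len(t) and s[p:] == t[:olen]:
                        candidates.append((olen, u, uo, v, vo))
    candidates.sort(key=lambda c: -c[0])

    orient = [-1] * n  # orientation fixed at first use
    right_used = [False] * n
    left_used = [False] * n
    succ: dict[int, tuple[int, int]] = {}
    pred: dict[int, int] = {}

    def chain_end(i):
        while i in succ:
            i = succ[i][0]
        return i

    for olen, u, uo, v, vo in candidates:
        if orient[u] not in (-1, uo) or orient[v] not in (-1, vo):
            continue
        if right_used[u] or left_used[v]:
            continue
        if chain_end(v) == u:  # would close a cycle
            continue
        orient[u], orient[v] = uo, vo
        right_used[u] = True
        left_used[v] = True
        succ[u] = (v, olen)
        pred[v] = u

    contigs: list[Contig] = []
    unassembled: list[str] = []
    visited = [False] * n
    for start in range(n):
        if visited[start] or start in pred:
            continue
        # walk the chain from its head
        path = []
        i = start
        overlaps = []
        while True:
            visited[i] = True
            path.append(i)
            if i in succ:
                j, olen = succ[i]
                overlaps.append(olen)
                i = j
            else:
                break
        n_reads = sum(multiplicity[i] for i in path)
        read_nt = sum(multiplicity[i] * len(nodes[i]) for i in path)
        if n_reads >= min_reads:
            seq = oriented[path[0]][max(orient[path[0]], 0)]
            for idx, j in enumerate(path[1:]):
                seq += oriented[j][max(orient[j], 0)][overlaps[idx] :]
            contigs.append(Contig(seq=seq, n_reads=n_reads, read_nt=read_nt))
        else:
            for i in path:
                unassembled.extend([nodes[i]] * multiplicity[i])
    return AssemblyResult(contigs=contigs, unassembled=unassembled)


# --- annotation --------------------------------------------------------------


@dataclass
class TEAnnotationResult:
    """Per-class annotated nucleotides of a 0.5x subsample.

    te_load excludes unknown repeats (assembled repeat candidates without a
    library hit: tandem repeats, duplications, unknown TEs).
    """

    sampled_nt: int
    per_class_nt: dict[str, float] = field(default_factory=dict)
    unknown_repeat_nt: float = 0.0

    @property
    def te_load_percent(self) -> float:
        return 100.0 * sum(self.per_class_nt.values()) / self.sampled_nt

    def per_class_percent(self) -> dict[str, float]:
        return {c: 100.0 * nt / self.sampled_nt for c, nt in self.per_class_nt.items()}

    def long_table(self):
        import pandas as pd

        rows = [dict(te_class=c, annotated_nt=nt, percent=100.0 * nt / self.sampled_nt)
                for c, nt in self.per_class_nt.items()]
        rows.append(dict(te_class="unknown", annotated_nt=self.unknown_repeat_nt,
                         percent=100.0 * self.unknown_repeat_nt / self.sampled_nt))
        return pd.DataFrame(rows)


class _SeedIndex:
    """Shared-word shortlist of library sequences for a query."""

    def __init__(self, library: list[TERecord], word: int = 13):
        self.word = word
        self.lib = library
        self.index: dict[str, set[int]] = {}
        for i, rec in enumerate(library):
            for seq in (rec.seq, dna.revcomp(rec.seq)):
                for p in range(0, len(seq) - word + 1, 4):
                    self.index.setdefault(seq[p : p + word], set()).add(i)

    def candidates(self, query: str) -> set[int]:
        out: set[int] = set()
        w = self.word
        for p in range(0, len(query) - w + 1, 3):
            out |= self.index.get(query[p : p + w], set())
        return out


_NT_ALIGNER = None


def _nt_aligner():
    global _NT_ALIGNER
    if _NT_ALIGNER is None:
        from Bio import Align

        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = 2
        a.mismatch_score = -3
        a.open_gap_score = -5
        a.extend_gap_score = -2
        _NT_ALIGNER = a
    return _NT_ALIGNER


def _best_hit(query: str, library: list[TERecord], seed_index: _SeedIndex,
              min_identity: float, min_len: int):
    """Best local alignment of query against shortlisted library sequences.

    Returns (te_class, aligned_query_length) or None.
    """
    cands = seed_index.candidates(query)
    if not cands:
        return None
    aligner = _nt_aligner()
    best = None
    for i in cands:
        target = library[i].seq
        for q in (query, dna.revcomp(query)):
            aln = aligner.align(target, q)
            if len(aln) == 0:
                continue
            a = aln[0]
            t_aln, q_aln = a.aligned
            if len(q_aln) == 0:
                continue
            qspan = int(sum(e - s for s, e in q_aln))
            # identity over aligned columns
            matches = 0
            for (ts, te_), (qs, qe) in zip(t_aln, q_aln):
                tt = target[ts:te_]
                qq = q[qs:qe]
                matches += sum(1 for x, y in zip(tt, qq) if x == y)
            cols = int(sum(te_ - ts for ts, te_ in t_aln))
            ident = matches / cols if cols else 0.0
            if qspan >= min_len and ident >= min_identity:
                key = (a.score, qspan)
                if best is None or key > best[0]:
                    best = (key, library[i].te_class, qspan)
    if best is None:
        return None
    return best[1], best[2]


def annotate_repeats(
    assembly: AssemblyResult,
    te_library: list[TERecord],
    sampled_nt: int,
    min_identity: float = 0.70,
    min_len: int = 80,
) -> TEAnnotationResult:
    """Annotate contigs and unassembled reads against the TE library.

    A contig contributes (aligned contig fraction) x (read nucleotides it
    assembled) to its best hit's class; an unassembled read contributes its own
    aligned length. Contigs without any hit feed unknown_repeat_nt. Hits whose
    library class is outside the five TE classes are routed to unknown as well
    (tandem/satellite-style repeats are not TEs).
    """
    if not te_library:
        raise ValueError("empty TE library")
    seed_index = _SeedIndex(te_library)
    per_class = {c: 0.0 for c in TE_CLASSES}
    unknown = 0.0
    for contig in assembly.contigs:
        hit = _best_hit(contig.seq, te_library, seed_index, min_identity, min_len)
        if hit is None:
            unknown += contig.read_nt
            continue
        cls, qspan = hit
        frac = min(1.0, qspan / len(contig.seq))
        if cls in per_class:
            per_class[cls] += frac * contig.read_nt
        else:
            unknown += frac * contig.read_nt
    for read in assembly.unassembled:
        hit = _best_hit(read, te_library, seed_index, min_identity, min_len)
        if hit is None:
            continue
        cls, qspan = hit
        if cls in per_class:
            per_class[cls] += min(qspan, len(read))
        else:
            unknown += min(qspan, len(read))
    return TEAnnotationResult(sampled_nt=sampled_nt, per_class_nt=per_class,
                              unknown_repeat_nt=unknown)


def estimate_te_load(
    reads: ReadSet,
    haploid_genome_size: float,
    te_library: list[TERecord],
    target_cov: float = 0.5,
    seed: int = 0,
    min_overlap: int = 31,
    min_reads: int = 2,
    min_identity: float = 0.70,
    min_len: int = 80,
) -> TEAnnotationResult:
    """Full stage: subsample -> assemble -> annotate -> per-class fractions."""
    sub = subsample_reads(reads, haploid_genome_size, target_cov, seed)
    asm = assemble_repeats(sub, min_overlap=min_overlap, min_reads=min_reads)
    return annotate_repeats(asm, te_library, sampled_nt=sub.total_bases,
                            min_identity=min_identity, min_len=min_len)
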