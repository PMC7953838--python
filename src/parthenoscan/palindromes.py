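"""Stage 3: palindromic gene arrangements from assembly annotation.

A genomic palindrome is a pair of homologous reverse-complementary segments on
the same scaffold — the only arrangement able to fold back into a hairpin and
sustain intra-chromosomal gene conversion. Detection works at gene resolution:
all-vs-all protein homology provides anchor pairs, anchors are chained into
collinear blocks by dynamic programming over gene ranks, and blocks are
filtered to reverse-oriented, same-scaffold, strand-consistent, non-overlapping
arrangements. Single-gene inverted duplications count as palindromic
arrangements by default; a strict mode restricts to blocks of at least five
genes (the classical synteny-block convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# BLAST-like Karlin-Altschul constants for gapped BLOSUM62 bit scores
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass
class HomologyHit:
    query: str
    subject: str
    score: float
    bitscore: float
    evalue: float
    identity: float
    aln_len: int


_AA_ALIGNER = None


def _aa_aligner():
    global _AA_ALIGNER
    if _AA_ALIGNER is None:
        from Bio import Align
        from Bio.Align import substitution_matrices

        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        _AA_ALIGNER = a
    return _AA_ALIGNER


def align_proteins(seq_a: str, seq_b: str):
    """Local BLOSUM62 alignment -> (score, identity, aligned_length) or None."""
    aligner = _aa_aligner()
    alns = aligner.align(seq_a, seq_b)
    if len(alns) == 0:
        return None
    a = alns[0]
    pa, pb = a.aligned
    matches = 0
    cols = 0
    for (s1, e1), (s2, e2) in zip(pa, pb):
        x, y = seq_a[s1:e1], seq_b[s2:e2]
        matches += sum(1 for u, v in zip(x, y) if u == v)
        cols += e1 - s1
    if cols == 0:
        return None
    return float(a.score), matches / cols, cols


def all_vs_all_homology(
    proteins: dict[str, str],
    min_identity: float = 0.5,
    min_aln_len: int = 100,
    max_evalue: float = 1e-5,
    seed_word: int = 5,
    min_shared_words: int = 2,
) -> list[HomologyHit]:
    """Significant local-alignment hits between all protein pairs.

    Pairs are shortlisted by shared amino-acid words (two random ~300-aa
    proteins share two 5-mers with probability << 1e-3, which keeps the
    empirical false-positive rate of the whole filter cascade below 1e-3),
    then aligned with BLOSUM62; hits are kept once per unordered pair when the
    e-value-like significance, identity and aligned length pass the
    thresholds. Self-hits are excluded.
    """
    ids = list(proteins)
    if len(ids) < 2:
        raise ValueError("need at least two proteins")
    word_index: dict[str, list[int]] = {}
    for i, pid in enumerate(ids):
        seq = proteins[pid]
        for p in range(len(seq) - seed_word + 1):
            word_index.setdefault(seq[p : p + seed_word], []).append(i)
    shared: dict[tuple[int, int], int] = {}
    for members in word_index.values():
        uniq = sorted(set(members))
        if len(uniq) < 2:
            continue
        for x in range(len(uniq)):
            for y in range(x + 1, len(uniq)):
                key = (uniq[x], uniq[y])
                shared[key] = shared.get(key, 0) + 1

    hits = []
    for (i, j), n_words in shared.items():
        if n_words < min_shared_words:
            continue
        sa, sb = proteins[ids[i]], proteins[ids[j]]
        res = align_proteins(sa, sb)
        if res is None:
            continue
        score, ident, cols = res
        bit = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2.0)
        evalue = len(sa) * len(sb) * 2.0 ** (-bit)
        if evalue <= max_evalue and ident >= min_identity and cols >= min_aln_len:
            hits.append(HomologyHit(query=ids[i], subject=ids[j], score=score,
                                    bitscore=bit, evalue=evalue, identity=ident,
                                    aln_len=cols))
    return hits


# --- collinear block chaining ------------------------------------------------


@dataclass
class Anchor:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    score: float


@dataclass
class CollinearBlock:
    scaffold_a: str
    scaffold_b: str
    orientation: str  # "same" | "reverse"
    anchors: list[Anchor]
    score: float

    @property
    def n_pairs(self) -> int:
        return len(self.anchors)


def _chain_anchors(anchors: list[Anchor], orientation: str, max_gap: int,
                   gap_penalty: float = 0.1) -> list[tuple[list[int], float]]:
    """DP chaining of anchors; returns maximal non-overlapping chains.

    A chain extends when both rank gaps are <= max_gap and the b-side moves in
    the chain's direction; chain score is the number of anchors minus
    ``gap_penalty`` per skipped rank unit. Best chains are extracted greedily
    (highest score first, anchors removed, repeat), so reported blocks never
    share an anchor.
    """
    sign = 1 if orientation == "same" else -1
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].rank_a, anchors[i].rank_b))
    chains: list[tuple[list[int], float]] = []
    active = set(order)
    while active:
        idx = [i for i in order if i in active]
        best_score = {i: 1.0 for i in idx}
        best_prev = {i: -1 for i in idx}
        for pos, j in enumerate(idx):
            aj = anchors[j]
            for i in idx[:pos]:
                ai = anchors[i]
                da = aj.rank_a - ai.rank_a
                db = sign * (aj.rank_b - ai.rank_b)
                if da < 1 or db < 1 or da > max_gap or db > max_gap:
                    continue
                cand = best_score[i] + 1.0 - 0.1 * ((da - 1) + (db - 1))
                if cand > best_score[j]:
                    best_score[j] = cand
                    best_prev[j] = i
        end = max(idx, key=lambda i: best_score[i])
        chain = []
        i = end
        while i != -1:
            chain.append(i)
            i = best_prev[i]
        chain.reverse()
        chains.append((chain, best_score[end]))
        active -= set(chain)
    return chains


def detect_collinear_blocks(
    hits: list[HomologyHit],
    genes: pd.DataFrame,
    max_gap: int = 25,
    min_pairs: int = 1,
) -> list[CollinearBlock]:
    """Chain homology anchors into collinear blocks per scaffold pair.

    ``genes`` must carry gene_id, scaffold, start, end, strand, rank (see
    io.add_gene_ranks). When a gene has several hits to the same scaffold
    pair/orientation only its best-scoring anchor is kept, so no gene appears
    twice within a block.
    """
    ginfo = genes.set_index("gene_id")
    anchors_by_key: dict[tuple[str, str, str], dict] = {}
    for h in hits:
        ga, gb = h.query, h.subject
        if ga not in ginfo.index or gb not in ginfo.index:
            continue
        ra, rb = ginfo.loc[ga], ginfo.loc[gb]
        if (ra.scaffold, ra["rank"]) > (rb.scaffold, rb["rank"]):
            ga, gb, ra, rb = gb, ga, rb, ra
        key_base = (ra.scaffold, rb.scaffold)
        anchor = Anchor(gene_a=ga, gene_b=gb, rank_a=int(ra["rank"]),
                        rank_b=int(rb["rank"]), score=h.score)
        for orientation in ("same", "reverse"):
            key = (*key_base, orientation)
            best = anchors_by_key.setdefault(key, {})
            for g in (ga, gb):
                prev = best.get(g)
                if prev is not None and prev.score >= anchor.score:
                    break
            else:
                for g in (ga, gb):
                    best[g] = anchor

    blocks: list[CollinearBlock] = []
    for (scf_a, scf_b, orientation), best in anchors_by_key.items():
        anchors = sorted({id(a): a for a in best.values()}.values(),
                         key=lambda a: (a.rank_a, a.rank_b))
        anchors = list(anchors)
        if not anchors:
            continue
        for chain, score in _chain_anchors(anchors, orientation, max_gap):
            if len(chain) >= min_pairs:
                chosen = [anchors[i] for i in chain]
                blocks.append(CollinearBlock(scaffold_a=scf_a, scaffold_b=scf_b,
                                             orientation=orientation,
                                             anchors=chosen, score=score))
    return blocks


def enumerate_chains_exhaustive(anchors: list[Anchor], orientation: str,
                                max_gap: int = 25) -> tuple[list[int], float]:
    """Brute-force best chain over all ordered anchor subsequences.

    Independent oracle for the DP on small instances (exponential; use for
    <= ~20 anchors).
    """
    sign = 1 if orientation == "same" else -1
    n = len(anchors)
    order = sorted(range(n), key=lambda i: (anchors[i].rank_a, anchors[i].rank_b))
    best: tuple[float, list[int]] = (-np.inf, [])

    def extend(chain: list[int], score: float):
        nonlocal best
        if score > best[0]:
            best = (score, list(chain))
        last = chain[-1]
        for j in order:
            if j in chain:
                continue
            da = anchors[j].rank_a - anchors[last].rank_a
            db = sign * (anchors[j].rank_b - anchors[last].rank_b)
            if da < 1 or db < 1 or da > max_gap or db > max_gap:
                continue
            chain.append(j)
            extend(chain, score + 1.0 - 0.1 * ((da - 1) + (db - 1)))
            chain.pop()

    for i in order:
        extend([i], 1.0)
    return best[1], best[0]


# --- palindrome filtering ----------------------------------------------------


@dataclass
class Palindrome:
    block: CollinearBlock
    n_genes: int
    gene_ids: list[str]


@dataclass
class PalindromeScreen:
    palindromes: list[Palindrome]
    rejected: list[tuple[CollinearBlock, str]] = field(default_factory=list)


def filter_palindromes(
    blocks: list[CollinearBlock],
    genes: pd.DataFrame,
    min_pairs: int = 1,
    tandem_rank_gap: int = 1,
) -> PalindromeScreen:
    """Keep only hairpin-capable blocks.

    A palindrome must lie on a single scaffold, be reverse-oriented, pair
    genes on opposite strands, and its two sides must not overlap in
    coordinates. Anchor pairs whose genes are within ``tandem_rank_gap`` ranks
    are removed first: an immediately adjacent inverted copy is
    indistinguishable from a tail-to-tail tandem artifact.
    """
    ginfo = genes.set_index("gene_id")
    palindromes: list[Palindrome] = []
    rejected: list[tuple[CollinearBlock, str]] = []
    for block in blocks:
        if block.scaffold_a != block.scaffold_b:
            rejected.append((block, "different scaffolds"))
            continue
        if block.orientation != "reverse":
            rejected.append((block, "same orientation"))
            continue
        anchors = [a for a in block.anchors
                   if abs(a.rank_b - a.rank_a) > tandem_rank_gap]
        if len(anchors) < min_pairs:
            rejected.append((block, "tandem-adjacent anchors only"))
            continue
        strands_ok = all(
            ginfo.loc[a.gene_a, "strand"] != ginfo.loc[a.gene_b, "strand"]
            for a in anchors
        )
        if not strands_ok:
            rejected.append((block, "strand-inconsistent"))
            continue
        a_end = max(int(ginfo.loc[a.gene_a, "end"]) for a in anchors)
        b_start = min(int(ginfo.loc[a.gene_b, "start"]) for a in anchors)
        if a_end > b_start:
            rejected.append((block, "overlapping sides"))
            continue
        gene_ids = sorted({g for a in anchors for g in (a.gene_a, a.gene_b)})
        pruned = CollinearBlock(block.scaffold_a, block.scaffold_b,
                                block.orientation, anchors, block.score)
        palindromes.append(Palindrome(block=pruned, n_genes=len(gene_ids),
                                      gene_ids=gene_ids))
    return PalindromeScreen(palindromes=palindromes, rejected=rejected)


def summarize_palindromes(palindromes: list[Palindrome], total_gene_count: int):
    """(n_palindromes, n_genes_affected, percent_genes); genes counted once."""
    if total_gene_count <= 0:
        raise ValueError("total_gene_count must be positive")
    affected = set()
    for p in palindromes:
        affected.update(p.gene_ids)
    n = len(affected)
    return len(palindromes), n, 100.0 * n / total_gene_count


def find_palindromes(
    proteins: dict[str, str],
    genes: pd.DataFrame,
    max_gap: int = 25,
    mcscanx_strict: bool = False,
    tandem_rank_gap: int = 1,
) -> PalindromeScreen:
    """Homology -> chaining -> hairpin filter, end to end.

    ``mcscanx_strict`` requires blocks of at least 5 anchor pairs (the
    classical synteny-block convention) instead of counting single-gene
    palindromic arrangements.
    """
    min_pairs = 5 if mcscanx_strict else 1
    hits = all_vs_all_homology(proteins)
    blocks = detect_collinear_blocks(hits, genes, max_gap=max_gap, min_pairs=min_pairs)
    return filter_palindromes(blocks, genes, min_pairs=min_pairs,
                              tandem_rank_gap=tandem_rank_gap)


def shuffled_palindrome_null(
    proteins: dict[str, str],
    genes: pd.DataFrame,
    n_shuffles: int = 10,
    seed: int = 0,
    **kwargs,
) -> list[int]:
    """Palindrome counts after shuffling which gene sits at which gene slot.

    Gene coordinates/strands stay with the slots; gene identities (and hence
    homology) are permuted across them. Reported alongside real results as an
    empirical misassembly-artifact null.
    """
    rng = np.random.default_rng(seed)
    hits = all_vs_all_homology(proteins)
    counts = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(genes))
        shuffled = genes.copy().reset_index(drop=True)
        shuffled["gene_id"] = shuffled["gene_id"].to_numpy()[perm]
        blocks = detect_collinear_blocks(hits, shuffled, **kwargs)
        screen = filter_palindromes(blocks, shuffled)
        counts.append(len(screen.palindromes))
    return counts
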