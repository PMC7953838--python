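"""Stage 4: candidate horizontally transferred genes with contamination control.

Each annotated protein is compared against a reference database split into a
metazoan and a non-metazoan partition. The hU index (best non-metazoan
alignment score minus best metazoan score) calls genes of likely foreign
origin; a candidate is only retained if its scaffold also carries at least one
gene of unambiguous metazoan origin, which removes whole-scaffold contaminants
that would otherwise masquerade as massive HGT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .palindromes import align_proteins
from .simulate import RefRecord

CALL_METAZOAN = "metazoan"
CALL_CANDIDATE = "hgt_candidate"
CALL_NO_HIT = "no_hit"
CALL_AMBIGUOUS = "ambiguous"


@dataclass
class OriginScore:
    gene_id: str
    best_metazoan_score: float
    best_nonmetazoan_score: float
    hU: float | None
    call: str


@dataclass
class HGTReport:
    n_genes_total: int
    n_candidates_prefilter: int
    n_candidates_linked: int
    hgt_c_percent: float
    per_scaffold: pd.DataFrame  # scaffold, n_genes, n_metazoan, n_candidates, n_linked
    scores: list[OriginScore] = field(default_factory=list)


class _WordIndex:
    def __init__(self, records: list[RefRecord], word: int = 5):
        self.word = word
        self.records = records
        self.index: dict[str, set[int]] = {}
        for i, rec in enumerate(records):
            for p in range(len(rec.seq) - word + 1):
                self.index.setdefault(rec.seq[p : p + word], set()).add(i)

    def candidates(self, query: str, min_shared: int = 2) -> list[int]:
        tally: dict[int, int] = {}
        for p in range(len(query) - self.word + 1):
            for i in self.index.get(query[p : p + self.word], ()):
                tally[i] = tally.get(i, 0) + 1
        return [i for i, n in tally.items() if n >= min_shared]


def score_gene_origin(
    gene_id: str,
    protein: str,
    db_index: "_WordIndex",
    threshold: float = 30.0,
) -> OriginScore:
    """hU = best non-metazoan minus best metazoan alignment score.

    A missing side contributes score 0. Calls: hgt_candidate when hU >=
    threshold, metazoan when hU <= -threshold, ambiguous in between, no_hit
    when neither partition aligns.
    """
    best_in = 0.0
    best_out = 0.0
    any_hit = False
    for i in db_index.candidates(protein):
        rec = db_index.records[i]
        res = align_proteins(protein, rec.seq)
        if res is None:
            continue
        score = res[0]
        any_hit = True
        if rec.label == "metazoan":
            best_in = max(best_in, score)
        else:
            best_out = max(best_out, score)
    if not any_hit:
        return OriginScore(gene_id, 0.0, 0.0, None, CALL_NO_HIT)
    hu = best_out - best_in
    if hu >= threshold:
        call = CALL_CANDIDATE
    elif hu <= -threshold:
        call = CALL_METAZOAN
    else:
        call = CALL_AMBIGUOUS
    return OriginScore(gene_id, best_in, best_out, hu, call)


def score_all_genes(
    proteins: dict[str, str],
    reference_db: list[RefRecord],
    threshold: float = 30.0,
) -> list[OriginScore]:
    labels = {r.label for r in reference_db}
    if "metazoan" not in labels or len(labels) < 2:
        raise ValueError("reference database must contain both partitions "
                         "(metazoan and non-metazoan records)")
    index = _WordIndex(reference_db)
    return [score_gene_origin(gid, seq, index, threshold)
            for gid, seq in proteins.items()]


def linkage_filter(origin_scores: list[OriginScore], genes: pd.DataFrame) -> HGTReport:
    """Retain candidates only on scaffolds that also carry a metazoan gene.

    Contaminant-only scaffolds therefore contribute zero linked candidates.
    Raises if a scored gene has no scaffold assignment.
    """
    scaffold_of = dict(zip(genes["gene_id"], genes["scaffold"]))
    for s in origin_scores:
        if s.gene_id not in scaffold_of:
            raise ValueError(f"gene {s.gene_id!r} has no scaffold mapping")
    by_scaffold: dict[str, list[OriginScore]] = {}
    for s in origin_scores:
        by_scaffold.setdefault(scaffold_of[s.gene_id], []).append(s)

    rows = []
    n_pre = 0
    n_linked = 0
    for scaffold, scores in sorted(by_scaffold.items()):
        n_met = sum(1 for s in scores if s.call == CALL_METAZOAN)
        cands = [s for s in scores if s.call == CALL_CANDIDATE]
        linked = len(cands) if n_met >= 1 else 0
        n_pre += len(cands)
        n_linked += linked
        rows.append(dict(scaffold=scaffold, n_genes=len(scores), n_metazoan=n_met,
                         n_candidates=len(cands), n_linked=linked))
    n_total = len(origin_scores)
    return HGTReport(
        n_genes_total=n_total,
        n_candidates_prefilter=n_pre,
        n_candidates_linked=n_linked,
        hgt_c_percent=100.0 * n_linked / n_total if n_total else 0.0,
        per_scaffold=pd.DataFrame(rows),
        scores=origin_scores,
    )


def call_hgt(
    proteins: dict[str, str],
    genes: pd.DataFrame,
    reference_db: list[RefRecord],
    threshold: float = 30.0,
) -> HGTReport:
    """Score all genes and apply the scaffold-linkage contamination control."""
    scores = score_all_genes(proteins, reference_db, threshold)
    return linkage_filter(scores, genes)
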