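"""Candidate-gene ranking, permutation benchmarking, and score fusion.

Candidates are ranked by descending score with competition (min) ranks;
the field's success criterion is placing a causative gene in the top
20th percentile of its candidate list (rank <= 0.2·N, e.g. rank <= 60 of
300).  The permutation protocol embeds the causative gene(s) in many
random candidate sets drawn from the network universe and records the
median rank.  The combined score fuses the propagated metabolomic score
with an external phenotype score (Exomiser-style) through a weighted
additive model C = p·E + (1−p)·M, where the prior weight p is the
fraction of network genes in the candidate's metabolic-first-neighbor
decile bin that the propagation ranks in the top 20th percentile of the
whole network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import GeneMetaboliteMap
from .network import Network
from .propagation import PropagationResult

__all__ = [
    "CandidateList",
    "RankingResult",
    "PermutationSummary",
    "NeighborStats",
    "CombinedScore",
    "rank_candidates",
    "permutation_evaluate",
    "neighbor_stats",
    "combine_scores",
]


@dataclass
class CandidateList:
    """Ordered candidate genes for one patient, optionally with an
    external per-gene phenotype score."""

    patient: str
    genes: List[str]
    phenotype_scores: Optional[pd.Series] = None

    def __post_init__(self):
        if len(self.genes) < 1:
            raise ValueError("candidate list must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("candidate genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_tsv(cls, source, patient: str = "") -> "CandidateList":
        df = pd.read_csv(source, sep="\t")
        if "gene" not in df.columns:
            df = pd.read_csv(source, sep="\t", header=None)
            df.columns = ["gene"] + [f"c{i}" for i in range(1, df.shape[1])]
        df["gene"] = df["gene"].astype(str)
        pheno = None
        if "exomiser_phenotype_score" in df.columns:
            pheno = pd.Series(
                df["exomiser_phenotype_score"].to_numpy(dtype=float),
                index=df["gene"].to_numpy(),
            )
        return cls(patient=patient, genes=list(df["gene"]), phenotype_scores=pheno)


@dataclass
class RankingResult:
    """Per-candidate score, competition rank (1 = best) and percentile
    100·rank/N, tagged with the scoring method."""

    table: pd.DataFrame  # index gene; columns score, rank, percentile
    method: str

    def rank_of(self, gene: str) -> int:
        return int(self.table.loc[gene, "rank"])

    def percentile_of(self, gene: str) -> float:
        return float(self.table.loc[gene, "percentile"])

    def in_top_fraction(self, gene: str, top_fraction: float = 0.20) -> bool:
        return self.percentile_of(gene) <= 100.0 * top_fraction

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["method"] = self.method
        out.rename_axis("gene").to_csv(path, sep="\t")


@dataclass
class PermutationSummary:
    """Median rank of each causative gene over seeded random candidate
    sets, with the full per-permutation rank record."""

    median_rank: Dict[str, float]
    ranks: Dict[str, np.ndarray]
    n_permutations: int
    set_size: int
    seed: int
    degenerate_ties: bool = False


@dataclass
class NeighborStats:
    """Per network gene: first-degree-neighbor count, fraction of those
    neighbors that carry metabolite annotations, and the decile bin
    index (bins [0,10), [10,20), ..., [90,100] percent)."""

    table: pd.DataFrame  # index gene; columns n_neighbors, frac_annotated, bin


@dataclass
class CombinedScore:
    """Fusion of phenotype (E) and propagated metabolomic (M) evidence."""

    table: pd.DataFrame  # index gene; columns p, e_scaled, m_scaled, term_e, term_m, C
    ranking: RankingResult


def _as_series(scores) -> pd.Series:
    if isinstance(scores, pd.Series):
        return scores
    if isinstance(scores, PropagationResult):
        return scores.scores
    return pd.Series(dict(scores), dtype=float)


def rank_candidates(scores, candidates: CandidateList, method: str = "score") -> RankingResult:
    """Rank candidates by descending score.

    Candidates absent from the score table get score 0 and therefore
    sort last; tied scores share the minimum (competition) rank.
    """
    s = _as_series(scores)
    vals = s.reindex(candidates.genes).fillna(0.0)
    rank = vals.rank(method="min", ascending=False).astype(int)
    n = len(candidates)
    table = pd.DataFrame(
        {"score": vals, "rank": rank, "percentile": 100.0 * rank / n}
    )
    return RankingResult(table=table, method=method)


def permutation_evaluate(
    scores,
    causative: Iterable[str],
    universe: Sequence[str],
    set_size: int = 300,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationSummary:
    """Median rank of causative genes over random candidate sets.

    Each permutation draws ``set_size − n`` distinct genes uniformly
    without replacement from ``universe`` minus the n causative genes,
    unions them with the causative genes, ranks the set by score
    (descending, min ranks) and records each causative gene's rank.
    Fully determined by ``seed``.
    """
    causative = sorted(set(causative))
    universe = list(universe)
    uset = set(universe)
    if not set(causative) <= uset:
        raise ValueError("causative genes must belong to the universe")
    n = len(causative)
    if set_size < n:
        raise ValueError("set_size must be at least the number of causative genes")
    if set_size > len(uset):
        raise ValueError("set_size exceeds the universe")

    s = _as_series(scores)
    pool = np.array(sorted(uset - set(causative)))
    pool_scores = s.reindex(pool).fillna(0.0).to_numpy(dtype=float)
    caus_scores = s.reindex(causative).fillna(0.0).to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    k = set_size - n
    ranks = {g: np.empty(n_perm, dtype=np.int64) for g in causative}
    degenerate = False
    for r in range(n_perm):
        idx = rng.choice(len(pool), size=k, replace=False)
        drawn = pool_scores[idx]
        # competition rank of each causative gene among the full set
        allsc = np.concatenate([caus_scores, drawn])
        if np.all(allsc == allsc[0]):
            degenerate = True
        for gi, g in enumerate(causative):
            ranks[g][r] = 1 + int(np.sum(allsc > caus_scores[gi]))
    med = {g: float(np.median(ranks[g])) for g in causative}
    return PermutationSummary(
        median_rank=med,
        ranks=ranks,
        n_permutations=n_perm,
        set_size=set_size,
        seed=seed,
        degenerate_ties=degenerate,
    )


def neighbor_stats(net: Network, gm_map: GeneMetaboliteMap) -> NeighborStats:
    """First-degree-neighbor counts and annotated-neighbor fractions.

    Zero-degree genes get fraction 0 and fall in bin [0,10)."""
    annotated = gm_map.genes
    e = net.edges
    rows = {g: [0, 0] for g in net.nodes}  # [n_neighbors, n_annotated]
    for g1, g2 in zip(e["gene1"], e["gene2"]):
        rows[g1][0] += 1
        rows[g2][0] += 1
        if g2 in annotated:
            rows[g1][1] += 1
        if g1 in annotated:
            rows[g2][1] += 1
    recs = []
    for g in net.nodes:
        nn, na = rows[g]
        frac = na / nn if nn else 0.0
        b = min(int(frac * 10), 9)  # [90,100] closed at the top
        recs.append((g, nn, frac, b))
    table = pd.DataFrame(
        recs, columns=["gene", "n_neighbors", "frac_annotated", "bin"]
    ).set_index("gene")
    return NeighborStats(table=table)


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        return np.zeros_like(v, dtype=float)
    return (v - lo) / (hi - lo)


def combine_scores(
    prop: PropagationResult,
    candidates: CandidateList,
    stats: NeighborStats,
    phenotype_scores: Optional[pd.Series] = None,
    top_fraction: float = 0.20,
) -> CombinedScore:
    """Weighted additive fusion C = scale(p·E) + scale((1−p)·M).

    The bin prior p_b is the fraction of network genes in
    metabolic-first-neighbor bin b whose full-network propagated
    percentile is at most ``100·top_fraction`` — genes whose
    neighborhood alone makes a high propagation rank likely lean on the
    phenotype score instead.  E (external phenotype score; missing → 0
    with a warning) and M (propagated score) are each min–max scaled
    over the candidates, multiplied by their prior weights, and the two
    resulting terms are min–max scaled again before summing.  A
    constant term scales to 0, so the fusion degenerates to
    phenotype-only at p ≡ 1 and propagation-only at p ≡ 0.
    """
    # full-network percentile of every gene under the propagated score
    full = CandidateList(patient=candidates.patient, genes=list(prop.scores.index))
    full_rank = rank_candidates(prop.scores, full, method="propagation")
    top = full_rank.table["percentile"] <= 100.0 * top_fraction

    st = stats.table
    prior_by_bin = {}
    for b in range(10):
        genes_b = st.index[st["bin"] == b]
        if len(genes_b):
            prior_by_bin[b] = float(top.reindex(genes_b).fillna(False).mean())
        else:
            prior_by_bin[b] = 0.0

    genes = candidates.genes
    if phenotype_scores is None:
        phenotype_scores = candidates.phenotype_scores
    if phenotype_scores is None:
        phenotype_scores = pd.Series(0.0, index=genes)
        warnings.warn("no external phenotype scores given; treated as 0")
    else:
        missing = [g for g in genes if g not in phenotype_scores.index
                   or pd.isna(phenotype_scores.get(g))]
        if missing:
            warnings.warn(
                f"{len(missing)} candidate(s) lack a phenotype score, treated as 0"
            )
    E = phenotype_scores.reindex(genes).fillna(0.0).to_numpy(dtype=float)
    M = prop.scores.reindex(genes).fillna(0.0).to_numpy(dtype=float)

    bins = st["bin"].reindex(genes).fillna(0).astype(int)
    p = np.array([prior_by_bin[b] for b in bins])

    e_scaled = _minmax(E)
    m_scaled = _minmax(M)
    term_e = _minmax(p * e_scaled)
    term_m = _minmax((1.0 - p) * m_scaled)
    C = term_e + term_m

    table = pd.DataFrame(
        {
            "p": p,
            "e_scaled": e_scaled,
            "m_scaled": m_scaled,
            "term_e": term_e,
            "term_m": term_m,
            "C": C,
        },
        index=pd.Index(genes, name="gene"),
    )
    ranking = rank_candidates(pd.Series(C, index=genes), candidates, method="combined")
    return CombinedScore(table=table, ranking=ranking)
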