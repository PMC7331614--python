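"""Per-gene metabolic enrichment (ME) seed scores.

For each gene with at least one annotated measured metabolite, a
one-sided Fisher's exact (hypergeometric upper-tail) test asks whether
the patient's differentially abundant metabolites are over-represented
among the gene's annotated metabolites; Benjamini–Hochberg FDR is
reported alongside but the score itself uses the unadjusted p.  The ME
score couples the p-value with the largest-magnitude z of the gene's
metabolites and is scaled per patient to [0, 1] to serve as the seed
label for propagation.

Two scoring transforms are available.  ``neglog`` (default):
raw = −log2(p) · |z|_max, which grows both with the significance of the
enrichment and with the strength of the strongest metabolite signal.
``eq3_literal``: raw = −log2(2 + p) · |z|_max, a published variant kept
for strict reproduction; note it is negative and decreases as |z|_max
grows, so after min–max scaling it inverts the z ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .abundance import DAMSet, ZScoreTable
from .annotations import GeneMetaboliteMap

__all__ = ["EnrichmentResult", "SeedLabels", "fisher_enrichment", "bh_adjust", "me_score"]


@dataclass
class EnrichmentResult:
    """Per-gene enrichment table.

    Columns: ``k`` gene-annotated DAMs, ``m`` gene-annotated measured
    metabolites, ``K`` total DAMs in the universe, ``M`` universe size,
    ``p`` one-sided Fisher p, ``fdr`` BH-adjusted p, ``z_max`` largest
    |z| over the gene's measured metabolites.  ``untested`` lists genes
    with no annotated measured metabolite (m = 0).
    """

    table: pd.DataFrame
    untested: List[str]

    @property
    def genes(self) -> list:
        return list(self.table.index)


@dataclass
class SeedLabels:
    """Raw and [0,1]-scaled ME scores, the propagation seeds.

    Genes with k = 0 (no differentially abundant annotated metabolite)
    carry label exactly 0; when any gene has k >= 1 the best of them
    scales to exactly 1.
    """

    raw: pd.Series
    scaled: pd.Series
    mode: str

    def to_tsv(self, path) -> None:
        pd.DataFrame({"me_raw": self.raw, "me_scaled": self.scaled}).rename_axis(
            "gene"
        ).to_csv(path, sep="\t")


def fisher_enrichment(
    dams: DAMSet,
    measured: Iterable[str],
    gm_map: GeneMetaboliteMap,
    z: ZScoreTable = None,
) -> EnrichmentResult:
    """One-sided over-representation test of DAMs per gene.

    The metabolite universe is the measured metabolites annotated to at
    least one gene (unannotated features are filtered upstream).  For a
    gene with m annotated metabolites of which k are DAMs, in a universe
    of M metabolites containing K DAMs,
    p = P(X >= k), X ~ Hypergeometric(M, K, m).  BH adjustment is
    applied across all tested genes.  ``z`` supplies per-metabolite
    z-scores for the z_max column (0 if absent).
    """
    measured = set(measured)
    if not set(dams.members) <= measured:
        raise ValueError("DAM set must be a subset of the measured metabolites")

    annotated = gm_map.metabolites
    universe = measured & annotated
    dam_in_universe = dams.members & universe
    M = len(universe)
    K = len(dam_in_universe)

    rows = []
    untested = []
    for gene in sorted(gm_map.genes):
        gene_mets = gm_map.mets_of(gene) & universe
        m = len(gene_mets)
        if m == 0:
            untested.append(gene)
            continue
        k = len(gene_mets & dam_in_universe)
        # upper tail P(X >= k) = sf(k-1)
        p = float(hypergeom.sf(k - 1, M, K, m))
        p = min(p, 1.0)
        if z is not None:
            zs = [abs(float(z.z[met])) for met in gene_mets if met in z.z.index]
            z_max = max(zs) if zs else 0.0
        else:
            z_max = 0.0
        rows.append((gene, k, m, K, M, p, z_max))

    table = pd.DataFrame(
        rows, columns=["gene", "k", "m", "K", "M", "p", "z_max"]
    ).set_index("gene")
    if len(table):
        table["fdr"] = bh_adjust(table["p"].tolist())
    else:
        table["fdr"] = []
    table = table[["k", "m", "K", "M", "p", "fdr", "z_max"]]
    return EnrichmentResult(table=table, untested=untested)


def bh_adjust(pvalues: Sequence[float]) -> List[float]:
    """Benjamini–Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if not ((p > 0) & (p <= 1)).all():
        raise ValueError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in adj]


def me_score(enr: EnrichmentResult, mode: str = "neglog") -> SeedLabels:
    """Turn an enrichment table into [0,1] seed labels.

    Genes with k = 0 get raw and scaled ME of exactly 0 (no
    differentially abundant metabolite ⇒ no direct evidence).  Over the
    k >= 1 genes, ``neglog`` raw scores (all >= 0) are divided by their
    maximum so the strongest gene sits at 1 and positivity is preserved;
    the ``eq3_literal`` raw scores (all < 0) are min–max scaled.  If all
    k >= 1 raws coincide each scales to 1.
    """
    if mode not in ("neglog", "eq3_literal"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    t = enr.table
    genes = t.index
    k = t["k"].to_numpy()
    p = t["p"].to_numpy(dtype=float)
    z_max = t["z_max"].to_numpy(dtype=float)

    if mode == "neglog":
        raw = -np.log2(p) * z_max
    else:
        raw = -np.log2(2.0 + p) * z_max
    raw = np.where(k == 0, 0.0, raw)

    scaled = np.zeros_like(raw)
    active = k >= 1
    if active.any():
        vals = raw[active]
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            scaled[active] = 1.0
        elif mode == "neglog":
            scaled[active] = vals / hi if hi > 0 else 0.0
        else:
            scaled[active] = (vals - lo) / (hi - lo)
    return SeedLabels(
        raw=pd.Series(raw, index=genes),
        scaled=pd.Series(scaled, index=genes),
        mode=mode,
    )
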