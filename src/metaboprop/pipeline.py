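"""End-to-end orchestration: files in, ranked candidate genes out.

``run_score`` executes the whole chain — network loading and
normalization, gene→metabolite map, patient metabolomics (either a
curated metabolite z-score table or a raw feature table with control
samples), DAM calling, Fisher enrichment, seed scoring, label
propagation, candidate ranking and optional phenotype-score fusion —
and writes one TSV per stage plus a JSON run manifest.  ``run_permutations``
runs the seeded random-candidate-set benchmark for given causative genes.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .abundance import (
    FeatureTable,
    ZScoreTable,
    call_dams,
    linear_baseline_normalize,
    merge_zscore_tables,
    preprocess_features,
    zscore_patient,
)
from .annotations import filter_features, match_features, read_gene_metabolite_map
from .enrichment import fisher_enrichment, me_score
from .network import normalize, read_alias_map, read_network
from .propagation import PropagationConfig, propagate
from .ranking import (
    CandidateList,
    combine_scores,
    neighbor_stats,
    permutation_evaluate,
    rank_candidates,
)

__all__ = ["RunConfig", "run_score", "run_permutations", "StageError"]


class StageError(RuntimeError):
    """Pipeline failure, named after the stage that raised it."""


@dataclass
class RunConfig:
    """Validated configuration of one scoring run.

    ``metabolomics_kind`` selects the input path: ``"curated"`` reads a
    metabolite-ID × z-score TSV; ``"raw"`` reads a feature table
    (``feature_id  mz  mode  isotope  <sample columns>``) plus a sample-
    role sidecar and derives metabolite z-scores by preprocessing, log
    transform, baseline normalization, z-scoring and exact-mass
    annotation.
    """

    network: str
    gene_metabolite_map: str
    metabolomics: str
    candidates: Optional[str] = None
    output_dir: str = "metaboprop_out"
    sample_roles: Optional[str] = None
    alias_map: Optional[str] = None
    metabolomics_kind: str = "curated"  # "curated" | "raw"
    scoring_mode: str = "neglog"  # "neglog" | "eq3_literal"
    adduct_model: str = "neutral"  # "neutral" | "protonation"
    physical_only: bool = False
    min_weight: float = 0.0
    lam: float = 0.99
    tol: float = 1e-6
    max_iter: int = 10000
    ppm_tol: float = 15.0
    dam_threshold: float = 2.0
    top_fraction: float = 0.20
    do_preprocess: bool = True
    do_baseline_normalize: bool = True
    seed: int = 0
    patient: str = ""

    def __post_init__(self):
        if self.metabolomics_kind not in ("curated", "raw"):
            raise ValueError(f"unknown metabolomics_kind {self.metabolomics_kind!r}")
        if self.metabolomics_kind == "raw" and not self.sample_roles:
            raise ValueError("raw metabolomics input requires a sample_roles file")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _load_raw_zscores(cfg: RunConfig, gm_map):
    """Raw feature table → per-metabolite z-score table + measured set."""
    df = pd.read_csv(cfg.metabolomics, sep="\t", dtype={"feature_id": str})
    df = df.set_index("feature_id")
    roles = pd.read_csv(cfg.sample_roles, sep="\t", dtype=str)
    patients = roles.loc[roles["role"] == "patient", "sample"].tolist()
    if len(patients) != 1:
        raise StageError(f"abundance: expected exactly 1 patient sample, got {len(patients)}")
    patient = cfg.patient or patients[0]
    sample_cols = roles["sample"].tolist()

    meta_cols = [c for c in ("mz", "mode", "isotope") if c in df.columns]
    if "mz" not in meta_cols:
        raise StageError("abundance: raw feature table needs an 'mz' column")
    table = FeatureTable(values=df[sample_cols].astype(float), patient=patient)
    if cfg.do_preprocess:
        table = preprocess_features(table)
    table = table.log2()
    if cfg.do_baseline_normalize:
        table = linear_baseline_normalize(table)
    ztab = zscore_patient(table)

    kept = df.loc[df.index.intersection(ztab.z.index)]
    feats = [
        (fid, float(kept.loc[fid, "mz"]),
         str(kept.loc[fid, "mode"]) if "mode" in kept.columns else "neutral")
        for fid in kept.index
    ]
    annots = match_features(feats, gm_map, ppm_tol=cfg.ppm_tol,
                            adduct_model=cfg.adduct_model)
    ann_df = kept.copy()
    ann_df["n_matches"] = [a.n_matches for a in annots]
    ann_df["matches"] = [a.matches for a in annots]
    surviving = filter_features(ann_df)

    # collapse features → metabolites, keeping the largest-|z| feature
    per_met = {}
    for fid in surviving.index:
        zval = float(ztab.z[fid])
        for met in surviving.loc[fid, "matches"]:
            if met not in per_met or abs(zval) > abs(per_met[met]):
                per_met[met] = zval
    met_z = ZScoreTable(
        z=pd.Series(per_met, dtype=float).sort_index(), patient=patient
    )
    counts = {
        "features_total": int(len(df)),
        "features_scored": int(len(ztab.z)),
        "features_after_filters": int(len(surviving)),
        "metabolites_measured": int(len(met_z.z)),
    }
    return met_z, counts


def run_score(cfg: RunConfig) -> dict:
    """Execute the full scoring pipeline; returns a result bundle and
    writes per-stage TSVs plus ``manifest.json`` into ``cfg.output_dir``."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    try:
        alias = read_alias_map(cfg.alias_map) if cfg.alias_map else None
        net = read_network(cfg.network, min_weight=cfg.min_weight,
                           physical_only=cfg.physical_only, alias_map=alias)
        norm = normalize(net)
    except Exception as exc:
        raise StageError(f"network: {exc}") from exc
    counts["network_genes"] = net.n_nodes
    counts["network_edges"] = net.n_edges

    try:
        gm_map = read_gene_metabolite_map(cfg.gene_metabolite_map)
    except Exception as exc:
        raise StageError(f"annotations: {exc}") from exc
    counts["annotated_genes"] = len(gm_map.genes)

    try:
        if cfg.metabolomics_kind == "curated":
            ztab = ZScoreTable.from_tsv(cfg.metabolomics, patient=cfg.patient)
        else:
            ztab, raw_counts = _load_raw_zscores(cfg, gm_map)
            counts.update(raw_counts)
        dams = call_dams(ztab, threshold=cfg.dam_threshold)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"abundance: {exc}") from exc
    counts["metabolites_measured"] = len(ztab.z)
    counts["dams"] = len(dams)

    try:
        enr = fisher_enrichment(dams, ztab.ids, gm_map, z=ztab)
        seeds = me_score(enr, mode=cfg.scoring_mode)
    except Exception as exc:
        raise StageError(f"enrichment: {exc}") from exc
    counts["genes_tested"] = len(enr.table)
    counts["seeds_positive"] = int((seeds.scaled > 0).sum())

    try:
        prop = propagate(norm, seeds,
                         PropagationConfig(lam=cfg.lam, tol=cfg.tol,
                                           max_iter=cfg.max_iter))
    except Exception as exc:
        raise StageError(f"propagation: {exc}") from exc
    counts["propagation_iterations"] = prop.iterations

    enr.table.join(seeds.raw.rename("me_raw")).join(
        seeds.scaled.rename("me_scaled")
    ).rename_axis("gene").to_csv(out / "enrichment.tsv", sep="\t")
    prop.to_tsv(out / "propagated_scores.tsv")

    bundle = {"network": net, "normalized": norm, "map": gm_map, "zscores": ztab,
              "dams": dams, "enrichment": enr, "seeds": seeds, "propagation": prop,
              "counts": counts}

    if cfg.candidates:
        try:
            cand = CandidateList.from_tsv(cfg.candidates, patient=cfg.patient)
            me_rank = rank_candidates(seeds.scaled, cand, method="me")
            prop_rank = rank_candidates(prop.scores, cand, method="propagation")
            me_rank.to_tsv(out / "ranking_me.tsv")
            prop_rank.to_tsv(out / "ranking_propagation.tsv")
            bundle["ranking_me"] = me_rank
            bundle["ranking_propagation"] = prop_rank
            if cand.phenotype_scores is not None:
                stats = neighbor_stats(net, gm_map)
                combined = combine_scores(prop, cand, stats,
                                          top_fraction=cfg.top_fraction)
                pheno_rank = rank_candidates(cand.phenotype_scores, cand,
                                             method="phenotype")
                pheno_rank.to_tsv(out / "ranking_phenotype.tsv")
                combined.ranking.to_tsv(out / "ranking_combined.tsv")
                combined.table.rename_axis("gene").to_csv(
                    out / "combined_terms.tsv", sep="\t")
                bundle["ranking_phenotype"] = pheno_rank
                bundle["combined"] = combined
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"ranking: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "counts": counts,
    }
    with open(out / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=1)
    bundle["manifest"] = manifest
    return bundle


def run_permutations(
    cfg: RunConfig,
    causative: List[str],
    set_size: int = 300,
    n_perm: int = 1000,
) -> "pd.DataFrame":
    """Seeded permutation benchmark of the propagated scores for the
    given causative genes; writes ``permutations.tsv``."""
    bundle = run_score(cfg)
    prop = bundle["propagation"]
    universe = list(prop.scores.index)
    summary = permutation_evaluate(
        prop.scores, causative, universe,
        set_size=set_size, n_perm=n_perm, seed=cfg.seed,
    )
    rows = [
        {
            "gene": g,
            "median_rank": summary.median_rank[g],
            "set_size": set_size,
            "n_permutations": n_perm,
            "seed": cfg.seed,
            "top20": summary.median_rank[g] <= 0.2 * set_size,
        }
        for g in sorted(summary.median_rank)
    ]
    df = pd.DataFrame(rows)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "permutations.tsv", sep="\t", index=False)
    return df
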