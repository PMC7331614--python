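"""Synthetic networks, annotation maps and patients for end-to-end testing.

Everything here is generated code — no downloads.  The generator
emulates the data shapes the method consumes in practice: a STRING-like
weighted gene network (integer combined scores in [150, 999]), an
HMDB-like gene→metabolite map covering a fraction of the genes, curated
per-patient metabolite z-score tables and raw feature
tables with control samples (untargeted LC-MS style).  Patients are
planted with a known causative gene under three modes:

``direct``        the causative gene's own metabolites are shifted
                  (the gene shows direct metabolic enrichment);
``neighbor-only`` the causative gene is unannotated but at least three
                  of its first-degree neighbors have their metabolites
                  shifted — the regime where only propagation can
                  recover the gene;
``null``          a random unrelated gene's metabolites are shifted.

Background z-scores are standard normal; the default shift of 3 z-units
makes most planted metabolites differentially abundant (|z| >= 2) while
leaving a realistic false-positive background (P(|Z|>=2) ≈ 4.6%).
All generators are bit-reproducible given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .abundance import FeatureTable, ZScoreTable
from .annotations import GeneMetaboliteMap
from .network import Network

__all__ = [
    "SynthConfig",
    "make_network",
    "make_gene_metabolite_map",
    "make_patient",
    "make_raw_patient",
    "make_candidates",
    "write_fixture_dir",
]


@dataclass
class SynthConfig:
    """Knobs of the synthetic study.

    ``seed`` is mandatory; every generator derives its randomness from
    it.  Defaults model a small but structurally faithful cohort: a
    500-gene network at mean degree ~10, half the genes
    metabolite-annotated with 1–8 metabolites each, 20 control samples,
    and a 3-z-unit abundance shift for planted metabolites.
    """

    seed: int
    n_genes: int = 500
    edge_model: str = "er"  # "er" | "scale_free"
    er_p: float = 0.02
    ba_m: int = 3
    annotated_fraction: float = 0.5
    mets_per_gene: Tuple[int, int] = (1, 8)
    metabolite_sharing: float = 0.6  # pool size ≈ sharing · total slots
    n_controls: int = 20
    causative_mode: str = "neighbor-only"  # "direct" | "neighbor-only" | "null"
    effect: float = 3.0
    noise_sd: float = 1.0
    min_enriched_neighbors: int = 3
    # direct-mode causative genes need a detectable biomarker set, mirroring
    # benchmark cohorts that exclude disorders with no measurable biomarkers
    min_causative_mets: int = 3

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.annotated_fraction <= 1:
            raise ValueError("annotated_fraction must lie in (0, 1]")
        if self.n_genes < 10:
            raise ValueError("need at least 10 genes")
        if self.causative_mode not in ("direct", "neighbor-only", "null"):
            raise ValueError(f"unknown causative_mode {self.causative_mode!r}")


def _gene_names(n: int):
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def make_network(cfg: SynthConfig) -> Network:
    """STRING-like weighted graph, deterministic under the seed."""
    rng = np.random.default_rng(cfg.seed)
    names = _gene_names(cfg.n_genes)
    if cfg.edge_model == "er":
        g = nx.gnp_random_graph(cfg.n_genes, cfg.er_p, seed=int(rng.integers(2**31)))
    elif cfg.edge_model == "scale_free":
        g = nx.barabasi_albert_graph(cfg.n_genes, cfg.ba_m,
                                     seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown edge_model {cfg.edge_model!r}")

    edges = sorted((min(u, v), max(u, v)) for u, v in g.edges())
    weights = rng.integers(150, 1000, size=len(edges))
    rows = [
        (names[u], names[v], int(w)) for (u, v), w in zip(edges, weights)
    ]
    df = pd.DataFrame(rows, columns=["gene1", "gene2", "weight"])
    df = df.sort_values(["gene1", "gene2"]).reset_index(drop=True)
    isolated = tuple(names[i] for i in range(cfg.n_genes) if g.degree(i) == 0)
    return Network(edges=df, extra_nodes=isolated)


def make_gene_metabolite_map(cfg: SynthConfig, net: Network) -> GeneMetaboliteMap:
    """HMDB-like map: a fraction of genes annotated with 1–8 metabolites
    drawn from a shared pool (metabolites are shared between genes, as
    pathway neighbors share substrates)."""
    rng = np.random.default_rng(cfg.seed + 1)
    nodes = list(net.nodes)
    n_annot = max(1, int(round(cfg.annotated_fraction * len(nodes))))
    annotated = sorted(rng.choice(len(nodes), size=n_annot, replace=False))
    lo, hi = cfg.mets_per_gene
    sizes = rng.integers(lo, hi + 1, size=n_annot)
    pool_n = max(int(cfg.metabolite_sharing * int(sizes.sum())), int(sizes.max()), 10)
    met_ids = [f"HMDB{i:07d}" for i in range(1, pool_n + 1)]
    masses = {m: float(np.round(rng.uniform(80.0, 900.0), 4)) for m in met_ids}

    gene_to_mets = {}
    for gi, sz in zip(annotated, sizes):
        mets = rng.choice(pool_n, size=int(sz), replace=False)
        gene_to_mets[nodes[gi]] = {met_ids[j] for j in mets}
    return GeneMetaboliteMap(gene_to_mets, masses, provenance="synthetic")


def _pick_causative(cfg, net, gm_map, rng):
    nodes = list(net.nodes)
    annotated = gm_map.genes
    if cfg.causative_mode == "direct":
        pool = sorted(g for g in annotated
                      if len(gm_map.mets_of(g)) >= cfg.min_causative_mets)
        if not pool:
            raise ValueError(
                "no annotated gene has enough metabolites to plant a "
                "direct causative gene"
            )
        return str(rng.choice(pool)), None
    if cfg.causative_mode == "null":
        causative = str(rng.choice(nodes))
        others = sorted(annotated - {causative})
        if not others:
            raise ValueError("no unrelated annotated gene for null mode")
        return causative, str(rng.choice(others))
    # neighbor-only: unannotated gene with enough annotated neighbors
    eligible = []
    for g in nodes:
        if g in annotated:
            continue
        ann_nb = sorted(net.neighbors(g) & annotated)
        if len(ann_nb) >= cfg.min_enriched_neighbors:
            eligible.append(g)
    if not eligible:
        raise ValueError(
            "no unannotated gene with enough annotated neighbors; "
            "increase density or annotated_fraction"
        )
    return str(rng.choice(sorted(eligible))), None


def make_patient(
    cfg: SynthConfig, net: Network, gm_map: GeneMetaboliteMap
) -> Tuple[ZScoreTable, str, dict]:
    """Curated patient: metabolite z-score table plus the
    planted truth record."""
    rng = np.random.default_rng(cfg.seed + 2)
    met_ids = sorted(gm_map.met_masses)
    z = rng.normal(0.0, cfg.noise_sd, size=len(met_ids))
    zs = pd.Series(z, index=met_ids)

    causative, surrogate = _pick_causative(cfg, net, gm_map, rng)
    if cfg.causative_mode == "direct":
        shifted_genes = [causative]
    elif cfg.causative_mode == "null":
        shifted_genes = [surrogate]
    else:
        ann_nb = sorted(net.neighbors(causative) & gm_map.genes)
        shifted_genes = ann_nb  # all annotated first neighbors

    shifted_mets = set()
    for g in shifted_genes:
        shifted_mets |= gm_map.mets_of(g)
    signs = rng.choice([-1.0, 1.0], size=len(shifted_mets))
    for met, s in zip(sorted(shifted_mets), signs):
        zs[met] += s * cfg.effect

    truth = {
        "mode": cfg.causative_mode,
        "causative": causative,
        "shifted_genes": list(shifted_genes),
        "shifted_metabolites": sorted(shifted_mets),
        "effect": cfg.effect,
        "seed": cfg.seed,
    }
    patient_id = f"P{cfg.seed}"
    return ZScoreTable(z=zs, patient=patient_id), causative, truth


def make_raw_patient(
    cfg: SynthConfig, net: Network, gm_map: GeneMetaboliteMap
) -> Tuple[FeatureTable, str, dict]:
    """Raw (untargeted LC-MS style) patient: features × samples intensity
    table whose features carry the metabolite monoisotopic masses as m/z
    (neutral presentation), one patient column plus controls.

    The planted z-shifts are injected on the log2 scale, so running the
    table through log transform and z-scoring recovers them up to
    sampling noise.
    """
    ztab, causative, truth = make_patient(cfg, net, gm_map)
    rng = np.random.default_rng(cfg.seed + 3)
    met_ids = list(ztab.z.index)
    n = cfg.n_controls
    patient_id = ztab.patient
    cols = [patient_id] + [f"C{j:02d}" for j in range(1, n + 1)]

    mu = rng.uniform(12.0, 20.0, size=len(met_ids))  # log2-intensity baselines
    data = np.empty((len(met_ids), n + 1))
    ctrl = rng.normal(0.0, 1.0, size=(len(met_ids), n))
    data[:, 1:] = mu[:, None] + ctrl
    data[:, 0] = mu + ztab.z.to_numpy()
    intensities = np.power(2.0, data)

    feat_ids = [f"F{i:05d}" for i in range(1, len(met_ids) + 1)]
    values = pd.DataFrame(intensities, index=feat_ids, columns=cols)
    mz = pd.Series([gm_map.met_masses[m] for m in met_ids], index=feat_ids)
    truth = dict(truth)
    truth["feature_to_metabolite"] = dict(zip(feat_ids, met_ids))
    table = FeatureTable(values=values, patient=patient_id, log_transformed=False)
    table.mz = mz  # observed m/z sidecar
    return table, causative, truth


def make_candidates(
    net: Network,
    causative: str,
    n_candidates: int = 300,
    seed: int = 0,
    with_phenotype: bool = True,
    patient: str = "P",
):
    """Random candidate list containing the causative gene, with optional
    uniform phenotype scores."""
    from .ranking import CandidateList

    rng = np.random.default_rng(seed)
    pool = sorted(set(net.nodes) - {causative})
    k = min(n_candidates - 1, len(pool))
    drawn = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
    genes = [causative] + drawn
    order = rng.permutation(len(genes))
    genes = [genes[i] for i in order]
    pheno = None
    if with_phenotype:
        pheno = pd.Series(rng.uniform(0.0, 1.0, size=len(genes)), index=genes)
    return CandidateList(patient=patient, genes=genes, phenotype_scores=pheno)


def write_fixture_dir(cfg: SynthConfig, out_dir, n_candidates: int = 300) -> dict:
    """Emit a complete fixture directory: network TSV, map TSV, curated
    z-score TSV, raw feature TSV + sample-role sidecar, candidate TSV
    and truth JSON.  Returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = make_network(cfg)
    gm_map = make_gene_metabolite_map(cfg, net)
    ztab, causative, truth = make_patient(cfg, net, gm_map)
    raw, _, raw_truth = make_raw_patient(cfg, net, gm_map)
    cand = make_candidates(net, causative, n_candidates=n_candidates,
                           seed=cfg.seed + 4, patient=ztab.patient)

    paths = {
        "network": out / "network.tsv",
        "map": out / "gene_metabolites.tsv",
        "zscores": out / "patient_zscores.tsv",
        "features": out / "patient_features.tsv",
        "roles": out / "sample_roles.tsv",
        "candidates": out / "candidates.tsv",
        "truth": out / "truth.json",
    }
    net.to_tsv(paths["network"])
    gm_map.to_tsv(paths["map"])
    ztab.to_tsv(paths["zscores"])

    feat = raw.values.copy()
    feat.insert(0, "mz", raw.mz)
    feat.insert(1, "mode", "neutral")
    feat.insert(2, "isotope", "[M]")
    feat.rename_axis("feature_id").to_csv(paths["features"], sep="\t")
    roles = pd.DataFrame(
        {
            "sample": list(raw.values.columns),
            "role": ["patient"] + ["control"] * (raw.values.shape[1] - 1),
            "biofluid": raw.biofluid,
        }
    )
    roles.to_csv(paths["roles"], sep="\t", index=False)

    cand_df = pd.DataFrame({"gene": cand.genes})
    if cand.phenotype_scores is not None:
        cand_df["exomiser_phenotype_score"] = (
            cand.phenotype_scores.reindex(cand.genes).to_numpy()
        )
    cand_df.to_csv(paths["candidates"], sep="\t", index=False)

    truth_out = dict(truth)
    truth_out["raw_feature_to_metabolite"] = raw_truth["feature_to_metabolite"]
    truth_out["config"] = asdict(cfg)
    with open(paths["truth"], "wt") as fh:
        json.dump(truth_out, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
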