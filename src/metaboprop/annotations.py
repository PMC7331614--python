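"""Gene→metabolite annotations and exact-mass feature matching.

Annotations map gene symbols to sets of metabolite accessions (HMDB-style)
with monoisotopic masses.  Observed m/z features are matched to all
metabolite identities within a ppm tolerance (default 15 ppm), optionally
under a ± proton adduct model, and feature tables are filtered by the two
standard untargeted-metabolomics rules: drop features with no metabolite
annotation and drop non-base isotopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "GeneMetaboliteMap",
    "FeatureAnnotation",
    "read_gene_metabolite_map",
    "match_features",
    "filter_features",
    "PROTON_MASS",
]

PROTON_MASS = 1.007276  # Da


@dataclass
class GeneMetaboliteMap:
    """gene symbol → set of metabolite IDs, plus metabolite masses (Da)."""

    gene_to_mets: dict
    met_masses: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        for g, mets in self.gene_to_mets.items():
            if not mets:
                raise ValueError(f"gene {g!r} has an empty metabolite set")
        for m, mass in self.met_masses.items():
            if not mass > 0:
                raise ValueError(f"metabolite {m!r} has non-positive mass {mass}")

    @property
    def genes(self) -> set:
        return set(self.gene_to_mets)

    @property
    def metabolites(self) -> set:
        out = set()
        for mets in self.gene_to_mets.values():
            out |= mets
        return out

    def mets_of(self, gene: str) -> set:
        return set(self.gene_to_mets.get(gene, set()))

    def genes_of(self, metabolite: str) -> set:
        return {g for g, mets in self.gene_to_mets.items() if metabolite in mets}

    def mass_unknown(self) -> set:
        """Metabolite IDs annotated to genes but lacking a mass."""
        return self.metabolites - set(self.met_masses)

    def to_tsv(self, path) -> None:
        rows = []
        for g in sorted(self.gene_to_mets):
            for m in sorted(self.gene_to_mets[g]):
                rows.append((g, m, self.met_masses.get(m, np.nan)))
        pd.DataFrame(rows, columns=["gene", "metabolite_id", "monoisotopic_mass"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class FeatureAnnotation:
    """One m/z feature with its metabolite identity matches."""

    feature_id: str
    mz: float
    mode: str  # positive | negative | neutral
    matches: List[str] = field(default_factory=list)
    ppm_errors: List[float] = field(default_factory=list)

    @property
    def n_matches(self) -> int:
        return len(self.matches)


def _read_map_tsv(source) -> GeneMetaboliteMap:
    df = pd.read_csv(source, sep="\t", dtype={"gene": str, "metabolite_id": str})
    required = {"gene", "metabolite_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene-metabolite TSV needs columns {sorted(required)}")
    gene_to_mets: dict = {}
    met_masses: dict = {}
    for _, row in df.iterrows():
        gene = row["gene"]
        met = row["metabolite_id"]
        if pd.isna(met) or (isinstance(met, str) and not met.strip()):
            warnings.warn(f"gene {gene!r}: empty metabolite field, row skipped")
            continue
        gene_to_mets.setdefault(gene, set()).add(met)
        if "monoisotopic_mass" in df.columns and pd.notna(row["monoisotopic_mass"]):
            mass = float(row["monoisotopic_mass"])
            if mass <= 0:
                raise ValueError(
                    f"metabolite {met!r} has non-positive monoisotopic mass {mass}"
                )
            met_masses[met] = mass
    gene_to_mets = {g: s for g, s in gene_to_mets.items() if s}
    return GeneMetaboliteMap(gene_to_mets, met_masses, provenance=str(source))


def _read_map_xml(source) -> GeneMetaboliteMap:
    """Reduced HMDB-export XML: per <metabolite> an accession, a
    monoisotopic mass and the associated gene symbols."""
    tree = etree.parse(source)
    root = tree.getroot()
    # tolerate a default namespace
    ns = root.nsmap.get(None)
    def tag(name):
        return f"{{{ns}}}{name}" if ns else name

    gene_to_mets: dict = {}
    met_masses: dict = {}
    for met in root.iter(tag("metabolite")):
        acc_el = met.find(tag("accession"))
        if acc_el is None or not (acc_el.text or "").strip():
            continue
        acc = acc_el.text.strip()
        mass_el = met.find(tag("monisotopic_molecular_weight"))
        if mass_el is None:
            mass_el = met.find(tag("monoisotopic_mass"))
        if mass_el is not None and (mass_el.text or "").strip():
            mass = float(mass_el.text)
            if mass <= 0:
                raise ValueError(f"metabolite {acc!r} has non-positive mass {mass}")
            met_masses[acc] = mass
        for gene_el in met.iter(tag("gene_name")):
            gname = (gene_el.text or "").strip()
            if gname:
                gene_to_mets.setdefault(gname, set()).add(acc)
    return GeneMetaboliteMap(gene_to_mets, met_masses, provenance=str(source))


def read_gene_metabolite_map(source, dialect: Optional[str] = None) -> GeneMetaboliteMap:
    """Read gene→metabolite annotations from TSV or reduced HMDB XML.

    TSV columns: ``gene``, ``metabolite_id``, optional ``monoisotopic_mass``.
    Duplicate rows union (set semantics).  The dialect is sniffed from the
    filename unless given explicitly (``"tsv"`` or ``"xml"``).
    """
    if dialect is None:
        name = getattr(source, "name", str(source))
        dialect = "xml" if str(name).lower().endswith(".xml") else "tsv"
    if dialect == "xml":
        return _read_map_xml(source)
    if dialect == "tsv":
        return _read_map_tsv(source)
    raise ValueError(f"unknown dialect {dialect!r}")


def match_features(
    features: Sequence[Tuple[str, float, str]],
    gm_map: GeneMetaboliteMap,
    ppm_tol: float = 15.0,
    adduct_model: str = "neutral",
) -> List[FeatureAnnotation]:
    """Match observed m/z values to metabolite identities by exact mass.

    Under ``adduct_model="neutral"`` the candidate mass is the metabolite
    monoisotopic mass; under ``"protonation"`` it is mass + 1.007276 Da in
    positive mode and mass − 1.007276 Da in negative mode ([M+H]+ / [M−H]−).
    A feature matches a metabolite iff
    ``|observed − candidate| / candidate * 1e6 <= ppm_tol`` (inclusive);
    every qualifying ID is retained, so one feature may carry many
    identities.
    """
    if not ppm_tol > 0:
        raise ValueError("ppm_tol must be positive")
    if adduct_model not in ("neutral", "protonation"):
        raise ValueError(f"unknown adduct_model {adduct_model!r}")

    met_ids = sorted(m for m in gm_map.met_masses)
    masses = np.array([gm_map.met_masses[m] for m in met_ids], dtype=float)

    out = []
    for feature_id, mz, mode in features:
        if mode not in ("positive", "negative", "neutral"):
            raise ValueError(f"feature {feature_id!r}: unknown ionization mode {mode!r}")
        if adduct_model == "neutral" or mode == "neutral":
            candidate = masses
        elif mode == "positive":
            candidate = masses + PROTON_MASS
        else:
            candidate = masses - PROTON_MASS
        with np.errstate(divide="ignore", invalid="ignore"):
            ppm = np.abs(mz - candidate) / candidate * 1e6
        # inclusive boundary; 1e-9 ppm guard absorbs float representation noise
        hit = np.flatnonzero((candidate > 0) & (ppm <= ppm_tol + 1e-9))
        out.append(
            FeatureAnnotation(
                feature_id=feature_id,
                mz=float(mz),
                mode=mode,
                matches=[met_ids[i] for i in hit],
                ppm_errors=[float(ppm[i]) for i in hit],
            )
        )
    return out


def _is_non_base_isotope(flag) -> bool:
    """CAMERA-style isotope annotation: '[M+1]', '[M+2]' ... are non-base;
    empty, '[M]' or '[M+0]' are base."""
    if flag is None or (isinstance(flag, float) and np.isnan(flag)):
        return False
    s = str(flag).strip()
    if not s or s.lower() in ("na", "none"):
        return False
    import re

    m = re.search(r"\[M\+?(\d+)\]", s)
    if m:
        return int(m.group(1)) > 0
    return False


def filter_features(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the two pre-enrichment feature filters.

    Removes (1) features with zero metabolite matches (``n_matches`` or a
    ``matches`` list column) and (2) features whose ``isotope`` column
    marks a non-base isotope.  Row order is otherwise preserved.
    """
    keep = pd.Series(True, index=table.index)
    if "n_matches" in table.columns:
        keep &= table["n_matches"] > 0
    elif "matches" in table.columns:
        keep &= table["matches"].map(lambda m: len(m) > 0)
    if "isotope" in table.columns:
        keep &= ~table["isotope"].map(_is_non_base_isotope)
    return table[keep]
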