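"""Intensity tables → per-patient metabolite z-scores → DAM sets.

A :class:`FeatureTable` holds a features × samples intensity matrix for a
single biofluid, with one patient and a set of control samples.  The
processing chain mirrors the standard untargeted-metabolomics recipe:
per-sample median scaling with minimum-intensity imputation and a 10%
prevalence filter, linear baseline normalization of the log intensities
(each run treated as a scalar multiple of the median baseline profile),
per-feature z-scoring against all samples, and calling differentially
abundant metabolites (DAMs) at |z| >= 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "ZScoreTable",
    "DAMSet",
    "preprocess_features",
    "linear_baseline_normalize",
    "zscore_patient",
    "call_dams",
    "merge_zscore_tables",
]


@dataclass
class FeatureTable:
    """Features × samples intensity matrix with sample roles.

    ``values`` is a DataFrame indexed by feature/metabolite ID with one
    column per sample; missing intensities are NaN.  ``patient`` names
    the single patient column, all other columns are controls.
    ``biofluid`` tags the matrix (tables from different biofluids are
    never mixed).  ``log_transformed`` records whether values are on the
    log scale expected by baseline normalization.
    """

    values: pd.DataFrame
    patient: str
    biofluid: str = "plasma"
    log_transformed: bool = False

    def __post_init__(self):
        if self.patient not in self.values.columns:
            raise ValueError(f"patient sample {self.patient!r} not in table columns")
        if (self.values.fillna(0) < 0).to_numpy().any() and not self.log_transformed:
            raise ValueError("raw intensities must be non-negative")
        if not self.values.index.is_unique:
            raise ValueError("feature IDs must be unique")

    @property
    def controls(self) -> list:
        return [c for c in self.values.columns if c != self.patient]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def log2(self) -> "FeatureTable":
        """log2(x + 1) transform of a raw table."""
        if self.log_transformed:
            return self
        return FeatureTable(
            values=np.log2(self.values + 1.0),
            patient=self.patient,
            biofluid=self.biofluid,
            log_transformed=True,
        )


@dataclass
class ZScoreTable:
    """metabolite/feature ID → z-score for one patient."""

    z: pd.Series
    patient: str = ""

    def __post_init__(self):
        if not self.z.index.is_unique:
            raise ValueError("IDs must be unique")
        if not np.isfinite(self.z.to_numpy(dtype=float)).all():
            raise ValueError("z-scores must be finite")

    @property
    def ids(self) -> set:
        return set(self.z.index)

    def to_tsv(self, path) -> None:
        self.z.rename("z").rename_axis("metabolite_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, source, patient: str = "") -> "ZScoreTable":
        df = pd.read_csv(source, sep="\t")
        df = df.set_index(df.columns[0])
        df.index = df.index.astype(str)
        return cls(z=df.iloc[:, 0].astype(float), patient=patient)


@dataclass
class DAMSet:
    """Differentially abundant metabolites: IDs with |z| >= threshold."""

    members: set
    threshold: float
    direction: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if set(self.direction) != set(self.members):
            raise ValueError("direction must be recorded for every member")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item) -> bool:
        return item in self.members


def preprocess_features(table: FeatureTable, min_prevalence: float = 0.10) -> FeatureTable:
    """Median scaling, minimum-intensity imputation, prevalence filter.

    Each sample is scaled so its median detected intensity equals the
    grand median of the per-sample medians; missing values are imputed
    with the feature's minimum detected (scaled) intensity; features
    detected in fewer than ``min_prevalence`` of samples are removed
    (inclusive boundary: a feature seen in exactly 10% of samples is
    kept).
    """
    v = table.values.copy().astype(float)
    detected = v.notna()

    all_missing = ~detected.any(axis=1)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} feature(s) missing in all samples, removed"
        )
        v = v[~all_missing]
        detected = detected[~all_missing]

    medians = v.median(axis=0, skipna=True)
    grand = float(np.median(medians))
    if (medians <= 0).any():
        raise ValueError("sample with non-positive median intensity")
    v = v / medians * grand

    # prevalence filter on detection before imputation
    prevalence = detected.mean(axis=1)
    keep = prevalence >= min_prevalence - 1e-12
    v = v[keep]

    row_min = v.min(axis=1, skipna=True)
    v = v.apply(lambda col: col.fillna(row_min))

    return FeatureTable(values=v, patient=table.patient, biofluid=table.biofluid,
                        log_transformed=table.log_transformed)


def linear_baseline_normalize(table: FeatureTable) -> FeatureTable:
    """Linear baseline normalization of log intensities.

    The baseline profile is the per-feature median across samples; each
    sample j is rescaled by beta_j = mean(baseline) / mean(sample j), so
    every run becomes a scalar multiple of the shared baseline and all
    per-sample means equal the baseline mean afterwards.
    """
    if not table.log_transformed:
        raise ValueError("baseline normalization expects a log-transformed table")
    v = table.values
    baseline = v.median(axis=1)
    sample_means = v.mean(axis=0)
    if (sample_means == 0).any():
        raise ValueError("sample with zero mean intensity")
    beta = float(baseline.mean()) / sample_means
    return FeatureTable(values=v * beta, patient=table.patient,
                        biofluid=table.biofluid, log_transformed=True)


def zscore_patient(
    table: FeatureTable,
    patient: Optional[str] = None,
    include_patient: bool = True,
) -> ZScoreTable:
    """Per-feature z-score of the patient against the sample population.

    z = (x_patient − mean) / sd with the sample (n−1) standard deviation;
    by default the patient is included in the mean/sd population, with a
    leave-patient-out mode available.  Zero-variance features have no
    defined z and are dropped with a warning.
    """
    patient = patient or table.patient
    v = table.values
    if v.shape[1] < 3:
        raise ValueError("z-scoring needs at least 3 samples")
    if patient not in v.columns:
        raise ValueError(f"unknown patient sample {patient!r}")

    pop = v if include_patient else v.drop(columns=[patient])
    mean = pop.mean(axis=1)
    sd = pop.std(axis=1, ddof=1)

    zero_sd = sd == 0
    if zero_sd.any():
        warnings.warn(f"{int(zero_sd.sum())} constant feature(s) dropped (zero sd)")
    z = (v[patient] - mean) / sd
    z = z[~zero_sd].dropna()
    return ZScoreTable(z=z, patient=patient)


def call_dams(z: ZScoreTable, threshold: float = 2.0) -> DAMSet:
    """IDs with |z| >= threshold (inclusive), with the sign recorded."""
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    mask = z.z.abs() >= threshold
    members = set(z.z.index[mask])
    direction = {m: int(np.sign(z.z[m])) for m in members}
    return DAMSet(members=members, threshold=threshold, direction=direction)


def merge_zscore_tables(*tables: ZScoreTable) -> ZScoreTable:
    """Union z-score tables (e.g. positive and negative ionization modes),
    keeping the largest-magnitude z for duplicate metabolite IDs."""
    if not tables:
        raise ValueError("need at least one table")
    df = pd.concat([t.z for t in tables]).rename("z").rename_axis("id").reset_index()
    df = (
        df.assign(absz=df["z"].abs())
        .sort_values("absz", ascending=False, kind="stable")
        .drop_duplicates(subset="id", keep="first")
        .sort_values("id")
    )
    best = pd.Series(df["z"].to_numpy(), index=df["id"].to_numpy())
    return ZScoreTable(z=best, patient=tables[0].patient)
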