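"""Core data containers shared across the analysis modules.

The package models one trial's worth of biomarker data: a clinical table
(one row per infused patient), longitudinal serum cytokines with
left-censoring at the assay LLOQ, gated flow-cytometry count tables for the
infused product, transgene qPCR expansion series, and an nCounter-style
expression experiment on tumor biopsies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

LDR_LEVELS = ("standard_fluCy", "cy_only", "reduced_fluCy")
BEST_RESPONSES = ("CR", "PR", "SD", "PD", "NE")
MEMORY_PHENOTYPES = ("Naive", "TSCM", "CM", "EM", "TEMRA")
PENTAMER_PARENTS = ("CD4Pent", "CD8Pent")
PROBE_CLASSES = ("Endogenous", "Housekeeping", "Positive", "Negative")


class ConfigError(ValueError):
    """Raised for invalid simulation or analysis configuration."""


@dataclass
class PatientRecord:
    """Clinical covariates and endpoints for one infused subject.

    ``responder`` is always consistent with ``best_response``: responders are
    exactly the patients with a confirmed complete or partial response.
    """

    patient_id: str
    cohort: int
    ldr: str
    weight_kg: float
    transduced_cell_dose: float
    responder: bool
    best_response: str
    pfs_days: float
    pfs_event: bool
    os_days: float
    os_event: bool

    def __post_init__(self) -> None:
        if self.cohort not in (1, 2, 3, 4):
            raise ValueError(f"cohort must be 1-4, got {self.cohort}")
        if self.ldr not in LDR_LEVELS:
            raise ValueError(f"unknown LDR {self.ldr!r}")
        if self.best_response not in BEST_RESPONSES:
            raise ValueError(f"unknown best response {self.best_response!r}")
        if self.responder != (self.best_response in ("CR", "PR")):
            raise ValueError("responder flag inconsistent with best_response")
        if self.weight_kg <= 0:
            raise ValueError("weight must be positive")
        if min(self.pfs_days, self.os_days) < 0:
            raise ValueError("survival durations must be non-negative")


def patients_frame(patients: list[PatientRecord]) -> pd.DataFrame:
    """Tabulate patient records as one DataFrame row per subject."""
    return pd.DataFrame([vars(p) for p in patients]).set_index(
        "patient_id", drop=False
    )


@dataclass
class FlowPanelCounts:
    """Gated cell counts and frequencies-of-parent for one sample x panel.

    ``pop_counts``/``pop_freqs`` are keyed by population name. Pentamer
    parents are named ``CD4Pent``/``CD8Pent`` (frequency of viable CD3+);
    memory children are ``<parent>/<phenotype>`` (frequency of the parent).
    Missing values (e.g. after flooring) are ``nan``.
    """

    sample_id: str
    panel: str
    viable_cd3_count: float
    pop_counts: dict[str, float] = field(default_factory=dict)
    pop_freqs: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "FlowPanelCounts":
        return FlowPanelCounts(
            self.sample_id,
            self.panel,
            self.viable_cd3_count,
            dict(self.pop_counts),
            dict(self.pop_freqs),
        )


@dataclass
class PhenotypeDose:
    """Absolute number of transduced cells of one memory phenotype infused."""

    patient_id: str
    phenotype: str
    parent: str
    n_cells: float
    n_cells_per_kg: float


@dataclass
class ExpansionSeries:
    """Transgene qPCR time series (copies per microgram genomic DNA)."""

    patient_id: str
    days: np.ndarray
    copies_per_ug: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.copies_per_ug = np.asarray(self.copies_per_ug, dtype=float)
        if self.days.shape != self.copies_per_ug.shape:
            raise ValueError("days and copies must align")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.copies_per_ug < 0) or np.any(self.days < 0):
            raise ValueError("days and copies must be non-negative")


@dataclass
class ExpansionSummary:
    patient_id: str
    cmax: float
    tmax_day: float
    auc_0_28: float
    persistence_wk4: float  # nan when no sample within the window


@dataclass
class ExpressionExperiment:
    """Probe-class-annotated count matrix with sample annotations.

    ``genes``: index = gene symbol, columns ``code_class`` (one of
    Endogenous/Housekeeping/Positive/Negative) and ``panel``.
    ``samples``: index = sample id, columns ``patient_id``, ``timepoint``
    (``pre``/``progression``) and ``responder``.
    ``raw_counts``: genes x samples non-negative integers.
    ``norm_log2`` is absent (None) until :func:`normalize_counts` runs.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame
    raw_counts: pd.DataFrame
    norm_log2: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.raw_counts.index.equals(self.genes.index):
            raise ValueError("raw_counts rows must match gene table")
        if not self.raw_counts.columns.equals(self.samples.index):
            raise ValueError("raw_counts columns must match sample table")
        vals = self.raw_counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("raw counts must be non-negative integers")
        bad = set(self.genes["code_class"]) - set(PROBE_CLASSES)
        if bad:
            raise ValueError(f"unknown probe classes: {sorted(bad)}")

    def class_genes(self, code_class: str) -> pd.Index:
        return self.genes.index[self.genes["code_class"] == code_class]

    def endogenous_log2(self) -> pd.DataFrame:
        if self.norm_log2 is None:
            raise ValueError("experiment is not normalized yet")
        return self.norm_log2.loc[self.class_genes("Endogenous")]


@dataclass
class GeneSet:
    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")


@dataclass
class TrialDataset:
    """All data domains for one (synthetic or real) trial, linked by patient id."""

    patients: list[PatientRecord]
    cytokines: pd.DataFrame  # patient_id, analyte, day, value, lloq, censored
    flow: list[FlowPanelCounts]
    noise_levels: dict[str, float]
    expansion: pd.DataFrame  # patient_id, day, copies_per_ug
    expression: ExpressionExperiment
    truth: dict = field(default_factory=dict)

    @property
    def patients_frame(self) -> pd.DataFrame:
        return patients_frame(self.patients)
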