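"""Flow-cytometry post-processing for the infused T-cell product.

Implements the post-gating rules: a viable-CD3 QC filter across both
phenotyping panels, flooring of pentamer parent gates that fall below the
healthy-donor negative-control noise level, the CD4/CD8 pentamer split, and
inference of absolute transduced cell numbers per memory phenotype from the
infused dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    FlowPanelCounts,
    MEMORY_PHENOTYPES,
    PENTAMER_PARENTS,
    PatientRecord,
    PhenotypeDose,
)


@dataclass
class QCRejection:
    sample_id: str
    reason: str


def qc_filter_samples(
    samples: list[FlowPanelCounts], min_viable: int = 5000
) -> tuple[list[FlowPanelCounts], list[QCRejection]]:
    """Drop samples with < ``min_viable`` viable CD3+ cells in either panel.

    A sample id is retained iff viable CD3 >= min_viable in BOTH panels; ids
    missing one of the two panels are treated as incomplete and rejected.
    Returns (retained samples, rejection log).
    """
    by_id: dict[str, dict[str, FlowPanelCounts]] = {}
    for s in samples:
        by_id.setdefault(s.sample_id, {})[s.panel] = s
    retained: list[FlowPanelCounts] = []
    rejections: list[QCRejection] = []
    kept_ids = set()
    for sid, panels in by_id.items():
        missing = {"Pheno1", "Pheno2"} - set(panels)
        if missing:
            rejections.append(QCRejection(sid, f"missing panel(s): {sorted(missing)}"))
            continue
        low = [p for p, s in panels.items() if s.viable_cd3_count < min_viable]
        if low:
            counts = {p: panels[p].viable_cd3_count for p in sorted(low)}
            rejections.append(
                QCRejection(sid, f"viable CD3 < {min_viable} in {counts}")
            )
            continue
        kept_ids.add(sid)
    for s in samples:
        if s.sample_id in kept_ids:
            retained.append(s)
    return retained, rejections


def floor_pentamer_frequencies(
    sample: FlowPanelCounts, noise: dict[str, float]
) -> FlowPanelCounts:
    """Floor pentamer parent gates below the negative-control noise level.

    For each pentamer parent (CD4Pent, CD8Pent, separately) whose frequency
    is strictly below its noise level, the parent frequency and count are set
    to 0 and all child memory-subset values to missing (NaN). Other
    populations are untouched. Idempotent; the input sample is not modified.
    """
    out = sample.copy()
    for parent in PENTAMER_PARENTS:
        if parent not in out.pop_freqs:
            continue
        if parent not in noise:
            raise ValueError(f"no noise level for pentamer parent {parent!r}")
        if out.pop_freqs[parent] < noise[parent]:
            out.pop_freqs[parent] = 0.0
            out.pop_counts[parent] = 0.0
            for pheno in MEMORY_PHENOTYPES:
                child = f"{parent}/{pheno}"
                if child in out.pop_counts:
                    out.pop_counts[child] = math.nan
                if child in out.pop_freqs:
                    out.pop_freqs[child] = math.nan
    return out


def infer_pentamer_split(n_cd4_pent: float, n_cd8_pent: float) -> tuple[float, float]:
    """CD4/CD8 split among pentamer+ cells.

    %CD4+Pentamer+ = n_CD4Pent / (n_CD4Pent + n_CD8Pent); the CD8 share is
    inferred as its complement so the two always sum to exactly 1.
    """
    if n_cd4_pent < 0 or n_cd8_pent < 0:
        raise ValueError("pentamer counts must be non-negative")
    total = n_cd4_pent + n_cd8_pent
    if total == 0:
        raise ValueError("pentamer split undefined: both counts are zero")
    pct_cd4 = n_cd4_pent / total
    return pct_cd4, 1.0 - pct_cd4


def transduced_cells_by_phenotype(
    split_fraction: float,
    total_transduced: float,
    phenotype_fraction: float,
    weight_kg: float,
    patient_id: str = "",
    phenotype: str = "",
    parent: str = "",
) -> PhenotypeDose:
    """Absolute transduced cells of one memory phenotype infused.

    n_cells = (pentamer split fraction) x (transduced cells in the product)
    x (phenotype frequency of the pentamer parent); normalized by body
    weight for the cells/kg scale used in product-attribute comparisons.
    Missing (NaN) fractions propagate to missing doses.
    """
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    if total_transduced <= 0:
        raise ValueError("total transduced cells must be positive")
    for frac in (split_fraction, phenotype_fraction):
        if not math.isnan(frac) and not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    n_cells = split_fraction * total_transduced * phenotype_fraction
    return PhenotypeDose(
        patient_id=patient_id,
        phenotype=phenotype,
        parent=parent,
        n_cells=n_cells,
        n_cells_per_kg=n_cells / weight_kg,
    )


def phenotype_dose_table(
    samples: list[FlowPanelCounts],
    noise: dict[str, float],
    patients: list[PatientRecord],
    min_viable: int = 5000,
) -> tuple[pd.DataFrame, list[QCRejection]]:
    """Full product-phenotyping pipeline for one trial.

    QC-filters samples (sample_id is the patient id for product samples),
    floors pentamer gates against the noise levels, computes the CD4/CD8
    pentamer split from the Pheno1 counts, and converts memory-phenotype
    frequencies into absolute transduced cells (per kg) using each patient's
    transduced cell dose. Floored (missing) values propagate as NaN.
    """
    retained, rejections = qc_filter_samples(samples, min_viable=min_viable)
    by_patient = {p.patient_id: p for p in patients}
    rows = []
    for s in retained:
        if s.panel != "Pheno1" or s.sample_id not in by_patient:
            continue
        pat = by_patient[s.sample_id]
        floored = floor_pentamer_frequencies(s, noise)
        n_cd4 = floored.pop_counts.get("CD4Pent", 0.0)
        n_cd8 = floored.pop_counts.get("CD8Pent", 0.0)
        if n_cd4 + n_cd8 == 0:
            rejections.append(QCRejection(s.sample_id, "both pentamer gates floored to 0"))
            continue
        pct_cd4, pct_cd8 = infer_pentamer_split(n_cd4, n_cd8)
        for parent, split in (("CD4Pent", pct_cd4), ("CD8Pent", pct_cd8)):
            for pheno in MEMORY_PHENOTYPES:
                frac = floored.pop_freqs.get(f"{parent}/{pheno}", math.nan)
                dose = transduced_cells_by_phenotype(
                    split,
                    pat.transduced_cell_dose,
                    frac,
                    pat.weight_kg,
                    patient_id=pat.patient_id,
                    phenotype=pheno,
                    parent=parent,
                )
                rows.append(
                    (
                        pat.patient_id,
                        parent,
                        pheno,
                        split,
                        frac,
                        dose.n_cells,
                        dose.n_cells_per_kg,
                    )
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "parent",
            "phenotype",
            "split_fraction",
            "phenotype_fraction",
            "n_cells",
            "n_cells_per_kg",
        ],
    )
    return table, rejections
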