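"""Readers and writers for the trial's plain-text interchange formats.

Tabular domains use CSV (pandas); expression uses the nCounter RCC text
dialect (tagged sections with CSV bodies) plus a sample-annotation CSV;
gene sets use GMT. All tables round-trip losslessly through these
functions, which the property suite checks.

Frequencies are stored as fractions in [0, 1]. A column header ending in
``_pct`` marks percent-formatted input, which is divided by 100 at parse
time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genesets import bundled_gene_sets, write_gmt
from .types import (
    ExpressionExperiment,
    FlowPanelCounts,
    PatientRecord,
    TrialDataset,
    patients_frame,
)

_VIABLE = "viable_CD3"


# ---------------------------------------------------------------------------
# CSV tables


def write_patients_csv(patients: list[PatientRecord], path: str | Path) -> None:
    patients_frame(patients).to_csv(path, index=False)


def read_patients_csv(path: str | Path) -> list[PatientRecord]:
    frame = pd.read_csv(path, float_precision="round_trip")
    records = []
    for _, row in frame.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                cohort=int(row["cohort"]),
                ldr=str(row["ldr"]),
                weight_kg=float(row["weight_kg"]),
                transduced_cell_dose=float(row["transduced_cell_dose"]),
                responder=bool(row["responder"]),
                best_response=str(row["best_response"]),
                pfs_days=float(row["pfs_days"]),
                pfs_event=bool(row["pfs_event"]),
                os_days=float(row["os_days"]),
                os_event=bool(row["os_event"]),
            )
        )
    return records


def write_flow_csv(samples: list[FlowPanelCounts], path: str | Path) -> None:
    rows = []
    for s in samples:
        rows.append((s.sample_id, s.panel, _VIABLE, "", s.viable_cd3_count, 1.0))
        for pop in s.pop_counts:
            parent = pop.split("/")[0] if "/" in pop else _VIABLE
            rows.append(
                (s.sample_id, s.panel, pop, parent, s.pop_counts[pop], s.pop_freqs.get(pop))
            )
    pd.DataFrame(
        rows,
        columns=["sample_id", "panel", "population", "parent", "count", "freq_of_parent"],
    ).to_csv(path, index=False)


def read_flow_csv(path: str | Path) -> list[FlowPanelCounts]:
    frame = pd.read_csv(path, float_precision="round_trip")
    freq_col = "freq_of_parent"
    scale = 1.0
    if freq_col not in frame.columns and "freq_of_parent_pct" in frame.columns:
        freq_col, scale = "freq_of_parent_pct", 0.01
    samples: list[FlowPanelCounts] = []
    for (sid, panel), grp in frame.groupby(["sample_id", "panel"], sort=False):
        viable_rows = grp[grp["population"] == _VIABLE]
        if viable_rows.empty:
            raise ValueError(f"sample {sid} panel {panel}: missing {_VIABLE} row")
        viable = float(viable_rows["count"].iloc[0])
        counts, freqs = {}, {}
        for _, row in grp[grp["population"] != _VIABLE].iterrows():
            counts[row["population"]] = float(row["count"])
            freqs[row["population"]] = float(row[freq_col]) * scale
        samples.append(FlowPanelCounts(str(sid), str(panel), viable, counts, freqs))
    return samples


def write_noise_csv(noise: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"population": list(noise), "max_negative_control_freq": list(noise.values())}
    ).to_csv(path, index=False)


def read_noise_csv(path: str | Path) -> dict[str, float]:
    frame = pd.read_csv(path, float_precision="round_trip")
    return dict(zip(frame["population"], frame["max_negative_control_freq"].astype(float)))


# ---------------------------------------------------------------------------
# RCC (nCounter reporter code count) text files


def write_rcc(
    sample_id: str,
    counts: pd.Series,
    code_classes: pd.Series,
    path: str | Path,
    attributes: dict[str, str] | None = None,
) -> None:
    """Write one sample's counts as an RCC text file.

    ``counts`` and ``code_classes`` are indexed by probe name.
    """
    lines = ["<Header>", "FileVersion,1.7", "SoftwareVersion,4.0.0.3", "</Header>", ""]
    lines += ["<Sample_Attributes>", f"ID,{sample_id}"]
    for key, val in (attributes or {}).items():
        lines.append(f"{key},{val}")
    lines += ["</Sample_Attributes>", ""]
    lines += ["<Lane_Attributes>", "ID,1", "</Lane_Attributes>", ""]
    lines += ["<Code_Summary>", "CodeClass,Name,Accession,Count"]
    for name in counts.index:
        lines.append(f"{code_classes[name]},{name},NA_{name},{int(counts[name])}")
    lines += ["</Code_Summary>", ""]
    Path(path).write_text("\n".join(lines))


def read_rcc(path: str | Path) -> tuple[str, pd.Series, pd.Series]:
    """Parse one RCC file -> (sample_id, counts, code_classes).

    Raises a parse error naming the offending line for malformed counts or a
    missing Code_Summary section.
    """
    text = Path(path).read_text().splitlines()
    sample_id = Path(path).stem
    section = None
    names: list[str] = []
    classes: list[str] = []
    counts: list[int] = []
    saw_code_summary = False
    for lineno, line in enumerate(text, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("<") and stripped.endswith(">"):
            section = None if stripped.startswith("</") else stripped[1:-1]
            if section == "Code_Summary":
                saw_code_summary = True
            continue
        if section == "Sample_Attributes":
            key, _, val = stripped.partition(",")
            if key == "ID":
                sample_id = val
        elif section == "Code_Summary":
            fields = stripped.split(",")
            if fields[0] == "CodeClass":
                continue
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: malformed Code_Summary row")
            try:
                count = int(fields[3])
            except ValueError as err:
                raise ValueError(
                    f"{path}:{lineno}: malformed count {fields[3]!r} for probe {fields[1]}"
                ) from err
            classes.append(fields[0])
            names.append(fields[1])
            counts.append(count)
    if not saw_code_summary:
        raise ValueError(f"{path}: missing <Code_Summary> section")
    idx = pd.Index(names, name="gene")
    return sample_id, pd.Series(counts, index=idx), pd.Series(classes, index=idx)


def write_expression(exp: ExpressionExperiment, outdir: str | Path) -> None:
    """Write one RCC file per sample plus a samples.csv annotation table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid in exp.samples.index:
        write_rcc(sid, exp.raw_counts[sid], exp.genes["code_class"], outdir / f"{sid}.RCC")
    exp.samples.reset_index().to_csv(outdir / "samples.csv", index=False)
    exp.genes.reset_index().to_csv(outdir / "genes.csv", index=False)


def read_expression(rcc_dir: str | Path, annotations: str | Path | None = None) -> ExpressionExperiment:
    """Assemble an experiment from a directory of RCC files.

    ``annotations`` defaults to ``samples.csv`` inside the directory. Sample
    order follows the annotation table; probe order follows the first RCC
    file (all files must agree on the probe set).
    """
    rcc_dir = Path(rcc_dir)
    if annotations is None:
        annotations = rcc_dir / "samples.csv"
    samples = pd.read_csv(annotations).set_index("sample_id")
    cols = {}
    classes = None
    for sid in samples.index:
        _, counts, cls = read_rcc(rcc_dir / f"{sid}.RCC")
        cols[sid] = counts
        if classes is None:
            classes = cls
    raw = pd.DataFrame(cols)
    raw.columns = samples.index.copy()
    genes = pd.DataFrame({"code_class": classes.loc[raw.index]})
    genes.index.name = "gene"
    genes_csv = rcc_dir / "genes.csv"
    if genes_csv.exists():
        extra = pd.read_csv(genes_csv).set_index("gene")
        for col in extra.columns:
            if col != "code_class":
                genes[col] = extra.loc[raw.index, col]
    if "responder" in samples.columns:
        samples["responder"] = samples["responder"].astype(bool)
    return ExpressionExperiment(genes=genes, samples=samples, raw_counts=raw)


# ---------------------------------------------------------------------------
# Whole-dataset round trip


def write_dataset(dataset: TrialDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_patients_csv(dataset.patients, outdir / "patients.csv")
    dataset.cytokines.to_csv(outdir / "cytokines.csv", index=False)
    write_flow_csv(dataset.flow, outdir / "flow_counts.csv")
    write_noise_csv(dataset.noise_levels, outdir / "noise.csv")
    dataset.expansion.to_csv(outdir / "expansion.csv", index=False)
    write_expression(dataset.expression, outdir / "rcc")
    write_gmt(bundled_gene_sets(), outdir / "genesets.gmt")
    (outdir / "truth.json").write_text(json.dumps(dataset.truth, indent=2, default=float))


def read_dataset(outdir: str | Path) -> TrialDataset:
    outdir = Path(outdir)
    cytokines = pd.read_csv(outdir / "cytokines.csv", float_precision="round_trip")
    cytokines["censored"] = cytokines["censored"].astype(bool)
    truth_path = outdir / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return TrialDataset(
        patients=read_patients_csv(outdir / "patients.csv"),
        cytokines=cytokines,
        flow=read_flow_csv(outdir / "flow_counts.csv"),
        noise_levels=read_noise_csv(outdir / "noise.csv"),
        expansion=pd.read_csv(outdir / "expansion.csv", float_precision="round_trip"),
        expression=read_expression(outdir / "rcc"),
        truth=truth,
    )
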