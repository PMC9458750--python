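"""Synthetic trial generator.

Builds a virtual TCR T-cell therapy trial with the statistical structure the
downstream analyses assume: a four-cohort clinical table with lymphodepletion
regimens and transduced cell doses; longitudinal serum cytokines generated
from a log-normal linear mixed model with responder x time effects and
left-censoring at per-analyte LLOQs; a memory-phenotype flow panel for the
infused product with healthy-donor negative-control noise levels; transgene
qPCR expansion series whose peak depends on weight-normalized dose and
lymphodepletion; an nCounter-style count matrix with control probe classes,
a macrophage gene-set shift at progression and an interferon-downstream
shift in non-responders; and exponential survival with a log-Cmax hazard
term. Ground-truth parameters are stored on the dataset so recovery tests
can compare estimates with the generating values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ConfigError,
    ExpressionExperiment,
    FlowPanelCounts,
    MEMORY_PHENOTYPES,
    PatientRecord,
    TrialDataset,
)

# Study sampling grid for serum cytokines: baseline (-7), infusion day 0,
# days 1/4/7 and weeks 2,3,4,6,8 post-infusion.
CYTOKINE_DAYS = (-7, 0, 1, 4, 7, 14, 21, 28, 42, 56)

# qPCR monitoring days used for the expansion series (within first 8 weeks).
EXPANSION_DAYS = (0, 4, 7, 14, 28, 56)

DEFAULT_ANALYTES = ("IFNg", "IL6", "IL2Ra", "IL15", "GMCSF", "IL17A")


@dataclass
class CytokineParams:
    """Per-analyte generative parameters on the natural-log scale.

    ``time_effect`` and ``responder_effect`` are vectors over the study grid
    (same length as ``CYTOKINE_DAYS``); the responder effect is the
    responder-vs-non-responder log-ratio at each timepoint.
    """

    baseline_log_mean: float
    time_effect: tuple[float, ...]
    responder_effect: tuple[float, ...]
    sigma_b: float = 0.5
    sigma_e: float = 0.5
    lloq: float = 1.0

    def validate(self, n_times: int) -> None:
        if self.sigma_b < 0 or self.sigma_e < 0:
            raise ConfigError("cytokine SDs must be non-negative")
        if self.lloq <= 0:
            raise ConfigError("LLOQ must be positive")
        if len(self.time_effect) != n_times or len(self.responder_effect) != n_times:
            raise ConfigError("effect vectors must match the timepoint grid")


@dataclass
class ExpansionParams:
    intercept: float = 2.0          # log Cmax at dose/kg = 1 with non-standard LDR
    dose_effect: float = 0.8        # per unit log(dose/kg)
    ldr_effect: float = 1.0         # standard fluCy vs other regimens
    noise_sd: float = 0.8
    peak_day: float = 7.0
    log_width: float = 0.55         # width of log-quadratic rise/decay shape
    point_noise_sd: float = 0.25    # multiplicative per-sample qPCR noise
    detection_limit: float = 50.0   # copies/ug below which qPCR reports 0

    def validate(self) -> None:
        if self.noise_sd < 0 or self.point_noise_sd < 0:
            raise ConfigError("expansion noise SDs must be non-negative")


@dataclass
class FlowParams:
    """Memory composition of the infused product per responder status.

    Responders carry an effector-memory-enriched product (about 28% EM among
    CD8+Pentamer+ cells versus 12% in non-responders, a roughly 2.3x
    enrichment mirroring the reported responder/non-responder EM contrast).
    """

    composition_responder: tuple[float, ...] = (0.18, 0.12, 0.22, 0.28, 0.20)
    composition_nonresponder: tuple[float, ...] = (0.26, 0.14, 0.25, 0.12, 0.23)
    dirichlet_concentration: float = 60.0
    cd8_pent_freq: float = 0.20     # of viable CD3+, ~35% transduction, CD8-skewed
    cd4_pent_freq: float = 0.02
    viable_cd3_mean: float = 50_000.0
    qc_fail_rate: float = 0.05      # samples acquired with too few viable cells
    noise_cd8: float = 1e-3         # healthy-donor max pentamer+ frequency
    noise_cd4: float = 5e-4

    def validate(self) -> None:
        for comp in (self.composition_responder, self.composition_nonresponder):
            if len(comp) != len(MEMORY_PHENOTYPES):
                raise ConfigError("composition must cover all memory phenotypes")
            if any(c < 0 for c in comp) or abs(sum(comp) - 1.0) > 1e-9:
                raise ConfigError("phenotype composition must be a simplex")
        if not 0 <= self.qc_fail_rate < 1:
            raise ConfigError("qc_fail_rate must be in [0, 1)")


@dataclass
class ExpressionParams:
    n_genes: int = 120              # endogenous probes
    n_housekeeping: int = 10
    n_positive: int = 6
    n_negative: int = 8
    n_pre: int = 10                 # pre-infusion biopsies
    n_progression: int = 5
    macrophage_shift: float = -1.0  # log2, at progression
    ifn_shift: float = 1.5          # log2, non-responder pre-infusion samples
    antigen_presentation_shift: float = -0.8  # log2, at progression
    dispersion: float = 0.08        # NB dispersion (1/size)
    base_log2_mean: float = 7.0
    base_log2_sd: float = 1.5
    lane_scale_sd: float = 0.2      # per-sample global scale on the log scale

    def validate(self) -> None:
        if min(self.n_genes, self.n_housekeeping, self.n_positive, self.n_negative) < 1:
            raise ConfigError("all probe-class counts must be positive")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")


@dataclass
class SurvivalParams:
    pfs_median_days: float = 105.0  # baseline exponential median (~15 weeks)
    os_median_days: float = 540.0   # ~18 months
    cmax_log_hr: float = -0.6       # per unit centered log Cmax (higher Cmax, lower hazard)
    censor_horizon_days: float = 730.0

    def validate(self) -> None:
        if self.pfs_median_days <= 0 or self.os_median_days <= 0:
            raise ConfigError("median survival times must be positive")


def _default_cytokines() -> dict[str, CytokineParams]:
    nt = len(CYTOKINE_DAYS)
    zero = (0.0,) * nt
    # Post-infusion activation pulse peaking day 4-7, decaying by week 4.
    pulse = (0.0, 0.0, 0.6, 1.4, 1.2, 0.5, 0.2, 0.1, 0.0, 0.0)
    # Responders activate earlier/stronger post-infusion.
    resp_post = (0.0, 0.0, 0.6, 1.2, 1.0, 0.5, 0.3, 0.2, 0.1, 0.0)
    # IL-15 is elevated pre-infusion in responders (lymphodepletion-driven).
    resp_pre = (0.6, 0.8, 0.4, 0.2, 0.1, 0.0, 0.0, 0.0, 0.0, 0.0)
    return {
        "IFNg": CytokineParams(1.5, pulse, resp_post, lloq=1.0),
        "IL6": CytokineParams(1.8, pulse, resp_post, lloq=1.0),
        "IL2Ra": CytokineParams(6.5, pulse, resp_post, lloq=50.0),
        "IL15": CytokineParams(2.2, zero, resp_pre, lloq=1.0),
        # Frequently below LLOQ, as for GM-CSF / IL-17A in serum.
        "GMCSF": CytokineParams(-0.5, pulse, resp_post, lloq=1.0),
        "IL17A": CytokineParams(-0.8, pulse, resp_post, lloq=1.0),
    }


@dataclass
class SimulationConfig:
    """Full generative specification for one virtual trial.

    Defaults reproduce the study conditions: a 45-patient mITT population
    split 12/13/5/15 across four cohorts, cohort-specific lymphodepletion
    and response rates, a 5e9-cell target dose bounded to [1e9, 6e9], and
    effect structure in which responders show pre-infusion IL-15 elevation,
    early post-infusion cytokine activation, EM-enriched product, higher
    expansion with dose/kg and standard lymphodepletion, and a macrophage
    gene-set decrease at progression.
    """

    n_patients: int = 45
    cohort_weights: tuple[float, ...] = (12 / 45, 13 / 45, 5 / 45, 15 / 45)
    seed: int = 0
    responder_rate_by_cohort: tuple[float, ...] = (0.50, 0.31, 0.20, 0.27)
    cytokine_params: dict[str, CytokineParams] = field(default_factory=_default_cytokines)
    expansion_params: ExpansionParams = field(default_factory=ExpansionParams)
    flow_params: FlowParams = field(default_factory=FlowParams)
    expression_params: ExpressionParams = field(default_factory=ExpressionParams)
    survival_params: SurvivalParams = field(default_factory=SurvivalParams)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be positive")
        w = np.asarray(self.cohort_weights, dtype=float)
        if len(w) != 4 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError("cohort_weights must be 4 non-negative weights summing to 1")
        if len(self.responder_rate_by_cohort) != 4:
            raise ConfigError("responder_rate_by_cohort must have 4 entries")
        for pars in self.cytokine_params.values():
            pars.validate(len(CYTOKINE_DAYS))
        self.expansion_params.validate()
        self.flow_params.validate()
        self.expression_params.validate()
        self.survival_params.validate()


_COHORT_LDR = {1: "standard_fluCy", 2: "standard_fluCy", 3: "cy_only", 4: "reduced_fluCy"}


def simulate_patients(config: SimulationConfig, rng: np.random.Generator) -> list[PatientRecord]:
    cohorts = rng.choice([1, 2, 3, 4], size=config.n_patients, p=config.cohort_weights)
    patients: list[PatientRecord] = []
    rates = dict(zip([1, 2, 3, 4], config.responder_rate_by_cohort))
    for i, cohort in enumerate(cohorts):
        weight = float(np.clip(rng.normal(70.0, 15.0), 40.0, 120.0))
        dose = float(np.clip(np.exp(rng.normal(np.log(3e9), 0.45)), 1e9, 6e9))
        responder = bool(rng.random() < rates[int(cohort)])
        if responder:
            best = "CR" if rng.random() < 0.1 else "PR"
        else:
            best = rng.choice(["SD", "PD", "NE"], p=[0.83, 0.10, 0.07])
        patients.append(
            PatientRecord(
                patient_id=f"P{i + 1:03d}",
                cohort=int(cohort),
                ldr=_COHORT_LDR[int(cohort)],
                weight_kg=weight,
                transduced_cell_dose=dose,
                responder=responder,
                best_response=str(best),
                pfs_days=0.0,  # filled by simulate_survival
                pfs_event=False,
                os_days=0.0,
                os_event=False,
            )
        )
    return patients


def simulate_cytokine_panel(
    patients: list[PatientRecord],
    cytokine_params: dict[str, CytokineParams],
    timepoints: tuple[int, ...] = CYTOKINE_DAYS,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate the long-format cytokine table.

    Values are exp(Normal LME): per subject a random intercept b ~ N(0, s_b^2)
    plus fixed responder x time effects and residual noise. Draws below the
    analyte LLOQ are flagged censored and reported at the LLOQ, as an
    immunoassay would.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    days = np.asarray(timepoints, dtype=float)
    rows = []
    for analyte, pars in cytokine_params.items():
        pars.validate(len(days))
        time_eff = np.asarray(pars.time_effect)
        resp_eff = np.asarray(pars.responder_effect)
        for pat in patients:
            b = rng.normal(0.0, pars.sigma_b)
            mu = pars.baseline_log_mean + time_eff + (resp_eff if pat.responder else 0.0)
            logy = mu + b + rng.normal(0.0, pars.sigma_e, size=len(days))
            y = np.exp(logy)
            cens = y < pars.lloq
            y = np.where(cens, pars.lloq, y)
            for d, v, c in zip(days, y, cens):
                rows.append((pat.patient_id, analyte, float(d), float(v), pars.lloq, bool(c)))
    return pd.DataFrame(
        rows, columns=["patient_id", "analyte", "day", "value", "lloq", "censored"]
    )


def simulate_flow_panel(
    patients: list[PatientRecord],
    flow_params: FlowParams,
    seed: int | np.random.Generator = 0,
) -> tuple[list[FlowPanelCounts], dict[str, float]]:
    """Generate product flow-panel counts (Pheno1 + Pheno2 per patient).

    Memory subsets are gated in the Pheno1 panel; Pheno2 carries the same
    pentamer parents (used for the viable-CD3 QC rule) without memory
    children. Returns the samples plus the healthy-donor noise levels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fp = flow_params
    samples: list[FlowPanelCounts] = []
    for pat in patients:
        comp = np.asarray(
            fp.composition_responder if pat.responder else fp.composition_nonresponder
        )
        comp = rng.dirichlet(comp * fp.dirichlet_concentration)
        for panel in ("Pheno1", "Pheno2"):
            fails_qc = rng.random() < fp.qc_fail_rate
            viable = float(
                rng.poisson(3000.0) if fails_qc else rng.poisson(fp.viable_cd3_mean)
            )
            counts: dict[str, float] = {}
            freqs: dict[str, float] = {}
            for parent, pfreq in (("CD8Pent", fp.cd8_pent_freq), ("CD4Pent", fp.cd4_pent_freq)):
                n_parent = float(rng.binomial(int(viable), pfreq))
                counts[parent] = n_parent
                freqs[parent] = n_parent / viable if viable else 0.0
                if panel == "Pheno1":
                    child = rng.multinomial(int(n_parent), comp)
                    for pheno, c in zip(MEMORY_PHENOTYPES, child):
                        key = f"{parent}/{pheno}"
                        counts[key] = float(c)
                        freqs[key] = float(c) / n_parent if n_parent else 0.0
            samples.append(FlowPanelCounts(pat.patient_id, panel, viable, counts, freqs))
    noise = {"CD8Pent": fp.noise_cd8, "CD4Pent": fp.noise_cd4}
    return samples, noise


def simulate_expansion(
    patients: list[PatientRecord],
    expansion_params: ExpansionParams,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Generate transgene qPCR series and the true per-patient log Cmax.

    log Cmax = intercept + dose_effect * log(dose/kg) + ldr_effect * 1[standard]
    + noise; the time course follows a fixed log-quadratic rise/decay shape
    peaking at ``peak_day``. Values below the detection limit report 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ep = expansion_params
    days = np.asarray(EXPANSION_DAYS, dtype=float)
    rows = []
    true_log_cmax: dict[str, float] = {}
    for pat in patients:
        dose_per_kg = pat.transduced_cell_dose / pat.weight_kg
        log_cmax = (
            ep.intercept
            + ep.dose_effect * np.log(dose_per_kg)
            + ep.ldr_effect * (pat.ldr == "standard_fluCy")
            + rng.normal(0.0, ep.noise_sd)
        )
        true_log_cmax[pat.patient_id] = float(log_cmax)
        with np.errstate(divide="ignore"):
            shape = np.where(
                days > 0,
                np.exp(-((np.log(days / ep.peak_day)) ** 2) / (2 * ep.log_width**2)),
                0.0,
            )
        copies = np.exp(log_cmax) * shape * np.exp(
            rng.normal(0.0, ep.point_noise_sd, size=len(days))
        )
        copies = np.where(copies < ep.detection_limit, 0.0, copies)
        copies[days == 0] = 0.0
        for d, c in zip(days, copies):
            rows.append((pat.patient_id, float(d), float(c)))
    frame = pd.DataFrame(rows, columns=["patient_id", "day", "copies_per_ug"])
    return frame, true_log_cmax


def simulate_survival(
    patients: list[PatientRecord],
    true_log_cmax: dict[str, float],
    survival_params: SurvivalParams,
    seed: int | np.random.Generator = 0,
) -> None:
    """Fill PFS/OS endpoints in place: exponential hazards linear in log Cmax."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sp = survival_params
    center = float(np.mean(list(true_log_cmax.values())))
    for pat in patients:
        z = true_log_cmax[pat.patient_id] - center
        for attr_days, attr_event, median in (
            ("pfs_days", "pfs_event", sp.pfs_median_days),
            ("os_days", "os_event", sp.os_median_days),
        ):
            rate = np.log(2) / median * np.exp(sp.cmax_log_hr * z)
            t = float(rng.exponential(1.0 / rate))
            event = t <= sp.censor_horizon_days
            setattr(pat, attr_days, min(t, sp.censor_horizon_days))
            setattr(pat, attr_event, bool(event))


def simulate_expression_experiment(
    patients: list[PatientRecord],
    expression_params: ExpressionParams,
    seed: int | np.random.Generator = 0,
    gene_sets: dict[str, tuple[str, ...]] | None = None,
) -> ExpressionExperiment:
    """Generate an nCounter-style count matrix for tumor biopsies.

    Biopsied patients contribute a pre-infusion sample; a subset of
    progressing (non-responder-leaning) patients contribute an
    at-progression sample. Counts are negative-binomial around log-normal
    gene means with a per-sample lane scale factor; configured log2 shifts
    are applied to the macrophage set (at progression), the IFN-downstream
    set (non-responder pre-infusion) and the antigen-presentation set (at
    progression).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xp = expression_params
    if gene_sets is None:
        from .genesets import bundled_gene_sets

        gene_sets = {gs.name: gs.genes for gs in bundled_gene_sets()}
    # Sets are only partially represented on a real panel; genes unique to
    # the checkpoint set beyond its first five stay off-panel so the
    # coverage filter has work to do downstream.
    off_panel: set[str] = set()
    if "checkpoint" in gene_sets:
        elsewhere = {
            g for name, gs in gene_sets.items() if name != "checkpoint" for g in gs
        }
        off_panel = set(gene_sets["checkpoint"][5:]) - elsewhere
    set_genes = sorted(
        {g for genes in gene_sets.values() for g in genes} - off_panel
    )
    if xp.n_genes < max(len(v) for v in gene_sets.values()):
        raise ConfigError("n_genes smaller than the largest bundled gene set")
    if xp.n_genes < len(set_genes):
        raise ConfigError("n_genes too small to host the bundled gene sets")
    gene_names = set_genes + [f"GENE{i:03d}" for i in range(xp.n_genes - len(set_genes))]
    hk = [f"HK{i + 1:02d}" for i in range(xp.n_housekeeping)]
    pos = [f"POS_{chr(65 + i)}" for i in range(xp.n_positive)]
    neg = [f"NEG_{chr(65 + i)}" for i in range(xp.n_negative)]
    genes = pd.DataFrame(
        {
            "code_class": ["Endogenous"] * len(gene_names)
            + ["Housekeeping"] * len(hk)
            + ["Positive"] * len(pos)
            + ["Negative"] * len(neg),
            "panel": "immune",
        },
        index=pd.Index(gene_names + hk + pos + neg, name="gene"),
    )

    # Sample design: pre-infusion biopsies from the first biopsied patients,
    # at-progression biopsies from patients with a progression event
    # (preferring non-responders, as progressors are).
    n_pre = min(xp.n_pre, len(patients))
    pre_pats = patients[:n_pre]
    prog_pool = [p for p in patients if not p.responder] + [p for p in patients if p.responder]
    prog_pats = prog_pool[: xp.n_progression]
    sample_rows = []
    for p in pre_pats:
        sample_rows.append((f"{p.patient_id}_pre", p.patient_id, "pre", p.responder))
    for p in prog_pats:
        sample_rows.append((f"{p.patient_id}_prog", p.patient_id, "progression", p.responder))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "patient_id", "timepoint", "responder"]
    ).set_index("sample_id")

    base_log2 = rng.normal(xp.base_log2_mean, xp.base_log2_sd, size=len(gene_names))
    hk_log2 = rng.normal(xp.base_log2_mean + 1.0, 0.5, size=len(hk))
    pos_log2 = np.log2(32.0 * 4.0 ** np.arange(len(pos), 0, -1))  # geometric ladder
    neg_mean = 2.0

    macro = set(gene_sets.get("macrophage", ()))
    ifn = set(gene_sets.get("IFN_downstream", ()))
    antigen = set(gene_sets.get("antigen_presentation", ()))
    counts = np.zeros((len(genes), len(samples)))
    size = 1.0 / xp.dispersion
    for j, (sid, row) in enumerate(samples.iterrows()):
        lane = rng.normal(0.0, xp.lane_scale_sd)  # log2 units
        log2_mu = base_log2.copy()
        for i, g in enumerate(gene_names):
            if g in macro and row["timepoint"] == "progression":
                log2_mu[i] += xp.macrophage_shift
            if g in antigen and row["timepoint"] == "progression":
                log2_mu[i] += xp.antigen_presentation_shift
            if g in ifn and row["timepoint"] == "pre" and not row["responder"]:
                log2_mu[i] += xp.ifn_shift
        mu = np.concatenate(
            [
                2.0 ** (log2_mu + lane),
                2.0 ** (hk_log2 + lane),
                2.0 ** (pos_log2 + lane),
                np.full(len(neg), neg_mean * 2.0**lane),
            ]
        )
        counts[:, j] = rng.negative_binomial(size, size / (size + mu))
    raw = pd.DataFrame(counts.astype(int), index=genes.index, columns=samples.index)
    return ExpressionExperiment(genes=genes, samples=samples, raw_counts=raw)


def simulate_trial(config: SimulationConfig) -> TrialDataset:
    """Generate the full virtual trial; deterministic for a given config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients = simulate_patients(config, rng)
    cytokines = simulate_cytokine_panel(patients, config.cytokine_params, CYTOKINE_DAYS, rng)
    flow, noise = simulate_flow_panel(patients, config.flow_params, rng)
    expansion, true_log_cmax = simulate_expansion(patients, config.expansion_params, rng)
    simulate_survival(patients, true_log_cmax, config.survival_params, rng)
    expression = simulate_expression_experiment(patients, config.expression_params, rng)
    truth = {
        "config": dataclasses.asdict(config),
        "true_log_cmax": true_log_cmax,
    }
    return TrialDataset(
        patients=patients,
        cytokines=cytokines,
        flow=flow,
        noise_levels=noise,
        expansion=expansion,
        expression=expression,
        truth=truth,
    )
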