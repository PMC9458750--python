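"""Generator behavior: determinism, linkage, censoring law, round trips."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from tcrbm.io import read_dataset, write_dataset
from tcrbm.synthetic import (
    CYTOKINE_DAYS,
    CytokineParams,
    ExpressionParams,
    FlowParams,
    SimulationConfig,
    simulate_cytokine_panel,
    simulate_expression_experiment,
    simulate_patients,
    simulate_trial,
)
from tcrbm.types import ConfigError


def test_seed_determinism(tmp_path):
    """Identical config + seed produce byte-identical written datasets."""
    for sub in ("a", "b"):
        write_dataset(simulate_trial(SimulationConfig(seed=7)), tmp_path / sub)
    files_a = sorted(p for p in (tmp_path / "a").rglob("*") if p.is_file())
    files_b = sorted(p for p in (tmp_path / "b").rglob("*") if p.is_file())
    assert [p.name for p in files_a] == [p.name for p in files_b]
    for pa, pb in zip(files_a, files_b):
        assert pa.read_bytes() == pb.read_bytes(), pa.name


def test_cardinality_and_linkage(default_dataset):
    """45 patients, all four data domains linked by patient id."""
    ds = default_dataset
    ids = {p.patient_id for p in ds.patients}
    assert len(ds.patients) == 45 and len(ids) == 45
    assert set(ds.cytokines["patient_id"]) == ids
    assert {s.sample_id for s in ds.flow} == ids
    assert set(ds.expansion["patient_id"]) == ids
    assert set(ds.expression.samples["patient_id"]) <= ids
    # responder flag consistent with best response for every record
    for p in ds.patients:
        assert p.responder == (p.best_response in ("CR", "PR"))


def test_noise_free_limit():
    """sigma_b = sigma_e = 0 reproduces the fixed-effect curve exactly."""
    pars = {
        "X": CytokineParams(
            baseline_log_mean=1.0,
            time_effect=tuple(0.1 * i for i in range(len(CYTOKINE_DAYS))),
            responder_effect=(0.5,) * len(CYTOKINE_DAYS),
            sigma_b=0.0,
            sigma_e=0.0,
            lloq=1e-6,
        )
    }
    patients = simulate_patients(SimulationConfig(n_patients=6, seed=0), np.random.default_rng(0))
    table = simulate_cytokine_panel(patients, pars, seed=1)
    for pat in patients:
        sub = table[table["patient_id"] == pat.patient_id].sort_values("day")
        expected = np.exp(
            1.0
            + np.array([0.1 * i for i in range(len(CYTOKINE_DAYS))])
            + (0.5 if pat.responder else 0.0)
        )
        np.testing.assert_allclose(sub["value"].to_numpy(), expected, rtol=1e-12)


def test_forced_censoring():
    """An LLOQ far above the generative distribution censors everything."""
    pars = {
        "X": CytokineParams(
            baseline_log_mean=0.0,
            time_effect=(0.0,) * len(CYTOKINE_DAYS),
            responder_effect=(0.0,) * len(CYTOKINE_DAYS),
            lloq=1e9,
        )
    }
    patients = simulate_patients(SimulationConfig(n_patients=10, seed=1), np.random.default_rng(1))
    table = simulate_cytokine_panel(patients, pars, seed=2)
    assert table["censored"].all()
    assert (table["value"] == 1e9).all()


def test_censoring_fraction_matches_normal_tail():
    """Empirical censoring frequency matches the closed-form normal tail.

    With no fixed effects, log values are N(mu, sb^2 + se^2), so the
    censored fraction converges to Phi((log LLOQ - mu) / sigma_total).
    """
    mu, sb, se, lloq = 1.0, 0.5, 0.5, 2.0
    pars = {
        "X": CytokineParams(
            baseline_log_mean=mu,
            time_effect=(0.0,) * len(CYTOKINE_DAYS),
            responder_effect=(0.0,) * len(CYTOKINE_DAYS),
            sigma_b=sb,
            sigma_e=se,
            lloq=lloq,
        )
    }
    patients = simulate_patients(
        SimulationConfig(n_patients=1000, seed=3), np.random.default_rng(3)
    )
    table = simulate_cytokine_panel(patients, pars, seed=4)
    expected = norm.cdf((np.log(lloq) - mu) / np.hypot(sb, se))
    assert len(table) == 10_000
    assert abs(table["censored"].mean() - expected) < 0.03


def test_expression_validity(default_dataset):
    exp = default_dataset.expression
    vals = exp.raw_counts.to_numpy()
    assert np.all(vals >= 0) and np.issubdtype(vals.dtype, np.integer)
    for cls in ("Endogenous", "Housekeeping", "Positive", "Negative"):
        assert (exp.genes["code_class"] == cls).any()


def test_expression_shift_recovery():
    """Paired LME on set-average recovers the configured macrophage shift.

    Mean estimate over replicates within +/- 0.2 log2 units of the -1
    generative shift.
    """
    from tcrbm.genesets import bundled_gene_sets
    from tcrbm.nanostring import normalize_counts, paired_timepoint_lme

    macro = next(g for g in bundled_gene_sets() if g.name == "macrophage")
    ests = []
    for rep in range(12):
        cfg = SimulationConfig(n_patients=20, seed=200 + rep)
        rng = np.random.default_rng(cfg.seed)
        patients = simulate_patients(cfg, rng)
        exp = simulate_expression_experiment(patients, cfg.expression_params, rng)
        norm_exp = normalize_counts(exp)
        ests.append(paired_timepoint_lme(norm_exp, set_average=macro)["estimate"].iloc[0])
    assert abs(np.mean(ests) - (-1.0)) < 0.2


def test_expression_null_shift():
    """With all shifts zero, pre vs progression set means differ only by noise."""
    from tcrbm.genesets import bundled_gene_sets
    from tcrbm.nanostring import normalize_counts, paired_timepoint_lme

    macro = next(g for g in bundled_gene_sets() if g.name == "macrophage")
    pvals = []
    for rep in range(10):
        cfg = SimulationConfig(
            n_patients=20,
            seed=300 + rep,
            expression_params=ExpressionParams(
                macrophage_shift=0.0, ifn_shift=0.0, antigen_presentation_shift=0.0
            ),
        )
        rng = np.random.default_rng(cfg.seed)
        patients = simulate_patients(cfg, rng)
        norm_exp = normalize_counts(
            simulate_expression_experiment(patients, cfg.expression_params, rng)
        )
        pvals.append(paired_timepoint_lme(norm_exp, set_average=macro)["p"].iloc[0])
    # no systematic shift: most nominal p-values are unremarkable
    assert np.min(pvals) > 1e-4
    assert np.mean(np.array(pvals) < 0.05) <= 0.3


def test_round_trip(default_dataset, tmp_path):
    """Every generated table survives the CSV/RCC writers and readers."""
    write_dataset(default_dataset, tmp_path)
    back = read_dataset(tmp_path)
    assert [vars(p) for p in back.patients] == [vars(p) for p in default_dataset.patients]
    pd.testing.assert_frame_equal(back.cytokines, default_dataset.cytokines)
    pd.testing.assert_frame_equal(back.expansion, default_dataset.expansion)
    assert back.noise_levels == default_dataset.noise_levels
    assert len(back.flow) == len(default_dataset.flow)
    for a, b in zip(back.flow, default_dataset.flow):
        assert a.sample_id == b.sample_id and a.panel == b.panel
        assert a.viable_cd3_count == b.viable_cd3_count
        assert a.pop_counts == b.pop_counts
        np.testing.assert_allclose(
            [a.pop_freqs[k] for k in sorted(a.pop_freqs)],
            [b.pop_freqs[k] for k in sorted(b.pop_freqs)],
        )
    pd.testing.assert_frame_equal(back.expression.raw_counts, default_dataset.expression.raw_counts)
    assert list(back.expression.genes["code_class"]) == list(
        default_dataset.expression.genes["code_class"]
    )


@pytest.mark.parametrize(
    "bad",
    [
        {"cohort_weights": (0.5, 0.5, 0.2, -0.2)},
        {"cohort_weights": (0.25, 0.25, 0.25)},
        {"flow_params": FlowParams(composition_responder=(0.5, 0.2, 0.2, 0.2, 0.2))},
        {"expression_params": ExpressionParams(dispersion=-1.0)},
    ],
)
def test_invalid_config_rejected(bad):
    with pytest.raises(ConfigError):
        simulate_trial(dataclasses.replace(SimulationConfig(), **bad))


def test_null_responder_effect_ratio_covers_one():
    """Under a null responder effect the LME ratio CI covers 1 most of the time."""
    from tcrbm.censored_lme import fit_censored_lme, wald_ratio_timecourse

    nt = len(CYTOKINE_DAYS)
    pars = {
        "X": CytokineParams(
            baseline_log_mean=1.0,
            time_effect=tuple(0.1 * i for i in range(nt)),
            responder_effect=(0.0,) * nt,
            lloq=1e-6,
        )
    }
    covered = total = 0
    for rep in range(25):
        cfg = SimulationConfig(n_patients=20, seed=400 + rep)
        rng = np.random.default_rng(cfg.seed)
        patients = simulate_patients(cfg, rng)
        table = simulate_cytokine_panel(patients, pars, seed=rng)
        table["responder"] = table["patient_id"].map(
            {p.patient_id: p.responder for p in patients}
        )
        if table.groupby("responder")["patient_id"].nunique().min() < 2:
            continue
        fit = fit_censored_lme(table, analyte="X", n_starts=1)
        row = wald_ratio_timecourse(fit).set_index("day").loc[4.0]
        covered += row["ci_lo"] <= 1.0 <= row["ci_hi"]
        total += 1
    assert covered / total >= 0.85
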