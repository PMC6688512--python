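"""End-to-end pipeline: cohort -> parameters -> matching -> comparisons ->
deltas -> improvement -> MCID -> regression, with file outputs.

By default the cohort is drawn at the parameter level (per-subject gait
variables from the configured group distributions); a configurable handful
of subjects is additionally rendered as full marker trials and pushed
through the kinematic extraction chain so every stage of the pipeline is
exercised on trajectory data in the same run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from gaitresp import parameters as par
from gaitresp import prediction as pred
from gaitresp import responsiveness as resp
from gaitresp import stats
from gaitresp.io import AnalysisConfig
from gaitresp.synthetic import SEX_CODING, CohortConfig, generate_cohort
from gaitresp.types import GaitError

log = logging.getLogger(__name__)

#: Variables whose improvement means a decrease toward control values.
LOWER_IS_BETTER = {"spatial_asymmetry_pct", "cadence", "stance_pct",
                   "double_support_pct"}

#: Anchor variables scored with the MCID analysis.
MCID_VARIABLES = ("spatial_asymmetry_pct", "trunk_rom_transverse")

#: Outcomes modelled by the clinical regression.
REGRESSION_OUTCOMES = ("speed", "cadence", "step_length_a",
                       "step_length_na", "trunk_rom_transverse")

COMPARISON_VARIABLES = (
    "cadence", "speed", "stance_pct", "double_support_pct",
    "step_length_a", "step_length_na", "step_width",
    "spatial_asymmetry_pct", "hip_rom_a", "hip_rom_na", "knee_rom_a",
    "knee_rom_na", "ankle_rom_a", "ankle_rom_na", "trunk_rom_sagittal",
    "trunk_rom_frontal", "trunk_rom_transverse",
)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns the in-memory results: parameter table, matched-control table,
    comparison tables, delta table, improvement counts, MCID results and
    fitted regression models.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("gaitresp")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out_dir)
    except Exception as exc:  # annotate the failing stage for the CLI
        raise GaitError(f"pipeline failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: AnalysisConfig, out_dir: Path) -> dict:
    log.info("stage simulate: drawing cohort (seed %d)", config.seed)
    cohort = generate_cohort(CohortConfig(
        n_patients=config.n_patients, n_controls=config.n_controls,
        n_trials_per_session=config.n_trials_per_session,
        sampling_rate=config.sampling_rate, seed=config.seed))
    parameters = cohort.parameters.copy()

    extraction_check = None
    if config.simulate_trajectories and config.n_trajectory_subjects > 0:
        log.info("stage kinematics: full extraction for %d subjects",
                 config.n_trajectory_subjects)
        extraction_check = _trajectory_extraction_check(cohort, config)

    # --- speed matching -------------------------------------------------
    matched = parameters
    excluded_controls: dict[str, list[str]] = {}
    if config.speed_matching:
        log.info("stage matching: control trials vs patient speed band")
        matched, excluded_controls = _speed_match(cohort, parameters)

    # --- group comparisons ----------------------------------------------
    log.info("stage stats: gated comparisons per session")
    comparisons = pd.concat([
        stats.comparison_table(matched, list(COMPARISON_VARIABLES), session)
        for session in ("baseline", "followup")
    ], ignore_index=True)

    # --- deltas and improvement -----------------------------------------
    deltas = _delta_table(parameters)
    control_fu = matched[(matched["group"] == "control")
                         & (matched["session"] == "followup")]
    improvement = _improvement_counts(deltas, control_fu)

    # --- MCID ------------------------------------------------------------
    log.info("stage responsiveness: anchor-based MCID")
    mcid_results = []
    for var in MCID_VARIABLES:
        try:
            mcid_results.append(mcid_for_variable(
                deltas, control_fu, var, k=config.normalization_k))
        except GaitError as exc:
            log.warning("MCID for %s skipped: %s", var, exc)

    # --- regression ------------------------------------------------------
    log.info("stage prediction: backward-selection regression")
    models = []
    reg_data = regression_frame(cohort.clinical, deltas)
    for outcome in REGRESSION_OUTCOMES:
        spec = pred.RegressionSpec(
            outcome=f"delta_{outcome}", baseline_predictor=f"baseline_{outcome}",
            removal_alpha=config.removal_alpha)
        models.append(pred.backward_eliminate(spec, reg_data))

    # --- outputs ---------------------------------------------------------
    parameters.to_csv(out_dir / "parameters.csv", index=False)
    comparisons.to_csv(out_dir / "comparisons.csv", index=False)
    deltas.to_csv(out_dir / "deltas.csv", index=False)
    (out_dir / "mcid.json").write_text(json.dumps(
        [asdict(m) for m in mcid_results], indent=2, default=float))
    (out_dir / "regression.json").write_text(json.dumps(
        pred.regression_report(models), indent=2, default=float))
    log.info("outputs written to %s", out_dir)

    return {
        "cohort": cohort,
        "parameters": parameters,
        "matched_parameters": matched,
        "excluded_controls": excluded_controls,
        "comparisons": comparisons,
        "deltas": deltas,
        "improvement": improvement,
        "mcid": mcid_results,
        "models": models,
        "extraction_check": extraction_check,
    }


def _speed_match(cohort, parameters: pd.DataFrame
                 ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Restrict control trials to the patients' speed band per session."""
    trial_speeds = cohort.trial_speeds()
    matched = parameters.copy()
    excluded: dict[str, list[str]] = {}
    for session in ("baseline", "followup"):
        pat = parameters[(parameters["group"] == "patient")
                         & (parameters["session"] == session)]
        mean, sd = pat["speed"].mean(), pat["speed"].std(ddof=1)
        dropped = []
        for sid in parameters.loc[parameters["group"] == "control",
                                  "subject_id"].unique():
            sub = trial_speeds[(trial_speeds["subject_id"] == sid)
                               & (trial_speeds["session"] == session)]
            keep = stats.match_speed_trials(sub["speed"].to_numpy(), mean, sd)
            row = (matched["subject_id"] == sid) & (matched["session"] == session)
            if not keep.any():
                log.warning("control %s excluded at %s: no trials in "
                            "[%.3f, %.3f] m/s", sid, session, mean - sd, mean + sd)
                dropped.append(sid)
                matched = matched[~row]
            else:
                matched.loc[row, "speed"] = sub["speed"].to_numpy()[keep].mean()
        excluded[session] = dropped
    return matched, excluded


def _delta_table(parameters: pd.DataFrame) -> pd.DataFrame:
    """Per-patient percent change of every variable between sessions."""
    pat = parameters[parameters["group"] == "patient"]
    base = pat[pat["session"] == "baseline"].set_index("subject_id")
    fu = pat[pat["session"] == "followup"].set_index("subject_id")
    rows = []
    for sid in base.index:
        if sid not in fu.index:
            log.warning("patient %s lacks a follow-up session; skipped", sid)
            continue
        for var in COMPARISON_VARIABLES:
            vb, vf = float(base.at[sid, var]), float(fu.at[sid, var])
            rows.append({"subject_id": sid, "variable": var,
                         "value_baseline": vb, "value_10week": vf,
                         "delta_pct": stats.delta(vb, vf)})
    return pd.DataFrame(rows)


def _improvement_counts(deltas: pd.DataFrame, control_fu: pd.DataFrame
                        ) -> pd.DataFrame:
    rows = []
    for var in COMPARISON_VARIABLES:
        cm = float(control_fu[var].mean())
        sub = deltas[deltas["variable"] == var]
        improved = sum(
            stats.classify_improvement(r.value_baseline, r.value_10week, cm)
            for r in sub.itertuples())
        chi2, p = stats.improvement_chi_square(improved, len(sub))
        rows.append({"variable": var, "n_improved": improved,
                     "n_total": len(sub), "chi2": chi2, "p": p})
    return pd.DataFrame(rows)


def mcid_for_variable(deltas: pd.DataFrame, control_fu: pd.DataFrame,
                      variable: str, k: float = 1.0) -> resp.MCIDResult:
    """Anchor labels + MCID analysis for one variable's percent change."""
    sub = deltas[deltas["variable"] == variable]
    cm = float(control_fu[variable].mean())
    csd = float(control_fu[variable].std(ddof=1))
    lower = variable in LOWER_IS_BETTER
    labels, values = [], []
    for r in sub.itertuples():
        lab = resp.anchor_classify(r.subject_id, variable, r.value_baseline,
                                   r.value_10week, cm, csd, lower, k)
        labels.append(lab.normalized)
        values.append(r.delta_pct)
    return resp.mcid_analysis(values, labels, variable)


def regression_frame(clinical: pd.DataFrame, deltas: pd.DataFrame
                     ) -> pd.DataFrame:
    """One row per patient: coded covariates, baselines and delta outcomes."""
    pat = clinical[clinical["group"] == "patient"].set_index("subject_id")
    wide = {}
    for var in REGRESSION_OUTCOMES:
        sub = deltas[deltas["variable"] == var].set_index("subject_id")
        wide[f"delta_{var}"] = sub["delta_pct"]
        wide[f"baseline_{var}"] = sub["value_baseline"]
    df = pd.DataFrame(wide)
    df["sex"] = pat["sex"].map(SEX_CODING)
    for cov in ("age", "disease_duration", "updrs2", "updrs3", "hy_stage", "led"):
        df[cov] = pat[cov]
    return df.dropna()


def _trajectory_extraction_check(cohort, config: AnalysisConfig) -> pd.DataFrame:
    """Run a few subjects through the full marker-level chain and report
    extracted-vs-truth values (a built-in forward/inverse consistency audit)."""
    rows = []
    subjects = cohort.clinical["subject_id"].head(config.n_trajectory_subjects)
    for sid in subjects:
        side = cohort.clinical.set_index("subject_id").at[sid, "affected_side"]
        for session in ("baseline",):
            trials = [t for t, _ in cohort.trials_for(sid, session)]
            extracted = par.extract_subject_session(
                trials, sid, session, side, cutoff=config.filter_cutoff_hz)
            profile = cohort.profiles[(sid, session)]
            rows.append({
                "subject_id": sid, "session": session,
                "cadence_true": profile.cadence,
                "cadence_extracted": extracted.values["cadence"],
                "speed_true": profile.speed,
                "speed_extracted": extracted.values["speed"],
                "step_length_l_true": profile.step_length("left"),
                "step_length_l_extracted": extracted.values["step_length_l"],
            })
    return pd.DataFrame(rows)
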