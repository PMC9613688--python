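"""End-to-end pipeline: simulate a cohort, score it, and run the statistics.

One run simulates ``n_subjects`` synthetic participants through the 11
conditions, computes per-trial oculometrics, per-condition summaries,
posturography, and the pupil spectral summary, then applies the
nonparametric battery to the resulting long table.  All randomness derives
from a single seed via ``numpy.random.SeedSequence`` spawning, so repeated
runs are byte-identical.

The cohort model builds in the dual-task effects the battery is designed to
detect: anti-saccades are slower and more error-prone than pro-saccades,
the memory and orientation environments add a cognitive latency cost, the
memory task amplifies sway, and eye closure amplifies it further.  These
effect sizes are the simulator's definition of the study conditions, not
fitted quantities.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import RunConfig, _FLOAT_FMT
from .posture import compute_posture_metrics
from .protocol import (
    Condition,
    Environment,
    OculomotorTask,
    build_schedule,
    get_condition,
)
from .saccades import aggregate_condition, pupil_psd, score_schedule
from .simulate import (
    DEFAULT_COP_RATE_HZ,
    SubjectModel,
    simulate_cop,
    simulate_gaze,
)
from .stats import (
    CONDITION,
    PARAMETER,
    SUBJECT,
    VALUE,
    check_distributions,
    friedman_by_factor,
    rank_factorial_anova,
    spearman_matrix,
    wilcoxon_pairwise,
)

log = logging.getLogger("oculosway")

OCULOMETRIC_PARAMS = ("latency_mean", "latency_sd", "peak_speed_mean",
                      "peak_speed_sd", "error_rate")
POSTURE_PARAMS = ("sd_ap", "sd_ml", "speed_total", "speed_ap", "speed_ml", "aec")

EO_EC_DURATION_S = 60.0


@dataclass(frozen=True)
class ConditionEffects:
    """Additive/multiplicative condition modifiers applied to a subject."""

    latency_shift: float = 0.0      # s
    error_shift: float = 0.0
    sway_diffusion_factor: float = 1.0
    pupil_amp_factor: float = 1.0


#: condition-specific loads, keyed by condition name
CONDITION_EFFECTS: dict[str, ConditionEffects] = {
    "EO": ConditionEffects(),
    "EC": ConditionEffects(sway_diffusion_factor=1.6),
    "2D-G": ConditionEffects(),
    "2D-P": ConditionEffects(),
    "2D-A": ConditionEffects(latency_shift=0.040, error_shift=0.12),
    "3D-P": ConditionEffects(latency_shift=0.010, error_shift=0.02),
    "3D-A": ConditionEffects(latency_shift=0.055, error_shift=0.14),
    "VM-P": ConditionEffects(latency_shift=0.130, error_shift=0.08,
                             sway_diffusion_factor=1.35,
                             pupil_amp_factor=1.10),
    "VM-A": ConditionEffects(latency_shift=0.150, error_shift=0.16,
                             sway_diffusion_factor=1.45,
                             pupil_amp_factor=0.95),
    "SO-P": ConditionEffects(latency_shift=0.110, error_shift=0.08,
                             sway_diffusion_factor=1.20),
    "SO-A": ConditionEffects(latency_shift=0.130, error_shift=0.15,
                             sway_diffusion_factor=1.25),
}


def draw_subject(rng: np.random.Generator) -> SubjectModel:
    """Sample a synthetic participant's baseline parameters."""
    return SubjectModel(
        latency_mean=float(np.clip(rng.normal(0.230, 0.025), 0.15, 0.40)),
        latency_sd=float(np.clip(rng.normal(0.045, 0.010), 0.02, 0.10)),
        error_prob=float(np.clip(rng.normal(0.06, 0.03), 0.0, 0.3)),
        main_sequence_vmax=float(np.clip(rng.normal(500.0, 40.0), 350, 650)),
        cop_relaxation=float(np.clip(rng.normal(1.0, 0.15), 0.5, 2.0)),
        cop_diffusion=float(np.clip(rng.normal(8.0, 2.0), 3.0, 16.0)),
        gaze_noise_sd=0.10,
        intrusion_rate=0.05,
        pupil_osc_amp=float(np.clip(rng.normal(0.10, 0.02), 0.04, 0.2)),
    )


def apply_condition(subject: SubjectModel, condition: Condition) -> SubjectModel:
    eff = CONDITION_EFFECTS[condition.name]
    return dataclasses.replace(
        subject,
        latency_mean=subject.latency_mean + eff.latency_shift,
        error_prob=float(np.clip(subject.error_prob + eff.error_shift, 0, 1)),
        cop_diffusion=subject.cop_diffusion * eff.sway_diffusion_factor,
        pupil_osc_amp=subject.pupil_osc_amp * eff.pupil_amp_factor,
    )


@dataclass
class PipelineReport:
    config: RunConfig
    trial_scores: pd.DataFrame
    condition_summary: pd.DataFrame
    long_table: pd.DataFrame
    distribution_checks: pd.DataFrame
    anova: pd.DataFrame
    friedman: pd.DataFrame
    pairwise: pd.DataFrame
    spearman: pd.DataFrame
    log_lines: list[str]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = {"config_hash": self.config.config_hash()}
        for name, df in [
            ("trial_scores", self.trial_scores),
            ("condition_summary", self.condition_summary),
            ("long_table", self.long_table),
            ("distribution_checks", self.distribution_checks),
            ("anova", self.anova),
            ("friedman", self.friedman),
            ("pairwise", self.pairwise),
            ("spearman", self.spearman),
        ]:
            path = outdir / f"{name}.csv"
            with open(path, "w", newline="") as fh:
                fh.write(f"# config_hash={tag['config_hash']}\n")
                df.to_csv(fh, index=False, float_format=_FLOAT_FMT)
        self.config.to_json(outdir / "config.json")
        with open(outdir / "run_log.json", "w") as fh:
            json.dump({"seed": self.config.seed, "version": __version__,
                       "config_hash": tag["config_hash"],
                       "log": self.log_lines}, fh, indent=1)


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Simulate, score, and analyse one synthetic cohort."""
    root_ss = np.random.SeedSequence(config.seed)
    subj_ss = root_ss.spawn(config.n_subjects)
    conditions = [get_condition(i) for i in config.conditions]
    log_lines: list[str] = []

    trial_rows, summary_rows, long_rows = [], [], []
    for s_idx, ss in enumerate(subj_ss):
        subj_rng = np.random.default_rng(ss.spawn(1)[0])
        base = draw_subject(subj_rng)
        cond_ss = ss.spawn(len(conditions))
        for cond, css in zip(conditions, cond_ss):
            subject = apply_condition(base, cond)
            seeds = css.generate_state(3) % (2**31)
            if cond.environment in (Environment.EO, Environment.EC):
                duration = EO_EC_DURATION_S
                posture_window = (0.0, duration)
                gaze = truth = None
                schedule = None
            else:
                schedule = build_schedule(cond, int(seeds[0]))
                duration = schedule.total_duration
                posture_window = (schedule.posture_recording_start, duration)
                gaze, truth = simulate_gaze(
                    schedule, subject, config.gaze_sample_rate, int(seeds[1])
                )
            cop = simulate_cop(duration, subject, config.cop_sample_rate,
                               int(seeds[2]))
            pm = compute_posture_metrics(cop, posture_window)
            for k, v in pm.as_dict().items():
                if k == "duration":
                    continue
                long_rows.append((s_idx, cond.index, k, v))

            if gaze is not None:
                psd = pupil_psd(gaze.pupil, gaze.sample_rate,
                                band=config.pupil_band)
                long_rows.append((s_idx, cond.index, "pupil_band_psd",
                                  psd.band_mean))

            if cond.has_saccade_task:
                scores = score_schedule(
                    schedule, gaze,
                    velocity_threshold=config.velocity_threshold,
                    min_duration=config.min_saccade_duration,
                    anticipation_floor=config.anticipation_floor,
                    roi_half_width=config.roi_half_width,
                )
                for sc in scores:
                    trial_rows.append({
                        "subject": s_idx, "condition": cond.index,
                        "condition_name": cond.name,
                        "trial_index": sc.trial_index,
                        "latency": sc.latency, "peak_speed": sc.peak_speed,
                        "correct": sc.correct, "valid": sc.valid,
                        "reason": sc.reason.value,
                    })
                agg = aggregate_condition(scores)
                summary_rows.append({"subject": s_idx, "condition": cond.index,
                                     "condition_name": cond.name,
                                     **agg.as_dict(), **pm.as_dict()})
                for k, v in agg.as_dict().items():
                    if k == "n_valid":
                        continue
                    long_rows.append((s_idx, cond.index, k, v))
                n_invalid = agg.n_trials - agg.n_valid
                log_lines.append(
                    f"subject {s_idx} {cond.name}: {agg.n_valid} valid trials, "
                    f"{n_invalid} invalid"
                )
            else:
                summary_rows.append({"subject": s_idx, "condition": cond.index,
                                     "condition_name": cond.name,
                                     **pm.as_dict()})
                log_lines.append(f"subject {s_idx} {cond.name}: posture only")

    long_table = pd.DataFrame(long_rows,
                              columns=[SUBJECT, CONDITION, PARAMETER, VALUE])
    trial_scores = pd.DataFrame(trial_rows)
    condition_summary = pd.DataFrame(summary_rows)

    # statistics over the factorial conditions present in this run
    fact_conds = [c for c in config.conditions if 4 <= c <= 11]
    stats_tables = {}
    if len(fact_conds) == 8 and config.n_subjects >= 5:
        dist = check_distributions(long_table)
        stats_tables["dist"] = pd.DataFrame(
            [{"parameter": d.parameter, "levene_p": d.levene_p,
              "shapiro_p": d.shapiro_p, "degenerate": d.degenerate}
             for d in dist])
        stats_tables["anova"] = rank_factorial_anova(long_table)
        stats_tables["friedman"] = friedman_by_factor(long_table)
        pw = wilcoxon_pairwise(long_table, adjust=config.adjust_method)
        stats_tables["pairwise"] = pd.DataFrame(
            [dataclasses.asdict(r) for r in pw])
        sp_rows = []
        ocular = [p for p in OCULOMETRIC_PARAMS
                  if p in long_table[PARAMETER].unique()]
        posture = list(POSTURE_PARAMS)
        for c in fact_conds:
            mat = spearman_matrix(long_table, c, ocular + posture)
            for pa in ocular:
                for pb in posture:
                    sp_rows.append({
                        "condition": c, "parameter_a": pa, "parameter_b": pb,
                        "rho": mat.rho.at[pa, pb], "p": mat.p.at[pa, pb],
                        "significant": bool(mat.significant.at[pa, pb]),
                    })
        stats_tables["spearman"] = pd.DataFrame(sp_rows)
        log_lines.append("statistics: factorial battery complete")
    else:
        empty = pd.DataFrame()
        stats_tables = {"dist": empty, "anova": empty, "friedman": empty,
                        "pairwise": empty, "spearman": empty}
        log_lines.append("statistics: skipped (factorial design incomplete)")

    return PipelineReport(
        config=config,
        trial_scores=trial_scores,
        condition_summary=condition_summary,
        long_table=long_table,
        distribution_checks=stats_tables["dist"],
        anova=stats_tables["anova"],
        friedman=stats_tables["friedman"],
        pairwise=stats_tables["pairwise"],
        spearman=stats_tables["spearman"],
        log_lines=log_lines,
    )
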