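"""High-level analysis steps chaining the modules end to end.

These helpers are what the command-line interface and the demonstration
workflow call: detect events on a batch of traces, tabulate behavior,
bootstrap the cueing-effect family with FDR correction, and score the
microsaccade direction bias per design cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import DetectorParams, apply_trial_exclusions, detect_events
from .inference import BootstrapResult, apply_fdr, hierarchical_bootstrap
from .io import trials_to_frame
from .metrics import align_events, trial_bias_table
from .sdt import cueing_effects, dprime, group_cueing_effects, tabulate_sdt
from .types import GazeTrace, OcularEvent, TrialRecord

__all__ = ["detect_all", "subject_delta_dprime", "bootstrap_cueing_effects",
           "bootstrap_direction_bias", "run_demo"]

logger = logging.getLogger(__name__)


def detect_all(traces: list[GazeTrace], params: DetectorParams | None = None,
               ) -> list[OcularEvent]:
    """Run the event detector over a batch of traces."""
    params = params or DetectorParams()
    events: list[OcularEvent] = []
    for trace in traces:
        events.extend(detect_events(trace, params))
    return events


def subject_delta_dprime(cell_trials: pd.DataFrame) -> float:
    """One subject's valid-minus-invalid d' from their trials in one cell.

    The false-alarm rate is shared between validities (validity is undefined
    on target-absent trials). NaN when any required sub-cell is empty.
    """
    present = cell_trials[cell_trials["target_present"] == 1]
    absent = cell_trials[cell_trials["target_present"] == 0]
    pv = present[present["cue_validity"] == "valid"]
    pi = present[present["cue_validity"] == "invalid"]
    if len(pv) == 0 or len(pi) == 0 or len(absent) == 0:
        return float("nan")
    fa = (absent["response"] == "present").mean()
    d_v = dprime((pv["response"] == "present").mean(), fa, len(pv), len(absent))
    d_i = dprime((pi["response"] == "present").mean(), fa, len(pi), len(absent))
    return d_v - d_i


def bootstrap_cueing_effects(trials: list[TrialRecord] | pd.DataFrame,
                             n_boot: int = 10_000,
                             seed: int | None = None,
                             rng: np.random.Generator | None = None,
                             alternative: str = "two-sided",
                             ) -> dict[tuple[str, int], BootstrapResult]:
    """Hierarchical bootstrap of the mean delta-d' in every condition x SOA
    cell, FDR-corrected as one family."""
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    df = df[df["excluded"] == 0] if "excluded" in df.columns else df
    rng = rng if rng is not None else np.random.default_rng(seed)
    keys, results = [], []
    for (cond, soa), cell in df.groupby(["condition", "soa_ms"], sort=True):
        res = hierarchical_bootstrap(
            cell, subject_statistic=subject_delta_dprime, n_boot=n_boot,
            rng=rng, null_value=0.0, alternative=alternative,
            label=f"delta_dprime[{cond},{soa}]")
        keys.append((str(cond), int(soa)))
        results.append(res)
    return dict(zip(keys, apply_fdr(results)))


def bootstrap_direction_bias(aligned: pd.DataFrame,
                             trials: list[TrialRecord],
                             window_ms: tuple[float, float] = (400.0, 800.0),
                             measure: str = "proportion_toward",
                             n_boot: int = 10_000,
                             seed: int | None = None,
                             rng: np.random.Generator | None = None,
                             alternative: str = "two-sided",
                             ) -> dict[tuple[str, int, str], BootstrapResult]:
    """Bootstrap the per-trial toward-cue statistic per condition x SOA x
    validity cell against its chance level (0.5 for the proportion, 0 for
    signed degrees), FDR-corrected as one family."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    null_value = 0.5 if measure == "proportion_toward" else 0.0
    table = trial_bias_table(aligned, trials, window_ms)
    table = table[table["cue_validity"].isin(["valid", "invalid"])]

    def subject_mean(sub: pd.DataFrame) -> float:
        vals = sub[measure].dropna()
        return float(vals.mean()) if len(vals) else float("nan")

    keys, results = [], []
    for (cond, soa, validity), cell in table.groupby(
            ["condition", "soa_ms", "cue_validity"], sort=True):
        res = hierarchical_bootstrap(
            cell, subject_statistic=subject_mean, n_boot=n_boot, rng=rng,
            null_value=null_value, alternative=alternative,
            label=f"{measure}[{cond},{soa},{validity}]")
        keys.append((str(cond), int(soa), str(validity)))
        results.append(res)
    return dict(zip(keys, apply_fdr(results)))


@dataclass
class DemoResult:
    """Everything the end-to-end demonstration computes."""

    trials: list
    kept_trials: list
    exclusion_report: dict
    events: list
    sdt_group: pd.DataFrame
    dprime_tests: dict
    bias_tests: dict


def run_demo(cfg, trace_subjects: int = 5, n_boot: int | None = None,
             rng: np.random.Generator | None = None) -> DemoResult:
    """Simulate -> detect -> behavior -> microsaccades -> bootstrap.

    The behavioral pipeline uses the full cohort; gaze traces (the compute-
    heavy part) are generated for the first ``trace_subjects`` subjects,
    which is enough to exercise detection, exclusion, and the direction-bias
    metrics.
    """
    from .simulate import simulate_experiment

    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n_boot = n_boot if n_boot is not None else cfg.n_boot
    trials, traces, _ = simulate_experiment(
        cfg.behavior, cfg.trace, rng=rng, toward_map=cfg.toward_map,
        trace_subjects=trace_subjects)
    events = detect_all(traces, cfg.detector)
    traced_ids = {t.trial_id for t in traces}
    kept, report = apply_trial_exclusions(
        [t for t in trials if t.trial_id in traced_ids], events, traces,
        cfg.detector.fixation_radius_deg)
    kept_ids = {t.trial_id for t in kept}
    # behavioral analysis keeps all subjects; traced trials excluded for
    # blinks/fixation breaks are dropped
    analysis_trials = [t for t in trials
                       if t.trial_id not in traced_ids
                       or t.trial_id in kept_ids]
    sdt_group = group_cueing_effects(cueing_effects(tabulate_sdt(analysis_trials)))
    dprime_tests = bootstrap_cueing_effects(analysis_trials, n_boot=n_boot,
                                            rng=rng,
                                            alternative=cfg.alternative)
    aligned = align_events(
        [e for e in events if e.trial_id in kept_ids], kept,
        anchor="array_onset")
    bias_tests = bootstrap_direction_bias(
        aligned, kept, window_ms=cfg.bias_window_ms, n_boot=n_boot, rng=rng,
        alternative=cfg.alternative)
    return DemoResult(trials=trials, kept_trials=kept,
                      exclusion_report=report, events=events,
                      sdt_group=sdt_group, dprime_tests=dprime_tests,
                      bias_tests=bias_tests)
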