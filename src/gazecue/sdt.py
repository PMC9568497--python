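"""Signal-detection tabulation and cueing-effect measures.

Hit rates are tabulated per subject x condition x SOA x cue validity; false
alarms are shared within the subject x condition x SOA cell because validity
is undefined on target-absent trials. Sensitivity is
d' = Phi^-1(h*) - Phi^-1(f*), with extreme rates clamped to
[1/(2n), 1 - 1/(2n)] of their trial counts so d' stays finite. The cueing
effect is the per-subject valid-minus-invalid difference in hit rate and d';
group effects are summarized across subjects (never from pooled rates, which
is a different and non-equivalent quantity).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError
from .io import trials_to_frame
from .types import TrialRecord

__all__ = ["SDTSummary", "CueingEffect", "dprime", "tabulate_sdt",
           "cueing_effects", "cueing_effect_frame", "group_cueing_effects",
           "cohens_d", "sdt_to_frame"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SDTSummary:
    """Per subject x condition x SOA detection counts and sensitivities.

    ``fa_rate``/``dprime_*`` are NaN when a required cell is empty (flagged
    via ``complete``).
    """

    subject_id: str
    condition: str
    soa_ms: int
    n_present_valid: int
    n_hits_valid: int
    n_present_invalid: int
    n_hits_invalid: int
    n_absent: int
    n_false_alarms: int
    hit_rate_valid: float
    hit_rate_invalid: float
    fa_rate: float
    dprime_valid: float
    dprime_invalid: float
    complete: bool


@dataclass(frozen=True)
class CueingEffect:
    """Per-subject valid-minus-invalid cueing effect in one cell."""

    subject_id: str
    condition: str
    soa_ms: int
    delta_hit_rate: float
    delta_dprime: float


def _clamp_rate(rate: float, n: int) -> float:
    lo = 1.0 / (2.0 * n)
    return min(max(rate, lo), 1.0 - lo)


def dprime(hit_rate: float, fa_rate: float, n_present: int, n_absent: int,
           correction: str = "clamp") -> float:
    """Sensitivity d' with extreme-rate correction.

    ``correction='clamp'`` (default) clamps each rate to
    ``[1/(2n), 1 - 1/(2n)]`` of its own trial count; ``'loglinear'`` adds
    0.5 to each count and 1 to each total before forming rates.
    """
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ValidationError("rates must lie in [0, 1]")
    if n_present < 1 or n_absent < 1:
        raise ValidationError("trial counts must be >= 1")
    if correction == "clamp":
        h = _clamp_rate(hit_rate, n_present)
        f = _clamp_rate(fa_rate, n_absent)
    elif correction == "loglinear":
        h = (hit_rate * n_present + 0.5) / (n_present + 1.0)
        f = (fa_rate * n_absent + 0.5) / (n_absent + 1.0)
    else:
        raise ValidationError(f"unknown correction {correction!r}")
    return float(norm.ppf(h) - norm.ppf(f))


def tabulate_sdt(trials: list[TrialRecord] | pd.DataFrame,
                 correction: str = "clamp") -> list[SDTSummary]:
    """Tabulate detection behavior per subject x condition x SOA cell.

    Excluded trials are ignored. Cells missing a validity or the absent
    trials emit a summary with NaN rates and ``complete=False`` plus a
    logged warning.
    """
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    if df.empty:
        return []
    df = df[df["excluded"] == 0] if "excluded" in df.columns else df
    out: list[SDTSummary] = []
    for (subj, cond, soa), cell in df.groupby(
            ["subject_id", "condition", "soa_ms"], sort=True):
        present = cell[cell["target_present"] == 1]
        absent = cell[cell["target_present"] == 0]
        pv = present[present["cue_validity"] == "valid"]
        pi = present[present["cue_validity"] == "invalid"]
        n_pv, n_pi, n_a = len(pv), len(pi), len(absent)
        hits_v = int((pv["response"] == "present").sum())
        hits_i = int((pi["response"] == "present").sum())
        fas = int((absent["response"] == "present").sum())
        complete = n_pv > 0 and n_pi > 0 and n_a > 0
        if not complete:
            logger.warning(
                "cell (%s, %s, %s) incomplete: %d valid-present, %d "
                "invalid-present, %d absent trials", subj, cond, soa,
                n_pv, n_pi, n_a)
        hr_v = hits_v / n_pv if n_pv else math.nan
        hr_i = hits_i / n_pi if n_pi else math.nan
        fa = fas / n_a if n_a else math.nan
        out.append(SDTSummary(
            subject_id=str(subj), condition=str(cond), soa_ms=int(soa),
            n_present_valid=n_pv, n_hits_valid=hits_v,
            n_present_invalid=n_pi, n_hits_invalid=hits_i,
            n_absent=n_a, n_false_alarms=fas,
            hit_rate_valid=hr_v, hit_rate_invalid=hr_i, fa_rate=fa,
            dprime_valid=(dprime(hr_v, fa, n_pv, n_a, correction)
                          if complete else math.nan),
            dprime_invalid=(dprime(hr_i, fa, n_pi, n_a, correction)
                            if complete else math.nan),
            complete=complete,
        ))
    return out


def sdt_to_frame(summaries: list[SDTSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def cueing_effects(summaries: list[SDTSummary]) -> list[CueingEffect]:
    """Per-subject valid-minus-invalid deltas; incomplete cells are omitted
    with a logged warning."""
    out = []
    for s in summaries:
        if not s.complete:
            logger.warning("cell (%s, %s, %s) incomplete; effect omitted",
                           s.subject_id, s.condition, s.soa_ms)
            continue
        out.append(CueingEffect(
            subject_id=s.subject_id, condition=s.condition, soa_ms=s.soa_ms,
            delta_hit_rate=s.hit_rate_valid - s.hit_rate_invalid,
            delta_dprime=s.dprime_valid - s.dprime_invalid,
        ))
    return out


def cueing_effect_frame(effects: list[CueingEffect]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in effects])


def group_cueing_effects(effects: list[CueingEffect]) -> pd.DataFrame:
    """Across-subject mean, SE, and Cohen's d per condition x SOA.

    Cells with a single subject carry NaN SE and effect size (flagged by
    ``n_subjects``).
    """
    df = cueing_effect_frame(effects)
    rows = []
    for (cond, soa), cell in df.groupby(["condition", "soa_ms"], sort=True):
        n = len(cell)
        for measure in ("delta_hit_rate", "delta_dprime"):
            vals = cell[measure].to_numpy(dtype=float)
            rows.append({
                "condition": cond, "soa_ms": soa, "measure": measure,
                "n_subjects": n,
                "mean": float(np.mean(vals)),
                "se": float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1
                      else math.nan,
                "cohens_d": cohens_d(vals) if n > 1 else math.nan,
            })
    return pd.DataFrame(rows)


def cohens_d(per_subject_deltas) -> float:
    """Paired-design effect size: mean(delta) / SD(delta).

    NaN (with a logged warning) when the deltas have zero spread.
    """
    deltas = np.asarray(per_subject_deltas, dtype=float)
    if deltas.size < 2:
        raise ValidationError("Cohen's d needs at least 2 subjects")
    sd = float(np.std(deltas, ddof=1))
    if sd == 0.0:
        logger.warning("zero SD across subjects; Cohen's d undefined")
        return math.nan
    return float(np.mean(deltas) / sd)
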