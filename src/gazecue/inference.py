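"""Hierarchical bootstrap inference, FDR correction, and the median test.

The bootstrap respects the nested participant/trial structure: each
replicate draws subjects with replacement and carries *all* trials of every
drawn subject (a subject drawn twice contributes its trials twice). The
p-value uses the smoothed null-crossing convention
``2 * min[(1 + #{theta* <= theta0}) / (B + 1), (1 + #{theta* >= theta0}) / (B + 1)]``
capped at 1, with one-sided variants available. Families of p-values are
corrected with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateTableError, InferenceError, ValidationError

__all__ = ["BootstrapResult", "hierarchical_bootstrap", "fdr_adjust",
           "apply_fdr", "median_test"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapResult:
    """Observed statistic plus its bootstrap distribution summary.

    ``p_fdr`` is NaN until the result is adjusted within a family via
    :func:`apply_fdr`.
    """

    statistic_label: str
    observed: float
    n_boot: int
    boot_mean: float
    boot_sd: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_fdr: float
    null_value: float
    alternative: str
    seed: int | None

    def significant(self, alpha: float = 0.05) -> bool:
        p = self.p_fdr if math.isfinite(self.p_fdr) else self.p_raw
        return p <= alpha


def _crossing_p(boots: np.ndarray, null_value: float, alternative: str) -> float:
    n = boots.size
    p_le = (1 + int(np.sum(boots <= null_value))) / (n + 1)
    p_ge = (1 + int(np.sum(boots >= null_value))) / (n + 1)
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_le, p_ge))
    if alternative == "greater":   # H1: theta > null_value
        return min(1.0, p_le)
    if alternative == "less":      # H1: theta < null_value
        return min(1.0, p_ge)
    raise ValidationError(
        f"alternative must be 'two-sided', 'greater' or 'less', "
        f"got {alternative!r}")


def hierarchical_bootstrap(data: pd.DataFrame, statistic=None, *,
                           subject_statistic=None, n_boot: int = 10_000,
                           rng: np.random.Generator | None = None,
                           seed: int | None = None, null_value: float = 0.0,
                           alternative: str = "two-sided",
                           subject_col: str = "subject_id",
                           label: str = "statistic",
                           max_undefined_frac: float = 0.01,
                           ) -> BootstrapResult:
    """Subject-level bootstrap of a dataset statistic.

    Parameters
    ----------
    data : DataFrame
        Trial-level records carrying a ``subject_col`` column.
    statistic : callable, optional
        Maps a resampled DataFrame to a scalar. Resamples on which it
        returns NaN are redrawn; more than ``max_undefined_frac`` undefined
        replicates aborts with :class:`InferenceError`.
    subject_statistic : callable, optional
        Fast path for statistics of the form "mean over subjects of a
        per-subject summary": maps one subject's trials to a scalar. The
        per-subject values are computed once and each replicate averages a
        with-replacement draw of them - algebraically identical to applying
        ``statistic = mean of per-subject summaries`` to the resampled
        trials, but vectorized.
    """
    if (statistic is None) == (subject_statistic is None):
        raise ValidationError(
            "provide exactly one of statistic / subject_statistic")
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_boot < 100:
        logger.warning("n_boot=%d is very small; p-values will be coarse",
                       n_boot)
    groups = {s: g for s, g in data.groupby(subject_col, sort=True)}
    subjects = list(groups)
    n_subj = len(subjects)
    if n_subj < 2:
        raise InferenceError(f"{label}: need >= 2 subjects, got {n_subj}")

    if subject_statistic is not None:
        values = np.array([float(subject_statistic(groups[s]))
                           for s in subjects])
        if not np.isfinite(values).all():
            bad = [s for s, v in zip(subjects, values) if not math.isfinite(v)]
            raise InferenceError(
                f"{label}: per-subject statistic undefined for {bad[:5]}")
        observed = float(values.mean())
        idx = rng.integers(0, n_subj, size=(n_boot, n_subj))
        boots = values[idx].mean(axis=1)
    else:
        observed = float(statistic(data))
        boots = np.empty(n_boot)
        frames = [groups[s] for s in subjects]
        n_undefined = 0
        max_undefined = max(1, int(max_undefined_frac * n_boot))
        for b in range(n_boot):
            while True:
                ids = rng.integers(0, n_subj, size=n_subj)
                val = float(statistic(
                    pd.concat([frames[i] for i in ids], ignore_index=True)))
                if math.isfinite(val):
                    boots[b] = val
                    break
                n_undefined += 1
                if n_undefined > max_undefined:
                    raise InferenceError(
                        f"{label}: more than {max_undefined_frac:.0%} of "
                        f"bootstrap replicates undefined")

    lo, hi = np.percentile(boots, [2.5, 97.5])
    return BootstrapResult(
        statistic_label=label, observed=observed, n_boot=int(n_boot),
        boot_mean=float(boots.mean()), boot_sd=float(boots.std(ddof=1)),
        ci_low=float(lo), ci_high=float(hi),
        p_raw=_crossing_p(boots, null_value, alternative),
        p_fdr=math.nan, null_value=float(null_value),
        alternative=alternative, seed=seed)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(results: list[BootstrapResult]) -> list[BootstrapResult]:
    """Fill ``p_fdr`` across one family of bootstrap results."""
    adjusted = fdr_adjust([r.p_raw for r in results])
    return [replace(r, p_fdr=float(q)) for r, q in zip(results, adjusted)]


def median_test(a, b) -> dict:
    """Mood's median test without continuity correction, plus phi.

    Pools both samples, counts values above vs. not-above the grand median
    per group (ties count as not-above), and computes the 1-df chi-square
    with effect size ``phi = sqrt(chi2 / N)``. Raises
    :class:`DegenerateTableError` when a margin of the 2x2 table is empty.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    try:
        chi2, p, grand_median, table = stats.median_test(
            a, b, ties="below", correction=False)
    except ValueError as exc:
        raise DegenerateTableError(str(exc)) from exc
    n = a.size + b.size
    return {"chi2": float(chi2), "p": float(p),
            "phi": float(math.sqrt(chi2 / n)),
            "grand_median": float(grand_median),
            "table": np.asarray(table)}
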