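"""From raw trial records to per-condition bias/SD summaries.

The chain mirrors the standard analysis of center-localization trials:

1. the response **endpoint** is the mean hand position over the final
   100 ms before the confirmation press;
2. for bilateral trials the empirical field center is the mean of the
   **zero-crossings** of the measured force (positions where the force
   changes sign, located by linear interpolation); unilateral trials use
   the designed center, since their force is zero on one whole side;
3. trials are rejected when the device quality flag is raised for more
   than 0.5 s consecutively, or when an endpoint error is more than 5
   leave-one-out SDs from the leave-one-out condition mean;
4. per condition: bias = mean signed error, SD across trials (n-1
   denominator); group level: unweighted participant means with standard
   errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import Condition, TrialRecord, SAMPLE_RATE

__all__ = [
    "ENDPOINT_WINDOW",
    "MAX_FLAGGED_RUN",
    "OUTLIER_SD_CRITERION",
    "ConditionSummary",
    "GroupSummary",
    "extract_endpoint",
    "zero_crossings",
    "estimate_center_exp1",
    "trial_error",
    "max_flagged_run",
    "reject_outliers",
    "summarize",
    "summarize_participant",
    "group_summarize",
    "preprocess_participant",
]

ENDPOINT_WINDOW: float = 0.1        # s, response-averaging window
MAX_FLAGGED_RUN: float = 0.5        # s, criterion-1 limit (strictly greater rejects)
OUTLIER_SD_CRITERION: float = 5.0   # criterion-2 leave-one-out threshold


@dataclass(frozen=True)
class ConditionSummary:
    """Bias and across-trial SD of one participant in one condition."""

    condition: Condition
    bias: float       # m, signed (+ rightward)
    sd: float         # m
    n_trials: int
    n_rejected: int = 0


@dataclass(frozen=True)
class GroupSummary:
    """Across-participant average of one condition's summaries."""

    condition: Condition
    bias: float       # m, mean of participant biases
    se: float         # m, SD of participant biases / sqrt(n)
    sd: float         # m, mean of participant SDs
    n_participants: int


def extract_endpoint(record: TrialRecord) -> float:
    """Mean hand position over the trial's final 100 ms, m."""
    t_end = record.end_pressed_at
    if record.t[-1] - record.t[0] < ENDPOINT_WINDOW:
        raise ValueError("record shorter than the endpoint window")
    window = record.t > t_end - ENDPOINT_WINDOW
    return float(np.mean(record.x[window]))


def zero_crossings(record: TrialRecord) -> list[float]:
    """Positions where the measured force changes sign, m.

    Each crossing is located by linear interpolation of position against
    force between the two samples that bracket the sign change.
    """
    F = record.F_measured
    x = record.x
    sign = np.sign(F)
    out: list[float] = []
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        f1, f2 = F[i], F[i + 1]
        out.append(float(x[i] + (0.0 - f1) * (x[i + 1] - x[i]) / (f2 - f1)))
    # a sample landing exactly on zero is itself a crossing position
    for i in np.nonzero(sign == 0)[0]:
        out.append(float(x[i]))
    return sorted(out)


def estimate_center_exp1(record: TrialRecord) -> float:
    """Per-trial empirical field center: mean of the force zero-crossings, m.

    Defined for bilateral trials only; a unilateral field's force is zero on
    an entire side, so its crossings do not localize the edge.
    """
    if record.design.condition.side != "bilateral":
        raise ValueError("zero-crossing center estimation is bilateral-only")
    crossings = zero_crossings(record)
    if not crossings:
        raise ValueError("no force zero-crossing found in record")
    return float(np.mean(crossings))


def trial_error(record: TrialRecord) -> float:
    """Signed endpoint error of one trial, m (positive = rightward).

    Bilateral trials are referenced to the per-trial mean zero-crossing;
    unilateral trials to the designed field center.
    """
    endpoint = extract_endpoint(record)
    if record.design.condition.side == "bilateral":
        return endpoint - estimate_center_exp1(record)
    return endpoint - record.design.center


def max_flagged_run(record: TrialRecord) -> float:
    """Longest consecutive quality-flagged stretch, s."""
    flag = np.asarray(record.quality_flag, dtype=bool)
    if not flag.any():
        return 0.0
    best = run = 0
    for f in flag:
        run = run + 1 if f else 0
        best = max(best, run)
    return best / SAMPLE_RATE


def reject_outliers(errors: list[float],
                    flagged_runs: list[float] | None = None
                    ) -> tuple[list[int], list[tuple[int, str]]]:
    """Outlier filtering of one condition's trials.

    Criterion 1 drops trials whose quality flag was raised for more than
    0.5 s consecutively.  Criterion 2 is a single leave-one-out pass over
    the endpoint errors of the surviving trials: trial i is dropped iff
    |e_i - mean(others)| > 5 * SD(others).  A trial deviating from an
    otherwise perfectly consistent condition (SD(others) = 0) is dropped.

    Returns (kept indices, [(rejected index, reason), ...]).
    """
    n = len(errors)
    rejected: list[tuple[int, str]] = []
    survivors = list(range(n))
    if flagged_runs is not None:
        survivors = []
        for i, run in enumerate(flagged_runs):
            if run > MAX_FLAGGED_RUN:
                rejected.append((i, "flagged_run"))
            else:
                survivors.append(i)
    kept: list[int] = []
    if len(survivors) >= 3:
        e = np.asarray([errors[i] for i in survivors])
        for j, i in enumerate(survivors):
            others = np.delete(e, j)
            dev = abs(e[j] - others.mean())
            sd = others.std(ddof=1)
            bad = dev > OUTLIER_SD_CRITERION * sd if sd > 0 else dev > 0
            if bad:
                rejected.append((i, "loo_5sd"))
            else:
                kept.append(i)
    else:
        kept = survivors
    return kept, rejected


def summarize(condition: Condition, errors: list[float],
              n_rejected: int = 0) -> ConditionSummary:
    """Bias (mean signed error) and SD (n-1) across a condition's trials."""
    if len(errors) < 2:
        raise ValueError("need at least 2 trials for a condition summary")
    e = np.asarray(errors, dtype=float)
    return ConditionSummary(condition, float(e.mean()),
                            float(e.std(ddof=1)), len(errors), n_rejected)


def summarize_participant(pairs: list[tuple["object", float]]
                          ) -> list[ConditionSummary]:
    """Condition summaries from (design, endpoint) pairs.

    Convenience path for endpoint-level simulations where no trajectory
    exists: errors are referenced to the designed centers.
    """
    by_cond: dict[Condition, list[float]] = {}
    for design, endpoint in pairs:
        by_cond.setdefault(design.condition, []).append(endpoint - design.center)
    out = []
    for cond, errors in by_cond.items():
        kept, rej = reject_outliers(errors)
        out.append(summarize(cond, [errors[i] for i in kept], len(rej)))
    return out


def preprocess_participant(records: list[TrialRecord]
                           ) -> tuple[list[ConditionSummary], pd.DataFrame]:
    """Full chain for one participant's trial records.

    Returns the condition summaries and a per-trial log (endpoint, error,
    kept/rejected and reason).
    """
    by_cond: dict[Condition, list[TrialRecord]] = {}
    for r in records:
        by_cond.setdefault(r.design.condition, []).append(r)
    summaries: list[ConditionSummary] = []
    rows = []
    for cond, trials in by_cond.items():
        errors = [trial_error(r) for r in trials]
        runs = [max_flagged_run(r) for r in trials]
        kept, rejected = reject_outliers(errors, runs)
        reasons = dict(rejected)
        for i, r in enumerate(trials):
            rows.append({"condition": cond.label, "endpoint_m": extract_endpoint(r),
                         "error_m": errors[i], "kept": i in kept,
                         "reject_reason": reasons.get(i, "")})
        summaries.append(summarize(cond, [errors[i] for i in kept],
                                   len(rejected)))
    return summaries, pd.DataFrame(rows)


def group_summarize(per_participant: list[list[ConditionSummary]]
                    ) -> list[GroupSummary]:
    """Average condition summaries across participants.

    Biases and SDs are averaged unweighted; the standard error is the
    across-participant SD of the bias divided by sqrt(n).
    """
    by_cond: dict[Condition, list[ConditionSummary]] = {}
    for summaries in per_participant:
        for s in summaries:
            by_cond.setdefault(s.condition, []).append(s)
    out = []
    for cond, rows in by_cond.items():
        biases = np.array([r.bias for r in rows])
        sds = np.array([r.sd for r in rows])
        n = len(rows)
        se = float(biases.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(GroupSummary(cond, float(biases.mean()), se,
                                float(sds.mean()), n))
    return out
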