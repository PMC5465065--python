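"""Per-animal seizure metrics and sex-group comparisons.

Metrics follow the cohort bookkeeping of the PTZ study: event counts
(events ≥ 5 s after the stabilization window), counts of events longer
than 2 min, mean event duration, latency from injection to the first
event, and whether the animal developed a status-epilepticus-like event.
Animals without seizures are excluded from group means and reported
separately as non-responders. Group comparisons use the classical
pooled-variance two-sample Student t-test (df = n1 + n2 − 2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import (
    AnimalMetrics,
    GroupComparison,
    InsufficientDataError,
    InvalidArgumentError,
    SeizureEvent,
    TimelineMarks,
)

LONG_EVENT_THRESHOLD_S = 120.0


def per_animal_metrics(
    events: list[SeizureEvent],
    marks: TimelineMarks,
    animal_id: str = "animal",
    sex: str | None = None,
) -> AnimalMetrics:
    """Summarize one animal's session. Latency is first onset minus
    injection time; duration and latency are NaN for zero events."""
    durations = np.array([ev.duration for ev in events])
    n = len(events)
    latency = (
        min(ev.onset for ev in events) - marks.injection_time if n else float("nan")
    )
    return AnimalMetrics(
        animal_id=animal_id,
        sex=sex,
        n_events=n,
        n_long_events=int(np.sum(durations > LONG_EVENT_THRESHOLD_S)) if n else 0,
        mean_duration=float(durations.mean()) if n else float("nan"),
        latency_first=float(latency),
        has_SE=any(ev.is_SE for ev in events),
    )


def metrics_frame(metrics: list[AnimalMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [m.animal_id for m in metrics],
            "sex": [m.sex for m in metrics],
            "n_events": [m.n_events for m in metrics],
            "n_long_events": [m.n_long_events for m in metrics],
            "mean_duration": [m.mean_duration for m in metrics],
            "latency_first": [m.latency_first for m in metrics],
            "has_SE": [m.has_SE for m in metrics],
        }
    )


def group_compare(
    metrics: list[AnimalMetrics],
    metric_name: str,
    group_field: str = "sex",
) -> GroupComparison:
    """Pooled-variance two-sample Student t-test between the two groups.

    Only animals with a defined (non-NaN) metric participate; each group
    needs at least two of them. Groups are ordered alphabetically, so the
    statistic's sign follows (first group − second group).
    """
    df = metrics_frame(metrics)
    if metric_name not in df.columns:
        raise InvalidArgumentError(f"unknown metric {metric_name!r}")
    df = df[np.isfinite(df[metric_name].astype(float))]
    groups = sorted(g for g in df[group_field].dropna().unique())
    if len(groups) != 2:
        raise InsufficientDataError(
            f"need exactly two groups in {group_field!r}, got {groups}"
        )
    a = df.loc[df[group_field] == groups[0], metric_name].to_numpy(dtype=float)
    b = df.loc[df[group_field] == groups[1], metric_name].to_numpy(dtype=float)
    if min(len(a), len(b)) < 2:
        raise InsufficientDataError(
            "each group needs >=2 animals with a defined metric"
        )
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        metric=metric_name,
        statistic=float(t),
        df=len(a) + len(b) - 2,
        p_value=float(p),
        group_means={groups[0]: float(a.mean()), groups[1]: float(b.mean())},
        group_sizes={groups[0]: len(a), groups[1]: len(b)},
    )


def pooled_t_oracle(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Textbook pooled-variance t statistic, kept as an independent
    cross-check of :func:`group_compare`."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return float(t), na + nb - 2


def cohort_summary(metrics: list[AnimalMetrics]) -> pd.DataFrame:
    """Per-sex and overall summary over seizing animals.

    Non-responders (zero events) are excluded from the means and counted
    in the ``n_nonresponders`` column, mirroring how the cohort's printed
    group statistics are defined.
    """
    if not metrics:
        raise InvalidArgumentError("need at least one animal")
    df = metrics_frame(metrics)
    rows = []
    sex_groups = [g for g in sorted(df["sex"].dropna().unique())]
    for group in ["all"] + sex_groups:
        sub = df if group == "all" else df[df["sex"] == group]
        seizing = sub[sub["n_events"] > 0]
        rows.append(
            {
                "group": group,
                "n_animals": len(sub),
                "n_seizing": len(seizing),
                "n_nonresponders": int((sub["n_events"] == 0).sum()),
                "mean_count": seizing["n_events"].mean(),
                "sd_count": seizing["n_events"].std(ddof=1),
                "mean_duration": seizing["mean_duration"].mean(),
                "mean_latency": seizing["latency_first"].mean(),
                "n_SE_animals": int(seizing["has_SE"].sum()),
            }
        )
    return pd.DataFrame(rows)


def summary_markdown(summary: pd.DataFrame) -> str:
    """Human-readable cohort summary."""
    lines = ["# Cohort summary", ""]
    for _, r in summary.iterrows():
        lines += [
            f"## {r['group']}",
            f"- animals: {r['n_animals']} ({r['n_seizing']} seizing, "
            f"{r['n_nonresponders']} non-responders)",
            f"- mean events / seizing animal: {r['mean_count']:.2f}",
            f"- mean event duration: {r['mean_duration']:.1f} s",
            f"- mean latency to first event: {r['mean_latency']:.1f} s",
            f"- animals with SE-like events: {r['n_SE_animals']}",
            "",
        ]
    return "\n".join(lines)
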