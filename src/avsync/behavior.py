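"""Behavioral response tables for McGurk-style audiovisual lag experiments.

A response table is a tidy DataFrame with columns ``subject_id``,
``av_lag_ms``, ``category`` and ``count``: per subject and audiovisual lag,
how often each perceptual category (the illusory /ta, the auditory /pa, or
"other") was reported.  Lags run from -300 to 450 ms in steps of 150 ms;
negative lags mean the auditory onset precedes the lip movement.  A
maximum of 40 responses is expected per (subject, lag) cell.

The module implements the descriptive pipeline — low-response filtering,
percentage conversion, illusion-perceiver classification, group curves with
bootstrap confidence bands — plus a synthetic cohort generator so the
pipeline is testable without human data.  The generator's /ta probability
is a bell over lag peaking at 0 ms with a heavier positive-lag shoulder,
matching the reported dominance of illusory perception at positive lags.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "LAGS_MS",
    "CATEGORIES",
    "validate_table",
    "filter_low_response",
    "percent_by_category",
    "classify_perceivers",
    "group_curves",
    "expected_ta_probability",
    "generate_synthetic_responses",
    "read_response_csv",
    "write_response_csv",
]

LAGS_MS = (-300, -150, 0, 150, 300, 450)
CATEGORIES = ("ta", "pa", "other")
MAX_RESPONSES_PER_CELL = 40
_COLS = ["subject_id", "av_lag_ms", "category", "count"]


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema, lag set, category set and count integrality."""
    missing = [c for c in _COLS if c not in table.columns]
    if missing:
        raise ValueError(f"response table missing columns {missing}")
    bad_lags = set(table["av_lag_ms"]) - set(LAGS_MS)
    if bad_lags:
        raise ValueError(f"unknown AV lags {sorted(bad_lags)}; expected {LAGS_MS}")
    bad_cat = set(table["category"]) - set(CATEGORIES)
    if bad_cat:
        raise ValueError(f"unknown categories {sorted(bad_cat)}; expected {CATEGORIES}")
    counts = table["count"]
    if (counts < 0).any() or (counts != counts.astype(int)).any():
        raise ValueError("counts must be non-negative integers")
    return table


def _cell_totals(table: pd.DataFrame) -> pd.DataFrame:
    return (
        table.groupby(["subject_id", "av_lag_ms"], as_index=False)["count"]
        .sum()
        .rename(columns={"count": "total"})
    )


def filter_low_response(
    table: pd.DataFrame, min_responses: int = 35
) -> pd.DataFrame:
    """Drop (subject, lag) cells with fewer than ``min_responses`` responses.

    Cells with too few attempted trials would bias the percentage
    estimates.  The default keeps cells with 35 or more responses out of
    the 40 expected.
    """
    if table.empty:
        return table.copy()
    validate_table(table)
    totals = _cell_totals(table)
    keep = totals[totals["total"] >= min_responses][["subject_id", "av_lag_ms"]]
    return table.merge(keep, on=["subject_id", "av_lag_ms"], how="inner")


def percent_by_category(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell percentages: 100 * count / cell total, one row per category.

    Raises on zero-total cells — filter those out first.
    """
    validate_table(table)
    out = table.merge(_cell_totals(table), on=["subject_id", "av_lag_ms"])
    if (out["total"] == 0).any():
        bad = out.loc[out["total"] == 0, ["subject_id", "av_lag_ms"]].iloc[0]
        raise ValueError(
            f"zero-total cell (subject {bad['subject_id']}, lag {bad['av_lag_ms']} ms): "
            "apply filter_low_response first"
        )
    out["percent"] = 100.0 * out["count"] / out["total"]
    return out[["subject_id", "av_lag_ms", "category", "count", "percent"]]


def classify_perceivers(
    table: pd.DataFrame, threshold_percent: float = 60.0
) -> List:
    """Subjects reporting /ta on at least ``threshold_percent`` of responses
    at any single AV lag (illusion perceivers), sorted."""
    if table.empty:
        return []
    pct = percent_by_category(table)
    ta = pct[pct["category"] == "ta"]
    best = ta.groupby("subject_id")["percent"].max()
    return sorted(best[best >= threshold_percent].index.tolist())


def group_curves(
    table: pd.DataFrame,
    n_boot: int = 1000,
    ci: float = 95.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Group-mean percentage per (lag, category) with bootstrap CI.

    Resamples subjects with replacement; the interval is the percentile
    bootstrap at level ``ci`` (a reproducible convention for descriptive
    error bars, not an inferential test).
    """
    pct = percent_by_category(table)
    wide = pct.pivot_table(
        index="subject_id", columns=["av_lag_ms", "category"], values="percent"
    )
    subjects = wide.index.to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    boot_means = np.empty((n_boot, wide.shape[1]))
    arr = wide.to_numpy()
    for b in range(n_boot):
        idx = rng.integers(0, len(subjects), len(subjects))
        boot_means[b] = np.nanmean(arr[idx], axis=0)
    lo_q, hi_q = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0
    mean = np.nanmean(arr, axis=0)
    lo = np.nanpercentile(boot_means, lo_q, axis=0)
    hi = np.nanpercentile(boot_means, hi_q, axis=0)
    for j, (lag, cat) in enumerate(wide.columns):
        rows.append(
            {"av_lag_ms": lag, "category": cat, "mean_percent": mean[j],
             "ci_low": lo[j], "ci_high": hi[j]}
        )
    return pd.DataFrame(rows).sort_values(["category", "av_lag_ms"]).reset_index(drop=True)


def expected_ta_probability(
    lags_ms: Iterable[float],
    peak_p_ta: float,
    width_ms: float,
    skew: float,
) -> np.ndarray:
    """Ground-truth /ta probability curve of the synthetic generator.

    A bell over lag peaking at 0 ms whose positive-lag side is ``skew``
    times wider than the negative side (skew > 1 shifts illusion dominance
    toward lags where the lip movement leads the sound).
    """
    lags = np.asarray(list(lags_ms), float)
    if width_ms <= 0 or skew <= 0:
        raise ValueError("width_ms and skew must be positive")
    sigma = np.where(lags >= 0, width_ms * skew, width_ms)
    with np.errstate(over="ignore"):
        p = peak_p_ta * np.exp(-0.5 * (lags / sigma) ** 2)
    return p


def generate_synthetic_responses(
    n_subjects: int = 34,
    per_lag_trials: int = 40,
    peak_p_ta: Union[float, Sequence[float]] = 0.85,
    width_ms: float = 220.0,
    skew: float = 1.6,
    p_other: float = 0.10,
    peak_sd: float = 0.10,
    response_rate: float = 1.0,
    lags_ms: Sequence[int] = LAGS_MS,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Seeded synthetic cohort of lag-dependent response counts.

    Per (subject, lag) the attempted-trial count is
    Binomial(``per_lag_trials``, ``response_rate``) and responses are a
    multinomial draw over {ta, pa, other} with p_ta the subject's skewed
    bell over lag (see :func:`expected_ta_probability`), p_other small and
    flat, and p_pa the remainder.  ``peak_p_ta`` may be a scalar (subject
    peaks are then drawn from a clipped normal with spread ``peak_sd``) or
    one value per subject.

    Returns a response table; subject peaks used are attached as the
    ``attrs['peak_p_ta']`` array for ground-truth checks.
    """
    rng = np.random.default_rng(seed)
    if not (0.0 < response_rate <= 1.0):
        raise ValueError("response_rate must lie in (0, 1]")
    if not (0.0 <= p_other < 1.0):
        raise ValueError("p_other must lie in [0, 1)")
    if np.isscalar(peak_p_ta):
        if not (0.0 <= peak_p_ta <= 1.0):
            raise ValueError("peak_p_ta must lie in [0, 1]")
        peaks = np.clip(
            rng.normal(float(peak_p_ta), peak_sd, n_subjects), 0.0, 0.98
        ) if peak_p_ta > 0 else np.zeros(n_subjects)
    else:
        peaks = np.asarray(peak_p_ta, float)
        if peaks.shape != (n_subjects,):
            raise ValueError("per-subject peak_p_ta must have length n_subjects")
        if (peaks < 0).any() or (peaks > 1).any():
            raise ValueError("peak_p_ta values must lie in [0, 1]")
    rows = []
    for s in range(n_subjects):
        p_ta = expected_ta_probability(lags_ms, peaks[s], width_ms, skew)
        for lag, pt in zip(lags_ms, p_ta):
            po = min(p_other, 1.0 - pt)
            pp = 1.0 - pt - po
            n = int(rng.binomial(per_lag_trials, response_rate))
            c_ta, c_pa, c_ot = rng.multinomial(n, [pt, pp, po])
            for cat, c in zip(CATEGORIES, (c_ta, c_pa, c_ot)):
                rows.append(
                    {"subject_id": f"S{s + 1:02d}", "av_lag_ms": int(lag),
                     "category": cat, "count": int(c)}
                )
    table = pd.DataFrame(rows, columns=_COLS)
    table.attrs["peak_p_ta"] = peaks
    return validate_table(table)


def read_response_csv(path) -> pd.DataFrame:
    """Read and validate a response table CSV."""
    return validate_table(pd.read_csv(path))


def write_response_csv(table: pd.DataFrame, path) -> None:
    validate_table(table).to_csv(path, index=False)
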