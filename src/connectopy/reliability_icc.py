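"""Test–retest and between-subject reliability of connectopic maps.

Reliability is quantified with the intraclass correlation coefficient
ICC(2,1): two-way random effects, absolute agreement, single measure.
For between-session reliability, the two sessions of one subject act as
the k = 2 raters over vertices; for between-subject reliability, every
unordered subject pair within a session does.  Summary values are the
mean ICC with a 10,000-sample percentile-bootstrap 95% CI of that mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._rng import STREAM_BOOTSTRAP, substream
from .connectopic_mapping import ConnectopicMap

logger = logging.getLogger(__name__)


@dataclass
class ICCResult:
    """Mean ICC over units (subjects or subject pairs) with bootstrap CI."""

    comparison: str           # "between_sessions" | "between_subjects"
    mode: int
    mean: float
    ci_low: float
    ci_high: float
    per_unit: np.ndarray
    unit_labels: list
    session_label: str | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean <= self.ci_high:
            raise ValueError("CI must bracket the mean")


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1) from a targets × raters matrix.

    Two-way random-effects ANOVA over targets (rows) and raters
    (columns)::

        ICC(2,1) = (MS_R - MS_E) /
                   (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

    with MS_R, MS_C, MS_E the row, column and residual mean squares.
    Measures absolute agreement of single measurements; 1 for identical
    columns with non-zero row variance.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D targets × raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 targets and 2 raters; got {x.shape}")
    grand = x.mean()
    if np.ptp(x) == 0:
        raise ValueError("ratings have zero total variance; ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ms_r = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ms_e = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float((ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n))


def _bootstrap_ci(
    values: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI of the mean of ``values``."""
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot = values[idx].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    # a percentile CI of the mean can narrowly miss the point estimate on
    # tiny samples; widen to bracket it so the summary stays coherent
    return float(min(lo, values.mean())), float(max(hi, values.mean()))


CohortMaps = dict[tuple[str, str], ConnectopicMap]  # (subject, session) → map


def _check_cohort(cohort_maps: CohortMaps) -> tuple[list[str], list[str], int]:
    subjects = sorted({s for s, _ in cohort_maps})
    sessions = sorted({ss for _, ss in cohort_maps})
    n_vertices = {m.n_vertices for m in cohort_maps.values()}
    if len(n_vertices) != 1:
        raise ValueError("all maps must share the same vertex indexing")
    return subjects, sessions, n_vertices.pop()


def between_session_icc(
    cohort_maps: CohortMaps,
    mode: int,
    n_boot: int = 10_000,
    rng_seed: int = 0,
) -> ICCResult:
    """Mean within-subject, between-session ICC(2,1) for one gradient.

    Per subject, the two sessions' aligned maps are the two raters over
    vertices; the mean over subjects is reported with a bootstrap CI
    from resampling subjects.
    """
    subjects, sessions, _ = _check_cohort(cohort_maps)
    if len(sessions) != 2:
        raise ValueError(f"between-session ICC needs exactly 2 sessions; got {sessions}")
    per_subject = []
    kept = []
    for subj in subjects:
        try:
            ratings = np.column_stack(
                [cohort_maps[(subj, ses)].mode(mode) for ses in sessions]
            )
        except KeyError:
            logger.warning("between_session_icc: subject %s misses a session; skipped", subj)
            continue
        per_subject.append(icc_2_1(ratings))
        kept.append(subj)
    if not kept:
        raise ValueError("no subject has both sessions")
    per_subject = np.asarray(per_subject)
    rng = substream(rng_seed, STREAM_BOOTSTRAP, 1, mode)
    lo, hi = _bootstrap_ci(per_subject, n_boot, rng)
    return ICCResult(
        comparison="between_sessions",
        mode=mode,
        mean=float(per_subject.mean()),
        ci_low=lo,
        ci_high=hi,
        per_unit=per_subject,
        unit_labels=kept,
    )


def between_subject_icc(
    cohort_maps: CohortMaps,
    session: str,
    mode: int,
    n_boot: int = 10_000,
    rng_seed: int = 0,
    resample: str = "pairs",
) -> ICCResult:
    """Mean between-subject ICC(2,1) within one session for one gradient.

    ICC is computed for every unordered distinct subject pair, the two
    subjects acting as raters over vertices.  The bootstrap CI of the
    mean resamples pairs by default (``resample="subjects"`` resamples
    subjects and recomputes the pair mean instead).
    """
    subjects, _, _ = _check_cohort(cohort_maps)
    in_session = [s for s in subjects if (s, session) in cohort_maps]
    if len(in_session) < 2:
        raise ValueError(f"between-subject ICC needs >= 2 subjects in session {session!r}")
    pairs = list(combinations(in_session, 2))
    per_pair = np.asarray(
        [
            icc_2_1(
                np.column_stack(
                    [cohort_maps[(a, session)].mode(mode), cohort_maps[(b, session)].mode(mode)]
                )
            )
            for a, b in pairs
        ]
    )
    rng = substream(rng_seed, STREAM_BOOTSTRAP, 2, mode)
    if resample == "pairs":
        lo, hi = _bootstrap_ci(per_pair, n_boot, rng)
    elif resample == "subjects":
        n_subj = len(in_session)
        pair_idx = {s: [] for s in in_session}
        for p, (a, b) in enumerate(pairs):
            pair_idx[a].append(p)
            pair_idx[b].append(p)
        boot = np.empty(n_boot)
        for t in range(n_boot):
            chosen = rng.integers(0, n_subj, size=n_subj)
            names = {in_session[c] for c in chosen}
            sel = [p for p, (a, b) in enumerate(pairs) if a in names and b in names]
            boot[t] = per_pair[sel].mean() if sel else per_pair.mean()
        lo_, hi_ = np.percentile(boot, [2.5, 97.5])
        lo = float(min(lo_, per_pair.mean()))
        hi = float(max(hi_, per_pair.mean()))
    else:
        raise ValueError(f"unknown resample scheme {resample!r}")
    return ICCResult(
        comparison="between_subjects",
        mode=mode,
        mean=float(per_pair.mean()),
        ci_low=lo,
        ci_high=hi,
        per_unit=per_pair,
        unit_labels=pairs,
        session_label=session,
    )


def icc_table(
    cohort_maps: CohortMaps,
    modes: list[int],
    n_boot: int = 10_000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Reliability summary across modes, mirroring the standard layout:
    one between-sessions row plus one between-subjects row per session.
    """
    _, sessions, _ = _check_cohort(cohort_maps)
    rows = []
    for mode in modes:
        res = between_session_icc(cohort_maps, mode, n_boot=n_boot, rng_seed=rng_seed)
        rows.append(res)
        for ses in sessions:
            rows.append(
                between_subject_icc(
                    cohort_maps, ses, mode, n_boot=n_boot, rng_seed=rng_seed
                )
            )
    return pd.DataFrame(
        {
            "comparison": [r.comparison for r in rows],
            "session": [r.session_label or "" for r in rows],
            "mode": [f"g{r.mode + 1}" for r in rows],
            "mean_icc": [r.mean for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "n_units": [r.per_unit.size for r in rows],
        }
    )
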