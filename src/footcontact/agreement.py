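"""Concurrent-validity statistics: detector events vs. force-plate reference.

The central quantity is the *offset*, defined as reference event time minus
detected event time, in milliseconds.  Positive offsets mean the detector
fired earlier than the force plate.  Agreement is summarized by the median
offset and interquartile range, by Bland-Altman mean offset and 1.96-SD
limits of agreement, and by a linear mixed-effects model asking whether the
error depends on task, sex or leg while accounting for repeated measures
per participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    ModelError,
    UndefinedCorrelationError,
)
from .signals import Algorithm, ContactEvent, EventType, Leg, Sex, Task, TrialMeta


@dataclass(frozen=True)
class OffsetRecord:
    """Timing error of one detected event on one trial.

    ``offset_ms`` = 1000 * (reference time - detected time); positive means
    the detector was early relative to the force plate.
    """

    meta: TrialMeta
    algorithm: Algorithm
    event: EventType
    offset_ms: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.offset_ms):
            raise InsufficientDataError("offset must be finite")


@dataclass(frozen=True)
class AgreementSummary:
    """Median/IQR plus Bland-Altman outputs for one algorithm x event."""

    n: int
    median_ms: float
    q1_ms: float
    q3_ms: float
    iqr_ms: float
    mean_ms: float
    sd_ms: float
    loa_low_ms: float
    loa_high_ms: float
    n_outliers: int


@dataclass(frozen=True)
class LmeResult:
    """Mixed-model decomposition of detector error.

    ``betas`` maps each fixed factor to its coefficient (ms) and p-value;
    factors are indicator-coded: task=COD, sex=male, leg=non-dominant, with
    DEC / female / dominant as reference levels.  ``r2_adj`` and
    ``model_p`` describe the fixed-effects (marginal) fit;
    ``random_intercept_var`` is the between-participant variance in ms^2.
    """

    betas: dict[str, tuple[float, float]]
    r2_adj: float
    model_p: float
    random_intercept_var: float


def compute_offset(
    reference: ContactEvent,
    detected: ContactEvent,
    event: EventType,
    meta: TrialMeta,
    algorithm: Algorithm,
) -> OffsetRecord:
    """Offset record for one event type on one trial (times on the shared clock)."""
    event = EventType(event)
    if event is EventType.IC:
        diff_s = reference.ic_time - detected.ic_time
    else:
        diff_s = reference.to_time - detected.to_time
    return OffsetRecord(
        meta=meta, algorithm=algorithm, event=event, offset_ms=1000.0 * diff_s
    )


def summarize(offsets: Sequence[OffsetRecord | float]) -> AgreementSummary:
    """Median/IQR and Bland-Altman summary of a set of offsets.

    Quantiles use linear interpolation between order statistics.  Limits of
    agreement are mean +/- 1.96 sample SD (n-1 denominator); outliers are
    offsets strictly outside the limits.
    """
    values = np.asarray(
        [o.offset_ms if isinstance(o, OffsetRecord) else float(o) for o in offsets]
    )
    if values.size < 3:
        raise InsufficientDataError(f"need >= 3 offsets, got {values.size}")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    loa_low = mean - 1.96 * sd
    loa_high = mean + 1.96 * sd
    n_out = int(np.sum((values < loa_low) | (values > loa_high)))
    return AgreementSummary(
        n=int(values.size),
        median_ms=float(med),
        q1_ms=float(q1),
        q3_ms=float(q3),
        iqr_ms=float(q3 - q1),
        mean_ms=mean,
        sd_ms=sd,
        loa_low_ms=float(loa_low),
        loa_high_ms=float(loa_high),
        n_outliers=n_out,
    )


def offsets_to_frame(offsets: Iterable[OffsetRecord]) -> pd.DataFrame:
    """Flat table with indicator-coded factors, ready for modelling."""
    rows = []
    for o in offsets:
        rows.append(
            {
                "trial_id": o.meta.trial_id,
                "participant_id": o.meta.participant_id,
                "task": o.meta.task.value,
                "sex": o.meta.sex.value,
                "leg": o.meta.leg.value,
                "algorithm": o.algorithm.value,
                "event": o.event.value,
                "offset_ms": o.offset_ms,
                "task_cod": float(o.meta.task is Task.COD),
                "sex_male": float(o.meta.sex is Sex.MALE),
                "leg_nondom": float(o.meta.leg is Leg.NONDOMINANT),
            }
        )
    return pd.DataFrame(rows)


_FACTORS = {"task_cod": "task", "sex_male": "sex", "leg_nondom": "leg"}


def fit_error_model(offsets: Sequence[OffsetRecord]) -> LmeResult:
    """Linear mixed model of offset on task, sex and leg.

    Fixed effects are the three binary factors (indicator coding); a per-
    participant random intercept absorbs repeated measures.  The model is
    fit by REML.  The adjusted R-squared and overall model p-value are
    computed from the fixed-effects-only (marginal) OLS fit, since an LME
    has no single canonical R-squared.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = offsets_to_frame(offsets)
    if df["participant_id"].nunique() < 2:
        raise ModelError("need >= 2 participants for a random intercept")
    if len(df) < 10:
        raise InsufficientDataError(f"need >= 10 records, got {len(df)}")
    for col, name in _FACTORS.items():
        if df[col].nunique() < 2:
            raise ModelError(f"factor '{name}' is constant in the data")

    formula = "offset_ms ~ task_cod + sex_male + leg_nondom"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mixed = smf.mixedlm(formula, df, groups=df["participant_id"]).fit(reml=True)
        ols = smf.ols(formula, df).fit()

    betas = {
        name: (float(mixed.fe_params[col]), float(mixed.pvalues[col]))
        for col, name in _FACTORS.items()
    }
    return LmeResult(
        betas=betas,
        r2_adj=float(ols.rsquared_adj),
        model_p=float(ols.f_pvalue),
        random_intercept_var=float(np.asarray(mixed.cov_re)[0, 0]),
    )


def correlate_error_source(
    offsets: Sequence[OffsetRecord | float], covariate: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between offsets and a per-trial covariate.

    The covariate is an error-source candidate: movement speed for the
    pelvis-velocity detector, acceleration magnitude at contact for the
    foot-acceleration detector.
    """
    y = np.asarray(
        [o.offset_ms if isinstance(o, OffsetRecord) else float(o) for o in offsets]
    )
    x = np.asarray(covariate, dtype=float)
    if x.size != y.size:
        raise InsufficientDataError("offsets and covariate must be paired")
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InsufficientDataError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in correlation input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bland_altman_plot(
    reference_ms: Sequence[float],
    detected_ms: Sequence[float],
    path,
    title: str = "",
) -> None:
    """Mean-vs-difference scatter with mean offset and limits of agreement.

    Differences follow the package sign convention (reference - detected);
    the x axis is the two methods' mean event time.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = np.asarray(reference_ms, dtype=float)
    det = np.asarray(detected_ms, dtype=float)
    diff = ref - det
    mean = (ref + det) / 2.0
    s = summarize(list(diff))

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=14, alpha=0.6, edgecolors="none")
    ax.axhline(s.mean_ms, color="black", linestyle="--", label=f"mean {s.mean_ms:.1f} ms")
    for loa in (s.loa_low_ms, s.loa_high_ms):
        ax.axhline(loa, color="red", linestyle="--")
    ax.set_xlabel("mean of methods [ms]")
    ax.set_ylabel("reference - detected [ms]")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def agreement_table(
    summaries: dict[tuple[str, str], AgreementSummary]
) -> pd.DataFrame:
    """Median/IQR table across algorithm x event, one row each."""
    rows = []
    for (alg, ev), s in summaries.items():
        rows.append(
            {
                "algorithm": alg,
                "event": ev,
                "n": s.n,
                "median_ms": s.median_ms,
                "iqr_ms": s.iqr_ms,
                "q1_ms": s.q1_ms,
                "q3_ms": s.q3_ms,
                "mean_ms": s.mean_ms,
                "loa_low_ms": s.loa_low_ms,
                "loa_high_ms": s.loa_high_ms,
                "n_outliers": s.n_outliers,
            }
        )
    return pd.DataFrame(rows)


def lme_table(results: dict[tuple[str, str], LmeResult]) -> pd.DataFrame:
    """Factor-effect table across algorithm x event (one row per factor)."""
    rows = []
    for (alg, ev), res in results.items():
        for factor, (beta, p) in res.betas.items():
            rows.append(
                {
                    "algorithm": alg,
                    "event": ev,
                    "factor": factor,
                    "beta_ms": beta,
                    "p": p,
                    "r2_adj": res.r2_adj,
                    "model_p": res.model_p,
                    "random_intercept_var": res.random_intercept_var,
                }
            )
    return pd.DataFrame(rows)
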