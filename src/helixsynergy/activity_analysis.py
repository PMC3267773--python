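"""Dual-luciferase activity analysis over spacer series and template panels.

Covers the reporter-side analysis of helical-phasing experiments:
normalization of firefly counts by the co-transfected Renilla control,
peak detection across a spacer series (same tie rule as the EMSA
minimum finder, applied to the negated curve), a periodic-attenuation
fit that estimates the helical repeat from activity data, synergy
ratios against a single-site reference, pairwise template comparisons
and dose-titration dominance checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import InputError

__all__ = [
    "ActivityTable",
    "ActivationCurve",
    "PeriodicFit",
    "SynergyResult",
    "TemplateComparison",
    "TitrationSummary",
    "read_activity_table",
    "normalize",
    "curve_from_table",
    "detect_peaks",
    "fit_periodic_attenuation",
    "synergy_ratio",
    "compare_templates",
    "titration_summary",
]

ACTIVITY_COLUMNS = ["template_id", "replicate", "firefly", "renilla"]


@dataclass(frozen=True)
class ActivityTable:
    """Replicate-level dual-luciferase measurements.

    Columns: ``template_id``, ``spacer_bp`` (optional), ``dose``
    (optional, for titrations), ``replicate``, ``firefly``, ``renilla``.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ACTIVITY_COLUMNS if c not in self.rows.columns]
        if missing:
            raise InputError(f"activity table missing columns: {missing}")
        if (self.rows["firefly"] <= 0).any():
            raise InputError("firefly counts must be positive")


@dataclass(frozen=True)
class ActivationCurve:
    """Mean normalized activity (+/- SD, n) over a spacer grid."""

    spacers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sd < 0) or np.any(self.n < 1):
            raise InputError("curve needs sd >= 0 and n >= 1")


def read_activity_table(path) -> ActivityTable:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return ActivityTable(rows=pd.read_csv(path, sep=sep))


def normalize(table: ActivityTable) -> pd.DataFrame:
    """Per-replicate normalized activity: firefly / renilla.

    Rows with non-positive Renilla counts are rejected with a warning
    (a failed transfection control cannot normalize anything).
    Returns the input rows plus an ``activity`` column.
    """
    df = table.rows.copy()
    bad = ~(df["renilla"] > 0)
    if bad.any():
        warnings.warn(
            f"rejecting {int(bad.sum())} rows with non-positive renilla",
            stacklevel=2,
        )
        df = df[~bad].copy()
    df["activity"] = df["firefly"] / df["renilla"]
    return df


def _condition_stats(df: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    g = df.groupby(by, sort=True)["activity"]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
                n="count").reset_index()
    return out


def curve_from_table(table: ActivityTable, template_id: str | None = None) -> ActivationCurve:
    """Collapse replicate rows into an activation curve over spacer_bp."""
    df = normalize(table)
    if template_id is not None:
        df = df[df["template_id"] == template_id]
    if "spacer_bp" not in df.columns:
        raise InputError("table has no spacer_bp column")
    stats_df = _condition_stats(df, ["spacer_bp"])
    return ActivationCurve(
        spacers=stats_df["spacer_bp"].to_numpy(dtype=float),
        mean=stats_df["mean"].to_numpy(dtype=float),
        sd=stats_df["sd"].to_numpy(dtype=float),
        n=stats_df["n"].to_numpy(dtype=int),
    )


def detect_peaks(curve: ActivationCurve, tie_epsilon: float | None = None) -> list[float]:
    """Spacers at interior local maxima of the activation curve.

    Exactly the EMSA minimum finder applied to the negated activities:
    the same near-tie rule (middle of an indistinguishable run) and the
    same exclusion of endpoints.
    """
    from .emsa_analysis import DetrendedSeries, find_local_minima

    series = DetrendedSeries(spacers=curve.spacers, residuals=-curve.mean)
    return find_local_minima(series, tie_epsilon)


@dataclass(frozen=True)
class PeriodicFit:
    """Periodic-attenuation model fitted to an activation curve.

    Model: ``A(s) = exp(-decay*s) * (baseline + amplitude *
    sin^2(pi*(s + phase)/period))``; ``period`` is the helical repeat
    estimate in bp.  ``converged`` is False for degenerate fits (flat
    curves, unidentifiable period).
    """

    period: float
    phase: float
    decay: float
    baseline: float
    amplitude: float
    residual_ss: float
    converged: bool
    message: str = ""

    def __call__(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return np.exp(-self.decay * s) * (
            self.baseline
            + self.amplitude * np.sin(np.pi * (s + self.phase) / self.period) ** 2
        )


def _periodic_model(s, period, phase, decay, baseline, amplitude):
    return np.exp(-decay * s) * (
        baseline + amplitude * np.sin(np.pi * (s + phase) / period) ** 2
    )


def fit_periodic_attenuation(
    curve: ActivationCurve,
    period_bounds: tuple[float, float] = (8.0, 13.0),
    n_period_grid: int = 51,
) -> PeriodicFit:
    """Fit the damped sin^2 model by period grid search plus refinement.

    The period axis is scanned over ``period_bounds`` (default 8-13 bp,
    bracketing plausible helical repeats); at each trial period the
    remaining parameters are fitted by nonlinear least squares, and the
    best period is then refined locally.  A flat or otherwise
    unidentifiable curve is returned flagged (``converged=False``)
    rather than raising.
    """
    s = np.asarray(curve.spacers, dtype=float)
    y = np.asarray(curve.mean, dtype=float)
    if s.size < 10:
        raise InputError("periodic fit needs >= 10 points")
    if np.ptp(s) < 2 * period_bounds[0]:
        raise InputError("grid must span at least two periods")
    span = float(y.max() - y.min())
    if span <= 1e-12 * max(1.0, abs(float(y.mean()))):
        return PeriodicFit(
            period=np.nan, phase=0.0, decay=0.0, baseline=float(y.mean()),
            amplitude=0.0, residual_ss=0.0, converged=False,
            message="flat curve: period unidentifiable",
        )

    def fit_at(period0, free_period):
        p0 = [period0, 0.0, 0.01, max(y.min(), 1e-9), span]
        lo = [period_bounds[0], -period_bounds[1], 0.0, 0.0, 0.0]
        hi = [period_bounds[1], period_bounds[1], 1.0, np.inf, np.inf]
        if not free_period:
            lo[0] = max(period_bounds[0], period0 - 1e-9)
            hi[0] = min(period_bounds[1], period0 + 1e-9)
            p0[0] = np.clip(period0, lo[0], hi[0])
        try:
            popt, _ = optimize.curve_fit(
                _periodic_model, s, y, p0=p0, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError):
            return None
        rss = float(np.sum((y - _periodic_model(s, *popt)) ** 2))
        return popt, rss

    best = None
    for period0 in np.linspace(*period_bounds, n_period_grid):
        res = fit_at(period0, free_period=False)
        if res is not None and (best is None or res[1] < best[1]):
            best = res
    if best is None:
        return PeriodicFit(
            period=np.nan, phase=0.0, decay=0.0, baseline=float(y.mean()),
            amplitude=0.0, residual_ss=float(np.sum((y - y.mean()) ** 2)),
            converged=False, message="no trial period converged",
        )
    refined = fit_at(best[0][0], free_period=True)
    if refined is not None and refined[1] <= best[1]:
        best = refined
    popt, rss = best
    return PeriodicFit(
        period=float(popt[0]), phase=float(popt[1]), decay=float(popt[2]),
        baseline=float(popt[3]), amplitude=float(popt[4]),
        residual_ss=rss, converged=True,
    )


@dataclass(frozen=True)
class SynergyResult:
    """Two-site / one-site activity ratios over a spacer grid."""

    spacers: np.ndarray
    ratios: np.ndarray
    min_ratio: float
    synergy: bool  # min ratio strictly exceeds additivity (ratio > 2)


def synergy_ratio(
    multi_site_curve: ActivationCurve, single_site_mean: float
) -> SynergyResult:
    """Ratio of multi-site to single-site mean activity at each spacer.

    Synergy is declared only where the ratio strictly exceeds 2: two
    independently acting sites would at most double the single-site
    signal, so ratio > 2 is the superadditivity criterion.
    """
    if not (single_site_mean > 0):
        raise InputError("single-site mean must be positive")
    ratios = multi_site_curve.mean / single_site_mean
    min_ratio = float(ratios.min())
    return SynergyResult(
        spacers=multi_site_curve.spacers,
        ratios=ratios,
        min_ratio=min_ratio,
        synergy=bool(min_ratio > 2.0),
    )


@dataclass(frozen=True)
class TemplateComparison:
    fold_change: float
    statistic: float
    p_value: float
    n_a: int
    n_b: int


def compare_templates(a_replicates, b_replicates) -> TemplateComparison:
    """Fold change b/a of normalized replicates plus a Welch t test.

    The test (unequal-variance two-sample t) is a descriptive aid; the
    primary readout is the fold change of condition means.
    """
    a = np.asarray(a_replicates, dtype=float)
    b = np.asarray(b_replicates, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("need >= 2 replicates per template")
    fold = float(b.mean() / a.mean())
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        # zero variance on both sides: the t statistic is undefined
        equal = np.isclose(a.mean(), b.mean())
        return TemplateComparison(
            fold_change=fold, statistic=0.0 if equal else np.inf,
            p_value=1.0 if equal else 0.0, n_a=a.size, n_b=b.size,
        )
    t, p = stats.ttest_ind(b, a, equal_var=False)
    return TemplateComparison(
        fold_change=fold, statistic=float(t), p_value=float(p),
        n_a=a.size, n_b=b.size,
    )


@dataclass(frozen=True)
class TitrationSummary:
    """Per-dose template means and the dose-wise dominance verdict."""

    doses: np.ndarray
    means: pd.DataFrame  # index dose, one column per template
    dominant_template: str
    other_template: str
    dominant_at_all_doses: bool


def titration_summary(
    table: ActivityTable, dominant_template: str, other_template: str
) -> TitrationSummary:
    """Check whether one template out-activates another at every dose.

    Mirrors the activator-dose titration control: if the opposite-face
    (or evenly spaced) design beats the same-face design at *every*
    expression-plasmid dose, the face effect is not a concentration
    artifact.  Dominance is evaluated on condition means.
    """
    df = normalize(table)
    if "dose" not in df.columns:
        raise InputError("titration table needs a dose column")
    df = df[df["template_id"].isin([dominant_template, other_template])]
    means = df.pivot_table(
        index="dose", columns="template_id", values="activity", aggfunc="mean"
    )
    for t in (dominant_template, other_template):
        if t not in means.columns:
            raise InputError(f"template {t!r} absent from table")
    if means[[dominant_template, other_template]].isna().any().any():
        raise InputError("dose grids of the two templates do not match")
    if len(means.index) < 2:
        raise InputError("titration needs >= 2 doses")
    dominant = bool(
        (means[dominant_template] > means[other_template]).all()
    )
    return TitrationSummary(
        doses=means.index.to_numpy(dtype=float),
        means=means,
        dominant_template=dominant_template,
        other_template=other_template,
        dominant_at_all_doses=dominant,
    )
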