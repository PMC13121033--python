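"""Quantitative support procedures around the tracing pipeline.

Covers: NRF2-activation scoring and on/off classification from dependency
and expression data; exchange-flux estimation against accumulated
cell-volume-hours; proliferation rate; response-ratio calibration; and the
isotopologue detection rule for tumour fractional labeling.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: The nine NRF2 target genes whose standardized expression is summed into
#: the activation score.
NRF2_TARGET_GENES: tuple[str, ...] = (
    "ABCC2", "ABCC3", "AKR1B10", "AKR1C1", "GCLM", "GSR", "ME1", "NQO1", "TXNRD1",
)


@dataclass
class ClassifierThresholds:
    """Top-quintile cutoffs from the public dependency/expression release."""

    dependency_max: float = -0.3028  # Chronos score, more negative = dependent
    score_min: float = 4.06


class NRF2Status(str, enum.Enum):
    on = "on"
    off = "off"


def nrf2_activation_score(
    expr: pd.DataFrame,
    cell_line: str,
    genes: Sequence[str] = NRF2_TARGET_GENES,
) -> float:
    """Sum of per-gene z-scores for ``cell_line``.

    ``expr`` is cell lines x genes; the mean and standard deviation (ddof=1)
    of each gene are taken across all cell lines in the matrix. The score is
    invariant to shifting or rescaling any gene column.
    """
    missing = [g for g in genes if g not in expr.columns]
    if missing:
        raise KeyError(f"expression matrix lacks gene(s): {missing}")
    if cell_line not in expr.index:
        raise KeyError(f"unknown cell line {cell_line!r}")
    score = 0.0
    for gene in genes:
        col = expr[gene].astype(float)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"gene {gene}: zero or undefined s.d. across cell lines")
        score += (col.loc[cell_line] - col.mean()) / sd
    return float(score)


def classify_nrf2(
    dependency: float,
    score: float,
    thresholds: ClassifierThresholds | None = None,
) -> NRF2Status:
    """NRF2^on iff dependency < dependency_max and score > score_min
    (both strict)."""
    thresholds = thresholds or ClassifierThresholds()
    on = dependency < thresholds.dependency_max and score > thresholds.score_min
    return NRF2Status.on if on else NRF2Status.off


def quintile_thresholds(
    dependencies: Sequence[float], scores: Sequence[float]
) -> ClassifierThresholds:
    """Recompute top-quintile cutoffs from a new dataset (dependency: most
    negative quintile; score: highest quintile)."""
    return ClassifierThresholds(
        dependency_max=float(np.quantile(np.asarray(dependencies, float), 0.2)),
        score_min=float(np.quantile(np.asarray(scores, float), 0.8)),
    )


def cell_volume_hours(N0: float, k: float, T: float) -> float:
    """Cell-volume-hours over an interval of length T (hours).

    Exponential growth N(t) = N0 * 2^(k t) integrates to
    N0 / (k ln 2) * (2^(k T) - 1); the k -> 0 limit is N0 * T.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    if abs(k) < 1e-12:
        return N0 * T
    return N0 / (k * np.log(2.0)) * (2.0 ** (k * T) - 1.0)


@dataclass
class GrowthSeries:
    """Time-resolved total cell volumes and medium metabolite moles.

    ``volumes`` has shape (n_timepoints,) for a single well or
    (n_timepoints, n_wells) for destructively sampled replicate wells.
    ``moles`` maps metabolite name -> per-timepoint medium moles.
    """

    times: np.ndarray  # hours, strictly increasing
    volumes: np.ndarray  # microliters, > 0
    moles: dict[str, np.ndarray] = field(default_factory=dict)
    k: float | None = None  # doublings per hour, if known
    N0: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.volumes = np.asarray(self.volumes, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be > 0")
        self.moles = {m: np.asarray(v, float) for m, v in self.moles.items()}


def accumulate_cvh(series: GrowthSeries) -> np.ndarray:
    """Accumulated cell-volume-hours at each timepoint.

    Per segment, the growth rate is inferred from the volume ratio and the
    closed-form integral applied with the segment's starting volume. With
    replicate wells, each well's interval value is added to the *average*
    accumulated value of the previous timepoint (wells are destructively
    sampled, so accumulation couples replicates through the running mean).
    Returns an array shaped like ``series.volumes`` with zeros at t[0].
    """
    vols = series.volumes
    single = vols.ndim == 1
    v = vols[:, None] if single else vols
    n_t, n_w = v.shape
    acc = np.zeros_like(v)
    prev_mean_acc = 0.0
    for i in range(1, n_t):
        dt = series.times[i] - series.times[i - 1]
        v0 = float(np.mean(v[i - 1]))
        for w in range(n_w):
            ratio = v[i, w] / v0
            k_seg = np.log2(ratio) / dt
            acc[i, w] = prev_mean_acc + cell_volume_hours(v0, k_seg, dt)
        prev_mean_acc = float(np.mean(acc[i]))
    return acc[:, 0] if single else acc


@dataclass
class FluxEstimate:
    """OLS slope of medium moles vs accumulated cell-volume-hours.

    Negative slope = net consumption, positive = net production.
    """

    slope: float  # mol per (microliter x hour)
    stderr: float
    intercept: float
    points_used: int
    points_excluded: list[tuple[int, str]] = field(default_factory=list)


class EstimationError(ValueError):
    pass


def flux_fit(
    accumulated_cvh: Sequence[float],
    moles: Sequence[float],
    cvh_max: float = 300.0,
    depletion_fraction: float = 0.1,
    extra_excluded: Mapping[int, str] | None = None,
) -> FluxEstimate:
    """Fit medium moles against accumulated cell-volume-hours by OLS.

    Points are excluded (with reason codes) when the well grew beyond
    ``cvh_max`` microliter-hours (``cvh_overgrowth``: growth slows and fluxes
    shift) or when the metabolite has fallen to <= ``depletion_fraction`` of
    its initial moles (``depletion``: uptake is no longer substrate-saturated).
    ``extra_excluded`` injects exclusions propagated from linked metabolites.
    """
    cvh = np.asarray(accumulated_cvh, float)
    y = np.asarray(moles, float)
    if cvh.shape != y.shape:
        raise ValueError("accumulated_cvh and moles must have the same shape")
    initial = y[0]
    excluded: list[tuple[int, str]] = []
    mask = np.ones(len(y), bool)
    for i in range(len(y)):
        if extra_excluded and i in extra_excluded:
            excluded.append((i, extra_excluded[i]))
            mask[i] = False
        elif cvh[i] > cvh_max:
            excluded.append((i, "cvh_overgrowth"))
            mask[i] = False
        elif initial > 0 and y[i] <= depletion_fraction * initial:
            excluded.append((i, "depletion"))
            mask[i] = False
    if mask.sum() < 2:
        raise EstimationError("fewer than 2 usable points after exclusions")
    fit = stats.linregress(cvh[mask], y[mask])
    return FluxEstimate(
        slope=float(fit.slope),
        stderr=float(fit.stderr),
        intercept=float(fit.intercept),
        points_used=int(mask.sum()),
        points_excluded=excluded,
    )


def fit_fluxes(
    series: GrowthSeries,
    links: Mapping[str, Sequence[str]] | None = None,
    cvh_max: float = 300.0,
    depletion_fraction: float = 0.1,
) -> dict[str, FluxEstimate]:
    """Fit one flux per metabolite, propagating depletion exclusions to
    linked metabolites (e.g. glutamate efflux when cystine is depleted)."""
    acc = accumulate_cvh(series)
    if acc.ndim > 1:
        acc = acc.mean(axis=1)
    links = links or {}
    depletion_points: dict[str, list[int]] = {}
    for met, y in series.moles.items():
        initial = y[0]
        depletion_points[met] = [
            i for i in range(len(y))
            if initial > 0 and y[i] <= depletion_fraction * initial
        ]
    out = {}
    for met, y in series.moles.items():
        extra: dict[int, str] = {}
        for other, linked in links.items():
            if met in linked:
                for i in depletion_points.get(other, []):
                    extra[i] = f"linked_depletion:{other}"
        out[met] = flux_fit(acc, y, cvh_max, depletion_fraction, extra)
    return out


def proliferation_rate(
    initial_count: float, final_count: float, days: float
) -> float:
    """Doublings per day: log2(final / initial) / days."""
    if initial_count <= 0 or final_count <= 0 or days <= 0:
        raise ValueError("counts and days must be > 0")
    return float(np.log2(final_count / initial_count) / days)


class CalibrationModel(str, enum.Enum):
    linear = "linear"
    power = "power"
    quadratic = "quadratic"


@dataclass
class CalibrationCurve:
    """Concentration as a function of response ratio.

    The best of a linear, power-law and quadratic fit by residual sum of
    squares, ties broken toward the simpler model.
    """

    model: CalibrationModel
    coefficients: tuple[float, ...]
    rss: float

    def predict(self, ratio: float) -> float:
        c = self.coefficients
        if self.model is CalibrationModel.linear:
            return c[0] + c[1] * ratio
        if self.model is CalibrationModel.power:
            return c[0] * ratio ** c[1]
        return c[0] + c[1] * ratio + c[2] * ratio**2


class ExtrapolationWarning(UserWarning):
    pass


def fit_calibration(standards: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Fit concentration ~ f(response ratio) over (ratio, concentration)
    standards; requires at least 3 points and positive ratios."""
    if len(standards) < 3:
        raise ValueError("calibration requires at least 3 standards")
    ratios = np.array([s[0] for s in standards], float)
    concs = np.array([s[1] for s in standards], float)
    if np.any(ratios <= 0):
        raise ValueError("response ratios must be positive")

    fits: list[CalibrationCurve] = []
    b, a = np.polyfit(ratios, concs, 1)
    pred = a + b * ratios
    fits.append(CalibrationCurve(
        CalibrationModel.linear, (float(a), float(b)), float(np.sum((concs - pred) ** 2))
    ))
    if np.all(concs > 0):
        expo, loga = np.polyfit(np.log(ratios), np.log(concs), 1)
        pa = float(np.exp(loga))
        pred = pa * ratios ** expo
        fits.append(CalibrationCurve(
            CalibrationModel.power, (pa, float(expo)), float(np.sum((concs - pred) ** 2))
        ))
    c2, c1, c0 = np.polyfit(ratios, concs, 2)
    pred = c0 + c1 * ratios + c2 * ratios**2
    fits.append(CalibrationCurve(
        CalibrationModel.quadratic, (float(c0), float(c1), float(c2)),
        float(np.sum((concs - pred) ** 2)),
    ))
    best_rss = min(f.rss for f in fits)
    scale = float(np.sum(concs**2)) or 1.0
    for fit in fits:  # models are ordered simple -> complex; first tie wins
        if fit.rss <= best_rss + 1e-12 * scale:
            return fit
    return fits[-1]  # pragma: no cover


def calibrate_and_quantify(
    standards: Sequence[tuple[float, float]], sample_ratio: float
) -> float:
    """Map a sample response ratio to a concentration via the best-fit
    calibration curve; warns when extrapolating beyond 2x the standard range."""
    curve = fit_calibration(standards)
    ratios = [s[0] for s in standards]
    if not (min(ratios) / 2 <= sample_ratio <= max(ratios) * 2):
        warnings.warn(
            f"sample ratio {sample_ratio} is outside 2x the standard range",
            ExtrapolationWarning,
        )
    return float(curve.predict(sample_ratio))


def labeled_fraction_with_detection_rule(
    isotopologue_areas: Sequence[float],
) -> float | None:
    """Fractional labeling M+3 / sum(M+0..M+3), requiring detection of both
    M+0 and M+3; returns None (sample excluded) otherwise."""
    areas = np.asarray(isotopologue_areas, float)
    if areas.ndim != 1 or len(areas) < 4:
        raise ValueError("expected areas for isotopologues M+0..M+3")
    if np.any(areas < 0):
        raise ValueError("areas must be >= 0")
    m0, m3 = areas[0], areas[3]
    if m0 <= 0 or m3 <= 0:
        return None
    return float(m3 / areas[:4].sum())
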