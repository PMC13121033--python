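"""Synthetic peak lists and growth series with known ground truth.

The peak-list generator emulates the tracing experiment itself: cells fed a
1:1 mix of light and fully labeled cystine, so every cysteine-derived
species shows a light/heavy twin at +4.0071 Da whose heavy share is the
incorporation probability p (one cysteine) or 2p/(1+p) (two cysteines,
because the M+8 species drops out of the pair's denominator). Around the
true fates it plants the confounders the screens must reject: adduct and
natural-isotope satellites, blank-enriched contaminants and unpaired noise.

Planted compound groups are rejection-sampled so that *different* groups
never sit within the pairing / merge / adduct / isotopologue windows of one
another: ground truth is identifiable by construction, and every planted
relation is intentional.

Mass and RT jitter have a component shared within a compound group plus an
independent residual: co-eluting isotopologues of one compound share their
chromatographic alignment and local mass-calibration error, so fully
independent per-peak errors would be physically wrong.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .artifact_screen import DEFAULT_ADDUCT_RULES, DEFAULT_ISOTOPE_RULES
from .context_analytics import GrowthSeries, accumulate_cvh
from .pair_detection import LabelConfig, PeakPair, heavy_shift
from .peaklist_io import Peak, Role, SampleEntry, SampleTable


def default_sample_table() -> SampleTable:
    """Six labeled-mix samples, three unlabeled controls, two blanks."""
    entries = (
        [SampleEntry(f"L{i}", Role.labeled_mix, "labeled") for i in range(1, 7)]
        + [SampleEntry(f"U{i}", Role.unlabeled_control, "control") for i in range(1, 4)]
        + [SampleEntry(f"B{i}", Role.blank, "blank") for i in range(1, 3)]
    )
    return SampleTable(entries)


@dataclass
class SimConfig:
    seed: int = 0
    n_true_fates: int = 50
    n_two_cys_fates: int = 10
    p_heavy: float = 0.24
    n_noise_peaks: int = 200
    n_blank_contaminants: int = 20
    n_adduct_satellites: int = 20
    n_isotope_satellites: int = 20
    ppm_jitter_sd: float = 0.0
    rt_jitter_sd: float = 0.0
    area_lognormal_sd: float = 0.05
    jitter_shared_fraction: float = 0.8  # within-compound-group share of jitter variance
    samples: SampleTable | None = None
    mass_range: tuple[float, float] = (150.0, 900.0)
    rt_range: tuple[float, float] = (1.0, 15.0)
    base_area: float = 1e7  # median total ion count of a planted compound
    compound_area_sd: float = 0.35  # lognormal sd of totals across compounds
    loading_sd: float = 0.2  # lognormal sd of per-sample loading factors
    label_config: LabelConfig = field(default_factory=LabelConfig)

    def __post_init__(self) -> None:
        if not (0 < self.p_heavy < 1):
            raise ValueError("p_heavy must lie in (0, 1)")
        for name in ("n_true_fates", "n_two_cys_fates", "n_noise_peaks",
                     "n_blank_contaminants", "n_adduct_satellites",
                     "n_isotope_satellites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if (self.n_adduct_satellites or self.n_isotope_satellites) and not self.n_true_fates:
            raise ValueError("satellites require at least one one-cysteine fate")
        if not (0 <= self.jitter_shared_fraction <= 1):
            raise ValueError("jitter_shared_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruthRecord:
    species_id: str  # peak id of the light (M+0) member
    klass: str  # fate_1cys | fate_2cys | adduct | isotope | noise | contaminant
    true_mass: float
    true_rt: float
    polarity: str
    parent_species: str = ""  # for satellites: species_id of the parent fate


_ADDUCT_DELTAS = [r.mass_delta for r in DEFAULT_ADDUCT_RULES if r.parent_multiplier == 1.0]
_ISO_DELTAS = [r.mass_delta for r in DEFAULT_ISOTOPE_RULES]


class _PlacementGuard:
    """Rejection-sampling guard keeping compound groups mutually inert.

    Any cross-group mass difference among co-eluting (RT within
    ``rt_window``) emitted masses must stay ``clearance`` Da away from every
    screening-relevant offset (0, tracer shifts, adduct and isotope deltas);
    dimer relations get a separate wider clearance.
    """

    def __init__(self, shift: float, rt_window: float = 1.2,
                 clearance: float = 0.25, dimer_clearance: float = 0.45) -> None:
        danger = [0.0, shift, 2 * shift]
        danger += [abs(d) for d in _ADDUCT_DELTAS]
        danger += list(_ISO_DELTAS)
        self.danger = np.array(sorted(danger))
        self.rt_window = rt_window
        self.clearance = clearance
        self.dimer_clearance = dimer_clearance
        self._masses: list[float] = []
        self._rts: list[float] = []

    def ok(self, derived_masses: Sequence[float], rt: float) -> bool:
        if not self._masses:
            return True
        masses = np.array(self._masses)
        rts = np.array(self._rts)
        near = np.abs(rts - rt) < self.rt_window
        if not near.any():
            return True
        existing = masses[near]
        cand = np.asarray(derived_masses)
        diffs = np.abs(cand[:, None] - existing[None, :]).ravel()
        if np.min(np.abs(diffs[:, None] - self.danger[None, :])) <= self.clearance:
            return False
        dimer = np.minimum(
            np.min(np.abs(cand[:, None] - 2 * existing[None, :])),
            np.min(np.abs(2 * cand[:, None] - existing[None, :])),
        )
        return dimer > self.dimer_clearance

    def add(self, derived_masses: Sequence[float], rt: float) -> None:
        self._masses.extend(float(m) for m in derived_masses)
        self._rts.extend([float(rt)] * len(derived_masses))


def _estimated_carbons(mass: float) -> int:
    return max(3, round(0.45 * mass / 12.0))


def simulate_peaklist(
    config: SimConfig | None = None,
) -> tuple[list[Peak], SampleTable, list[GroundTruthRecord]]:
    """Generate a feature table with planted fates, satellites and noise.

    Deterministic under a fixed seed. Returns (peaks, samples, ground truth).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    samples = config.samples or default_sample_table()
    labeled = samples.labeled_ids
    controls = samples.ids_with_role(Role.unlabeled_control)
    blanks = samples.blank_ids
    shift = heavy_shift(config.label_config)
    guard = _PlacementGuard(shift)
    p = config.p_heavy

    # which fates carry which satellites (fixed cyclic assignment)
    adducts_of: dict[int, list[float]] = {}
    for i in range(config.n_adduct_satellites):
        fate = i % config.n_true_fates
        delta = _ADDUCT_DELTAS[i % len(_ADDUCT_DELTAS)]
        adducts_of.setdefault(fate, []).append(delta)
    isotopes_of: dict[int, list[float]] = {}
    for j in range(config.n_isotope_satellites):
        fate = j % config.n_true_fates
        delta = _ISO_DELTAS[j % len(_ISO_DELTAS)]
        isotopes_of.setdefault(fate, []).append(delta)

    peaks: list[Peak] = []
    truth: list[GroundTruthRecord] = []
    counter = 0
    # jitter bookkeeping: (peak index, group index) for correlated errors
    group_of_peak: list[int] = []
    n_groups = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"pk{counter:05d}"

    mass_lo, mass_hi = config.mass_range
    rt_lo, rt_hi = config.rt_range

    def draw_position(offsets: Sequence[float], max_tries: int = 500) -> tuple[float, float]:
        for _ in range(max_tries):
            m = rng.uniform(mass_lo, max(mass_lo + 1.0, mass_hi - 60.0))
            r = rng.uniform(rt_lo, rt_hi)
            derived = [m + o for o in offsets]
            if guard.ok(derived, r):
                guard.add(derived, r)
                return m, r
        raise RuntimeError(
            "could not place a compound without collisions; "
            "reduce counts or widen the mass/RT ranges"
        )

    def loading_factors() -> dict[str, float]:
        return {
            e.sample_id: float(rng.lognormal(0.0, config.loading_sd))
            for e in samples.entries
        }

    def emit(mass: float, rt: float, polarity: str, areas: dict[str, float],
             group: int) -> Peak:
        peak = Peak(new_id(), polarity, mass, rt, dict(areas))
        peaks.append(peak)
        group_of_peak.append(group)
        return peak

    def area_noise() -> float:
        return float(rng.lognormal(0.0, config.area_lognormal_sd))

    one_cys_positions: list[tuple[float, float, str, str]] = []  # mass, rt, pol, id

    # --- one-cysteine fates (plus their satellites, sharing a group) -------
    for i in range(config.n_true_fates):
        offsets = [0.0, shift]
        for d in adducts_of.get(i, []):
            offsets += [d, d + shift]
        for d in isotopes_of.get(i, []):
            offsets += [d, d + shift]
        m, r = draw_position(offsets)
        polarity = "negative" if rng.random() < 0.5 else "positive"
        total = config.base_area * float(rng.lognormal(0.0, config.compound_area_sd))
        load = loading_factors()
        group = n_groups
        n_groups += 1

        parent_areas = {s: total * load[s] * (1 - p) * area_noise() for s in labeled}
        parent_areas |= {s: total * load[s] * area_noise() for s in controls}
        partner_areas = {s: total * load[s] * p * area_noise() for s in labeled}
        parent = emit(m, r, polarity, parent_areas, group)
        emit(m + shift, r, polarity, partner_areas, group)
        truth.append(GroundTruthRecord(parent.peak_id, "fate_1cys", m, r, polarity))
        one_cys_positions.append((m, r, polarity, parent.peak_id))

        for d in adducts_of.get(i, []):
            rel = 0.2
            a_parent = emit(m + d, r, polarity,
                            {s: v * rel * area_noise() for s, v in parent_areas.items()},
                            group)
            emit(m + d + shift, r, polarity,
                 {s: v * rel * area_noise() for s, v in partner_areas.items()},
                 group)
            truth.append(GroundTruthRecord(
                a_parent.peak_id, "adduct", m + d, r, polarity, parent.peak_id
            ))
        for d in isotopes_of.get(i, []):
            rel = min(0.3, max(0.03, 0.011 * _estimated_carbons(m)))
            i_parent = emit(m + d, r, polarity,
                            {s: v * rel * area_noise() for s, v in parent_areas.items()},
                            group)
            emit(m + d + shift, r, polarity,
                 {s: v * rel * area_noise() for s, v in partner_areas.items()},
                 group)
            truth.append(GroundTruthRecord(
                i_parent.peak_id, "isotope", m + d, r, polarity, parent.peak_id
            ))

    # --- two-cysteine fates: binomial M+0 / M+4 / M+8 ----------------------
    for _ in range(config.n_two_cys_fates):
        m, r = draw_position([0.0, shift, 2 * shift])
        polarity = "negative" if rng.random() < 0.5 else "positive"
        total = config.base_area * float(rng.lognormal(0.0, config.compound_area_sd))
        load = loading_factors()
        shares = ((1 - p) ** 2, 2 * p * (1 - p), p * p)
        group = n_groups
        n_groups += 1
        m0_areas = {s: total * load[s] * shares[0] * area_noise() for s in labeled}
        m0_areas |= {s: total * load[s] * area_noise() for s in controls}
        m0 = emit(m, r, polarity, m0_areas, group)
        emit(m + shift, r, polarity,
             {s: total * load[s] * shares[1] * area_noise() for s in labeled}, group)
        emit(m + 2 * shift, r, polarity,
             {s: total * load[s] * shares[2] * area_noise() for s in labeled}, group)
        truth.append(GroundTruthRecord(m0.peak_id, "fate_2cys", m, r, polarity))

    # --- blank-enriched contaminants ---------------------------------------
    for _ in range(config.n_blank_contaminants):
        m, r = draw_position([0.0])
        polarity = "negative" if rng.random() < 0.5 else "positive"
        total = config.base_area * float(rng.lognormal(0.0, config.compound_area_sd))
        load = loading_factors()
        group = n_groups
        n_groups += 1
        areas = {s: total * load[s] for s in blanks}
        areas |= {
            s: 0.3 * total * load[s] * area_noise()
            for s in samples.nonblank_ids
        }
        peak = emit(m, r, polarity, areas, group)
        truth.append(GroundTruthRecord(peak.peak_id, "contaminant", m, r, polarity))

    # --- unpaired low-intensity noise --------------------------------------
    for _ in range(config.n_noise_peaks):
        m, r = draw_position([0.0])
        polarity = "negative" if rng.random() < 0.5 else "positive"
        total = 1e5 * float(rng.lognormal(0.0, 1.0))
        group = n_groups
        n_groups += 1
        areas = {}
        for e in samples.entries:
            if e.role != Role.blank and rng.random() < 0.7:
                areas[e.sample_id] = total * float(rng.lognormal(0.0, 0.3))
        if not areas:
            areas = {labeled[0]: total}
        peak = emit(m, r, polarity, areas, group)
        truth.append(GroundTruthRecord(peak.peak_id, "noise", m, r, polarity))

    # --- jitter, applied last: shared within a group + independent residual -
    if config.ppm_jitter_sd > 0 or config.rt_jitter_sd > 0:
        w_shared = math.sqrt(config.jitter_shared_fraction)
        w_ind = math.sqrt(1.0 - config.jitter_shared_fraction)
        group_ppm = rng.normal(0.0, 1.0, n_groups)
        group_rt = rng.normal(0.0, 1.0, n_groups)
        for idx, peak in enumerate(peaks):
            g = group_of_peak[idx]
            e_ppm = config.ppm_jitter_sd * (
                w_shared * group_ppm[g] + w_ind * rng.normal()
            )
            e_rt = config.rt_jitter_sd * (
                w_shared * group_rt[g] + w_ind * rng.normal()
            )
            peak.neutral_mass *= 1.0 + e_ppm * 1e-6
            peak.rt = max(0.0, peak.rt + e_rt)

    return peaks, samples, truth


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    n_detected: int
    n_true_positive: int
    n_planted: int
    matched_species: list[str] = field(default_factory=list)
    precision_undefined: bool = False


def score_recovery(
    final_pairs: Sequence[PeakPair],
    truth: Sequence[GroundTruthRecord],
    ppm_tol: float = 10.0,
    rt_tol: float = 0.25,
) -> RecoveryScore:
    """Precision/recall of detected pairs against planted fates.

    A detection is a true positive when its parent lies within ``ppm_tol``
    and ``rt_tol`` of a planted fate (one- or two-cysteine). With zero
    detections precision is reported as 1.0 by convention, with a warning
    flag set.
    """
    fates = [t for t in truth if t.klass in ("fate_1cys", "fate_2cys")]
    matched: set[str] = set()
    n_tp = 0
    for pair in final_pairs:
        hit = False
        for t in fates:
            if (abs(pair.parent_mass - t.true_mass) / t.true_mass * 1e6 <= ppm_tol
                    and abs(pair.parent_rt - t.true_rt) <= rt_tol):
                matched.add(t.species_id)
                hit = True
        if hit:
            n_tp += 1
    n_det = len(final_pairs)
    if n_det == 0:
        precision = 1.0
        undefined = True
        if fates:
            warnings.warn("no detections; precision reported as 1.0 by convention")
    else:
        precision = n_tp / n_det
        undefined = False
    recall = len(matched) / len(fates) if fates else 1.0
    return RecoveryScore(
        precision, recall, n_det, n_tp, len(fates), sorted(matched), undefined
    )


def simulate_growth_series(
    N0: float,
    k: float,
    flux: float | dict[str, float],
    noise_sd: float = 0.0,
    schedule: Sequence[float] = (0, 12, 24, 36, 48, 60, 72, 84, 96),
    seed: int = 0,
    initial_moles: float = 4e-6,
) -> GrowthSeries:
    """Exponential growth with linear medium exchange.

    Volumes follow N0 * 2^(k t); each metabolite's medium moles follow
    initial - rate * accumulated CVH plus Gaussian noise with sd
    ``noise_sd`` x the noise-free dynamic range (positive rate = consumption,
    so the fitted slope is -rate).
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(schedule, float)
    volumes = N0 * 2.0 ** (k * times)
    series = GrowthSeries(times=times, volumes=volumes, k=k, N0=N0)
    acc = accumulate_cvh(series)
    rates = flux if isinstance(flux, dict) else {"metabolite": float(flux)}
    for name, rate in rates.items():
        clean = initial_moles - rate * acc
        span = float(np.ptp(clean)) or abs(initial_moles)
        series.moles[name] = clean + rng.normal(0.0, noise_sd * span, len(times))
    return series
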