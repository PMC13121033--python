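"""Isotopologue peak-pair search: the core of RMA tracing.

A 1:1 mixture of light and heavy tracer (here U-13C3,15N cysteine after
cystine cleavage) stamps every downstream metabolite with a twin feature
shifted by the tracer mass difference (3x(13C-12C) + (15N-14N) = 4.0071 Da).
Candidate fates are features with a partner at that shift, co-eluting, whose
heavy share of the summed signal falls in an empirically calibrated window:
around the incorporation probability p for one-cysteine species, and around
2p/(1+p) for two-cysteine species (binomial isotopologue algebra: the pair
only compares M+0 with M+4, so the M+8 species drops out of the denominator).
"""

from __future__ import annotations

import enum
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Sequence

from .chem import DELTA_13C, DELTA_15N
from .peaklist_io import ConfigError, Peak, SampleTable


@dataclass
class LabelConfig:
    """Tracer composition and pair-search gates."""

    n_heavy_C: int = 3
    n_heavy_N: int = 1
    pair_ppm_max: float = 10.0
    pair_rt_max: float = 0.25
    fraction_windows: tuple[tuple[float, float], ...] = ((0.20, 0.28), (0.34, 0.42))

    def __post_init__(self) -> None:
        if self.n_heavy_C < 0 or self.n_heavy_N < 0:
            raise ValueError("heavy atom counts must be >= 0")
        if self.pair_ppm_max <= 0 or self.pair_rt_max <= 0:
            raise ValueError("pair tolerances must be positive")
        windows = sorted(self.fraction_windows)
        for lo, hi in windows:
            if not (0 <= lo < hi <= 1):
                raise ValueError(f"invalid fraction window ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(windows, windows[1:]):
            if lo2 < hi:
                raise ValueError("fraction windows must not overlap")


class PairStatus(str, enum.Enum):
    candidate = "candidate"
    flagged = "flagged"
    stringent_pass = "stringent_pass"
    final = "final"


@dataclass
class PeakPair:
    """A light parent feature plus its heavy-shifted partner."""

    parent_id: str
    partner_id: str
    parent_mass: float
    partner_mass: float
    parent_rt: float
    partner_rt: float
    delta_ppm: float  # |observed - theoretical| partner mass, ppm
    delta_rt: float
    fractions: dict[str, float] = field(default_factory=dict)
    qualifying_window: int = 0
    flags: set[str] = field(default_factory=set)
    status: PairStatus = PairStatus.candidate
    polarity: str = ""


def heavy_shift(config: LabelConfig | None = None) -> float:
    """Tracer mass shift in Da from standard atomic masses."""
    config = config or LabelConfig()
    return config.n_heavy_C * DELTA_13C + config.n_heavy_N * DELTA_15N


def labeling_fraction(parent_area: float, partner_area: float) -> float:
    """Heavy share of the pair signal: partner / (parent + partner)."""
    if parent_area < 0 or partner_area < 0:
        raise ValueError("areas must be >= 0")
    total = parent_area + partner_area
    if total == 0:
        raise ValueError("labeling fraction undefined when both areas are 0")
    return partner_area / total


def _pair_fractions(
    parent: Peak, partner: Peak, labeled_ids: Sequence[str]
) -> dict[str, float]:
    """Per-labeled-sample fractions where parent or partner is detected.

    An undetected peak contributes area 0, so a partner detected without its
    parent yields fraction 1.0 (which no window accepts) rather than an error.
    """
    fractions = {}
    for s in labeled_ids:
        if s in parent.areas or s in partner.areas:
            total = parent.area(s) + partner.area(s)
            if total > 0:
                fractions[s] = partner.area(s) / total
    return fractions


def _qualifying_window(
    fractions: dict[str, float], windows: Sequence[tuple[float, float]]
) -> int | None:
    """Smallest window index containing at least one sample fraction."""
    for idx, (lo, hi) in enumerate(windows):
        if any(lo <= f <= hi for f in fractions.values()):
            return idx
    return None


def find_pairs(
    peaks: Sequence[Peak],
    samples: SampleTable,
    config: LabelConfig | None = None,
) -> list[PeakPair]:
    """Search every peak for a heavy partner and gate on ppm, RT and window.

    The ppm error is referenced to the theoretical partner mass
    (parent + shift). All qualifying partners are emitted as separate
    candidates; output is sorted by (parent mass, partner mass) and is
    therefore invariant to input row order.
    """
    config = config or LabelConfig()
    labeled = samples.labeled_ids
    if not labeled:
        raise ConfigError("find_pairs requires at least one labeled_mix sample")
    shift = heavy_shift(config)

    by_pol: dict[str, list[Peak]] = {}
    for p in peaks:
        by_pol.setdefault(p.polarity.value, []).append(p)

    pairs: list[PeakPair] = []
    for polarity, group in by_pol.items():
        group = sorted(group, key=lambda p: (p.neutral_mass, p.peak_id))
        masses = [p.neutral_mass for p in group]
        for parent in group:
            theo = parent.neutral_mass + shift
            tol = config.pair_ppm_max * 1e-6 * theo
            lo = bisect_left(masses, theo - tol)
            hi = bisect_right(masses, theo + tol)
            for partner in group[lo:hi]:
                if partner.peak_id == parent.peak_id:
                    continue
                delta_rt = abs(partner.rt - parent.rt)
                if delta_rt > config.pair_rt_max:
                    continue
                fractions = _pair_fractions(parent, partner, labeled)
                window = _qualifying_window(fractions, config.fraction_windows)
                if window is None:
                    continue
                pairs.append(PeakPair(
                    parent_id=parent.peak_id,
                    partner_id=partner.peak_id,
                    parent_mass=parent.neutral_mass,
                    partner_mass=partner.neutral_mass,
                    parent_rt=parent.rt,
                    partner_rt=partner.rt,
                    delta_ppm=abs(partner.neutral_mass - theo) / theo * 1e6,
                    delta_rt=delta_rt,
                    fractions=fractions,
                    qualifying_window=window,
                    polarity=polarity,
                ))
    pairs.sort(key=lambda q: (q.parent_mass, q.partner_mass, q.parent_id))
    return pairs
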