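"""Pre-pairing peak filters and duplicate-peak merging.

These reproduce the candidate-peak cleanup applied before isotopologue pair
search: intensity floors, blank subtraction, a low-mass cutoff one Dalton
below cysteine, and merging of split features caused by small mass defects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .peaklist_io import ConfigError, Peak, SampleTable


@dataclass
class FilterConfig:
    """Thresholds for the pre-pairing filters.

    Intensity floors are strict (``>``); ion counts at exactly the floor are
    removed. ``blank_fold`` is inclusive (``>=``). The mass floor keeps
    features at exactly 120 Da.
    """

    min_any_area: float = 25_000.0
    min_labeled_area: float = 15_000.0
    blank_fold: float = 4.0
    mass_floor: float = 120.0
    merge_ppm: float = 50.0
    merge_rt_tight: float = 0.1
    merge_rt_loose: float = 0.2
    merge_corr_min: float = 0.9

    def __post_init__(self) -> None:
        for name in ("min_any_area", "min_labeled_area", "blank_fold",
                     "mass_floor", "merge_ppm", "merge_rt_tight",
                     "merge_rt_loose", "merge_corr_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.merge_rt_tight > self.merge_rt_loose:
            raise ValueError("merge_rt_tight must be <= merge_rt_loose")


def pearson_over_shared(
    a: Peak, b: Peak, sample_ids: Sequence[str], min_n: int = 3
) -> float | None:
    """Pearson r of two peaks' areas over samples where both are detected.

    Returns None when fewer than ``min_n`` shared samples exist or either
    profile is constant (r undefined).
    """
    shared = [s for s in sample_ids if s in a.areas and s in b.areas]
    if len(shared) < min_n:
        return None
    xs = [a.areas[s] for s in shared]
    ys = [b.areas[s] for s in shared]
    n = len(shared)
    mx, my = sum(xs) / n, sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    if sxx == 0 or syy == 0:
        return None
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    return sxy / math.sqrt(sxx * syy)


def intensity_filter(
    peaks: Sequence[Peak], samples: SampleTable, config: FilterConfig | None = None
) -> list[Peak]:
    """Keep peaks with at least one non-blank sample above ``min_any_area``
    and at least one labeled-mix sample above ``min_labeled_area`` (strict)."""
    config = config or FilterConfig()
    labeled = samples.labeled_ids
    if not labeled:
        raise ConfigError("intensity_filter requires at least one labeled_mix sample")
    nonblank = samples.nonblank_ids
    return [
        p for p in peaks
        if p.max_area(nonblank) > config.min_any_area
        and p.max_area(labeled) > config.min_labeled_area
    ]


def blank_filter(
    peaks: Sequence[Peak], samples: SampleTable, config: FilterConfig | None = None
) -> list[Peak]:
    """Keep peaks whose best non-blank signal is >= blank_fold x the best
    blank signal. With no blank samples this is the identity."""
    config = config or FilterConfig()
    blanks = samples.blank_ids
    if not blanks:
        return list(peaks)
    nonblank = samples.nonblank_ids
    kept = []
    for p in peaks:
        blank_max = p.max_area(blanks)
        if blank_max == 0.0 or p.max_area(nonblank) >= config.blank_fold * blank_max:
            kept.append(p)
    return kept


def mass_floor_filter(
    peaks: Sequence[Peak], config: FilterConfig | None = None
) -> list[Peak]:
    """Discard peaks below the mass floor (inclusive at the floor itself)."""
    config = config or FilterConfig()
    return [p for p in peaks if p.neutral_mass >= config.mass_floor]


def _mergeable(a: Peak, b: Peak, sample_ids: Sequence[str], config: FilterConfig) -> bool:
    # ppm relative to the smaller mass (conservative, symmetric)
    small = min(a.neutral_mass, b.neutral_mass)
    if abs(a.neutral_mass - b.neutral_mass) / small * 1e6 > config.merge_ppm:
        return False
    drt = abs(a.rt - b.rt)
    if drt <= config.merge_rt_tight:
        return True
    if drt <= config.merge_rt_loose:
        r = pearson_over_shared(a, b, sample_ids)
        return r is not None and r >= config.merge_corr_min
    return False


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_duplicates(
    peaks: Sequence[Peak], samples: SampleTable, config: FilterConfig | None = None
) -> list[Peak]:
    """Merge split features of the same compound (transitive closure).

    Two same-polarity peaks merge when their masses agree within
    ``merge_ppm`` and either their RTs are within ``merge_rt_tight`` min, or
    within ``merge_rt_loose`` min with area correlation >= ``merge_corr_min``
    over at least 3 shared samples. Groups are replaced by one peak carrying
    the element-wise area sums and the mass/RT of the largest member.
    """
    config = config or FilterConfig()
    peaks = list(peaks)
    sample_ids = [e.sample_id for e in samples.entries]
    n = len(peaks)
    uf = _UnionFind(n)
    # compare within a mass-sorted window to skip hopeless pairs
    order = sorted(range(n), key=lambda i: peaks[i].neutral_mass)
    for oi in range(n):
        i = order[oi]
        for oj in range(oi + 1, n):
            j = order[oj]
            small = min(peaks[i].neutral_mass, peaks[j].neutral_mass)
            if (peaks[j].neutral_mass - peaks[i].neutral_mass) / small * 1e6 > config.merge_ppm:
                break
            if peaks[i].polarity != peaks[j].polarity:
                continue
            if _mergeable(peaks[i], peaks[j], sample_ids, config):
                uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    merged: list[tuple[int, Peak]] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append((members[0], peaks[members[0]]))
            continue
        best = max(members, key=lambda i: (peaks[i].total_area(), peaks[i].peak_id))
        areas: dict[str, float] = {}
        annotations: set[str] = set()
        for i in members:
            annotations |= peaks[i].annotations
            for s, v in peaks[i].areas.items():
                areas[s] = areas.get(s, 0.0) + v
        annotations.add("merged")
        merged.append((
            min(members),
            replace(peaks[best], areas=areas, annotations=annotations),
        ))
    merged.sort(key=lambda t: t[0])  # preserve input order by first member
    return [p for _, p in merged]
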