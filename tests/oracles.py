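"""Independent brute-force references used to cross-check the fast paths.

Everything here is written as plain nested loops over all pairs, with no
sorting, indexing or union-find shortcuts, so it stays independent of the
implementations it checks.
"""

from __future__ import annotations

import math

from rmatrace.pair_detection import LabelConfig, heavy_shift
from rmatrace.prefilter import FilterConfig


def _pearson(xs, ys):
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    if sxx == 0 or syy == 0:
        return None
    return sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / math.sqrt(sxx * syy)


def brute_force_pairs(peaks, samples, config: LabelConfig | None = None):
    """All-pairs pair search; returns the set of (parent_id, partner_id)."""
    config = config or LabelConfig()
    shift = heavy_shift(config)
    labeled = samples.labeled_ids
    found = set()
    for parent in peaks:
        for partner in peaks:
            if partner.peak_id == parent.peak_id:
                continue
            if partner.polarity != parent.polarity:
                continue
            theo = parent.neutral_mass + shift
            if abs(partner.neutral_mass - theo) / theo * 1e6 > config.pair_ppm_max:
                continue
            if abs(partner.rt - parent.rt) > config.pair_rt_max:
                continue
            in_window = False
            for s in labeled:
                if s not in parent.areas and s not in partner.areas:
                    continue
                total = parent.areas.get(s, 0.0) + partner.areas.get(s, 0.0)
                if total == 0:
                    continue
                f = partner.areas.get(s, 0.0) / total
                if any(lo <= f <= hi for lo, hi in config.fraction_windows):
                    in_window = True
            if in_window:
                found.add((parent.peak_id, partner.peak_id))
    return found


def _merge_edge(a, b, sample_ids, config: FilterConfig):
    if a.polarity != b.polarity:
        return False
    small = min(a.neutral_mass, b.neutral_mass)
    if abs(a.neutral_mass - b.neutral_mass) / small * 1e6 > config.merge_ppm:
        return False
    drt = abs(a.rt - b.rt)
    if drt <= config.merge_rt_tight:
        return True
    if drt <= config.merge_rt_loose:
        shared = [s for s in sample_ids if s in a.areas and s in b.areas]
        if len(shared) < 3:
            return False
        r = _pearson([a.areas[s] for s in shared], [b.areas[s] for s in shared])
        return r is not None and r >= config.merge_corr_min
    return False


def _components(items, edge):
    """Connected components by repeated flooding (no union-find)."""
    remaining = list(items)
    groups = []
    while remaining:
        component = [remaining.pop()]
        changed = True
        while changed:
            changed = False
            for other in list(remaining):
                if any(edge(member, other) for member in component):
                    component.append(other)
                    remaining.remove(other)
                    changed = True
        groups.append(component)
    return groups


def brute_force_merge_groups(peaks, samples, config: FilterConfig | None = None):
    """Transitive-closure merge groups as a frozenset of peak-id frozensets."""
    config = config or FilterConfig()
    sample_ids = [e.sample_id for e in samples.entries]
    groups = _components(peaks, lambda a, b: _merge_edge(a, b, sample_ids, config))
    return frozenset(frozenset(p.peak_id for p in g) for g in groups)


def brute_force_dedup_groups(pairs, config: LabelConfig | None = None):
    """Cross-polarity identity groups of pair parents."""
    config = config or LabelConfig()

    def edge(a, b):
        small = min(a.parent_mass, b.parent_mass)
        if abs(a.parent_mass - b.parent_mass) / small * 1e6 > config.pair_ppm_max:
            return False
        return abs(a.parent_rt - b.parent_rt) <= config.pair_rt_max

    groups = _components(pairs, edge)
    return frozenset(
        frozenset((p.parent_id, p.partner_id) for p in g) for g in groups
    )


def naive_formula_enumeration(target_mass, tol_ppm, caps):
    """Six nested loops over CHNOPS; returns the set of retained formulas.

    Applies the same plausibility screens as the fast path (rdbe >= 0 and
    element ratios, waived for carbon-free candidates).
    """
    from rmatrace.chem import ELEMENT_MASS, format_formula

    mC, mH, mN, mO, mP, mS = (ELEMENT_MASS[e] for e in "CHNOPS")
    tol = tol_ppm * 1e-6 * target_mass
    out = set()
    for c in range(caps["C"] + 1):
        for h in range(caps["H"] + 1):
            for n in range(caps["N"] + 1):
                for o in range(caps["O"] + 1):
                    for p in range(caps["P"] + 1):
                        for s in range(caps["S"] + 1):
                            mass = c * mC + h * mH + n * mN + o * mO + p * mP + s * mS
                            if abs(mass - target_mass) > tol:
                                continue
                            if c > 0:
                                if c - h / 2 + n / 2 + 1 < 0:
                                    continue
                                if not (0.1 <= h / c <= 6):
                                    continue
                                if n / c > 4 or o / c > 3 or p / c > 2 or s / c > 3:
                                    continue
                            out.add(format_formula(
                                {k: v for k, v in
                                 zip("CHNOPS", (c, h, n, o, p, s)) if v}
                            ))
    return out
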