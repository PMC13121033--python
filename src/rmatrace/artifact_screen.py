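"""Adduct/isotopologue flagging, stringent filtering, polarity dedup, naming.

Candidate pairs can echo the same underlying compound several times: as
ionization adducts (sodiated, potassiated, ...), as natural-abundance
isotopologue satellites (one 13C, one 34S, ...), or once per ionization
polarity. These screens flag the echoes, drop flagged and poorly matching
pairs, and keep one feature per compound, named ``C<int mass>_<rt>``.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from . import chem
from .pair_detection import LabelConfig, PairStatus, PeakPair
from .peaklist_io import Peak, Polarity
from .prefilter import _UnionFind, pearson_over_shared


class AdductScope(str, enum.Enum):
    any = "any"
    positive = "positive"
    negative = "negative"


@dataclass(frozen=True)
class AdductRule:
    """Neutral-mass offset of a known adduct form.

    ``parent_multiplier`` is 2 for dimers ([2M+X] species), 1 otherwise.
    """

    name: str
    mass_delta: float
    polarity_scope: AdductScope = AdductScope.any
    parent_multiplier: float = 1.0

    def target_mass(self, parent_mass: float) -> float:
        return self.parent_multiplier * parent_mass + self.mass_delta


@dataclass(frozen=True)
class IsotopeRule:
    """Mass offset of an abundant natural-isotope satellite."""

    name: str
    mass_delta: float
    max_area_ratio: float = 1.0  # advisory; the screen requires area < parent

    def __post_init__(self) -> None:
        if self.mass_delta <= 0:
            raise ValueError("isotope mass_delta must be > 0")


@dataclass
class ScreenConfig:
    adduct_ppm: float = 200.0
    adduct_rt: float = 0.8
    iso_ppm: float = 200.0
    iso_rt: float = 0.4
    iso_corr_min: float = 0.7
    stringent_dppm: float = 1.0
    stringent_drt: float = 0.06

    def __post_init__(self) -> None:
        for name in ("adduct_ppm", "adduct_rt", "iso_ppm", "iso_rt",
                     "iso_corr_min", "stringent_dppm", "stringent_drt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


_H = chem.ELEMENT_MASS["H"]

#: Common neutral adduct offsets (CSV-overridable).
DEFAULT_ADDUCT_RULES: tuple[AdductRule, ...] = (
    AdductRule("Na-H", chem.ELEMENT_MASS["Na"] - _H),
    AdductRule("K-H", chem.ELEMENT_MASS["K"] - _H),
    AdductRule("+NH3", chem.formula_mass("NH3")),
    AdductRule("-H2O", -chem.MASS_H2O),
    AdductRule("+HCOOH", chem.formula_mass("CH2O2")),
    AdductRule("+HCl", chem.ELEMENT_MASS["Cl"] + _H),
    AdductRule("dimer", 0.0, parent_multiplier=2.0),
)

#: Most abundant isotope satellites for CHNOPS metabolites.
DEFAULT_ISOTOPE_RULES: tuple[IsotopeRule, ...] = (
    IsotopeRule("13C", chem.DELTA_13C),
    IsotopeRule("13C2", 2 * chem.DELTA_13C),
    IsotopeRule("34S", chem.DELTA_34S),
    IsotopeRule("18O", chem.DELTA_18O),
)


def read_adduct_rules(path: str | Path) -> list[AdductRule]:
    """Load adduct rules from CSV (name, mass_delta[, scope[, multiplier]])."""
    rules = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            rules.append(AdductRule(
                row["name"],
                float(row["mass_delta"]),
                AdductScope((row.get("scope") or "any").strip()),
                float(row.get("multiplier") or 1.0),
            ))
    return rules


def read_isotope_rules(path: str | Path) -> list[IsotopeRule]:
    rules = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            rules.append(IsotopeRule(
                row["name"],
                float(row["mass_delta"]),
                float(row.get("max_area_ratio") or 1.0),
            ))
    return rules


def _scope_matches(rule: AdductRule, polarity: str) -> bool:
    return rule.polarity_scope is AdductScope.any or rule.polarity_scope.value == polarity


def flag_adducts(
    pairs: Sequence[PeakPair],
    rules: Sequence[AdductRule] | None = None,
    config: ScreenConfig | None = None,
) -> list[PeakPair]:
    """Flag candidate pairs whose parent sits at a known adduct offset from
    another candidate's parent (same polarity). Flags never delete rows."""
    if rules is None:
        rules = DEFAULT_ADDUCT_RULES
    if not rules:
        warnings.warn("flag_adducts called with an empty rule list; no-op")
        return list(pairs)
    config = config or ScreenConfig()
    pairs = list(pairs)
    for a in pairs:
        for b in pairs:
            if b is a or b.polarity != a.polarity:
                continue
            if abs(b.parent_rt - a.parent_rt) > config.adduct_rt:
                continue
            for rule in rules:
                if not _scope_matches(rule, b.polarity):
                    continue
                target = rule.target_mass(a.parent_mass)
                if abs(b.parent_mass - target) / target * 1e6 <= config.adduct_ppm:
                    b.flags.add(f"adduct_of:{a.parent_id}")
                    b.status = PairStatus.flagged
                    break
    return pairs


def flag_isotopologues(
    pairs: Sequence[PeakPair],
    peaks: Mapping[str, Peak] | Sequence[Peak],
    rules: Sequence[IsotopeRule] | None = None,
    config: ScreenConfig | None = None,
    sample_ids: Sequence[str] | None = None,
) -> list[PeakPair]:
    """Flag pairs whose parent is a natural-isotope satellite of another
    pair's parent: mass offset within ``iso_ppm``, RT within ``iso_rt``,
    area correlation >= ``iso_corr_min``, and total area below the parent's."""
    if rules is None:
        rules = DEFAULT_ISOTOPE_RULES
    config = config or ScreenConfig()
    peak_map = peaks if isinstance(peaks, Mapping) else {p.peak_id: p for p in peaks}
    pairs = list(pairs)
    for a in pairs:
        pa = peak_map[a.parent_id]
        for b in pairs:
            if b is a or b.polarity != a.polarity:
                continue
            if abs(b.parent_rt - a.parent_rt) > config.iso_rt:
                continue
            pb = peak_map[b.parent_id]
            if pb.total_area() >= pa.total_area():
                continue
            for rule in rules:
                target = a.parent_mass + rule.mass_delta
                if abs(b.parent_mass - target) / target * 1e6 > config.iso_ppm:
                    continue
                ids = sample_ids if sample_ids is not None else sorted(
                    set(pa.areas) | set(pb.areas)
                )
                r = pearson_over_shared(pa, pb, ids)
                if r is not None and r >= config.iso_corr_min:
                    b.flags.add(f"isotopologue_of:{a.parent_id}")
                    b.status = PairStatus.flagged
                break
    return pairs


def stringent_filter(
    pairs: Sequence[PeakPair], config: ScreenConfig | None = None
) -> list[PeakPair]:
    """Drop flagged pairs, then pairs with dppm >= 1.0 or dRT >= 0.06 min.

    The cutoffs were calibrated on known fates, none of which exceeded
    0.66 ppm or 0.04 min between the light and heavy members.
    """
    config = config or ScreenConfig()
    kept = []
    for p in pairs:
        if p.flags:
            continue
        if p.delta_ppm >= config.stringent_dppm or p.delta_rt >= config.stringent_drt:
            continue
        p.status = PairStatus.stringent_pass
        kept.append(p)
    return kept


def dedup_polarity(
    pairs: Sequence[PeakPair],
    peaks: Mapping[str, Peak] | Sequence[Peak],
    label_config: LabelConfig | None = None,
) -> list[PeakPair]:
    """Collapse the same compound detected in both polarities.

    Pairs whose parents agree within the pair-search tolerances are grouped
    (transitive closure); within a group only the parent with the highest
    total ion count survives, ties going to negative mode then lexicographic
    peak id. Survivors get status ``final``.
    """
    label_config = label_config or LabelConfig()
    peak_map = peaks if isinstance(peaks, Mapping) else {p.peak_id: p for p in peaks}
    pairs = list(pairs)
    n = len(pairs)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = pairs[i], pairs[j]
            small = min(a.parent_mass, b.parent_mass)
            if abs(a.parent_mass - b.parent_mass) / small * 1e6 > label_config.pair_ppm_max:
                continue
            if abs(a.parent_rt - b.parent_rt) > label_config.pair_rt_max:
                continue
            uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    kept: list[PeakPair] = []
    for members in groups.values():
        def rank(i: int) -> tuple:
            p = pairs[i]
            ion_count = peak_map[p.parent_id].total_area()
            neg_first = 0 if p.polarity == Polarity.negative.value else 1
            return (-ion_count, neg_first, p.parent_id)

        winner = pairs[min(members, key=rank)]
        winner.status = PairStatus.final
        kept.append(winner)
    kept.sort(key=lambda p: (p.parent_mass, p.partner_mass, p.parent_id))
    return kept


def name_feature(neutral_mass: float, rt: float) -> str:
    """Feature name: 'C' + integer part of the neutral mass + '_' + RT to
    one decimal, e.g. C193_7.3."""
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be > 0")
    return f"C{int(neutral_mass)}_{rt:.1f}"
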