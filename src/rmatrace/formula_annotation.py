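"""Elemental-composition prediction and conjugate-mass chemistry.

Two complementary views of an unknown feature:

* enumerate plausible CHNOPS formulas for the feature mass itself and for
  the *added mass* left after subtracting a base metabolite (cysteine or
  glutathione) — sugar-derived conjugates leave sugar-like added masses;
* compute expected conjugate masses for candidate reactions of cysteine's
  thiol/amine with carbonyl or sugar-phosphate partners: thioether formation
  with loss of phosphoric acid, condensation with loss of water
  (hemithioacetal ring closure to a thiazolidine), or plain addition.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import chem


@dataclass(frozen=True)
class FormulaCandidate:
    element_counts: tuple[tuple[str, int], ...]
    theoretical_mass: float
    ppm_error: float
    rdbe: float

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.element_counts)

    @property
    def formula(self) -> str:
        return chem.format_formula(self.counts)


@dataclass(frozen=True)
class BaseMetabolite:
    name: str
    formula: str

    @property
    def monoisotopic_mass(self) -> float:
        return chem.formula_mass(self.formula)


CYS = BaseMetabolite("CYS", "C3H7NO2S")
GSH = BaseMetabolite("GSH", "C10H17N3O6S")


class ReactionMode(enum.Enum):
    """Cysteine conjugation chemistries with their leaving-group masses."""

    thioether_phosphate_loss = chem.MASS_H3PO4
    condensation_water_loss = chem.MASS_H2O
    hemithioacetal_addition = 0.0

    @property
    def leaving_mass(self) -> float:
        return self.value


def added_mass(feature_mass: float, base: BaseMetabolite) -> float:
    """Implied added mass: feature mass minus the base metabolite mass.

    Negative results are permitted (the caller decides how to flag them).
    """
    return feature_mass - base.monoisotopic_mass


def conjugate_mass(
    base: BaseMetabolite, partner_mass: float, mode: ReactionMode
) -> float:
    """Neutral monoisotopic mass of base + partner - leaving group."""
    result = base.monoisotopic_mass + partner_mass - mode.leaving_mass
    if result <= 0:
        raise ValueError(
            f"conjugate mass is non-positive for partner {partner_mass} under {mode.name}"
        )
    return result


# Per-element caps at a 500 Da reference mass; actual caps scale linearly
# with the target mass (mass-scaled heuristics of the common formula rules).
_BASE_CAPS = {"C": 39, "H": 72, "N": 20, "O": 20, "P": 9, "S": 10}
_RATIO_SCREENS = {  # applied only when C >= 1
    "H": (0.1, 6.0),
    "N": (0.0, 4.0),
    "O": (0.0, 3.0),
    "P": (0.0, 2.0),
    "S": (0.0, 3.0),
}


def _element_caps(target_mass: float, bounds: dict[str, int] | None) -> dict[str, int]:
    caps = {}
    for el, base_cap in _BASE_CAPS.items():
        scaled = math.ceil(base_cap * target_mass / 500.0)
        hard = int(target_mass * 1.001 / chem.ELEMENT_MASS[el]) + 1
        caps[el] = min(scaled, hard)
        if bounds and el in bounds:
            caps[el] = min(caps[el], bounds[el])
    return caps


def _passes_screens(c: int, h: int, n: int, o: int, p: int, s: int) -> bool:
    if c == 0:
        # pure inorganic candidates (e.g. H3PO4) bypass rdbe/ratio screens
        return True
    rdbe = c - h / 2 + n / 2 + 1
    if rdbe < 0:
        return False
    for el, count in (("H", h), ("N", n), ("O", o), ("P", p), ("S", s)):
        lo, hi = _RATIO_SCREENS[el]
        if not (lo <= count / c <= hi):
            return False
    return True


def enumerate_formulas(
    target_mass: float,
    tol_ppm: float = 5.0,
    bounds: dict[str, int] | None = None,
    max_candidates: int = 10_000,
) -> list[FormulaCandidate]:
    """Exhaustively enumerate CHNOPS formulas matching ``target_mass``.

    Retains candidates within ``tol_ppm`` that pass the ring-plus-double-bond
    (rdbe >= 0) and element-ratio plausibility screens; sorted by |ppm error|.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if target_mass <= 0:
        return []
    caps = _element_caps(target_mass, bounds)
    tol_da = tol_ppm * 1e-6 * target_mass
    mC, mH, mN, mO, mP, mS = (chem.ELEMENT_MASS[e] for e in "CHNOPS")
    out: list[FormulaCandidate] = []
    for c in range(caps["C"] + 1):
        base_c = c * mC
        if base_c > target_mass + tol_da:
            break
        for n in range(caps["N"] + 1):
            base_n = base_c + n * mN
            if base_n > target_mass + tol_da:
                break
            for s in range(caps["S"] + 1):
                base_s = base_n + s * mS
                if base_s > target_mass + tol_da:
                    break
                for p in range(caps["P"] + 1):
                    base_p = base_s + p * mP
                    if base_p > target_mass + tol_da:
                        break
                    for o in range(caps["O"] + 1):
                        base_o = base_p + o * mO
                        if base_o > target_mass + tol_da:
                            break
                        # hydrogen count is pinned by the residual mass
                        h_lo = math.ceil((target_mass - tol_da - base_o) / mH)
                        h_hi = math.floor((target_mass + tol_da - base_o) / mH)
                        for h in range(max(h_lo, 0), min(h_hi, caps["H"]) + 1):
                            mass = base_o + h * mH
                            if abs(mass - target_mass) > tol_da:
                                continue
                            if not _passes_screens(c, h, n, o, p, s):
                                continue
                            counts = {k: v for k, v in
                                      zip("CHNOPS", (c, h, n, o, p, s)) if v}
                            out.append(FormulaCandidate(
                                tuple(sorted(counts.items())),
                                mass,
                                chem.ppm_diff(mass, target_mass),
                                c - h / 2 + n / 2 + 1,
                            ))
                            if len(out) > max_candidates:
                                raise ValueError(
                                    "more than "
                                    f"{max_candidates} candidates; narrow tol_ppm"
                                )
    out.sort(key=lambda f: (abs(f.ppm_error), f.formula))
    return out


@dataclass(frozen=True)
class PartnerCompound:
    """A candidate reaction partner (e.g. DHAP, pyruvate)."""

    name: str
    monoisotopic_mass: float
    modes: tuple[ReactionMode, ...] = tuple(ReactionMode)


def read_partner_library(path: str | Path) -> list[PartnerCompound]:
    """Load partners from CSV (name, formula or mass, optional modes list)."""
    partners = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            if row.get("formula"):
                mass = chem.formula_mass(row["formula"])
            else:
                mass = float(row["mass"])
            modes_cell = (row.get("modes") or "").strip()
            modes = (
                tuple(ReactionMode[m.strip()] for m in modes_cell.split(";"))
                if modes_cell else tuple(ReactionMode)
            )
            partners.append(PartnerCompound(row["name"], mass, modes))
    return partners


def annotate_features(
    features: Iterable[tuple[str, float]],
    bases: Sequence[BaseMetabolite] = (CYS, GSH),
    partner_library: Sequence[PartnerCompound] = (),
    modes: Sequence[ReactionMode] = tuple(ReactionMode),
    tol_ppm: float = 5.0,
    added_mass_tol_ppm: float = 10.0,
) -> pd.DataFrame:
    """Annotate (name, neutral mass) features.

    For each feature: best whole-feature formulas, the added mass and its
    best formulas against each base, and any conjugate-library match within
    ``tol_ppm`` of the feature mass.
    """
    rows = []
    for feat_name, mass in features:
        feature_formulas = enumerate_formulas(mass, tol_ppm)
        top = feature_formulas[0].formula if feature_formulas else ""
        for base in bases:
            add = added_mass(mass, base)
            add_formulas = (
                enumerate_formulas(add, added_mass_tol_ppm) if add > 0 else []
            )
            matches = []
            for partner in partner_library:
                for mode in partner.modes:
                    if mode not in modes:
                        continue
                    try:
                        expected = conjugate_mass(base, partner.monoisotopic_mass, mode)
                    except ValueError:
                        continue
                    if abs(chem.ppm_diff(mass, expected)) <= tol_ppm:
                        matches.append(f"{base.name}+{partner.name}[{mode.name}]")
            rows.append({
                "feature": feat_name,
                "neutral_mass": mass,
                "best_formula": top,
                "base": base.name,
                "added_mass": add,
                "added_mass_negative": add < 0,
                "best_added_formula": (
                    add_formulas[0].formula if add_formulas else ""
                ),
                "conjugate_matches": ";".join(matches),
            })
    return pd.DataFrame(rows)
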