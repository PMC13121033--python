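"""Full-chain orchestration: filter -> merge -> pair -> flag -> stringent -> dedup.

The stage order mirrors the method: pre-pairing cleanup of the feature
table, isotopologue pair search, artifact flagging, stringent quality
filtering and polarity deduplication, with every intermediate table written
out and a machine-readable run report of survivor counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .artifact_screen import (
    AdductRule,
    IsotopeRule,
    ScreenConfig,
    dedup_polarity,
    flag_adducts,
    flag_isotopologues,
    name_feature,
    read_adduct_rules,
    read_isotope_rules,
    stringent_filter,
)
from .pair_detection import LabelConfig, find_pairs
from .peaklist_io import (
    Peak,
    PeakTableSchema,
    SampleTable,
    read_peak_table,
    read_sample_table,
    write_pair_table,
    write_peak_table,
)
from .prefilter import (
    FilterConfig,
    blank_filter,
    intensity_filter,
    mass_floor_filter,
    merge_duplicates,
)


@dataclass
class RunConfig:
    peak_table: str
    sample_table: str
    out_dir: str = "rmatrace_out"
    schema: PeakTableSchema = field(default_factory=PeakTableSchema)
    filter: FilterConfig = field(default_factory=FilterConfig)
    label: LabelConfig = field(default_factory=LabelConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    adduct_rules: str | None = None  # CSV path; None -> built-in defaults
    isotope_rules: str | None = None
    seed: int = 0
    log_level: str = "info"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs = dict(raw)
        for key, klass in (
            ("schema", PeakTableSchema), ("filter", FilterConfig),
            ("label", LabelConfig), ("screen", ScreenConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                section = kwargs[key]
                if key == "label" and "fraction_windows" in section:
                    section["fraction_windows"] = tuple(
                        tuple(w) for w in section["fraction_windows"]
                    )
                kwargs[key] = klass(**section)
        return cls(**kwargs)


def _echo_params(config: RunConfig) -> dict:
    def as_dict(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: as_dict(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [as_dict(v) for v in obj]
        return obj

    return as_dict(config)


def run_pipeline(
    config: RunConfig,
    peaks: list[Peak] | None = None,
    samples: SampleTable | None = None,
) -> dict:
    """Run the full chain; returns the run report (also written to disk).

    ``peaks``/``samples`` may be passed directly (e.g. from the simulator)
    to bypass file reading; otherwise they are read from the configured
    paths. Deterministic for fixed inputs and configuration.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if peaks is None:
        peaks = read_peak_table(config.peak_table, config.schema)
    if samples is None:
        samples = read_sample_table(config.sample_table)

    counts = {"input": len(peaks)}
    stage = intensity_filter(peaks, samples, config.filter)
    counts["after_intensity_filter"] = len(stage)
    stage = blank_filter(stage, samples, config.filter)
    counts["after_blank_filter"] = len(stage)
    stage = mass_floor_filter(stage, config.filter)
    counts["after_mass_floor"] = len(stage)
    stage = merge_duplicates(stage, samples, config.filter)
    counts["after_merge"] = len(stage)

    pairs = find_pairs(stage, samples, config.label)
    counts["candidate_pairs"] = len(pairs)
    write_pair_table(pairs, out / "candidates.csv")

    adduct_rules: list[AdductRule] | None = (
        read_adduct_rules(config.adduct_rules) if config.adduct_rules else None
    )
    isotope_rules: list[IsotopeRule] | None = (
        read_isotope_rules(config.isotope_rules) if config.isotope_rules else None
    )
    pairs = flag_adducts(pairs, adduct_rules, config.screen)
    pairs = flag_isotopologues(pairs, stage, isotope_rules, config.screen)
    counts["flagged_pairs"] = sum(1 for p in pairs if p.flags)
    write_pair_table(pairs, out / "flagged.csv")

    pairs = stringent_filter(pairs, config.screen)
    counts["after_stringent"] = len(pairs)
    pairs = dedup_polarity(pairs, stage, config.label)
    counts["final_pairs"] = len(pairs)
    write_pair_table(pairs, out / "final_pairs.csv")

    peak_map = {p.peak_id: p for p in stage}
    finals = []
    for pair in pairs:
        parent = peak_map[pair.parent_id]
        finals.append(dataclasses.replace(
            parent,
            peak_id=name_feature(pair.parent_mass, pair.parent_rt),
        ))
    write_peak_table(finals, out / "final_features.csv",
                     [e.sample_id for e in samples.entries])

    report = {
        "version": __version__,
        "seed": config.seed,
        "counts": counts,
        "parameters": _echo_params(config),
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, default=str), encoding="utf-8"
    )
    return report
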