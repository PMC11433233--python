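"""Summary-report arithmetic over count tables.

Turns raw counts from the pipeline (or from any published counts table) into
the derived ratio statistics of a kingdom-wide GCF survey: exploited
fraction of biosynthetic resources, singleton shares, per-genus and
per-group shares, virtual (not-yet-observed) families, and drug-hit
statistics.  Each statistic carries the raw value and a printed rendering
rounded half-up at a per-statistic precision, matching how such figures are
normally reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd


@dataclass(frozen=True)
class Statistic:
    name: str
    raw: float
    printed: str
    unit: str  # "%" or "count"


def round_half_up(x: float, decimals: int) -> str:
    quantum = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class SummaryReport:
    stats: dict[str, Statistic]

    def __getitem__(self, name: str) -> Statistic:
        return self.stats[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.raw, s.printed, s.unit) for s in self.stats.values()],
            columns=["statistic", "raw", "printed", "unit"],
        )


# statistic name -> (numerator key, denominator key, decimals)
_SHARE_SPECS = [
    ("known_gcf_share", "known_gcfs", "total_gcfs", 1),
    ("genus_gcf_share", "genus_gcfs", "total_gcfs", 1),
    ("top_group_gcf_share", "group_gcfs", "total_gcfs", 1),
    ("type_in_genus_share", "type_gcfs", "genus_gcfs", 1),
    ("known_in_phylum_share", "known_phylum_gcfs", "phylum_gcfs", 1),
    ("drug_focal_share", "focal_hits", "total_hits", 1),
]


def report(counts: Mapping[str, object]) -> SummaryReport:
    """Compute every derivable ratio statistic from ``counts``.

    Recognised keys (all optional; a statistic is produced whenever its
    inputs are present): total_gcfs, total_bgcs, known_gcfs,
    singleton_gcf_fraction, genus_gcfs, group_gcfs, type_gcfs,
    known_phylum_gcfs, phylum_gcfs, pgcf, gcfs, focal_hits, total_hits,
    hit_genus_counts (a sequence of per-genus hit counts).
    Zero denominators drop the statistic with a warning.
    """
    for key, value in counts.items():
        if key == "hit_genus_counts":
            if any(v < 0 for v in value):  # type: ignore[operator]
                raise ValueError(f"count {key} must be non-negative")
        elif isinstance(value, (int, float)) and value < 0:
            raise ValueError(f"count {key} must be non-negative")
    stats: dict[str, Statistic] = {}

    def add_pct(name: str, num: float, den: float, decimals: int) -> None:
        if den == 0:
            warnings.warn(f"{name}: zero denominator; omitted", stacklevel=3)
            return
        raw = 100.0 * num / den
        stats[name] = Statistic(name, raw, round_half_up(raw, decimals), "%")

    for name, num_key, den_key, decimals in _SHARE_SPECS:
        if num_key in counts and den_key in counts:
            add_pct(name, float(counts[num_key]), float(counts[den_key]), decimals)

    if {"singleton_gcf_fraction", "total_gcfs", "total_bgcs"} <= counts.keys():
        den = float(counts["total_bgcs"])
        if den == 0:
            warnings.warn("singleton_bgc_share: zero denominator; omitted", stacklevel=2)
        else:
            num = float(counts["singleton_gcf_fraction"]) * float(counts["total_gcfs"])
            raw = 100.0 * num / den
            stats["singleton_bgc_share"] = Statistic(
                "singleton_bgc_share", raw, round_half_up(raw, 2), "%"
            )

    if {"pgcf", "gcfs"} <= counts.keys():
        raw = float(counts["pgcf"]) - float(counts["gcfs"])
        stats["virtual_gcfs"] = Statistic(
            "virtual_gcfs", raw, round_half_up(raw, 0), "count"
        )

    if "hit_genus_counts" in counts:
        total = float(sum(counts["hit_genus_counts"]))  # type: ignore[arg-type]
        stats["drug_hit_total"] = Statistic(
            "drug_hit_total", total, round_half_up(total, 0), "count"
        )

    return SummaryReport(stats=stats)
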