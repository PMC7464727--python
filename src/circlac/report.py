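"""Summary arithmetic and report assembly.

All percentages are computed from the stated counts at report time (never
stored independently) and rounded half away from zero, the convention that
reproduces every printed value in the source dataset's published summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = ["percent", "mean_ccr_per_lac", "ccr_sr_ratio", "SummaryReport", "format_report"]


def _round_half_away(x: float, decimals: int = 0) -> float:
    scaled = x * 10**decimals
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / 10**decimals


def percent(part: int, whole: int, decimals: int = 1, rounding: str = "half_away") -> float:
    """100 * part / whole rounded to ``decimals``.

    ``rounding`` is "half_away" (default; half away from zero) or "floor".
    Raises ``ValueError`` when whole is zero.
    """
    if whole == 0:
        raise ValueError("percentage of a zero whole is undefined")
    value = 100.0 * part / whole
    if rounding == "floor":
        return math.floor(value * 10**decimals) / 10**decimals
    if rounding != "half_away":
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return _round_half_away(value, decimals)


def mean_ccr_per_lac(total_ccr: int, total_lac: int, decimals: int = 1) -> float:
    """Mean reads per locus, rounded half away from zero."""
    if total_lac == 0:
        raise ValueError("mean CCRs per LAC undefined for zero LACs")
    return _round_half_away(total_ccr / total_lac, decimals)


def ccr_sr_ratio(ccr_count: int, sr_count: int) -> float:
    """Circular-to-linear read ratio, rounded to the nearest integer.

    A zero split-read count yields ``inf`` (the circle dominates completely),
    not an error.
    """
    if sr_count == 0:
        return math.inf
    return _round_half_away(ccr_count / sr_count, 0)


@dataclass
class SummaryReport:
    """Funnel and per-class summary of one pipeline run."""

    n_chimeric_lines: int = 0
    n_after_multiline_filter: int = 0
    n_ccr: int = 0
    n_ccr_retained_chroms: int = 0
    n_lac: int = 0
    n_lac_retained: int = 0
    n_ccr_retained: int = 0
    class_lac_counts: dict = field(default_factory=dict)
    class_ccr_counts: dict = field(default_factory=dict)
    origin_ccr_counts: dict = field(default_factory=dict)  # coding / lnc / other
    mean_lariat_size: Optional[float] = None
    n_events: Optional[int] = None
    n_distinct_circrnas: Optional[int] = None
    mate_split: dict = field(default_factory=dict)  # lac_id -> (r1, r2)

    def origin_percentages(self, decimals: int = 2) -> dict:
        return {
            origin: percent(n, self.n_ccr_retained, decimals)
            for origin, n in self.origin_ccr_counts.items()
            if self.n_ccr_retained
        }

    def validate(self) -> None:
        """Internal consistency: classes partition the retained set."""
        if self.class_lac_counts:
            assert sum(self.class_lac_counts.values()) == self.n_lac_retained
        if self.class_ccr_counts:
            assert sum(self.class_ccr_counts.values()) == self.n_ccr_retained


def format_report(report: SummaryReport) -> str:
    lines = [
        "# circlac summary (percentages rounded half away from zero)",
        f"chimeric lines parsed\t{report.n_chimeric_lines}",
        f"after multi-line read filter\t{report.n_after_multiline_filter}",
        f"circular chimeric reads (CCRs)\t{report.n_ccr}",
        f"CCRs on retained chromosomes\t{report.n_ccr_retained_chroms}",
        f"LACs (pre-threshold)\t{report.n_lac}",
        f"LACs retained\t{report.n_lac_retained}",
        f"CCRs in retained LACs\t{report.n_ccr_retained}",
    ]
    if report.n_lac:
        lines.append(
            "mean CCRs per LAC (pre-threshold)\t"
            f"{mean_ccr_per_lac(report.n_ccr_retained_chroms, report.n_lac)}"
        )
    for klass in sorted(report.class_lac_counts):
        n_lac = report.class_lac_counts[klass]
        n_ccr = report.class_ccr_counts.get(klass, 0)
        pct = (
            percent(n_ccr, report.n_ccr_retained, 1)
            if report.n_ccr_retained
            else 0.0
        )
        lines.append(f"class {klass}\t{n_lac} LACs\t{n_ccr} CCRs\t{pct}%")
    for origin, n in sorted(report.origin_ccr_counts.items()):
        pct = percent(n, report.n_ccr_retained, 2) if report.n_ccr_retained else 0.0
        lines.append(f"exonic origin {origin}\t{n} CCRs\t{pct}%")
    if report.mean_lariat_size is not None:
        lines.append(f"mean lariat circle size (nt)\t{report.mean_lariat_size:.0f}")
    if report.n_events is not None:
        lines.append(f"circularization events\t{report.n_events}")
        lines.append(f"distinct circRNAs\t{report.n_distinct_circrnas}")
    return "\n".join(lines) + "\n"
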