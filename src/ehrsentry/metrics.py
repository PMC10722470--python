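"""Funnel metrics: alerts → screened → highly suspicious, per period.

Percentages are always recomputed from the summed integer counts (the Total
row is never an average of period percentages) and rounded half-up to two
decimals, the precision the funnel is conventionally reported at.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .navigator_workflow import Disposition, ScreeningOutcome, month_key
from .sentry_engine import Alert

__all__ = [
    "PeriodSummary",
    "summarize",
    "summarize_from_counts",
    "monthly_series",
    "baseline_comparison",
    "summaries_to_dataframe",
    "DEFAULT_PERIODS",
]

#: Reporting periods used throughout the examples: a partial launch year,
#: one full calendar year, and a partial closing year.
DEFAULT_PERIODS: List[Tuple[str, date, date]] = [
    ("September to December 2019", date(2019, 9, 1), date(2019, 12, 31)),
    ("2020", date(2020, 1, 1), date(2020, 12, 31)),
    ("January to July 2021", date(2021, 1, 1), date(2021, 7, 31)),
]

TOTAL_LABEL = "Total"


def _pct(numerator: int, denominator: int) -> Optional[float]:
    """Half-up percentage at 2 decimals; None when the denominator is 0."""
    if denominator == 0:
        return None
    q = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass(frozen=True)
class PeriodSummary:
    period_label: str
    n_alerts: int
    n_screened: int
    pct_screened: Optional[float]
    n_suspicious: int
    pct_screened_in: Optional[float]

    def __post_init__(self):
        if self.n_screened > self.n_alerts:
            raise ValueError(f"{self.period_label}: screened ({self.n_screened}) exceeds alerts ({self.n_alerts})")
        if self.n_suspicious > self.n_screened:
            raise ValueError(
                f"{self.period_label}: suspicious ({self.n_suspicious}) exceeds screened ({self.n_screened})"
            )


def _row(label: str, n_alerts: int, n_screened: int, n_suspicious: int) -> PeriodSummary:
    return PeriodSummary(
        period_label=label,
        n_alerts=n_alerts,
        n_screened=n_screened,
        pct_screened=_pct(n_screened, n_alerts),
        n_suspicious=n_suspicious,
        pct_screened_in=_pct(n_suspicious, n_screened),
    )


def summarize_from_counts(period_counts: Sequence[Tuple[str, int, int, int]]) -> List[PeriodSummary]:
    """Build the funnel from per-period (label, alerts, screened, suspicious)
    integer counts, appending a Total row whose percentages are recomputed
    from the summed integers."""
    rows = [_row(*pc) for pc in period_counts]
    rows.append(
        _row(
            TOTAL_LABEL,
            sum(r.n_alerts for r in rows),
            sum(r.n_screened for r in rows),
            sum(r.n_suspicious for r in rows),
        )
    )
    return rows


def summarize(
    alerts: Sequence[Alert],
    outcomes: Sequence[ScreeningOutcome],
    period_boundaries: Sequence[Tuple[str, date, date]] = DEFAULT_PERIODS,
) -> List[PeriodSummary]:
    """Aggregate alerts and screening outcomes into per-period funnel rows.

    Periods are (label, first day, last day) with inclusive bounds; they must
    not overlap and must cover every alert. Outcomes attach to periods via
    their alert's fired_at.
    """
    ordered = sorted(period_boundaries, key=lambda p: p[1])
    for (la, sa, ea), (lb, sb, eb) in zip(ordered, ordered[1:]):
        if sb <= ea:
            raise ValueError(f"periods {la!r} and {lb!r} overlap")

    alert_period: Dict[str, str] = {}
    outside = []
    for alert in alerts:
        d = alert.fired_at.date()
        for label, start, end in ordered:
            if start <= d <= end:
                alert_period[alert.alert_id] = label
                break
        else:
            outside.append(alert.alert_id)
    if outside:
        raise ValueError(f"alerts outside all periods: {sorted(outside)}")

    unknown = sorted({oc.alert_id for oc in outcomes} - set(alert_period))
    if unknown:
        raise ValueError(f"outcomes reference unknown alert ids: {unknown}")

    counts = {label: [0, 0, 0] for label, _, _ in ordered}
    for alert in alerts:
        counts[alert_period[alert.alert_id]][0] += 1
    for oc in outcomes:
        row = counts[alert_period[oc.alert_id]]
        row[1] += 1
        if oc.disposition == Disposition.HIGHLY_SUSPICIOUS:
            row[2] += 1
    return summarize_from_counts([(label, *counts[label]) for label, _, _ in ordered])


def monthly_series(
    alerts: Sequence[Alert],
    outcomes: Sequence[ScreeningOutcome],
) -> Dict[str, Tuple[int, int]]:
    """Per-month (n_reviewed, n_suspicious), zero-filled over the span.

    Reviews are binned by their ``reviewed_at`` month. Months inside the span
    of activity (earliest to latest alert or review) with nothing to report
    appear with (0, 0); empty inputs give an empty map.
    """
    months = [month_key(a.fired_at) for a in alerts] + [month_key(o.reviewed_at) for o in outcomes]
    if not months:
        return {}
    lo, hi = min(months), max(months)
    series: Dict[str, List[int]] = {}
    y, m = (int(x) for x in lo.split("-"))
    while f"{y:04d}-{m:02d}" <= hi:
        series[f"{y:04d}-{m:02d}"] = [0, 0]
        m += 1
        if m > 12:
            y, m = y + 1, 1
    for oc in outcomes:
        row = series[month_key(oc.reviewed_at)]
        row[0] += 1
        if oc.disposition == Disposition.HIGHLY_SUSPICIOUS:
            row[1] += 1
    return {k: (v[0], v[1]) for k, v in series.items()}


def baseline_comparison(total_suspicious: int, baseline_per_year: int, observation_months: int) -> float:
    """Ratio of the annualized highly-suspicious detection rate to a
    pre-program baseline of cases identified per year."""
    if total_suspicious <= 0 or observation_months <= 0:
        raise ValueError("total_suspicious and observation_months must be positive")
    if baseline_per_year <= 0:
        raise ValueError("baseline_per_year must be positive")
    return (12 * total_suspicious / observation_months) / baseline_per_year


def summaries_to_dataframe(rows: Sequence[PeriodSummary]) -> pd.DataFrame:
    """Tabular view of funnel rows; undefined percentages render empty."""
    return pd.DataFrame(
        [
            {
                "period_label": r.period_label,
                "n_alerts": r.n_alerts,
                "n_screened": r.n_screened,
                "pct_screened": "" if r.pct_screened is None else r.pct_screened,
                "n_suspicious": r.n_suspicious,
                "pct_screened_in": "" if r.pct_screened_in is None else r.pct_screened_in,
            }
            for r in rows
        ]
    )
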