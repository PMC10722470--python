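"""Capacity-limited navigator screening of the alert queue.

A single High-Risk Patient Navigator (HRPN) reviews alerts earliest-first
within each calendar month, up to that month's capacity; alerts left over at
month end expire (they are not back-filled later). Whether a reviewed case
is labeled "highly suspicious" is modeled as a Bernoulli draw — in practice
it is a subjective judgment of the navigator, so no deterministic rule is
pretended here.
"""

from __future__ import annotations

import json
from datetime import datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from .sentry_engine import Alert, AlertStatus

__all__ = [
    "Disposition",
    "NavigatorCapacity",
    "ScreeningOutcome",
    "simulate_screening",
    "load_capacity",
    "read_outcomes",
    "write_outcomes",
    "month_key",
]

#: Lag between an alert firing and the navigator's review of it.
REVIEW_DELAY = timedelta(hours=1)


def month_key(ts: datetime) -> str:
    return f"{ts.year:04d}-{ts.month:02d}"


class Disposition(str, Enum):
    HIGHLY_SUSPICIOUS = "highly_suspicious"
    NOT_SUSPICIOUS = "not_suspicious"


class NavigatorCapacity(BaseModel):
    """A navigator's monthly review capacity and screened-in propensity.

    ``monthly_capacity`` maps ``YYYY-MM`` to the maximum number of alerts the
    navigator can review that month (0 is legal: a month fully diverted to
    other duties). Months absent from the map fall back to
    ``default_capacity``; ``None`` means unbounded.
    """

    navigator_id: str = "hrpn-1"
    monthly_capacity: Dict[str, int] = Field(default_factory=dict)
    default_capacity: Optional[int] = None
    suspicion_rate: float = Field(ge=0.0, le=1.0)
    contact_rate: float = Field(default=0.5, ge=0.0, le=1.0)

    @field_validator("monthly_capacity")
    @classmethod
    def _nonnegative(cls, v: Dict[str, int]) -> Dict[str, int]:
        for month, cap in v.items():
            if cap < 0:
                raise ValueError(f"capacity for {month} is negative")
        return v

    @field_validator("default_capacity")
    @classmethod
    def _default_ok(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and v < 0:
            raise ValueError("default_capacity is negative")
        return v

    def capacity_for(self, month: str) -> Optional[int]:
        return self.monthly_capacity.get(month, self.default_capacity)


class ScreeningOutcome(BaseModel):
    alert_id: str
    navigator_id: str
    reviewed_at: datetime
    disposition: Disposition
    contact_made: bool = False


def simulate_screening(
    alerts: Sequence[Alert],
    capacity: NavigatorCapacity,
    seed: int,
) -> List[ScreeningOutcome]:
    """Simulate navigator review of a time-ordered alert queue.

    Within each month at most ``capacity_for(month)`` alerts are reviewed,
    earliest-fired first. Each reviewed alert is labeled highly suspicious
    with probability ``suspicion_rate`` and contacted with probability
    ``contact_rate`` (two draws per review, in queue order, from a single
    seeded generator). Reviewed alerts get status ``screened``; the rest of
    the month's queue expires.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    for a, b in zip(alerts, alerts[1:]):
        if b.fired_at < a.fired_at:
            raise ValueError("alerts must be time-ordered by fired_at")

    rng = np.random.default_rng(seed)
    outcomes: List[ScreeningOutcome] = []
    reviewed_in_month: Dict[str, int] = {}
    for alert in alerts:
        month = month_key(alert.fired_at)
        cap = capacity.capacity_for(month)
        used = reviewed_in_month.get(month, 0)
        if cap is not None and used >= cap:
            alert.status = AlertStatus.EXPIRED
            continue
        reviewed_in_month[month] = used + 1
        suspicious = rng.random() < capacity.suspicion_rate
        contact = rng.random() < capacity.contact_rate
        alert.status = AlertStatus.SCREENED
        outcomes.append(
            ScreeningOutcome(
                alert_id=alert.alert_id,
                navigator_id=capacity.navigator_id,
                reviewed_at=alert.fired_at + REVIEW_DELAY,
                disposition=Disposition.HIGHLY_SUSPICIOUS if suspicious else Disposition.NOT_SUSPICIOUS,
                contact_made=contact,
            )
        )
    return outcomes


def load_capacity(path: Union[str, Path]) -> NavigatorCapacity:
    """Load a capacity file: YAML with ``suspicion_rate``, optional
    ``navigator_id``/``default``/``contact_rate`` and a ``monthly`` map of
    ``YYYY-MM`` to integer capacity."""
    with Path(path).open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    return NavigatorCapacity(
        navigator_id=str(doc.get("navigator_id", "hrpn-1")),
        monthly_capacity={str(k): int(v) for k, v in (doc.get("monthly") or {}).items()},
        default_capacity=doc.get("default"),
        suspicion_rate=float(doc["suspicion_rate"]),
        contact_rate=float(doc.get("contact_rate", 0.5)),
    )


def write_outcomes(outcomes: Iterable[ScreeningOutcome], path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for oc in outcomes:
            fh.write(oc.model_dump_json() + "\n")


def read_outcomes(path: Union[str, Path]) -> List[ScreeningOutcome]:
    out = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(ScreeningOutcome.model_validate_json(line))
    return out
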