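"""Discretization of raw context-probe readings into observation vectors.

Eight context probes (mobile phone + PC activity) each map onto a three-level
code ``{0, 1, 2}``: categorical probes via fixed label tables, rate probes via
two cut points.  An :class:`ObservationVector` collects the eight codes at one
timestamp using last-valid-reading semantics within a lookback window; probes
with no recent reading fall back to code 0 (the "unknown"/"not active" level
of every probe).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed probe order used for every serialization and observation slot.
PROBE_ORDER: tuple[str, ...] = (
    "location",
    "ambient_volume",
    "physical_activity",
    "call_status",
    "ringer_status",
    "pc_keys",
    "pc_backspace",
    "pc_clicks",
)

CATEGORICAL_PROBES: tuple[str, ...] = ("location", "call_status", "ringer_status")
RATE_PROBES: tuple[str, ...] = (
    "ambient_volume",
    "physical_activity",
    "pc_keys",
    "pc_backspace",
    "pc_clicks",
)

N_SENSORS = 8
N_CODES = 3
N_JOINT = N_CODES**N_SENSORS  # 6561 joint observation symbols

#: Canonical label -> code tables for the categorical probes.
DEFAULT_CATEGORICAL_MAPS: dict[str, dict[str, int]] = {
    "location": {"unknown": 0, "home": 1, "at work": 2, "at_work": 2, "work": 2},
    "call_status": {"idle": 0, "ringing": 1, "in a call": 2, "in_a_call": 2},
    "ringer_status": {"silent": 0, "vibrator": 1, "normal": 2},
}

#: (low_cut, high_cut) per rate probe; values below low_cut code 0, in
#: [low_cut, high_cut) code 1, at or above high_cut code 2.
DEFAULT_RATE_CUTS: dict[str, tuple[float, float]] = {
    "ambient_volume": (40.0, 70.0),  # dB SPL
    "physical_activity": (20.0, 100.0),  # activity counts / min
    "pc_keys": (10.0, 60.0),  # keystrokes / min
    "pc_backspace": (2.0, 10.0),  # backspaces / min
    "pc_clicks": (5.0, 30.0),  # clicks / min
}


@dataclass(frozen=True)
class ProbeEvent:
    """One raw timestamped reading from a single context probe.

    Parameters
    ----------
    probe_id : str
        One of the eight probes in :data:`PROBE_ORDER`.
    timestamp : float
        Seconds since the Unix epoch (UTC).
    raw_value : str or float
        Probe-specific payload: a categorical label for location/call/ringer
        probes, a non-negative rate for the remaining probes.
    """

    probe_id: str
    timestamp: float
    raw_value: str | float

    def __post_init__(self) -> None:
        if self.probe_id not in PROBE_ORDER:
            raise ValueError(f"unknown probe_id {self.probe_id!r}")
        if not math.isfinite(self.timestamp):
            raise ValueError("timestamp must be finite")
        if self.probe_id in RATE_PROBES:
            v = float(self.raw_value)
            if v < 0:
                raise ValueError(f"rate for {self.probe_id} must be >= 0, got {v}")


@dataclass
class DiscretizationConfig:
    """Label tables and numeric cut points mapping raw readings to codes.

    ``default_value`` is the code assigned to a probe slot when no valid
    reading exists in the lookback window (0 by default: the unknown/idle/
    not-active level of every probe).
    """

    categorical_maps: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CATEGORICAL_MAPS.items()}
    )
    rate_cuts: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATE_CUTS)
    )
    default_value: int = 0

    def __post_init__(self) -> None:
        for probe, table in self.categorical_maps.items():
            bad = {c for c in table.values() if c not in (0, 1, 2)}
            if bad:
                raise ValueError(f"{probe}: codes outside {{0,1,2}}: {bad}")
        for probe, (low, high) in self.rate_cuts.items():
            if not low < high:
                raise ValueError(f"{probe}: low_cut {low} must be < high_cut {high}")
        if self.default_value not in (0, 1, 2):
            raise ValueError("default_value must be in {0,1,2}")


@dataclass(frozen=True)
class ObservationVector:
    """Eight discrete sensor codes at one timestamp, in :data:`PROBE_ORDER`.

    ``provenance`` flags each slot as ``"observed"`` (a reading existed in
    the lookback window) or ``"defaulted"`` (filled with the default code).
    """

    timestamp: float
    values: tuple[int, ...]
    provenance: tuple[str, ...] = ("observed",) * N_SENSORS

    def __post_init__(self) -> None:
        if len(self.values) != N_SENSORS:
            raise ValueError(f"expected {N_SENSORS} codes, got {len(self.values)}")
        if any(v not in (0, 1, 2) for v in self.values):
            raise ValueError(f"codes must be in {{0,1,2}}: {self.values}")
        if len(self.provenance) != N_SENSORS:
            raise ValueError("provenance must have one flag per slot")


def discretize_event(event: ProbeEvent, config: DiscretizationConfig | None = None) -> int:
    """Map one raw probe reading to its discrete code in ``{0, 1, 2}``.

    Categorical probes use the configured label tables; an unrecognized label
    maps to code 0 (the unknown level) with a logged warning.  Rate probes use
    half-open binning: ``[0, low_cut) -> 0``, ``[low_cut, high_cut) -> 1``,
    ``[high_cut, inf) -> 2``.
    """
    config = config or DiscretizationConfig()
    if event.probe_id in CATEGORICAL_PROBES:
        table = config.categorical_maps[event.probe_id]
        label = str(event.raw_value).strip().lower()
        if label not in table:
            logger.warning(
                "probe %s: unknown label %r, mapping to code 0", event.probe_id, event.raw_value
            )
            return 0
        return table[label]
    if event.probe_id in RATE_PROBES:
        low, high = config.rate_cuts[event.probe_id]
        v = float(event.raw_value)
        if v < low:
            return 0
        if v < high:
            return 1
        return 2
    raise ValueError(f"unknown probe_id {event.probe_id!r}")


def build_observation(
    events: Sequence[ProbeEvent],
    t: float,
    lookback: float = 900.0,
    config: DiscretizationConfig | None = None,
) -> ObservationVector:
    """Assemble the observation vector at time ``t`` from last valid readings.

    For each probe, the most recent event with timestamp in ``(t - lookback, t]``
    is discretized; probes with no event in the window receive
    ``config.default_value`` with provenance ``"defaulted"``.

    Parameters
    ----------
    events : sequence of ProbeEvent
        Raw probe events; sorted internally if needed.
    t : float
        Evaluation timestamp (epoch seconds).
    lookback : float
        Window length in seconds (default 900 s = 15 min, matching the
        minimum prompt spacing so one observation cannot span two prompts).
    """
    if lookback <= 0:
        raise ValueError("lookback must be positive")
    config = config or DiscretizationConfig()
    latest: dict[str, ProbeEvent] = {}
    for ev in events:
        if t - lookback < ev.timestamp <= t:
            prev = latest.get(ev.probe_id)
            if prev is None or ev.timestamp >= prev.timestamp:
                latest[ev.probe_id] = ev
    values: list[int] = []
    provenance: list[str] = []
    for probe in PROBE_ORDER:
        ev = latest.get(probe)
        if ev is None:
            values.append(config.default_value)
            provenance.append("defaulted")
        else:
            values.append(discretize_event(ev, config))
            provenance.append("observed")
    return ObservationVector(timestamp=t, values=tuple(values), provenance=tuple(provenance))


def encode_joint(obs: ObservationVector | Sequence[int]) -> int:
    """Mixed-radix (base-3) encoding of the 8-tuple into ``[0, 6561)``."""
    values = obs.values if isinstance(obs, ObservationVector) else tuple(obs)
    if len(values) != N_SENSORS or any(v not in (0, 1, 2) for v in values):
        raise ValueError(f"expected 8 codes in {{0,1,2}}, got {values}")
    symbol = 0
    for v in values:
        symbol = symbol * N_CODES + v
    return symbol


def decode_joint(symbol: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_joint`."""
    if not 0 <= symbol < N_JOINT:
        raise ValueError(f"symbol must be in [0, {N_JOINT}), got {symbol}")
    values = []
    for _ in range(N_SENSORS):
        values.append(symbol % N_CODES)
        symbol //= N_CODES
    return tuple(reversed(values))


# ---------------------------------------------------------------------------
# I/O: JSONL / CSV event logs and observation tables
# ---------------------------------------------------------------------------


def _parse_timestamp(value) -> float:
    if isinstance(value, (int, float)):
        return float(value)
    dt = datetime.fromisoformat(str(value).replace("Z", "+00:00"))
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


def _iso(ts: float) -> str:
    return datetime.fromtimestamp(ts, tz=timezone.utc).isoformat()


def read_events_jsonl(path) -> list[ProbeEvent]:
    """Read probe events from JSONL (keys: probe_id, timestamp, raw_value)."""
    events = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            events.append(
                ProbeEvent(rec["probe_id"], _parse_timestamp(rec["timestamp"]), rec["raw_value"])
            )
    events.sort(key=lambda e: e.timestamp)
    return events


def write_events_jsonl(events: Iterable[ProbeEvent], path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(
                json.dumps(
                    {"probe_id": ev.probe_id, "timestamp": _iso(ev.timestamp), "raw_value": ev.raw_value}
                )
                + "\n"
            )


def read_events_csv(path) -> list[ProbeEvent]:
    """Read probe events from a 3-column CSV (probe_id, timestamp, raw_value)."""
    df = pd.read_csv(path)
    events = [
        ProbeEvent(row.probe_id, _parse_timestamp(row.timestamp), row.raw_value)
        for row in df.itertuples()
    ]
    events.sort(key=lambda e: e.timestamp)
    return events


def write_events_csv(events: Iterable[ProbeEvent], path) -> None:
    pd.DataFrame(
        [{"probe_id": e.probe_id, "timestamp": _iso(e.timestamp), "raw_value": e.raw_value} for e in events]
    ).to_csv(path, index=False)


def observations_to_frame(observations: Sequence[ObservationVector]) -> pd.DataFrame:
    """Tabulate observations: timestamp + 8 code columns + 8 provenance flags."""
    rows = []
    for obs in observations:
        row: dict[str, object] = {"timestamp": _iso(obs.timestamp)}
        for probe, code, prov in zip(PROBE_ORDER, obs.values, obs.provenance):
            row[probe] = code
            row[f"{probe}_provenance"] = prov
        rows.append(row)
    return pd.DataFrame(rows)


def write_observations_csv(observations: Sequence[ObservationVector], path) -> None:
    observations_to_frame(observations).to_csv(path, index=False)
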