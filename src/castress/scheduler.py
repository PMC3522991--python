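"""Signal-contingent questionnaire prompt scheduling.

One prompt is drawn uniformly at random inside each 60-minute block of the
daily prompting window, subject to consecutive prompts being at least
``min_gap_minutes`` apart.  The draw range of each block is clipped so the
spacing constraint is always satisfiable (rejection-free construction), which
makes the schedule a deterministic function of its parameters and seed.  The
schedule never consults context or physiology: prompts are unrelated to
external events by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86400.0


def _parse_clock(value: str | float) -> float:
    """Clock time 'HH:MM' (or minutes since midnight) -> minutes since midnight."""
    if isinstance(value, (int, float)):
        return float(value)
    hh, mm = str(value).split(":")
    return 60.0 * int(hh) + int(mm)


@dataclass
class PromptSchedule:
    """A multi-day list of questionnaire prompt times.

    ``prompt_times`` are epoch seconds, strictly increasing, exactly one per
    block per day, all inside the ``[day_start, day_end]`` clock window of
    their day, with every within-day consecutive gap >= ``min_gap_minutes``.
    """

    prompt_times: list[float]
    day_start: float  # minutes since midnight
    day_end: float
    block_minutes: float = 60.0
    min_gap_minutes: float = 15.0
    n_days: int = 7
    seed: int | None = None
    start_epoch: float = 0.0  # midnight of day 0, epoch seconds

    @property
    def blocks_per_day(self) -> int:
        return int(round((self.day_end - self.day_start) / self.block_minutes))

    def day_index(self, t: float) -> int:
        return int((t - self.start_epoch) // SECONDS_PER_DAY)

    def to_frame(self) -> pd.DataFrame:
        iso = [
            datetime.fromtimestamp(t, tz=timezone.utc).isoformat() for t in self.prompt_times
        ]
        return pd.DataFrame({"prompt_time": iso})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_schedule(
    n_days: int = 7,
    day_start: str | float = "07:00",
    day_end: str | float = "23:00",
    block_minutes: float = 60.0,
    min_gap_minutes: float = 15.0,
    seed: int | None = None,
    start_epoch: float = 0.0,
) -> PromptSchedule:
    """Generate prompt times: one uniform draw per block, >= min_gap apart.

    Block ``k`` of each day spans ``[start + k*block, start + (k+1)*block)``
    minutes of clock time.  The prompt for block ``k`` is drawn uniformly from
    that block clipped below at ``previous_prompt + min_gap``; because
    ``min_gap_minutes < block_minutes`` the clipped interval is never empty.
    The first block of each day is unconstrained by the previous day.

    Raises
    ------
    ValueError
        If ``min_gap_minutes >= block_minutes`` (constraint could become
        infeasible across consecutive blocks) or the prompting window does
        not divide into whole blocks.
    """
    start_min = _parse_clock(day_start)
    end_min = _parse_clock(day_end)
    if end_min <= start_min:
        raise ValueError("day_end must be after day_start")
    span = end_min - start_min
    n_blocks = span / block_minutes
    if abs(n_blocks - round(n_blocks)) > 1e-9:
        raise ValueError(
            f"prompting window of {span} min does not divide into {block_minutes}-min blocks"
        )
    n_blocks = int(round(n_blocks))
    if min_gap_minutes >= block_minutes:
        raise ValueError("min_gap_minutes must be < block_minutes")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")

    rng = np.random.default_rng(seed)
    prompt_times: list[float] = []
    for day in range(n_days):
        day_origin = start_epoch + day * SECONDS_PER_DAY
        prev: float | None = None
        for k in range(n_blocks):
            block_lo = day_origin + 60.0 * (start_min + k * block_minutes)
            block_hi = block_lo + 60.0 * block_minutes
            lo = block_lo if prev is None else max(block_lo, prev + 60.0 * min_gap_minutes)
            t = rng.uniform(lo, block_hi)
            prompt_times.append(t)
            prev = t

    return PromptSchedule(
        prompt_times=prompt_times,
        day_start=start_min,
        day_end=end_min,
        block_minutes=block_minutes,
        min_gap_minutes=min_gap_minutes,
        n_days=n_days,
        seed=seed,
        start_epoch=start_epoch,
    )


@dataclass
class ScheduleReport:
    ok: bool
    violations: list[dict] = field(default_factory=list)


def validate_schedule(schedule: PromptSchedule) -> ScheduleReport:
    """Independently re-check every schedule invariant.

    Checks monotonicity, the within-day minimum gap, the one-prompt-per-block
    rule, and that every prompt lies inside its day's prompting window.
    Implemented directly from the invariants (not by re-running the
    generator) so it can serve as an oracle for the construction.
    """
    violations: list[dict] = []
    times = schedule.prompt_times
    for a, b in zip(times, times[1:]):
        if b <= a:
            violations.append({"type": "order", "detail": f"{b} <= {a}"})

    # group prompts by day, then check gaps and block occupancy per day
    by_day: dict[int, list[float]] = {}
    for t in times:
        by_day.setdefault(schedule.day_index(t), []).append(t)

    gap_s = 60.0 * schedule.min_gap_minutes
    for day, day_times in sorted(by_day.items()):
        day_times = sorted(day_times)
        for a, b in zip(day_times, day_times[1:]):
            if b - a < gap_s - 1e-9:
                violations.append(
                    {"type": "min_gap", "detail": f"day {day}: gap {(b - a) / 60:.2f} min"}
                )
        day_origin = schedule.start_epoch + day * SECONDS_PER_DAY
        window_lo = day_origin + 60.0 * schedule.day_start
        window_hi = day_origin + 60.0 * schedule.day_end
        counts: dict[int, int] = {}
        for t in day_times:
            if not window_lo <= t <= window_hi:
                violations.append({"type": "window", "detail": f"day {day}: {t} outside window"})
                continue
            block = int((t - window_lo) // (60.0 * schedule.block_minutes))
            counts[block] = counts.get(block, 0) + 1
        for block in range(schedule.blocks_per_day):
            if counts.get(block, 0) != 1:
                violations.append(
                    {
                        "type": "block_count",
                        "detail": f"day {day} block {block}: {counts.get(block, 0)} prompts",
                    }
                )

    return ScheduleReport(ok=not violations, violations=violations)
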