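"""Electrotactile stimulation protocol: schedule generation and validation.

The experimental protocol delivers biphasic current pulses to two forearm
sites — D (dorsal, extensor carpi radialis) and V (volar, flexor carpi
radialis longus) — while the subject attends one site per block.  A session
comprises ``n_blocks`` blocks of ``stimuli_per_block`` stimuli each, every
block split into 5 sub-blocks of 60 stimuli with a pseudo-random D/V order
subject to three constraints:

* within each sub-block, each site receives between 25 and 35 stimuli;
* no more than 3 consecutive stimuli at the same site;
* the D/V split is exactly balanced over the whole session.

The attended site alternates between blocks.  Stimuli within a sub-block
are spaced by the inter-stimulus interval (700 ms by default); sub-blocks
and blocks are separated by a 10 s pause during which the subject reports
the counted number of attended stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RATE_HZ = 1200.0

__all__ = [
    "RATE_HZ",
    "Location",
    "StimulusEvent",
    "ProtocolConfig",
    "StimulusSchedule",
    "ValidationReport",
    "generate_schedule",
    "validate_schedule",
    "read_schedule_tsv",
    "write_schedule_tsv",
]


class Location(str, Enum):
    """Stimulation / attention site on the right forearm."""

    D = "D"
    V = "V"

    def other(self) -> "Location":
        return Location.V if self is Location.D else Location.D


@dataclass(frozen=True)
class StimulusEvent:
    """A single electrotactile pulse on the 1,200 Hz sample clock."""

    onset_sample: int
    location: Location
    block: int
    sub_block: int
    attended_location: Location


class ConfigurationError(ValueError):
    """Raised when a protocol configuration cannot satisfy its constraints."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Parameters of the stimulation schedule.

    Defaults reproduce the published protocol: 6 blocks x 300 stimuli,
    5 sub-blocks of 60 stimuli with 25-35 per site, 700 ms inter-stimulus
    interval, 10 s pauses, runs of at most 3 same-site stimuli.
    """

    n_blocks: int = 6
    stimuli_per_block: int = 300
    sub_blocks_per_block: int = 5
    per_site_sub_block_range: tuple[int, int] = (25, 35)
    isi_ms: float = 700.0
    pause_s: float = 10.0
    max_run_length: int = 3
    start_target: str = "randomized"  # "D", "V" or "randomized"
    warmup_s: float = 2.0
    rate_hz: float = RATE_HZ
    seed: int = 0

    @property
    def sub_block_size(self) -> int:
        return self.stimuli_per_block // self.sub_blocks_per_block

    @property
    def isi_samples(self) -> int:
        return int(round(self.isi_ms / 1000.0 * self.rate_hz))

    def validate(self) -> None:
        lo, hi = self.per_site_sub_block_range
        if self.stimuli_per_block % self.sub_blocks_per_block != 0:
            raise ConfigurationError(
                "stimuli_per_block must be divisible by sub_blocks_per_block"
            )
        size = self.sub_block_size
        if not (2 * lo <= size <= 2 * hi):
            raise ConfigurationError(
                f"per-site range {lo}-{hi} cannot sum to the sub-block total {size}"
            )
        if lo > hi or lo < 0:
            raise ConfigurationError(f"invalid per-site range {lo}-{hi}")
        if self.isi_ms < 500.0:
            raise ConfigurationError(
                "isi_ms must be >= 500 ms so 500 ms epochs never overlap"
            )
        if self.max_run_length < 1:
            raise ConfigurationError("max_run_length must be >= 1")
        if self.start_target not in ("D", "V", "randomized"):
            raise ConfigurationError("start_target must be 'D', 'V' or 'randomized'")


@dataclass
class StimulusSchedule:
    """Ordered electrotactile events plus the configuration that produced them."""

    events: list[StimulusEvent]
    config: ProtocolConfig

    def __len__(self) -> int:
        return len(self.events)

    def locations(self) -> np.ndarray:
        return np.array([e.location.value for e in self.events])

    def onsets(self) -> np.ndarray:
        return np.array([e.onset_sample for e in self.events], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_sample": [e.onset_sample for e in self.events],
                "location": [e.location.value for e in self.events],
                "block": [e.block for e in self.events],
                "sub_block": [e.sub_block for e in self.events],
                "attended_location": [e.attended_location.value for e in self.events],
            }
        )


def _draw_subblock_counts(
    rng: np.random.Generator, n_sub: int, size: int, lo: int, hi: int, block_d_total: int
) -> list[int]:
    """Per-sub-block D counts in [lo, hi] summing to block_d_total.

    Rejection sampling; the feasible region is ample for the default
    protocol (5 draws from 25-35 summing to 150).
    """
    for _ in range(100_000):
        counts = rng.integers(lo, hi + 1, size=n_sub)
        if counts.sum() == block_d_total:
            # the complementary site count must also lie in [lo, hi]
            if np.all((size - counts >= lo) & (size - counts <= hi)):
                return [int(c) for c in counts]
    raise ConfigurationError(
        f"could not draw {n_sub} per-site counts in [{lo},{hi}] summing to {block_d_total}"
    )


def _shuffle_no_long_runs(
    rng: np.random.Generator,
    n_d: int,
    n_v: int,
    max_run: int,
    carry: tuple[int, int] = (-1, 0),
) -> list[Location]:
    """Shuffle a D/V multiset, rejecting permutations with runs > max_run.

    ``carry`` is the (location code, run length) trailing the previous
    sub-block, so runs cannot exceed the limit across sub-block boundaries
    either.
    """
    pool = np.array([0] * n_d + [1] * n_v, dtype=np.int8)
    for _ in range(100_000):
        rng.shuffle(pool)
        prev, run = carry
        ok = True
        for x in pool:
            run = run + 1 if x == prev else 1
            prev = x
            if run > max_run:
                ok = False
                break
        if ok:
            return [Location.D if x == 0 else Location.V for x in pool]
    raise ConfigurationError(
        f"could not order {n_d}+{n_v} stimuli with max run {max_run}"
    )


def generate_schedule(config: ProtocolConfig | None = None) -> StimulusSchedule:
    """Generate a pseudo-randomized stimulation schedule.

    Deterministic given ``config.seed``.  Per block, per-sub-block D counts
    are drawn in the allowed range constrained to an exact D/V split of the
    block, which makes the whole-session split exact as well; each
    sub-block's D/V order is then a uniformly shuffled multiset rejected
    until no same-site run exceeds ``max_run_length``.
    """
    config = config or ProtocolConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    if config.start_target == "randomized":
        first = Location.D if rng.integers(2) == 0 else Location.V
    else:
        first = Location(config.start_target)

    lo, hi = config.per_site_sub_block_range
    size = config.sub_block_size
    block_d_total = config.stimuli_per_block // 2
    if config.stimuli_per_block % 2 != 0:
        raise ConfigurationError("stimuli_per_block must be even for an exact D/V split")

    isi = config.isi_samples
    pause = int(round(config.pause_s * config.rate_hz))
    onset = int(round(config.warmup_s * config.rate_hz))

    events: list[StimulusEvent] = []
    carry = (-1, 0)  # (location code, trailing run length) across sub-blocks
    for b in range(1, config.n_blocks + 1):
        attended = first if b % 2 == 1 else first.other()
        d_counts = _draw_subblock_counts(
            rng, config.sub_blocks_per_block, size, lo, hi, block_d_total
        )
        for sb in range(1, config.sub_blocks_per_block + 1):
            n_d = d_counts[sb - 1]
            order = _shuffle_no_long_runs(
                rng, n_d, size - n_d, config.max_run_length, carry
            )
            tail = order[-1]
            run = 1
            for loc in reversed(order[:-1]):
                if loc is tail:
                    run += 1
                else:
                    break
            carry = (0 if tail is Location.D else 1, run)
            for loc in order:
                events.append(StimulusEvent(onset, loc, b, sb, attended))
                onset += isi
            onset += pause  # report-the-count pause after every sub-block
    return StimulusSchedule(events, config)


@dataclass
class CheckResult:
    name: str
    passed: bool
    detail: str = ""
    first_violation_index: int | None = None


@dataclass
class ValidationReport:
    checks: list[CheckResult] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def __getitem__(self, name: str) -> CheckResult:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)


def validate_schedule(schedule: StimulusSchedule) -> ValidationReport:
    """Check every schedule invariant; never raises.

    Checks: total count, overall D/V balance, per-block count, per-sub-block
    site counts within range, maximum same-site run length, strictly
    increasing onsets, constant attended site within a block, alternating
    attended site across blocks.
    """
    cfg = schedule.config
    ev = schedule.events
    report = ValidationReport()

    expected_total = cfg.n_blocks * cfg.stimuli_per_block
    report.checks.append(
        CheckResult(
            "total_count",
            len(ev) == expected_total,
            f"{len(ev)} events, expected {expected_total}",
        )
    )

    n_d = sum(1 for e in ev if e.location is Location.D)
    n_v = len(ev) - n_d
    report.checks.append(
        CheckResult("location_balance", n_d == n_v, f"D={n_d}, V={n_v}")
    )

    # run-length: exhaustive scan
    run, prev, viol = 0, None, None
    for i, e in enumerate(ev):
        run = run + 1 if e.location is prev else 1
        prev = e.location
        if run > cfg.max_run_length:
            viol = i
            break
    report.checks.append(
        CheckResult(
            "max_run_length",
            viol is None,
            "" if viol is None else f"run > {cfg.max_run_length} ending at index {viol}",
            viol,
        )
    )

    onsets = schedule.onsets()
    inc_viol = None
    bad = np.nonzero(np.diff(onsets) <= 0)[0]
    if bad.size:
        inc_viol = int(bad[0] + 1)
    report.checks.append(
        CheckResult("onsets_increasing", inc_viol is None, "", inc_viol)
    )

    lo, hi = cfg.per_site_sub_block_range
    sb_ok, sb_detail = True, ""
    df = schedule.to_frame()
    if len(df):
        counts = df.groupby(["block", "sub_block", "location"], observed=True).size()
        for (b, sb) in df[["block", "sub_block"]].drop_duplicates().itertuples(index=False):
            for loc in ("D", "V"):
                c = int(counts.get((b, sb, loc), 0))
                if not (lo <= c <= hi):
                    sb_ok, sb_detail = False, f"block {b} sub-block {sb} {loc}: {c}"
                    break
            if not sb_ok:
                break
    report.checks.append(CheckResult("sub_block_site_range", sb_ok, sb_detail))

    att_ok, att_detail = True, ""
    per_block = {}
    for e in ev:
        per_block.setdefault(e.block, set()).add(e.attended_location)
    for b, atts in per_block.items():
        if len(atts) != 1:
            att_ok, att_detail = False, f"block {b} has mixed attended locations"
            break
    blocks = sorted(per_block)
    if att_ok:
        for a, b in zip(blocks, blocks[1:]):
            if per_block[a] == per_block[b]:
                att_ok, att_detail = False, f"blocks {a} and {b} share the attended location"
                break
    report.checks.append(CheckResult("attended_alternation", att_ok, att_detail))
    return report


def write_schedule_tsv(schedule: StimulusSchedule, path: str | Path) -> None:
    schedule.to_frame().to_csv(path, sep="\t", index=False)


def read_schedule_tsv(
    path: str | Path, config: ProtocolConfig | None = None
) -> StimulusSchedule:
    df = pd.read_csv(path, sep="\t")
    events = [
        StimulusEvent(
            int(r.onset_sample),
            Location(r.location),
            int(r.block),
            int(r.sub_block),
            Location(r.attended_location),
        )
        for r in df.itertuples(index=False)
    ]
    return StimulusSchedule(events, config or ProtocolConfig())
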