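"""Shared fixtures and builders for protocol-valid stage performances."""

from __future__ import annotations

import numpy as np
import pytest

from radcog.scoring import StagePerformance, TrialRecord


def perf(day1, day2=(), stage="SD", latency=10.0):
    """Build a StagePerformance from 0/1 sequences (1 = correct)."""

    def records(bits):
        return [TrialRecord(bool(b), latency if b else None) for b in bits]

    return StagePerformance(stage=stage, day1=records(day1), day2=records(day2))


def perf_from_stream(bits, stage="SD"):
    """Run the stage protocol over an i.i.d. bit stream: stop a day at six
    consecutive correct or 30 attempts; day 2 only if day 1 fails."""
    bits = iter(bits)
    days = []
    for _ in (1, 2):
        day, run = [], 0
        while len(day) < 30 and run < 6:
            b = next(bits)
            day.append(b)
            run = run + 1 if b else 0
        days.append(day)
        if run >= 6:
            break
    return perf(days[0], days[1] if len(days) > 1 else ())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
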