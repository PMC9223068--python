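"""Independent brute-force reference for the fall trigger state machine.

Instead of replaying a per-sample state machine, this reference scans the
whole trace with explicit index arithmetic: it enumerates threshold
crossings, skips the capture window on timestamps alone, and searches the
quiescence window for a cancelling peak.  Used as the oracle that the
incremental ``step`` implementation must match event-for-event.
"""

from __future__ import annotations

import math


def reference_fall_event_times(
    samples,
    threshold: float = 2.5,
    post_peak_ms: int = 1000,
    post_fall_ms: int = 1500,
) -> list[int]:
    """Event timestamps a trigger state machine must emit on this trace."""
    svms = [math.sqrt(s.ax**2 + s.ay**2 + s.az**2) for s in samples]
    times = [s.t_ms for s in samples]
    n = len(samples)
    events: list[int] = []
    i = 0
    while i < n:
        if svms[i] <= threshold:
            i += 1
            continue
        trigger = times[i]
        # capture window: samples up to trigger + post_peak_ms are logged
        j = i + 1
        while j < n and times[j] <= trigger + post_peak_ms:
            j += 1
        if j >= n:
            break
        # sample j opens the quiescence check
        deadline = times[j] + post_fall_ms
        k = j + 1
        retriggered = False
        while k < n and times[k] <= deadline:
            if svms[k] > threshold:
                i = k
                retriggered = True
                break
            k += 1
        if retriggered:
            continue
        if k >= n:
            break
        if svms[k] > threshold:
            # deadline expired on a sample that is itself a new peak: the
            # peak wins and capture restarts
            i = k
            continue
        events.append(times[k])
        i = k + 1
    return events


def random_spiky_trace(rng, rate_hz: float = 50.0):
    """A quiescent upright trace with random supra/sub-threshold spikes."""
    from bedwatch.sensors import ImuSample

    dt = 1000.0 / rate_hz
    n = int(rng.integers(100, 300))
    ax = 1.0 + rng.normal(0.0, 0.05, n)
    n_spikes = int(rng.integers(0, 7))
    for _ in range(n_spikes):
        ax[int(rng.integers(0, n))] = rng.uniform(2.0, 4.5)
    return [
        ImuSample(int(round(i * dt)), float(ax[i]), 0.0, 0.0, 0.0, 0.0, 0.0) for i in range(n)
    ]
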