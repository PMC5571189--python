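"""Timed event schedules defining one experimental condition.

A :class:`ProtocolSpec` describes the pairing/reinforcement timing of one
plasticity experiment: repeated STDP pairings (cortical stimulation paired
with a postsynaptic spike at +/-10 ms) delivered at ~0.1 Hz, each optionally
followed by a conditioned light flash 1 s later and brain-stimulation reward
(BSR) a further second later.  The same object drives both the synthetic
membrane-potential generator and the plasticity model, so a "condition" is
defined in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Tuple

__all__ = ["ProtocolSpec", "Event", "EVENT_KINDS"]

EVENT_KINDS = ("cortical_stim", "light", "bsr", "spike", "trial_start")

#: one annotated event: (time in seconds, kind)
Event = Tuple[float, str]


@dataclass
class ProtocolSpec:
    """Event schedule for one plasticity-protocol condition.

    Parameters
    ----------
    n_events
        Number of pairing trials (60 in the standard protocol).
    event_rate_hz
        Trial repetition rate (~0.1 Hz in vivo).
    pairing_dt_ms
        Pre->post spike interval: +10 for positive pairings (potentiation
        eligible), -10 for negative pairings (depression eligible), 0 or
        None for no pairing.
    light_delay_s, bsr_delay_s
        Delay of the conditioned light flash and of BSR from the pairing.
    light_on, bsr_on
        Which reinforcement components the condition includes.
    thalamus_lesioned
        If True the thalamic reinforcement signal is silenced.
    reinforcement_delay_shift_s
        Extra delay added to *both* reinforcement components (the "delayed
        by 2 s" condition uses shift = 1 s on top of the standard 1 s/2 s).
    """

    n_events: int = 60
    event_rate_hz: float = 0.1
    pairing_dt_ms: float = 10.0
    light_delay_s: float = 1.0
    bsr_delay_s: float = 2.0
    stim_on: bool = True
    light_on: bool = True
    bsr_on: bool = True
    thalamus_lesioned: bool = False
    reinforcement_delay_shift_s: float = 0.0
    baseline_s: float = 30.0
    test_s: float = 30.0
    extra_events: List[Event] = field(default_factory=list)

    def __post_init__(self):
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.event_rate_hz <= 0:
            raise ValueError("event_rate_hz must be positive")
        for name in ("light_delay_s", "bsr_delay_s", "reinforcement_delay_shift_s",
                     "baseline_s", "test_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def pairing_period_s(self) -> float:
        return 1.0 / self.event_rate_hz

    @property
    def pairing_duration_s(self) -> float:
        return self.n_events * self.pairing_period_s

    @property
    def duration_s(self) -> float:
        """Total protocol duration: baseline + pairing phase + test."""
        return self.baseline_s + self.pairing_duration_s + self.test_s

    def trial_times(self) -> List[float]:
        """Pairing (cortical stimulation) times, trial-absolute seconds."""
        t0 = self.baseline_s
        period = self.pairing_period_s
        return [t0 + k * period for k in range(self.n_events)]

    def events(self) -> List[Event]:
        """Flat, time-sorted schedule of annotated events."""
        shift = self.reinforcement_delay_shift_s
        out: List[Event] = []
        for k, t in enumerate(self.trial_times()):
            out.append((t, "trial_start"))
            if self.stim_on:
                out.append((t, "cortical_stim"))
                if self.pairing_dt_ms:
                    out.append((t + self.pairing_dt_ms / 1000.0, "spike"))
            if self.light_on:
                out.append((t + self.light_delay_s + shift, "light"))
            if self.bsr_on:
                out.append((t + self.bsr_delay_s + shift, "bsr"))
        out.extend(self.extra_events)
        out.sort(key=lambda ev: ev[0])
        return out

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        return cls(**d)
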