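"""Gas protocol: ordered CO2 epochs with analyzer-delay correction.

The CO2 analyzer samples the chamber inflow through a gas line and reports
concentration with a readout delay of roughly 15-20 s.  Epoch onsets logged
from the analyzer channel therefore lag the true chamber gas change; the
*effective* (delay-corrected) epochs shift the nominal ones back by the
delay.  All epoch intervals are half-open ``[start, end)`` seconds from
recording start.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Epoch:
    co2_percent: float
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class GasProtocol:
    """Ordered, contiguous CO2 epochs plus the analyzer readout delay.

    Parameters
    ----------
    epochs:
        Nominal epochs as logged from the gas-analyzer channel.
    analyzer_delay_s:
        Readout delay of the analyzer; effective onsets are the nominal
        onsets minus this delay.
    """

    epochs: list[Epoch] = field(default_factory=list)
    analyzer_delay_s: float = 17.5

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("protocol needs at least one epoch")
        for ep in self.epochs:
            if ep.end_s <= ep.start_s:
                raise ValueError(f"epoch {ep} has non-positive duration")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if abs(a.end_s - b.start_s) > 1e-9:
                raise ValueError("epochs must be contiguous and non-overlapping")
        if self.epochs[0].co2_percent != 0:
            raise ValueError("first epoch must be the 0% CO2 baseline")
        if self.analyzer_delay_s < 0:
            raise ValueError("analyzer delay must be >= 0")

    @classmethod
    def from_levels(
        cls,
        levels: list[float],
        durations: list[float],
        analyzer_delay_s: float = 17.5,
    ) -> "GasProtocol":
        if len(levels) != len(durations):
            raise ValueError("levels and durations must have equal length")
        t, epochs = 0.0, []
        for lvl, dur in zip(levels, durations):
            epochs.append(Epoch(float(lvl), t, t + float(dur)))
            t += float(dur)
        return cls(epochs, analyzer_delay_s)

    @property
    def levels(self) -> list[float]:
        return [ep.co2_percent for ep in self.epochs]

    @property
    def total_duration_s(self) -> float:
        return self.epochs[-1].end_s

    def effective_epochs(self) -> list[Epoch]:
        """Epochs shifted back by the analyzer delay (true chamber-gas times)."""
        d = self.analyzer_delay_s
        return [Epoch(ep.co2_percent, ep.start_s - d, ep.end_s - d) for ep in self.epochs]

    def hypercapnic_epochs(self) -> list[Epoch]:
        """Delay-corrected epochs with CO2 > 0, in protocol order."""
        return [ep for ep in self.effective_epochs() if ep.co2_percent > 0]

    def level_at(self, t: float) -> float:
        """True chamber CO2 level at time ``t`` (delay-corrected)."""
        for ep in self.effective_epochs():
            if ep.start_s <= t < ep.end_s:
                return ep.co2_percent
        return self.epochs[-1].co2_percent if t >= 0 else self.epochs[0].co2_percent
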