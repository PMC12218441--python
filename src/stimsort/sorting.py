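"""In-silico Raman-activated sorting: the Pc and PL indices and the gate.

Pc (cell index) is the raw integrated intensity of the trapped object over
1620-1670 cm^-1 divided by the same integral of the carrier fluid; it detects
that a cell is captured.  PL (labeling index) is the raw integral over the
deuterium band 2040-2300 cm^-1 divided by the 1850-1900 cm^-1 reference
region; it separates deuterium-labeled from unlabeled cells.  Both use raw
(not baseline-subtracted) integrals: a flat spectrum then gives
PL = 260/50 = 5.2, just below the operational threshold of 5.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .errors import InvalidReferenceError, InvalidSpectrumError, ValidationError
from .spectra import BandWindow, RamanSpectrum, integrate_band

__all__ = [
    "GateConfig",
    "SortEvent",
    "SortSummary",
    "cell_index",
    "labeling_index",
    "gate_decision",
    "simulate_sort",
]

Decision = Literal["collect", "waste"]


@dataclass(frozen=True)
class GateConfig:
    """Windows and thresholds driving the collect/waste decision.

    The PL threshold 5.7 is the deployed operating point; the Pc threshold is
    not published and defaults to 1.2 (declared, configurable).
    """

    pc_window: BandWindow = BandWindow(1620.0, 1670.0)
    pl_num_window: BandWindow = BandWindow(2040.0, 2300.0)
    pl_den_window: BandWindow = BandWindow(1850.0, 1900.0)
    pc_threshold: float = 1.2
    pl_threshold: float = 5.7

    def __post_init__(self) -> None:
        if self.pc_threshold <= 0 or self.pl_threshold <= 0:
            raise ValidationError("gate thresholds must be positive")
        if self.pl_den_window.hi > self.pl_num_window.lo:
            raise ValidationError(
                "PL denominator window must lie below the numerator window"
            )


@dataclass
class SortEvent:
    cell_id: str
    pc: float
    pl: float
    decision: Decision
    truth_labeled: bool | None = None


@dataclass
class SortSummary:
    n_events: int
    n_collected: int
    n_waste: int
    sensitivity: float | None = None
    specificity: float | None = None

    def __post_init__(self) -> None:
        if self.n_collected + self.n_waste != self.n_events:
            raise ValidationError("collected + waste must equal total events")


def cell_index(
    spec: RamanSpectrum, fluid: RamanSpectrum, cfg: GateConfig = GateConfig()
) -> float:
    """Pc: raw band integral of the cell over the fluid's, in pc_window."""
    denom = integrate_band(fluid, cfg.pc_window, "raw")
    if denom <= 0:
        raise InvalidReferenceError(
            f"fluid integral over pc window is {denom}; must be positive"
        )
    return integrate_band(spec, cfg.pc_window, "raw") / denom


def labeling_index(spec: RamanSpectrum, cfg: GateConfig = GateConfig()) -> float:
    """PL: raw deuterium-band integral over the raw reference-band integral."""
    denom = integrate_band(spec, cfg.pl_den_window, "raw")
    if denom <= 0:
        raise InvalidSpectrumError(
            f"PL denominator integral is {denom}; must be positive"
        )
    return integrate_band(spec, cfg.pl_num_window, "raw") / denom


def gate_decision(pc: float, pl: float, cfg: GateConfig = GateConfig()) -> Decision:
    """Collect iff pc > pc_threshold AND pl > pl_threshold; ties go to waste."""
    return "collect" if (pc > cfg.pc_threshold and pl > cfg.pl_threshold) else "waste"


def simulate_sort(
    stream: Iterable[tuple[RamanSpectrum, bool | None]],
    fluid: RamanSpectrum,
    cfg: GateConfig = GateConfig(),
) -> tuple[SortSummary, list[SortEvent]]:
    """Run the gate over a stream of (spectrum, truth_labeled) pairs.

    Sensitivity = collected & labeled / labeled; specificity = wasted &
    unlabeled / unlabeled.  Either is None when its denominator is empty or
    truth is absent.
    """
    events: list[SortEvent] = []
    for spec, truth in stream:
        pc = cell_index(spec, fluid, cfg)
        pl = labeling_index(spec, cfg)
        events.append(
            SortEvent(
                cell_id=spec.cell_id,
                pc=pc,
                pl=pl,
                decision=gate_decision(pc, pl, cfg),
                truth_labeled=truth,
            )
        )
    n_collected = sum(e.decision == "collect" for e in events)
    labeled = [e for e in events if e.truth_labeled is True]
    unlabeled = [e for e in events if e.truth_labeled is False]
    sensitivity = (
        sum(e.decision == "collect" for e in labeled) / len(labeled)
        if labeled
        else None
    )
    specificity = (
        sum(e.decision == "waste" for e in unlabeled) / len(unlabeled)
        if unlabeled
        else None
    )
    summary = SortSummary(
        n_events=len(events),
        n_collected=n_collected,
        n_waste=len(events) - n_collected,
        sensitivity=sensitivity,
        specificity=specificity,
    )
    return summary, events
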