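"""Flight-record containers: one tethered fly's angle series plus metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .solar import BUJARUELO, Site

__all__ = ["FlightRecord", "TruthRecord", "TREATMENTS", "SPECIES"]

TREATMENTS = ("sun_compass", "restricted_view", "clock_shift")
SPECIES = ("S. pyrastri", "S. selenitica")


@dataclass
class FlightRecord:
    """One fly's compass-angle time series with experiment metadata.

    ``angles_deg`` are compass bearings sampled at ``rate_hz``.
    ``flight_events`` are (start_s, stop_s) intervals of active flight
    within the recording; ``perturbations`` are intervals (shadows, loss of
    control) that interrupt otherwise continuous flight. Segment selection
    operates on these event lists.
    """

    fly_id: str
    treatment: str
    angles_deg: np.ndarray
    rate_hz: float = 5.0
    species: str = "S. pyrastri"
    sex: str = "F"
    start_time: datetime | None = None
    site: Site = BUJARUELO
    flight_events: list[tuple[float, float]] | None = None
    perturbations: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.angles_deg.ndim != 1 or self.angles_deg.size == 0:
            raise ValueError("angles_deg must be a non-empty 1-D array")
        if np.any((self.angles_deg < 0) | (self.angles_deg >= 360)):
            raise ValueError("angles must lie in [0, 360)")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.flight_events is None:
            # unannotated recordings default to continuous flight throughout
            self.flight_events = [(0.0, self.duration_s)]
        for t0, t1 in list(self.flight_events) + list(self.perturbations):
            if not (0.0 <= t0 < t1 <= self.duration_s + 1e-9):
                raise ValueError("event interval outside recording duration")

    @property
    def duration_s(self) -> float:
        return self.angles_deg.size / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.angles_deg.size) / self.rate_hz


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one synthetic fly (for recovery tests)."""

    fly_id: str
    true_heading_deg: float
    true_angles_deg: np.ndarray
    true_r: float
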