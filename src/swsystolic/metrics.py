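"""GCUPS (giga cell updates per second) performance accounting.

Two standard formulations:

* achieved throughput — cells computed divided by elapsed time,
  ``GCUPS = cells / seconds / 1e9``;
* peak throughput of a systolic array — one cell per PE per clock,
  ``GCUPS = pe_count * clock_hz * 1e-9``.

They are kept as separate operations because they measure different
things: the first is a measurement, the second a design ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass


__all__ = ["PerfReport", "gcups_from_time", "gcups_from_frequency"]


def gcups_from_time(cell_count: int, elapsed_seconds: float) -> float:
    """Achieved GCUPS: cells computed divided by processing time."""
    if cell_count < 1:
        raise ValueError(f"cell_count must be >= 1, got {cell_count}")
    if elapsed_seconds <= 0:
        raise ValueError(
            f"elapsed_seconds must be positive, got {elapsed_seconds}"
        )
    return cell_count / elapsed_seconds / 1e9


def gcups_from_frequency(pe_count: int, clock_hz: float) -> float:
    """Peak GCUPS of a PE array: one cell update per PE per clock cycle."""
    if pe_count < 1:
        raise ValueError(f"pe_count must be >= 1, got {pe_count}")
    if clock_hz <= 0:
        raise ValueError(f"clock_hz must be positive, got {clock_hz}")
    return pe_count * clock_hz * 1e-9


@dataclass(frozen=True)
class PerfReport:
    """A GCUPS figure together with the quantities that produced it.

    Exactly one of ``elapsed_seconds`` / ``clock_hz`` is set, marking which
    formula drove the computation.
    """

    cell_count: int
    gcups: float
    elapsed_seconds: float | None = None
    clock_hz: float | None = None

    def __post_init__(self) -> None:
        if (self.elapsed_seconds is None) == (self.clock_hz is None):
            raise ValueError(
                "exactly one of elapsed_seconds / clock_hz must be set"
            )
        if self.gcups <= 0:
            raise ValueError(f"gcups must be positive, got {self.gcups}")

    @classmethod
    def from_time(cls, cell_count: int, elapsed_seconds: float) -> "PerfReport":
        return cls(
            cell_count=cell_count,
            gcups=gcups_from_time(cell_count, elapsed_seconds),
            elapsed_seconds=elapsed_seconds,
        )

    @classmethod
    def from_frequency(cls, pe_count: int, clock_hz: float) -> "PerfReport":
        # For the peak formula the cell count per cycle equals the PE count.
        return cls(
            cell_count=pe_count,
            gcups=gcups_from_frequency(pe_count, clock_hz),
            clock_hz=clock_hz,
        )

    def to_dict(self) -> dict:
        return {
            "cell_count": self.cell_count,
            "gcups": self.gcups,
            "elapsed_seconds": self.elapsed_seconds,
            "clock_hz": self.clock_hz,
        }
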