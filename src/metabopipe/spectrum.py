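"""MS2 spectrum container shared by the IO, annotation and MRM modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Spectrum:
    """One MS2 scan.

    Parameters
    ----------
    precursor_mz
        Precursor ion m/z in Da.
    polarity
        ``"pos"`` or ``"neg"``.
    peaks
        Fragment (m/z, intensity) pairs. Stored sorted ascending by m/z;
        intensities must be nonnegative and at least one peak is required.
    rt
        Retention time in seconds, if known.
    """

    precursor_mz: float
    polarity: str = "pos"
    peaks: list[tuple[float, float]] = field(default_factory=list)
    rt: float | None = None

    def __post_init__(self):
        if self.polarity not in ("pos", "neg"):
            raise ValueError(f"polarity must be 'pos' or 'neg', got {self.polarity!r}")
        if len(self.peaks) == 0:
            raise ValueError("a Spectrum needs at least one peak")
        pk = [(float(m), float(i)) for m, i in self.peaks]
        if any(i < 0 for _, i in pk):
            raise ValueError("fragment intensities must be nonnegative")
        self.peaks = sorted(pk)  # ascending m/z; normalization contract

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])

    def __eq__(self, other):
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.precursor_mz == other.precursor_mz
            and self.polarity == other.polarity
            and self.rt == other.rt
            and self.peaks == other.peaks
        )
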