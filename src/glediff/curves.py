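"""Sampled time-domain observables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterDomainError

#: default units per observable kind (internal unit system)
DEFAULT_UNITS = {
    "msd": ("ps", "nm^2"),
    "vacf": ("ps", "nm^2/ps^2"),
    "dcoef": ("ps", "nm^2/ps"),
    "alpha": ("ps", "1"),
    "spectrum": ("ps^-1", "ps"),
}

KINDS = tuple(DEFAULT_UNITS)


@dataclass
class ObservableCurve:
    """A sampled observable: MSD, VACF, D(t), local exponent, or spectrum.

    Attributes
    ----------
    times : ndarray
        Strictly increasing, positive abscissae (ps, or ps^-1 for spectra).
    values : ndarray
        Observable samples.
    kind : str
        One of ``msd``, ``vacf``, ``dcoef``, ``alpha``, ``spectrum``.
    units : tuple of str
        (abscissa unit, value unit).
    meta : dict
        Free-form provenance (estimator settings, seeds, origin spacing...).
    """

    times: np.ndarray
    values: np.ndarray
    kind: str
    units: tuple = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in KINDS:
            raise ParameterDomainError(f"unknown curve kind {self.kind!r}")
        if self.units is None:
            self.units = DEFAULT_UNITS[self.kind]
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ParameterDomainError("times and values must be matching 1-d arrays")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ParameterDomainError("times must be strictly increasing")
        if self.kind == "msd" and np.any(self.values < 0):
            raise ParameterDomainError("MSD values must be nonnegative")

    def __len__(self) -> int:
        return len(self.times)
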