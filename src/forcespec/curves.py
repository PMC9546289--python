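"""Force-curve data model.

A :class:`ForceCurve` is an ordered list of approach/pause/retract
:class:`Segment` records of piezo height (nm) versus vertical force (pN),
together with the cantilever metadata needed downstream (spring constant,
pulling speed, temperature).

Height convention: during *approach* the piezo height decreases strictly
(the tip closes on the sample); during *retract* it increases strictly.
Pause segments hold position and carry no monotonicity constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SEGMENT_KINDS = ("approach", "pause", "retract")
CURVE_MODES = ("indentation", "adhesion", "unfolding")


class CurveValidationError(ValueError):
    """A curve or segment violates a structural invariant."""


@dataclass
class Segment:
    """One contiguous piece of a force-distance record.

    Parameters
    ----------
    kind : {'approach', 'pause', 'retract'}
    height : ndarray
        Piezo z positions in nm; strictly decreasing for approach,
        strictly increasing for retract.
    force : ndarray
        Vertical force in pN, same length as ``height``.
    sampling_rate : float
        Acquisition rate in Hz.
    """

    kind: str
    height: np.ndarray
    force: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height, dtype=float)
        self.force = np.asarray(self.force, dtype=float)

    def validate(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise CurveValidationError(f"unknown segment kind {self.kind!r}")
        if self.height.ndim != 1 or self.force.ndim != 1:
            raise CurveValidationError("height and force must be 1-D")
        if len(self.height) != len(self.force):
            raise CurveValidationError(
                f"height ({len(self.height)}) and force ({len(self.force)}) "
                "differ in length"
            )
        if len(self.height) < 2:
            raise CurveValidationError("segment needs at least 2 samples")
        if not (np.all(np.isfinite(self.height)) and np.all(np.isfinite(self.force))):
            raise CurveValidationError("non-finite values in segment")
        if self.sampling_rate <= 0:
            raise CurveValidationError("sampling_rate must be positive")
        dh = np.diff(self.height)
        if self.kind == "approach" and not np.all(dh < 0):
            raise CurveValidationError("approach heights must strictly decrease")
        if self.kind == "retract" and not np.all(dh > 0):
            raise CurveValidationError("retract heights must strictly increase")

    @property
    def n_samples(self) -> int:
        return len(self.height)


@dataclass
class ForceCurve:
    """A segmented force-distance record with cantilever metadata.

    ``annotations`` is a free-form string->string map; the synthetic
    generators use it to carry ground truth (e.g. the true Young's modulus)
    and the FDC-TSV container round-trips it.
    """

    segments: list[Segment]
    spring_constant: float  # pN/nm
    velocity: float  # nm/s
    temperature: float  # K
    mode: str
    curve_id: str
    cell_id: str = ""
    group_label: str = ""
    annotations: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.spring_constant <= 0:
            raise CurveValidationError("spring_constant must be positive")
        if self.temperature <= 0:
            raise CurveValidationError("temperature must be positive")
        if self.velocity <= 0:
            raise CurveValidationError("velocity must be positive")
        if self.mode not in CURVE_MODES:
            raise CurveValidationError(f"unknown mode {self.mode!r}")
        if not self.segments:
            raise CurveValidationError("curve has no segments")
        kinds = {s.kind for s in self.segments}
        if not kinds & {"approach", "retract"}:
            raise CurveValidationError(
                "curve needs at least one approach or retract segment"
            )
        for seg in self.segments:
            seg.validate()

    def _first(self, kind: str) -> Segment | None:
        for seg in self.segments:
            if seg.kind == kind:
                return seg
        return None

    @property
    def approach(self) -> Segment | None:
        return self._first("approach")

    @property
    def retract(self) -> Segment | None:
        return self._first("retract")

    @property
    def pause(self) -> Segment | None:
        return self._first("pause")
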