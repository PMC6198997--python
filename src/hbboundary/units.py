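"""Coordinate systems along the anterior-posterior (AP) axis.

Positions are expressed in three mutually consistent units:

``x_ln``
    Log relative transcription-factor concentration, ``X = ln [TF]``,
    zero at the mid-boundary (half-maximal expression) point.  Because
    the Bicoid gradient decays exponentially with decay length
    ``lambda``, ``X`` is also a physical distance measured in gradient
    decay lengths, increasing toward the anterior.
``x_el``
    Percent egg length (% EL); -50 is the anterior pole, +50 the
    posterior pole.  The wild-type boundary sits near -5% EL.
``x_nuclei``
    Nucleus widths; one nucleus spans about 2% EL.

The decay length of the gradient is about 100 um, i.e. about 20% EL,
so 1 unit of ``x_ln`` corresponds to 20% EL (anterior-ward, hence the
minus sign in the conversion).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Mid-boundary position in % egg length (anterior of mid-embryo).
EL_BOUNDARY: float = -5.0
#: Gradient decay length in % egg length.
LAMBDA_EL: float = 20.0
#: Width of one nucleus in % egg length.
NUCLEUS_EL: float = 2.0


def ln_to_el(x_ln: float) -> float:
    """Absolute position: log-concentration units -> % egg length."""
    return EL_BOUNDARY - LAMBDA_EL * x_ln


def el_to_ln(x_el: float) -> float:
    """Absolute position: % egg length -> log-concentration units."""
    return (EL_BOUNDARY - x_el) / LAMBDA_EL


def el_to_nuclei(x_el: float) -> float:
    return x_el / NUCLEUS_EL


def dist_ln_to_el(d_ln: float) -> float:
    """Distance (offset-free) conversion: ln units -> % EL."""
    return LAMBDA_EL * d_ln


def dist_el_to_ln(d_el: float) -> float:
    return d_el / LAMBDA_EL


@dataclass(frozen=True)
class Position:
    """A position on the AP axis, canonically stored in ``x_ln``."""

    x_ln: float

    @classmethod
    def from_el(cls, x_el: float) -> "Position":
        return cls(el_to_ln(x_el))

    @classmethod
    def from_nuclei(cls, x_nuclei: float) -> "Position":
        return cls(el_to_ln(x_nuclei * NUCLEUS_EL))

    @property
    def x_el(self) -> float:
        return ln_to_el(self.x_ln)

    @property
    def x_nuclei(self) -> float:
        return el_to_nuclei(self.x_el)

    @property
    def tf_concentration(self) -> float:
        """Relative TF concentration, 1 at the mid-boundary."""
        import math

        return math.exp(self.x_ln)

    def __float__(self) -> float:
        return self.x_ln
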