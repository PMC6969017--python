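"""Choroidal spatial distribution indexes (CSDIs).

The CSDIs quantify how the macular choroidal volume is tilted away from the
fovea, as log-ratios of opposing directional volumes:

    vertical CSDI   = ln(superior volume / inferior volume)
    horizontal CSDI = ln(temporal volume / nasal volume)

where each directional volume is the sum of the corresponding inner and
outer ETDRS quadrant volumes (the central subfield is excluded).  Positive
vertical CSDI means the choroid is tilted superiorly; positive horizontal
CSDI, temporally; zero means symmetry about the fovea.  Being log-ratios,
the indexes are dimensionless, antisymmetric under swapping the opposing
directions, and invariant to a common rescaling of all volumes.

CSDIs are computed from volumes, per the definition — never from mean
thicknesses.  For opposing sectors of equal area the two would coincide,
but volumes are the defined quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .volumetrics import SubfieldSummary

#: Directional volumes as sums of inner+outer quadrant subfields.
DIRECTION_SUBFIELDS = {
    "superior": ("SI", "SO"),
    "inferior": ("II", "IO"),
    "temporal": ("TI", "TO"),
    "nasal": ("NI", "NO"),
}

#: Display rounding for human-readable output (matches the conventional
#: 3-decimal presentation, e.g. ln(1/2) → −0.693).
DISPLAY_DECIMALS = 3


@dataclass(frozen=True)
class CSDIResult:
    """Vertical and horizontal CSDIs plus the four directional volumes."""

    vertical_csdi: float
    horizontal_csdi: float
    superior_volume_mm3: float
    inferior_volume_mm3: float
    temporal_volume_mm3: float
    nasal_volume_mm3: float
    subject_id: str = "anon"

    def rounded(self, decimals: int = DISPLAY_DECIMALS) -> tuple[float, float]:
        """(vertical, horizontal) rounded for display."""
        return (round(self.vertical_csdi, decimals), round(self.horizontal_csdi, decimals))


def directional_volumes(summary: SubfieldSummary) -> dict[str, float]:
    """Superior/inferior/temporal/nasal volumes from a nine-subfield summary."""
    out = {}
    for direction, subfields in DIRECTION_SUBFIELDS.items():
        for s in subfields:
            if s not in summary.volume_mm3:
                raise ValueError(f"summary is missing subfield {s}")
        out[direction] = sum(summary.volume_mm3[s] for s in subfields)
    return out


def csdi_from_volumes(
    superior: float,
    inferior: float,
    temporal: float,
    nasal: float,
    subject_id: str = "anon",
) -> CSDIResult:
    """CSDIs from four directional volumes (any common positive unit).

    Raises
    ------
    ValueError
        If any directional volume is ≤ 0 (the log-ratio is undefined).
    """
    vols = {
        "superior": superior,
        "inferior": inferior,
        "temporal": temporal,
        "nasal": nasal,
    }
    bad = [d for d, v in vols.items() if not v > 0]
    if bad:
        raise ValueError(
            "directional volume(s) must be positive for the log-ratio: "
            + ", ".join(f"{d}={vols[d]!r}" for d in bad)
        )
    return CSDIResult(
        vertical_csdi=math.log(superior / inferior),
        horizontal_csdi=math.log(temporal / nasal),
        superior_volume_mm3=superior,
        inferior_volume_mm3=inferior,
        temporal_volume_mm3=temporal,
        nasal_volume_mm3=nasal,
        subject_id=subject_id,
    )


def compute_csdi(summary: SubfieldSummary) -> CSDIResult:
    """Vertical and horizontal CSDIs for one eye's subfield summary."""
    v = directional_volumes(summary)
    return csdi_from_volumes(
        v["superior"], v["inferior"], v["temporal"], v["nasal"],
        subject_id=summary.subject_id,
    )
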