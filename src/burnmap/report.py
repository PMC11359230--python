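"""Quantitative reporting: burned hectares, discrepancy vs a reference
delimitation, and severity-class percentages.

The discrepancy convention matches emergency-service practice: the signed
difference is reference − estimated, and the percent is relative to the
reference delimitation area. Severity percentages are surface-weighted
(consistent with the slope-corrected area pipeline); on flat terrain they
reduce to pixel shares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io_geodata import GridGeometry, InputError, VectorMask, rasterize_mask
from .mapping import SEVERITY_LABELS, SeverityMap
from .terrain import SlopeWeights, weighted_area

__all__ = [
    "AreaReport",
    "area_discrepancy",
    "severity_percentages",
    "reference_area_from_mask",
]


def area_discrepancy(estimated_ha: float, reference_ha: float) -> tuple[float, float]:
    """Signed difference (reference − estimated, ha) and percent of reference.

    Both are rounded to 2 decimals for reporting, e.g. an estimate of
    4766.90 ha against a 6076.21 ha delimitation gives (1309.31, 21.55).
    """
    if reference_ha <= 0:
        raise InputError("reference area must be positive")
    diff = reference_ha - estimated_ha
    pct = 100.0 * diff / reference_ha
    return round(diff, 2), round(pct, 2)


def severity_percentages(
    sev: SeverityMap, weights: SlopeWeights | None = None
) -> np.ndarray:
    """Surface share of each severity class as percentages of the burned surface.

    Returns the unrounded 4-vector (sums to 100); display rounding is the
    caller's concern.
    """
    burned = sev.values >= 0
    if not burned.any():
        raise InputError("severity map is empty")
    if weights is not None:
        if weights.grid.shape != sev.grid.shape:
            raise InputError("weights are on a different grid than the severity map")
        w = weights.weight
    else:
        w = np.ones(sev.grid.shape)
    surfaces = np.array(
        [float(w[sev.values == c].sum()) for c in range(4)], dtype=np.float64
    )
    return 100.0 * surfaces / surfaces.sum()


def reference_area_from_mask(
    mask: VectorMask, grid: GridGeometry, weights: SlopeWeights | None = None
) -> float:
    """Hectares of a reference delimitation polygon, rasterized onto the grid.

    Uses the same center-containment rasterization and slope weighting as
    the estimated burned area, so estimate and reference are comparable.
    """
    plane = rasterize_mask(mask, grid)
    if not plane.any():
        raise InputError("reference polygon does not intersect the grid")
    return weighted_area(plane, grid, weights)


@dataclass
class AreaReport:
    """Machine- and human-readable summary of a mapping run."""

    estimated_burned_ha: float
    reference_ha: float | None = None
    difference_ha: float | None = None
    difference_pct: float | None = None
    severity_pct: list[float] | None = None
    flags: list[str] = field(default_factory=list)

    @classmethod
    def build(
        cls,
        estimated_burned_ha: float,
        reference_ha: float | None = None,
        severity_pct: np.ndarray | None = None,
        flags: list[str] | None = None,
    ) -> "AreaReport":
        diff = pct = None
        if reference_ha is not None:
            diff, pct = area_discrepancy(estimated_burned_ha, reference_ha)
        return cls(
            estimated_burned_ha=round(float(estimated_burned_ha), 2),
            reference_ha=None if reference_ha is None else round(float(reference_ha), 2),
            difference_ha=diff,
            difference_pct=pct,
            severity_pct=None if severity_pct is None else [float(p) for p in severity_pct],
            flags=list(flags or []),
        )

    def to_dict(self) -> dict:
        return {
            "estimated_burned_ha": self.estimated_burned_ha,
            "reference_ha": self.reference_ha,
            "difference_ha": self.difference_ha,
            "difference_pct": self.difference_pct,
            "severity_pct": self.severity_pct,
            "severity_labels": list(SEVERITY_LABELS),
            "flags": self.flags,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AreaReport":
        d = json.loads(text)
        return cls(
            estimated_burned_ha=d["estimated_burned_ha"],
            reference_ha=d.get("reference_ha"),
            difference_ha=d.get("difference_ha"),
            difference_pct=d.get("difference_pct"),
            severity_pct=d.get("severity_pct"),
            flags=list(d.get("flags", [])),
        )

    def to_text(self) -> str:
        lines = ["Burned-area report", "==================",
                 f"Estimated burned area : {self.estimated_burned_ha:.2f} ha"]
        if self.reference_ha is not None:
            lines.append(f"Reference delimitation: {self.reference_ha:.2f} ha")
            lines.append(
                f"Difference            : {self.difference_ha:.2f} ha ({self.difference_pct:.2f}%)"
            )
        if self.severity_pct is not None:
            lines.append("Severity shares of burned surface:")
            for label, p in zip(SEVERITY_LABELS, self.severity_pct):
                lines.append(f"  {label:<28s} {round(p):d}%")
        if self.flags:
            lines.append("Flags: " + ", ".join(self.flags))
        return "\n".join(lines)
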