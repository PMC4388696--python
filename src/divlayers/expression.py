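"""Fluorescence-based fusion-protein expression calibration.

Integrated cellular fluorescence of a fluorescent-protein fusion is
converted to copies per cell through a reference fusion whose expression
fraction is known.  If the reference fusion is present at a fraction
``f_ref`` of the total (wild-type + fusion) protein and the wild-type copy
number is N_ref, the reference fusion copy number is
N_fus,ref = f_ref / (1 - f_ref) * N_ref, and the per-molecule intensity is

    k_int = reference_intensity / N_fus,ref.

Any other fusion's copies are then intensity / k_int, and its expression
fraction of total is copies / (endogenous + copies).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ExpressionCalibration", "fusion_fraction"]


@dataclass(frozen=True)
class ExpressionCalibration:
    """Reference calibration for intensity -> copy-number conversion.

    ``reference_fraction`` is interpreted as fusion / (wild-type + fusion)
    by default; set ``fraction_of_wildtype=True`` if the known fraction is
    relative to the wild-type copy number instead (non-default reading).
    """

    reference_intensity: float
    reference_fraction: float
    reference_endogenous: float
    fraction_of_wildtype: bool = False

    def __post_init__(self):
        if not (0 < self.reference_fraction < 1):
            raise ValueError("reference_fraction must be in (0, 1)")
        if self.reference_endogenous <= 0 or self.reference_intensity <= 0:
            raise ValueError("intensity and copy numbers must be positive")

    @property
    def reference_copies(self) -> float:
        """Copies per cell of the reference fusion implied by its fraction."""
        f = self.reference_fraction
        if self.fraction_of_wildtype:
            return f * self.reference_endogenous
        return f / (1.0 - f) * self.reference_endogenous

    @property
    def per_molecule_intensity(self) -> float:
        """Integrated intensity units per fusion molecule (k_int)."""
        return self.reference_intensity / self.reference_copies


def fusion_fraction(
    intensity: float, calib: ExpressionCalibration, endogenous: float
) -> tuple[float, float]:
    """Copies per cell and expression fraction (percent of total) of a
    fusion with the given integrated cellular intensity.

    fraction = 100 * copies / (endogenous + copies); strictly increasing in
    intensity and strictly decreasing in the endogenous copy number.
    """
    if intensity <= 0 or endogenous <= 0:
        raise ValueError("intensity and endogenous copies must be positive")
    copies = intensity / calib.per_molecule_intensity
    fraction = 100.0 * copies / (endogenous + copies)
    return copies, fraction
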