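"""NPCDCS interpretation of chart risk bands and the treatment rule.

India's NPCDCS programme maps the five WHO/ISH bands onto clinical
categories (low / moderate / high / very high) and initiates treatment
(the T_HR group) for subjects whose risk band is 30% or more, or whose
band is 20-<30% with systolic blood pressure strictly over 140 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .charts import RiskBand


class RiskCategory(str, Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    VERY_HIGH = "very_high"


_CATEGORY_BY_LEVEL = {
    0: RiskCategory.LOW,
    1: RiskCategory.MODERATE,
    2: RiskCategory.HIGH,
    3: RiskCategory.VERY_HIGH,
    4: RiskCategory.VERY_HIGH,
}


def categorize_risk(band: RiskBand) -> RiskCategory:
    """NPCDCS clinical category for a risk band.

    <10% -> low; 10-<20% -> moderate; 20-<30% -> high; >=30% -> very high.
    """
    return _CATEGORY_BY_LEVEL[int(RiskBand(band))]


@dataclass(frozen=True)
class ThrDecision:
    """Treatment-initiation decision with the rule that triggered it."""

    is_thr: bool
    triggering_rule: str  # "band_ge_30" | "band_20_30_and_sbp_gt_140" | "none"

    def __post_init__(self) -> None:
        assert self.is_thr == (self.triggering_rule != "none")


def is_treatment_high_risk(band: RiskBand, sbp: float) -> ThrDecision:
    """NPCDCS treatment-initiation (T_HR) rule.

    Treatment starts if the band is at or above 30%, or if the band is
    20-<30% and SBP exceeds 140 mmHg (strict: exactly 140 does not
    qualify).  Quantized chart output makes "above 30%" the two top
    bands.
    """
    if not sbp > 0:
        raise ValueError(f"sbp must be positive, got {sbp}")
    level = int(RiskBand(band))
    if level >= 3:
        return ThrDecision(True, "band_ge_30")
    if level == 2 and sbp > 140:
        return ThrDecision(True, "band_20_30_and_sbp_gt_140")
    return ThrDecision(False, "none")
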