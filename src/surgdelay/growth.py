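"""Deterministic tumor growth under the volume-doubling-time (VDT) law.

The primary tumor is modelled as a sphere whose volume doubles every VDT
days, so its greatest diameter grows exponentially:

    TD(d) = TD0 * f ** (d / VDT)

where ``f`` is the per-VDT diameter multiplier. One volume doubling
multiplies the diameter by 2**(1/3) ~ 1.2599; the conventional rounded
value 1.26 is the default (the difference is < 0.03% per VDT). Growth is
stratified by hormone-receptor (HR) status: HR+ tumors double their volume
in about 170 days, HR- tumors in about 72 days, a growth-speed ratio of
roughly 2.4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "HR_POS",
    "HR_NEG",
    "GrowthParams",
    "grown_diameter",
    "days_to_diameter",
    "weighted_mean_vdt",
]

HR_POS = "HR+"
HR_NEG = "HR-"

_HR_ALIASES = {
    "HR+": HR_POS,
    "HR-": HR_NEG,
    "HR−": HR_NEG,  # unicode minus
    "HR_POS": HR_POS,
    "HR_NEG": HR_NEG,
}


def normalize_hr(hr: str) -> str:
    """Map an HR-status spelling onto the canonical ``"HR+"`` / ``"HR-"``."""
    try:
        return _HR_ALIASES[str(hr).strip().upper().replace("POSITIVE", "+").replace("NEGATIVE", "-")]
    except KeyError:
        raise ValueError(f"unknown HR status: {hr!r} (expected 'HR+' or 'HR-')") from None


@dataclass(frozen=True)
class GrowthParams:
    """Growth-law parameters.

    Parameters
    ----------
    td0 : float
        Mean tumor diameter at initial diagnosis, mm. The default 19.8 mm
        is the population mean of M0 breast cancers.
    diameter_factor : float
        Diameter multiplier per volume doubling. Default 1.26; set to
        ``2 ** (1/3)`` for exact volume doubling.
    vdt_hr_pos, vdt_hr_neg : float
        Volume doubling times in days for HR+ and HR- tumors.
    """

    td0: float = 19.8
    diameter_factor: float = 1.26
    vdt_hr_pos: float = 170.0
    vdt_hr_neg: float = 72.0

    def __post_init__(self) -> None:
        if not self.td0 > 0:
            raise ValueError("td0 must be positive")
        if not self.diameter_factor > 1:
            raise ValueError("diameter_factor must exceed 1")
        if not (self.vdt_hr_pos > 0 and self.vdt_hr_neg > 0):
            raise ValueError("volume doubling times must be positive")

    def vdt(self, hr: str) -> float:
        """VDT in days for the given HR status."""
        return self.vdt_hr_pos if normalize_hr(hr) == HR_POS else self.vdt_hr_neg

    @property
    def hr_speed_ratio(self) -> float:
        """Growth-speed ratio HR+ / HR- (~2.36 at defaults)."""
        return self.vdt_hr_pos / self.vdt_hr_neg


def grown_diameter(
    td0: float,
    delay_days: float,
    vdt: float,
    diameter_factor: float = 1.26,
) -> float:
    """Tumor diameter after ``delay_days`` of exponential growth.

    Evaluates ``td0 * diameter_factor ** (delay_days / vdt)`` (mm).
    """
    if not td0 > 0:
        raise ValueError("td0 must be positive")
    if not vdt > 0:
        raise ValueError("vdt must be positive")
    if delay_days < 0:
        raise ValueError("delay_days must be non-negative")
    return td0 * diameter_factor ** (delay_days / vdt)


def days_to_diameter(
    td0: float,
    td_target: float,
    vdt: float,
    diameter_factor: float = 1.26,
) -> float:
    """Days of growth needed to reach ``td_target`` from ``td0``.

    Inverse of :func:`grown_diameter`: returns
    ``vdt * log(td_target / td0) / log(diameter_factor)``.
    """
    if not td0 > 0:
        raise ValueError("td0 must be positive")
    if not vdt > 0:
        raise ValueError("vdt must be positive")
    if td_target < td0:
        raise ValueError("td_target must be >= td0")
    return vdt * math.log(td_target / td0) / math.log(diameter_factor)


def weighted_mean_vdt(weights: Sequence[float], vdts: Sequence[float]) -> float:
    """Population-weighted mean VDT, e.g. across HR strata.

    ``weights`` must be non-negative and sum to 1 (within 1e-6). At the
    default HR mix (0.85, 0.15) and VDTs (170, 72) this is 155.3 days; a
    rounded value near 150 days is sometimes quoted in the literature but
    is not used by any cohort computation here.
    """
    if len(weights) != len(vdts):
        raise ValueError("weights and vdts must have the same length")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    total = math.fsum(weights)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"weights must sum to 1, got {total}")
    return math.fsum(w * v for w, v in zip(weights, vdts))
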