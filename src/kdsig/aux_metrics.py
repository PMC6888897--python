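"""Small defined calculations: EMT marker-ratio calls, IHC H-score, qPCR
fold change by the delta-delta-Ct method, and scratch-assay relative wound
density.

These are exact arithmetic transformations of already-quantified inputs; no
image analysis is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .exceptions import ParameterError, ValidationError

INTENSITY_LEVELS = (0, 1, 2, 3)
INTENSITY_NAMES = {0: "negative", 1: "faint", 2: "moderate", 3: "intense"}


@dataclass
class EMTCall:
    """A VIM/CDH1 ratio and its phenotype label."""

    ratio: float
    label: str  # epithelial | intermediate | mesenchymal


def h_score(percent_by_intensity: Mapping[int, float]) -> float:
    """IHC H-score: H = sum over intensities i of P_i * (i + 1).

    ``percent_by_intensity`` maps staining intensity (0 = negative to
    3 = intense) to the percentage of tumor cells at that intensity; the
    percentages must sum to 100 (+-0.01). With the (i + 1) weighting the
    score ranges from 100 (all negative) to 400 (all intense).
    """
    unknown = set(percent_by_intensity) - set(INTENSITY_LEVELS)
    if unknown:
        raise ValidationError(f"unknown intensity levels: {sorted(unknown)}")
    pcts = {i: float(percent_by_intensity.get(i, 0.0)) for i in INTENSITY_LEVELS}
    if any(p < 0 for p in pcts.values()):
        raise ValidationError("percentages must be >= 0")
    total = sum(pcts.values())
    if abs(total - 100.0) > 0.01:
        raise ValidationError(f"percentages sum to {total}, expected 100")
    return sum(p * (i + 1) for i, p in pcts.items())


def classify_emt(
    vim: float,
    cdh1: float,
    threshold: float = 2.0,
    intermediate_band: tuple[float, float] | None = None,
) -> EMTCall:
    """Classify a sample from its linear-scale VIM/CDH1 expression ratio.

    ratio < threshold is epithelial, ratio > threshold mesenchymal; a ratio
    exactly at the threshold is intermediate. When ``intermediate_band =
    (lo, hi)`` is supplied, any ratio in [lo, hi] is called intermediate
    instead, making the three-class split explicit.
    """
    if cdh1 <= 0:
        raise ValidationError("CDH1 expression must be > 0 (ratio undefined)")
    if vim <= 0:
        raise ValidationError("VIM expression must be > 0 on the linear scale")
    ratio = vim / cdh1
    if intermediate_band is not None:
        lo, hi = intermediate_band
        if not lo <= hi:
            raise ParameterError("intermediate_band must satisfy lo <= hi")
        if lo <= ratio <= hi:
            return EMTCall(ratio=ratio, label="intermediate")
    if ratio < threshold:
        label = "epithelial"
    elif ratio > threshold:
        label = "mesenchymal"
    else:
        label = "intermediate"
    return EMTCall(ratio=ratio, label=label)


def delta_delta_ct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative qPCR fold change: 2 ** -((dCt_case) - (dCt_ctrl)).

    dCt is the target Ct minus the reference-gene Ct within each condition;
    a lower Ct means more template, hence the negative exponent.
    """
    for name, ct in (
        ("ct_target_case", ct_target_case),
        ("ct_ref_case", ct_ref_case),
        ("ct_target_ctrl", ct_target_ctrl),
        ("ct_ref_ctrl", ct_ref_ctrl),
    ):
        if not math.isfinite(ct):
            raise ValidationError(f"{name} is not finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0**-ddct


def relative_wound_density(w0: float, wt: float, ct: float) -> float:
    """Scratch-assay migration metric, as a percentage in [0, 100].

    ``w0`` is the initial cell density inside the wound, ``wt`` the density
    inside the wound at the measured time point, and ``ct`` the density
    outside the wound at that time (the proliferation reference). RWD =
    100 * (wt - w0) / (ct - w0), clipped to [0, 100]; the normalization is
    undefined unless the outside region is denser than the initial wound.
    """
    if ct <= w0:
        raise ValidationError(
            f"outside density ({ct}) must exceed initial wound density ({w0})"
        )
    rwd = 100.0 * (wt - w0) / (ct - w0)
    return min(100.0, max(0.0, rwd))
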