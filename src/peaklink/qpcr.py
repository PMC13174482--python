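"""Comparative-Ct (2^-ddCt) quantification for locus validation by qPCR.

Per measurement, dCt = Ct(target) - Ct(reference). The group ddCt is the
mean treated dCt minus the mean control dCt, and the fold change is
2^-ddCt, so the control group sits at fold change 1 by construction and
each cycle of advantage doubles the estimate. Per-replicate fold changes
(each replicate's dCt against the control mean) are also reported for
dispersion display. Amplification-efficiency correction is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["QpcrMeasurement", "DdctResult", "ddct_fold_change"]


@dataclass(frozen=True)
class QpcrMeasurement:
    """Paired target/reference threshold cycles for one well pair."""

    ct_target: float
    ct_reference: float
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        for name, v in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
            if not 5 <= v <= 40:
                warnings.warn(
                    f"{name}={v} outside the typical 5-40 cycle range", stacklevel=3
                )

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class DdctResult:
    delta_ct_treated: tuple[float, ...]
    delta_ct_control: tuple[float, ...]
    ddct: float
    fold_change: float
    per_replicate_fold_changes: tuple[float, ...]  # treated reps vs control mean


def ddct_fold_change(
    treated: Sequence[QpcrMeasurement], control: Sequence[QpcrMeasurement]
) -> DdctResult:
    """Fold change of the treated group relative to control by 2^-ddCt."""
    if not treated or not control:
        raise ValueError("each group needs at least one measurement")
    dct_t = np.array([m.delta_ct for m in treated])
    dct_c = np.array([m.delta_ct for m in control])
    ddct = float(dct_t.mean() - dct_c.mean())
    return DdctResult(
        delta_ct_treated=tuple(dct_t),
        delta_ct_control=tuple(dct_c),
        ddct=ddct,
        fold_change=float(2.0 ** (-ddct)),
        per_replicate_fold_changes=tuple(2.0 ** (-(dct_t - dct_c.mean()))),
    )
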