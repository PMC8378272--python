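"""Effluent biomarker panel and the limit-of-detection retention filter.

Multiplex proximity-extension panels report relative abundances for ~92
markers per sample.  A marker's limit of detection (LOD) is the mean of the
negative-control samples plus 3 standard deviations (sample SD); a marker is
retained for analysis only when strictly more than 65% of the study samples
lie strictly above its LOD.  Both boundaries are strict by a literal reading
of the rule; samples missing for technical reasons are excluded from the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

__all__ = ["BiomarkerPanel", "LodResult", "lod_filter"]


@dataclass
class BiomarkerPanel:
    """Marker x sample abundance matrix plus matched negative controls.

    ``values`` and ``negative_controls`` are DataFrames with markers as the
    row index; ``sample_meta`` (optional) carries drug/dose per sample
    column of ``values``.
    """

    values: pd.DataFrame
    negative_controls: pd.DataFrame
    sample_meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.negative_controls.index):
            raise ValueError(
                "values and negative_controls must share the same marker index"
            )
        n_ctrl = self.negative_controls.notna().sum(axis=1)
        if (n_ctrl < 2).any():
            bad = list(self.negative_controls.index[n_ctrl < 2])
            raise ValueError(
                f"markers with fewer than 2 negative controls (SD undefined): {bad}"
            )

    @property
    def markers(self) -> List[str]:
        return list(self.values.index)


@dataclass
class LodResult:
    retained: List[str]
    detection_fraction: pd.Series  # per marker, fraction of samples above LOD
    lod: pd.Series                 # per marker, mean(neg) + k * SD(neg)


def lod_filter(
    panel: BiomarkerPanel,
    sd_multiplier: float = 3.0,
    min_detect_fraction: float = 0.65,
) -> LodResult:
    """Apply the limit-of-detection retention rule to a biomarker panel.

    ``LOD_m = mean(controls_m) + sd_multiplier * SD(controls_m)`` with the
    sample (ddof=1) standard deviation.  A marker is retained iff the
    fraction of non-missing study samples strictly above ``LOD_m`` is
    strictly greater than ``min_detect_fraction``.
    """
    ctrl = panel.negative_controls
    lod = ctrl.mean(axis=1) + sd_multiplier * ctrl.std(axis=1, ddof=1)
    above = panel.values.gt(lod, axis=0)
    n_valid = panel.values.notna().sum(axis=1)
    if (n_valid == 0).any():
        bad = list(panel.values.index[n_valid == 0])
        raise ValueError(f"markers with no non-missing study samples: {bad}")
    detection = above.sum(axis=1) / n_valid
    retained = list(detection.index[detection > min_detect_fraction])
    return LodResult(
        retained=retained,
        detection_fraction=detection.rename("detection_fraction"),
        lod=lod.rename("lod"),
    )
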