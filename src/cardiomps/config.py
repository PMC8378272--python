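"""Analysis configuration: every tunable threshold of the pipeline, named.

Defaults mirror the values used throughout the package documentation.  All
thresholds can be overridden from a single YAML file so that a study run is
fully described by (input traces, design, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    # beat segmentation
    min_prominence: float = 0.3       # in units of the nominal (control) beat amplitude
    refractory_ms: float = 200.0
    smooth_samples: int = 3           # boxcar width for crossing/event detection
    # detrending
    detrend_window_s: float = 2.0
    detrend_method_voltage: str = "linear"
    detrend_method_calcium: str = "exponential"
    # pacing capture
    capture_tol: float = 0.05
    # afterdepolarization detectors
    theta_ead: float = 0.05           # min rise, fraction of parent beat amplitude
    theta_dad: float = 0.10           # min prominence, fraction of preceding amplitude
    dad_beat_threshold: float = 0.60  # deflections at/above this fraction are beats
    event_min_width_samples: int = 2
    # tissue classification
    weak_amplitude_ratio: float = 0.60
    shape_irregularity_threshold: float = 0.20
    instability_threshold: float = 0.05
    arrhythmic_min_events: int = 1
    # study rules
    inclusion_apd80_ms: float = 500.0  # strict: baseline APD80 must be < this
    apd_aggregate: str = "median"      # per-recording APD summary over resolved beats
    prefer_paced_metrics: bool = True
    # statistics
    chi2_correction: bool = False
    # biomarker limit-of-detection filter
    lod_sd_multiplier: float = 3.0
    lod_min_detect_fraction: float = 0.65
    # reproducibility
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        """Stable hash of the configuration, echoed in run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
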