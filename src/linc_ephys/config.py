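"""Analysis configuration: every fixed constant of the pipeline in one place.

The defaults encode the analysis conventions used throughout the package:
theta 5-12 Hz, delta 1-3 Hz, theta-state criterion 4.5 (strict), movement
artifact rejection at 2x the mean trial range, a 1 Hz band (+-0.5 Hz) around
the stimulation frequency, 1 s / 0.1 s spectrogram windows, the +-20
encoding-day discrimination-index exclusion, minimum investigation times of
3 s (object tasks) and 2 s (odor task), and the +-10 pA postsynaptic-current
criteria. Taper settings (NW, K) are free choices and are therefore embedded
in every output so results are interpretable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # Multitaper settings
    nw: float = 3.0
    k: int = 5
    pad: int = 0
    # Bands (Hz)
    theta_band: tuple[float, float] = (5.0, 12.0)
    delta_band: tuple[float, float] = (1.0, 3.0)
    # Theta-state selection: theta/delta ratio must strictly exceed this
    theta_criterion: float = 4.5
    # Artifact rejection: trial range > multiplier * mean range is removed
    artifact_multiplier: float = 2.0
    # Half-width of the band around the stimulation frequency (1 Hz band)
    stim_band_halfwidth: float = 0.5
    # Moving-spectrogram geometry (s)
    spectrogram_window: float = 1.0
    spectrogram_step: float = 0.1
    # Trial window lengths around light onset (s)
    pre_window: float = 3.0
    during_window: float = 3.0
    # Behavior: encoding-day DI exclusion bound (strict >) and minimum
    # investigation times per phase (s)
    di_exclusion_bound: float = 20.0
    min_investigation_olm_orm: float = 3.0
    min_investigation_odor: float = 2.0
    # Postsynaptic-current classification
    psc_criterion_pa: float = 10.0
    gabaa_search_ms: tuple[float, float] = (0.0, 50.0)
    gabab_search_ms: tuple[float, float] = (50.0, 400.0)
    psc_baseline_ms: float = 50.0
    # Spike detection
    spike_dvdt_threshold: float = 20.0   # mV/ms
    spike_peak_criterion: float = -10.0  # mV
    spike_refractory_ms: float = 1.0
    # Seeds
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    def hash(self) -> str:
        """Short stable hash of the effective configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_TUPLE_FIELDS = {
    "theta_band", "delta_band", "gabaa_search_ms", "gabab_search_ms",
}


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a JSON or YAML file.

    Absent keys take the package defaults; unknown keys raise (no silent
    typos). An empty file yields the full default configuration.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        if text.strip():
            loaded = yaml.safe_load(text)  # YAML is a superset of JSON
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must contain a mapping")
            data = loaded
    data.update(overrides)
    valid = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown config key(s): {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    for key in _TUPLE_FIELDS & set(data):
        data[key] = tuple(data[key])
    return AnalysisConfig(**data)
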