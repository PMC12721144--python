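"""Pipeline configuration.

Every threshold of the extraction pipeline is exposed here; the defaults
are the values used throughout the study design (1.5 mbar cycle
threshold, 1.2 s burst gap, 0.5-20 Hz band, 100 Hz working rate).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class ExtractConfig:
    """Signal-conditioning and segmentation parameters.

    Attributes
    ----------
    cycle_threshold_mbar : float
        Minimum conditioned peak pressure for a suck cycle (mbar).
    burst_gap_s : float
        Consecutive cycles closer than this belong to the same burst (s);
        the boundary is strict (a gap of exactly `burst_gap_s` splits).
    min_cycles_per_burst : int
        Minimum run length for a run of cycles to count as a burst.
    min_peak_separation_s : float
        Peaks closer than this are deduplicated, keeping the larger.
    band_low_hz, band_high_hz : float
        Zero-phase Butterworth band-pass edges.
    target_rate_hz : float
        Working rate after anti-aliased decimation.
    smooth_window_s : float
        Zero-phase moving-average window.
    resting_decile : float
        Fraction of lowest samples whose median estimates resting pressure.
    include_isolated_cycles : bool
        Whether isolated (non-burst) cycles count toward cycles/trial.
    cycle_interval_all_gaps : bool
        If True, cycle_interval averages every consecutive-cycle gap in the
        trial (including between-burst gaps); if False, within-burst only.
    wav_calibration_mbar : float
        mbar per unit full-scale for WAV input.
    """

    cycle_threshold_mbar: float = 1.5
    burst_gap_s: float = 1.2
    min_cycles_per_burst: int = 2
    min_peak_separation_s: float = 0.2
    band_low_hz: float = 0.5
    band_high_hz: float = 20.0
    target_rate_hz: float = 100.0
    smooth_window_s: float = 0.05
    resting_decile: float = 0.1
    include_isolated_cycles: bool = True
    cycle_interval_all_gaps: bool = True
    wav_calibration_mbar: float = 1.0


@dataclass
class StatsConfig:
    """Statistical-stage options."""

    alpha: float = 0.05
    pairwise_adjustment: str = "tukey"  # over the 6 condition pairs
    fdr_method: str = "fdr_bh"
    #: epsilon for the log transform before PCA, as a fraction of each
    #: variable's median.
    pca_log_eps_fraction: float = 1e-3
    pca_n_components: int = 2


@dataclass
class RunConfig:
    """Top-level configuration chaining all stages."""

    extract: ExtractConfig = field(default_factory=ExtractConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    sim_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        extract = ExtractConfig(**raw.get("extract", {}))
        stats = StatsConfig(**raw.get("stats", {}))
        return cls(
            extract=extract,
            stats=stats,
            seed=int(raw.get("seed", 0)),
            sim_params=dict(raw.get("sim_params", {})),
        )

    def to_dict(self) -> dict:
        return {
            "extract": dataclasses.asdict(self.extract),
            "stats": dataclasses.asdict(self.stats),
            "seed": self.seed,
            "sim_params": self.sim_params,
        }

    def to_yaml(self, path: Optional[str] = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
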