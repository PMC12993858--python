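"""Configuration objects for the simulation and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigurationError

#: the four joint oil-and-gas development groups, in canonical order
OGD_GROUPS = ("none", "cogd_only", "uogd_only", "both")

#: the five analyzed functional feeding groups, in canonical order
FFGS = ("collector-gatherer", "filter-collector", "predator", "scraper", "shredder")

#: FFG labels excluded from functional metrics
EXCLUDED_FFGS = ("unknown", "piercer")

ORDERS = ("Ephemeroptera", "Plecoptera", "Trichoptera", "other")

#: default linear calibration (floor, ceiling) for the surrogate composite
#: condition index; each component is rescaled to [0, 100] between these.
DEFAULT_IBI_CALIBRATION = {
    "richness": (0.0, 40.0),
    "ept_richness": (0.0, 15.0),
    "shannon": (0.0, 3.2),
    "tolerance_complement": (0.0, 10.0),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic data generator.

    ``samples_per_stratum`` maps ``(huc8, ogd_group)`` to a sample count;
    when ``None`` a default of ``default_stratum_size`` samples for every
    (huc8, group) combination over ``n_huc8`` watersheds is used.

    ``effect_sizes`` are planted per-unit-stress log-abundance slopes for
    the three stressors; they act with sign graded by pollution tolerance
    (negative slope: sensitive taxa decline, tolerant taxa increase).
    """

    n_huc8: int = 3
    samples_per_stratum: Mapping[tuple[str, str], int] | None = None
    default_stratum_size: int = 20
    n_taxa: int = 60
    target_total: int = 200
    tolerance_halfwidth: int = 20
    effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {"cogd": 0.0, "uogd": 0.0, "dlc": 0.0}
    )
    n_blocks: int = 4
    block_strength: float = 0.0
    seed: int = 0
    # covariate mix; defaults generate a fully network-eligible dataset
    p_fall: float = 0.0
    p_semiwadeable: float = 0.0
    p_amd: float = 0.0
    dlc_max: float = 0.15
    n_ecoregions: int = 4

    def __post_init__(self):
        for name in ("n_huc8", "n_taxa", "target_total", "tolerance_halfwidth",
                     "n_blocks", "n_ecoregions", "default_stratum_size"):
            value = getattr(self, name)
            if not isinstance(value, int) or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if self.tolerance_halfwidth >= self.target_total:
            raise ConfigurationError("tolerance_halfwidth must be < target_total")
        if not all(k in self.effect_sizes for k in ("cogd", "uogd", "dlc")):
            raise ConfigurationError("effect_sizes must define cogd, uogd and dlc")
        import math

        if not math.isfinite(self.block_strength) or self.block_strength < 0:
            raise ConfigurationError("block_strength must be finite and >= 0")
        for p in ("p_fall", "p_semiwadeable", "p_amd"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ConfigurationError(f"{p} must be in [0, 1]")
        if not 0.0 < self.dlc_max <= 1.0:
            raise ConfigurationError("dlc_max must be in (0, 1]")
        if self.samples_per_stratum is not None:
            if len(self.samples_per_stratum) == 0:
                raise ConfigurationError("samples_per_stratum must be non-empty")
            for (huc8, group), n in self.samples_per_stratum.items():
                if group not in OGD_GROUPS:
                    raise ConfigurationError(f"unknown ogd_group {group!r}")
                if n <= 0:
                    raise ConfigurationError(f"stratum ({huc8}, {group}) size must be positive")

    def stratum_map(self) -> dict[tuple[str, str], int]:
        """Resolved (huc8, ogd_group) -> sample count map."""
        if self.samples_per_stratum is not None:
            return dict(self.samples_per_stratum)
        hucs = [f"HUC{i + 1:08d}" for i in range(self.n_huc8)]
        return {(h, g): self.default_stratum_size for h in hucs for g in OGD_GROUPS}


@dataclass
class PipelineConfig:
    """Full-pipeline settings: simulation block, ensemble knobs, calibration."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    reps: int = 100
    k: int = 10
    min_n: int = 15
    dlc_filter_max: float = 0.20
    q_threshold: float = 1e-4
    n_perm: int = 100
    seed: int = 0
    ibi_calibration: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_IBI_CALIBRATION)
    )

    def __post_init__(self):
        for name in ("reps", "k", "min_n", "n_perm"):
            value = getattr(self, name)
            if not isinstance(value, int) or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if not 0.0 < self.q_threshold < 1.0:
            raise ConfigurationError("q_threshold must be in (0, 1)")
        if not 0.0 <= self.dlc_filter_max <= 1.0:
            raise ConfigurationError("dlc_filter_max must be in [0, 1]")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        sim_raw = dict(raw.pop("simulation", {}))
        if "samples_per_stratum" in sim_raw and sim_raw["samples_per_stratum"] is not None:
            # YAML maps keys as "huc8:group" strings; normalize to tuples
            spm = {}
            for key, n in dict(sim_raw["samples_per_stratum"]).items():
                if isinstance(key, str):
                    huc8, _, group = key.rpartition(":")
                    key = (huc8, group)
                spm[tuple(key)] = int(n)
            sim_raw["samples_per_stratum"] = spm
        if "ibi_calibration" in raw and raw["ibi_calibration"] is not None:
            raw["ibi_calibration"] = {
                k: (float(v[0]), float(v[1])) for k, v in dict(raw["ibi_calibration"]).items()
            }
        return cls(simulation=SimulationConfig(**sim_raw), **raw)
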