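"""Configuration schema for fiber simulations and analysis runs.

Every stochastic parameter of the synthetic-data generator lives here, so a
single :class:`SimulationConfig` (plus its seed) fully determines a run.
Configs can be built in code or loaded from YAML; unknown keys are rejected
so that typos never silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from typing import Any, Mapping

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration values."""


def _check_keys(cls, data: Mapping[str, Any]) -> None:
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"{cls.__name__}: unknown keys {sorted(unknown)}; allowed keys are {sorted(allowed)}"
        )


@dataclass(frozen=True)
class DistributionSpec:
    """A one-dimensional distribution used for fiber and tract lengths (kb).

    Supported kinds:

    - ``constant``: ``value``
    - ``uniform``: ``low``, ``high``
    - ``normal``: ``mean``, ``sd``
    - ``lognormal``: ``mean`` (arithmetic mean), ``sigma_log`` (SD of log)
    - ``exponential``: ``mean``

    ``lo``/``hi`` optionally truncate the support by rejection sampling.
    """

    kind: str = "constant"
    value: float = 1.0
    low: float = 0.0
    high: float = 1.0
    mean: float = 1.0
    sd: float = 1.0
    sigma_log: float = 0.5
    lo: float | None = None
    hi: float | None = None

    _KINDS = ("constant", "uniform", "normal", "lognormal", "exponential")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ConfigError(f"unknown distribution kind {self.kind!r}; choose from {self._KINDS}")
        if self.lo is not None and self.hi is not None and self.lo >= self.hi:
            raise ConfigError("distribution truncation requires lo < hi")

    def _draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, float(self.value))
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, n)
        if self.kind == "normal":
            return rng.normal(self.mean, self.sd, n)
        if self.kind == "exponential":
            return rng.exponential(self.mean, n)
        # lognormal parametrized by its arithmetic mean
        if self.mean <= 0:
            raise ConfigError("lognormal mean must be positive")
        mu = np.log(self.mean) - 0.5 * self.sigma_log**2
        return rng.lognormal(mu, self.sigma_log, n)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values, applying truncation by rejection (max 1000 rounds)."""
        out = self._draw(n, rng)
        if self.lo is None and self.hi is None:
            return out
        lo = -np.inf if self.lo is None else self.lo
        hi = np.inf if self.hi is None else self.hi
        for _ in range(1000):
            bad = (out < lo) | (out > hi)
            if not bad.any():
                return out
            out[bad] = self._draw(int(bad.sum()), rng)
        raise ConfigError("truncated distribution rejection sampling did not converge")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "DistributionSpec":
        _check_keys(cls, data)
        return cls(**data)


@dataclass(frozen=True)
class AccessibilityConfig:
    """Two-zone chromatin-accessibility model for adduct placement.

    A contiguous fraction ``accessible_fraction`` of each fiber reacts with
    the crosslinker at ``rate_ratio`` times the rate of the rest; the
    length-weighted mean rate always equals the configured adduct rate.
    ``rate_ratio = 1`` recovers a homogeneous Poisson process.
    """

    accessible_fraction: float = 0.3
    rate_ratio: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.accessible_fraction <= 1.0:
            raise ConfigError("accessible_fraction must lie in [0, 1]")
        if self.rate_ratio <= 0:
            raise ConfigError("rate_ratio must be positive")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "AccessibilityConfig":
        _check_keys(cls, data)
        return cls(**data)


@dataclass(frozen=True)
class ReplicationConfig:
    """Replication-tract model: IdU tracts laid down during a 1-h pulse.

    Each adduct independently has an adjacent replication event with
    probability ``encounter_fraction``; the event is single-sided (one tract
    abutting the adduct) with probability ``single_sided_prob``, else
    double-sided (tracts flanking both sides). Fibers can additionally carry
    a replication tract unlinked to any adduct (``distant_tract_prob`` per
    fiber), kept at least ``distant_clearance_kb`` away from every adduct.
    """

    encounter_fraction: float = 0.7
    single_sided_prob: float = 0.15
    tract_length_dist: DistributionSpec = field(
        default_factory=lambda: DistributionSpec(kind="lognormal", mean=30.0, sigma_log=0.35, lo=5.0, hi=120.0)
    )
    distant_tract_prob: float = 0.3
    distant_clearance_kb: float = 10.0

    def __post_init__(self) -> None:
        for name in ("encounter_fraction", "single_sided_prob", "distant_tract_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.distant_clearance_kb < 0:
            raise ConfigError("distant_clearance_kb must be non-negative")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ReplicationConfig":
        data = dict(data)
        _check_keys(cls, data)
        if "tract_length_dist" in data and isinstance(data["tract_length_dist"], Mapping):
            data["tract_length_dist"] = DistributionSpec.from_dict(data["tract_length_dist"])
        return cls(**data)


@dataclass(frozen=True)
class RenderConfig:
    """Parameters for rendering fibers as multi-channel fluorescence images.

    Calibration: arc positions map kb -> um -> px through ``kb_per_um``
    (stretching constant of spread fibers, default 2.59 kb/um) and
    ``pixel_um`` (microscope sampling, default 0.16 um/px). Fibers are drawn
    as smooth curvilinear paths, quantum-dot adduct signals as
    diffraction-limited spots (Gaussian PSF of ``psf_sigma_px``), and images
    carry a constant background plus shot noise and Gaussian read noise.
    Setting ``shot_noise=False`` and ``read_noise_sd=0`` gives noise-free
    renders for validation.
    """

    pixel_um: float = 0.16
    kb_per_um: float = 2.59
    psf_sigma_px: float = 1.2
    background_level: float = 100.0
    read_noise_sd: float = 2.0
    photon_gain: float = 1.0
    shot_noise: bool = True
    image_shape: tuple[int, int] = (1024, 2048)
    channel_gains: Mapping[str, float] = field(
        default_factory=lambda: {"cldU": 600.0, "idU": 600.0, "qdot": 12000.0}
    )
    margin_px: int = 24
    row_height_px: int = 16
    min_gap_px: int = 30
    curvature_sd: float = 0.015
    max_heading_rad: float = 0.30

    def __post_init__(self) -> None:
        if self.pixel_um <= 0 or self.kb_per_um <= 0:
            raise ConfigError("pixel_um and kb_per_um must be positive")
        if self.psf_sigma_px < 0:
            raise ConfigError("psf_sigma_px must be non-negative")
        if len(self.image_shape) != 2 or min(self.image_shape) < 2 * self.margin_px:
            raise ConfigError("image_shape must be 2-D and larger than twice the margin")

    @property
    def px_per_kb(self) -> float:
        return 1.0 / (self.kb_per_um * self.pixel_um)

    @property
    def kb_per_px(self) -> float:
        return self.kb_per_um * self.pixel_um

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RenderConfig":
        data = dict(data)
        _check_keys(cls, data)
        if "image_shape" in data:
            data["image_shape"] = tuple(data["image_shape"])
        if "channel_gains" in data:
            data["channel_gains"] = dict(data["channel_gains"])
        return cls(**data)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic fiber-field experiment.

    ``adduct_rate`` is the expected number of Dig-TMP adducts per 10^3 kb of
    fiber; ``icl_fraction`` the probability an adduct is an interstrand
    crosslink rather than a monoadduct (default 10/11, i.e. a 10:1 ratio).
    ``treatment_mode`` selects whole-population photoactivation (``lamp``)
    or laser-localized activation, where only ``roi_fiber_fraction`` of the
    harvested fibers derive from exposed nuclei and carry adducts; the
    per-fiber adduct law itself is identical across modes.
    """

    n_fibers: int = 300
    fiber_length_dist: DistributionSpec = field(
        default_factory=lambda: DistributionSpec(kind="lognormal", mean=210.0, sigma_log=0.45, lo=50.0, hi=500.0)
    )
    adduct_rate: float = 2.69
    icl_fraction: float = 10.0 / 11.0
    accessibility: AccessibilityConfig = field(default_factory=AccessibilityConfig)
    replication: ReplicationConfig = field(default_factory=ReplicationConfig)
    treatment_mode: str = "lamp"
    roi_fiber_fraction: float = 0.7
    experiment_label: str = ""
    render: RenderConfig = field(default_factory=RenderConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 0:
            raise ConfigError("n_fibers must be non-negative")
        if self.adduct_rate < 0:
            raise ConfigError("adduct_rate must be non-negative")
        if not 0.0 <= self.icl_fraction <= 1.0:
            raise ConfigError("icl_fraction must lie in [0, 1]")
        if self.treatment_mode not in ("lamp", "laser"):
            raise ConfigError("treatment_mode must be 'lamp' or 'laser'")
        if not 0.0 <= self.roi_fiber_fraction <= 1.0:
            raise ConfigError("roi_fiber_fraction must lie in [0, 1]")
        if not self.experiment_label:
            object.__setattr__(self, "experiment_label", self.treatment_mode)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationConfig":
        data = dict(data)
        _check_keys(cls, data)
        if "fiber_length_dist" in data and isinstance(data["fiber_length_dist"], Mapping):
            data["fiber_length_dist"] = DistributionSpec.from_dict(data["fiber_length_dist"])
        if "accessibility" in data and isinstance(data["accessibility"], Mapping):
            data["accessibility"] = AccessibilityConfig.from_dict(data["accessibility"])
        if "replication" in data and isinstance(data["replication"], Mapping):
            data["replication"] = ReplicationConfig.from_dict(data["replication"])
        if "render" in data and isinstance(data["render"], Mapping):
            data["render"] = RenderConfig.from_dict(data["render"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} must contain a mapping at top level")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["render"]["image_shape"] = list(self.render.image_shape)
        return d

    def config_hash(self) -> str:
        """Stable hex digest of the full configuration (seed included)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
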