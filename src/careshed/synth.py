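"""Synthetic provider/participant scenarios with known ground truth.

Real geocoded addresses of care recipients cannot be shared, so every
downstream stage is exercised on generated scenarios instead.  Three
participant placement models are provided:

* ``zone_cluster`` — the urban regime: participants scatter as isotropic
  Gaussian clusters around administrative-zone centroids (with a uniform
  background fraction) while providers are spread over the extent.  The
  nearest-provider distance distribution then rises to an interior peak, the
  regime in which a PWD is detectable.
* ``provider_decay`` — the rural regime: participants concentrate near the
  few providers with an exponentially decaying distance profile (a two-scale
  mixture: villages close to providers plus a diffuse hinterland), so binned
  nearest-distance counts decrease monotonically and no PWD exists.
* ``planted`` — estimator calibration: each participant is placed at a
  distance drawn from a closed-form density (gamma or lognormal) from a
  randomly chosen provider at a uniform bearing.  With a single provider the
  nearest distance *is* the sampled distance, so the analytic mode and the
  analytic concave-down -> concave-up curvature-change point of the density
  are exactly the quantities the PWD and TLD estimate.

Randomness: each draw site uses its own named stream derived from
``(seed, component name)``, so adding a new draw site never shifts the
output of existing ones.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .binning import DEFAULT_BIN_WIDTH_M
from .curve import DEFAULT_DEGREE, DEFAULT_TAIL_QUANTILE
from .points import Frame, PointSet, ValidationError, ZoneCentroidMap


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: a generator keyed by (seed, stable hash of name)."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass(frozen=True)
class PlantedDistance:
    """A closed-form nearest-distance density with analytic index truth."""

    family: str = "gamma"  # "gamma" or "lognormal"
    shape: float = 4.0     # gamma shape k / lognormal sigma
    scale_m: float = 150.0  # gamma scale theta / lognormal scale exp(mu), meters

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "lognormal"):
            raise ValidationError(f"unknown planted family {self.family!r}")
        if self.shape <= 0 or self.scale_m <= 0:
            raise ValidationError("planted shape and scale must be positive")

    def _dist(self):
        if self.family == "gamma":
            return stats.gamma(self.shape, scale=self.scale_m)
        return stats.lognorm(self.shape, scale=self.scale_m)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "gamma":
            return rng.gamma(self.shape, self.scale_m, n)
        return rng.lognormal(math.log(self.scale_m), self.shape, n)

    def analytic_mode(self) -> Optional[float]:
        """Distance of the density's peak (the quantity the PWD estimates)."""
        if self.family == "gamma":
            if self.shape <= 1:
                return None  # mode at 0: monotone decreasing, no interior peak
            return (self.shape - 1.0) * self.scale_m
        return self.scale_m * math.exp(-self.shape**2)

    def analytic_curvature_change(self) -> Optional[float]:
        """First - -> + root of the density's second derivative beyond the mode
        (the quantity the TLD estimates)."""
        if self.family == "gamma":
            if self.shape <= 1:
                return None
            a = self.shape - 1.0
            return self.scale_m * (a + math.sqrt(a))
        # lognormal: f'' = f * (g^2 + g') with g = (ln f)'; root via brentq
        mu, s2 = math.log(self.scale_m), self.shape**2

        def h(x: float) -> float:
            g = -(1.0 + (math.log(x) - mu) / s2) / x
            gp = (1.0 + (math.log(x) - mu) / s2) / x**2 - 1.0 / (x**2 * s2)
            return g * g + gp

        mode = self.analytic_mode()
        lo, hi = mode * 1.0000001, mode * 1.0000001
        while h(hi) < 0 and hi < mode * 1e6:
            hi *= 2.0
        return float(optimize.brentq(h, lo, hi))

    def quantile(self, q: float) -> float:
        return float(self._dist().ppf(q))


@dataclass(frozen=True)
class AnalysisConfig:
    """Recommended trend-curve settings bundled with a scenario preset."""

    bin_width_m: float = DEFAULT_BIN_WIDTH_M
    degree: int = DEFAULT_DEGREE
    tail_quantile: Optional[float] = DEFAULT_TAIL_QUANTILE


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic two-population scenario."""

    name: str = "custom"
    extent_m: tuple[float, float] = (15000.0, 15000.0)
    n_participants: int = 1000
    n_providers: int = 30
    participant_model: str = "zone_cluster"  # zone_cluster | provider_decay | planted
    # zone_cluster parameters
    n_zones: int = 100
    zone_layout: str = "grid"  # grid | uniform
    cluster_sd_m: float = 500.0
    background_fraction: float = 0.2
    # provider_decay parameters (two-scale exponential distance decay)
    decay_scales_m: tuple[float, ...] = (500.0, 3000.0)
    decay_weights: tuple[float, ...] = (0.65, 0.35)
    # planted-distance parameters
    planted: Optional[PlantedDistance] = None
    provider_placement: str = "uniform"  # uniform | clustered
    snap_to_centroids: bool = False
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_providers < 1:
            raise ValidationError("participant and provider counts must be positive")
        if self.extent_m[0] <= 0 or self.extent_m[1] <= 0:
            raise ValidationError("extent must be nondegenerate")
        if self.participant_model not in ("zone_cluster", "provider_decay", "planted"):
            raise ValidationError(
                f"unknown participant model {self.participant_model!r}")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValidationError("background_fraction must lie in [0, 1]")
        if self.participant_model == "zone_cluster" and self.n_zones < 1:
            raise ValidationError("zone_cluster model needs n_zones >= 1")
        if self.participant_model == "provider_decay":
            if len(self.decay_scales_m) != len(self.decay_weights):
                raise ValidationError("decay scales and weights must align")
            if not math.isclose(sum(self.decay_weights), 1.0, abs_tol=1e-9):
                raise ValidationError("decay weights must sum to 1")
        if self.participant_model == "planted":
            planted = self.planted or PlantedDistance()
            margin = planted.quantile(0.999)
            if 2 * margin >= min(self.extent_m):
                raise ValidationError(
                    f"planted distances (99.9% quantile {margin:.0f} m) exceed the "
                    f"extent {self.extent_m}")

    def to_dict(self) -> dict:
        d = {
            "name": self.name, "extent_m": list(self.extent_m),
            "n_participants": self.n_participants, "n_providers": self.n_providers,
            "participant_model": self.participant_model,
            "n_zones": self.n_zones, "zone_layout": self.zone_layout,
            "cluster_sd_m": self.cluster_sd_m,
            "background_fraction": self.background_fraction,
            "decay_scales_m": list(self.decay_scales_m),
            "decay_weights": list(self.decay_weights),
            "planted": None if self.planted is None else vars(self.planted).copy(),
            "provider_placement": self.provider_placement,
            "snap_to_centroids": self.snap_to_centroids,
            "analysis": vars(self.analysis).copy(),
        }
        return d


@dataclass(frozen=True)
class ScenarioTruth:
    """Known ground truth carried alongside a generated scenario."""

    pwd_m: Optional[float] = None  # analytic density mode (planted mode only)
    tld_m: Optional[float] = None  # analytic curvature-change point
    monotone_regime: bool = False  # True when counts are decreasing by design

    def to_dict(self) -> dict:
        return {"pwd_m": self.pwd_m, "tld_m": self.tld_m,
                "monotone_regime": self.monotone_regime}


@dataclass(frozen=True)
class Scenario:
    config: ScenarioConfig
    seed: int
    participants: PointSet
    providers: PointSet
    truth: ScenarioTruth
    zones: Optional[ZoneCentroidMap] = None

    def write(self, out_dir: "str | Path") -> None:
        """Write participants.csv, providers.csv and truth.json to a directory."""
        from .io import write_points_csv  # local import avoids a cycle

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_points_csv(self.participants, out / "participants.csv")
        write_points_csv(self.providers, out / "providers.csv")
        payload = {
            "schema_version": 1,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "truth": self.truth.to_dict(),
        }
        (out / "truth.json").write_text(json.dumps(payload, indent=1), encoding="utf-8")


def _ids(prefix: str, n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"{prefix}{i:0{width}d}" for i in range(1, n + 1)], dtype=object)


def _place_providers(cfg: ScenarioConfig, seed: int) -> np.ndarray:
    rng = _rng(seed, "providers")
    w, h = cfg.extent_m
    if cfg.participant_model == "planted":
        planted = cfg.planted or PlantedDistance()
        m = planted.quantile(0.999)
        if cfg.n_providers == 1:
            return np.array([[w / 2.0, h / 2.0]])
        return rng.uniform([m, m], [w - m, h - m], (cfg.n_providers, 2))
    if cfg.provider_placement == "clustered":
        n_hubs = max(1, cfg.n_providers // 5)
        hubs = rng.uniform([0, 0], [w, h], (n_hubs, 2))
        pick = rng.integers(0, n_hubs, cfg.n_providers)
        xy = hubs[pick] + rng.normal(0.0, min(w, h) / 20.0, (cfg.n_providers, 2))
        return np.clip(xy, [0, 0], [w, h])
    return rng.uniform([0, 0], [w, h], (cfg.n_providers, 2))


def _zone_centroids(cfg: ScenarioConfig, seed: int) -> np.ndarray:
    w, h = cfg.extent_m
    if cfg.zone_layout == "uniform":
        return _rng(seed, "zones").uniform([0, 0], [w, h], (cfg.n_zones, 2))
    g = math.ceil(math.sqrt(cfg.n_zones))
    gx, gy = np.meshgrid((np.arange(g) + 0.5) * w / g, (np.arange(g) + 0.5) * h / g)
    return np.stack([gx.ravel(), gy.ravel()], axis=1)[: cfg.n_zones]


def _place_participants(cfg: ScenarioConfig, seed: int,
                        providers: np.ndarray,
                        centroids: Optional[np.ndarray]) -> np.ndarray:
    n = cfg.n_participants
    w, h = cfg.extent_m
    rng = _rng(seed, "participants")
    if cfg.participant_model == "zone_cluster":
        z = rng.integers(0, len(centroids), n)
        xy = centroids[z] + rng.normal(0.0, cfg.cluster_sd_m, (n, 2))
        bg = rng.random(n) < cfg.background_fraction
        xy[bg] = rng.uniform([0, 0], [w, h], (int(bg.sum()), 2))
        return np.clip(xy, [0, 0], [w, h])
    if cfg.participant_model == "provider_decay":
        k = rng.integers(0, len(providers), n)
        comp = rng.choice(len(cfg.decay_scales_m), size=n, p=cfg.decay_weights)
        r = rng.exponential(np.asarray(cfg.decay_scales_m)[comp])
        theta = rng.uniform(0.0, 2.0 * math.pi, n)
        xy = providers[k] + np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
        return np.clip(xy, [0, 0], [w, h])
    # planted: sampled distance from a random provider at a uniform bearing
    planted = cfg.planted or PlantedDistance()
    k = rng.integers(0, len(providers), n)
    r = planted.sample(rng, n)
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    return providers[k] + np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)


def generate_scenario(cfg: ScenarioConfig, seed: int) -> Scenario:
    """Generate a reproducible scenario from a config and a seed."""
    cfg.validate()
    providers_xy = _place_providers(cfg, seed)
    centroids = (_zone_centroids(cfg, seed)
                 if cfg.participant_model == "zone_cluster" else None)
    participants_xy = _place_participants(cfg, seed, providers_xy, centroids)

    zones = None
    zone_ids = None
    if centroids is not None:
        zone_labels = _ids("Z", len(centroids))
        zones = ZoneCentroidMap(
            {str(z): (x, y) for z, (x, y) in zip(zone_labels, centroids)},
            frame=Frame.PLANAR)
        # administrative membership = nearest zone centroid
        d2 = ((participants_xy[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        zone_ids = zone_labels[np.argmin(d2, axis=1)]

    participants = PointSet(ids=_ids("p", cfg.n_participants), xy=participants_xy,
                            frame=Frame.PLANAR, zone_ids=zone_ids)
    providers = PointSet(ids=_ids("s", cfg.n_providers), xy=providers_xy,
                         frame=Frame.PLANAR)
    if cfg.snap_to_centroids:
        if zones is None:
            raise ValidationError("snap_to_centroids requires the zone_cluster model")
        from .points import snap_to_zone_centroid

        participants = snap_to_zone_centroid(participants, zones)

    if cfg.participant_model == "planted":
        planted = cfg.planted or PlantedDistance()
        truth = ScenarioTruth(pwd_m=planted.analytic_mode(),
                              tld_m=planted.analytic_curvature_change())
    else:
        truth = ScenarioTruth(monotone_regime=cfg.participant_model == "provider_decay")
    return Scenario(config=cfg, seed=seed, participants=participants,
                    providers=providers, truth=truth, zones=zones)


#: Named presets.  ``urban-default`` and ``rural-default`` are
#: order-of-magnitude stand-ins for a dense metropolitan service area
#: (~15 x 15 km, many providers) and a sparse county (~20 x 20 km, few
#: providers); ``planted-gamma`` ties the estimators to closed-form truth.
PRESETS: dict[str, ScenarioConfig] = {
    "urban-default": ScenarioConfig(
        name="urban-default", extent_m=(15000.0, 15000.0),
        n_participants=1000, n_providers=30,
        participant_model="zone_cluster", n_zones=100, zone_layout="grid",
        cluster_sd_m=500.0, background_fraction=0.2,
        analysis=AnalysisConfig(degree=4),
    ),
    "rural-default": ScenarioConfig(
        name="rural-default", extent_m=(20000.0, 20000.0),
        n_participants=1000, n_providers=5,
        participant_model="provider_decay",
        decay_scales_m=(500.0, 3000.0), decay_weights=(0.65, 0.35),
        n_zones=0,
        analysis=AnalysisConfig(degree=4),
    ),
    "planted-gamma": ScenarioConfig(
        name="planted-gamma", extent_m=(20000.0, 20000.0),
        n_participants=5000, n_providers=1,
        participant_model="planted",
        planted=PlantedDistance(family="gamma", shape=4.0, scale_m=150.0),
        n_zones=0,
        analysis=AnalysisConfig(degree=6),
    ),
}


def preset(name: str, **overrides) -> ScenarioConfig:
    """Fetch a preset config by name, optionally overriding fields."""
    if name not in PRESETS:
        raise ValidationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return replace(cfg, **overrides) if overrides else cfg


def make_rural_shape(seed: int, **overrides) -> Scenario:
    """A scenario whose binned nearest-distance counts decrease monotonically.

    Participants co-cluster around the few providers with exponentially
    decaying distance (two-scale mixture), so the count curve has no interior
    peak and the PWD is undetected by design.
    """
    return generate_scenario(preset("rural-default", **overrides), seed)


def config_from_json(path: "str | Path") -> ScenarioConfig:
    """Load a ScenarioConfig from a declarative JSON file."""
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    if "planted" in obj and obj["planted"] is not None:
        p = obj["planted"]
        obj["planted"] = PlantedDistance(
            family=p.get("family", "gamma"),
            shape=p.get("shape", 4.0),
            scale_m=p.get("scale_m", 150.0))
    if "analysis" in obj and obj["analysis"] is not None:
        a = obj["analysis"]
        obj["analysis"] = AnalysisConfig(
            bin_width_m=a.get("bin_width_m", DEFAULT_BIN_WIDTH_M),
            degree=a.get("degree", DEFAULT_DEGREE),
            tail_quantile=a.get("tail_quantile", DEFAULT_TAIL_QUANTILE))
    for tup in ("extent_m", "decay_scales_m", "decay_weights"):
        if tup in obj:
            obj[tup] = tuple(obj[tup])
    return ScenarioConfig(**obj)
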