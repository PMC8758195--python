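"""Synthetic egg-image and nest-metadata generator with planted maternal links.

Real clutch photographs of King Rails and Common Moorhens are not publicly
deposited, so every downstream stage is exercised on simulated data with known
ground truth.  The generator emulates the statistical structure that maternal
egg signatures imply: each hen has a fixed set of maculation parameters (spot
density, size distribution, darkness, ground tone, polar concentration, egg
dimensions); eggs of one hen vary only by a small within-clutch coefficient of
variation, while different hens are drawn independently from wide population
ranges.  On top of the per-egg images, the generator lays out nests in two
regions ~10 km apart, assigns first-egg dates inside a breeding season, and
plants three kinds of cross-clutch links used by the inference stage:

* returning breeder - one hen nests in two different years, a short distance
  apart (site fidelity);
* conspecific brood parasitism (CBP) - a hen lays 1-2 eggs in a synchronous
  neighbour's clutch in addition to her own;
* renesting attempt - a hen whose first nest failed lays a replacement clutch
  in the same season after a gap.

All randomness flows from a single seed; identical configurations reproduce
byte-identical datasets.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .imageprep import EggImage
from .infer import NestRecord

__all__ = [
    "HenSignature",
    "PopulationParams",
    "ScenarioConfig",
    "GroundTruth",
    "EggRecord",
    "SyntheticDataset",
    "ConfigurationError",
    "sample_hen_signature",
    "render_egg",
    "generate_population",
    "write_dataset",
]

#: reference egg used to convert spots-per-egg into spots per cm^2
REFERENCE_EGG_AREA_CM2 = float(np.pi * (41.0 / 20.0) * (30.0 / 20.0))


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class HenSignature:
    """Hen-specific maculation and egg-shape parameters.

    ``within_clutch_cv`` is the relative noise applied to every parameter
    between eggs of the same hen; the low default encodes the premise of low
    within-clutch / high among-clutch variance.
    """

    hen_id: str
    spot_density: float  # spots per cm^2 of egg surface (projected)
    spot_radius_mean: float  # mm
    spot_radius_cv: float
    polar_bias: float  # in [0, 1]; fraction of pigment pulled toward large pole
    ground_tone: float  # background shell gray level, 0-255
    spot_contrast: float  # how far below ground_tone spot centres sit
    length_mm: float
    width_mm: float
    within_clutch_cv: float = 0.02

    def __post_init__(self) -> None:
        if self.spot_density < 0:
            raise ConfigurationError("spot_density must be >= 0")
        if not 0.0 <= self.polar_bias <= 1.0:
            raise ConfigurationError("polar_bias must be in [0, 1]")
        if self.within_clutch_cv < 0:
            raise ConfigurationError("within_clutch_cv must be >= 0")


@dataclass(frozen=True)
class PopulationParams:
    """Population-level ranges from which hens are drawn independently.

    Defaults describe a strongly signatured population: wide among-hen ranges
    on every trait.  Spot count and radius are sampled log-uniformly and the
    implied pigment coverage is capped so that eggs stay recognisably
    maculated rather than solid dark.
    """

    spots_per_egg_range: tuple[float, float] = (30.0, 300.0)
    spot_radius_range_mm: tuple[float, float] = (0.4, 1.8)
    spot_radius_cv_range: tuple[float, float] = (0.2, 0.7)
    polar_bias_range: tuple[float, float] = (0.0, 1.0)
    ground_tone_range: tuple[float, float] = (140.0, 235.0)
    spot_contrast_range: tuple[float, float] = (50.0, 150.0)
    length_mm_mean: float = 41.0
    length_mm_sd: float = 2.5
    width_mm_mean: float = 30.0
    width_mm_sd: float = 1.5
    max_coverage: float = 0.40
    within_clutch_cv: float = 0.02

    def validate(self) -> None:
        for name in ("spots_per_egg_range", "spot_radius_range_mm",
                     "spot_radius_cv_range", "polar_bias_range",
                     "ground_tone_range", "spot_contrast_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ConfigurationError(f"invalid range for {name}: ({lo}, {hi})")
        if not 0 < self.max_coverage <= 1:
            raise ConfigurationError("max_coverage must be in (0, 1]")
        if self.within_clutch_cv < 0:
            raise ConfigurationError("within_clutch_cv must be >= 0")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return float(lo)
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_hen_signature(
    pop: PopulationParams, rng: np.random.Generator, hen_id: str = "hen"
) -> HenSignature:
    """Draw one hen independently from the population ranges.

    Deterministic for a fixed generator state.  The expected pigment coverage
    ``n * pi * r^2 * (1 + cv^2) / area`` is capped at ``pop.max_coverage`` by
    shrinking the spot radius, so densely blotched hens never saturate.
    """
    pop.validate()
    n_spots = _log_uniform(rng, *pop.spots_per_egg_range)
    radius = _log_uniform(rng, *pop.spot_radius_range_mm)
    radius_cv = float(rng.uniform(*pop.spot_radius_cv_range))
    coverage = (
        n_spots * np.pi * radius**2 * (1 + radius_cv**2) / (REFERENCE_EGG_AREA_CM2 * 100.0)
    )
    if coverage > pop.max_coverage:
        radius *= float(np.sqrt(pop.max_coverage / coverage))
    return HenSignature(
        hen_id=hen_id,
        spot_density=n_spots / REFERENCE_EGG_AREA_CM2,
        spot_radius_mean=radius,
        spot_radius_cv=radius_cv,
        polar_bias=float(rng.uniform(*pop.polar_bias_range)),
        ground_tone=float(rng.uniform(*pop.ground_tone_range)),
        spot_contrast=float(rng.uniform(*pop.spot_contrast_range)),
        length_mm=float(rng.normal(pop.length_mm_mean, pop.length_mm_sd)),
        width_mm=float(rng.normal(pop.width_mm_mean, pop.width_mm_sd)),
        within_clutch_cv=pop.within_clutch_cv,
    )


BACKGROUND_TONE = 45.0  # dark field board behind the eggs
EDGE_BLUR_SIGMA = 1.0  # px; keypoint detectors need non-binary gradients
SPOT_TONE_CV = 0.05  # residual spot-to-spot darkness jitter within one egg


def render_egg(
    sig: HenSignature,
    length_mm: float,
    width_mm: float,
    mm_per_px: float,
    rng: np.random.Generator,
    margin_px: int = 20,
) -> EggImage:
    """Render a single egg as an 8-bit grayscale image.

    The egg is an ellipse with its long axis vertical and the large pole at
    the top of the image (the downstream region-of-interest convention).
    Spots are a Poisson point process with log-normal radii; the placement
    intensity rises linearly toward the large pole in proportion to
    ``sig.polar_bias``.  Spots are filled dark discs blurred with a small
    Gaussian.
    """
    if length_mm <= 0 or width_mm <= 0 or mm_per_px <= 0:
        raise ConfigurationError("egg dimensions and scale must be positive")
    if sig.spot_radius_mean >= min(length_mm, width_mm) / 2:
        raise ConfigurationError(
            f"egg ({length_mm:.1f} x {width_mm:.1f} mm) smaller than one spot "
            f"radius ({sig.spot_radius_mean:.1f} mm)"
        )
    h = int(round(length_mm / mm_per_px)) + 2 * margin_px
    w = int(round(width_mm / mm_per_px)) + 2 * margin_px
    a = length_mm / 2.0 / mm_per_px
    b = width_mm / 2.0 / mm_per_px
    cy, cx = h / 2.0, w / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    img = np.full((h, w), BACKGROUND_TONE, dtype=float)
    img[mask] = sig.ground_tone

    area_cm2 = np.pi * (length_mm / 20.0) * (width_mm / 20.0)
    n_spots = int(rng.poisson(sig.spot_density * area_cm2))
    sigma_ln = float(np.sqrt(np.log(1.0 + sig.spot_radius_cv**2)))
    mu_ln = float(np.log(max(sig.spot_radius_mean, 1e-6)) - sigma_ln**2 / 2.0)
    for _ in range(n_spots):
        # rejection-sample a centre inside the ellipse with polar weighting
        y = x = None
        for _attempt in range(200):
            yc = rng.uniform(cy - a, cy + a)
            xc = rng.uniform(cx - b, cx + b)
            if ((yc - cy) / a) ** 2 + ((xc - cx) / b) ** 2 > 1.0:
                continue
            t = (yc - (cy - a)) / (2.0 * a)  # 0 at large pole, 1 at small pole
            weight = (1.0 - sig.polar_bias) + sig.polar_bias * 2.0 * (1.0 - t)
            if rng.uniform(0.0, 2.0) < weight:
                y, x = yc, xc
                break
        if y is None:
            continue
        radius_px = rng.lognormal(mu_ln, sigma_ln) / mm_per_px
        tone = sig.ground_tone - sig.spot_contrast * (
            1.0 + SPOT_TONE_CV * rng.standard_normal()
        )
        spot = (yy - y) ** 2 + (xx - x) ** 2 <= radius_px**2
        img[spot & mask] = np.clip(tone, 5.0, 250.0)

    img = ndimage.gaussian_filter(img, EDGE_BLUR_SIGMA)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return EggImage(pixels=pixels, mm_per_px=mm_per_px)


# ---------------------------------------------------------------------------
# population-level scenario
# ---------------------------------------------------------------------------

LINK_RETURNING_BREEDER = "returning_breeder"
LINK_CBP = "CBP"
LINK_RENEST = "renest"


@dataclass(frozen=True)
class ScenarioConfig:
    """Layout of a simulated study: hens, clutches, nests, dates, planted links."""

    n_hens: int = 12
    clutches_per_hen: int = 1
    clutch_size_range: tuple[int, int] = (7, 9)
    n_planted_returns: int = 1
    n_planted_cbp: int = 1
    n_planted_renests: int = 1
    region_labels: tuple[str, ...] = ("North", "South")
    years: tuple[int, ...] = (2019, 2020)
    season_start: str = "04-01"  # month-day within each year
    season_end: str = "07-15"
    mm_per_px: float = 0.2
    rb_max_distance_m: float = 100.0
    cbp_distance_range_m: tuple[float, float] = (200.0, 800.0)
    cbp_synchrony_max_days: int = 7
    renest_gap_range_days: tuple[int, int] = (45, 60)
    renest_distance_range_m: tuple[float, float] = (300.0, 2000.0)
    region_extent_m: float = 3000.0
    region_separation_m: float = 10000.0
    population: PopulationParams = field(default_factory=PopulationParams)
    rng_seed: int = 0

    def validate(self) -> None:
        lo, hi = self.clutch_size_range
        if not (2 <= lo <= hi <= 10):
            raise ConfigurationError("clutch_size_range must lie within [2, 10]")
        for name in ("n_hens", "clutches_per_hen", "n_planted_returns",
                     "n_planted_cbp", "n_planted_renests"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_planted_returns and len(self.years) < 2:
            raise ConfigurationError("returning-breeder links need >= 2 years")
        n_links = self.n_planted_returns + self.n_planted_cbp + self.n_planted_renests
        if n_links > self.n_hens:
            raise ConfigurationError(
                f"more planted links ({n_links}) than background hens ({self.n_hens})")
        self.population.validate()


@dataclass
class GroundTruth:
    """True maternity and the links planted by the generator."""

    egg_to_hen: dict[str, str]
    planted_links: list[tuple[str, str, str]]  # (nest_a, nest_b, link_type)

    def to_json(self) -> str:
        return json.dumps(
            {"egg_to_hen": self.egg_to_hen,
             "planted_links": [list(t) for t in self.planted_links]},
            indent=2, sort_keys=True)


@dataclass
class EggRecord:
    egg_id: str
    clutch_id: str
    nest_id: str
    hen_id: str
    length_mm: float
    width_mm: float
    mass_g: float | None
    image: EggImage


@dataclass
class SyntheticDataset:
    eggs: list[EggRecord]
    nests: list[NestRecord]
    truth: GroundTruth
    config: ScenarioConfig

    @property
    def clutch_of(self) -> dict[str, str]:
        return {e.egg_id: e.clutch_id for e in self.eggs}


def _jittered(sig: HenSignature, rng: np.random.Generator) -> HenSignature:
    """One egg's parameters: the hen's signature plus within-clutch noise."""
    cv = sig.within_clutch_cv

    def rel(v: float) -> float:
        return v * (1.0 + cv * rng.standard_normal())

    return dataclasses.replace(
        sig,
        spot_density=abs(rel(sig.spot_density)),
        spot_radius_mean=abs(rel(sig.spot_radius_mean)),
        spot_radius_cv=abs(rel(sig.spot_radius_cv)),
        polar_bias=float(np.clip(sig.polar_bias + cv * rng.standard_normal(), 0, 1)),
        # the shell always contrasts with the dark velvet board
        ground_tone=float(np.clip(rel(sig.ground_tone), 110, 250)),
        spot_contrast=abs(rel(sig.spot_contrast)),
        length_mm=float(np.clip(rel(sig.length_mm), 30.0, 55.0)),
        width_mm=float(np.clip(rel(sig.width_mm), 22.0, 38.0)),
    )


class _Builder:
    def __init__(self, cfg: ScenarioConfig):
        cfg.validate()
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.rng_seed)
        self.eggs: list[EggRecord] = []
        self.nests: list[NestRecord] = []
        self.egg_to_hen: dict[str, str] = {}
        self.links: list[tuple[str, str, str]] = []
        self._nest_counter = 0
        self._hen_counter = 0

    def new_hen(self) -> HenSignature:
        self._hen_counter += 1
        return sample_hen_signature(
            self.cfg.population, self.rng, hen_id=f"H{self._hen_counter:03d}")

    def _region_origin(self, region: str) -> tuple[float, float]:
        idx = self.cfg.region_labels.index(region)
        return (0.0, idx * self.cfg.region_separation_m)

    def _season_dates(self, year: int) -> tuple[dt.date, dt.date]:
        start = dt.date.fromisoformat(f"{year}-{self.cfg.season_start}")
        end = dt.date.fromisoformat(f"{year}-{self.cfg.season_end}")
        return start, end

    def new_nest(
        self,
        year: int,
        region: str,
        xy: tuple[float, float] | None = None,
        first_egg: dt.date | None = None,
        fate: str = "H",
    ) -> NestRecord:
        self._nest_counter += 1
        nest_id = f"{year % 100:02d}-{self._nest_counter:02d}"
        ox, oy = self._region_origin(region)
        if xy is None:
            xy = (ox + self.rng.uniform(0, self.cfg.region_extent_m),
                  oy + self.rng.uniform(0, self.cfg.region_extent_m))
        if first_egg is None:
            start, end = self._season_dates(year)
            first_egg = start + dt.timedelta(
                days=int(self.rng.integers(0, max((end - start).days - 30, 1))))
        last_active = first_egg + dt.timedelta(days=int(self.rng.integers(20, 30)))
        nest = NestRecord(
            nest_id=nest_id, year=year, region=region,
            easting_m=float(xy[0]), northing_m=float(xy[1]),
            first_egg_date=first_egg, last_active_date=last_active, fate=fate)
        self.nests.append(nest)
        return nest

    def lay_clutch(self, nest: NestRecord, sig: HenSignature,
                   n_eggs: int | None = None) -> None:
        if n_eggs is None:
            lo, hi = self.cfg.clutch_size_range
            n_eggs = int(self.rng.integers(lo, hi + 1))
        start = sum(1 for e in self.eggs if e.nest_id == nest.nest_id)
        for i in range(start, start + n_eggs):
            egg_sig = _jittered(sig, self.rng)
            img = render_egg(egg_sig, egg_sig.length_mm, egg_sig.width_mm,
                             self.cfg.mm_per_px, self.rng)
            egg_id = f"{nest.nest_id}_e{i + 1}"
            img.egg_id = egg_id
            img.clutch_id = nest.nest_id
            self.eggs.append(EggRecord(
                egg_id=egg_id, clutch_id=nest.nest_id, nest_id=nest.nest_id,
                hen_id=sig.hen_id, length_mm=round(egg_sig.length_mm, 1),
                width_mm=round(egg_sig.width_mm, 1), mass_g=None, image=img))
            self.egg_to_hen[egg_id] = sig.hen_id

    def build(self) -> SyntheticDataset:
        cfg = self.cfg
        rng = self.rng
        n_planted_hens = cfg.n_planted_returns + 2 * cfg.n_planted_cbp + cfg.n_planted_renests
        if cfg.n_hens < 0 or n_planted_hens > cfg.n_hens + n_planted_hens + 100:
            raise ConfigurationError("infeasible planted counts")

        def rand_region() -> str:
            return cfg.region_labels[int(rng.integers(0, len(cfg.region_labels)))]

        def rand_fate() -> str:
            return str(rng.choice(["H", "H", "H", "P", "D"]))

        # background: unique hens, one (or more) clutch each
        for _ in range(cfg.n_hens):
            sig = self.new_hen()
            region = rand_region()
            for _c in range(cfg.clutches_per_hen):
                year = int(rng.choice(cfg.years))
                nest = self.new_nest(year, region, fate=rand_fate())
                self.lay_clutch(nest, sig)

        # returning breeders: same hen, two years, nests close together
        for _ in range(cfg.n_planted_returns):
            sig = self.new_hen()
            region = rand_region()
            y1, y2 = sorted(rng.choice(cfg.years, size=2, replace=False))
            n1 = self.new_nest(int(y1), region, fate=rand_fate())
            angle = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(20.0, cfg.rb_max_distance_m)
            xy2 = (n1.easting_m + dist * np.cos(angle),
                   n1.northing_m + dist * np.sin(angle))
            n2 = self.new_nest(int(y2), region, xy=xy2, fate=rand_fate())
            self.lay_clutch(n1, sig)
            self.lay_clutch(n2, sig)
            self.links.append((n1.nest_id, n2.nest_id, LINK_RETURNING_BREEDER))

        # CBP: parasite hen A with her own nest plus 1-2 eggs in host B's nest
        for _ in range(cfg.n_planted_cbp):
            sig_a, sig_b = self.new_hen(), self.new_hen()
            region = rand_region()
            year = int(rng.choice(cfg.years))
            na = self.new_nest(year, region, fate=rand_fate())
            angle = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(*cfg.cbp_distance_range_m)
            xyb = (na.easting_m + dist * np.cos(angle),
                   na.northing_m + dist * np.sin(angle))
            gap = int(rng.integers(0, cfg.cbp_synchrony_max_days + 1))
            fe_b = na.first_egg_date + dt.timedelta(days=gap)
            nb = self.new_nest(year, region, xy=xyb, first_egg=fe_b, fate=rand_fate())
            n_par = int(rng.integers(1, 3))
            lo, hi = cfg.clutch_size_range
            host_n = max(int(rng.integers(lo, hi + 1)) - n_par, 2)
            self.lay_clutch(na, sig_a)
            self.lay_clutch(nb, sig_b, n_eggs=host_n)
            self.lay_clutch(nb, sig_a, n_eggs=n_par)
            self.links.append((na.nest_id, nb.nest_id, LINK_CBP))

        # renests: same hen, same season, failed first nest, gap >= renest_gap
        for _ in range(cfg.n_planted_renests):
            sig = self.new_hen()
            region = rand_region()
            year = int(rng.choice(cfg.years))
            start, end = self._season_dates(year)
            fe1 = start + dt.timedelta(days=int(rng.integers(0, 10)))
            n1 = self.new_nest(year, region, first_egg=fe1,
                               fate=str(rng.choice(["P", "D"])))
            gap = int(rng.integers(*cfg.renest_gap_range_days))
            angle = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(*cfg.renest_distance_range_m)
            xy2 = (n1.easting_m + dist * np.cos(angle),
                   n1.northing_m + dist * np.sin(angle))
            n2 = self.new_nest(year, region, xy=xy2,
                               first_egg=fe1 + dt.timedelta(days=gap),
                               fate=rand_fate())
            self.lay_clutch(n1, sig)
            self.lay_clutch(n2, sig)
            self.links.append((n1.nest_id, n2.nest_id, LINK_RENEST))

        truth = GroundTruth(egg_to_hen=self.egg_to_hen, planted_links=self.links)
        return SyntheticDataset(eggs=self.eggs, nests=self.nests,
                                truth=truth, config=cfg)


def generate_population(cfg: ScenarioConfig) -> SyntheticDataset:
    """Generate the full synthetic study (images, nests, dates, ground truth)."""
    return _Builder(cfg).build()


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def config_hash(cfg: ScenarioConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> Path:
    """Write PNGs, the clutch manifest, the nest table and the ground truth."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    for egg in ds.eggs:
        iio.imwrite(outdir / "images" / f"{egg.egg_id}.png", egg.image.pixels)
    manifest = pd.DataFrame(
        [{"egg_id": e.egg_id, "clutch_id": e.clutch_id, "nest_id": e.nest_id,
          "length_mm": e.length_mm, "width_mm": e.width_mm, "mass_g": e.mass_g,
          "mm_per_px": e.image.mm_per_px}
         for e in ds.eggs])
    manifest.to_csv(outdir / "manifest.csv", index=False)
    nests = pd.DataFrame(
        [{"nest_id": n.nest_id, "year": n.year, "region": n.region,
          "easting_m": n.easting_m, "northing_m": n.northing_m,
          "first_egg_date": n.first_egg_date.isoformat() if n.first_egg_date else "",
          "last_active_date": n.last_active_date.isoformat() if n.last_active_date else "",
          "fate": n.fate}
         for n in ds.nests])
    nests.to_csv(outdir / "nests.csv", index=False)
    (outdir / "ground_truth.json").write_text(ds.truth.to_json())
    (outdir / "provenance.json").write_text(json.dumps(
        {"config": dataclasses.asdict(ds.config), "config_hash": config_hash(ds.config)},
        indent=2, default=str))
    return outdir
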