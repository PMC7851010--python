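"""Synthetic two-species, multi-population landmark studies.

Generates datasets with the statistical structure the analysis pipeline
assumes, so every stage is testable without any real digitized material:

* two species with distinct mean shapes and centroid-size distributions
  (body scales echoing ~250 µm vs ~170 µm mites),
* several populations per species whose mean shapes diverge from the
  species mean by an isotropic Gaussian perturbation — the endpoint of a
  Brownian-motion (random-walk) model of neutral trait evolution,
* isotropic landmark (digitization + individual) noise,
* a weak allometric component: a fixed shape direction coupled to centroid
  size and scaled to a chosen fraction of within-species shape variance,
* lognormal centroid sizes, randomized specimen order, optional random
  similarity transforms to exercise superimposition, and optional
  singleton populations to exercise passive projection.

The default configuration mirrors a realistic mite-morphometrics study:
sample sizes 10/10/9/9/6 for the first species and 13/12/9/4 plus three
singletons for the second, a more divergent second species (the
non-phoretic scenario), and ~3% within-species allometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .landmark_io import LandmarkConfiguration, LandmarkDataset, write_tps
from .superimposition import centroid_size

# Stylized 13-landmark sternal plate: six bilaterally paired setal
# insertions (3a, 3b, 3c, 4a, 4b, 4c) and the unpaired apodeme crossing,
# ordered LM1..LM13 with pairs (1,12) (2,11) (3,10) (4,9) (5,8) (6,7).
_BASE_SHAPE = np.array(
    [
        (0.15, 0.55),  # LM1  3a right
        (0.35, 0.45),  # LM2  3b right
        (0.55, 0.30),  # LM3  3c right (plate margin)
        (0.50, -0.30),  # LM4  4c right (plate margin)
        (0.30, -0.40),  # LM5  4b right
        (0.12, -0.35),  # LM6  4a right
        (-0.12, -0.35),  # LM7  4a left
        (-0.30, -0.40),  # LM8  4b left
        (-0.50, -0.30),  # LM9  4c left
        (-0.55, 0.30),  # LM10 3c left
        (-0.35, 0.45),  # LM11 3b left
        (-0.15, 0.55),  # LM12 3a left
        (0.00, -0.05),  # LM13 apodeme crossing
    ]
)


def base_sternal_plate() -> np.ndarray:
    """The stylized 13-landmark plate, centered and at unit centroid size."""
    c = _BASE_SHAPE - _BASE_SHAPE.mean(axis=0)
    return c / centroid_size(_BASE_SHAPE)


@dataclass
class SyntheticStudyConfig:
    """Full parameterization of a simulated two-species landmark study.

    Shape-space parameters (offsets, divergence, noise) are expressed in
    units of the unit-centroid-size base shape, i.e. on the same scale as
    Procrustes distances.  ``divergence_sd`` is the per-coordinate standard
    deviation of the Brownian endpoint perturbation of population means;
    ``allometry_strength`` is the fraction of within-species shape variance
    attributable to the size-coupled direction.
    """

    base_shape: np.ndarray = field(default_factory=base_sternal_plate)
    species_names: tuple[str, ...] = ("speciesA", "speciesB")
    species_shape_offset: float = 0.06
    n_per_population: tuple[tuple[int, ...], ...] = ((10, 10, 9, 9, 6), (13, 12, 9, 4))
    singletons_per_species: tuple[int, ...] = (0, 3)
    divergence_sd: tuple[float, ...] = (0.0015, 0.005)
    landmark_noise_sd: float = 0.005
    allometry_strength: tuple[float, ...] = (0.03, 0.03)
    size_mean_by_species: tuple[float, ...] = (250.0, 170.0)
    size_cv: float = 0.05
    random_similarity: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.base_shape = np.asarray(self.base_shape, dtype=float)
        if any(s < 0 for s in self.divergence_sd) or self.landmark_noise_sd < 0:
            raise ValueError("variance parameters must be >= 0")
        if any(not (0 <= a < 1) for a in self.allometry_strength):
            raise ValueError("allometry_strength must be in [0, 1)")
        if any(min(ns) < 1 for ns in self.n_per_population):
            raise ValueError("population sizes must be >= 1")

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_landmarks(self) -> int:
        return self.base_shape.shape[0]

    @property
    def total_specimens(self) -> int:
        return int(
            sum(sum(ns) for ns in self.n_per_population) + sum(self.singletons_per_species)
        )


@dataclass
class PopulationMeans:
    """Population mean shapes plus the fixed directions used to build them."""

    species_means: list[np.ndarray]  # per species, (k, 2)
    population_means: list[list[np.ndarray]]  # per species, per population
    singleton_means: list[list[np.ndarray]]
    species_contrast: np.ndarray  # unit (2k,) direction of species offset
    allometry_direction: np.ndarray  # unit (2k,)


def _unit_shape_direction(rng: np.random.Generator, k: int) -> np.ndarray:
    """Random unit vector in the 2k shape-variable space, orthogonalized
    against translation (so it is a genuine shape direction)."""
    v = rng.standard_normal((k, 2))
    v -= v.mean(axis=0)
    v = v.reshape(-1)
    return v / np.linalg.norm(v)


def simulate_population_means(
    config: SyntheticStudyConfig, rng: np.random.Generator
) -> PopulationMeans:
    """Draw species and population mean shapes.

    Species means sit at base ± (offset/2) along a fixed contrast
    direction; each population mean adds an independent isotropic Gaussian
    perturbation of scale ``divergence_sd`` — the endpoint of a Brownian
    random walk, under which the expected squared shape distance between
    population means grows linearly with divergence_sd².
    """
    k = config.n_landmarks
    contrast = _unit_shape_direction(rng, k)
    allom = _unit_shape_direction(rng, k)
    base = config.base_shape
    species_means = []
    for s in range(config.n_species):
        sign = 1.0 if s % 2 == 0 else -1.0
        species_means.append(
            base + sign * 0.5 * config.species_shape_offset * contrast.reshape(k, 2)
        )
    population_means: list[list[np.ndarray]] = []
    singleton_means: list[list[np.ndarray]] = []
    for s in range(config.n_species):
        div = config.divergence_sd[s]
        pops = [
            species_means[s] + rng.normal(0.0, div, size=(k, 2))
            for _ in config.n_per_population[s]
        ]
        population_means.append(pops)
        n_single = config.singletons_per_species[s] if s < len(config.singletons_per_species) else 0
        singleton_means.append(
            [species_means[s] + rng.normal(0.0, div, size=(k, 2)) for _ in range(n_single)]
        )
    return PopulationMeans(
        species_means=species_means,
        population_means=population_means,
        singleton_means=singleton_means,
        species_contrast=contrast,
        allometry_direction=allom,
    )


def _allometry_coefficient(config: SyntheticStudyConfig, species: int) -> float:
    """Scale of the size-coupled shape direction such that allometry
    explains ``allometry_strength`` of within-species shape variance
    (noise + population divergence being the remainder)."""
    strength = config.allometry_strength[species]
    if strength == 0:
        return 0.0
    k2 = 2 * config.n_landmarks
    v_rest = k2 * (config.landmark_noise_sd**2 + config.divergence_sd[species] ** 2)
    size_sd = config.size_cv * config.size_mean_by_species[species]
    return float(np.sqrt(strength / (1.0 - strength) * v_rest) / size_sd)


def _draw_sizes(
    rng: np.random.Generator, n: int, mean: float, cv: float
) -> np.ndarray:
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def simulate_specimens(
    config: SyntheticStudyConfig, rng: np.random.Generator | None = None
) -> LandmarkDataset:
    """Simulate a full labelled study.

    Specimen shape = population mean + allometric deviation x (size −
    species mean size) + isotropic landmark noise; raw coordinates are the
    shape rescaled to a centroid size drawn lognormally (µm scale) and,
    by default, hit with a random rotation and translation so the
    superimposition stage has real work to do.  Specimens are emitted in
    randomized order with IDs encoding species and population.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    means = simulate_population_means(config, rng)
    k = config.n_landmarks
    u_allom = means.allometry_direction.reshape(k, 2)

    records: list[tuple[str, str, str, np.ndarray]] = []
    for s, sp_name in enumerate(config.species_names):
        coeff = _allometry_coefficient(config, s)
        mean_size = config.size_mean_by_species[s]
        pops = [
            (f"{sp_name}_pop{p + 1}", means.population_means[s][p], n)
            for p, n in enumerate(config.n_per_population[s])
        ]
        pops += [
            (f"{sp_name}_single{q + 1}", m, 1)
            for q, m in enumerate(means.singleton_means[s])
        ]
        for pop_name, pop_mean, n in pops:
            sizes = _draw_sizes(rng, n, mean_size, config.size_cv)
            for j in range(n):
                shape = (
                    pop_mean
                    + coeff * (sizes[j] - mean_size) * u_allom
                    + rng.normal(0.0, config.landmark_noise_sd, size=(k, 2))
                )
                shape = shape - shape.mean(axis=0)
                raw = shape / centroid_size(shape) * sizes[j]
                if config.random_similarity:
                    theta = rng.uniform(0.0, 2.0 * np.pi)
                    rot = np.array(
                        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
                    )
                    raw = raw @ rot + rng.uniform(-500.0, 500.0, size=2)
                sid = f"{pop_name}_{j + 1:02d}"
                records.append((sid, pop_name, sp_name, raw))

    order = rng.permutation(len(records))
    configs = [
        LandmarkConfiguration(specimen_id=records[i][0], coords=records[i][3])
        for i in order
    ]
    mapping = {rec[0]: (rec[1], rec[2]) for rec in records}
    return LandmarkDataset(configurations=configs).with_labels(mapping)


def default_latlon(config: SyntheticStudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Plausible European sampling coordinates for every non-singleton
    population (uniform over roughly 36–55° N, −10–20° E)."""
    rows = []
    for s, sp_name in enumerate(config.species_names):
        for p in range(len(config.n_per_population[s])):
            rows.append(
                {
                    "population": f"{sp_name}_pop{p + 1}",
                    "lat": float(rng.uniform(36.0, 55.0)),
                    "lon": float(rng.uniform(-10.0, 20.0)),
                }
            )
    return pd.DataFrame(rows)


def make_fixture_files(config: SyntheticStudyConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic study in the external formats the
    pipeline consumes: tps landmarks, CSV specimen mapping, CSV population
    coordinates.  Returns the paths keyed 'tps', 'mapping', 'latlon'."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ds = simulate_specimens(config, rng)
    tps_path = out / "synthetic_study.tps"
    write_tps(ds, tps_path)
    mapping = pd.DataFrame(
        {
            "specimen_id": ds.specimen_ids,
            "population": [ds.group_of[i] for i in ds.specimen_ids],
            "species": [ds.species_of[i] for i in ds.specimen_ids],
            "excluded": [i in ds.excluded_from_stats for i in ds.specimen_ids],
        }
    )
    map_path = out / "specimen_mapping.csv"
    mapping.to_csv(map_path, index=False)
    latlon_path = out / "population_latlon.csv"
    default_latlon(config, np.random.default_rng(config.seed + 1)).to_csv(
        latlon_path, index=False
    )
    return {"tps": tps_path, "mapping": map_path, "latlon": latlon_path}
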