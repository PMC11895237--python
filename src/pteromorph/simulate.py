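"""Synthetic specimen generator with the study's statistical structure.

Museum-specimen landmark data for the flying-squirrel study are not
publicly deposited, so this module generates datasets carrying the same
generative structure the downstream analysis assumes:

* species mean shapes evolve by Brownian motion on an ultrametric
  phylogeny (optionally lambda-rescaled), displaced additively by a
  diet-effect vector and an allometric (log-size) vector;
* log centroid sizes are normal within diet categories (folivores and
  generalists large, frugivores and nucivores smaller);
* specimens scatter around their species mean with iid Gaussian
  coordinate noise, and each raw specimen is given a random rotation,
  translation and scale that superimposition must undo;
* biome occupancy follows a latitudinal richness gradient with the same
  per-biome species counts as the sampling table, built from a latent
  "tropicality" score so that tropical biomes share tropical species.

Every generating quantity is returned in ``true_values`` so downstream
stages can be tested as parameter-recovery problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
import yaml

from .datasets import pteromyini_metadata, TROPICAL_BIOMES, TEMPERATE_BIOMES
from .io import Configuration, BIOME_LABELS
from .phylo import bm_covariance, lambda_transform
from .procrustes import standardize
from .template import LandmarkTemplate, pteromyini_template, template_mean_shape

__all__ = ["SimulationParams", "simulate_tree", "simulate_dataset", "default_biome_richness"]

#: Diet categories carried by the generator (informative ones only).
SIM_DIETS = ("Folivore_1", "Folivore_2", "Frugivore", "Nucivore", "Generalist")


def default_biome_richness() -> dict[str, int]:
    """Per-biome species counts of the sampling table (max richness 26)."""
    meta = pteromyini_metadata()
    return {b: int(meta[b].sum()) for b in BIOME_LABELS}


def _default_diet_effects() -> dict[str, float]:
    # Procrustes-distance magnitude of each diet's shape displacement.
    # Scaled so that diet explains roughly 30% of among-species shape
    # variance under the default rates (Folivore_2 most extreme, matching
    # the conifer-needle specialists' position in morphospace).
    return {
        "Folivore_1": 0.0042,
        "Folivore_2": 0.0063,
        "Frugivore": 0.0032,
        "Nucivore": 0.0032,
        "Generalist": 0.0042,
    }


def _default_size_by_diet() -> dict[str, tuple[float, float]]:
    # (mean, sd) of log centroid size per diet; folivores slightly larger,
    # but with broad overlap so that size depends only weakly on diet
    # (diet explains ~20% of size variance, consistent with the weak,
    # non-significant size-diet association in this clade).
    return {
        "Folivore_1": (3.95, 0.25),
        "Folivore_2": (4.05, 0.25),
        "Frugivore": (3.85, 0.25),
        "Nucivore": (3.85, 0.30),
        "Generalist": (3.95, 0.30),
    }


@dataclass
class SimulationParams:
    """Generating parameters; defaults emulate the sampled study system.

    ``sigma_bm`` is the expected squared Procrustes deviation accumulated
    per unit tree depth (spread evenly over coordinates);
    ``specimen_noise_sd`` is the per-coordinate digitization/individual
    scatter of a unit-size shape.  ``n_specimens_per_species`` may be an
    int, an inclusive (low, high) range, or "table" to resample the
    empirical specimen counts of the sampling table.
    """

    n_species: int = 35
    n_specimens_per_species: object = "table"
    tree_mode: str = "pure_birth"  # pure_birth | fixed
    sigma_bm: float = 1e-4
    lambda_true: float = 1.0
    diet_effects: dict = field(default_factory=_default_diet_effects)
    allometry_slope: float = 0.013
    size_by_diet: dict = field(default_factory=_default_size_by_diet)
    specimen_noise_sd: float = 5e-4
    biome_richness: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.biome_richness is None:
            # study occupancy counts, scaled to the requested pool size
            study = default_biome_richness()
            self.biome_richness = {
                b: min(self.n_species, max(2, round(r * self.n_species / 35)))
                for b, r in study.items()
            }
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")
        for name in ("sigma_bm", "specimen_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for b, r in self.biome_richness.items():
            if r > self.n_species:
                raise ValueError(
                    f"biome {b!r} richness {r} exceeds n_species={self.n_species}"
                )

    @classmethod
    def from_yaml(cls, path) -> "SimulationParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "size_by_diet" in raw:
            raw["size_by_diet"] = {k: tuple(v) for k, v in raw["size_by_diet"].items()}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["size_by_diet"] = {k: list(v) for k, v in data["size_by_diet"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------- tree --


def simulate_tree(n_species: int, mode: str = "pure_birth", seed: int | None = None) -> dendropy.Tree:
    """An ultrametric binary tree with total depth 1.

    ``pure_birth`` runs a Yule process (exponential waiting times, uniform
    choice of splitting lineage); ``fixed`` uses the same construction with
    deterministic waits and always splits the oldest lineage, giving a
    reproducible reference topology.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    # active lineages: (node, birth_time)
    t = 0.0
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    active = [(c1, 0.0), (c2, 0.0)]
    while len(active) < n_species:
        j = len(active)
        if mode == "pure_birth":
            t += rng.exponential(1.0 / j)
            pick = int(rng.integers(j))
        elif mode == "fixed":
            t += 1.0 / j
            pick = int(np.argmin([b for _, b in active]))
        else:
            raise ValueError(f"unknown tree mode {mode!r}")
        node, birth = active.pop(pick)
        node.edge.length = t - birth
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        active.append((a, t))
        active.append((b, t))
    if mode == "pure_birth":
        T = t + rng.exponential(1.0 / n_species)
    else:
        T = t + 1.0 / n_species
    for i, (node, birth) in enumerate(active):
        node.edge.length = T - birth
        node.taxon = taxa.new_taxon(label=f"sp{i + 1:02d}")
    # normalise total depth to 1
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= T
    return tree


# ------------------------------------------------------------- dataset --


def _nuisance_basis(flat_base: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity (translation/scale/rotation)
    directions at a centred unit-size base shape, flattened (x, y) pairs."""
    k = flat_base.size // 2
    base = flat_base.reshape(k, 2)
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    scale = flat_base.copy()
    rot = np.column_stack([-base[:, 1], base[:, 0]]).reshape(-1)
    B = np.column_stack([tx, ty, scale, rot])
    Q, _ = np.linalg.qr(B)
    return Q


def _effect_directions(flat_base: np.ndarray, n_dirs: int, rng) -> np.ndarray:
    """Random orthonormal shape directions orthogonal to the similarity
    subspace, so superimposition cannot absorb the generated effects."""
    Q = _nuisance_basis(flat_base)
    dirs = []
    basis = [Q[:, i] for i in range(Q.shape[1])]
    while len(dirs) < n_dirs:
        v = rng.standard_normal(flat_base.size)
        for b in basis:
            v -= (v @ b) * b
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            v /= norm
            basis.append(v)
            dirs.append(v)
    return np.array(dirs)


def _specimen_counts(params: SimulationParams, rng) -> np.ndarray:
    spec = params.n_specimens_per_species
    n = params.n_species
    if spec == "table":
        counts = pteromyini_metadata()["N"].to_numpy()
        if n == len(counts):
            return rng.permutation(counts)
        return rng.choice(counts, size=n, replace=True)
    if isinstance(spec, int):
        return np.full(n, spec)
    low, high = spec
    return rng.integers(low, high + 1, size=n)


def _biome_occupancy(params: SimulationParams, species: list[str], rng) -> pd.DataFrame:
    """Occupancy flags with the requested per-biome richness.

    Each species gets a latent tropicality score; a tropical biome takes
    the top-scoring species under a biome-specific jitter, a temperate one
    the bottom-scoring, so biomes of the same climatic pole overlap in
    membership the way real biomes share wide-ranging species.
    """
    n = len(species)
    tropicality = rng.uniform(size=n)
    occ = pd.DataFrame({"species": species})
    for biome in BIOME_LABELS:
        r = int(params.biome_richness.get(biome, 0))
        flags = np.zeros(n, dtype=int)
        if r > 0:
            key = tropicality + rng.normal(0.0, 0.15, size=n)
            order = np.argsort(key)
            chosen = order[-r:] if biome in TROPICAL_BIOMES else order[:r]
            flags[chosen] = 1
        occ[biome] = flags
    return occ


def simulate_dataset(
    params: SimulationParams,
    template: LandmarkTemplate | None = None,
):
    """Generate (configurations, metadata, tree, true_values).

    Configurations are raw one-sided digitizations (nuisance rotation,
    translation and scale applied); metadata mirrors the sampling-table
    layout (species, N, diet, biome flags); ``true_values`` records every
    generating quantity for recovery tests.
    """
    if template is None:
        template = pteromyini_template()
    rng = np.random.default_rng(params.seed)
    tree = simulate_tree(params.n_species, params.tree_mode, seed=int(rng.integers(2**31)))
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    n = len(species)
    k = template.n_points

    diets = np.array(
        [SIM_DIETS[i % len(SIM_DIETS)] for i in range(n)], dtype=object
    )
    diets = rng.permutation(diets)

    log_sizes = np.array(
        [rng.normal(*params.size_by_diet[d]) for d in diets]
    )

    base, _ = standardize(template_mean_shape(template))
    flat_base = base.reshape(-1)

    dirs = _effect_directions(flat_base, len(SIM_DIETS) + 1, rng)
    diet_dirs = {d: dirs[i] for i, d in enumerate(SIM_DIETS)}
    allo_dir = dirs[-1]

    cov = bm_covariance(tree, taxa=species)
    Ct = lambda_transform(cov, params.lambda_true).C
    L = np.linalg.cholesky(Ct)
    per_coord_sd = np.sqrt(params.sigma_bm / (2 * k))
    bm_dev = per_coord_sd * (L @ rng.standard_normal((n, 2 * k)))

    mean_log_size = log_sizes.mean()
    species_flat = np.empty((n, 2 * k))
    diet_offsets = {d: params.diet_effects.get(d, 0.0) * diet_dirs[d] for d in SIM_DIETS}
    for i, sp in enumerate(species):
        species_flat[i] = (
            flat_base
            + diet_offsets[diets[i]]
            + params.allometry_slope * (log_sizes[i] - mean_log_size) * allo_dir
            + bm_dev[i]
        )
    species_shapes = species_flat.reshape(n, k, 2)

    counts = _specimen_counts(params, rng)
    configs: list[Configuration] = []
    for i, sp in enumerate(species):
        for j in range(int(counts[i])):
            pts = species_shapes[i] + rng.normal(0.0, params.specimen_noise_sd, size=(k, 2))
            pts = pts * np.exp(log_sizes[i])
            theta = rng.uniform(0.0, 2.0 * np.pi)
            R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
            scale = np.exp(rng.normal(0.0, 0.2))
            shift = rng.uniform(-10.0, 10.0, size=2)
            pts = scale * (pts @ R.T) + shift
            configs.append(
                Configuration(
                    specimen_id=f"{sp}_{j + 1:02d}", species=sp, points=pts, side="left"
                )
            )

    occ = _biome_occupancy(params, species, rng)
    metadata = pd.DataFrame({"species": species, "N": counts.astype(int), "diet": diets})
    metadata = metadata.merge(occ, on="species")

    true_values = {
        "tree": tree,
        "species": species,
        "diets": dict(zip(species, diets)),
        "log_sizes": dict(zip(species, log_sizes)),
        "species_shapes": species_shapes,
        "base_shape": base,
        "diet_directions": diet_dirs,
        "diet_offsets": diet_offsets,
        "allometry_direction": allo_dir,
        "bm_deviations": bm_dev,
        "params": params,
    }
    return configs, metadata, tree, true_values
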