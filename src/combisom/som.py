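"""Self-organizing-map training on combined multi-omics profiles.

Genes (their combined profile vectors) are quantized onto a square grid
of ``grid_side**2`` units ("metagenes") so that neighbouring units hold
similar profiles.  Training is the classical two-phase batch Kohonen
recipe: units are initialized on a lattice spanning the first two
principal components of the data, then updated per epoch as
neighborhood-weighted means of the profiles mapped to them, with a
Gaussian neighborhood kernel whose radius shrinks from ``grid_side/2``
to 3 (ordering phase) and from 3 to 1 (fine-tuning phase).  The run is
fully deterministic for a given seed.

Unit index ``u`` maps to grid coordinates ``(row, col) =
(u // grid_side, u % grid_side)`` with row 0 at the top; all portraits
and maps share this convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
from scipy.spatial.distance import cdist

from .datamodel import WeightConfig
from .preprocess import CombinedProfiles

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "SOMModel",
    "train_som",
    "assign_bmu",
    "population_map",
    "quantization_error",
    "write_model",
    "read_model",
]


@dataclass
class TrainingConfig:
    """Batch-SOM schedule.

    ``radius_start`` defaults to ``grid_side / 2`` at train time.  The
    learning rates damp the batch update (``new = old + lr * (batch_mean
    - old)``); the default of 1.0 at both ends is the plain batch rule.
    """

    seed: int = 0
    phase1_epochs: int = 20
    phase2_epochs: int = 30
    radius_start: float | None = None
    radius_mid: float = 3.0
    radius_end: float = 1.0
    lr_start: float = 1.0
    lr_end: float = 1.0
    init: str = "pca"  # "pca" | "sample"


@dataclass
class SOMModel:
    """A trained grid: unit vectors in combined block layout plus the
    gene -> best-matching-unit assignment."""

    grid_side: int
    unit_vectors: np.ndarray  # (grid_side**2, 3*S)
    weights: WeightConfig
    gene_ids: tuple[str, ...]
    assignment: dict[str, int]
    training_config: TrainingConfig
    sample_ids: tuple[str, ...]
    combination: str = "linear"  # weight-scaling scheme of the combined blocks

    def __post_init__(self) -> None:
        if self.unit_vectors.shape[0] != self.grid_side**2:
            raise ValueError("unit count must equal grid_side**2")
        if set(self.assignment) != set(self.gene_ids):
            raise ValueError("assignment must cover exactly the model's genes")

    @property
    def n_units(self) -> int:
        return self.grid_side**2

    def unit_coords(self, unit: int | np.ndarray) -> tuple:
        """Unit index -> (row, col), row 0 at top."""
        return np.divmod(unit, self.grid_side)

    def assignment_array(self) -> np.ndarray:
        return np.array([self.assignment[g] for g in self.gene_ids], dtype=int)


def _grid_coordinates(grid_side: int) -> np.ndarray:
    rows, cols = np.divmod(np.arange(grid_side**2), grid_side)
    return np.column_stack([rows, cols]).astype(float)


def _pca_lattice_init(x: np.ndarray, grid_side: int, rng: np.random.Generator) -> np.ndarray:
    """Lattice spanning the first two principal components of the data.

    Falls back to sampling data points when the data has rank < 2.
    """
    mean = x.mean(axis=0)
    xc = x - mean
    # economy SVD; deterministic up to sign, which we fix below
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    if len(s) < 2 or s[1] <= 1e-12 * max(s[0], 1.0):
        logger.warning("data rank < 2: falling back to sampled-point initialization")
        idx = rng.choice(x.shape[0], size=grid_side**2, replace=x.shape[0] < grid_side**2)
        return x[idx].astype(float).copy()
    pcs = vt[:2]
    for k in range(2):  # sign convention: largest-|.| loading positive
        j = np.argmax(np.abs(pcs[k]))
        if pcs[k, j] < 0:
            pcs[k] = -pcs[k]
    # component scores' SDs set the lattice span
    scale = s[:2] / np.sqrt(max(x.shape[0] - 1, 1))
    ax = np.linspace(-2.0, 2.0, grid_side)
    rowpos, colpos = np.divmod(np.arange(grid_side**2), grid_side)
    units = (
        mean
        + np.outer(ax[rowpos] * scale[0], pcs[0])
        + np.outer(ax[colpos] * scale[1], pcs[1])
    )
    return units


def _bmu_fast(x: np.ndarray, units: np.ndarray) -> np.ndarray:
    """Argmin Euclidean unit per row of x (matmul trick; ties -> lowest index)."""
    d = -2.0 * (x @ units.T) + np.einsum("ij,ij->i", units, units)
    return np.argmin(d, axis=1)


def train_som(
    profiles: CombinedProfiles | np.ndarray,
    grid_side: int = 45,
    config: TrainingConfig | None = None,
    seed: int | None = None,
) -> SOMModel:
    """Train a batch SOM on combined profiles.

    ``profiles`` is normally a :class:`CombinedProfiles`; a bare
    genes x D array is accepted for single-matrix training (the model
    then records balanced weights and requires D = 3S for decomposition).
    """
    if grid_side < 2:
        raise ValueError("grid_side must be at least 2")
    cfg = config or TrainingConfig()
    if seed is not None:
        cfg = TrainingConfig(**{**asdict(cfg), "seed": int(seed)})
    if isinstance(profiles, CombinedProfiles):
        x = np.asarray(profiles.vectors, dtype=float)
        gene_ids = profiles.gene_ids
        sample_ids = profiles.sample_ids
        weights = profiles.weights
    else:
        x = np.asarray(profiles, dtype=float)
        gene_ids = tuple(f"g{i}" for i in range(x.shape[0]))
        sample_ids = tuple(f"s{j}" for j in range(x.shape[1]))
        weights = WeightConfig(1 / 3, 1 / 3, 1 / 3)
    if not np.isfinite(x).all():
        raise ValueError("profiles contain non-finite values")
    n_units = grid_side**2
    if x.shape[0] < n_units / 10:
        logger.warning(
            "only %d genes for %d units; the map will be sparsely populated",
            x.shape[0], n_units,
        )

    rng = np.random.default_rng(cfg.seed)
    if cfg.init == "pca":
        units = _pca_lattice_init(x, grid_side, rng)
    elif cfg.init == "sample":
        idx = rng.choice(x.shape[0], size=n_units, replace=x.shape[0] < n_units)
        units = x[idx].astype(float).copy()
    else:
        raise ValueError(f"unknown init scheme {cfg.init!r}")

    coords = _grid_coordinates(grid_side)
    grid_d2 = cdist(coords, coords, "sqeuclidean")

    r0 = cfg.radius_start if cfg.radius_start is not None else grid_side / 2.0
    radii = np.concatenate([
        np.linspace(r0, cfg.radius_mid, cfg.phase1_epochs),
        np.linspace(cfg.radius_mid, cfg.radius_end, cfg.phase2_epochs),
    ])
    if len(radii) == 0:
        raise ValueError("training schedule has no epochs")
    lrs = np.linspace(cfg.lr_start, cfg.lr_end, len(radii))

    for radius, lr in zip(radii, lrs):
        bmu = _bmu_fast(x, units)
        sums = np.zeros_like(units)
        np.add.at(sums, bmu, x)
        counts = np.bincount(bmu, minlength=n_units).astype(float)
        h = np.exp(-grid_d2 / (2.0 * radius**2))
        num = h @ sums
        den = h @ counts
        ok = den > 1e-12
        target = units.copy()
        target[ok] = num[ok] / den[ok, None]
        units = units + lr * (target - units)

    assignment_idx = _bmu_exact(x, units)
    model = SOMModel(
        grid_side=grid_side,
        unit_vectors=units,
        weights=weights,
        gene_ids=gene_ids,
        assignment={g: int(u) for g, u in zip(gene_ids, assignment_idx)},
        training_config=cfg,
        sample_ids=sample_ids,
    )
    return model


def _bmu_exact(x: np.ndarray, units: np.ndarray) -> np.ndarray:
    """Exact pairwise distances so that symmetric ties resolve to the
    lowest unit index."""
    d = cdist(x, units, "sqeuclidean")
    return np.argmin(d, axis=1)


def assign_bmu(profiles: CombinedProfiles | np.ndarray, model: SOMModel) -> dict[str, int]:
    """Nearest unit (Euclidean) per gene; ties break to the lowest index."""
    if isinstance(profiles, CombinedProfiles):
        x = profiles.vectors
        gene_ids = profiles.gene_ids
    else:
        x = np.asarray(profiles, dtype=float)
        gene_ids = tuple(f"g{i}" for i in range(x.shape[0]))
    if x.shape[1] != model.unit_vectors.shape[1]:
        raise ValueError(
            f"profile length {x.shape[1]} does not match unit vector length "
            f"{model.unit_vectors.shape[1]}"
        )
    idx = _bmu_exact(x, model.unit_vectors)
    return {g: int(u) for g, u in zip(gene_ids, idx)}


def population_map(model: SOMModel) -> np.ndarray:
    """Genes per unit, as a grid_side x grid_side integer grid."""
    counts = np.bincount(model.assignment_array(), minlength=model.n_units)
    return counts.reshape(model.grid_side, model.grid_side)


def quantization_error(profiles: CombinedProfiles | np.ndarray, model: SOMModel) -> float:
    """Mean Euclidean distance of each gene to its best-matching unit."""
    x = profiles.vectors if isinstance(profiles, CombinedProfiles) else np.asarray(profiles)
    d = cdist(x, model.unit_vectors)
    return float(d.min(axis=1).mean())


# ---------------------------------------------------------------------------
# Persistence (self-describing HDF5 container; bit-exact round trip)
# ---------------------------------------------------------------------------

def write_model(model: SOMModel, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "combisom-model"
        f.attrs["grid_side"] = model.grid_side
        f.attrs["combination"] = model.combination
        f.attrs["weights"] = model.weights.as_array()
        f.attrs["training_config"] = json.dumps(asdict(model.training_config))
        f.create_dataset("unit_vectors", data=model.unit_vectors)
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("gene_ids", data=np.array(model.gene_ids, dtype=object), dtype=str_dt)
        f.create_dataset("sample_ids", data=np.array(model.sample_ids, dtype=object), dtype=str_dt)
        f.create_dataset("assignment", data=model.assignment_array())


def read_model(path: str | Path) -> SOMModel:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "combisom-model":
            raise ValueError(f"{path} is not a combisom model file")
        gene_ids = tuple(g.decode() if isinstance(g, bytes) else str(g) for g in f["gene_ids"][()])
        sample_ids = tuple(
            s.decode() if isinstance(s, bytes) else str(s) for s in f["sample_ids"][()]
        )
        w = np.asarray(f.attrs["weights"], dtype=float)
        assignment_idx = f["assignment"][()]
        cfg = TrainingConfig(**json.loads(f.attrs["training_config"]))
        return SOMModel(
            grid_side=int(f.attrs["grid_side"]),
            unit_vectors=f["unit_vectors"][()],
            weights=WeightConfig(*w),
            gene_ids=gene_ids,
            assignment={g: int(u) for g, u in zip(gene_ids, assignment_idx)},
            training_config=cfg,
            sample_ids=sample_ids,
            combination=str(f.attrs["combination"]),
        )
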