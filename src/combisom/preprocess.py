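"""Centralization, harmonization and weighted combination of the omics layers.

The pipeline order is: per-gene centralization of each matrix (subtract
the row mean over all samples), cross-modality harmonization (divide
each modality by its global standard deviation so the numerical scales
become comparable), then per-gene concatenation of the three S-length
profiles into one combined vector with block ``b`` multiplied by its
weight ``w_b``.  The Euclidean distance between two combined vectors is
then ``sqrt(sum_b w_b^2 d_b^2)`` over the per-modality distances, so the
weights tune how strongly each layer shapes the trained map.  After
training, :func:`decompose` inverts the scaling to recover per-modality
metagene matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import (
    MODALITIES,
    Modality,
    MultiOmicsDataset,
    OmicsMatrix,
    WeightConfig,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CombinedProfiles",
    "centralize",
    "centralize_dataset",
    "harmonize",
    "combine",
    "decompose",
]


@dataclass
class CombinedProfiles:
    """Per-gene concatenated, weight-scaled multi-omics profile vectors.

    ``vectors`` is genes x 3S with three contiguous S-length blocks in
    fixed (Gex, Dme, CNV) order; block ``b`` is the harmonized profile
    multiplied by ``w_b``.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    vectors: np.ndarray
    weights: WeightConfig
    block_boundaries: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        s = len(self.sample_ids)
        if self.vectors.shape != (len(self.gene_ids), 3 * s):
            raise ValueError(
                f"combined vectors must be genes x 3S, got {self.vectors.shape}"
            )
        expected = tuple((b * s, (b + 1) * s) for b in range(3))
        if tuple(self.block_boundaries) != expected:
            raise ValueError("block boundaries corrupted or out of order")

    def block(self, modality: Modality) -> np.ndarray:
        b = MODALITIES.index(Modality(modality))
        lo, hi = self.block_boundaries[b]
        return self.vectors[:, lo:hi]


def centralize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Subtract each gene's mean score over all samples."""
    if matrix.centralized:
        raise ValueError(f"{matrix.modality} matrix is already centralized")
    if matrix.n_samples < 2:
        raise ValueError("centralization needs at least two samples")
    vals = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    return OmicsMatrix(
        matrix.modality, matrix.gene_ids, matrix.sample_ids, vals, centralized=True
    )


def centralize_dataset(dataset: MultiOmicsDataset) -> MultiOmicsDataset:
    return MultiOmicsDataset(
        centralize(dataset.gex),
        centralize(dataset.dme),
        centralize(dataset.cnv),
        annotations=dataset.annotations,
        gene_sets=dataset.gene_sets,
    )


def harmonize(dataset: MultiOmicsDataset) -> MultiOmicsDataset:
    """Divide each modality by its global standard deviation over all entries.

    Afterwards every modality contributes on the same numerical scale
    (global SD 1).  An all-constant modality (SD 0) is left untouched
    with a warning.
    """
    out = []
    for m in dataset.matrices():
        if not m.centralized:
            raise ValueError(f"{m.modality} matrix must be centralized before harmonization")
        sd = float(m.values.std())
        if sd == 0.0:
            logger.warning("%s: global SD is 0, modality left as all-zeros", m.modality)
            vals = m.values.copy()
        else:
            vals = m.values / sd
        out.append(
            OmicsMatrix(
                m.modality, m.gene_ids, m.sample_ids, vals,
                centralized=True, harmonized=True,
            )
        )
    return MultiOmicsDataset(
        *out, annotations=dataset.annotations, gene_sets=dataset.gene_sets
    )


def combine(dataset: MultiOmicsDataset, weights: WeightConfig) -> CombinedProfiles:
    """Concatenate the three harmonized profiles per gene, scaling block b by w_b."""
    w = weights.as_array()
    mats = dataset.matrices()
    for m in mats:
        if not m.harmonized:
            raise ValueError(f"{m.modality} matrix must be harmonized before combination")
    s = dataset.n_samples
    vectors = np.concatenate([w[b] * mats[b].values for b in range(3)], axis=1)
    return CombinedProfiles(
        gene_ids=dataset.gene_ids,
        sample_ids=dataset.sample_ids,
        vectors=vectors,
        weights=weights,
        block_boundaries=tuple((b * s, (b + 1) * s) for b in range(3)),
    )


def decompose(model) -> dict[Modality, np.ndarray]:
    """Back-transform trained unit vectors into per-modality metagene matrices.

    Returns, for each modality, a units x samples matrix equal to the
    corresponding block of every unit vector divided by its weight; a
    zero-weight modality yields an all-NaN matrix with a warning.

    Parameters
    ----------
    model : SOMModel
        A trained model carrying weights and the combined block layout.
    """
    s = len(model.sample_ids)
    if model.unit_vectors.shape[1] != 3 * s:
        raise ValueError(
            f"unit vectors have width {model.unit_vectors.shape[1]}, expected {3 * s}"
        )
    out: dict[Modality, np.ndarray] = {}
    for b, modality in enumerate(MODALITIES):
        w_b = model.weights.as_array()[b]
        block = model.unit_vectors[:, b * s : (b + 1) * s]
        if w_b == 0.0:
            logger.warning("%s weight is 0: decomposed component is undefined (NaN)", modality)
            out[modality] = np.full_like(block, np.nan)
        else:
            out[modality] = block / w_b
    return out
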