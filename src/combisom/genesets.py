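"""Sample-wise gene-set Z (GSZ) scoring, ternary composition and signature maps.

The GSZ of a set in one sample compares the mean centralized score of
the member genes with the all-gene background of that sample:

    GSZ_s = (mean_members - mean_all) / (SD_all / sqrt(n_members))

where the mean and SD run over all genes of the matrix in sample ``s``
(population SD).  The same formula applies to expression, methylation
and copy-number scores.  For ternary diagrams the three modality GSZ of
a sample are turned into non-negative percentage shares of their
absolute values, with the signs retained as tags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import GeneSet, Modality, OmicsMatrix, SampleAnnotation
from .som import SOMModel

logger = logging.getLogger(__name__)

__all__ = [
    "GSZResult",
    "TernaryCoordinates",
    "gsz",
    "ternary_coordinates",
    "signature_map",
    "ranked_profile",
]


@dataclass
class GSZResult:
    set_name: str
    modality: Modality
    sample_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids),):
            raise ValueError("one GSZ score per sample required")
        if not np.isfinite(self.scores).all():
            raise ValueError("GSZ scores must be finite")


@dataclass
class TernaryCoordinates:
    """Per-sample percentage shares (p_Gex, p_Dme, p_CNV) with sign tags."""

    sample_ids: tuple[str, ...]
    percentages: np.ndarray  # (S, 3), rows sum to 100 (or 0 for all-zero triples)
    signs: np.ndarray  # (S, 3) in {-1, 0, +1}
    all_zero: np.ndarray  # (S,) bool flag

    def __post_init__(self) -> None:
        sums = self.percentages.sum(axis=1)
        ok = np.where(self.all_zero, np.abs(sums) < 1e-9, np.abs(sums - 100.0) < 1e-9)
        if not ok.all():
            raise ValueError("ternary percentages must sum to 100 (or 0 when flagged)")


def gsz(matrix: OmicsMatrix, gene_set: GeneSet) -> GSZResult:
    """Gene-set Z score of ``gene_set`` in every sample of ``matrix``."""
    if not matrix.centralized:
        raise ValueError("GSZ expects a centralized matrix")
    members = gene_set.member_gene_ids & set(matrix.gene_ids)
    if not members:
        raise KeyError(
            f"gene set {gene_set.name!r} has no members in the matrix"
        )
    gi = {g: k for k, g in enumerate(matrix.gene_ids)}
    rows = sorted(gi[g] for g in members)
    vals = matrix.values
    mean_all = vals.mean(axis=0)
    sd_all = vals.std(axis=0)  # population SD
    mean_set = vals[rows].mean(axis=0)
    scores = np.zeros(matrix.n_samples)
    nz = sd_all > 0
    scores[nz] = (mean_set[nz] - mean_all[nz]) / (sd_all[nz] / np.sqrt(len(rows)))
    if not nz.all():
        logger.warning(
            "%s: %d sample(s) with zero all-gene SD, GSZ set to 0 there",
            gene_set.name, int((~nz).sum()),
        )
    return GSZResult(gene_set.name, matrix.modality, matrix.sample_ids, scores)


def ternary_coordinates(
    gsz_e: GSZResult, gsz_m: GSZResult, gsz_c: GSZResult
) -> TernaryCoordinates:
    """Absolute-value percentage shares of the three modality GSZ per sample."""
    if not (gsz_e.sample_ids == gsz_m.sample_ids == gsz_c.sample_ids):
        raise ValueError("the three GSZ results must cover the same samples in order")
    z = np.column_stack([gsz_e.scores, gsz_m.scores, gsz_c.scores])
    absz = np.abs(z)
    total = absz.sum(axis=1)
    all_zero = total == 0.0
    p = np.zeros_like(absz)
    nz = ~all_zero
    p[nz] = 100.0 * absz[nz] / total[nz, None]
    return TernaryCoordinates(gsz_e.sample_ids, p, np.sign(z).astype(int), all_zero)


def signature_map(gene_set: GeneSet, model: SOMModel) -> np.ndarray:
    """Grid of member-gene counts per unit (total = overlap with the model)."""
    counts = np.zeros(model.n_units, dtype=int)
    overlap = gene_set.member_gene_ids & set(model.gene_ids)
    if not overlap:
        logger.warning("gene set %s has no genes on the map", gene_set.name)
    for g in overlap:
        counts[model.assignment[g]] += 1
    return counts.reshape(model.grid_side, model.grid_side)


def ranked_profile(
    result: GSZResult, annotations: Sequence[SampleAnnotation] = ()
) -> tuple[list[str], list[str]]:
    """Samples ordered by increasing GSZ (ties by sample ID) plus the
    matching group-label colour track."""
    order = sorted(
        range(len(result.sample_ids)),
        key=lambda k: (result.scores[k], result.sample_ids[k]),
    )
    samples = [result.sample_ids[k] for k in order]
    by_id = {a.sample_id: a.group_label for a in annotations}
    track = [by_id.get(s, "") for s in samples]
    return samples, track
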