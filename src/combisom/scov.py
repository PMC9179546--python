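"""Signed square-root covariance (ScoV) maps coupling pairs of omics layers.

The ScoV transform compresses a covariance ``c`` to ``sign(c) *
sqrt(|c|)``, which keeps the sign (anti-correlated couplings such as
promoter methylation repressing expression show up negative, dose
responses between copy number and expression positive) while taming the
dynamic range.  Per sample, the single-sample analogue is the
signed-root product of the two centralized metagene scores; per group,
the true cross-sample covariance (denominator S-1) is used.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from .datamodel import Modality
from .portraits import Portrait

logger = logging.getLogger(__name__)

__all__ = ["signed_sqrt", "scov_sample", "scov_group", "SCOV_PAIRS"]

#: The three ordered modality pairs.
SCOV_PAIRS: tuple[tuple[Modality, Modality], ...] = (
    (Modality.GEX, Modality.DME),
    (Modality.GEX, Modality.CNV),
    (Modality.DME, Modality.CNV),
)


def signed_sqrt(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.sqrt(np.abs(x))


def scov_sample(portrait_a: Portrait, portrait_b: Portrait) -> Portrait:
    """Cell-wise signed-root product of two same-sample portraits."""
    if portrait_a.grid.shape != portrait_b.grid.shape:
        raise ValueError(
            f"portrait shapes differ: {portrait_a.grid.shape} vs {portrait_b.grid.shape}"
        )
    if portrait_a.subject != portrait_b.subject:
        raise ValueError(
            f"ScoV pairs portraits of one sample, got {portrait_a.subject!r} "
            f"and {portrait_b.subject!r}"
        )
    grid = signed_sqrt(portrait_a.grid * portrait_b.grid)
    return Portrait(grid, f"ScoV:{portrait_a.kind}*{portrait_b.kind}", portrait_a.subject)


def scov_group(
    decomposed_a: np.ndarray,
    decomposed_b: np.ndarray,
    sample_ids: Sequence[str],
    group_samples: Sequence[str],
    grid_side: int | None = None,
    label: str = "group",
    kinds: tuple[str, str] = ("a", "b"),
) -> Portrait:
    """Signed-root cross-sample covariance between two modalities per unit.

    ``decomposed_a``/``decomposed_b`` are units x samples metagene
    matrices; the covariance runs over the listed group members
    (denominator S-1).
    """
    idx = [list(sample_ids).index(s) for s in group_samples]
    if len(idx) < 2:
        raise ValueError("group ScoV needs at least two samples")
    a = decomposed_a[:, idx]
    b = decomposed_b[:, idx]
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    cov = (a_c * b_c).sum(axis=1) / (len(idx) - 1)
    if grid_side is None:
        grid_side = int(round(np.sqrt(decomposed_a.shape[0])))
    return Portrait(
        signed_sqrt(cov).reshape(grid_side, grid_side),
        f"ScoV:{kinds[0]}*{kinds[1]}",
        label,
    )
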