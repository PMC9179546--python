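"""Sample and group portraits plus gene-space summary maps.

A portrait renders one sample's metagene values for one modality on the
trained grid: cell (r, c) holds the decomposed metagene score of unit
``u = r * grid_side + c``.  Because every gene sits at the same grid
position in all three modalities, the Gex, Dme and CNV portraits of a
sample can be compared cell by cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datamodel import Modality
from .som import SOMModel

logger = logging.getLogger(__name__)

__all__ = [
    "Portrait",
    "sample_portrait",
    "group_mean_portrait",
    "group_portraits",
    "variance_map",
    "metagene_covariance_map",
    "write_portrait_tsv",
    "write_portrait_png",
]


@dataclass
class Portrait:
    """A grid-valued map: one sample/group/statistic on the SOM lattice."""

    grid: np.ndarray  # (grid_side, grid_side)
    kind: str  # "Gex" | "Dme" | "CNV" | "Variance" | "Covariance" | "ScoV:..." | "HR"
    subject: str  # sample id, group label, or "global"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError(f"portrait grid must be square 2-D, got {self.grid.shape}")
        if self.kind != "HR" and not np.isfinite(self.grid).all():
            if not (np.isnan(self.grid).all()):  # all-NaN = zero-weight modality
                raise ValueError(f"non-finite entries in {self.kind} portrait")


def _sample_index(sample_ids: Sequence[str], sample_id: str) -> int:
    try:
        return list(sample_ids).index(sample_id)
    except ValueError:
        raise KeyError(f"unknown sample {sample_id!r}") from None


def sample_portrait(
    model: SOMModel,
    decomposed: Mapping[Modality, np.ndarray],
    sample_id: str,
    modality: Modality,
) -> Portrait:
    """One sample's metagene values for one modality, on the grid."""
    j = _sample_index(model.sample_ids, sample_id)
    col = decomposed[Modality(modality)][:, j]
    return Portrait(
        col.reshape(model.grid_side, model.grid_side), Modality(modality).value, sample_id
    )


def group_mean_portrait(portraits: Sequence[Portrait], group_label: str = "group") -> Portrait:
    """Cell-wise mean over the individual portraits of one group."""
    if len(portraits) == 0:
        raise ValueError("empty group: no portraits to average")
    kinds = {p.kind for p in portraits}
    if len(kinds) > 1:
        raise ValueError(f"cannot average portraits of mixed kinds {kinds}")
    grid = np.mean([p.grid for p in portraits], axis=0)
    return Portrait(grid, portraits[0].kind, group_label)


def group_portraits(
    model: SOMModel,
    decomposed: Mapping[Modality, np.ndarray],
    groups: Mapping[str, Sequence[str]],
    modality: Modality,
) -> dict[str, Portrait]:
    """Mean portrait per group for one modality."""
    out = {}
    for label, members in groups.items():
        singles = [sample_portrait(model, decomposed, s, modality) for s in members]
        out[label] = group_mean_portrait(singles, label)
    return out


def variance_map(
    decomposed: Mapping[Modality, np.ndarray], modality: Modality, grid_side: int | None = None
) -> Portrait:
    """Cross-sample variance (denominator S-1) of each unit's metagene profile."""
    mat = decomposed[Modality(modality)]
    if mat.shape[1] < 2:
        raise ValueError("variance map needs at least two samples")
    if grid_side is None:
        grid_side = int(round(np.sqrt(mat.shape[0])))
    v = mat.var(axis=1, ddof=1)
    return Portrait(v.reshape(grid_side, grid_side), "Variance", Modality(modality).value)


def metagene_covariance_map(
    model: SOMModel,
    gene_values: np.ndarray,
    gene_ids: Sequence[str],
    decomposed: Mapping[Modality, np.ndarray],
    modality: Modality,
) -> Portrait:
    """Mean covariance between single-gene and metagene profiles per unit.

    For each unit, the covariance (across samples, denominator S-1)
    between each assigned gene's harmonized profile and the unit's
    metagene profile is averaged; units without genes map to 0.
    """
    modality = Modality(modality)
    meta = decomposed[modality]
    s = meta.shape[1]
    if gene_values.shape[1] != s:
        raise ValueError("gene matrix and metagene matrix differ in sample count")
    gene_c = gene_values - gene_values.mean(axis=1, keepdims=True)
    meta_c = meta - meta.mean(axis=1, keepdims=True)
    out = np.zeros(model.n_units)
    counts = np.zeros(model.n_units)
    for g, row in zip(gene_ids, gene_c):
        u = model.assignment[g]
        out[u] += float(row @ meta_c[u]) / (s - 1)
        counts[u] += 1
    nz = counts > 0
    out[nz] /= counts[nz]
    return Portrait(
        out.reshape(model.grid_side, model.grid_side), "Covariance", modality.value
    )


def write_portrait_tsv(portrait: Portrait, path: str | Path) -> None:
    np.savetxt(path, portrait.grid, delimiter="\t", fmt="%.10g")


def write_portrait_png(portrait: Portrait, path: str | Path) -> None:
    """Render with the standard blue -> white -> maroon diverging scale,
    symmetric about 0 (presentation only; the grid is the artifact)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("scov", ["#1f3b9b", "white", "#800000"])
    grid = portrait.grid
    lim = np.nanmax(np.abs(grid)) if np.isfinite(grid).any() else 1.0
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    ax.imshow(grid, cmap=cmap, vmin=-lim, vmax=lim, interpolation="nearest")
    ax.set_title(f"{portrait.kind}: {portrait.subject}", fontsize=8)
    ax.set_xticks([]), ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
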