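"""Spot-module detection on the metagene grid.

Because SOM training places similar metagenes next to each other,
portraits show smooth textures with localized extreme regions
("spots") that collect co-expressed, co-methylated and/or co-aberrant
genes.  A spot is the 8-connected component of grid cells whose value
reaches a fraction (default 90%) of the portrait's maximum (sign
"over") or minimum (sign "under"); components smaller than ``min_size``
cells are treated as speckle and dropped.  The cohort-level spot
summary map unions the spots of all group portraits over all
modalities, merges overlapping regions, and labels them A, B, ... in
clockwise order around the grid centre starting in the top-left
quadrant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .datamodel import MODALITIES, Modality
from .portraits import Portrait
from .som import SOMModel

logger = logging.getLogger(__name__)

__all__ = [
    "SpotModule",
    "SpotFrequencyTable",
    "detect_spots",
    "spot_summary_map",
    "attach_genes",
    "spot_profiles",
    "spot_correlation",
    "spot_frequencies",
]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


@dataclass
class SpotModule:
    """A contiguous high-|score| grid region and its gene content."""

    sign: str  # "over" | "under" | "mixed"
    member_units: frozenset[int]
    label: str | None = None
    member_genes: tuple[str, ...] = ()
    dominant_modality: Modality | None = None
    profiles: dict = field(default_factory=dict)  # modality -> sample-length vector
    source: str = ""  # portrait the component was found in

    def __post_init__(self) -> None:
        if not self.member_units:
            raise ValueError("spot must have at least one member unit")

    @property
    def n_units(self) -> int:
        return len(self.member_units)

    def mask(self, grid_side: int) -> np.ndarray:
        m = np.zeros(grid_side**2, dtype=bool)
        m[list(self.member_units)] = True
        return m.reshape(grid_side, grid_side)


@dataclass
class SpotFrequencyTable:
    """Per group, the fraction of samples showing each spot count."""

    fractions: dict[str, dict[int, float]]

    def __post_init__(self) -> None:
        for g, dist in self.fractions.items():
            if dist and abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"fractions for group {g!r} do not sum to 1")


def detect_spots(
    portrait: Portrait,
    threshold_fraction: float = 0.9,
    sign: str = "over",
    min_size: int = 3,
    reference: float | None = None,
) -> list[SpotModule]:
    """8-connected components above ``threshold_fraction`` of the extremum.

    For sign "over" the portrait maximum must be positive (otherwise an
    empty list is returned with a warning); for "under", the minimum
    negative, mirrored.  ``reference`` overrides the portrait's own
    extremum, e.g. with a cohort-wide one, so that portraits without
    genuine extremes do not promote noise to spots.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    grid = portrait.grid
    if sign == "over":
        ref = np.nanmax(grid) if reference is None else float(reference)
        if not ref > 0:
            logger.warning(
                "%s/%s: maximum is not positive, no over-spots", portrait.kind, portrait.subject
            )
            return []
        mask = grid >= threshold_fraction * ref
    elif sign == "under":
        ref = np.nanmin(grid) if reference is None else float(reference)
        if not ref < 0:
            logger.warning(
                "%s/%s: minimum is not negative, no under-spots", portrait.kind, portrait.subject
            )
            return []
        mask = grid <= threshold_fraction * ref
    else:
        raise ValueError(f"sign must be 'over' or 'under', got {sign!r}")
    mask &= np.isfinite(grid)
    labeled, n = ndimage.label(mask, structure=_EIGHT)
    spots = []
    for k in range(1, n + 1):
        units = np.flatnonzero(labeled.ravel() == k)
        if len(units) < min_size:
            continue
        spots.append(
            SpotModule(
                sign=sign,
                member_units=frozenset(int(u) for u in units),
                source=f"{portrait.kind}/{portrait.subject}",
            )
        )
    return spots


def _clockwise_key(units: Iterable[int], grid_side: int) -> float:
    """Angular position of a spot centroid, clockwise from the top-left
    diagonal of the grid centre (used for A, B, ... labelling)."""
    units = np.asarray(list(units))
    rows, cols = np.divmod(units, grid_side)
    c = (grid_side - 1) / 2.0
    dx = cols.mean() - c
    dy = c - rows.mean()  # y axis up
    theta = math.atan2(dy, dx)
    start = 3.0 * math.pi / 4.0  # top-left diagonal
    return (start - theta) % (2.0 * math.pi)


def attach_genes(spot: SpotModule, model: SOMModel) -> SpotModule:
    """Fill ``member_genes`` as the union of the member units' assignments."""
    genes = tuple(
        g for g in model.gene_ids if model.assignment[g] in spot.member_units
    )
    spot.member_genes = genes
    return spot


def spot_summary_map(
    group_portraits: Sequence[Portrait],
    model: SOMModel,
    threshold_fraction: float = 0.9,
    min_size: int = 3,
) -> tuple[np.ndarray, list[SpotModule]]:
    """Cohort-level spot map over all group portraits and modalities.

    Over- and under-spots of every group portrait are collected (each
    against its own portrait extremum), then components describing the
    same map region are merged: two components count as overlapping
    when they share at least ``min_size`` cells — a spot-sized overlap —
    so that single boundary cells do not chain unrelated regions
    together.  Residual contested cells are assigned to the largest
    claiming spot, keeping the labelled regions disjoint; spots reduced
    below ``min_size`` by that resolution are dropped.  Labels run
    A, B, ... clockwise; genes are attached from the model assignment
    and each spot is tagged with its dominant modality (largest variance
    of the spot-mean value across that modality's group portraits).

    Returns the labelled grid (0 = background, i = spot i, in label
    order) and the spot list.
    """
    if len(group_portraits) == 0:
        raise ValueError("need at least one group portrait")
    gs = model.grid_side
    contributions: list[SpotModule] = []
    for p in group_portraits:
        for sign in ("over", "under"):
            contributions.extend(detect_spots(p, threshold_fraction, sign, min_size))
    # union-find over the spot-sized-overlap graph
    parent = list(range(len(contributions)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(contributions)):
        for j in range(i + 1, len(contributions)):
            shared = contributions[i].member_units & contributions[j].member_units
            if len(shared) >= min_size:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, list[SpotModule]] = {}
    for i, c in enumerate(contributions):
        clusters.setdefault(find(i), []).append(c)
    merged: list[SpotModule] = []
    for comps in clusters.values():
        units = set().union(*(c.member_units for c in comps))
        signs = {c.sign for c in comps}
        merged.append(
            SpotModule(
                sign=signs.pop() if len(signs) == 1 else "mixed",
                member_units=frozenset(units),
            )
        )
    # resolve sub-min_size overlaps: each contested cell goes to the
    # largest claiming spot (ties: lowest minimum unit index)
    claim: dict[int, SpotModule] = {}
    order = sorted(merged, key=lambda s: (-s.n_units, min(s.member_units)))
    for s in order:
        for u in s.member_units:
            claim.setdefault(u, s)
    resolved: list[SpotModule] = []
    for s in merged:
        units = frozenset(u for u in s.member_units if claim[u] is s)
        if len(units) >= min_size:
            resolved.append(SpotModule(sign=s.sign, member_units=units))
    merged = resolved
    merged.sort(key=lambda s: _clockwise_key(s.member_units, gs))
    by_mod: dict[Modality, list[Portrait]] = {m: [] for m in MODALITIES}
    for p in group_portraits:
        try:
            by_mod[Modality(p.kind)].append(p)
        except ValueError:
            pass  # derived-kind portraits do not vote on dominance
    label_grid = np.zeros((gs, gs), dtype=int)
    for i, spot in enumerate(merged):
        spot.label = _letter_label(i)
        attach_genes(spot, model)
        spot.dominant_modality = _dominant_modality(spot, by_mod, gs)
        label_grid[spot.mask(gs)] = i + 1
    return label_grid, merged


def _letter_label(i: int) -> str:
    # A..Z, then AA, AB, ... for maps with many spots
    letters = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        letters = chr(ord("A") + r) + letters
    return letters


def _dominant_modality(
    spot: SpotModule, by_mod: Mapping[Modality, Sequence[Portrait]], grid_side: int
) -> Modality | None:
    mask = spot.mask(grid_side)
    best, best_var = None, -np.inf
    for m, portraits in by_mod.items():
        if len(portraits) < 2:
            continue
        means = [float(np.nanmean(p.grid[mask])) for p in portraits]
        v = float(np.var(means, ddof=1))
        if v > best_var:
            best, best_var = m, v
    return best


def spot_profiles(
    spot: SpotModule, decomposed: Mapping[Modality, np.ndarray]
) -> dict[Modality, np.ndarray]:
    """Per modality, the mean metagene value over member units for each
    sample (NaN throughout for a zero-weight modality)."""
    units = sorted(spot.member_units)
    return {Modality(m): decomposed[m][units].mean(axis=0) for m in decomposed}


def spot_correlation(
    spot: SpotModule,
    values_a: np.ndarray,
    values_b: np.ndarray,
    gene_ids: Sequence[str],
    sample_idx: Sequence[int] | None = None,
) -> tuple[np.ndarray, float]:
    """Per member gene, (mean score in a, mean score in b) across the
    chosen samples, plus the Pearson correlation of those pairs."""
    gi = {g: k for k, g in enumerate(gene_ids)}
    rows = [gi[g] for g in spot.member_genes if g in gi]
    if len(rows) < 3:
        raise ValueError(f"spot {spot.label or '?'} has fewer than 3 genes in the matrix")
    cols = slice(None) if sample_idx is None else list(sample_idx)
    a = values_a[rows][:, cols].mean(axis=1)
    b = values_b[rows][:, cols].mean(axis=1)
    pairs = np.column_stack([a, b])
    r = float(np.corrcoef(a, b)[0, 1])
    return pairs, r


def spot_frequencies(
    sample_portraits: Mapping[str, Portrait],
    groups: Mapping[str, Sequence[str]],
    threshold_fraction: float = 0.9,
    min_size: int = 3,
    signs: tuple[str, ...] = ("over", "under"),
) -> SpotFrequencyTable:
    """Distribution of per-sample spot counts within each group."""
    counts: dict[str, int] = {}
    for s, p in sample_portraits.items():
        counts[s] = sum(
            len(detect_spots(p, threshold_fraction, sign, min_size)) for sign in signs
        )
    fractions: dict[str, dict[int, float]] = {}
    for g, members in groups.items():
        members = [m for m in members if m in counts]
        if not members:
            fractions[g] = {}
            continue
        tally: dict[int, int] = {}
        for m in members:
            tally[counts[m]] = tally.get(counts[m], 0) + 1
        fractions[g] = {k: v / len(members) for k, v in sorted(tally.items())}
    return SpotFrequencyTable(fractions)
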