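"""Metagene-resolved hazard-ratio maps.

For each unit and modality, samples whose metagene score exceeds the
unit's cross-sample mean by more than one standard deviation form the
"high" group; a univariate Cox proportional-hazards fit of high vs the
remaining samples gives the hazard ratio HR = exp(beta) rendered at
that grid cell.  Cells where the high group is smaller than
``min_group`` or where either arm has no events are left undefined
(NaN).  Cox fitting is delegated to lifelines; the per-metagene
dichotomization and map assembly are this module's contract.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .datamodel import Modality
from .spots import SpotModule

logger = logging.getLogger(__name__)

__all__ = ["HRMap", "fit_hazard_ratio", "hr_map", "hr_maps", "spot_hr"]


@dataclass
class HRMap:
    """Hazard-ratio grid for one modality with companion grids."""

    modality: Modality
    hr: np.ndarray  # positive reals or NaN
    ci_low: np.ndarray
    ci_high: np.ndarray
    high_group_size: np.ndarray  # int grid
    high_group_events: np.ndarray  # int grid

    def __post_init__(self) -> None:
        defined = np.isfinite(self.hr)
        if defined.any() and not (self.hr[defined] > 0).all():
            raise ValueError("defined hazard ratios must be positive")


def fit_hazard_ratio(
    time: np.ndarray, event: np.ndarray, high: np.ndarray
) -> tuple[float, float, float]:
    """Univariate Cox PH of a binary high/rest indicator.

    Returns (HR, CI low, CI high); NaNs when the fit is degenerate
    (no events in an arm, or non-convergence).
    """
    high = np.asarray(high, dtype=bool)
    ev = np.asarray(event, dtype=bool)
    if not high.any() or high.all():
        return (np.nan, np.nan, np.nan)
    if ev[high].sum() == 0 or ev[~high].sum() == 0:
        return (np.nan, np.nan, np.nan)
    df = pd.DataFrame(
        {"time": np.asarray(time, float), "event": ev.astype(int), "high": high.astype(int)}
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError) as exc:
        logger.debug("Cox fit failed: %s", exc)
        return (np.nan, np.nan, np.nan)
    hr = float(np.exp(cph.params_["high"]))
    lo, hi = np.exp(cph.confidence_intervals_.loc["high"]).to_numpy()
    return (hr, float(lo), float(hi))


def _survival_arrays(
    sample_ids: Sequence[str], survival: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column indices (into the metagene matrix) and aligned time/event
    arrays for the samples that carry survival data."""
    have = [k for k, s in enumerate(sample_ids) if s in survival.index]
    if not have:
        raise ValueError("no samples with survival data")
    sub = survival.loc[[sample_ids[k] for k in have]]
    return np.array(have), sub["time"].to_numpy(float), sub["event"].to_numpy(bool)


def hr_map(
    decomposed_modality: np.ndarray,
    sample_ids: Sequence[str],
    survival: pd.DataFrame,
    modality: Modality = Modality.GEX,
    min_group: int = 5,
    grid_side: int | None = None,
) -> HRMap:
    """Hazard-ratio map of one modality.

    ``survival`` is a frame indexed by sample ID with ``time`` (months)
    and ``event`` (bool) columns, as produced by
    :meth:`MultiOmicsDataset.survival_frame`.
    """
    cols, time, event = _survival_arrays(sample_ids, survival)
    if len(cols) < 2 * min_group:
        raise ValueError(
            f"need at least {2 * min_group} samples with survival data, have {len(cols)}"
        )
    if event.sum() == 0:
        raise ValueError("no events in the survival data")
    mat = decomposed_modality[:, cols]
    n_units = mat.shape[0]
    if grid_side is None:
        grid_side = int(round(np.sqrt(n_units)))
    hr = np.full(n_units, np.nan)
    lo = np.full(n_units, np.nan)
    hi = np.full(n_units, np.nan)
    sizes = np.zeros(n_units, dtype=int)
    events = np.zeros(n_units, dtype=int)
    cache: dict[bytes, tuple[float, float, float]] = {}
    for u in range(n_units):
        profile = mat[u]
        if not np.isfinite(profile).all():
            continue
        thr = profile.mean() + profile.std(ddof=1)
        high = profile > thr
        sizes[u] = int(high.sum())
        events[u] = int(event[high].sum())
        if sizes[u] < min_group:
            continue
        key = high.tobytes()
        if key not in cache:
            cache[key] = fit_hazard_ratio(time, event, high)
        hr[u], lo[u], hi[u] = cache[key]
    shape = (grid_side, grid_side)
    return HRMap(
        Modality(modality),
        hr.reshape(shape),
        lo.reshape(shape),
        hi.reshape(shape),
        sizes.reshape(shape),
        events.reshape(shape),
    )


def hr_maps(
    decomposed: Mapping[Modality, np.ndarray],
    sample_ids: Sequence[str],
    survival: pd.DataFrame,
    min_group: int = 5,
) -> dict[Modality, HRMap]:
    return {
        Modality(m): hr_map(decomposed[m], sample_ids, survival, m, min_group)
        for m in decomposed
    }


def spot_hr(
    spot: SpotModule,
    decomposed: Mapping[Modality, np.ndarray],
    sample_ids: Sequence[str],
    survival: pd.DataFrame,
    min_group: int = 5,
) -> dict[Modality, tuple[float, float, float]]:
    """HR and 95% CI per modality from the spot's mean metagene profile,
    with the same mean + 1 SD high/rest dichotomization."""
    if not spot.member_units:
        raise ValueError("empty spot")
    cols, time, event = _survival_arrays(sample_ids, survival)
    units = sorted(spot.member_units)
    out: dict[Modality, tuple[float, float, float]] = {}
    for m, mat in decomposed.items():
        profile = mat[units][:, cols].mean(axis=0)
        if not np.isfinite(profile).all():
            out[Modality(m)] = (np.nan, np.nan, np.nan)
            continue
        high = profile > profile.mean() + profile.std(ddof=1)
        if high.sum() < min_group:
            out[Modality(m)] = (np.nan, np.nan, np.nan)
            continue
        out[Modality(m)] = fit_hazard_ratio(time, event, high)
    return out
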