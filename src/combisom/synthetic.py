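"""Synthetic multi-omics cohorts with known ground truth.

The generator emulates the statistical structure the portrayal method
assumes in a glioma-like cohort: genetic sample groups carrying
arm-level trinary copy-number segments with a positive dose-response on
expression; repressive promoter-methylation modules that push
expression down; a global methylation gradient (hypermethylator
phenotype) with per-gene susceptibility; pure-expression modules driven
by transcription-factor programmes rather than Dme or CNV; a fraction
of low-tumour-content ("neuronal-like") samples whose group effects are
attenuated; and exponential survival with group-dependent hazard
multipliers.  All effect sizes and noise levels live in
:class:`SyntheticConfig`; a fixed seed makes every draw reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    Modality,
    MultiOmicsDataset,
    OmicsMatrix,
    SampleAnnotation,
    GeneSet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedModule",
    "GroupSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "default_cohort",
    "default_config",
]


@dataclass(frozen=True)
class PlantedModule:
    """One planted gene module.

    ``kind`` selects the generative rule:

    - ``"cnv"``: ``group_levels`` are trinary copy-number states
      (-1 loss, 0 neutral, +1 gain); expression responds with the
      dose-response slope gamma > 0.
    - ``"repressive"``: ``group_levels`` are methylation shifts;
      expression responds with the repression slope beta < 0.
    - ``"gex"``: ``group_levels`` are pure expression shifts (TF-driven),
      leaving Dme and CNV untouched.

    ``gene_ranges`` are half-open index ranges into the gene axis; a
    module may span several ranges (e.g. a co-deletion of two arms).
    """

    name: str
    kind: str  # "cnv" | "repressive" | "gex"
    gene_ranges: tuple[tuple[int, int], ...]
    group_levels: Mapping[str, float]

    def gene_indices(self) -> np.ndarray:
        return np.concatenate([np.arange(a, b) for a, b in self.gene_ranges])


@dataclass(frozen=True)
class GroupSpec:
    name: str
    size: int
    methylation_gradient: float = 0.0  # group level of the global Dme gradient
    hazard: float = 1.0  # multiplicative hazard vs baseline


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    groups: tuple[GroupSpec, ...] = ()
    modules: tuple[PlantedModule, ...] = ()
    cnv_dose_response: float = 1.0  # gamma > 0: log2-ish Gex response per CNV unit
    dme_repression: float = -0.8  # beta < 0: Gex response per Dme shift unit
    gradient_amplitude: float = 0.8  # scales per-gene susceptibility x group level
    noise_sd: dict = field(
        default_factory=lambda: {Modality.GEX: 0.4, Modality.DME: 0.3, Modality.CNV: 0.3}
    )
    low_purity_fraction: float = 0.1
    purity_attenuation: float = 0.3  # alpha: signal retained in low-purity samples
    module_loading_spread: float = 0.0  # per-gene effect multipliers ~ U(1-s, 1+s)
    survival_base_rate: float = 1.0 / 60.0  # events per month at hazard 1
    censor_time: float = 120.0  # administrative censoring (months)

    @property
    def n_samples(self) -> int:
        return sum(g.size for g in self.groups)

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("config needs at least one group")
        if not 0 < self.purity_attenuation <= 1:
            raise ValueError("purity_attenuation must lie in (0, 1]")
        if not 0 <= self.low_purity_fraction < 1:
            raise ValueError("low_purity_fraction must lie in [0, 1)")
        if self.cnv_dose_response < 0:
            raise ValueError("cnv_dose_response (gamma) must be non-negative")
        if self.dme_repression >= 0:
            raise ValueError("dme_repression (beta) must be negative")
        names = {g.name for g in self.groups}
        for m in self.modules:
            for a, b in m.gene_ranges:
                if not (0 <= a < b <= self.n_genes):
                    raise ValueError(f"module {m.name}: range ({a},{b}) outside gene axis")
            unknown = set(m.group_levels) - names
            if unknown:
                raise ValueError(f"module {m.name}: unknown groups {unknown}")


@dataclass
class GroundTruth:
    """What was planted: per-gene module membership, per-sample group,
    purity and true hazard multiplier."""

    gene_modules: dict[str, tuple[str, ...]]
    samples: pd.DataFrame  # index sample_id; columns group, purity, hazard
    config: SyntheticConfig

    def module_genes(self, name: str) -> tuple[str, ...]:
        return tuple(g for g, mods in self.gene_modules.items() if name in mods)


def generate(config: SyntheticConfig, seed: int = 0) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Draw one cohort.  Deterministic for a given (config, seed)."""
    config.validate()
    rng = np.random.default_rng(seed)
    n_g, n_s = config.n_genes, config.n_samples
    gene_ids = tuple(f"G{i:05d}" for i in range(n_g))
    sample_ids = tuple(f"S{j:03d}" for j in range(n_s))
    group_of = np.concatenate(
        [np.full(g.size, gi) for gi, g in enumerate(config.groups)]
    )
    group_names = [config.groups[gi].name for gi in group_of]

    # low-purity samples: attenuated group effects, tagged NL-like
    n_low = int(round(config.low_purity_fraction * n_s))
    low_idx = rng.choice(n_s, size=n_low, replace=False) if n_low else np.array([], int)
    purity = np.ones(n_s)
    purity[low_idx] = config.purity_attenuation

    # deterministic mean structure -----------------------------------------
    cnv_sig = np.zeros((n_g, n_s))
    dme_sig = np.zeros((n_g, n_s))
    gex_sig = np.zeros((n_g, n_s))
    gene_modules: dict[str, list[str]] = {g: [] for g in gene_ids}
    for m in config.modules:
        idx = m.gene_indices()
        level = np.array([m.group_levels.get(config.groups[gi].name, 0.0) for gi in group_of])
        # per-gene effect multipliers: member genes respond with different
        # strengths (probe effects, dosage sensitivity)
        s = config.module_loading_spread
        loading = rng.uniform(1.0 - s, 1.0 + s, size=len(idx)) if s > 0 else np.ones(len(idx))
        effect = np.outer(loading, level)  # genes x samples
        if m.kind == "cnv":
            cnv_sig[idx] += effect
            gex_sig[idx] += config.cnv_dose_response * effect
        elif m.kind == "repressive":
            dme_sig[idx] += effect
            gex_sig[idx] += config.dme_repression * effect
        elif m.kind == "gex":
            gex_sig[idx] += effect
        else:
            raise ValueError(f"unknown module kind {m.kind!r}")
        for i in idx:
            gene_modules[gene_ids[i]].append(m.name)

    # global methylation gradient with per-gene susceptibility
    susceptibility = rng.uniform(0.0, 1.0, size=n_g)
    grad_level = np.array([config.groups[gi].methylation_gradient for gi in group_of])
    dme_sig += config.gradient_amplitude * np.outer(susceptibility, grad_level)

    # purity attenuation applies to every group-driven effect
    cnv_sig *= purity[None, :]
    dme_sig *= purity[None, :]
    gex_sig *= purity[None, :]

    # gene-specific baselines (removed again by centralization)
    gex_base = rng.normal(8.0, 2.0, size=n_g)
    dme_base = rng.normal(-2.0, 1.5, size=n_g)

    def noisy(sig: np.ndarray, base: np.ndarray | None, mod: Modality) -> np.ndarray:
        sd = config.noise_sd[mod]
        noise = rng.normal(0.0, sd, size=(n_g, n_s)) if sd > 0 else 0.0
        out = sig + noise
        if base is not None:
            out = out + base[:, None]
        return out

    gex = OmicsMatrix(Modality.GEX, gene_ids, sample_ids, noisy(gex_sig, gex_base, Modality.GEX))
    dme = OmicsMatrix(Modality.DME, gene_ids, sample_ids, noisy(dme_sig, dme_base, Modality.DME))
    cnv = OmicsMatrix(Modality.CNV, gene_ids, sample_ids, noisy(cnv_sig, None, Modality.CNV))

    # survival: exponential with group hazard multipliers, censored at censor_time
    hazard = np.array([config.groups[gi].hazard for gi in group_of]) * config.survival_base_rate
    t_true = rng.exponential(1.0 / hazard)
    event = t_true <= config.censor_time
    time = np.minimum(t_true, config.censor_time)

    annotations = [
        SampleAnnotation(
            sample_id=s,
            group_label=group_names[j],
            subtype_labels={"purity": "NL-like" if purity[j] < 1 else "tumour"},
            survival_time=float(time[j]),
            event=bool(event[j]),
        )
        for j, s in enumerate(sample_ids)
    ]
    gene_sets = [
        GeneSet(m.name, f"planted:{m.kind}", frozenset(gene_ids[i] for i in m.gene_indices()))
        for m in config.modules
    ]
    dataset = MultiOmicsDataset(gex, dme, cnv, annotations=annotations, gene_sets=gene_sets)
    truth = GroundTruth(
        gene_modules={g: tuple(v) for g, v in gene_modules.items()},
        samples=pd.DataFrame(
            {"group": group_names, "purity": purity, "hazard": hazard / config.survival_base_rate},
            index=list(sample_ids),
        ),
        config=config,
    )
    return dataset, truth


def default_config() -> SyntheticConfig:
    """The default study cohort: 2000 genes, 120 samples, three genetic
    groups and five planted modules.

    - ``IDH-wt-like`` (40): a Chr7-like arm gain and a Chr10-like arm
      loss, a strong repressive hypermethylation module, lowest global
      methylation, hazard x3.
    - ``IDH-A-like`` (50): intermediate methylation gradient and a
      TF-driven pure-expression module.
    - ``IDH-O-like`` (30): two co-deleted segments (Chr1p/19q-like) and
      the highest methylation gradient.
    """
    groups = (
        GroupSpec("IDH-wt-like", 40, methylation_gradient=0.0, hazard=3.0),
        GroupSpec("IDH-A-like", 50, methylation_gradient=0.6, hazard=1.0),
        GroupSpec("IDH-O-like", 30, methylation_gradient=1.0, hazard=1.0),
    )
    modules = (
        PlantedModule("chr7-like-gain", "cnv", ((0, 180),), {"IDH-wt-like": 1.0}),
        PlantedModule("chr10-like-loss", "cnv", ((200, 380),), {"IDH-wt-like": -1.0}),
        PlantedModule(
            "chr1p19q-like-codel", "cnv", ((420, 510), (540, 630)), {"IDH-O-like": -1.0}
        ),
        PlantedModule("rtk-like-hyperMe", "repressive", ((700, 780),), {"IDH-wt-like": 1.5}),
        PlantedModule("tf-cycling", "gex", ((950, 1030),), {"IDH-A-like": 1.2}),
    )
    return SyntheticConfig(n_genes=2000, groups=groups, modules=modules)


def default_cohort(seed: int = 7) -> tuple[MultiOmicsDataset, GroundTruth]:
    """The fixture cohort used throughout the test suite."""
    return generate(default_config(), seed=seed)
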