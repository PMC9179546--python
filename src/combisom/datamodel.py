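"""Core domain types and text-format I/O.

The analysis operates on three patient-matched gene-by-sample score
matrices — gene expression (Gex, log scale), promoter DNA methylation
(Dme) and gene-centric copy-number variation (CNV) — together with a
sample annotation table (group label, survival) and gene-set
collections in GMT format.  Everything downstream assumes the three
matrices share one gene order and one sample order; :func:`align_dataset`
establishes that contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Modality",
    "MODALITIES",
    "OmicsMatrix",
    "SampleAnnotation",
    "GeneSet",
    "MultiOmicsDataset",
    "WeightConfig",
    "WEIGHT_PRESETS",
    "weight_preset",
    "read_omics_matrix",
    "write_omics_matrix",
    "read_annotations",
    "write_annotations",
    "read_gmt",
    "write_gmt",
    "align_dataset",
]


class Modality(str, Enum):
    """The three omics layers handled by the combined portrayal."""

    GEX = "Gex"
    DME = "Dme"
    CNV = "CNV"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical block order used everywhere (combined vectors, decomposition).
MODALITIES: tuple[Modality, ...] = (Modality.GEX, Modality.DME, Modality.CNV)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what}: {', '.join(map(str, dups))}")


@dataclass
class OmicsMatrix:
    """One modality's gene-by-sample score matrix.

    ``values[i, j]`` is the score of gene ``gene_ids[i]`` in sample
    ``sample_ids[j]``.  ``centralized`` records that every gene row has
    zero mean across samples; ``harmonized`` that the global standard
    deviation of all entries is 1 (cross-modality scale equalization).
    """

    modality: Modality
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    centralized: bool = False
    harmonized: bool = False

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.gene_ids = tuple(map(str, self.gene_ids))
        self.sample_ids = tuple(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene IDs")
        _check_unique(self.sample_ids, "sample IDs")
        if self.centralized and self.values.size:
            rm = np.abs(self.values.mean(axis=1))
            if rm.size and rm.max() > 1e-9:
                raise ValueError("centralized flag set but a gene row mean exceeds 1e-9")
        if self.harmonized and self.values.size:
            sd = float(self.values.std())
            if not (abs(sd - 1.0) < 1e-6 or sd == 0.0):
                raise ValueError("harmonized flag set but global SD is neither 1 nor 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def subset(
        self,
        gene_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "OmicsMatrix":
        """Row/column restriction in the requested order (flags are kept only
        when they remain valid, i.e. never after a sample subset)."""
        genes = tuple(gene_ids) if gene_ids is not None else self.gene_ids
        samples = tuple(sample_ids) if sample_ids is not None else self.sample_ids
        gi = {g: k for k, g in enumerate(self.gene_ids)}
        si = {s: k for k, s in enumerate(self.sample_ids)}
        rows = [gi[g] for g in genes]
        cols = [si[s] for s in samples]
        same_samples = samples == self.sample_ids
        return OmicsMatrix(
            self.modality,
            genes,
            samples,
            self.values[np.ix_(rows, cols)],
            centralized=self.centralized and same_samples,
            harmonized=False if not same_samples else self.harmonized and gene_ids is None,
        )


@dataclass
class SampleAnnotation:
    """Clinical metadata for one sample; consumed, never computed."""

    sample_id: str
    group_label: str
    subtype_labels: dict[str, str] = field(default_factory=dict)
    survival_time: float | None = None  # months
    event: bool | None = None  # death observed

    def __post_init__(self) -> None:
        if self.survival_time is not None and self.survival_time < 0:
            raise ValueError(f"negative survival time for {self.sample_id}")
        if self.survival_time is None and self.event is not None:
            raise ValueError(f"event flag without survival time for {self.sample_id}")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (GMT semantics)."""

    name: str
    category: str
    member_gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_gene_ids:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass
class WeightConfig:
    """Mixing weights of the three omics blocks in the combined vectors.

    Must be non-negative and sum to 1; a zero weight switches the
    corresponding modality off ("bi-variant" setting).
    """

    w_e: float
    w_m: float
    w_c: float

    def __post_init__(self) -> None:
        w = (self.w_e, self.w_m, self.w_c)
        if any(x < 0 or x > 1 for x in w):
            raise ValueError(f"weights must lie in [0, 1], got {w}")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got sum {sum(w)!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_e, self.w_m, self.w_c], dtype=float)

    def weight_of(self, modality: Modality) -> float:
        return {Modality.GEX: self.w_e, Modality.DME: self.w_m, Modality.CNV: self.w_c}[
            Modality(modality)
        ]


WEIGHT_PRESETS: dict[str, tuple[float, float, float]] = {
    "balanced": (1 / 3, 1 / 3, 1 / 3),
    "gex-dominant": (0.99, 0.005, 0.005),
    "dme-dominant": (0.005, 0.99, 0.005),
    "cnv-dominant": (0.005, 0.005, 0.99),
    "gex-dme-bivariant": (0.5, 0.5, 0.0),
}


def weight_preset(name: str) -> WeightConfig:
    """Look up a named weight preset.

    Dominant presets use minor weights 0.005 so that the sum-to-1
    constraint holds; the occasionally quoted minor weight of 0.0005
    would give a total of 0.991 and is therefore not offered.
    """
    try:
        w = WEIGHT_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown weight preset {name!r}; available: {sorted(WEIGHT_PRESETS)}"
        ) from None
    if name.endswith("-dominant"):
        logger.info(
            "preset %s uses minor weights 0.005 (not 0.0005) so that the weights sum to 1",
            name,
        )
    return WeightConfig(*w)


@dataclass
class MultiOmicsDataset:
    """Three aligned matrices plus annotations and gene sets."""

    gex: OmicsMatrix
    dme: OmicsMatrix
    cnv: OmicsMatrix
    annotations: list[SampleAnnotation] = field(default_factory=list)
    gene_sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ref_g, ref_s = self.gex.gene_ids, self.gex.sample_ids
        for m in (self.dme, self.cnv):
            if m.gene_ids != ref_g or m.sample_ids != ref_s:
                raise ValueError(
                    "matrices are not aligned: gene/sample indices differ "
                    f"between Gex and {m.modality}"
                )
        known = set(ref_s)
        for a in self.annotations:
            if a.sample_id not in known:
                raise ValueError(f"annotation for unknown sample {a.sample_id!r}")
        names = [g.name for g in self.gene_sets]
        _check_unique(names, "gene-set names")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return self.gex.gene_ids

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.gex.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def matrix(self, modality: Modality) -> OmicsMatrix:
        return {
            Modality.GEX: self.gex,
            Modality.DME: self.dme,
            Modality.CNV: self.cnv,
        }[Modality(modality)]

    def matrices(self) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix]:
        return (self.gex, self.dme, self.cnv)

    def groups(self) -> dict[str, list[str]]:
        """Group label -> ordered member sample IDs (annotation order
        follows the dataset's sample order)."""
        by_id = {a.sample_id: a.group_label for a in self.annotations}
        out: dict[str, list[str]] = {}
        for s in self.sample_ids:
            if s in by_id:
                out.setdefault(by_id[s], []).append(s)
        return out

    def survival_frame(self) -> pd.DataFrame:
        """Samples with survival data as a (time, event) frame, indexed by
        sample ID in dataset order."""
        rows = {
            a.sample_id: (float(a.survival_time), bool(a.event))
            for a in self.annotations
            if a.survival_time is not None and a.event is not None
        }
        ordered = [s for s in self.sample_ids if s in rows]
        return pd.DataFrame(
            [rows[s] for s in ordered], index=ordered, columns=["time", "event"]
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_omics_matrix(path: str | Path, modality: Modality) -> OmicsMatrix:
    """Read a gene-by-sample TSV (first column gene IDs, header sample IDs).

    Missing cells are imputed with the gene-row mean; rows that are
    entirely missing are dropped with a warning.  Duplicate gene IDs or
    non-numeric cells raise with the offending address.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = [str(g) for g in df.index]
    _check_unique(genes, f"gene IDs in {path}")
    converted = {}
    for col in df.columns:
        conv = pd.to_numeric(df[col], errors="coerce")
        bad = conv.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        bad &= ~df[col].astype(str).str.upper().isin({"NA", "NAN", "NULL"})
        if bad.any():
            g = df.index[bad.values][0]
            raise ValueError(
                f"non-numeric cell in {path}: gene {g!r}, sample {col!r}, "
                f"value {df.loc[g, col]!r}"
            )
        converted[col] = conv
    numeric = pd.DataFrame(converted, index=df.index)
    all_na = numeric.isna().all(axis=1)
    if all_na.any():
        dropped = list(numeric.index[all_na])
        logger.warning(
            "%s: dropping %d all-missing gene row(s): %s",
            path,
            len(dropped),
            ", ".join(map(str, dropped[:10])),
        )
        numeric = numeric.loc[~all_na]
    if numeric.isna().any().any():
        row_means = numeric.mean(axis=1)
        numeric = numeric.apply(lambda r: r.fillna(row_means[r.name]), axis=1)
    return OmicsMatrix(
        Modality(modality),
        tuple(map(str, numeric.index)),
        tuple(map(str, numeric.columns)),
        numeric.to_numpy(dtype=float),
    )


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write a matrix in the same TSV dialect (10 significant digits)."""
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read the sample annotation TSV (sample_id, group[, time, event])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        time = row.get("time")
        has_time = time is not None and pd.notna(time)
        ev = row.get("event")
        out.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                group_label=str(row["group"]),
                survival_time=float(time) if has_time else None,
                event=bool(int(ev)) if has_time and pd.notna(ev) else None,
            )
        )
    return out


def write_annotations(annotations: Iterable[SampleAnnotation], path: str | Path) -> None:
    rows = [
        {
            "sample_id": a.sample_id,
            "group": a.group_label,
            "time": a.survival_time if a.survival_time is not None else "",
            "event": int(a.event) if a.event is not None else "",
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets in GMT dialect: name TAB description TAB members...

    The description field is used as the set category.  Lines with fewer
    than three fields raise with their line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), needs >= 3"
                )
            name, category, *members = fields
            members = [m for m in members if m.strip()]
            sets.append(GeneSet(name, category, frozenset(members)))
    if not sets:
        logger.warning("%s: empty GMT file, no gene sets read", path)
    _check_unique([s.name for s in sets], "gene-set names")
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in gene_sets:
            fh.write("\t".join([s.name, s.category, *sorted(s.member_gene_ids)]) + "\n")


def align_dataset(
    gex: OmicsMatrix,
    dme: OmicsMatrix,
    cnv: OmicsMatrix,
    annotations: Iterable[SampleAnnotation] = (),
    gene_sets: Iterable[GeneSet] = (),
) -> MultiOmicsDataset:
    """Restrict the three matrices to their common genes and samples.

    Order follows the Gex matrix.  Annotations referring to dropped
    samples are discarded with a warning.  Raises if the gene or sample
    intersection is empty.
    """
    for m in (gex, dme, cnv):
        if m.n_genes == 0 or m.n_samples == 0:
            raise ValueError(f"empty {m.modality} matrix")
    gsets = [set(m.gene_ids) for m in (gex, dme, cnv)]
    ssets = [set(m.sample_ids) for m in (gex, dme, cnv)]
    common_g = gsets[0] & gsets[1] & gsets[2]
    common_s = ssets[0] & ssets[1] & ssets[2]
    if not common_g:
        raise ValueError("empty gene intersection across modalities")
    if not common_s:
        raise ValueError("empty sample intersection across modalities")
    genes = tuple(g for g in gex.gene_ids if g in common_g)
    samples = tuple(s for s in gex.sample_ids if s in common_s)
    for m in (gex, dme, cnv):
        dg, ds = m.n_genes - len(genes), m.n_samples - len(samples)
        if dg or ds:
            logger.info("align: dropped %d gene(s), %d sample(s) from %s", dg, ds, m.modality)
    kept, skipped = [], []
    for a in annotations:
        (kept if a.sample_id in common_s else skipped).append(a)
    if skipped:
        logger.warning(
            "align: discarding %d annotation(s) for samples absent from the data", len(skipped)
        )
    return MultiOmicsDataset(
        gex.subset(genes, samples),
        dme.subset(genes, samples),
        cnv.subset(genes, samples),
        annotations=kept,
        gene_sets=list(gene_sets),
    )
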