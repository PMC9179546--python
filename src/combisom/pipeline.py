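"""End-to-end workflow: ingest -> preprocess -> train -> maps -> tables.

Driven by a YAML/dict config; every stage writes plain-text artifacts
into the output directory and a ``manifest.json`` records input
checksums, the effective configuration and the artifact list so a rerun
with the same config is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import group_agreement, portrait_correlation_matrix, similarity_network
from .datamodel import (
    MODALITIES,
    Modality,
    WeightConfig,
    align_dataset,
    read_annotations,
    read_gmt,
    read_omics_matrix,
    weight_preset,
)
from .genesets import gsz, ternary_coordinates
from .portraits import group_portraits, sample_portrait, variance_map, write_portrait_tsv
from .preprocess import centralize_dataset, combine, decompose, harmonize
from .prognosis import hr_map
from .scov import scov_group
from .som import population_map, train_som, write_model
from .spots import spot_frequencies, spot_profiles, spot_summary_map
from .synthetic import default_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _resolve_weights(value: Any) -> WeightConfig:
    if value is None:
        return weight_preset("balanced")
    if isinstance(value, str):
        return weight_preset(value)
    return WeightConfig(*[float(x) for x in value])


def _ingest(cfg: dict, manifest: dict):
    inp = cfg.get("input", {})
    if "synthetic" in inp:
        seed = int(inp["synthetic"].get("seed", 7))
        dataset, _ = default_cohort(seed=seed)
        manifest["inputs"] = {"synthetic": {"seed": seed}}
        return dataset
    paths = {k: Path(inp[k]) for k in ("gex", "dme", "cnv")}
    for k, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing input {k}: {p}")
    ann_path = inp.get("annotations")
    gmt_path = inp.get("gene_sets")
    for p in filter(None, (ann_path, gmt_path)):
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input: {p}")
    manifest["inputs"] = {
        k: {"path": str(p), "sha256": _sha256(p)} for k, p in paths.items()
    }
    mats = {k: read_omics_matrix(p, m) for (k, p), m in zip(paths.items(), MODALITIES)}
    annotations = read_annotations(ann_path) if ann_path else []
    gene_sets = read_gmt(gmt_path) if gmt_path else []
    if ann_path:
        manifest["inputs"]["annotations"] = {"path": str(ann_path), "sha256": _sha256(Path(ann_path))}
    if gmt_path:
        manifest["inputs"]["gene_sets"] = {"path": str(gmt_path), "sha256": _sha256(Path(gmt_path))}
    return align_dataset(mats["gex"], mats["dme"], mats["cnv"], annotations, gene_sets)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Execute the full portrayal workflow and return the output directory."""
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": cfg, "artifacts": []}
    timings: dict[str, float] = {}

    def artifact(path: Path) -> Path:
        manifest["artifacts"].append(str(path.relative_to(out)))
        return path

    # pre-flight: weights validated before any computation
    weights = _resolve_weights(cfg.get("weights"))
    grid_side = int(cfg.get("grid_side", 45))
    seed = int(cfg.get("seed", 0))
    threshold = float(cfg.get("threshold_fraction", 0.9))
    min_group = int(cfg.get("min_group", 5))
    np.random.seed(seed % 2**31)  # libraries that use global state

    t0 = _time.perf_counter()
    dataset = _ingest(cfg, manifest)
    timings["ingest"] = _time.perf_counter() - t0
    logger.info(
        "ingested %d genes x %d samples", len(dataset.gene_ids), dataset.n_samples
    )

    t0 = _time.perf_counter()
    harmonized = harmonize(centralize_dataset(dataset))
    profiles = combine(harmonized, weights)
    timings["preprocess"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    model = train_som(profiles, grid_side=grid_side, seed=seed)
    write_model(model, artifact(out / "model.h5"))
    timings["train"] = _time.perf_counter() - t0
    logger.info("trained %dx%d map (seed %d)", grid_side, grid_side, seed)

    decomposed = decompose(model)
    groups = dataset.groups()
    gs = model.grid_side

    # portraits and variance maps
    t0 = _time.perf_counter()
    np.savetxt(
        artifact(out / "population_map.tsv"), population_map(model), fmt="%d", delimiter="\t"
    )
    gp_all = []
    for m in MODALITIES:
        if np.isnan(decomposed[m]).all():
            continue
        vm = variance_map(decomposed, m, gs)
        write_portrait_tsv(vm, artifact(out / f"variance_{m.value.lower()}.tsv"))
        for label, portrait in group_portraits(model, decomposed, groups, m).items():
            write_portrait_tsv(
                portrait, artifact(out / f"portrait_{m.value.lower()}_{label}.tsv")
            )
            gp_all.append(portrait)
    timings["portraits"] = _time.perf_counter() - t0

    # group ScoV maps for all pairs with both weights > 0
    t0 = _time.perf_counter()
    for a, b in ((Modality.GEX, Modality.DME), (Modality.GEX, Modality.CNV), (Modality.DME, Modality.CNV)):
        if np.isnan(decomposed[a]).all() or np.isnan(decomposed[b]).all():
            continue
        for label, members in groups.items():
            if len(members) < 2:
                continue
            p = scov_group(
                decomposed[a], decomposed[b], dataset.sample_ids, members, gs,
                label=label, kinds=(a.value, b.value),
            )
            write_portrait_tsv(
                p,
                artifact(out / f"scov_{a.value.lower()}_{b.value.lower()}_{label}.tsv"),
            )
    timings["scov"] = _time.perf_counter() - t0

    # spot modules
    t0 = _time.perf_counter()
    label_grid, spot_list = spot_summary_map(gp_all, model, threshold, min_size=int(cfg.get("min_size", 3)))
    np.savetxt(artifact(out / "spot_labels.tsv"), label_grid, fmt="%d", delimiter="\t")
    rows = []
    for s in spot_list:
        rows.append(
            {
                "label": s.label,
                "sign": s.sign,
                "n_units": s.n_units,
                "n_genes": len(s.member_genes),
                "dominant_modality": s.dominant_modality.value if s.dominant_modality else "",
                "genes": ";".join(s.member_genes),
            }
        )
    pd.DataFrame(rows).to_csv(artifact(out / "spots.tsv"), sep="\t", index=False)
    # spot frequency distributions per modality
    freq_rows = []
    for m in MODALITIES:
        if np.isnan(decomposed[m]).all():
            continue
        sp = {s: sample_portrait(model, decomposed, s, m) for s in dataset.sample_ids}
        table = spot_frequencies(sp, groups, threshold)
        for g, dist in table.fractions.items():
            for count, frac in dist.items():
                freq_rows.append(
                    {"modality": m.value, "group": g, "n_spots": count, "fraction": frac}
                )
    pd.DataFrame(freq_rows).to_csv(artifact(out / "spot_frequencies.tsv"), sep="\t", index=False)
    timings["spots"] = _time.perf_counter() - t0

    # gene-set scoring
    t0 = _time.perf_counter()
    if dataset.gene_sets:
        centered = harmonized  # centralized and harmonized
        long_rows = []
        ternary_rows = []
        for gset in dataset.gene_sets:
            results = {}
            for m in MODALITIES:
                try:
                    res = gsz(centered.matrix(m), gset)
                except KeyError:
                    continue
                results[m] = res
                for sid, score in zip(res.sample_ids, res.scores):
                    long_rows.append(
                        {"set": gset.name, "modality": m.value, "sample": sid, "gsz": score}
                    )
            if len(results) == 3:
                tern = ternary_coordinates(*(results[m] for m in MODALITIES))
                for j, sid in enumerate(tern.sample_ids):
                    ternary_rows.append(
                        {
                            "set": gset.name,
                            "sample": sid,
                            "p_gex": tern.percentages[j, 0],
                            "p_dme": tern.percentages[j, 1],
                            "p_cnv": tern.percentages[j, 2],
                            "signs": "".join(
                                {1: "+", 0: "0", -1: "-"}[int(x)] for x in tern.signs[j]
                            ),
                        }
                    )
        pd.DataFrame(long_rows).to_csv(artifact(out / "gsz.tsv"), sep="\t", index=False)
        pd.DataFrame(ternary_rows).to_csv(artifact(out / "ternary.tsv"), sep="\t", index=False)
    timings["genesets"] = _time.perf_counter() - t0

    # prognosis
    t0 = _time.perf_counter()
    survival = dataset.survival_frame()
    if len(survival) >= 2 * min_group and survival["event"].any():
        for m in MODALITIES:
            if np.isnan(decomposed[m]).all():
                continue
            hm = hr_map(decomposed[m], dataset.sample_ids, survival, m, min_group, gs)
            np.savetxt(
                artifact(out / f"hr_{m.value.lower()}.tsv"), hm.hr, delimiter="\t", fmt="%.10g"
            )
    timings["prognosis"] = _time.perf_counter() - t0

    # sample-space similarity
    t0 = _time.perf_counter()
    for m in MODALITIES:
        if np.isnan(decomposed[m]).all():
            continue
        corr = portrait_correlation_matrix(decomposed[m], dataset.sample_ids)
        corr.to_csv(artifact(out / f"correlation_{m.value.lower()}.tsv"), sep="\t")
        if corr.notna().all().all() and corr.shape[0] > int(cfg.get("network_k", 3)):
            g, pos = similarity_network(corr, k=int(cfg.get("network_k", 3)), seed=seed)
            pd.DataFrame(
                [(u, v, d["weight"]) for u, v, d in g.edges(data=True)],
                columns=["a", "b", "corr"],
            ).to_csv(artifact(out / f"network_{m.value.lower()}.tsv"), sep="\t", index=False)
            pd.DataFrame(
                {s: p for s, p in pos.items()}, index=["x", "y"]
            ).T.to_csv(artifact(out / f"layout_{m.value.lower()}.tsv"), sep="\t")
            if groups:
                _, ari = group_agreement(corr, groups)
                logger.info("%s portrait clusters vs groups: ARI %.3f", m.value, ari)
    timings["cohort"] = _time.perf_counter() - t0

    manifest["timings_note"] = "per-stage wall times logged, not stored (manifest is config-deterministic)"
    for stage, dt in timings.items():
        logger.info("stage %-10s %6.2f s", stage, dt)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    # every declared artifact must exist and be non-empty
    for rel in manifest["artifacts"]:
        p = out / rel
        if not p.exists() or p.stat().st_size == 0:
            raise RuntimeError(f"artifact {rel} missing or empty")
    return out
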