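"""Pipeline orchestration and report rendering.

`run_pipeline` chains the stages — filtering, specificity assignment,
marker-set quantification, ORF statistics, repeat counting, HCPC — over one
validated configuration and collects every stage's outputs plus a manifest
(parameters, seed, per-stage row counts, content hashes of written files).
`render_reports` writes the composition grid, the SNP-category tallies, the
repeat histograms and the clustering outputs as TSV/JSON files.

Inputs may be given as paths (TSV/VCF/FASTA/GFF3) or as already-built
in-memory objects; the analysis drivers under ``analysis/`` use the latter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import composition, hcpc, orf_stats, pe38_repeats, specificity
from .snpio import (
    IsolatePanel,
    OrfRecord,
    ReferenceGenome,
    SnpMatrix,
    read_annotation,
    read_count_table,
    read_reference,
    read_vcf_counts,
)
from .variant_filter import FilterConfig, FilteredMatrix, apply_filters, flag_reference_anomalies

logger = logging.getLogger("gvpop")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    counts: str | Path | SnpMatrix
    reference: str | Path | ReferenceGenome | None = None
    annotation: str | Path | Sequence[OrfRecord] | None = None
    panel: IsolatePanel | None = None
    reads: Mapping[str, object] | None = None  # isolate -> FASTQ path / sequences
    repeat_spec: pe38_repeats.RepeatRegionSpec | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    statistic: str = "median"
    specificity_within_role: str | None = "field"
    reference_isolate: str | None = None
    n_components: int = 7
    k: int = 6
    scale: bool = True
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        for attr in ("counts", "reference", "annotation"):
            val = getattr(self, attr)
            if isinstance(val, (str, Path)) and not Path(val).exists():
                raise FileNotFoundError(f"{attr} file {val} does not exist")


@dataclass
class PipelineBundle:
    config: PipelineConfig
    filtered: FilteredMatrix
    assignment: specificity.SpecificityAssignment
    marker_sets: list[specificity.MarkerSet]
    quantifications: list[composition.MarkerSetQuantification]
    anomalies: list[int]
    effects: list | None
    tallies: dict | None
    histograms: list[pe38_repeats.RepeatHistogram]
    pca: hcpc.PcaResult
    hclust: hcpc.HclustResult
    hcpc_result: hcpc.HcpcResult
    manifest: dict


def _load_counts(cfg: PipelineConfig) -> SnpMatrix:
    if isinstance(cfg.counts, SnpMatrix):
        return cfg.counts
    path = Path(cfg.counts)
    if path.suffix.lower() in (".vcf",):
        return read_vcf_counts(path)
    return read_count_table(path)


def run_pipeline(cfg: PipelineConfig) -> PipelineBundle:
    manifest: dict = {
        "seed": cfg.seed,
        "parameters": {
            "min_total_depth": cfg.filter_config.min_total_depth,
            "min_alt_count": cfg.filter_config.min_alt_count,
            "min_freq": cfg.filter_config.min_freq,
            "freq_applies": cfg.filter_config.freq_applies,
            "statistic": cfg.statistic,
            "n_components": cfg.n_components,
            "k": cfg.k,
            "scale": cfg.scale,
        },
        "stages": {},
    }

    def stage(name):
        logger.info("[%s] running", name)
        return name

    name = stage("load")
    try:
        matrix = _load_counts(cfg)
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, str(exc)) from exc
    manifest["stages"]["load"] = {
        "n_sites": matrix.n_sites, "n_isolates": len(matrix.isolates),
    }

    name = stage("filter")
    try:
        filtered = apply_filters(matrix, cfg.filter_config)
        anomalies = (
            flag_reference_anomalies(filtered) if len(filtered.isolates) > 1 else []
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, str(exc)) from exc
    manifest["stages"]["filter"] = {
        "n_retained": filtered.n_sites,
        "n_reference_anomalies": len(anomalies),
    }

    name = stage("specificity")
    try:
        within = None
        if cfg.specificity_within_role and cfg.panel is not None:
            within = [
                i for i in cfg.panel.ids(cfg.specificity_within_role)
                if i in filtered.isolates
            ]
        assignment = specificity.assign_specificity(filtered, within=within)
        marker_sets = specificity.build_marker_sets(assignment)
        if cfg.reference_isolate:
            ref_set = specificity.reference_marker_set(
                assignment, cfg.reference_isolate, marker_sets
            )
            if ref_set is not None:
                marker_sets = [
                    ref_set if s.label == ref_set.label else s for s in marker_sets
                ]
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, str(exc)) from exc
    manifest["stages"]["specificity"] = {
        "n_marker_sets": len(marker_sets),
        "n_isolate_specific": sum(1 for s in marker_sets if len(s.label) == 1),
    }

    name = stage("composition")
    try:
        quants = composition.quantify(
            filtered, marker_sets, statistic=cfg.statistic
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, str(exc)) from exc
    manifest["stages"]["composition"] = {"n_cells": len(quants)}

    effects = None
    tallies = None
    if cfg.annotation is not None:
        name = stage("orf_stats")
        try:
            if cfg.reference is None:
                raise ValueError("orf_stats requested but no reference given")
            reference = (
                cfg.reference
                if isinstance(cfg.reference, ReferenceGenome)
                else read_reference(cfg.reference)
            )
            annotation = (
                list(cfg.annotation)
                if not isinstance(cfg.annotation, (str, Path))
                else read_annotation(cfg.annotation, reference.length,
                                     reference.circular)
            )
            effects = orf_stats.classify_all(
                filtered.positions, filtered.ref_bases, filtered.alt_bases,
                annotation, reference,
            )
            tallies = orf_stats.category_tallies(effects)
        except Exception as exc:  # noqa: BLE001
            raise StageError(name, str(exc)) from exc
        manifest["stages"]["orf_stats"] = dict(tallies)

    histograms: list[pe38_repeats.RepeatHistogram] = []
    if cfg.reads:
        name = stage("repeats")
        try:
            if cfg.repeat_spec is None:
                raise ValueError("reads given but no repeat region spec")
            for isolate, source in cfg.reads.items():
                histograms.append(
                    pe38_repeats.count_repeats(source, cfg.repeat_spec, isolate)
                )
        except Exception as exc:  # noqa: BLE001
            raise StageError(name, str(exc)) from exc
        manifest["stages"]["repeats"] = {
            h.isolate: h.total_informative for h in histograms
        }

    name = stage("hcpc")
    try:
        freq = hcpc.frequency_matrix(filtered)
        pca = hcpc.run_pca(freq, scale=cfg.scale)
        ncomp = min(cfg.n_components, pca.n_components)
        hclust = hcpc.hierarchical_cluster(pca, n_components=ncomp)
        k = min(cfg.k, len(filtered.isolates))
        result = hcpc.cut_and_consolidate(hclust, k=k)
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, str(exc)) from exc
    manifest["stages"]["hcpc"] = {
        "n_components": ncomp,
        "cumulative_percent": round(pca.cumulative_at(ncomp), 4),
        "suggested_k": hclust.suggested_k,
        "k": k,
    }

    bundle = PipelineBundle(
        config=cfg, filtered=filtered, assignment=assignment,
        marker_sets=marker_sets, quantifications=quants, anomalies=anomalies,
        effects=effects, tallies=tallies, histograms=histograms,
        pca=pca, hclust=hclust, hcpc_result=result, manifest=manifest,
    )
    if cfg.out_dir is not None:
        render_reports(bundle, cfg.out_dir)
    return bundle


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def composition_grid(bundle: PipelineBundle, min_set_size: int = 1) -> pd.DataFrame:
    """Isolates x marker-set grid of ``median (p5–p95)`` cells."""
    cells: dict[tuple[str, str], str] = {}
    set_names = []
    for q in bundle.quantifications:
        if q.n_snps < min_set_size:
            continue
        name = q.set_name or "+".join(q.label)
        col = f"{name} ({q.n_snps})"
        if col not in set_names:
            set_names.append(col)
        cells[(q.isolate, col)] = q.format_cell()
    isolates = list(bundle.filtered.isolates)
    grid = pd.DataFrame(index=isolates, columns=set_names, dtype=object)
    for (iso, col), text in cells.items():
        grid.loc[iso, col] = text
    grid.index.name = "isolate"
    return grid


def render_reports(bundle: PipelineBundle, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    grid = composition_grid(bundle, min_set_size=20)
    path = out / "table2.tsv"
    grid.to_csv(path, sep="\t")
    written.append(path)

    if bundle.tallies is not None:
        path = out / "fig1_counts.tsv"
        pd.Series(bundle.tallies).rename("count").to_csv(path, sep="\t")
        written.append(path)

    path = out / "fig4_repeats.tsv"
    pe38_repeats.summarize_panel(bundle.histograms).to_csv(path, sep="\t", index=False)
    written.append(path)

    path = out / "fig5_variance.tsv"
    pd.DataFrame(
        {
            "component": np.arange(1, bundle.pca.n_components + 1),
            "percent_variance": bundle.pca.percent_variance,
            "cumulative_percent": bundle.pca.cumulative_percent,
        }
    ).to_csv(path, sep="\t", index=False)
    written.append(path)

    path = out / "tree.nwk"
    path.write_text(
        hcpc.export_tree(bundle.hclust.linkage, list(bundle.hclust.labels)) + "\n"
    )
    written.append(path)

    path = out / "assignments.tsv"
    pd.DataFrame(
        {
            "isolate": bundle.hcpc_result.assignments.index,
            "cluster_tree": bundle.hcpc_result.assignments_tree.to_numpy(),
            "cluster": bundle.hcpc_result.assignments.to_numpy(),
            "dim1": bundle.hcpc_result.factor_map.iloc[:, 0].to_numpy(),
            "dim2": bundle.hcpc_result.factor_map.iloc[:, 1].to_numpy()
            if bundle.hcpc_result.factor_map.shape[1] > 1
            else np.zeros(len(bundle.hcpc_result.assignments)),
        }
    ).to_csv(path, sep="\t", index=False)
    written.append(path)

    path = out / "specificity.tsv"
    pd.DataFrame(
        {
            "position": bundle.assignment.positions,
            "label": ["+".join(l) for l in bundle.assignment.labels],
        }
    ).to_csv(path, sep="\t", index=False)
    written.append(path)

    bundle.manifest["outputs"] = {p.name: _sha256(p) for p in written}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(bundle.manifest, indent=1, sort_keys=True))
    return bundle.manifest
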