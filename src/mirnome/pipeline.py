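"""End-to-end pipeline: simulate (or ingest) -> screen -> profile -> classify ->
qPCR -> network -> report bundle.

Every output table lands in the output directory as TSV/JSON, and a
``manifest.json`` records the seed, a hash of the configuration, per-stage
wall-clock timings, warnings, and the SHA-256 of every written file, so two
runs with the same seed can be compared by hash equality alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cross_disease, diffexp, io, network, qpcr, synthetic
from .classifier import classification_report, evaluate
from .errors import ConfigurationError

log = logging.getLogger("mirnome")

__all__ = ["run_all"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: io.PipelineConfig) -> str:
    from dataclasses import asdict

    return hashlib.sha256(
        yaml.safe_dump(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_all(
    config: io.PipelineConfig,
    outdir: str | Path,
    design: synthetic.StudyDesign | None = None,
    signal: synthetic.PlantedSignalSpec | None = None,
) -> dict:
    """Run every stage on (by default) the package's simulated study.

    If ``config.paths`` names an expression/annotation pair those are ingested
    instead of simulating; qPCR and interaction tables are likewise read from
    ``config.paths`` when given, otherwise generated.  Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
        "files": {},
        "warnings": [],
    }
    written: list[Path] = []

    def _save(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    def _stage(name: str):
        log.info("stage %s", name)
        return _Timer(name, manifest)

    design = design or synthetic.default_study_design()
    signal = signal or synthetic.default_signal_spec(design)

    with _stage("simulate"):
        if "expression" in config.paths:
            matrix = io.read_expression(config.paths["expression"])
            annotation = io.read_annotation(config.paths["annotation"])
        else:
            matrix, annotation = synthetic.generate_cohort(design, signal, config.seed)
        io.validate_matrix_annotation(matrix, annotation)
        if not annotation["is_control"].any():
            raise ConfigurationError("no control samples in annotation")
        io.write_expression(matrix, outdir / "expression.tsv")
        io.write_annotation(annotation, outdir / "annotation.tsv")
        written.extend([outdir / "expression.tsv", outdir / "annotation.tsv"])

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        with _stage("diffexp"):
            disease = diffexp.run_comparison(
                matrix, annotation, "all-disease", "controls",
                alpha=config.alpha, equal_var=config.equal_var,
                n_boot=0, seed=config.seed,
            )
            cancer = diffexp.run_comparison(
                matrix, annotation, "all-cancer", "controls",
                alpha=config.alpha, equal_var=config.equal_var,
                n_boot=0, seed=config.seed,
            )
            _save(disease, "diffexp_disease_vs_control.tsv")
            _save(cancer, "diffexp_cancer_vs_control.tsv")

        with _stage("cross_disease"):
            profiles = cross_disease.per_disease_profiles(
                matrix, annotation, alpha=config.alpha, equal_var=config.equal_var
            )
            counts = profiles.counts.reset_index().rename(columns={"index": "feature_id"})
            _save(counts, "specificity_profiles.tsv")
            _save(
                cross_disease.balloon_table(profiles, config.balloon_min_total),
                "balloon.tsv",
            )
            markers = cross_disease.call_general_markers(
                profiles, min_diseases=config.general_marker_min
            )
            _save(markers, "general_markers.tsv")
            sigs = cross_disease.pairwise_signatures(
                matrix, annotation, alpha=config.alpha, equal_var=config.equal_var
            )
            _save(
                pd.DataFrame(
                    [
                        {"class_a": s.class_a, "class_b": s.class_b,
                         "n_significant": s.n_significant}
                        for s in sigs
                    ]
                ),
                "pairwise_signatures.tsv",
            )
            cc = cross_disease.comparison_counts(sigs)
            _save(
                cc.rename("n_comparisons").rename_axis("feature_id").reset_index(),
                "comparison_counts.tsv",
            )
            anova = cross_disease.anova_across_classes(
                matrix, annotation, alpha=config.alpha
            )
            _save(anova, "anova.tsv")

            sig_d = set(disease.loc[disease["significant"], "feature_id"])
            sig_c = set(cancer.loc[cancer["significant"], "feature_id"])
            only_d, shared, only_c = cross_disease.set_overlap(sig_d, sig_c)
            venn = {
                "disease_only": only_d,
                "shared": shared,
                "cancer_only": only_c,
                "auc_correlation": cross_disease.auc_correlation(disease, cancer),
            }
            (outdir / "venn.json").write_text(json.dumps(venn, indent=2))
            written.append(outdir / "venn.json")

        with _stage("classify"):
            ev = evaluate(config.classifier, matrix, annotation, "all-disease", "controls")
            report = classification_report(ev)
            _save(report["long"], "classifier_metrics.tsv")
            _save(report["roc"], "classifier_best_roc.tsv")
            _save(report["decisions"], "classifier_best_decisions.tsv")
            (outdir / "classifier_summary.json").write_text(
                json.dumps(report["best"], indent=2)
            )
            written.append(outdir / "classifier_summary.json")

        with _stage("qpcr"):
            if "qpcr" in config.paths:
                ct = io.read_qpcr(config.paths["qpcr"])
                control = config.paths.get("qpcr_control", "normal")
            else:
                qdesign = synthetic.default_qpcr_design()
                ct = synthetic.generate_qpcr(qdesign, config.seed)
                control = qdesign.control_label
            io.write_qpcr(ct, outdir / "qpcr_ct.tsv")
            written.append(outdir / "qpcr_ct.tsv")
            _save(qpcr.per_disease_qpcr(ct, control, alpha=config.alpha), "qpcr_results.tsv")

        with _stage("network"):
            query = markers["feature_id"].tolist()
            if "interactions" in config.paths:
                inter = io.read_interactions(config.paths["interactions"])
            else:
                inter = synthetic.generate_interactions(query, config.seed)
            graph = network.build_graph(inter, query, evidence_filter="reporter_assay")
            _save(network.graph_to_edges(graph), "network_edges.tsv")
            _save(network.hub_targets(graph, k=1), "network_degrees.tsv")
            universe = set(inter["gene_id"])
            if "gene_sets" in config.paths:
                sets = io.read_gmt(config.paths["gene_sets"])
            else:  # split the synthetic universe into decile gene sets
                genes = sorted(universe)
                sets = {
                    f"set_{i}": set(genes[i::10]) for i in range(10)
                }
            targets = network.targeted_genes(graph) & universe
            if universe:
                enrich = network.ora_hypergeometric(targets, sets, universe)
            else:  # no interactions for the called markers
                enrich = pd.DataFrame(
                    columns=["set_name", "overlap_count", "set_size",
                             "query_size", "universe_size", "p_raw", "p_adjusted"]
                )
            _save(enrich, "enrichment.tsv")

    manifest["warnings"] = [str(w.message) for w in caught]
    for path in written:
        manifest["files"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


class _Timer:
    def __init__(self, name: str, manifest: dict):
        self.name, self.manifest = name, manifest

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest["stages"][self.name] = round(time.perf_counter() - self.t0, 3)
        if exc is not None:
            log.error("stage %s failed: %s", self.name, exc)
            raise RuntimeError(f"pipeline stage {self.name!r} failed") from exc
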