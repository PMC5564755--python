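"""End-to-end orchestration: ingest -> cascade -> annotate -> associate -> report.

A :class:`RunConfig` (built directly or from YAML) names the inputs and
thresholds; :func:`run_pipeline` produces the nomination report, the
association table, chimeric peptides, the stage-count cascade log and
the clustering leaf order, all as TSV/FASTA under the output directory.
Given identical inputs the run is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import filters, io, junctions
from .records import CandidateRecord
from .stats import cluster_profiles, format_pvalue, normalize_differential

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """The run configuration is unusable (missing paths, bad thresholds)."""


@dataclass
class RunConfig:
    calls_dir: Path
    manifest: Path
    gtf: Path
    out_dir: Path
    fasta: Path | None = None
    gene_expression: Path | None = None
    exon_expression: Path | None = None
    thresholds: filters.FilterThresholds = field(default_factory=filters.FilterThresholds)
    distance_cap: int = 60_000
    dialect: dict[str, str] | None = None
    linkage: str = "average"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("calls_dir", "manifest", "gtf", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        for name in ("fasta", "gene_expression", "exon_expression"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        for name in ("calls_dir", "manifest", "gtf"):
            if not getattr(self, name).exists():
                raise ConfigError(f"{name} path does not exist: {getattr(self, name)}")
        for name in ("fasta", "gene_expression", "exon_expression"):
            v = getattr(self, name)
            if v is not None and not v.exists():
                raise ConfigError(f"{name} path does not exist: {v}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        thr = raw.pop("thresholds", {})
        if thr:
            try:
                raw["thresholds"] = filters.FilterThresholds(
                    **{**thr, "allowed_biotypes": frozenset(
                        thr.get("allowed_biotypes",
                                filters.FilterThresholds().allowed_biotypes))})
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"bad thresholds: {exc}") from exc
        raw.update(overrides)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


@dataclass
class PipelineResult:
    records: list[CandidateRecord]
    log: filters.CascadeLog
    removed: dict[tuple[str, str], str]
    associations: list[assoc.AssociationResult]
    cluster_leaf_order: list[str]
    out_dir: Path


def _read_all_calls(cfg: RunConfig) -> list[io.FusionCall]:
    calls: list[io.FusionCall] = []
    files = sorted(cfg.calls_dir.glob("*.tsv"))
    if not files:
        raise io.ValidationError(f"no call tables (*.tsv) under {cfg.calls_dir}")
    for f in files:
        res = io.read_fusion_table(f, dialect=cfg.dialect, strict=False)
        for row, reason in res.rejected:
            logger.warning("%s row %d rejected: %s", f.name, row, reason)
        calls.extend(res.calls)
    return calls


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the whole nomination analysis and write all outputs."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = io.read_manifest(cfg.manifest)
    logger.info("cohort: %d tumors, %d benign, %d pairs",
                manifest.n_tumor, manifest.n_benign, manifest.n_pairs)
    calls = _read_all_calls(cfg)
    db = io.read_annotation(cfg.gtf, fasta=cfg.fasta)
    t = cfg.thresholds

    result = filters.run_cascade(calls, manifest, db, t)
    records, m = result.records, result.matrix

    # junction annotation for every survivor
    for r in records:
        try:
            r.geometry = junctions.classify_pair(r.gene5, r.gene3, db, cfg.distance_cap)
        except io.AnnotationError:
            r.geometry = None
        if r.representative_call is not None:
            r.junction = junctions.predict_frame(r.representative_call, db)

    # 3'-partner association
    associations: list[assoc.AssociationResult] = []
    gene_expr = (io.read_expression_matrix(cfg.gene_expression, "FPKM", manifest)
                 if cfg.gene_expression else None)
    if gene_expr is not None:
        for r in records:
            if r.gene3 not in gene_expr.features:
                continue
            part = assoc.partition_samples(r.pair, m, manifest)
            pos, neg, _ = part
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                p_neg, p_ben = assoc.three_prime_partner_test(gene_expr, r.gene3, part)
                tumor_ids = pos + neg
                fus = [m.rpkm(r.pair, s, t.read_length) for s in tumor_ids]
                par = gene_expr.vector(r.gene3, tumor_ids)
                rho, rho_p = assoc.fusion_partner_correlation(fus, par)
            res = assoc.AssociationResult(
                candidate=r.pair_label, p_pos_vs_neg_tumor=p_neg, p_pos_vs_benign=p_ben,
                spearman_rho=rho, spearman_p=rho_p, n_pos=len(pos), n_neg=len(neg),
            )
            r.association = res
            associations.append(res)

    # expression-profile clustering over the paired cohort
    leaf_labels: list[str] = []
    if len(records) >= 2 and manifest.n_pairs >= 2:
        profiles, labels = [], []
        for r in records:
            tv, bv = m.paired_rpkm_vectors(r.pair, t.read_length)
            profiles.append(normalize_differential(tv, bv))
            labels.append(r.pair_label)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            try:
                _, order, kept = cluster_profiles(np.array(profiles), labels,
                                                  linkage=cfg.linkage)
                leaf_labels = [kept[i] for i in order]
            except ValueError:
                leaf_labels = []

    _write_outputs(cfg, records, result.log, associations, leaf_labels)
    return PipelineResult(records=records, log=result.log, removed=result.removed,
                          associations=associations, cluster_leaf_order=leaf_labels,
                          out_dir=cfg.out_dir)


def _write_outputs(cfg, records, log, associations, leaf_labels) -> None:
    io.write_nomination_report(records, cfg.out_dir / "nominations.tsv")
    pd.DataFrame(log.to_rows()).to_csv(cfg.out_dir / "cascade_log.tsv", sep="\t", index=False)
    arows = [{
        "candidate": a.candidate,
        "p_pos_vs_neg_tumor": format_pvalue(a.p_pos_vs_neg_tumor),
        "p_pos_vs_benign": format_pvalue(a.p_pos_vs_benign),
        "spearman_rho": "*" if a.spearman_rho is None else f"{a.spearman_rho:.3f}",
        "spearman_p": format_pvalue(a.spearman_p),
        "n_pos": a.n_pos, "n_neg": a.n_neg,
    } for a in associations]
    pd.DataFrame(arows, columns=["candidate", "p_pos_vs_neg_tumor", "p_pos_vs_benign",
                                 "spearman_rho", "spearman_p", "n_pos", "n_neg"]
                 ).to_csv(cfg.out_dir / "association.tsv", sep="\t", index=False)
    with open(cfg.out_dir / "peptides.fa", "w") as fh:
        for r in records:
            if r.junction is not None and r.junction.peptide:
                fh.write(f">{r.pair_label} length={r.junction.fusion_peptide_length}\n")
                pep = r.junction.peptide
                for i in range(0, len(pep), 60):
                    fh.write(pep[i:i + 60] + "\n")
    (cfg.out_dir / "cluster_order.txt").write_text(
        "\n".join(leaf_labels) + ("\n" if leaf_labels else ""))
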