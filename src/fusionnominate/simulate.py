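"""Seeded synthetic cohorts for end-to-end testing of the pipeline.

The generator emulates the artifacts a fusion-calling workflow produces
for a paired tumor/benign cohort (44 pairs plus 50 unpaired tumors by
default): per-sample fusion-call tables in the deFuse-style dialect, a
toy GTF with explicit contig sequences, gene- and exon-level expression
matrices, and the sample manifest — together with a ground-truth table
of what was planted.

Planted structure:

* *enriched* fusions detected at a high tumor rate and low benign rate
  (defaults 0.6 vs 0.02, matching a strongly tumor-associated fusion);
* a *homology artifact* with a high multimapping fraction, which the
  cascade must remove at the multimap-ratio stage;
* *background* pairs detected at equal low rates in both conditions;
* optional expression *coupling*: the 3' partner's FPKM is shifted by a
  log2 offset in fusion-positive samples, and its downstream-of-junction
  exon counts rise with it (the read-through signature).

Detection is Bernoulli per sample; split-read support is Poisson;
multimapping spanning reads are binomial in the planted fraction.
Everything is driven by one integer seed: identical seeds give
byte-identical output bundles.

The toy genome uses short contigs with fully coding gene models whose
exon lengths are chosen so that planted ``frame_compatible`` values
round-trip through the frame predictor (all-coding exons, codon-aligned
boundaries; incompatible junctions shift the donor exon by one base and
rebalance the final exon to keep the native ORF intact).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import DEFUSE_061_DIALECT, GeneModel, TranscriptModel
from .records import CandidateRecord

__all__ = [
    "PlantedFusion",
    "SyntheticConfig",
    "SyntheticTruth",
    "CohortBundle",
    "generate_cohort",
    "truth_evaluation",
    "write_gtf",
]

Pair = tuple[str, str]

_GEOMETRIES = ("read_through", "distal", "interchromosomal")
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
)


@dataclass(frozen=True)
class PlantedFusion:
    """Ground-truth description of one planted gene pair."""

    name: str
    tumor_detection_rate: float
    benign_detection_rate: float
    geometry: str = "read_through"
    multimap_fraction: float = 0.05
    coupling: float = 0.0  # log2 shift on the 3' partner in positive samples
    splice_concordant: bool = True
    frame_compatible: bool = True
    lincRNA_5p: bool = False
    mean_split_reads: float = 6.0

    def __post_init__(self) -> None:
        for r in (self.tumor_detection_rate, self.benign_detection_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"detection rate {r} outside [0,1]")
        if not (0.0 <= self.multimap_fraction <= 1.0):
            raise ValueError("multimap_fraction must be in [0,1]")
        if self.coupling < 0:
            raise ValueError("coupling must be nonnegative")
        if self.geometry not in _GEOMETRIES:
            raise ValueError(f"geometry must be one of {_GEOMETRIES}")

    @property
    def gene5(self) -> str:
        return f"{self.name}_5P"

    @property
    def gene3(self) -> str:
        return f"{self.name}_3P"

    @property
    def pair(self) -> Pair:
        return (self.gene5, self.gene3)


def default_planted() -> tuple[PlantedFusion, ...]:
    """The reference planting: three enriched fusions plus one homology artifact."""
    return (
        PlantedFusion("RT1", 0.6, 0.02, coupling=2.0),
        PlantedFusion("RT2", 0.6, 0.02, frame_compatible=False),
        PlantedFusion("RT3", 0.6, 0.02, lincRNA_5p=True),
        PlantedFusion("ART1", 0.6, 0.02, multimap_fraction=0.9),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort design and noise model for one synthetic study."""

    seed: int
    n_pairs: int = 44
    n_extra_tumors: int = 50
    n_background_pairs: int = 200
    background_tumor_rate: float = 0.05
    background_benign_rate: float = 0.05
    planted: tuple[PlantedFusion, ...] = field(default_factory=default_planted)
    read_length: int = 100
    total_mapped_reads_range: tuple[int, int] = (30_000_000, 60_000_000)

    def __post_init__(self) -> None:
        for r in (self.background_tumor_rate, self.background_benign_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("background rates must be in [0,1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class _GenePlan:
    model: GeneModel
    transcript: TranscriptModel
    coding: bool


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for recovery scoring."""

    config: SyntheticConfig
    planted: dict[Pair, PlantedFusion]
    categories: dict[Pair, str]  # enriched | artifact | background
    detections: dict[Pair, set[str]]  # pair -> positive sample ids
    genes: dict[str, GeneModel]
    transcripts: dict[str, TranscriptModel]
    junctions: dict[Pair, tuple[int, int]]  # (breakpoint5, breakpoint3)
    exon_features: dict[str, dict[str, tuple[int, int]]]  # gene -> exon_id -> coords

    def category(self, pair: Pair) -> str:
        return self.categories.get(pair, "unplanted")


@dataclass(frozen=True)
class CohortBundle:
    """File paths of one generated cohort."""

    root: Path
    manifest: Path
    calls_dir: Path
    gtf: Path
    fasta: Path
    gene_expression: Path
    exon_expression: Path
    truth_table: Path


def _cds_frames(exon_lens: list[int]) -> list[int]:
    frames, cum = [], 0
    for ln in exon_lens:
        frames.append((3 - cum % 3) % 3)
        cum += ln
    return frames


def _build_gene(
    gene_id: str,
    contig: str,
    offset: int,
    exon_lens: list[int],
    intron_len: int,
    biotype: str,
    coding: bool,
) -> _GenePlan:
    """Lay out a '+'-strand gene at ``offset`` (1-based first base)."""
    exons = []
    pos = offset
    for ln in exon_lens:
        exons.append((pos, pos + ln - 1))
        pos += ln + intron_len
    start, end = exons[0][0], exons[-1][1]
    model = GeneModel(gene_id=gene_id, name=gene_id, chrom=contig, strand="+",
                      start=start, end=end, biotype=biotype)
    cds = tuple(
        (s, e, f) for (s, e), f in zip(exons, _cds_frames(exon_lens))
    ) if coding else ()
    tr = TranscriptModel(
        transcript_id=f"{gene_id}_T1", gene_id=gene_id, chrom=contig, strand="+",
        exons=tuple(exons), cds=cds,
    )
    return _GenePlan(model=model, transcript=tr, coding=coding)


def _coding_sequence(rng: np.random.Generator, n_bases: int) -> str:
    """ATG + non-stop codons + stop, exactly ``n_bases`` long (multiple of 3)."""
    assert n_bases % 3 == 0 and n_bases >= 9
    n_mid = n_bases // 3 - 2
    mid = "".join(rng.choice(_CODONS, size=n_mid))
    return "ATG" + mid + "TAA"


def _paint_gene(seq: np.ndarray, plan: _GenePlan, rng: np.random.Generator) -> None:
    """Overwrite exon positions with a designed coding sequence."""
    if not plan.coding:
        return
    total = sum(e - s + 1 for s, e in plan.transcript.exons)
    cds = _coding_sequence(rng, total)
    i = 0
    for s, e in plan.transcript.exons:
        ln = e - s + 1
        seq[s - 1:e] = np.frombuffer(cds[i:i + ln].encode(), dtype="S1")
        i += ln


def write_gtf(genes: dict[str, GeneModel], transcripts: dict[str, TranscriptModel],
              path: Path) -> None:
    """Write gene/transcript/exon/CDS features in Ensembl GTF dialect."""
    lines = []
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts.values():
        by_gene.setdefault(t.gene_id, []).append(t)
    for gid in sorted(genes):
        g = genes[gid]
        attrs = (f'gene_id "{gid}"; gene_name "{g.name}"; gene_biotype "{g.biotype}";')
        lines.append("\t".join([g.chrom, "synth", "gene", str(g.start), str(g.end),
                                ".", g.strand, ".", attrs]))
        for t in sorted(by_gene.get(gid, []), key=lambda x: x.transcript_id):
            tattrs = (f'gene_id "{gid}"; transcript_id "{t.transcript_id}"; '
                      f'gene_name "{g.name}"; gene_biotype "{g.biotype}";')
            lines.append("\t".join([t.chrom, "synth", "transcript", str(t.exons[0][0]),
                                    str(t.exons[-1][1]), ".", t.strand, ".", tattrs]))
            for i, (s, e) in enumerate(t.exons, start=1):
                ex = tattrs + f' exon_number "{i}";'
                lines.append("\t".join([t.chrom, "synth", "exon", str(s), str(e),
                                        ".", t.strand, ".", ex]))
            for s, e, f in t.cds:
                lines.append("\t".join([t.chrom, "synth", "CDS", str(s), str(e),
                                        ".", t.strand, str(f), tattrs]))
    path.write_text("\n".join(lines) + "\n")


def _write_fasta(contigs: dict[str, np.ndarray], path: Path) -> None:
    with path.open("w") as fh:
        for name in sorted(contigs):
            fh.write(f">{name}\n")
            s = contigs[name].tobytes().decode()
            for i in range(0, len(s), 80):
                fh.write(s[i:i + 80] + "\n")


_CALL_COLUMNS = [DEFUSE_061_DIALECT[f] for f in (
    "sample_id", "gene5", "gene3", "chrom5", "chrom3", "breakpoint5", "breakpoint3",
    "strand5", "strand3", "discordant_pairs", "split_reads", "multimap_spanning",
    "total_spanning", "probability",
)]


def generate_cohort(cfg: SyntheticConfig, out_dir: str | Path) -> tuple[CohortBundle, SyntheticTruth]:
    """Generate the full input bundle for one synthetic cohort.

    Writes manifest, per-sample call tables, GTF + FASTA, gene-FPKM and
    exon-count matrices, and the truth table under ``out_dir``; returns
    the file bundle and the in-memory truth.
    """
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    calls_dir = out / "calls"
    calls_dir.mkdir(parents=True, exist_ok=True)

    # ---- samples -----------------------------------------------------------
    lo, hi = cfg.total_mapped_reads_range
    rows = []
    for i in range(1, cfg.n_pairs + 1):
        for cond, prefix in (("tumor", "T"), ("benign", "B")):
            rows.append({
                "sample_id": f"{prefix}{i:03d}", "condition": cond, "pair_id": f"P{i:03d}",
                "total_mapped_reads": int(rng.integers(lo, hi)),
            })
    for i in range(1, cfg.n_extra_tumors + 1):
        rows.append({
            "sample_id": f"X{i:03d}", "condition": "tumor", "pair_id": "",
            "total_mapped_reads": int(rng.integers(lo, hi)),
        })
    manifest_df = pd.DataFrame(rows)
    manifest_path = out / "manifest.tsv"
    manifest_df.to_csv(manifest_path, sep="\t", index=False)
    sample_conditions = {r["sample_id"]: r["condition"] for r in rows}

    # ---- genome ------------------------------------------------------------
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, TranscriptModel] = {}
    contigs: dict[str, np.ndarray] = {}
    junctions: dict[Pair, tuple[int, int]] = {}
    planted_map: dict[Pair, PlantedFusion] = {}
    categories: dict[Pair, str] = {}
    exon_features: dict[str, dict[str, tuple[int, int]]] = {}

    def _new_contig(name: str, length: int) -> np.ndarray:
        seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length)
        contigs[name] = seq
        return seq

    donor_exon = 3  # junction follows this exon of the 5' gene
    for pf in cfg.planted:
        planted_map[pf.pair] = pf
        categories[pf.pair] = "artifact" if pf.multimap_fraction > 0.5 else "enriched"
        # 5' gene: 5 exons; codon-aligned boundaries unless frame-incompatible,
        # in which case the donor exon gains 1 nt and the last exon loses 1.
        lens5 = [90] * 5
        if not pf.frame_compatible and not pf.lincRNA_5p:
            lens5[donor_exon - 1] += 1
            lens5[-1] -= 1
        lens3 = [90] * 6
        gap = {"read_through": 1_000, "distal": 200_000, "interchromosomal": 1_000}[pf.geometry]
        g5 = _build_gene(pf.gene5, f"ctg{pf.name}", 501, lens5, 300,
                         "lincRNA" if pf.lincRNA_5p else "protein_coding",
                         coding=not pf.lincRNA_5p)
        if pf.geometry == "interchromosomal":
            contig3 = f"ctg{pf.name}b"
            off3 = 501
        else:
            contig3 = f"ctg{pf.name}"
            off3 = g5.model.end + gap + 1
        g3 = _build_gene(pf.gene3, contig3, off3, lens3, 300, "protein_coding", coding=True)
        for plan in (g5, g3):
            genes[plan.model.gene_id] = plan.model
            transcripts[plan.transcript.transcript_id] = plan.transcript
        seq5 = _new_contig(f"ctg{pf.name}", (g3.model.end if contig3 == f"ctg{pf.name}"
                                             else g5.model.end) + 500)
        _paint_gene(seq5, g5, rng)
        if pf.geometry == "interchromosomal":
            seqb = _new_contig(contig3, g3.model.end + 500)
            _paint_gene(seqb, g3, rng)
        else:
            _paint_gene(seq5, g3, rng)
        bp5 = g5.transcript.exons[donor_exon - 1][1]
        bp3 = g3.transcript.exons[1][0]  # acceptor: start of exon 2
        if not pf.splice_concordant:
            bp3 += 2  # inside the exon: junction off the annotated splice site
        junctions[pf.pair] = (bp5, bp3)
        exon_features[pf.gene3] = {
            f"{pf.gene3}:E{i}": (s, e)
            for i, (s, e) in enumerate(g3.transcript.exons, start=1)
        }

    background_pairs: list[Pair] = []
    for j in range(1, cfg.n_background_pairs + 1):
        ga_id, gb_id = f"BGA{j:03d}", f"BGB{j:03d}"
        contig = f"bg{j:03d}"
        ga = _build_gene(ga_id, contig, 301, [90, 90], 200, "protein_coding", True)
        gb = _build_gene(gb_id, contig, ga.model.end + 2_001, [90, 90], 200,
                         "protein_coding", True)
        seq = _new_contig(contig, gb.model.end + 300)
        _paint_gene(seq, ga, rng)
        _paint_gene(seq, gb, rng)
        for plan in (ga, gb):
            genes[plan.model.gene_id] = plan.model
            transcripts[plan.transcript.transcript_id] = plan.transcript
        pair = (ga_id, gb_id)
        background_pairs.append(pair)
        categories[pair] = "background"
        # breakpoints inside the genes, deliberately off splice sites
        junctions[pair] = (ga.model.start + int(rng.integers(5, 80)),
                           gb.model.start + int(rng.integers(5, 80)))

    gtf_path = out / "annotation.gtf"
    write_gtf(genes, transcripts, gtf_path)
    fasta_path = out / "genome.fa"
    _write_fasta(contigs, fasta_path)

    # ---- detections and per-sample call tables -----------------------------
    detections: dict[Pair, set[str]] = {p: set() for p in list(planted_map) + background_pairs}
    sample_calls: dict[str, list[dict[str, object]]] = {r["sample_id"]: [] for r in rows}

    def _emit_call(sample_id: str, pair: Pair, mm_frac: float, mean_split: float) -> None:
        split = 1 + int(rng.poisson(max(mean_split - 1, 0)))
        discordant = max(5, split + int(rng.poisson(2)))
        total_span = discordant
        mm = int(rng.binomial(total_span, mm_frac))
        bp5, bp3 = junctions[pair]
        g5, g3 = genes[pair[0]], genes[pair[1]]
        sample_calls[sample_id].append(dict(zip(_CALL_COLUMNS, (
            sample_id, pair[0], pair[1], g5.chrom, g3.chrom, bp5, bp3,
            g5.strand, g3.strand, discordant, split, mm, total_span,
            round(float(rng.uniform(0.05, 1.0)), 4),
        ))))
        detections[pair].add(sample_id)

    for pair in list(planted_map) + background_pairs:
        if pair in planted_map:
            pf = planted_map[pair]
            t_rate, b_rate = pf.tumor_detection_rate, pf.benign_detection_rate
            mm_frac, mean_split = pf.multimap_fraction, pf.mean_split_reads
        else:
            t_rate, b_rate = cfg.background_tumor_rate, cfg.background_benign_rate
            mm_frac, mean_split = 0.05, 3.0
        for r in rows:
            rate = t_rate if r["condition"] == "tumor" else b_rate
            if rng.random() < rate:
                _emit_call(str(r["sample_id"]), pair, mm_frac, mean_split)

    # low-support junk calls that the initial criteria must screen out
    for r in rows:
        for _ in range(int(rng.poisson(1.0))):
            pair = background_pairs[int(rng.integers(len(background_pairs)))]
            bp5, bp3 = junctions[pair]
            g5, g3 = genes[pair[0]], genes[pair[1]]
            split = int(rng.integers(0, 2))
            disc = int(rng.integers(0, 5))  # below the discordant-pair floor
            total = max(disc, 1)
            sample_calls[str(r["sample_id"])].append(dict(zip(_CALL_COLUMNS, (
                str(r["sample_id"]), pair[0], pair[1], g5.chrom, g3.chrom, bp5, bp3,
                g5.strand, g3.strand, disc, split, int(rng.binomial(total, 0.05)),
                total, round(float(rng.uniform(0.0, 1.0)), 4),
            ))))

    for sample_id, calls in sample_calls.items():
        pd.DataFrame(calls, columns=_CALL_COLUMNS).to_csv(
            calls_dir / f"{sample_id}.tsv", sep="\t", index=False)

    # ---- expression matrices -----------------------------------------------
    sample_ids = [str(r["sample_id"]) for r in rows]
    gene_ids = sorted(genes)
    base = 2.0 ** rng.normal(3.0, 1.0, size=len(gene_ids))
    noise = 2.0 ** rng.normal(0.0, 0.25, size=(len(gene_ids), len(sample_ids)))
    fpkm = base[:, None] * noise
    idx = {g: i for i, g in enumerate(gene_ids)}
    sidx = {s: j for j, s in enumerate(sample_ids)}
    for pair, pf in planted_map.items():
        if pf.coupling > 0:
            for s in detections[pair]:
                fpkm[idx[pf.gene3], sidx[s]] *= 2.0 ** pf.coupling
    gene_expr_path = out / "gene_fpkm.tsv"
    pd.DataFrame(np.round(fpkm, 4), index=gene_ids, columns=sample_ids).to_csv(
        gene_expr_path, sep="\t", index_label="gene_id")

    exon_rows, exon_ids = [], []
    libsize = {str(r["sample_id"]): int(r["total_mapped_reads"]) for r in rows}
    for pair, pf in planted_map.items():
        bp3 = junctions[pair][1]
        for exon_id, (s, e) in exon_features[pf.gene3].items():
            base_cpm = float(2.0 ** rng.normal(4.0, 0.5))
            vals = []
            for sid in sample_ids:
                cpm = base_cpm
                downstream = e >= bp3  # '+' strand genes throughout the toy genome
                if downstream and pf.coupling > 0 and sid in detections[pair]:
                    cpm *= 2.0 ** pf.coupling
                lam = cpm * libsize[sid] / 1e6
                vals.append(int(rng.poisson(lam)))
            exon_rows.append(vals)
            exon_ids.append(exon_id)
    exon_expr_path = out / "exon_counts.tsv"
    pd.DataFrame(exon_rows, index=exon_ids, columns=sample_ids).to_csv(
        exon_expr_path, sep="\t", index_label="exon_id")

    # ---- truth table -------------------------------------------------------
    truth_rows = []
    for pair in list(planted_map) + background_pairs:
        pf = planted_map.get(pair)
        n_t = sum(1 for s in detections[pair] if sample_conditions[s] == "tumor")
        n_b = sum(1 for s in detections[pair] if sample_conditions[s] == "benign")
        truth_rows.append({
            "gene5": pair[0], "gene3": pair[1],
            "category": categories[pair],
            "tumor_rate": pf.tumor_detection_rate if pf else cfg.background_tumor_rate,
            "benign_rate": pf.benign_detection_rate if pf else cfg.background_benign_rate,
            "geometry": pf.geometry if pf else "distal",
            "multimap_fraction": pf.multimap_fraction if pf else 0.05,
            "coupling": pf.coupling if pf else 0.0,
            "splice_concordant": pf.splice_concordant if pf else False,
            "frame_compatible": pf.frame_compatible if pf else False,
            "breakpoint5": junctions[pair][0], "breakpoint3": junctions[pair][1],
            "n_tumor_positive": n_t, "n_benign_positive": n_b,
        })
    truth_path = out / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)

    bundle = CohortBundle(
        root=out, manifest=manifest_path, calls_dir=calls_dir, gtf=gtf_path,
        fasta=fasta_path, gene_expression=gene_expr_path,
        exon_expression=exon_expr_path, truth_table=truth_path,
    )
    truth = SyntheticTruth(
        config=cfg, planted=planted_map, categories=categories, detections=detections,
        genes=genes, transcripts=transcripts, junctions=junctions,
        exon_features=exon_features,
    )
    return bundle, truth


def truth_evaluation(nominated: list[CandidateRecord], truth: SyntheticTruth) -> dict[str, object]:
    """Recovery statistics of a nomination run against the planted truth.

    Recall counts recovered *enriched* plantings; precision is the
    fraction of nominations that are planted enriched fusions. With
    nothing planted and nothing nominated both are defined as 1.0.
    """
    nominated_pairs = {r.pair for r in nominated}
    enriched = {p for p, c in truth.categories.items() if c == "enriched"}
    artifacts = {p for p, c in truth.categories.items() if c == "artifact"}
    recovered = nominated_pairs & enriched
    recall = len(recovered) / len(enriched) if enriched else 1.0
    precision = len(recovered) / len(nominated_pairs) if nominated_pairs else 1.0
    return {
        "recall": recall,
        "precision": precision,
        "recovered": sorted(recovered),
        "missed": sorted(enriched - nominated_pairs),
        "false_positives": sorted(nominated_pairs - enriched),
        "artifacts_nominated": sorted(nominated_pairs & artifacts),
        "n_nominated": len(nominated_pairs),
    }
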