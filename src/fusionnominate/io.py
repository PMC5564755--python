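"""Reading and validation of cohort inputs, and the nomination report.

Inputs are the artifacts a fusion-calling workflow leaves behind:

* per-sample fusion-call tables (TSV, deFuse-style; the column mapping is
  config-driven because caller versions rename columns);
* a sample manifest (sample id, tumor/benign condition, pairing, library
  size);
* gene annotation as Ensembl-dialect GTF (gene/transcript/exon/CDS rows
  carrying ``gene_id``/``transcript_id``/``gene_biotype``);
* gene- or exon-level expression matrices (features x samples, TSV).

Coordinates are 1-based inclusive throughout (GTF convention).
Chromosome names are normalised by stripping any ``chr`` prefix unless
configured otherwise.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import format_pvalue

__all__ = [
    "FusionCall",
    "ParseResult",
    "CohortManifest",
    "ManifestSample",
    "GeneModel",
    "TranscriptModel",
    "AnnotationDB",
    "ExpressionMatrix",
    "FusionTableFormatError",
    "ValidationError",
    "AnnotationError",
    "DEFUSE_061_DIALECT",
    "read_fusion_table",
    "read_manifest",
    "read_annotation",
    "read_expression_matrix",
    "write_nomination_report",
    "read_nomination_report",
    "normalize_chrom",
    "REPORT_COLUMNS",
]


class FusionTableFormatError(ValueError):
    """A fusion-call table does not match the configured dialect."""


class ValidationError(ValueError):
    """An input value violates a domain invariant."""


class AnnotationError(KeyError):
    """A gene or transcript id is missing from the annotation."""


def normalize_chrom(name: str, mode: str = "strip") -> str:
    """Normalise chromosome naming ('chr1' vs '1') per config."""
    name = str(name)
    if mode == "strip":
        return name[3:] if name.lower().startswith("chr") else name
    if mode == "add":
        return name if name.lower().startswith("chr") else f"chr{name}"
    if mode == "none":
        return name
    raise ValueError(f"unknown chromosome normalisation mode {mode!r}")


@dataclass(frozen=True)
class FusionCall:
    """One predicted fusion transcript in one sample, with read evidence.

    ``breakpoint5`` is the last base of the 5' segment and ``breakpoint3``
    the first base of the 3' segment (1-based genomic coordinates).
    """

    sample_id: str
    gene5: str
    gene3: str
    chrom5: str
    chrom3: str
    breakpoint5: int
    breakpoint3: int
    strand5: str
    strand3: str
    discordant_pairs: int
    split_reads: int
    multimap_spanning: int
    total_spanning: int
    probability: float

    def __post_init__(self) -> None:
        for name in ("discordant_pairs", "split_reads", "multimap_spanning", "total_spanning"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.multimap_spanning > self.total_spanning:
            raise ValidationError(
                f"multimap_spanning={self.multimap_spanning} exceeds "
                f"total_spanning={self.total_spanning}"
            )
        if not (0.0 <= self.probability <= 1.0):
            raise ValidationError(f"probability must be in [0,1], got {self.probability}")
        for s in (self.strand5, self.strand3):
            if s not in ("+", "-"):
                raise ValidationError(f"strand must be '+' or '-', got {s!r}")

    @property
    def pair(self) -> tuple[str, str]:
        """Ordered (5', 3') gene-pair key; reciprocal orientations are distinct."""
        return (self.gene5, self.gene3)


#: Default column mapping targeting deFuse 0.6.1-style headers.
DEFUSE_061_DIALECT: dict[str, str] = {
    "sample_id": "library_name",
    "gene5": "gene_name1",
    "gene3": "gene_name2",
    "chrom5": "gene_chromosome1",
    "chrom3": "gene_chromosome2",
    "breakpoint5": "genomic_break_pos1",
    "breakpoint3": "genomic_break_pos2",
    "strand5": "genomic_strand1",
    "strand3": "genomic_strand2",
    "discordant_pairs": "span_count",
    "split_reads": "splitr_count",
    "multimap_spanning": "multi_map_span_count",
    "total_spanning": "total_span_count",
    "probability": "probability",
}

_INT_FIELDS = ("breakpoint5", "breakpoint3", "discordant_pairs", "split_reads",
               "multimap_spanning", "total_spanning")


@dataclass
class ParseResult:
    """Accepted calls plus per-row rejection diagnostics.

    The parser never silently drops rows: every input row is either in
    ``calls`` or in ``rejected`` as ``(row_number, reason)`` (1-based,
    excluding the header).
    """

    calls: list[FusionCall]
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.calls) + len(self.rejected)


def read_fusion_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sample_id: str | None = None,
    chrom_mode: str = "strip",
    strict: bool = True,
) -> ParseResult:
    """Parse one fusion-call TSV into validated :class:`FusionCall` rows.

    ``dialect`` maps FusionCall field names to the file's column names;
    ``sample_id`` overrides/replaces the sample-id column (per-sample
    files usually do not repeat it). With ``strict`` a bad row raises a
    :class:`ValidationError` naming the row; otherwise bad rows are
    collected in :attr:`ParseResult.rejected`.
    """
    dialect = dict(dialect or DEFUSE_061_DIALECT)
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        needed = {f: col for f, col in dialect.items() if f != "sample_id"}
        for fld, col in needed.items():
            if col not in header:
                raise FusionTableFormatError(
                    f"{path.name}: missing mandatory column {col!r} (for field {fld!r})"
                )
        has_sample_col = dialect.get("sample_id") in header
        if sample_id is None and not has_sample_col:
            raise FusionTableFormatError(
                f"{path.name}: no sample id column {dialect.get('sample_id')!r} "
                "and no sample_id given"
            )
        calls: list[FusionCall] = []
        rejected: list[tuple[int, str]] = []
        for i, row in enumerate(reader, start=1):
            try:
                kwargs: dict[str, object] = {}
                for fld, col in needed.items():
                    raw = row[col]
                    if fld in _INT_FIELDS:
                        kwargs[fld] = int(raw)
                    elif fld == "probability":
                        kwargs[fld] = float(raw)
                    elif fld in ("chrom5", "chrom3"):
                        kwargs[fld] = normalize_chrom(raw, chrom_mode)
                    else:
                        kwargs[fld] = str(raw)
                kwargs["sample_id"] = (
                    sample_id if sample_id is not None else str(row[dialect["sample_id"]])
                )
                calls.append(FusionCall(**kwargs))
            except (ValueError, KeyError) as exc:
                if strict:
                    raise ValidationError(f"{path.name} row {i}: {exc}") from exc
                rejected.append((i, str(exc)))
    return ParseResult(calls=calls, rejected=rejected)


@dataclass(frozen=True)
class ManifestSample:
    sample_id: str
    condition: str  # "tumor" or "benign"
    pair_id: str | None
    total_mapped_reads: int


@dataclass
class CohortManifest:
    """Cohort design: which samples exist, their condition and pairing."""

    samples: list[ManifestSample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicated sample ids: {dup}")
        for s in self.samples:
            if s.condition not in ("tumor", "benign"):
                raise ValidationError(f"{s.sample_id}: condition must be tumor/benign")
            if s.total_mapped_reads <= 0:
                raise ValidationError(f"{s.sample_id}: total_mapped_reads must be positive")
        pairs: dict[str, list[str]] = {}
        for s in self.samples:
            if s.pair_id:
                pairs.setdefault(s.pair_id, []).append(s.condition)
        for pid, conds in pairs.items():
            if sorted(conds) != ["benign", "tumor"]:
                raise ValidationError(
                    f"pair {pid!r} must have exactly one tumor and one benign sample, got {conds}"
                )

    @property
    def tumors(self) -> list[ManifestSample]:
        return [s for s in self.samples if s.condition == "tumor"]

    @property
    def benigns(self) -> list[ManifestSample]:
        return [s for s in self.samples if s.condition == "benign"]

    @property
    def n_tumor(self) -> int:
        return len(self.tumors)

    @property
    def n_benign(self) -> int:
        return len(self.benigns)

    @property
    def n_pairs(self) -> int:
        return len({s.pair_id for s in self.samples if s.pair_id})

    @property
    def pair_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.pair_id and s.pair_id not in seen:
                seen.append(s.pair_id)
        return seen

    def sample(self, sample_id: str) -> ManifestSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def pair_members(self, pair_id: str) -> tuple[ManifestSample, ManifestSample]:
        """(tumor, benign) samples of a pair."""
        members = [s for s in self.samples if s.pair_id == pair_id]
        tum = next(s for s in members if s.condition == "tumor")
        ben = next(s for s in members if s.condition == "benign")
        return tum, ben


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a CSV/TSV manifest with sample_id, condition, pair_id, total_mapped_reads."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"sample_id", "condition", "pair_id", "total_mapped_reads"}
    missing = required - set(df.columns)
    if missing:
        raise FusionTableFormatError(f"manifest missing columns: {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        pid = row["pair_id"]
        pid = None if (pd.isna(pid) or str(pid).strip() in ("", "NA", "none")) else str(pid)
        samples.append(
            ManifestSample(
                sample_id=str(row["sample_id"]),
                condition=str(row["condition"]).strip().lower(),
                pair_id=pid,
                total_mapped_reads=int(float(row["total_mapped_reads"])),
            )
        )
    return CohortManifest(samples=samples)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    name: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive
    end: int
    biotype: str


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # genomic ascending, 1-based inclusive
    cds: tuple[tuple[int, int, int], ...]  # (start, end, frame), genomic ascending

    @property
    def exons_transcription_order(self) -> tuple[tuple[int, int], ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)


class AnnotationDB:
    """Gene/transcript/exon/CDS geometry with simple lookup helpers.

    Optionally carries contig sequences (dict chrom -> str, 0-based
    indexing into the string) so fusion transcripts can be translated.
    """

    def __init__(
        self,
        genes: Mapping[str, GeneModel],
        transcripts: Mapping[str, TranscriptModel],
        sequences: Mapping[str, str] | None = None,
    ) -> None:
        self.genes = dict(genes)
        self.transcripts = dict(transcripts)
        self.sequences = dict(sequences) if sequences else None
        self._by_gene: dict[str, list[str]] = {}
        for tid, t in self.transcripts.items():
            self._by_gene.setdefault(t.gene_id, []).append(tid)
        for tids in self._by_gene.values():
            tids.sort()
        self._by_name = {g.name: gid for gid, g in self.genes.items()}

    def gene(self, key: str) -> GeneModel:
        """Look up a gene by id, falling back to gene name."""
        if key in self.genes:
            return self.genes[key]
        if key in self._by_name:
            return self.genes[self._by_name[key]]
        raise AnnotationError(f"gene {key!r} not in annotation")

    def has_gene(self, key: str) -> bool:
        return key in self.genes or key in self._by_name

    def transcripts_of(self, gene_key: str) -> list[TranscriptModel]:
        gid = self.gene(gene_key).gene_id
        return [self.transcripts[t] for t in self._by_gene.get(gid, [])]

    def spans_overlap(self, key_a: str, key_b: str) -> bool:
        a, b = self.gene(key_a), self.gene(key_b)
        if a.chrom != b.chrom:
            return False
        return a.start <= b.end and b.start <= a.end

    def sequence(self, chrom: str) -> str:
        if not self.sequences or chrom not in self.sequences:
            raise AnnotationError(f"no sequence available for contig {chrom!r}")
        return self.sequences[chrom]


def read_annotation(
    path: str | Path,
    fasta: str | Path | None = None,
    chrom_mode: str = "strip",
    clamp: bool = True,
) -> AnnotationDB:
    """Load an Ensembl-dialect GTF (and optional genome FASTA) into an AnnotationDB.

    Exons falling outside their gene's recorded span are clamped with a
    warning (or rejected with ``clamp=False``). Genes without a
    ``gene_biotype`` attribute get biotype ``"unknown"``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        gid = g.attributes["gene_id"][0]
        biotype = g.attributes.get("gene_biotype", ["unknown"])[0]
        name = g.attributes.get("gene_name", [gid])[0]
        genes[gid] = GeneModel(
            gene_id=gid,
            name=name,
            chrom=normalize_chrom(g.seqid, chrom_mode),
            strand=g.strand,
            start=g.start,
            end=g.end,
            biotype=biotype,
        )
    transcripts: dict[str, TranscriptModel] = {}
    for t in db.features_of_type("transcript"):
        tid = t.attributes["transcript_id"][0]
        gid = t.attributes["gene_id"][0]
        exons: list[tuple[int, int]] = []
        for e in db.children(t, featuretype="exon", order_by="start"):
            s, en = e.start, e.end
            if gid in genes:
                gspan = genes[gid]
                if s < gspan.start or en > gspan.end:
                    if not clamp:
                        raise ValidationError(
                            f"exon {s}-{en} outside span of gene {gid} "
                            f"({gspan.start}-{gspan.end})"
                        )
                    warnings.warn(f"clamping exon {s}-{en} to span of gene {gid}", stacklevel=2)
                    s, en = max(s, gspan.start), min(en, gspan.end)
            exons.append((s, en))
        cds: list[tuple[int, int, int]] = []
        for c in db.children(t, featuretype="CDS", order_by="start"):
            frame = int(c.frame) if c.frame not in (None, ".") else 0
            cds.append((c.start, c.end, frame))
        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            chrom=normalize_chrom(t.seqid, chrom_mode),
            strand=t.strand,
            exons=tuple(exons),
            cds=tuple(cds),
        )
    sequences = None
    if fasta is not None:
        from Bio import SeqIO

        sequences = {
            normalize_chrom(rec.id, chrom_mode): str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta), "fasta")
        }
    return AnnotationDB(genes, transcripts, sequences)


@dataclass
class ExpressionMatrix:
    """Feature x sample expression values tagged with their unit."""

    values: pd.DataFrame
    unit: str  # "FPKM", "RPKM" or "count"

    def __post_init__(self) -> None:
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValidationError("expression matrix contains negative values")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def vector(self, feature: str, sample_ids: Sequence[str]) -> np.ndarray:
        return self.values.loc[feature, list(sample_ids)].to_numpy(dtype=float)


def read_expression_matrix(
    path: str | Path, unit: str, manifest: CohortManifest | None = None
) -> ExpressionMatrix:
    """Read a features-x-samples TSV; sample columns must be in the manifest."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if manifest is not None:
        known = {s.sample_id for s in manifest.samples}
        extra = [c for c in df.columns if c not in known]
        if extra:
            raise ValidationError(f"expression samples not in manifest: {extra[:5]}")
    return ExpressionMatrix(values=df, unit=unit)


REPORT_COLUMNS = [
    "gene_pair", "gene5", "gene3", "chrom5", "chrom3", "strand5", "strand3",
    "distance_bp", "read_through", "junction_at_splice_site", "in_frame",
    "n_tumor_positive", "n_benign_positive", "fisher_p", "fisher_q",
    "wilcoxon_p", "mean_rpkm_tumor", "var_rpkm_tumor",
    "mean_rpkm_benign", "var_rpkm_benign",
]


def _fmt_num(x: float | None) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "*"
    return f"{x:.4g}"


def _fmt_flag(x: bool | None) -> str:
    return "*" if x is None else ("Y" if x else "N")


def write_nomination_report(records: Iterable, path: str | Path) -> None:
    """Write the nomination table (one row per surviving candidate).

    P-values are rendered to 2 significant figures in scientific
    notation; unavailable cells are rendered ``"*"``.
    """
    rows = []
    for r in records:
        geom = r.geometry
        junc = r.junction
        rows.append({
            "gene_pair": f"{r.gene5}-{r.gene3}",
            "gene5": r.gene5,
            "gene3": r.gene3,
            "chrom5": geom.chrom5 if geom else "*",
            "chrom3": geom.chrom3 if geom else "*",
            "strand5": geom.strand5 if geom else "*",
            "strand3": geom.strand3 if geom else "*",
            "distance_bp": ("NA" if geom is None or geom.inner_distance_bp is None
                            else str(geom.inner_distance_bp)),
            "read_through": _fmt_flag(geom.read_through_candidate if geom else None),
            "junction_at_splice_site": _fmt_flag(junc.at_splice_sites if junc else None),
            "in_frame": _fmt_flag(junc.in_frame if junc else None),
            "n_tumor_positive": str(r.contingency.a),
            "n_benign_positive": str(r.contingency.c),
            "fisher_p": format_pvalue(r.fisher_p),
            "fisher_q": format_pvalue(r.fisher_q),
            "wilcoxon_p": format_pvalue(r.wilcoxon_p),
            "mean_rpkm_tumor": _fmt_num(r.mean_rpkm_tumor),
            "var_rpkm_tumor": _fmt_num(r.var_rpkm_tumor),
            "mean_rpkm_benign": _fmt_num(r.mean_rpkm_benign),
            "var_rpkm_benign": _fmt_num(r.var_rpkm_benign),
        })
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_nomination_report(path: str | Path) -> pd.DataFrame:
    """Re-read a nomination report; ``"*"`` placeholders become NaN."""
    return pd.read_csv(path, sep="\t", na_values=["*"], keep_default_na=False,
                       dtype={"distance_bp": str})
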