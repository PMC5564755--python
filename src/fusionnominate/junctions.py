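"""Junction-level annotation of fusion candidates.

Given a candidate's representative call and gene annotation, this module
answers four questions:

* partner geometry — same chromosome? how far apart? compatible with an
  RNA-polymerase read-through event (same strand, 5' gene transcriptionally
  upstream, gap below a configurable cap, 60 kb by default)?
* splice-site concordance — do both breakpoints coincide with annotated
  exon boundaries (donor side of the 5' partner, acceptor side of the 3'
  partner)?
* reading frame — does the 3' partner's coding phase at the junction
  continue the phase carried over from the 5' partner's CDS, and if so,
  what chimeric peptide results?
* domain retention — which user-supplied protein domains survive the
  truncation on either side of the junction?

All coordinates are 1-based genomic (GTF convention). Frame bookkeeping
uses the GTF frame field: the number of bases at the (transcription-wise)
start of a CDS segment that complete an upstream codon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .io import AnnotationDB, AnnotationError, FusionCall, TranscriptModel

__all__ = [
    "PairGeometry",
    "JunctionAnnotation",
    "classify_pair",
    "junction_at_splice_sites",
    "predict_frame",
    "domain_retention",
    "DomainInterval",
]


@dataclass(frozen=True)
class PairGeometry:
    """Genomic relationship between the two partner genes."""

    chrom5: str
    chrom3: str
    strand5: str
    strand3: str
    same_chromosome: bool
    inner_distance_bp: int | None  # gap between gene spans; None if interchromosomal
    read_through_candidate: bool

    @property
    def strand_config(self) -> tuple[str, str]:
        return (self.strand5, self.strand3)


@dataclass
class JunctionAnnotation:
    """Splice-site and reading-frame annotation of one fusion junction."""

    at_splice_sites: bool
    in_frame: bool
    transcript5: str | None = None
    transcript3: str | None = None
    retained_exons5: list[tuple[int, int]] = field(default_factory=list)
    retained_exons3: list[tuple[int, int]] = field(default_factory=list)
    residues_from_5p: int | None = None       # complete codons contributed by the 5' CDS
    first_retained_residue_3p: int | None = None  # 1-based index into the native 3' protein
    peptide: str | None = None
    fusion_peptide_length: int | None = None


def classify_pair(
    gene5_key: str,
    gene3_key: str,
    db: AnnotationDB,
    distance_cap: int = 60_000,
) -> PairGeometry:
    """Geometry of a partner pair; flags plausible read-through events.

    A pair is a read-through candidate iff both genes sit on the same
    chromosome and strand, their spans are at most ``distance_cap`` bp
    apart, and the 5' gene lies transcriptionally upstream of the 3'
    gene. The inner distance (gap between spans, 0 if abutting or
    overlapping) is symmetric in gene order; the read-through flag is not.
    """
    g5 = db.gene(gene5_key)
    g3 = db.gene(gene3_key)
    same_chrom = g5.chrom == g3.chrom
    if same_chrom:
        gap = max(g3.start - g5.end, g5.start - g3.end, 0) - 1
        distance = max(gap, 0)
    else:
        distance = None
    read_through = False
    if same_chrom and g5.strand == g3.strand and distance is not None and distance <= distance_cap:
        if g5.strand == "+":
            read_through = g5.end < g3.start
        else:
            read_through = g5.start > g3.end
    return PairGeometry(
        chrom5=g5.chrom,
        chrom3=g3.chrom,
        strand5=g5.strand,
        strand3=g3.strand,
        same_chromosome=same_chrom,
        inner_distance_bp=distance,
        read_through_candidate=read_through,
    )


def _donor_transcripts(db: AnnotationDB, gene_key: str, breakpoint: int) -> list[TranscriptModel]:
    """Transcripts with an exon whose (strand-aware) 3' end is at the breakpoint."""
    out = []
    for t in db.transcripts_of(gene_key):
        ends = {e[1] if t.strand == "+" else e[0] for e in t.exons}
        if breakpoint in ends:
            out.append(t)
    return out


def _acceptor_transcripts(db: AnnotationDB, gene_key: str, breakpoint: int) -> list[TranscriptModel]:
    """Transcripts with an exon whose (strand-aware) 5' start is at the breakpoint."""
    out = []
    for t in db.transcripts_of(gene_key):
        starts = {e[0] if t.strand == "+" else e[1] for e in t.exons}
        if breakpoint in starts:
            out.append(t)
    return out


def junction_at_splice_sites(call: FusionCall, db: AnnotationDB) -> bool:
    """True iff both breakpoints coincide with annotated exon boundaries.

    The 5' breakpoint must equal an exon's transcription-wise 3' end in
    some transcript of the 5' partner, and the 3' breakpoint an exon's
    5' start in some transcript of the 3' partner (existential over
    transcripts, strand-aware). Unannotated genes yield False with a
    warning rather than an error.
    """
    try:
        donors = _donor_transcripts(db, call.gene5, call.breakpoint5)
        acceptors = _acceptor_transcripts(db, call.gene3, call.breakpoint3)
    except AnnotationError as exc:
        warnings.warn(f"splice-site check skipped: {exc}", stacklevel=2)
        return False
    return bool(donors) and bool(acceptors)


def _coding_bases_through(t: TranscriptModel, breakpoint: int) -> int:
    """CDS bases of ``t`` at or transcriptionally upstream of the breakpoint."""
    total = 0
    for s, e, _ in t.cds:
        if t.strand == "+":
            if s <= breakpoint:
                total += min(e, breakpoint) - s + 1
        else:
            if e >= breakpoint:
                total += e - max(s, breakpoint) + 1
    return total


def _breakpoint_in_cds(t: TranscriptModel, breakpoint: int) -> bool:
    return any(s <= breakpoint <= e for s, e, _ in t.cds)


def _acceptor_frame(t: TranscriptModel, breakpoint: int) -> int | None:
    """GTF frame of the CDS segment whose coding begins at the junction base.

    Returns None when the junction base is not the first base of a CDS
    segment (e.g. the junction exon is noncoding or has a 5' UTR), in
    which case phase continuation across the junction is undefined.
    """
    for s, e, frame in t.cds:
        first = s if t.strand == "+" else e
        if first == breakpoint:
            return frame
    return None


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def _exon_seq(db: AnnotationDB, chrom: str, strand: str, exons: list[tuple[int, int]]) -> str:
    seq = db.sequence(chrom)
    parts = [seq[s - 1:e] for s, e in exons]
    joined = "".join(parts)
    return _revcomp(joined) if strand == "-" else joined


def predict_frame(call: FusionCall, db: AnnotationDB) -> JunctionAnnotation:
    """Frame/ORF prediction for a fusion junction.

    The transcript pair is chosen to maximise total CDS coverage
    (canonical-like), ties broken by transcript id. The fused transcript
    concatenates the 5' partner's exons through the breakpoint with the
    3' partner's exons from the breakpoint. It is in frame iff the
    phase carried over from the 5' CDS plus the 3' CDS frame at the
    junction is a whole number of codons; junctions away from annotated
    splice sites are never called in frame. When contig sequence is
    available the chimeric peptide is translated (standard nuclear code)
    to the first stop.
    """
    at_ss = junction_at_splice_sites(call, db)
    if not at_ss:
        return JunctionAnnotation(at_splice_sites=False, in_frame=False)
    donors = _donor_transcripts(db, call.gene5, call.breakpoint5)
    acceptors = _acceptor_transcripts(db, call.gene3, call.breakpoint3)
    t5, t3 = max(
        ((a, b) for a in donors for b in acceptors),
        key=lambda p: (p[0].cds_length + p[1].cds_length,
                       p[0].transcript_id, p[1].transcript_id),
    )

    exons5 = [e for e in t5.exons_transcription_order]
    idx5 = next(i for i, e in enumerate(exons5)
                if (e[1] if t5.strand == "+" else e[0]) == call.breakpoint5)
    retained5 = exons5[: idx5 + 1]
    exons3 = [e for e in t3.exons_transcription_order]
    idx3 = next(i for i, e in enumerate(exons3)
                if (e[0] if t3.strand == "+" else e[1]) == call.breakpoint3)
    retained3 = exons3[idx3:]

    ann = JunctionAnnotation(
        at_splice_sites=True,
        in_frame=False,
        transcript5=t5.transcript_id,
        transcript3=t3.transcript_id,
        retained_exons5=retained5,
        retained_exons3=retained3,
    )

    coding5 = _coding_bases_through(t5, call.breakpoint5)
    if coding5 == 0 or not t5.cds or not t3.cds:
        return ann  # noncoding 5' partner (e.g. lincRNA) or no CDS at all
    if not _breakpoint_in_cds(t5, call.breakpoint5):
        return ann  # 5' CDS already terminated upstream of the junction
    frame3 = _acceptor_frame(t3, call.breakpoint3)
    if frame3 is None:
        return ann
    carried = coding5 % 3
    ann.in_frame = (carried + frame3) % 3 == 0
    if not ann.in_frame:
        return ann

    ann.residues_from_5p = coding5 // 3
    skipped3 = (t3.cds_length and (3 - frame3) % 3) or 0
    # native 3' residues upstream of the junction phase boundary
    coding3_before = sum(
        (e - s + 1) for s, e, _ in t3.cds
        if ((t3.strand == "+" and e < call.breakpoint3)
            or (t3.strand == "-" and s > call.breakpoint3))
    )
    ann.first_retained_residue_3p = (coding3_before + skipped3) // 3 + 1
    if db.sequences is not None:
        utr5 = sum(e - s + 1 for s, e in retained5) - coding5
        cdna = (_exon_seq(db, t5.chrom, t5.strand, retained5)
                + _exon_seq(db, t3.chrom, t3.strand, retained3))
        from Bio.Seq import Seq

        orf = Seq(cdna[utr5:])
        orf = orf[: len(orf) - len(orf) % 3]
        peptide = str(orf.translate(to_stop=True))
        ann.peptide = peptide
        ann.fusion_peptide_length = len(peptide)
    return ann


@dataclass(frozen=True)
class DomainInterval:
    """A protein domain in native protein coordinates of one partner."""

    name: str
    start_aa: int  # 1-based, inclusive
    end_aa: int
    partner: str  # "5p" or "3p"

    def __post_init__(self) -> None:
        if self.start_aa < 1 or self.end_aa < self.start_aa:
            raise ValueError(f"bad domain interval {self.start_aa}-{self.end_aa}")
        if self.partner not in ("5p", "3p"):
            raise ValueError("partner must be '5p' or '3p'")


def domain_retention(
    ja: JunctionAnnotation,
    domains: list[DomainInterval],
    protein5_length: int | None = None,
    protein3_length: int | None = None,
) -> dict[str, str]:
    """Classify each supplied domain as retained, truncated or lost.

    A domain is retained iff its interval lies entirely within the
    translated portion contributed by its source partner: residues
    1..``residues_from_5p`` of the 5' protein, or residues from
    ``first_retained_residue_3p`` onward of the 3' protein. Intervals
    straddling the junction boundary are truncated; intervals entirely
    on the lost side are lost.
    """
    if not ja.in_frame:
        raise ValueError("domain retention is defined only for in-frame junctions")
    out: dict[str, str] = {}
    for d in domains:
        limit = protein5_length if d.partner == "5p" else protein3_length
        if limit is not None and d.end_aa > limit:
            raise ValueError(f"domain {d.name} extends past protein length {limit}")
        if d.partner == "5p":
            boundary = ja.residues_from_5p or 0
            if d.end_aa <= boundary:
                out[d.name] = "retained"
            elif d.start_aa > boundary:
                out[d.name] = "lost"
            else:
                out[d.name] = "truncated"
        else:
            first = ja.first_retained_residue_3p or 1
            if d.start_aa >= first:
                out[d.name] = "retained"
            elif d.end_aa < first:
                out[d.name] = "lost"
            else:
                out[d.name] = "truncated"
    return out
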