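"""The candidate filter cascade.

Call-level screening plus five successive pair-level filters turn raw
per-sample fusion calls into a short list of recurrent, tumor-enriched
candidates:

0. call-level initial criteria: >=5 discordant read pairs, >=1 junction
   split read, caller probability >=0.05 (all configurable);
1. recurrence: the pair must be positive in >=5 tumor samples;
2. enrichment: one-sided Fisher exact test, tumor vs matched benign
   positivity, keep p < alpha;
3. conditional overexpression: pairs seen in more than two benign
   samples must also show higher breakpoint RPKM in tumors (one-sided
   paired signed-rank, keep p < alpha);
4. homology control: pooled multimapping-to-total spanning-read ratio
   must not exceed 0.6 (removal is strictly greater);
5. annotation: both partners protein-coding/lincRNA/miRNA, overlapping
   gene spans discarded.

Each stage appends a :class:`CascadeLogEntry`; survivor counts are
monotonically nonincreasing. Every removed pair carries exactly one
removal reason.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import AnnotationDB, CohortManifest, FusionCall, ValidationError
from .records import CandidateRecord
from .stats import (
    DetectionContingency,
    bh_qvalues,
    breakpoint_rpkm,
    fisher_enrichment,
    paired_overexpression_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterThresholds",
    "PairSupport",
    "PairDetectionMatrix",
    "CascadeLogEntry",
    "CascadeLog",
    "CascadeResult",
    "call_passes_initial",
    "aggregate_gene_pairs",
    "recurrence_filter",
    "multimap_ratio",
    "biotype_overlap_filter",
    "run_cascade",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class FilterThresholds:
    """All tunable cutoffs of the cascade, with the published defaults."""

    min_discordant_pairs: int = 5
    min_split_reads: int = 1
    min_probability: float = 0.05
    min_tumor_samples: int = 5
    alpha: float = 0.05
    max_multimap_ratio: float = 0.6
    benign_presence_trigger: int = 2
    allowed_biotypes: frozenset[str] = frozenset({"protein_coding", "lincRNA", "miRNA"})
    read_length: int = 100  # bp; breakpoint region is 2x this

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0,1)")
        for name in ("min_discordant_pairs", "min_split_reads", "min_tumor_samples",
                     "benign_presence_trigger", "read_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 <= self.min_probability <= 1.0):
            raise ValueError("min_probability must be in [0,1]")
        if self.max_multimap_ratio < 0:
            raise ValueError("max_multimap_ratio must be nonnegative")


@dataclass(frozen=True)
class PairSupport:
    """Per-sample read support for a gene pair (from its best call)."""

    split_reads: int
    multimap_spanning: int
    total_spanning: int
    call: FusionCall


class PairDetectionMatrix:
    """Gene-pair x sample positivity with per-sample read support.

    A sample is positive for an (ordered 5',3') pair iff at least one
    screened call with that pair exists in the sample; the stored
    support comes from the call with the most split reads (aggregation
    is idempotent across duplicate calls).
    """

    def __init__(self, manifest: CohortManifest) -> None:
        self.manifest = manifest
        self._cells: dict[Pair, dict[str, PairSupport]] = {}

    def add_call(self, call: FusionCall) -> None:
        try:
            self.manifest.sample(call.sample_id)
        except KeyError:
            raise ValidationError(f"sample {call.sample_id!r} absent from manifest") from None
        cell = self._cells.setdefault(call.pair, {})
        prev = cell.get(call.sample_id)
        if prev is None or call.split_reads > prev.split_reads:
            cell[call.sample_id] = PairSupport(
                split_reads=call.split_reads,
                multimap_spanning=call.multimap_spanning,
                total_spanning=call.total_spanning,
                call=call,
            )

    @property
    def pairs(self) -> list[Pair]:
        return sorted(self._cells)

    def positive_samples(self, pair: Pair) -> list[str]:
        return sorted(self._cells.get(pair, {}))

    def support(self, pair: Pair, sample_id: str) -> PairSupport | None:
        return self._cells.get(pair, {}).get(sample_id)

    def tumor_positive_count(self, pair: Pair) -> int:
        tums = {s.sample_id for s in self.manifest.tumors}
        return sum(1 for s in self._cells.get(pair, {}) if s in tums)

    def benign_positive_count(self, pair: Pair) -> int:
        bens = {s.sample_id for s in self.manifest.benigns}
        return sum(1 for s in self._cells.get(pair, {}) if s in bens)

    def contingency(self, pair: Pair, paired_only: bool = True) -> DetectionContingency:
        """Detection 2x2 table; by default over the paired cohort only."""
        if paired_only:
            tums = [s for s in self.manifest.tumors if s.pair_id]
            bens = [s for s in self.manifest.benigns if s.pair_id]
        else:
            tums, bens = self.manifest.tumors, self.manifest.benigns
        cell = self._cells.get(pair, {})
        a = sum(1 for s in tums if s.sample_id in cell)
        c = sum(1 for s in bens if s.sample_id in cell)
        return DetectionContingency(a=a, b=len(tums) - a, c=c, d=len(bens) - c)

    def representative_call(self, pair: Pair) -> FusionCall | None:
        cell = self._cells.get(pair, {})
        if not cell:
            return None
        best = max(cell.values(), key=lambda s: (s.split_reads, s.call.sample_id))
        return best.call

    def rpkm(self, pair: Pair, sample_id: str, read_length: int) -> float:
        """Breakpoint RPKM for one sample; 0 when the fusion is undetected."""
        sup = self.support(pair, sample_id)
        if sup is None:
            return 0.0
        total = self.manifest.sample(sample_id).total_mapped_reads
        return breakpoint_rpkm(sup.split_reads, 2 * read_length, total)

    def paired_rpkm_vectors(self, pair: Pair, read_length: int) -> tuple[np.ndarray, np.ndarray]:
        """Matched (tumor, benign) breakpoint-RPKM vectors over cohort pairs."""
        t_vals, b_vals = [], []
        for pid in self.manifest.pair_ids:
            tum, ben = self.manifest.pair_members(pid)
            t_vals.append(self.rpkm(pair, tum.sample_id, read_length))
            b_vals.append(self.rpkm(pair, ben.sample_id, read_length))
        return np.array(t_vals), np.array(b_vals)


@dataclass(frozen=True)
class CascadeLogEntry:
    stage: str
    n_before: int
    n_after: int
    reason: str


class CascadeLog:
    """Ordered per-stage survivor counts (the filtering flowchart)."""

    def __init__(self) -> None:
        self.entries: list[CascadeLogEntry] = []

    def add(self, stage: str, n_before: int, n_after: int, reason: str) -> None:
        if self.entries and n_before > self.entries[-1].n_after:
            raise ValueError(
                f"stage {stage!r} starts with {n_before} candidates but the previous "
                f"stage left {self.entries[-1].n_after}"
            )
        if n_after > n_before:
            raise ValueError(f"stage {stage!r} increased the candidate count")
        self.entries.append(CascadeLogEntry(stage, n_before, n_after, reason))
        logger.info("cascade stage %-18s %6d -> %6d (%s)", stage, n_before, n_after, reason)

    @property
    def counts(self) -> list[int]:
        if not self.entries:
            return []
        return [self.entries[0].n_before] + [e.n_after for e in self.entries]

    def is_monotone(self) -> bool:
        c = self.counts
        return all(x >= y for x, y in zip(c, c[1:]))

    def to_rows(self) -> list[dict[str, object]]:
        return [
            {"stage": e.stage, "n_before": e.n_before, "n_after": e.n_after, "reason": e.reason}
            for e in self.entries
        ]


def call_passes_initial(call: FusionCall, t: FilterThresholds) -> bool:
    """Call-level screening; all boundaries are inclusive ('at least')."""
    return (
        call.discordant_pairs >= t.min_discordant_pairs
        and call.split_reads >= t.min_split_reads
        and call.probability >= t.min_probability
    )


def aggregate_gene_pairs(
    calls: Iterable[FusionCall],
    manifest: CohortManifest,
    t: FilterThresholds,
) -> PairDetectionMatrix:
    """Collapse screened calls into the pair x sample detection matrix."""
    m = PairDetectionMatrix(manifest)
    for call in calls:
        m.add_call(call)
    return m


def recurrence_filter(
    m: PairDetectionMatrix, t: FilterThresholds, pairs: Sequence[Pair] | None = None
) -> tuple[list[Pair], dict[Pair, str]]:
    """Keep pairs positive in at least ``min_tumor_samples`` tumors."""
    pairs = list(pairs) if pairs is not None else m.pairs
    removed: dict[Pair, str] = {}
    kept = []
    for p in pairs:
        n = m.tumor_positive_count(p)
        if n >= t.min_tumor_samples:
            kept.append(p)
        else:
            removed[p] = f"recurrence: positive in {n} < {t.min_tumor_samples} tumors"
    return kept, removed


def multimap_ratio(m: PairDetectionMatrix, pair: Pair) -> float:
    """Pooled multimapping-spanning to total-spanning ratio over positive samples."""
    cell_samples = m.positive_samples(pair)
    mm = sum(m.support(pair, s).multimap_spanning for s in cell_samples)
    tot = sum(m.support(pair, s).total_spanning for s in cell_samples)
    if tot == 0:
        warnings.warn(f"pair {pair}: zero total spanning reads; ratio set to 0", stacklevel=2)
        return 0.0
    return mm / tot


def biotype_overlap_filter(
    pair: Pair, db: AnnotationDB, t: FilterThresholds
) -> tuple[bool, str | None]:
    """Drop pairs with disallowed biotypes or overlapping gene spans."""
    for key in pair:
        if not db.has_gene(key):
            return False, f"biotype: gene {key!r} unannotated"
    for key in pair:
        bt = db.gene(key).biotype
        if "pseudogene" in bt or bt not in t.allowed_biotypes:
            return False, f"biotype: {key} is {bt}"
    if db.spans_overlap(pair[0], pair[1]):
        return False, "overlap: partner gene spans overlap"
    return True, None


@dataclass
class CascadeResult:
    """Survivors plus the full audit trail of a cascade run."""

    records: list[CandidateRecord]
    log: CascadeLog
    removed: dict[Pair, str]
    matrix: PairDetectionMatrix

    @property
    def surviving_pairs(self) -> list[Pair]:
        return [r.pair for r in self.records]


def run_cascade(
    calls: Iterable[FusionCall],
    manifest: CohortManifest,
    db: AnnotationDB | None,
    t: FilterThresholds | None = None,
) -> CascadeResult:
    """Run the full cascade and emit survivors as CandidateRecords.

    Stage order: call-level screening, recurrence, Fisher enrichment,
    conditional paired overexpression, multimap ratio, biotype/overlap.
    Passing ``db=None`` skips the annotation stage (useful for purely
    statistical cohorts). The result carries the surviving records, the
    stage log, the per-pair removal reasons (exactly one per removed
    pair) and the detection matrix for downstream association analysis.
    """
    t = t or FilterThresholds()
    log = CascadeLog()
    removed: dict[Pair, str] = {}

    calls = list(calls)
    passing = [c for c in calls if call_passes_initial(c, t)]
    log.add("initial_criteria", len(calls), len(passing),
            f">={t.min_discordant_pairs} discordant pairs, >={t.min_split_reads} "
            f"split reads, probability>={t.min_probability}")

    m = aggregate_gene_pairs(passing, manifest, t)
    all_pairs = m.pairs
    log.add("aggregate_pairs", len(passing), len(all_pairs), "distinct ordered gene pairs")

    surviving, rem = recurrence_filter(m, t)
    removed.update(rem)
    log.add("recurrence", len(all_pairs), len(surviving),
            f"positive in >= {t.min_tumor_samples} tumors")

    fisher_ps: dict[Pair, float] = {}
    kept = []
    for p in surviving:
        fisher_ps[p] = fisher_enrichment(m.contingency(p))
        if fisher_ps[p] < t.alpha:
            kept.append(p)
        else:
            removed[p] = f"enrichment: Fisher p={fisher_ps[p]:.3g} >= {t.alpha}"
    qvals = dict(zip(surviving, bh_qvalues([fisher_ps[p] for p in surviving])))
    log.add("enrichment", len(surviving), len(kept),
            f"one-sided Fisher p < {t.alpha}")
    surviving = kept

    wilcoxon_ps: dict[Pair, float] = {}
    kept = []
    for p in surviving:
        if m.benign_positive_count(p) > t.benign_presence_trigger:
            tv, bv = m.paired_rpkm_vectors(p, t.read_length)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                wilcoxon_ps[p] = paired_overexpression_test(tv, bv)
            if wilcoxon_ps[p] < t.alpha:
                kept.append(p)
            else:
                removed[p] = (f"overexpression: signed-rank p={wilcoxon_ps[p]:.3g} "
                              f">= {t.alpha}")
        else:
            kept.append(p)  # not benign-prevalent enough to require the test
    log.add("overexpression", len(surviving), len(kept),
            f"paired signed-rank p < {t.alpha} when benign-positive "
            f"> {t.benign_presence_trigger}")
    surviving = kept

    kept = []
    for p in surviving:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = multimap_ratio(m, p)
        if r > t.max_multimap_ratio:
            removed[p] = f"multimap: ratio {r:.3f} > {t.max_multimap_ratio}"
        else:
            kept.append(p)
    log.add("multimap_ratio", len(surviving), len(kept),
            f"pooled multimap/total spanning ratio <= {t.max_multimap_ratio}")
    surviving = kept

    if db is not None:
        kept = []
        for p in surviving:
            ok, reason = biotype_overlap_filter(p, db, t)
            if ok:
                kept.append(p)
            else:
                removed[p] = reason
        log.add("biotype_overlap", len(surviving), len(kept),
                "partners protein-coding/lincRNA/miRNA, non-overlapping")
        surviving = kept

    records = []
    for p in surviving:
        tv_pos = [m.rpkm(p, s, t.read_length)
                  for s in m.positive_samples(p)
                  if manifest.sample(s).condition == "tumor"]
        bv_pos = [m.rpkm(p, s, t.read_length)
                  for s in m.positive_samples(p)
                  if manifest.sample(s).condition == "benign"]
        records.append(
            CandidateRecord(
                gene5=p[0],
                gene3=p[1],
                contingency=m.contingency(p),
                fisher_p=fisher_ps[p],
                fisher_q=qvals.get(p),
                wilcoxon_p=wilcoxon_ps.get(p),
                mean_rpkm_tumor=float(np.mean(tv_pos)) if tv_pos else 0.0,
                var_rpkm_tumor=float(np.var(tv_pos, ddof=1)) if len(tv_pos) >= 2 else None,
                mean_rpkm_benign=float(np.mean(bv_pos)) if bv_pos else 0.0,
                var_rpkm_benign=float(np.var(bv_pos, ddof=1)) if len(bv_pos) >= 2 else None,
                representative_call=m.representative_call(p),
            )
        )
    return CascadeResult(records=records, log=log, removed=removed, matrix=m)
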