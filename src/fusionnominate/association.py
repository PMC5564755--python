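"""3'-partner expression association: the read-through signature.

A fusion transcribed by RNA-polymerase read-through runs off the 5'
partner's promoter, so its presence should (i) raise the expression of
the 3' partner gene in fusion-positive samples, (ii) correlate the
fusion's breakpoint expression with the partner's expression across
samples, and (iii) raise only the exons downstream of the junction —
the 3' partner's own first exon, which the fusion does not contain,
should not follow. This module quantifies all three.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .filters import Pair, PairDetectionMatrix
from .io import CohortManifest, ExpressionMatrix
from .stats import unpaired_overexpression_test

__all__ = [
    "AssociationResult",
    "ExonContrast",
    "partition_samples",
    "three_prime_partner_test",
    "fusion_partner_correlation",
    "exon_contrast",
    "read_through_signature",
]


@dataclass
class AssociationResult:
    candidate: str
    p_pos_vs_neg_tumor: float | None
    p_pos_vs_benign: float | None
    spearman_rho: float | None
    spearman_p: float | None
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class ExonContrast:
    exon_id: str
    upstream_of_junction: bool
    mean_pos: float
    mean_neg: float
    p: float


def partition_samples(
    pair: Pair, m: PairDetectionMatrix, manifest: CohortManifest
) -> tuple[list[str], list[str], list[str]]:
    """(fusion-positive tumors, fusion-negative tumors, benign samples).

    A disjoint, exhaustive partition of the manifest's samples; benign
    samples are not split by positivity (they serve as the reference
    group regardless).
    """
    positives = set(m.positive_samples(pair))
    pos = [s.sample_id for s in manifest.tumors if s.sample_id in positives]
    neg = [s.sample_id for s in manifest.tumors if s.sample_id not in positives]
    ben = [s.sample_id for s in manifest.benigns]
    return pos, neg, ben


def three_prime_partner_test(
    expr: ExpressionMatrix,
    gene3: str,
    partition: tuple[list[str], list[str], list[str]],
) -> tuple[float | None, float | None]:
    """One-sided rank-sum p-values for 3'-partner overexpression.

    Tests positive tumors against negative tumors and against benign
    samples; an empty group yields None with a warning.
    """
    pos, neg, ben = partition
    results: list[float | None] = []
    for other, label in ((neg, "fusion-negative tumors"), (ben, "benign samples")):
        if not pos or not other:
            warnings.warn(f"empty group for contrast vs {label}; p undefined", stacklevel=2)
            results.append(None)
            continue
        results.append(unpaired_overexpression_test(
            expr.vector(gene3, pos), expr.vector(gene3, other)))
    return results[0], results[1]


def fusion_partner_correlation(
    fusion_expr: Sequence[float],
    partner_expr: Sequence[float],
    log_transform: bool = True,
) -> tuple[float | None, float | None]:
    """Spearman correlation of fusion breakpoint expression vs 3'-partner expression.

    With ``log_transform`` both vectors get log2(x+1) first (rank-
    preserving; kept for consistency with plotted values). Constant
    input yields (None, None) with a warning.
    """
    f = np.asarray(fusion_expr, dtype=float)
    p = np.asarray(partner_expr, dtype=float)
    if f.shape != p.shape or f.ndim != 1:
        raise ValueError("vectors must be 1-d and of equal length")
    if log_transform:
        f, p = np.log2(f + 1), np.log2(p + 1)
    if np.all(f == f[0]) or np.all(p == p[0]):
        warnings.warn("constant vector; Spearman correlation undefined", stacklevel=2)
        return None, None
    rho, pval = _sps.spearmanr(f, p, alternative="greater")
    n = f.size
    tie_free = len(np.unique(f)) == n and len(np.unique(p)) == n
    if n <= 7 and tie_free:
        # exact one-sided permutation tail (n! pairings) instead of the
        # t-distribution approximation
        from itertools import permutations

        rf = _sps.rankdata(f)
        rp = _sps.rankdata(p)
        count = total = 0
        for perm in permutations(rp):
            r = np.corrcoef(rf, perm)[0, 1]
            count += r >= rho - 1e-12
            total += 1
        pval = count / total
    return float(rho), float(pval)


def exon_contrast(
    exon_counts: ExpressionMatrix,
    exon_coords: Mapping[str, tuple[int, int]],
    junction_pos: int,
    strand: str,
    partition: tuple[list[str], list[str], list[str]],
    manifest: CohortManifest,
) -> list[ExonContrast]:
    """Per-exon positive-vs-negative contrast around the fusion junction.

    Exon counts are normalised to counts-per-million by each sample's
    library size, exons are labelled upstream/downstream of the junction
    in the 3' partner's transcription direction, and each exon gets a
    one-sided rank-sum p (positive tumors > negative tumors). Exons
    whose id is missing from ``exon_coords`` raise; an empty coordinate
    map is an error.
    """
    if not exon_coords:
        raise ValueError("no exon features supplied")
    pos, neg, _ = partition
    if not pos or not neg:
        raise ValueError("both tumor groups must be nonempty for the exon contrast")
    libsize = {s.sample_id: s.total_mapped_reads for s in manifest.samples}
    out = []
    for exon_id, (start, end) in exon_coords.items():
        if exon_id not in exon_counts.features:
            raise KeyError(f"exon {exon_id!r} not in count matrix")
        if strand == "+":
            upstream = end < junction_pos
        else:
            upstream = start > junction_pos
        cpm_pos = np.array([
            exon_counts.values.loc[exon_id, s] / libsize[s] * 1e6 for s in pos])
        cpm_neg = np.array([
            exon_counts.values.loc[exon_id, s] / libsize[s] * 1e6 for s in neg])
        p = unpaired_overexpression_test(cpm_pos, cpm_neg)
        out.append(ExonContrast(
            exon_id=exon_id,
            upstream_of_junction=upstream,
            mean_pos=float(cpm_pos.mean()),
            mean_neg=float(cpm_neg.mean()),
            p=p,
        ))
    return out


def read_through_signature(contrasts: Sequence[ExonContrast], alpha: float = 0.05) -> bool:
    """True when downstream exons rise in positives but the most-upstream does not.

    Detection rule: at least half of the downstream exons show a
    significant one-sided contrast, while the most-upstream exon does
    not. With no upstream exon (junction upstream of the whole gene)
    only the downstream condition applies.
    """
    down = [c for c in contrasts if not c.upstream_of_junction]
    up = [c for c in contrasts if c.upstream_of_junction]
    if not down:
        return False
    down_hit = sum(c.p < alpha for c in down) >= max(1, len(down) / 2)
    if not up:
        return down_hit
    most_upstream = up[0]
    return down_hit and most_upstream.p >= alpha
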