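"""Cohort-level statistics for fusion-transcript nomination.

The nomination cascade rests on four statistical primitives:

* a one-sided Fisher exact test for enrichment of fusion-positive samples
  in tumors relative to matched benign tissue (exact rational arithmetic,
  so that reported tail probabilities are reproducible to the last digit);
* a one-sided paired Wilcoxon signed-rank test for overexpression of the
  fusion transcript in tumor versus matched benign tissue, with an exact
  dynamic-programming null for small cohorts and a tie-corrected normal
  approximation otherwise;
* a one-sided Mann-Whitney rank-sum test for unpaired contrasts;
* breakpoint RPKM: split reads mapped to the junction region, normalised
  by region length and library size.

Also provided: the per-fusion differential-expression normalisation used
for expression profiling (each fusion's tumor-minus-benign differences
scaled by their maximum absolute value, so profiles live in [-1, 1]) and
hierarchical clustering of those profiles under Pearson-correlation
distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats as _sps
from scipy.cluster import hierarchy as _sch
from scipy.spatial.distance import squareform

__all__ = [
    "DetectionContingency",
    "fisher_enrichment",
    "fisher_enrichment_exact",
    "paired_overexpression_test",
    "unpaired_overexpression_test",
    "breakpoint_rpkm",
    "normalize_differential",
    "cluster_profiles",
    "format_pvalue",
    "bh_qvalues",
]


@dataclass(frozen=True)
class DetectionContingency:
    """2x2 detection table: positive/negative sample counts per condition.

    ``a``/``b`` are tumor positive/negative counts, ``c``/``d`` benign
    positive/negative counts.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"contingency cell {name}={v!r} must be a nonnegative integer")

    @property
    def n_tumor(self) -> int:
        return self.a + self.b

    @property
    def n_benign(self) -> int:
        return self.c + self.d


def fisher_enrichment_exact(ct: DetectionContingency) -> Fraction:
    """One-sided Fisher exact tail as an exact rational.

    Probability, under the hypergeometric null with the table's margins,
    of observing at least ``a`` tumor-positive samples (alternative:
    positivity is greater in tumors).
    """
    a, b, c, d = ct.a, ct.b, ct.c, ct.d
    n = a + b + c + d
    k_pos = a + c           # total positives
    n_tum = a + b
    a_max = min(k_pos, n_tum)
    num = sum(math.comb(k_pos, k) * math.comb(n - k_pos, n_tum - k) for k in range(a, a_max + 1))
    return Fraction(num, math.comb(n, n_tum))


def fisher_enrichment(ct: DetectionContingency) -> float:
    """One-sided (greater positivity in tumors) Fisher exact p-value.

    Computed in exact integer arithmetic and converted to float at the
    end; rounding for display happens only at the report layer.
    """
    return float(fisher_enrichment_exact(ct))


def _signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of ranks of positive differences) and the midranks used."""
    ranks = _sps.rankdata(np.abs(diffs))
    w_pos = float(ranks[diffs > 0].sum())
    return w_pos, ranks


def _exact_signed_rank_sf(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ >= w_obs) by dynamic programming over sign assignments.

    Midranks are half-integers, so everything is doubled to stay in
    integer arithmetic. Exact for arbitrary tie patterns.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w2 = int(math.ceil(round(2 * w_obs, 6)))
    tail = int(sum(counts[w2:]))
    return tail / float(2 ** len(ranks))


def paired_overexpression_test(
    tumor_values: Sequence[float],
    benign_values: Sequence[float],
    *,
    exact_limit: int = 25,
) -> float:
    """One-sided paired Wilcoxon signed-rank p (alternative: tumor > benign).

    Zero differences are dropped before ranking (classic Wilcoxon
    treatment). With at most ``exact_limit`` nonzero pairs the null is
    enumerated exactly; beyond that a tie-corrected normal approximation
    with continuity correction is used.
    """
    t = np.asarray(tumor_values, dtype=float)
    b = np.asarray(benign_values, dtype=float)
    if t.shape != b.shape or t.ndim != 1:
        raise ValueError("paired test needs equal-length 1-d vectors")
    diffs = t - b
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1.0", stacklevel=2)
        return 1.0
    w_pos, ranks = _signed_rank_statistic(diffs)
    if n <= exact_limit:
        return _exact_signed_rank_sf(ranks, w_pos)
    mean = n * (n + 1) / 4.0
    # tie correction on the variance of W+
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w_pos - mean - 0.5) / math.sqrt(var)
    return float(_sps.norm.sf(z))


def unpaired_overexpression_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """One-sided Mann-Whitney rank-sum p (alternative: a > b), tie-corrected.

    No continuity correction, so two identical groups give p = 0.5 under
    the normal approximation (exact enumeration is used by scipy when
    the samples are small and tie-free).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    return float(_sps.mannwhitneyu(a, b, alternative="greater", use_continuity=False).pvalue)


def breakpoint_rpkm(split_reads: int, region_length_bp: int, total_mapped: int) -> float:
    """Reads per kilobase of breakpoint region per million mapped reads.

    The junction region is the window in which a read can align across
    the breakpoint; its length is a configuration choice (by default
    twice the read length).
    """
    if region_length_bp <= 0:
        raise ValueError("region_length_bp must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if split_reads < 0:
        raise ValueError("split_reads must be nonnegative")
    return split_reads / (region_length_bp / 1_000.0) / (total_mapped / 1_000_000.0)


def normalize_differential(tumor: np.ndarray, benign: np.ndarray) -> np.ndarray:
    """Row-wise max-scaled tumor-minus-benign differential expression.

    For fusion i and pair j the normalised value is
    ``(T_ij - N_ij) / max_j |T_ij - N_ij|``, so each fusion's profile is
    in [-1, 1] with at least one entry hitting +-1 unless the row is
    identically zero (which maps to zeros).
    """
    t = np.asarray(tumor, dtype=float)
    n = np.asarray(benign, dtype=float)
    if t.shape != n.shape:
        raise ValueError("tumor and benign matrices must have the same shape")
    if np.isnan(t).any() or np.isnan(n).any():
        raise ValueError("NaN in expression input")
    diff = np.atleast_2d(t - n)
    denom = np.abs(diff).max(axis=1, keepdims=True)
    out = np.divide(diff, denom, out=np.zeros_like(diff), where=denom > 0)
    return out[0] if t.ndim == 1 else out


def cluster_profiles(
    profiles: np.ndarray,
    ids: Sequence[str] | None = None,
    linkage: str = "average",
) -> tuple[np.ndarray, list[int], list[str]]:
    """Hierarchical clustering of expression profiles under Pearson distance.

    Distance between two profiles is ``1 - r`` (Pearson correlation), so
    identical profiles merge at 0 and a profile and its negation sit at
    distance 2. Zero-variance rows (Pearson undefined) are excluded with
    a warning. Returns the linkage matrix, the leaf order (indices into
    the kept rows) and the kept row ids.
    """
    m = np.atleast_2d(np.asarray(profiles, dtype=float))
    if ids is None:
        ids = [str(i) for i in range(m.shape[0])]
    ids = list(ids)
    keep = m.std(axis=1) > 0
    if not keep.all():
        dropped = [ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"excluding zero-variance profiles from clustering: {dropped}", stacklevel=2)
    m = m[keep]
    kept_ids = [i for i, k in zip(ids, keep) if k]
    if m.shape[0] < 2:
        raise ValueError("need at least two non-degenerate profiles to cluster")
    corr = np.corrcoef(m)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    z = _sch.linkage(squareform(dist, checks=False), method=linkage)
    order = list(_sch.leaves_list(z))
    return z, order, kept_ids


def format_pvalue(p: float | None) -> str:
    """Render a p-value to 2 significant figures in scientific notation.

    ``None`` (unavailable) renders as ``"*"``, the placeholder used in
    the nomination report for cells that cannot be computed.
    """
    if p is None:
        return "*"
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value out of range: {p}")
    return f"{p:.1E}"


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported for transparency only)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
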