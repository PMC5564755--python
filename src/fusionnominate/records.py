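"""Summary record for one nominated fusion candidate.

A :class:`CandidateRecord` collects everything the nomination report
prints for a gene pair: detection contingency and enrichment p-value,
the conditional paired overexpression p-value, breakpoint-expression
summaries, partner geometry and junction annotation, and (optionally)
the 3'-partner association results. Fields that cannot be computed stay
``None`` and render as ``"*"`` in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import FusionCall
from .stats import DetectionContingency


@dataclass
class CandidateRecord:
    gene5: str
    gene3: str
    contingency: DetectionContingency
    fisher_p: float
    fisher_q: float | None = None
    wilcoxon_p: float | None = None
    mean_rpkm_tumor: float | None = None
    var_rpkm_tumor: float | None = None
    mean_rpkm_benign: float | None = None
    var_rpkm_benign: float | None = None
    geometry: object | None = None       # PairGeometry
    junction: object | None = None       # JunctionAnnotation
    association: object | None = None    # AssociationResult
    representative_call: FusionCall | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)

    @property
    def pair_label(self) -> str:
        return f"{self.gene5}-{self.gene3}"
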