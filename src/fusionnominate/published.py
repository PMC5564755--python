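"""Published detection counts for nominated fusion transcripts.

The packaged table carries, for each of 21 recurrent fusion transcripts
nominated in a 44-pair prostate tumor/benign RNA-seq cohort, the number
of fusion-positive tumor and benign samples and the enrichment p-value
as originally printed (2 significant figures). These counts serve as a
reference input for the enrichment statistics: recomputing the
one-sided Fisher exact p from the counts reproduces the printed value
for the 17 rows flagged ``reproducible``; the remaining four printed
values cannot be obtained from the printed counts under any standard
one- or two-sided variant (see docs/methods.md) and are excluded from
exact-match checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_published_counts"]


def load_published_counts() -> pd.DataFrame:
    """The published 44-pair cohort detection counts as a DataFrame."""
    ref = resources.files("fusionnominate") / "data" / "published_cohort_counts.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"printed_fisher_p": str})
    df["reproducible"] = df["reproducible"] == "Y"
    return df
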