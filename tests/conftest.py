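import warnings
from pathlib import Path

import pytest

from fusionnominate import filters, io
from fusionnominate.simulate import SyntheticConfig, generate_cohort

COHORT_SEED = 20260


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Default synthetic cohort: 44 pairs + 50 extra tumors, 3 planted
    enriched read-through fusions, 1 homology artifact, 200 background pairs."""
    out = tmp_path_factory.mktemp("cohort")
    bundle, truth = generate_cohort(SyntheticConfig(seed=COHORT_SEED), out)
    return bundle, truth


@pytest.fixture(scope="session")
def cohort_inputs(cohort):
    """Parsed inputs of the default cohort: (calls, manifest, annotation db)."""
    bundle, _ = cohort
    manifest = io.read_manifest(bundle.manifest)
    calls = []
    for f in sorted(bundle.calls_dir.glob("*.tsv")):
        calls.extend(io.read_fusion_table(f, strict=False).calls)
    db = io.read_annotation(bundle.gtf, fasta=bundle.fasta)
    return calls, manifest, db


@pytest.fixture(scope="session")
def cascade_result(cohort_inputs):
    calls, manifest, db = cohort_inputs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return filters.run_cascade(calls, manifest, db)
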