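import random

import pytest
from hypothesis import HealthCheck, settings

from coconut_census import (
    GenomeBundle,
    SimConfig,
    annotate_proteins,
    classify_all,
    generate_genome,
    mock_profile_adapter,
    run_census,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: random.Random, n: int, forbid: str = "") -> str:
    alphabet = [a for a in AA if a not in forbid]
    return "".join(rng.choice(alphabet) for _ in range(n))


@pytest.fixture(scope="session")
def genome():
    """One deterministic synthetic genome shared by read-only tests."""
    return generate_genome(SimConfig(seed=11, loci_per_subtype=1))


@pytest.fixture(scope="session")
def pipeline(genome):
    """The full pipeline run on the shared genome: annotated bundle, hits,
    systems, funnel, and classification calls."""
    bundle, truth, planted = genome
    adapter = mock_profile_adapter(planted)
    hits = annotate_proteins(bundle, adapter)
    annotated = GenomeBundle(
        contigs=bundle.contigs, proteins=bundle.proteins, hits=hits
    )
    systems, funnel = run_census(annotated, adapter)
    calls = classify_all(systems, annotated, hits)
    return {
        "bundle": annotated,
        "truth": truth,
        "planted": planted,
        "adapter": adapter,
        "hits": hits,
        "systems": systems,
        "funnel": funnel,
        "calls": calls,
    }
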