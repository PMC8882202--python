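import pytest

from sdhbcurate import GeneratorConfig, generate
from sdhbcurate.acmg_engine import classify_acmg
from sdhbcurate.consensus import DualClassification, run_consensus
from sdhbcurate.ngsnppgl_engine import classify_ngsnppgl


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic cohort (737 cases, 223 distinct variants)."""
    return generate(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def pipeline_results(bundle):
    """Full pipeline run on the session cohort with an empty override ledger."""
    pairs = []
    for profile in bundle.profiles:
        acmg_class, _ = classify_acmg(profile)
        ngs_class, _ = classify_ngsnppgl(profile)
        pairs.append(DualClassification(profile.variant, acmg_class, ngs_class))
    profile_map = {p.variant.cdna: p for p in bundle.profiles}
    return run_consensus(pairs, profile_map)
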