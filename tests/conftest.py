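import pytest

from risipipe import (
    ReferenceIndex,
    attach_adapters,
    build_default_reference,
    build_profile,
    load_preset,
    run_pipeline,
    simulate_library,
)
from risipipe.reference import RdnaUnit, RegionInterval


@pytest.fixture(scope="session")
def reference():
    """Default deterministic reference (unit + decoys), seed 1."""
    return build_default_reference(1)


@pytest.fixture(scope="session")
def unit(reference):
    return reference[0]


@pytest.fixture(scope="session")
def decoys(reference):
    return reference[1]


@pytest.fixture(scope="session")
def index(unit, decoys):
    return ReferenceIndex(unit, decoys)


@pytest.fixture
def tiny_unit():
    """100 nt unit with the minimal valid 7-region tiling."""
    seq = ("ACGT" * 25)[:100]
    bounds = [(0, 10), (10, 40), (40, 50), (50, 55), (55, 60), (60, 95), (95, 100)]
    names = ["5ETS", "18S", "ITS1", "5.8S", "ITS2", "26S", "3ETS"]
    regions = tuple(RegionInterval(n, s, e) for n, (s, e) in zip(names, bounds))
    return RdnaUnit(name="tiny", sequence=seq, regions=regions)


@pytest.fixture(scope="session")
def disl2_run(unit, decoys, index):
    """Full noise-free disl-2 run at n=100,000, seed 1 (shared across tests)."""
    profile = load_preset("disl-2", n_reads=100_000, seed=1)
    reads, truth = simulate_library(profile, unit, decoys)
    with_adapters = attach_adapters(reads)
    classified = run_pipeline(with_adapters, index)
    risiprofile = build_profile(classified, unit)
    return {
        "profile": profile,
        "reads": reads,
        "truth": truth,
        "classified": classified,
        "risiprofile": risiprofile,
    }
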