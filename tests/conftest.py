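import pytest

from butenolide_scout import synthetic
from butenolide_scout.synthetic import FamilySpec, GenomePlan


@pytest.fixture(scope="session")
def three_family_records():
    """3 families x 10 members, length 200, identities 0.9 within / 0.3 between."""
    spec = FamilySpec(
        n_families=3, members_per_family=10, length=200,
        within_identity=0.9, between_identity=0.3, seed=11,
    )
    records, truth = synthetic.make_families(spec)
    return records, truth


@pytest.fixture(scope="session")
def planted_genome():
    """One genome: 3 true operons + 4 decoys (one per decoy class)."""
    plan = GenomePlan(seed=7)
    genome, table, truth = synthetic.make_genomes(plan)
    return genome, table, truth
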