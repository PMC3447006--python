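import pytest

from ploidysel import (
    DesignConfig,
    default_architecture,
    run_experiment,
)
from ploidysel.pedigree import Pedigree, PedigreeRecord


def rec(
    id,
    dam="0",
    sire="0",
    fam=None,
    line="L",
    gen=0,
    ploidy=2,
    fertile=True,
):
    return PedigreeRecord(
        id=id,
        dam_id=dam,
        sire_id=sire,
        maternal_family=fam if fam is not None else f"fam.{dam}",
        line=line,
        generation=gen,
        ploidy=ploidy,
        fertile=fertile,
    )


@pytest.fixture(scope="session")
def diploid_record():
    """One full simulated diploid experiment, shared across tests."""
    design = DesignConfig.diploid()
    arch = default_architecture(design, 0.40)
    return run_experiment(design, arch, seed=2024)


@pytest.fixture(scope="session")
def neo_record():
    design = DesignConfig.neotetraploid()
    arch = default_architecture(design, 0.55)
    return run_experiment(design, arch, seed=2024)


@pytest.fixture()
def full_sib_pedigree():
    """A, B founders; C, D full sibs; X their offspring (F = 1/4)."""
    return Pedigree.from_records(
        [
            rec("A"),
            rec("B"),
            rec("C", "A", "B", gen=1),
            rec("D", "A", "B", gen=1),
            rec("X", "C", "D", gen=2),
        ]
    )
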