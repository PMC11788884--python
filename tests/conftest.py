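import pytest

from dsog import DomainHit, ProteinRecord
from dsog.fixtures import reference_tree


def make_hit(
    species: str,
    gene: str,
    acc: str,
    start: int = 10,
    end: int = 100,
    evalue: float = 1e-10,
    cov: float = 0.9,
    length: int = 1000,
    protein: str | None = None,
) -> DomainHit:
    return DomainHit(
        protein=ProteinRecord(
            species_id=species,
            gene_id=gene,
            protein_id=protein or f"{gene}.p1",
            length=length,
        ),
        pfam_acc=acc,
        pfam_name=acc,
        env_start=start,
        env_end=end,
        evalue=evalue,
        model_cov=cov,
    )


@pytest.fixture(scope="session")
def tree22():
    """The packaged 22-species tree with the three named clades."""
    return reference_tree()
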