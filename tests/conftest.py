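import numpy as np
import pytest

from privar.consequence import TranscriptModel
from privar.simulate import CohortSimSpec, simulate_fixture

# Reduced-scale generator spec used by most tests: same structure as the
# full study-shaped fixture but seconds-fast.
SMALL_SPEC_KWARGS = dict(
    contig_lengths=(60_000, 60_000),
    genes_per_contig=4,
    het_shared=30,
    hom_shared=6,
    protein_changing_het=4,
    protein_changing_hom=0,
    background_shared=20,
    singletons_per_sample=1,
    n_cases=2,
    n_controls=6,
)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    spec = CohortSimSpec(seed=11, **SMALL_SPEC_KWARGS)
    return simulate_fixture(spec, tmp_path_factory.mktemp("fixture"))


def random_reference(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def random_transcript(
    rng: np.random.Generator,
    contig: str,
    contig_len: int,
    n_codons: int,
    strand: str,
    n_exons: int | None = None,
) -> TranscriptModel:
    """Random multi-exon transcript with interval-spanning codons."""
    n_exons = n_exons or int(rng.integers(2, 5))
    total = 3 * n_codons
    cuts = sorted(rng.choice(np.arange(1, total), size=n_exons - 1, replace=False))
    lengths = np.diff([0, *cuts, total])
    start = int(rng.integers(1, contig_len - total - 100 * n_exons))
    ivs = []
    pos = start
    for el in lengths:
        ivs.append((pos, pos + int(el) - 1))
        pos += int(el) + int(rng.integers(5, 60))
    if strand == "-":
        ivs = ivs[::-1]
    return TranscriptModel("tx-rand", "RANDGENE", contig, strand, tuple(ivs))
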