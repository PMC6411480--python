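import numpy as np
import pytest

from domarch.io_formats import DomainHit, GeneRecord, Source, Strand
from domarch.synthetic_data import CohortConfig, simulate


def make_hit(
    protein_id="p1",
    domain_id="PDZ",
    source=Source.PFAM,
    seq_evalue=1e-10,
    dom_evalue=1e-10,
    start=1,
    end=80,
    bit_score=100.0,
):
    return DomainHit(
        protein_id=protein_id,
        domain_id=domain_id,
        source=source,
        seq_evalue=seq_evalue,
        dom_evalue=dom_evalue,
        start=start,
        end=end,
        bit_score=bit_score,
    )


def make_gene(start, end, strand="+", locus="g", name="", replicon="chr", pid="", product=""):
    return GeneRecord(
        replicon_id=replicon,
        start=start,
        end=end,
        strand=Strand(strand),
        locus_tag=locus,
        gene_name=name,
        product=product,
        protein_id=pid,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort reused by several test modules (seeded, deterministic)."""
    return simulate(CohortConfig(n_genomes=20, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
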