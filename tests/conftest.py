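import numpy as np
import pytest

from chrysodiag import (
    ComplexSimConfig,
    MultiLocusAlignment,
    ScanOptions,
    SequenceRecord,
    simulate_locus_alignments,
)


@pytest.fixture(scope="session")
def default_complex():
    """A moderate synthetic complex shared by read-only tests."""
    cfg = ComplexSimConfig(n_isolates_per_species=5, seed=3)
    mla, truth = simulate_locus_alignments(cfg)
    return cfg, mla, truth


@pytest.fixture(scope="session")
def scan_options():
    return ScanOptions(outgroup_species=frozenset(("flavigenum",)))


def make_alignment(columns_by_species, locus="locA"):
    """Build a tiny single-locus alignment from per-species sequence lists.

    ``columns_by_species``: dict species -> list of equal-length strings.
    """
    records = []
    partition = {}
    for sp, seqs in columns_by_species.items():
        for i, s in enumerate(seqs):
            iid = f"{sp}{i}"
            records.append(SequenceRecord(id=iid, residues=s, locus=locus))
            partition[iid] = sp
    return MultiLocusAlignment([locus], {locus: records}, partition)


@pytest.fixture
def tiny_alignment_factory():
    return make_alignment


def random_alignment(rng, n_species=4, n_per_species=2, length=200, locus="locA"):
    """Random alignment with species-level divergence so diagnostic columns
    occur by chance; used for oracle-equivalence tests."""
    bases = np.array(list("ACGT"))
    species_seqs = {}
    root = rng.integers(0, 4, size=length)
    for s in range(n_species):
        sp_seq = root.copy()
        mut = rng.random(length) < 0.05
        sp_seq[mut] = (sp_seq[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
        seqs = []
        for _ in range(n_per_species):
            iso = sp_seq.copy()
            mut = rng.random(length) < 0.01
            iso[mut] = (iso[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
            seqs.append("".join(bases[iso]))
        species_seqs[f"sp{s}"] = seqs
    return make_alignment(species_seqs, locus=locus)
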