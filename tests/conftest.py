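import gzip

import pytest

from repliskew.genome_io import GeneAnnotation, SequenceRecord
from repliskew.synthetic import SyntheticSpec, simulate_genome


@pytest.fixture
def fasta_file(tmp_path):
    """Write a FASTA file from (header, sequence) pairs; returns the path."""

    def _write(entries, name="test.fasta", compress=False):
        text = "".join(f">{header}\n{seq}\n" for header, seq in entries)
        path = tmp_path / name
        if compress:
            path = tmp_path / (name + ".gz")
            with gzip.open(path, "wt") as handle:
                handle.write(text)
        else:
            path.write_text(text)
        return path

    return _write


@pytest.fixture
def gff3_file(tmp_path):
    """Write a GFF3 file from raw feature lines; returns the path."""

    def _write(lines, name="test.gff3"):
        path = tmp_path / name
        path.write_text("##gff-version 3\n" + "".join(line + "\n" for line in lines))
        return path

    return _write


def make_record(residues, accession="X", description=""):
    return SequenceRecord(
        accession=accession,
        description=description,
        residues=residues,
        is_plasmid="plasmid" in description.lower(),
    )


def make_gene(start, end, strand=1, seq_id="X", name=""):
    return GeneAnnotation(seq_id=seq_id, start=start, end=end, strand=strand, name=name)


@pytest.fixture(scope="session")
def megabase_deterministic():
    """A 1 Mb noiseless genome with the 0.046 example rate (shared, slow)."""
    spec = SyntheticSpec(
        length=1_048_576,
        gc_alpha1=0.046,
        gc_alpha2=0.046,
        ta_alpha1=0.03,
        ta_alpha2=0.03,
        div=0.5,
        shift=0.0,
    )
    return spec, simulate_genome(spec)


@pytest.fixture(scope="session")
def megabase_binomial():
    """A 1 Mb stochastic genome with genes (shared, slow)."""
    spec = SyntheticSpec(
        length=1_048_576,
        gc_alpha1=0.04,
        gc_alpha2=0.04,
        ta_alpha1=0.025,
        ta_alpha2=0.025,
        div=0.55,
        shift=0.1,
        gene_density=0.5,
        leading_strand_gene_fraction=0.8,
        codon_g_fraction=0.6,
        noise="binomial",
        seed=42,
    )
    return spec, simulate_genome(spec)
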