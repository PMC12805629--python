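import pytest

from thymito.region_annotate import Transcript, TranscriptAnnotation
from thymito.synthetic_data import CohortConfig, generate_cohort, generate_reference
from thymito.variant_io import ReferenceGenome, SomaticVariant


@pytest.fixture(scope="session")
def default_cohort():
    """Full cohort under the study-condition defaults (10 patients)."""
    return generate_cohort(CohortConfig(), seed=11)


@pytest.fixture(scope="session")
def small_reference():
    cfg = CohortConfig(
        n_nuclear_contigs=1,
        nuclear_contig_length=200_000,
        genes_per_contig=6,
        ncrna_per_contig=1,
        n_ccre=40,
        n_hotspots=20,
    )
    return generate_reference(cfg, seed=3)


def make_variant(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="C",
    qscore=30.0,
    filter_status="PASS",
    t_depth=100,
    t_alt=50,
    n_depth=100,
    n_alt=0,
):
    return SomaticVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        qscore=qscore,
        filter_status=filter_status,
        t_depth=t_depth,
        t_alt=t_alt,
        n_depth=n_depth,
        n_alt=n_alt,
    )


@pytest.fixture(scope="session")
def toy_coding_setup():
    """Hand-built genome + single-gene annotation for codon-level checks.

    chr1 carries a forward-strand gene whose CDS is one exon starting at
    0-based 100; the codon layout is therefore directly readable from the
    contig string. chrM carries a forward-strand single-exon gene at the
    same offset for vertebrate-mito-code checks.
    """
    # CDS: ATG CGA TGG TTT TAA  (M R W F stop) at positions 100..115
    cds = "ATGCGATGGTTTTAA"
    chr1 = "A" * 100 + cds + "G" * 100 + "ACGT" * 50
    chrm = "C" * 100 + cds + "T" * 100
    genome = ReferenceGenome(
        sequences={"chr1": chr1, "chrM": chrm}, circular={"chrM"}
    )
    tx_nuc = Transcript(
        "TOY1", "chr1", "+", exons=[(90, 130)], cds=[(100, 115)]
    )
    tx_mito = Transcript(
        "MT-TOY", "chrM", "+", exons=[(100, 115)], cds=[(100, 115)]
    )
    annotation = TranscriptAnnotation([tx_nuc, tx_mito])
    return genome, annotation
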