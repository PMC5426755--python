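import numpy as np
import pytest

from ebfunnel import (
    FilterConfig,
    Genotype,
    SimConfig,
    Site,
    Transcript,
    Variant,
    generate_dataset,
    load_eb_panel,
)
from ebfunnel.io_formats import GenomeSequence

# --- toy single-gene world used across consequence / filter tests ----------

TOY_CDS = "ATGCGATAA"  # M, R, stop


@pytest.fixture(scope="session")
def toy_plus():
    """A 3-codon '+'-strand gene whose CDS reads ATG CGA TAA, with flanks."""
    genome = GenomeSequence({"chrT": "TTTTT" + TOY_CDS + "TTTTT"})
    transcript = Transcript(
        id="toy-t1", gene_symbol="TOY", chrom="chrT", strand="+",
        cds_exons=((6, 14),),
    )
    return transcript, genome


@pytest.fixture(scope="session")
def toy_minus():
    """The same CDS on the '-' strand: genomic interval holds its reverse
    complement."""
    from helpers import revcomp

    genome = GenomeSequence({"chrT": "TTTTT" + revcomp(TOY_CDS) + "TTTTT"})
    transcript = Transcript(
        id="toy-m1", gene_symbol="TOY", chrom="chrT", strand="-",
        cds_exons=((6, 14),),
    )
    return transcript, genome


@pytest.fixture(scope="session")
def two_exon_plus():
    """The 2-exon '+' transcript with CDS intervals (101,160) and (201,260);
    CDS length 120, over a fixed random genome."""
    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
    genome = GenomeSequence({"chrT": seq})
    transcript = Transcript(
        id="t2e", gene_symbol="G2E", chrom="chrT", strand="+",
        cds_exons=((101, 160), (201, 260)),
    )
    return transcript, genome


# --- default synthetic study (shared, read-only) ----------------------------

@pytest.fixture(scope="session")
def study():
    """One default-configuration synthetic study, generated once."""
    config = SimConfig(seed=11)
    (genome, transcripts, samples, sites, pedigree, family_genotypes,
     truth) = generate_dataset(config)
    return {
        "config": config,
        "genome": genome,
        "transcripts": transcripts,
        "samples": samples,
        "sites": sites,
        "pedigree": pedigree,
        "family_genotypes": family_genotypes,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def eb_panel():
    return frozenset(load_eb_panel())


@pytest.fixture(scope="session")
def study_filter_config(study, eb_panel):
    return FilterConfig(
        case_sample="CASE",
        control_samples=[s for s in study["samples"] if s != "CASE"],
        panel=eb_panel,
    )


# --- hand-built 10-site funnel fixture --------------------------------------

@pytest.fixture(scope="session")
def funnel_toy():
    """Ten hand-enumerated sites over CASE + 2 controls and two genes, one
    on the disease panel.  Expected stage survivors: 10 -> 6 -> 3 -> 1 -> 1.

    Sites 1-4: case not homozygous (removed at the case stage).
    Sites 5-7: case homozygous but some control also homozygous.
    Sites 8-9: survive the control stage but lie outside every CDS.
    Site 10:   coding in the on-panel gene; survives everything.
    """
    rng = np.random.default_rng(13)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=300))
    genome = GenomeSequence({"chrT": "".join(seq)})
    on_panel = Transcript(
        id="tA", gene_symbol="COL7A1", chrom="chrT", strand="+",
        cds_exons=((101, 160), (201, 260)),
    )
    off_panel = Transcript(
        id="tB", gene_symbol="GENEX", chrom="chrT", strand="+",
        cds_exons=((271, 300),),
    )
    HR, HE, HA, MI = (
        Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.MISSING
    )

    def site(pos, case, c1, c2):
        ref = genome["chrT"][pos - 1]
        alt = "A" if ref != "A" else "C"
        return Site(Variant("chrT", pos, ref, alt),
                    {"CASE": case, "C1": c1, "C2": c2})

    sites = [
        site(5, HE, HR, HR),
        site(10, HR, HR, HR),
        site(15, MI, HR, HR),
        site(20, HE, HA, HR),
        site(30, HA, HA, HR),
        site(40, HA, HR, HA),
        site(50, HA, HA, HA),
        site(70, HA, HE, HR),      # control carrier allowed by default policy
        site(95, HA, HR, MI),      # intergenic
        site(101, HA, HR, HR),     # first CDS base of the on-panel gene
    ]
    return {
        "genome": genome,
        "transcripts": [on_panel, off_panel],
        "sites": sites,
        "config": FilterConfig(
            case_sample="CASE", control_samples=("C1", "C2"),
            panel=frozenset({"COL7A1"}),
        ),
    }
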