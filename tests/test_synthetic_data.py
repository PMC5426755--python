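import filecmp

import pytest

from ebfunnel import (
    DomainError,
    FilterConfig,
    Genotype,
    LayoutError,
    SimConfig,
    check_recessive_segregation,
    emit_dataset,
    load_eb_panel,
    read_cohorts,
    read_fasta,
    read_gene_models,
    read_panel,
    read_pedigree,
    read_vcf,
    reference_codon,
    run_funnel,
    simulate_pedigree_genotypes,
    translate_codon,
)
from ebfunnel.cohort_stats import screen_summary
from ebfunnel.consequence import annotate_variant
from helpers import splice_cds


class TestGenomeAndGenes:
    def test_every_transcript_has_a_clean_open_reading_frame(self, study):
        """Each spliced CDS starts ATG, ends in a stop, and has no internal
        stop codon (checked by brute-force splice and translate)."""
        for tx in study["transcripts"]:
            cds = splice_cds(tx, study["genome"])
            assert len(cds) % 3 == 0
            codons = [cds[i: i + 3] for i in range(0, len(cds), 3)]
            aa = [translate_codon(c) for c in codons]
            assert aa[0] == "M"
            assert aa[-1] == "*"
            assert "*" not in aa[:-1]

    def test_causal_codon_is_arginine_cga(self, study):
        config = study["config"]
        tx = study["transcripts"][config.causal_gene_index]
        assert tx.gene_symbol == "COL7A1"
        assert (
            reference_codon(tx, config.causal_codon_number, study["genome"])
            == "CGA"
        )

    def test_too_small_chromosome_is_layout_error(self):
        with pytest.raises(LayoutError):
            from ebfunnel.synthetic_data import build_genome_and_genes

            build_genome_and_genes(SimConfig(seed=1, chrom_length=5_000))

    def test_interior_causal_codon_enforced(self):
        with pytest.raises(DomainError):
            SimConfig(seed=1, causal_codon_number=1, causal_codon_count=100)


class TestPlantedVariant:
    def test_annotation_matches_construction(self, study):
        truth = study["truth"]
        anns = annotate_variant(
            truth.causal_variant, study["transcripts"], study["genome"]
        )
        (ann,) = [a for a in anns if a.gene_symbol == truth.causal_gene]
        assert ann.effect == "nonsense"
        assert ann.alt_codon == "TGA" and ann.ref_codon == "CGA"
        assert ann.hgvs_c == truth.hgvs_c
        assert ann.hgvs_p == truth.hgvs_p

    def test_minus_strand_gene_yields_mirrored_genomic_alleles(self):
        """Whatever the gene's strand, the CDS change is C>T; the genomic
        alleles are C>T on '+' and G>A on '-'."""
        seen = set()
        for seed in range(6):
            config = SimConfig(
                seed=seed, chrom_length=15_000, n_genes=3,
                causal_gene_index=1, causal_codon_count=150,
                causal_codon_number=40, decoy_codon_count=60,
                background_site_count=10,
            )
            from ebfunnel.synthetic_data import (
                build_genome_and_genes,
                plant_causal_variant,
            )

            genome, transcripts = build_genome_and_genes(config)
            tx = transcripts[1]
            v = plant_causal_variant(genome, tx, 40)
            seen.add(tx.strand)
            if tx.strand == "+":
                assert (v.ref, v.alt) == ("C", "T")
            else:
                assert (v.ref, v.alt) == ("G", "A")
            (ann,) = [
                a for a in annotate_variant(v, transcripts, genome)
                if a.transcript_id == tx.id
            ]
            assert ann.hgvs_c == "c.118C>T" and ann.effect == "nonsense"
        assert seen == {"+", "-"}  # both strands exercised across seeds


class TestPedigreeSimulation:
    def test_offspring_counts_and_full_penetrance(self, study):
        pedigree = study["pedigree"]
        genotypes = study["family_genotypes"]
        config = study["config"]
        assert len(pedigree) == config.litter_size + 2
        for ind in pedigree:
            if ind.sire is None:
                continue
            affected = genotypes[ind.id] is Genotype.HOM_ALT
            assert (ind.phenotype.value == "affected") == affected

    def test_mendelian_ratio_at_ten_thousand_offspring(self):
        """HET x HET transmission recovers 1:2:1 within 3 binomial standard
        errors at n = 10,000."""
        config = SimConfig(seed=97, litter_size=10_000)
        _, genotypes = simulate_pedigree_genotypes(config)
        pups = [g for k, g in genotypes.items() if k.startswith("PUP")]
        n = len(pups)
        assert n == 10_000
        for state, p in [
            (Genotype.HOM_REF, 0.25),
            (Genotype.HET, 0.5),
            (Genotype.HOM_ALT, 0.25),
        ]:
            observed = sum(1 for g in pups if g is state)
            se = (n * p * (1 - p)) ** 0.5
            assert abs(observed - n * p) <= 3 * se

    def test_simulated_family_always_segregates(self):
        for seed in range(8):
            config = SimConfig(seed=seed)
            pedigree, genotypes = simulate_pedigree_genotypes(config)
            assert check_recessive_segregation(pedigree, genotypes).segregates


class TestBackgroundAndControls:
    def test_causal_allele_absent_from_controls(self, study):
        truth = study["truth"]
        causal_site = next(
            s for s in study["sites"] if s.variant == truth.causal_variant
        )
        assert causal_site.genotypes["CASE"] is Genotype.HOM_ALT
        for sample, g in causal_site.genotypes.items():
            if sample != "CASE":
                assert g is Genotype.HOM_REF

    def test_carrier_controls_option_plants_heterozygotes(self):
        from ebfunnel.synthetic_data import generate_dataset

        config = SimConfig(
            seed=3, carrier_controls=5, chrom_length=15_000, n_genes=3,
            causal_gene_index=1, causal_codon_count=150,
            causal_codon_number=40, decoy_codon_count=60,
            background_site_count=20,
        )
        _, _, samples, sites, _, _, truth = generate_dataset(config)
        causal_site = next(
            s for s in sites if s.variant == truth.causal_variant
        )
        hets = [
            s for s, g in causal_site.genotypes.items() if g is Genotype.HET
        ]
        assert len(hets) == 5 and "CASE" not in hets

    def test_background_genotypes_consistent_with_hardy_weinberg(self):
        """Aggregate chi-square smoke check: pooled genotype counts across
        many background sites should not wildly contradict HWE."""
        from scipy.stats import chi2

        config = SimConfig(seed=55, n_controls=63, background_site_count=300)
        from ebfunnel.synthetic_data import generate_dataset

        _, _, samples, sites, _, _, truth = generate_dataset(config)
        stat = 0.0
        dof = 0
        for site in sites:
            if site.variant == truth.causal_variant:
                continue
            counts = {g: 0 for g in Genotype}
            for g in site.genotypes.values():
                counts[g] += 1
            n = len(samples)
            q = (counts[Genotype.HET] + 2 * counts[Genotype.HOM_ALT]) / (2 * n)
            if q in (0.0, 1.0):
                continue
            expected = {
                Genotype.HOM_REF: n * (1 - q) ** 2,
                Genotype.HET: n * 2 * q * (1 - q),
                Genotype.HOM_ALT: n * q * q,
            }
            stat += sum(
                (counts[g] - e) ** 2 / e for g, e in expected.items() if e > 0
            )
            dof += 1
        # loose smoke threshold, far in the tail of chi2(dof)
        assert stat < chi2.ppf(1 - 1e-6, dof)


@pytest.fixture(scope="module")
def emitted(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("dataset")
    config = SimConfig(seed=11)
    truth = emit_dataset(config, outdir)
    return config, outdir, truth


class TestEmittedDataset:
    def test_rerun_is_byte_identical(self, emitted, tmp_path_factory):
        config, outdir, _ = emitted
        other = tmp_path_factory.mktemp("dataset2")
        emit_dataset(config, other)
        names = sorted(p.name for p in outdir.iterdir())
        assert names == sorted(p.name for p in other.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(
            outdir, other, names, shallow=False
        )
        assert mismatch == [] and errors == []

    def test_all_files_parse_back(self, emitted):
        _, outdir, truth = emitted
        genome = read_fasta(outdir / "genome.fasta")
        transcripts = read_gene_models(outdir / "genes.gff3")
        samples, sites = read_vcf(outdir / "variants.vcf")
        pedigree = read_pedigree(outdir / "pedigree.ped")
        panel = read_panel(outdir / "panel.txt")
        cohorts = read_cohorts(outdir / "cohorts.tsv")
        assert len(transcripts) == 8
        assert samples[0] == "CASE" and len(samples) == 32
        assert len(pedigree) == 10
        assert panel == load_eb_panel()
        assert tuple(cohorts) == truth.cohorts

    def test_truth_hgvs_matches_annotation_on_emitted_files(self, emitted):
        _, outdir, truth = emitted
        genome = read_fasta(outdir / "genome.fasta")
        transcripts = read_gene_models(outdir / "genes.gff3")
        anns = annotate_variant(truth.causal_variant, transcripts, genome)
        (ann,) = [a for a in anns if a.gene_symbol == truth.causal_gene]
        assert (ann.hgvs_c, ann.hgvs_p) == (truth.hgvs_c, truth.hgvs_p)

    def test_full_funnel_and_screen_on_emitted_files(self, emitted):
        _, outdir, truth = emitted
        genome = read_fasta(outdir / "genome.fasta")
        transcripts = read_gene_models(outdir / "genes.gff3")
        samples, sites = read_vcf(outdir / "variants.vcf")
        config = FilterConfig(
            case_sample="CASE",
            control_samples=[s for s in samples if s != "CASE"],
            panel=frozenset(read_panel(outdir / "panel.txt")),
        )
        report = run_funnel(sites, config, transcripts, genome)
        assert truth.causal_variant in [c.variant for c in report.candidates]

        result = screen_summary(
            read_cohorts(outdir / "cohorts.tsv"), "Central Asian Shepherd Dog"
        )
        assert result.breed_specific and result.non_index_total == 143
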