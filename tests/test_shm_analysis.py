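import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vquad import (
    GermlineSimConfig,
    IghvAllele,
    MutantRecord,
    ReferenceG4Scorer,
    RepertoireAlignment,
    ShmSimConfig,
    ccc_split_comparison,
    motif_mutability,
    mutability_table,
    mutated_vs_germline_potential,
    read_mutation_counts,
    reference_g4_score,
    reverse_complement,
    saturation_mutagenesis,
    score_both_strands,
    simulate_germline_alleles,
    simulate_shm_repertoire,
    site_mutation_frequencies,
    topbottom_difference_vs_potential,
)

from oracles import brute_site_freqs


def _aln(germ, reads, allele_id="IGHV4-4*01"):
    return RepertoireAlignment(
        germline=IghvAllele(allele_id=allele_id, gapped_seq=germ), reads=reads
    )


class TestSiteFrequencies:
    def test_simple_counts(self):
        reads = ["ACGT"] * 7 + ["AAGT"] * 3
        freqs = site_mutation_frequencies(_aln("ACGT", reads))
        assert freqs.loc[1, "frequency"] == pytest.approx(0.3)
        assert (freqs["coverage"] == 10).all()

    def test_identical_reads_have_zero_frequency(self):
        freqs = site_mutation_frequencies(_aln("ACGT", ["ACGT"] * 5))
        assert (freqs["frequency"] == 0).all()

    def test_n_positions_do_not_count_as_coverage(self):
        freqs = site_mutation_frequencies(_aln("ACGT", ["NCGT", "TCGT"]))
        assert freqs.loc[0, "coverage"] == 1
        assert freqs.loc[0, "frequency"] == pytest.approx(1.0)

    def test_zero_coverage_is_missing(self):
        freqs = site_mutation_frequencies(_aln("ACGT", ["NCGT"]))
        assert np.isnan(freqs.loc[0, "frequency"])

    @given(st.data())
    @settings(max_examples=30)
    def test_matches_column_counting_oracle(self, data):
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        length = int(rng.integers(3, 15))
        germ = "".join(rng.choice(list("ACGT"), size=length))
        reads = [
            "".join(rng.choice(list("ACGTN"), size=length, p=[0.2] * 4 + [0.2]))
            for _ in range(int(rng.integers(0, 8)))
        ]
        freqs = site_mutation_frequencies(_aln(germ, reads))
        for (cov, mut), row in zip(brute_site_freqs(germ, reads), freqs.itertuples()):
            assert row.coverage == cov
            assert row.mutated == mut

    def test_length_mismatch_rejected(self):
        with pytest.raises(Exception):
            _aln("ACGT", ["ACG"])


class TestMotifMutability:
    def test_mean_over_motif_occurrences(self):
        # Two top-strand AGC sites (C at 5 and 11) with frequencies 0.1 and 0.3.
        germ = "TTAGCTTTAGCTT"
        reads = ["TTAGGTTTAGCTT"] + ["TTAGCTTTAGGTT"] * 3 + [germ] * 6
        rows = mutability_table(motif_mutability(_aln(germ, reads)))
        agc_top = rows[(rows["motif"] == "AGC") & (rows["strand"] == "top")]
        assert agc_top["n_sites"].iloc[0] == 2
        assert agc_top["mean_freq"].iloc[0] == pytest.approx((0.1 + 0.3) / 2)

    def test_strand_relabeling_swaps_rows_exactly(self):
        rng = np.random.default_rng(9)
        germ = "".join(rng.choice(list("ACGT"), size=60))
        reads = []
        for _ in range(20):
            read = list(germ)
            for pos in rng.choice(60, size=3, replace=False):
                read[pos] = rng.choice([b for b in "ACGT" if b != germ[pos]])
            reads.append("".join(read))
        aln = _aln(germ, reads)
        fwd = mutability_table(motif_mutability(aln))
        rev = mutability_table(motif_mutability(aln.reverse_complemented()))
        swap = {"top": "bottom", "bottom": "top"}
        fwd_set = {(r.motif, r.strand, round(r.mean_freq, 12), r.n_sites) for r in fwd.itertuples()}
        rev_set = {(r.motif, swap[r.strand], round(r.mean_freq, 12), r.n_sites) for r in rev.itertuples()}
        assert fwd_set == rev_set

    def test_accepts_precomputed_count_table(self, tmp_path):
        germ = "TTAGCTT"
        path = tmp_path / "counts.tsv"
        pd.DataFrame(
            {"allele_id": ["IGHV4-4*01"] * 7, "pos": range(1, 8),
             "mutated": [0, 0, 0, 0, 2, 0, 0], "coverage": [10] * 7}
        ).to_csv(path, sep="\t", index=False)
        counts = read_mutation_counts(path)
        rows = mutability_table(
            motif_mutability(_aln(germ, []), site_freqs=counts)
        )
        agc = rows[(rows["motif"] == "AGC") & (rows["strand"] == "top")]
        assert agc["mean_freq"].iloc[0] == pytest.approx(0.2)


def _two_strand_gene_panel(shm_seed, coupling):
    """Genes with top-strand cassettes and genes with bottom-strand cassettes."""
    top_cfg = GermlineSimConfig(n_alleles=4, cassette_fraction=1.0, id_prefix="T", seed=31)
    bot_cfg = GermlineSimConfig(n_alleles=4, cassette_fraction=1.0, id_prefix="B", seed=32)
    bot_cfg.g4_cassette.strand = "bottom"
    panel = []
    for cfg, strand in ((top_cfg, "top"), (bot_cfg, "bottom")):
        alleles, truth = simulate_germline_alleles(cfg)
        for allele in alleles:
            info = truth["alleles"][allele.allele_id]
            fps = [(c["start"], c["end"]) for c in info["cassettes"]]
            panel.append((allele, strand, fps))
    scorer = ReferenceG4Scorer()
    mutab, scores = [], {}
    for i, (allele, strand, fps) in enumerate(panel):
        cfg = ShmSimConfig(
            n_reads=600, base_rate=2e-3, hotspot_multiplier=3.0,
            coldspot_multiplier=1.0, g4_strand_coupling=coupling,
            seed=shm_seed + i,
        )
        aln = simulate_shm_repertoire(allele, cfg, cassette_strand=strand, cassette_footprints=fps)
        mutab.extend(motif_mutability(aln))
        scores[allele.gene_id] = score_both_strands(allele.ungapped_seq, scorer)
    return mutab, scores


class TestTopBottomCorrelation:
    def test_planted_strand_coupling_recovered_with_correct_signs(self):
        mutab, scores = _two_strand_gene_panel(shm_seed=100, coupling=4.0)
        table = topbottom_difference_vs_potential(mutab, scores)
        defined = table[~table["undefined"]]
        top = defined[defined["strand"] == "top"]
        bottom = defined[defined["strand"] == "bottom"]
        assert (top["pearson_r"] > 0).mean() > 0.7
        assert (bottom["pearson_r"] < 0).mean() > 0.7

    def test_null_coupling_gives_correlations_centered_on_zero(self):
        rs = []
        for rep in range(25):
            mutab, scores = _two_strand_gene_panel(shm_seed=1000 + 10 * rep, coupling=1.0)
            table = topbottom_difference_vs_potential(mutab, scores)
            rs.extend(table.loc[~table["undefined"], "pearson_r"].tolist())
        assert abs(float(np.mean(rs))) < 0.15

    def test_two_genes_refused(self):
        alleles, _ = simulate_germline_alleles(GermlineSimConfig(n_alleles=2, seed=5))
        scorer = ReferenceG4Scorer()
        mutab, scores = [], {}
        for allele in alleles:
            aln = simulate_shm_repertoire(allele, ShmSimConfig(n_reads=50, seed=6))
            mutab.extend(motif_mutability(aln))
            scores[allele.gene_id] = score_both_strands(allele.ungapped_seq, scorer)
        with pytest.raises(ValueError):
            topbottom_difference_vs_potential(mutab, scores, motifs=("AGC",))


class TestMutatedVsGermline:
    def test_identical_reads_equal_germline_score(self, ref_scorer):
        germ = "TT" + "GGGAGGGTTGGGAGGG" + "TT"
        result = mutated_vs_germline_potential(_aln(germ, [germ] * 4), ref_scorer)
        assert result["mutated_mean"]["top"] == result["germline"]["top"]

    def test_motif_destroying_reads_lower_the_mean(self, ref_scorer):
        germ = "TT" + "GGGAGGGTTGGGAGGG" + "TT"
        broken = germ.replace("GGGA", "GTGA", 1)
        result = mutated_vs_germline_potential(_aln(germ, [broken] * 4), ref_scorer)
        assert result["mutated_mean"]["top"] < result["germline"]["top"]

    def test_mean_matches_per_read_oracle(self, ref_scorer):
        rng = np.random.default_rng(12)
        germ = "".join(rng.choice(list("ACGT"), size=40))
        reads = []
        for _ in range(6):
            read = list(germ)
            pos = int(rng.integers(0, 40))
            read[pos] = rng.choice([b for b in "ACGT" if b != germ[pos]])
            reads.append("".join(read))
        result = mutated_vs_germline_potential(_aln(germ, reads), ref_scorer)
        assert result["mutated_mean"]["top"] == pytest.approx(
            np.mean([reference_g4_score(r) for r in reads])
        )
        assert result["mutated_mean"]["bottom"] == pytest.approx(
            np.mean([reference_g4_score(reverse_complement(r)) for r in reads])
        )


class TestCccSplit:
    def _mutant(self, pos, delta_bottom, allele_id="IGHV4-4*01"):
        return MutantRecord(
            allele_id=allele_id, ungapped_pos=pos, gapped_pos=pos, ref_base="C",
            alt_base="G", strand_mutated="top", delta_top=0.0,
            delta_bottom=delta_bottom, site_class="SYC_coldspot", trinucleotide="CCC",
        )

    def test_partition_rule(self):
        germ = "ACCCACCCACCCA"
        reads = [germ] * 10
        aln = _aln(germ, reads)
        mutants = [
            self._mutant(4, -0.5),   # negative_change
            self._mutant(8, 0.0),    # no_difference
            self._mutant(12, +0.5),  # excluded
        ]
        neg, nodiff, p = ccc_split_comparison(aln, mutants, epsilon=0.01)
        assert len(neg.frequencies) == 1
        assert len(nodiff.frequencies) == 1
        assert p is not None

    def test_empty_group_skips_test(self):
        germ = "ACCCA"
        aln = _aln(germ, [germ] * 3)
        neg, nodiff, p = ccc_split_comparison(aln, [self._mutant(4, -0.5)])
        assert p is None
        assert nodiff.frequencies == []

    def test_planted_coupling_detected(self, ref_scorer, ccc_design):
        allele, truth = ccc_design
        info = truth["alleles"][allele.allele_id]
        fps = [(c["start"], c["end"]) for c in info["cassettes"]]
        mutants = saturation_mutagenesis(allele, ref_scorer)
        cfg = ShmSimConfig(
            n_reads=2000, base_rate=1e-3, hotspot_multiplier=1.0,
            coldspot_multiplier=1.0, g4_strand_coupling=3.0, seed=77,
        )
        aln = simulate_shm_repertoire(
            allele, cfg, cassette_strand="bottom", cassette_footprints=fps
        )
        neg, nodiff, p = ccc_split_comparison(aln, mutants)
        assert np.median(neg.frequencies) > np.median(nodiff.frequencies)
        assert p is not None and p < 0.05
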