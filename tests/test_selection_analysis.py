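"""Codon usage, neutral dN/dS expectation and coding-density tests."""

import numpy as np
import pytest
from Bio.Seq import Seq

from mutacc.genome_model import CodingInterval, GenomeModel
from mutacc.mutation_catalog import MutationRecord, MutationSet, annotate_mutations
from mutacc.selection_analysis import (
    CodonUsage,
    SENSE_CODONS,
    coding_counts_test,
    coding_test,
    codon_usage_from_annotation,
    dnds_test,
    ecoli_codon_usage,
    expected_dnds,
    observed_dnds,
)

GENETIC_CODE = {}
for codon in (a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"):
    GENETIC_CODE[codon] = str(Seq(codon).translate(table=11))


def brute_force_expected_dnds(usage: dict[str, int], R: float) -> float:
    """Independent enumeration over every weighted single-base change."""
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    nonsyn = syn = 0.0
    for codon, n in usage.items():
        for pos in range(3):
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                w = n * (2 * R if (codon[pos], alt) in transitions else 1.0)
                mutant = codon[:pos] + alt + codon[pos + 1:]
                if GENETIC_CODE[mutant] == "*" or GENETIC_CODE[mutant] != GENETIC_CODE[codon]:
                    nonsyn += w
                else:
                    syn += w
    return nonsyn / syn


def toy_model(genes: list[tuple[str, int]], spacer: str = "T" * 12) -> GenomeModel:
    seq = spacer
    intervals = []
    for k, (gene, strand) in enumerate(genes):
        start = len(seq) + 1
        top = gene if strand > 0 else str(Seq(gene).reverse_complement())
        seq += top
        intervals.append(CodingInterval(start, start + len(gene), strand, f"g{k}"))
        seq += spacer
    return GenomeModel(
        sequence=seq, ori_position=1, ter_position=len(seq) // 2,
        coding_intervals=intervals,
    )


class TestCodonUsage:
    def test_single_gene_stop_excluded(self):
        usage = codon_usage_from_annotation(toy_model([("ATGGGGTAA", 1)]))
        nonzero = {c: n for c, n in usage.counts.items() if n}
        assert nonzero == {"ATG": 1, "GGG": 1}

    def test_two_identical_genes_double_counts(self):
        u1 = codon_usage_from_annotation(toy_model([("ATGCATTGGTAA", 1)]))
        u2 = codon_usage_from_annotation(
            toy_model([("ATGCATTGGTAA", 1), ("ATGCATTGGTAA", 1)])
        )
        for codon in SENSE_CODONS:
            assert u2.counts[codon] == 2 * u1.counts[codon]

    def test_reverse_strand_counted_in_coding_orientation(self):
        fwd = codon_usage_from_annotation(toy_model([("ATGCATTGGTAA", 1)]))
        rev = codon_usage_from_annotation(toy_model([("ATGCATTGGTAA", -1)]))
        assert fwd.counts == rev.counts

    def test_partial_codon_cds_skipped_with_warning(self):
        model = toy_model([("ATGGGGTAA", 1), ("ATGGG", 1)])
        with pytest.warns(UserWarning, match="not divisible"):
            usage = codon_usage_from_annotation(model)
        assert usage.total() == 2  # only the clean gene

    def test_length_accounting(self, toy_bundle):
        model, _ = toy_bundle
        usage = codon_usage_from_annotation(model)
        total_codons = sum((iv.end - iv.start) // 3 for iv in model.coding_intervals)
        n_stops = 0
        for iv in model.coding_intervals:
            s = model.sequence[iv.start - 1 : iv.end - 1]
            if iv.strand < 0:
                s = str(Seq(s).reverse_complement())
            n_stops += sum(
                1 for i in range(0, len(s), 3) if s[i : i + 3] in ("TAA", "TAG", "TGA")
            )
        # every codon lands in the table except stop triplets
        assert usage.total() == total_codons - n_stops

    def test_round_trip(self, tmp_path):
        usage = ecoli_codon_usage()
        path = tmp_path / "usage.tsv"
        usage.write(path)
        assert CodonUsage.read(path).counts == dict(usage.counts)


class TestExpectedDnds:
    @pytest.mark.parametrize("R", [0.5, 1.0, 2.08, 10.0])
    def test_ggg_only_is_analytically_two(self, R):
        assert expected_dnds(CodonUsage({"GGG": 3}), R) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        codons = rng.choice(len(SENSE_CODONS), size=2, replace=False)
        usage = {SENSE_CODONS[i]: int(rng.integers(1, 20)) for i in codons}
        R = float(rng.uniform(0.2, 5))
        assert expected_dnds(CodonUsage(usage), R) == pytest.approx(
            brute_force_expected_dnds(usage, R), rel=1e-12
        )

    def test_invariant_to_usage_scaling(self):
        usage = {c: n for c, n in ecoli_codon_usage().counts.items()}
        scaled = {c: 7 * n for c, n in usage.items()}
        assert expected_dnds(CodonUsage(usage), 2.0) == pytest.approx(
            expected_dnds(CodonUsage(scaled), 2.0)
        )

    def test_large_R_approaches_transition_only_enumeration(self):
        usage = dict(ecoli_codon_usage().counts)
        big = expected_dnds(CodonUsage(usage), 1e6)
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        nonsyn = syn = 0.0
        for codon, n in usage.items():
            for pos in range(3):
                for alt in "ACGT":
                    if alt == codon[pos] or (codon[pos], alt) not in transitions:
                        continue
                    mutant = codon[:pos] + alt + codon[pos + 1:]
                    if GENETIC_CODE[mutant] == "*" or GENETIC_CODE[mutant] != GENETIC_CODE[codon]:
                        nonsyn += n
                    else:
                        syn += n
        assert big == pytest.approx(nonsyn / syn, rel=1e-4)

    def test_invalid_R_rejected(self):
        with pytest.raises(ValueError):
            expected_dnds(ecoli_codon_usage(), 0)


class TestObservedDnds:
    def annotated_catalog(self, effects):
        records = []
        for i, eff in enumerate(effects):
            rec = MutationRecord("l1", "aerobic", i + 1, "BPS", ref_base="A", alt_base="G")
            rec.effect = eff
            rec.coding_status = "coding" if eff != "intergenic" else "noncoding"
            records.append(rec)
        return MutationSet(records=records)

    def test_definitional_ratio(self):
        mset = self.annotated_catalog(["nonsynonymous"] * 27 + ["synonymous"] * 10)
        assert observed_dnds(mset).observed_ratio == pytest.approx(2.70)

    def test_no_coding_bps_refused(self):
        with pytest.raises(ValueError, match="no coding"):
            observed_dnds(self.annotated_catalog(["intergenic"] * 5))

    def test_zero_synonymous_signalled(self):
        with pytest.raises(ZeroDivisionError, match="no synonymous"):
            observed_dnds(self.annotated_catalog(["nonsynonymous"] * 3))

    def test_unannotated_refused(self):
        mset = MutationSet(records=[
            MutationRecord("l1", "aerobic", 1, "BPS", ref_base="A", alt_base="G")
        ])
        with pytest.raises(ValueError, match="annotate"):
            observed_dnds(mset)

    def test_neutral_simulation_matches_expectation(self):
        # random substitutions in a gene-dense toy genome, effects via
        # annotation, compared with expected_dnds of the same genome's usage
        rng = np.random.default_rng(12)
        gene = "".join(rng.choice(list("ACGT"), size=3000))
        gene = "ATG" + gene[: 2994] + "TAA"
        # strip internal stops to keep translation well-defined
        codons = [gene[i:i + 3] for i in range(0, len(gene), 3)]
        codons = [("CAA" if (c in ("TAA", "TAG", "TGA") and i != len(codons) - 1) else c)
                  for i, c in enumerate(codons)]
        gene = "".join(codons)
        model = toy_model([(gene, 1)])
        usage = codon_usage_from_annotation(model)
        records = []
        start = 13  # first base of the gene
        for _ in range(4000):
            pos = int(rng.integers(start + 3, start + len(gene) - 3))  # avoid start/stop
            ref = model.base_at(pos)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            records.append(MutationRecord("l1", "aerobic", pos, "BPS",
                                          ref_base=ref, alt_base=alt))
        annotated = annotate_mutations(MutationSet(records=records), model)
        observed = observed_dnds(annotated).observed_ratio
        expected = expected_dnds(usage, 0.5)  # uniform alt choice => ts:tv = 1:2
        assert observed == pytest.approx(expected, rel=0.12)


class TestChiSquareTests:
    def test_exact_expected_split_is_zero(self):
        assert dnds_test(30, 10, 3.0).chi_square == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_hand_computed(self, seed):
        rng = np.random.default_rng(seed)
        nonsyn, syn = int(rng.integers(1, 60)), int(rng.integers(1, 60))
        ratio = float(rng.uniform(0.3, 8))
        total = nonsyn + syn
        e1, e2 = total * ratio / (1 + ratio), total / (1 + ratio)
        expected_stat = (nonsyn - e1) ** 2 / e1 + (syn - e2) ** 2 / e2
        assert dnds_test(nonsyn, syn, ratio).chi_square == pytest.approx(expected_stat)

    def test_coding_counts_published_values(self):
        aero = coding_counts_test(60, 14, 7.83)
        assert aero.chi_square == pytest.approx(4.25, abs=0.01)
        assert aero.observed_ratio == pytest.approx(4.29, abs=0.01)
        anae = coding_counts_test(50, 23, 7.83)
        assert anae.chi_square == pytest.approx(29.61, abs=0.01)
        assert anae.observed_ratio == pytest.approx(2.17, abs=0.01)

    def test_coding_test_from_annotated_set(self, midsize_model):
        rng = np.random.default_rng(4)
        records = []
        for _ in range(50):
            pos = int(rng.integers(1, midsize_model.length + 1))
            ref = midsize_model.base_at(pos)
            records.append(MutationRecord("l1", "aerobic", pos, "BPS",
                                          ref_base=ref, alt_base="A" if ref != "A" else "C"))
        annotated = annotate_mutations(MutationSet(records=records), midsize_model)
        summary = coding_test(annotated, coding_ratio=7.83)
        assert summary.nonsyn + summary.syn == 50  # coding+noncoding counts
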