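"""Spectrum summaries, strand-bias expectations and positional chi-squares."""

import numpy as np
import pytest
from scipy import stats

from mutacc.genome_model import CLOCKWISE, COUNTER_CLOCKWISE, GenomeModel
from mutacc.mutation_catalog import MutationRecord, MutationSet
from mutacc.spectrum_analysis import (
    InfiniteRatioError,
    chi_square_gof,
    cumulative_positions,
    expected_replichore_split,
    macrodomain_test,
    replichore_counts,
    strand_bias_test,
    ts_tv_ratio,
)


def bps(pos, ref, alt, lid="l1", env="aerobic"):
    return MutationRecord(lid, env, pos, "BPS", ref_base=ref, alt_base=alt)


class TestTsTv:
    def test_simple_ratio(self):
        mset = MutationSet(
            records=[bps(1, "A", "G"), bps(2, "T", "C"), bps(3, "G", "A"), bps(4, "A", "C")]
        )
        assert ts_tv_ratio(mset) == pytest.approx(3.0)

    def test_zero_transversions_signalled(self):
        mset = MutationSet(records=[bps(1, "A", "G")])
        with pytest.raises(InfiniteRatioError):
            ts_tv_ratio(mset)

    def test_simulation_recovery(self, midsize_model):
        # transitions drawn twice as often as transversions -> ratio ~ 2
        rng = np.random.default_rng(9)
        ts_target = {"A": "G", "G": "A", "C": "T", "T": "C"}
        records = []
        for _ in range(3000):
            pos = int(rng.integers(1, midsize_model.length + 1))
            ref = midsize_model.base_at(pos)
            if rng.random() < 2 / 3:
                alt = ts_target[ref]
            else:
                alt = rng.choice([b for b in "ACGT" if b != ref and b != ts_target[ref]])
            records.append(bps(pos, ref, alt))
        r = ts_tv_ratio(MutationSet(records=records))
        assert r == pytest.approx(2.0, rel=0.12)


class TestReplichoreCounts:
    def test_all_clockwise(self, uniform_model):
        mset = MutationSet(records=[bps(p, "A", "G") for p in (1, 5, 9)])
        assert replichore_counts(mset, "A:T>G:C", "A", uniform_model) == (3, 0)

    def test_focal_base_filters(self, uniform_model):
        mset = MutationSet(records=[bps(1, "A", "G"), bps(4, "T", "C")])
        assert replichore_counts(mset, "A:T>G:C", "A", uniform_model) == (1, 0)
        assert replichore_counts(mset, "A:T>G:C", "T", uniform_model) == (1, 0)

    def test_exhaustive_catalog_recovers_composition(self, uniform_model):
        ts_target = {"A": "G", "G": "A", "C": "T", "T": "C"}
        records = [
            bps(p, uniform_model.base_at(p), ts_target[uniform_model.base_at(p)])
            for p in range(1, uniform_model.length + 1)
        ]
        mset = MutationSet(records=records)
        total_cw = total_ccw = 0
        for pc, focal in [("A:T>G:C", "A"), ("A:T>G:C", "T"),
                          ("G:C>A:T", "G"), ("G:C>A:T", "C")]:
            cw, ccw = replichore_counts(mset, pc, focal, uniform_model)
            total_cw += cw
            total_ccw += ccw
        assert total_cw == uniform_model.replichores[CLOCKWISE][2]
        assert total_ccw == uniform_model.replichores[COUNTER_CLOCKWISE][2]

    def test_empty_class(self, uniform_model):
        assert replichore_counts(MutationSet(), "A:T>T:A", "A", uniform_model) == (0, 0)


class TestExpectedSplit:
    def test_symmetric(self, uniform_model):
        assert expected_replichore_split(100, uniform_model) == (50.0, 50.0)

    def test_published_proportions(self):
        # replichores 206 : 254 bp reproduce the published 2.06 : 2.54 Mb split
        model = GenomeModel(sequence="A" * 460, ori_position=1, ter_position=207)
        cw, ccw = expected_replichore_split(46, model)
        assert cw == pytest.approx(20.6)
        assert ccw == pytest.approx(25.4)

    def test_composition_equals_length_in_uniform_limit(self, uniform_model):
        by_len = expected_replichore_split(80, uniform_model, mode="length")
        by_comp = expected_replichore_split(80, uniform_model, mode="composition",
                                            focal_base="A")
        assert by_comp == pytest.approx(by_len)

    def test_composition_requires_focal_base(self, uniform_model):
        with pytest.raises(ValueError, match="focal_base"):
            expected_replichore_split(10, uniform_model, mode="composition")

    def test_expected_sums_to_total(self, midsize_model):
        for total in (0, 7, 46):
            cw, ccw = expected_replichore_split(total, midsize_model)
            assert cw + ccw == pytest.approx(total)


class TestChiSquare:
    def test_exact_match_is_zero(self):
        stat, df, p = chi_square_gof([30, 10], [30, 10])
        assert stat == 0.0 and df == 1 and p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hand_computation(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        obs = rng.integers(0, 50, size=k).astype(float)
        exp = rng.uniform(1, 50, size=k)
        exp *= obs.sum() / exp.sum() if obs.sum() else 1
        if obs.sum() == 0:
            obs[0] = 1
            exp *= 1 / exp.sum()
        stat, df, p = chi_square_gof(obs, exp)
        assert stat == pytest.approx(float(((obs - exp) ** 2 / exp).sum()))
        assert df == k - 1
        assert p == pytest.approx(float(stats.chi2.sf(stat, df)))

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            chi_square_gof([1, 2], [0, 3])


class TestStrandBias:
    def test_expected_sums_to_observed_total(self, midsize_model):
        rng = np.random.default_rng(2)
        records = []
        for _ in range(60):
            pos = int(rng.integers(1, midsize_model.length + 1))
            ref = midsize_model.base_at(pos)
            if ref in "AT":
                alt = "G" if ref == "A" else "C"
            else:
                alt = "A" if ref == "G" else "T"
            records.append(bps(pos, ref, alt))
        mset = MutationSet(records=records)
        tbl = strand_bias_test(mset, "A:T>G:C", "A", midsize_model)
        assert sum(tbl.expected) == pytest.approx(sum(tbl.observed))
        assert tbl.df == 1


class TestMacrodomain:
    def six_md_model(self):
        return GenomeModel(
            sequence="ACGT" * 300,
            ori_position=1,
            ter_position=601,
            macrodomains=[(f"MD{i}", 1 + 200 * i, 201 + 200 * i) for i in range(6)],
        )

    def test_point_mass_closed_form(self):
        model = self.six_md_model()
        n = 30
        records = []
        for i in range(n):
            pos = 10 + i  # all inside MD0
            ref = model.base_at(pos)
            alt = "G" if ref != "G" else "A"
            records.append(bps(pos, ref, alt))
        stat, df, p, table = macrodomain_test(MutationSet(records=records), model)
        # all mass in one of six equal macrodomains: chi2 = 5n
        assert stat == pytest.approx(5 * n)
        assert df == 5
        assert table["observed"].sum() == n

    def test_single_macrodomain_refused(self):
        model = GenomeModel(
            sequence="ACGT" * 250, ori_position=1, ter_position=501,
            macrodomains=[("ALL", 1, 1001)],
        )
        with pytest.raises(ValueError, match="at least two"):
            macrodomain_test(MutationSet(), model)

    def test_uniform_positions_small_statistic(self):
        model = self.six_md_model()
        rng = np.random.default_rng(5)
        records = [bps(int(p), model.base_at(int(p)), "G"
                       if model.base_at(int(p)) != "G" else "A")
                   for p in rng.integers(1, model.length + 1, size=600)]
        stat, df, p, _ = macrodomain_test(MutationSet(records=records), model)
        assert p > 0.001


class TestCumulative:
    def test_steps_and_monotonicity(self):
        mset = MutationSet(records=[bps(30, "A", "G"), bps(10, "T", "C"), bps(20, "A", "C")])
        curve = cumulative_positions(mset)
        assert list(curve["position"]) == [10, 20, 30]
        assert list(curve["cumulative"]) == [1, 2, 3]

    def test_empty(self):
        assert cumulative_positions(MutationSet()).empty

    def test_uniform_simulation_ks_consistent(self, midsize_model):
        rng = np.random.default_rng(8)
        positions = rng.integers(1, midsize_model.length + 1, size=400)
        records = []
        for p in positions:
            ref = midsize_model.base_at(int(p))
            records.append(bps(int(p), ref, "A" if ref != "A" else "G"))
        curve = cumulative_positions(MutationSet(records=records))
        ks = stats.kstest(curve["position"] / midsize_model.length, "uniform")
        assert ks.pvalue > 1e-3
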