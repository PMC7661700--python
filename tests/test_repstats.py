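"""Repertoire statistics: worked-example arithmetic on published counts,
chi-square behaviour, sharing detection and the CDR3 Gaussian fit."""

from types import SimpleNamespace

import numpy as np
import pytest

from vdjrep.annotator import CellRecord, group_cells
from vdjrep.repstats import (
    UsageTable,
    cdr3_gaussian_fit,
    chi_square_usage,
    detection_rate,
    genomic_distribution,
    patterns_per_cell,
    percent,
    productivity_fraction,
    shared_rearrangements,
    usage_frequencies,
)


def _cells(spec):
    """CellRecords from (donor, cell, n_patterns) triples."""
    out = []
    for donor, cell, n in spec:
        rec = CellRecord(donor, cell, [])
        rec.patterns = [object()] * n
        out.append(rec)
    return out


def _ann(**kw):
    defaults = dict(v_call="IGHV1-24", d_call="IGHD2-15", j_call="IGHJ4",
                    n1_seq="", n2_seq="", productive=True)
    defaults.update(kw)
    ns = SimpleNamespace(**defaults)
    ns.pattern_key = (ns.v_call, ns.d_call, ns.j_call, ns.n1_seq, ns.n2_seq)
    return ns


class TestPercent:
    @pytest.mark.parametrize("num,den,nd,expected", [
        (91, 111, 0, 82.0),      # pooled detection
        (45, 49, 1, 91.8),       # donor 1
        (46, 62, 1, 74.2),       # donor 2
        (27, 469, 1, 5.8),       # nonfunctional
        (130, 3300, 1, 3.9),     # B-cell nonfunctional
        (79, 91, 1, 86.8),       # one pattern
        (10, 91, 1, 11.0),
        (2, 91, 1, 2.2),
        (1, 8, 1, 12.5),
        (1, 16, 1, 6.3),         # half-up at the .25 boundary
    ])
    def test_exact_rational_rounding(self, num, den, nd, expected):
        assert percent(num, den, nd) == expected

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)


class TestDetectionRate:
    def test_two_donor_worked_example(self):
        cells = (
            _cells([("1", f"1-{i}", 1) for i in range(1, 46)])      # 45 pos
            + _cells([("1", f"1-n{i}", 0) for i in range(1, 5)])    # 4 neg
            + _cells([("2", f"2-{i}", 1) for i in range(1, 47)])    # 46 pos
            + _cells([("2", f"2-n{i}", 0) for i in range(1, 17)])   # 16 neg
        )
        res = detection_rate(cells)
        assert (res.positive, res.total) == (91, 111)
        assert res.percent_pooled == 82.0
        assert res.per_donor["1"] == (45, 49, 91.8)
        assert res.per_donor["2"] == (46, 62, 74.2)

    def test_no_positives(self):
        res = detection_rate(_cells([("1", f"c{i}", 0) for i in range(10)]))
        assert res.percent_pooled == 0.0

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            detection_rate([])


class TestProductivityFraction:
    @pytest.mark.parametrize("bad,total,expected", [
        (27, 469, 5.8), (130, 3300, 3.9), (0, 50, 0.0),
    ])
    def test_worked_examples(self, bad, total, expected):
        anns = [SimpleNamespace(productive=False)] * bad + \
               [SimpleNamespace(productive=True)] * (total - bad)
        res = productivity_fraction(anns)
        assert res.nonfunctional == bad
        assert res.percent_nonfunctional == expected


class TestUsage:
    def test_family_counting(self):
        patterns = [_ann(v_call="IGHV1-24"), _ann(v_call="IGHV1-18"),
                    _ann(v_call="IGHV3-23")]
        table = usage_frequencies(patterns, "family", "V")
        assert table.counts == {"VH1": 2, "VH3": 1}
        assert table.frequencies["VH1"] == pytest.approx(2 / 3)
        assert sum(table.frequencies.values()) == pytest.approx(1.0)

    def test_unassigned_d_reported_separately(self):
        patterns = [_ann(d_call="unassigned"), _ann(d_call="IGHD2-15")]
        table = usage_frequencies(patterns, "gene", "D")
        assert table.counts == {"IGHD2-15": 1}
        assert table.unassigned == 1

    def test_all_d_unassigned_yields_empty_table(self):
        patterns = [_ann(d_call="unassigned")] * 3
        table = usage_frequencies(patterns, "gene", "D")
        assert table.counts == {} and table.unassigned == 3

    def test_preset_usage_recovered_from_simulation(
            self, ptec_rep, ptec_annotations):
        """VH1-heavy usage survives simulate -> annotate -> count."""
        cells = group_cells(ptec_annotations)
        patterns = [p for c in cells for p in c.patterns]
        table = usage_frequencies(patterns, "family", "V")
        p = 0.71
        se = np.sqrt(p * (1 - p) / table.total)
        # patterns are not fully independent draws (shared clonotypes), so
        # allow a slightly wider band than plain binomial
        assert abs(table.frequencies["VH1"] - p) < 4 * se + 0.02


class TestChiSquare:
    def _table(self, counts, cls="V"):
        return UsageTable("family", cls, counts, sum(counts.values()))

    def test_identical_tables_give_zero(self):
        t = self._table({"VH1": 30, "VH3": 20})
        res = chi_square_usage(t, t)
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        a = self._table({"VH1": 10, "VH3": 20})
        b = self._table({"VH1": 20, "VH3": 10})
        res = chi_square_usage(a, b)
        assert res.statistic == pytest.approx(20 / 3)
        assert res.df == 1

    def test_symmetry(self):
        a = self._table({"VH1": 12, "VH3": 7, "VH4": 4})
        b = self._table({"VH1": 3, "VH3": 14, "VH4": 9})
        assert chi_square_usage(a, b).statistic == \
            pytest.approx(chi_square_usage(b, a).statistic)

    def test_zero_margin_names_labels(self):
        a = self._table({"VH1": 10, "VH9": 0})
        b = self._table({"VH1": 10})
        with pytest.raises(ValueError, match="VH9"):
            chi_square_usage(a, b)

    def test_type_one_error_rate_near_nominal(self):
        """Two samples from one multinomial rejected at ~5% under alpha=.05."""
        rng = np.random.default_rng(2024)
        probs = np.array([0.4, 0.3, 0.2, 0.1])
        labels = ["VH1", "VH2", "VH3", "VH4"]
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.multinomial(120, probs)
            b = rng.multinomial(120, probs)
            ta = self._table(dict(zip(labels, map(int, a))))
            tb = self._table(dict(zip(labels, map(int, b))))
            rejections += chi_square_usage(ta, tb).pvalue < 0.05
        assert 0.03 < rejections / n_rep < 0.07


class TestPatternsPerCell:
    def test_published_distribution(self):
        cells = _cells(
            [("1", f"a{i}", 1) for i in range(79)]
            + [("1", f"b{i}", 2) for i in range(10)]
            + [("1", f"c{i}", 3) for i in range(2)]
        )
        res = patterns_per_cell(cells)
        assert res.counts == {"1": 79, "2": 10, ">2": 2}
        assert res.percents == {"1": 86.8, "2": 11.0, ">2": 2.2}

    def test_all_single_pattern(self):
        res = patterns_per_cell(_cells([("1", f"c{i}", 1) for i in range(9)]))
        assert res.percents == {"1": 100.0, "2": 0.0, ">2": 0.0}


class TestSharedRearrangements:
    # the ten published cross-donor identical-junction sets and the cells
    # they were amplified in (donor-cell labels)
    TABLE = [
        (("IGHV1-24", "TT", "IGHD2-15", "ACCCGATCCGAC", "IGHJ4"),
         ["1-3", "1-6", "1-15", "1-19", "1-21", "1-29", "1-39",
          "2-10", "2-11", "2-18", "2-30", "2-42", "2-45"]),
        (("IGHV1-18", "TCTTAGTGGTTC", "IGHD3-9", "", "IGHJ6"),
         ["1-16", "1-32", "1-41", "2-16"]),
        (("IGHV1-2", "TCGGGGGG", "IGHD3-3", "CTTGGAGCCT", "IGHJ6"),
         ["1-8", "2-37"]),
        (("IGHV1-2", "CTCTAT", "IGHD3-9", "AGCTGACA", "IGHJ5"),
         ["1-45", "2-38"]),
        (("IGHV1-3", "CTTACC", "IGHD3-22", "GGATC", "IGHJ4"),
         ["1-17", "2-43"]),
        (("IGHV1-69", "TCTGCCATTG", "IGHD5-12", "ATCCCCG", "IGHJ4"),
         ["1-23", "2-14"]),
        (("IGHV1-69", "CCCTAAAG", "IGHD2-15", "GTTCTTTCTTGACGGCCC", "IGHJ4"),
         ["1-20", "2-44"]),
        (("IGHV1-8", "CAACCGGGGCCAGCATACTG", "IGHD3-3", "CCTATGG", "IGHJ5"),
         ["1-24", "2-12"]),
        (("IGHV3-23", "TAAATCAATCGATAT", "IGHD3-3", "GTTACGGA", "IGHJ3"),
         ["1-22", "2-26"]),
        (("IGHV4-59", "TCGTTCA", "IGHD3-22", "CCGGAGTTTTTACCC", "IGHJ3"),
         ["1-43", "2-2"]),
    ]

    def _cells_from_table(self):
        cells = []
        for (v, n1, d, n2, j), members in self.TABLE:
            for cell in members:
                donor = cell.split("-")[0]
                rec = CellRecord(donor, cell, [])
                rec.patterns = [_ann(v_call=v, d_call=d, j_call=j,
                                     n1_seq=n1, n2_seq=n2)]
                cells.append(rec)
        return cells

    def test_published_table_yields_ten_cross_donor_sets(self):
        sets = shared_rearrangements(self._cells_from_table())
        assert len(sets) == 10
        assert all(s.cross_donor for s in sets)
        big = [s for s in sets if s.key[0] == "IGHV1-24"]
        assert len(big) == 1 and len(big[0].member_cells) == 13

    def test_unique_keys_share_nothing(self):
        cells = []
        for i in range(10):
            rec = CellRecord("1", f"1-{i}", [])
            rec.patterns = [_ann(n1_seq="A" * (i + 1))]
            cells.append(rec)
        assert shared_rearrangements(cells) == []

    def test_order_invariance(self):
        cells = self._cells_from_table()
        a = shared_rearrangements(cells)
        b = shared_rearrangements(list(reversed(cells)))
        assert [s.key for s in a] == [s.key for s in b]

    def test_simulated_sets_map_to_single_truth_clones(
            self, ptec_rep, ptec_annotations):
        cells = group_cells(ptec_annotations)
        sets = shared_rearrangements(cells)
        assert sets, "preset should produce shared clonotypes"
        truth = ptec_rep.truth
        key_cols = ["v_name", "n1_seq", "d_name", "n2_seq", "j_name"]
        for s in sets:
            v, d, j, n1, n2 = s.key
            rows = truth[(truth.v_name == v) & (truth.d_name == d)
                         & (truth.j_name == j) & (truth.n1_seq == n1)
                         & (truth.n2_seq == n2)
                         & truth.cell_id.isin([c for _, c in s.member_cells])]
            if len(rows):
                assert rows.clone_id.nunique() == 1


class TestCdr3Fit:
    def test_selffit_of_discretised_gaussian(self):
        x = np.arange(5, 26)
        weights = np.exp(-((x - 15) ** 2) / (2 * 2.5 ** 2))
        lengths = np.repeat(x, np.round(weights * 1000).astype(int))
        fit = cdr3_gaussian_fit(lengths)
        assert fit.r_squared >= 0.999
        assert fit.mean == pytest.approx(15, abs=0.1)

    def test_unimodal_sample_fits_well(self):
        rng = np.random.default_rng(61)
        lengths = np.clip(np.round(rng.normal(15, 2, size=3000)), 5, 30)
        fit = cdr3_gaussian_fit(lengths.astype(int))
        assert fit.r_squared >= 0.95

    def test_bimodal_sample_fits_worse_than_unimodal(self):
        rng = np.random.default_rng(62)
        uni = np.round(rng.normal(15, 2, size=1500)).astype(int)
        bi = np.concatenate([
            np.round(rng.normal(9, 1, size=750)),
            np.round(rng.normal(21, 1, size=750)),
        ]).astype(int)
        assert cdr3_gaussian_fit(bi).r_squared < cdr3_gaussian_fit(uni).r_squared

    def test_r_squared_never_exceeds_one(self):
        rng = np.random.default_rng(63)
        for _ in range(20):
            lengths = rng.integers(5, 30, size=rng.integers(10, 200))
            if np.unique(lengths).size < 3:
                continue
            assert cdr3_gaussian_fit(lengths).r_squared <= 1.0

    def test_degenerate_input_is_an_error(self):
        with pytest.raises(ValueError):
            cdr3_gaussian_fit([12] * 50)
        with pytest.raises(ValueError):
            cdr3_gaussian_fit([])

    def test_histogram_totals_match_input(self):
        fit = cdr3_gaussian_fit([10, 10, 12, 14, 14, 14])
        assert sum(fit.histogram.values()) == 6


class TestGenomicDistribution:
    def _gene_table(self, counts):
        return UsageTable("gene", "V", counts, sum(counts.values()))

    def test_all_mass_on_most_proximal_gene(self, reference):
        rank0 = next(s.name for s in reference.v_segments
                     if s.genomic_order_index == 0)
        res = genomic_distribution(self._gene_table({rank0: 10}), reference)
        assert res.concentration == 0.0

    def test_uniform_usage_is_centred(self, reference):
        table = self._gene_table({s.name: 1 for s in reference.v_segments})
        res = genomic_distribution(table, reference)
        assert res.concentration == pytest.approx(0.5)

    def test_unknown_gene_is_an_error(self, reference):
        with pytest.raises(Exception):
            genomic_distribution(self._gene_table({"IGHV9-99": 5}), reference)

    def test_ptec_usage_is_more_three_prime_than_bcell(
            self, ptec_annotations, bcell_annotations, reference):
        stats = {}
        for name, anns in (("ptec", ptec_annotations),
                           ("bcell", bcell_annotations)):
            cells = group_cells(anns)
            patterns = [p for c in cells for p in c.patterns]
            table = usage_frequencies(patterns, "gene", "V")
            stats[name] = genomic_distribution(table, reference).concentration
        assert stats["ptec"] < stats["bcell"]
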