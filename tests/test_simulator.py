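"""Simulator: recombination arithmetic, SHM statistics, truth integrity,
and recovery of the configured study conditions."""

import numpy as np
import pytest

from vdjrep.shm import scan_hotspots
from vdjrep.simulator import (
    JunctionLayout,
    SimulationError,
    Trims,
    _amplicon_region_map,
    apply_shm,
    make_config,
    recombine,
    reconstruct_truth,
    simulate_repertoire,
    translate_frame,
)


def _pattern_table(truth):
    """One row per distinct (cell, clone) rearrangement pattern."""
    return truth.drop_duplicates(["cell_id", "clone_id"])


class TestRecombine:
    def test_zero_trims_is_exact_concatenation(self, reference):
        v = reference.get("IGHV1-24")
        d = reference.get("IGHD2-15")
        j = reference.get("IGHJ4")
        seq, layout = recombine(reference, v.name, d.name, j.name, Trims())
        assert seq == v.sequence + d.sequence + j.sequence
        assert len(seq) == len(v.sequence) + len(d.sequence) + len(j.sequence)
        assert layout.v_end == layout.d_start == len(v.sequence)

    def test_junction_strings_are_embedded_verbatim(self, reference):
        # the archetypal shared rearrangement: V-D junction TT, D-J junction
        # ACCCGATCCGAC between IGHV1-24, IGHD2-15 and IGHJ4
        trims = Trims(v_trim3=2, d_trim5=1, d_trim3=1, j_trim5=2)
        n1, n2 = "TT", "ACCCGATCCGAC"
        seq, layout = recombine(reference, "IGHV1-24", "IGHD2-15", "IGHJ4",
                                trims, n1, n2)
        v = reference.get("IGHV1-24").sequence
        d = reference.get("IGHD2-15").sequence
        j = reference.get("IGHJ4").sequence
        assert seq[layout.v_end:layout.d_start] == n1
        assert seq[layout.d_end:layout.j_start] == n2
        assert seq == v[:-2] + n1 + d[1:-1] + n2 + j[2:]

    def test_excessive_d_trim_is_an_error(self, reference):
        d_len = len(reference.get("IGHD2-15").sequence)
        with pytest.raises(SimulationError, match="trims exceed"):
            recombine(reference, "IGHV1-24", "IGHD2-15", "IGHJ4",
                      Trims(d_trim5=d_len, d_trim3=1))

    def test_trimming_into_anchors_is_an_error(self, reference):
        with pytest.raises(SimulationError, match="Cys"):
            recombine(reference, "IGHV1-24", "IGHD2-15", "IGHJ4",
                      Trims(v_trim3=50))
        with pytest.raises(SimulationError, match="Trp"):
            recombine(reference, "IGHV1-24", "IGHD2-15", "IGHJ4",
                      Trims(j_trim5=30))


def _demo_amplicon(reference):
    """A fixed productive amplicon plus its region map."""
    v = reference.get("IGHV1-18")
    n2 = "CA"
    full, layout = recombine(reference, "IGHV1-18", "IGHD3-9", "IGHJ4",
                             Trims(0, 0, 0, 0), "GTAC", n2)
    n2 += "GCT"[: (-layout.trp_start) % 3]        # bring the Trp in frame
    full, layout = recombine(reference, "IGHV1-18", "IGHD3-9", "IGHJ4",
                             Trims(0, 0, 0, 0), "GTAC", n2)
    fr2 = layout.fr2_start
    amplicon = full[fr2:]
    layout = layout.shifted(-fr2)
    assert layout.trp_start % 3 == 0
    return amplicon, _amplicon_region_map(v, len(amplicon), layout)


class TestApplyShm:
    def test_zero_rate_is_identity(self, reference):
        amp, rmap = _demo_amplicon(reference)
        rng = np.random.default_rng(0)
        out, muts = apply_shm(amp, rmap, 0.0, 10.0, 3.0, rng)
        assert out == amp and muts == []

    def test_unbiased_mutation_count_matches_binomial_expectation(self, reference):
        amp, rmap = _demo_amplicon(reference)
        rate, n_rep = 0.05, 1000
        n_mutable = int(rmap.mutable.sum())
        expected = rate * n_mutable
        rng = np.random.default_rng(42)
        counts = [len(apply_shm(amp, rmap, rate, 1.0, 1.0, rng)[1])
                  for _ in range(n_rep)]
        se = np.sqrt(expected * (1 - rate) / n_rep)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_hotspot_bias_concentrates_mutations_by_closed_form(self, reference):
        amp, rmap = _demo_amplicon(reference)
        bias = 10.0
        hot = scan_hotspots(amp) & rmap.mutable
        f = hot.sum() / rmap.mutable.sum()
        expected = bias * f / (bias * f + (1 - f))
        rng = np.random.default_rng(7)
        in_hot = total = 0
        for _ in range(1000):
            _, muts = apply_shm(amp, rmap, 0.05, bias, 1.0, rng)
            in_hot += sum(hot[m.position] for m in muts)
            total += len(muts)
        se = np.sqrt(expected * (1 - expected) / total)
        assert abs(in_hot / total - expected) < 3 * se

    def test_mutations_never_hit_n_regions(self, reference):
        amp, rmap = _demo_amplicon(reference)
        rng = np.random.default_rng(3)
        for _ in range(50):
            _, muts = apply_shm(amp, rmap, 0.2, 20.0, 4.0, rng)
            assert all(rmap.mutable[m.position] for m in muts)

    def test_rejects_invalid_parameters(self, reference):
        amp, rmap = _demo_amplicon(reference)
        rng = np.random.default_rng(0)
        with pytest.raises(SimulationError):
            apply_shm(amp, rmap, 0.5, 1.0, 1.0, rng)
        with pytest.raises(SimulationError):
            apply_shm(amp, rmap, 0.1, 0.5, 1.0, rng)


class TestNonfunctional:
    def test_stop_rows_carry_an_in_frame_stop_before_the_j_end(self, reference):
        cfg = make_config("ptec-like", seed=21, p_nonfunctional=1.0,
                          shm_rate_dist=((1.0, 0.0, 0.0),))
        truth = simulate_repertoire(reference, cfg).truth
        stops = truth[truth.nonfunctional_kind == "stop"]
        assert len(stops) > 0
        for _, row in stops.iterrows():
            assert "*" in translate_frame(row.full_sequence)

    def test_frameshift_rows_break_the_v_to_j_frame(self, reference):
        cfg = make_config("ptec-like", seed=22, p_nonfunctional=1.0,
                          shm_rate_dist=((1.0, 0.0, 0.0),))
        truth = simulate_repertoire(reference, cfg).truth
        shifts = truth[truth.nonfunctional_kind == "frameshift"]
        assert len(shifts) > 0
        for _, row in shifts.iterrows():
            full, layout = recombine(
                reference, row.v_name, row.d_name, row.j_name,
                Trims(row.v_trim3, row.d_trim5, row.d_trim3, row.j_trim5),
                row.n1_seq, row.n2_seq)
            assert (layout.trp_start - layout.fr2_start) % 3 != 0

    def test_productive_rows_are_in_frame_and_stop_free(self, clean_rep, reference):
        truth = clean_rep.truth
        assert (truth.nonfunctional_kind == "none").all()
        for _, row in truth.sample(40, random_state=0).iterrows():
            assert "*" not in translate_frame(row.full_sequence)


class TestSimulateRepertoire:
    def test_seed_determinism_bytes(self, reference):
        cfg = make_config("ptec-like", seed=9, cells_per_donor=5)
        a = simulate_repertoire(reference, cfg)
        b = simulate_repertoire(reference, make_config("ptec-like", seed=9,
                                                       cells_per_donor=5))
        assert [(r.id, str(r.seq)) for r in a.records] == \
               [(r.id, str(r.seq)) for r in b.records]
        assert a.truth.equals(b.truth)

    def test_different_seeds_differ(self, reference):
        cfg_a = make_config("ptec-like", seed=1, cells_per_donor=5)
        cfg_b = make_config("ptec-like", seed=2, cells_per_donor=5)
        a = simulate_repertoire(reference, cfg_a)
        b = simulate_repertoire(reference, cfg_b)
        assert [str(r.seq) for r in a.records] != [str(r.seq) for r in b.records]

    def test_truth_reconstruction_is_exact(self, ptec_rep, reference):
        for _, row in ptec_rep.truth.iterrows():
            assert reconstruct_truth(reference, row) == row.full_sequence

    def test_unknown_gene_in_usage_is_an_error(self, reference):
        cfg = make_config("ptec-like", seed=0)
        cfg.v_usage = {"IGHV99-1": 1.0}
        with pytest.raises(SimulationError, match="IGHV99-1"):
            simulate_repertoire(reference, cfg)

    def test_colony_counts_respect_configuration(self, ptec_rep):
        per_cell = ptec_rep.truth.groupby("cell_id").sequence_id.nunique()
        assert per_cell.between(4, 8).all()

    def test_patterns_within_a_cell_have_distinct_junction_keys(self, ptec_rep):
        key_cols = ["v_name", "d_name", "j_name", "n1_seq", "n2_seq"]
        pat = _pattern_table(ptec_rep.truth)
        grouped = pat.groupby("cell_id")[key_cols].apply(
            lambda g: len(g) - len(g.drop_duplicates()))
        assert (grouped == 0).all()


class TestGeneratorRecovery:
    def test_v_usage_recovered_without_shm(self, reference):
        cfg = make_config(
            "ptec-like", seed=31, shm_rate_dist=((1.0, 0.0, 0.0),),
            p_nonfunctional=0.0, p_shared_clone=0.0,
            patterns_per_cell_dist=(1.0, 0.0, 0.0),
            colonies_per_cell=(1, 1), cells_per_donor=2500,
        )
        truth = simulate_repertoire(reference, cfg).truth
        n = len(truth)
        assert n == 5000
        freqs = truth.v_name.value_counts(normalize=True)
        for gene, p in cfg.v_usage.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freqs.get(gene, 0.0) - p) <= 3 * se + 1e-12, gene

    def test_nonfunctional_fraction_recovered(self, reference):
        p = 0.058
        cfg = make_config(
            "ptec-like", seed=32, p_nonfunctional=p, p_shared_clone=0.0,
            patterns_per_cell_dist=(1.0, 0.0, 0.0), colonies_per_cell=(1, 1),
            cells_per_donor=1000, shm_rate_dist=((1.0, 0.0, 0.0),),
        )
        truth = simulate_repertoire(reference, cfg).truth
        pat = _pattern_table(truth)
        frac = (pat.nonfunctional_kind != "none").mean()
        se = np.sqrt(p * (1 - p) / len(pat))
        assert abs(frac - p) < 3 * se

    def test_patterns_per_cell_distribution_recovered(self, reference):
        dist = (0.868, 0.110, 0.022)
        cfg = make_config(
            "ptec-like", seed=33, p_shared_clone=0.0,
            cells_per_donor=1000, colonies_per_cell=(3, 3),
            shm_rate_dist=((1.0, 0.0, 0.0),), p_nonfunctional=0.0,
        )
        truth = simulate_repertoire(reference, cfg).truth
        counts = truth.groupby("cell_id").clone_id.nunique()
        n = counts.size
        for k, p in zip((1, 2, 3), dist):
            se = np.sqrt(p * (1 - p) / n)
            assert abs((counts == k).mean() - p) <= 3 * se, k

    def test_shm_rate_mixture_puts_60pct_in_5_to_10(self, reference):
        cfg = make_config(
            "ptec-like", seed=34, p_shared_clone=0.0,
            patterns_per_cell_dist=(1.0, 0.0, 0.0), colonies_per_cell=(1, 1),
            cells_per_donor=500,
        )
        truth = simulate_repertoire(reference, cfg).truth
        rates = truth.shm_rate
        assert rates.between(0.029, 0.205).all()
        frac = rates.between(0.05, 0.10).mean()
        se = np.sqrt(0.6 * 0.4 / len(rates))
        assert abs(frac - 0.6) < 3 * se

    def test_shared_clones_span_multiple_cells_and_donors(self, ptec_rep):
        truth = ptec_rep.truth
        shared = truth[truth.clone_id.str.startswith("shared")]
        per_clone = shared.groupby("clone_id").cell_id.nunique()
        assert (per_clone >= 2).any()
        # a shared clone emits byte-identical sequences in every cell
        for clone_id, grp in shared.groupby("clone_id"):
            assert grp.full_sequence.nunique() == 1
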