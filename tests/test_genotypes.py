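"""Genotype reconstruction, linkage grouping, decomposition, event calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_genotypes
from phagetrace.genotypes import (
    cluster_trajectories,
    cooccurrence_lower_bound,
    decompose_sample,
    derive_genotypes,
    detect_clonal_samples,
    detect_novel_blocks,
    detect_recombination,
    summarize_catalog,
)


def matrix_of(rows, variants=None):
    variants = variants or list(range(1, len(rows[0]) + 1))
    return pd.DataFrame(rows, columns=variants, index=[f"s{i}" for i in range(len(rows))])


class TestClonality:
    def test_all_zero_is_reference_clonal(self):
        m = matrix_of([[0.0] * 5])
        [(sample, hap)] = detect_clonal_samples(m)
        assert sample == "s0" and not hap.any()

    def test_near_fixed_alt_sites(self):
        # nine sites near fixation (minimum 0.971), rest at zero
        freqs = [0.971, 0.99, 1.0, 0.98, 1.0, 0.995, 0.975, 1.0, 0.99] + [0.0] * 10
        [(_, hap)] = detect_clonal_samples(matrix_of([freqs]))
        assert hap.sum() == 9
        assert list(hap[:9]) == [1] * 9

    def test_intermediate_site_breaks_clonality(self):
        assert detect_clonal_samples(matrix_of([[0.0, 0.5, 1.0]])) == []

    def test_missing_entries_never_clonal(self):
        assert detect_clonal_samples(matrix_of([[0.0, np.nan, 0.0]])) == []

    def test_ref_alt_relabel_flips_bit_only(self):
        m = matrix_of([[0.99, 0.0, 1.0]])
        flipped = m.copy()
        flipped[2] = 1.0 - flipped[2]
        [(_, h1)] = detect_clonal_samples(m)
        [(_, h2)] = detect_clonal_samples(flipped)
        assert h1[0] == h2[0] and h1[2] == h2[2]
        assert h1[1] != h2[1]


class TestCooccurrenceBound:
    @pytest.mark.parametrize(
        "freqs,expected",
        [([0.9, 0.9], 0.8), ([0.8, 0.8, 0.8], 0.4), ([0.6, 0.3], 0.0)],
    )
    def test_examples(self, freqs, expected):
        assert cooccurrence_lower_bound(freqs) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cooccurrence_lower_bound([])


class TestDeriveGenotypes:
    def test_deduplication_merges_sources(self):
        hap = np.array([1, 0, 1])
        genos = derive_genotypes([("a", hap), ("b", hap.copy())])
        assert len(genos) == 1
        assert genos[0].source_samples == ["a", "b"]

    def test_reference_and_marker_genotypes(self):
        ref = np.zeros(9, dtype=int)
        alt = np.ones(9, dtype=int)
        genos = derive_genotypes([("wk0_ref", ref), ("wk6_alt", alt)])
        by_prov = {g.provenance: g for g in genos}
        assert by_prov["reference"].haplotype.sum() == 0
        assert by_prov["founder"].haplotype.sum() == 9
        assert (
            np.sum(by_prov["reference"].haplotype != by_prov["founder"].haplotype) == 9
        )

    def test_pigeonhole_proposal_from_high_frequency_sample(self):
        clonal = [("c", np.zeros(5, dtype=int))]
        m = matrix_of([[0.0] * 5, [0.85, 0.9, 0.88, 0.0, 0.01]])
        genos = derive_genotypes(clonal, m)
        proposals = [g for g in genos if g.provenance == "pigeonhole"]
        assert len(proposals) == 1
        assert list(proposals[0].haplotype) == [1, 1, 1, 0, 0]
        assert proposals[0].cooccurrence_bound == pytest.approx(0.63)


class TestClusterTrajectories:
    def test_identical_trajectories_merge(self):
        t = [0.1, 0.4, 0.9, 0.2, 0.5]
        m = matrix_of([[a, a] for a in t])
        groups = cluster_trajectories(m)
        assert len(groups) == 1 and set(groups[0].members) == {1, 2}

    def test_opposite_trajectories_split(self):
        m = matrix_of([[0, 1], [0, 1], [1, 0], [1, 0]])
        assert len(cluster_trajectories(m)) == 2

    def test_sparse_coobservation_never_merges(self):
        m = matrix_of(
            [[0.5, np.nan], [np.nan, 0.5], [0.5, np.nan], [np.nan, 0.5]]
        )
        assert len(cluster_trajectories(m)) == 2

    def test_recovers_marker_sets_from_simulation(self):
        # three genotypes with exclusive markers, deep uniform coverage
        rng = np.random.default_rng(0)
        depth = 200
        haps = {
            "A": [1, 1, 1, 0, 0, 0, 0, 0],
            "B": [0, 0, 0, 1, 1, 1, 0, 0],
            "C": [0, 0, 0, 0, 0, 0, 1, 1],
        }
        H = np.array(list(haps.values()))
        rows = []
        for _ in range(9):
            a = rng.dirichlet([2, 2, 2])
            f = a @ H
            rows.append(rng.binomial(depth, f) / depth)
        groups = cluster_trajectories(matrix_of(rows))
        member_sets = {frozenset(g.members) for g in groups}
        assert member_sets == {
            frozenset({1, 2, 3}), frozenset({4, 5, 6}), frozenset({7, 8}),
        }


class TestDecomposition:
    haps = {
        "G1": [0, 0, 0, 0, 0],
        "G2": [1, 1, 1, 0, 0],
        "G4": [0, 0, 0, 1, 1],
    }

    def test_clonal_sample_is_unit_vector(self):
        genos = make_genotypes(self.haps)
        f = pd.Series([1.0, 1.0, 1.0, 0.0, 0.0])
        for mode in ("paper_averaging", "simplex_lsq"):
            a = decompose_sample(f, genos, mode=mode)
            assert a["G2"] == pytest.approx(1.0, abs=1e-9)
            assert a.sum() == pytest.approx(1.0)

    def test_even_two_genotype_mixture(self):
        genos = make_genotypes({"G1": [0, 0, 0], "G2": [1, 1, 1]})
        f = pd.Series([0.5, 0.5, 0.5])
        for mode in ("paper_averaging", "simplex_lsq"):
            a = decompose_sample(f, genos, mode=mode)
            assert a["G1"] == pytest.approx(0.5, abs=1e-9)
            assert a["G2"] == pytest.approx(0.5, abs=1e-9)

    def test_simplex_lsq_inverts_forward_construction(self, table1_haplotypes):
        rng = np.random.default_rng(1)
        genos = make_genotypes(table1_haplotypes)
        H = np.array([g.haplotype for g in genos])
        for _ in range(5):
            a_true = rng.dirichlet([1, 1, 1, 1])
            f = pd.Series(a_true @ H)
            a = decompose_sample(f, genos, mode="simplex_lsq")
            assert np.allclose(a[[g.id for g in genos]], a_true, atol=1e-6)

    def test_mode_agreement_on_exclusive_markers(self):
        genos = make_genotypes(self.haps)
        a_true = np.array([0.2, 0.5, 0.3])
        H = np.array(list(self.haps.values()))
        f = pd.Series(a_true @ H)
        avg = decompose_sample(f, genos, mode="paper_averaging")
        lsq = decompose_sample(f, genos, mode="simplex_lsq")
        assert np.allclose(avg, lsq[avg.index], atol=1e-6)

    def test_shared_marker_windowing(self):
        # one marker shared between two genotypes: attributed to whichever
        # genotype is present, as in the published averaging recipe
        haps = {"G2": [1, 1, 0], "G4": [0, 1, 1]}  # variant 2 is shared
        genos = make_genotypes(haps)
        late = pd.Series([0.0, 0.9, 0.9])  # only G4 present
        a = decompose_sample(late, genos, mode="paper_averaging")
        assert a["G4"] == pytest.approx(0.9, abs=1e-9)
        assert a["G2"] == pytest.approx(0.0, abs=1e-9)

    @given(st.lists(st.floats(0, 1), min_size=5, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_output_is_simplex(self, freqs):
        genos = make_genotypes(self.haps)
        a = decompose_sample(pd.Series(freqs), genos, mode="simplex_lsq")
        assert (a >= -1e-12).all()
        assert a.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_genotype_set_errors(self):
        with pytest.raises(ValueError):
            decompose_sample(pd.Series([0.5]), [])


class TestRecombination:
    @staticmethod
    def _setup(rows, weeks, mesocosm="6_open"):
        variants = list(range(1, len(rows[0]) + 1))
        samples = [f"{mesocosm}_w{w}" for w in weeks]
        m = pd.DataFrame(rows, columns=variants, index=samples)
        meta = pd.DataFrame(
            {
                "sample": samples,
                "mesocosm": mesocosm.split("_")[0],
                "regime": "open",
                "week": weeks,
            }
        )
        return m, meta

    def test_single_genotype_mesocosm_has_no_events(self):
        rows = [[0, 0, 1, 1]] * 4
        m, meta = self._setup(rows, [0, 2, 4, 6])
        groups = cluster_trajectories(m)
        assert detect_recombination(m, meta, groups) == []

    def test_fixed_vs_lost_group_pattern(self):
        # pink group (v1-3) sweeps to fixation while green/blue (v4-9)
        # drop to zero after a window of coexistence: the signature of a
        # recombinant carrying only the pink markers
        pink, rest = [0.5, 0.5, 0.75, 1.0, 1.0], [0.5, 0.5, 0.25, 0.0, 0.0]
        rows = [[p] * 3 + [r] * 6 for p, r in zip(pink, rest)]
        m, meta = self._setup(rows, [0, 2, 4, 6, 8])
        groups = cluster_trajectories(m)
        genos = make_genotypes(
            {"G1": [0] * 9, "G2": [1] * 9, "G3": [1, 1, 1, 0, 0, 0, 0, 0, 0]}
        )
        events = detect_recombination(m, meta, groups, genos)
        assert len(events) == 1
        ev = events[0]
        assert ev.mesocosm == "6_open" and ev.first_week == 4
        assert list(ev.child_haplotype) == [1, 1, 1, 0, 0, 0, 0, 0, 0]
        assert ev.parents == ("G2", "G1")
        assert ev.primary

    def test_requires_prior_coexistence(self):
        # groups that were never simultaneously intermediate do not decouple
        rows = [[0.0, 1.0], [0.0, 1.0], [0.0, 0.4], [0.0, 0.2]]
        m, meta = self._setup(rows, [0, 2, 4, 6])
        groups = cluster_trajectories(m)
        assert detect_recombination(m, meta, groups) == []


class TestNovelBlocks:
    def test_no_candidates(self):
        m = pd.DataFrame(
            [[0.5, 0.5], [0.4, 0.6]],
            columns=[1, 2],
            index=["a_open_w0", "a_open_w2"],
        )
        meta = pd.DataFrame(
            {
                "sample": m.index,
                "mesocosm": "a",
                "regime": "open",
                "week": [0, 2],
            }
        )
        genos = make_genotypes({"G1": [0, 0], "G2": [1, 1]})
        assert detect_novel_blocks(m, meta, genos) == []

    def test_block_shadowing_carrier_trajectory(self):
        # carrier genotype G2 rises 0 -> 1; block variants track it exactly
        carrier = [0.0, 0.0, 0.3, 0.7, 1.0]
        weeks = [0, 2, 4, 6, 8]
        samples = [f"m_open_w{w}" for w in weeks] + ["m_closed_w0"]
        rows = [[c, c, c, c] for c in carrier] + [[0.0, 0.0, 0.0, 0.0]]
        m = pd.DataFrame(rows, columns=[10, 20, 100, 200], index=samples)
        meta = pd.DataFrame(
            {
                "sample": samples,
                "mesocosm": "m",
                "regime": ["open"] * 5 + ["closed"],
                "week": weeks + [0],
            }
        )
        # variants 10/20 are the carrier's backbone markers (present at
        # week 0 in the open founder sample? no: they rise with it) --
        # make them baseline-present so only 100/200 are candidates
        m.loc["m_closed_w0", [10, 20]] = 1.0
        genos = make_genotypes({"G1": [0, 0, 0, 0], "G2": [1, 1, 0, 0]})
        blocks = detect_novel_blocks(m, meta, genos)
        assert len(blocks) == 1
        block = blocks[0]
        assert set(block.variants) == {100, 200}
        assert block.carrier == "G2"
        assert block.first_week == 4
        assert all(v == "G2" for v in block.member_assignments.values())


class TestSummarizeCatalog:
    def test_table1_accounting(self, table1):
        report = summarize_catalog(table1)
        assert report["total_snps"] == 76
        assert report["assigned_pct"] == 92.1
        assert report["type_B_exclusive_pct"] == 80.3
        assert report["per_condition"]["open_B"] == 70
        assert report["cluster_novel_snp_count"] == 46

    def test_empty_catalog(self):
        empty = pd.DataFrame(columns=["G1", "G2", "orf"]).set_index(
            pd.Index([], name="position")
        )
        report = summarize_catalog(empty)
        assert report["total_snps"] == 0
        assert report["assigned_count"] == 0
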