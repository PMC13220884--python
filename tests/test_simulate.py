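"""The serial-transfer metacommunity simulator and its ground truth."""

import numpy as np
import pandas as pd
import pytest

from phagetrace.simulate import (
    ConfigurationError,
    NovelBlockSpec,
    RecombinationSpec,
    SimulationConfig,
    mesocosm_experiment_config,
    simulate_metacommunity,
)


def tiny_config(**overrides):
    base = dict(
        community_type_assignment={"1": "A"},
        founder_genotype_map={"1": "G2"},
        regimes=("closed",),
        total_weeks=8,
        sampling_weeks=(0, 2, 4, 8),
        include_cocktail_samples=False,
        rng_seed=5,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_zero_reads_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(reads_per_sample=0)

    def test_bad_dilution_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(dilution_factor=1.5)

    def test_off_grid_sampling_week_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(sampling_weeks=(0, 3))

    def test_event_with_absent_parent_rejected(self):
        cfg = tiny_config(
            recombination_events=(
                RecombinationSpec(
                    mesocosm="1_closed", transfer=2,
                    parents=("G1", "G2"), crossovers=(100,),
                ),
            )
        )
        with pytest.raises(ConfigurationError, match="coexist"):
            simulate_metacommunity(cfg)

    def test_block_with_absent_carrier_rejected(self):
        cfg = tiny_config(
            novel_block=NovelBlockSpec(
                mesocosm="1_closed", transfer=2, carrier="G9", n_snps=5
            )
        )
        with pytest.raises(ConfigurationError, match="G9"):
            simulate_metacommunity(cfg)


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        cfg = mesocosm_experiment_config(rng_seed=3, total_weeks=16,
                                         sampling_weeks=(0, 2, 4, 6, 8),
                                         recombination_events=(), novel_block=None)
        d1, t1 = simulate_metacommunity(cfg)
        d2, t2 = simulate_metacommunity(cfg)
        for key in d1:
            pd.testing.assert_frame_equal(d1[key], d2[key])
        pd.testing.assert_frame_equal(t1.abundances, t2.abundances)
        assert t1.genotypes == t2.genotypes

    def test_different_seed_differs(self):
        mk = lambda s: mesocosm_experiment_config(
            rng_seed=s, total_weeks=8, sampling_weeks=(0, 4, 8),
            recombination_events=(), novel_block=None,
        )
        d1, _ = simulate_metacommunity(mk(0))
        d2, _ = simulate_metacommunity(mk(1))
        assert not d1["allele_depths"].equals(d2["allele_depths"])


class TestSingleCloneIdentity:
    def test_no_events_single_genotype(self):
        cfg = tiny_config(sequencing_error_rate=0.0)
        dataset, truth = simulate_metacommunity(cfg)
        depths = dataset["allele_depths"]
        # the lone founder carries G2, so every alt frequency is 0 or 1
        # depending on the marker state, with no intermediate values
        g2 = dict(zip(truth.positions, truth.genotypes["G2"]))
        covered = depths[(depths.ref_depth + depths.alt_depth) > 0]
        for _, r in covered.iterrows():
            freq = r.alt_depth / (r.ref_depth + r.alt_depth)
            assert freq == pytest.approx(float(g2[r.position]))
        # truth abundance is the unit vector wherever the phage is present
        present = truth.phage_fraction[truth.phage_fraction > 0].index
        assert np.allclose(truth.abundances.loc[present, "G2"], 1.0)


class TestConservation:
    def test_expected_frequency_is_abundance_weighted_mean(self):
        # high depth, zero error: observed frequencies converge on H' a
        cfg = mesocosm_experiment_config(
            rng_seed=11, total_weeks=8, sampling_weeks=(0, 2, 4, 6, 8),
            mean_depth_at_peak=50_000, sequencing_error_rate=0.0,
        )
        dataset, truth = simulate_metacommunity(cfg)
        H = np.array([truth.genotypes[g] for g in truth.abundances.columns])
        depths = dataset["allele_depths"].set_index(["sample", "position"])
        for sample in truth.abundances.index:
            a = truth.abundances.loc[sample].to_numpy()
            if a.sum() == 0:
                continue
            expected = a @ H
            sub = depths.loc[sample]
            total = sub.ref_depth + sub.alt_depth
            deep = total > 5000
            if not deep.any():
                continue
            observed = (sub.alt_depth / total)[deep]
            exp = pd.Series(expected, index=list(truth.positions))[deep.index[deep]]
            assert np.allclose(observed, exp, atol=0.02)


class TestClosedRegimeIsolation:
    def test_no_genotype_crosses_into_closed_mesocosms(self, study_run):
        config, dataset, truth = study_run
        meta = dataset["metadata"].set_index("sample")
        founders = config.founder_genotype_map
        for sample, row in truth.abundances.iterrows():
            if meta.loc[sample, "regime"] != "closed":
                continue
            mesocosm = meta.loc[sample, "mesocosm"]
            allowed = {founders.get(mesocosm)}
            carried = set(row.index[row > 0])
            assert carried <= allowed

    def test_closed_founders_are_monomorphic(self, study_run):
        # closed type-A mesocosms carry exactly their founder genotype:
        # one reference-genotype mesocosm and three marker-genotype ones
        config, dataset, truth = study_run
        for m, gid in config.founder_genotype_map.items():
            for week in (2, 6, 8):
                s = f"{m}_closed_w{week}"
                if truth.phage_fraction[s] > 0:
                    assert truth.abundances.loc[s, gid] == pytest.approx(1.0)


class TestObservationModel:
    def test_depth_scales_with_phage_fraction(self, study_run):
        _, dataset, truth = study_run
        cov = dataset["coverage"].set_index("sample")
        meso = [s for s in cov.index if not s.startswith("cocktail")]
        f = truth.phage_fraction[meso]
        lam = cov.loc[meso, "mean_depth"]
        ratio = lam[f > 0] / f[f > 0]
        assert ratio.std() / ratio.mean() < 1e-9  # exact proportionality

    def test_abundance_rows_are_simplex_where_present(self, study_run):
        _, dataset, truth = study_run
        present = truth.phage_fraction > 0
        sums = truth.abundances.loc[present].sum(axis=1)
        assert np.allclose(sums, 1.0)
        assert (truth.abundances.to_numpy() >= 0).all()

    def test_novel_block_absent_before_event(self, study_run):
        config, dataset, truth = study_run
        block = next(e for e in truth.event_log if e["type"] == "novel_block")
        meta = dataset["metadata"].set_index("sample")
        depths = dataset["allele_depths"]
        early = meta.index[meta["week"] < block["week"]]
        pre = depths[
            depths["sample"].isin(early) & depths["position"].isin(block["positions"])
        ]
        freqs = pre["alt_depth"] / (pre["ref_depth"] + pre["alt_depth"]).replace(0, 1)
        # only sequencing error, never real presence
        assert (freqs < 0.05).all()


class TestStudyScenarioShape:
    def test_sample_grid_and_tables(self, study_run):
        config, dataset, truth = study_run
        meta = dataset["metadata"]
        mesocosm_samples = meta[meta["mesocosm"] != "cocktail"]
        assert len(mesocosm_samples) == 10 * 2 * len(config.sampling_weeks)
        assert set(dataset["coverage"]["sample"]) == set(meta["sample"])
        # cocktail carries no cellular taxa
        assert not any(
            s.startswith("cocktail") for s in dataset["genus_counts"].index
        )

    def test_type_b_invasion_is_weaker(self, study_run):
        # the phage colonises open type-B mesocosms at roughly an order of
        # magnitude lower read fraction than its native type-A context
        config, dataset, truth = study_run
        meta = dataset["metadata"].set_index("sample")
        peak = {}
        for sample, f in truth.phage_fraction.items():
            if sample.startswith("cocktail"):
                continue
            m = meta.loc[sample, "mesocosm"]
            key = (config.community_type_assignment[m], meta.loc[sample, "regime"])
            peak[key] = max(peak.get(key, 0.0), f)
        assert peak[("B", "open")] > 0.01  # invasion succeeded
        assert peak[("B", "open")] < peak[("A", "open")]
        assert peak[("B", "closed")] == 0.0  # no native phage in closed type B
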