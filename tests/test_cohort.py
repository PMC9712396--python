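import numpy as np
import pytest

from ocsnet.cohort import (
    CohortSpec,
    GroupEffect,
    generate_cohort,
    generate_phenotypes,
    generate_timeseries,
    planted_layout,
    write_cohort,
)
from ocsnet.community import Partition
from ocsnet.connectome import build_connectivity
from ocsnet.phenotype import classify_groups
from ocsnet.subnetwork import between_subnetwork_means


def block_means(w, memb):
    """Mean |r| within and between planted blocks (off-diagonal only)."""
    same = memb[:, None] == memb[None, :]
    off = ~np.eye(len(memb), dtype=bool)
    return w[same & off].mean(), w[~same].mean()


class TestGenerateTimeseries:
    def _partition(self, n=30, k=3):
        return Partition(
            tuple(f"n{i}" for i in range(n)), np.arange(n) * k // n
        )

    def test_within_block_correlation_exceeds_between(self):
        p = self._partition()
        ts = generate_timeseries(p, 0.9, 0.0, T=200, noise_sd=0.1, rng_seed=0)
        w = build_connectivity(ts).w
        within, between = block_means(w, p.membership)
        assert within > between

    def test_equal_couplings_equalize_blocks(self):
        p = self._partition()
        vals = []
        for seed in range(10):
            ts = generate_timeseries(p, 0.5, 0.5, T=400, noise_sd=0.5, rng_seed=seed)
            w = build_connectivity(ts).w
            within, between = block_means(w, p.membership)
            vals.append(within - between)
        assert np.mean(vals) == pytest.approx(0.0, abs=0.02)

    def test_deterministic_given_seed(self):
        p = self._partition()
        a = generate_timeseries(p, 0.6, 0.1, T=50, noise_sd=0.5, rng_seed=42)
        b = generate_timeseries(p, 0.6, 0.1, T=50, noise_sd=0.5, rng_seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValueError):
            generate_timeseries(self._partition(), 0.5, 0.1, T=50, noise_sd=0.0, rng_seed=0)


class TestGeneratePhenotypes:
    def test_probable_ocd_prevalence_binomial(self):
        n, p = 1000, 0.06
        recs = generate_phenotypes(n, {"probable_ocd": p, "high_ocs": 0.0}, rng_seed=5)
        frac = np.mean([classify_groups(r.socs_items)["probable_ocd"] for r in recs])
        tol = 3 * np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) <= tol + 0.01  # + slack for missing-item reclassification

    def test_zero_prevalence_never_reaches_cutoff(self):
        recs = generate_phenotypes(500, {"probable_ocd": 0.0, "high_ocs": 0.0}, rng_seed=1)
        assert not any(classify_groups(r.socs_items)["probable_ocd"] for r in recs)

    def test_high_ocs_prevalence_tracks_nominal(self):
        recs = generate_phenotypes(2000, {"probable_ocd": 0.0, "high_ocs": 0.15}, rng_seed=2)
        frac = np.mean([classify_groups(r.socs_items)["high_ocs"] for r in recs])
        assert frac == pytest.approx(0.15, abs=0.03)

    def test_item_and_covariate_ranges(self):
        recs = generate_phenotypes(300, rng_seed=3)
        for r in recs:
            observed = [v for v in r.socs_items if not np.isnan(v)]
            assert len(r.socs_items) == 7
            assert len(observed) >= 6  # at most one missing item
            assert set(observed) <= {0.0, 1.0, 2.0}
            assert 7 < r.age < 13
            assert r.sex in (0, 1)
            assert r.cbcl_adj >= 0

    def test_missing_items_injected_at_configured_rate(self):
        recs = generate_phenotypes(2000, rng_seed=4, missing_item_rate=0.1)
        frac = np.mean([any(np.isnan(v) for v in r.socs_items) for r in recs])
        assert frac == pytest.approx(0.1, abs=0.03)


class TestGenerateCohort:
    def test_deterministic(self):
        spec = CohortSpec(n_subjects=3, n_nodes=30, thalamic_pairs=False, seed=7)
        a, b = generate_cohort(spec), generate_cohort(spec)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.timeseries.values, s2.timeseries.values)
            np.testing.assert_array_equal(s1.fd_trace, s2.fd_trace)
            assert s1.phenotype == s2.phenotype

    def test_all_subjects_share_planted_partition(self):
        subs = generate_cohort(CohortSpec(n_subjects=4, seed=0))
        parts = {tuple(s.planted_partition.membership) for s in subs}
        assert len(parts) == 1
        assert subs[0].planted_partition.K == 5

    def test_single_subject_cohort(self):
        subs = generate_cohort(CohortSpec(n_subjects=1, seed=1))
        assert len(subs) == 1
        build_connectivity(subs[0].timeseries)  # downstream stage still runs

    def test_between_pair_effect_lowers_targeted_pair(self):
        effect = GroupEffect("between_coupling_pair", 0.08, "high_ocs", pair=(1, 2))
        spec = CohortSpec(
            n_subjects=200, n_nodes=40, prevalence={"high_ocs": 0.3},
            effect=effect, seed=13, timeseries_length=150,
        )
        subs = generate_cohort(spec)
        part = subs[0].planted_partition
        target, others = {True: [], False: []}, {True: [], False: []}
        for s in subs:
            high = classify_groups(s.phenotype.socs_items)["high_ocs"]
            sc = between_subnetwork_means(build_connectivity(s.timeseries), part)
            target[high].append(sc.pair_means[(1, 2)])
            others[high].append(sc.pair_means[(0, 3)])
        assert np.mean(target[True]) < np.mean(target[False]) - 0.02
        assert abs(np.mean(others[True]) - np.mean(others[False])) < 0.02

    def test_effect_making_coupling_negative_rejected(self):
        effect = GroupEffect("between_coupling_pair", 0.5, "high_ocs", pair=(0, 1))
        with pytest.raises(ValueError, match="negative"):
            CohortSpec(n_subjects=5, between_coupling=0.1, effect=effect)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=5, between_coupling=0.6, within_coupling=0.5)
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=5, timeseries_length=10)
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=5, prevalence={"probable_ocd": 0.6, "high_ocs": 0.5})


class TestPlantedLayout:
    def test_balanced_communities_with_thalamic_pairs(self):
        part, node_set = planted_layout(60, 5)
        sizes = np.bincount(part.membership)
        assert sizes.min() >= 10 and sizes.max() <= 14
        assert len(node_set.pairs) == 8

    def test_exactly_one_split_pair(self):
        part, node_set = planted_layout(60, 5)
        split = [
            sub for sub, l, r in node_set.pairs
            if part.community_of(l) != part.community_of(r)
        ]
        assert split == ["cTtha"]

    def test_no_thalamic_tagging_when_disabled(self):
        part, node_set = planted_layout(20, 4, thalamic=False)
        assert node_set is None
        assert part.K == 4


def test_write_cohort_roundtrip(tmp_path):
    import pandas as pd

    spec = CohortSpec(n_subjects=3, n_nodes=30, thalamic_pairs=False, seed=2)
    subs = generate_cohort(spec)
    write_cohort(subs, tmp_path, spec)
    pheno = pd.read_csv(tmp_path / "phenotypes.tsv", sep="\t")
    assert len(pheno) == 3
    ts = pd.read_csv(tmp_path / "timeseries" / "sub-0000.tsv", sep="\t")
    assert ts.shape == (spec.timeseries_length, 30)
    part = pd.read_csv(tmp_path / "planted_partition.tsv", sep="\t")
    assert part["community"].nunique() == 5
    assert (tmp_path / "manifest.yaml").exists()
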