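import numpy as np
import pytest

from surf.aggregation import BUILTIN_MODELS, WeightModel, prioritise
from surf.annotation import GenomicInterval, VariantRecord
from surf.evaluation import (
    RegionSet,
    auc_columns,
    auc_mann_whitney,
    negative_control,
    roc_auc,
    spike_in,
)
from surf.fixtures import FixtureSpec, generate_benchmark, generate_bundle, generate_labelled_variants
from surf.ranking import RankConfig

from conftest import brute_force_auc


class TestRocAuc:
    def test_perfect_separation(self):
        points, auc = roc_auc([5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert auc == 1.0

    def test_reversed_scores(self):
        _, auc = roc_auc([1, 2, 3, 5, 6, 7], [1, 1, 1, 0, 0, 0])
        assert auc == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            auc_mann_whitney([1.0, 2.0], [0, 0])

    def test_curve_shape(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        points, _ = roc_auc(scores, labels)
        assert points.iloc[0].tolist() == [0.0, 0.0]
        assert points.iloc[-1].tolist() == [1.0, 1.0]
        assert (points.diff().dropna() >= 0).all().all()  # monotone sweep

    def test_matches_all_pairs_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for trial in range(50):
            n = int(rng.integers(4, 40))
            # integer scores force ties, exercising the half-count rule
            scores = rng.integers(0, 6, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            expect = brute_force_auc(scores, labels)
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(expect)
            assert auc_mann_whitney(scores, labels) == pytest.approx(expect)

    def test_auc_columns_matches_scalar_version(self):
        rng = np.random.default_rng(2)
        S = rng.normal(size=(30, 5))
        y = rng.integers(0, 2, 30)
        y[:3] = 1
        y[-3:] = 0
        cols = auc_columns(S, y)
        for j in range(5):
            assert cols[j] == pytest.approx(auc_mann_whitney(S[:, j], y))


def _two_region_setup():
    """Two tiny regions with hand-placed backgrounds."""
    regions = {
        "r1": GenomicInterval("chr1", 0, 1000),
        "r2": GenomicInterval("chr2", 0, 1000),
    }
    backgrounds = {
        "r1": [VariantRecord("chr1", p, id=f"b1_{p}", maf=0.3)
               for p in (100, 200)],
        "r2": [VariantRecord("chr2", p, id=f"b2_{p}", maf=0.3)
               for p in (150, 250)],
    }
    return RegionSet(regions=regions, backgrounds=backgrounds)


class TestRegionSet:
    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RegionSet(regions={"a": GenomicInterval("chr1", 0, 100),
                               "b": GenomicInterval("chr1", 50, 150)},
                      backgrounds={})

    def test_background_outside_region_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            RegionSet(regions={"a": GenomicInterval("chr1", 0, 100)},
                      backgrounds={"a": [VariantRecord("chr1", 500)]})


class TestSpikeIn:
    def test_dominant_positives_reach_auc_one(self, hand_bundle):
        region_set = _two_region_setup()
        # positives sit on the annotation hotspot at chr1:170 equivalents
        positives = [VariantRecord("chr1", 170, id="p1", maf=0.001),
                     VariantRecord("chr1", 171, id="p2", maf=0.002)]
        report = spike_in(positives, region_set, BUILTIN_MODELS["DM"],
                          hand_bundle)
        assert report.mean_region_auc == 1.0
        assert set(report.region_aucs) == {"r1", "r2"}

    def test_id_clash_with_background_rejected(self, hand_bundle):
        region_set = _two_region_setup()
        positives = [VariantRecord("chr1", 170, id="b1_100")]
        with pytest.raises(ValueError, match="overlap"):
            spike_in(positives, region_set, BUILTIN_MODELS["DM"], hand_bundle)

    def test_empty_region_skipped_with_warning(self, hand_bundle):
        region_set = _two_region_setup()
        region_set.backgrounds["r2"] = []
        positives = [VariantRecord("chr1", 170, id="p1", maf=0.001)]
        with pytest.warns(UserWarning, match="no background"):
            report = spike_in(positives, region_set, BUILTIN_MODELS["DM"],
                              hand_bundle)
        assert list(report.region_aucs) == ["r1"]

    def test_per_region_aucs_match_hand_computation(self, enriched_fixture):
        spec, bundle, region_set, lvs = enriched_fixture
        cfg = RankConfig(state_order=spec.state_order)
        positives = [v for v, y in zip(lvs.variants, lvs.labels) if y == 1][:10]
        report = spike_in(positives, region_set, BUILTIN_MODELS["DM"],
                          bundle, cfg)
        for name, auc in report.region_aucs.items():
            pool = positives + region_set.backgrounds[name]
            labels = [1] * len(positives) + [0] * len(region_set.backgrounds[name])
            res = prioritise(pool, bundle, BUILTIN_MODELS["DM"], cfg)
            assert auc == pytest.approx(
                brute_force_auc(res["weighted_sum"].tolist(), labels))
        assert report.mean_region_auc == pytest.approx(
            np.mean(list(report.region_aucs.values())))

    def test_exchangeable_positives_score_near_half(self):
        # positives drawn from the same distribution as the backgrounds
        spec = FixtureSpec(seed=31, n_regions=3, n_background_per_region=150,
                           n_functional=0)
        bundle, region_set, lvs = generate_benchmark(spec)
        cfg = RankConfig(state_order=spec.state_order)
        rng = np.random.default_rng(32)
        take = rng.choice(len(lvs.variants), size=30, replace=False)
        positives = [lvs.variants[i] for i in sorted(take)]
        kept = {
            name: [v for v in vs if v.id not in {p.id for p in positives}]
            for name, vs in region_set.backgrounds.items()
        }
        region_set = RegionSet(regions=region_set.regions, backgrounds=kept)
        report = spike_in(positives, region_set, BUILTIN_MODELS["ALL"],
                          bundle, cfg)
        assert abs(report.mean_region_auc - 0.5) < 0.1

    def test_region_processing_order_invariance(self, hand_bundle):
        rs1 = _two_region_setup()
        rs2 = RegionSet(regions=dict(reversed(rs1.regions.items())),
                        backgrounds=dict(reversed(rs1.backgrounds.items())))
        positives = [VariantRecord("chr1", 170, id="p1", maf=0.001)]
        r1 = spike_in(positives, rs1, BUILTIN_MODELS["DM"], hand_bundle)
        r2 = spike_in(positives, rs2, BUILTIN_MODELS["DM"], hand_bundle)
        assert r1.region_aucs == r2.region_aucs
        assert r1.mean_region_auc == r2.mean_region_auc


class TestNegativeControl:
    @pytest.fixture(scope="class")
    def background(self):
        spec = FixtureSpec(seed=41, n_regions=3, n_background_per_region=400,
                           n_functional=0)
        bundle, _ = generate_bundle(spec)
        lvs = generate_labelled_variants(spec, bundle)
        return spec, bundle, lvs.variants

    def test_exchangeable_background_gives_half(self, background):
        spec, bundle, variants = background
        cfg = RankConfig(state_order=spec.state_order)
        res = negative_control(variants, BUILTIN_MODELS["DM"], bundle,
                               subset_size=95, n_repeats=40, seed=42,
                               config=cfg)
        assert res.mean_auc == pytest.approx(0.5, abs=0.03)

    def test_deterministic_under_seed(self, background):
        spec, bundle, variants = background
        cfg = RankConfig(state_order=spec.state_order)
        a = negative_control(variants, BUILTIN_MODELS["ALL"], bundle,
                             subset_size=20, n_repeats=1, seed=5, config=cfg)
        b = negative_control(variants, BUILTIN_MODELS["ALL"], bundle,
                             subset_size=20, n_repeats=1, seed=5, config=cfg)
        assert a.aucs.tolist() == b.aucs.tolist()

    def test_top_decile_subset_scores_above_half(self, background):
        spec, bundle, variants = background
        cfg = RankConfig(state_order=spec.state_order)
        res = prioritise(list(variants), bundle, BUILTIN_MODELS["DM"], cfg)
        order = np.argsort(-res["weighted_sum"].to_numpy())
        top = [variants[i] for i in order[: len(variants) // 10]]
        labels = np.isin(np.arange(len(variants)),
                         order[: len(variants) // 10]).astype(int)
        auc = auc_mann_whitney(res["weighted_sum"].to_numpy(), labels)
        assert auc > 0.9

    def test_subset_size_bound(self, background):
        spec, bundle, variants = background
        with pytest.raises(ValueError):
            negative_control(variants[:50], BUILTIN_MODELS["DM"], bundle,
                             subset_size=50, n_repeats=1, seed=1)
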