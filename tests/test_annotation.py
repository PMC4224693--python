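import numpy as np
import pytest

from surf.annotation import (
    DEFAULT_POSITION_ORDER,
    AnnotationBundle,
    GeneModel,
    GenomicInterval,
    TrackIndex,
    VariantParseError,
    VariantRecord,
    assign_position_category,
    best_chromatin_state,
    build_feature_table,
    count_overlap_labels,
    load_bundle,
    max_overlap_score,
    read_variants,
)
from surf.fixtures import FixtureSpec, write_fixture_dir
from surf.ranking import DEFAULT_STATE_ORDER


class TestTypes:
    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10, score=float("nan"))

    def test_chrom_normalisation(self):
        assert GenomicInterval("1", 0, 10).chrom == "chr1"
        assert VariantRecord("chr2", 5).chrom == "chr2"
        assert VariantRecord("2", 5).chrom == "chr2"

    def test_maf_bounds(self):
        with pytest.raises(ValueError):
            VariantRecord("chr1", 5, maf=0.6)

    def test_chromatin_partition_enforced(self):
        with pytest.raises(ValueError, match="overlapping chromatin states"):
            AnnotationBundle(chromatin_states={"c1": [
                GenomicInterval("chr1", 0, 100, label="A"),
                GenomicInterval("chr1", 50, 150, label="B"),
            ]})


class TestReadVariants:
    def test_bed3_line_maps_to_record(self, tmp_path):
        p = tmp_path / "v.bed"
        p.write_text("chr1\t99\t100\n")
        (v,) = read_variants(p)
        assert (v.chrom, v.pos) == ("chr1", 99)

    def test_multibase_record_rejected(self, tmp_path):
        p = tmp_path / "v.bed"
        p.write_text("chr1\t99\t105\n")
        with pytest.raises(VariantParseError, match="line 1"):
            read_variants(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "v.bed"
        p.write_text("chr1\t0\t1\nchr1\tx\t2\n")
        with pytest.raises(VariantParseError, match="line 2"):
            read_variants(p)

    def test_round_trip_preserves_order_id_and_maf(self, tmp_path):
        records = [("chr1", 5, "rs1", 0.01), ("chr2", 9, "rs2", 0.4),
                   ("chr1", 2, "rs3", None)]
        p = tmp_path / "v.bed"
        with open(p, "w") as fh:  # hand-written writer, independent of package
            for c, s, i, m in records:
                maf = "." if m is None else str(m)
                fh.write(f"{c}\t{s}\t{s + 1}\t{i}\t{maf}\n")
        out = read_variants(p)
        assert [(v.chrom, v.pos, v.id, v.maf) for v in out] == records


class TestOverlapOps:
    def test_max_score_of_nested_peaks(self):
        v = VariantRecord("chr1", 250)
        track = [GenomicInterval("chr1", 100, 400, score=5.0),
                 GenomicInterval("chr1", 200, 350, score=7.5)]
        assert max_overlap_score(v, track) == 7.5

    def test_no_overlap_is_neutral_zero(self):
        assert max_overlap_score(VariantRecord("chr1", 999), [
            GenomicInterval("chr1", 0, 10, score=3.0)]) == 0.0
        assert count_overlap_labels(VariantRecord("chr1", 999), []) == 0

    def test_distinct_label_count(self):
        v = VariantRecord("chr1", 170)
        track = [GenomicInterval("chr1", 120, 180, label="A"),
                 GenomicInterval("chr1", 150, 190, label="B"),
                 GenomicInterval("chr1", 160, 185, label="B")]
        assert count_overlap_labels(v, track) == 2

    def test_random_instances_match_all_pairs_oracle(self):
        rng = np.random.default_rng(42)
        starts = rng.integers(0, 5000, size=20)
        track = [GenomicInterval("chr1", int(s), int(s + rng.integers(1, 300)),
                                 score=float(rng.normal()),
                                 label=str(rng.integers(0, 4)))
                 for s in starts]
        for pos in rng.integers(0, 5300, size=50):
            v = VariantRecord("chr1", int(pos))
            hits = [iv for iv in track if iv.start <= v.pos < iv.end]
            expect_max = max((iv.score for iv in hits), default=0.0)
            expect_cnt = len({iv.label for iv in hits})
            assert max_overlap_score(v, track) == expect_max
            assert count_overlap_labels(v, track) == expect_cnt


class TestPositionCategory:
    def test_precedence_promoter_vs_exon(self, hand_bundle):
        # 500 bp from the TSS and inside an exon: exon outranks promoter
        gm = hand_bundle.gene_model
        v = VariantRecord("chr1", 5500)
        assert assign_position_category(v, gm) == "exon"
        # custom order can invert the call
        custom = ["promoter", "exon", "intron", "intergenic"]
        assert assign_position_category(v, gm, custom) == "promoter"

    def test_far_variant_is_intergenic(self, hand_bundle):
        v = VariantRecord("chr1", 90000)
        assert assign_position_category(v, hand_bundle.gene_model) == "intergenic"

    def test_oracle_equivalence_on_fixture_genome(self, enriched_fixture):
        spec, bundle, _, lvs = enriched_fixture
        gm = bundle.gene_model

        def brute(v):
            def hits(ivs, pad=0):
                return any(iv.chrom == v.chrom and
                           iv.start - pad <= v.pos < iv.end + pad
                           for iv in ivs)
            checks = {
                "splice_site": hits(gm.splice_sites),
                "exon": hits(gm.exons),
                "promoter": any(
                    t.chrom == v.chrom and abs(v.pos - t.start) <= 1000
                    for t in gm.tss),
                "cpg_island": hits(gm.cpg_islands),
                "cpg_shore": hits(gm.cpg_shores),
                "upstream_10kb": any(
                    b.chrom == v.chrom and (
                        (b.label == "+" and b.start - 10000 <= v.pos < b.start)
                        or (b.label == "-" and b.end <= v.pos < b.end + 10000))
                    for b in gm.gene_bodies),
                "downstream_10kb": any(
                    b.chrom == v.chrom and (
                        (b.label == "+" and b.end <= v.pos < b.end + 10000)
                        or (b.label == "-" and b.start - 10000 <= v.pos < b.start))
                    for b in gm.gene_bodies),
                "intron": hits(gm.introns),
            }
            for cat in DEFAULT_POSITION_ORDER:
                if checks.get(cat, False):
                    return cat
            return "intergenic"

        for v in lvs.variants[:150]:
            assert assign_position_category(v, gm) == brute(v)


class TestChromatinState:
    def test_order_selection(self, hand_bundle):
        v = VariantRecord("chr1", 100)  # Weak Enhancer (cell1) + Strong (cell2)
        got = best_chromatin_state(v, hand_bundle.chromatin_states,
                                   DEFAULT_STATE_ORDER)
        assert got == "Strong Enhancer"

    def test_no_coverage_is_none(self, hand_bundle):
        v = VariantRecord("chr1", 5000)
        assert best_chromatin_state(v, hand_bundle.chromatin_states,
                                    DEFAULT_STATE_ORDER) == "none"

    def test_unknown_state_is_configuration_error(self, hand_bundle):
        v = VariantRecord("chr1", 100)
        with pytest.raises(ValueError, match="absent from state_order"):
            best_chromatin_state(v, hand_bundle.chromatin_states, ["Repressed"])

    def test_oracle_on_random_nine_track_fixture(self, enriched_fixture):
        spec, bundle, _, lvs = enriched_fixture
        order = spec.state_order
        pos_of = {s: i for i, s in enumerate(order)}
        for v in lvs.variants[:100]:
            per_cell = set()
            for track in bundle.chromatin_states.values():
                for iv in track:
                    if iv.chrom == v.chrom and iv.start <= v.pos < iv.end:
                        per_cell.add(iv.label)
            expected = (min(per_cell, key=lambda s: pos_of[s])
                        if per_cell else "none")
            assert best_chromatin_state(v, bundle.chromatin_states, order) == expected


class TestFeatureTable:
    def test_empty_bundle_gives_neutral_row(self):
        ft = build_feature_table([VariantRecord("chr1", 10, id="v")],
                                 AnnotationBundle(), DEFAULT_STATE_ORDER)
        row = ft.iloc[0]
        assert row["rs_score"] == 0 and row["dnase_hs_max"] == 0
        assert row["footprint_cell_count"] == 0 and row["tfbs_max"] == 0
        assert row["chromatin_state_best"] == "none"
        assert row["position_category"] == "intergenic"
        assert not row["enhancer_overlap"] and np.isnan(row["maf"])

    def test_known_overlaps_hand_computed_row(self, hand_bundle):
        v = VariantRecord("chr1", 170, id="x", maf=0.02)
        ft = build_feature_table([v], hand_bundle, DEFAULT_STATE_ORDER)
        row = ft.iloc[0]
        assert row["maf"] == 0.02
        assert row["rs_score"] == 3.5          # only the first peak covers 170
        assert row["dnase_hs_max"] == 5.0      # the 7.5 peak starts at 200
        assert row["footprint_cell_count"] == 2  # cellA + cellB
        assert row["chromatin_state_best"] == "Strong Enhancer"
        assert row["enhancer_overlap"]
        assert row["tfbs_max"] == 9.0

    def test_pure_function_and_track_order_invariance(self, hand_bundle):
        variants = [VariantRecord("chr1", p, id=f"v{p}")
                    for p in (170, 250, 5500, 90000)]
        ft1 = build_feature_table(variants, hand_bundle, DEFAULT_STATE_ORDER)
        shuffled = AnnotationBundle(
            conservation=hand_bundle.conservation[::-1],
            dnase_hs=hand_bundle.dnase_hs[::-1],
            footprints=hand_bundle.footprints[::-1],
            chromatin_states=dict(reversed(hand_bundle.chromatin_states.items())),
            enhancers=hand_bundle.enhancers[::-1],
            tfbs=hand_bundle.tfbs[::-1],
            gene_model=hand_bundle.gene_model,
        )
        ft2 = build_feature_table(variants, shuffled, DEFAULT_STATE_ORDER)
        assert ft1.equals(ft2)

    def test_empty_variant_list_rejected(self, hand_bundle):
        with pytest.raises(ValueError):
            build_feature_table([], hand_bundle, DEFAULT_STATE_ORDER)


def test_fixture_round_trip_through_bundle_config(tmp_path):
    """Files written by the fixture generator reload into an identical
    feature table (the on-disk round-trip guarantee)."""
    spec = FixtureSpec(seed=7, n_regions=2, n_background_per_region=40,
                       n_functional=10, weights={"Position": 5})
    config_path, variants_path = write_fixture_dir(spec, tmp_path)
    bundle, state_order = load_bundle(config_path)
    variants = read_variants(variants_path)
    ft = build_feature_table(variants, bundle, state_order)

    from surf.fixtures import generate_benchmark
    bundle0, _, lvs0 = generate_benchmark(spec)
    ft0 = build_feature_table(lvs0.variants, bundle0, spec.state_order)
    assert ft.equals(ft0)
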