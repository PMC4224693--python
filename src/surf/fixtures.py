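"""Self-contained synthetic toy genomes for testing and benchmarking.

The generator builds a small multi-region "genome" — gene models, scored
conservation / DNase / TFBS tracks, per-cell-line footprints, nine
chromatin-state segmentations, enhancers — and then places two classes of
variants in it:

* **background** variants, uniform over each region with MAF ~ U(0, 0.5);
* **functional** variants, placed by rejection sampling so that their
  annotation profile is enriched in proportion to a known *generating
  weight vector* over the eight annotation categories.

A proposal at a candidate position is accepted with probability
``expit(scale * (u - threshold))`` where ``u`` is the candidate's
generator-weighted, standardized annotation score (standardized against a
uniform probe sample of the same genome).  With the default
``scale = 4, threshold = 1`` accepted variants sit in roughly the upper
sixth of the combined-annotation distribution, emulating the strong
separation of curated functional variants from background.  When the
generating vector is all zeros the acceptance probability is constant, so
functional and background positions are exchangeable and any ranker's
expected AUC is exactly 0.5 — the generator is analytically null.

MAF is generated separately (frequency is not a positional annotation):
functional MAFs follow ``0.5 * Beta(1, 1 + w_MAF / 2)``, skewing toward
rare alleles as the MAF generating weight grows and reducing to the
background's uniform distribution at weight 0.

Everything is driven by a single seeded generator: the same
:class:`FixtureSpec` yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .annotation import (
    DEFAULT_POSITION_ORDER,
    AnnotationBundle,
    GeneModel,
    GenomicInterval,
    VariantRecord,
    build_feature_table,
)
from .evaluation import RegionSet
from .ranking import CATEGORIES, DEFAULT_STATE_ORDER
from .training import LabelledVariantSet

__all__ = [
    "FixtureSpec",
    "generate_bundle",
    "generate_labelled_variants",
    "generate_benchmark",
    "write_fixture_dir",
]

# state palette frequencies, aligned with DEFAULT_STATE_ORDER: regulatory
# states are rare, repressed/heterochromatic sequence dominates
_STATE_PROBS = np.array(
    [0.03, 0.04, 0.04, 0.06, 0.03, 0.06, 0.12, 0.15, 0.22, 0.25])

_FOOTPRINT_CELLS = [f"fpcell{i}" for i in range(1, 9)]
_STATE_CELLS = [f"cell{i}" for i in range(1, 10)]
_FACTORS = [f"TF{i}" for i in range(1, 11)]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic genome + variant set.

    ``weights`` is the generating weight vector over the eight categories
    (missing categories count as 0); it controls how strongly functional
    variants are enriched for each annotation.  ``seed`` is mandatory —
    every random choice flows from it.
    """

    seed: int
    n_regions: int = 4
    region_length: int = 100_000
    n_background_per_region: int = 250
    n_functional: int = 100
    weights: dict[str, float] = field(default_factory=dict)
    genes_per_region: int = 3
    exons_per_gene: int = 4
    conservation_peaks: int = 60
    dnase_peaks: int = 40
    footprint_loci: int = 25
    enhancer_count: int = 12
    tfbs_peaks: int = 30
    enrichment_scale: float = 4.0
    enrichment_threshold: float = 1.0
    state_order: list[str] = field(default_factory=lambda: list(DEFAULT_STATE_ORDER))

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        counts = (self.n_regions, self.region_length,
                  self.n_background_per_region, self.genes_per_region,
                  self.exons_per_gene)
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.n_functional < 0:
            raise ValueError("n_functional must be non-negative")
        unknown = set(self.weights) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in weights: {sorted(unknown)}")

    def weight_vector(self) -> np.ndarray:
        return np.array([float(self.weights.get(c, 0.0)) for c in CATEGORIES])

    def region_chrom(self, r: int) -> str:
        return f"chr{r + 1}"


def _regions(spec: FixtureSpec) -> dict[str, GenomicInterval]:
    return {
        f"region{r + 1}": GenomicInterval(spec.region_chrom(r), 0,
                                          spec.region_length)
        for r in range(spec.n_regions)
    }


# --------------------------------------------------------------------------
# bundle generation
# --------------------------------------------------------------------------

def _make_genes(spec: FixtureSpec, chrom: str, rng: np.random.Generator,
                gm: GeneModel) -> None:
    """Lay genes in equal slots across the region; each contributes a
    stranded body, alternating exons/introns, 2 bp splice sites at the
    boundaries, a TSS, a CpG island around the TSS and flanking shores."""
    L = spec.region_length
    slot = L // spec.genes_per_region
    for g in range(spec.genes_per_region):
        s0 = g * slot
        body_len = int(slot * rng.uniform(0.3, 0.5))
        start = s0 + int(rng.uniform(0.15, 0.45) * slot)
        end = min(start + body_len, s0 + slot - 100)
        strand = "+" if rng.random() < 0.5 else "-"
        gm.gene_bodies.append(GenomicInterval(chrom, start, end, label=strand))
        # alternating exon/intron pieces
        n_pieces = 2 * spec.exons_per_gene - 1
        cuts = np.sort(rng.choice(
            np.arange(start + 1, end - 1), size=n_pieces - 1, replace=False))
        edges = [start, *cuts.tolist(), end]
        for p in range(n_pieces):
            iv = GenomicInterval(chrom, edges[p], edges[p + 1])
            (gm.exons if p % 2 == 0 else gm.introns).append(iv)
            if p % 2 == 1:  # intron: splice sites at both boundaries
                gm.splice_sites.append(
                    GenomicInterval(chrom, max(0, edges[p] - 1), edges[p] + 1))
                gm.splice_sites.append(
                    GenomicInterval(chrom, max(0, edges[p + 1] - 1),
                                    edges[p + 1] + 1))
        tss_pos = start if strand == "+" else end - 1
        gm.tss.append(GenomicInterval(chrom, tss_pos, tss_pos + 1, label=strand))
        isl = GenomicInterval(chrom, max(0, tss_pos - 150), tss_pos + 150)
        gm.cpg_islands.append(isl)


def _derive_shores(gm: GeneModel) -> None:
    """1 kb flanks of each CpG island, with any island-covered stretch cut
    out so shores never overlap islands (genes can sit close together)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for isl in gm.cpg_islands:
        by_chrom.setdefault(isl.chrom, []).append(isl)
    for isls in by_chrom.values():
        isls.sort(key=lambda iv: iv.start)
    for isl in gm.cpg_islands:
        for s, e in ((max(0, isl.start - 1000), isl.start),
                     (isl.end, isl.end + 1000)):
            pieces = [(s, e)]
            for other in by_chrom[isl.chrom]:
                nxt = []
                for ps, pe in pieces:
                    if other.end <= ps or other.start >= pe:
                        nxt.append((ps, pe))
                        continue
                    if ps < other.start:
                        nxt.append((ps, other.start))
                    if other.end < pe:
                        nxt.append((other.end, pe))
                pieces = nxt
            gm.cpg_shores.extend(
                GenomicInterval(isl.chrom, ps, pe)
                for ps, pe in pieces if pe > ps)


def _random_intervals(chrom: str, L: int, n: int, min_len: int, max_len: int,
                      rng: np.random.Generator) -> list[tuple[int, int]]:
    starts = rng.integers(0, L - max_len, size=n)
    lengths = rng.integers(min_len, max_len + 1, size=n)
    return [(int(s), int(s + l)) for s, l in zip(starts, lengths)]


def _partition_states(spec: FixtureSpec, chrom: str,
                      rng: np.random.Generator) -> list[GenomicInterval]:
    """One cell line's segmentation: random-length segments covering the
    region exactly once."""
    out, pos = [], 0
    order = spec.state_order
    probs = _STATE_PROBS[: len(order)]
    probs = probs / probs.sum()
    while pos < spec.region_length:
        seg = int(rng.uniform(500, 4000))
        end = min(pos + seg, spec.region_length)
        state = order[rng.choice(len(order), p=probs)]
        out.append(GenomicInterval(chrom, pos, end, label=state))
        pos = end
    return out


def generate_bundle(spec: FixtureSpec) -> tuple[AnnotationBundle, RegionSet]:
    """Generate the annotation bundle and the (empty-background) region
    set for a fixture spec.  Deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    if spec.region_length < 5_000:
        raise ValueError("region_length too small to lay out gene features")
    gm = GeneModel()
    conservation: list[GenomicInterval] = []
    dnase: list[GenomicInterval] = []
    footprints: list[GenomicInterval] = []
    enhancers: list[GenomicInterval] = []
    tfbs: list[GenomicInterval] = []
    states: dict[str, list[GenomicInterval]] = {c: [] for c in _STATE_CELLS}

    for r in range(spec.n_regions):
        chrom = spec.region_chrom(r)
        L = spec.region_length
        _make_genes(spec, chrom, rng, gm)
        for s, e in _random_intervals(chrom, L, spec.conservation_peaks,
                                      50, 500, rng):
            conservation.append(GenomicInterval(
                chrom, s, e, score=float(rng.normal(0.0, 2.0))))
        for s, e in _random_intervals(chrom, L, spec.dnase_peaks, 100, 600, rng):
            dnase.append(GenomicInterval(
                chrom, s, e, score=float(rng.gamma(2.0, 2.0))))
        # footprint loci shared across a random subset of cell lines, so
        # per-variant cell counts span 1..8
        for s, e in _random_intervals(chrom, L, spec.footprint_loci,
                                      10, 40, rng):
            k = 1 + rng.binomial(len(_FOOTPRINT_CELLS) - 1, 0.4)
            cells = rng.choice(_FOOTPRINT_CELLS, size=k, replace=False)
            for cell in cells:
                jitter = int(rng.integers(-5, 6))
                footprints.append(GenomicInterval(
                    chrom, max(0, s + jitter), e + jitter, label=str(cell)))
        for s, e in _random_intervals(chrom, L, spec.enhancer_count,
                                      200, 800, rng):
            enhancers.append(GenomicInterval(chrom, s, e))
        for s, e in _random_intervals(chrom, L, spec.tfbs_peaks, 50, 300, rng):
            tfbs.append(GenomicInterval(
                chrom, s, e, score=float(rng.gamma(2.0, 3.0)),
                label=str(rng.choice(_FACTORS))))
        for cell in _STATE_CELLS:
            states[cell].extend(_partition_states(spec, chrom, rng))

    _derive_shores(gm)
    gm.validate()
    bundle = AnnotationBundle(
        conservation=conservation, dnase_hs=dnase, footprints=footprints,
        chromatin_states=states, enhancers=enhancers, tfbs=tfbs,
        gene_model=gm)
    region_set = RegionSet(regions=_regions(spec),
                           backgrounds={name: [] for name in _regions(spec)})
    return bundle, region_set


# --------------------------------------------------------------------------
# variant generation
# --------------------------------------------------------------------------

def _numeric_propensities(ft: pd.DataFrame, spec: FixtureSpec) -> np.ndarray:
    """Per-variant numeric propensity for the 7 positional/annotation
    categories (MAF excluded — handled by the MAF distribution), aligned
    with CATEGORIES[1:]."""
    state_ord = {s: float(len(spec.state_order) - i)
                 for i, s in enumerate(spec.state_order)}
    state_ord["none"] = 0.0
    pos_order = DEFAULT_POSITION_ORDER
    pos_ord = {c: float(len(pos_order) - i) for i, c in enumerate(pos_order)}
    cols = [
        np.maximum(ft["rs_score"].to_numpy(dtype=float), 0.0),
        ft["chromatin_state_best"].map(state_ord).to_numpy(dtype=float),
        ft["dnase_hs_max"].to_numpy(dtype=float),
        ft["position_category"].map(pos_ord).to_numpy(dtype=float),
        ft["footprint_cell_count"].to_numpy(dtype=float),
        ft["enhancer_overlap"].to_numpy(dtype=float),
        ft["tfbs_max"].to_numpy(dtype=float),
    ]
    return np.column_stack(cols)


def _propose(spec: FixtureSpec, n: int, rng: np.random.Generator
             ) -> list[VariantRecord]:
    regions = rng.integers(0, spec.n_regions, size=n)
    positions = rng.integers(0, spec.region_length, size=n)
    return [VariantRecord(spec.region_chrom(r), int(p))
            for r, p in zip(regions, positions)]


def generate_labelled_variants(spec: FixtureSpec, bundle: AnnotationBundle
                               ) -> LabelledVariantSet:
    """Place background and functional variants in a generated bundle.

    Background variants are uniform within each region (sampled without
    replacement, so ids and positions are unique per region).  Functional
    variants are rejection-sampled with acceptance probability rising in
    the generator-weighted annotation score; see the module docstring.
    Labels: functional = 1, background = 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    if spec.n_background_per_region > spec.region_length:
        raise ValueError("more background variants requested than positions")

    background: list[VariantRecord] = []
    for r in range(spec.n_regions):
        chrom = spec.region_chrom(r)
        positions = rng.choice(spec.region_length,
                               size=spec.n_background_per_region, replace=False)
        for i, p in enumerate(np.sort(positions)):
            background.append(VariantRecord(
                chrom, int(p), id=f"bg_r{r + 1}_{i}",
                maf=float(rng.uniform(0.0, 0.5))))

    w = spec.weight_vector()
    w_pos = w[1:]            # placement weights (all categories except MAF)
    w_maf = w[0]
    functional: list[VariantRecord] = []
    if spec.n_functional > 0:
        if np.all(w_pos == 0):
            # constant acceptance probability == uniform placement
            accepted = _propose(spec, spec.n_functional, rng)
        else:
            probe = _propose(spec, 2000, rng)
            probe_ft = build_feature_table(probe, bundle, spec.state_order)
            X = _numeric_propensities(probe_ft, spec)
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd[sd == 0] = 1.0
            norm = np.sqrt(float(np.sum(w_pos ** 2)))
            accepted = []
            for _ in range(400):
                if len(accepted) >= spec.n_functional:
                    break
                batch = _propose(spec, max(500, 2 * spec.n_functional), rng)
                ftb = build_feature_table(batch, bundle, spec.state_order)
                u = ((_numeric_propensities(ftb, spec) - mu) / sd) @ w_pos / norm
                p = expit(spec.enrichment_scale
                          * (u - spec.enrichment_threshold))
                keep = rng.random(len(batch)) < p
                accepted.extend(v for v, k in zip(batch, keep) if k)
            if len(accepted) < spec.n_functional:
                raise ValueError(
                    "enrichment too strong for the requested number of "
                    "functional variants (rejection sampling starved)")
            accepted = accepted[: spec.n_functional]
        if w_maf > 0:
            mafs = 0.5 * rng.beta(1.0, 1.0 + w_maf / 2.0,
                                  size=spec.n_functional)
        else:
            mafs = rng.uniform(0.0, 0.5, size=spec.n_functional)
        functional = [
            VariantRecord(v.chrom, v.pos, id=f"fn_{i}", maf=float(m))
            for i, (v, m) in enumerate(zip(accepted, mafs))
        ]

    variants = functional + background
    labels = np.array([1] * len(functional) + [0] * len(background))
    ft = build_feature_table(variants, bundle, spec.state_order)
    return LabelledVariantSet(labels=labels, features=ft, variants=variants)


def generate_benchmark(spec: FixtureSpec
                       ) -> tuple[AnnotationBundle, RegionSet, LabelledVariantSet]:
    """Convenience: bundle + region set with its backgrounds filled in +
    labelled variant set, all from one spec/seed."""
    bundle, region_set = generate_bundle(spec)
    lvs = generate_labelled_variants(spec, bundle)
    for v, lab in zip(lvs.variants, lvs.labels):
        if lab == 0:
            name = f"region{int(v.chrom.removeprefix('chr'))}"
            region_set.backgrounds[name].append(v)
    return bundle, region_set, lvs


# --------------------------------------------------------------------------
# on-disk round trip
# --------------------------------------------------------------------------

def _write_bed(path: Path, rows: Sequence[Sequence[object]]) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_fixture_dir(spec: FixtureSpec, out_dir: str | Path
                      ) -> tuple[Path, Path]:
    """Materialise a fixture as BED/TSV files in exactly the formats the
    annotation readers consume; returns (bundle config path, variants
    path).  ``load_bundle`` on the written config reproduces the bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle, region_set, lvs = generate_benchmark(spec)

    def bed5(track):  # chrom start end name score
        return [(iv.chrom, iv.start, iv.end, iv.label or ".",
                 "" if iv.score is None else repr(float(iv.score)))
                for iv in track]

    _write_bed(out / "conservation.bed", bed5(bundle.conservation))
    _write_bed(out / "dnase_hs.bed", bed5(bundle.dnase_hs))
    _write_bed(out / "tfbs.bed", bed5(bundle.tfbs))
    _write_bed(out / "footprints.bed",
               [(iv.chrom, iv.start, iv.end, iv.label)
                for iv in bundle.footprints])
    _write_bed(out / "enhancers.bed",
               [(iv.chrom, iv.start, iv.end) for iv in bundle.enhancers])
    _write_bed(out / "chromatin_states.tsv",
               [(iv.chrom, iv.start, iv.end, iv.label, cell)
                for cell, track in bundle.chromatin_states.items()
                for iv in track])
    gm = bundle.gene_model
    _write_bed(out / "tss.bed",
               [(iv.chrom, iv.start, iv.end, ".", 0, iv.label or "+")
                for iv in gm.tss])
    _write_bed(out / "gene_bodies.bed",
               [(iv.chrom, iv.start, iv.end, ".", 0, iv.label or "+")
                for iv in gm.gene_bodies])
    for name in ("exons", "introns", "splice_sites", "cpg_islands",
                 "cpg_shores"):
        _write_bed(out / f"{name}.bed",
                   [(iv.chrom, iv.start, iv.end)
                    for iv in getattr(gm, name)])
    _write_bed(out / "regions.bed",
               [(iv.chrom, iv.start, iv.end, name)
                for name, iv in region_set.regions.items()])

    variants_path = out / "variants.bed"
    _write_bed(variants_path,
               [(v.chrom, v.pos, v.pos + 1, v.id,
                 "" if v.maf is None else repr(float(v.maf)))
                for v in lvs.variants])
    _write_bed(out / "labels.tsv",
               [(v.id, int(lab)) for v, lab in zip(lvs.variants, lvs.labels)])

    config = {
        "conservation": "conservation.bed",
        "dnase_hs": "dnase_hs.bed",
        "tfbs": "tfbs.bed",
        "footprints": "footprints.bed",
        "enhancers": "enhancers.bed",
        "chromatin_states": "chromatin_states.tsv",
        "gene_model": {
            "tss": "tss.bed",
            "gene_bodies": "gene_bodies.bed",
            "exons": "exons.bed",
            "introns": "introns.bed",
            "splice_sites": "splice_sites.bed",
            "cpg_islands": "cpg_islands.bed",
            "cpg_shores": "cpg_shores.bed",
        },
        "state_order": list(spec.state_order),
        "seed": spec.seed,
    }
    config_path = out / "bundle.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config_path, variants_path
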