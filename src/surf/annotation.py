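"""Genomic data model and per-variant feature table construction.

Variants are single-nucleotide, BED-style 0-based half-open: a SNP at
position ``pos`` occupies the interval ``[pos, pos + 1)``.  Annotation
tracks are lists of :class:`GenomicInterval`; the engine is
assembly-agnostic (chromosome labels and coordinates are opaque, they only
need to be mutually consistent between variants and tracks).

The feature table collects, per variant, the raw (pre-rank) value of each
of the eight annotation categories used by the prioritiser:

========================  =====================================================
column                    meaning
========================  =====================================================
``maf``                   minor allele frequency (NaN when unknown)
``rs_score``              conservation: rejected-substitution score at the site
``dnase_hs_max``          max DNase-hypersensitivity peak signal, any cell line
``footprint_cell_count``  number of distinct cell lines with a DNase footprint
``chromatin_state_best``  best chromatin state across cell lines
``position_category``     positional class relative to gene features
``enhancer_overlap``      overlap with a transcribed (CAGE-defined) enhancer
``tfbs_max``              max TF ChIP peak signal, any factor / cell line
========================  =====================================================

Absence of overlap is encoded by the category's neutral value: 0 for
signals and counts, ``False`` for the enhancer flag, ``"none"`` for the
chromatin state, ``"intergenic"`` for position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "VariantRecord",
    "GeneModel",
    "AnnotationBundle",
    "TrackIndex",
    "FEATURE_COLUMNS",
    "POSITION_CATEGORIES",
    "DEFAULT_POSITION_ORDER",
    "normalise_chrom",
    "read_variants",
    "read_scored_track",
    "read_labelled_track",
    "read_chromatin_states",
    "max_overlap_score",
    "count_overlap_labels",
    "assign_position_category",
    "best_chromatin_state",
    "build_feature_table",
    "write_feature_table",
    "load_bundle",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

def normalise_chrom(chrom: str) -> str:
    """Normalise a chromosome label: accepts ``"1"`` and ``"chr1"``,
    returns the ``chr``-prefixed form."""
    chrom = str(chrom).strip()
    if not chrom:
        raise ValueError("empty chromosome label")
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally scored and/or labelled.

    ``score`` carries real-valued signal (peak strength, RS score);
    ``label`` carries a category string (chromatin-state name, cell-line
    id, transcription-factor name, or a strand for stranded features).
    """

    chrom: str
    start: int
    end: int
    score: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalise_chrom(self.chrom))
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})")
        if self.score is not None and not math.isfinite(self.score):
            raise ValueError(f"non-finite score: {self.score}")

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == normalise_chrom(chrom) and self.start <= pos < self.end


@dataclass(frozen=True)
class VariantRecord:
    """A single SNP: chromosome, 0-based position, optional id and MAF."""

    chrom: str
    pos: int
    id: str | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalise_chrom(self.chrom))
        if self.pos < 0:
            raise ValueError(f"negative position: {self.pos}")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"MAF outside [0, 0.5]: {self.maf}")


@dataclass
class GeneModel:
    """Gene-feature intervals used for positional classification.

    ``tss`` intervals are single-base with strand in ``label``;
    ``gene_bodies`` carry strand in ``label`` so that 10 kb upstream /
    downstream windows can be oriented.  Splice sites sit at exon/intron
    boundaries; CpG shores must not overlap CpG islands.
    """

    tss: list[GenomicInterval] = field(default_factory=list)
    exons: list[GenomicInterval] = field(default_factory=list)
    introns: list[GenomicInterval] = field(default_factory=list)
    splice_sites: list[GenomicInterval] = field(default_factory=list)
    cpg_islands: list[GenomicInterval] = field(default_factory=list)
    cpg_shores: list[GenomicInterval] = field(default_factory=list)
    gene_bodies: list[GenomicInterval] = field(default_factory=list)

    def validate(self) -> None:
        shore_idx = TrackIndex(self.cpg_shores)
        for isl in self.cpg_islands:
            for pos in (isl.start, isl.end - 1):
                if shore_idx.overlapping(isl.chrom, pos):
                    raise ValueError("CpG shore overlaps a CpG island")


@dataclass
class AnnotationBundle:
    """All scored / labelled tracks plus the gene model for one analysis.

    Tracks are sorted by (chrom, start) on construction.  Chromatin
    states are one track per cell line; within a cell line the states
    partition covered sequence (no overlaps).
    """

    conservation: list[GenomicInterval] = field(default_factory=list)
    dnase_hs: list[GenomicInterval] = field(default_factory=list)
    footprints: list[GenomicInterval] = field(default_factory=list)
    chromatin_states: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    enhancers: list[GenomicInterval] = field(default_factory=list)
    tfbs: list[GenomicInterval] = field(default_factory=list)
    gene_model: GeneModel = field(default_factory=GeneModel)

    def __post_init__(self) -> None:
        key = lambda iv: (iv.chrom, iv.start, iv.end)
        self.conservation = sorted(self.conservation, key=key)
        self.dnase_hs = sorted(self.dnase_hs, key=key)
        self.footprints = sorted(self.footprints, key=key)
        self.enhancers = sorted(self.enhancers, key=key)
        self.tfbs = sorted(self.tfbs, key=key)
        self.chromatin_states = {
            cl: sorted(track, key=key)
            for cl, track in sorted(self.chromatin_states.items())
        }
        for cl, track in self.chromatin_states.items():
            prev: GenomicInterval | None = None
            for iv in track:
                if prev is not None and iv.chrom == prev.chrom and iv.start < prev.end:
                    raise ValueError(
                        f"overlapping chromatin states in cell line {cl!r} "
                        f"at {iv.chrom}:{iv.start}")
                prev = iv

    def state_names(self) -> set[str]:
        return {
            iv.label
            for track in self.chromatin_states.values()
            for iv in track
            if iv.label is not None
        }


class TrackIndex:
    """Point-query index over a track (interval tree per chromosome)."""

    def __init__(self, track: Iterable[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        for iv in track:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, iv)

    def overlapping(self, chrom: str, pos: int) -> list[GenomicInterval]:
        tree = self._trees.get(normalise_chrom(chrom))
        if tree is None:
            return []
        return [hit.data for hit in tree[pos]]


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

class VariantParseError(ValueError):
    """Raised for a malformed variant line; carries the 1-based line number."""


def _split_fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_variants(path: str | Path, dialect: str = "bed3") -> list[VariantRecord]:
    """Read SNPs from a BED3(+)/tab-delimited file.

    The three leading columns are chromosome, start, end; SNPs only, so
    ``end`` must equal ``start + 1``.  Column 4, when present, is the
    variant id; column 5, when numeric and within [0, 0.5], is the minor
    allele frequency.  Lines starting with ``#``, ``track`` or ``browser``
    are skipped.  File order is preserved.
    """
    if dialect not in {"bed3", "tab-delimited"}:
        raise ValueError(f"unknown dialect: {dialect!r}")
    variants: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_fields(line)
            if len(fields) < 3:
                raise VariantParseError(
                    f"line {lineno}: expected ≥3 tab-delimited columns, "
                    f"got {len(fields)}")
            chrom, s_start, s_end = fields[0], fields[1], fields[2]
            try:
                start, end = int(s_start), int(s_end)
            except ValueError as exc:
                raise VariantParseError(
                    f"line {lineno}: non-integer coordinates "
                    f"({s_start!r}, {s_end!r})") from exc
            if end != start + 1:
                raise VariantParseError(
                    f"line {lineno}: record spans {end - start} bp; only "
                    f"single-base SNPs are supported (indels are out of scope)")
            vid = fields[3] if len(fields) > 3 and fields[3] not in {"", "."} else None
            maf: float | None = None
            if len(fields) > 4 and fields[4] not in {"", "."}:
                try:
                    maf = float(fields[4])
                except ValueError as exc:
                    raise VariantParseError(
                        f"line {lineno}: malformed MAF {fields[4]!r}") from exc
            try:
                variants.append(VariantRecord(chrom, start, id=vid, maf=maf))
            except ValueError as exc:
                raise VariantParseError(f"line {lineno}: {exc}") from exc
    return variants


def read_scored_track(path: str | Path, score_col: int = 4) -> list[GenomicInterval]:
    """Read a scored track (BED5-style, score in ``score_col``; pass
    ``score_col=3`` for bedGraph)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_fields(line)
            try:
                score = float(fields[score_col]) if len(fields) > score_col else None
                out.append(GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]), score=score))
            except (ValueError, IndexError) as exc:
                raise VariantParseError(f"line {lineno}: {exc}") from exc
    return out


def read_labelled_track(path: str | Path, label_col: int = 3,
                        score_col: int | None = None) -> list[GenomicInterval]:
    """Read a labelled (and optionally scored) track, label in ``label_col``."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_fields(line)
            try:
                score = (float(fields[score_col])
                         if score_col is not None and len(fields) > score_col
                         else None)
                out.append(GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]),
                    score=score, label=fields[label_col]))
            except (ValueError, IndexError) as exc:
                raise VariantParseError(f"line {lineno}: {exc}") from exc
    return out


def read_chromatin_states(path: str | Path) -> dict[str, list[GenomicInterval]]:
    """Read chromatin-state segmentations from a tab-delimited file with
    columns (chrom, start, end, state, cell_line); returns one track per
    cell line."""
    tracks: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_fields(line)
            if len(fields) < 5:
                raise VariantParseError(
                    f"line {lineno}: chromatin-state rows need 5 columns")
            chrom, start, end, state, cell = fields[:5]
            tracks.setdefault(cell, []).append(
                GenomicInterval(chrom, int(start), int(end), label=state))
    return tracks


# --------------------------------------------------------------------------
# per-category overlap operations
# --------------------------------------------------------------------------

def max_overlap_score(v: VariantRecord,
                      track: Sequence[GenomicInterval] | TrackIndex) -> float:
    """Maximum score over intervals containing the variant; 0 when none
    overlap (no-overlap is a valid state, not an error)."""
    idx = track if isinstance(track, TrackIndex) else TrackIndex(track)
    hits = idx.overlapping(v.chrom, v.pos)
    scores = [iv.score for iv in hits if iv.score is not None]
    return max(scores) if scores else 0.0


def count_overlap_labels(v: VariantRecord,
                         track: Sequence[GenomicInterval] | TrackIndex) -> int:
    """Number of distinct labels among intervals containing the variant."""
    idx = track if isinstance(track, TrackIndex) else TrackIndex(track)
    return len({iv.label for iv in idx.overlapping(v.chrom, v.pos)})


POSITION_CATEGORIES = (
    "splice_site", "exon", "promoter", "cpg_island", "cpg_shore",
    "upstream_10kb", "downstream_10kb", "intron", "intergenic",
)

#: Default positional precedence, best -> worst.  Disease variants are
#: enriched in coding sequence and promoters over introns and intergenic
#: space, so categories closer to genes outrank distal ones.  The order is
#: configuration, not a constant of the method: pass your own list to
#: :func:`assign_position_category` / the rank configuration to override.
DEFAULT_POSITION_ORDER = list(POSITION_CATEGORIES)

PROMOTER_WINDOW = 1_000  # bp either side of a TSS
FLANK_WINDOW = 10_000    # bp up/downstream of a gene body


class _GeneModelIndex:
    """Precedence-aware positional classifier for one gene model."""

    def __init__(self, gm: GeneModel):
        self._idx = {
            "splice_site": TrackIndex(gm.splice_sites),
            "exon": TrackIndex(gm.exons),
            "intron": TrackIndex(gm.introns),
            "cpg_island": TrackIndex(gm.cpg_islands),
            "cpg_shore": TrackIndex(gm.cpg_shores),
        }
        # promoter = within 1 kb of a TSS, strand-ignoring
        self._promoters = TrackIndex(
            GenomicInterval(t.chrom, max(0, t.start - PROMOTER_WINDOW),
                            t.end + PROMOTER_WINDOW)
            for t in gm.tss)
        up, down = [], []
        for body in gm.gene_bodies:
            strand = body.label or "+"
            five, three = ((body.start, body.end) if strand == "+"
                           else (body.end, body.start))
            if strand == "+":
                if five > 0:
                    up.append(GenomicInterval(
                        body.chrom, max(0, five - FLANK_WINDOW), five))
                down.append(GenomicInterval(body.chrom, three, three + FLANK_WINDOW))
            else:
                up.append(GenomicInterval(body.chrom, five, five + FLANK_WINDOW))
                if three > 0:
                    down.append(GenomicInterval(
                        body.chrom, max(0, three - FLANK_WINDOW), three))
        self._upstream = TrackIndex(up)
        self._downstream = TrackIndex(down)

    def matches(self, v: VariantRecord, category: str) -> bool:
        if category == "intergenic":
            return True
        if category == "promoter":
            return bool(self._promoters.overlapping(v.chrom, v.pos))
        if category == "upstream_10kb":
            return bool(self._upstream.overlapping(v.chrom, v.pos))
        if category == "downstream_10kb":
            return bool(self._downstream.overlapping(v.chrom, v.pos))
        return bool(self._idx[category].overlapping(v.chrom, v.pos))


def assign_position_category(v: VariantRecord, gm: GeneModel | _GeneModelIndex,
                             order: Sequence[str] = DEFAULT_POSITION_ORDER) -> str:
    """Classify a variant's position relative to gene features.

    When a variant qualifies for several categories the highest-precedence
    (earliest in ``order``) wins; a variant matching nothing is
    ``"intergenic"``.
    """
    idx = gm if isinstance(gm, _GeneModelIndex) else _GeneModelIndex(gm)
    unknown = set(order) - set(POSITION_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown position categories in order: {sorted(unknown)}")
    for category in order:
        if idx.matches(v, category):
            return category
    return "intergenic"


def best_chromatin_state(v: VariantRecord,
                         states: Mapping[str, Sequence[GenomicInterval]] | Mapping[str, TrackIndex],
                         state_order: Sequence[str]) -> str:
    """Best chromatin state across cell lines.

    Each cell line contributes at most one state at the position; the
    state earliest in ``state_order`` (most to least informative) is
    returned, or ``"none"`` when no cell line covers the position.
    """
    found: set[str] = set()
    for track in states.values():
        idx = track if isinstance(track, TrackIndex) else TrackIndex(track)
        for iv in idx.overlapping(v.chrom, v.pos):
            if iv.label is not None:
                found.add(iv.label)
    if not found:
        return "none"
    missing = found - set(state_order)
    if missing:
        raise ValueError(
            f"chromatin state(s) {sorted(missing)} absent from state_order")
    pos = {s: i for i, s in enumerate(state_order)}
    return min(found, key=lambda s: pos[s])


# --------------------------------------------------------------------------
# feature table
# --------------------------------------------------------------------------

FEATURE_COLUMNS = [
    "id", "chrom", "pos", "maf", "rs_score", "dnase_hs_max",
    "footprint_cell_count", "chromatin_state_best", "position_category",
    "enhancer_overlap", "tfbs_max",
]


def build_feature_table(variants: Sequence[VariantRecord],
                        bundle: AnnotationBundle,
                        state_order: Sequence[str],
                        position_order: Sequence[str] = DEFAULT_POSITION_ORDER,
                        ) -> pd.DataFrame:
    """Annotate variants against a bundle; one row per variant, input
    order preserved.  Pure function of its arguments: repeated calls give
    identical tables regardless of track insertion order (tracks are
    sorted by the bundle, overlap reductions are max / distinct-count /
    argmin over a fixed order)."""
    if not variants:
        raise ValueError("no variants supplied")
    cons_idx = TrackIndex(bundle.conservation)
    dnase_idx = TrackIndex(bundle.dnase_hs)
    fp_idx = TrackIndex(bundle.footprints)
    enh_idx = TrackIndex(bundle.enhancers)
    tfbs_idx = TrackIndex(bundle.tfbs)
    state_idx = {cl: TrackIndex(t) for cl, t in bundle.chromatin_states.items()}
    gm_idx = _GeneModelIndex(bundle.gene_model)

    rows = []
    for i, v in enumerate(variants):
        rows.append({
            "id": v.id if v.id is not None else f"var{i}",
            "chrom": v.chrom,
            "pos": v.pos,
            "maf": np.nan if v.maf is None else v.maf,
            "rs_score": max_overlap_score(v, cons_idx),
            "dnase_hs_max": max_overlap_score(v, dnase_idx),
            "footprint_cell_count": count_overlap_labels(v, fp_idx),
            "chromatin_state_best": best_chromatin_state(v, state_idx, state_order),
            "position_category": assign_position_category(v, gm_idx, position_order),
            "enhancer_overlap": bool(enh_idx.overlapping(v.chrom, v.pos)),
            "tfbs_max": max_overlap_score(v, tfbs_idx),
        })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def write_feature_table(ft: pd.DataFrame, path: str | Path,
                        header_lines: Sequence[str] = ()) -> None:
    """Write a feature table as tab-delimited text with a header row;
    optional ``#``-prefixed provenance lines first."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        ft.to_csv(fh, sep="\t", index=False)


def load_bundle(config_path: str | Path) -> tuple["AnnotationBundle", list[str] | None]:
    """Load an annotation bundle from a YAML config naming per-track files.

    Keys: ``conservation``, ``dnase_hs``, ``tfbs`` (BED5, name col 4,
    score col 5), ``footprints`` (BED4, label = cell line), ``enhancers``
    (BED3), ``chromatin_states`` (5-column TSV), and a ``gene_model``
    mapping of per-feature BED files (``tss`` / ``gene_bodies`` as BED6
    with strand).  Paths are resolved relative to the config file.
    Returns the bundle plus the config's ``state_order`` (or ``None``).
    """
    import yaml  # local import: only needed for config-driven loading

    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent

    def resolve(name: str) -> Path:
        return base / cfg[name]

    gm_cfg = cfg.get("gene_model", {})

    def gm_track(name: str, label_col: int | None = None) -> list[GenomicInterval]:
        if name not in gm_cfg:
            return []
        path = base / gm_cfg[name]
        if label_col is None:
            return read_scored_track(path, score_col=10**6)  # BED3: no score
        return read_labelled_track(path, label_col=label_col)

    gene_model = GeneModel(
        tss=gm_track("tss", label_col=5),
        gene_bodies=gm_track("gene_bodies", label_col=5),
        exons=gm_track("exons"),
        introns=gm_track("introns"),
        splice_sites=gm_track("splice_sites"),
        cpg_islands=gm_track("cpg_islands"),
        cpg_shores=gm_track("cpg_shores"),
    )
    bundle = AnnotationBundle(
        conservation=read_scored_track(resolve("conservation")) if "conservation" in cfg else [],
        dnase_hs=read_scored_track(resolve("dnase_hs")) if "dnase_hs" in cfg else [],
        tfbs=read_labelled_track(resolve("tfbs"), label_col=3, score_col=4) if "tfbs" in cfg else [],
        footprints=read_labelled_track(resolve("footprints"), label_col=3) if "footprints" in cfg else [],
        enhancers=read_scored_track(resolve("enhancers"), score_col=10**6) if "enhancers" in cfg else [],
        chromatin_states=read_chromatin_states(resolve("chromatin_states")) if "chromatin_states" in cfg else {},
        gene_model=gene_model,
    )
    state_order = cfg.get("state_order")
    return bundle, state_order
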