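"""Conserved-region detection by k-mer tiling.

One genome is split into overlapping k bp tiles (default k=30, step 1);
each tile is placed in the other genome, and tiles with exactly one
placement across both strands are kept. The union of the covered
destination positions, merged into maximal intervals, is the conserved
track (BED semantics, destination-genome coordinates).

An alternate ingestion path accepts an externally produced SAM of tile
alignments and applies a literal MAPQ >= 30 filter, for users who prefer
an external aligner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from ._fasta import read_fasta, revcomp

DEFAULT_K = 30
DEFAULT_STEP = 1


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Tile:
    chrom: str
    start: int
    seq: str
    has_n: bool


@dataclass(frozen=True)
class TileHit:
    tile_origin: Tuple[str, int]
    hit: Optional[Tuple[str, int]]
    unique: bool
    mismatches: int


def tile_sequences(
    genome: Dict[str, str], k: int = DEFAULT_K, step: int = DEFAULT_STEP
) -> Iterator[Tile]:
    """Yield one tile per offset i in [0, L-k] with i % step == 0.

    Tiles containing N are emitted but flagged; sequences shorter than k
    yield no tiles (with a warning).
    """
    if k < 1 or step < 1:
        raise ValueError("k and step must be >= 1")
    for chrom, seq in genome.items():
        if len(seq) < k:
            warnings.warn(f"sequence {chrom!r} shorter than k={k}: no tiles")
            continue
        for i in range(0, len(seq) - k + 1, step):
            sub = seq[i : i + k]
            yield Tile(chrom, i, sub, "N" in sub)


class KmerIndex:
    """Exact k-mer -> forward-strand placements index over a genome."""

    def __init__(self, genome: Dict[str, str], k: int):
        self.k = k
        self.genome = genome
        self._index: Dict[str, List[Tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, i))

    def placements(self, kmer: str) -> List[Tuple[str, int]]:
        """Forward-strand loci where the tile or its reverse complement
        occurs exactly (a palindromic locus counts once)."""
        hits = set(self._index.get(kmer, ()))
        hits.update(self._index.get(revcomp(kmer), ()))
        return sorted(hits)


def _placements_with_mismatches(
    genome: Dict[str, str], kmer: str, max_mismatches: int
) -> List[Tuple[str, int, int]]:
    """Brute-force (chrom, pos, mismatches) placements allowing mismatches.

    O(genome * k); intended for small genomes only.
    """
    k = len(kmer)
    rc = revcomp(kmer)
    out = []
    for chrom, seq in genome.items():
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if "N" in window:
                continue
            mm_f = sum(a != b for a, b in zip(window, kmer))
            mm_r = sum(a != b for a, b in zip(window, rc))
            mm = min(mm_f, mm_r)
            if mm <= max_mismatches:
                out.append((chrom, i, mm))
    return out


def map_tiles_unique(
    tiles: Iterable[Tile],
    destination: Dict[str, str],
    max_mismatches: int = 0,
    index: Optional[KmerIndex] = None,
) -> Iterator[TileHit]:
    """Place tiles in the destination genome; a tile is unique iff it has
    exactly one placement with <= max_mismatches across both strands.

    N-containing tiles never match. Hit coordinates are always on the
    forward strand of the destination.
    """
    tiles = list(tiles)
    if max_mismatches == 0:
        if index is None:
            k = len(tiles[0].seq) if tiles else DEFAULT_K
            index = KmerIndex(destination, k)
        for tile in tiles:
            if tile.has_n:
                yield TileHit((tile.chrom, tile.start), None, False, 0)
                continue
            places = index.placements(tile.seq)
            if len(places) == 1:
                yield TileHit((tile.chrom, tile.start), places[0], True, 0)
            else:
                yield TileHit((tile.chrom, tile.start), None, False, 0)
    else:
        for tile in tiles:
            if tile.has_n:
                yield TileHit((tile.chrom, tile.start), None, False, 0)
                continue
            places = _placements_with_mismatches(
                destination, tile.seq, max_mismatches
            )
            if len(places) == 1:
                chrom, pos, mm = places[0]
                yield TileHit((tile.chrom, tile.start), (chrom, pos), True, mm)
            else:
                yield TileHit((tile.chrom, tile.start), None, False, 0)


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Merge into maximal sorted non-overlapping intervals (touching
    intervals coalesce). Idempotent."""
    ivals = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: List[Interval] = []
    for iv in ivals:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = Interval(out[-1].chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def call_conserved_regions(hits: Iterable[TileHit], k: int) -> List[Interval]:
    """Union of [pos, pos+k) over unique hits, merged, destination coords."""
    covered = [
        Interval(chrom, pos, pos + k)
        for hit in hits
        if hit.unique
        for chrom, pos in [hit.hit]
    ]
    return merge_intervals(covered)


def conserved_regions(
    source: Dict[str, str],
    destination: Dict[str, str],
    k: int = DEFAULT_K,
    step: int = DEFAULT_STEP,
    max_mismatches: int = 0,
) -> List[Interval]:
    """End-to-end: tile ``source``, map uniquely into ``destination``,
    return the merged conserved track in destination coordinates."""
    tiles = tile_sequences(source, k=k, step=step)
    hits = map_tiles_unique(tiles, destination, max_mismatches=max_mismatches)
    return call_conserved_regions(hits, k)


def conserved_regions_from_sam(
    sam_path, k: int, min_mapq: int = 30
) -> List[Interval]:
    """Alternate path: derive the conserved track from an external SAM of
    tile alignments, keeping records with MAPQ >= ``min_mapq``."""
    import pysam

    covered: List[Interval] = []
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            if seg.mapping_quality < min_mapq:
                continue
            covered.append(
                Interval(seg.reference_name, seg.reference_start,
                         seg.reference_start + k)
            )
    return merge_intervals(covered)


def write_bed(intervals: Iterable[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed(path) -> List[Interval]:
    out: List[Interval] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        out.append(Interval(chrom, int(start), int(end)))
    return out


def conserved_regions_from_fasta_paths(
    source_path, dest_path, k: int = DEFAULT_K, step: int = DEFAULT_STEP,
    max_mismatches: int = 0,
) -> List[Interval]:
    return conserved_regions(
        read_fasta(source_path), read_fasta(dest_path), k=k, step=step,
        max_mismatches=max_mismatches,
    )
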