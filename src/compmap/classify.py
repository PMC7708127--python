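"""Read-fate classification against a concatenated reference.

Every primary alignment record is assigned exactly one fate:

* ``TARGET`` — confidently placed (MAPQ above threshold) in the target part;
* ``CONTAMINANT`` — confidently placed in the human part;
* ``AMBIGUOUS`` — mapped but at or below the MAPQ threshold; reads fitting
  both parts receive low mapping quality from the aligner and end up here;
* ``UNMAPPED`` — no placement;
* ``TOO_SHORT`` — below the minimum read length.

Only TARGET and CONTAMINANT records are materialized into per-part output
files, with reference names restored to the original genome names.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import pysam

from .refbuild import PartManifest

DEFAULT_MQ_THRESHOLD = 30
DEFAULT_MIN_LENGTH = 30


class ReadFate(enum.Enum):
    TARGET = "TARGET"
    CONTAMINANT = "CONTAMINANT"
    AMBIGUOUS = "AMBIGUOUS"
    UNMAPPED = "UNMAPPED"
    TOO_SHORT = "TOO_SHORT"


@dataclass
class AlignedRead:
    """One alignment record, 0-based half-open coordinates.

    ``bases``/``qualities``/``ref_bases`` are in SAM (forward-reference)
    orientation; ``ref_bases`` holds the reference base aligned to each
    query position, with ``-`` at query positions that have no reference
    counterpart (insertions/soft clips), or ``None`` when unavailable.
    """

    query_name: str
    reference_name: Optional[str]
    start: int
    end: int
    mapq: int
    strand: str
    bases: str
    qualities: Sequence[int]
    ref_bases: Optional[str] = None
    is_unmapped: bool = False

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.bases):
            raise ValueError(
                f"{self.query_name}: {len(self.qualities)} qualities for "
                f"{len(self.bases)} bases"
            )
        if not self.is_unmapped and self.end <= self.start:
            raise ValueError(f"{self.query_name}: end must exceed start")
        if self.mapq < 0:
            raise ValueError(f"{self.query_name}: negative MAPQ")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def alignment_length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_pysam(
        cls, seg: pysam.AlignedSegment, reference=None
    ) -> "AlignedRead":
        """Build from a pysam record; ``reference`` (a ``pysam.FastaFile``
        or name->sequence dict) supplies aligned reference bases when the
        record carries no MD tag."""
        bases = seg.query_sequence or ""
        quals = list(seg.query_qualities) if seg.query_qualities is not None else [0] * len(bases)
        if seg.is_unmapped:
            return cls(
                query_name=seg.query_name,
                reference_name=None,
                start=0,
                end=0,
                mapq=seg.mapping_quality,
                strand="+",
                bases=bases,
                qualities=quals,
                is_unmapped=True,
            )
        ref_bases = _aligned_ref_bases(seg, reference)
        return cls(
            query_name=seg.query_name,
            reference_name=seg.reference_name,
            start=seg.reference_start,
            end=seg.reference_end,
            mapq=seg.mapping_quality,
            strand="-" if seg.is_reverse else "+",
            bases=bases,
            qualities=quals,
            ref_bases=ref_bases,
        )


def _aligned_ref_bases(seg: pysam.AlignedSegment, reference) -> Optional[str]:
    qlen = len(seg.query_sequence or "")
    out = ["-"] * qlen
    if seg.has_tag("MD"):
        pairs = seg.get_aligned_pairs(with_seq=True)
        for qpos, _rpos, rbase in pairs:
            if qpos is not None and rbase is not None:
                out[qpos] = rbase.upper()
        return "".join(out)
    if reference is None:
        return None
    if isinstance(reference, dict):
        chrom = reference[seg.reference_name]
        fetch = lambda s, e: chrom[s:e]  # noqa: E731
    else:
        fetch = lambda s, e: reference.fetch(seg.reference_name, s, e)  # noqa: E731
    ref_seq = fetch(seg.reference_start, seg.reference_end).upper()
    for qpos, rpos in seg.get_aligned_pairs(matches_only=True):
        out[qpos] = ref_seq[rpos - seg.reference_start]
    return "".join(out)


@dataclass
class FateCounts:
    n_total: int = 0
    n_target: int = 0
    n_contaminant: int = 0
    n_ambiguous: int = 0
    n_unmapped: int = 0
    n_too_short: int = 0

    def add(self, fate: ReadFate) -> None:
        self.n_total += 1
        if fate is ReadFate.TARGET:
            self.n_target += 1
        elif fate is ReadFate.CONTAMINANT:
            self.n_contaminant += 1
        elif fate is ReadFate.AMBIGUOUS:
            self.n_ambiguous += 1
        elif fate is ReadFate.UNMAPPED:
            self.n_unmapped += 1
        else:
            self.n_too_short += 1

    def validate(self) -> None:
        parts = (
            self.n_target
            + self.n_contaminant
            + self.n_ambiguous
            + self.n_unmapped
            + self.n_too_short
        )
        if parts != self.n_total:
            raise ValueError(
                f"fate counts {parts} do not sum to n_total {self.n_total}"
            )

    def as_dict(self) -> Dict[str, int]:
        return {
            "n_total": self.n_total,
            "n_target": self.n_target,
            "n_contaminant": self.n_contaminant,
            "n_ambiguous": self.n_ambiguous,
            "n_unmapped": self.n_unmapped,
            "n_too_short": self.n_too_short,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_tsv(self, path) -> None:
        d = self.as_dict()
        with open(path, "w") as fh:
            fh.write("\t".join(d) + "\n")
            fh.write("\t".join(str(v) for v in d.values()) + "\n")


def assign_fate(
    read: AlignedRead,
    manifest: PartManifest,
    target_label: str = "target",
    mq_threshold: int = DEFAULT_MQ_THRESHOLD,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> ReadFate:
    """Assign one fate to an alignment record.

    Precedence: UNMAPPED, then TOO_SHORT (read length below ``min_length``),
    then AMBIGUOUS (MAPQ <= ``mq_threshold``; strict ``>`` passes), then
    TARGET or CONTAMINANT per the manifest part of the reference sequence.
    """
    if read.is_unmapped:
        return ReadFate.UNMAPPED
    if len(read) < min_length:
        return ReadFate.TOO_SHORT
    if read.mapq <= mq_threshold:
        return ReadFate.AMBIGUOUS
    part = manifest.part_of(read.reference_name)  # KeyError if unknown
    return ReadFate.TARGET if part == target_label else ReadFate.CONTAMINANT


def _part_header(manifest: PartManifest, part_label: str) -> Dict:
    entries = manifest.entries_for(part_label)
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": e.original_name, "LN": e.length} for e in entries],
    }


def split_by_fate(
    in_path,
    manifest: PartManifest,
    out_target,
    out_contaminant,
    target_label: str = "target",
    mq_threshold: int = DEFAULT_MQ_THRESHOLD,
    min_length: int = DEFAULT_MIN_LENGTH,
    out_ambiguous=None,
) -> FateCounts:
    """Split a SAM/BAM against the concatenated reference by read fate.

    TARGET and CONTAMINANT primary records are written to per-part files
    whose headers contain only the sequences of that part, with reference
    names restored to the original genome names and coordinates unchanged.
    AMBIGUOUS records can optionally be materialized (against the full
    concatenated header). Secondary and supplementary records are ignored.
    Returns conserving fate counts.
    """
    labels = manifest.labels
    if target_label not in labels:
        raise ValueError(f"target label {target_label!r} not in manifest labels {labels}")
    human_labels = [l for l in labels if l != target_label]

    counts = FateCounts()
    with pysam.AlignmentFile(str(in_path), check_sq=False) as infile:
        for sq in infile.header.get("SQ", []):
            manifest.part_of(sq["SN"])  # KeyError if header has unknown sequence

        tgt_header = pysam.AlignmentHeader.from_dict(
            _part_header(manifest, target_label)
        )
        con_entries = [e for l in human_labels for e in manifest.entries_for(l)]
        con_header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unsorted"},
                "SQ": [{"SN": e.original_name, "LN": e.length} for e in con_entries],
            }
        )

        out_t = pysam.AlignmentFile(str(out_target), "w", header=tgt_header)
        out_c = pysam.AlignmentFile(str(out_contaminant), "w", header=con_header)
        out_a = (
            pysam.AlignmentFile(
                str(out_ambiguous), "w", header=infile.header
            )
            if out_ambiguous is not None
            else None
        )
        try:
            for seg in infile:
                if seg.is_secondary or seg.is_supplementary:
                    continue
                read = AlignedRead.from_pysam(seg)
                fate = assign_fate(
                    read, manifest, target_label, mq_threshold, min_length
                )
                counts.add(fate)
                if fate is ReadFate.TARGET:
                    _write_renamed(out_t, seg, manifest)
                elif fate is ReadFate.CONTAMINANT:
                    _write_renamed(out_c, seg, manifest)
                elif fate is ReadFate.AMBIGUOUS and out_a is not None:
                    out_a.write(seg)
        finally:
            out_t.close()
            out_c.close()
            if out_a is not None:
                out_a.close()
    counts.validate()
    return counts


def _write_renamed(
    out: pysam.AlignmentFile, seg: pysam.AlignedSegment, manifest: PartManifest
) -> None:
    rec = pysam.AlignedSegment(out.header)
    rec.query_name = seg.query_name
    rec.flag = seg.flag
    rec.reference_name = manifest.original_name(seg.reference_name)
    rec.reference_start = seg.reference_start
    rec.mapping_quality = seg.mapping_quality
    rec.cigarstring = seg.cigarstring
    rec.query_sequence = seg.query_sequence
    rec.query_qualities = seg.query_qualities
    for tag, value in seg.get_tags():
        rec.set_tag(tag, value)
    out.write(rec)


def deduplicate_alignments(
    reads: Iterable[AlignedRead], ignore_strand: bool = False
) -> Iterator[AlignedRead]:
    """Collapse duplicates sharing (reference, start, end, strand).

    Both start AND end coordinates define the duplicate key (not start
    alone). Among duplicates the record with the highest summed base
    quality is kept; ties break to the first occurrence in file order.
    Unmapped records pass through unchanged. Output preserves the input
    order of the retained records (deterministic).
    """
    best: Dict[Tuple, Tuple[int, float, AlignedRead]] = {}
    passthrough: List[Tuple[int, AlignedRead]] = []
    for idx, read in enumerate(reads):
        if read.is_unmapped:
            passthrough.append((idx, read))
            continue
        key = (
            read.reference_name,
            read.start,
            read.end,
            "+" if ignore_strand else read.strand,
        )
        score = float(sum(read.qualities))
        prev = best.get(key)
        if prev is None or score > prev[1]:
            best[key] = (idx, score, read)
    retained = passthrough + [(i, r) for i, _s, r in best.values()]
    retained.sort(key=lambda t: t[0])
    for _i, read in retained:
        yield read


@dataclass
class LossReport:
    """Data-loss accounting: single-reference vs competitive mapping."""

    n_original: int
    n_competitive: int
    loss_genomewide: Optional[float]
    n_original_conserved: int
    n_competitive_conserved: int
    loss_conserved: Optional[float]

    def as_dict(self) -> Dict:
        return {
            "n_original": self.n_original,
            "n_competitive": self.n_competitive,
            "loss_genomewide": self.loss_genomewide,
            "n_original_conserved": self.n_original_conserved,
            "n_competitive_conserved": self.n_competitive_conserved,
            "loss_conserved": self.loss_conserved,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)
            fh.write("\n")


def _merge(ivals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    ivals = sorted(ivals)
    out: List[Tuple[int, int]] = []
    for s, e in ivals:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlaps_any(
    chrom: str, start: int, end: int, by_chrom: Dict[str, List[Tuple[int, int]]]
) -> bool:
    import bisect

    ivals = by_chrom.get(chrom)
    if not ivals:
        return False
    # ivals are merged and sorted: only the last interval starting before
    # `end` can overlap [start, end)
    starts = [s for s, _e in ivals]
    i = bisect.bisect_left(starts, end)
    if i == 0:
        return False
    _s, e = ivals[i - 1]
    return e > start


def compute_loss(
    original_reads: Iterable[AlignedRead],
    competitive_reads: Iterable[AlignedRead],
    conserved_regions: Sequence,
) -> LossReport:
    """Quantify reads lost to competitive mapping, genome-wide and within
    conserved regions.

    Both inputs must already be filtered to MAPQ-passing reads in the same
    target-genome coordinates. A read counts as "in conserved regions" when
    its [start, end) interval overlaps any conserved interval by >= 1 bp.
    """
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in conserved_regions:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    by_chrom = {c: _merge(v) for c, v in by_chrom.items()}

    def count(reads: Iterable[AlignedRead]) -> Tuple[int, int]:
        total = cons = 0
        for r in reads:
            if r.is_unmapped:
                continue
            total += 1
            if _overlaps_any(r.reference_name, r.start, r.end, by_chrom):
                cons += 1
        return total, cons

    n_orig, n_orig_cons = count(original_reads)
    n_comp, n_comp_cons = count(competitive_reads)

    if n_orig == 0:
        warnings.warn("no original reads: genome-wide loss undefined")
        loss_gw = None
    else:
        loss_gw = 1.0 - n_comp / n_orig
    if n_orig_cons == 0:
        warnings.warn("no original reads in conserved regions: conserved loss undefined")
        loss_cons = None
    else:
        loss_cons = 1.0 - n_comp_cons / n_orig_cons

    return LossReport(
        n_original=n_orig,
        n_competitive=n_comp,
        loss_genomewide=loss_gw,
        n_original_conserved=n_orig_cons,
        n_competitive_conserved=n_comp_cons,
        loss_conserved=loss_cons,
    )


def read_alignments(path, reference=None, min_mapq: Optional[int] = None) -> List[AlignedRead]:
    """Load primary records from a SAM/BAM as :class:`AlignedRead` objects,
    optionally keeping only records with MAPQ strictly above ``min_mapq``."""
    out: List[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_secondary or seg.is_supplementary:
                continue
            if min_mapq is not None and (seg.is_unmapped or seg.mapping_quality <= min_mapq):
                continue
            out.append(AlignedRead.from_pysam(seg, reference))
    return out
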