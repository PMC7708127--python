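"""Synthetic ancient-read simulator with full truth labels.

Generates a mixture of short, deaminated fragments drawn from a target
genome and (by default longer, undamaged) fragments from a contaminant
genome. Outputs a FASTQ, a truth table, and a truth SAM that places every
read at its origin against the concatenated two-part reference, so the
whole classification pipeline is testable without an external aligner.

All randomness flows through one ``numpy.random.Generator`` (PCG64),
making every output byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pysam

from ._fasta import read_fasta, revcomp
from .pmd import DamageModel
from .refbuild import ManifestEntry, PartManifest

MAX_QUALITY = 41


@dataclass(frozen=True)
class FragmentLengthModel:
    """Lognormal fragment-length distribution truncated to [min_len, max_len]."""

    mean_log: float = 4.0
    sd_log: float = 0.25
    min_len: int = 30
    max_len: int = 150

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")


@dataclass
class SimConfig:
    target_genome: str
    contaminant_genome: str
    n_reads: int = 1000
    contamination_fraction: float = 0.0
    fraglen_target: FragmentLengthModel = field(default_factory=FragmentLengthModel)
    fraglen_contaminant: FragmentLengthModel = field(
        default_factory=lambda: FragmentLengthModel(mean_log=4.4)
    )
    damage_target: DamageModel = field(default_factory=lambda: DamageModel(p=0.3, c=0.01))
    damage_contaminant: DamageModel = field(default_factory=lambda: DamageModel(p=0.0, c=0.0))
    error_rate: float = 0.001
    seed: int = 0
    target_label: str = "target"
    contaminant_label: str = "human"
    sep: str = "|"
    competitive_mapq: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.contamination_fraction <= 1.0):
            raise ValueError("contamination_fraction must be in [0, 1]")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")

    @classmethod
    def from_toml(cls, path) -> "SimConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls(
            target_genome=raw["target_genome"],
            contaminant_genome=raw["contaminant_genome"],
        )
        for key in ("n_reads", "contamination_fraction", "error_rate", "seed",
                    "target_label", "contaminant_label", "sep", "competitive_mapq"):
            if key in raw:
                cfg = replace(cfg, **{key: raw[key]})
        for attr, prefix in (("fraglen_target", "target_fraglen"),
                             ("fraglen_contaminant", "contaminant_fraglen")):
            kwargs = {
                f: raw[f"{prefix}_{f}"]
                for f in ("mean_log", "sd_log", "min_len", "max_len")
                if f"{prefix}_{f}" in raw
            }
            if kwargs:
                cfg = replace(cfg, **{attr: replace(getattr(cfg, attr), **kwargs)})
        for attr, prefix in (("damage_target", "target_damage"),
                             ("damage_contaminant", "contaminant_damage")):
            kwargs = {
                f: raw[f"{prefix}_{f}"] for f in ("p", "c", "pi")
                if f"{prefix}_{f}" in raw
            }
            if kwargs:
                cfg = replace(cfg, **{attr: replace(getattr(cfg, attr), **kwargs)})
        return cfg


@dataclass(frozen=True)
class TruthRecord:
    read_name: str
    origin: str  # "target" or "contaminant"
    chrom: str
    start: int
    end: int
    strand: str
    n_damage_events: int


TRUTH_COLUMNS = ("read_name", "origin", "chrom", "start", "end", "strand",
                 "n_damage_events")


def _sample_length(model: FragmentLengthModel, rng: np.random.Generator) -> int:
    # rejection sampling against the truncation bounds
    for _ in range(10000):
        length = int(round(rng.lognormal(model.mean_log, model.sd_log)))
        if model.min_len <= length <= model.max_len:
            return length
    raise RuntimeError(
        "fragment-length rejection sampling failed; truncation bounds "
        f"{model.min_len}..{model.max_len} are incompatible with the "
        f"lognormal({model.mean_log}, {model.sd_log})"
    )


def _sample_placement(
    genome: Dict[str, str], length: int, rng: np.random.Generator
) -> Tuple[str, int, str]:
    chroms = [c for c, s in genome.items() if len(s) >= length]
    if not chroms:
        raise ValueError(
            f"no genome sequence can host a fragment of length {length}"
        )
    weights = np.array([len(genome[c]) - length + 1 for c in chroms], dtype=float)
    idx = rng.choice(len(chroms), p=weights / weights.sum())
    chrom = chroms[idx]
    start = int(rng.integers(0, len(genome[chrom]) - length + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    return chrom, start, strand


def sample_fragments(
    genome: Dict[str, str],
    fraglen_model: FragmentLengthModel,
    n: int,
    rng: np.random.Generator,
) -> List[Tuple[str, int, int, str, str]]:
    """Draw n fragments: positions uniform over valid placements, strand
    uniform; the returned sequence is in molecule (sequenced) orientation.
    """
    if max(len(s) for s in genome.values()) < fraglen_model.min_len:
        raise ValueError("genome too short for the minimum fragment length")
    out = []
    for _ in range(n):
        length = _sample_length(fraglen_model, rng)
        chrom, start, strand = _sample_placement(genome, length, rng)
        seq = genome[chrom][start : start + length]
        if strand == "-":
            seq = revcomp(seq)
        out.append((chrom, start, start + length, strand, seq))
    return out


_C, _G, _T, _A = (ord(b) for b in "CGTA")


def apply_damage(
    sequence: str, model: DamageModel, rng: np.random.Generator
) -> Tuple[str, int]:
    """Deaminate: each C at 1-based distance z from the 5' end becomes T
    with probability D(z); each G at distance z from the 3' end becomes A
    with probability D(z)."""
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    L = len(arr)
    if L == 0:
        return sequence, 0
    z = np.arange(1, L + 1, dtype=float)
    d5 = np.clip(model.p * (1.0 - model.p) ** (z - 1) + model.c, 0.0, 1.0)
    d3 = d5[::-1]
    u = rng.random(L)
    ct = (arr == _C) & (u < d5)
    ga = (arr == _G) & (u < d3)
    arr[ct] = _T
    arr[ga] = _A
    return arr.tobytes().decode(), int(ct.sum() + ga.sum())


def apply_sequencing_errors(
    sequence: str, error_rate: float, rng: np.random.Generator
) -> Tuple[str, List[int]]:
    """Substitute each base to a uniformly chosen different base with
    probability ``error_rate``; emit a constant Phred quality
    Q = round(-10 log10(error_rate)), capped at 41."""
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    L = len(sequence)
    if error_rate == 0.0:
        q = MAX_QUALITY
        return sequence, [q] * L
    q = min(MAX_QUALITY, round(-10.0 * math.log10(error_rate)))
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(L) < error_rate)
    if hit.size:
        picks = rng.integers(0, 3, size=hit.size)
        bases = b"ACGT"
        for pos, pick in zip(hit, picks):
            others = [b for b in bases if b != arr[pos]]
            arr[pos] = others[pick]
    return arr.tobytes().decode(), [q] * L


@dataclass
class SimResult:
    fastq: Path
    truth_tsv: Path
    truth_sam: Path
    manifest_tsv: Path
    original_sam: Optional[Path]
    truth: List[TruthRecord]
    manifest: PartManifest


def _occurs_in(genome_blob: str, seq: str) -> bool:
    return seq in genome_blob or revcomp(seq) in genome_blob


def simulate_dataset(config: SimConfig, outdir, emit_original_sam: bool = False) -> SimResult:
    """Generate FASTQ + truth TSV + truth SAM (+ part manifest).

    Each read is drawn from the contaminant genome with probability
    ``contamination_fraction``, else from the target genome; damage and
    sequencing errors are applied per origin. The truth SAM places every
    read at its origin against the concatenated reference with MAPQ 60 —
    or, when ``competitive_mapq`` is set, MAPQ 0 for fragments whose
    undamaged sequence also occurs in the other genome (emulating the low
    mapping quality a competitive aligner assigns to dual-part reads).

    ``emit_original_sam`` additionally writes the target-origin reads as a
    single-reference alignment (original chromosome names, MAPQ 60),
    standing in for the pre-competitive-mapping target BAM.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    target = read_fasta(config.target_genome)
    contaminant = read_fasta(config.contaminant_genome)
    # one blob per genome for dual-placement checks
    target_blob = "$".join(target.values())
    contaminant_blob = "$".join(contaminant.values())

    entries = [
        ManifestEntry(f"{config.target_label}{config.sep}{c}",
                      config.target_label, c, len(s))
        for c, s in target.items()
    ] + [
        ManifestEntry(f"{config.contaminant_label}{config.sep}{c}",
                      config.contaminant_label, c, len(s))
        for c, s in contaminant.items()
    ]
    manifest = PartManifest(entries)

    fastq_path = outdir / "reads.fastq"
    truth_tsv_path = outdir / "truth.tsv"
    truth_sam_path = outdir / "truth.sam"
    manifest_path = outdir / "concat.parts.tsv"
    original_sam_path = outdir / "original_target.sam" if emit_original_sam else None
    manifest.write(manifest_path)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": e.sequence_name, "LN": e.length} for e in entries],
        }
    )
    orig_header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in target.items()],
        }
    )

    truth: List[TruthRecord] = []
    sam_out = pysam.AlignmentFile(str(truth_sam_path), "w", header=header)
    orig_out = (
        pysam.AlignmentFile(str(original_sam_path), "w", header=orig_header)
        if emit_original_sam
        else None
    )
    try:
        with open(fastq_path, "w") as fq, open(truth_tsv_path, "w") as tt:
            tt.write("\t".join(TRUTH_COLUMNS) + "\n")
            for i in range(config.n_reads):
                is_contaminant = rng.random() < config.contamination_fraction
                if is_contaminant:
                    origin, genome = "contaminant", contaminant
                    fraglen, damage = config.fraglen_contaminant, config.damage_contaminant
                    label, other_blob = config.contaminant_label, target_blob
                else:
                    origin, genome = "target", target
                    fraglen, damage = config.fraglen_target, config.damage_target
                    label, other_blob = config.target_label, contaminant_blob

                length = _sample_length(fraglen, rng)
                chrom, start, strand = _sample_placement(genome, length, rng)
                frag = genome[chrom][start : start + length]
                if strand == "-":
                    frag = revcomp(frag)

                mapq = 60
                if config.competitive_mapq and _occurs_in(other_blob, frag):
                    mapq = 0

                damaged, n_events = apply_damage(frag, damage, rng)
                final, quals = apply_sequencing_errors(
                    damaged, config.error_rate, rng
                )
                name = f"sim{i:07d}"

                fq.write(f"@{name}\n{final}\n+\n")
                fq.write("".join(chr(q + 33) for q in quals) + "\n")
                rec = TruthRecord(name, origin, chrom, start, start + length,
                                  strand, n_events)
                truth.append(rec)
                tt.write(
                    f"{name}\t{origin}\t{chrom}\t{start}\t{start + length}\t"
                    f"{strand}\t{n_events}\n"
                )

                seg = pysam.AlignedSegment(header)
                seg.query_name = name
                seg.flag = 16 if strand == "-" else 0
                seg.reference_name = f"{label}{config.sep}{chrom}"
                seg.reference_start = start
                seg.mapping_quality = mapq
                seg.cigarstring = f"{length}M"
                seg.query_sequence = final if strand == "+" else revcomp(final)
                seg.query_qualities = quals if strand == "+" else quals[::-1]
                sam_out.write(seg)

                if orig_out is not None and origin == "target":
                    oseg = pysam.AlignedSegment(orig_header)
                    oseg.query_name = name
                    oseg.flag = seg.flag
                    oseg.reference_name = chrom
                    oseg.reference_start = start
                    oseg.mapping_quality = 60
                    oseg.cigarstring = seg.cigarstring
                    oseg.query_sequence = seg.query_sequence
                    oseg.query_qualities = seg.query_qualities
                    orig_out.write(oseg)
    finally:
        sam_out.close()
        if orig_out is not None:
            orig_out.close()

    return SimResult(
        fastq=fastq_path,
        truth_tsv=truth_tsv_path,
        truth_sam=truth_sam_path,
        manifest_tsv=manifest_path,
        original_sam=original_sam_path,
        truth=truth,
        manifest=manifest,
    )


def load_truth_tsv(path) -> List[TruthRecord]:
    out: List[TruthRecord] = []
    with open(path) as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth header in {path}: {header}")
        for line in fh:
            name, origin, chrom, start, end, strand, n_ev = line.rstrip("\n").split("\t")
            out.append(TruthRecord(name, origin, chrom, int(start), int(end),
                                   strand, int(n_ev)))
    return out


def random_genome(
    rng: np.random.Generator, length: int, chrom: str = "chr1"
) -> Dict[str, str]:
    """Uniform-random genome; two independent draws are divergent for any
    practically relevant k (shared 30-mers have probability ~ L^2 / 4^30)."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = rng.choice(bases, size=length).tobytes().decode()
    return {chrom: seq}
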