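import numpy as np
import pysam
import pytest

from compmap._fasta import write_fasta
from compmap.refbuild import ManifestEntry, PartManifest
from compmap.simulate import random_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def divergent_genomes(rng, tmp_path):
    """Two independent random 20 kb genomes written as FASTA files."""
    target = random_genome(rng, 20_000, chrom="chrT")
    contaminant = random_genome(rng, 20_000, chrom="chrH")
    t_path = tmp_path / "target.fa"
    h_path = tmp_path / "human.fa"
    write_fasta(target, t_path)
    write_fasta(contaminant, h_path)
    return target, contaminant, t_path, h_path


@pytest.fixture
def simple_manifest():
    return PartManifest([
        ManifestEntry("target|chrT", "target", "chrT", 600),
        ManifestEntry("human|chr1", "human", "chr1", 400),
    ])


def plant_segment(src_seq, dst_seq, src_start, dst_start, length):
    """Copy src_seq[src_start : src_start+length] into dst_seq at dst_start,
    forcing the destination bases flanking the copy to differ from the
    source's flanks so boundary-straddling k-mers cannot match by chance.
    The planted copy occupies dst positions [dst_start, dst_start+length).
    """
    assert 0 < src_start and src_start + length < len(src_seq)
    assert 0 < dst_start and dst_start + length + 1 <= len(dst_seq)
    seg = src_seq[src_start : src_start + length]

    def different(base):
        return "A" if base != "A" else "C"

    left = different(src_seq[src_start - 1])
    right = different(src_seq[src_start + length])
    return (dst_seq[: dst_start - 1] + left + seg + right
            + dst_seq[dst_start + length + 1 :])


def make_sam(path, records, sq=(("target|chrT", 600), ("human|chr1", 400))):
    """Write a SAM from simple record dicts; returns the path.

    Record keys: name, ref (None for unmapped), pos, mapq, seq, quals
    (optional, default q30), flag (optional).
    """
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": sn, "LN": ln} for sn, ln in sq],
    })
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec["name"]
            seq = rec.get("seq", "A" * 40)
            seg.query_sequence = seq
            seg.query_qualities = rec.get("quals", [30] * len(seq))
            if rec.get("ref") is None:
                seg.flag = 4
            else:
                seg.flag = rec.get("flag", 0)
                seg.reference_name = rec["ref"]
                seg.reference_start = rec.get("pos", 0)
                seg.mapping_quality = rec.get("mapq", 60)
                seg.cigarstring = rec.get("cigar", f"{len(seq)}M")
            out.write(seg)
    return path
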