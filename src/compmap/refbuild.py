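"""Concatenated two-species reference construction and part attribution.

A concatenated reference merges every sequence of a target-species genome
with every sequence of the human genome into a single FASTA. Each output
sequence name is prefixed with its part label so that downstream tools can
attribute alignments to a source genome; a tab-separated *part manifest*
written alongside is the authoritative record of that attribution (name
prefixes are a human-readable convenience only, since aligners may mangle
names).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from ._fasta import read_fasta, write_fasta

MANIFEST_COLUMNS = ("sequence_name", "part_label", "original_name", "length")


@dataclass(frozen=True)
class ManifestEntry:
    sequence_name: str
    part_label: str
    original_name: str
    length: int


@dataclass
class PartManifest:
    """Maps every sequence of a concatenated reference to its source part."""

    entries: List[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.sequence_name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate sequence_name in manifest")
        for e in self.entries:
            if e.length <= 0:
                raise ValueError(
                    f"non-positive length for {e.sequence_name!r}: {e.length}"
                )

    def __eq__(self, other) -> bool:
        return isinstance(other, PartManifest) and self.entries == other.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> List[str]:
        """Distinct part labels in first-seen order."""
        seen: Dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.part_label, None)
        return list(seen)

    def part_of(self, sequence_name: str) -> str:
        """Part label for a concatenated-reference sequence name."""
        entry = self._by_name().get(sequence_name)
        if entry is None:
            raise KeyError(
                f"sequence {sequence_name!r} not present in part manifest"
            )
        return entry.part_label

    def original_name(self, sequence_name: str) -> str:
        entry = self._by_name().get(sequence_name)
        if entry is None:
            raise KeyError(
                f"sequence {sequence_name!r} not present in part manifest"
            )
        return entry.original_name

    def entries_for(self, part_label: str) -> List[ManifestEntry]:
        return [e for e in self.entries if e.part_label == part_label]

    def _by_name(self) -> Dict[str, ManifestEntry]:
        return {e.sequence_name: e for e in self.entries}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
            for e in self.entries:
                fh.write(
                    f"{e.sequence_name}\t{e.part_label}\t{e.original_name}\t{e.length}\n"
                )


def load_part_manifest(
    path, allowed_labels: Optional[Sequence[str]] = None
) -> PartManifest:
    """Load a 4-column TSV part manifest.

    ``allowed_labels``, when given, restricts part labels to the declared
    set; any other label is an error. Round-trips with
    :meth:`PartManifest.write`.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"empty manifest file: {path}")
    header = lines[0].split("\t")
    if tuple(header) != MANIFEST_COLUMNS:
        raise ValueError(
            f"manifest {path} header {header!r} does not match "
            f"{list(MANIFEST_COLUMNS)!r}"
        )
    entries = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise ValueError(
                f"manifest {path} line {lineno}: expected 4 columns, got {len(cols)}"
            )
        name, label, orig, length = cols
        if allowed_labels is not None and label not in allowed_labels:
            raise ValueError(
                f"manifest {path} line {lineno}: unknown part_label {label!r} "
                f"(declared labels: {sorted(allowed_labels)})"
            )
        entries.append(ManifestEntry(name, label, orig, int(length)))
    if not entries:
        raise ValueError(f"manifest {path} contains no entries")
    return PartManifest(entries)


def build_concatenated_reference(
    target_fasta,
    human_fasta,
    out_fasta,
    manifest_path,
    target_label: str = "target",
    human_label: str = "human",
    sep: str = "|",
    line_width: int = 60,
) -> PartManifest:
    """Merge two genomes into one FASTA, target sequences first.

    Each output name is ``<part_label><sep><original_name>``; the returned
    (and written) manifest records the attribution of every sequence.
    """
    if target_label == human_label:
        raise ValueError("target and human part labels must differ")
    target = read_fasta(target_fasta)
    human = read_fasta(human_fasta)

    out: Dict[str, str] = {}
    entries: List[ManifestEntry] = []
    for label, genome in ((target_label, target), (human_label, human)):
        for name, seq in genome.items():
            new_name = f"{label}{sep}{name}"
            if new_name in out:
                raise ValueError(
                    f"name collision after prefixing: {new_name!r}"
                )
            out[new_name] = seq
            entries.append(ManifestEntry(new_name, label, name, len(seq)))

    manifest = PartManifest(entries)
    write_fasta(out, out_fasta, width=line_width)
    manifest.write(manifest_path)
    return manifest


def concatenated_header(
    manifest: PartManifest, part_labels: Optional[Iterable[str]] = None
) -> Tuple[List[str], List[int]]:
    """(names, lengths) for a SAM header over the given parts (default all)."""
    labels = list(part_labels) if part_labels is not None else manifest.labels
    names, lengths = [], []
    for e in manifest.entries:
        if e.part_label in labels:
            names.append(e.sequence_name)
            lengths.append(e.length)
    return names, lengths
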