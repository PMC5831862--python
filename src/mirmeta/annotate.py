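"""Classify clean reads against reference annotation categories.

A read matches a category when it occurs as an exact full-length substring of
one of the category's reference sequences (both strands for genome-interval
categories, with sense/antisense recorded for exon/intron).  Reads matching
several categories take the highest-priority one; everything else is "other".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._util import revcomp_dna, to_dna
from .qc import SmallRNARead

DEFAULT_PRIORITY = (
    "known_miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "repeat",
    "exon",
    "intron",
)

STRANDED_CATEGORIES = {"exon", "intron"}
OTHER = "other"


@dataclass
class AnnotationIndex:
    """Per-category reference sequences plus a priority order.

    ``references`` maps category -> list of DNA sequences.  Categories in
    ``STRANDED_CATEGORIES`` are searched on both strands and labelled
    ``exon:+`` / ``exon:-`` etc.; all others are sense-only sequence sets.
    """

    references: dict[str, list[str]]
    priority: Sequence[str] = DEFAULT_PRIORITY

    def __post_init__(self) -> None:
        unknown = set(self.references) - set(self.priority)
        if unknown:
            raise ValueError(f"categories without priority: {sorted(unknown)}")
        self.references = {
            cat: [to_dna(s) for s in seqs] for cat, seqs in self.references.items()
        }

    @classmethod
    def from_fasta_dir(
        cls, directory: str | Path, priority: Sequence[str] = DEFAULT_PRIORITY
    ) -> "AnnotationIndex":
        """Load ``<category>.fasta`` files from a directory."""
        from Bio import SeqIO

        refs: dict[str, list[str]] = {}
        for path in sorted(Path(directory).glob("*.fasta")):
            category = path.stem
            refs[category] = [str(r.seq) for r in SeqIO.parse(str(path), "fasta")]
        if not refs:
            raise ValueError(f"no .fasta reference files in {directory}")
        return cls(refs, priority)

    @classmethod
    def from_gff3(
        cls,
        gff3_path: str | Path,
        genome_fasta: str | Path,
        priority: Sequence[str] = DEFAULT_PRIORITY,
        feature_map: dict[str, str] | None = None,
    ) -> "AnnotationIndex":
        """Extract interval sequences from a genome, one category per feature
        type.  GFF3 coordinates are 1-based inclusive; minus-strand intervals
        are reverse-complemented so references are always sense sequences.
        """
        from Bio import SeqIO

        genome = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(genome_fasta), "fasta")}
        feature_map = feature_map or {}
        refs: dict[str, list[str]] = {}
        with open(gff3_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 8:
                    raise ValueError(f"malformed GFF3 line: {line!r}")
                seqid, _, ftype, start, end, _, strand = parts[:7]
                category = feature_map.get(ftype, ftype)
                if seqid not in genome:
                    raise ValueError(f"GFF3 seqid {seqid!r} not in genome")
                start_i, end_i = int(start) - 1, int(end)  # to 0-based half-open
                if start_i < 0 or end_i > len(genome[seqid]) or start_i >= end_i:
                    raise ValueError(
                        f"GFF3 interval {seqid}:{start}-{end} outside genome bounds"
                    )
                seq = genome[seqid][start_i:end_i]
                if strand == "-":
                    seq = revcomp_dna(seq)
                refs.setdefault(category, []).append(seq)
        return cls(refs, priority)


@dataclass
class ClassificationReport:
    counts: dict[str, int] = field(default_factory=dict)
    mapped_total: int = 0
    removed_total: int = 0
    remaining: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def _matches(read_seq: str, index: AnnotationIndex, category: str) -> str | None:
    """Return the (sub)label under which the read hits the category, if any."""
    refs = index.references.get(category, [])
    if category in STRANDED_CATEGORIES:
        rc = revcomp_dna(read_seq)
        for ref in refs:
            if read_seq in ref:
                return f"{category}:+"
        for ref in refs:
            if rc in ref:
                return f"{category}:-"
        return None
    for ref in refs:
        if read_seq in ref:
            return category
    return None


def classify_reads(
    reads: Iterable[SmallRNARead], index: AnnotationIndex
) -> tuple[ClassificationReport, dict[str, str]]:
    """Label every read with its highest-priority matching category.

    Returns the report and a read id -> label mapping (labels include strand
    sub-labels such as ``exon:+``; unmatched reads are ``other``).
    """
    labels: dict[str, str] = {}
    counts: dict[str, int] = {}
    for read in reads:
        seq = to_dna(read.sequence)
        label = OTHER
        for category in index.priority:
            if category not in index.references:
                continue
            hit = _matches(seq, index, category)
            if hit is not None:
                label = hit
                break
        labels[read.id] = label
        counts[label] = counts.get(label, 0) + 1

    report = ClassificationReport(counts=dict(sorted(counts.items())))
    report.mapped_total = sum(c for lab, c in counts.items() if lab != OTHER)
    report.removed_total = sum(
        c
        for lab, c in counts.items()
        if lab not in (OTHER, "known_miRNA")
    )
    report.remaining = report.mapped_total - report.removed_total
    return report, labels


def remove_annotated(labels: dict[str, str]) -> tuple[set[str], tuple[int, int, int]]:
    """Drop reads annotated to non-miRNA categories.

    Returns the candidate read ids (known miRNA plus unannotated) and the
    bookkeeping triple ``(mapped, removed, remaining)`` where remaining is
    counted among mapped reads only, i.e. remaining = mapped - removed.
    """
    mapped = sum(1 for lab in labels.values() if lab != OTHER)
    removed = sum(
        1 for lab in labels.values() if lab not in (OTHER, "known_miRNA")
    )
    candidates = {
        rid for rid, lab in labels.items() if lab in (OTHER, "known_miRNA")
    }
    return candidates, (mapped, removed, mapped - removed)


def remaining_reads(mapped: int, removed: int) -> int:
    """Bookkeeping identity: reads left for miRNA analysis after removing
    annotated non-miRNA reads from the mapped total."""
    if removed > mapped:
        raise ValueError("removed cannot exceed mapped")
    return mapped - removed


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcategory\n")
        for rid in sorted(labels):
            fh.write(f"{rid}\t{labels[rid]}\n")
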