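"""Raw small RNA read filtering and summary statistics.

Filters run in a fixed order and a removed read is attributed to the first
filter it fails:

1. poly-N (``max_n`` or more Ns)
2. 5' adapter contaminant (read prefix matches the 5' adapter)
3. missing 3' adapter (no prefix-suffix overlap found; found adapters are
   trimmed off)
4. post-trim homopolymer (pure poly-A/U/G/C by default)
5. low mean base quality
6. post-trim length outside the accepted window

Thresholds are deliberate defaults for small RNA practice and are all
exposed on :class:`QCParams`.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from ._util import to_rna

FILTER_ORDER = (
    "poly_n",
    "adapter5_contaminant",
    "no_adapter3",
    "homopolymer",
    "low_quality",
    "length",
)

REPORT_BASES = "AUCG"  # reporting order; U stands for U/T


@dataclass
class SmallRNARead:
    id: str
    sequence: str
    quality: list[int] | None = None
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id}: quality/sequence length mismatch")


@dataclass(frozen=True)
class QCParams:
    max_n: int = 1  # any N at all fails by default
    min_adapter_overlap: int = 6
    adapter_mismatches: int = 1
    homopolymer_frac: float = 1.0
    min_mean_q: float = 20.0
    min_len: int = 18
    max_len: int = 32


@dataclass
class QCReport:
    total_reads: int = 0
    removed_per_filter: dict[str, int] = field(
        default_factory=lambda: {f: 0 for f in FILTER_ORDER}
    )
    clean_reads: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)
    base_frequency: list[list[float]] | None = None  # 4 x L, rows A/U/C/G

    def check(self) -> None:
        removed = sum(self.removed_per_filter.values())
        if self.clean_reads + removed != self.total_reads:
            raise AssertionError("read count not conserved")

    def to_json(self, path: str | Path) -> None:
        self.check()
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def parse_fastq(path: str | Path) -> Iterator[SmallRNARead]:
    """Sanger-quality FASTQ parser yielding :class:`SmallRNARead`."""
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record at index {idx}")
            if len(qual) != len(seq):
                raise ValueError(f"malformed FASTQ record at index {idx}")
            yield SmallRNARead(
                id=header[1:].split()[0],
                sequence=seq.upper(),
                quality=[ord(c) - 33 for c in qual],
            )
            idx += 1


def parse_fasta(path: str | Path) -> Iterator[SmallRNARead]:
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        yield SmallRNARead(id=rec.id, sequence=str(rec.seq).upper())


def _hamming_leq(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def locate_adapter3(
    sequence: str, adapter_3p: str, params: QCParams
) -> int | None:
    """Best 3' adapter start within the read, or None.

    Considers every suffix of the read against a prefix of the adapter with
    overlap >= ``min_adapter_overlap``; candidates rank by (mismatches,
    -overlap, position).
    """
    best: tuple[int, int, int] | None = None
    n = len(sequence)
    for start in range(0, n - params.min_adapter_overlap + 1):
        overlap = min(n - start, len(adapter_3p))
        if overlap < params.min_adapter_overlap:
            break
        window = sequence[start : start + overlap]
        mism = sum(x != y for x, y in zip(window, adapter_3p))
        if mism <= params.adapter_mismatches:
            key = (mism, -overlap, start)
            if best is None or key < best:
                best = key
    return None if best is None else best[2]


def _first_failure(
    read: SmallRNARead, adapter_3p: str, adapter_5p: str | None, params: QCParams
) -> tuple[str | None, SmallRNARead]:
    seq = read.sequence
    if seq.count("N") >= params.max_n:
        return "poly_n", read
    if adapter_5p and len(seq) >= len(adapter_5p) and _hamming_leq(
        seq[: len(adapter_5p)], adapter_5p, params.adapter_mismatches
    ):
        return "adapter5_contaminant", read
    start = locate_adapter3(seq, adapter_3p, params)
    if start is None or start == 0:
        return "no_adapter3", read
    trimmed = SmallRNARead(
        id=read.id,
        sequence=seq[:start],
        quality=read.quality[:start] if read.quality is not None else None,
    )
    counts = Counter(to_rna(trimmed.sequence))
    if max(counts.values()) >= params.homopolymer_frac * len(trimmed.sequence):
        return "homopolymer", trimmed
    if trimmed.quality is not None and np.mean(trimmed.quality) < params.min_mean_q:
        return "low_quality", trimmed
    if not params.min_len <= len(trimmed.sequence) <= params.max_len:
        return "length", trimmed
    return None, trimmed


def filter_reads(
    reads: Iterable[SmallRNARead],
    adapter_3p: str,
    adapter_5p: str | None = None,
    params: QCParams | None = None,
) -> tuple[list[SmallRNARead], QCReport]:
    """Apply the filter cascade; returns clean trimmed reads and a report."""
    if not adapter_3p:
        raise ValueError("3' adapter must be non-empty")
    adapter_3p = adapter_3p.upper().replace("U", "T")
    if adapter_5p:
        adapter_5p = adapter_5p.upper().replace("U", "T")
    params = params or QCParams()

    report = QCReport()
    clean: list[SmallRNARead] = []
    for read in reads:
        report.total_reads += 1
        failure, out = _first_failure(read, adapter_3p, adapter_5p, params)
        if failure is None:
            clean.append(out)
        else:
            report.removed_per_filter[failure] += 1
    report.clean_reads = len(clean)
    report.length_histogram = length_distribution(clean) if clean else {}
    if clean:
        report.base_frequency = first_base_profile(clean).tolist()
    report.check()
    return clean, report


def length_distribution(clean_reads: list[SmallRNARead]) -> dict[int, int]:
    if not clean_reads:
        raise ValueError("no reads after filtering")
    hist = Counter(len(r.sequence) for r in clean_reads)
    return dict(sorted(hist.items()))


def first_base_profile(
    clean_reads: list[SmallRNARead], positions: int | None = None
) -> np.ndarray:
    """4 x L per-position base frequency matrix (rows A, U, C, G).

    Column j uses only the reads of length >= j+1, so every column sums to 1.
    """
    if not clean_reads:
        raise ValueError("no reads to profile")
    length = positions or max(len(r.sequence) for r in clean_reads)
    counts = np.zeros((4, length))
    index = {b: i for i, b in enumerate(REPORT_BASES)}
    for read in clean_reads:
        seq = to_rna(read.sequence)
        for j, base in enumerate(seq[:length]):
            counts[index[base], j] += 1
    totals = counts.sum(axis=0)
    totals[totals == 0] = 1.0
    return counts / totals


def write_clean_fasta(reads: list[SmallRNARead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.id}\n{read.sequence}\n")
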