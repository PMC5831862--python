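"""Cluster mature miRNAs into families by seed-anchored ungapped similarity.

Two mature sequences belong to the same family when they admit an ungapped
overlap of at least ``min_overlap`` nucleotides with at most ``max_mismatches``
substitutions, a relative 5'-end offset of at most ``max_overhang``, and the
overlap covering the seed region (positions 2-8) of both sequences.  Families
are the connected components of the resulting match graph (single linkage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from ._util import to_rna, validate_rna

SEED_START = 1  # 0-based, inclusive: position 2
SEED_END = 8  # 0-based, exclusive: position 8


@dataclass(frozen=True)
class MatureMiRNA:
    """One mature miRNA sequence tagged with its species of origin."""

    id: str
    species: str
    sequence: str
    known_or_novel: str = "known"

    def __post_init__(self) -> None:
        seq = validate_rna(self.sequence, context=f"miRNA {self.id}")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 15:
            raise ValueError(f"miRNA {self.id}: sequence shorter than 15 nt")


@dataclass(frozen=True)
class MatchParams:
    min_overlap: int = 15
    max_mismatches: int = 2
    max_overhang: int = 1
    seed_cover_both: bool = True  # require seed coverage on both sequences


@dataclass(frozen=True)
class MatchResult:
    matched: bool
    offset: int | None = None
    mismatches: int | None = None


@dataclass
class FamilyPartition:
    """Disjoint families covering every input miRNA exactly once."""

    members: dict[str, list[str]] = field(default_factory=dict)
    species: dict[str, set[str]] = field(default_factory=dict)

    @property
    def n_families(self) -> int:
        return len(self.members)

    def family_of(self) -> dict[str, str]:
        return {m: fam for fam, ms in self.members.items() for m in ms}


def _offset_alignment(a: str, b: str, offset: int) -> tuple[int, int, int, int]:
    """Aligned coordinates for a given relative 5' offset.

    ``offset`` is the position of b's 5' end on a's coordinates: with
    offset=+1 b starts one base inside a; with offset=-1 a starts one base
    inside b.  Returns (a_start, b_start, overlap, n/a placeholder).
    """
    if offset >= 0:
        a_start, b_start = offset, 0
    else:
        a_start, b_start = 0, -offset
    overlap = min(len(a) - a_start, len(b) - b_start)
    return a_start, b_start, overlap, 0


def pairwise_match(
    a: MatureMiRNA | str, b: MatureMiRNA | str, params: MatchParams | None = None
) -> MatchResult:
    """Ungapped seed-anchored match test between two mature sequences.

    Scans all 5' offsets in ``[-max_overhang, +max_overhang]`` and accepts the
    pair if some offset yields overlap >= min_overlap, <= max_mismatches
    substitutions within the overlap, and the overlap covers positions 2-8 of
    both sequences (of sequence ``a`` only when ``seed_cover_both`` is off).
    Ties between passing offsets break by fewest mismatches, then offset 0.
    """
    params = params or MatchParams()
    sa = a.sequence if isinstance(a, MatureMiRNA) else validate_rna(a)
    sb = b.sequence if isinstance(b, MatureMiRNA) else validate_rna(b)

    best: tuple[int, int] | None = None  # (mismatches, |offset| ranking key)
    best_off: int | None = None
    for offset in range(-params.max_overhang, params.max_overhang + 1):
        a_start, b_start, overlap, _ = _offset_alignment(sa, sb, offset)
        if overlap < params.min_overlap:
            continue
        # seed coverage: aligned window must span positions 2-8 (0-based 1..7)
        if not (a_start <= SEED_START and a_start + overlap >= SEED_END):
            continue
        if params.seed_cover_both and not (
            b_start <= SEED_START and b_start + overlap >= SEED_END
        ):
            continue
        mism = sum(
            sa[a_start + i] != sb[b_start + i] for i in range(overlap)
        )
        if mism > params.max_mismatches:
            continue
        key = (mism, abs(offset))
        if best is None or key < best:
            best, best_off = key, offset
    if best is None:
        return MatchResult(False)
    return MatchResult(True, offset=best_off, mismatches=best[0])


def build_families(
    mirnas: Sequence[MatureMiRNA], params: MatchParams | None = None
) -> FamilyPartition:
    """Single-linkage clustering: connected components of the match graph.

    Family ids are the lexicographically smallest member id, so the partition
    is independent of input order.
    """
    if not mirnas:
        raise ValueError("need at least one miRNA")
    ids = [m.id for m in mirnas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate miRNA ids")
    params = params or MatchParams()

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    by_id = {m.id: m for m in mirnas}
    for i, mi in enumerate(mirnas):
        for mj in mirnas[i + 1 :]:
            if pairwise_match(mi, mj, params).matched:
                graph.add_edge(mi.id, mj.id)

    partition = FamilyPartition()
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        fam_id = members[0]
        partition.members[fam_id] = members
        partition.species[fam_id] = {by_id[m].species for m in members}
    partition.members = dict(sorted(partition.members.items()))
    partition.species = {f: partition.species[f] for f in partition.members}
    return partition


def presence_absence(
    partition: FamilyPartition, species_list: Sequence[str]
) -> pd.DataFrame:
    """Binary families x species matrix; entry 1 iff the family has a member
    from that species.  Species contributing no miRNAs yield all-zero columns.
    """
    seen = set().union(*partition.species.values()) if partition.species else set()
    unknown = seen - set(species_list)
    if unknown:
        raise ValueError(f"species not in species_list: {sorted(unknown)}")
    rows = {
        fam: [1 if sp in spset else 0 for sp in species_list]
        for fam, spset in partition.species.items()
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(species_list), dtype=int
    )


def read_catalog(paths: Iterable[str | Path]) -> list[MatureMiRNA]:
    """Read species-tagged FASTA catalogs with ``>id|species`` headers."""
    from Bio import SeqIO

    mirnas: list[MatureMiRNA] = []
    for path in paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            if "|" not in rec.id:
                raise ValueError(
                    f"{path}: header {rec.id!r} lacks '|species' tag"
                )
            mid, species = rec.id.rsplit("|", 1)
            mirnas.append(MatureMiRNA(mid, species, to_rna(str(rec.seq))))
    return mirnas


def write_partition(partition: FamilyPartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tmember\tspecies_count\n")
        for fam, members in partition.members.items():
            for m in members:
                fh.write(f"{fam}\t{m}\t{len(partition.species[fam])}\n")
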