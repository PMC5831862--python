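"""Synthetic inputs with planted ground truth for every pipeline stage.

Everything is driven by :class:`SimulationConfig` and a single integer seed;
identical config + seed yields byte-identical files.  Per-category read
counts are allocated deterministically by largest-remainder rounding so that
count assertions against the ground truth are exact; only ordering and
sequence content are randomized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import revcomp_dna, to_rna
from .families import MatchParams, MatureMiRNA

DNA = "ACGT"

# categories whose reads survive QC and are classified downstream
CLEAN_CATEGORIES = (
    "miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "repeat",
    "exon",
    "intron",
    "other",
)
# categories removed by the QC cascade
CONTAMINANT_CATEGORIES = (
    "polyN",
    "adapter5",
    "no_adapter3",
    "homopolymer",
    "low_quality",
)
ALL_CATEGORIES = CLEAN_CATEGORIES + CONTAMINANT_CATEGORIES

# category -> annotation reference FASTA stem used by the classifier
ANNOTATION_OF = {
    "miRNA": "known_miRNA",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "repeat": "repeat",
    "exon": "exon",
    "intron": "intron",
}

DEFAULT_MIXTURE = {
    "miRNA": 0.40,
    "rRNA": 0.10,
    "tRNA": 0.06,
    "snRNA": 0.03,
    "snoRNA": 0.03,
    "repeat": 0.05,
    "exon": 0.06,
    "intron": 0.05,
    "other": 0.07,
    "polyN": 0.03,
    "adapter5": 0.03,
    "no_adapter3": 0.04,
    "homopolymer": 0.02,
    "low_quality": 0.03,
}

# 17-leaf metazoan topology with named internal nodes.  This stands in for
# the study tree, which is an input, not an output, of the method.
DEFAULT_TREE_NEWICK = (
    "(Amphimedon_queenslandica,(Nematostella_vectensis,((Lottia_gigantea,"
    "(Drosophila_melanogaster,Caenorhabditis_elegans)Ecdysozoa)Protostomia,"
    "((Strongylocentrotus_purpuratus,Saccoglossus_kowalevskii)Ambulacraria,"
    "(Branchiostoma_floridae,((Danio_rerio,(Xenopus_tropicalis,(Gallus_gallus,"
    "(Mus_musculus,Homo_sapiens)Mammalia_like)Amniota)Tetrapoda)Vertebrata,"
    "(Oikopleura_dioica,(Halocynthia_roretzi,(Ciona_intestinalis,"
    "Ciona_savignyi)Ciona)Ascidiacea)Tunicata)Olfactores)Chordata)"
    "Deuterostomia)Nephrozoa)Eumetazoa)Metazoa;"
)

DEFAULT_STAGES = (18, 21, 42)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_species: int = 17
    n_families: int = 50
    gain_rate: float = 0.5  # weight toward internal (vs terminal) gains
    loss_rate: float = 0.1
    read_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    n_reads: int = 10_000
    adapter_3p: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter_5p: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    first_base_u_bias: float = 0.8
    n_mirnas: int = 50  # size of the known mature catalog behind miRNA reads
    stages: tuple = DEFAULT_STAGES
    reference_stage: int = 18
    n_replicates: int = 3
    stage_effects: dict[str, dict] = field(default_factory=dict)
    ct_noise_sd: float = 0.1
    n_genes: int = 40

    def __post_init__(self) -> None:
        total = sum(self.read_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"read_mixture fractions sum to {total}, not 1")
        unknown = set(self.read_mixture) - set(ALL_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown read categories: {sorted(unknown)}")
        for name in ("loss_rate", "gain_rate", "first_base_u_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    read_category: dict[str, str] = field(default_factory=dict)
    family_gain: dict[str, str] = field(default_factory=dict)
    family_losses: dict[str, frozenset[str]] = field(default_factory=dict)
    family_members: dict[str, list[str]] = field(default_factory=dict)
    stage_effects: dict[str, dict] = field(default_factory=dict)
    target_pairs: dict[tuple[str, str], str] = field(default_factory=dict)
    kept_pairs: set[tuple[str, str]] = field(default_factory=set)


def largest_remainder(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Integer allocation of n items by fractions, exact by construction."""
    raw = {k: f * n for k, f in fractions.items()}
    counts = {k: math.floor(v) for k, v in raw.items()}
    shortfall = n - sum(counts.values())
    order = sorted(raw, key=lambda k: (raw[k] - counts[k], k), reverse=True)
    for k in order[:shortfall]:
        counts[k] += 1
    return counts


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA), size=length))


# ---------------------------------------------------------------------------
# family history on the tree


def gen_family_history(tree, config: SimulationConfig):
    """Evolve families on a species tree: single gain, per-branch losses.

    Returns the presence/absence matrix (families x leaves) and a
    :class:`GroundTruth` carrying gain node and loss branches per family.
    All-absent families are discarded and regenerated.
    """
    from .dollo import SpeciesTree

    if not isinstance(tree, SpeciesTree):
        tree = SpeciesTree.from_newick(tree)
    rng = np.random.default_rng(config.seed)
    nodes = tree.node_names()
    internal = [n for n in nodes if not tree.node(n).is_leaf()]
    leaves = tree.leaves
    if len(leaves) < 2:
        raise ValueError("degenerate tree")

    truth = GroundTruth()
    rows = {}
    fam_idx = 0
    while fam_idx < config.n_families:
        if rng.random() < config.gain_rate or not leaves:
            gain = internal[rng.integers(len(internal))]
        else:
            gain = leaves[rng.integers(len(leaves))]
        present, losses = _replay_history(tree, gain, config.loss_rate, rng)
        if not present:
            continue  # extinct everywhere: regenerate
        fam = f"fam{fam_idx:04d}"
        rows[fam] = [1 if sp in present else 0 for sp in leaves]
        truth.family_gain[fam] = gain
        truth.family_losses[fam] = frozenset(losses)
        fam_idx += 1
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=leaves, dtype=int)
    return matrix, truth


def _replay_history(tree, gain: str, loss_rate: float, rng) -> tuple[set, set]:
    """Simulate losses below the gain node; a lost subtree stays lost."""
    present: set[str] = set()
    losses: set[str] = set()

    def walk(node) -> None:
        if node.is_leaf():
            present.add(node.taxon.label)
            return
        for child in node.child_nodes():
            if rng.random() < loss_rate:
                losses.add(tree.node_name(child))
            else:
                walk(child)

    gnode = tree.node(gain)
    walk(gnode)
    # prune loss events that ended up redundant (none possible here since a
    # lost subtree is never descended), then drop losses with no effect
    return present, losses


# ---------------------------------------------------------------------------
# mature sequences per family


def gen_family_sequences(
    matrix: pd.DataFrame,
    config: SimulationConfig,
    match_params: MatchParams | None = None,
    per_species_mutations: int = 1,
    min_cross_mismatches: int = 6,
) -> list[MatureMiRNA]:
    """Species-tagged mature catalogs realizing a presence/absence matrix.

    Within a family every species carries a variant of a family consensus
    with at most ``per_species_mutations`` substitutions, so any two members
    differ by at most twice that (2 by default, satisfying the family match
    predicate).  Consensus sequences of different families are rejected until
    they differ by at least ``min_cross_mismatches`` at every 5' offset in
    {-2..2}, so no cross-family pair can pass the predicate even after
    per-species mutation.
    """
    rng = np.random.default_rng(config.seed + 1)
    match_params = match_params or MatchParams()
    consensi: dict[str, str] = {}
    mirnas: list[MatureMiRNA] = []
    for fam, row in matrix.iterrows():
        length = int(rng.integers(21, 25))  # 21-24 nt
        for _attempt in range(10_000):
            cand = _random_dna(rng, length)
            if all(
                _min_offset_mismatches(cand, other) >= min_cross_mismatches
                for other in consensi.values()
            ):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not place a distinct family consensus")
        consensi[str(fam)] = cand
        for species in matrix.columns:
            if not row[species]:
                continue
            seq = list(cand)
            n_mut = int(rng.integers(0, per_species_mutations + 1))
            for pos in rng.choice(length, size=n_mut, replace=False):
                alternatives = [b for b in DNA if b != seq[pos]]
                seq[pos] = alternatives[rng.integers(3)]
            mirnas.append(
                MatureMiRNA(
                    id=f"{fam}_{species}",
                    species=species,
                    sequence=to_rna("".join(seq)),
                    known_or_novel="known",
                )
            )
    return mirnas


def _min_offset_mismatches(a: str, b: str, max_shift: int = 2) -> int:
    """Minimum mismatch count over 5' offsets in [-max_shift, max_shift],
    counted within the overlap."""
    best = min(len(a), len(b))
    for offset in range(-max_shift, max_shift + 1):
        if offset >= 0:
            wa, wb = a[offset:], b
        else:
            wa, wb = a, b[-offset:]
        overlap = min(len(wa), len(wb))
        if overlap < 10:
            continue
        mism = sum(x != y for x, y in zip(wa[:overlap], wb[:overlap]))
        best = min(best, mism)
    return best


def write_catalogs(mirnas: list[MatureMiRNA], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in mirnas:
            fh.write(f">{m.id}|{m.species}\n{m.sequence}\n")


# ---------------------------------------------------------------------------
# reads


@dataclass
class ReadSet:
    records: list[tuple[str, str, str]]  # (id, sequence, quality string)
    references: dict[str, list[str]]  # annotation category -> reference seqs
    truth: GroundTruth


def _ref_annotations(rng: np.random.Generator, config: SimulationConfig):
    """Reference sequences per annotation category, mutually substring-free."""
    refs: dict[str, list[str]] = {}
    mature_pool: list[str] = []
    n_u = round(config.first_base_u_bias * config.n_mirnas)
    for i in range(config.n_mirnas):
        first = "T" if i < n_u else rng.choice(["A", "C", "G"])
        body = _random_dna(rng, int(rng.integers(21, 25)) - 1)
        mature_pool.append(first + body)
    refs["known_miRNA"] = mature_pool
    for cat in ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon", "intron"):
        refs[cat] = [_random_dna(rng, 600) for _ in range(2)]
    return refs


def _substring_of_any(seq: str, refs: dict[str, list[str]], skip: str | None = None):
    rc = revcomp_dna(seq)
    for cat, seqs in refs.items():
        if cat == skip:
            continue
        for ref in seqs:
            if seq in ref or rc in ref:
                return cat
    return None


def gen_reads(config: SimulationConfig) -> ReadSet:
    """Planted FASTQ read mixture plus annotation references and truth.

    Per-category counts follow the config fractions exactly; only the read
    order is shuffled.  Clean-category inserts are guaranteed to classify to
    their planted annotation category (and contaminants to their planted QC
    filter) by construction.
    """
    if config.n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not config.adapter_3p or not config.adapter_5p:
        raise ValueError("adapters must be non-empty")
    rng = np.random.default_rng(config.seed + 2)
    refs = _ref_annotations(rng, config)
    counts = largest_remainder(config.read_mixture, config.n_reads)

    a3 = config.adapter_3p.upper()
    a5 = config.adapter_5p.upper()
    q_good = "I" * 200  # Q40
    q_bad = "$" * 200  # Q3

    records: list[tuple[str, str, str]] = []
    truth = GroundTruth()
    idx = 0
    for category in ALL_CATEGORIES:
        for _ in range(counts.get(category, 0)):
            rid = f"read{idx:06d}"
            idx += 1
            seq, qual = _make_read(rng, category, refs, a3, a5, q_good, q_bad)
            records.append((rid, seq, qual))
            truth.read_category[rid] = category
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth.read_category = dict(truth.read_category)  # ids keep their category
    return ReadSet(records=records, references=refs, truth=truth)


def _clean_insert(rng, category: str, refs, a5: str) -> str:
    """Insert that maps uniquely to its planted category (or nowhere)."""
    for _ in range(10_000):
        if category == "miRNA":
            pool = refs["known_miRNA"]
            seq = pool[rng.integers(len(pool))]
        elif category == "other":
            seq = _random_dna(rng, int(rng.integers(19, 29)))
        else:
            ref = refs[ANNOTATION_OF[category]][
                rng.integers(len(refs[ANNOTATION_OF[category]]))
            ]
            length = int(rng.integers(19, 29))
            start = int(rng.integers(0, len(ref) - length + 1))
            seq = ref[start : start + length]
            if category == "intron" and rng.random() < 0.5:
                seq = revcomp_dna(seq)  # exercise the antisense path
        skip = ANNOTATION_OF.get(category)
        hit = _substring_of_any(seq, refs, skip=skip)
        if category == "other" and hit is not None:
            continue
        if category != "other" and hit is not None:
            continue  # would collide with a higher/lower priority category
        if len(set(seq)) == 1:
            continue  # would trip the homopolymer filter
        if _prefix_matches(seq, a5):
            continue
        return seq
    raise RuntimeError(f"could not build a clean {category} insert")


def _prefix_matches(seq: str, adapter: str, mismatches: int = 1) -> bool:
    if len(seq) < len(adapter):
        return False
    return sum(x != y for x, y in zip(seq, adapter)) <= mismatches


def _tail_without_adapter(rng, length: int, a3: str, min_overlap: int = 6) -> str:
    """Random tail whose suffix alignment with the adapter never matches."""
    for _ in range(10_000):
        tail = _random_dna(rng, length)
        if _find_overlap(tail, a3, min_overlap) is None:
            return tail
    raise RuntimeError("could not build an adapter-free tail")


def _find_overlap(seq: str, adapter: str, min_overlap: int, mismatches: int = 1):
    for start in range(0, len(seq) - min_overlap + 1):
        overlap = min(len(seq) - start, len(adapter))
        window = seq[start : start + overlap]
        if sum(x != y for x, y in zip(window, adapter)) <= mismatches:
            return start
    return None


def _make_read(rng, category, refs, a3, a5, q_good, q_bad):
    if category == "polyN":
        insert = _clean_insert(rng, "other", refs, a5)
        pos = int(rng.integers(len(insert)))
        insert = insert[:pos] + "N" * int(rng.integers(1, 4)) + insert[pos + 1 :]
        seq = insert + a3
    elif category == "adapter5":
        insert = _clean_insert(rng, "other", refs, a5)
        seq = a5 + insert + a3
    elif category == "no_adapter3":
        insert = _clean_insert(rng, "other", refs, a5)
        seq = insert + _tail_without_adapter(rng, len(a3), a3)
        if _find_overlap(seq, a3, 6) is not None:
            # insert/tail junction formed an adapter-like window; retry
            return _make_read(rng, category, refs, a3, a5, q_good, q_bad)
    elif category == "homopolymer":
        base = "ACGT"[rng.integers(4)]
        length = int(rng.integers(19, 29))
        seq = base * length + a3
        if _prefix_matches(base * length, a5):  # pragma: no cover
            return _make_read(rng, category, refs, a3, a5, q_good, q_bad)
    elif category == "low_quality":
        insert = _clean_insert(rng, "other", refs, a5)
        seq = insert + a3
        return seq, q_bad[: len(seq)]
    else:
        insert = _clean_insert(rng, category, refs, a5)
        seq = insert + a3
    return seq, q_good[: len(seq)]


def write_fastq(read_set: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in read_set.records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_references(read_set: ReadSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cat, seqs in read_set.references.items():
        with open(directory / f"{cat}.fasta", "w") as fh:
            for i, seq in enumerate(seqs):
                fh.write(f">{cat}_{i}\n{seq}\n")


def write_read_truth(read_set: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcategory\n")
        for rid in sorted(read_set.truth.read_category):
            fh.write(f"{rid}\t{read_set.truth.read_category[rid]}\n")


# ---------------------------------------------------------------------------
# expression


def gen_expression(
    config: SimulationConfig, mirna_ids: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Ct table with U6 reference rows plus a stage count matrix.

    ``stage_effects`` maps miRNA -> {stage: fold change relative to the
    reference stage}; the reference gene has no stage effect by definition.
    With zero noise, 2^-ddCt equals the planted fold change exactly.
    """
    if len(config.stages) < 2:
        raise ValueError("need at least two stages")
    if config.n_replicates < 2:
        raise ValueError("need at least two replicates")
    rng = np.random.default_rng(config.seed + 3)
    if mirna_ids is None:
        mirna_ids = sorted(config.stage_effects) or [
            f"mir{i:03d}" for i in range(10)
        ]

    truth = GroundTruth()
    rows = []
    u6_base = 18.0
    for stage in config.stages:
        for rep in range(1, config.n_replicates + 1):
            ct = u6_base + rng.normal(0, config.ct_noise_sd)
            rows.append(
                {"mirna": "U6", "stage": stage, "replicate": rep, "ct": ct}
            )
    count_rows = {}
    for mid in mirna_ids:
        effects = config.stage_effects.get(mid, {})
        truth.stage_effects[mid] = {
            s: float(effects.get(s, 1.0)) for s in config.stages
        }
        base_ct = float(rng.uniform(22, 30))
        profile = []
        for stage in config.stages:
            fold = truth.stage_effects[mid][stage]
            if fold <= 0:
                raise ValueError("stage effects must be positive fold changes")
            for rep in range(1, config.n_replicates + 1):
                ct = base_ct - math.log2(fold) + rng.normal(0, config.ct_noise_sd)
                rows.append(
                    {"mirna": mid, "stage": stage, "replicate": rep, "ct": ct}
                )
            profile.append(1000.0 * fold)
        count_rows[mid] = profile
    ct_table = pd.DataFrame(rows)
    count_matrix = pd.DataFrame.from_dict(
        count_rows, orient="index", columns=[str(s) for s in config.stages]
    )
    count_matrix.index.name = "mirna"
    return ct_table, count_matrix, truth


# ---------------------------------------------------------------------------
# prediction tables


def gen_prediction_tables(
    config: SimulationConfig,
    n_both: int = 10,
    n_a_neg: int = 5,
    n_a_pos: int = 5,
    n_b_only: int = 5,
):
    """Two predictor tables plus stage profiles with four planted pair
    classes; the truth records which pairs the integration rule must keep
    (both-predictor and A-only anti-correlated ones).
    """
    if config.n_genes < 10:
        raise ValueError("gene universe must hold at least 10 genes")
    rng = np.random.default_rng(config.seed + 4)
    n_pairs = n_both + n_a_neg + n_a_pos + n_b_only
    if n_pairs > config.n_genes:
        raise ValueError("not enough genes for the requested pair classes")

    mirnas = [f"mir{i:03d}" for i in range(max(3, n_pairs // 5 + 1))]
    genes = [f"gene{i:03d}" for i in range(config.n_genes)]
    gene_pool = list(rng.permutation(genes))

    stages = [str(s) for s in config.stages]
    mirna_profiles = {
        m: rng.uniform(1, 10, size=len(stages)) for m in mirnas
    }
    # ensure non-constant profiles
    for m, v in mirna_profiles.items():
        v[0] += 1.0

    truth = GroundTruth()
    rows_a, rows_b = [], []
    gene_profiles: dict[str, np.ndarray] = {}

    def take_gene() -> str:
        return gene_pool.pop()

    def add_pair(table_rows, mirna, gene):
        table_rows.append(
            {
                "mirna": mirna,
                "gene": gene,
                "score": float(np.round(rng.uniform(50, 100), 2)),
                "energy": float(np.round(-rng.uniform(5, 30), 2)),
            }
        )

    for cls, n in (
        ("both", n_both),
        ("a_only_neg", n_a_neg),
        ("a_only_pos", n_a_pos),
        ("b_only", n_b_only),
    ):
        for _ in range(n):
            mirna = mirnas[rng.integers(len(mirnas))]
            gene = take_gene()
            mp = mirna_profiles[mirna]
            if cls in ("both", "b_only"):
                gene_profiles[gene] = rng.uniform(1, 10, size=len(stages))
            elif cls == "a_only_neg":
                gene_profiles[gene] = float(mp.max() + mp.min()) - mp  # r = -1
            else:
                gene_profiles[gene] = mp * 2.0 + 1.0  # r = +1
            if cls in ("both", "a_only_neg", "a_only_pos"):
                add_pair(rows_a, mirna, gene)
            if cls in ("both", "b_only"):
                add_pair(rows_b, mirna, gene)
            truth.target_pairs[(mirna, gene)] = cls
            if cls in ("both", "a_only_neg"):
                truth.kept_pairs.add((mirna, gene))

    for gene in gene_pool:  # background genes, uncorrelated
        gene_profiles[gene] = rng.uniform(1, 10, size=len(stages))

    table_a = pd.DataFrame(rows_a)
    table_b = pd.DataFrame(rows_b)
    mirna_df = pd.DataFrame(mirna_profiles).T
    mirna_df.columns = stages
    mirna_df.index.name = "mirna"
    gene_df = pd.DataFrame({g: gene_profiles[g] for g in sorted(gene_profiles)}).T
    gene_df.columns = stages
    gene_df.index.name = "gene"
    return table_a, table_b, mirna_df, gene_df, truth


def gen_gene_sets(
    config: SimulationConfig, kept_genes: set[str], n_sets: int = 5
) -> dict[str, set[str]]:
    """GMT-style gene sets: one enriched in the kept target genes, the rest
    random."""
    rng = np.random.default_rng(config.seed + 5)
    genes = [f"gene{i:03d}" for i in range(config.n_genes)]
    sets: dict[str, set[str]] = {}
    enriched = set(
        rng.choice(sorted(kept_genes), size=min(5, len(kept_genes)), replace=False)
    ) if kept_genes else set()
    filler = [g for g in genes if g not in enriched]
    sets["pathway_enriched"] = enriched | set(
        rng.choice(filler, size=3, replace=False)
    )
    for i in range(1, n_sets):
        sets[f"pathway_{i:02d}"] = set(
            rng.choice(genes, size=int(rng.integers(5, 12)), replace=False)
        )
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tsynthetic\t{members}\n")
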