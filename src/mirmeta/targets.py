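"""miRNA-target selection, seed-site scanning, network export, enrichment.

The integration rule keeps a (miRNA, gene) pair when it is predicted by both
predictor tables, or when it is predicted by table A and the gene's stage
expression profile is negatively correlated (Pearson r below ``max_r``) with
the miRNA's profile.  Table-B-only pairs never enter through the correlation
clause unless ``symmetric`` is set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import revcomp_rna, to_rna, validate_rna

SEED_START = 1  # miRNA position 2, 0-based inclusive
SEED_END = 8  # miRNA position 8, 0-based exclusive


@dataclass(frozen=True)
class SeedSite:
    gene: str
    start: int  # 0-based, half-open on the UTR
    end: int
    site_type: str
    matched: str


@dataclass(frozen=True)
class TargetEdge:
    mirna: str
    gene: str
    evidence: str  # overlap | anti_correlation | both
    correlation: float | None = None
    energy: float | None = None


@dataclass(frozen=True)
class IntegrationParams:
    max_r: float = 0.0
    symmetric: bool = False  # let table-B pairs use the correlation clause


def seed_sites(
    mirna_seq: str, utr_seq: str, gene: str = "", wobble: bool = False
) -> list[SeedSite]:
    """All UTR heptamers reverse-complementary to miRNA positions 2-8.

    Watson-Crick pairing only by default; ``wobble`` additionally accepts G:U
    pairs.  Positions ascend along the UTR.
    """
    mseq = validate_rna(mirna_seq, context="miRNA")
    useq = validate_rna(utr_seq, context="UTR")
    if len(useq) < SEED_END - SEED_START:
        raise ValueError("UTR shorter than the seed length")
    if len(mseq) < SEED_END:
        raise ValueError("miRNA shorter than 8 nt")
    seed = mseq[SEED_START:SEED_END]
    target = revcomp_rna(seed)
    width = len(target)
    sites = []
    for i in range(len(useq) - width + 1):
        window = useq[i : i + width]
        if wobble:
            # window pairs antiparallel with seed; check base by base
            ok = all(
                _pairs(sb, wb, wobble=True)
                for sb, wb in zip(seed, window[::-1])
            )
        else:
            ok = window == target
        if ok:
            sites.append(
                SeedSite(
                    gene=gene,
                    start=i,
                    end=i + width,
                    site_type="7mer-2-8",
                    matched=window,
                )
            )
    return sites


def _pairs(a: str, b: str, wobble: bool) -> bool:
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    if (a, b) in wc:
        return True
    return wobble and (a, b) in {("G", "U"), ("U", "G")}


def read_prediction_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"mirna", "gene"}
    if required - set(df.columns):
        raise ValueError("prediction table needs 'mirna' and 'gene' columns")
    if df.duplicated(["mirna", "gene"]).any():
        raise ValueError("duplicate (mirna, gene) rows in prediction table")
    if "energy" in df.columns:
        energies = df["energy"].dropna()
        if (energies > 0).any():
            raise ValueError("duplex free energy must be <= 0")
    return df


def read_profiles(path: str | Path) -> pd.DataFrame:
    """Stage-profile TSV: first column is the feature id, remaining columns
    are stages in order."""
    return pd.read_csv(path, sep="\t", index_col=0)


def integrate_targets(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    mirna_profiles: Mapping[str, Sequence[float]] | pd.DataFrame,
    gene_profiles: Mapping[str, Sequence[float]] | pd.DataFrame,
    params: IntegrationParams | None = None,
) -> list[TargetEdge]:
    """Apply the two-clause keep rule and annotate evidence per edge."""
    params = params or IntegrationParams()
    if isinstance(mirna_profiles, pd.DataFrame):
        mirna_profiles = {k: v.to_numpy() for k, v in mirna_profiles.iterrows()}
    if isinstance(gene_profiles, pd.DataFrame):
        gene_profiles = {k: v.to_numpy() for k, v in gene_profiles.iterrows()}

    pairs_a = set(zip(table_a["mirna"], table_a["gene"]))
    pairs_b = set(zip(table_b["mirna"], table_b["gene"]))
    energy: dict[tuple[str, str], float] = {}
    if "energy" in table_a.columns:
        for _, row in table_a.iterrows():
            if pd.notna(row["energy"]):
                energy[(row["mirna"], row["gene"])] = float(row["energy"])

    profile_len = min(
        (len(v) for v in list(mirna_profiles.values())[:1]), default=0
    )
    corr_enabled = True
    if profile_len < 3:
        warnings.warn(
            "stage profiles shorter than 3: correlation clause disabled",
            stacklevel=2,
        )
        corr_enabled = False

    corr_candidates = pairs_a if not params.symmetric else pairs_a | pairs_b
    edges = []
    for mirna, gene in sorted(pairs_a | pairs_b):
        overlap = (mirna, gene) in pairs_a and (mirna, gene) in pairs_b
        r: float | None = None
        anti = False
        if (
            corr_enabled
            and (mirna, gene) in corr_candidates
            and mirna in mirna_profiles
            and gene in gene_profiles
        ):
            mp = np.asarray(mirna_profiles[mirna], dtype=float)
            gp = np.asarray(gene_profiles[gene], dtype=float)
            if len(mp) != len(gp):
                raise ValueError("stage order mismatch between profile sets")
            if mp.std() > 0 and gp.std() > 0:
                r = float(stats.pearsonr(mp, gp).statistic)
                anti = r < params.max_r
        if not overlap and not anti:
            continue
        evidence = "both" if (overlap and anti) else (
            "overlap" if overlap else "anti_correlation"
        )
        edges.append(
            TargetEdge(
                mirna=mirna,
                gene=gene,
                evidence=evidence,
                correlation=r,
                energy=energy.get((mirna, gene)),
            )
        )
    return edges


def export_network(edges: Sequence[TargetEdge], path: str | Path) -> None:
    """Deterministic TSV edge list sorted by (mirna, gene)."""
    with open(path, "w") as fh:
        fh.write("mirna\tgene\tevidence\tcorrelation\tenergy\n")
        for e in sorted(edges, key=lambda e: (e.mirna, e.gene)):
            corr = "" if e.correlation is None else f"{e.correlation:.6g}"
            energy = "" if e.energy is None else f"{e.energy:.6g}"
            fh.write(f"{e.mirna}\t{e.gene}\t{e.evidence}\t{corr}\t{energy}\n")


def read_network(path: str | Path) -> list[TargetEdge]:
    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["mirna", "gene", "evidence"]:
            raise ValueError("not a mirmeta edge-list file")
        for line in fh:
            mirna, gene, evidence, corr, energy = line.rstrip("\n").split("\t")
            edges.append(
                TargetEdge(
                    mirna=mirna,
                    gene=gene,
                    evidence=evidence,
                    correlation=float(corr) if corr else None,
                    energy=float(energy) if energy else None,
                )
            )
    return edges


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def enrich(
    genes: set[str],
    gene_sets: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH adjustment.

    For each set S: p = P(X >= |genes & S|) with X ~ Hypergeom(N=|universe|,
    K=|S & universe|, n=|genes|).
    """
    if not universe:
        raise ValueError("empty universe")
    if not genes <= universe:
        raise ValueError("target genes must be a subset of the universe")
    rows = []
    for name, members in gene_sets.items():
        in_universe = members & universe
        overlap = genes & in_universe
        k, big_n, big_k, n = len(overlap), len(universe), len(in_universe), len(genes)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if k else 1.0
        rows.append(
            {
                "gene_set": name,
                "overlap": k,
                "set_size": big_k,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        from .expression import bh_adjust

        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
        table = table.sort_values(["p_value", "gene_set"]).reset_index(drop=True)
    return table
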