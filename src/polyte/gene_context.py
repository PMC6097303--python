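"""TE analytics in the vicinity of genes.

Closest flanking TE on each side of every gene, TE copies in 2-kb
promoters, per-subgenome family enrichment in promoters and in
coexpression modules (log2 of foreground vs background copy-percentage),
and conservation of the upstream flanking TE across homeolog triplets.
"""
from __future__ import annotations

from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .core import PolyteError

FLANK_COLUMNS = [
    "gene_id",
    "up_copy",
    "up_family",
    "up_dist",
    "down_copy",
    "down_family",
    "down_dist",
]


def _left_neighbor(tes: pd.DataFrame, boundary: int) -> Optional[pd.Series]:
    """TE starting before ``boundary`` with the largest end (ties: larger
    start, then copy_id)."""
    cand = tes[tes["start"] < boundary]
    if cand.empty:
        return None
    best = cand.sort_values(["end", "start", "copy_id"]).iloc[-1]
    return best


def _right_neighbor(tes: pd.DataFrame, boundary: int) -> Optional[pd.Series]:
    """TE ending after ``boundary`` with the smallest start (ties: smaller
    end, then copy_id)."""
    cand = tes[tes["end"] > boundary]
    if cand.empty:
        return None
    best = cand.sort_values(["start", "end", "copy_id"]).iloc[0]
    return best


def closest_flanking_te(genes: pd.DataFrame, tes: pd.DataFrame) -> pd.DataFrame:
    """Closest TE on each (strand-aware) side of every gene.

    Upstream is 5' of the TSS, downstream 3' of the TTS. Distances are
    gap lengths between nearest interval edges; a TE overlapping the gene
    boundary gives distance 0. Genes with no TE on a side get NA there.
    """
    rows = []
    tes_by_chrom = {c: g.reset_index(drop=True) for c, g in tes.groupby("chrom")}
    for gene in genes.itertuples(index=False):
        sub = tes_by_chrom.get(gene.chrom)
        left = right = None
        if sub is not None:
            left = _left_neighbor(sub, gene.start)
            right = _right_neighbor(sub, gene.end)
        ldist = max(0, gene.start - int(left["end"])) if left is not None else None
        rdist = max(0, int(right["start"]) - gene.end) if right is not None else None
        if gene.strand == "-":
            up, up_dist, down, down_dist = right, rdist, left, ldist
        else:
            up, up_dist, down, down_dist = left, ldist, right, rdist
        rows.append(
            (
                gene.gene_id,
                up["copy_id"] if up is not None else None,
                up["family"] if up is not None else None,
                up_dist,
                down["copy_id"] if down is not None else None,
                down["family"] if down is not None else None,
                down_dist,
            )
        )
    return pd.DataFrame(rows, columns=FLANK_COLUMNS)


def promoter_intervals(genes: pd.DataFrame, window: int = 2000) -> pd.DataFrame:
    """Strand-aware promoter interval ([TSS-window, TSS)) per gene,
    truncated at the chromosome start."""
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for gene in genes.itertuples(index=False):
        if gene.strand == "-":
            p_start, p_end = gene.end, gene.end + window
        else:
            p_start, p_end = max(0, gene.start - window), gene.start
        if p_end > p_start:
            rows.append((gene.gene_id, gene.chrom, p_start, p_end))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def promoter_te_copies(
    genes: pd.DataFrame, tes: pd.DataFrame, window: int = 2000
) -> pd.DataFrame:
    """TE copies entirely or partially (>= 1 bp overlap) inside promoters.

    Returns one row per (gene, copy) pair; a copy overlapping several
    promoters appears once per gene but is deduplicated by downstream
    per-subgenome counting.
    """
    promoters = promoter_intervals(genes, window)
    rows = []
    for chrom, prom in promoters.groupby("chrom"):
        sub = tes[tes["chrom"] == chrom].sort_values(["start", "end", "copy_id"])
        starts = sub["start"].to_numpy()
        for p in prom.itertuples(index=False):
            hi = np.searchsorted(starts, p.end, side="left")
            cand = sub.iloc[:hi]
            hit = cand[cand["end"] > p.start]
            for te in hit.itertuples(index=False):
                rows.append((p.gene_id, te.copy_id, te.family, chrom))
    return pd.DataFrame(rows, columns=["gene_id", "copy_id", "family", "chrom"])


def _percentages(counts: pd.Series) -> pd.Series:
    total = counts.sum()
    return counts / total * 100.0 if total else counts * 0.0


def promoter_enrichment(
    promoter_copies: pd.DataFrame,
    genome_copies: pd.DataFrame,
    min_copies: int = 500,
) -> pd.DataFrame:
    """Per-family, per-subgenome promoter enrichment log2 ratios.

    For each subgenome independently: the percentage of promoter-
    overlapping copies assigned to each family is compared to the
    family's percentage among all copies of that subgenome,
    ratio = log2(%fam_promoter / %fam_subgenome). Families with fewer
    than ``min_copies`` copies genome-wide are dropped.
    """
    from .core import subgenome_of

    genome_copies = genome_copies.assign(
        _sg=[subgenome_of(c) for c in genome_copies["chrom"]]
    )
    promoter_copies = promoter_copies.drop_duplicates("copy_id")
    promoter_copies = promoter_copies.assign(
        _sg=[subgenome_of(c) for c in promoter_copies["chrom"]]
    )
    stray = set(promoter_copies["copy_id"]) - set(genome_copies["copy_id"])
    assert not stray, "promoter copies must be a subset of genome copies"
    genome_wide = genome_copies.groupby("family").size()
    eligible = set(genome_wide[genome_wide >= min_copies].index)
    rows = []
    for sg, bg in genome_copies.groupby("_sg"):
        fg = promoter_copies[promoter_copies["_sg"] == sg]
        pct_bg = _percentages(bg.groupby("family").size())
        pct_fg = _percentages(fg.groupby("family").size())
        for fam in sorted(set(pct_bg.index)):
            if fam not in eligible:
                continue
            p_fg = float(pct_fg.get(fam, 0.0))
            p_bg = float(pct_bg.get(fam, 0.0))
            ratio = np.log2(p_fg / p_bg) if p_fg > 0 and p_bg > 0 else np.nan
            rows.append(
                (fam, sg, int(fg[fg["family"] == fam].shape[0]),
                 int(bg[bg["family"] == fam].shape[0]), p_fg, p_bg, ratio)
            )
    return pd.DataFrame(
        rows,
        columns=["family", "subgenome", "n_fg", "n_bg", "pct_fg", "pct_bg", "log2_ratio"],
    )


def module_enrichment(
    upstream_families: pd.DataFrame,
    modules: pd.DataFrame,
    min_module_genes: int = 1000,
    min_copies: int = 500,
    family_copy_counts: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Family enrichment of closest-upstream TEs per coexpression module.

    ``upstream_families`` has columns gene_id, family (the family of the
    closest TE 5' of each gene; genes lacking one are excluded from both
    foreground and background). ``modules`` has gene_id, module_id;
    unexpressed genes should carry their own module label. Modules with
    fewer than ``min_module_genes`` genes are skipped; families with
    fewer than ``min_copies`` genome-wide copies are dropped when counts
    are provided.
    """
    stray = set(modules["gene_id"]) - set(upstream_families["gene_id"])
    if stray:
        raise PolyteError(f"module genes absent from gene set: {sorted(stray)[:5]}")
    background = upstream_families.dropna(subset=["family"])
    pct_bg = _percentages(background.groupby("family").size())
    merged = modules.merge(background, on="gene_id", how="inner")
    rows = []
    for module_id, grp in merged.groupby("module_id"):
        n_genes = modules[modules["module_id"] == module_id].shape[0]
        if n_genes < min_module_genes:
            continue
        pct_fg = _percentages(grp.groupby("family").size())
        for fam in sorted(pct_bg.index):
            if family_copy_counts is not None and family_copy_counts.get(fam, 0) < min_copies:
                continue
            p_fg = float(pct_fg.get(fam, 0.0))
            p_bg = float(pct_bg.get(fam, 0.0))
            ratio = np.log2(p_fg / p_bg) if p_fg > 0 and p_bg > 0 else np.nan
            rows.append(
                (module_id, fam, int(grp[grp["family"] == fam].shape[0]),
                 int(background[background["family"] == fam].shape[0]), p_fg, p_bg, ratio)
            )
    return pd.DataFrame(
        rows,
        columns=["module_id", "family", "n_fg", "n_bg", "pct_fg", "pct_bg", "log2_ratio"],
    )


def triplet_flank_conservation(
    triplets: pd.DataFrame, flanks: pd.DataFrame
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Conservation of the upstream flanking TE family across homeolog
    triplets.

    Each 1:1:1 triplet is categorized by its three upstream flanking
    families: ``all_same`` (CNS candidate), ``two_same`` or
    ``all_different``; triplets with a missing upstream TE are
    ``incomplete``. Returns the per-triplet table plus summary fractions
    over complete triplets.
    """
    fam_by_gene = dict(zip(flanks["gene_id"], flanks["up_family"]))
    rows = []
    for t in triplets.itertuples(index=False):
        gids = [t.gene_A, t.gene_B, t.gene_D]
        if len(set(gids)) != 3 or any(pd.isna(g) for g in gids):
            rows.append((t.group_id, None, None, None, "rejected_not_1_1_1"))
            continue
        fams = [fam_by_gene.get(g) for g in gids]
        if any(f is None or (isinstance(f, float) and np.isnan(f)) for f in fams):
            rows.append((t.group_id, *fams, "incomplete"))
            continue
        distinct = len(set(fams))
        category = {1: "all_same", 2: "two_same", 3: "all_different"}[distinct]
        rows.append((t.group_id, *fams, category))
    out = pd.DataFrame(
        rows, columns=["group_id", "family_A", "family_B", "family_D", "category"]
    )
    complete = out[out["category"].isin(["all_same", "two_same", "all_different"])]
    n = len(complete)
    summary = {
        cat: (complete["category"] == cat).sum() / n if n else 0.0
        for cat in ("all_same", "two_same", "all_different")
    }
    summary["n_complete"] = float(n)
    return out, summary
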