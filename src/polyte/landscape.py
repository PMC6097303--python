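"""Genome-wide TE composition statistics across subgenomes.

Proportion tables (bp occupied and fraction of each subgenome per family
or superfamily), between-subgenome abundance ratios with balanced /
strong-difference flags, windowed family abundance profiles, and k-mer
repeat-coverage curves.
"""
from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import PolyteError, subgenome_of


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent [start, end) rows; returns merged array."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.asarray(intervals, dtype=np.int64)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    merged = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    return np.asarray(merged, dtype=np.int64)


def _subgenome_lengths(chrom_lengths: Mapping[str, int]) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for chrom, length in chrom_lengths.items():
        sg = subgenome_of(chrom)
        out[sg] = out.get(sg, 0) + length
    return out


def family_proportions(
    tes: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    by: str = "family",
) -> pd.DataFrame:
    """bp occupied, copy count and subgenome fraction per family (or
    superfamily) per subgenome.

    Overlapping copies of the same family are merged before measuring bp,
    so a region is never counted twice within one family track.
    """
    if by not in ("family", "superfamily"):
        raise ValueError("by must be 'family' or 'superfamily'")
    unknown = set(tes["chrom"]) - set(chrom_lengths)
    if unknown:
        raise PolyteError(f"TE copies on unknown chromosomes: {sorted(unknown)[:5]}")
    sg_len = _subgenome_lengths(chrom_lengths)
    tes = tes.assign(_sg=[subgenome_of(c) for c in tes["chrom"]])
    rows = []
    for (fam, sg), grp in tes.groupby([by, "_sg"]):
        bp = 0
        for _, sub in grp.groupby("chrom"):
            merged = merge_intervals(sub[["start", "end"]].to_numpy())
            bp += int((merged[:, 1] - merged[:, 0]).sum())
        rows.append((fam, sg, bp, len(grp), bp / sg_len[sg]))
    out = pd.DataFrame(rows, columns=[by, "subgenome", "bp", "n_copies", "fraction"])
    return out.sort_values([by, "subgenome"]).reset_index(drop=True)


def subgenome_ratios(
    proportions: pd.DataFrame,
    min_total_fraction: float = 0.001,
    strong_fold: float = 3.0,
    balanced_fold: float = 2.0,
) -> pd.DataFrame:
    """Pairwise A/B, A/D, B/D abundance ratios per family with flags.

    A family is *balanced* when every pairwise ratio stays within
    [1/balanced_fold, balanced_fold] and *strong* when some ratio reaches
    strong_fold (or its inverse). Families contributing less than
    ``min_total_fraction`` of the total genome are excluded from strong
    calls.
    """
    key = proportions.columns[0]
    piv_bp = proportions.pivot_table(index=key, columns="subgenome", values="bp", fill_value=0)
    piv_n = proportions.pivot_table(
        index=key, columns="subgenome", values="n_copies", fill_value=0
    )
    sg_len = {}
    for sg in "ABD":
        sub = proportions[proportions["subgenome"] == sg]
        nz = sub[sub["fraction"] > 0]
        if len(nz):
            sg_len[sg] = nz["bp"].iloc[0] / nz["fraction"].iloc[0]
    total_len = sum(sg_len.values())
    rows = []
    for fam in piv_bp.index:
        bp = {sg: float(piv_bp.loc[fam].get(sg, 0.0)) for sg in "ABD"}
        ratios = {}
        for a, b in (("A", "B"), ("A", "D"), ("B", "D")):
            ratios[f"{a}/{b}"] = bp[a] / bp[b] if bp[b] > 0 else float("inf")
        finite = [r for r in ratios.values() if np.isfinite(r) and r > 0]
        balanced = bool(finite) and all(
            1 / balanced_fold <= r <= balanced_fold for r in ratios.values()
        )
        total_fraction = sum(bp.values()) / total_len if total_len else 0.0
        eligible = total_fraction >= min_total_fraction
        strong = eligible and any(
            r >= strong_fold or (r > 0 and r <= 1 / strong_fold) for r in ratios.values()
        )
        comment = ""
        if strong:
            fracs = {sg: bp[sg] / sg_len[sg] if sg in sg_len else 0.0 for sg in "ABD"}
            lo = min(fracs, key=fracs.get)
            hi = max(fracs, key=fracs.get)
            mean_others = np.mean([v for k, v in fracs.items() if k != lo])
            if mean_others > 0 and fracs[lo] <= mean_others / strong_fold:
                comment = f"Depleted {lo}"
            else:
                comment = f"Enriched {hi}"
        rows.append(
            (
                fam,
                ratios["A/B"],
                ratios["A/D"],
                ratios["B/D"],
                int(piv_n.loc[fam].sum()),
                total_fraction,
                balanced,
                strong,
                comment,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            key,
            "A/B",
            "A/D",
            "B/D",
            "n_copies",
            "total_fraction",
            "balanced",
            "strong",
            "comment",
        ],
    ).sort_values(key).reset_index(drop=True)


def windowed_abundance(
    tes: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window: int = 30_000_000,
) -> pd.DataFrame:
    """Per-window kb occupied by each family in non-overlapping windows.

    Windows tile each chromosome from 0; a copy spanning a boundary
    contributes its overlap length to each window it touches.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_win = int(np.ceil(length / window))
        sub = tes[tes["chrom"] == chrom]
        acc: Dict[Tuple[str, int], int] = {}
        for row in sub.itertuples(index=False):
            w = row.start // window
            pos = row.start
            while pos < row.end:
                w_end = min((w + 1) * window, length)
                ov = min(row.end, w_end) - pos
                acc[(row.family, w)] = acc.get((row.family, w), 0) + ov
                pos = w_end
                w += 1
        fams = sorted({r.family for r in sub.itertuples(index=False)})
        for fam in fams:
            for w in range(n_win):
                rows.append(
                    (
                        chrom,
                        w * window,
                        min((w + 1) * window, length),
                        fam,
                        acc.get((fam, w), 0) / 1000.0,
                    )
                )
    return pd.DataFrame(rows, columns=["chrom", "win_start", "win_end", "family", "kb"])


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _canonical(kmer: str) -> str:
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def kmer_coverage(
    sequences: Mapping[str, str],
    k: int,
    thresholds: Sequence[int],
) -> pd.DataFrame:
    """Fraction of genome positions covered by repeated k-mers.

    k-mers are counted strand-collapsed (canonical form); windows
    containing N are skipped. A position is covered at occurrence
    threshold tau if at least one k-mer window overlapping it occurs >=
    tau times in the whole sequence set. Returns rows (k, threshold,
    coverage).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Dict[str, int] = {}
    windows: Dict[str, list] = {}
    total_positions = 0
    for name, seq in sequences.items():
        seq = seq.upper()
        total_positions += len(seq)
        kms = []
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                kms.append(None)
                continue
            c = _canonical(w)
            kms.append(c)
            counts[c] = counts.get(c, 0) + 1
        windows[name] = kms
    rows = []
    for tau in sorted(thresholds):
        covered = 0
        for name, seq in sequences.items():
            kms = windows[name]
            mask = np.zeros(len(seq) + 1, dtype=np.int32)
            for i, c in enumerate(kms):
                if c is not None and counts[c] >= tau:
                    mask[i] += 1
                    mask[i + k] -= 1
            covered += int(np.count_nonzero(np.cumsum(mask[:-1])))
        rows.append((k, tau, covered / total_positions if total_positions else 0.0))
    return pd.DataFrame(rows, columns=["k", "threshold", "coverage"])
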