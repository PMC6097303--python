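"""Full-length LTR retrotransposon (flLTR-RT) pipeline.

Takes structure-based candidates (LTRharvest-shaped table) plus their
protein domain hits, filters them down to canonical elements, classifies
them into Copia (RLC) / Gypsy (RLG) / unclassified (RLX) by internal
domain order, dates each insertion from the divergence of its two LTRs,
clusters elements into families/subfamilies at identity/coverage
stringencies, assigns subgenome specificity to clusters, and derives
age statistics (subfamily lifespans, persistence curves, density tracks).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment import (
    SaturationError,
    align_ltr_pair,
    alignment_stats,
    estimate_age,
    kimura2p_distance,
    make_aligner,
)
from .core import DEFAULT_MUTATION_RATE, PolyteError, subgenome_of

# Canonical internal domain orders (5'->3'): Copia vs Gypsy.
RLC_ORDER = ("INT", "RT", "RH")
RLG_ORDER = ("RH", "RT", "INT")
RETRO_DOMAIN_SET = frozenset({"GAG", "PROT", "INT", "RT", "RH"})
CORE_DOMAIN_SET = frozenset({"INT", "RT", "RH"})

# Rejection reason tokens emitted by filter_canonical.
REASON_NO_DOMAIN = "no_retro_domain"
REASON_INCONSISTENT = "inconsistent_domains"
REASON_GENE = "gene_domain"
REASON_STRAND = "strand_inconsistency"
REASON_TANDEM = "tandem_repeats"
REASON_LTR_SIZE = "ltr_oversized"
REASON_N = "n_content"
ALL_REASONS = (
    REASON_NO_DOMAIN,
    REASON_INCONSISTENT,
    REASON_GENE,
    REASON_STRAND,
    REASON_TANDEM,
    REASON_LTR_SIZE,
    REASON_N,
)


@dataclass
class FilterParams:
    """Thresholds of the canonical-element filter."""

    max_tandem_fraction: float = 0.25
    max_ltr_fraction: float = 0.25
    max_n_fraction: float = 0.05


def _is_subsequence(sub: Sequence[str], full: Sequence[str]) -> bool:
    it = iter(full)
    return all(any(x == y for y in it) for x in sub)


def tandem_repeat_fraction(
    seq: str, min_unit: int = 2, max_unit: int = 12, min_units: int = 3
) -> float:
    """Fraction of positions inside exact tandem arrays.

    A tandem array is >= ``min_units`` exact repetitions of a unit of size
    ``min_unit``..``max_unit`` bp.
    """
    n = len(seq)
    if n == 0:
        return 0.0
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    covered = np.zeros(n, dtype=bool)
    for p in range(min_unit, max_unit + 1):
        if n < min_units * p:
            break
        eq = (arr[p:] == arr[:-p]).astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], eq, [0]))))
        run_min = (min_units - 1) * p
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= run_min:
                covered[s : e + p] = True
    return float(covered.mean())


def _n_fraction(seq: str) -> float:
    return seq.upper().count("N") / len(seq) if seq else 0.0


def classify_superfamily(core_domains: Sequence[str]) -> str:
    """Copia/Gypsy/unknown call from the element's ordered core domains.

    The ordered core domains (INT/RT/RH) must embed as a subsequence into
    exactly one of the canonical patterns INT-RT-RH (RLC) or RH-RT-INT
    (RLG); anything ambiguous or contradictory is RLX.
    """
    core = [d for d in core_domains if d in CORE_DOMAIN_SET]
    is_rlc = _is_subsequence(core, RLC_ORDER)
    is_rlg = _is_subsequence(core, RLG_ORDER)
    if is_rlc and not is_rlg:
        return "RLC"
    if is_rlg and not is_rlc:
        return "RLG"
    return "RLX"


def filter_canonical(
    candidates: pd.DataFrame,
    domains: pd.DataFrame,
    get_sequence: Callable[[str], str],
    params: Optional[FilterParams] = None,
) -> Tuple[List[str], Dict[str, List[str]]]:
    """Apply the seven-criterion canonical flLTR-RT filter.

    A candidate is retained iff it (1) has at least one retrotransposon
    domain, (2) shows a consistent core-domain order (no repeats, embeds
    in a canonical pattern), (3) carries no gene-related domain, (4) has
    all domain strands equal to the candidate strand, (5) has < 25%
    tandem-repeat content, (6) has each LTR <= 25% of the element length,
    and (7) has < 5% N content.

    Returns the retained element ids plus, per rejected candidate, the
    list of violated-criterion tokens.
    """
    if params is None:
        params = FilterParams()
    known = set(candidates["element_id"])
    stray = set(domains["element_id"]) - known
    if stray:
        raise PolyteError(f"domain hits reference unknown elements: {sorted(stray)[:5]}")

    dom_by_el: Dict[str, pd.DataFrame] = {
        eid: grp.sort_values("order_index") for eid, grp in domains.groupby("element_id")
    }
    retained: List[str] = []
    reasons: Dict[str, List[str]] = {}
    for row in candidates.itertuples(index=False):
        eid = row.element_id
        dom = dom_by_el.get(eid)
        names = list(dom["domain"]) if dom is not None else []
        why: List[str] = []
        if not RETRO_DOMAIN_SET.intersection(names):
            why.append(REASON_NO_DOMAIN)
        core = [d for d in names if d in CORE_DOMAIN_SET]
        if len(core) != len(set(core)) or (
            core
            and not _is_subsequence(core, RLC_ORDER)
            and not _is_subsequence(core, RLG_ORDER)
        ):
            why.append(REASON_INCONSISTENT)
        if "GENE" in names:
            why.append(REASON_GENE)
        if dom is not None and len(dom):
            strands = set(dom["strand"])
            if len(strands) > 1 or strands != {row.strand}:
                why.append(REASON_STRAND)
        elem_len = row.elem_end - row.elem_start
        seq = get_sequence(eid)
        if tandem_repeat_fraction(seq) >= params.max_tandem_fraction:
            why.append(REASON_TANDEM)
        ltr5_len = row.ltr5_end - row.ltr5_start
        ltr3_len = row.ltr3_end - row.ltr3_start
        if max(ltr5_len, ltr3_len) > params.max_ltr_fraction * elem_len:
            why.append(REASON_LTR_SIZE)
        if _n_fraction(seq) >= params.max_n_fraction:
            why.append(REASON_N)
        if why:
            reasons[eid] = why
        else:
            retained.append(eid)
    return retained, reasons


def date_elements(
    candidates: pd.DataFrame,
    get_ltr_sequences: Callable[[str], Tuple[str, str]],
    mu: float = DEFAULT_MUTATION_RATE,
    aligner=None,
) -> pd.DataFrame:
    """Kimura-date each candidate from its 5'/3' LTR pair.

    Returns element_id, kimura_distance, age_years (NaN when divergence
    is saturated beyond the K2P correction).
    """
    if aligner is None:
        aligner = make_aligner()
    rows = []
    for eid in candidates["element_id"]:
        ltr5, ltr3 = get_ltr_sequences(eid)
        ra, rb = align_ltr_pair(ltr5, ltr3, aligner)
        try:
            d = kimura2p_distance(ra, rb)
            age = estimate_age(d, mu)
        except SaturationError:
            d, age = float("nan"), float("nan")
        rows.append((eid, d, age))
    return pd.DataFrame(rows, columns=["element_id", "kimura_distance", "age_years"])


# ---------------------------------------------------------------------------
# Identity/coverage clustering


@dataclass(frozen=True)
class SubfamilyCluster:
    cluster_id: str
    stringency: str
    member_ids: Tuple[str, ...]
    specificity: Optional[str] = None


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def pair_identity_coverage(seq_a: str, seq_b: str, aligner=None) -> Tuple[float, float, float]:
    """(identity, coverage_a, coverage_b) of the global alignment of a pair.

    Identity is matches over all alignment columns (gap columns included);
    coverage of each sequence is the aligned span (columns where both
    sequences have a residue) over that sequence's length.
    """
    if aligner is None:
        aligner = make_aligner()
    ra, rb = align_ltr_pair(seq_a, seq_b, aligner)
    st = alignment_stats(ra, rb)
    return st.identity, st.ungapped / len(seq_a), st.ungapped / len(seq_b)


def cluster_elements(
    sequences: Mapping[str, str],
    identity: float,
    coverage: float,
    aligner=None,
    stringency_label: Optional[str] = None,
    pair_fn: Optional[Callable[[str, str], Tuple[float, float, float]]] = None,
) -> List[SubfamilyCluster]:
    """Single-linkage clustering at an identity/coverage stringency.

    Two elements are linked iff their global alignment identity reaches
    ``identity`` and the aligned span covers at least ``coverage`` of BOTH
    sequence lengths (mutual length coverage); clusters are the connected
    components. Cluster ids are deterministic (smallest member id).
    """
    if not (0 < identity <= 1 and 0 < coverage <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    if aligner is None:
        aligner = make_aligner()
    ids = sorted(sequences)
    if not ids:
        return []
    label = stringency_label or f"{int(round(identity * 100))}/{int(round(coverage * 100))}"
    uf = _UnionFind(ids)
    bound = max(identity, coverage)
    for i, a in enumerate(ids):
        la = len(sequences[a])
        for b in ids[i + 1 :]:
            if uf.find(a) == uf.find(b):
                continue
            lb = len(sequences[b])
            # span <= min length, so both identity and coverage of the longer
            # sequence are bounded by the length ratio
            if min(la, lb) / max(la, lb) < bound:
                continue
            if pair_fn is not None:
                ident, cov_a, cov_b = pair_fn(a, b)
            else:
                ident, cov_a, cov_b = pair_identity_coverage(
                    sequences[a], sequences[b], aligner
                )
            if ident >= identity and cov_a >= coverage and cov_b >= coverage:
                uf.union(a, b)
    groups: Dict[str, List[str]] = {}
    for x in ids:
        groups.setdefault(uf.find(x), []).append(x)
    clusters = [
        SubfamilyCluster(f"{label}:{min(members)}", label, tuple(sorted(members)))
        for members in groups.values()
    ]
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def assign_specificity(counts: Mapping[str, int]) -> str:
    """Subgenome-specificity decision tree for one cluster.

    Rules applied in order: (1) a single subgenome holding >= 90% of the
    members claims the cluster; (2) if exactly one subgenome holds < 10%
    the cluster belongs to the other two; (3) otherwise it is ABD-common.
    """
    total = sum(counts.get(sg, 0) for sg in "ABD")
    if total == 0:
        raise PolyteError("cluster without members on placed chromosomes")
    frac = {sg: counts.get(sg, 0) / total for sg in "ABD"}
    for sg in "ABD":
        if frac[sg] >= 0.90:
            return sg
    low = [sg for sg in "ABD" if frac[sg] < 0.10]
    if len(low) == 1:
        return "".join(sg for sg in "ABD" if sg != low[0])
    return "ABD"


# ---------------------------------------------------------------------------
# Age statistics


def lifespan(ages: Sequence[float]) -> Tuple[float, float]:
    """(5th, 95th) percentile of insertion ages within one cluster.

    Percentiles use linear interpolation between order statistics
    (index h = q*(n-1)). Requires at least two dated members.
    """
    ages = np.asarray(ages, dtype=float)
    ages = ages[~np.isnan(ages)]
    if ages.size < 2:
        raise PolyteError("lifespan undefined for clusters with < 2 dated members")
    p5, p95 = np.percentile(ages, [5, 95], method="linear")
    return float(p5), float(p95)


def persistence_curve(
    ages: Sequence[float], bin_width: float = 10_000.0, smooth_window: Optional[int] = None
) -> pd.DataFrame:
    """Histogram of insertion ages in consecutive ``bin_width``-year bins.

    The count in a bin is the number of elements of that age that have
    remained intact until now. Optional centered moving-average smoothing.
    """
    ages = np.asarray(ages, dtype=float)
    ages = ages[~np.isnan(ages)]
    if ages.size == 0:
        return pd.DataFrame(columns=["bin_start", "count"])
    n_bins = int(np.floor(ages.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(ages, bins=edges)
    out = pd.DataFrame({"bin_start": edges[:-1], "count": counts})
    if smooth_window and smooth_window > 1:
        out["smoothed"] = (
            out["count"].rolling(smooth_window, center=True, min_periods=1).mean()
        )
    return out


def density_track(
    elements: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window: int = 4_000_000,
    step: int = 800_000,
) -> pd.DataFrame:
    """Sliding-window element counts per chromosome.

    Windows of ``window`` bp advance by ``step`` bp from position 0; an
    element is counted in every window containing its start; the last
    partial window is kept.
    """
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        starts = np.sort(
            elements.loc[elements["chrom"] == chrom, "start"].to_numpy(dtype=np.int64)
        )
        w0 = 0
        while w0 < length:
            w1 = min(w0 + window, length)
            count = int(
                np.searchsorted(starts, w1, side="left")
                - np.searchsorted(starts, w0, side="left")
            )
            rows.append((chrom, w0, w1, count))
            w0 += step
    return pd.DataFrame(rows, columns=["chrom", "win_start", "win_end", "count"])


# ---------------------------------------------------------------------------
# End-to-end convenience


@dataclass
class FlltrResult:
    canonical: pd.DataFrame
    rejection_reasons: Dict[str, List[str]]
    clusters: pd.DataFrame
    lifespans: pd.DataFrame
    persistence: pd.DataFrame
    density: pd.DataFrame


STRINGENCIES = ((0.95, 0.95, "95/95"), (0.90, 0.90, "90/90"), (0.80, 0.80, "80/80"))


def run_pipeline(
    candidates: pd.DataFrame,
    domains: pd.DataFrame,
    genome: Mapping[str, str],
    mu: float = DEFAULT_MUTATION_RATE,
    params: Optional[FilterParams] = None,
    stringencies=STRINGENCIES,
    density_window: int = 4_000_000,
    density_step: int = 800_000,
) -> FlltrResult:
    """Filter, classify, date, cluster and summarize a candidate set."""

    def elem_seq(eid: str) -> str:
        row = cand_by_id.loc[eid]
        return genome[row["chrom"]][row["elem_start"] : row["elem_end"]]

    def ltr_seqs(eid: str) -> Tuple[str, str]:
        row = cand_by_id.loc[eid]
        chrom = genome[row["chrom"]]
        return (
            chrom[row["ltr5_start"] : row["ltr5_end"]],
            chrom[row["ltr3_start"] : row["ltr3_end"]],
        )

    cand_by_id = candidates.set_index("element_id", drop=False)
    retained, reasons = filter_canonical(candidates, domains, elem_seq, params)
    kept = candidates[candidates["element_id"].isin(retained)].copy()

    dom_by_el = {eid: grp.sort_values("order_index") for eid, grp in domains.groupby("element_id")}
    kept["superfamily"] = [
        classify_superfamily(list(dom_by_el[eid]["domain"])) if eid in dom_by_el else "RLX"
        for eid in kept["element_id"]
    ]
    dated = date_elements(kept, ltr_seqs, mu)
    canonical = kept.merge(dated, on="element_id")
    canonical["subgenome"] = [subgenome_of(c) for c in canonical["chrom"]]
    canonical = canonical.rename(columns={"elem_start": "start", "elem_end": "end"})

    ages_by_id = dict(zip(canonical["element_id"], canonical["age_years"]))
    seqs = {eid: elem_seq(eid) for eid in canonical["element_id"]}
    aligner = make_aligner()
    pair_cache: Dict[Tuple[str, str], Tuple[float, float, float]] = {}

    def cached_pair(a: str, b: str) -> Tuple[float, float, float]:
        key = (a, b) if a <= b else (b, a)
        if key not in pair_cache:
            pair_cache[key] = pair_identity_coverage(seqs[key[0]], seqs[key[1]], aligner)
        return pair_cache[key]

    cluster_rows, lifespan_rows = [], []
    for ident, cov, label in stringencies:
        for cl in cluster_elements(seqs, ident, cov, stringency_label=label,
                                   pair_fn=cached_pair):
            counts: Dict[str, int] = {}
            for m in cl.member_ids:
                sg = subgenome_of(canonical.loc[canonical["element_id"] == m, "chrom"].iloc[0])
                counts[sg] = counts.get(sg, 0) + 1
            spec = assign_specificity(counts)
            for m in cl.member_ids:
                cluster_rows.append((label, cl.cluster_id, m, spec))
            member_ages = [ages_by_id[m] for m in cl.member_ids if not np.isnan(ages_by_id[m])]
            if len(member_ages) >= 2:
                p5, p95 = lifespan(member_ages)
                lifespan_rows.append((label, cl.cluster_id, len(cl.member_ids), p5, p95))
    clusters_df = pd.DataFrame(
        cluster_rows, columns=["stringency", "cluster_id", "element_id", "specificity"]
    )
    lifespans_df = pd.DataFrame(
        lifespan_rows, columns=["stringency", "cluster_id", "n_members", "p5_years", "p95_years"]
    )
    persistence = persistence_curve(canonical["age_years"].to_numpy())
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    density = density_track(canonical, chrom_lengths, density_window, density_step)
    return FlltrResult(canonical, reasons, clusters_df, lifespans_df, persistence, density)
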