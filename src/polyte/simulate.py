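"""Synthetic three-subgenome genome generator with known ground truth.

Emulates the features of a hexaploid (A/B/D) genome that the analysis
pipeline measures: TE families shared between subgenomes in conserved
proportions, full-length LTR retrotransposons whose two LTRs have
diverged according to known insertion ages (per-site substitution rate
mu, transition:transversion ratio 2:1), subfamily structure at nested
identity tiers, planted promoter enrichments, 1:1:1 homeolog triplets
with controllable intergenic-spacing conservation, and expression-module
labels. Truth tables record every planted quantity so recovery can be
checked exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment import SaturationError
from .core import DEFAULT_MUTATION_RATE, PolyteError, subgenome_of
from . import io as pio
from .flltr import (
    REASON_GENE,
    REASON_INCONSISTENT,
    REASON_LTR_SIZE,
    REASON_N,
    REASON_NO_DOMAIN,
    REASON_STRAND,
    REASON_TANDEM,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# Canonical internal domain layout per superfamily (5'->3').
DOMAIN_LAYOUT = {
    "RLC": ("GAG", "INT", "RT", "RH"),
    "RLG": ("GAG", "RH", "RT", "INT"),
    "RLX": ("GAG", "RT"),
}

CANDIDATE_COLUMNS = [
    "element_id", "chrom", "elem_start", "elem_end",
    "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end",
    "tsd_len", "motif", "strand",
]
DOMAIN_COLUMNS = ["element_id", "domain", "order_index", "strand"]


def _default_family_spectrum() -> Dict[str, Tuple[str, float]]:
    # family -> (superfamily code, target fraction of each subgenome)
    return {
        "DTC_famc1": ("DTC", 0.040),
        "DTM_famc1": ("DTM", 0.015),
        "DTT_famc1": ("DTT", 0.010),
        "DTH_famc1": ("DTH", 0.010),
        "DTA_famc1": ("DTA", 0.008),
        "RSX_famc1": ("RSX", 0.008),
        "RIX_famc1": ("RIX", 0.012),
        "XXX_famc1": ("XXX", 0.010),
    }


def _default_copy_lengths() -> Dict[str, int]:
    # typical fragment sizes: MITEs/SINEs are small, CACTAs/LINEs larger
    return {
        "DTC": 1200, "DTM": 400, "DTT": 200, "DTH": 250,
        "DTA": 500, "RSX": 180, "RIX": 900, "XXX": 300, "DTX": 220,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genome; defaults give a small
    three-chromosome genome with one chromosome per subgenome."""

    seed: int = 0
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1A": 1_200_000, "chr1B": 1_200_000, "chr1D": 1_200_000}
    )
    n_genes_per_subgenome: int = 100
    gene_length_range: Tuple[int, int] = (1_000, 8_000)
    family_spectrum: Dict[str, Tuple[str, float]] = field(default_factory=_default_family_spectrum)
    copy_lengths: Dict[str, int] = field(default_factory=_default_copy_lengths)
    # flLTR-RT content
    n_flltr: int = 60
    flltr_families: Tuple[Tuple[str, str], ...] = (
        ("RLC_famc1", "RLC"), ("RLG_famc1", "RLG"), ("RLG_famc2", "RLG"),
    )
    n_subfamilies_per_family: int = 3
    age_distribution: Tuple[str, float, float] = ("uniform", 0.0, 3.0e6)
    mutation_rate: float = DEFAULT_MUTATION_RATE
    ts_tv_ratio: float = 2.0
    indel_rate_factor: float = 0.0  # indels per substitution
    ltr_length_range: Tuple[int, int] = (500, 1_500)
    internal_length_range: Tuple[int, int] = (2_000, 4_000)
    subfamily_identity_tiers: Tuple[float, float] = (0.97, 0.85)
    include_violators: bool = True
    # gene-vicinity TE planting
    promoter_window: int = 2_000
    promoter_copy_fraction: float = 0.12
    promoter_enrichment_spec: Dict[str, float] = field(
        default_factory=lambda: {"DTT_famc1": 4.0, "DTM_famc1": 1.0, "RSX_famc1": 0.25}
    )
    cns_fraction: float = 0.05
    cns_family: str = "DTX_famc1"
    # homeolog layout
    spacing_conservation: float = 0.9
    spacing_noise: float = 0.05
    inversion_fraction: float = 0.05
    # expression modules
    module_sizes: Tuple[int, ...] = (80, 60)
    unexpressed_label: str = "unexpressed"
    module_enrichment_spec: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be positive")
        for fam, (code, frac) in self.family_spectrum.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"spectrum fraction for {fam} outside [0, 1]")
        if not 0 <= self.spacing_conservation <= 1:
            raise ValueError("spacing_conservation must lie in [0, 1]")
        sgs = {subgenome_of(c) for c in self.chrom_lengths}
        if sgs != {"A", "B", "D"}:
            raise ValueError("chrom_lengths must cover subgenomes A, B and D")

    def sample_age(self, rng: np.random.Generator) -> float:
        kind, lo, hi = self.age_distribution
        if kind != "uniform":
            raise ValueError(f"unsupported age distribution {kind!r}")
        return float(rng.uniform(lo, hi))

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        for key in ("family_spectrum",):
            if key in data:
                data[key] = {k: tuple(v) for k, v in data[key].items()}
        for key in ("flltr_families",):
            if key in data:
                data[key] = tuple(tuple(x) for x in data[key])
        for key in (
            "gene_length_range", "age_distribution", "ltr_length_range",
            "internal_length_range", "subfamily_identity_tiers", "module_sizes",
        ):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# Sequence-level primitives


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate_sequence(
    seq: str,
    p_sub: float,
    rng: np.random.Generator,
    ts_tv_ratio: float = 2.0,
    indel_rate: float = 0.0,
) -> str:
    """Mutate a sequence with expected ``p_sub`` substitutions per site.

    Transitions occur at ``ts_tv_ratio`` times the transversion rate
    (default 2:1). ``indel_rate`` is the expected per-site indel count;
    indel lengths are uniform on 1..5 bp, insertions and deletions
    equally likely.
    """
    n = len(seq)
    chars = list(seq)
    n_sub = rng.binomial(n, min(p_sub, 1.0)) if p_sub > 0 else 0
    if n_sub:
        p_transition = ts_tv_ratio / (ts_tv_ratio + 1.0)
        for i in rng.choice(n, size=n_sub, replace=False):
            base = chars[i]
            if base not in _TRANSITION:
                continue
            if rng.random() < p_transition:
                chars[i] = _TRANSITION[base]
            else:
                chars[i] = _TRANSVERSIONS[base][rng.integers(0, 2)]
    if indel_rate > 0:
        n_indel = rng.poisson(indel_rate * n)
        for _ in range(n_indel):
            pos = int(rng.integers(0, max(len(chars), 1)))
            size = int(rng.integers(1, 6))
            if rng.random() < 0.5 and len(chars) > size:
                del chars[pos : pos + size]
            else:
                chars[pos:pos] = list(random_sequence(size, rng))
    return "".join(chars)


# ---------------------------------------------------------------------------
# flLTR-RT generation


def generate_flltr(
    config: SimulationConfig,
    family_seed_sequence: str,
    age: float,
    rng: np.random.Generator,
    element_id: str = "el00000",
    superfamily: str = "RLC",
    ltr_length: Optional[int] = None,
    strand: str = "+",
) -> Tuple[str, dict, List[dict], dict]:
    """One full-length LTR-RT: LTR + internal + LTR, each LTR mutated
    independently so the expected LTR-LTR raw divergence is 2*mu*age.

    ``family_seed_sequence`` is the ancestral element template: its first
    ``ltr_length`` bases are the ancestral LTR, the remainder the
    internal region. Returns (element sequence, candidate row, domain
    rows, truth row).
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    mu = config.mutation_rate
    p = mu * age
    if 2.0 * p > 0.75:
        raise SaturationError(f"age {age:.3g} yr implies divergence beyond saturation")
    if ltr_length is None:
        ltr_length = int(rng.integers(config.ltr_length_range[0], config.ltr_length_range[1] + 1))
    if len(family_seed_sequence) <= ltr_length:
        raise ValueError("seed sequence shorter than the requested LTR")
    ancestral_ltr = family_seed_sequence[:ltr_length]
    ancestral_internal = family_seed_sequence[ltr_length:]
    indel = config.indel_rate_factor * p
    ltr5 = mutate_sequence(ancestral_ltr, p, rng, config.ts_tv_ratio, indel)
    ltr3 = mutate_sequence(ancestral_ltr, p, rng, config.ts_tv_ratio, indel)
    internal = mutate_sequence(ancestral_internal, p, rng, config.ts_tv_ratio, indel)
    element = ltr5 + internal + ltr3
    candidate = {
        "element_id": element_id,
        "chrom": "",
        "elem_start": 0,
        "elem_end": len(element),
        "ltr5_start": 0,
        "ltr5_end": len(ltr5),
        "ltr3_start": len(element) - len(ltr3),
        "ltr3_end": len(element),
        "tsd_len": int(rng.integers(4, 7)),
        "motif": "TGCA",
        "strand": strand,
    }
    layout = DOMAIN_LAYOUT[superfamily]
    domains = [
        {"element_id": element_id, "domain": d, "order_index": i, "strand": strand}
        for i, d in enumerate(layout)
    ]
    truth = {
        "element_id": element_id,
        "true_age": age,
        "expected_divergence": 2.0 * p,
        "superfamily": superfamily,
    }
    return element, candidate, domains, truth


@dataclass
class _Element:
    element_id: str
    sequence: str
    candidate: dict
    domains: List[dict]
    truth: dict
    subgenome: str


def generate_flltr_set(config: SimulationConfig, rng: np.random.Generator) -> List[_Element]:
    """The configured number of flLTR-RTs with subfamily structure.

    Each family has an ancestral template; subfamily consensi diverge
    from it so that between-subfamily identity matches the lower tier,
    and members diverge from their consensus to match the upper tier.
    Subfamilies cycle through home subgenomes (A, B, D, then ABD-shared)
    to exercise the specificity decision tree.
    """
    within, between = config.subfamily_identity_tiers
    elements: List[_Element] = []
    homes = ("A", "B", "D", "ABD")
    subfam_specs = []
    for fam, code in config.flltr_families:
        ltr_len = int(rng.integers(*config.ltr_length_range))
        internal_len = int(rng.integers(*config.internal_length_range))
        ancestor = random_sequence(ltr_len + internal_len, rng)
        for k in range(config.n_subfamilies_per_family):
            consensus = mutate_sequence(ancestor, (1.0 - between) / 2.0, rng, config.ts_tv_ratio)
            subfam_specs.append(
                (fam, code, f"{fam}.{k + 1}", consensus, ltr_len, homes[k % len(homes)])
            )
    for i in range(config.n_flltr):
        fam, code, subfam, consensus, ltr_len, home = subfam_specs[i % len(subfam_specs)]
        template = mutate_sequence(consensus, (1.0 - within) / 2.0, rng, config.ts_tv_ratio)
        age = config.sample_age(rng)
        eid = f"el{i:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        seq, cand, doms, truth = generate_flltr(
            config, template, age, rng, eid, code, ltr_len, strand
        )
        sg = home if home != "ABD" else "ABD"[int(rng.integers(0, 3))]
        truth.update({"family": fam, "subfamily": subfam, "home": home, "subgenome": sg})
        elements.append(_Element(eid, seq, cand, doms, truth, sg))
    return elements


def generate_filter_violators(
    config: SimulationConfig, rng: np.random.Generator, start_index: int = 0
) -> Tuple[List[_Element], pd.DataFrame]:
    """Seven candidates, each violating exactly one canonical-filter
    criterion; the planted violation is recorded in the truth table."""
    violators: List[_Element] = []
    rows = []
    ltr_len = 400
    seed = random_sequence(ltr_len + 2500, rng)

    def fresh(idx: int) -> Tuple[str, dict, List[dict], dict]:
        eid = f"vi{start_index + idx:05d}"
        return generate_flltr(config, seed, 2.0e5, rng, eid, "RLC", ltr_len)

    # 1: no retrotransposon domain at all
    seq, cand, _, truth = fresh(0)
    violators.append(_Element(cand["element_id"], seq, cand, [], truth, "A"))
    rows.append((cand["element_id"], REASON_NO_DOMAIN))
    # 2: repeated core domains (RT-RH-INT-RT-RH)
    seq, cand, _, truth = fresh(1)
    doms = [
        {"element_id": cand["element_id"], "domain": d, "order_index": i, "strand": "+"}
        for i, d in enumerate(("RT", "RH", "INT", "RT", "RH"))
    ]
    violators.append(_Element(cand["element_id"], seq, cand, doms, truth, "A"))
    rows.append((cand["element_id"], REASON_INCONSISTENT))
    # 3: gene-related domain present
    seq, cand, doms, truth = fresh(2)
    doms.append(
        {"element_id": cand["element_id"], "domain": "GENE",
         "order_index": len(doms), "strand": "+"}
    )
    violators.append(_Element(cand["element_id"], seq, cand, doms, truth, "B"))
    rows.append((cand["element_id"], REASON_GENE))
    # 4: one domain on the wrong strand
    seq, cand, doms, truth = fresh(3)
    doms[1]["strand"] = "-"
    violators.append(_Element(cand["element_id"], seq, cand, doms, truth, "B"))
    rows.append((cand["element_id"], REASON_STRAND))
    # 5: tandem-repeat content >= 25%
    seq, cand, doms, truth = fresh(4)
    block = "AC" * (int(0.16 * len(seq)))  # 32% of element length
    mid = len(seq) // 2
    seq = seq[: mid - len(block) // 2] + block + seq[mid + len(block) - len(block) // 2 :]
    cand["elem_end"] = len(seq)
    cand["ltr3_start"] = len(seq) - ltr_len
    cand["ltr3_end"] = len(seq)
    violators.append(_Element(cand["element_id"], seq, cand, doms, truth, "D"))
    rows.append((cand["element_id"], REASON_TANDEM))
    # 6: LTRs longer than 25% of the element
    big_ltr = 900
    short_seed = random_sequence(big_ltr + 900, rng)  # element 2700 bp, LTR 33%
    seq, cand, doms, truth = generate_flltr(
        config, short_seed, 2.0e5, rng, f"vi{start_index + 5:05d}", "RLC", big_ltr
    )
    violators.append(_Element(cand["element_id"], seq, cand, doms, truth, "D"))
    rows.append((cand["element_id"], REASON_LTR_SIZE))
    # 7: N content >= 5%
    seq, cand, doms, truth = fresh(6)
    n_run = int(0.08 * len(seq))
    mid = len(seq) // 2
    seq = seq[:mid] + "N" * n_run + seq[mid + n_run :]
    violators.append(_Element(cand["element_id"], seq, cand, doms, truth, "A"))
    rows.append((cand["element_id"], REASON_N))
    truth_df = pd.DataFrame(rows, columns=["element_id", "planted_violation"])
    return violators, truth_df


# ---------------------------------------------------------------------------
# Homeolog layout


def _one_chrom_per_subgenome(chrom_lengths: Mapping[str, int]) -> Dict[str, str]:
    by_sg: Dict[str, str] = {}
    for chrom in sorted(chrom_lengths):
        sg = subgenome_of(chrom)
        if sg in by_sg:
            raise PolyteError("layout generator expects one chromosome per subgenome")
        by_sg[sg] = chrom
    return by_sg


def _uniform_layout(
    n: int, lengths: np.ndarray, usable: int, rng: np.random.Generator, margin: int
) -> np.ndarray:
    """Sorted non-overlapping starts: uniform anchors in the free space
    plus the cumulative length of preceding genes."""
    free = usable - int(lengths.sum())
    if free <= n:
        raise PolyteError("genes overflow chromosome length")
    anchors = np.sort(rng.integers(0, free, size=n))
    offsets = np.concatenate(([0], np.cumsum(lengths[:-1])))
    return margin + anchors + offsets


def generate_homeolog_layout(
    config: SimulationConfig, rng: np.random.Generator
) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame, Dict[str, set]]:
    """Gene layouts per subgenome, the 1:1:1 triplet table, and truth.

    Triplet i covers gene i of each subgenome; for a ``spacing_conservation``
    fraction of triplets the gene-to-downstream-neighbor gap in B and D
    equals the A gap up to ±``spacing_noise`` multiplicative noise, the
    rest keep independently drawn gaps. An ``inversion_fraction`` of
    B-subgenome genes is flipped relative to A.
    """
    n = config.n_genes_per_subgenome
    if n < 2:
        raise PolyteError("need at least 2 genes per chromosome")
    chrom_by_sg = _one_chrom_per_subgenome(config.chrom_lengths)
    margin = max(config.promoter_window, 2_000) + 500
    lo, hi = config.gene_length_range

    lengths = {sg: rng.integers(lo, hi + 1, size=n) for sg in "ABD"}
    usable = {
        sg: config.chrom_lengths[chrom_by_sg[sg]] - 2 * margin for sg in "ABD"
    }
    starts_a = _uniform_layout(n, lengths["A"], int(usable["A"] * 0.85), rng, margin)
    ends_a = starts_a + lengths["A"]
    gaps_a = starts_a[1:] - ends_a[:-1]

    n_cons = int(round(config.spacing_conservation * (n - 1)))
    conserved_idx = set(rng.permutation(n - 1)[:n_cons].tolist())

    strands_a = np.where(rng.random(n) < 0.5, "+", "-")
    flipped_b = rng.random(n) < config.inversion_fraction

    frames: Dict[str, pd.DataFrame] = {}
    for sg in "ABD":
        chrom = chrom_by_sg[sg]
        if sg == "A":
            starts = starts_a
        else:
            base_starts = _uniform_layout(
                n, lengths[sg], int(usable[sg] * 0.85), rng, margin
            )
            base_gaps = base_starts[1:] - (base_starts[:-1] + lengths[sg][:-1])
            gaps = base_gaps.astype(float)
            for i in range(n - 1):
                if i in conserved_idx:
                    gaps[i] = gaps_a[i] * (1.0 + rng.uniform(-config.spacing_noise,
                                                             config.spacing_noise))
            starts = np.empty(n, dtype=np.int64)
            # anchor near the chromosome start so the conserved-gap series
            # cannot overflow the chromosome
            starts[0] = margin + int(rng.integers(0, max(usable[sg] // 50, 1_000)))
            for i in range(1, n):
                starts[i] = starts[i - 1] + lengths[sg][i - 1] + int(round(gaps[i - 1]))
            if starts[-1] + lengths[sg][-1] > config.chrom_lengths[chrom] - margin:
                raise PolyteError("genes overflow chromosome length")
        strands = strands_a.copy()
        if sg == "B":
            strands = np.where(flipped_b, np.where(strands_a == "+", "-", "+"), strands_a)
        frames[sg] = pd.DataFrame(
            {
                "gene_id": [f"G{i:05d}{sg}" for i in range(n)],
                "chrom": chrom,
                "start": starts,
                "end": starts + lengths[sg],
                "strand": strands,
                "subgenome": sg,
            }
        )
    triplets = pd.DataFrame(
        {
            "group_id": [f"T{i:05d}" for i in range(n)],
            "gene_A": frames["A"]["gene_id"],
            "gene_B": frames["B"]["gene_id"],
            "gene_D": frames["D"]["gene_id"],
        }
    )
    truth = {
        "conserved_spacing_triplets": {f"T{i:05d}" for i in sorted(conserved_idx)},
    }
    return frames, triplets, truth


# ---------------------------------------------------------------------------
# TE placement


def merge_simple(intervals: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[List[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def subtract_intervals(
    base: Sequence[Tuple[int, int]], holes: Sequence[Tuple[int, int]]
) -> List[Tuple[int, int]]:
    """Set difference base \\ holes over [start, end) intervals."""
    holes = merge_simple(holes)
    out: List[Tuple[int, int]] = []
    for s, e in merge_simple(base):
        pos = s
        for hs, he in holes:
            if he <= pos or hs >= e:
                continue
            if hs > pos:
                out.append((pos, hs))
            pos = max(pos, he)
            if pos >= e:
                break
        if pos < e:
            out.append((pos, e))
    return out


def _free_segments(
    chrom_length: int, occupied: Sequence[Tuple[int, int]], margin: int = 0
) -> List[Tuple[int, int]]:
    return subtract_intervals([(margin, chrom_length - margin)], occupied)


def _place_in_segments(
    segments: Sequence[Tuple[str, int, int]],
    lengths: Sequence[int],
    rng: np.random.Generator,
) -> List[Tuple[str, int]]:
    """Non-overlapping placements of copies of the given lengths into
    (chrom, start, end) free segments; returns (chrom, start) per copy,
    spread roughly uniformly over the free space."""
    caps = np.array([e - s for _c, s, e in segments], dtype=np.int64)
    if len(segments) == 0 or sum(lengths) > caps.sum():
        raise PolyteError("requested copies exceed available intergenic space")
    assigned: List[List[int]] = [[] for _ in segments]
    seg_load = np.zeros(len(segments), dtype=np.int64)
    order = rng.permutation(len(lengths))
    for idx in order:
        length = lengths[idx]
        room = caps - seg_load - length
        ok = np.flatnonzero(room >= 0)
        if ok.size == 0:
            raise PolyteError("requested copies exceed available intergenic space")
        weights = (room[ok] + 1).astype(float)
        seg = int(ok[rng.choice(ok.size, p=weights / weights.sum())])
        assigned[seg].append(idx)
        seg_load[seg] += length
    placements: List[Tuple[str, int]] = [("", 0)] * len(lengths)
    for seg_i, (chrom, s, _e) in enumerate(segments):
        idxs = assigned[seg_i]
        if not idxs:
            continue
        lens = np.array([lengths[i] for i in idxs], dtype=np.int64)
        free = caps[seg_i] - int(lens.sum())
        anchors = np.sort(rng.integers(0, free + 1, size=len(idxs)))
        offsets = np.concatenate(([0], np.cumsum(lens[:-1])))
        for k, i in enumerate(idxs):
            placements[i] = (chrom, s + int(anchors[k]) + int(offsets[k]))
    return placements


def plant_promoter_enrichment(
    genes: pd.DataFrame,
    family_spectrum: Mapping[str, Tuple[str, float]],
    promoter_enrichment_spec: Mapping[str, float],
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int],
    copy_lengths: Optional[Mapping[str, int]] = None,
    promoter_window: int = 2_000,
    promoter_copy_fraction: float = 0.12,
    exclude: Optional[Mapping[str, List[Tuple[int, int]]]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """TE annotation with planted promoter enrichments.

    Per subgenome, each family receives a copy budget from its target
    genome fraction. A family with fold f gets a promoter copy share of
    f times its genome-wide copy share; the remaining mass is spread over
    unspecified families proportionally. Background copies are placed
    uniformly in intergenic space outside promoters (and outside
    ``exclude`` intervals); promoter copies inside 2-kb promoters.
    Returns (TE table, truth table of planted folds).
    """
    if any(f < 0 for f in promoter_enrichment_spec.values()):
        raise ValueError("fold values must be non-negative")
    if copy_lengths is None:
        copy_lengths = _default_copy_lengths()
    from .gene_context import promoter_intervals

    te_rows = []
    truth_rows = []
    copy_counter = 0
    for sg in sorted({subgenome_of(c) for c in chrom_lengths}):
        chroms = sorted(c for c in chrom_lengths if subgenome_of(c) == sg)
        sg_genes = genes[genes["subgenome"] == sg]
        fams = sorted(family_spectrum)
        n_by_fam = {}
        for fam in fams:
            code, frac = family_spectrum[fam]
            length = copy_lengths.get(code, 300)
            total_bp = frac * sum(chrom_lengths[c] for c in chroms)
            n_by_fam[fam] = max(int(round(total_bp / length)), 0)
        total = sum(n_by_fam.values())
        if total == 0:
            continue
        p = {fam: n_by_fam[fam] / total for fam in fams}
        m_total = int(round(promoter_copy_fraction * total))
        spec_mass = sum(promoter_enrichment_spec.get(f, 0.0) * p[f]
                        for f in fams if f in promoter_enrichment_spec)
        plain_mass = sum(p[f] for f in fams if f not in promoter_enrichment_spec)
        if spec_mass > 1.0:
            raise PolyteError("promoter enrichment folds exceed the available copy mass")
        implied = (1.0 - spec_mass) / plain_mass if plain_mass > 0 else 0.0
        m_by_fam = {}
        for fam in fams:
            fold = promoter_enrichment_spec.get(fam, implied)
            m = int(round(fold * p[fam] * m_total))
            if m > n_by_fam[fam]:
                raise PolyteError(f"promoter copies for {fam} exceed its total budget")
            m_by_fam[fam] = m
        # promoter placement: promoter windows minus genes and exclusions
        promoters = promoter_intervals(sg_genes, promoter_window)
        gene_iv = {
            c: [(int(r.start), int(r.end))
                for r in sg_genes[sg_genes["chrom"] == c].itertuples(index=False)]
            for c in chroms
        }
        prom_merged = {
            c: merge_simple(
                [(int(r.start), int(r.end))
                 for r in promoters[promoters["chrom"] == c].itertuples(index=False)]
            )
            for c in chroms
        }
        prom_segments: List[Tuple[str, int, int]] = []
        for c in chroms:
            holes = gene_iv[c] + list(exclude.get(c, []) if exclude else [])
            prom_segments.extend(
                (c, s, e) for s, e in subtract_intervals(prom_merged[c], holes)
            )
        prom_lengths, prom_fams = [], []
        for fam in fams:
            code = family_spectrum[fam][0]
            prom_lengths.extend([copy_lengths.get(code, 300)] * m_by_fam[fam])
            prom_fams.extend([fam] * m_by_fam[fam])
        placed_prom: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
        if prom_lengths:
            for (chrom, start), length, fam in zip(
                _place_in_segments(prom_segments, prom_lengths, rng), prom_lengths, prom_fams
            ):
                te_rows.append(self_row(copy_counter, chrom, start, length, fam,
                                        family_spectrum[fam][0], sg))
                placed_prom[chrom].append((start, start + length))
                copy_counter += 1
        # background placement outside genes, promoters and exclusions
        bg_segments: List[Tuple[str, int, int]] = []
        for chrom in chroms:
            occupied = (
                gene_iv[chrom]
                + prom_merged[chrom]
                + placed_prom[chrom]
                + list(exclude.get(chrom, []) if exclude else [])
            )
            bg_segments.extend(
                (chrom, s, e)
                for s, e in _free_segments(chrom_lengths[chrom], occupied, margin=100)
            )
        bg_lengths, bg_fams = [], []
        for fam in fams:
            code = family_spectrum[fam][0]
            n_bg = n_by_fam[fam] - m_by_fam[fam]
            bg_lengths.extend([copy_lengths.get(code, 300)] * n_bg)
            bg_fams.extend([fam] * n_bg)
        if bg_lengths:
            for (chrom, start), length, fam in zip(
                _place_in_segments(bg_segments, bg_lengths, rng), bg_lengths, bg_fams
            ):
                te_rows.append(self_row(copy_counter, chrom, start, length, fam,
                                        family_spectrum[fam][0], sg))
                copy_counter += 1
        for fam in fams:
            planted = (
                (m_by_fam[fam] / m_total) / p[fam] if m_total and p[fam] > 0 else np.nan
            )
            truth_rows.append((fam, sg, promoter_enrichment_spec.get(fam, implied), planted))
    tes = pd.DataFrame(
        te_rows,
        columns=["copy_id", "chrom", "start", "end", "strand", "family", "subfamily",
                 "superfamily"],
    ).sort_values(["chrom", "start", "end", "copy_id"]).reset_index(drop=True)
    truth = pd.DataFrame(
        truth_rows, columns=["family", "subgenome", "target_fold", "planted_fold"]
    )
    return tes, truth


def self_row(counter: int, chrom: str, start: int, length: int, fam: str,
             code: str, sg: str) -> tuple:
    return (f"te_{sg}_{counter:06d}", chrom, start, start + length, "+", fam, None, code)


# ---------------------------------------------------------------------------
# Whole-genome orchestration


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: Dict[str, str]
    genes: pd.DataFrame
    tes: pd.DataFrame
    candidates: pd.DataFrame
    domains: pd.DataFrame
    triplets: pd.DataFrame
    modules: pd.DataFrame
    truth: Dict[str, pd.DataFrame]


def assign_modules(
    genes: pd.DataFrame,
    module_sizes: Sequence[int],
    rng: np.random.Generator,
    unexpressed_label: str = "unexpressed",
    upstream_family: Optional[Mapping[str, str]] = None,
    module_enrichment_spec: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> pd.DataFrame:
    """Assign genes to coexpression modules; leftovers are unexpressed.

    A module whose enrichment spec maps family f to fold w draws genes
    whose closest-upstream TE belongs to f with w-fold weight, planting a
    detectable association."""
    if sum(module_sizes) > len(genes):
        raise PolyteError("module sizes exceed the number of genes")
    pool = list(genes["gene_id"])
    rows = []
    for m, size in enumerate(module_sizes, start=1):
        label = f"M{m}"
        spec = (module_enrichment_spec or {}).get(label, {})
        weights = np.ones(len(pool))
        if spec and upstream_family is not None:
            for i, gid in enumerate(pool):
                fam = upstream_family.get(gid)
                if fam in spec:
                    weights[i] = spec[fam]
        weights = weights / weights.sum()
        chosen = rng.choice(len(pool), size=size, replace=False, p=weights)
        chosen_ids = {pool[i] for i in chosen}
        rows.extend((gid, label) for gid in sorted(chosen_ids))
        pool = [g for g in pool if g not in chosen_ids]
    rows.extend((gid, unexpressed_label) for gid in pool)
    return pd.DataFrame(rows, columns=["gene_id", "module_id"]).sort_values(
        ["gene_id"]
    ).reset_index(drop=True)


def simulate_genome(config: SimulationConfig) -> SimulationResult:
    """Generate the full synthetic genome, annotations and truth tables."""
    rng = np.random.default_rng(config.seed)
    frames, triplets, layout_truth = generate_homeolog_layout(config, rng)
    genes = pd.concat([frames[sg] for sg in "ABD"], ignore_index=True)
    chrom_by_sg = _one_chrom_per_subgenome(config.chrom_lengths)

    from .gene_context import promoter_intervals

    # flLTR-RT elements placed outside genes and promoters
    elements = generate_flltr_set(config, rng)
    violators_truth = pd.DataFrame(columns=["element_id", "planted_violation"])
    if config.include_violators:
        violators, violators_truth = generate_filter_violators(config, rng)
        elements = elements + violators
    promoters = promoter_intervals(genes, config.promoter_window)
    occupied_by_chrom: Dict[str, List[Tuple[int, int]]] = {
        c: [] for c in config.chrom_lengths
    }
    for r in genes.itertuples(index=False):
        occupied_by_chrom[r.chrom].append((int(r.start), int(r.end)))
    for r in promoters.itertuples(index=False):
        occupied_by_chrom[r.chrom].append((int(r.start), int(r.end)))
    flltr_by_chrom: Dict[str, List[_Element]] = {c: [] for c in config.chrom_lengths}
    for el in elements:
        flltr_by_chrom[chrom_by_sg[el.subgenome]].append(el)
    cand_rows, dom_rows, age_rows = [], [], []
    element_intervals: Dict[str, List[Tuple[int, int]]] = {c: [] for c in config.chrom_lengths}
    for chrom in sorted(config.chrom_lengths):
        els = flltr_by_chrom[chrom]
        if not els:
            continue
        free = _free_segments(config.chrom_lengths[chrom], occupied_by_chrom[chrom], margin=200)
        placements = _place_in_segments(
            [(chrom, s, e) for s, e in free], [len(e.sequence) for e in els], rng
        )
        for el, (_c, start) in zip(els, placements):
            cand = dict(el.candidate)
            offset = start
            cand["chrom"] = chrom
            for key in ("elem_start", "elem_end", "ltr5_start", "ltr5_end",
                        "ltr3_start", "ltr3_end"):
                cand[key] = cand[key] + offset
            cand_rows.append(cand)
            dom_rows.extend(el.domains)
            age_rows.append(el.truth)
            element_intervals[chrom].append((cand["elem_start"], cand["elem_end"]))
    candidates = pd.DataFrame(cand_rows, columns=CANDIDATE_COLUMNS).sort_values(
        ["chrom", "elem_start", "element_id"]
    ).reset_index(drop=True)
    domains = pd.DataFrame(dom_rows, columns=DOMAIN_COLUMNS)
    ages_truth = pd.DataFrame(age_rows)

    exclude = {c: list(element_intervals[c]) for c in config.chrom_lengths}
    # CNS planting: a same-family copy immediately upstream of all three
    # homeolog TSSs for a subset of triplets
    cns_rows = []
    cns_len = config.copy_lengths.get(config.cns_family[:3], 220)
    n_cns = int(round(config.cns_fraction * len(triplets)))
    cns_ids = sorted(rng.permutation(len(triplets))[:n_cns].tolist())
    gene_by_id = {r.gene_id: r for r in genes.itertuples(index=False)}
    cns_counter = 0
    cns_gap = 60  # < minimum copy length, so nothing can slip in between
    planted_cns = []
    for ti in cns_ids:
        t = triplets.iloc[ti]
        placements = []
        ok = True
        for gid in (t.gene_A, t.gene_B, t.gene_D):
            g = gene_by_id[gid]
            if g.strand == "-":
                s = g.end + cns_gap
            else:
                s = g.start - cns_gap - cns_len
            if s < 0:
                ok = False
                break
            placements.append((g.chrom, s, s + cns_len))
        if not ok:
            continue
        for chrom, s, e in placements:
            cns_rows.append(
                (f"cns_{cns_counter:05d}", chrom, s, e, "+", config.cns_family,
                 None, config.cns_family[:3])
            )
            exclude[chrom] = exclude[chrom] + [(s - cns_gap - 1, e + cns_gap + 1)]
            cns_counter += 1
        planted_cns.append(t.group_id)
    cns_df = pd.DataFrame(
        cns_rows, columns=["copy_id", "chrom", "start", "end", "strand", "family",
                           "subfamily", "superfamily"],
    )
    tes, enrichment_truth = plant_promoter_enrichment(
        genes,
        config.family_spectrum,
        config.promoter_enrichment_spec,
        rng,
        config.chrom_lengths,
        config.copy_lengths,
        config.promoter_window,
        config.promoter_copy_fraction,
        exclude=exclude,
    )
    tes = pd.concat([tes, cns_df], ignore_index=True).sort_values(
        ["chrom", "start", "end", "copy_id"]
    ).reset_index(drop=True)

    # genome sequences: random background with flLTR sequences embedded
    genome: Dict[str, str] = {}
    for chrom in sorted(config.chrom_lengths):
        arr = np.frombuffer(
            random_sequence(config.chrom_lengths[chrom], rng).encode(), dtype=np.uint8
        ).copy()
        for el, (s, e) in zip(
            flltr_by_chrom[chrom], element_intervals[chrom]
        ):
            arr[s:e] = np.frombuffer(el.sequence.encode(), dtype=np.uint8)
        genome[chrom] = arr.tobytes().decode()

    # expression modules, optionally enriched for upstream families
    upstream = None
    if config.module_enrichment_spec:
        from .gene_context import closest_flanking_te

        flanks = closest_flanking_te(genes, tes)
        upstream = dict(zip(flanks["gene_id"], flanks["up_family"]))
    modules = assign_modules(
        genes, config.module_sizes, rng, config.unexpressed_label,
        upstream, config.module_enrichment_spec,
    )

    truth = {
        "ages": ages_truth,
        "violations": violators_truth,
        "enrichment": enrichment_truth,
        "conserved_spacing": pd.DataFrame(
            {"group_id": sorted(layout_truth["conserved_spacing_triplets"])}
        ),
        "cns_triplets": pd.DataFrame({"group_id": planted_cns}),
    }
    return SimulationResult(
        config, genome, genes, tes, candidates, domains, triplets, modules, truth
    )


def write_outputs(result: SimulationResult, outdir) -> Dict[str, str]:
    """Write the simulated genome and all annotation/truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_fasta(result.genome, outdir / "genome.fasta")
    _write_genes_gff(result.genes, outdir / "genes.gff3")
    _write_tes_gff(result.tes, outdir / "tes.gff3")
    pio.write_tsv_table(result.candidates, outdir / "candidates.tsv")
    pio.write_tsv_table(result.domains, outdir / "domains.tsv")
    pio.write_tsv_table(result.triplets, outdir / "triplets.tsv")
    pio.write_tsv_table(result.modules, outdir / "modules.tsv")
    for name, df in result.truth.items():
        pio.write_tsv_table(df, outdir / f"truth_{name}.tsv")
    return {p.name: str(p) for p in sorted(outdir.iterdir())}


def _write_genes_gff(genes: pd.DataFrame, path) -> None:
    lines = ["##gff-version 3"]
    for r in genes.sort_values(["chrom", "start", "end", "gene_id"]).itertuples(index=False):
        lines.append(
            "\t".join([r.chrom, "polyte_sim", "gene", str(r.start + 1), str(r.end),
                       ".", r.strand, ".", f"ID={r.gene_id}"])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _write_tes_gff(tes: pd.DataFrame, path) -> None:
    lines = ["##gff-version 3"]
    for r in tes.sort_values(["chrom", "start", "end", "copy_id"]).itertuples(index=False):
        attrs = f"ID={r.copy_id};Family={r.family};Superfamily={r.superfamily}"
        if r.subfamily and not pd.isna(r.subfamily):
            attrs += f";Subfamily={r.subfamily}"
        lines.append(
            "\t".join([r.chrom, "polyte_sim", "repeat_region", str(r.start + 1),
                       str(r.end), ".", r.strand, ".", attrs])
        )
    Path(path).write_text("\n".join(lines) + "\n")
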