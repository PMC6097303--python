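import itertools

import numpy as np
import pandas as pd
import pytest

from polyte.core import PolyteError
from polyte.flltr import (
    REASON_INCONSISTENT,
    REASON_LTR_SIZE,
    REASON_NO_DOMAIN,
    classify_superfamily,
    cluster_elements,
    density_track,
    filter_canonical,
    lifespan,
    pair_identity_coverage,
    persistence_curve,
    tandem_repeat_fraction,
    assign_specificity,
)
from polyte.simulate import mutate_sequence, random_sequence


def _candidate(eid, elem_len=6000, ltr_len=600, strand="+"):
    return {
        "element_id": eid,
        "chrom": "chr1A",
        "elem_start": 0,
        "elem_end": elem_len,
        "ltr5_start": 0,
        "ltr5_end": ltr_len,
        "ltr3_start": elem_len - ltr_len,
        "ltr3_end": elem_len,
        "tsd_len": 5,
        "motif": "TGCA",
        "strand": strand,
    }


def _domains(eid, names, strand="+"):
    return [
        {"element_id": eid, "domain": d, "order_index": i, "strand": strand}
        for i, d in enumerate(names)
    ]


class TestFilterCanonical:
    def _run(self, cands, doms, seqs):
        return filter_canonical(
            pd.DataFrame(cands),
            pd.DataFrame(doms, columns=["element_id", "domain", "order_index", "strand"]),
            lambda eid: seqs[eid],
        )

    def test_repeated_core_domains_rejected(self, rng):
        seq = random_sequence(6000, rng)
        cands = [_candidate("e1")]
        doms = _domains("e1", ["RT", "RH", "INT", "RT", "RH"])
        retained, reasons = self._run(cands, doms, {"e1": seq})
        assert retained == []
        assert reasons["e1"] == [REASON_INCONSISTENT]

    def test_oversized_ltr_rejected(self, rng):
        # LTRs of 500 bp on an 1800-bp element: 0.278 > 0.25
        seq = random_sequence(1800, rng)
        cands = [_candidate("e1", elem_len=1800, ltr_len=500)]
        doms = _domains("e1", ["GAG", "INT", "RT", "RH"])
        retained, reasons = self._run(cands, doms, {"e1": seq})
        assert retained == []
        assert reasons["e1"] == [REASON_LTR_SIZE]

    def test_no_domains_rejected(self, rng):
        seq = random_sequence(6000, rng)
        retained, reasons = self._run([_candidate("e1")], [], {"e1": seq})
        assert retained == []
        assert REASON_NO_DOMAIN in reasons["e1"]

    def test_clean_candidate_retained(self, rng):
        seq = random_sequence(6000, rng)
        cands = [_candidate("e1")]
        doms = _domains("e1", ["GAG", "INT", "RT", "RH"])
        retained, reasons = self._run(cands, doms, {"e1": seq})
        assert retained == ["e1"]
        assert reasons == {}

    def test_unknown_element_in_domains_errors(self, rng):
        seq = random_sequence(6000, rng)
        with pytest.raises(PolyteError):
            self._run([_candidate("e1")], _domains("ghost", ["RT"]), {"e1": seq})

    def test_filter_is_a_pure_conjunction(self, rng):
        """Dropping any one criterion can only enlarge the retained set."""
        from polyte.simulate import SimulationConfig, generate_filter_violators
        from polyte.flltr import FilterParams

        cfg = SimulationConfig()
        violators, truth = generate_filter_violators(cfg, rng)
        cands = pd.DataFrame([v.candidate for v in violators])
        doms = pd.DataFrame(
            [d for v in violators for d in v.domains],
            columns=["element_id", "domain", "order_index", "strand"],
        )
        seqs = {v.element_id: v.sequence for v in violators}
        retained, _ = filter_canonical(cands, doms, lambda e: seqs[e])
        relaxed = FilterParams(max_tandem_fraction=1.1, max_ltr_fraction=1.1,
                               max_n_fraction=1.1)
        retained_relaxed, _ = filter_canonical(cands, doms, lambda e: seqs[e], relaxed)
        assert set(retained) <= set(retained_relaxed)


class TestTandemRepeatFraction:
    def test_pure_dinucleotide_array(self):
        assert tandem_repeat_fraction("AC" * 20) == 1.0

    def test_random_sequence_is_low(self, rng):
        assert tandem_repeat_fraction(random_sequence(5000, rng)) < 0.15

    def test_embedded_array_measured(self, rng):
        seq = random_sequence(700, rng) + "ACG" * 100 + random_sequence(700, rng)
        frac = tandem_repeat_fraction(seq)
        assert 0.15 < frac < 0.35


class TestClassifySuperfamily:
    @pytest.mark.parametrize(
        "domains,expected",
        [
            (("GAG", "INT", "RT", "RH"), "RLC"),
            (("RH", "RT", "INT"), "RLG"),
            (("RT",), "RLX"),
            ((), "RLX"),
        ],
    )
    def test_known_orders(self, domains, expected):
        assert classify_superfamily(domains) == expected

    def test_exhaustive_against_subsequence_oracle(self):
        """All domain orders up to length 5 match an independent oracle."""

        def oracle_embeds(order, pattern):
            pos = -1
            for d in order:
                try:
                    pos = pattern.index(d, pos + 1)
                except ValueError:
                    return False
            return True

        alphabet = ["GAG", "PROT", "INT", "RT", "RH"]
        for n in range(0, 6):
            for order in itertools.product(alphabet, repeat=n):
                core = tuple(d for d in order if d in ("INT", "RT", "RH"))
                rlc = oracle_embeds(core, ("INT", "RT", "RH"))
                rlg = oracle_embeds(core, ("RH", "RT", "INT"))
                expected = "RLC" if rlc and not rlg else "RLG" if rlg and not rlc else "RLX"
                assert classify_superfamily(order) == expected, order


class TestClustering:
    def test_identical_pair_one_cluster(self, rng):
        seq = random_sequence(500, rng)
        for ident, cov in ((0.95, 0.95), (0.8, 0.8)):
            clusters = cluster_elements({"a": seq, "b": seq}, ident, cov)
            assert len(clusters) == 1
            assert clusters[0].member_ids == ("a", "b")

    def test_threshold_separates(self, rng):
        base = random_sequence(600, rng)
        near = mutate_sequence(base, 0.02, rng)  # ~96% identity to base
        far = mutate_sequence(base, 0.18, rng)  # ~70-75% to both
        clusters = cluster_elements({"s1": base, "s2": near, "s3": far}, 0.95, 0.95)
        members = {c.member_ids for c in clusters}
        assert ("s1", "s2") in members
        assert ("s3",) in members

    def test_matches_brute_force_single_linkage(self, rng):
        """Connected components of the pairwise-threshold graph."""
        import networkx as nx

        seqs = {}
        for f in range(3):
            anc = random_sequence(400, rng)
            for k in range(6):
                seqs[f"f{f}m{k}"] = mutate_sequence(anc, rng.uniform(0, 0.1), rng)
        for ident, cov in ((0.9, 0.9), (0.8, 0.8)):
            g = nx.Graph()
            g.add_nodes_from(seqs)
            for a, b in itertools.combinations(sorted(seqs), 2):
                i, ca, cb = pair_identity_coverage(seqs[a], seqs[b])
                if i >= ident and ca >= cov and cb >= cov:
                    g.add_edge(a, b)
            oracle = {tuple(sorted(c)) for c in nx.connected_components(g)}
            ours = {c.member_ids for c in cluster_elements(seqs, ident, cov)}
            assert ours == oracle

    def test_empty_input(self):
        assert cluster_elements({}, 0.9, 0.9) == []


class TestSpecificity:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"A": 9, "B": 1, "D": 0}, "A"),
            ({"A": 45, "B": 50, "D": 5}, "AB"),
            ({"A": 5, "B": 4, "D": 1}, "ABD"),
            ({"A": 1, "B": 0, "D": 0}, "A"),
        ],
    )
    def test_decision_tree_examples(self, counts, expected):
        assert assign_specificity(counts) == expected

    def test_exhaustive_against_rule_oracle(self):
        """All membership tables with totals <= 30 match a rule-by-rule oracle."""

        def oracle(a, b, d):
            total = a + b + d
            fr = {"A": a / total, "B": b / total, "D": d / total}
            for sg in "ABD":
                if fr[sg] >= 0.90:
                    return sg
            low = [sg for sg in "ABD" if fr[sg] < 0.10]
            if len(low) == 1:
                return "".join(s for s in "ABD" if s != low[0])
            return "ABD"

        for a in range(31):
            for b in range(31 - a):
                for d in range(31 - a - b):
                    if a + b + d == 0:
                        continue
                    assert assign_specificity({"A": a, "B": b, "D": d}) == oracle(a, b, d)

    def test_empty_cluster_errors(self):
        with pytest.raises(PolyteError):
            assign_specificity({"A": 0, "B": 0, "D": 0})


class TestAgeStatistics:
    def test_lifespan_interpolation(self):
        ages = [i / 10 * 1e6 for i in range(1, 11)]
        p5, p95 = lifespan(ages)
        assert p5 == pytest.approx(0.145e6)
        assert p95 == pytest.approx(0.955e6)

    def test_lifespan_equal_ages(self):
        assert lifespan([2.0e5, 2.0e5, 2.0e5]) == (2.0e5, 2.0e5)

    def test_lifespan_two_points(self):
        a, b = 1.0e5, 9.0e5
        p5, p95 = lifespan([a, b])
        assert p5 == pytest.approx(a + 0.05 * (b - a))
        assert p95 == pytest.approx(a + 0.95 * (b - a))

    def test_lifespan_needs_two(self):
        with pytest.raises(PolyteError):
            lifespan([1.0])

    def test_persistence_conserves_count(self, rng):
        ages = rng.uniform(0, 1e6, size=300)
        curve = persistence_curve(ages)
        assert curve["count"].sum() == 300
        assert len(curve) == 100
        assert abs(curve["count"].mean() - 3.0) < 1e-9

    def test_persistence_single_bin(self):
        curve = persistence_curve([5000.0, 1000.0, 9999.0])
        assert len(curve) == 1
        assert curve["count"].iloc[0] == 3

    def test_persistence_empty(self):
        assert persistence_curve([]).empty


class TestDensityTrack:
    def test_covering_windows(self):
        els = pd.DataFrame({"chrom": ["c1A"], "start": [1_000_000]})
        track = density_track(els, {"c1A": 10_000_000})
        hit = track[track["count"] > 0]
        assert set(hit["win_start"]) == {0, 800_000}

    def test_empty_track_is_zero(self):
        els = pd.DataFrame({"chrom": [], "start": []})
        track = density_track(els, {"c1A": 5_000_000})
        assert (track["count"] == 0).all()

    def test_uniform_expectation(self, rng):
        n = 1000
        L = 20_000_000
        els = pd.DataFrame({"chrom": "c1A", "start": rng.integers(0, L, n)})
        track = density_track(els, {"c1A": L})
        full = track[track["win_end"] - track["win_start"] == 4_000_000]
        expected = n * 4_000_000 / L
        assert abs(full["count"].mean() - expected) < 0.15 * expected
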