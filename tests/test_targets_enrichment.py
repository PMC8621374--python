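"""Target-site penalty scoring against a brute-force scan, and
hypergeometric enrichment against exhaustive draw enumeration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mirpipe import enrichment, targets
from mirpipe.util import revcomp


def penalty_oracle(mature, site):
    """Score one mature/site alignment position by position."""
    total = 0.0
    mm = 0
    gu = 0
    L = len(mature)
    for k in range(L):
        a = mature[k]
        b = site[L - 1 - k]  # antiparallel pairing
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[a]
        if b == comp:
            pen = 0.0
        elif (a, b) in (("G", "T"), ("T", "G")):
            pen = 0.5
            gu += 1
        else:
            pen = 1.0
            mm += 1
        if 2 <= k + 1 <= 13:
            pen *= 2
        total += pen
    return total, mm, gu


class TestTargetScoring:
    MATURE = "ACGTACGTACGTACGTACGTA"  # 21 nt

    def test_exact_reverse_complement_scores_zero(self):
        site = revcomp(self.MATURE)
        tx = {"t1": "AAAA" + site + "CCCC"}
        hits = targets.predict_targets("m", self.MATURE, tx)
        best = [h for h in hits if h.is_best_match][0]
        assert best.penalty_score == 0.0
        assert best.mismatches == 0
        assert best.site_start == 4

    def test_single_gu_outside_seed_region_scores_half(self):
        site = list(revcomp(self.MATURE))
        # mature position 15 (1-based 16, outside 2-13) pairs site index L-1-15 = 5
        k = 15
        a = self.MATURE[k]
        site[len(site) - 1 - k] = "T" if a == "G" else "G"
        if a not in "GT":
            pytest.skip("construction needs G or T at that position")
        tx = {"t1": "AAAA" + "".join(site) + "CCCC"}
        hits = targets.predict_targets("m", self.MATURE, tx)
        best = [h for h in hits if h.is_best_match][0]
        assert best.penalty_score == 0.5
        assert best.gu_pairs == 1
        assert best.mismatches == 0

    def test_mismatch_in_seed_region_scores_two(self):
        site = list(revcomp(self.MATURE))
        k = 5  # 1-based position 6, inside 2-13
        a = self.MATURE[k]
        bad = {"A": "C", "C": "A", "G": "A", "T": "C"}[a]
        site[len(site) - 1 - k] = bad
        tx = {"t1": "AAAA" + "".join(site) + "CCCC"}
        hits = targets.predict_targets("m", self.MATURE, tx)
        best = [h for h in hits if h.is_best_match][0]
        assert best.penalty_score == 2.0
        assert best.mismatches == 1

    def test_agrees_with_bruteforce_scan(self, rng):
        mature = "".join(rng.choice(list("ACGT"), 21))
        txs = {}
        for i in range(10):
            seq = list("".join(rng.choice(list("ACGT"), 300)))
            if i % 2 == 0:  # plant a degenerate site
                site = list(revcomp(mature))
                for _ in range(int(rng.integers(0, 4))):
                    p = int(rng.integers(0, len(site)))
                    site[p] = "ACGT"[int(rng.integers(0, 4))]
                pos = int(rng.integers(0, 300 - len(site)))
                seq[pos : pos + len(site)] = site
            txs[f"t{i}"] = "".join(seq)
        hits = targets.predict_targets("m", mature, txs, report_best_if_none=False)
        expected = []
        for tid, seq in txs.items():
            for off in range(len(seq) - len(mature) + 1):
                pen, mm, gu = penalty_oracle(mature, seq[off : off + len(mature)])
                if pen <= 4.0 and mm <= 3:
                    expected.append((tid, off, pen, mm, gu))
        got = [(h.transcript_id, h.site_start, h.penalty_score, h.mismatches, h.gu_pairs)
               for h in hits]
        assert sorted(got) == sorted(expected)

    def test_best_match_reported_when_nothing_qualifies(self, rng):
        mature = "".join(rng.choice(list("ACGT"), 21))
        txs = {"t1": "".join(rng.choice(list("ACGT"), 200))}
        hits = targets.predict_targets("m", mature, txs)
        if all(h.penalty_score > 4.0 or h.mismatches > 3 for h in hits):
            assert len(hits) == 1
            assert hits[0].is_best_match

    def test_short_mature_rejected(self):
        with pytest.raises(ValueError):
            targets.predict_targets("m", "ACGTACGT", {"t": "ACGT" * 30})


def enumeration_oracle(N, K, n, k):
    """P(X >= k) by enumerating every n-draw from an N-gene universe."""
    genes = range(N)
    special = set(range(K))
    total = 0
    hit = 0
    for draw in itertools.combinations(genes, n):
        total += 1
        if len(special & set(draw)) >= k:
            hit += 1
    return hit / total


class TestEnrichment:
    def _table(self, assignment):
        return pd.DataFrame(
            [(g, t, "BP") for g, terms in assignment.items() for t in terms],
            columns=["gene_id", "term_id", "domain"],
        )

    def test_closed_form_full_overlap(self):
        # all 5 target genes carry the term held by exactly 5 of 20 genes
        genes = [f"g{i}" for i in range(20)]
        table = self._table({g: ["T1"] if i < 5 else ["T2"] for i, g in enumerate(genes)})
        out = enrichment.enrich(genes[:5], table, genes)
        t1 = [t for t in out if t.term_id == "T1"][0]
        assert math.isclose(t1.p_value, 1 / math.comb(20, 5), rel_tol=1e-12)

    def test_universe_covering_term_is_not_significant(self):
        genes = [f"g{i}" for i in range(10)]
        table = self._table({g: ["ALL"] for g in genes})
        out = enrichment.enrich(genes[:4], table, genes)
        assert out[0].p_value == 1.0

    def test_matches_exhaustive_enumeration(self):
        for N, K, n in ((8, 3, 4), (10, 4, 5), (12, 6, 4)):
            genes = [f"g{i}" for i in range(N)]
            table = self._table(
                {g: (["T"] if i < K else ["other"]) for i, g in enumerate(genes)}
            )
            for k in range(1, min(K, n) + 1):
                # target set with exactly k term genes
                target = genes[:k] + genes[K : K + n - k]
                out = enrichment.enrich(target, table, genes)
                t = [x for x in out if x.term_id == "T"][0]
                assert math.isclose(
                    t.p_value, enumeration_oracle(N, K, n, k), rel_tol=1e-9
                ), (N, K, n, k)

    def test_bonferroni_never_below_raw(self, rng):
        genes = [f"g{i}" for i in range(30)]
        table = self._table(
            {g: [f"T{int(rng.integers(6))}" for _ in range(2)] for g in genes}
        )
        out = enrichment.enrich(genes[:8], table, genes)
        for t in out:
            assert t.p_bonferroni >= t.p_value
            assert t.p_bonferroni <= 1.0

    def test_p_monotone_nonincreasing_in_k(self):
        ps = [enrichment.hypergeom_tail(k, 40, 10, 12) for k in range(1, 10)]
        assert all(nxt <= prev for prev, nxt in zip(ps, ps[1:]))  # larger k -> smaller p

    def test_target_outside_universe_rejected(self):
        table = self._table({"g1": ["T"]})
        with pytest.raises(ValueError):
            enrichment.enrich(["gX"], table, ["g1"])


class TestSummarize:
    def _terms(self, specs):
        return [
            enrichment.EnrichmentTerm(
                term_id=t, domain="pathway", k=2, K=5, n=10, N=50,
                p_value=p, p_bonferroni=min(1, p * len(specs)), rich_factor=0.4,
                significant=p * len(specs) < 0.05,
            )
            for t, p in specs
        ]

    def test_keeps_only_significant_rows(self):
        terms = self._terms([("a", 0.001), ("b", 0.01), ("c", 0.2), ("d", 0.04)])
        out = enrichment.summarize_pathways(terms)
        assert list(out["term_id"]) == ["a", "b", "d"]

    def test_ties_break_by_term_id(self):
        terms = self._terms([("zz", 0.01), ("aa", 0.01)])
        out = enrichment.summarize_pathways(terms)
        assert list(out["term_id"]) == ["aa", "zz"]

    def test_invariant_to_input_order(self):
        terms = self._terms([("a", 0.02), ("b", 0.001), ("c", 0.03)])
        a = enrichment.summarize_pathways(terms)
        b = enrichment.summarize_pathways(list(reversed(terms)))
        pd.testing.assert_frame_equal(a, b)

    def test_top_m_cap(self):
        terms = self._terms([(f"t{i:02d}", 0.0001 * (i + 1)) for i in range(30)])
        out = enrichment.summarize_pathways(terms, top_m=20)
        assert len(out) == 20
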