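"""cis/trans pairing rules, random-pair null, neighbor classes, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lnckit.annotation import AnnotationSet
from lnckit.expression import ExpressionMatrix
from lnckit.targets import (
    cis_targets,
    hypergeometric_enrichment,
    neighbor_correlation_analysis,
    random_pair_null,
    read_gmt,
    rich_factor,
    trans_targets,
    write_gmt,
)
from .conftest import make_transcript


def coding_locus(locus, start, chrom="chr1", length=2000):
    return make_transcript(
        f"{locus}.1", [(start, start + length)], chrom=chrom, locus=locus,
        biotype="protein_coding",
    )


def expr_from_rows(rows: dict[str, np.ndarray]):
    vals = pd.DataFrame(rows).T
    vals.columns = [f"s{i}" for i in range(vals.shape[1])]
    return ExpressionMatrix(vals.clip(lower=0), {c: "g" for c in vals.columns})


class TestCisTargets:
    def setup_method(self):
        self.lnc = make_transcript("lnc1", [(0, 1000)])
        self.mrnas = AnnotationSet(
            [
                coding_locus("near", 51_000),  # 50 kb gap
                coding_locus("boundary", 101_000),  # exactly 100,000 gap
                coding_locus("far", 151_000),  # 150 kb gap
                coding_locus("other", 1000, chrom="chr2"),
            ]
        )

    def test_window_rule_inclusive(self):
        pairs = cis_targets([self.lnc], self.mrnas, window=100_000)
        found = {p.mrna_id: p.distance for p in pairs}
        assert set(found) == {"near", "boundary"}
        assert found["near"] == 50_000
        assert found["boundary"] == 100_000

    def test_overlapping_locus_distance_zero(self):
        mrnas = AnnotationSet([coding_locus("ov", 500)])
        (pair,) = cis_targets([self.lnc], mrnas)
        assert pair.distance == 0 and pair.mode == "cis"

    def test_pcc_attached_from_expression(self):
        rng = np.random.default_rng(71)
        x = rng.uniform(1, 10, 9)
        expr = expr_from_rows({"lnc1": x, "near.1": x, "boundary.1": rng.uniform(1, 10, 9)})
        pairs = {p.mrna_id: p for p in cis_targets([self.lnc], self.mrnas, expr)}
        assert pairs["near"].pcc == pytest.approx(1.0)


class TestTransTargets:
    def test_rules(self):
        lnc = make_transcript("lnc1", [(0, 1000)])
        mrnas = AnnotationSet(
            [
                coding_locus("close", 51_000),
                coding_locus("distant", 300_000),
                coding_locus("elsewhere", 1000, chrom="chr2"),
            ]
        )
        rng = np.random.default_rng(73)
        x = np.arange(9, dtype=float) + 1
        expr = expr_from_rows(
            {
                "lnc1": x,
                "close.1": 2 * x,  # perfectly correlated but within window
                "distant.1": 100 - 5 * x,  # anticorrelated beyond window
                "elsewhere.1": 3 * x,  # correlated, other chromosome
            }
        )
        pairs = trans_targets([lnc], mrnas, expr, pcc_min=0.95, window=100_000)
        modes = {p.mrna_id: p for p in pairs}
        assert set(modes) == {"distant", "elsewhere"}
        assert modes["distant"].pcc < -0.95
        assert math.isinf(modes["elsewhere"].distance)

    def test_disjoint_from_cis(self):
        lnc = make_transcript("lnc1", [(0, 1000)])
        mrnas = AnnotationSet([coding_locus(f"g{i}", 10_000 + 120_000 * i) for i in range(4)])
        rng = np.random.default_rng(79)
        rows = {"lnc1": rng.uniform(1, 10, 9)}
        rows.update({f"g{i}.1": rng.uniform(1, 10, 9) for i in range(4)})
        expr = expr_from_rows(rows)
        cis_keys = {(p.lncrna_id, p.mrna_id) for p in cis_targets([lnc], mrnas, expr)}
        trans_keys = {
            (p.lncrna_id, p.mrna_id)
            for p in trans_targets([lnc], mrnas, expr, pcc_min=0.0)
        }
        assert cis_keys and cis_keys.isdisjoint(trans_keys)


class TestRandomPairNull:
    def test_deterministic_under_seed(self):
        ids = [f"g{i}" for i in range(50)]
        assert random_pair_null(ids, 20, seed=5) == random_pair_null(ids, 20, seed=5)
        assert random_pair_null(ids, 20, seed=5) != random_pair_null(ids, 20, seed=6)

    def test_exhausts_all_pairs_of_four(self):
        pairs = random_pair_null(list("abcd"), 6, seed=1)
        assert len(pairs) == 6
        assert {frozenset(p) for p in pairs} == {
            frozenset(c) for c in itertools.combinations("abcd", 2)
        }

    def test_too_many_pairs_errors(self):
        with pytest.raises(ValueError):
            random_pair_null(list("abc"), 4, seed=1)

    def test_null_mean_pcc_near_zero(self):
        rng = np.random.default_rng(83)
        n_genes, n_samples = 60, 9
        rows = {f"g{i}": rng.uniform(0, 4, n_samples) for i in range(n_genes)}
        frame = pd.DataFrame(rows).T
        pairs = random_pair_null(list(rows), 1000, seed=2)
        pccs = np.array(
            [np.corrcoef(frame.loc[a], frame.loc[b])[0, 1] for a, b in pairs]
        )
        se = pccs.std(ddof=1) / np.sqrt(pccs.size)
        assert abs(pccs.mean()) < 3 * se + 0.05


class TestNeighborCorrelation:
    @staticmethod
    def _design(rho=0.3, seed=89, n_lnc=30):
        """Each lncRNA sits near one coding gene; neighbor log-expression is
        correlated at rho, the coding genes also pair with a second nearby
        coding gene at rho, and everything else is independent."""
        rng = np.random.default_rng(seed)
        lncs, coding, rows = [], [], {}
        n_samples = 60  # many samples so the sample PCC concentrates near rho
        for i in range(n_lnc):
            base = 3_000_000 * i
            lnc = make_transcript(f"lnc{i}", [(base, base + 1000)])
            g1 = coding_locus(f"gA{i}", base + 31_000)
            g2 = coding_locus(f"gB{i}", base + 81_000)
            lncs.append(lnc)
            coding.extend([g1, g2])
            z = rng.normal(size=(3, n_samples))
            shared = rng.normal(size=n_samples)
            w = np.sqrt(rho)
            trio = [
                w * shared + np.sqrt(1 - rho) * z[j] for j in range(3)
            ]
            rows[f"lnc{i}"] = 10 ** (3 + trio[0]) - 1
            rows[f"gA{i}.1"] = 10 ** (3 + trio[1]) - 1
            rows[f"gB{i}.1"] = 10 ** (3 + trio[2]) - 1
        return lncs, AnnotationSet(coding), expr_from_rows(rows)

    def test_recovers_planted_rho(self):
        rho = 0.3
        lncs, mrnas, expr = self._design(rho=rho)
        summaries, pvalues = neighbor_correlation_analysis(
            lncs, mrnas, expr, window=100_000, seed=3
        )
        for cls in ("lnc_cis", "mrna_cis"):
            s = summaries[cls]
            se = s.pccs.std(ddof=1) / np.sqrt(s.n)
            assert abs(s.mean_pcc - rho) < 4 * se + 0.02, cls
        r = summaries["random"]
        se_r = r.pccs.std(ddof=1) / np.sqrt(r.n)
        assert abs(r.mean_pcc) < 4 * se_r + 0.02
        assert pvalues["lnc_cis_vs_random"] < 0.01
        assert pvalues["mrna_cis_vs_random"] < 0.01

    def test_matched_classes_show_no_false_difference(self):
        lncs, mrnas, expr = self._design(rho=0.3, seed=97)
        _, pvalues = neighbor_correlation_analysis(lncs, mrnas, expr, seed=4)
        assert pvalues["lnc_cis_vs_mrna_cis"] > 0.001

    def test_degenerate_expression_errors(self):
        lncs, mrnas, _ = self._design(n_lnc=3)
        ids = [t.transcript_id for t in lncs] + [t.transcript_id for t in mrnas]
        flat = expr_from_rows({tid: np.ones(9) for tid in ids})
        with pytest.raises(ValueError):
            neighbor_correlation_analysis(lncs, mrnas, flat, seed=5)


class TestEnrichment:
    def test_closed_form_example(self):
        res = hypergeometric_enrichment(
            foreground=["a", "b", "c", "d"],
            background=[*"abcdefghij"],
            gene_sets={"T": ["a", "b", "c", "d", "e"]},
        )
        assert res[0].p_raw == pytest.approx(5 / 210)
        assert res[0].rich_factor == pytest.approx(4 / 5)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(101)
        for _ in range(30):
            N = int(rng.integers(4, 13))
            background = [f"g{i}" for i in range(N)]
            n = int(rng.integers(1, N + 1))
            foreground = list(rng.choice(background, size=n, replace=False))
            K = int(rng.integers(1, N + 1))
            term = list(rng.choice(background, size=K, replace=False))
            (res,) = hypergeometric_enrichment(foreground, background, {"T": term})
            k_obs = len(set(term) & set(foreground))
            hits = sum(
                1
                for combo in itertools.combinations(background, n)
                if len(set(combo) & set(term)) >= k_obs
            )
            expected = hits / math.comb(N, n)
            assert res.p_raw == pytest.approx(expected, abs=1e-12)

    def test_tail_definition_edges(self):
        res = hypergeometric_enrichment(["a"], [*"abcdef"], {"none": ["b", "c"], "all": [*"abcdef"]})
        by_term = {r.term_id: r for r in res}
        assert by_term["all"].p_raw == pytest.approx(1.0)  # term holds everything
        assert by_term["none"].k == 0 and by_term["none"].p_raw == pytest.approx(1.0)

    def test_q_at_least_p_and_family_growth_shrinks_calls(self):
        rng = np.random.default_rng(103)
        background = [f"g{i}" for i in range(40)]
        foreground = background[:10]
        sets_small = {f"T{i}": list(rng.choice(background, 8, replace=False)) for i in range(4)}
        sets_small["hit"] = foreground[:8]
        sets_big = dict(sets_small)
        sets_big.update(
            {f"U{i}": list(rng.choice(background, 8, replace=False)) for i in range(20)}
        )
        small = hypergeometric_enrichment(foreground, background, sets_small)
        big = hypergeometric_enrichment(foreground, background, sets_big)
        for r in small + big:
            assert r.q >= r.p_raw - 1e-12
        sig_small = {r.term_id for r in small if r.significant}
        sig_big = {r.term_id for r in big if r.significant and r.term_id in sets_small}
        assert sig_big <= sig_small

    def test_foreground_outside_background_errors(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(["zz"], ["a", "b"], {"T": ["a"]})

    def test_rich_factor(self):
        assert rich_factor(5, 20) == pytest.approx(0.25)
        assert rich_factor(0, 7) == 0.0
        assert rich_factor(7, 7) == 1.0
        with pytest.raises(ValueError):
            rich_factor(1, 0)


def test_gmt_round_trip(tmp_path):
    sets = {"T1": ["a", "b"], "T2": ["c"]}
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path, descriptions={"T1": "first"})
    assert read_gmt(path) == sets
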