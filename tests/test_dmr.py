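"""Bump hunting: clustering, smoothing, region calling, permutation FWER."""

import numpy as np
import pandas as pd
import pytest

from lifemeth.dmp import build_design
from lifemeth.dmr import (
    DMRParams,
    DMRResult,
    assess_fwer,
    cluster_probes,
    dmr_table,
    find_bumps,
    run_dmr_ewas,
    smooth_effects,
)


def ann_from(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "chromosome": chrom if isinstance(chrom, list) else [chrom] * len(positions),
            "position": positions,
            "gene": ["G"] * len(positions),
        },
        index=[f"cg{i}" for i in range(len(positions))],
    )


class TestClustering:
    def test_gap_rule(self):
        cl = cluster_probes(ann_from([100, 300, 1200]), max_gap=500)
        assert cl.tolist() == [0, 0, 1]

    def test_chromosomes_never_share_clusters(self):
        ann = ann_from([100, 150], chrom=["chr1", "chr2"])
        cl = cluster_probes(ann, max_gap=10**9)
        assert cl.nunique() == 2

    def test_zero_gap_makes_singletons(self):
        cl = cluster_probes(ann_from([100, 101, 102]), max_gap=0)
        assert cl.nunique() == 3

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="chr1:100"):
            cluster_probes(ann_from([100, 100]))


class TestSmoothing:
    def test_constant_signal_is_fixed_point(self):
        e = np.full(7, 0.3)
        assert np.allclose(smooth_effects(e, np.zeros(7, int), 5), 0.3)

    def test_window_one_is_identity(self):
        e = np.array([0.1, -0.2, 0.5])
        assert np.allclose(smooth_effects(e, np.zeros(3, int), 1), e)

    def test_hand_computed_truncated_mean(self):
        e = np.array([0.0, 0.3, 0.0])
        out = smooth_effects(e, np.zeros(3, int), 3)
        assert np.allclose(out, [0.15, 0.1, 0.15])

    def test_small_clusters_pass_through(self):
        e = np.array([0.5, -0.5, 0.1, 0.2, 0.3])
        cl = np.array([0, 0, 1, 1, 1])
        out = smooth_effects(e, cl, 3)
        assert np.allclose(out[:2], e[:2])  # 2-probe cluster untouched
        assert out[2] == pytest.approx((0.1 + 0.2) / 2)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_effects(np.zeros(3), np.zeros(3, int), 4)


class TestFindBumps:
    def test_subthreshold_signal_yields_nothing(self):
        sm = np.full(10, 0.005)
        assert find_bumps(sm, sm, np.zeros(10, int), ann_from(range(10)), 0.01) == []

    def test_run_of_five_called_once(self):
        sm = np.array([0.0, 0.05, 0.05, 0.05, 0.05, 0.05, 0.0])
        ann = ann_from([100 * i for i in range(1, 8)])
        out = find_bumps(sm, sm, np.zeros(7, int), ann, 0.01, 3)
        assert len(out) == 1
        assert out[0].n_probes == 5
        assert out[0].area == pytest.approx(0.25)

    def test_short_run_discarded(self):
        sm = np.array([0.0, 0.05, 0.05, 0.0])
        ann = ann_from([100, 200, 300, 400])
        assert find_bumps(sm, sm, np.zeros(4, int), ann, 0.01, 3) == []

    def test_sign_change_splits_runs(self):
        sm = np.array([0.05, 0.05, 0.05, -0.05, -0.05, -0.05])
        ann = ann_from([100 * i for i in range(1, 7)])
        out = find_bumps(sm, sm, np.zeros(6, int), ann, 0.01, 3)
        assert len(out) == 2
        assert {r.n_probes for r in out} == {3}

    def test_regions_disjoint_and_within_bounds(self, spiked_bundle):
        _, pheno, meth, _ = spiked_bundle
        dmrs = run_dmr_ewas(meth, pheno, DMRParams(n_permutations=10, seed=0))
        spans = sorted(
            ((d.chromosome, d.start, d.end) for d in dmrs), key=lambda t: (t[0], t[1])
        )
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            assert c1 != c2 or e1 < s2
        for d in dmrs:
            assert d.n_probes >= 3 and d.start <= d.end


class TestFWER:
    def _toy(self, seed=0, n=120, probes=300):
        rng = np.random.default_rng(seed)
        pheno = pd.DataFrame(
            {
                "cli_index": rng.integers(0, 2, n),
                "age": rng.normal(50, 10, n),
                "sex": rng.choice(["male", "female"], n),
            },
            index=[f"S{i}" for i in range(n)],
        )
        beta = np.clip(rng.normal(0.5, 0.05, (probes, n)), 0, 1)
        return pheno, beta

    def test_dominant_candidate_gets_floor_fwer(self):
        pheno, beta = self._toy()
        design = build_design(pheno)
        cand = [
            DMRResult(
                chromosome="chr1", start=1, end=999, n_probes=3,
                probe_ids=("a", "b", "c"), area=1e9, avg_delta_beta=0.1,
            )
        ]
        params = DMRParams(n_permutations=100, seed=1)
        out = assess_fwer(beta, design, cand, np.zeros(beta.shape[0], int), params)
        assert out[0].fwer == pytest.approx(1 / 101)

    def test_fwer_monotone_in_area(self):
        pheno, beta = self._toy(seed=3)
        design = build_design(pheno)
        cands = [
            DMRResult("chr1", 1, 10, 3, ("a", "b", "c"), area, 0.05)
            for area in (0.02, 0.08, 0.4)
        ]
        clusters = np.repeat(np.arange(100), 3)
        out = assess_fwer(beta, design, cands, clusters, DMRParams(n_permutations=50, seed=2))
        fwers = [d.fwer for d in sorted(out, key=lambda d: d.area)]
        assert fwers == sorted(fwers, reverse=True)

    def test_empty_candidates_short_circuit(self):
        pheno, beta = self._toy()
        out = assess_fwer(beta, build_design(pheno), [], np.zeros(beta.shape[0], int),
                          DMRParams(n_permutations=10))
        assert out == []


class TestRunDMR:
    def test_spiked_region_recovered(self, spiked_bundle):
        _, pheno, meth, truth = spiked_bundle
        dmrs = run_dmr_ewas(meth, pheno, DMRParams(n_permutations=100, seed=5))
        span = truth.spiked_region_spans[0]
        hits = [
            d for d in dmrs
            if d.chromosome == span["chromosome"] and d.fwer is not None
            and d.fwer < 0.05
        ]
        assert hits, "spiked region not detected at FWER < 0.05"
        best = max(hits, key=lambda d: d.area)
        overlap = len(set(best.probe_ids) & set(span["probe_ids"]))
        assert overlap / len(span["probe_ids"]) >= 0.8
        assert best.avg_delta_beta == pytest.approx(span["delta_beta"], abs=0.02)

    def test_null_data_has_no_significant_region(self, null_bundle):
        _, pheno, meth, _ = null_bundle
        dmrs = run_dmr_ewas(meth, pheno, DMRParams(n_permutations=100, seed=8))
        assert all(d.fwer >= 0.05 for d in dmrs)

    def test_fixed_seed_reproduces_fwer(self, spiked_bundle):
        _, pheno, meth, _ = spiked_bundle
        p = DMRParams(n_permutations=30, seed=11)
        t1 = dmr_table(run_dmr_ewas(meth, pheno, p))
        t2 = dmr_table(run_dmr_ewas(meth, pheno, p))
        pd.testing.assert_frame_equal(t1, t2)


def test_min_probes_floor_enforced():
    with pytest.raises(ValueError, match="3"):
        DMRParams(min_probes=2)
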