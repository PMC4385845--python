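"""Probe selection, single-linkage clustering, region aggregation."""

import numpy as np
import pandas as pd
import pytest

from dysmark.errors import DegenerateDataError
from dysmark.methylation import (
    aggregate_regions,
    meth_expr_correlation,
    select_probes,
    single_linkage_cluster,
)

from conftest import make_paired_matrix


def make_beta_matrix(probe_deltas, n_pairs=10, baseline=0.5, noise=0.0, seed=0):
    """Paired beta matrix where each probe's tumors are shifted by a fixed
    delta from the shared baseline."""
    rng = np.random.default_rng(seed)
    rows = {}
    for probe, delta in probe_deltas.items():
        nrm = baseline + noise * rng.standard_normal(n_pairs)
        tum = nrm + delta + noise * rng.standard_normal(n_pairs)
        rows[probe] = np.concatenate([tum, nrm])
    tids = [f"P{i}-T" for i in range(n_pairs)]
    nids = [f"P{i}-N" for i in range(n_pairs)]
    values = pd.DataFrame(rows, index=tids + nids).T
    m, c = make_paired_matrix([0.0] * n_pairs, [0.0] * n_pairs)
    from dysmark.matrix import FeatureMatrix

    return FeatureMatrix(values=values, sample_meta=m.sample_meta), c


def naive_single_linkage(points):
    """O(n^3) agglomeration oracle: repeatedly merge the two clusters with
    the smallest minimum pairwise distance.  Returns a list of
    (frozenset_a, frozenset_b, distance) merge records."""
    pts = np.asarray(points, dtype=float)
    clusters = [frozenset([i]) for i in range(len(pts))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = min(
                    np.linalg.norm(pts[a] - pts[b])
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], d))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def scipy_merge_sets(merges, n):
    """Convert a scipy linkage matrix into (set_a, set_b, distance) records."""
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, d, _) in enumerate(merges):
        sa, sb = members[int(a)], members[int(b)]
        out.append((sa, sb, float(d)))
        members[n + k] = sa | sb
    return out


class TestSelectProbes:
    def test_flat_probe_excluded_shifted_probe_included(self):
        m, c = make_beta_matrix({"flat": 0.0, "shifted": -0.3})
        selected, p = select_probes(m, c)
        assert "flat" not in selected  # identical betas -> p=1
        assert p["flat"] == 1.0
        assert "shifted" in selected  # constant nonzero shift -> p=0
        assert p["shifted"] == 0.0

    def test_noisy_shift_detected(self):
        m, c = make_beta_matrix({"dm": -0.2, "null": 0.0}, n_pairs=20,
                                noise=0.03, seed=3)
        selected, _ = select_probes(m, c)
        assert selected == ["dm"]

    def test_invariant_to_probe_and_sample_order(self):
        m, c = make_beta_matrix({"a": -0.2, "b": 0.0, "c": 0.1},
                                n_pairs=12, noise=0.05, seed=4)
        sel1, _ = select_probes(m, c, alpha=0.05)
        from dysmark.matrix import FeatureMatrix

        perm = m.values.iloc[::-1, ::-1]
        m2 = FeatureMatrix(values=perm, sample_meta=m.sample_meta)
        sel2, _ = select_probes(m2, c, alpha=0.05)
        assert sorted(sel1) == sorted(sel2)

    def test_no_passing_probe_is_empty_not_error(self):
        m, c = make_beta_matrix({"null1": 0.0, "null2": 0.0}, noise=0.05)
        selected, _ = select_probes(m, c)
        assert selected == []


class TestSingleLinkage:
    def test_three_points_on_a_line(self):
        df = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        res = single_linkage_cluster(df, axis="probes")
        assert res.merges[0, 2] == pytest.approx(1.0)
        assert res.merges[1, 2] == pytest.approx(9.0)
        assert sorted(res.merges[0, :2]) == [0, 1]

    def test_identical_items_merge_at_zero(self):
        df = pd.DataFrame([[0.3, 0.6], [0.3, 0.6], [0.9, 0.1]],
                          index=["a", "b", "c"])
        res = single_linkage_cluster(df)
        assert res.merges[0, 2] == 0.0

    def test_matches_naive_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 11))
            pts = rng.uniform(size=(n, 3))
            df = pd.DataFrame(pts, index=[f"p{i}" for i in range(n)])
            res = single_linkage_cluster(df)
            got = scipy_merge_sets(res.merges, n)
            want = naive_single_linkage(pts)
            for (ga, gb, gd), (wa, wb, wd) in zip(got, want):
                assert {ga, gb} == {wa, wb}
                assert gd == pytest.approx(wd, rel=1e-9)

    def test_merge_distances_never_decrease(self, rng):
        pts = rng.uniform(size=(15, 4))
        res = single_linkage_cluster(pd.DataFrame(pts))
        assert np.all(np.diff(res.merges[:, 2]) >= -1e-12)

    def test_missing_values_imputed_by_probe_median(self):
        df = pd.DataFrame(
            [[0.1, np.nan, 0.3], [0.1, 0.2, 0.3], [0.8, 0.9, 0.7]],
            index=["a", "b", "c"],
        )
        res = single_linkage_cluster(df)
        assert res.merges.shape == (2, 4)


class TestAggregateRegions:
    def _annotation(self, mapping):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": range(len(mapping)),
                "end": range(1, len(mapping) + 1),
                "probe_id": list(mapping),
                "region_label": list(mapping.values()),
            }
        )

    def test_uniform_shift_recovered_exactly(self):
        m, c = make_beta_matrix({"p1": -0.2, "p2": -0.2})
        ann = self._annotation({"p1": "alpha_promoter", "p2": "alpha_promoter"})
        regions = aggregate_regions(m, c, ann)
        assert len(regions) == 1
        assert regions[0].mean_delta_beta == pytest.approx(-0.2)
        assert regions[0].direction == "hypo"

    def test_mixed_probes_average(self):
        m, c = make_beta_matrix({"up": 0.1, "down": -0.3})
        ann = self._annotation({"up": "beta_promoter", "down": "beta_promoter"})
        regions = aggregate_regions(m, c, ann)
        assert regions[0].mean_delta_beta == pytest.approx(-0.1)
        assert regions[0].direction == "hypo"

    def test_probe_permutation_invariance(self):
        deltas = {"a": -0.1, "b": 0.05, "c": -0.2}
        ann = self._annotation({k: "body" for k in deltas})
        m1, c = make_beta_matrix(deltas)
        m2, _ = make_beta_matrix(dict(reversed(deltas.items())))
        r1 = aggregate_regions(m1, c, ann)[0]
        r2 = aggregate_regions(m2, c, ann)[0]
        assert r1.mean_delta_beta == pytest.approx(r2.mean_delta_beta)


class TestMethExprCorrelation:
    def test_perfect_anticorrelation(self, default_cohort):
        syn = default_cohort
        probe = syn.truth.correlated_probe_id
        from dysmark.matrix import FeatureMatrix

        # expression constructed as an exact affine flip of the probe's beta
        beta = syn.methylation.feature(probe)
        expr = FeatureMatrix(
            values=pd.DataFrame({s: [1.0 - beta[s]] for s in beta.index},
                                index=["FLIP"]),
            sample_meta=syn.methylation.sample_meta,
        )
        r, p, n = meth_expr_correlation(
            syn.methylation, expr, probe, "FLIP", log2_expression=False
        )
        assert r == pytest.approx(-1.0)

    def test_null_correlation_is_small(self, rng):
        hits = 0
        for trial in range(20):
            m, c = make_beta_matrix({"p": 0.0}, n_pairs=500, noise=0.05,
                                    seed=trial)
            from dysmark.matrix import FeatureMatrix

            expr = FeatureMatrix(
                values=pd.DataFrame(
                    [rng.lognormal(5, 1, len(m.sample_ids))],
                    index=["G"], columns=m.sample_ids,
                ),
                sample_meta=m.sample_meta,
            )
            r, _, n = meth_expr_correlation(m, expr, "p", "G")
            assert n == 1000
            if abs(r) < 0.1:
                hits += 1
        assert hits >= 19

    def test_zero_variance_rejected(self):
        m, c = make_beta_matrix({"p": 0.0})  # constant betas
        from dysmark.matrix import FeatureMatrix

        expr = FeatureMatrix(
            values=pd.DataFrame([np.arange(len(m.sample_ids), dtype=float)],
                                index=["G"], columns=m.sample_ids),
            sample_meta=m.sample_meta,
        )
        with pytest.raises(DegenerateDataError):
            meth_expr_correlation(m, expr, "p", "G")
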