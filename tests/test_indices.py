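"""Vegetation-index families, pair-correlation maps and feature assembly."""

import itertools

import numpy as np
import pytest

from anthospec.containers import SpectraSet
from anthospec.indices import (build_feature_matrix, compute_index,
                               pair_correlation_map, top_k_pairs)
from anthospec.preprocess import pearson_with_p


def spectra_from(values, wl, kind="fd"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    return SpectraSet(np.asarray(wl, dtype=float), values,
                      [f"s{i}" for i in range(n)], np.full(n, 7),
                      ["2-4"] * n, kind)


class TestComputeIndex:
    def test_hand_values(self):
        # Ri=0.2, Rj=0.5: ARI = 5 - 2 = 3; CI = -0.3/0.5 = -0.6;
        # DVI = -0.3; NARI = (0.5-0.2)/(0.7) = 3/7
        assert compute_index("ARI", 0.2, 0.5) == pytest.approx(3.0)
        assert compute_index("CI", 0.2, 0.5) == pytest.approx(-0.6)
        assert compute_index("DVI", 0.2, 0.5) == pytest.approx(-0.3)
        assert compute_index("NARI", 0.2, 0.5) == pytest.approx(3.0 / 7.0)

    def test_ci_half(self):
        # Ri=0.3, Rj=0.2 -> CI = 0.1/0.2 = 0.5
        assert compute_index("CI", 0.3, 0.2) == pytest.approx(0.5)

    def test_nari_equivalent_forms(self, rng):
        ri = rng.uniform(0.05, 0.9, size=50)
        rj = rng.uniform(0.05, 0.9, size=50)
        direct = (1 / ri - 1 / rj) / (1 / ri + 1 / rj)
        np.testing.assert_allclose(compute_index("NARI", ri, rj), direct,
                                   rtol=1e-12)

    def test_antisymmetry(self, rng):
        ri = rng.uniform(0.05, 0.9, size=30)
        rj = rng.uniform(0.05, 0.9, size=30)
        for fam in ("ARI", "DVI", "NARI"):
            np.testing.assert_allclose(compute_index(fam, ri, rj),
                                       -compute_index(fam, rj, ri),
                                       rtol=1e-12)
        # CI is *not* antisymmetric: orientation carries information
        assert not np.allclose(compute_index("CI", ri, rj),
                               -compute_index("CI", rj, ri))

    def test_near_zero_denominator_masked(self):
        v = compute_index("ARI", np.array([1e-12, 0.5]),
                          np.array([0.5, 1e-12]))
        assert np.isnan(v).all()
        v = compute_index("CI", np.array([0.5]), np.array([1e-12]))
        assert np.isnan(v[0])
        # DVI has no denominator -> never masked
        v = compute_index("DVI", np.array([1e-12]), np.array([1e-12]))
        assert np.isfinite(v[0])

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            compute_index("NDVI", 0.2, 0.5)

    def test_incompatible_shapes_rejected(self):
        with pytest.raises(ValueError):
            compute_index("DVI", np.zeros(3), np.zeros(4))


def brute_force_map(values, wl, ant, family, eps=1e-8):
    """Independent oracle: python loops + scipy Pearson per ordered pair."""
    m = len(wl)
    n = len(ant)
    pairs = []
    for a, b in itertools.permutations(range(m), 2):
        v = compute_index(family, values[:, a], values[:, b], eps)
        keep = np.isfinite(v)
        if keep.sum() < max(3, int(np.ceil(0.8 * n))):
            continue
        vv, yy = v[keep], np.asarray(ant, dtype=float)[keep]
        if vv.std() == 0 or yy.std() == 0:
            continue
        r, _ = pearson_with_p(vv, yy)
        if np.isfinite(r):
            pairs.append((float(wl[a]), float(wl[b]), float(r)))
    pairs.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    return pairs


class TestPairCorrelationMap:
    def make_case(self, seed=0, m=8, n=40):
        rng = np.random.default_rng(seed)
        ant = rng.uniform(50, 1200, size=n)
        vals = np.clip(0.3 + 0.1 * rng.normal(size=(n, m)), 0.02, 0.95)
        vals[:, 2] = np.clip(0.1 + ant / 2000.0
                             + 0.01 * rng.normal(size=n), 0.02, 0.95)
        wl = 500.0 + 10.0 * np.arange(m)
        return spectra_from(vals, wl, kind="smoothed"), ant, vals, wl

    @pytest.mark.parametrize("family", ["ARI", "CI", "DVI", "NARI"])
    def test_matches_brute_force(self, family):
        s, ant, vals, wl = self.make_case()
        cmap = pair_correlation_map(s, ant, family, k=10)
        oracle = brute_force_map(vals, wl, ant, family)
        # same ranked pairs, correlations equal to numerical precision
        got_pairs = [(i, j) for i, j, _ in cmap.top_k]
        want_pairs = [(i, j) for i, j, _ in oracle[:10]]
        assert got_pairs == want_pairs
        np.testing.assert_allclose([r for _, _, r in cmap.top_k],
                                   [r for _, _, r in oracle[:10]],
                                   rtol=1e-10)
        # full map agrees where both define a value
        for (i_nm, j_nm, r) in oracle:
            a = int(np.argmin(np.abs(wl - i_nm)))
            b = int(np.argmin(np.abs(wl - j_nm)))
            assert cmap.valid[a, b]
            assert cmap.r[a, b] == pytest.approx(r, abs=1e-10)

    def test_diagonal_excluded(self):
        s, ant, _, _ = self.make_case()
        cmap = pair_correlation_map(s, ant, "DVI")
        assert not cmap.valid.diagonal().any()
        assert np.isnan(cmap.r.diagonal()).all()

    def test_over_masked_pair_dropped(self):
        rng = np.random.default_rng(3)
        n = 20
        ant = rng.uniform(100, 1000, size=n)
        vals = np.clip(0.4 + 0.1 * rng.normal(size=(n, 3)), 0.05, 0.95)
        vals[: int(0.5 * n), 1] = 0.0      # 50 % masked for reciprocal pairs
        s = spectra_from(vals, [500.0, 510.0, 520.0], kind="fd")
        cmap = pair_correlation_map(s, ant, "ARI")
        assert not cmap.valid[0, 1] and not cmap.valid[1, 0]
        assert cmap.valid[0, 2]

    def test_top_k_reranking(self):
        s, ant, _, _ = self.make_case(seed=5)
        cmap = pair_correlation_map(s, ant, "DVI", k=10)
        top3 = top_k_pairs(cmap, 3)
        assert top3 == cmap.top_k[:3]
        mags = [abs(r) for _, _, r in top_k_pairs(cmap, 20)]
        assert mags == sorted(mags, reverse=True)

    def test_sample_count_mismatch_rejected(self):
        s, ant, _, _ = self.make_case()
        with pytest.raises(ValueError):
            pair_correlation_map(s, ant[:-1], "DVI")


class TestFeatureMatrix:
    def test_forty_columns_small_dataset(self, small_preprocessed):
        kinds, table = small_preprocessed
        sub = kinds["fd"].select_bands(np.arange(140, 152))
        fm = build_feature_matrix(sub, table.ant, k=10)
        assert fm.n_features == 40
        assert np.isfinite(fm.values).all()
        fams = [c["family"] for c in fm.columns]
        assert fams == ["ARI"] * 10 + ["CI"] * 10 + ["DVI"] * 10 \
            + ["NARI"] * 10
        assert fm.values.shape == (50, 40)

    def test_columns_match_recomputed_index(self):
        rng = np.random.default_rng(8)
        n, m = 30, 6
        ant = rng.uniform(100, 1000, size=n)
        vals = np.clip(0.3 + 0.15 * rng.normal(size=(n, m)), 0.05, 0.95)
        wl = 600.0 + 5.0 * np.arange(m)
        s = spectra_from(vals, wl, kind="smoothed")
        fm = build_feature_matrix(s, ant, k=3)
        assert fm.n_features == 12
        for col, v in zip(fm.columns, fm.values.T):
            a = int(np.argmin(np.abs(wl - col["i_nm"])))
            b = int(np.argmin(np.abs(wl - col["j_nm"])))
            direct = compute_index(col["family"], vals[:, a], vals[:, b])
            keep = np.isfinite(direct)
            np.testing.assert_allclose(v[keep], direct[keep], rtol=1e-12)
            assert col["n_imputed"] == int((~keep).sum())

    def test_frame_labels(self, small_preprocessed):
        kinds, table = small_preprocessed
        sub = kinds["sd"].select_bands(np.arange(120, 130))
        fm = build_feature_matrix(sub, table.ant, k=2)
        frame = fm.to_frame()
        assert frame.shape == (50, 8)
        assert frame.columns[0].startswith("ARI(")
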