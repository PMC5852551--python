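import numpy as np
import pandas as pd
import pytest

from empaikit.structure import (
    islands_frame,
    pca_profiles,
    project_profiles,
    quality_filter,
    silent_islands,
)

from .conftest import lpai_matrix, make_records


class TestQualityFilter:
    def test_detected_anywhere_kept_never_detected_dropped(self):
        lpai = np.array([[-3.0, -3.0], [0.2, -3.0], [-3.0, 0.1]])
        m = lpai_matrix(lpai, ["base", "alt"], ["A", "B", "C"], "base")
        kept = quality_filter(m)
        assert list(kept) == ["B", "C"]


class TestPCA:
    def _random_matrix(self, seed=0, n=200, k=4, rho=0.8):
        rng = np.random.default_rng(seed)
        shared = rng.normal(0, 1, size=(n, 1))
        lpai = rho * shared + (1 - rho) * rng.normal(0, 1, size=(n, k))
        loci = [f"L{i}" for i in range(n)]
        return lpai_matrix(lpai, [f"c{j}" for j in range(k)], loci, "c0")

    def test_identical_scaled_columns_are_rank_one(self):
        rng = np.random.default_rng(1)
        col = rng.normal(0, 1, 50)
        lpai = np.column_stack([col, 2 * col + 1, -0.5 * col])
        m = lpai_matrix(lpai, ["a", "b", "c"], [f"L{i}" for i in range(50)], "a")
        pca = pca_profiles(m, subset=m.lpai.index)
        assert pca.variance_fraction.iloc[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one_components_orthogonal(self):
        pca = pca_profiles(self._random_matrix(), subset=None)
        assert pca.variance_fraction.sum() == pytest.approx(1.0)
        gram = pca.loadings.values.T @ pca.loadings.values
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_shared_signal_loads_pc1_same_sign(self):
        pca = pca_profiles(self._random_matrix(rho=0.9))
        signs = np.sign(pca.loadings["PC1"].values)
        assert (signs == signs[0]).all()
        assert pca.variance_fraction.iloc[0] > 0.5

    def test_affine_rescaling_invariance(self):
        m = self._random_matrix(seed=3)
        rescaled = m.lpai * np.array([2.0, 0.5, 7.0, 1.0]) + np.array([1.0, -2.0, 0.0, 5.0])
        m2 = lpai_matrix(rescaled.values, m.conditions, m.loci, "c0")
        a = pca_profiles(m, subset=m.lpai.index)
        b = pca_profiles(m2, subset=m2.lpai.index)
        assert np.allclose(a.variance_fraction.values, b.variance_fraction.values)

    def test_row_permutation_invariance(self):
        m = self._random_matrix(seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.lpai.index)
        m2 = lpai_matrix(m.lpai.loc[perm].values, m.conditions, list(perm), "c0")
        a = pca_profiles(m, subset=m.lpai.index)
        b = pca_profiles(m2, subset=m2.lpai.index)
        assert np.allclose(a.variance_fraction.values, b.variance_fraction.values)

    def test_zero_variance_column_rejected_by_name(self):
        lpai = np.column_stack([np.random.default_rng(0).normal(size=10), np.full(10, 0.3)])
        m = lpai_matrix(lpai, ["ok", "flat"], [f"L{i}" for i in range(10)], "ok")
        with pytest.raises(ValueError, match="flat"):
            pca_profiles(m, subset=m.lpai.index)

    def test_too_small_inputs_rejected(self):
        lpai = np.zeros((2, 3)) + np.arange(3)
        m = lpai_matrix(lpai, ["a", "b", "c"], ["L0", "L1"], "a")
        with pytest.raises(ValueError):
            pca_profiles(m, subset=m.lpai.index)


class TestProjection:
    def _matrix(self, seed=0, n=300, k=4):
        rng = np.random.default_rng(seed)
        shared = rng.normal(0, 0.8, size=(n, 1))
        lpai = shared + rng.normal(0, 0.3, size=(n, k))
        loci = [f"L{i}" for i in range(n)]
        return lpai_matrix(lpai, [f"c{j}" for j in range(k)], loci, "c0")

    def test_identical_external_profile_coincides(self):
        m = self._matrix()
        external = m.lpai["c1"].copy()
        pca = project_profiles(m, external, label="ext")
        pts = pca.condition_points
        assert np.allclose(pts.loc["ext"].values, pts.loc["c1"].values, atol=1e-8)

    def test_permuted_profile_lands_far_outside(self):
        # decorrelation by permutation: the external point must sit farther
        # from every internal point than internal points sit from each other
        for seed in range(20):
            m = self._matrix(seed=seed)
            rng = np.random.default_rng(seed + 1000)
            external = pd.Series(
                rng.permutation(m.lpai["c1"].values), index=m.lpai.index
            )
            pts = project_profiles(m, external, label="ext").condition_points[["PC1", "PC2"]]
            internal = pts.drop("ext").values
            ext = pts.loc["ext"].values
            internal_d = max(
                np.linalg.norm(a - b) for a in internal for b in internal
            )
            ext_d = min(np.linalg.norm(ext - a) for a in internal)
            assert ext_d > internal_d

    def test_low_coverage_rejected_with_figure(self):
        m = self._matrix()
        external = m.lpai["c1"].iloc[:60]  # 20% coverage
        with pytest.raises(ValueError, match="20"):
            project_profiles(m, external)

    def test_ortholog_map_translation(self):
        m = self._matrix()
        mapping = {f"X{i}": f"L{i}" for i in range(300)}
        external = pd.Series(m.lpai["c2"].values, index=[f"X{i}" for i in range(300)])
        pca = project_profiles(m, external, ortholog_map=mapping, label="ext")
        pts = pca.condition_points
        assert np.allclose(pts.loc["ext"].values, pts.loc["c2"].values, atol=1e-8)


class TestSilentIslands:
    def _matrix_from_flags(self, flags):
        lpai = np.where(np.asarray(flags, bool), 0.0, -3.0)[:, None]
        records = make_records(flags)
        loci = [r.locus_tag for r in records]
        return lpai_matrix(lpai, ["base"], loci, "base"), records

    def test_all_detected_no_islands(self):
        m, records = self._matrix_from_flags([1] * 8)
        assert silent_islands(m, records, "base", min_run=2) == []

    def test_run_length_scan(self):
        m, records = self._matrix_from_flags([1, 1, 0, 0, 0, 0, 0, 1])
        (island,) = silent_islands(m, records, "base", min_run=5)
        assert (island.start_order, island.end_order, island.size) == (3, 7, 5)
        assert island.member_loci == ("L002", "L003", "L004", "L005", "L006")

    def test_short_runs_below_min_run_ignored(self):
        m, records = self._matrix_from_flags([0, 0, 1, 0, 0, 0, 1, 0])
        assert silent_islands(m, records, "base", min_run=4) == []
        islands = silent_islands(m, records, "base", min_run=2)
        assert [(i.start_order, i.size) for i in islands] == [(1, 2), (4, 3)]

    def test_runs_do_not_cross_contig_boundaries(self):
        flags = [0, 0, 0, 0]
        lpai = np.full((4, 1), -3.0)
        records = make_records([0, 0], contig="c1") + [
            r for r in make_records([0, 0], contig="c2")
        ]
        # rename loci to be unique across contigs
        from empaikit.io_tables import ProteinRecord

        records = [
            ProteinRecord("A1", "c1", 1),
            ProteinRecord("A2", "c1", 2),
            ProteinRecord("B1", "c2", 1),
            ProteinRecord("B2", "c2", 2),
        ]
        m = lpai_matrix(lpai, ["base"], ["A1", "A2", "B1", "B2"], "base")
        assert silent_islands(m, records, "base", min_run=3) == []
        islands = silent_islands(m, records, "base", min_run=2)
        assert {i.contig for i in islands} == {"c1", "c2"}

    def test_gap_in_genome_order_breaks_run(self):
        from empaikit.io_tables import ProteinRecord

        records = [ProteinRecord(f"L{i}", "c1", o) for i, o in enumerate([1, 2, 5, 6])]
        lpai = np.full((4, 1), -3.0)
        m = lpai_matrix(lpai, ["base"], [f"L{i}" for i in range(4)], "base")
        islands = silent_islands(m, records, "base", min_run=2)
        assert [(i.start_order, i.end_order) for i in islands] == [(1, 2), (5, 6)]

    def test_islands_cover_every_qualifying_silent_gene_and_are_disjoint(self):
        rng = np.random.default_rng(9)
        flags = (rng.random(200) > 0.4).astype(int)
        m, records = self._matrix_from_flags(flags)
        islands = silent_islands(m, records, "base", min_run=3)
        covered = set()
        for isl in islands:
            assert not (set(isl.member_loci) & covered)  # disjoint
            covered |= set(isl.member_loci)
            assert isl.size >= 3
        # maximality/coverage: brute-force run scan oracle
        silent = [r.locus_tag for r in records if not flags[int(r.locus_tag[1:])]]
        runs, cur = [], []
        for i, f in enumerate(flags):
            if not f:
                cur.append(f"L{i:03d}")
            else:
                if len(cur) >= 3:
                    runs.append(tuple(cur))
                cur = []
        if len(cur) >= 3:
            runs.append(tuple(cur))
        assert sorted(i.member_loci for i in islands) == sorted(runs)

    def test_frame_view(self):
        m, records = self._matrix_from_flags([0, 0, 0, 1])
        df = islands_frame(silent_islands(m, records, "base", min_run=3))
        assert list(df.columns) == ["contig", "start_order", "end_order", "size", "member_loci"]
        assert df.loc[0, "size"] == 3
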