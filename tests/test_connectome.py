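import numpy as np
import pytest

import mesoconn as mc
from mesoconn.connectome import (
    build_connectivity,
    build_tensor,
    cre_average_matrix,
    distal_mask,
    normalize_connectivity,
    top_targets,
    write_long_tsv,
    write_wide_csv,
)
from mesoconn.estimators import EstimatorModel
from mesoconn.brain_model import region_distance

from conftest import make_experiment


@pytest.fixture
def toy(small_brain):
    _, ont = small_brain
    rng = np.random.default_rng(81)
    exps = []
    # classes a/b in leaf blocks 0 and 1; block 2 has only class b; block 3 empty
    for block, classes in [(0, "aab"), (1, "ab"), (2, "b")]:
        for j, v in enumerate(classes):
            vox = (3 * block + j % 3, rng.integers(0, 3), rng.integers(0, 3))
            exps.append(make_experiment(ont, f"c{block}{j}", v, vox, rng.random(ont.n_targets)))
    return mc.Dataset(exps, ont)


class TestBuildConnectivity:
    def test_constant_estimator_row_is_size_times_u(self, toy):
        ont = toy.ontology
        model = EstimatorModel(kind="cre_nw", sigma_x=1e12).fit(toy)  # NW at sigma->inf: support mean
        C = build_connectivity(model, toy, ont, "a", mode="structure")
        leaf0 = ont.source_leafs[0]
        mask = toy.in_leaf(leaf0) & toy.of_class("a")
        u = toy.Y[mask].mean(axis=0)  # constant prediction everywhere in the leaf
        assert np.allclose(C[0], ont.source_size(leaf0) * u, atol=1e-6)

    def test_class_absent_row_is_missing(self, toy):
        model = EstimatorModel(kind="cre_nw", sigma_x=200.0).fit(toy)
        C = build_connectivity(model, toy, toy.ontology, "a")
        assert np.all(np.isnan(C[2]))  # block 2 has no class-a centroid
        assert np.all(np.isnan(C[3]))  # block 3 has no experiments at all
        assert not np.any(np.isnan(C[0]))

    def test_voxel_mode_equals_explicit_voxel_loop(self, toy):
        ont = toy.ontology
        model = EstimatorModel(kind="el", sigma_x=150.0, sigma_c=0.5, alpha=0.4).fit(toy)
        C = build_connectivity(model, toy, ont, "b", mode="voxel")
        for si, leaf in enumerate(ont.source_leafs[:2]):
            acc = np.zeros(ont.n_targets)
            for vox in ont.voxels(leaf, "L"):
                pos = (vox + 0.5) * ont.lattice.spacing_um
                acc += model.predict(pos, "b", toy, leaf=leaf)
            assert np.allclose(C[si], acc, atol=1e-10)

    def test_structure_mode_is_size_times_voxel_average(self, toy):
        ont = toy.ontology
        model = EstimatorModel(kind="el", sigma_x=150.0, sigma_c=0.5, alpha=0.4).fit(toy)
        Cs = build_connectivity(model, toy, ont, "b", mode="structure")
        Cv = build_connectivity(model, toy, ont, "b", mode="voxel")
        # same voxel predictions averaged vs summed: identical here
        assert np.allclose(Cs[~np.isnan(Cs)], Cv[~np.isnan(Cv)], atol=1e-10)


class TestNormalization:
    def test_three_variant_arithmetic_for_constant_field(self, small_brain):
        _, ont = small_brain
        # constant f = 1: strength row = |s| * 1 per target... construct directly
        S, T = ont.n_sources, ont.n_targets
        sizes_s = np.array([ont.source_size(l) for l in ont.source_leafs], float)
        sizes_t = np.array([ont.target_size(t) for t in ont.targets], float)
        C = np.outer(sizes_s, sizes_t)  # strength when f == 1 everywhere
        CN = normalize_connectivity(C, ont, "normalized")
        CD = normalize_connectivity(C, ont, "density")
        assert np.allclose(CN, sizes_t[None, :])
        assert np.allclose(CD, 1.0)

    def test_strength_is_identity(self, small_brain):
        _, ont = small_brain
        rng = np.random.default_rng(82)
        C = rng.random((ont.n_sources, ont.n_targets))
        assert np.array_equal(normalize_connectivity(C, ont, "strength"), C)

    def test_roundtrip_identities_exact(self, small_brain):
        _, ont = small_brain
        rng = np.random.default_rng(83)
        C = rng.random((ont.n_sources, ont.n_targets))
        sizes_s = np.array([ont.source_size(l) for l in ont.source_leafs], float)
        sizes_t = np.array([ont.target_size(t) for t in ont.targets], float)
        CN = normalize_connectivity(C, ont, "normalized")
        CD = normalize_connectivity(C, ont, "density")
        assert np.allclose(CN * sizes_s[:, None], C, atol=1e-12)
        assert np.allclose(CD * sizes_s[:, None] * sizes_t[None, :], C, atol=1e-12)

    def test_missing_stays_missing(self, small_brain):
        _, ont = small_brain
        C = np.full((ont.n_sources, ont.n_targets), 2.0)
        C[1] = np.nan
        CN = normalize_connectivity(C, ont, "normalized")
        assert np.all(np.isnan(CN[1])) and not np.any(np.isnan(CN[0]))


class TestCreAverage:
    def _tensor(self, ont, mats):
        return mc.ConnectivityTensor(values=np.stack(mats), classes=[f"v{i}" for i in range(len(mats))],
                                     source_leafs=list(ont.source_leafs), targets=list(ont.targets))

    def test_single_class_is_identity(self, small_brain):
        _, ont = small_brain
        A = np.random.default_rng(84).random((ont.n_sources, ont.n_targets))
        assert np.allclose(cre_average_matrix(self._tensor(ont, [A])), A)

    def test_missing_rows_ignored(self, small_brain):
        _, ont = small_brain
        A = np.ones((ont.n_sources, ont.n_targets))
        B = np.full_like(A, np.nan)
        avg = cre_average_matrix(self._tensor(ont, [A, B]))
        assert np.allclose(avg, 1.0)

    def test_matches_mask_aware_mean_oracle(self, small_brain):
        _, ont = small_brain
        rng = np.random.default_rng(85)
        mats = [rng.random((ont.n_sources, ont.n_targets)) for _ in range(3)]
        mats[0][1, :] = np.nan
        mats[2][1, :] = np.nan
        avg = cre_average_matrix(self._tensor(ont, mats))
        stacked = np.stack(mats)
        for i in range(ont.n_sources):
            for j in range(ont.n_targets):
                vals = stacked[:, i, j]
                vals = vals[~np.isnan(vals)]
                assert avg[i, j] == pytest.approx(vals.mean())


class TestTopTargets:
    def test_top_decile_of_1_to_10(self):
        row = np.arange(1.0, 11.0)
        assert list(top_targets(row, 90.0)) == [9]

    def test_percentile_zero_keeps_all(self):
        row = np.arange(1.0, 11.0)
        assert len(top_targets(row, 0.0)) == 10

    def test_ties_at_cut_included(self):
        row = np.array([1.0, 5.0, 5.0, 0.0])
        idx = top_targets(row, 75.0)
        assert set(idx) == {1, 2}

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(86)
        row = rng.random(100)
        cut = np.percentile(row, 75.0)
        expected = {i for i, x in enumerate(row) if x >= cut}
        assert set(top_targets(row, 75.0)) == expected

    def test_empty_row_errors(self):
        with pytest.raises(ValueError):
            top_targets(np.array([np.nan, np.nan]))


class TestDistalMask:
    def test_self_pairs_masked_and_threshold_kept(self, small_brain):
        _, ont = small_brain
        keep = distal_mask(ont, threshold_um=300.0)
        # ipsi target j corresponds to source leaf j for the first n_sources targets
        for i in range(ont.n_sources):
            assert not keep[i, i]  # distance 0 < threshold

    def test_exact_threshold_is_kept(self):
        # two single-voxel regions exactly 1,500 um apart: "less than" is strict
        a, b = np.array([[0, 0, 0]]), np.array([[0, 0, 15]])
        assert region_distance(a, b, 100.0) == 1500.0
        # mirrors the mask rule: kept iff distance >= threshold
        assert region_distance(a, b, 100.0) >= 1500.0

    def test_matches_pairwise_distance_oracle(self, small_brain):
        _, ont = small_brain
        thr = 400.0
        keep = distal_mask(ont, thr, mode="min_voxel")
        for i, leaf in enumerate(ont.source_leafs):
            for j, target in enumerate(ont.targets):
                d = region_distance(ont.voxels(leaf, "L"), ont.target_voxels(target),
                                    ont.lattice.spacing_um, "min_voxel")
                assert keep[i, j] == (d >= thr)


class TestWriters:
    def test_wide_csv_missing_is_empty_field(self, small_brain, tmp_path):
        _, ont = small_brain
        C = np.ones((ont.n_sources, ont.n_targets))
        C[0, 0] = np.nan
        path = tmp_path / "c.csv"
        write_wide_csv(C, ont, path)
        line = path.read_text().splitlines()[1]
        first_value = line.split(",")[1]
        assert first_value == ""

    def test_long_tsv_flags_missing(self, small_brain, tmp_path, toy):
        import pandas as pd
        model = EstimatorModel(kind="cre_nw", sigma_x=200.0)
        tensor = build_tensor(model, toy, toy.ontology, classes=["a"])
        path = tmp_path / "long.tsv"
        write_long_tsv(tensor, toy.ontology, path)
        df = pd.read_csv(path, sep="\t")
        missing = df[df.missing == 1]
        assert (missing["value"].isna()).all()
        present = df[df.missing == 0]
        assert (~present["value"].isna()).all()

    def test_provenance_counts_match_eval_tallies(self, toy):
        model = EstimatorModel(kind="cre_nw", sigma_x=200.0)
        tensor = build_tensor(model, toy, toy.ontology)
        for vi, v in enumerate(tensor.classes):
            for si, leaf in enumerate(tensor.source_leafs):
                n = int((toy.in_leaf(leaf) & toy.of_class(v)).sum())
                assert tensor.provenance[vi, si] == n
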