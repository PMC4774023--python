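import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from hic3d.datamodel import ContactMap, FISHDataset, LoopSet, Structure3D, TrackCovariates
from hic3d.evaluate import (
    distance_pcc,
    fish_scale_fit,
    fitted_map_pcc,
    local_window_correlation,
    loop_distance_test,
    superposition_rmsd,
)
from hic3d.inference import init_betas
from hic3d.simulate import make_random_walk

from conftest import dense_counts_map, make_instance, random_rotation


def similarity_transform(s, rng, scale=1.0, reflect=False):
    R = random_rotation(rng)
    if reflect:
        R = R @ np.diag([1.0, 1.0, -1.0])
    return Structure3D(s.loci, scale * (s.coords @ R.T) + rng.normal(size=3))


class TestDistancePCC:
    def test_similarity_invariances(self):
        rng = np.random.default_rng(0)
        a = make_random_walk(20, 1.0, seed=1)
        assert distance_pcc(a, a) == pytest.approx(1.0)
        scaled = Structure3D(a.loci, 2.7 * a.coords)
        assert distance_pcc(a, scaled) == pytest.approx(1.0)
        rotated = similarity_transform(a, rng)
        assert distance_pcc(a, rotated) == pytest.approx(1.0, abs=1e-12)
        reflected = similarity_transform(a, rng, reflect=True)
        assert distance_pcc(a, reflected) == pytest.approx(1.0, abs=1e-12)

    def test_requires_shared_loci(self):
        a = make_random_walk(5, 1.0, seed=2)
        b = Structure3D(a.loci + 1, a.coords)
        with pytest.raises(ValueError, match="loci"):
            distance_pcc(a, b)

    def test_too_few_loci_rejected(self):
        a = Structure3D([0, 1], np.array([[0.0, 0, 0], [1, 0, 0.0]]))
        with pytest.raises(ValueError):
            distance_pcc(a, a)


class TestSuperpositionRMSD:
    def test_exact_zero_cases(self):
        rng = np.random.default_rng(3)
        a = make_random_walk(15, 1.0, seed=3)
        assert superposition_rmsd(a, a) == pytest.approx(0.0, abs=1e-10)
        translated = Structure3D(a.loci, a.coords + np.array([5.0, -2.0, 9.0]))
        assert superposition_rmsd(a, translated) == pytest.approx(0.0, abs=1e-10)
        mirrored = Structure3D(a.loci, a.coords * np.array([1.0, 1.0, -1.0]))
        assert superposition_rmsd(a, mirrored, allow_reflection=True) == pytest.approx(0.0, abs=1e-10)
        assert superposition_rmsd(a, mirrored, allow_reflection=False) > 0.1
        scaled = similarity_transform(a, rng, scale=3.0)
        assert superposition_rmsd(a, scaled, allow_scale=True) == pytest.approx(0.0, abs=1e-9)
        assert superposition_rmsd(a, scaled, allow_scale=False) > 0.1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("allow_reflection", [True, False])
    def test_matches_rotation_search_oracle(self, seed, allow_reflection):
        # brute-force oracle: coarse Euler-angle grid refined by simplex,
        # with the reflection branch enumerated explicitly
        rng = np.random.default_rng(seed)
        a = Structure3D(np.arange(5), rng.normal(size=(5, 3)))
        b = Structure3D(np.arange(5), rng.normal(size=(5, 3)))
        A = a.coords - a.coords.mean(axis=0)
        B = b.coords - b.coords.mean(axis=0)

        def rmsd_at(angles, mirror):
            R = Rotation.from_euler("xyz", angles).as_matrix()
            if mirror:
                R = R @ np.diag([1.0, 1.0, -1.0])
            BR = B @ R.T
            denom = float(np.sum(BR * BR))
            s = max(float(np.sum(A * BR)), 0.0) / denom
            return float(np.sqrt(np.mean(np.sum((A - s * BR) ** 2, axis=1))))

        mirrors = [False, True] if allow_reflection else [False]
        best = np.inf
        grid = np.linspace(-np.pi, np.pi, 13)
        for mirror in mirrors:
            for ax in grid:
                for ay in grid[:7]:
                    for az in grid:
                        best = min(best, rmsd_at((ax, ay, az), mirror))
            for _ in range(20):
                x0 = rng.uniform(-np.pi, np.pi, size=3)
                r = minimize(lambda t: rmsd_at(t, mirror), x0, method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-12})
                best = min(best, r.fun)
        ours = superposition_rmsd(a, b, allow_scale=True,
                                  allow_reflection=allow_reflection)
        assert ours == pytest.approx(best, abs=1e-3)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    seed=st.integers(0, 2**20),
    scale=st.floats(0.1, 10.0),
    reflect=st.booleans(),
)
def test_similarity_transform_invariance_property(seed, scale, reflect):
    """Distance-PCC is exactly 1 and similarity-RMSD exactly 0 under any
    rotation + reflection + scaling + translation of a structure."""
    rng = np.random.default_rng(seed)
    a = make_random_walk(8, 1.0, seed=seed)
    b = similarity_transform(a, rng, scale=scale, reflect=reflect)
    assert distance_pcc(a, b) == pytest.approx(1.0, abs=1e-9)
    assert superposition_rmsd(a, b) == pytest.approx(0.0, abs=1e-7)


class TestFittedMapPCC:
    def test_noiseless_map_near_perfect(self):
        # large intercept keeps mu >> 1 so rounding noise is negligible
        cmap, covs, structure, model = make_instance(seed=20, n=25, beta0=6.0)
        # rebuild the map deterministically: n_ij = round(mu_ij)
        from hic3d.likelihood import _eta, _pair_distances, build_pair_data

        (pd,) = build_pair_data([cmap], [covs], structure)
        mu = np.exp(_eta(model, pd, _pair_distances(structure.coords, pd)))
        counts = np.round(mu)
        entries = {
            (int(structure.loci[i]), int(structure.loci[j])): float(c)
            for i, j, c in zip(pd.rows_i, pd.rows_j, counts) if c > 0
        }
        noiseless = ContactMap("t", cmap.n_bins, entries, available=cmap.available)
        assert fitted_map_pcc(structure, model, noiseless, covs) >= 0.99

    def test_shuffled_structure_fits_worse(self):
        cmap, covs, structure, model = make_instance(seed=21, n=25, beta0=3.0)
        base = fitted_map_pcc(structure, model, cmap, covs)
        rng = np.random.default_rng(0)
        perm = rng.permutation(structure.n)
        shuffled = Structure3D(structure.loci, structure.coords[perm])
        assert fitted_map_pcc(shuffled, model, cmap, covs) < base

    def test_raw_and_normalized_interfaces(self):
        cmap, covs, structure, model = make_instance(seed=22, n=20, beta0=2.0)
        raw_pcc = fitted_map_pcc(structure, model, cmap, covs)
        norm = ContactMap("t", cmap.n_bins, dict(cmap.entries),
                          is_normalized=True, available=cmap.available)
        norm_pcc = fitted_map_pcc(structure, model, norm, None)
        assert np.isfinite(raw_pcc) and np.isfinite(norm_pcc)

    def test_invariant_to_consistent_relabeling(self):
        cmap, covs, structure, model = make_instance(seed=23, n=15, beta0=2.0)
        base = fitted_map_pcc(structure, model, cmap, covs)
        # spread bins onto even indices, remapping everything consistently
        remap = {int(b): 2 * int(b) for b in structure.loci}
        n2 = 2 * cmap.n_bins
        entries = {(remap[i], remap[j]): v for (i, j), v in cmap.entries.items()}
        avail = np.zeros(n2, dtype=bool)
        avail[[remap[int(b)] for b in cmap.available_loci]] = True
        x2 = np.full((n2, covs.values.shape[1]), 0.5)
        for b_old, b_new in remap.items():
            x2[b_new] = covs.values[b_old]
        cmap2 = ContactMap("t", n2, entries, available=avail)
        covs2 = TrackCovariates("t", x2)
        structure2 = Structure3D([remap[int(b)] for b in structure.loci],
                                 structure.coords)
        assert fitted_map_pcc(structure2, model, cmap2, covs2) == pytest.approx(base, rel=1e-12)


class TestFishScaleFit:
    def test_closed_form_single_structure(self):
        # beta = sum(FISH * d) / sum(d^2) = (2*1 + 4*2) / (1 + 4) = 2
        s = Structure3D(np.arange(3), np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0.0]]))
        fish = FISHDataset(
            end1_bins=[[0, 0], [0, 0]],
            end2_bins=[[1, 1], [2, 2]],
            distances=[2.0, 4.0],
        )
        res = fish_scale_fit([s], fish)
        for beta in res.betas.values():
            assert beta == pytest.approx([2.0])
        assert res.pcc_range == pytest.approx((1.0, 1.0))

    def test_identity_when_fish_equals_distances(self):
        rng = np.random.default_rng(4)
        s = make_random_walk(10, 1.0, seed=5)
        pairs = [(0, 4), (1, 7), (2, 9), (3, 8)]
        d = [float(np.linalg.norm(s.coords[i] - s.coords[j])) for i, j in pairs]
        fish = FISHDataset(
            end1_bins=[[i, i] for i, _ in pairs],
            end2_bins=[[j, j] for _, j in pairs],
            distances=d,
        )
        res = fish_scale_fit([s], fish)
        for beta in res.betas.values():
            assert beta == pytest.approx([1.0])
        assert res.pcc_range[0] == pytest.approx(1.0)

    def test_block_diagonal_recovery_two_structures(self):
        # two disjoint structures, each perfectly proportional to its FISH
        s1 = Structure3D(np.arange(5), make_random_walk(5, 1.0, seed=6).coords)
        s2 = Structure3D(np.arange(10, 15), make_random_walk(5, 1.0, seed=7).coords)
        recs, scales = [], (3.0, 0.5)
        for s, scale, pairs in (
            (s1, scales[0], [(0, 2), (1, 4)]),
            (s2, scales[1], [(10, 13), (11, 14)]),
        ):
            pos = s.index_of()
            for i, j in pairs:
                d = float(np.linalg.norm(s.coords[pos[i]] - s.coords[pos[j]]))
                recs.append(((i, i), (j, j), scale * d))
        fish = FISHDataset(
            end1_bins=[r[0] for r in recs],
            end2_bins=[r[1] for r in recs],
            distances=[r[2] for r in recs],
        )
        res = fish_scale_fit([s1, s2], fish)
        for beta in res.betas.values():
            assert beta == pytest.approx(scales)

    def test_candidate_bins_produce_pcc_range(self):
        s = make_random_walk(12, 1.0, seed=8)
        fish = FISHDataset(
            end1_bins=[[0, 1], [2, 3], [4, 5]],
            end2_bins=[[6, 7], [8, 9], [10, 11]],
            distances=[1.0, 2.0, 3.0],
        )
        res = fish_scale_fit([s], fish)
        assert len(res.pccs) == 4
        lo, hi = res.pcc_range
        assert lo <= hi


class TestLoopDistanceTest:
    def test_constructed_separation_is_significant(self):
        # looped anchors adjacent, non-looped far apart, by construction
        rng = np.random.default_rng(9)
        coords = []
        for k in range(24):
            base = np.array([0.0, 0, 0]) if k % 2 == 0 else np.array([50.0 * k, 0, 0])
            coords.append(base + rng.normal(scale=0.1, size=3))
        s = Structure3D(np.arange(24), np.asarray(coords))
        evens = list(range(0, 24, 2))
        loops = {(evens[i], evens[i + 1]) for i in range(0, len(evens) - 1, 2)}
        ls = LoopSet(np.arange(24), loops)
        res = loop_distance_test(s, ls)
        assert res.p_value < 0.01

    def test_null_loops_give_uniformish_p(self):
        ps = []
        for seed in range(21):
            rng = np.random.default_rng(seed)
            s = make_random_walk(20, 1.0, seed=100 + seed)
            anchors = np.arange(20)
            all_pairs = [(i, j) for i in range(20) for j in range(i + 1, 20)]
            chosen = rng.choice(len(all_pairs), size=15, replace=False)
            loops = {all_pairs[k] for k in chosen}
            res = loop_distance_test(s, LoopSet(anchors, loops))
            ps.append(res.p_value)
        assert np.median(ps) > 0.1

    def test_distances_scaled_by_maximum(self):
        s = make_random_walk(10, 1.0, seed=10)
        ls = LoopSet(np.arange(10), {(0, 1), (2, 5)})
        res = loop_distance_test(s, ls)
        assert max(res.loop_distances.max(), res.nonloop_distances.max()) == pytest.approx(1.0)


class TestLocalWindowCorrelation:
    def test_identical_structures_fully_conserved(self):
        s = make_random_walk(30, 1.0, seed=11)
        s2 = Structure3D(s.loci, s.coords.copy())
        res = local_window_correlation([s, s2], window=21, threshold=0.99)
        assert res.fraction_pcc == 1.0
        assert res.fraction_spearman == 1.0
        assert res.truncated[:10].all() and res.truncated[-10:].all()

    def test_independent_walks_not_conserved(self):
        ss = [make_random_walk(40, 1.0, seed=200 + k) for k in range(3)]
        ss = [Structure3D(ss[0].loci, s.coords) for s in ss]
        res = local_window_correlation(ss, window=21, threshold=0.7)
        assert res.fraction_pcc < 0.2

    def test_degenerate_window_excluded_and_counted(self):
        # one structure collapsed to a point: every window's distance vector
        # is exactly constant, so all correlations are undefined
        a = Structure3D(np.arange(3), np.zeros((3, 3)))
        b = make_random_walk(3, 1.0, seed=12)
        res = local_window_correlation([a, b], window=3)
        assert res.n_undefined == 3
        assert np.isnan(res.fraction_pcc)
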