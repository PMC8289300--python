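import numpy as np
import pytest

from cdx import confanalysis, synthetic
from cdx.confanalysis import (
    crossref_patches,
    daura_cluster,
    daura_cluster_from_matrix,
    kabsch_superpose,
    parse_apr_ranges,
    patch_frequency,
    qres,
    unstable_patches,
)
from cdx.geometry import DegenerateSelectionError, random_rotation


def _greedy_oracle(rmsd, cutoff):
    """Independent reimplementation of the max-neighbour greedy loop."""
    n = len(rmsd)
    neigh = [
        {j for j in range(n) if rmsd[i][j] < cutoff} | {i} for i in range(n)
    ]
    remaining = set(range(n))
    clusters = []
    while remaining:
        best, best_count = None, -1
        for i in sorted(remaining):  # lowest index wins ties
            c = len(neigh[i] & remaining)
            if c > best_count:
                best, best_count = i, c
        members = neigh[best] & remaining
        clusters.append((best, frozenset(members)))
        remaining -= members
    return clusters


class TestKabsch:
    def test_recovers_rigid_motion(self, rng):
        x = rng.uniform(0, 2, (25, 3))
        rot = random_rotation(rng)
        y = x @ rot.T + np.array([1.0, -0.5, 2.0])
        r, t, rmsd = kabsch_superpose(y, x)
        assert rmsd < 1e-8
        assert np.allclose(r @ rot, np.eye(3), atol=1e-8)
        assert np.linalg.det(r) == pytest.approx(1.0)

    def test_identity_inputs(self, rng):
        x = rng.uniform(0, 2, (10, 3))
        r, t, rmsd = kabsch_superpose(x, x)
        assert np.allclose(r, np.eye(3), atol=1e-10)
        assert np.allclose(t, 0, atol=1e-10)
        assert rmsd < 1e-10

    def test_optimal_among_random_rotations(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 2, (15, 3))
            y = x + rng.normal(0, 0.3, x.shape)
            _, _, best = kabsch_superpose(x, y)
            xc = x - x.mean(0)
            yc = y - y.mean(0)
            for _ in range(1000):
                rot = random_rotation(rng)
                trial = np.sqrt(np.mean(np.sum((xc @ rot.T - yc) ** 2, axis=1)))
                assert best <= trial + 1e-12

    def test_collinear_selection_rejected(self):
        x = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateSelectionError):
            kabsch_superpose(x, x[::-1])


class TestDauraCluster:
    def test_all_identical_one_cluster(self, rng):
        frame = rng.uniform(0, 2, (9, 3))
        res = daura_cluster([frame.copy() for _ in range(8)], cutoff=0.1)
        assert res.n_clusters == 1
        assert res.populations.tolist() == [8]
        assert res.weighted_fractions.sum() == pytest.approx(1.0)

    def test_matches_independent_greedy_oracle(self, rng):
        for trial in range(10):
            n = 20
            pts = rng.uniform(0, 1, (n, 2))
            rmsd = np.round(
                np.linalg.norm(pts[:, None] - pts[None, :], axis=-1), 1
            )  # rounding forces ties
            res = daura_cluster_from_matrix(rmsd, cutoff=0.3)
            expect = _greedy_oracle(rmsd.tolist(), 0.3)
            assert res.n_clusters == len(expect)
            for cid, (center, members) in enumerate(expect):
                assert res.centroids[cid] == center
                assert frozenset(np.flatnonzero(res.assignment == cid)) == members

    def test_two_planted_groups(self, helix12):
        top, frame = helix12
        sel = top.backbone_indices(("N", "CA", "C"))
        groups = []
        for seed, offset in ((1, 0.0), (2, 3.0)):
            base = frame.coords + np.array([offset, 0.0, 0.0])
            base_frame = synthetic.perturb_to_rmsd(
                synthetic.Frame(base, frame.box), 0.5, seed=100 + seed
            )
            for k in range(6):
                pert = synthetic.perturb_to_rmsd(base_frame, 0.02, seed=10 * seed + k)
                groups.append(pert.coords[sel])
        res = daura_cluster(groups, cutoff=0.1)
        assert res.n_clusters == 2
        assert sorted(res.populations.tolist()) == [6, 6]

    def test_invariant_under_frame_reordering(self, rng):
        # well-separated blobs of distinct sizes: the greedy choice is
        # unambiguous, so the partition cannot depend on frame order
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        pts = np.vstack(
            [c + rng.uniform(-0.1, 0.1, (n, 2))
             for c, n in zip(centers, (7, 5, 3))]
        )
        rmsd = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res1 = daura_cluster_from_matrix(rmsd, 0.5)
        perm = rng.permutation(15)
        res2 = daura_cluster_from_matrix(rmsd[np.ix_(perm, perm)], 0.5)
        # same partition up to relabeling
        part1 = {frozenset(np.flatnonzero(res1.assignment == c))
                 for c in range(res1.n_clusters)}
        part2 = {frozenset(perm[np.flatnonzero(res2.assignment == c)])
                 for c in range(res2.n_clusters)}
        assert part1 == part2

    def test_weights_enter_populations_only(self, rng):
        frame = rng.uniform(0, 2, (6, 3))
        scrambled = rng.uniform(0, 2, (6, 3))  # unrelated conformation
        frames = [frame + 0.0, frame + 0.001, scrambled]
        w = np.array([0.5, 0.5, 9.0])
        res = daura_cluster(frames, cutoff=0.1, weights=w)
        assert res.n_clusters == 2
        assert res.populations.tolist() == [2, 1]  # geometry unweighted
        assert res.weighted_fractions[1] == pytest.approx(0.9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            daura_cluster([])


def _qres_oracle(a, b, exponent=0.15, min_sep=2):
    n = len(a)
    q = np.zeros(n)
    for i in range(n):
        acc, cnt = 0.0, 0
        for j in range(n):
            if abs(i - j) < min_sep:
                continue
            da = np.linalg.norm(a[i] - a[j])
            db = np.linalg.norm(b[i] - b[j])
            s2 = abs(i - j) ** exponent
            acc += np.exp(-((da - db) ** 2) / (2.0 * s2))
            cnt += 1
        q[i] = acc / cnt
    return q


class TestQres:
    def test_identical_structures_give_one(self, rng):
        ca = rng.uniform(0, 3, (30, 3))
        prof = qres(ca, ca.copy())
        assert np.allclose(prof.q, 1.0)

    def test_five_residue_toy_hand_evaluated(self):
        ca = np.array([[0, 0, 0], [0.4, 0, 0], [0.8, 0, 0],
                       [1.2, 0, 0], [1.6, 0, 0]], dtype=float)
        moved = ca.copy()
        moved[2, 1] += 0.5  # displace the middle CA by 0.5 nm
        prof = qres(ca, moved)
        assert np.allclose(prof.q, _qres_oracle(ca, moved), atol=1e-12)
        # the displaced residue's partners all changed; its q is lowest
        assert np.argmin(prof.q) == 2

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(20):
            a = rng.uniform(0, 2, (15, 3))
            b = a + rng.normal(0, 0.3, a.shape)
            prof = qres(a, b)
            assert np.allclose(prof.q, _qres_oracle(a, b), atol=1e-10)
            assert np.all((prof.q >= 0) & (prof.q <= 1))

    def test_symmetric_in_arguments(self, rng):
        a = rng.uniform(0, 2, (20, 3))
        b = a + rng.normal(0, 0.2, a.shape)
        assert np.allclose(qres(a, b).q, qres(b, a).q, atol=1e-12)

    def test_median_q_decreases_with_planted_rmsd(self):
        top, frame = synthetic.make_ideal_helix(40)
        ca = top.backbone_indices(("CA",))
        medians = []
        for target in (0.05, 0.1, 0.2, 0.4):
            qs = []
            for seed in range(20):
                pert = synthetic.perturb_to_rmsd(frame, target, seed=seed)
                qs.append(np.median(qres(frame.coords[ca], pert.coords[ca]).q))
            medians.append(np.median(qs))
        assert all(m2 < m1 for m1, m2 in zip(medians, medians[1:]))


class TestPatches:
    def test_thresholding(self):
        prof = confanalysis.QresProfile(
            q=np.array([0.9, 0.4, 0.6, 0.49]), resids=np.arange(1, 5)
        )
        assert unstable_patches(prof) == {2, 4}
        assert unstable_patches(prof, threshold=0.0) == set()
        all_one = confanalysis.QresProfile(q=np.ones(4), resids=np.arange(1, 5))
        assert unstable_patches(all_one) == set()

    def test_frequency_counting(self):
        sets = [{3, 4}, {4}, {4, 7}, set(), {1}, {4}, {2}, {4, 5}]
        resids, freq = patch_frequency(sets, (1, 8))
        assert freq[resids == 4][0] == pytest.approx(5 / 8)
        assert freq[resids == 3][0] == pytest.approx(1 / 8)

    def test_single_system_is_indicator(self):
        resids, freq = patch_frequency([{2, 5}], (1, 6))
        assert freq.tolist() == [0, 1, 0, 0, 1, 0]

    def test_stratified_averages_to_pooled(self):
        sets = [{1}, {1, 2}, {3}, {2, 3}, {1, 3}]
        labels = ["none", "bcd", "bcd", "hpbcd", "hpbcd"]
        resids, pooled, by_label = patch_frequency(sets, (1, 3), labels=labels)
        counts = {lab: labels.count(lab) for lab in set(labels)}
        recombined = sum(
            by_label[lab] * counts[lab] for lab in by_label
        ) / len(sets)
        assert np.allclose(recombined, pooled)


class TestCrossref:
    def test_apr_parsing(self):
        ranges = parse_apr_ranges("PHE13-CYS17, CYS36-LYS40\nILE56")
        assert ranges == [(13, 17), (36, 40), (56, 56)]

    def test_identical_frequencies_correlate_perfectly(self, rng):
        resids = np.arange(1, 21)
        f = rng.uniform(0, 1, 20)
        rep = crossref_patches(resids, f, dict(zip(resids, f)), [(2, 4)])
        assert rep["rank_correlation"] == pytest.approx(1.0)

    def test_jaccard_of_constructed_overlap(self):
        resids = np.arange(1, 31)
        patch = np.zeros(30)
        patch[0:10] = 1.0  # residues 1-10 unstable
        rep = crossref_patches(resids, patch, {}, [(7, 16)])  # residues 7-16
        assert rep["jaccard_apr"] == pytest.approx(4 / 16)

    def test_disjoint_sets_give_zero(self):
        resids = np.arange(1, 21)
        patch = (resids <= 5).astype(float)
        rep = crossref_patches(resids, patch, {}, [(10, 14)])
        assert rep["jaccard_apr"] == 0.0

    def test_out_of_range_apr_rejected(self):
        with pytest.raises(ValueError, match="17-90"):
            crossref_patches(np.arange(1, 31), np.zeros(30), {}, [(17, 90)])


class TestEndToEndPatchRecovery:
    def test_planted_unstable_residues_recovered(self):
        top, frame = synthetic.make_ideal_helix(60)
        ca = top.backbone_indices(("CA",))
        planted = {7} | set(range(42, 53))
        planted_atoms = np.concatenate(
            [idx for resid, idx in top.protein_residues() if resid in planted]
        )
        patch_sets = []
        for system in range(3):
            pert = synthetic.perturb_to_rmsd(
                frame, 5.0, seed=50 + system, atom_indices=planted_atoms
            )
            prof = qres(frame.coords[ca], pert.coords[ca],
                        resids=top.resids[ca])
            patch_sets.append(unstable_patches(prof, 0.5))
        resids, freq = patch_frequency(patch_sets, (1, 60))
        # the support of the frequency distribution is exactly the planted set
        recovered = {int(r) for r, f in zip(resids, freq) if f > 0.0}
        assert recovered == planted
        assert np.all(freq[[r not in planted for r in resids]] == 0.0)
        # cross-reference against an APR list equal to the planted set
        rep = crossref_patches(resids, freq, {}, [(7, 7), (42, 52)])
        assert rep["jaccard_apr"] == pytest.approx(1.0)
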