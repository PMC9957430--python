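"""Bernoulli-HMM segmentation: binarization, EM, decoding, enrichment."""

import itertools

import numpy as np
import pytest
from scipy import stats as st

import ladscape as L
from ladscape.chromstates import (
    BinarizedTracks,
    HMMModel,
    attribute_targets,
    baum_welch,
    binarize,
    decode,
    empirical_single_state,
    fold_enrichment,
    forward_loglik,
    posterior,
)
from ladscape.signal import CoverageTrack


def make_tracks(calls_by_chrom, genome, bin_size=100, marks=("m1",)):
    return BinarizedTracks(
        genome=dict(genome),
        bin_size=bin_size,
        marks=list(marks),
        calls={c: np.asarray(a, dtype=np.uint8) for c, a in calls_by_chrom.items()},
    )


def two_state_model(e_hi=0.9, e_lo=0.1, stay=0.95):
    return HMMModel(
        emission=np.array([[e_hi], [e_lo]]),
        transition=np.array([[stay, 1 - stay], [1 - stay, stay]]),
        initial=np.array([0.5, 0.5]),
        marks=["m1"],
    )


def sample_from(model, n_bins, rng):
    S = model.n_states
    path = np.zeros(n_bins, dtype=int)
    path[0] = rng.choice(S, p=model.initial)
    for t in range(1, n_bins):
        path[t] = rng.choice(S, p=model.transition[path[t - 1]])
    obs = (rng.random((n_bins, model.emission.shape[1])) < model.emission[path]).astype(
        np.uint8
    )
    return path, obs


def brute_force_loglik(model, obs):
    """Sum P(path, obs) over every state path (exponential; tiny chains only)."""
    T = len(obs)
    total = 0.0
    for path in itertools.product(range(model.n_states), repeat=T):
        p = model.initial[path[0]]
        for t in range(T):
            e = model.emission[path[t]]
            x = obs[t].astype(float)
            p *= float(np.prod(e**x * (1 - e) ** (1 - x)))
            if t > 0:
                p *= model.transition[path[t - 1], path[t]]
        total += p
    return np.log(total)


class TestBinarize:
    def test_uniform_low_counts_no_calls(self):
        g = {"chrT": 10_000}
        track = CoverageTrack(g, 200, {"chrT": np.full(50, 1.0)})
        out = binarize({"m1": track}, bin_size=200)
        assert out.calls["chrT"].sum() == 0

    def test_extreme_count_called(self):
        g = {"chrT": 10_000}
        vals = np.ones(50)
        vals[10] = 50.0
        track = CoverageTrack(g, 200, {"chrT": vals})
        out = binarize({"m1": track}, bin_size=200)
        assert out.calls["chrT"][10, 0] == 1

    def test_threshold_matches_inverse_poisson_cdf(self):
        """The minimal called count equals the smallest k with
        P(X >= k) < p_cut under the genome-wide mean rate."""
        g = {"chrT": 200_000}
        rng = np.random.default_rng(0)
        vals = rng.poisson(5.0, size=1000).astype(float)
        track = CoverageTrack(g, 200, {"chrT": vals})
        out = binarize({"m1": track}, bin_size=200, p_cut=1e-4)
        rate = vals.mean()
        k_min = int(st.poisson.isf(1e-4, rate)) + 1
        while st.poisson.sf(k_min - 2, rate) < 1e-4:
            k_min -= 1
        called = vals[out.calls["chrT"][:, 0] == 1]
        uncalled = vals[out.calls["chrT"][:, 0] == 0]
        if called.size:
            assert called.min() >= k_min
        assert (uncalled < k_min).all()

    def test_all_zero_track_warns(self):
        g = {"chrT": 2_000}
        track = CoverageTrack(g, 200, {"chrT": np.zeros(10)})
        with pytest.warns(UserWarning, match="all-zero"):
            out = binarize({"m1": track}, bin_size=200)
        assert out.calls["chrT"].sum() == 0


class TestForwardLikelihood:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_path_sum_on_toy_chain(self, seed):
        rng = np.random.default_rng(seed)
        model = HMMModel(
            emission=rng.uniform(0.1, 0.9, size=(3, 2)),
            transition=rng.dirichlet(np.ones(3), size=3),
            initial=rng.dirichlet(np.ones(3)),
            marks=["a", "b"],
        )
        obs = rng.integers(0, 2, size=(6, 2)).astype(np.uint8)
        assert forward_loglik(model, obs) == pytest.approx(
            brute_force_loglik(model, obs), abs=1e-8
        )

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        model = two_state_model()
        _, obs = sample_from(model, 200, rng)
        post = posterior(model, obs)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)


class TestBaumWelch:
    def test_single_state_closed_form(self):
        rng = np.random.default_rng(2)
        obs = (rng.random((500, 2)) < [0.3, 0.7]).astype(np.uint8)
        tracks = make_tracks({"chrT": obs}, {"chrT": 50_000}, marks=("a", "b"))
        freq = empirical_single_state(tracks)
        assert freq == pytest.approx(obs.mean(axis=0), abs=1e-12)

    def test_loglik_monotone_and_deterministic(self):
        rng = np.random.default_rng(3)
        model = two_state_model()
        _, obs = sample_from(model, 1000, rng)
        tracks = make_tracks({"chrT": obs}, {"chrT": 100_000})
        fit1, hist1 = baum_welch(tracks, 2, seed=7, max_iter=50)
        fit2, hist2 = baum_welch(tracks, 2, seed=7, max_iter=50)
        assert np.all(np.diff(hist1) >= -1e-8)
        assert hist1 == hist2
        assert np.array_equal(fit1.emission, fit2.emission)

    def test_two_state_parameter_recovery(self):
        """Emissions 0.9/0.1, self-transition 0.95, 10,000 bins: recovered
        emissions within ±0.05 up to state relabeling."""
        rng = np.random.default_rng(4)
        truth = two_state_model(0.9, 0.1, 0.95)
        _, obs = sample_from(truth, 10_000, rng)
        tracks = make_tracks({"chrT": obs}, {"chrT": 1_000_000})
        fit, hist = baum_welch(tracks, 2, seed=0, max_iter=200, tol=1e-6)
        got = np.sort(fit.emission[:, 0])
        assert got[1] == pytest.approx(0.9, abs=0.05)
        assert got[0] == pytest.approx(0.1, abs=0.05)

    def test_transition_rows_stochastic_after_fit(self):
        rng = np.random.default_rng(6)
        _, obs = sample_from(two_state_model(), 500, rng)
        tracks = make_tracks({"chrT": obs}, {"chrT": 50_000})
        fit, _ = baum_welch(tracks, 2, seed=1, max_iter=20)
        assert np.allclose(fit.transition.sum(axis=1), 1.0, atol=1e-9)
        assert np.isclose(fit.initial.sum(), 1.0, atol=1e-9)

    def test_label_permutation_invariance_across_seeds(self):
        """Well-separated states: training from different seeds yields the
        same model up to relabeling (emission distance < 0.05)."""
        rng = np.random.default_rng(8)
        truth = two_state_model(0.95, 0.05, 0.97)
        _, obs = sample_from(truth, 5_000, rng)
        tracks = make_tracks({"chrT": obs}, {"chrT": 500_000})
        fits = [baum_welch(tracks, 2, seed=s, max_iter=100)[0] for s in (0, 1, 2)]
        ref = np.sort(fits[0].emission[:, 0])
        for f in fits[1:]:
            assert np.abs(np.sort(f.emission[:, 0]) - ref).max() < 0.05

    def test_too_many_states_rejected(self):
        tracks = make_tracks({"chrT": np.zeros((5, 1), dtype=np.uint8)}, {"chrT": 500})
        with pytest.raises(ValueError, match="exceeds bin count"):
            baum_welch(tracks, 10)


class TestDecode:
    def test_near_deterministic_emissions_recover_path(self):
        rng = np.random.default_rng(10)
        model = two_state_model(0.999, 0.001, 0.9)
        path, obs = sample_from(model, 500, rng)
        tracks = make_tracks({"chrT": obs}, {"chrT": 50_000})
        seg = decode(model, tracks)
        assert (seg.states["chrT"] == path).mean() > 0.99

    def test_all_zero_data_symmetric_model_constant_state(self):
        model = two_state_model(0.8, 0.2, 0.9)
        obs = np.zeros((100, 1), dtype=np.uint8)
        tracks = make_tracks({"chrT": obs}, {"chrT": 10_000})
        seg = decode(model, tracks)
        assert len(np.unique(seg.states["chrT"])) == 1

    def test_viterbi_agrees_on_clean_data(self):
        rng = np.random.default_rng(12)
        model = two_state_model(0.99, 0.01, 0.95)
        path, obs = sample_from(model, 300, rng)
        tracks = make_tracks({"chrT": obs}, {"chrT": 30_000})
        a = decode(model, tracks, method="posterior")
        b = decode(model, tracks, method="viterbi")
        assert (a.states["chrT"] == b.states["chrT"]).mean() > 0.98


class TestFoldEnrichment:
    def _segmentation(self):
        g = {"chrT": 10_000}
        labels = np.zeros(100, dtype=int)
        labels[:10] = 1  # state 2 occupies [0, 1000)
        from ladscape.chromstates import Segmentation

        return Segmentation(genome=g, bin_size=100, states={"chrT": labels},
                            state_names=["E1", "E2"])

    def test_hand_computed_toy_case(self):
        # genome 10,000; state E2 1,000 bp; annotation 500 bp, 100 bp inside E2
        seg = self._segmentation()
        ann = L.IntervalSet(
            [L.GenomicInterval("chrT", 900, 1000), L.GenomicInterval("chrT", 5000, 5400)],
            seg.genome,
        )
        table = fold_enrichment(seg, ann).frame.set_index("state")
        assert table.loc["E2", "fold_enrichment"] == pytest.approx(2.0)
        assert table.loc["E2", "bases_in_state"] == 1000
        assert table.loc["E2", "bases_overlap"] == 100

    def test_whole_genome_annotation_gives_one(self):
        seg = self._segmentation()
        ann = L.IntervalSet([L.GenomicInterval("chrT", 0, 10_000)], seg.genome)
        folds = fold_enrichment(seg, ann).frame.fold_enrichment
        assert np.allclose(folds, 1.0)

    def test_disjoint_annotation_gives_zero(self):
        seg = self._segmentation()
        ann = L.IntervalSet([L.GenomicInterval("chrT", 5000, 5500)], seg.genome)
        table = fold_enrichment(seg, ann).frame.set_index("state")
        assert table.loc["E2", "fold_enrichment"] == 0.0

    def test_empty_annotation_rejected(self):
        seg = self._segmentation()
        with pytest.raises(ValueError, match="empty"):
            fold_enrichment(seg, L.IntervalSet([], seg.genome))

    def test_matches_per_base_brute_force(self, bool_oracle, make_random_set):
        rng = np.random.default_rng(20)
        g = {"chrT": 10_000}
        labels = rng.integers(0, 3, size=100)
        from ladscape.chromstates import Segmentation

        seg = Segmentation(genome=g, bin_size=100, states={"chrT": labels},
                           state_names=["E1", "E2", "E3"])
        ann = make_random_set(rng, g)
        mask = bool_oracle.to_mask(ann)["chrT"]
        table = fold_enrichment(seg, ann).frame.set_index("state")
        per_base_state = np.repeat(labels, 100)
        ann_bases = mask.sum()
        for s, name in enumerate(["E1", "E2", "E3"]):
            in_state = (per_base_state == s).sum()
            overlap = (mask & (per_base_state == s)).sum()
            expected = (overlap / in_state) / (ann_bases / 10_000)
            assert table.loc[name, "fold_enrichment"] == pytest.approx(expected)


class TestAttributeTargets:
    def _segmentation(self):
        g = {"chrT": 10_000}
        labels = np.zeros(100, dtype=int)
        labels[50:] = 1
        from ladscape.chromstates import Segmentation

        return Segmentation(genome=g, bin_size=100, states={"chrT": labels},
                            state_names=["A", "B"])

    def test_single_state_target(self):
        seg = self._segmentation()
        out = attribute_targets([L.GenomicInterval("chrT", 100, 300)], seg)
        assert out.set_index("state").attributions.to_dict() == {"A": 1, "B": 0}

    def test_straddling_target_multi_counted(self):
        seg = self._segmentation()
        out = attribute_targets([L.GenomicInterval("chrT", 4_900, 5_100)], seg)
        assert out.attributions.tolist() == [1, 1]

    def test_exclusion_and_suppression_flags(self):
        seg = self._segmentation()
        targets = [L.GenomicInterval("chrT", 100, 200)] * 999 + [
            L.GenomicInterval("chrT", 6_000, 6_100)
        ]
        out = attribute_targets(targets, seg, min_fraction=0.003).set_index("state")
        assert bool(out.loc["B", "suppressed"])
        only_b = attribute_targets(targets, seg, exclude_states=["A"]).set_index("state")
        assert only_b.loc["B", "proportion"] == 1.0

    def test_known_state_mix_recovered(self):
        """Targets placed into a known segmentation with a 70/30 state mix
        come back within 3 binomial SDs of the mix."""
        rng = np.random.default_rng(30)
        seg = self._segmentation()  # A = [0, 5000), B = [5000, 10000)
        n = 2_000
        targets = []
        for _ in range(n):
            if rng.random() < 0.7:
                s = int(rng.integers(0, 4_900))
            else:
                s = int(rng.integers(5_000, 9_900))
            targets.append(L.GenomicInterval("chrT", s, s + 50))
        out = attribute_targets(targets, seg).set_index("state")
        frac_a = out.loc["A", "attributions"] / out.attributions.sum()
        assert abs(frac_a - 0.7) < 3 * np.sqrt(0.7 * 0.3 / n) + 0.01  # straddlers


def test_synthetic_hmm_recovery_up_to_relabeling(dataset):
    """EM on generator-emitted tracks recovers the generating emissions to
    within 0.05 after the best state permutation."""
    fit, hist = baum_welch(dataset.binarized, dataset.truth.hmm_model.n_states,
                           seed=0, max_iter=100)
    truth = dataset.truth.hmm_model.emission
    best = min(
        np.abs(fit.emission[list(perm)] - truth).max()
        for perm in itertools.permutations(range(truth.shape[0]))
    )
    assert best < 0.05
    assert np.all(np.diff(hist) >= -1e-8)
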