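"""Bayesian matching engine: likelihood matrix, sequential updates, verdicts.

The reference oracle here evaluates the posterior by naive products in
linear space — prior * prod p(D_k|Y) against (1-prior) * prod p(D_k|N) —
independently of the log-space sequential engine it checks.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sketchid.match import (
    CandidateState,
    MatchConfig,
    MatchResult,
    likelihood_match,
    likelihood_mismatch,
    match_sketch,
    update_candidate,
)
from sketchid.panel import SnpMarker, SnpPanel
from sketchid.reference import ReferenceDatabase, ReferenceGenotypes
from sketchid.sketch import Sketch, SketchObservation


def naive_posterior(prior, items):
    """Direct Bayes evaluation; items = [(genotype, observed, epsilon, freq_a)]."""
    ly = lmn = 1.0
    for genotype, observed, eps, freq_a in items:
        if genotype is None:
            continue
        f_obs = freq_a if observed == "A" else 1.0 - freq_a
        ly *= likelihood_match(genotype, observed, eps)
        lmn *= likelihood_mismatch(observed, f_obs, eps)
    return prior * ly / (prior * ly + (1.0 - prior) * lmn)


def make_case(rng, n_obs, n_markers=30):
    """Random small panel + candidate + observation stream."""
    markers = [
        SnpMarker("1", 100 * (i + 1), f"rs{i}", "A", "G",
                  float(rng.uniform(0.05, 0.95)))
        for i in range(n_markers)
    ]
    panel = SnpPanel(markers)
    genos = {}
    for m in markers:
        if rng.random() < 0.8:
            genos[m.rsid] = ("AA", "AB", "BB")[rng.integers(0, 3)]
    cand = ReferenceGenotypes("c", genos)
    idx = rng.choice(n_markers, size=n_obs, replace=False)
    obs = [
        SketchObservation(
            markers[i].rsid,
            "A" if rng.random() < 0.5 else "B",
            float(k),
            float(rng.uniform(0.005, 0.25)),
        )
        for k, i in enumerate(idx)
    ]
    return panel, cand, obs


class TestLikelihoodMatrix:
    @pytest.mark.parametrize(
        "genotype, observed, eps, expected",
        [
            ("AA", "A", 0.02, 0.98),
            ("AA", "B", 0.02, 0.02),
            ("AB", "A", 0.37, 0.5),
            ("AB", "B", 0.37, 0.5),
            ("BB", "A", 0.1, 0.1),
            ("BB", "B", 0.1, 0.9),
            ("AA", "B", 0.0, 0.0),
        ],
    )
    def test_matrix_entries(self, genotype, observed, eps, expected):
        assert likelihood_match(genotype, observed, eps) == pytest.approx(expected)

    def test_invalid_genotype_rejected(self):
        with pytest.raises(ValueError):
            likelihood_match("AC", "A", 0.1)

    @pytest.mark.parametrize(
        "observed, freq, eps, expected",
        [
            ("A", 0.5, 0.3, 0.5),        # symmetric at f=0.5 for any epsilon
            ("A", 0.3, 0.1, 0.34),
            ("B", 0.99, 0.02, 0.9704),
        ],
    )
    def test_mismatch_likelihood(self, observed, freq, eps, expected):
        assert likelihood_mismatch(observed, freq, eps) == pytest.approx(expected)

    def test_mismatch_frequency_bounds(self):
        with pytest.raises(ValueError):
            likelihood_mismatch("A", 0.001, 0.1)

    @given(
        eps=st.floats(0.0, 0.4999),
        f=st.floats(0.01, 0.99),
    )
    @settings(max_examples=100, derandomize=True)
    def test_likelihoods_are_probabilities(self, eps, f):
        for g in ("AA", "AB", "BB"):
            for o in ("A", "B"):
                assert 0.0 <= likelihood_match(g, o, eps) <= 1.0
        assert 0.0 < likelihood_mismatch("A", f, eps) < 1.0


class TestSequentialUpdate:
    def test_worked_single_marker_update(self):
        """prior 1e-5, genotype AA, observed A, eps 0.02, f=0.5 -> ~1.96e-5."""
        config = MatchConfig(prior=1e-5)
        state = CandidateState.fresh("x", config)
        marker = SnpMarker("1", 1, "rs1", "A", "G", 0.5)
        obs = SketchObservation("rs1", "A", 0.0, 0.02)
        new = update_candidate(state, obs, marker, "AA", config)
        # independent arithmetic: odds scale by 0.98/0.5
        odds = (1e-5 / (1 - 1e-5)) * (0.98 / 0.5)
        assert new.posterior == pytest.approx(odds / (1 + odds), rel=1e-9)
        assert new.posterior == pytest.approx(1.96e-5, rel=1e-3)
        assert new.n_intersected == 1
        assert new.n_mismatch == 0

    def test_het_at_half_frequency_is_uninformative(self):
        config = MatchConfig()
        state = CandidateState.fresh("x", config)
        marker = SnpMarker("1", 1, "rs1", "A", "G", 0.5)
        obs = SketchObservation("rs1", "A", 0.0, 0.1)
        new = update_candidate(state, obs, marker, "AB", config)
        assert new.posterior == pytest.approx(state.posterior, rel=1e-12)
        assert new.n_intersected == 1

    def test_missing_genotype_leaves_state_untouched(self):
        config = MatchConfig()
        state = CandidateState.fresh("x", config)
        obs = SketchObservation("rs1", "A", 0.0, 0.1)
        marker = SnpMarker("1", 1, "rs1", "A", "G", 0.5)
        assert update_candidate(state, obs, marker, None, config) == state

    def test_mismatch_counter_counts_hom_inconsistencies_only(self):
        config = MatchConfig()
        state = CandidateState.fresh("x", config)
        marker = SnpMarker("1", 1, "rs1", "A", "G", 0.5)
        state = update_candidate(
            state, SketchObservation("rs1", "B", 0.0, 0.1), marker, "AA", config
        )
        assert state.n_mismatch == 1
        marker2 = SnpMarker("1", 2, "rs2", "A", "G", 0.5)
        state = update_candidate(
            state, SketchObservation("rs2", "B", 1.0, 0.1), marker2, "AB", config
        )
        assert state.n_mismatch == 1  # het observations are not mismatches

    @pytest.mark.parametrize("n_obs", [1, 5, 20])
    def test_sequential_engine_equals_naive_oracle(self, n_obs):
        rng = np.random.default_rng(n_obs)
        for rep in range(20):
            panel, cand, obs_list = make_case(rng, n_obs)
            prior = 10.0 ** -rng.uniform(1, 8)
            config = MatchConfig(
                prior=prior, match_threshold=1 - 1e-15, reject_threshold=1e-300,
                stop_snps=10_000, max_data_seconds=None,
            )
            # scalar sequential path
            state = CandidateState.fresh("c", config)
            items = []
            for o in obs_list:
                m = panel.marker(o.rsid)
                g = cand.get(o.rsid)
                state = update_candidate(state, o, m, g, config)
                state.status = "active"  # arithmetic check only: no early stopping
                items.append((g, o.observed, o.epsilon, m.freq_a))
            expected = naive_posterior(prior, items)
            assert state.posterior == pytest.approx(expected, rel=1e-10)
            # vectorized path
            sketch = Sketch(observations=obs_list)
            res = match_sketch(sketch, ReferenceDatabase([cand]), panel, config)
            assert res.get("c").posterior == pytest.approx(expected, rel=1e-10)

    def test_final_posterior_invariant_to_observation_order(self):
        rng = np.random.default_rng(7)
        panel, cand, obs_list = make_case(rng, 15)
        config = MatchConfig(match_threshold=1 - 1e-15, reject_threshold=1e-300,
                             max_data_seconds=None)
        db = ReferenceDatabase([cand])

        def run(obs):
            sk = Sketch(observations=[
                SketchObservation(o.rsid, o.observed, float(k), o.epsilon)
                for k, o in enumerate(obs)
            ])
            return match_sketch(sk, db, panel, config).get("c").posterior

        base = run(obs_list)
        for seed in range(3):
            perm = np.random.default_rng(seed).permutation(len(obs_list))
            assert run([obs_list[i] for i in perm]) == pytest.approx(base, rel=1e-10)


class TestMatchSketch:
    def _self_sketch(self, panel, cand, eps=0.0):
        obs = []
        for k, m in enumerate(panel):
            g = cand.get(m.rsid)
            if g is None:
                continue
            allele = {"AA": "A", "BB": "B", "AB": "A"}[g]
            obs.append(SketchObservation(m.rsid, allele, float(k), eps))
        return Sketch(observations=obs)

    def _pair(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        markers = [
            SnpMarker("1", 10 * (i + 1), f"rs{i}", "A", "G",
                      float(rng.uniform(0.05, 0.95)))
            for i in range(n)
        ]
        panel = SnpPanel(markers)
        genos = {
            m.rsid: ("AA", "AB", "BB")[rng.integers(0, 3)] for m in markers
        }
        other = {
            m.rsid: ("AA", "AB", "BB")[rng.integers(0, 3)] for m in markers
        }
        return panel, ReferenceGenotypes("self", genos), ReferenceGenotypes("other", other)

    def test_errorless_self_sketch_matches(self):
        panel, cand, other = self._pair()
        config = MatchConfig(max_data_seconds=None)
        sketch = self._self_sketch(panel, cand, eps=0.001)
        res = match_sketch(sketch, ReferenceDatabase([cand, other]), panel, config)
        best = res.get("self")
        assert best.status == "matched"
        assert best.posterior >= 0.999
        assert res.verdict == "self"

    def test_rejected_candidate_reports_zero(self):
        panel, cand, other = self._pair()
        config = MatchConfig(max_data_seconds=None)
        sketch = self._self_sketch(panel, cand, eps=0.001)
        res = match_sketch(sketch, ReferenceDatabase([cand, other]), panel, config)
        o = res.get("other")
        assert o.status == "rejected"
        assert o.posterior == 0.0

    def test_empty_sketch_returns_priors(self):
        panel, cand, other = self._pair()
        config = MatchConfig()
        res = match_sketch(Sketch(), ReferenceDatabase([cand, other]), panel, config)
        for c in res.candidates:
            assert c.posterior == pytest.approx(config.prior)
            assert c.status == "exhausted"
            assert c.n_intersected == 0
        assert res.verdict == "no match in database"

    def test_stop_snps_budget_exhausts_undecided_candidates(self):
        panel, cand, other = self._pair()
        # uninformative observer: all het markers against f=0.5 would be ideal;
        # instead cap the budget very low so nothing can decide
        config = MatchConfig(stop_snps=3, match_threshold=1 - 1e-15,
                             reject_threshold=1e-300, max_data_seconds=None)
        sketch = self._self_sketch(panel, cand, eps=0.001)
        res = match_sketch(sketch, ReferenceDatabase([cand]), panel, config)
        assert res.get("self").n_intersected == 3
        assert res.get("self").status == "exhausted"

    def test_trajectory_n_snps_strictly_increasing(self):
        panel, cand, other = self._pair()
        config = MatchConfig(max_data_seconds=None)
        sketch = self._self_sketch(panel, cand, eps=0.001)
        res = match_sketch(sketch, ReferenceDatabase([cand]), panel, config,
                           trajectories_for=["self"])
        traj = res.trajectories["self"]
        assert np.all(np.diff(traj[:, 0]) > 0)
        assert np.all((traj[:, 2] >= 0) & (traj[:, 2] <= 1))

    def test_ranking_breaks_ties_lexicographically(self):
        panel, cand, _ = self._pair()
        twin = ReferenceGenotypes("aaa_twin", dict(cand.genotypes))
        config = MatchConfig(max_data_seconds=None)
        sketch = self._self_sketch(panel, cand, eps=0.001)
        res = match_sketch(sketch, ReferenceDatabase([cand, twin]), panel, config)
        assert [c.sample_id for c in res.candidates] == ["aaa_twin", "self"]
        assert len(res.matched) == 2  # both identical profiles reported matched

    def test_prior_invariance_of_verdict(self):
        """A true match is reached for priors from 1e-15 to 1e-2, with more
        SNPs needed as the prior shrinks."""
        panel, cand, other = self._pair()
        sketch = self._self_sketch(panel, cand, eps=0.001)
        db = ReferenceDatabase([cand, other])
        needed = []
        for prior in (1e-2, 1e-5, 1e-10, 1e-15):
            config = MatchConfig(prior=prior, stop_snps=1000, max_data_seconds=None)
            res = match_sketch(sketch, db, panel, config)
            c = res.get("self")
            assert c.status == "matched", f"prior {prior}"
            needed.append(c.snps_to_match)
        assert needed == sorted(needed)  # smaller prior cannot need fewer SNPs

    def test_max_data_seconds_truncates_stream(self):
        panel, cand, other = self._pair()
        sketch = self._self_sketch(panel, cand, eps=0.001)
        # timestamps are 0..n-1 seconds; cap at 9.5 s leaves 10 observations
        config = MatchConfig(max_data_seconds=9.5, match_threshold=1 - 1e-15,
                             reject_threshold=1e-300)
        res = match_sketch(sketch, ReferenceDatabase([cand]), panel, config)
        assert res.get("self").n_intersected == 10

    def test_empty_database_rejected(self):
        panel, cand, _ = self._pair()
        with pytest.raises(ValueError):
            match_sketch(Sketch(), ReferenceDatabase([]), panel, MatchConfig())


class TestMatchConfigValidation:
    def test_prior_bounds(self):
        with pytest.raises(ValueError):
            MatchConfig(prior=0.0)
        with pytest.raises(ValueError):
            MatchConfig(prior=1.0)

    def test_threshold_ordering(self):
        with pytest.raises(ValueError):
            MatchConfig(match_threshold=1e-10, reject_threshold=1e-9)
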