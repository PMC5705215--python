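"""Sequential Bayesian identity matching of a sketch against a genotype database.

For candidate *i* with match indicator x_i ∈ {Y, N} and observation stream
D = (D_1, ..., D_n) of allele labels at independent panel markers, the
posterior p(x_i = Y | D) follows from Bayes' rule with a per-marker
product likelihood.  Under an exact match the observation likelihood is a
genotype-conditional error matrix with symmetric allele confusion rate ε:

    p(D_k | Y)  =  1-ε / ε      if the candidate is homozygous,
                   0.5          if heterozygous,

and under no match the observed allele simply comes from a random member
of the population:

    p(D_k | N)  =  (1-ε)·f(D_k) + ε·(1-f(D_k)),

where f(D_k) is the observed allele's population frequency.  Each
candidate is evaluated independently as a binary Y/N hypothesis test —
posteriors are not normalized across the database.

All accumulation is in natural-log odds: products of hundreds of
likelihood terms against priors as small as 1e-15 underflow in linear
space.  A candidate is declared matched when its posterior reaches
``match_threshold`` (default 99.9%), abandoned once it drops below
``reject_threshold`` (default 1e-9, reported as 0), and declared a
no-match once ``stop_snps`` intersected markers (default 300) fail to
produce a match.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from .panel import SnpMarker, SnpPanel
from .reference import ReferenceDatabase
from .sketch import Sketch, SketchObservation

STATUS_ACTIVE = "active"
STATUS_MATCHED = "matched"
STATUS_REJECTED = "rejected"
STATUS_EXHAUSTED = "exhausted"

_LABEL_CODE = {"A": 0, "B": 1}


@dataclass(frozen=True)
class MatchConfig:
    """Decision thresholds of the sequential matcher."""

    prior: float = 1e-5              # prior match probability per candidate
    match_threshold: float = 0.999   # posterior declaring a match
    reject_threshold: float = 1e-9   # posterior below which a candidate is abandoned
    stop_snps: int = 300             # intersected-SNP budget before a no-match verdict
    max_data_seconds: Optional[float] = 3600.0

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ValueError(f"prior must be in (0, 1), got {self.prior}")
        if not self.reject_threshold < self.match_threshold:
            raise ValueError("reject_threshold must be below match_threshold")
        if self.stop_snps < 1:
            raise ValueError("stop_snps must be positive")


def likelihood_match(genotype: str, observed: str, epsilon: float) -> float:
    """p(observed allele | candidate genotype, exact match) — the error matrix."""
    if not 0.0 <= epsilon < 0.5:
        raise ValueError(f"epsilon must be in [0, 0.5), got {epsilon}")
    if observed not in _LABEL_CODE:
        raise ValueError(f"observed allele must be 'A' or 'B', got {observed!r}")
    if genotype == "AB":
        return 0.5
    if genotype == "AA":
        return 1.0 - epsilon if observed == "A" else epsilon
    if genotype == "BB":
        return 1.0 - epsilon if observed == "B" else epsilon
    raise ValueError(f"invalid genotype symbol: {genotype!r}")


def likelihood_mismatch(observed: str, freq_observed: float, epsilon: float) -> float:
    """p(observed allele | no match): an errorless draw of the same allele from
    a random person, or an error flipping the other allele."""
    if not 0.01 <= freq_observed <= 0.99:
        raise ValueError(f"allele frequency out of panel bounds: {freq_observed}")
    if observed not in _LABEL_CODE:
        raise ValueError(f"observed allele must be 'A' or 'B', got {observed!r}")
    return (1.0 - epsilon) * freq_observed + epsilon * (1.0 - freq_observed)


@dataclass
class CandidateState:
    """Running per-candidate state of the sequential scan."""

    sample_id: str
    log_odds: float
    n_intersected: int = 0
    n_mismatch: int = 0
    status: str = STATUS_ACTIVE

    @classmethod
    def fresh(cls, sample_id: str, config: MatchConfig) -> "CandidateState":
        return cls(sample_id=sample_id, log_odds=float(logit(config.prior)))

    @property
    def posterior(self) -> float:
        """Posterior match probability; truncated to 0 once rejected."""
        if self.status == STATUS_REJECTED:
            return 0.0
        return float(expit(self.log_odds))


def update_candidate(
    state: CandidateState,
    obs: SketchObservation,
    marker: SnpMarker,
    genotype: Optional[str],
    config: MatchConfig = MatchConfig(),
) -> CandidateState:
    """One sequential Bayes update for one candidate and one observation.

    A missing genotype leaves the state untouched (the marker does not
    intersect).  Otherwise the log odds move by the log likelihood ratio
    of match vs mismatch, counters advance, and the match / rejection /
    exhaustion thresholds are applied.
    """
    if state.status != STATUS_ACTIVE:
        return state
    if genotype is None:
        return state
    freq_obs = marker.freq_a if obs.observed == "A" else marker.freq_b
    lm = likelihood_match(genotype, obs.observed, obs.epsilon)
    lmm = likelihood_mismatch(obs.observed, freq_obs, obs.epsilon)
    with np.errstate(divide="ignore"):
        log_odds = state.log_odds + float(np.log(lm) - np.log(lmm))
    mismatch = (genotype == "AA" and obs.observed == "B") or (
        genotype == "BB" and obs.observed == "A"
    )
    new = replace(
        state,
        log_odds=log_odds,
        n_intersected=state.n_intersected + 1,
        n_mismatch=state.n_mismatch + int(mismatch),
    )
    post = expit(log_odds)
    if post >= config.match_threshold:
        new.status = STATUS_MATCHED
    elif post < config.reject_threshold and config.prior > config.reject_threshold:
        new.status = STATUS_REJECTED
    elif new.n_intersected >= config.stop_snps:
        new.status = STATUS_EXHAUSTED
    return new


@dataclass
class CandidateResult:
    sample_id: str
    posterior: float
    status: str
    n_intersected: int
    n_mismatch: int
    log_odds: float
    snps_to_match: Optional[int] = None  # intersected SNPs at first threshold crossing


@dataclass
class MatchResult:
    """Ranked per-candidate outcomes plus optional posterior trajectories."""

    candidates: list[CandidateResult]
    trajectories: dict[str, np.ndarray] = field(default_factory=dict)
    config: MatchConfig = field(default_factory=MatchConfig)

    @property
    def best(self) -> CandidateResult:
        return self.candidates[0]

    @property
    def matched(self) -> list[CandidateResult]:
        return [c for c in self.candidates if c.status == STATUS_MATCHED]

    @property
    def verdict(self) -> str:
        m = self.matched
        return m[0].sample_id if len(m) >= 1 else "no match in database"

    def get(self, sample_id: str) -> CandidateResult:
        for c in self.candidates:
            if c.sample_id == sample_id:
                return c
        raise KeyError(sample_id)

    def to_rows(self) -> list[dict]:
        return [
            {
                "sample_id": c.sample_id,
                "posterior": c.posterior,
                "status": c.status,
                "n_intersected": c.n_intersected,
                "n_mismatch": c.n_mismatch,
            }
            for c in self.candidates
        ]


def _observation_arrays(
    sketch: Sketch, panel: SnpPanel, config: MatchConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Panel-index, label, epsilon and timestamp arrays for in-panel
    observations within the data-time cap, in time order."""
    midx, labels, eps, ts = [], [], [], []
    for o in sketch.observations:
        if o.rsid not in panel:
            continue
        if (
            config.max_data_seconds is not None
            and o.timestamp > config.max_data_seconds
        ):
            continue
        midx.append(panel.index_of(o.rsid))
        labels.append(_LABEL_CODE[o.observed])
        eps.append(o.epsilon)
        ts.append(o.timestamp)
    return (
        np.asarray(midx, dtype=np.intp),
        np.asarray(labels, dtype=np.int8),
        np.asarray(eps, dtype=float),
        np.asarray(ts, dtype=float),
    )


def _core(
    G: np.ndarray,
    midx: np.ndarray,
    labels: np.ndarray,
    eps: np.ndarray,
    freq_a: np.ndarray,
    config: MatchConfig,
) -> dict[str, np.ndarray]:
    """Vectorized sequential scan over (candidates x observations).

    Computes, for every candidate row of the genotype matrix ``G``, the
    cumulative log odds along the observation stream, applies the match /
    reject / stop thresholds in stream order, and returns per-candidate
    summary arrays.  Results are identical to the scalar sequential
    update; the cumulative-sum formulation merely exploits the fact that
    the update is a running sum in log space.
    """
    n_cand = G.shape[0]
    n_obs = midx.size
    prior_lo = float(logit(config.prior))
    if n_obs == 0:
        return {
            "log_odds": np.full(n_cand, prior_lo),
            "posterior": np.full(n_cand, float(config.prior)),
            "status": np.array([STATUS_EXHAUSTED] * n_cand, dtype=object),
            "n_intersected": np.zeros(n_cand, dtype=int),
            "n_mismatch": np.zeros(n_cand, dtype=int),
            "snps_to_match": np.full(n_cand, -1, dtype=int),
            "cum": np.full((n_cand, 0), prior_lo),
            "inter": np.zeros((n_cand, 0), dtype=bool),
            "cumint": np.zeros((n_cand, 0), dtype=int),
            "stop_col": np.full(n_cand, -1, dtype=int),
        }

    g = G[:, midx]                      # (n_cand, n_obs)
    lab = labels[None, :]
    with np.errstate(divide="ignore"):
        log_e = np.log(eps)
        log_1me = np.log1p(-eps)
        f_obs = np.where(labels == 0, freq_a[midx], 1.0 - freq_a[midx])
        log_mm = np.log((1.0 - eps) * f_obs + eps * (1.0 - f_obs))

    lm = np.full((n_cand, n_obs), np.log(0.5))
    consistent = ((g == 0) & (lab == 0)) | ((g == 2) & (lab == 1))
    inconsistent = ((g == 0) & (lab == 1)) | ((g == 2) & (lab == 0))
    lm = np.where(consistent, log_1me[None, :], lm)
    lm = np.where(inconsistent, log_e[None, :], lm)

    llr = lm - log_mm[None, :]
    inter = g >= 0
    llr = np.where(inter, llr, 0.0)

    cumint = np.cumsum(inter, axis=1)
    within = cumint <= config.stop_snps
    llr = np.where(within, llr, 0.0)
    cum = prior_lo + np.cumsum(llr, axis=1)

    hi = float(logit(config.match_threshold))
    # "drops below" semantics: early rejection is meaningful only when the
    # candidate starts above the rejection bound; with a prior at or below
    # it (e.g. prior 1e-15) the rule is disabled.
    if config.prior > config.reject_threshold:
        lo = float(logit(config.reject_threshold))
    else:
        lo = -np.inf
    eligible = inter & within
    over = (cum >= hi) & eligible
    under = (cum < lo) & eligible

    first_over = np.where(over.any(axis=1), over.argmax(axis=1), n_obs)
    first_under = np.where(under.any(axis=1), under.argmax(axis=1), n_obs)

    rejected = first_under < first_over
    matched = first_over < first_under  # ties are impossible: hi > lo

    n_int_total = np.minimum(cumint[:, -1], config.stop_snps)
    exhausted = ~matched & ~rejected & (cumint[:, -1] >= config.stop_snps)

    status = np.array([STATUS_ACTIVE] * n_cand, dtype=object)
    status[exhausted] = STATUS_EXHAUSTED
    status[matched] = STATUS_MATCHED
    status[rejected] = STATUS_REJECTED

    # column index at which each candidate stops consuming the stream
    stop_col = np.full(n_cand, n_obs - 1, dtype=int)
    stop_col[rejected] = first_under[rejected]

    cols = np.arange(n_obs)[None, :]
    consumed = cols <= stop_col[:, None]
    n_mismatch = (inconsistent & eligible & consumed).sum(axis=1)

    n_intersected = np.where(rejected, cumint[np.arange(n_cand), stop_col], n_int_total)

    final_lo = cum[np.arange(n_cand), stop_col]
    posterior = expit(final_lo)
    posterior[rejected] = 0.0

    snps_to_match = np.full(n_cand, -1, dtype=int)
    if matched.any():
        rows = np.where(matched)[0]
        snps_to_match[rows] = cumint[rows, first_over[rows]]

    return {
        "log_odds": final_lo,
        "posterior": posterior,
        "status": status,
        "n_intersected": n_intersected.astype(int),
        "n_mismatch": n_mismatch.astype(int),
        "snps_to_match": snps_to_match,
        "cum": cum,
        "inter": inter,
        "cumint": cumint,
        "stop_col": stop_col,
    }


def match_sketch(
    sketch: Sketch,
    db: ReferenceDatabase,
    panel: SnpPanel,
    config: MatchConfig = MatchConfig(),
    trajectories_for: Sequence[str] = (),
) -> MatchResult:
    """Match a sketch against every database candidate.

    Observations are consumed in time order; each active candidate's log
    odds are updated at every marker it intersects.  Candidates crossing
    the match threshold are reported matched (scanning continues so that
    multiple simultaneous matches are detected and reported); candidates
    falling below the rejection threshold are abandoned and reported with
    posterior 0; candidates still undecided after the intersected-SNP
    budget are exhausted (a no-match verdict).  Results are ranked by
    posterior, ties broken lexicographically by sample id.
    """
    if len(db) == 0:
        raise ValueError("empty reference database")
    midx, labels, eps, ts = _observation_arrays(sketch, panel, config)
    G = db.genotype_matrix(panel)
    out = _core(G, midx, labels, eps, panel.freq_a, config)

    ids = db.sample_ids
    candidates = []
    for i, sid in enumerate(ids):
        stm = int(out["snps_to_match"][i])
        candidates.append(
            CandidateResult(
                sample_id=sid,
                posterior=float(out["posterior"][i]),
                status=str(out["status"][i]),
                n_intersected=int(out["n_intersected"][i]),
                n_mismatch=int(out["n_mismatch"][i]),
                log_odds=float(out["log_odds"][i]),
                snps_to_match=stm if stm >= 0 else None,
            )
        )
    candidates.sort(key=lambda c: (-c.posterior, c.sample_id))

    trajectories: dict[str, np.ndarray] = {}
    for sid in trajectories_for:
        i = ids.index(sid)
        if midx.size == 0:
            trajectories[sid] = np.empty((0, 3))
            continue
        take = out["inter"][i] & (np.arange(midx.size) <= out["stop_col"][i])
        take &= out["cumint"][i] <= config.stop_snps
        n_snps = out["cumint"][i][take]
        post = expit(out["cum"][i][take])
        trajectories[sid] = np.column_stack([n_snps, ts[take], post])

    return MatchResult(candidates=candidates, trajectories=trajectories, config=config)
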