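"""Synthetic panels, genotypes, sketches, mixtures, relatives and growth curves.

The generators here define the in-silico study conditions used by the test
experiments: a common-SNP panel with allele-A frequencies drawn uniformly
on [0.05, 0.95], Hardy-Weinberg genotypes for unrelated individuals,
Mendelian transmission for pedigrees, and a sketching process that samples
markers without replacement, draws the transmitted allele from the true
genotype and flips it with a symmetric error rate ε (0.02 for the faster
R9 chemistry regime, 0.089 for R7).  Markers are independent by
construction — no linkage disequilibrium and no population structure.

All stochastic operations take an explicit seed (or an already-spawned
``numpy.random.Generator``); the same seed reproduces the same draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import expit, logit

from .match import MatchConfig, _core
from .panel import SnpMarker, SnpPanel
from .reference import ReferenceDatabase, ReferenceGenotypes
from .sketch import Sketch, SketchObservation

_CODE_TO_GENOTYPE = ("AA", "AB", "BB")
_BASES = np.array(list("ACGT"))

RngLike = Union[int, np.random.Generator, None]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed is required for stochastic simulation")
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the sketching simulation.

    ``snps_per_minute`` is the panel-SNP yield of the run at the reference
    translocation speed (250 bases/sec); at slower chemistries the same
    yield takes proportionally longer, which is how the time axis encodes
    the 70 vs 250 bases/sec regimes.
    """

    n_markers: int = 5000
    maf_low: float = 0.05
    maf_high: float = 0.95
    epsilon: float = 0.02          # per-observation allele error rate (R9 regime)
    snps_per_minute: float = 30.0  # observation yield at 250 bases/sec
    bases_per_second: float = 250.0
    reads_total: int = 3000        # mixture experiment size
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")
        if self.snps_per_minute <= 0 or self.bases_per_second <= 0:
            raise ValueError("rates must be positive")

    @property
    def seconds_per_observation(self) -> float:
        return (60.0 / self.snps_per_minute) * (250.0 / self.bases_per_second)


def simulate_panel(config: SimConfig, seed: RngLike = None) -> SnpPanel:
    """Synthetic common-SNP panel with uniform allele-A frequencies."""
    rng = _rng(seed if seed is not None else config.seed)
    n = config.n_markers
    freqs = rng.uniform(config.maf_low, config.maf_high, size=n)
    allele_a_idx = rng.integers(0, 4, size=n)
    allele_b_idx = (allele_a_idx + rng.integers(1, 4, size=n)) % 4
    markers = [
        SnpMarker(
            chrom=str(i % 22 + 1),
            pos=10_000 * (i // 22 + 1),
            rsid=f"rs{1_000_000 + i}",
            allele_a=str(_BASES[allele_a_idx[i]]),
            allele_b=str(_BASES[allele_b_idx[i]]),
            freq_a=float(freqs[i]),
        )
        for i in range(n)
    ]
    return SnpPanel(markers)


def simulate_individual(
    panel: SnpPanel, seed: RngLike, sample_id: str = "sim"
) -> ReferenceGenotypes:
    """Unrelated individual: genotypes drawn under Hardy-Weinberg equilibrium.

    Per marker the B-allele count is Binomial(2, 1 - f_A), i.e. genotype
    probabilities f², 2f(1-f), (1-f)² for AA, AB, BB.
    """
    rng = _rng(seed)
    codes = rng.binomial(2, 1.0 - panel.freq_a)
    genotypes = {
        m.rsid: _CODE_TO_GENOTYPE[codes[i]] for i, m in enumerate(panel.markers)
    }
    return ReferenceGenotypes(sample_id=sample_id, genotypes=genotypes)


def _transmitted_allele_b(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per marker, one gamete allele (0=A, 1=B) drawn from a parent's genotype."""
    het = codes == 1
    out = (codes == 2).astype(np.int8)
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return out


def simulate_child(
    p1: ReferenceGenotypes,
    p2: ReferenceGenotypes,
    panel: SnpPanel,
    seed: RngLike,
    sample_id: str = "child",
) -> ReferenceGenotypes:
    """Mendelian offspring: one allele sampled uniformly from each parent."""
    rng = _rng(seed)
    c1 = p1.codes(panel)
    c2 = p2.codes(panel)
    if (c1 < 0).any() or (c2 < 0).any():
        raise ValueError("parents must be fully genotyped on the panel")
    codes = _transmitted_allele_b(c1, rng) + _transmitted_allele_b(c2, rng)
    genotypes = {
        m.rsid: _CODE_TO_GENOTYPE[codes[i]] for i, m in enumerate(panel.markers)
    }
    return ReferenceGenotypes(sample_id=sample_id, genotypes=genotypes)


def simulate_sketch(
    truth: ReferenceGenotypes,
    panel: SnpPanel,
    config: SimConfig,
    n_obs: int,
    seed: RngLike = None,
) -> Sketch:
    """Simulate the sketching process for a known individual.

    Samples ``n_obs`` distinct markers uniformly without replacement; at
    each, one allele is transmitted from the true genotype (homozygotes
    deterministically, heterozygotes by fair coin) and flipped with
    probability ε.  Timestamps advance at the configured SNP yield,
    scaled by the translocation-speed regime.
    """
    if n_obs > len(panel):
        raise ValueError(f"n_obs={n_obs} exceeds panel size {len(panel)}")
    rng = _rng(seed if seed is not None else config.seed)
    codes = truth.codes(panel)
    midx = rng.choice(len(panel), size=n_obs, replace=False)
    true_b = _transmitted_allele_b(codes[midx], rng)
    flip = rng.random(n_obs) < config.epsilon
    obs_b = true_b ^ flip
    dt = config.seconds_per_observation
    sketch = Sketch(reads_in=n_obs, reads_pass_qc=n_obs, bases_at_panel=n_obs)
    for k in range(n_obs):
        m = panel.markers[midx[k]]
        sketch.observations.append(
            SketchObservation(
                rsid=m.rsid,
                observed="B" if obs_b[k] else "A",
                timestamp=(k + 1) * dt,
                epsilon=config.epsilon,
            )
        )
    return sketch


def simulate_mixture(
    sketch_a: Sketch,
    sketch_b: Sketch,
    fraction_b: float,
    reads_total: int,
    seed: RngLike,
) -> Sketch:
    """Pool observations from two sketches at a given contamination fraction.

    Draws round(reads_total * fraction_b) observations from the
    contaminant sketch and the remainder from the host sketch, keeping
    marker sets disjoint (at sketch coverage each locus is seen by at
    most one read), shuffles the pool and re-times it at the host
    sketch's observation spacing.
    """
    if not 0.0 <= fraction_b <= 1.0:
        raise ValueError("fraction_b must be in [0, 1]")
    rng = _rng(seed)
    n_b = round(reads_total * fraction_b)
    n_a = reads_total - n_b
    if n_a > len(sketch_a):
        raise ValueError(f"host sketch has {len(sketch_a)} observations, need {n_a}")
    obs_a = [sketch_a.observations[i] for i in rng.permutation(len(sketch_a))[:n_a]]
    taken = {o.rsid for o in obs_a}
    pool_b = [sketch_b.observations[i] for i in rng.permutation(len(sketch_b))]
    obs_b = [o for o in pool_b if o.rsid not in taken][:n_b]
    if len(obs_b) < n_b:
        raise ValueError(
            f"contaminant sketch yields only {len(obs_b)} disjoint observations, need {n_b}"
        )
    pooled = obs_a + obs_b
    order = rng.permutation(len(pooled))
    if len(sketch_a) > 1:
        dt = sketch_a.observations[1].timestamp - sketch_a.observations[0].timestamp
    else:
        dt = 1.0
    mixed = Sketch(reads_in=reads_total, reads_pass_qc=reads_total,
                   bases_at_panel=reads_total)
    for k, i in enumerate(order):
        o = pooled[i]
        mixed.observations.append(
            SketchObservation(o.rsid, o.observed, (k + 1) * dt, o.epsilon)
        )
    return mixed


@dataclass
class MixtureRun:
    fraction_b: float
    replicate: int
    final_posterior_a: float
    final_posterior_b: float
    status_a: str
    status_b: str


def simulate_mixture_replicates(
    sketch_a: Sketch,
    sketch_b: Sketch,
    db: ReferenceDatabase,
    panel: SnpPanel,
    fractions: Sequence[float],
    reads_total: int,
    n_replicates: int,
    seed: int,
    id_a: str,
    id_b: str,
    match_config: MatchConfig = MatchConfig(),
) -> list[MixtureRun]:
    """Contamination grid: n_replicates mixtures per fraction, each matched
    against the database; reports the truncated posterior of both
    contributing references."""
    from .match import match_sketch

    ss = np.random.SeedSequence(seed)
    runs: list[MixtureRun] = []
    for frac in fractions:
        for rep in range(n_replicates):
            child = np.random.default_rng(ss.spawn(1)[0])
            mixed = simulate_mixture(sketch_a, sketch_b, frac, reads_total, child)
            res = match_sketch(mixed, db, panel, match_config)
            runs.append(
                MixtureRun(
                    fraction_b=frac,
                    replicate=rep,
                    final_posterior_a=res.get(id_a).posterior,
                    final_posterior_b=res.get(id_b).posterior,
                    status_a=res.get(id_a).status,
                    status_b=res.get(id_b).status,
                )
            )
    return runs


@dataclass
class EnsembleResult:
    """Distribution of intersected-SNPs-to-match over repeated sketching runs."""

    snps_to_match: np.ndarray          # per matched run; NaN where the run failed
    n_runs: int
    n_failures: int                    # true candidate not matched within budget
    n_false_matches: int               # some other candidate reached the threshold

    @property
    def matched_mask(self) -> np.ndarray:
        return ~np.isnan(self.snps_to_match)

    def quantile(self, q: float) -> float:
        vals = self.snps_to_match[self.matched_mask]
        return float(np.quantile(vals, q)) if vals.size else math.nan

    @property
    def median(self) -> float:
        return self.quantile(0.5)

    def fraction_matched_within(self, k: int) -> float:
        """Fraction of all runs whose match arrived at or before k SNPs."""
        vals = self.snps_to_match[self.matched_mask]
        return float((vals <= k).sum()) / self.n_runs

    def histogram(self, bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
        vals = self.snps_to_match[self.matched_mask]
        return np.histogram(vals, bins=bins)


def ensemble_snps_to_match(
    truth: ReferenceGenotypes,
    panel: SnpPanel,
    db: ReferenceDatabase,
    config: SimConfig,
    n_runs: int,
    seed: int,
    match_config: MatchConfig = MatchConfig(),
) -> EnsembleResult:
    """Repeatedly sketch a known individual and record, per run, the number
    of intersected SNPs at which the true candidate first reaches the
    match threshold (or a failure at the stop budget).

    The whole database is scanned each run, so false matches by other
    candidates are also counted.
    """
    if truth.sample_id not in db.sample_ids:
        raise ValueError(f"truth sample {truth.sample_id!r} not in database")
    rng = np.random.default_rng(seed)
    G = db.genotype_matrix(panel)
    true_row = db.sample_ids.index(truth.sample_id)
    codes = truth.codes(panel)
    n_obs = min(match_config.stop_snps, len(panel))
    eps = np.full(n_obs, config.epsilon)
    # disable the wall-clock cap: ensemble runs are indexed by SNP count
    mc = MatchConfig(
        prior=match_config.prior,
        match_threshold=match_config.match_threshold,
        reject_threshold=match_config.reject_threshold,
        stop_snps=match_config.stop_snps,
        max_data_seconds=None,
    )
    snps = np.full(n_runs, np.nan)
    n_fail = 0
    n_false = 0
    for run in range(n_runs):
        midx = rng.choice(len(panel), size=n_obs, replace=False)
        true_b = _transmitted_allele_b(codes[midx], rng)
        flip = rng.random(n_obs) < config.epsilon
        labels = (true_b ^ flip).astype(np.int8)
        out = _core(G, midx.astype(np.intp), labels, eps, panel.freq_a, mc)
        stm = out["snps_to_match"]
        if stm[true_row] >= 0:
            snps[run] = stm[true_row]
        else:
            n_fail += 1
        n_false += int(((stm >= 0).sum()) - int(stm[true_row] >= 0))
    return EnsembleResult(
        snps_to_match=snps, n_runs=n_runs, n_failures=n_fail, n_false_matches=n_false
    )


@dataclass
class Pedigree:
    """Three-generation pedigree around one focal individual."""

    focal: ReferenceGenotypes        # the sketched person
    child: ReferenceGenotypes        # first-degree relative
    grandchild: ReferenceGenotypes   # second-degree relative


def simulate_pedigree(panel: SnpPanel, seed: RngLike) -> Pedigree:
    """Focal individual, their child (with an unrelated spouse) and the
    child's child (with an unrelated in-law), all by Mendelian transmission."""
    rng = _rng(seed)
    focal = simulate_individual(panel, rng, "focal")
    spouse = simulate_individual(panel, rng, "spouse")
    child = simulate_child(focal, spouse, panel, rng, "child")
    in_law = simulate_individual(panel, rng, "in_law")
    grandchild = simulate_child(child, in_law, panel, rng, "grandchild")
    return Pedigree(focal=focal, child=child, grandchild=grandchild)


@dataclass
class RelativeRun:
    focal_snps_to_match: Optional[int]
    child_matched_by_stop: bool
    grandchild_matched_by_stop: bool
    child_max_posterior: float
    grandchild_max_posterior: float


def relative_discrimination(
    pedigree: Pedigree,
    panel: SnpPanel,
    config: SimConfig,
    n_runs: int,
    seed: int,
    match_config: MatchConfig = MatchConfig(),
) -> list[RelativeRun]:
    """Sketch the focal individual repeatedly against a database holding their
    own, their child's and their grandchild's reference files.

    The matcher is sequential and sketching stops once a match is declared,
    so each relative is assessed on the observations consumed up to the
    focal individual's own match (or the full stop budget when no match
    arrives): the question is whether a relative ever reaches the match
    threshold while the instrument is still running.
    """
    rng = np.random.default_rng(seed)
    G = np.stack(
        [
            pedigree.focal.codes(panel),
            pedigree.child.codes(panel),
            pedigree.grandchild.codes(panel),
        ]
    )
    codes = pedigree.focal.codes(panel)
    n_obs = min(match_config.stop_snps, len(panel))
    eps = np.full(n_obs, config.epsilon)
    mc = MatchConfig(
        prior=match_config.prior,
        match_threshold=match_config.match_threshold,
        reject_threshold=match_config.reject_threshold,
        stop_snps=match_config.stop_snps,
        max_data_seconds=None,
    )
    hi = logit(mc.match_threshold)
    runs: list[RelativeRun] = []
    for _ in range(n_runs):
        midx = rng.choice(len(panel), size=n_obs, replace=False)
        true_b = _transmitted_allele_b(codes[midx], rng)
        flip = rng.random(n_obs) < config.epsilon
        labels = (true_b ^ flip).astype(np.int8)
        out = _core(G, midx.astype(np.intp), labels, eps, panel.freq_a, mc)
        stm = out["snps_to_match"]
        # column index where data acquisition stops: the focal match, if any
        if stm[0] >= 0:
            cum_f = out["cumint"][0]
            stop_col = int(np.argmax(cum_f >= stm[0]))
        else:
            stop_col = n_obs - 1
        rel = []
        for row in (1, 2):
            cum = out["cum"][row][: stop_col + 1]
            inter = out["inter"][row][: stop_col + 1]
            crossed = bool((cum[inter] >= hi).any()) if inter.any() else False
            max_post = float(expit(cum[inter].max())) if inter.any() else mc.prior
            rel.append((crossed, max_post))
        runs.append(
            RelativeRun(
                focal_snps_to_match=int(stm[0]) if stm[0] >= 0 else None,
                child_matched_by_stop=rel[0][0],
                grandchild_matched_by_stop=rel[1][0],
                child_max_posterior=rel[0][1],
                grandchild_max_posterior=rel[1][1],
            )
        )
    return runs


@dataclass(frozen=True)
class GrowthParams:
    """Deterministic exponential competition between host and contaminant lines."""

    n_host0: float = 1e6      # initial host cells
    n_cont0: float = 10.0     # initial contaminant cells
    t_host: float = 24.0      # host doubling time, hours
    t_cont: float = 20.0      # contaminant doubling time, hours
    horizon_hours: float = 336.0  # 2 weeks
    dt_hours: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_host0, self.n_cont0, self.t_host, self.t_cont,
               self.horizon_hours, self.dt_hours) <= 0:
            raise ValueError("all growth parameters must be positive")


@dataclass
class GrowthResult:
    times_hours: np.ndarray
    fraction_contaminant: np.ndarray
    crossover_hours: Optional[float]   # None means the contaminant never overtakes


def growth_competition(params: GrowthParams) -> GrowthResult:
    """Contaminant fraction over time under pure exponential (log-phase) growth.

    N(t) = N0 * 2^(t/T) for each line; the 50% crossover has the closed
    form t* = log2(N_host0/N_cont0) / (1/T_cont - 1/T_host), defined only
    when the contaminant doubles faster than the host.
    """
    t = np.arange(0.0, params.horizon_hours + params.dt_hours / 2, params.dt_hours)
    # work with log2 cell counts to avoid overflow over long horizons
    l_host = math.log2(params.n_host0) + t / params.t_host
    l_cont = math.log2(params.n_cont0) + t / params.t_cont
    frac = 1.0 / (1.0 + np.exp2(l_host - l_cont))
    if params.t_cont < params.t_host:
        crossover = math.log2(params.n_host0 / params.n_cont0) / (
            1.0 / params.t_cont - 1.0 / params.t_host
        )
    else:
        crossover = None
    return GrowthResult(times_hours=t, fraction_contaminant=frac,
                        crossover_hours=crossover)
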