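"""HMM copy-number inference and tumor-fraction estimation.

A six-state HMM (clonal copy numbers {0,1,2,3} plus subclonal {1,3})
with Student-t emissions centered at the expected log2 depth ratio for
each copy state at the current tumor fraction. EM alternates
forward-backward posteriors with bounded, derivative-free maximization
of the tumor fraction, subclone prevalence and emission scale. The
estimator is run from a grid of initial normal proportions and the
highest-likelihood solution kept, ties broken toward the lower tumor
fraction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import gammaln

from shallowcn.bins import BinScheme
from shallowcn.cbs import SegmentRecord, SegmentSet
from shallowcn.normalize import NormalizedProfile

logger = logging.getLogger(__name__)

# state table: (copy number, is_subclonal)
STATES: tuple[tuple[int, bool], ...] = (
    (0, False),
    (1, False),
    (2, False),
    (3, False),
    (1, True),
    (3, True),
)
N_STATES = len(STATES)
NEUTRAL_STATE = 2

TF_MIN, TF_MAX = 0.005, 0.6
SP_MIN, SP_MAX = 0.1, 0.9
SIGMA_MIN = 1e-4
BASELINE_MIN, BASELINE_MAX = -0.02, 0.02

DEFAULT_NORMAL_GRID = (0.7, 0.8, 0.9, 0.95, 0.99)


@dataclass
class HMMConfig:
    normal_grid: tuple[float, ...] = DEFAULT_NORMAL_GRID
    ploidy: int = 2
    max_copy: int = 3
    self_transition: float = 0.9999
    emission_df: float = 3.0
    # per-bin log-prior favoring the neutral state over altered states, and
    # subclonal states least; without these the EM can tile the genome with
    # tiny-shift states that soak up correlated noise (whole-genome-altered
    # solutions at deflated tumor fraction)
    alteration_penalty: float = 0.05
    subclone_penalty: float = 0.1
    max_iter: int = 50
    tol: float = 1e-3
    use_autosomes_only: bool = True

    def __post_init__(self):
        if not all(0.0 < n < 1.0 for n in self.normal_grid):
            raise ValueError("normal_grid values must lie in (0,1)")
        if not 0.0 < self.self_transition < 1.0:
            raise ValueError("self_transition must lie in (0,1)")
        if self.ploidy != 2 or self.max_copy != 3:
            raise ValueError("this model fixes ploidy=2 and max_copy=3")


@dataclass
class TumorFractionEstimate:
    sample_id: str
    tumor_fraction: float
    normal_proportion: float
    subclone_prevalence: float
    log_likelihood: float
    fraction_genome_altered: float
    baseline_offset: float = 0.0
    converged: bool = True
    n_iter: int = 0
    grid_trace: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TumorFractionEstimate":
        with open(path) as fh:
            return cls(**json.load(fh))


def expected_log2(tf: float, c: int, ploidy: int = 2) -> float:
    """Expected log2 depth ratio of a copy-c region at tumor fraction tf."""
    if not 0.0 <= tf <= 1.0:
        raise ValueError("tumor fraction must be in [0,1]")
    if c < 0 or ploidy <= 0:
        raise ValueError("copy number must be >= 0 and ploidy > 0")
    if tf == 1.0 and c == 0:
        raise ValueError("log2 ratio undefined at tf=1 with zero copies")
    return float(np.log2((tf * c + (1.0 - tf) * ploidy) / ploidy))


def _state_means(tf: float, sp: float, ploidy: int = 2) -> np.ndarray:
    means = np.empty(N_STATES)
    for k, (c, sub) in enumerate(STATES):
        eff = tf * sp if sub else tf
        means[k] = expected_log2(eff, c, ploidy)
    return means


def _t_logpdf(x: np.ndarray, loc: np.ndarray, scale: float, df: float) -> np.ndarray:
    """Student-t log density, broadcasting x (n,1) against loc (k,)."""
    z = (x - loc) / scale
    const = (
        gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
    )
    return const - (df + 1.0) / 2.0 * np.log1p(z * z / df)


def _log_emissions(
    x: np.ndarray, tf: float, sp: float, sigma: float, config: HMMConfig, delta: float = 0.0
) -> np.ndarray:
    """Per-bin, per-state log emission terms (with the subclonal penalty).

    ``delta`` is a global baseline offset added to every state mean: after
    median centering the neutral peak can sit slightly off zero whenever a
    large genome fraction is altered, and treating the residual as a
    nuisance parameter removes that bias from the tumor fraction.
    """
    means = _state_means(tf, sp, config.ploidy) + delta
    logB = _t_logpdf(x[:, None], means[None, :], sigma, config.emission_df)
    if config.alteration_penalty:
        logB[:, [0, 1, 3, 4, 5]] -= config.alteration_penalty
    if config.subclone_penalty:
        logB[:, 4:] -= config.subclone_penalty
    return logB


def _golden_max(f, lo: float, hi: float, tol: float = 1e-4, max_eval: int = 40):
    """Golden-section maximization; returns (argmax, max) over evaluated points."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    best_x, best_f = (c, fc) if fc >= fd else (d, fd)
    evals = 2
    while (b - a) > tol and evals < max_eval:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
            if fc > best_f:
                best_x, best_f = c, fc
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
            if fd > best_f:
                best_x, best_f = d, fd
        evals += 1
    for x in (lo, hi):
        fx = f(x)
        if fx > best_f:
            best_x, best_f = x, fx
    return best_x, best_f


class _Chains:
    """Per-chromosome observation sequences extracted from a profile."""

    def __init__(self, profile: NormalizedProfile, scheme: BinScheme, autosomes_only: bool):
        self.chroms: list[str] = []
        self.bin_idx: list[np.ndarray] = []  # global bin indices per chain
        self.x: list[np.ndarray] = []
        keep = profile.valid.copy()
        if autosomes_only:
            keep &= scheme.autosomal
        for chrom, sl in scheme.chrom_slices():
            idx = np.arange(sl.start, sl.stop)
            sel = idx[keep[idx]]
            if len(sel) == 0:
                continue
            self.chroms.append(chrom)
            self.bin_idx.append(sel)
            self.x.append(profile.log2_ratio[sel])
        self.n_obs = int(sum(len(x) for x in self.x))


def _forward_backward(logB: np.ndarray, self_p: float) -> tuple[np.ndarray, float]:
    """Scaled forward-backward for one chain; returns (posteriors, loglik)."""
    n, k = logB.shape
    off = (1.0 - self_p) / (k - 1)
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    bmax = logB.max(axis=1)
    alpha = np.empty((n, k))
    scale = np.empty(n)
    a = B[0] / k
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, n):
        # uniform-off-diagonal transition: pred = off*sum + (self-off)*alpha
        s = alpha[t - 1].sum()
        pred = off * s + (self_p - off) * alpha[t - 1]
        a = pred * B[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta = np.empty((n, k))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        v = B[t + 1] * beta[t + 1]
        s = v.sum()
        beta[t] = (off * s + (self_p - off) * v) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    ll = float(np.sum(np.log(scale)) + np.sum(bmax))
    return gamma, ll


def forward_backward_posteriors(
    x: np.ndarray, tf: float, sp: float, sigma: float, config: HMMConfig
) -> tuple[np.ndarray, float]:
    """Posterior state probabilities for one observation chain (testing hook)."""
    return _forward_backward(_log_emissions(x, tf, sp, sigma, config), config.self_transition)


def _viterbi(logB: np.ndarray, self_p: float) -> np.ndarray:
    n, k = logB.shape
    log_self = np.log(self_p)
    log_off = np.log((1.0 - self_p) / (k - 1))
    delta = logB[0] - np.log(k)
    back = np.zeros((n, k), dtype=np.int8)
    for t in range(1, n):
        stay = delta + log_self
        jump_from = int(np.argmax(delta))
        jump = delta[jump_from] + log_off
        choose_stay = stay >= jump
        best = np.where(choose_stay, stay, jump)
        back[t] = np.where(choose_stay, np.arange(k), jump_from)
        delta = best + logB[t]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def viterbi_path(
    x: np.ndarray, tf: float, sp: float, sigma: float, config: HMMConfig
) -> np.ndarray:
    """Most likely state path for one observation chain (testing hook)."""
    return _viterbi(_log_emissions(x, tf, sp, sigma, config), config.self_transition)


def _q_value(
    xs: list[np.ndarray], gammas: list[np.ndarray], tf, sp, sigma, config, delta=0.0
) -> float:
    means = _state_means(tf, sp, config.ploidy) + delta
    q = 0.0
    for x, g in zip(xs, gammas):
        q += float(np.sum(g * _t_logpdf(x[:, None], means[None, :], sigma, config.emission_df)))
    return q


def run_hmm(
    profile: NormalizedProfile,
    scheme: BinScheme,
    config: HMMConfig,
    init_n: float,
) -> tuple[SegmentSet, TumorFractionEstimate]:
    """Fit the HMM by EM from one initial normal proportion.

    Returns the Viterbi segmentation (method_tag ``hmm_arm``) and the
    converged tumor-fraction estimate. On non-convergence the best
    iterate is returned with ``converged=False``.
    """
    if not 0.0 < init_n < 1.0:
        raise ValueError("init_n must be in (0,1)")
    chains = _Chains(profile, scheme, config.use_autosomes_only)
    if chains.n_obs == 0:
        raise ValueError("no usable bins for HMM fitting")
    if chains.n_obs < 100:
        logger.warning("only %d usable bins; tumor-fraction estimate unstable", chains.n_obs)

    xs = chains.x
    allx = np.concatenate(xs)
    tf = float(np.clip(1.0 - init_n, TF_MIN, TF_MAX))
    sp = 0.5
    delta = 0.0
    sigma = max(1.4826 * float(np.median(np.abs(allx - np.median(allx)))), 0.01)
    df = config.emission_df

    prev_ll = -np.inf
    converged = False
    n_iter = 0
    gammas: list[np.ndarray] = []
    for n_iter in range(1, config.max_iter + 1):
        gammas, ll = [], 0.0
        for x in xs:
            logB = _log_emissions(x, tf, sp, sigma, config, delta)
            g, l = _forward_backward(logB, config.self_transition)
            gammas.append(g)
            ll += l
        if ll + 1e-6 * max(1.0, abs(ll)) < prev_ll:
            logger.warning("EM log-likelihood decreased (%.6g -> %.6g); stopping", prev_ll, ll)
            break
        if abs(ll - prev_ll) < config.tol:
            prev_ll = ll
            converged = True
            break
        prev_ll = ll

        # M-step: baseline, tf, subclone prevalence, then t-scale via
        # latent weights; every sub-step is guarded to not decrease Q
        q_now = _q_value(xs, gammas, tf, sp, sigma, config, delta)
        delta_new, q_d = _golden_max(
            lambda v: _q_value(xs, gammas, tf, sp, sigma, config, v),
            BASELINE_MIN, BASELINE_MAX, tol=1e-4,
        )
        if q_d > q_now:
            delta, q_now = delta_new, q_d
        tf_new, q_tf = _golden_max(
            lambda v: _q_value(xs, gammas, v, sp, sigma, config, delta), TF_MIN, TF_MAX, tol=1e-4
        )
        if q_tf > q_now:
            tf, q_now = tf_new, q_tf
        sub_mass = sum(float(g[:, 4:].sum()) for g in gammas)
        if sub_mass > 1e-6:
            sp_new, q_sp = _golden_max(
                lambda v: _q_value(xs, gammas, tf, v, sigma, config, delta), SP_MIN, SP_MAX, tol=1e-3
            )
            if q_sp > q_now:
                sp, q_now = sp_new, q_sp
        means = _state_means(tf, sp, config.ploidy) + delta
        num = den = 0.0
        for x, g in zip(xs, gammas):
            resid = x[:, None] - means[None, :]
            z2 = (resid / sigma) ** 2
            u = (df + 1.0) / (df + z2)  # latent t scale weights
            num += float(np.sum(g * u * resid**2))
            den += float(np.sum(g))
        sigma_new = max(np.sqrt(num / den), SIGMA_MIN)
        if _q_value(xs, gammas, tf, sp, sigma_new, config, delta) > q_now:
            sigma = sigma_new

    # final decode
    segments: list[SegmentRecord] = []
    n_altered = 0
    for chrom, bidx, x in zip(chains.chroms, chains.bin_idx, xs):
        logB = _log_emissions(x, tf, sp, sigma, config, delta)
        path = _viterbi(logB, config.self_transition)
        copies = np.array([STATES[s][0] for s in path])
        n_altered += int(np.sum(copies != config.ploidy))
        breaks = np.flatnonzero(np.diff(copies) != 0) + 1
        edges = np.concatenate([[0], breaks, [len(x)]])
        for a, b in zip(edges[:-1], edges[1:]):
            member = bidx[a:b]
            segments.append(
                SegmentRecord(
                    chrom=chrom,
                    start=int(scheme.start[member[0]]),
                    end=int(scheme.end[member[-1]]),
                    n_bins=int(b - a),
                    mean_log2=float(np.mean(x[a:b])),
                    copy_state=int(copies[a]),
                    first_bin=int(member[0]),
                    last_bin=int(member[-1]),
                )
            )
    segset = SegmentSet(sample_id=profile.sample_id, method_tag="hmm_arm", segments=segments)
    est = TumorFractionEstimate(
        sample_id=profile.sample_id,
        tumor_fraction=float(tf),
        normal_proportion=float(1.0 - tf),
        subclone_prevalence=float(sp),
        log_likelihood=float(prev_ll),
        fraction_genome_altered=n_altered / chains.n_obs,
        baseline_offset=float(delta),
        converged=converged,
        n_iter=n_iter,
    )
    return segset, est


def estimate_tumor_fraction(
    profile: NormalizedProfile, scheme: BinScheme, config: HMMConfig | None = None
) -> tuple[SegmentSet, TumorFractionEstimate]:
    """Grid-initialized tumor-fraction estimate.

    Runs the EM once per initial normal proportion in ``config.normal_grid``
    and keeps the highest-likelihood solution; likelihood ties are broken
    toward the LOWER tumor fraction. The full grid trace is retained on
    the returned estimate.
    """
    config = config or HMMConfig()
    results = []
    for init_n in config.normal_grid:
        segset, est = run_hmm(profile, scheme, config, init_n)
        results.append((init_n, segset, est))
    best_ll = max(est.log_likelihood for _, _, est in results)
    tied = [r for r in results if r[2].log_likelihood >= best_ll - 1e-6]
    init_n, segset, est = min(tied, key=lambda r: r[2].tumor_fraction)
    est.grid_trace = [
        {
            "init_normal": n,
            "tumor_fraction": e.tumor_fraction,
            "log_likelihood": e.log_likelihood,
            "converged": e.converged,
        }
        for n, _, e in results
    ]
    return segset, est
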