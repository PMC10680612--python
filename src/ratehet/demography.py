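"""Two-epoch demographic inference from the unfolded SFS.

The expected SFS under a piecewise-constant single-population history
is computed from the expected time the sample genealogy spends with k
lineages (E[T_k]), combined with the classical branch-subtending
weights: a random branch present while k lineages remain subtends i of
the n sampled leaves with probability C(n-i-1, k-2)/C(n-1, k-1), so

    E[xi_i] = mu * L * sum_k  k * E[T_k] * C(n-i-1, k-2) / C(n-1, k-1).

E[T_k] is obtained either by deterministic quadrature of the
time-inhomogeneous pure-death lineage chain (matrix exponential within
each constant epoch, closed form in the final infinite epoch) or by
Monte-Carlo coalescent simulation; the two serve as mutual oracles.

Fitting offers the two flavors used by coalescent- and diffusion-style
SFS tools: an absolute Poisson composite likelihood over (N_ancestral,
N_current, tau in generations) with mu fixed, and a relative
multinomial likelihood over (nu = N_current/N_ancestral,
tau_rel = tau/(2 N_ancestral)) with the mutation intensity profiled
out by normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, gammaln, logit

from .sfs import SFS

__all__ = ["TwoEpochModel", "BranchExpectations", "DemographyFit",
           "branch_time_expectations", "expected_sfs", "fit_equilibrium",
           "fit_two_epoch", "scale_by_truth"]


@dataclass(frozen=True)
class TwoEpochModel:
    """Piecewise-constant history with one instantaneous size change.

    ``tau`` is the number of generations before sampling at which the
    population switched from N_ancestral to N_current diploids;
    nu = 1 (or tau = 0) reduces to the equilibrium model.
    """

    N_ancestral: float
    N_current: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.N_ancestral <= 0 or self.N_current <= 0 or self.tau < 0:
            raise ValueError("sizes must be > 0 and tau >= 0")

    @property
    def nu(self) -> float:
        return self.N_current / self.N_ancestral

    @property
    def tau_rel(self) -> float:
        return self.tau / (2.0 * self.N_ancestral)

    @classmethod
    def equilibrium(cls, N: float) -> "TwoEpochModel":
        return cls(N, N, 0.0)

    @classmethod
    def relative(cls, nu: float, tau_rel: float) -> "TwoEpochModel":
        """Unit-N_ancestral model carrying only (nu, tau_rel)."""
        return cls(1.0, nu, 2.0 * tau_rel)


@dataclass
class BranchExpectations:
    """E[T_k]: expected generations with k lineages, k = 2..n.

    ``E[k]`` is addressed directly (entries 0, 1 unused and zero).
    """

    n: int
    E: np.ndarray
    method: str
    reps: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.E[2:] <= 0):
            raise ValueError("branch time expectations must be > 0")


def _death_rates(n: int, N: float) -> np.ndarray:
    """Coalescence rate per generation for k = 2..n lineages."""
    k = np.arange(2, n + 1)
    return k * (k - 1) / 2.0 / (2.0 * N)


def _quadrature_expectations(model: TwoEpochModel, n: int) -> np.ndarray:
    """Occupancy integrals of the lineage-count chain, exactly.

    State vector p over k = 2..n (index k-2). Within the recent epoch
    the chain is linear with constant generator A (upper bidiagonal),
    so p(tau) = expm(A tau) p0 and the occupancy integral solves
    A I = p(tau) - p0. The infinite ancestral epoch contributes
    4 N_anc / (k(k-1)) * P(K(tau) >= k) in closed form.
    """
    m = n - 1
    p0 = np.zeros(m)
    p0[m - 1] = 1.0  # start with n lineages
    E = np.zeros(n + 1)
    lam_anc = _death_rates(n, model.N_ancestral)
    if model.tau > 0 and model.nu != 1.0:
        lam = _death_rates(n, model.N_current)
        A = np.diag(-lam) + np.diag(lam[1:], 1)
        # dense scaling-and-squaring: robust for the very stiff
        # generators that small-N proposals produce
        p_tau = np.clip(expm(A * model.tau) @ p0, 0.0, None)
        # solve A I = p(tau) - p0 (upper bidiagonal back-substitution)
        b = p_tau - p0
        I = np.zeros(m)
        I[m - 1] = b[m - 1] / -lam[m - 1]
        for j in range(m - 2, -1, -1):
            I[j] = -(b[j] - lam[j + 1] * I[j + 1]) / lam[j]
        surv = np.cumsum(p_tau[::-1])[::-1]  # P(K(tau) >= k), k = 2..n
        E[2:] = I + surv / lam_anc
    else:
        E[2:] = 1.0 / lam_anc
    return E


def _monte_carlo_expectations(model: TwoEpochModel, n: int, reps: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Simulate the pure-death coalescent across the two epochs."""
    t = np.zeros(reps)
    E = np.zeros(n + 1)
    tau, nu = model.tau, model.nu
    for k in range(n, 1, -1):
        lam_anc = k * (k - 1) / 2.0 / (2.0 * model.N_ancestral)
        u1 = rng.random(reps)
        e_anc = -np.log(u1) / lam_anc
        if tau > 0 and nu != 1.0:
            lam_cur = k * (k - 1) / 2.0 / (2.0 * model.N_current)
            e_cur = -np.log(u1) / lam_cur
            e2 = -np.log(rng.random(reps)) / lam_anc
            in_cur = t < tau
            stays = in_cur & (t + e_cur <= tau)
            crosses = in_cur & ~stays
            wait = np.where(stays, e_cur,
                            np.where(crosses, (tau - t) + e2, e_anc))
        else:
            wait = e_anc
        E[k] = wait.mean()
        t += wait
    return E


def branch_time_expectations(model: TwoEpochModel, n: int,
                             method: str = "quadrature",
                             reps: int = 100_000,
                             seed: int | None = None,
                             rng: np.random.Generator | None = None
                             ) -> BranchExpectations:
    if n < 2:
        raise ValueError("need n >= 2")
    if method == "quadrature":
        E = _quadrature_expectations(model, n)
        return BranchExpectations(n, E, method)
    if method == "monte_carlo":
        if rng is None:
            rng = np.random.default_rng(seed)
        E = _monte_carlo_expectations(model, n, reps, rng)
        return BranchExpectations(n, E, method, reps=reps)
    raise ValueError("method must be 'quadrature' or 'monte_carlo'")


_SUBTEND_CACHE: dict[int, np.ndarray] = {}


def _subtending_weights(n: int) -> np.ndarray:
    """W[i-1, k-2] = k * C(n-i-1, k-2) / C(n-1, k-1)."""
    if n in _SUBTEND_CACHE:
        return _SUBTEND_CACHE[n]

    def lchoose(a, b):
        out = np.full(np.broadcast(a, b).shape, -np.inf)
        ok = (b >= 0) & (a >= b)
        aa, bb = np.broadcast_arrays(a, b)
        out[ok] = (gammaln(aa[ok] + 1) - gammaln(bb[ok] + 1)
                   - gammaln(aa[ok] - bb[ok] + 1))
        return out

    i = np.arange(1, n)[:, None]
    k = np.arange(2, n + 1)[None, :]
    logw = lchoose(n - i - 1, k - 2) - lchoose(n - 1, k - 1)
    W = np.exp(logw) * k
    _SUBTEND_CACHE[n] = W
    return W


def expected_sfs(model: TwoEpochModel, n: int, mu_per_site: float, L: float,
                 method: str = "quadrature", reps: int = 100_000,
                 seed: int | None = None,
                 rng: np.random.Generator | None = None) -> SFS:
    """Expected unfolded SFS (real-valued counts; bins 0 and n zero)."""
    bt = branch_time_expectations(model, n, method, reps, seed, rng)
    xi = mu_per_site * L * (_subtending_weights(n) @ bt.E[2:])
    counts = np.zeros(n + 1)
    counts[1:n] = xi
    return SFS(n, counts, span_bp=float(L))


# ---------------------------------------------------------------------------
# fitting

@dataclass
class DemographyFit:
    model: TwoEpochModel
    loglik: float
    flavor: str
    boundary_pinned: bool
    starts: list = field(default_factory=list)  # (params, loglik, success)
    scaled: dict | None = None


def _poisson_ll(obs: np.ndarray, exp: np.ndarray) -> float:
    exp = np.clip(exp, 1e-300, None)
    return float(np.sum(obs * np.log(exp) - exp))


def fit_equilibrium(sfs: SFS, mu: float, L: float,
                    log10_bounds=(0.0, 7.0)) -> DemographyFit:
    """Single-parameter fit of the constant-size model.

    Maximises the Poisson composite likelihood of E[xi_i] = 4 N mu L / i
    over log10 N by 1-D bounded optimisation.
    """
    n = sfs.n
    obs = sfs.counts[1:n]
    inv_i = 1.0 / np.arange(1, n)

    def nll(log10N):
        return -_poisson_ll(obs, 4.0 * 10 ** log10N * mu * L * inv_i)

    res = minimize_scalar(nll, bounds=log10_bounds, method="bounded",
                          options={"xatol": 1e-10})
    N_hat = 10 ** res.x
    pinned = min(res.x - log10_bounds[0], log10_bounds[1] - res.x) < 1e-3
    return DemographyFit(TwoEpochModel.equilibrium(N_hat), -res.fun,
                         "equilibrium_poisson", pinned)


#: parameter search boxes: population sizes 10..100,000 diploids, change
#: times 10..10,000 generations (absolute flavor); log10 nu and tau_rel
#: in [-2, 2] (relative flavor)
DEFAULT_SEARCH = {
    "poisson_absolute": {"N_ancestral": (10.0, 1e5), "N_current": (10.0, 1e5),
                         "tau": (10.0, 1e4)},
    "multinomial_relative": {"nu": (1e-2, 1e2), "tau_rel": (1e-2, 1e2)},
}


def _to_box(z, lo, hi):
    return lo * (hi / lo) ** expit(z)  # log-space sigmoid into (lo, hi)


def _from_box(x, lo, hi):
    return logit(np.log(x / lo) / np.log(hi / lo))


def fit_two_epoch(sfs: SFS, likelihood: str = "multinomial_relative",
                  mu: float | None = None, L: float | None = None,
                  search_cfg: dict | None = None, n_starts: int = 12,
                  seed: int | None = None, method: str = "quadrature",
                  mc_reps: int = 100_000) -> DemographyFit:
    """Fit the two-epoch model by multi-start derivative-free search.

    ``poisson_absolute`` infers (N_ancestral, N_current, tau) with mu
    fixed; ``multinomial_relative`` infers (nu, tau_rel) from the SFS
    shape only. Monomorphic bins are masked. Monte-Carlo expectations
    use common random numbers across proposals within one fit.
    """
    if sfs.folded:
        raise ValueError("need an unfolded spectrum")
    n = sfs.n
    obs = sfs.counts[1:n]
    cfg = dict(DEFAULT_SEARCH[likelihood])
    if search_cfg:
        cfg.update(search_cfg)
    rng = np.random.default_rng(seed)
    mc_seed = None if seed is None else int(
        np.random.SeedSequence([seed, 0xC0A1]).generate_state(1)[0] % 2**31)

    if likelihood == "poisson_absolute":
        if mu is None or L is None:
            raise ValueError("absolute fitting needs mu and L")
        names = ["N_ancestral", "N_current", "tau"]

        def build(x):
            return TwoEpochModel(*x)

        def ll(x):
            exp = expected_sfs(build(x), n, mu, L, method, mc_reps,
                               seed=mc_seed).counts[1:n]
            return _poisson_ll(obs, exp)
    elif likelihood == "multinomial_relative":
        names = ["nu", "tau_rel"]

        def build(x):
            return TwoEpochModel.relative(*x)

        def ll(x):
            exp = expected_sfs(build(x), n, 1.0, 1.0, method, mc_reps,
                               seed=mc_seed).counts[1:n]
            p = np.clip(exp / exp.sum(), 1e-300, None)
            return float(np.sum(obs * np.log(p)))
    else:
        raise ValueError("unknown likelihood flavor")

    los = np.array([cfg[nm][0] for nm in names])
    his = np.array([cfg[nm][1] for nm in names])

    def nll_z(z):
        return -ll(_to_box(z, los, his))

    starts_log = []
    best = None
    for s in range(n_starts):
        x0 = np.exp(rng.uniform(np.log(los), np.log(his)))
        res = minimize(nll_z, _from_box(x0, los, his), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8,
                                "maxiter": 250})
        x_hat = _to_box(res.x, los, his)
        starts_log.append((dict(zip(names, x0)), -float(res.fun),
                           bool(res.success)))
        if best is None or res.fun < best[0]:
            best = (float(res.fun), x_hat, res)
    if best is None or not np.isfinite(best[0]):
        raise RuntimeError("all optimizer starts failed to converge")
    x_hat = best[1]
    rel = np.minimum(x_hat / los, his / x_hat)
    pinned = bool(np.any(rel < 1.001))
    return DemographyFit(build(x_hat), -best[0], likelihood, pinned,
                         starts_log)


def scale_by_truth(estimates: dict, truth: dict) -> dict:
    """Elementwise ratio estimate/truth; 1 means a perfect estimate."""
    out = {}
    for k, v in estimates.items():
        if k in truth:
            if truth[k] == 0:
                raise ValueError(f"true value of {k} is zero")
            out[k] = v / truth[k]
    return out
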