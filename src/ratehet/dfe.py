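"""Gamma-DFE inference from selected site frequency spectra.

Expected spectra at directly selected sites come from two engines:

* ``prf`` — the equilibrium Poisson-random-field closed form. For a
  semi-dominant deleterious mutation with population-scaled strength
  gamma = 2 N s (s the homozygote fitness reduction, h = 0.5),

      E[xi_i] = thetaL * Int_0^1 C(n,i) x^i (1-x)^(n-i) g(x; gamma) dx,
      g(x; gamma) = (1 - exp(-gamma (1-x)))
                    / ((1 - exp(-gamma)) x (1-x)),

  evaluated by composite Gauss-Legendre quadrature with extra panels
  near x = 1 where strong selection forms a boundary layer.

* ``wfmatrix`` — a reduced-size Wright-Fisher transition-matrix engine
  (reference size N_ref, selection rescaled so 2 N_ref s_ref = gamma):
  the expected density of segregating sites over derived-count classes
  evolves under constant mutational influx into count 1; its
  stationary state is solved exactly as a linear system, size-change
  epochs are stepped generation by generation with the state re-binned
  at each change, and the final state is binomially projected to the
  sample size. This engine handles non-equilibrium demography and also
  pins the gamma <-> 2Ns factor convention of the PRF form.

A gamma distribution of gamma over new deleterious mutations (shape
beta, mean mean_gamma) is discretised on a fixed log grid and fitted
by maximising a Poisson composite likelihood with the mutation
intensity theta_sel profiled out in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import binom as binom_dist
from scipy.stats import chi2
from scipy.stats import gamma as gamma_dist

from .demography import TwoEpochModel
from .sfs import SFS

__all__ = [
    "GammaDFE", "ClassProportions", "GammaDFEFit",
    "selected_sfs_equilibrium", "wf_transition_matrix",
    "selected_sfs_dynamic", "expected_sfs_under_gamma", "fit_gamma_dfe",
    "class_proportions", "compare_neutral_vs_gamma", "fragmented_loglik",
    "GAMMA_NODES",
]


@dataclass(frozen=True)
class GammaDFE:
    """Gamma-distributed DFE of new deleterious mutations over
    gamma = 2 N_ancestral s: shape beta and mean mean_gamma, plus the
    nuisance mutation intensity theta_sel."""

    shape: float
    mean_gamma: float
    theta_sel: float = 1.0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.mean_gamma <= 0:
            raise ValueError("shape and mean_gamma must be > 0")


@dataclass(frozen=True)
class ClassProportions:
    """Mass of the DFE in the four 2Ns classes [0,1), [1,10), [10,100),
    [100, inf)."""

    f0: float
    f1: float
    f2: float
    f3: float

    def __post_init__(self) -> None:
        if abs(self.f0 + self.f1 + self.f2 + self.f3 - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")

    @property
    def f(self):
        return (self.f0, self.f1, self.f2, self.f3)


# ---------------------------------------------------------------------------
# PRF equilibrium engine

_QUAD_SEGMENTS = (0.0, 0.5, 0.9, 0.99, 0.999, 1.0)
_QUAD_ORDER = 96
_NODE_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _quad_basis(n: int):
    """Quadrature nodes/weights and binomial sampling kernel for n."""
    if n in _NODE_CACHE:
        return _NODE_CACHE[n]
    xg, wg = np.polynomial.legendre.leggauss(_QUAD_ORDER)
    xs, ws = [], []
    for a, b in zip(_QUAD_SEGMENTS[:-1], _QUAD_SEGMENTS[1:]):
        xs.append(0.5 * (b - a) * xg + 0.5 * (a + b))
        ws.append(0.5 * (b - a) * wg)
    x = np.concatenate(xs)
    w = np.concatenate(ws)
    i = np.arange(1, n)[:, None]
    B = binom_dist.pmf(i, n, x[None, :])  # (n-1, K)
    _NODE_CACHE[n] = (x, w, B)
    return x, w, B


def _sojourn_g(x: np.ndarray, gamma: float) -> np.ndarray:
    """PRF frequency density g(x; gamma) for a semi-dominant deleterious
    mutation of magnitude gamma = 2Ns >= 0,

        g(x; gamma) = (e^{gamma (1-x)} - 1) / ((e^{gamma} - 1) x (1-x)),

    evaluated in log space so that strong selection (gamma up to ~1e5)
    does not overflow; the gamma -> 0 limit is the neutral 1/x."""
    if gamma < 1e-12:
        return 1.0 / x
    a = gamma * (1.0 - x)
    with np.errstate(divide="ignore"):
        log_num = np.where(a > 30.0, a,
                           np.log(np.expm1(np.minimum(a, 30.0))))
    log_den = gamma if gamma > 30.0 else np.log(np.expm1(gamma))
    return np.exp(log_num - log_den) / (x * (1.0 - x))


def selected_sfs_equilibrium(gamma: float, n: int,
                             thetaL: float = 1.0) -> SFS:
    """Expected selected SFS at equilibrium (PRF closed form)."""
    if gamma < 0:
        raise ValueError("gamma is a deleterious magnitude, >= 0")
    if n < 2:
        raise ValueError("need n >= 2")
    x, w, B = _quad_basis(n)
    xi = thetaL * (B @ (w * _sojourn_g(x, gamma)))
    counts = np.zeros(n + 1)
    counts[1:n] = xi
    return SFS(n, counts)


# ---------------------------------------------------------------------------
# Wright-Fisher transition-matrix engine

def wf_transition_matrix(N_ref: int, s: float, h: float = 0.5) -> np.ndarray:
    """Row-stochastic matrix over derived counts 0..2N_ref.

    Deterministic selection (genotype fitnesses 1, 1-hs, 1-s) followed
    by binomial sampling of 2N_ref gametes; counts 0 and 2N_ref are
    absorbing.
    """
    two_n = 2 * N_ref
    x = np.arange(two_n + 1) / two_n
    w_bar = x**2 * (1 - s) + 2 * x * (1 - x) * (1 - h * s) + (1 - x) ** 2
    with np.errstate(invalid="ignore"):
        x_prime = (x**2 * (1 - s) + x * (1 - x) * (1 - h * s)) / w_bar
    x_prime[0] = 0.0
    x_prime[-1] = 1.0  # fixed class stays fixed even at s = 1 (w_bar = 0)
    j = np.arange(two_n + 1)
    return binom_dist.pmf(j[None, :], two_n, x_prime[:, None])


def _stationary_density(M: np.ndarray, influx: float) -> np.ndarray:
    """Expected segregating-site density over interior counts under
    constant influx into count 1 (exact fixed point of the linear
    recursion phi <- M^T phi + influx e1)."""
    two_n = M.shape[0] - 1
    M_int = M[1:two_n, 1:two_n]
    b = np.zeros(two_n - 1)
    b[0] = influx
    return np.linalg.solve(np.eye(two_n - 1) - M_int.T, b)


_PROJ_CACHE: dict[tuple[int, int], np.ndarray] = {}
_REBIN_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _project_sample(phi: np.ndarray, two_n: int, n: int) -> np.ndarray:
    """Project interior-count density to sample bins by hypergeometric
    sampling of n haplotypes from the 2N_ref population (exact finite-N
    subsampling; converges to binomial as N_ref grows).

    The projection kernel depends only on (2N_ref, n) and is cached.
    """
    from scipy.stats import hypergeom
    key = (two_n, n)
    if key not in _PROJ_CACHE:
        j = np.arange(1, two_n)
        i = np.arange(1, n)[:, None]
        if n > two_n:
            # population smaller than the sample (severe contraction at
            # a capped engine size): binomial resampling approximation
            P = binom_dist.pmf(i, n, (j / two_n)[None, :])
        else:
            P = hypergeom.pmf(i, two_n, j[None, :], n)
        _PROJ_CACHE[key] = P
    return _PROJ_CACHE[key] @ phi


def _rebin_density(phi: np.ndarray, two_old: int, two_new: int) -> np.ndarray:
    """Map interior density between state-space sizes by binomial
    resampling of class frequencies (mass hitting 0 or 2N_new drops);
    the kernel depends only on the two sizes and is cached."""
    key = (two_old, two_new)
    if key not in _REBIN_CACHE:
        freqs = np.arange(1, two_old) / two_old
        jp = np.arange(1, two_new)[:, None]
        _REBIN_CACHE[key] = binom_dist.pmf(jp, two_new, freqs[None, :])
    return _REBIN_CACHE[key] @ phi


def selected_sfs_dynamic(model: TwoEpochModel | None, gamma: float, n: int,
                         N_ref: int = 100, thetaL: float = 1.0,
                         h: float = 0.5) -> SFS:
    """Expected selected SFS under at most one size change.

    Time and selection are rescaled to the reference size: one engine
    generation equals N_ancestral/N_ref real generations, s_ref =
    gamma/(2 N_ref), epoch sizes scale with nu and the mutational
    influx scales with the current population size.
    """
    influx = thetaL / 2.0
    if model is not None and model.nu < 1.0:
        # contractions shrink the engine's state space; start larger so
        # the final population still resolves the sample. Sizes are
        # quantised so projection/rebin kernels cache across fits;
        # very severe contractions fall back to binomial projection.
        need = int(np.ceil(max(n, 40) / (2.0 * model.nu)))
        for cand in (100, 150, 200, 300):
            if cand >= need:
                break
        N_ref = max(N_ref, cand)
    s_ref = gamma / (2.0 * N_ref)
    if s_ref > 1.0:
        raise ValueError("gamma too strong for this N_ref (s_ref > 1)")
    M_anc = wf_transition_matrix(N_ref, s_ref, h)
    phi = _stationary_density(M_anc, influx)
    two_n_cur = 2 * N_ref
    if model is not None and model.tau > 0 and model.nu != 1.0:
        # engine size follows nu but is capped: extreme expansions
        # (e.g. boundary-pinned nuisance fits) would otherwise demand
        # enormous state spaces; beyond the cap the re-binned density
        # keeps the frequency resolution of the capped size
        N_ref_cur = max(2, min(500, int(round(model.nu * N_ref))))
        two_n_cur = 2 * N_ref_cur
        phi = _rebin_density(phi, 2 * N_ref, two_n_cur)
        # rescale selection and time to the current engine size so that
        # 2 N_cur s and the drift clock are preserved whatever the cap
        s_cur = min(1.0, gamma * model.nu / (2.0 * N_ref_cur))
        M_cur = wf_transition_matrix(N_ref_cur, s_cur, h)
        T = int(round(model.tau * N_ref_cur
                      / (model.nu * model.N_ancestral)))
        influx_cur = influx * model.nu
        if T >= 20 * two_n_cur:
            # epoch far exceeds the chain's relaxation time: the state
            # has converged to the current-size stationary density
            phi = _stationary_density(M_cur, influx_cur)
        else:
            M_int_T = M_cur[1:two_n_cur, 1:two_n_cur].T.copy()
            e1 = np.zeros(two_n_cur - 1)
            e1[0] = influx_cur
            for _ in range(T):
                phi = M_int_T @ phi + e1
    xi = _project_sample(phi, two_n_cur, n)
    counts = np.zeros(n + 1)
    counts[1:n] = xi
    return SFS(n, counts)


# ---------------------------------------------------------------------------
# gamma mixture

#: fixed log-spaced discretisation of gamma used by all fits
GAMMA_NODES = 64
_GAMMA_EDGES = np.logspace(-4, 5, GAMMA_NODES + 1)
_GAMMA_MID = np.sqrt(_GAMMA_EDGES[:-1] * _GAMMA_EDGES[1:])


def _gamma_masses(shape: float, mean_gamma: float) -> np.ndarray:
    scale = mean_gamma / shape
    cdf = gamma_dist.cdf(_GAMMA_EDGES, a=shape, scale=scale)
    mass = np.diff(cdf)
    mass[0] += cdf[0]          # mass below the grid: effectively neutral
    mass[-1] += 1.0 - cdf[-1]  # mass above: strongest node
    return mass


def _node_spectra(model: TwoEpochModel | None, n: int, engine: str,
                  N_ref: int) -> np.ndarray:
    """Unit-theta spectra (n-1, nodes) at each gamma grid node."""
    if engine == "prf":
        if model is not None and model.tau > 0 and model.nu != 1.0:
            raise ValueError("the prf engine is equilibrium-only")
        x, w, B = _quad_basis(n)
        G = np.stack([w * _sojourn_g(x, g) for g in _GAMMA_MID], axis=1)
        return B @ G
    if engine == "wfmatrix":
        # nodes beyond the chain's range (s_ref > 1) are clamped to the
        # lethal limit (their spectra are vanishingly small anyway) and
        # computed once
        cache: dict[float, np.ndarray] = {}
        cols = []
        for g in _GAMMA_MID:
            gc = min(g, 2.0 * N_ref)
            if gc not in cache:
                cache[gc] = selected_sfs_dynamic(model, gc, n,
                                                 N_ref).counts[1:n]
            cols.append(cache[gc])
        return np.stack(cols, axis=1)
    raise ValueError("engine must be 'prf' or 'wfmatrix'")


def expected_sfs_under_gamma(dfe: GammaDFE,
                             model: TwoEpochModel | None = None,
                             n: int = 100, engine: str = "prf",
                             N_ref: int = 100) -> SFS:
    """Mixture over gamma ~ Gamma(shape, mean mean_gamma) of engine
    spectra, scaled by theta_sel."""
    U = _node_spectra(model, n, engine, N_ref)
    xi = dfe.theta_sel * (U @ _gamma_masses(dfe.shape, dfe.mean_gamma))
    counts = np.zeros(n + 1)
    counts[1:n] = xi
    return SFS(n, counts)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class GammaDFEFit:
    dfe: GammaDFE
    loglik: float
    boundary_pinned: bool
    proportions: ClassProportions
    starts: list = field(default_factory=list)


_FIT_BOUNDS = {"shape": (0.01, 100.0), "mean_gamma": (1e-3, 1e5)}


def _profile_theta(obs: np.ndarray, unit: np.ndarray) -> float:
    tot = unit.sum()
    return float(obs.sum() / tot) if tot > 0 else 0.0


def _poisson_ll(obs: np.ndarray, exp: np.ndarray) -> float:
    exp = np.clip(exp, 1e-300, None)
    return float(np.sum(obs * np.log(exp) - exp))


def _joint_distortion_ll(neu_obs: np.ndarray, sel_obs: np.ndarray,
                         u0: np.ndarray, u: np.ndarray,
                         n_iter: int = 50, tol: float = 1e-10):
    """Joint Poisson likelihood of neutral + selected spectra with
    shared per-bin distortion factors r_i.

    Because putatively neutral and selected sites share their
    mutation-rate and linked-selection environment, both spectra are
    modelled as (theta_neu * u0_i * r_i) and (theta_sel * u_i * r_i)
    with free r_i — the nuisance-distortion device of the standard
    two-step DFE tools. Given (u0, u), the ML nuisances have the
    closed-form fixed point

        r_i = (n_i + s_i) / (theta_neu u0_i + theta_sel u_i),
        theta = sum(obs) / sum(unit * r),

    iterated to convergence (the overall r-vs-theta scale is a
    harmless degeneracy). Returns (loglik, theta_sel, r).
    """
    r = np.ones_like(u0)
    t_n = t_s = 1.0
    tot = neu_obs + sel_obs
    for _ in range(n_iter):
        t_n = neu_obs.sum() / max(np.dot(u0, r), 1e-300)
        t_s = sel_obs.sum() / max(np.dot(u, r), 1e-300)
        denom = np.clip(t_n * u0 + t_s * u, 1e-300, None)
        r_new = tot / denom
        if np.max(np.abs(r_new - r)) < tol:
            r = r_new
            break
        r = r_new
    ll = (_poisson_ll(neu_obs, t_n * u0 * r)
          + _poisson_ll(sel_obs, t_s * u * r))
    return ll, t_s, r


def _neutral_unit(model: TwoEpochModel | None, n: int, engine: str,
                  N_ref: int) -> np.ndarray:
    if engine == "prf":
        return selected_sfs_equilibrium(0.0, n).counts[1:n]
    return selected_sfs_dynamic(model, 0.0, n, N_ref).counts[1:n]


def fit_gamma_dfe(neutral_sfs: SFS | None, selected_sfs: SFS,
                  demography_fitted: TwoEpochModel | None = None,
                  engine: str = "prf", n_starts: int = 8,
                  seed: int | None = None, N_ref: int = 100) -> GammaDFEFit:
    """Maximum-likelihood gamma DFE from a selected SFS, conditional on
    an already-inferred demography (two-step inference).

    ``neutral_sfs`` (the synonymous-site spectrum), when given, fixes
    per-bin distortion factors shared by the two site classes (see
    :func:`_neutral_distortion`). theta_sel is profiled in closed form;
    (shape, mean_gamma) are found by multi-start Nelder-Mead on log
    parameters. Fits pinned at the parameter bounds are flagged rather
    than silently returned — a fit driven to a tiny mean_gamma is the
    "largely neutral" failure mode.
    """
    n = selected_sfs.n
    obs = selected_sfs.counts[1:n]
    if engine == "auto":
        eq = (demography_fitted is None or demography_fitted.tau == 0
              or demography_fitted.nu == 1.0)
        engine = "prf" if eq else "wfmatrix"
    U = _node_spectra(demography_fitted, n, engine, N_ref)

    los = np.array([_FIT_BOUNDS["shape"][0], _FIT_BOUNDS["mean_gamma"][0]])
    his = np.array([_FIT_BOUNDS["shape"][1], _FIT_BOUNDS["mean_gamma"][1]])

    if neutral_sfs is not None:
        u0 = _neutral_unit(demography_fitted, n, engine, N_ref)
        neu_obs = neutral_sfs.counts[1:n]

        def ll_of(x):
            unit = U @ _gamma_masses(x[0], x[1])
            ll, theta, _ = _joint_distortion_ll(neu_obs, obs, u0, unit)
            return ll, theta
    else:
        def ll_of(x):
            unit = U @ _gamma_masses(x[0], x[1])
            theta = _profile_theta(obs, unit)
            return _poisson_ll(obs, theta * unit), theta

    def nll_z(z):
        return -ll_of(lo_hi(z))[0]

    def lo_hi(z):
        return los * (his / los) ** expit(z)

    rng = np.random.default_rng(seed)
    best = None
    starts_log = []
    for _ in range(n_starts):
        x0 = np.exp(rng.uniform(np.log(los), np.log(his)))
        z0 = logit(np.log(x0 / los) / np.log(his / los))
        res = minimize(nll_z, z0, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-8,
                                "maxiter": 2000})
        x_hat = lo_hi(res.x)
        starts_log.append((tuple(x0), -float(res.fun), bool(res.success)))
        if best is None or res.fun < best[0]:
            best = (float(res.fun), x_hat)
    x_hat = best[1]
    ll, theta = ll_of(x_hat)
    rel = np.minimum(x_hat / los, his / x_hat)
    pinned = bool(np.any(rel < 1.01))
    dfe = GammaDFE(float(x_hat[0]), float(x_hat[1]), theta)
    return GammaDFEFit(dfe, ll, pinned, class_proportions(dfe), starts_log)


def class_proportions(dfe: GammaDFE) -> ClassProportions:
    """Mass of the fitted gamma in the four 2Ns classes (the analogue
    of DFE-alpha's prop_muts_in_s_ranges)."""
    F = gamma_dist.cdf([1.0, 10.0, 100.0], a=dfe.shape,
                       scale=dfe.mean_gamma / dfe.shape)
    return ClassProportions(F[0], F[1] - F[0], F[2] - F[1], 1.0 - F[2])


def compare_neutral_vs_gamma(selected_sfs: SFS,
                             demography: TwoEpochModel | None = None,
                             engine: str = "prf", n_starts: int = 8,
                             seed: int | None = None,
                             N_ref: int = 100) -> dict:
    """Likelihood-ratio comparison of the theta-only neutral model
    against the nested gamma-DFE model (2 d.f. chi-square, a pragmatic
    approximation given the boundary null)."""
    n = selected_sfs.n
    obs = selected_sfs.counts[1:n]
    if engine == "prf":
        unit_neutral = selected_sfs_equilibrium(0.0, n).counts[1:n]
    else:
        unit_neutral = selected_sfs_dynamic(demography, 0.0, n,
                                            N_ref).counts[1:n]
    theta0 = _profile_theta(obs, unit_neutral)
    ll_neutral = _poisson_ll(obs, theta0 * unit_neutral)
    fit = fit_gamma_dfe(None, selected_sfs, demography, engine,
                        n_starts, seed, N_ref)
    delta = max(fit.loglik - ll_neutral, 0.0)
    return {"delta_loglik": delta, "loglik_gamma": fit.loglik,
            "loglik_neutral": ll_neutral, "fit": fit,
            "p_value": float(chi2.sf(2.0 * delta, df=2))}


def fragmented_loglik(fragment_sfs_list, dfe: GammaDFE,
                      demography: TwoEpochModel | None = None,
                      engine: str = "prf", N_ref: int = 100) -> float:
    """Composite likelihood over per-fragment spectra sharing one
    gamma DFE, with each fragment's mutation intensity theta_f profiled
    in closed form (the per-fragment-SFS handling used to absorb
    mutation-rate variation)."""
    fragments = list(fragment_sfs_list)
    if not fragments:
        raise ValueError("no fragments")
    n = fragments[0].n
    if any(f.n != n for f in fragments):
        raise ValueError("fragments have inconsistent sample sizes")
    U = _node_spectra(demography, n, engine, N_ref)
    unit = U @ _gamma_masses(dfe.shape, dfe.mean_gamma)
    ll = 0.0
    for f in fragments:
        obs = f.counts[1:n]
        theta = _profile_theta(obs, unit)
        if theta > 0:
            ll += _poisson_ll(obs, theta * unit)
    return ll
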