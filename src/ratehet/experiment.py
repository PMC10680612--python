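"""Factorial bias experiment: rate regimes x demographies x DFEs.

Orchestrates the full pipeline — forward simulation, SFS pooling,
two-flavor demographic inference on exon-masked spectra, and gamma-DFE
inference on synonymous/selected spectra — and summarises truth-scaled
estimates (1 = unbiased) per scenario.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .architecture import GenicStructure, build_layout, exon_mask, \
    make_rate_map
from .demography import TwoEpochModel, fit_equilibrium, fit_two_epoch
from .dfe import fit_gamma_dfe
from .sfs import sfs_from_replicates
from .simulate import DemographyPlan, DiscreteDFE, simulate_replicate

__all__ = ["Scenario", "Profile", "DESK", "PAPER", "DFE_PRESETS",
           "RATE_REGIMES", "DEMOGRAPHY_PRESETS", "scenario_grid",
           "run_scenario", "summarize_bias"]

#: fixed chromosome-average rates (mutation /site/gen; recombination
#: cM/Mb) and the uniform-draw limits for the variable regimes
MU_FIXED = 2.8e-9
MU_LIMITS = (1e-9, 6.1e-9)
REC_FIXED_CM_MB = 2.32
REC_LIMITS_CM_MB = (0.0127, 7.40)
N_ANCESTRAL_UNSCALED = 1.4e6

#: representative four-class weights (f0, f1, f2, f3) for the six
#: discrete DFEs: excess weakly / moderately / strongly deleterious,
#: uniform, and two bimodal shapes. Configurable; not canonical.
DFE_PRESETS = {
    "DFE1": (0.1, 0.7, 0.1, 0.1),
    "DFE2": (0.1, 0.1, 0.7, 0.1),
    "DFE3": (0.1, 0.1, 0.1, 0.7),
    "DFE4": (0.25, 0.25, 0.25, 0.25),
    "DFE5": (0.5, 0.0, 0.0, 0.5),
    "DFE6": (0.3, 0.0, 0.0, 0.7),
}

#: (mutation variable?, recombination variable?)
RATE_REGIMES = {
    "fixed_theta_fixed_rho": (False, False),
    "fixed_theta_var_rho": (False, True),
    "var_theta_fixed_rho": (True, False),
    "var_theta_var_rho": (True, True),
}

#: relative size after the instantaneous change (None = no change)
DEMOGRAPHY_PRESETS = {
    "equilibrium": None,
    "expansion100": 2.0,
    "contraction50": 0.5,
    "contraction99": 0.01,
}


@dataclass(frozen=True)
class Profile:
    """Problem-size profile: chromosome extent and rescaling factor."""

    name: str
    n_genes: int
    Q: float
    n_reps: int
    pool_size: int
    sample_n: int = 100

    @property
    def N_rescaled(self) -> int:
        return int(round(N_ANCESTRAL_UNSCALED / self.Q))


#: desk-scale profile used by the test-suite-sized experiments
DESK = Profile("desk", n_genes=7, Q=5600.0, n_reps=20, pool_size=5)
#: full-scale profile matching the original study conditions
PAPER = Profile("paper", n_genes=127, Q=200.0, n_reps=100, pool_size=10)


@dataclass(frozen=True)
class Scenario:
    regime: str
    demography: str
    dfe: str | None  # None = strictly neutral
    n_reps: int
    pool_size: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_reps % self.pool_size:
            raise ValueError("n_reps must be divisible by pool_size")
        if self.regime not in RATE_REGIMES:
            raise ValueError(f"unknown rate regime {self.regime}")
        if self.demography not in DEMOGRAPHY_PRESETS:
            raise ValueError(f"unknown demography {self.demography}")
        if self.dfe is not None and self.dfe not in DFE_PRESETS:
            raise ValueError(f"unknown DFE {self.dfe}")


def _scenario_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence(
        [int(master_seed), int(index)]).generate_state(1)[0] % 2**31)


def scenario_grid(config: dict | None = None,
                  master_seed: int = 0) -> list[Scenario]:
    """Cartesian product of the configured axes with deterministic
    per-scenario seeds derived from the master seed."""
    config = config or {}
    regimes = config.get("regimes", list(RATE_REGIMES))
    demographies = config.get("demographies", list(DEMOGRAPHY_PRESETS))
    dfes = config.get("dfes", [None] + list(DFE_PRESETS))
    n_reps = config.get("n_reps", 100)
    pool_size = config.get("pool_size", 10)
    out = []
    for idx, (rg, dm, df) in enumerate(
            itertools.product(regimes, demographies, dfes)):
        out.append(Scenario(rg, dm, df, n_reps, pool_size,
                            _scenario_seed(master_seed, idx)))
    return out


def _demography_plan(name: str, sample_n: int) -> DemographyPlan:
    nu = DEMOGRAPHY_PRESETS[name]
    if nu is None:
        return DemographyPlan.equilibrium(N_ANCESTRAL_UNSCALED, sample_n)
    return DemographyPlan.size_change(N_ANCESTRAL_UNSCALED, nu,
                                      sample_n=sample_n)


def _truth(name: str, profile: Profile) -> dict:
    N0 = profile.N_rescaled
    nu = DEMOGRAPHY_PRESETS[name]
    if nu is None:
        return {"N_current": N0, "N_ancestral": N0, "nu": 1.0}
    Ncur = max(10, int(round(nu * N0)))
    tau = int(round(1.0 * Ncur))
    return {"N_current": Ncur, "N_ancestral": N0, "tau": tau,
            "nu": Ncur / N0, "tau_rel": tau / (2.0 * N0)}


def simulate_scenario_reps(scenario: Scenario, profile: Profile,
                           purge_interval: int = 25):
    """Run the scenario's forward replicates; variable-rate regimes draw
    a fresh per-1kb map for every replicate. Returns (layout, reps)."""
    structure = GenicStructure(n_genes=profile.n_genes)
    layout = build_layout(structure)
    L = layout.total_length
    mut_var, rec_var = RATE_REGIMES[scenario.regime]
    plan = _demography_plan(scenario.demography, profile.sample_n)
    dfe = None if scenario.dfe is None else DiscreteDFE(
        *DFE_PRESETS[scenario.dfe])
    ss = np.random.SeedSequence([scenario.seed, 0xA11])
    rep_seeds = [int(s % 2**31) for s in ss.generate_state(2 * scenario.n_reps)]
    reps = []
    for r in range(scenario.n_reps):
        map_rng = np.random.default_rng(rep_seeds[2 * r])
        mut_map = make_rate_map("mutation", L, MU_FIXED, mut_var,
                                *MU_LIMITS, rng=map_rng)
        rec_map = make_rate_map("recombination", L, REC_FIXED_CM_MB,
                                rec_var, *REC_LIMITS_CM_MB, rng=map_rng)
        reps.append(simulate_replicate(layout, mut_map, rec_map, dfe, plan,
                                       Q=profile.Q,
                                       seed=rep_seeds[2 * r + 1],
                                       purge_interval=purge_interval))
    return layout, reps


def run_scenario(scenario: Scenario, profile: Profile | str = "desk",
                 n_starts: int = 8, reps=None, layout=None,
                 stages: tuple = ("demography", "dfe")) -> pd.DataFrame:
    """Simulate, pool, infer, and report truth-scaled estimates.

    One row per (pooled SFS, likelihood flavor); stage failures are
    recorded in the ``error`` column rather than aborting the scenario.
    Pre-simulated ``reps`` (with their ``layout``) may be passed in;
    ``stages`` selects which inference stages to run.
    """
    if isinstance(profile, str):
        profile = DESK if profile == "desk" else PAPER
    if reps is None:
        layout, reps = simulate_scenario_reps(scenario, profile)
    mask = exon_mask(layout)
    truth = _truth(scenario.demography, profile)
    mu_sim = MU_FIXED * profile.Q
    is_eq = DEMOGRAPHY_PRESETS[scenario.demography] is None
    true_f = None if scenario.dfe is None else DFE_PRESETS[scenario.dfe]

    rows = []
    n_pools = scenario.n_reps // scenario.pool_size
    for p in range(n_pools):
        batch = reps[p * scenario.pool_size:(p + 1) * scenario.pool_size]
        neutral = sfs_from_replicates(batch, mask=mask)
        base = {"regime": scenario.regime,
                "demography": scenario.demography,
                "dfe": scenario.dfe or "neutral", "pool": p}
        fit_seed = _scenario_seed(scenario.seed, 7000 + p)

        if "demography" not in stages:
            if true_f is not None and "dfe" in stages:
                rows.append(_dfe_stage(base, batch, layout, true_f,
                                       n_starts, fit_seed))
            continue
        # coalescent-style absolute fit (equilibrium model when the
        # scenario is an equilibrium population, per the study design)
        row = dict(base, flavor="poisson_absolute")
        try:
            if is_eq:
                f = fit_equilibrium(neutral, mu_sim, neutral.span_bp)
                row.update(N_current=f.model.N_current,
                           loglik=f.loglik, pinned=f.boundary_pinned,
                           scaled_N_current=f.model.N_current
                           / truth["N_current"])
            else:
                f = fit_two_epoch(neutral, "poisson_absolute", mu=mu_sim,
                                  L=neutral.span_bp, n_starts=n_starts,
                                  seed=fit_seed)
                row.update(N_ancestral=f.model.N_ancestral,
                           N_current=f.model.N_current, tau=f.model.tau,
                           loglik=f.loglik, pinned=f.boundary_pinned,
                           scaled_N_ancestral=f.model.N_ancestral
                           / truth["N_ancestral"],
                           scaled_N_current=f.model.N_current
                           / truth["N_current"],
                           scaled_tau=f.model.tau / truth["tau"])
        except Exception as exc:  # recorded, not fatal
            row["error"] = repr(exc)
        rows.append(row)

        # diffusion-tool-style relative fit (two-epoch always)
        row = dict(base, flavor="multinomial_relative")
        fitted_rel = None
        try:
            f = fit_two_epoch(neutral, "multinomial_relative",
                              n_starts=n_starts, seed=fit_seed)
            fitted_rel = f.model
            row.update(nu=f.model.nu, tau_rel=f.model.tau_rel,
                       loglik=f.loglik, pinned=f.boundary_pinned,
                       scaled_nu=f.model.nu / truth["nu"])
            if "tau_rel" in truth:
                row["scaled_tau_rel"] = f.model.tau_rel / truth["tau_rel"]
        except Exception as exc:
            row["error"] = repr(exc)
        rows.append(row)

        if true_f is not None and "dfe" in stages:
            rows.append(_dfe_stage(base, batch, layout, true_f, n_starts,
                                   fit_seed))
    return pd.DataFrame(rows)


def _dfe_stage(base, batch, layout, true_f, n_starts, fit_seed):
    """Two-step gamma-DFE inference for one pooled batch.

    The synonymous spectrum is the neutral class (it shares the exons'
    rate and linked-selection environment); demography is re-fitted to
    it and the DFE is estimated conditional on that fit.
    """
    row = dict(base, flavor="gamma_dfe")
    try:
        syn = sfs_from_replicates(batch, class_filter=["exon_syn"],
                                  layout=layout)
        sel = sfs_from_replicates(batch, class_filter=["exon_sel"],
                                  layout=layout)
        dem_fit = fit_two_epoch(syn, "multinomial_relative",
                                n_starts=n_starts, seed=fit_seed)
        model, engine = dem_fit.model, "wfmatrix"
        if abs(np.log(model.nu)) < np.log(1.02):
            model, engine = None, "prf"
        g = fit_gamma_dfe(syn, sel, model, engine=engine,
                          n_starts=n_starts, seed=fit_seed)
        cp = g.proportions
        row.update(beta=g.dfe.shape, mean_gamma=g.dfe.mean_gamma,
                   loglik=g.loglik, pinned=g.boundary_pinned,
                   f0=cp.f0, f1=cp.f1, f2=cp.f2, f3=cp.f3,
                   delta_f0=cp.f0 - true_f[0],
                   true_f0=true_f[0], true_f1=true_f[1],
                   true_f2=true_f[2], true_f3=true_f[3])
    except Exception as exc:
        row["error"] = repr(exc)
    return row


def summarize_bias(results: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and quartiles of truth-scaled estimates (and DFE class
    proportions) per scenario x flavor x parameter."""
    value_cols = [c for c in results.columns
                  if c.startswith("scaled_")
                  or c in ("f0", "f1", "f2", "f3", "delta_f0")]
    keys = ["regime", "demography", "dfe", "flavor"]
    out = []
    for key, grp in results.groupby(keys, dropna=False):
        for col in value_cols:
            if col not in grp or grp[col].dropna().empty:
                continue
            v = grp[col].dropna()
            out.append(dict(zip(keys, key), parameter=col,
                            mean=v.mean(), sd=v.std(ddof=1),
                            q25=v.quantile(0.25), median=v.median(),
                            q75=v.quantile(0.75), n=len(v)))
    return pd.DataFrame(out)
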