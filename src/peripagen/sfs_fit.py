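"""Composite-likelihood fitting of demographic scenarios to the observed
joint site-frequency spectrum, with AIC comparison and parametric-bootstrap
confidence intervals.

The likelihood conditions on polymorphic entries (the monomorphic corners are
excluded — loci are ascertained as sequenced alignments, not SNP panels):

    log10 CL = Σ_e m_e · log10(p̂_e)

over polymorphic cells e with observed count m_e, where p̂ is the expected
spectrum normalized over polymorphic cells.  Expected spectra are Monte-Carlo
estimates (branch lengths per cell, see
:func:`peripagen.coalescent.expected_joint_sfs`), recomputed with common
random numbers within each optimization loop so the surface seen by the
optimizer is smooth; fresh draws between loops take the place of the
ECM-style loop structure of SFS fitting tools.  Optimization is Nelder–Mead
in log-parameter space with box constraints enforced by a sigmoid transform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import coalescent as ce

LN10 = math.log(10.0)

# scenario-family free parameters (fitting dimension kept minimal per family)
FAMILY_FREE = {
    "A": ["N1", "N2", "N2f", "t1", "t3"],
    "B": ["N1", "N2", "N2f", "N1b", "t0", "t1", "t3"],
    "C": ["N1", "N2", "N2f", "NA", "t1", "t2", "t3"],
    "D": ["N1", "N2", "N2f", "NA", "N1b", "t0", "t1", "t2", "t3"],
}
MIG_FREE = {"1": [], "2": ["m12", "m21"], "3": ["m12", "m21"],
            "4": ["m12", "m21"], "5": ["m12", "m21"]}


def free_parameters(code: str) -> list:
    return FAMILY_FREE[code[0]] + MIG_FREE[code[1]]


def composite_loglik(obs: np.ndarray, expected: np.ndarray,
                     floor_total: float = None) -> float:
    """Σ m_e log10(p̂_e) over polymorphic cells (corners excluded).

    ``expected`` may be counts or probabilities; it is renormalized over
    polymorphic cells.  Zero expected cells are floored at ``1/(10·Z)`` with
    Z = ``floor_total`` (simulated-SNP total) or, failing that, the observed
    SNP total, then renormalized.
    """
    obs = np.asarray(obs, float)
    expected = np.asarray(expected, float)
    if obs.shape != expected.shape:
        raise ValueError("observed and expected spectra differ in shape")
    mask = np.ones(obs.shape, bool)
    mask[0, 0] = mask[-1, -1] = False
    m = obs[mask]
    if m.sum() < 1:
        raise ValueError("observed spectrum has no polymorphic entries")
    p = expected[mask].copy()
    if p.sum() <= 0:
        raise ValueError("expected spectrum is all zero")
    p = p / p.sum()
    Z = floor_total if floor_total else m.sum()
    p[p <= 0] = 1.0 / (10.0 * Z)
    p = p / p.sum()
    return float((m * np.log10(p)).sum())


def aic(maxlog10L: float, k: int) -> float:
    """AIC = 2k − 2·ln(10)·max log10 CL."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * k - 2.0 * LN10 * maxlog10L


@dataclass
class FitSettings:
    n_sims: int = 2000
    n_loops: int = 10
    n_restarts: int = 5
    maxiter_per_loop: int = 40
    loci: list = None  # list of LocusConfig
    fixed: dict = field(default_factory=dict)  # pinned non-free parameters


@dataclass
class FitResult:
    scenario: str
    params: dict
    maxlog10L: float
    aic: float
    n_sims: int
    loops: int
    restarts: int
    ci: dict = None  # parameter -> (2.5%, 97.5%)

    @property
    def k(self) -> int:
        return len([p for p in self.params if p in free_parameters(self.scenario)])


def _transform(z, lo, hi):
    """R -> (lo, hi) on a log scale via sigmoid."""
    s = 1.0 / (1.0 + np.exp(-z))
    return lo * (hi / lo) ** s


def _inverse(p, lo, hi):
    s = np.log(p / lo) / np.log(hi / lo)
    s = np.clip(s, 1e-9, 1 - 1e-9)
    return np.log(s / (1.0 - s))


_DEFAULT_FIXED = {"N1": 3e5, "N2": 3e4, "N2f": 1e3, "NA": 3e5, "N1b": 3e4,
                  "t0": 2e4, "t1": 4e4, "t2": 6e4, "t3": 1.5e5,
                  "m12": 0.0, "m21": 0.0}


def _params_from_vector(code, names, values, fixed):
    full = dict(_DEFAULT_FIXED)
    full.update(fixed)
    full.update(dict(zip(names, values)))
    # keep time ordering feasible for the family
    if code[0] in "CD":
        full["t2"] = max(full["t2"], full["t1"] * (1 + 1e-9))
        full["t3"] = max(full["t3"], full["t2"] * (1 + 1e-9))
    full["t3"] = max(full["t3"], max(full["t0"], full["t1"]) * (1 + 1e-9))
    return ce.ScenarioParams(**full)


def fit_scenario(obs, code: str, bounds: dict, n1: int, n2: int, seed: int,
                 settings: FitSettings = None) -> FitResult:
    """Maximize the composite likelihood of ``obs`` under scenario ``code``.

    ``bounds``: free parameter -> (low, high); free parameters not bounded
    here fall back to the defaults in :data:`peripagen.abc.DEFAULT_PRIORS`.
    Deterministic given ``seed``.
    """
    from .abc import DEFAULT_PRIORS

    settings = settings or FitSettings()
    loci = settings.loci or [ce.LocusConfig(500)] * 8
    names = [p for p in free_parameters(code) if p not in settings.fixed]
    bnds = []
    for p in names:
        b = bounds.get(p) or DEFAULT_PRIORS.bounds.get(p)
        lo, hi = b[0], b[1]
        if lo <= 0:  # migration rates: optimize on a floored log scale
            lo = 1e-12
        bnds.append((lo, hi))
    lo = np.array([b[0] for b in bnds])
    hi = np.array([b[1] for b in bnds])
    point = np.isclose(lo, hi, rtol=1e-12).all() and len(names) > 0

    obs = np.asarray(obs, float)
    best = None

    def objective(z, crn_seed):
        vals = _transform(np.asarray(z), lo, hi)
        params = _params_from_vector(code, names, vals, settings.fixed)
        try:
            scen = ce.build_scenario(code, params)
            P = ce.expected_joint_sfs(scen, loci, n1, n2, settings.n_sims,
                                      seed=crn_seed)
            return -composite_loglik(obs, P)
        except (ValueError, OverflowError):
            return 1e12

    if point:
        vals = lo.copy()
        params = _params_from_vector(code, names, vals, settings.fixed)
        scen = ce.build_scenario(code, params)
        P = ce.expected_joint_sfs(scen, loci, n1, n2, settings.n_sims,
                                  seed=ce._substream(seed, 9, 0))
        cl = composite_loglik(obs, P)
        pdict = dict(zip(names, vals.tolist()))
        return FitResult(code, pdict, cl, aic(cl, len(names)),
                         settings.n_sims, settings.n_loops, settings.n_restarts)

    rng = np.random.default_rng(ce._substream(seed, 8))
    errors = []
    for restart in range(settings.n_restarts):
        z = _inverse(np.exp(rng.uniform(np.log(lo), np.log(hi))), lo, hi)
        fz = None
        for loop in range(settings.n_loops):
            crn = ce._substream(seed, 9, restart, loop)
            try:
                res = minimize(objective, z, args=(crn,), method="Nelder-Mead",
                               options={"maxiter": settings.maxiter_per_loop,
                                        "xatol": 1e-3, "fatol": 1e-3})
            except Exception as exc:  # optimizer blow-up on this restart
                errors.append(str(exc))
                break
            z, fz = res.x, res.fun
        if fz is None or fz >= 1e12:
            continue
        # score the final point once with a common evaluation seed
        final = objective(z, ce._substream(seed, 10))
        if best is None or final < best[0]:
            best = (final, z.copy())
    if best is None:
        raise RuntimeError(f"all restarts failed for {code}: {errors}")
    vals = _transform(best[1], lo, hi)
    cl = -best[0]
    pdict = dict(zip(names, vals.tolist()))
    return FitResult(code, pdict, cl, aic(cl, len(names)), settings.n_sims,
                     settings.n_loops, settings.n_restarts)


def compare_scenarios(obs, codes, bounds: dict, n1: int, n2: int, seed: int,
                      settings: FitSettings = None):
    """Fit each scenario and rank by AIC ascending; returns a DataFrame."""
    import pandas as pd

    if len(set(codes)) != len(codes):
        warnings.warn("duplicate scenario codes deduplicated")
        codes = list(dict.fromkeys(codes))
    fits = []
    for i, code in enumerate(codes):
        fits.append(fit_scenario(obs, code, bounds, n1, n2,
                                 seed=ce._substream(seed, 20, i),
                                 settings=settings))
    rows = [{"scenario": f.scenario, "maxlog10L": f.maxlog10L, "k": f.k,
             "AIC": f.aic, **{f"p_{k}": v for k, v in f.params.items()}}
            for f in fits]
    df = pd.DataFrame(rows).sort_values("AIC", ignore_index=True)
    df["dAIC"] = df["AIC"] - df["AIC"].min()
    return df, fits


def bootstrap_ci(code: str, mle: dict, bounds: dict, n1: int, n2: int,
                 n_boot: int, seed: int, settings: FitSettings = None,
                 obs_snp_total: int = 1000) -> dict:
    """Parametric bootstrap: simulate ``n_boot`` spectra at the MLE, refit
    each, and report 2.5/97.5 percentile intervals per free parameter."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    settings = settings or FitSettings()
    loci = settings.loci or [ce.LocusConfig(500)] * 8
    params = _params_from_vector(code, list(mle), list(mle.values()),
                                 settings.fixed)
    scen = ce.build_scenario(code, params)
    rng = np.random.default_rng(ce._substream(seed, 30))
    draws = {p: [] for p in mle}
    for b in range(n_boot):
        P = ce.expected_joint_sfs(scen, loci, n1, n2, settings.n_sims,
                                  seed=ce._substream(seed, 31, b))
        m = rng.multinomial(obs_snp_total, (P / P.sum()).ravel()).reshape(P.shape)
        fit = fit_scenario(m, code, bounds, n1, n2,
                           seed=ce._substream(seed, 32, b), settings=settings)
        for p in mle:
            if p in fit.params:
                draws[p].append(fit.params[p])
    return {p: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for p, v in draws.items() if v}
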