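"""DIYABC-style approximate Bayesian computation: rejection sampling on
summary statistics, direct and logistic-regression scenario posteriors,
local-linear parameter adjustment, and pseudo-observed-dataset (pod)
confidence evaluation.

The summary-statistic set is fixed and versioned (``STAT_SET_V1``): per
population {segregating sites, nucleotide diversity, haplotype count,
Tajima's D, private segregating sites} and between populations {ΦST, mean
between-population pairwise difference per site, shared segregating sites},
each summarized as the unweighted mean and variance across loci.  Statistics
are standardized by median/MAD before Euclidean distance (robust, with a
flag for mean/SD).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coalescent as ce

PER_LOCUS_STATS = ["S1", "S2", "pi1", "pi2", "Nh1", "Nh2", "D1", "D2",
                   "priv1", "priv2", "shared", "phist", "dxy"]
STAT_SET_V1 = [f"{s}_{agg}" for s in PER_LOCUS_STATS for agg in ("mean", "var")]

PARAM_NAMES = ["N1", "N2", "N2f", "NA", "N1b", "t0", "t1", "t2", "t3",
               "m12", "m21"]


# ---------------------------------------------------------------------------
# priors


@dataclass
class PriorSpec:
    """Uniform (or log-uniform) priors with cross-parameter order constraints.

    ``bounds``: name -> (low, high) or (low, high, "log").
    ``constraints``: list of (smaller_name, larger_name) pairs.
    """

    bounds: dict
    constraints: list = field(default_factory=list)

    def __post_init__(self):
        for name, b in self.bounds.items():
            if b[0] >= b[1]:
                raise ValueError(f"{name}: lower bound must be < upper")

    @property
    def names(self):
        return list(self.bounds)

    def support(self, name):
        b = self.bounds[name]
        return b[0], b[1]


def sample_priors(spec: PriorSpec, R: int, seed: int) -> pd.DataFrame:
    """R prior draws satisfying all order constraints, by rejection."""
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    names = spec.names
    rows = np.empty((0, len(names)))
    attempts = 0
    while rows.shape[0] < R:
        chunk = max(R, 1024)
        draw = np.empty((chunk, len(names)))
        for k, name in enumerate(names):
            b = spec.bounds[name]
            if len(b) > 2 and b[2] == "log":
                draw[:, k] = np.exp(rng.uniform(math.log(b[0]), math.log(b[1]),
                                                chunk))
            else:
                draw[:, k] = rng.uniform(b[0], b[1], chunk)
        ok = np.ones(chunk, bool)
        for lo_name, hi_name in spec.constraints:
            ok &= draw[:, names.index(lo_name)] < draw[:, names.index(hi_name)]
        rows = np.vstack([rows, draw[ok]])
        attempts += chunk
        if attempts > 1e4 and rows.shape[0] / attempts < 1e-4:
            raise RuntimeError("prior constraint acceptance rate < 1e-4")
    return pd.DataFrame(rows[:R], columns=names)


DEFAULT_PRIORS = PriorSpec(
    bounds={
        "N1": (1e5, 1e6),
        "N2": (1e4, 1e5),
        "N2f": (1e2, 1e4),
        "NA": (1e5, 1e6),
        "N1b": (1e4, 1e5),
        "t0": (1e3, 5e4),
        "t1": (1e4, 1.2e5),
        "t2": (2e4, 1.4e5),
        "t3": (5e4, 3e5),
        "m12": (0.0, 2e-6),
        "m21": (0.0, 2e-6),
    },
    constraints=[("t0", "t3"), ("t1", "t2"), ("t2", "t3"), ("t1", "t3"),
                 ("t0", "t1")],
)


# ---------------------------------------------------------------------------
# fast per-dataset summary statistics (binary matrices from the simulator)


def _tajima_from_counts(n: int, S: int, pi_L: float) -> float:
    if n < 2 or S == 0:
        return 0.0  # imputed neutral value for the ABC vector
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_L - S / a1) / math.sqrt(var) if var > 0 else 0.0


def binary_locus_stats(derived: np.ndarray, L: int, n1: int, n2: int) -> dict:
    """Per-locus summary vector from an (S, n) derived-allele matrix."""
    n = n1 + n2
    c1 = derived[:, :n1].sum(axis=1)
    c2 = derived[:, n1:].sum(axis=1)
    seg1 = (c1 > 0) & (c1 < n1)
    seg2 = (c2 > 0) & (c2 < n2)
    S1, S2 = int(seg1.sum()), int(seg2.sum())
    pi1_L = float((2.0 * c1 * (n1 - c1)).sum() / (n1 * (n1 - 1)))
    pi2_L = float((2.0 * c2 * (n2 - c2)).sum() / (n2 * (n2 - 1)))
    dxy_L = float((c1 * (n2 - c2) + c2 * (n1 - c1)).sum() / (n1 * n2))
    if derived.shape[0]:
        Nh1 = np.unique(derived[:, :n1].T, axis=0).shape[0]
        Nh2 = np.unique(derived[:, n1:].T, axis=0).shape[0]
    else:
        Nh1 = Nh2 = 1
    priv1 = int((seg1 & ~seg2).sum())
    priv2 = int((seg2 & ~seg1).sum())
    shared = int((seg1 & seg2).sum())
    # AMOVA PhiST from pairwise-difference sums
    ctot = c1 + c2
    ps_t = float((ctot * (n - ctot)).sum())
    ps_1 = float((c1 * (n1 - c1)).sum())
    ps_2 = float((c2 * (n2 - c2)).sum())
    ss_t = ps_t / n
    ss_w = ps_1 / n1 + ps_2 / n2
    ms_a = ss_t - ss_w
    ms_w = ss_w / (n - 2)
    nbar = n - (n1**2 + n2**2) / n
    sig_a = (ms_a - ms_w) / nbar
    phist = sig_a / (sig_a + ms_w) if (sig_a + ms_w) > 0 else 0.0
    return {
        "S1": S1, "S2": S2, "pi1": pi1_L / L, "pi2": pi2_L / L,
        "Nh1": Nh1, "Nh2": Nh2,
        "D1": _tajima_from_counts(n1, S1, pi1_L),
        "D2": _tajima_from_counts(n2, S2, pi2_L),
        "priv1": priv1, "priv2": priv2, "shared": shared,
        "phist": phist, "dxy": dxy_L / L,
    }


def dataset_stat_vector(dataset, n1: int, n2: int) -> np.ndarray:
    """STAT_SET_V1 vector (means and variances across loci) for a simulated
    dataset (list of (locus, derived, positions))."""
    per = {s: [] for s in PER_LOCUS_STATS}
    for locus, derived, _ in dataset:
        row = binary_locus_stats(derived, locus.length_bp, n1, n2)
        for s in PER_LOCUS_STATS:
            per[s].append(row[s])
    out = []
    for s in PER_LOCUS_STATS:
        v = np.asarray(per[s], float)
        out.append(v.mean())
        out.append(v.var(ddof=0))
    return np.array(out)


def observed_stat_vector(loci, popmap) -> np.ndarray:
    """STAT_SET_V1 vector from real alignments (two-population popmap).

    Sites are reduced to biallelic 0/1 patterns (complete cases); population 1
    is the first population in the popmap.
    """
    from .stats import _biallelic_partitions, _pop_masks

    per = {s: [] for s in PER_LOCUS_STATS}
    for aln in loci:
        pops, masks = _pop_masks(aln, popmap)
        order = np.concatenate([np.where(masks[0])[0], np.where(masks[1])[0]])
        n1 = int(masks[0].sum())
        n2 = int(masks[1].sum())
        pats = [pat[order] for _, pat in _biallelic_partitions(aln)]
        pats = [p for p in pats if (p >= 0).all()]
        derived = (np.array(pats, np.int64).astype(bool)
                   if pats else np.zeros((0, n1 + n2), bool))
        row = binary_locus_stats(derived, aln.length_bp, n1, n2)
        for s in PER_LOCUS_STATS:
            per[s].append(row[s])
    out = []
    for s in PER_LOCUS_STATS:
        v = np.asarray(per[s], float)
        out.extend([v.mean(), v.var(ddof=0)])
    return np.array(out)


# ---------------------------------------------------------------------------
# reference table


@dataclass
class ReferenceTable:
    df: pd.DataFrame  # columns: scenario, parameters, statistics
    stat_names: list
    param_names: list

    @property
    def scenarios(self):
        return sorted(self.df["scenario"].unique())

    def stats_matrix(self) -> np.ndarray:
        return self.df[self.stat_names].to_numpy(float)

    def standardization(self, robust: bool = True):
        X = self.stats_matrix()
        if robust:
            center = np.median(X, axis=0)
            scale = np.median(np.abs(X - center), axis=0)
        else:
            center = X.mean(axis=0)
            scale = X.std(axis=0)
        return center, scale


def build_reference_table(scenarios, spec: PriorSpec, R_per_scenario: int,
                          loci, n1: int, n2: int, seed: int,
                          stat_names=None) -> ReferenceTable:
    """Simulate R datasets per scenario from the prior and record statistics."""
    stat_names = list(stat_names or STAT_SET_V1)
    rows = []
    for si, code in enumerate(scenarios):
        params_df = sample_priors(spec, R_per_scenario, seed=seed * 7919 + si)
        for r in range(R_per_scenario):
            pr = params_df.iloc[r]
            params = ce.ScenarioParams(**{k: float(pr[k]) for k in spec.names
                                          if k in PARAM_NAMES})
            scen = ce.build_scenario(code, params)
            sub = ce._substream(seed, si, r)
            ds = ce.simulate_dataset(scen, loci, n1, n2, sub)
            vec = dataset_stat_vector(ds, n1, n2)
            row = {"scenario": code}
            row.update({k: float(pr[k]) for k in spec.names})
            row.update(dict(zip(stat_names, vec)))
            rows.append(row)
    df = pd.DataFrame(rows)
    return ReferenceTable(df, stat_names, list(spec.names))


# ---------------------------------------------------------------------------
# rejection and posteriors


def abc_reject(observed: np.ndarray, table: ReferenceTable,
               tolerance: float = 0.01, robust: bool = True) -> pd.DataFrame:
    """Retain the ⌈tolerance · rows⌉ simulations closest to ``observed``.

    Euclidean distance on median/MAD-standardized statistics; zero-MAD
    statistics are dropped from the distance with a warning; ties broken by
    row index (stable sort).  The returned frame carries a ``distance``
    column and the original row index.
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    center, scale = table.standardization(robust=robust)
    keep = scale > 0
    if not keep.all():
        dropped = [s for s, k in zip(table.stat_names, keep) if not k]
        warnings.warn(f"zero-spread statistics dropped from distance: {dropped}")
    X = table.stats_matrix()
    z = (X[:, keep] - center[keep]) / scale[keep]
    zo = (np.asarray(observed)[keep] - center[keep]) / scale[keep]
    d = np.sqrt(((z - zo) ** 2).sum(axis=1))
    n_keep = math.ceil(tolerance * len(d))
    idx = np.argsort(d, kind="stable")[:n_keep]
    out = table.df.iloc[idx].copy()
    out["distance"] = d[idx]
    return out


def posterior_direct(retained: pd.DataFrame, scenarios=None) -> dict:
    """Scenario frequencies among retained simulations."""
    if retained.empty:
        raise ValueError("retained set is empty")
    counts = retained["scenario"].value_counts()
    scenarios = scenarios or sorted(set(retained["scenario"]))
    total = counts.sum()
    return {s: float(counts.get(s, 0)) / total for s in scenarios}


def _fit_multinomial_ridge(X, y_idx, K, lam, max_iter=200, tol=1e-10):
    """Newton-IRLS ridge multinomial logistic; class K-1 is the reference.

    Returns (B, H) with B of shape (p, K-1) and H the Hessian at optimum.
    """
    m, p = X.shape
    B = np.zeros((p, K - 1))
    Y = np.zeros((m, K - 1))
    for c in range(K - 1):
        Y[:, c] = y_idx == c
    dim = p * (K - 1)
    H = None
    for _ in range(max_iter):
        eta = X @ B
        mx = np.maximum(eta.max(axis=1, keepdims=True), 0)
        ex = np.exp(eta - mx)
        denom = ex.sum(axis=1, keepdims=True) + np.exp(-mx)
        P = ex / denom
        G = X.T @ (P - Y) + lam * B
        H = np.zeros((dim, dim))
        for a in range(K - 1):
            for b in range(K - 1):
                w = P[:, a] * ((a == b) - P[:, b])
                blk = X.T @ (X * w[:, None])
                H[a * p:(a + 1) * p, b * p:(b + 1) * p] = blk
        H += lam * np.eye(dim)
        step = np.linalg.solve(H, G.flatten(order="F")).reshape((p, K - 1),
                                                                order="F")
        B = B - step
        if np.abs(step).max() < tol:
            break
    return B, H


def posterior_logistic(retained: pd.DataFrame, observed: np.ndarray,
                       stat_names, lam: float = 1e-6,
                       table: ReferenceTable = None):
    """Multinomial logistic regression of scenario on (stats − observed),
    evaluated at the observed point; ridge-regularized.

    Returns (probabilities dict, 95% CI dict).  On numerical failure
    (complete separation) the ridge is escalated with a warning.
    """
    scen = sorted(set(retained["scenario"]))
    K = len(scen)
    if K < 2:
        raise ValueError("logistic posterior needs >= 2 scenarios retained")
    X = retained[stat_names].to_numpy(float) - np.asarray(observed)
    if table is not None:
        _, scale = table.standardization()
        ok = scale > 0
        X = X[:, ok] / scale[ok]
    sd = X.std(axis=0)
    X = X[:, sd > 0]
    X = np.hstack([np.ones((X.shape[0], 1)), X])
    y = np.array([scen.index(s) for s in retained["scenario"]])
    p = X.shape[1]
    for ridge in (lam, lam * 1e4, 1.0):
        B, H = _fit_multinomial_ridge(X, y, K, ridge)
        if np.isfinite(B).all():
            if ridge > lam:
                warnings.warn("separation: logistic fit used escalated ridge")
            break
    # probabilities at x = 0: softmax of the intercepts
    b0 = np.concatenate([B[0], [0.0]])
    ex = np.exp(b0 - b0.max())
    probs = ex / ex.sum()
    # delta-method CI from the intercept covariance block
    cov = np.linalg.inv(H)
    idx = [c * p for c in range(K - 1)]
    V0 = cov[np.ix_(idx, idx)]
    J = np.zeros((K, K - 1))
    for i in range(K):
        for j in range(K - 1):
            J[i, j] = probs[i] * ((i == j) - probs[j])
    var = np.clip(np.diag(J @ V0 @ J.T), 0, None)
    half = 1.96 * np.sqrt(var)
    ci = {s: (max(0.0, probs[i] - half[i]), min(1.0, probs[i] + half[i]))
          for i, s in enumerate(scen)}
    return {s: float(probs[i]) for i, s in enumerate(scen)}, ci


def adjust_params_loclinear(retained: pd.DataFrame, observed: np.ndarray,
                            stat_names, param_names, spec: PriorSpec = None,
                            kernel: str = "epanechnikov"):
    """Beaumont-style local-linear regression adjustment of parameters.

    Weighted regression of each parameter on the (stats − observed) design,
    Epanechnikov weights on relative distance (or uniform with
    ``kernel='uniform'``); adjusted draws are clipped to the prior support.
    Returns (samples DataFrame, percentile DataFrame with 2.5/50/97.5).
    """
    if len(retained) < 50:
        raise ValueError("need >= 50 retained rows for local-linear adjustment")
    X = retained[stat_names].to_numpy(float) - np.asarray(observed)
    sd = X.std(axis=0)
    X = X[:, sd > 0] / sd[sd > 0]
    d = retained["distance"].to_numpy(float) if "distance" in retained else \
        np.sqrt((X**2).sum(axis=1))
    dmax = d.max() if d.max() > 0 else 1.0
    if kernel == "uniform":
        w = np.ones_like(d)
    else:
        w = np.clip(1.0 - (d / dmax) ** 2, 0, None)
        if w.sum() <= 0:
            w = np.ones_like(d)
    Xd = np.hstack([np.ones((X.shape[0], 1)), X])
    W = w[:, None]
    theta = retained[param_names].to_numpy(float)
    XtWX = Xd.T @ (Xd * W)
    XtWY = Xd.T @ (theta * W)
    try:
        beta = np.linalg.solve(XtWX + 1e-10 * np.eye(Xd.shape[1]), XtWY)
    except np.linalg.LinAlgError:
        warnings.warn("singular local-linear design; returning raw draws")
        beta = np.zeros((Xd.shape[1], theta.shape[1]))
        beta[0] = 0.0
    adjusted = theta - X @ beta[1:]
    if spec is not None:
        for j, name in enumerate(param_names):
            lo, hi = spec.support(name)
            adjusted[:, j] = np.clip(adjusted[:, j], lo, hi)
    samples = pd.DataFrame(adjusted, columns=param_names)
    samples["weight"] = w
    qs = samples[param_names].quantile([0.025, 0.5, 0.975])
    return samples, qs


@dataclass
class ABCResult:
    direct: dict
    logistic: dict
    logistic_ci: dict
    best: str
    retained_index: np.ndarray
    posterior_percentiles: pd.DataFrame = None


def run_abc(observed: np.ndarray, table: ReferenceTable,
            tolerance: float = 0.01, spec: PriorSpec = None,
            adjust: bool = True) -> ABCResult:
    """Rejection + both posteriors + parameter adjustment for the winner."""
    retained = abc_reject(observed, table, tolerance)
    direct = posterior_direct(retained, table.scenarios)
    try:
        logi, ci = posterior_logistic(retained, observed, table.stat_names,
                                      table=table)
    except ValueError:
        logi = dict(direct)
        ci = {s: (p, p) for s, p in logi.items()}
    best = max(direct, key=direct.get)
    pct = None
    if adjust:
        sub = retained[retained["scenario"] == best]
        if len(sub) >= 50:
            _, pct = adjust_params_loclinear(sub, observed, table.stat_names,
                                             table.param_names, spec)
    return ABCResult(direct, logi, ci, best, retained.index.to_numpy(), pct)


def evaluate_confidence(table: ReferenceTable, n_pods: int, seed: int,
                        tolerance: float = 0.01) -> pd.DataFrame:
    """Pod-based confusion matrix (rows: true scenario, columns: assigned).

    Each pod row is held out of the table before classification.  The frame
    carries per-scenario ``type1`` (true scenario not selected) and ``type2``
    (selected when another scenario is true) columns.
    """
    if n_pods < 1:
        raise ValueError("n_pods must be >= 1")
    rng = np.random.default_rng(seed)
    scen = table.scenarios
    conf = pd.DataFrame(0.0, index=scen, columns=scen)
    for s in scen:
        rows = table.df.index[table.df["scenario"] == s].to_numpy()
        picks = rng.choice(rows, size=min(n_pods, len(rows)), replace=False)
        for r in picks:
            obs = table.df.loc[r, table.stat_names].to_numpy(float)
            sub = ReferenceTable(table.df.drop(index=r), table.stat_names,
                                 table.param_names)
            retained = abc_reject(obs, sub, tolerance)
            direct = posterior_direct(retained, scen)
            conf.loc[s, max(direct, key=direct.get)] += 1
        conf.loc[s] /= conf.loc[s].sum()
    conf["type1"] = 1.0 - np.diag(conf[scen])
    type2 = []
    for s in scen:
        others = [t for t in scen if t != s]
        type2.append(float(conf.loc[others, s].mean()))
    conf["type2"] = type2
    return conf
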