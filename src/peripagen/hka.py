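"""Multilocus Hudson–Kreitman–Aguadé neutrality test.

One-taxon configuration: polymorphism (S_i, from n_i sequences) within a
single ingroup taxon is contrasted with mean divergence D_i to an outgroup
across L >= 2 loci.  Under neutrality all loci share one divergence time T
(in units of 2N generations) while locus mutation rates are free, giving the
moment equations

    S_i + D_i = θ_i (a(n_i) + T + 1)      for each locus i,
    Σ_i D_i   = (T + 1) Σ_i θ_i,

with a(n) = Σ_{j<n} 1/j.  θ_i here is the *per-locus* population mutation
parameter (4 N μ_i L_i).  Given T the first set is linear in θ_i, so fitting
reduces to one-dimensional root finding in T.  The goodness-of-fit statistic
sums squared Pearson residuals of S and D over loci with the Hudson et al.
(1987) variances,

    Var S_i = θ_i a(n_i) + θ_i² b(n_i),      b(n) = Σ_{j<n} 1/j²,
    Var D_i = θ_i (T + 1) + θ_i²,

and is referred to a χ² distribution with L − 1 degrees of freedom
(2L observations minus L + 1 fitted parameters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import chi2

from .stats import _harmonic


@dataclass
class HKAInput:
    """Per-locus observations: ids, S, D, n (ingroup haplotypes), L (sites)."""

    locus_ids: list
    S: np.ndarray
    D: np.ndarray
    n: np.ndarray
    L: np.ndarray

    def __post_init__(self):
        self.S = np.asarray(self.S, float)
        self.D = np.asarray(self.D, float)
        self.n = np.asarray(self.n, int)
        self.L = np.asarray(self.L, float)
        if len(self.S) < 2:
            raise ValueError("HKA needs >= 2 loci")
        if (self.S < 0).any() or (self.D < 0).any():
            raise ValueError("S and D must be >= 0")
        if (self.n < 2).any():
            raise ValueError("each locus needs >= 2 ingroup haplotypes")


@dataclass
class HKAResult:
    theta_hat: np.ndarray
    T_hat: float
    chi2: float
    df: int
    p: float
    expected_S: np.ndarray
    expected_D: np.ndarray
    var_S: np.ndarray
    var_D: np.ndarray


def chi2_upper_tail(x: float, df: int) -> float:
    """Upper-tail (survival) probability of the χ² distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if x < 0:
        raise ValueError("statistic must be >= 0")
    return float(chi2.sf(x, df))


def _theta_given_T(inp: HKAInput, T: float) -> np.ndarray:
    a = np.array([_harmonic(int(ni)) for ni in inp.n])
    return (inp.S + inp.D) / (a + T + 1.0)


def _moment_gap(inp: HKAInput, T: float) -> float:
    return float(inp.D.sum() - (T + 1.0) * _theta_given_T(inp, T).sum())


def hka_fit(inp: HKAInput, tol: float = 1e-10) -> HKAResult:
    """Fit the HKA moment equations and return the χ² test.

    Root-finds T on a bracket grown geometrically; if no sign change exists
    (degenerate data) falls back to Nelder–Mead on the squared moment gap.
    """
    df = len(inp.S) - 1
    if df <= 0:
        raise ValueError("df <= 0: need >= 2 loci")
    lo, hi = 1e-9, 10.0
    glo = _moment_gap(inp, lo)
    T_hat = None
    for _ in range(60):
        if glo * _moment_gap(inp, hi) <= 0:
            T_hat = brentq(lambda T: _moment_gap(inp, T), lo, hi, xtol=tol)
            break
        hi *= 2.0
    if T_hat is None:
        res = minimize(lambda v: _moment_gap(inp, abs(v[0])) ** 2, [1.0],
                       method="Nelder-Mead", options={"xatol": tol})
        if not res.success or res.fun > 1e-6:
            raise RuntimeError(
                f"HKA moment equations did not converge; residual {res.fun:g}")
        T_hat = abs(res.x[0])
    theta = _theta_given_T(inp, T_hat)
    a = np.array([_harmonic(int(ni)) for ni in inp.n])
    b = np.array([_harmonic(int(ni), 2) for ni in inp.n])
    eS = theta * a
    eD = theta * (T_hat + 1.0)
    vS = theta * a + theta**2 * b
    vD = theta * (T_hat + 1.0) + theta**2
    x2 = float((((inp.S - eS) ** 2) / vS + ((inp.D - eD) ** 2) / vD).sum())
    return HKAResult(theta_hat=theta, T_hat=float(T_hat), chi2=x2, df=df,
                     p=chi2_upper_tail(x2, df), expected_S=eS, expected_D=eD,
                     var_S=vS, var_D=vD)


def hka_input_from_alignments(loci, outgroup_required: bool = True,
                              net_divergence: bool = False) -> HKAInput:
    """Build HKA input from gap-masked alignments carrying outgroups.

    D_i is the mean pairwise ingroup–outgroup difference count; with
    ``net_divergence`` the within-ingroup mean pairwise difference is
    subtracted (net-of-within correction, off by default).
    """
    from .stats import _encode, mean_pairwise_differences, segregating_sites

    ids, S, D, n, L = [], [], [], [], []
    for aln in loci:
        if not aln.outgroup:
            if outgroup_required:
                raise ValueError(f"{aln.locus_id}: outgroup required for HKA")
            continue
        codes = _encode(aln.matrix())
        og = _encode(aln.outgroup_matrix())
        tot = cnt = 0
        for o in range(og.shape[0]):
            for i in range(codes.shape[0]):
                ok = (codes[i] >= 0) & (og[o] >= 0)
                tot += int(((codes[i] != og[o]) & ok).sum())
                cnt += 1
        d = tot / cnt
        if net_divergence:
            d -= mean_pairwise_differences(aln)
        ids.append(aln.locus_id)
        S.append(segregating_sites(aln))
        D.append(max(d, 0.0))
        n.append(aln.n)
        L.append(aln.length_bp)
    return HKAInput(ids, np.array(S, float), np.array(D, float),
                    np.array(n), np.array(L, float))
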