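"""Per-locus diversity and neutrality statistics, SFS construction, and
AMOVA-based ΦST with permutation significance.

All statistics operate on gap-masked alignments (see
:func:`peripagen.alignments.mask_indel_columns`).  'N' is treated as missing:
pairwise comparisons skip sites where either sequence is N, while the site
still counts in L.  Statistics that are undefined on a given input (e.g.
Tajima's D with S = 0) return ``None`` — never a silent 0.

Neutrality tests implemented:

- Tajima's D (1989), with the standard e1/e2 variance constants;
- Fu & Li's D* and F* (1993, starred versions needing no outgroup), with the
  Simonsen et al. (1995) corrected variance constants as used by DnaSP;
- Fu's F_S (1997) via the exact Ewens sampling distribution (unsigned
  Stirling numbers of the first kind, evaluated in log space);
- Fay & Wu's H (2000), unnormalized, with outgroup polarization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from .alignments import LocusAlignment, PopulationMap

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1, "-": -2}


def _encode(mat: np.ndarray) -> np.ndarray:
    out = np.empty(mat.shape, np.int8)
    for ch, v in _CODE.items():
        out[mat == ch] = v
    return out


def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


# ---------------------------------------------------------------------------
# basic per-locus statistics


def site_allele_counts(aln: LocusAlignment):
    """Per-site allele counts of the ingroup: (L, 4) array, N/- ignored."""
    codes = _encode(aln.matrix())
    L = codes.shape[1]
    counts = np.zeros((L, 4), np.int64)
    for a in range(4):
        counts[:, a] = (codes == a).sum(axis=0)
    return codes, counts


def segregating_sites(aln: LocusAlignment) -> int:
    _, counts = site_allele_counts(aln)
    return int(((counts > 0).sum(axis=1) >= 2).sum())


def total_mutations(aln: LocusAlignment) -> int:
    """η: minimum mutation count, Σ(alleles−1) over sites."""
    _, counts = site_allele_counts(aln)
    k = (counts > 0).sum(axis=1)
    return int(np.maximum(k - 1, 0).sum())


def singleton_mutations(aln: LocusAlignment) -> int:
    """η_s: alleles observed in exactly one sequence (at segregating sites)."""
    _, counts = site_allele_counts(aln)
    seg = (counts > 0).sum(axis=1) >= 2
    return int((counts[seg] == 1).sum())


def haplotype_summary(aln: LocusAlignment):
    """(N_h, H_d) with the n/(n−1) sample correction for H_d."""
    n = aln.n
    seqs = [s for _, _, s in aln.sequences]
    uniq, cnt = np.unique(seqs, return_counts=True)
    N_h = len(uniq)
    if n < 2:
        return N_h, None
    p = cnt / n
    H_d = n * (1.0 - float((p**2).sum())) / (n - 1)
    return N_h, H_d


def pairwise_diff_matrix(aln: LocusAlignment) -> np.ndarray:
    """(n, n) matrix of pairwise nucleotide differences (N-aware)."""
    codes = _encode(aln.matrix())
    n = codes.shape[0]
    D = np.zeros((n, n))
    var = np.where((np.ptp(np.where(codes >= 0, codes, 99), axis=0) > 0))[0]
    for s in var:
        c = codes[:, s]
        ok = c >= 0
        diff = (c[:, None] != c[None, :]) & ok[:, None] & ok[None, :]
        D += diff
    return D


def mean_pairwise_differences(aln: LocusAlignment) -> float:
    """π_L: mean number of pairwise differences per locus."""
    n = aln.n
    if n < 2:
        return None
    D = pairwise_diff_matrix(aln)
    return float(D.sum() / (n * (n - 1)))


def nucleotide_diversity(aln: LocusAlignment) -> float:
    """π per site."""
    pi_L = mean_pairwise_differences(aln)
    return None if pi_L is None else pi_L / aln.length_bp


def watterson_theta(aln: LocusAlignment) -> float:
    """θ_w per site: S / (a1 · L)."""
    if aln.n < 2:
        return None
    return segregating_sites(aln) / (_harmonic(aln.n) * aln.length_bp)


# ---------------------------------------------------------------------------
# minimum number of recombination events (Hudson & Kaplan 1985)


def _biallelic_partitions(aln: LocusAlignment):
    """0/1 site patterns at biallelic segregating sites (None where missing)."""
    codes, counts = site_allele_counts(aln)
    sites = []
    for s in range(codes.shape[1]):
        alleles = np.where(counts[s] > 0)[0]
        if len(alleles) != 2:
            continue
        col = codes[:, s]
        pat = np.where(col == alleles[1], 1, np.where(col == alleles[0], 0, -1))
        sites.append((s, pat))
    return sites


def four_gamete_incompatible(pat_a, pat_b) -> bool:
    ok = (pat_a >= 0) & (pat_b >= 0)
    gam = {(int(x), int(y)) for x, y in zip(pat_a[ok], pat_b[ok])}
    return len(gam) == 4


def min_recombination(aln: LocusAlignment) -> int:
    """Hudson–Kaplan R_m: greedy disjoint-interval count over four-gamete
    violations (optimal for interval scheduling)."""
    sites = _biallelic_partitions(aln)
    intervals = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            if four_gamete_incompatible(sites[i][1], sites[j][1]):
                intervals.append((sites[i][0], sites[j][0]))
    intervals.sort(key=lambda iv: iv[1])
    rm, last_end = 0, -1
    for a, b in intervals:
        if a >= last_end:
            rm += 1
            last_end = b
    return rm


# ---------------------------------------------------------------------------
# neutrality tests


def tajima_d(aln: LocusAlignment):
    n = aln.n
    S = segregating_sites(aln)
    if n < 2 or S == 0:
        return None
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi_L = mean_pairwise_differences(aln)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return (pi_L - S / a1) / math.sqrt(var)


def fu_li_star(aln: LocusAlignment):
    """Fu & Li's (D*, F*) with Simonsen et al. (1995) variance constants."""
    n = aln.n
    eta = total_mutations(aln)
    if n < 3 or eta == 0:
        return None, None
    eta_s = singleton_mutations(aln)
    an = _harmonic(n)
    bn = _harmonic(n, 2)
    an1 = an + 1.0 / n  # a_{n+1}
    cn = 2.0 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (cn + (n - 2.0) / (n - 1) ** 2
          + (2.0 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n))
    vD = ((n / (n - 1.0)) ** 2 * bn + an**2 * dn
          - 2 * (n * an * (an + 1)) / (n - 1.0) ** 2) / (an**2 + bn)
    uD = (n / (n - 1.0)) * (an - n / (n - 1.0)) - vD
    num_D = (n / (n - 1.0)) * eta - an * eta_s
    var_D = uD * eta + vD * eta**2
    Dstar = num_D / math.sqrt(var_D) if var_D > 0 else None

    pi_L = mean_pairwise_differences(aln)
    vF = (dn + 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
          - (2.0 / (n - 1)) * (4 * bn - 6 + 8.0 / n)) / (an**2 + bn)
    uF = ((n / (n - 1.0) + (n + 1) / (3.0 * (n - 1)) - 4.0 / (n * (n - 1))
           + 2 * (n + 1) / (n - 1.0) ** 2 * (an1 - 2.0 * n / (n + 1))) / an
          - vF)
    num_F = pi_L - ((n - 1.0) / n) * eta_s
    var_F = uF * eta + vF * eta**2
    Fstar = num_F / math.sqrt(var_F) if var_F > 0 else None
    return Dstar, Fstar


@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> tuple:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        # |s(m,k)| = (m-1)|s(m-1,k)| + |s(m-1,k-1)|
        shifted = np.concatenate([[-np.inf], row[:-1]])
        grown = row + (math.log(m - 1) if m > 1 else -np.inf)
        row = np.logaddexp(grown, shifted)
    return tuple(row)


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k | n, θ) for k = 1..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    ls = np.array(_log_stirling_row(n))[1:]
    k = np.arange(1, n + 1)
    logp = ls + k * math.log(theta) - sum(math.log(theta + i) for i in range(n))
    logp -= logsumexp(logp)
    return np.exp(logp)


def fu_fs(aln: LocusAlignment):
    """Fu's F_S = ln(S'/(1−S')), S' = P(K ≥ k_obs | θ̂ = π_L)."""
    n = aln.n
    if n < 2:
        return None
    theta = mean_pairwise_differences(aln)
    k_obs, _ = haplotype_summary(aln)
    if theta is None or theta <= 0 or k_obs <= 1:
        return None
    pk = ewens_k_distribution(n, theta)
    s_prime = float(pk[k_obs - 1:].sum())
    if s_prime <= 0 or s_prime >= 1:
        return None
    return math.log(s_prime / (1.0 - s_prime))


# ---------------------------------------------------------------------------
# outgroup polarization, SFS, Fay & Wu's H


def _polarized_counts(aln: LocusAlignment, popmap: PopulationMap = None):
    """Derived-allele counts per polarizable site.

    Polarization rule: all outgroup sequences agree, the outgroup allele is one
    of exactly two ingroup alleles; tri-allelic ingroup sites and third-allele
    outgroups are skipped (the skipped count is reported).
    Returns (list of (i_total, per-pop counts), n per pop, n_skipped).
    """
    if not aln.outgroup:
        raise ValueError(f"{aln.locus_id}: outgroup required for polarization")
    codes, counts = site_allele_counts(aln)
    og = _encode(aln.outgroup_matrix())
    if popmap is not None:
        pops = popmap.populations
        masks = [np.array([popmap[sid] == p for sid in aln.sample_ids])
                 for p in pops]
    else:
        masks = []
    out, skipped = [], 0
    seg = np.where((counts > 0).sum(axis=1) >= 2)[0]
    for s in seg:
        alleles = np.where(counts[s] > 0)[0]
        ogc = og[:, s]
        ogc = ogc[ogc >= 0]
        if len(alleles) != 2 or len(ogc) == 0 or len(set(ogc.tolist())) != 1:
            skipped += 1
            continue
        anc = int(ogc[0])
        if anc not in alleles:
            skipped += 1
            continue
        der = int(alleles[alleles != anc][0])
        col = codes[:, s]
        if (col < 0).any():  # missing ingroup call: skip to keep n constant
            skipped += 1
            continue
        i_tot = int((col == der).sum())
        per_pop = tuple(int((col[m] == der).sum()) for m in masks)
        out.append((i_tot, per_pop))
    return out, [int(m.sum()) for m in masks], skipped


@dataclass
class SiteFrequencySpectrum:
    n: int
    counts: np.ndarray  # ξ_i for i = 1..n−1 (index 0 unused)
    polarized: bool
    n_skipped: int = 0

    def pi_per_locus(self) -> float:
        i = np.arange(self.n + 1)
        return float((self.counts * 2.0 * i * (self.n - i)).sum()
                     / (self.n * (self.n - 1)))


def unfolded_sfs(aln: LocusAlignment) -> SiteFrequencySpectrum:
    polar, _, skipped = _polarized_counts(aln)
    n = aln.n
    xi = np.zeros(n + 1, np.int64)
    for i_tot, _ in polar:
        xi[i_tot] += 1
    return SiteFrequencySpectrum(n, xi, polarized=True, n_skipped=skipped)


def fay_wu_h(aln: LocusAlignment):
    """Unnormalized H = π_L − θ_H over polarizable sites."""
    n = aln.n
    if n < 2:
        return None
    sfs = unfolded_sfs(aln)
    if sfs.counts.sum() == 0:
        return None
    i = np.arange(n + 1)
    theta_H = float((2.0 * sfs.counts * i**2).sum() / (n * (n - 1)))
    return sfs.pi_per_locus() - theta_H


@dataclass
class JointSFS:
    matrix: np.ndarray  # (n1+1, n2+1)
    n1: int
    n2: int
    mode: str = "counts"  # counts | probabilities
    n_skipped: int = 0


def joint_sfs(aln: LocusAlignment, popmap: PopulationMap) -> JointSFS:
    pops = popmap.populations
    if len(pops) != 2:
        raise ValueError("joint SFS requires exactly two populations")
    polar, (n1, n2), skipped = _polarized_counts(aln, popmap)
    M = np.zeros((n1 + 1, n2 + 1), np.int64)
    for _, (i, j) in polar:
        M[i, j] += 1
    return JointSFS(M, n1, n2, n_skipped=skipped)


def write_jsfs_tsv(jsfs: JointSFS, path) -> None:
    """Write the joint SFS as a TSV matrix.

    Dialect: first line ``# jsfs mode=<counts|probabilities> n1=<n1> n2=<n2>``;
    a header row ``d1\\d2`` then derived-allele counts 0..n2; one row per
    deme-1 derived count 0..n1.  Cell [i][j] = sites with i derived copies in
    population 1 and j in population 2.
    """
    M = jsfs.matrix
    with open(path, "w") as fh:
        fh.write(f"# jsfs mode={jsfs.mode} n1={jsfs.n1} n2={jsfs.n2}\n")
        fh.write("d1\\d2\t" + "\t".join(str(j) for j in range(jsfs.n2 + 1)) + "\n")
        for i in range(jsfs.n1 + 1):
            fh.write(str(i) + "\t" + "\t".join(f"{M[i, j]:g}" for j in
                                               range(jsfs.n2 + 1)) + "\n")


def read_jsfs_tsv(path) -> JointSFS:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# jsfs"):
            raise ValueError(f"{path}: not a jsfs TSV")
        meta = dict(kv.split("=") for kv in header[7:].split())
        fh.readline()  # column header
        rows = [[float(x) for x in line.split("\t")[1:]] for line in fh]
    M = np.array(rows)
    if meta["mode"] == "counts":
        M = M.astype(np.int64)
    return JointSFS(M, int(meta["n1"]), int(meta["n2"]), mode=meta["mode"])


def pooled_joint_sfs(alns, popmap) -> JointSFS:
    total = None
    for aln in alns:
        j = joint_sfs(aln, popmap)
        if total is None:
            total = j
        else:
            if j.matrix.shape != total.matrix.shape:
                raise ValueError("loci have differing sample configurations")
            total.matrix = total.matrix + j.matrix
            total.n_skipped += j.n_skipped
    return total


# ---------------------------------------------------------------------------
# population structure


def _pop_masks(aln: LocusAlignment, popmap: PopulationMap):
    pops = popmap.populations
    ids = aln.sample_ids
    return pops, [np.array([popmap[s] == p for s in ids]) for p in pops]


def hudson_fst(aln: LocusAlignment, popmap: PopulationMap) -> float:
    """Hudson's 1 − Hw/Hb cross-check estimator."""
    pops, masks = _pop_masks(aln, popmap)
    if len(pops) != 2:
        raise ValueError("two populations required")
    D = pairwise_diff_matrix(aln)
    m1, m2 = masks
    n1, n2 = int(m1.sum()), int(m2.sum())
    hw = 0.5 * (D[np.ix_(m1, m1)].sum() / (n1 * (n1 - 1))
                + D[np.ix_(m2, m2)].sum() / (n2 * (n2 - 1)))
    hb = D[np.ix_(m1, m2)].sum() / (n1 * n2)
    if hb == 0:
        return None
    return 1.0 - hw / hb


def _amova_phist_from_D(D: np.ndarray, m1: np.ndarray):
    """ΦST variance components from a squared-distance matrix and a mask."""
    N = D.shape[0]
    m2 = ~m1
    n1, n2 = int(m1.sum()), int(m2.sum())
    ss_t = D.sum() / 2.0 / N
    ss_w = (D[np.ix_(m1, m1)].sum() / 2.0 / n1
            + D[np.ix_(m2, m2)].sum() / 2.0 / n2)
    ss_a = ss_t - ss_w
    ms_a = ss_a / 1.0
    ms_w = ss_w / (N - 2)
    nbar = (N - (n1**2 + n2**2) / N) / 1.0
    sig_a = (ms_a - ms_w) / nbar
    denom = sig_a + ms_w
    return sig_a / denom if denom > 0 else 0.0


def phi_st(alns, popmap: PopulationMap, n_perm: int = 0, seed: int = 0,
           permute_individuals: bool = False):
    """AMOVA ΦST from pairwise-difference distances, multi-locus pooled.

    ``alns`` may be a single alignment or a list sharing one sample set; the
    per-haplotype distance matrices are summed over loci.  Significance by
    permuting haplotypes (or whole individuals with ``permute_individuals``)
    across populations: p = (#perm ≥ observed + 1) / (n_perm + 1).
    """
    if isinstance(alns, LocusAlignment):
        alns = [alns]
    D = None
    for aln in alns:
        Di = pairwise_diff_matrix(aln)
        D = Di if D is None else D + Di
    pops, masks = _pop_masks(alns[0], popmap)
    if len(pops) != 2:
        raise ValueError("two populations required")
    n1, n2 = int(masks[0].sum()), int(masks[1].sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each population needs >= 2 sequences")
    obs = _amova_phist_from_D(D, masks[0])
    if n_perm <= 0:
        return obs, None
    rng = np.random.default_rng(seed)
    N = n1 + n2
    if permute_individuals:
        ids = alns[0].sample_ids
        uniq = list(dict.fromkeys(ids))
        idx_of = {u: [i for i, s in enumerate(ids) if s == u] for u in uniq}
        k1 = sum(1 for u in uniq if popmap[u] == pops[0])
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(uniq))
            mask = np.zeros(N, bool)
            for u in perm[:k1]:
                mask[idx_of[uniq[u]]] = True
            if _amova_phist_from_D(D, mask) >= obs:
                hits += 1
    else:
        hits = 0
        for _ in range(n_perm):
            mask = np.zeros(N, bool)
            mask[rng.permutation(N)[:n1]] = True
            if _amova_phist_from_D(D, mask) >= obs:
                hits += 1
    p = (hits + 1.0) / (n_perm + 1.0)
    return obs, p


def private_shared_sites(aln: LocusAlignment, popmap: PopulationMap):
    """(private_pop1, private_pop2, shared, fixed_diffs) segregating-site
    classification between the two populations."""
    pops, masks = _pop_masks(aln, popmap)
    codes, counts = site_allele_counts(aln)
    m1, m2 = masks
    priv1 = priv2 = shared = fixed = 0
    seg = np.where((counts > 0).sum(axis=1) >= 2)[0]
    for s in seg:
        c1 = codes[m1, s]
        c2 = codes[m2, s]
        p1 = len(set(c1[c1 >= 0].tolist())) > 1
        p2 = len(set(c2[c2 >= 0].tolist())) > 1
        if p1 and p2:
            shared += 1
        elif p1:
            priv1 += 1
        elif p2:
            priv2 += 1
        else:
            fixed += 1
    return priv1, priv2, shared, fixed


# ---------------------------------------------------------------------------
# summary container and tables


@dataclass
class SummaryStats:
    """Per-locus (or pooled) statistic vector; ``None`` marks undefined."""

    locus_id: str
    population: str
    n: int
    L: int
    S: int
    eta: int
    N_h: int
    H_d: float
    pi: float
    theta_w: float
    R_m: int
    tajima_D: float = None
    fuli_Dstar: float = None
    fuli_Fstar: float = None
    fu_FS: float = None
    faywu_H: float = None


def compute_summary(aln: LocusAlignment, population: str = "pooled",
                    with_fs: bool = True, with_h: bool = None) -> SummaryStats:
    N_h, H_d = haplotype_summary(aln)
    Dstar, Fstar = fu_li_star(aln)
    if with_h is None:
        with_h = bool(aln.outgroup)
    return SummaryStats(
        locus_id=aln.locus_id, population=population, n=aln.n,
        L=aln.length_bp,
        S=segregating_sites(aln), eta=total_mutations(aln),
        N_h=N_h, H_d=H_d,
        pi=nucleotide_diversity(aln), theta_w=watterson_theta(aln),
        R_m=min_recombination(aln), tajima_D=tajima_d(aln),
        fuli_Dstar=Dstar, fuli_Fstar=Fstar,
        fu_FS=fu_fs(aln) if with_fs else None,
        faywu_H=fay_wu_h(aln) if with_h else None,
    )


def summary_table(loci, popmap: PopulationMap, with_fs: bool = True):
    """DataFrame: one row per locus per population plus pooled, plus an
    unweighted multi-locus mean row per population (per-site statistics)."""
    import pandas as pd

    rows = []
    groups = [("pooled", None)] + [(p, p) for p in popmap.populations]
    for aln in loci:
        for label, pop in groups:
            sub = aln if pop is None else aln.subset(popmap.samples(pop))
            rows.append(vars(compute_summary(sub, label, with_fs=with_fs)))
    df = pd.DataFrame(rows)
    means = (df.groupby("population", sort=False)
             [["H_d", "pi", "theta_w", "tajima_D"]]
             .mean(numeric_only=True).reset_index())
    means.insert(0, "locus_id", "MEAN")
    return pd.concat([df, means], ignore_index=True)
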