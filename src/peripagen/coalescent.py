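"""Two-deme structured-coalescent engine with the study's scenario grammar.

Scenario codes combine a topology family with a migration regime:

- **A**: deme 2 (the peripheral variety) is founded from deme 1 at time ``t3``
  at founder size ``N2f`` and recovers to ``N2`` at ``t1`` (peripatric core).
- **B**: A plus a recent expansion of deme 1, ``N1b`` → ``N1`` at ``t0``.
- **C**: both demes split from an ancestor of size ``NA`` at ``t3``; deme 2
  passes through a bottleneck ``N2f`` during ``(t1, t2)`` (vicariant core).
- **D**: C plus the recent deme-1 expansion at ``t0``.
- Suffix ``1``–``5``: migration off / initial epoch ``[t1, t3]`` only /
  recent epoch ``[0, t0]`` only / both / ongoing ``[0, t3]``.

All times are in generations (backward from the present); sizes are diploid
effective sizes.  Conversion to years happens only at reporting time via
:mod:`peripagen.scaling`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

VALID_CODES = tuple(f"{f}{m}" for f in "ABCD" for m in range(1, 6))

_MODE = {}
for _c in VALID_CODES:
    if _c in ("A1", "A3", "B1", "B3"):
        _MODE[_c] = "peripatric"
    elif _c in ("C1", "C3", "D1", "D3"):
        _MODE[_c] = "vicariant"
    elif _c in ("A2", "A4", "B2", "B4"):
        _MODE[_c] = "parapatric"
    else:
        _MODE[_c] = "complex"


@dataclass
class ScenarioParams:
    """Demographic parameters shared by all scenario codes.

    N1, N2   current diploid Ne of demes 1 and 2
    N1b      pre-expansion size of deme 1 (B/D families)
    N2f      founder/bottleneck size of deme 2
    NA       ancestral size (population sizes after the merge at t3)
    t0       deme-1 expansion time, generations
    t1       deme-2 recovery time
    t2       deme-2 bottleneck onset (C/D families only)
    t3       divergence time
    m12      backward migration rate: lineage in deme 1 jumps to deme 2
    m21      backward migration rate: lineage in deme 2 jumps to deme 1
    """

    N1: float
    N2: float
    N2f: float
    NA: float
    t1: float
    t3: float
    N1b: float = 0.0
    t0: float = 0.0
    t2: float = 0.0
    m12: float = 0.0
    m21: float = 0.0

    def validate(self, code: str) -> None:
        fam, mig = code[0], code[1]
        for name in ("N1", "N2", "N2f", "NA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if fam in "BD" and self.N1b <= 0:
            raise ValueError("N1b must be > 0 for B/D scenarios")
        if not 0 < self.t1 < self.t3:
            raise ValueError("require 0 < t1 < t3")
        if fam in "BD" or mig in "34":
            if not 0 < self.t0 < self.t3:
                raise ValueError("require 0 < t0 < t3")
        if fam in "CD":
            if not self.t1 <= self.t2 < self.t3:
                raise ValueError("require t1 <= t2 < t3")
        if self.m12 < 0 or self.m21 < 0:
            raise ValueError("migration rates must be >= 0")


@dataclass
class DemographicScenario:
    """A compiled scenario: ordered backward-time events plus a mode tag."""

    code: str
    params: ScenarioParams
    events: list = field(default_factory=list)  # (time, description)
    mode: str = ""
    # epoch arrays consumed by the kernels
    t_bounds: np.ndarray = None
    size0: np.ndarray = None
    size1: np.ndarray = None
    mig01: np.ndarray = None
    mig10: np.ndarray = None
    merged: np.ndarray = None

    @property
    def migration_windows(self):
        """List of (start, stop) epochs with nonzero migration, backward time."""
        out = []
        for e in range(len(self.t_bounds) - 1):
            if self.mig01[e] > 0 or self.mig10[e] > 0:
                a, b = float(self.t_bounds[e]), float(self.t_bounds[e + 1])
                if out and out[-1][1] == a:
                    out[-1] = (out[-1][0], b)
                else:
                    out.append((a, b))
        return out


@dataclass
class LocusConfig:
    """Per-locus simulation settings."""

    length_bp: int
    mu: float = 5.58e-9  # per site per generation
    ploidy_factor: float = 1.0  # 1.0 diploid nuclear, 0.5 haploid cpDNA
    locus_id: str = ""

    def __post_init__(self):
        if self.length_bp < 1:
            raise ValueError("length_bp must be >= 1")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


def build_scenario(code: str, params: ScenarioParams) -> DemographicScenario:
    """Compile a scenario code + parameters into an event list and epochs."""
    code = code.upper()
    if code not in VALID_CODES:
        raise ValueError(f"unknown scenario code {code!r}; valid: A1..D5")
    params.validate(code)
    fam, mig = code[0], code[1]
    p = params

    # deme sizes as piecewise-constant (time, size) change points, backward
    sz0 = [(0.0, p.N1)]
    if fam in "BD":
        sz0.append((p.t0, p.N1b))
    sz0.append((p.t3, p.NA))

    if fam in "AB":
        sz1 = [(0.0, p.N2), (p.t1, p.N2f)]
    else:  # C/D: bottleneck window (t1, t2)
        sz1 = [(0.0, p.N2), (p.t1, p.N2f), (p.t2, p.N2)]

    if mig == "1":
        mwin = []
    elif mig == "2":
        mwin = [(p.t1, p.t3)]
    elif mig == "3":
        mwin = [(0.0, p.t0)]
    elif mig == "4":
        mwin = [(0.0, p.t0), (p.t1, p.t3)]
    else:
        mwin = [(0.0, p.t3)]

    bounds = {0.0, p.t1, p.t3}
    if fam in "BD" or mig in "345":
        bounds.add(p.t0)
    if fam in "CD":
        bounds.add(p.t2)
    for a, b in mwin:
        bounds.add(a)
        bounds.add(b)
    tb = sorted(bounds)
    t_bounds = np.array(tb + [np.inf])
    E = len(tb)

    def piecewise(changes, t):
        v = changes[0][1]
        for ct, cv in changes:
            if t >= ct:
                v = cv
        return v

    size0 = np.array([piecewise(sz0, t) for t in tb])
    size1 = np.array([piecewise(sz1, t) for t in tb])
    in_win = [any(a <= t < b for a, b in mwin) for t in tb]
    mig01 = np.array([p.m12 if w else 0.0 for w in in_win])
    mig10 = np.array([p.m21 if w else 0.0 for w in in_win])
    merged = np.array([1 if t >= p.t3 else 0 for t in tb], np.int64)
    mig01[merged == 1] = 0.0
    mig10[merged == 1] = 0.0

    events = [(p.t3, f"merge deme 2 into deme 1; ancestral size {p.NA:g}")]
    events.append((p.t1, f"deme 2 size change {p.N2:g} -> {p.N2f:g}"))
    if fam in "CD":
        events.append((p.t2, f"deme 2 bottleneck ends (size back to {p.N2:g})"))
    if fam in "BD":
        events.append((p.t0, f"deme 1 size change {p.N1:g} -> {p.N1b:g}"))
    for a, b in mwin:
        events.append((a, f"migration on over [{a:g}, {b:g}]"))
    events.sort(key=lambda x: x[0])

    return DemographicScenario(
        code=code, params=p, events=events, mode=_MODE[code],
        t_bounds=t_bounds, size0=size0, size1=size1,
        mig01=mig01, mig10=mig10, merged=merged,
    )


def single_deme_scenario(N: float) -> DemographicScenario:
    """Panmictic constant-size control (used for calibration tests)."""
    return DemographicScenario(
        code="PANMIXIA", params=None, events=[], mode="panmictic",
        t_bounds=np.array([0.0, np.inf]),
        size0=np.array([N]), size1=np.array([N]),
        mig01=np.zeros(1), mig10=np.zeros(1),
        merged=np.ones(1, np.int64),
    )


def _substream(seed: int, *key) -> int:
    """Counter-based 31-bit substream seed: reproducible per (locus, rep)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31 - 1)) + 1


@dataclass
class Genealogy:
    """Coalescent tree: node times (generations), parent pointers, node demes."""

    times: np.ndarray
    parent: np.ndarray
    node_deme: np.ndarray
    n1: int
    n2: int
    n_migrations: int = 0

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    @property
    def tmrca(self) -> float:
        return float(self.times[-1]) if self.n > 1 else 0.0

    @property
    def total_branch_length(self) -> float:
        return float(_kernels.total_branch_length(self.parent, self.times))


def simulate_genealogy(scenario: DemographicScenario, n1: int, n2: int,
                       seed: int, ploidy_factor: float = 1.0) -> Genealogy:
    """Simulate one genealogy of ``n1 + n2`` haplotypes under ``scenario``."""
    n = n1 + n2
    if n < 1:
        raise ValueError("need at least one sampled haplotype")
    if n == 1:
        return Genealogy(np.zeros(1), np.array([-1]), np.zeros(1, np.int64), n1, n2)
    times, parent, node_deme, n_mig = _kernels.sim_tree(
        n1, n2, scenario.t_bounds, scenario.size0, scenario.size1,
        scenario.mig01, scenario.mig10, scenario.merged,
        ploidy_factor, _substream(seed, 0))
    return Genealogy(times, parent, node_deme, n1, n2, n_mig)


def drop_mutations(genealogy: Genealogy, locus: LocusConfig, seed: int):
    """Place infinite-sites mutations on a genealogy.

    Returns ``(derived, positions)``: a boolean (S, n) matrix of derived-allele
    carriers and the 0-based site positions in ``[0, length_bp)``.
    """
    n = genealogy.n
    rate = locus.mu * locus.length_bp
    if rate == 0 or n < 2:
        return np.zeros((0, n), bool), np.zeros(0, np.int64)
    exp_s = rate * genealogy.total_branch_length
    if exp_s > locus.length_bp / 2:
        raise OverflowError(
            f"expected {exp_s:.0f} mutations on {locus.length_bp} sites; "
            "infinite-sites mapping would collide")
    derived = _kernels.mutate_tree(genealogy.parent, genealogy.times, n,
                                   rate, _substream(seed, 1))
    rng = np.random.default_rng(_substream(seed, 2))
    positions = np.sort(rng.choice(locus.length_bp, size=derived.shape[0],
                                   replace=False))
    return derived, positions


def simulate_locus_matrix(scenario, locus: LocusConfig, n1, n2, seed):
    """One locus end-to-end: genealogy + mutations -> (derived, positions)."""
    g = simulate_genealogy(scenario, n1, n2, seed,
                           ploidy_factor=locus.ploidy_factor)
    derived, positions = drop_mutations(g, locus, _substream(seed, 3))
    return derived, positions


def matrix_to_sequences(derived: np.ndarray, positions: np.ndarray,
                        length_bp: int, ancestral: str = "A",
                        derived_base: str = "T") -> list[str]:
    """Encode a 0/1 derived matrix as nucleotide strings (ancestral=A)."""
    n = derived.shape[1]
    base = np.full((n, length_bp), ancestral, dtype="U1")
    for s, pos in enumerate(positions):
        base[derived[s], pos] = derived_base
    return ["".join(row) for row in base]


def simulate_dataset(scenario, loci: list[LocusConfig], n1: int, n2: int,
                     seed: int):
    """Independent genealogy per locus; deterministic given ``seed``.

    Returns a list of ``(locus, derived, positions)`` triples; FASTA export
    lives in :mod:`peripagen.synth`.
    """
    out = []
    for li, locus in enumerate(loci):
        sub = _substream(seed, 100 + li)
        out.append((locus, *simulate_locus_matrix(scenario, locus, n1, n2, sub)))
    return out


def expected_joint_sfs(scenario, loci, n1: int, n2: int, n_sims: int,
                       seed: int, floor_total: float = None) -> np.ndarray:
    """Monte-Carlo expected joint SFS as entry probabilities.

    Averages branch lengths subtending each (i, j) cell over ``n_sims``
    genealogies, weights by per-locus mutational target ``mu * L`` (summed over
    loci), and normalizes over polymorphic cells.  Zero cells are floored at
    ``1 / (10 * Z)`` (Z = total expected segregating sites across the
    simulation) and the spectrum renormalized, so downstream log-likelihoods
    stay finite.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    target = sum(l.mu * l.length_bp for l in loci)
    if target <= 0:
        raise ValueError("total mutation rate is zero; spectrum degenerate")
    B = np.zeros((n1 + 1, n2 + 1))
    pf = loci[0].ploidy_factor
    for r in range(n_sims):
        B += _kernels.sim_sfs_branches(
            n1, n2, scenario.t_bounds, scenario.size0, scenario.size1,
            scenario.mig01, scenario.mig10, scenario.merged,
            pf, _substream(seed, 7, r))
    M = B * target  # expected SNP counts per cell over all sims
    M[0, 0] = 0.0
    M[n1, n2] = 0.0
    Z = M.sum()
    if Z <= 0:
        raise ValueError("no polymorphism simulated; spectrum degenerate")
    floor = 1.0 / (10.0 * (floor_total if floor_total else Z))
    P = M / Z
    mask = np.ones_like(P, bool)
    mask[0, 0] = mask[n1, n2] = False
    P[mask & (P <= 0)] = floor
    P[0, 0] = P[n1, n2] = 0.0
    return P / P.sum()
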