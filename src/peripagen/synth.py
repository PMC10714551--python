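"""Study-shaped synthetic datasets and deterministic micro-fixtures.

The default template mirrors the study design this package is built around:
14 nuclear loci totalling 6,077 bp (433 bp × 13 + 448 bp × 1; per-locus true
lengths are not published, so equal lengths are the default and a config
override exists), 112 + 63 diploid individuals in two populations (224 + 126
phased haplotypes), and one haploid cpDNA locus of 901 + 688 = 1,589 bp
sampled once per individual.  The generative default is scenario B3 at the
study's point estimates: the peripheral variety founded from the widespread
one 3.65 Ma ago (146,000 generations at 25 years/generation), founder
recovery at 0.65 Ma, recent expansion of the widespread variety at 0.61 Ma,
and weak asymmetric migration confined to the expansion epoch.

Within-variety substructure (10 + 6 sampling populations) is *not* simulated:
inference pools each variety, so a two-deme model is the generative world.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import coalescent as ce
from .alignments import (LocusAlignment, PopulationMap, StudyDataset,
                         write_alignment, write_popmap)

POP1, POP2 = "fargesii", "yunnanensis"

#: B3 point estimates (times in generations at 25 years/generation).
#: N1b (pre-expansion size of pop 1) and N2f (founder size) are not printed
#: in the source study; the defaults below are package choices, configurable.
B3_POINT_ESTIMATES = dict(
    N1=5.17e5, N2=3.63e4,
    N1b=5.0e4, N2f=2.0e3, NA=5.17e5,
    t0=0.61e6 / 25.0, t1=0.65e6 / 25.0, t2=0.65e6 / 25.0, t3=3.65e6 / 25.0,
    m12=8.37e-7,  # backward: widespread-variety lineage traces to peripheral
    m21=1.91e-7,
)

MU_NUCLEAR = 5.58e-9  # per site per generation
MU_CPDNA = 3.0e-10  # chosen to yield the observed handful of cpDNA variants


@dataclass
class StudyTemplate:
    nuclear_lengths: list = field(default_factory=lambda: [433] * 13 + [448])
    n_diploid_1: int = 112
    n_diploid_2: int = 63
    cpdna_length: int = 1589
    mu: float = MU_NUCLEAR
    mu_cpdna: float = MU_CPDNA
    generation_time: float = 25.0
    scenario_code: str = "B3"
    params: ce.ScenarioParams = None

    def __post_init__(self):
        if self.params is None:
            self.params = ce.ScenarioParams(**B3_POINT_ESTIMATES)

    @property
    def total_nuclear_bp(self) -> int:
        return sum(self.nuclear_lengths)

    @property
    def n_haplotypes(self):
        return 2 * self.n_diploid_1, 2 * self.n_diploid_2

    def nuclear_loci(self):
        return [ce.LocusConfig(L, mu=self.mu, locus_id=f"T{i+1:03d}")
                for i, L in enumerate(self.nuclear_lengths)]

    def cpdna_locus(self):
        return ce.LocusConfig(self.cpdna_length, mu=self.mu_cpdna,
                              ploidy_factor=0.5, locus_id="cpDNA")


def study_template() -> StudyTemplate:
    return StudyTemplate()


def _sample_ids(template):
    ids1 = [f"F{i+1:03d}" for i in range(template.n_diploid_1)]
    ids2 = [f"Y{i+1:03d}" for i in range(template.n_diploid_2)]
    return ids1, ids2


def _to_alignment(locus, derived, positions, ids1, ids2, ploidy):
    seqs = ce.matrix_to_sequences(derived, positions, locus.length_bp)
    recs = []
    k = 0
    for sid in ids1 + ids2:
        for hap in range(ploidy):
            recs.append((sid, hap, seqs[k]))
            k += 1
    # simulated sequences are polarized: the all-ancestral outgroup string
    return LocusAlignment(locus.locus_id, recs,
                          outgroup=["A" * locus.length_bp])


def generate_dataset(template: StudyTemplate, scenario_code: str = None,
                     params: ce.ScenarioParams = None, seed: int = 0,
                     outdir=None) -> StudyDataset:
    """Simulate a study-shaped dataset; optionally write it to ``outdir``.

    Writes one FASTA per locus, a popmap TSV, and a provenance JSON
    (scenario, parameters, seed); byte-deterministic given ``seed``.
    """
    code = scenario_code or template.scenario_code
    p = params or template.params
    scen = ce.build_scenario(code, p)
    ids1, ids2 = _sample_ids(template)
    n1, n2 = template.n_haplotypes
    loci = []
    for li, locus in enumerate(template.nuclear_loci()):
        derived, pos = ce.simulate_locus_matrix(
            scen, locus, n1, n2, ce._substream(seed, 100 + li))
        loci.append(_to_alignment(locus, derived, pos, ids1, ids2, 2))
    cp = template.cpdna_locus()
    derived, pos = ce.simulate_locus_matrix(
        scen, cp, template.n_diploid_1, template.n_diploid_2,
        ce._substream(seed, 99))
    cpdna = _to_alignment(cp, derived, pos, ids1, ids2, 1)
    popmap = PopulationMap({**{s: POP1 for s in ids1},
                            **{s: POP2 for s in ids2}})
    ds = StudyDataset(nuclear_loci=loci, popmap=popmap, cpdna=cpdna)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for aln in loci + [cpdna]:
            write_alignment(aln, outdir / f"{aln.locus_id}.fasta")
        write_popmap(popmap, outdir / "popmap.tsv")
        prov = {"scenario": code, "seed": int(seed),
                "params": {k: float(v) for k, v in vars(p).items()},
                "template": {"nuclear_lengths": template.nuclear_lengths,
                             "n_diploid": [template.n_diploid_1,
                                           template.n_diploid_2],
                             "mu": template.mu, "mu_cpdna": template.mu_cpdna,
                             "generation_time": template.generation_time}}
        (outdir / "provenance.json").write_text(json.dumps(prov, indent=2,
                                                           sort_keys=True))
    return ds


# ---------------------------------------------------------------------------
# micro-fixtures


T4_SEQS = [("s1", 0, "AAAAAAAAAA"), ("s2", 0, "AAAAAAAAAT"),
           ("s3", 0, "AAAAAAAATT"), ("s4", 0, "AAAAAAAATT")]
T4_OUTGROUP = ["AAAAAAAAAA"]
T4_POPS = {"s1": "p1", "s2": "p1", "s3": "p2", "s4": "p2"}

#: hand-enumerated expectations for the T4 toy (oracle: direct enumeration)
T4_EXPECTED = {
    "S": 2, "N_h": 3, "H_d": 5.0 / 6.0, "pi": 7.0 / 60.0,
    "theta_w": 12.0 / 110.0, "tajima_D": 0.5916, "faywu_H": -1.0,
    "joint_sfs": {(0, 2): 1, (1, 2): 1},
}

FOUR_GAMETE_SEQS = [("a", 0, "AA"), ("b", 0, "AT"), ("c", 0, "TA"),
                    ("d", 0, "TT")]

HKA_TOY = {"locus_ids": ["L1", "L2"], "S": [8, 3], "D": [20, 10],
           "n": [10, 10], "L": [500, 400]}


def t4_alignment() -> LocusAlignment:
    return LocusAlignment("T4", list(T4_SEQS), outgroup=list(T4_OUTGROUP))


def four_gamete_alignment() -> LocusAlignment:
    return LocusAlignment("FG", list(FOUR_GAMETE_SEQS))


def make_fixtures(outdir) -> dict:
    """Write the micro-fixtures (T4 toy, four-gamete toy, HKA toy, ABC toy
    table) with a README of expected values; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    aln = t4_alignment()
    write_alignment(aln, outdir / "t4.fasta")
    write_popmap(PopulationMap(dict(T4_POPS)), outdir / "t4_popmap.tsv")
    paths["t4"] = outdir / "t4.fasta"

    write_alignment(four_gamete_alignment(), outdir / "four_gamete.fasta")
    paths["four_gamete"] = outdir / "four_gamete.fasta"

    with open(outdir / "hka_toy.tsv", "w") as fh:
        fh.write("locus\tS\tD\tn\tL\n")
        for i, lid in enumerate(HKA_TOY["locus_ids"]):
            fh.write(f"{lid}\t{HKA_TOY['S'][i]}\t{HKA_TOY['D'][i]}\t"
                     f"{HKA_TOY['n'][i]}\t{HKA_TOY['L'][i]}\n")
    paths["hka_toy"] = outdir / "hka_toy.tsv"

    # tiny 2-scenario ABC table: Gaussian statistics, separated means
    rng = np.random.default_rng(20230)
    with open(outdir / "abc_toy.tsv", "w") as fh:
        fh.write("scenario\tstat1\tstat2\n")
        for s, mu in (("S1", 0.0), ("S2", 3.0)):
            for _ in range(50):
                x = rng.normal(mu, 1.0, 2)
                fh.write(f"{s}\t{x[0]:.6f}\t{x[1]:.6f}\n")
    paths["abc_toy"] = outdir / "abc_toy.tsv"

    readme = ["# Micro-fixtures and their expected values", "",
              "All values below are frozen from independent hand enumeration",
              "or closed forms (synthetic fixtures; no external data).", "",
              "## t4.fasta (4 seqs x 10 bp, outgroup all-A)",
              f"S = {T4_EXPECTED['S']}, N_h = {T4_EXPECTED['N_h']}, "
              f"H_d = 5/6, pi = 7/60 per site, theta_w = 2/(11/6*10),",
              "Tajima's D ~ 0.5916, Fay & Wu's H = -1.0 per locus,",
              "joint SFS (pops {s1,s2}/{s3,s4}): M[0][2]=1, M[1][2]=1.",
              "",
              "## four_gamete.fasta (AA/AT/TA/TT)",
              "All four gametes present at the site pair: R_m = 1.",
              "",
              "## hka_toy.tsv",
              "2-locus HKA input; chi-square equals brute-force grid",
              "minimization over (theta1, theta2, T) (see test suite).",
              "",
              "## abc_toy.tsv",
              "2 scenarios x 50 rows, stats ~ N(0,1) vs N(3,1), seed 20230;",
              "rejection retains rows matching a brute-force distance sort."]
    (outdir / "README.md").write_text("\n".join(readme) + "\n")
    paths["readme"] = outdir / "README.md"
    return paths
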