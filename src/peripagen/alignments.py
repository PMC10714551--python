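"""Multi-locus alignment containers and FASTA / population-map I/O.

Sequences are phased haplotypes: FASTA record ids follow the convention
``<sample_id>_<haplotype_index>`` (e.g. ``F001_0``, ``F001_1`` for a diploid
individual).  A record id without a trailing ``_<int>`` is treated as a single
haplotype with index 0 (the cpDNA / outgroup case).

Coordinates are 0-based half-open internally; reports are 1-based.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = set("ACGT-N")
_HAP_RE = re.compile(r"^(.*)_(\d+)$")


class AlignmentError(ValueError):
    pass


@dataclass
class LocusAlignment:
    """Phased haplotype alignment for one locus."""

    locus_id: str
    sequences: list  # of (sample_id, haplotype_index, str)
    outgroup: list = field(default_factory=list)  # nucleotide strings

    def __post_init__(self):
        if not self.sequences:
            raise AlignmentError(f"{self.locus_id}: empty alignment")
        L = len(self.sequences[0][2])
        seen = set()
        for sid, hap, seq in self.sequences:
            if len(seq) != L:
                raise AlignmentError(
                    f"{self.locus_id}: ragged alignment ({sid}_{hap}: "
                    f"{len(seq)} bp vs {L} bp)")
            bad = set(seq) - ALPHABET
            if bad:
                raise AlignmentError(f"{self.locus_id}: invalid characters {bad}")
            key = (sid, hap)
            if key in seen:
                raise AlignmentError(f"{self.locus_id}: duplicate id {sid}_{hap}")
            seen.add(key)
        for seq in self.outgroup:
            if len(seq) != L:
                raise AlignmentError(f"{self.locus_id}: outgroup length mismatch")

    @property
    def length_bp(self) -> int:
        return len(self.sequences[0][2])

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def sample_ids(self) -> list:
        return [sid for sid, _, _ in self.sequences]

    def matrix(self) -> np.ndarray:
        """(n, L) byte matrix of the ingroup."""
        return np.array([list(s) for _, _, s in self.sequences], dtype="U1")

    def outgroup_matrix(self) -> np.ndarray:
        return np.array([list(s) for s in self.outgroup], dtype="U1")

    def subset(self, sample_ids) -> "LocusAlignment":
        keep = set(sample_ids)
        seqs = [rec for rec in self.sequences if rec[0] in keep]
        return LocusAlignment(self.locus_id, seqs, outgroup=list(self.outgroup))


@dataclass
class PopulationMap:
    """sample_id -> population label, preserving file order within pops."""

    assignments: dict

    @property
    def populations(self) -> list:
        seen = []
        for p in self.assignments.values():
            if p not in seen:
                seen.append(p)
        return seen

    def samples(self, population: str) -> list:
        return [s for s, p in self.assignments.items() if p == population]

    def __getitem__(self, sample_id):
        return self.assignments[sample_id]

    def __contains__(self, sample_id):
        return sample_id in self.assignments


@dataclass
class StudyDataset:
    """The full study design: nuclear loci + optional cpDNA + population map."""

    nuclear_loci: list  # of LocusAlignment
    popmap: PopulationMap
    cpdna: LocusAlignment = None


def read_alignment(path, locus_id: str = None, outgroup_prefix: str = "outgroup"
                   ) -> LocusAlignment:
    """Read a FASTA alignment; records whose id starts with ``outgroup_prefix``
    become outgroup sequences."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: empty or unparseable FASTA")
    seqs, out = [], []
    for rec in records:
        s = str(rec.seq).upper()
        if rec.id.startswith(outgroup_prefix):
            out.append(s)
            continue
        m = _HAP_RE.match(rec.id)
        if m:
            seqs.append((m.group(1), int(m.group(2)), s))
        else:
            seqs.append((rec.id, 0, s))
    return LocusAlignment(locus_id or path.stem, seqs, outgroup=out)


def write_alignment(aln: LocusAlignment, path) -> None:
    records = [SeqRecord(Seq(s), id=f"{sid}_{hap}", description="")
               for sid, hap, s in aln.sequences]
    records += [SeqRecord(Seq(s), id=f"outgroup_{i}", description="")
                for i, s in enumerate(aln.outgroup)]
    SeqIO.write(records, str(path), "fasta")


def read_popmap(path) -> PopulationMap:
    assignments = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AlignmentError(f"{path}:{ln}: expected sample<TAB>population")
            if parts[0] in assignments:
                raise AlignmentError(f"{path}:{ln}: duplicate sample {parts[0]}")
            assignments[parts[0]] = parts[1]
    return PopulationMap(assignments)


def write_popmap(popmap: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for s, p in popmap.assignments.items():
            fh.write(f"{s}\t{p}\n")


def mask_indel_columns(aln: LocusAlignment, collapse_runs: bool = False):
    """Remove every column containing '-' from nucleotide analyses.

    Returns ``(masked_alignment, n_removed)``.  With ``collapse_runs`` the
    count is the number of contiguous gap *events* rather than columns (the
    indel-as-one-character convention used for haplotype counting).
    """
    mat = aln.matrix()
    ogm = aln.outgroup_matrix() if aln.outgroup else None
    gap = (mat == "-").any(axis=0)
    if ogm is not None and ogm.size:
        gap |= (ogm == "-").any(axis=0)
    keep = ~gap
    seqs = [(sid, hap, "".join(row[keep]))
            for (sid, hap, _), row in zip(aln.sequences, mat)]
    out = ["".join(row[keep]) for row in ogm] if ogm is not None else []
    if gap.sum() == aln.length_bp:
        raise AlignmentError(f"{aln.locus_id}: all columns are gapped")
    masked = LocusAlignment(aln.locus_id, seqs, outgroup=out)
    if collapse_runs:
        runs = int(np.diff(np.concatenate([[0], gap.view(np.int8)])).clip(0).sum())
        return masked, runs
    return masked, int(gap.sum())


def concatenate_loci(alns: list, locus_id: str = "concat") -> LocusAlignment:
    """Concatenate loci sharing an identical sample set, order-preserving."""
    if len(alns) == 1:
        return alns[0]
    keys0 = [(sid, hap) for sid, hap, _ in alns[0].sequences]
    parts = {k: [] for k in keys0}
    for aln in alns:
        keys = {(sid, hap): s for sid, hap, s in aln.sequences}
        if set(keys) != set(keys0):
            raise AlignmentError("sample sets differ between loci")
        for k in keys0:
            parts[k].append(keys[k])
    n_out = {len(a.outgroup) for a in alns}
    out = []
    if n_out == {len(alns[0].outgroup)} and len(alns[0].outgroup) > 0:
        if len(n_out) == 1:
            out = ["".join(a.outgroup[i] for a in alns)
                   for i in range(len(alns[0].outgroup))]
    return LocusAlignment(locus_id,
                          [(sid, hap, "".join(parts[(sid, hap)]))
                           for sid, hap in keys0],
                          outgroup=out)


def validate_dataset(ds: StudyDataset) -> list:
    """Report-based validation; returns a list of violation strings."""
    report = []
    for aln in ds.nuclear_loci:
        unmapped = [s for s in set(aln.sample_ids) if s not in ds.popmap]
        for s in sorted(unmapped):
            report.append(f"mapping: {aln.locus_id}: sample {s} not in popmap")
        per_sample = {}
        for sid, hap, _ in aln.sequences:
            per_sample.setdefault(sid, set()).add(hap)
        for sid, haps in sorted(per_sample.items()):
            if len(haps) != 2:
                report.append(
                    f"ploidy: {aln.locus_id}: sample {sid} has {len(haps)} "
                    "haplotypes, expected 2 (diploid nuclear)")
    if ds.cpdna is not None:
        per_sample = {}
        for sid, hap, _ in ds.cpdna.sequences:
            per_sample.setdefault(sid, set()).add(hap)
        for sid, haps in sorted(per_sample.items()):
            if len(haps) != 1:
                report.append(
                    f"ploidy: {ds.cpdna.locus_id}: sample {sid} has "
                    f"{len(haps)} haplotypes, expected 1 (haploid cpDNA)")
            if sid not in ds.popmap:
                report.append(f"mapping: {ds.cpdna.locus_id}: sample {sid} "
                              "not in popmap")
    return report


def write_validation_report(report: list, path) -> None:
    with open(path, "w") as fh:
        json.dump({"valid": not report, "violations": report}, fh, indent=2)
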