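"""Synthetic rearranged light-chain cohorts with known ground truth.

Cohorts emulate the monoclonal (AL / MM) and polyclonal control structure
the analysis assumes: each record is a germline V+J concatenation carrying
simulated somatic changes (per-residue substitutions, Poisson-count
single-residue indels), optional N-/C-terminal truncation producing the
"incomplete" or "excluded" coverage classes, and optional near-identical
duplicate emissions to exercise consensus collapsing.

Simulation operates on amino acids; a thin nucleotide mode back-translates
records with a fixed codon table to test the translation path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from lcrep.assign import RearrangedRecord
from lcrep.reference import AA_ALPHABET, ReferenceSet

_AA = sorted(AA_ALPHABET)

#: Fixed back-translation table (one codon per residue).
_CODON: Mapping[str, str] = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_DEFAULT_CLINICAL = {
    "AL": ("AL-PCD", "AL"),
    "MM": ("Other-PCD", "MM"),
    "control": ("control", "control"),
}


@dataclass(frozen=True)
class ShmResult:
    """Outcome of one simulated hypermutation pass."""

    seq: str
    substitutions: int
    insertions: int
    deletions: int
    # edit script relative to the germline: (0-based germline position, new
    # residue) substitutions, deleted germline positions, and sequential
    # (slot, residue) insertions — enough to replay the transformation
    sub_events: tuple[tuple[int, str], ...] = ()
    del_positions: tuple[int, ...] = ()
    ins_events: tuple[tuple[int, str], ...] = ()


@dataclass
class CohortSpec:
    """Parameters for one simulated cohort."""

    name: str
    n_sequences: int
    gene_usage: dict[str, float]
    j_usage: dict[str, float]
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    truncate_prob: float = 0.0
    fragment_prob: float = 0.0
    duplicate_prob: float = 0.0
    molecule: str = "protein"
    category: str = ""
    subcategory: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be >= 0")
        if not 0 <= self.sub_rate < 1:
            raise ValueError("sub_rate must be in [0, 1)")
        if self.ins_rate < 0 or self.del_rate < 0:
            raise ValueError("indel rates must be >= 0")
        for p in (self.truncate_prob, self.fragment_prob, self.duplicate_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        for label, usage in (("gene_usage", self.gene_usage), ("j_usage", self.j_usage)):
            if not usage:
                raise ValueError(f"{label} must be non-empty")
            total = sum(usage.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{label} probabilities sum to {total}, expected 1")
        if not self.category or not self.subcategory:
            cat, sub = _DEFAULT_CLINICAL.get(self.name, ("control", self.name))
            if not self.category:
                self.category = cat
            if not self.subcategory:
                self.subcategory = sub

    def validate_against(self, reference: ReferenceSet) -> None:
        for gene_id in list(self.gene_usage) + list(self.j_usage):
            if gene_id not in reference:
                raise ValueError(f"cohort {self.name!r} references unknown gene {gene_id!r}")


def simulate_shm(
    germline_vj_seq: str,
    sub_rate: float = 0.0,
    ins_rate: float = 0.0,
    del_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ShmResult:
    """Apply simulated somatic hypermutation to a germline V-J sequence.

    Substitutions are drawn per residue at ``sub_rate`` (always to a
    different residue); insertion and deletion counts are Poisson with the
    stated per-sequence expectations, applied as single-residue events.
    Deletion draws that would remove the whole sequence are resampled.
    """
    if not germline_vj_seq:
        raise ValueError("germline sequence must be non-empty")
    rng = rng if rng is not None else np.random.default_rng()
    n = len(germline_vj_seq)

    n_del = int(rng.poisson(del_rate)) if del_rate > 0 else 0
    while n_del >= n:
        n_del = int(rng.poisson(del_rate))
    del_positions = (
        tuple(sorted(rng.choice(n, size=n_del, replace=False).tolist()))
        if n_del
        else ()
    )
    deleted = set(del_positions)

    sub_events = []
    residues = []
    for pos, aa in enumerate(germline_vj_seq):
        if pos in deleted:
            continue
        if sub_rate > 0 and rng.random() < sub_rate:
            choices = [c for c in _AA if c != aa]
            new_aa = choices[int(rng.integers(len(choices)))]
            residues.append(new_aa)
            sub_events.append((pos, new_aa))
        else:
            residues.append(aa)

    n_ins = int(rng.poisson(ins_rate)) if ins_rate > 0 else 0
    ins_events = []
    for _ in range(n_ins):
        slot = int(rng.integers(len(residues) + 1))
        residue = _AA[int(rng.integers(len(_AA)))]
        residues.insert(slot, residue)
        ins_events.append((slot, residue))

    return ShmResult(
        seq="".join(residues),
        substitutions=len(sub_events),
        insertions=n_ins,
        deletions=n_del,
        sub_events=tuple(sub_events),
        del_positions=del_positions,
        ins_events=tuple(ins_events),
    )


def replay_edits(germline_vj_seq: str, result: ShmResult) -> str:
    """Reconstruct the emitted sequence from the germline and edit script."""
    deleted = set(result.del_positions)
    subs = dict(result.sub_events)
    out = [
        subs.get(pos, aa)
        for pos, aa in enumerate(germline_vj_seq)
        if pos not in deleted
    ]
    for slot, residue in result.ins_events:
        out.insert(slot, residue)
    return "".join(out)


def back_translate(aa_seq: str) -> str:
    """Deterministic nucleotide back-translation with a fixed codon table."""
    return "".join(_CODON[aa] for aa in aa_seq)


def _truncation_bounds(reference: ReferenceSet, length: int) -> tuple[int, int]:
    """Max removable residues from the N and C termini while keeping all
    CDR windows and >= 80 contiguous residues."""
    windows = [(min(s, length), min(e, length)) for s, e in reference.cdr_windows]
    n_max = windows[0][0] - 1
    c_max = length - windows[-1][1]
    return n_max, c_max


def generate_cohort(
    spec: CohortSpec,
    reference: ReferenceSet,
) -> tuple[list[RearrangedRecord], pd.DataFrame, pd.DataFrame]:
    """Generate one cohort: records, metadata table and ground truth.

    Reproducible for a fixed ``spec.seed``; per-gene record counts are
    multinomial draws from ``spec.gene_usage``.
    """
    spec.validate_against(reference)
    rng = np.random.default_rng(spec.seed)
    v_names = sorted(spec.gene_usage)
    v_probs = np.array([spec.gene_usage[g] for g in v_names])
    j_names = sorted(spec.j_usage)
    j_probs = np.array([spec.j_usage[g] for g in j_names])

    records: list[RearrangedRecord] = []
    meta_rows = []
    truth_rows = []

    def emit(record_id: str, aa_seq: str, truth: dict) -> None:
        seq = aa_seq
        molecule = spec.molecule
        if molecule == "nucleotide":
            seq = back_translate(aa_seq)
        records.append(
            RearrangedRecord(
                record_id=record_id,
                seq=seq,
                molecule=molecule,
                category=spec.category,
                subcategory=spec.subcategory,
                cohort=spec.name,
            )
        )
        meta_rows.append(
            {
                "record_id": record_id,
                "cohort": spec.name,
                "category": spec.category,
                "subcategory": spec.subcategory,
                "molecule": molecule,
            }
        )
        truth_rows.append({"record_id": record_id, **truth})

    for i in range(spec.n_sequences):
        v_gene = v_names[int(rng.choice(len(v_names), p=v_probs))]
        # J locus must match the V locus; restrict to same-locus J usage
        v_locus = reference.get(v_gene).locus
        j_idx = [k for k, g in enumerate(j_names) if reference.get(g).locus == v_locus]
        if not j_idx:
            raise ValueError(f"no J gene in j_usage for locus {v_locus}")
        jp = j_probs[j_idx] / j_probs[j_idx].sum()
        j_gene = j_names[j_idx[int(rng.choice(len(j_idx), p=jp))]]

        germline = reference.get(v_gene).aa_seq + reference.get(j_gene).aa_seq
        shm = simulate_shm(germline, spec.sub_rate, spec.ins_rate, spec.del_rate, rng)
        seq = shm.seq

        intended = "complete"
        u = rng.random()
        if u < spec.fragment_prob:
            intended = "excluded"
        elif u < spec.fragment_prob + spec.truncate_prob:
            intended = "incomplete"

        if intended == "incomplete":
            n_max, c_max = _truncation_bounds(reference, len(germline))
            from_n = bool(rng.random() < 0.5)
            if from_n and n_max >= 1:
                cut = int(rng.integers(1, n_max + 1))
                seq = seq[cut:]
            elif c_max >= 1:
                cut = int(rng.integers(1, c_max + 1))
                seq = seq[: len(seq) - cut]
            else:
                intended = "complete"
        elif intended == "excluded":
            keep = min(len(seq), 70)
            seq = seq[:keep]

        record_id = f"{spec.name}_{i:05d}"
        truth = {
            "cohort": spec.name,
            "true_v_gene": v_gene,
            "true_j_gene": j_gene,
            "true_substitutions": shm.substitutions,
            "true_insertions": shm.insertions,
            "true_deletions": shm.deletions,
            "true_coverage_class": intended,
            "duplicate_of": "",
        }
        emit(record_id, seq, truth)

        if spec.duplicate_prob > 0 and rng.random() < spec.duplicate_prob:
            dup_seq = seq
            extra = 0
            if rng.random() < 0.5 and len(seq) > 0:
                pos = int(rng.integers(len(seq)))
                choices = [c for c in _AA if c != seq[pos]]
                dup_seq = seq[:pos] + choices[int(rng.integers(len(choices)))] + seq[pos + 1:]
                extra = 1
            emit(
                f"{record_id}_dup",
                dup_seq,
                {**truth,
                 "true_substitutions": shm.substitutions + extra,
                 "duplicate_of": record_id},
            )

    meta_cols = ["record_id", "cohort", "category", "subcategory", "molecule"]
    truth_cols = [
        "record_id", "cohort", "true_v_gene", "true_j_gene",
        "true_substitutions", "true_insertions", "true_deletions",
        "true_coverage_class", "duplicate_of",
    ]
    metadata = pd.DataFrame(meta_rows, columns=meta_cols)
    truth = pd.DataFrame(truth_rows, columns=truth_cols)
    return records, metadata, truth


def write_cohort_fasta(records: list[RearrangedRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.record_id}\n{rec.seq}\n")


def load_cohort_specs(path, reference: ReferenceSet | None = None) -> list[CohortSpec]:
    """Load cohort specs from a YAML config (list under key ``cohorts``)."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    blocks = doc["cohorts"] if isinstance(doc, dict) else doc
    specs = [CohortSpec(**block) for block in blocks]
    if reference is not None:
        for spec in specs:
            spec.validate_against(reference)
    return specs
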