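"""Germline V/J assignment, coverage classification and duplicate collapsing.

Each rearranged light-chain record is aligned against every same-locus
functional (V, J) germline pair (concatenated into a single template) with
an affine-gap BLOSUM62 aligner that is global on the germline and allows
free end gaps on the query, so truncated records are not penalised for
missing termini. The best pair is chosen by score, then fewest edits, then
lexicographic gene id, which makes assignment independent of reference
ordering. Reported V genes are paralog-collapsed and reported J genes pass
the IGLJ2/IGLJ3 merged-label rule.

Edit-count conventions: an aligned column with differing residues is a
substitution; an internal gap in the germline is an insertion; an internal
gap in the query is a deletion; end gaps arising from truncation count as
coverage, not deletions. All germline differences are attributed to
somatic change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from lcrep.reference import ReferenceSet, collapse_paralog, j_ambiguity_label

GAP_OPEN = -10
GAP_EXTEND = -1
MIN_QUERY_LENGTH = 20
DEFAULT_MIN_IDENTITY = 0.5

COVERAGE_COMPLETE = "complete"
COVERAGE_INCOMPLETE = "incomplete"
COVERAGE_EXCLUDED = "excluded"


@dataclass(frozen=True)
class RearrangedRecord:
    """One observed light-chain sequence with clinical labels."""

    record_id: str
    seq: str
    molecule: str = "protein"  # "protein" | "nucleotide"
    category: str = "control"
    subcategory: str = "control"
    cohort: str = "control"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.record_id}: empty sequence")
        if self.molecule not in ("protein", "nucleotide"):
            raise ValueError(f"{self.record_id}: bad molecule {self.molecule!r}")


@dataclass
class GermlineAssignment:
    """Best-scoring germline alignment of one record, with edit counts."""

    record_id: str
    v_gene: str | None
    j_gene: str | None
    v_gene_raw: str | None = None
    j_gene_raw: str | None = None
    germline_aln: str = ""
    query_aln: str = ""
    score: float = float("-inf")
    substitutions: int = 0
    insertions: int = 0
    deletions: int = 0
    ambiguous: int = 0
    germline_length: int = 0
    covered_start: int = 0  # 1-based inclusive germline positions
    covered_end: int = 0
    identity: float = 0.0
    coverage_class: str = COVERAGE_EXCLUDED
    reason: str = ""


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    # free end gaps on the query: germline overhang over a truncated query
    # is coverage information, not a scored gap
    aligner.open_left_deletion_score = 0
    aligner.extend_left_deletion_score = 0
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    return aligner


_ALIGNER = _make_aligner()


def _count_edits(alignment, germline: str, query: str) -> dict:
    """Tally substitutions / insertions / deletions from aligned blocks."""
    tb, qb = alignment.aligned
    subs = matches = ambiguous = 0
    for (ts, te), (qs, qe) in zip(tb, qb):
        for tpos, qpos in zip(range(ts, te), range(qs, qe)):
            g, q = germline[tpos], query[qpos]
            if q == "X":
                ambiguous += 1
            elif g == q:
                matches += 1
            else:
                subs += 1
    insertions = deletions = 0
    for i in range(1, len(tb)):
        deletions += int(tb[i][0] - tb[i - 1][1])
        insertions += int(qb[i][0] - qb[i - 1][1])
    aligned_cols = matches + subs + ambiguous
    return {
        "substitutions": subs,
        "insertions": insertions,
        "deletions": deletions,
        "ambiguous": ambiguous,
        "matches": matches,
        "identity": matches / aligned_cols if aligned_cols else 0.0,
        "covered_start": int(tb[0][0]) + 1 if len(tb) else 0,
        "covered_end": int(tb[-1][1]) if len(tb) else 0,
    }


def _candidate_protein_seqs(record: RearrangedRecord) -> list[str]:
    """Protein sequences to try: the record itself, or productive translations.

    Nucleotide inputs are translated in all three forward frames; frames
    containing an internal stop codon are rejected as non-productive.
    """
    if record.molecule == "protein":
        return [record.seq.upper()]
    nt = record.seq.upper().replace("U", "T")
    candidates = []
    for frame in range(3):
        sub = nt[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            continue
        aa = str(Seq(sub).translate())
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa or not aa:
            continue
        candidates.append(aa)
    return candidates


def assign_germline(
    record: RearrangedRecord,
    reference: ReferenceSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> GermlineAssignment:
    """Assign the best functional germline V and J genes to one record.

    Deterministic: ties on score are broken by fewest total edits, then by
    lexicographic (V, J) gene id, so permuting the reference never changes
    the result.
    """
    candidates = _candidate_protein_seqs(record)
    if not candidates:
        return GermlineAssignment(
            record_id=record.record_id,
            v_gene=None,
            j_gene=None,
            coverage_class=COVERAGE_EXCLUDED,
            reason="non-productive",
        )
    if max(len(c) for c in candidates) < MIN_QUERY_LENGTH:
        return GermlineAssignment(
            record_id=record.record_id,
            v_gene=None,
            j_gene=None,
            coverage_class=COVERAGE_EXCLUDED,
            reason="too-short",
        )

    pairs = reference.vj_pairs()
    best: list[tuple] = []  # (v, j, query, score)
    best_score = float("-inf")
    for query in candidates:
        for v, j in pairs:
            template = v.aa_seq + j.aa_seq
            score = _ALIGNER.score(template, query)
            if score > best_score + 1e-9:
                best_score = score
                best = [(v, j, query, score)]
            elif abs(score - best_score) <= 1e-9:
                best.append((v, j, query, score))

    # resolve ties: fewest edits, then lexicographic gene ids
    resolved = []
    for v, j, query, score in best:
        template = v.aa_seq + j.aa_seq
        aln = _ALIGNER.align(template, query)[0]
        counts = _count_edits(aln, template, query)
        edits = counts["substitutions"] + counts["insertions"] + counts["deletions"]
        resolved.append((edits, v.gene_id, j.gene_id, v, j, query, aln, counts, score))
    resolved.sort(key=lambda t: (t[0], t[1], t[2]))
    _, _, _, v, j, query, aln, counts, score = resolved[0]
    template = v.aa_seq + j.aa_seq

    assignment = GermlineAssignment(
        record_id=record.record_id,
        v_gene=collapse_paralog(v.gene_id, reference),
        j_gene=j_ambiguity_label(j.gene_id, reference),
        v_gene_raw=v.gene_id,
        j_gene_raw=j.gene_id,
        germline_aln=str(aln[0]),
        query_aln=str(aln[1]),
        score=float(score),
        substitutions=counts["substitutions"],
        insertions=counts["insertions"],
        deletions=counts["deletions"],
        ambiguous=counts["ambiguous"],
        germline_length=len(template),
        covered_start=counts["covered_start"],
        covered_end=counts["covered_end"],
        identity=counts["identity"],
    )
    if assignment.identity < min_identity:
        assignment.v_gene = None
        assignment.j_gene = None
        assignment.coverage_class = COVERAGE_EXCLUDED
        assignment.reason = "unassignable"
        return assignment
    assignment.coverage_class = classify_coverage(assignment, record, reference)
    if assignment.coverage_class == COVERAGE_EXCLUDED:
        assignment.reason = "coverage"
    return assignment


def classify_coverage(
    assignment: GermlineAssignment,
    record: RearrangedRecord,
    reference: ReferenceSet,
) -> str:
    """Classify a record's V-J coverage as complete / incomplete / excluded.

    Complete: the full germline V-J span is aligned and the record carries
    no ambiguous residues. Incomplete: V and J unambiguously assigned, at
    least 80 contiguous germline positions covered, and all three CDR
    windows inside the covered span. Anything else is excluded. Total over
    all records.
    """
    if assignment.v_gene is None or assignment.j_gene is None:
        return COVERAGE_EXCLUDED
    L = assignment.germline_length
    start, end = assignment.covered_start, assignment.covered_end
    if start <= 0 or end <= 0:
        return COVERAGE_EXCLUDED
    has_x = assignment.ambiguous > 0 or (
        record.molecule == "protein" and "X" in record.seq.upper()
    )
    if start == 1 and end == L and not has_x:
        return COVERAGE_COMPLETE
    if end - start + 1 < 80:
        return COVERAGE_EXCLUDED
    for w_start, w_end in reference.cdr_windows:
        w_start, w_end = min(w_start, L), min(w_end, L)
        if not (start <= w_start and w_end <= end):
            return COVERAGE_EXCLUDED
    return COVERAGE_INCOMPLETE


def assign_all(
    records: Iterable[RearrangedRecord],
    reference: ReferenceSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> pd.DataFrame:
    """Assign a batch of records; returns an AIRR-style table."""
    rows = []
    for record in records:
        a = assign_germline(record, reference, min_identity=min_identity)
        rows.append(
            {
                "sequence_id": record.record_id,
                "cohort": record.cohort,
                "category": record.category,
                "subcategory": record.subcategory,
                "molecule": record.molecule,
                "v_call": a.v_gene,
                "j_call": a.j_gene,
                "locus": a.v_gene[:3] if a.v_gene else None,
                "score": a.score,
                "identity": round(a.identity, 6),
                "substitutions": a.substitutions,
                "insertions": a.insertions,
                "deletions": a.deletions,
                "ambiguous": a.ambiguous,
                "germline_length": a.germline_length,
                "covered_start": a.covered_start,
                "covered_end": a.covered_end,
                "coverage_class": a.coverage_class,
                "reason": a.reason,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# duplicate / near-duplicate collapsing
# ---------------------------------------------------------------------------


def _pair_identity(a: str, b: str) -> float:
    """Overlap identity: best of N- and C-anchored match fraction over the
    shorter sequence."""
    if a == b:
        return 1.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    n = len(short)
    m_n = sum(1 for x, y in zip(short, long_) if x == y)
    m_c = sum(1 for x, y in zip(reversed(short), reversed(long_)) if x == y)
    return max(m_n, m_c) / n


def _cluster(records: Sequence[RearrangedRecord], threshold: float) -> list[list[int]]:
    """Single-linkage clusters of records at pairwise overlap identity >= threshold."""
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(n), key=lambda i: len(records[i].seq))
    seqs = [records[i].seq.upper() for i in range(n)]
    # exact-duplicate fast path
    by_seq: dict[str, int] = {}
    for i in range(n):
        j = by_seq.setdefault(seqs[i], i)
        if j != i:
            union(i, j)
    for a_idx in range(n):
        i = order[a_idx]
        li = len(seqs[i])
        for b_idx in range(a_idx + 1, n):
            j = order[b_idx]
            lj = len(seqs[j])
            if li / lj < threshold - 0.05:
                break  # lengths too different for near-identity
            if find(i) == find(j):
                continue
            if _pair_identity(seqs[i], seqs[j]) >= threshold:
                union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())


def _consensus(seqs: Sequence[str]) -> str | None:
    """Per-column majority consensus, N-anchored; None on any column tie."""
    out = []
    for col in range(max(len(s) for s in seqs)):
        residues = [s[col] for s in seqs if len(s) > col]
        counts: dict[str, int] = {}
        for r in residues:
            counts[r] = counts.get(r, 0) + 1
        top = max(counts.values())
        winners = [r for r, c in counts.items() if c == top]
        if len(winners) > 1:
            return None
        out.append(winners[0])
    return "".join(out)


def _representative(members: Sequence[RearrangedRecord]) -> RearrangedRecord:
    """Longest sequence wins; nucleotide-derived records beat protein."""
    return max(
        members,
        key=lambda r: (len(r.seq), r.molecule == "nucleotide", r.record_id),
    )


def collapse_duplicates(
    records: Sequence[RearrangedRecord],
    identity_threshold: float = 0.98,
) -> tuple[list[RearrangedRecord], list[RearrangedRecord], pd.DataFrame]:
    """Collapse identical / near-identical records to a single entry.

    Clusters at pairwise identity >= ``identity_threshold`` are replaced by
    a per-column majority consensus; a tied column makes the consensus
    ambiguous and the whole cluster is excluded. Clusters whose members
    agree everywhere they overlap keep the longest (nucleotide-preferred)
    member directly.

    Returns (kept records, consensus records, disposition log). Every input
    record appears exactly once in the log with disposition kept / merged /
    consensus / excluded.
    """
    if not 0.9 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0.9, 1]")
    kept: list[RearrangedRecord] = []
    consensus_records: list[RearrangedRecord] = []
    log_rows = []
    for cluster_id, idxs in enumerate(_cluster(records, identity_threshold)):
        members = [records[i] for i in idxs]
        if len(members) == 1:
            kept.append(members[0])
            log_rows.append(
                {"record_id": members[0].record_id, "disposition": "kept",
                 "cluster_id": cluster_id, "reason": ""}
            )
            continue
        rep = _representative(members)
        conflict = any(
            _pair_identity(a.seq.upper(), b.seq.upper()) < 1.0
            for k, a in enumerate(members)
            for b in members[k + 1:]
        )
        if not conflict:
            kept.append(rep)
            for m in members:
                log_rows.append(
                    {"record_id": m.record_id,
                     "disposition": "kept" if m is rep else "merged",
                     "cluster_id": cluster_id,
                     "reason": "" if m is rep else f"duplicate of {rep.record_id}"}
                )
            continue
        cons = _consensus([m.seq.upper() for m in members])
        if cons is None:
            for m in members:
                log_rows.append(
                    {"record_id": m.record_id, "disposition": "excluded",
                     "cluster_id": cluster_id, "reason": "ambiguous consensus"}
                )
            continue
        cons_record = RearrangedRecord(
            record_id=f"{rep.record_id}_consensus",
            seq=cons,
            molecule=rep.molecule,
            category=rep.category,
            subcategory=rep.subcategory,
            cohort=rep.cohort,
        )
        consensus_records.append(cons_record)
        for m in members:
            log_rows.append(
                {"record_id": m.record_id, "disposition": "consensus",
                 "cluster_id": cluster_id,
                 "reason": f"merged into {cons_record.record_id}"}
            )
    log = pd.DataFrame(
        log_rows, columns=["record_id", "disposition", "cluster_id", "reason"]
    )
    return kept, consensus_records, log
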