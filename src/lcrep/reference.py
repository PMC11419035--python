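"""Germline V/J reference sets.

A reference set holds the germline gene segments against which rearranged
light-chain sequences are assigned, together with the paralog-collapsing
map (indistinguishable proximal/distal IGKV copies counted under the
proximal name) and the positions of the three CDR windows used by the
coverage classifier.

Only functional genes participate in assignment; non-functional genes are
retained in the set but flagged.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default CDR windows, 1-based inclusive intervals on the rearranged
#: V-J germline coordinate (IMGT unique-numbering derived). Configurable
#: per reference; the bundled test reference ships its own windows.
DEFAULT_CDR_WINDOWS: tuple[tuple[int, int], ...] = ((27, 38), (56, 65), (105, 117))

#: J genes whose germline sequences are indistinguishable; both are
#: reported under a single merged label.
_MERGED_J_LABELS: Mapping[str, str] = {
    "IGLJ2": "IGLJ2/IGLJ3",
    "IGLJ3": "IGLJ2/IGLJ3",
}


class ReferenceError(ValueError):
    """Raised when a reference set fails validation."""


@dataclass(frozen=True)
class GermlineGene:
    """One germline V or J segment."""

    gene_id: str
    locus: str  # "IGK" | "IGL"
    segment: str  # "V" | "J"
    aa_seq: str
    functional: bool = True
    paralog_canonical: str = ""

    def __post_init__(self) -> None:
        if self.locus not in ("IGK", "IGL"):
            raise ReferenceError(f"{self.gene_id}: locus must be IGK or IGL, got {self.locus!r}")
        if self.segment not in ("V", "J"):
            raise ReferenceError(f"{self.gene_id}: segment must be V or J, got {self.segment!r}")
        if not self.aa_seq:
            raise ReferenceError(f"{self.gene_id}: empty sequence")
        bad = set(self.aa_seq) - AA_ALPHABET
        if bad:
            raise ReferenceError(
                f"{self.gene_id}: non-amino-acid characters {sorted(bad)!r} in sequence"
            )
        if not self.paralog_canonical:
            object.__setattr__(self, "paralog_canonical", self.gene_id)


@dataclass
class ReferenceSet:
    """Validated collection of germline genes plus CDR window positions."""

    genes: dict[str, GermlineGene]
    cdr_windows: tuple[tuple[int, int], ...] = DEFAULT_CDR_WINDOWS

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        if len(self.cdr_windows) != 3:
            raise ReferenceError("exactly three CDR windows are required")
        prev_end = 0
        for start, end in self.cdr_windows:
            if not (0 < start <= end):
                raise ReferenceError(f"invalid CDR window ({start}, {end})")
            if start <= prev_end:
                raise ReferenceError("CDR windows must be ordered and non-overlapping")
            prev_end = end
        for gene in self.genes.values():
            target = self.genes.get(gene.paralog_canonical)
            if target is None:
                raise ReferenceError(
                    f"{gene.gene_id}: paralog_canonical {gene.paralog_canonical!r} "
                    "not present in reference"
                )
            if (target.locus, target.segment) != (gene.locus, gene.segment):
                raise ReferenceError(
                    f"{gene.gene_id}: paralog_canonical {gene.paralog_canonical!r} "
                    "differs in locus or segment"
                )
        for locus in {g.locus for g in self.genes.values()}:
            for segment in ("V", "J"):
                if not self.functional_genes(locus, segment):
                    raise ReferenceError(
                        f"no functional {segment} gene for locus {locus}"
                    )
        v_min = min(
            (len(g.aa_seq) for g in self.genes.values() if g.segment == "V"),
            default=0,
        )
        j_max = max(
            (len(g.aa_seq) for g in self.genes.values() if g.segment == "J"),
            default=0,
        )
        if v_min and j_max and v_min <= j_max:
            raise ReferenceError("V segments must be longer than J segments")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, gene_id: str) -> GermlineGene:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise ReferenceError(f"unknown gene id {gene_id!r}") from None

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(sorted({g.locus for g in self.genes.values()}))

    def functional_genes(self, locus: str, segment: str) -> list[GermlineGene]:
        """Assignment candidates: functional genes of one locus and segment."""
        return sorted(
            (
                g
                for g in self.genes.values()
                if g.functional and g.locus == locus and g.segment == segment
            ),
            key=lambda g: g.gene_id,
        )

    def vj_pairs(self) -> list[tuple[GermlineGene, GermlineGene]]:
        """All same-locus functional (V, J) candidate pairs, sorted."""
        pairs = []
        for locus in self.loci:
            for v in self.functional_genes(locus, "V"):
                for j in self.functional_genes(locus, "J"):
                    pairs.append((v, j))
        return pairs


def collapse_paralog(gene_id: str, reference: ReferenceSet) -> str:
    """Map a gene to its counting name (proximal paralog); idempotent."""
    return reference.get(gene_id).paralog_canonical


def j_ambiguity_label(gene_id: str, reference: ReferenceSet | None = None) -> str:
    """Reporting label for a J gene; merges the indistinguishable IGLJ2/IGLJ3 pair."""
    if reference is not None:
        gene = reference.get(gene_id)
        if gene.segment != "J":
            raise ReferenceError(f"{gene_id} is not a J gene")
    elif "J" not in gene_id:
        raise ReferenceError(f"{gene_id} is not a J gene")
    return _MERGED_J_LABELS.get(gene_id, gene_id)


def _parse_bool(value: str, context: str) -> bool:
    norm = value.strip().lower()
    if norm in ("true", "t", "1", "yes"):
        return True
    if norm in ("false", "f", "0", "no"):
        return False
    raise ReferenceError(f"{context}: cannot parse boolean {value!r}")


def _read_metadata(metadata_path: Path) -> dict[str, dict[str, str]]:
    rows: dict[str, dict[str, str]] = {}
    with open(metadata_path) as handle:
        header: list[str] | None = None
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                required = {"gene_id", "locus", "segment", "functional", "paralog_canonical"}
                missing = required - set(header)
                if missing:
                    raise ReferenceError(f"metadata missing columns: {sorted(missing)}")
                continue
            row = dict(zip(header, fields))
            gene_id = row["gene_id"]
            if gene_id in rows:
                raise ReferenceError(f"duplicate metadata row for {gene_id!r}")
            rows[gene_id] = row
    if not rows:
        raise ReferenceError(f"no metadata rows in {metadata_path}")
    return rows


def load_reference(
    fasta_path: str | Path,
    metadata_path: str | Path,
    cdr_windows: tuple[tuple[int, int], ...] = DEFAULT_CDR_WINDOWS,
) -> ReferenceSet:
    """Load a germline reference from FASTA + tab-separated metadata.

    The FASTA supplies amino-acid sequences; the metadata table supplies
    locus, segment, functionality and the paralog-collapse target, keyed
    by identical record ids. Errors name the offending record.
    """
    meta = _read_metadata(Path(metadata_path))
    genes: dict[str, GermlineGene] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        gene_id = rec.id
        if gene_id in genes:
            raise ReferenceError(f"duplicate FASTA record {gene_id!r}")
        row = meta.get(gene_id)
        if row is None:
            raise ReferenceError(f"FASTA record {gene_id!r} has no metadata row")
        genes[gene_id] = GermlineGene(
            gene_id=gene_id,
            locus=row["locus"],
            segment=row["segment"],
            aa_seq=str(rec.seq).upper(),
            functional=_parse_bool(row["functional"], gene_id),
            paralog_canonical=row["paralog_canonical"] or gene_id,
        )
    missing_fasta = set(meta) - set(genes)
    if missing_fasta:
        raise ReferenceError(
            f"metadata rows without FASTA records: {sorted(missing_fasta)}"
        )
    return ReferenceSet(genes=genes, cdr_windows=cdr_windows)


#: CDR windows matching the bundled test reference (100-residue V segments,
#: 10-residue J segments; windows on the ungapped rearranged coordinate).
BUNDLED_CDR_WINDOWS: tuple[tuple[int, int], ...] = ((27, 38), (56, 65), (89, 98))


def bundled_data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("lcrep").joinpath("data", name)))


def load_bundled_reference() -> ReferenceSet:
    """Small bundled test reference: 12 V and 4 J genes over both loci.

    Gene names follow IMGT nomenclature; sequences are synthetic so no
    external download is required for tests or demos.
    """
    return load_reference(
        bundled_data_path("germline_ref.fasta"),
        bundled_data_path("germline_ref.tsv"),
        cdr_windows=BUNDLED_CDR_WINDOWS,
    )
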