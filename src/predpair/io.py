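"""File formats: FASTA, CT (connect), dot-bracket and Stockholm alignments."""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, TextIO

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structures import (
    FamilyRecord,
    SecondaryStructure,
    pairs_to_dotbracket,
    project_consensus,
)


def read_fasta(path: str | Path) -> list[SecondaryStructure]:
    """Read FASTA records as structures with empty pair sets."""
    return [
        SecondaryStructure(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(structures: Iterable[SecondaryStructure], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description="") for s in structures
    ]
    SeqIO.write(records, str(path), "fasta")


def write_ct(structure: SecondaryStructure, handle: TextIO) -> None:
    """Write one structure in CT (connect) format; CT is 1-based."""
    partner = structure.partner()
    L = len(structure)
    handle.write(f"{L} {structure.id}\n")
    for i in range(L):
        j = partner.get(i, -1) + 1  # 0 means unpaired in CT
        handle.write(
            f"{i + 1} {structure.sequence[i]} {i} {i + 2 if i + 1 < L else 0} {j} {i + 1}\n"
        )


def write_ct_file(structures: Iterable[SecondaryStructure], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in structures:
            write_ct(s, fh)


def read_ct(path: str | Path) -> list[SecondaryStructure]:
    """Read a (possibly multi-record) CT file."""
    structures: list[SecondaryStructure] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    k = 0
    while k < len(lines):
        header = lines[k].split()
        try:
            L = int(header[0])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"malformed CT header at line {k + 1}") from exc
        seq_id = header[1] if len(header) > 1 else f"ct_{len(structures)}"
        body = lines[k + 1 : k + 1 + L]
        if len(body) != L:
            raise ValueError(
                f"CT record '{seq_id}' starting at line {k + 1}: "
                f"expected {L} rows, found {len(body)}"
            )
        seq_chars: list[str] = []
        pairs: set[tuple[int, int]] = set()
        for off, ln in enumerate(body):
            fields = ln.split()
            if len(fields) < 6:
                raise ValueError(f"malformed CT row at line {k + 2 + off}")
            seq_chars.append(fields[1])
            j = int(fields[4])
            i = int(fields[0])
            if j > 0 and i < j:
                pairs.add((i - 1, j - 1))
        structures.append(SecondaryStructure(seq_id, "".join(seq_chars), pairs))
        k += 1 + L
    return structures


def write_dotbracket(structure: SecondaryStructure, handle: TextIO) -> None:
    """Write one structure as a FASTA-like record with a dot-bracket line.

    Crossing pairs are rendered with additional bracket layers
    (``<>``, ``[]``, ``{}``, then letter pairs).
    """
    handle.write(f">{structure.id}\n{structure.sequence}\n")
    handle.write(pairs_to_dotbracket(len(structure), structure.pairs) + "\n")


def read_dotbracket(path: str | Path) -> list[SecondaryStructure]:
    """Read records written by :func:`write_dotbracket`."""
    from .structures import parse_wuss

    structures = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    for k in range(0, len(lines), 3):
        if not lines[k].startswith(">"):
            raise ValueError(f"expected '>' header at line {k + 1}")
        seq, db = lines[k + 1], lines[k + 2]
        structures.append(
            SecondaryStructure(lines[k][1:].split()[0], seq, parse_wuss(db))
        )
    return structures


_GF_AC = re.compile(r"^#=GF\s+AC\s+(\S+)")
_GF_ID = re.compile(r"^#=GF\s+ID\s+(\S+)")


def read_stockholm(path: str | Path) -> list[FamilyRecord]:
    """Read one or more Stockholm alignments with ``#=GC SS_cons`` lines.

    Per-sequence structures are obtained by projecting the consensus
    structure onto each ungapped member (dropping pairs that touch gaps
    or are non-canonical in that member).  The family id is taken from
    ``#=GF AC`` (falling back to ``#=GF ID`` or a counter).
    """
    path = Path(path)
    # Family accessions: Bio.AlignIO does not expose GF lines uniformly.
    accessions: list[str] = []
    with open(path) as fh:
        current_ac: str | None = None
        current_id: str | None = None
        for line in fh:
            m = _GF_AC.match(line)
            if m:
                current_ac = m.group(1)
            m = _GF_ID.match(line)
            if m:
                current_id = m.group(1)
            if line.strip() == "//":
                accessions.append(current_ac or current_id or f"family_{len(accessions)}")
                current_ac = current_id = None

    families: list[FamilyRecord] = []
    with open(path) as fh:
        for idx, aln in enumerate(AlignIO.parse(fh, "stockholm")):
            ss_cons = aln.column_annotations.get("secondary_structure")
            if ss_cons is None:
                raise ValueError(
                    f"alignment {idx} in {path.name} has no #=GC SS_cons line"
                )
            fam_id = accessions[idx] if idx < len(accessions) else f"family_{idx}"
            members = [
                project_consensus(rec.id, str(rec.seq), ss_cons) for rec in aln
            ]
            annotated = sum(
                len(project_consensus(rec.id, str(rec.seq), ss_cons, canonical_only=False).pairs)
                for rec in aln
            )
            families.append(FamilyRecord(fam_id, members, annotated_pair_count=annotated))
    return families
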