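"""Parsers and writers: mutation tokens, FASTA, NCBI ASCII PSSM, TSV.

File-format heavy lifting is delegated to Biopython where a format exists
(FASTA); the NCBI ASCII PSSM dialect and the small TSV conventions are
handled here.  All readers raise :class:`~resvar.errors.InputError` with the
offending token or file named.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .biochem import ConservationProfile, PssmProfile
from .codonspace import CodingDomain, normalize_codon
from .errors import InputError
from .msaprofile import PointMutation

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True)
class CompoundMutation:
    """Two or more point mutations in one clone, order preserved.

    Written ``E255K/T315I``; the order can matter clinically (which
    mutation arose first), so it is never normalised.
    """

    components: tuple[PointMutation, ...]

    def __post_init__(self) -> None:
        if len(self.components) < 2:
            raise InputError("compound mutation needs at least two components")

    @property
    def first(self) -> PointMutation:
        return self.components[0]

    @property
    def second(self) -> PointMutation:
        return self.components[1]

    def __str__(self) -> str:
        return "/".join(str(m) for m in self.components)


def parse_mutation(token: str) -> PointMutation | CompoundMutation:
    """Parse ``T315I`` or ``E255K/T315I`` tokens (1-based positions)."""
    token = token.strip()
    if not token:
        raise InputError("empty mutation token")
    parts = token.split("/")
    parsed = []
    for part in parts:
        match = _MUTATION_RE.match(part)
        if not match:
            raise InputError(
                f"malformed mutation token {part!r} (expected e.g. T315I)"
            )
        wt, pos, mut = match.groups()
        parsed.append(PointMutation(wt=wt, position=int(pos), mut=mut))
    if len(parsed) == 1:
        return parsed[0]
    return CompoundMutation(components=tuple(parsed))


def read_mutations(source: str | Path) -> list[PointMutation | CompoundMutation]:
    """Read mutation tokens from a file (one or more per line) or a string.

    Tokens are separated by whitespace or commas; lines starting with ``#``
    are comments.
    """
    path = Path(source)
    text = path.read_text(encoding="utf-8") if path.is_file() else str(source)
    tokens = []
    for line in text.splitlines() or [text]:
        line = line.split("#", 1)[0]
        tokens.extend(t for t in re.split(r"[\s,]+", line) if t)
    if not tokens:
        raise InputError(f"no mutation tokens found in {source!r}")
    return [parse_mutation(t) for t in tokens]


def read_alignment(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA file into (id, sequence) rows.

    Enforces non-emptiness, unique ids and rectangularity.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    rows = [(rec.id, str(rec.seq)) for rec in records]
    seen = set()
    for rid, _ in rows:
        if rid in seen:
            raise InputError(f"{path}: duplicate sequence id {rid!r}")
        seen.add(rid)
    widths = {len(seq) for _, seq in rows}
    if len(widths) != 1:
        raise InputError(
            f"{path}: ragged alignment (row lengths {sorted(widths)})"
        )
    return rows


def write_alignment(rows: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for rid, seq in rows:
            handle.write(f">{rid}\n{seq}\n")


def read_fasta_nt(path: str | Path) -> tuple[str, str]:
    """Read the single nucleotide FASTA record (id, sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise InputError(f"{path}: expected one CDS record, found {len(records)}")
    return records[0].id, str(records[0].seq).upper().replace("U", "T")


def coding_domain_from_cds(
    cds: str,
    protein_start: int,
    protein_end: int,
    gene_id: str = "",
) -> CodingDomain:
    """Slice a coding sequence into the codons of a protein sub-domain.

    The reading frame starts at codon 1 of the supplied sequence, i.e. the
    first three bases encode protein position 1.
    """
    if protein_start < 1 or protein_end < protein_start:
        raise InputError(
            f"invalid domain coordinates {protein_start}-{protein_end}"
        )
    needed = protein_end * 3
    if len(cds) < needed:
        raise InputError(
            f"{gene_id or 'CDS'}: sequence has {len(cds)} nt, but positions "
            f"up to {protein_end} need {needed}"
        )
    codons = tuple(
        normalize_codon(cds[3 * (p - 1) : 3 * p])
        for p in range(protein_start, protein_end + 1)
    )
    return CodingDomain(
        gene_id=gene_id,
        codons=codons,
        protein_start=protein_start,
        protein_end=protein_end,
    )


def write_tsv(
    records: Iterable[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str],
) -> None:
    """Write records as headered, tab-delimited UTF-8 with '.' decimals."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.DictWriter(
            handle, fieldnames=list(columns), delimiter="\t", lineterminator="\n"
        )
        writer.writeheader()
        for record in records:
            writer.writerow({col: record.get(col, "") for col in columns})


def read_tsv(path: str | Path) -> list[dict[str, str]]:
    with open(path, "r", encoding="utf-8", newline="") as handle:
        return list(csv.DictReader(handle, delimiter="\t"))


# position, wt residue, >=20 integer log-odds (and optionally 20 integer
# frequency percents), then optional float info-content/weight columns
_AA_ROW_RE = re.compile(
    r"^\s*(\d+)\s+([A-Za-z])((?:\s+-?\d+)+)(?:\s+-?\d*\.\d+)*\s*$"
)


def read_pssm(path: str | Path, domain_id: str = "") -> PssmProfile:
    """Parse an NCBI ASCII PSSM (as written by ``psiblast -out_ascii_pssm``).

    The dialect: free-form header lines, then a line naming 20 residue
    columns (twice when observed frequency percentages are included), then
    one row per position: index, wild-type residue, 20 log-odds integers and
    optionally 20 frequency percentages (trailing information-content and
    weight columns are ignored).
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    residue_order: list[str] | None = None
    scores: dict[int, dict[str, float]] = {}
    freqs: dict[int, dict[str, float]] = {}
    wt: dict[int, str] = {}
    for line in lines:
        fields = line.split()
        if (
            residue_order is None
            and len(fields) >= 20
            and all(len(f) == 1 and f.isalpha() for f in fields[:20])
        ):
            residue_order = [f.upper() for f in fields[:20]]
            continue
        match = _AA_ROW_RE.match(line)
        if not match or residue_order is None:
            continue
        position = int(match.group(1))
        values = [float(v) for v in match.group(3).split()]
        if len(values) < 20:
            raise InputError(
                f"{path}: position {position} has only {len(values)} score columns"
            )
        wt[position] = match.group(2).upper()
        scores[position] = dict(zip(residue_order, values[:20]))
        if len(values) >= 40:
            freqs[position] = dict(zip(residue_order, values[20:40]))
    if not scores:
        raise InputError(f"{path}: no PSSM rows recognised")
    return PssmProfile(
        scores=scores,
        wt=wt,
        frequencies=freqs or None,
        domain_id=domain_id,
    )


def read_conservation(path: str | Path, source: str = "") -> ConservationProfile:
    """Read a (position, score[, grade]) conservation TSV; grades are ignored."""
    scores: dict[int, float] = {}
    for i, row in enumerate(Path(path).read_text(encoding="utf-8").splitlines()):
        fields = row.strip().split("\t")
        if not row.strip() or row.lstrip().startswith("#"):
            continue
        if i == 0 and not _is_number(fields[0]):
            continue  # header line
        if len(fields) < 2:
            raise InputError(f"{path}: malformed conservation row {row!r}")
        position = int(fields[0])
        if position in scores:
            raise InputError(f"{path}: duplicate position {position}")
        scores[position] = float(fields[1])
    if not scores:
        raise InputError(f"{path}: no conservation scores found")
    return ConservationProfile(scores=scores, source=source or str(path))


def _is_number(text: str) -> bool:
    try:
        float(text)
    except ValueError:
        return False
    return True
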