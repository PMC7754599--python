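"""Sequence and repeat-annotation I/O.

All coordinates exposed by this package are 0-based half-open on the query
sequence.  RepeatMasker ``.out`` files use 1-based inclusive coordinates and a
``C`` flag for minus-strand hits; conversion happens only at the format
boundary.  Soft-masked (lower-case) residues are upper-cased on read; masking
state is not preserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

REPEAT_CLASSES = ("SINE", "LINE", "LTR", "DNA", "Helitron", "TR", "Unknown")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    id: str
    description: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class RepeatConsensus:
    """A named repeat consensus with its classification.

    ``is_monomer`` marks tandem-repeat monomers, which are treated as circular
    sequences (arbitrary phase) by downstream homology operations.
    """

    name: str
    repeat_class: str
    superfamily: str
    sequence: str
    is_monomer: bool = False

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(
                f"repeat_class {self.repeat_class!r} not in {REPEAT_CLASSES}"
            )
        if len(self.sequence) < 1:
            raise ValueError(f"consensus {self.name!r} has empty sequence")


@dataclass
class SubstitutionCounts:
    """Transition (P) and transversion (Q) proportions over compared sites."""

    P: float
    Q: float
    n_sites: int

    def __post_init__(self) -> None:
        if self.n_sites == 0 and (self.P or self.Q):
            raise ValueError("P and Q must be 0 when n_sites is 0")
        if self.P + self.Q > 1 + 1e-12:
            raise ValueError("P + Q must not exceed 1")


@dataclass
class AlignedCopy:
    """One repeat copy aligned to its consensus.

    ``start``/``end`` are 0-based half-open on the query; ``bp`` is the number
    of aligned query bases (gaps in the query excluded), so ``bp <= end-start``.
    ``k2p`` is a fraction in [0, 1] or ``None`` when the distance is saturated
    or unknown.
    """

    query_id: str
    start: int
    end: int
    strand: str
    consensus_name: str
    bp: int
    subst: SubstitutionCounts | None = None
    k2p: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad interval [{self.start}, {self.end}) on {self.query_id}"
            )
        if self.bp > self.end - self.start:
            raise ValueError("bp exceeds query span")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.k2p is not None and self.k2p < 0:
            raise ValueError("k2p must be non-negative")


def parse_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into upper-cased records, preserving order.

    Raises ``ValueError`` on duplicate ids.  An empty file yields an empty
    list.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, desc, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def parse_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read FASTQ; qualities are dropped (abundance work is sequence-only)."""
    return [
        SequenceRecord(rec.id, "", str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(records: Iterable[SequenceRecord], path: str | Path, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.residues}\n+\n{quality * len(rec.residues)}\n")


# --- RepeatMasker .out -------------------------------------------------------

def parse_rm_out(path: str | Path) -> list[AlignedCopy]:
    """Parse a 15-column RepeatMasker ``.out`` file.

    Query coordinates are converted from 1-based inclusive to 0-based
    half-open; orientation ``C`` maps to strand ``-``.  The %div column is
    stored as ``k2p`` divided by 100.  Up to three header lines are tolerated
    (detected by non-numeric first field).
    """
    copies: list[AlignedCopy] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if not fields[0].lstrip("-").replace(".", "").isdigit():
                continue  # header / banner line
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: expected >=11 fields, got {len(fields)}")
            try:
                div = float(fields[1])
                qbegin = int(fields[5])
                qend = int(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate field: {exc}") from exc
            strand = "-" if fields[8] == "C" else "+"
            name = fields[9]
            start, end = qbegin - 1, qend
            copies.append(
                AlignedCopy(
                    query_id=fields[4],
                    start=start,
                    end=end,
                    strand=strand,
                    consensus_name=name,
                    bp=end - start,
                    k2p=div / 100.0,
                )
            )
    return copies


def write_rm_out(copies: Sequence[AlignedCopy], path: str | Path) -> None:
    """Write copies back out in the 15-column ``.out`` layout (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW   perc perc perc  query     position in query    matching repeat\n"
            "score   div. del. ins.  sequence  begin end   (left)   repeat class/family\n"
            "\n"
        )
        for c in copies:
            div = 0.0 if c.k2p is None else c.k2p * 100.0
            orient = "C" if c.strand == "-" else "+"
            fh.write(
                f"  {0:>5d} {div:5.1f}  0.0  0.0  {c.query_id}  {c.start + 1} {c.end} (0) "
                f"{orient} {c.consensus_name} Unknown (0) 1 {c.bp} 1\n"
            )


# --- RepeatMasker .align -----------------------------------------------------

def parse_rm_align(
    path: str | Path,
) -> list[tuple[AlignedCopy, str, str]]:
    """Parse alignment blocks of a RepeatMasker-style ``.align`` file.

    Each block is a score/header line followed by paired gapped sequence
    lines (query line, then consensus line, possibly in several chunks) and an
    optional ``Kimura`` divergence line.  Returns, per block, the
    :class:`AlignedCopy` plus the gapped query and consensus strings.

    The stated divergence is advisory: K2P is always recomputed from the
    gapped pair downstream, and a warning is logged when the two disagree by
    more than one percentage point.
    """
    from .landscape import count_substitutions, k2p_distance  # cycle-free at call time

    blocks: list[tuple[AlignedCopy, str, str]] = []
    header: list[str] | None = None
    qparts: list[str] = []
    cparts: list[str] = []
    stated_div: float | None = None
    block_index = 0

    def flush() -> None:
        nonlocal header, qparts, cparts, stated_div, block_index
        if header is None:
            return
        block_index += 1
        gq, gc = "".join(qparts), "".join(cparts)
        if not gq or len(gq) != len(gc):
            raise ValueError(
                f"{path}: malformed alignment block {block_index}: "
                f"gapped lengths {len(gq)} != {len(gc)}"
            )
        qbegin, qend = int(header[5]), int(header[6])
        strand = "-" if "C" in header[8:10] else "+"
        name_idx = 9 if strand == "-" else 8
        name = header[name_idx].split("#")[0]
        subst = count_substitutions(gq, gc)
        k2p = k2p_distance(subst)
        if stated_div is not None and k2p is not None:
            if abs(k2p * 100.0 - stated_div) > 1.0:
                log.warning(
                    "block %d: stated divergence %.2f%% differs from recomputed "
                    "K2P %.2f%%; recomputed value wins",
                    block_index,
                    stated_div,
                    k2p * 100.0,
                )
        bp = sum(1 for ch in gq if ch != "-")
        copy = AlignedCopy(
            query_id=header[4],
            start=qbegin - 1,
            end=qend,
            strand=strand,
            consensus_name=name,
            bp=bp,
            subst=subst,
            k2p=k2p,
        )
        blocks.append((copy, gq, gc))
        header, qparts, cparts, stated_div = None, [], [], None

    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split()
            first_numeric = fields[0].lstrip("-").isdigit()
            if first_numeric and len(fields) >= 12:
                flush()
                header = fields
            elif stripped.startswith("Kimura"):
                stated_div = float(fields[-1])
            elif header is not None and len(fields) >= 3 and not first_numeric:
                # sequence chunk: [C] name begin SEQ end
                seq_field = fields[-2]
                if fields[0] == "C":
                    owner = fields[1]
                else:
                    owner = fields[0]
                if owner == header[4] and len(qparts) == len(cparts):
                    qparts.append(seq_field.upper())
                else:
                    cparts.append(seq_field.upper())
            elif stripped.startswith(("Matrix", "Transitions", "Gap_init")):
                continue
        if header is not None and len(qparts) != len(cparts):
            raise ValueError(f"{path}: truncated final block {block_index + 1}")
        flush()
    return blocks


def write_rm_align(blocks: Sequence[tuple[AlignedCopy, str, str]], path: str | Path) -> None:
    """Write alignment blocks in the dialect :func:`parse_rm_align` reads."""
    with open(path, "w") as fh:
        for copy, gq, gc in blocks:
            div = 0.0 if copy.k2p is None else copy.k2p * 100.0
            if copy.strand == "-":
                tail = f"C {copy.consensus_name}#Unknown (0) {len(gc)} 1 m_b1"
            else:
                tail = f"{copy.consensus_name}#Unknown 1 {len(gc)} (0) m_b1"
            fh.write(
                f"100 {div:.2f} 0.00 0.00 {copy.query_id} "
                f"{copy.start + 1} {copy.end} (0) {tail}\n\n"
            )
            width = 50
            for i in range(0, len(gq), width):
                fh.write(f"  {copy.query_id:<20s} {copy.start + 1 + i:>8d} {gq[i:i+width]} 0\n")
                fh.write(f"  {copy.consensus_name:<20s} {1 + i:>8d} {gc[i:i+width]} 0\n")
            fh.write(f"\nKimura (with divCpGMod): {div:.2f}\n\n")


# --- generic TSV tables ------------------------------------------------------

def write_table(
    rows: Sequence[dict],
    path: str | Path,
    dialect: str = "tsv",
    fieldnames: Sequence[str] | None = None,
) -> None:
    """Write homogeneous records as a TSV with a header row.

    With zero rows the header is taken from ``fieldnames`` (header-only
    file).  Fields containing a tab raise (there is no quoting dialect).
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    with open(path, "w") as fh:
        if not rows:
            if fieldnames:
                fh.write("\t".join(fieldnames) + "\n")
            return
        keys = list(fieldnames) if fieldnames else list(rows[0].keys())
        fh.write("\t".join(keys) + "\n")
        for row in rows:
            if list(row.keys()) != keys:
                raise ValueError("heterogeneous records")
            values = []
            for k in keys:
                v = row[k]
                s = repr(v) if isinstance(v, float) else str(v)
                if "\t" in s:
                    raise ValueError(f"field {k!r} contains a tab; no quoting dialect")
                values.append(s)
            fh.write("\t".join(values) + "\n")


def read_table(path: str | Path) -> list[dict]:
    """Read a TSV written by :func:`write_table`, restoring int/float types."""
    rows: list[dict] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return rows
    keys = lines[0].split("\t")
    for line in lines[1:]:
        values = line.split("\t")
        row = {}
        for k, v in zip(keys, values):
            row[k] = _coerce(v)
        rows.append(row)
    return rows


def _coerce(s: str):
    for cast in (int, float):
        try:
            v = cast(s)
        except ValueError:
            continue
        if cast is float and not math.isfinite(v):
            return s
        return v
    if s == "True":
        return True
    if s == "False":
        return False
    return s
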