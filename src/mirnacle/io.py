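"""Readers and writers for the standard formats used by the toolkit.

FASTA in/out (gzip-transparent), GFF3/BED6 prediction output, BED truth
intervals, structure FASTA (sequence + dot-bracket), and a minimal ARFF
reader/writer for training sets.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, List, Sequence, Tuple, Union

from Bio import SeqIO

from .errors import InvalidInputError
from .pairing_matrix import RNASequence, normalize_residues

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: PathLike) -> List[RNASequence]:
    """Read a (possibly gzipped) multi-record FASTA file.

    T is mapped to U; IUPAC ambiguity codes are rejected with an error that
    names the offending record and position.
    """
    records = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            residues = normalize_residues(str(rec.seq), record_id=rec.id)
            if not residues:
                raise InvalidInputError(f"record {rec.id!r}: empty sequence")
            records.append(RNASequence(id=rec.id, residues=residues))
    if not records:
        raise InvalidInputError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: Iterable[RNASequence], path: PathLike, width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for seq in seqs:
            out.write(f">{seq.id}\n")
            for k in range(0, len(seq.residues), width):
                out.write(seq.residues[k : k + width] + "\n")


def write_structure_fasta(
    records: Iterable[Tuple[str, str, str]], path: PathLike
) -> None:
    """Write (id, sequence, dot-bracket) records: two lines per record under
    the header, sequence then structure."""
    with _open_text(path, "wt") as out:
        for rec_id, residues, structure in records:
            out.write(f">{rec_id}\n{residues}\n{structure}\n")


# ---------------------------------------------------------------------------
# Interval formats


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "+"

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    def __len__(self) -> int:
        return self.end - self.start


def read_bed(path: PathLike) -> List[Interval]:
    """Read BED3/BED6 intervals (0-based half-open)."""
    out: List[Interval] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InvalidInputError(f"malformed BED line: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "+"
            out.append(Interval(chrom, start, end, name, score, strand))
    return out


def write_bed(intervals: Sequence[Interval], path: PathLike) -> None:
    """Write intervals as BED6 (0-based half-open)."""
    with _open_text(path, "wt") as out:
        for iv in intervals:
            out.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                f"{iv.score:.4f}\t{iv.strand}\n"
            )


def write_gff3(intervals: Sequence[Interval], path: PathLike, source: str = "mirnacle") -> None:
    """Write predictions as GFF3 (1-based closed coordinates, type
    ``pre_miRNA``, score = probability)."""
    with _open_text(path, "wt") as out:
        out.write("##gff-version 3\n")
        for k, iv in enumerate(intervals, start=1):
            attrs = f"ID={iv.name if iv.name != '.' else f'pre_miRNA_{k}'}"
            out.write(
                f"{iv.chrom}\t{source}\tpre_miRNA\t{iv.start + 1}\t{iv.end}\t"
                f"{iv.score:.4f}\t{iv.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: PathLike) -> List[Interval]:
    """Read GFF3 features back as 0-based half-open intervals."""
    out: List[Interval] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise InvalidInputError(f"malformed GFF3 line: {line!r}")
            chrom, _src, _type, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
            score = 0.0 if parts[5] == "." else float(parts[5])
            strand = parts[6] if parts[6] in "+-" else "+"
            name = "."
            if len(parts) > 8:
                for field in parts[8].split(";"):
                    if field.startswith("ID="):
                        name = field[3:]
            out.append(Interval(chrom, int(start) - 1, int(end), name, score, strand))
    return out


# ---------------------------------------------------------------------------
# ARFF (numeric attributes + nominal class attribute last)


def write_arff(
    path: PathLike,
    relation: str,
    attribute_names: Sequence[str],
    rows: Sequence[Sequence[float]],
    labels: Sequence[str],
    classes: Sequence[str] = ("positive", "negative"),
) -> None:
    """Write a numeric ARFF file with the class as the final nominal attribute."""
    if len(rows) != len(labels):
        raise InvalidInputError("rows and labels differ in length")
    with _open_text(path, "wt") as out:
        out.write(f"@RELATION {relation}\n\n")
        for name in attribute_names:
            safe = name.replace(" ", "_")
            out.write(f"@ATTRIBUTE {safe} NUMERIC\n")
        out.write(f"@ATTRIBUTE class {{{','.join(classes)}}}\n\n@DATA\n")
        for row, label in zip(rows, labels):
            out.write(",".join(f"{v:.6g}" for v in row) + f",{label}\n")


def read_arff(path: PathLike) -> Tuple[str, List[str], List[List[float]], List[str]]:
    """Read an ARFF file written by :func:`write_arff`.

    Returns ``(relation, attribute_names, rows, labels)`` where the final
    nominal attribute is treated as the class label.
    """
    relation = ""
    names: List[str] = []
    nominal_seen = False
    rows: List[List[float]] = []
    labels: List[str] = []
    in_data = False
    with _open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            lower = line.lower()
            if not in_data:
                if lower.startswith("@relation"):
                    relation = line.split(None, 1)[1].strip()
                elif lower.startswith("@attribute"):
                    _, name, kind = line.split(None, 2)
                    if kind.strip().startswith("{"):
                        nominal_seen = True
                    else:
                        names.append(name)
                elif lower.startswith("@data"):
                    if not nominal_seen:
                        raise InvalidInputError(
                            "ARFF file lacks a nominal class attribute"
                        )
                    in_data = True
            else:
                parts = line.split(",")
                if len(parts) != len(names) + 1:
                    raise InvalidInputError(f"malformed ARFF data line: {line!r}")
                rows.append([float(v) for v in parts[:-1]])
                labels.append(parts[-1].strip())
    return relation, names, rows, labels
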