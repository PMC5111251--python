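"""Readers and writers for the pipeline's plain-text dialects.

FASTA via Biopython; taxonomy, Δg, annotation and count tables as
tab-separated text; contingency and p-value matrices as CSV. Readers raise
informative errors with line numbers; all writers produce deterministic,
diffable output.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import DifferentialGenus, GenusAnnotation, drop_zero_deltas


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping.

    Raises
    ------
    ValueError
        On duplicate ids or an unparseable file.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"duplicate FASTA id {record.id!r} in {path}")
        out[record.id] = str(record.seq).upper()
    return out


def write_fasta(records: Iterable[tuple[str, str]], dest: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=seq_id, description="") for seq_id, seq in records
    ]
    SeqIO.write(seq_records, str(dest), "fasta")


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read ``seq_id<TAB>domain;phylum;...;species`` lineage lines.

    Comment lines (``#``) and blank lines are skipped.
    """
    out: dict[str, str] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(
                f"{path}, line {lineno}: expected 'seq_id<TAB>lineage', "
                f"got {len(parts)} fields"
            )
        if parts[0] in out:
            raise ValueError(f"{path}, line {lineno}: duplicate id {parts[0]!r}")
        out[parts[0]] = parts[1]
    return out


def read_delta_table(path: str | Path) -> list[DifferentialGenus]:
    """Read a Δg table: ``condition_pair<TAB>genus<TAB>delta`` per line.

    A header line starting with ``condition_pair`` is tolerated. Zero deltas
    are dropped with a log line; non-numeric deltas raise with the line
    number.
    """
    rows: list[tuple[str, str, float]] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if lineno == 1 and parts[0].strip().lower() in ("condition_pair", "pair"):
            continue
        if len(parts) != 3:
            raise ValueError(
                f"{path}, line {lineno}: expected 3 tab-separated fields, "
                f"got {len(parts)}"
            )
        try:
            delta = float(parts[2])
        except ValueError:
            raise ValueError(
                f"{path}, line {lineno}: non-numeric delta {parts[2]!r}"
            ) from None
        rows.append((parts[0].strip(), parts[1].strip(), delta))
    if not rows:
        raise ValueError(f"delta table {path} contains no records")
    return drop_zero_deltas(rows)


def write_delta_table(
    diffs: Iterable[DifferentialGenus], dest: str | Path
) -> None:
    with open(dest, "w", encoding="utf-8") as fh:
        fh.write("condition_pair\tgenus\tdelta\n")
        for d in diffs:
            fh.write(f"{d.condition_pair}\t{d.genus}\t{d.delta:g}\n")


def write_annotations(
    annotations: Iterable[GenusAnnotation], dest: str | Path
) -> None:
    """Write ``condition_pair<TAB>genus<TAB>label<TAB>evidence`` lines."""
    with open(dest, "w", encoding="utf-8") as fh:
        fh.write("condition_pair\tgenus\tlabel\tevidence\n")
        for a in annotations:
            fh.write(
                f"{a.condition_pair}\t{a.genus}\t{a.label}\t"
                f"{','.join(a.evidence)}\n"
            )


def read_annotations(path: str | Path) -> list[GenusAnnotation]:
    out = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    start = 1 if lines and lines[0].startswith("condition_pair\t") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(
                f"{path}, line {lineno}: expected 4 fields, got {len(parts)}"
            )
        evidence = tuple(s for s in parts[3].split(",") if s)
        out.append(
            GenusAnnotation(
                condition_pair=parts[0], genus=parts[1],
                label=parts[2], evidence=evidence,
            )
        )
    return out


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples × taxa count matrix from tab-separated text.

    First column holds sample ids; remaining columns are taxa. Negative
    entries are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"count matrix {path}: non-numeric entry ({exc})") from None
    if (values.to_numpy() < 0).any():
        bad = values.lt(0).any()
        raise ValueError(
            f"count matrix {path}: negative entries in columns "
            f"{list(values.columns[bad])[:5]}"
        )
    return values


def write_count_matrix(matrix: pd.DataFrame, dest: str | Path) -> None:
    matrix.to_csv(dest, sep="\t", index_label="sample")


def write_species_map_tsv(
    species_map: Mapping[str, set[str]], dest: str | Path
) -> None:
    from .classify import write_species_map

    write_species_map(dict(species_map), dest)
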