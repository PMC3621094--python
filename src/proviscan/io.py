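"""File-format boundaries: FASTA, GFF3, JSON, TSV.

Internally every span is 0-based half-open; GFF3 output converts to 1-based
inclusive at this boundary and nowhere else.
"""
from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def to_gff3_line(seqid: str, ftype: str, span: tuple[int, int], strand: str = "+",
                 source: str = "proviscan", attrs: dict | None = None) -> str:
    start, end = span
    attr_str = ";".join(f"{k}={v}" for k, v in (attrs or {}).items()) or "."
    return "\t".join([seqid, source, ftype, str(start + 1), str(end), ".",
                      strand, ".", attr_str])


def write_gff3(path: str | Path, lines: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in lines:
            fh.write(line + "\n")


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = [_jsonable(v) for v in obj]
        return sorted(items, key=repr) if isinstance(obj, (set, frozenset)) else items
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
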