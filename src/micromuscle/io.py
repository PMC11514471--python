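"""Readers and writers for the formats the pipeline touches.

FASTA and FASTQ go through Biopython.  The GFF3 dialect is the miRBase one:
``miRNA`` records with hairpin-local coordinates and a ``Derives_from``
attribute linking the arm to its hairpin, and ``miRNA_primary_transcript``
records giving each hairpin's genomic locus.  GFF3 coordinates are 1-based
inclusive on disk and converted to 0-based half-open in memory.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

from .core import AnnotationError, HairpinRecord, Locus, MatureAnnotation


def _handle(source) -> TextIO:
    """Accept a path, a file object, or literal text (contains a newline)."""
    if hasattr(source, "read"):
        return source
    s = str(source)
    if "\n" in s or s.startswith(">") or s.startswith("@"):
        return _io.StringIO(s)
    return open(s)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(source) -> dict[str, str]:
    """FASTA id -> sequence (uppercased, U converted to T)."""
    with _handle(source) as fh:
        return {
            rec.id: str(rec.seq).upper().replace("U", "T")
            for rec in SeqIO.parse(fh, "fasta")
        }


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]]) -> str:
    items = records.items() if hasattr(records, "items") else records
    out = []
    for name, seq in items:
        out.append(f">{name}\n{seq}\n")
    return "".join(out)


def read_fastq(source) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (id, sequence, phred qualities) from FASTQ (Phred+33)."""
    with _handle(source) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]


def write_fastq(reads: Iterable[tuple[str, str, int]]) -> str:
    """Reads as (name, sequence, constant phred quality) -> FASTQ text."""
    out = []
    for name, seq, q in reads:
        out.append(f"@{name}\n{seq}\n+\n{chr(33 + q) * len(seq)}\n")
    return "".join(out)


# ---------------------------------------------------------------------------
# Collapsed reads (fastx_collapser dialect)


def write_collapsed_fasta(collapsed: dict[str, int]) -> str:
    out = []
    for k, (seq, count) in enumerate(sorted(collapsed.items(), key=lambda x: (-x[1], x[0])), 1):
        out.append(f">seq{k}_x{count}\n{seq}\n")
    return "".join(out)


def read_collapsed_fasta(source) -> dict[str, int]:
    collapsed: dict[str, int] = {}
    with _handle(source) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            count = int(rec.id.rsplit("_x", 1)[1])
            collapsed[str(rec.seq).upper()] = collapsed.get(str(rec.seq).upper(), 0) + count
    return collapsed


def write_collapsed_tsv(collapsed: dict[str, int]) -> str:
    lines = ["sequence\tcount"]
    for seq, count in sorted(collapsed.items(), key=lambda x: (-x[1], x[0])):
        lines.append(f"{seq}\t{count}")
    return "\n".join(lines) + "\n"


def read_collapsed_tsv(source) -> dict[str, int]:
    collapsed: dict[str, int] = {}
    with _handle(source) as fh:
        header = fh.readline()
        if not header.startswith("sequence"):
            raise ValueError("collapsed TSV must have a 'sequence\\tcount' header")
        for line in fh:
            if line.strip():
                seq, count = line.rstrip("\n").split("\t")
                collapsed[seq.upper()] = collapsed.get(seq.upper(), 0) + int(count)
    return collapsed


# ---------------------------------------------------------------------------
# GFF3 (miRBase dialect)


def _fmt_attrs(**attrs: str) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items() if v is not None)


def write_gff3(hairpins: Iterable[HairpinRecord]) -> str:
    lines = ["##gff-version 3"]
    for h in hairpins:
        if h.locus is not None:
            lines.append(
                "\t".join(
                    [
                        h.locus.chrom,
                        "micromuscle",
                        "miRNA_primary_transcript",
                        str(h.locus.start + 1),
                        str(h.locus.start + len(h.sequence)),
                        ".",
                        h.locus.strand,
                        ".",
                        _fmt_attrs(ID=h.hairpin_id, Name=h.hairpin_id),
                    ]
                )
            )
        for m in h.matures:
            lines.append(
                "\t".join(
                    [
                        h.hairpin_id,
                        "micromuscle",
                        "miRNA",
                        str(m.start + 1),
                        str(m.end),
                        ".",
                        "+",
                        ".",
                        _fmt_attrs(
                            ID=m.mature_id,
                            Name=m.mature_id,
                            Derives_from=h.hairpin_id,
                            Arm=m.arm,
                        ),
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def _parse_attrs(col: str) -> dict[str, str]:
    out = {}
    for part in col.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_hairpins(fasta_source, gff3_source) -> list[HairpinRecord]:
    """Assemble HairpinRecords from a hairpin FASTA and a miRBase-style GFF3."""
    seqs = read_fasta(fasta_source)
    matures: dict[str, list[MatureAnnotation]] = {hid: [] for hid in seqs}
    loci: dict[str, Locus] = {}
    with _handle(gff3_source) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(f"malformed GFF3 line: {line!r}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attr_col = cols
            attrs = _parse_attrs(attr_col)
            if ftype == "miRNA_primary_transcript":
                loci[attrs["ID"]] = Locus(seqid, strand, int(start) - 1)
            elif ftype == "miRNA":
                hid = attrs.get("Derives_from", seqid)
                if hid not in matures:
                    raise AnnotationError(
                        f"mature {attrs.get('ID')} derives from unknown hairpin {hid}"
                    )
                matures[hid].append(
                    MatureAnnotation(
                        mature_id=attrs["ID"],
                        arm=attrs.get("Arm", "unlabelled"),
                        start=int(start) - 1,
                        end=int(end),
                    )
                )
    return [
        HairpinRecord(hid, seq, matures=matures[hid], locus=loci.get(hid))
        for hid, seq in seqs.items()
    ]
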