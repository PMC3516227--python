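"""FASTA reading/writing on top of Bio.SeqIO.

Species provenance travels in a ``species=`` token inside the FASTA
description, so mixed-species files are supported; a ``source=`` token
carries the record's origin (genomic/est/simulated/consensus).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import AA_ALPHABET, NT_ALPHABET, SequenceRecord, Source

_SPECIES_RE = re.compile(r"\bspecies=(\S+)")
_SOURCE_RE = re.compile(r"\bsource=(\S+)")


def _guess_moltype(residues: str) -> str:
    letters = set(residues.upper())
    if letters <= NT_ALPHABET:
        return "nt"
    if letters <= AA_ALPHABET:
        return "aa"
    raise ValueError(f"residues {sorted(letters - AA_ALPHABET)} fit no alphabet")


def read_fasta(path: str | Path, moltype: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Lowercase residues are uppercased; ``species=``/``source=`` tokens in
    the description populate the provenance fields.  Raises on an empty
    file and on duplicate ids.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise ValueError(f"duplicate record id: {bio.id!r} in {path}")
        seen.add(bio.id)
        desc = bio.description
        if desc.startswith(bio.id):
            desc = desc[len(bio.id):].strip()
        m = _SPECIES_RE.search(desc)
        species = m.group(1) if m else "unknown"
        m = _SOURCE_RE.search(desc)
        source = Source(m.group(1)) if m else Source.GENOMIC
        residues = str(bio.seq).upper()
        records.append(
            SequenceRecord(
                id=bio.id,
                residues=residues,
                description=desc,
                species=species,
                source=source,
                moltype=moltype or _guess_moltype(residues),
            )
        )
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> Path:
    """Write records as FASTA, 60-column wrapped; round-trips with read_fasta."""
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    path = Path(path)
    bios = []
    for rec in records:
        desc = rec.description
        if f"species={rec.species}" not in desc and rec.species != "unknown":
            desc = (desc + f" species={rec.species}").strip()
        if f"source={rec.source.value}" not in desc and rec.source != Source.GENOMIC:
            desc = (desc + f" source={rec.source.value}").strip()
        bios.append(BioSeqRecord(Seq(rec.residues), id=rec.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bios)
    return path


def write_tsv(rows: Iterable[Sequence], header: Sequence[str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path
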