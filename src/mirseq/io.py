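"""File-format helpers: FASTA/FASTQ via Biopython, GMT, ground-truth JSON."""
from __future__ import annotations

import json
from dataclasses import asdict

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import GeneSet

PHRED_OFFSET = 33


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) pairs, preserving file order."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fastq(reads: list[tuple[str, str, list[int]]], path) -> None:
    """Write (id, sequence, phred qualities) triples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            qstring = "".join(chr(q + PHRED_OFFSET) for q in qual)
            fh.write(f"@{name}\n{seq}\n+\n{qstring}\n")


def iter_fastq(path):
    """Yield (id, sequence, phred qualities) from a Phred+33 FASTQ file.

    Raises ValueError naming the offending record on malformed input.
    """
    last_id = "<start of file>"
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            last_id = rec.id
            yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]
    except ValueError as exc:
        raise ValueError(
            f"FASTQ parse failure in {path} after record {last_id!r}: {exc}"
        ) from exc


def write_gmt(gene_sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.set_id, gs.description, *gs.members]) + "\n")


def read_gmt(path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need id, description, members): {line!r}")
            sets.append(GeneSet(parts[0], parts[1], tuple(parts[2:])))
    return sets


def write_ground_truth(ground_truth, path) -> None:
    payload = {
        "de_mirnas": ground_truth.de_mirnas,
        "enriched_sets": ground_truth.enriched_sets,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
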