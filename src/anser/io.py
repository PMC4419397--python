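"""Shared sequence/table readers and writers.

All tables are TSV with a header line; genomic coordinates in files are
0-based half-open. FASTA/FASTQ parsing is delegated to Biopython.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("anser")


def _normalize(seq: str, rna: bool = False) -> str:
    """Upper-case a sequence; optionally convert T->U for RNA inputs."""
    s = seq.upper()
    if s != seq:
        logger.debug("mixed-case sequence normalized to upper case")
    if rna:
        s = s.replace("T", "U")
    return s


def read_fasta(path: str | Path, rna: bool = False) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs.

    Sequences are upper-cased; with ``rna=True`` thymine is rewritten to
    uracil so miRNA inputs may use either alphabet.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return [(rec.id, _normalize(str(rec.seq), rna)) for rec in SeqIO.parse(str(path), "fasta")]


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file into (id, sequence) pairs (qualities discarded)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return [(rec.id, _normalize(str(rec.seq))) for rec in SeqIO.parse(str(path), "fastq")]


def read_sequences(path: str | Path, rna: bool = False) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ based on file suffix (.fq/.fastq -> FASTQ)."""
    p = Path(path)
    if p.suffix.lower() in {".fq", ".fastq"}:
        return read_fastq(p)
    return read_fasta(p, rna=rna)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write reads as FASTQ with a flat maximum quality string."""
    recs = []
    for i, s in records:
        r = SeqRecord(Seq(s), id=i, description="")
        r.letter_annotations["phred_quality"] = [40] * len(s)
        recs.append(r)
    SeqIO.write(recs, str(path), "fastq")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, stage: str, params: dict,
                   inputs: Iterable[str | Path] = ()) -> Path:
    """Write a JSON manifest echoing the resolved parameters and seed.

    Every CLI run emits one so that a result file can always be traced
    back to the exact invocation that produced it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "parameters": {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()},
        "inputs": {str(p): file_sha256(p) for p in inputs if Path(p).exists()},
    }
    path = out_dir / f"{stage}.manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, level.upper()),
                        format="%(levelname)s %(name)s: %(message)s")
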