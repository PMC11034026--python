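"""FASTA and manifest I/O (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .sgt import SequenceRecord

MANIFEST_COLUMNS = ("id", "label", "genome_id", "group", "fold")


def read_fasta(path) -> list[SequenceRecord]:
    """All records of a (multi-)FASTA file, wrapped lines and any case."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    return [SequenceRecord(id=rec.id, bases=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[SequenceRecord], path, width: int = 70) -> None:
    bio = [BioSeqRecord(Seq(r.bases), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_manifest(fragment_set, path) -> None:
    """TSV label manifest: id, label, genome_id, group, fold."""
    rows = [(f.record.id, f.label, f.source_genome_id, f.group, f.fold)
            for f in fragment_set]
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path!r} lacks required columns: {sorted(missing)}")
    return df


def save_matrices(matrices, path, kappa: float) -> None:
    """Archive of pattern matrices keyed by sequence id, kappa in the header."""
    arrays = {f"m{i}": m.weights for i, m in enumerate(matrices)}
    ids = np.array([m.sequence_id for m in matrices])
    with open(path, "wb") as fh:
        np.savez(fh, ids=ids, kappa=np.float64(kappa), **arrays)


def load_matrices(path):
    from .sgt import PatternMatrix
    with np.load(path, allow_pickle=False) as z:
        kappa = float(z["kappa"])
        ids = [str(s) for s in z["ids"]]
        return [PatternMatrix(weights=z[f"m{i}"], kappa=kappa, sequence_id=sid)
                for i, sid in enumerate(ids)]
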