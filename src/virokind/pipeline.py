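"""End-to-end prediction on FASTA input.

Long sequences are cut into non-overlapping windows (default 1,000 bp,
trailing windows shorter than ``min_tail`` dropped), each window is
SGT-encoded at the model's kappa and scored by the classifier, and the
per-window score vectors are combined by a length-weighted average,
renormalized to sum to 1.  The result is one row per input record, in
input order, written as a TSV with fixed-precision scores so repeat
runs are byte-identical.

An optional second pass scores every record with a separately trained
viral-vs-nonviral classifier of the same architecture and flags (or
drops) records whose viral score falls below a threshold.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cnn import TrainedClassifier
from .io import read_fasta
from .sgt import SequenceRecord, encode_batch, sgt_matrix, stack_weights, tokenize_trinucleotides

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1000
DEFAULT_MIN_TAIL = 100

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNUacgtryswkmbdhvnu",
                            "TGCAYRSWMKVHDBNAtgcayrswmkvhdbna")


def reverse_complement(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


def split_windows(seq: SequenceRecord, window: int = DEFAULT_WINDOW,
                  min_tail: int = DEFAULT_MIN_TAIL) -> list[SequenceRecord]:
    """Non-overlapping consecutive windows of ``window`` bases.

    A final shorter window is kept iff its length >= ``min_tail``.  A
    sequence no longer than ``window`` passes through as one window.
    """
    if not window >= min_tail >= 4:
        raise ValueError(f"need window >= min_tail >= 4, got {window}, {min_tail}")
    n = len(seq)
    if n <= window:
        return [seq]
    out = []
    for k, start in enumerate(range(0, n, window)):
        piece = seq.bases[start:start + window]
        if len(piece) < window and len(piece) < min_tail:
            break
        out.append(SequenceRecord(id=f"{seq.id}|w{k}", bases=piece))
    return out


def aggregate_scores(window_scores, weights) -> np.ndarray:
    """Weighted elementwise mean of score vectors, renormalized to sum 1."""
    s = np.asarray(window_scores, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if s.ndim != 2 or s.shape[0] == 0:
        raise ValueError("aggregate_scores needs >= 1 score vector")
    if w.shape != (s.shape[0],):
        raise ValueError("one weight per score vector required")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    agg = (s * w[:, None]).sum(axis=0) / w.sum()
    return agg / agg.sum()


def _score_record(seq: SequenceRecord, model: TrainedClassifier,
                  window: int, min_tail: int, rc_average: bool):
    """(scores, n_windows, flags) for one record."""
    cfg = model.config
    pieces = split_windows(seq, window=window, min_tail=min_tail)
    tracks = [tokenize_trinucleotides(p) for p in pieces]
    usable = [len(t) >= 2 for t in tracks]
    if not any(usable):
        u = np.full(cfg.n_classes, 1.0 / cfg.n_classes)
        return u, len(pieces), "low_information"
    mats, lens = [], []
    for p, t, ok in zip(pieces, tracks, usable):
        if not ok:
            continue
        mats.append(sgt_matrix(t, kappa=cfg.kappa, sequence_id=p.id).weights)
        lens.append(len(p))
    x = np.asarray(mats, dtype=np.float32)
    probs = model.predict_proba(x).astype(np.float64)
    if rc_average:
        rc = [SequenceRecord(p.id + "|rc", reverse_complement(p.bases))
              for p, ok in zip(pieces, usable) if ok]
        rc_mats = stack_weights(encode_batch(rc, kappa=cfg.kappa))
        probs = (probs + model.predict_proba(rc_mats).astype(np.float64)) / 2.0
    return aggregate_scores(probs, lens), len(pieces), ""


def predict_records(records: list[SequenceRecord], model: TrainedClassifier,
                    window: int = DEFAULT_WINDOW, min_tail: int = DEFAULT_MIN_TAIL,
                    rc_average: bool = False) -> pd.DataFrame:
    """Score table for a list of records (one row each, input order)."""
    names = list(model.class_names)
    rows = []
    for seq in records:
        scores, n_win, flags = _score_record(seq, model, window, min_tail, rc_average)
        pred = names[int(np.argmax(scores))]
        if scores.max() == scores.min():
            logger.info("record %r: tied scores; predicting %r", seq.id, pred)
        row = {"seq_id": seq.id, "length": len(seq), "n_windows": n_win}
        for name, s in zip(names, scores):
            row[f"score_{name}"] = float(s)
        row["predicted_label"] = pred
        row["flags"] = flags
        rows.append(row)
    return pd.DataFrame(rows)


def write_score_table(table: pd.DataFrame, path, model: TrainedClassifier) -> None:
    """Deterministic TSV: header comment names the classes and kappa."""
    with open(path, "w") as fh:
        fh.write(f"# classes={','.join(model.class_names)} kappa={model.config.kappa:g} "
                 f"format=1\n")
        out = table.copy()
        for c in out.columns:
            if c.startswith("score_"):
                out[c] = out[c].map(lambda v: f"{v:.6f}")
        out.to_csv(fh, sep="\t", index=False)


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def predict_fasta(fasta_path, weights_path, out_path=None,
                  window: int = DEFAULT_WINDOW, min_tail: int = DEFAULT_MIN_TAIL,
                  rc_average: bool = False,
                  filter_model_path=None, filter_threshold: float = 0.5,
                  drop_nonviral: bool = False) -> pd.DataFrame:
    """Split -> encode -> classify -> aggregate for every FASTA record.

    Returns the score table (and writes it as TSV when ``out_path`` is
    given).  With ``filter_model_path`` set, a viral-vs-nonviral model
    flags records whose viral score is below ``filter_threshold``.
    """
    model = TrainedClassifier.load(weights_path)
    records = read_fasta(fasta_path)
    if not records:
        logger.warning("empty FASTA %r: writing empty score table", str(fasta_path))
        cols = (["seq_id", "length", "n_windows"]
                + [f"score_{n}" for n in model.class_names]
                + ["predicted_label", "flags"])
        table = pd.DataFrame(columns=cols)
    else:
        table = predict_records(records, model, window=window, min_tail=min_tail,
                                rc_average=rc_average)
    if filter_model_path is not None:
        table = filter_nonviral(table, filter_model_path, filter_threshold,
                                records=records, window=window, min_tail=min_tail,
                                drop=drop_nonviral)
    if out_path is not None:
        write_score_table(table, out_path, model)
    return table


def filter_nonviral(table: pd.DataFrame, filter_model_path, threshold: float,
                    records: list[SequenceRecord] | None = None, fasta_path=None,
                    window: int = DEFAULT_WINDOW, min_tail: int = DEFAULT_MIN_TAIL,
                    drop: bool = False) -> pd.DataFrame:
    """Flag (or drop) rows whose viral score is below ``threshold``.

    The filter model is a viral-vs-nonviral classifier of the same
    architecture (class index 0 = viral).  Sequences are re-scored from
    ``records`` or ``fasta_path``.
    """
    if records is None:
        if fasta_path is None:
            raise ValueError("filter_nonviral needs records or fasta_path")
        records = read_fasta(fasta_path)
    fmodel = TrainedClassifier.load(filter_model_path)
    ftab = predict_records(records, fmodel, window=window, min_tail=min_tail)
    viral = ftab.set_index("seq_id")[f"score_{fmodel.class_names[0]}"]
    table = table.copy()
    below = table["seq_id"].map(viral) < threshold
    n = int(below.sum())
    if n:
        logger.info("nonviral filter: %d of %d records below %.3g", n, len(table), threshold)
    if drop:
        return table[~below].reset_index(drop=True)
    flags = table["flags"].fillna("").astype(str)
    flagged = np.where(below, np.where(flags == "", "nonviral", flags + ";nonviral"), flags)
    table["flags"] = flagged
    return table
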