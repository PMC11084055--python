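"""Clinical-note risk scoring: cleaning, chunking, and probability aggregation.

Long per-case note text is split into fixed-length subsequences ("chunks"),
each chunk is scored by a pluggable classifier, and the chunk probabilities
are combined into a single case-level risk score

    P_final = (P_max + P_mean * n/C) / (1 + n/C)

where ``n`` is the number of chunks and the scaling factor ``C`` controls how
strongly the mean pulls the aggregate away from the max as documents grow.
P_final is a convex combination of P_max and P_mean with weights
``1/(1 + n/C)`` and ``(n/C)/(1 + n/C)``.

The chunk scorer abstracts the study's fine-tuned clinical transformer behind
a fit/score contract; the packaged default is a hashed bag-of-words logistic
model trained on chunk-level labels inherited from the case label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import HashingVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score

MIN_NOTE_CHARS = 200
MAX_CHUNK_UNITS = 512
#: Candidate scaling factors: 1 to 100 in steps of 0.5 (199 values).
DEFAULT_C_GRID = tuple(np.arange(1.0, 100.5, 0.5))

_SPECIAL_RUNS = re.compile(r"[=_-]{2,}")
_WS_RUNS = re.compile(r"\s+")


@dataclass(frozen=True)
class NoteAggregate:
    """Chunk-probability aggregate for one case."""

    case_id: str
    n: int
    p_max: float
    p_mean: float
    c: float
    p_final: float


class ChunkScorer(Protocol):
    """Scores text chunks with endpoint probabilities; deterministic after
    fit for a given seed."""

    def fit(self, chunks: Sequence[str], labels: Sequence[int]) -> "ChunkScorer": ...

    def score(self, chunks: Sequence[str]) -> np.ndarray: ...


def clean_text(text: str) -> str:
    """Remove runs of '=', '_' or '-' and collapse whitespace runs."""
    return _WS_RUNS.sub(" ", _SPECIAL_RUNS.sub("", text)).strip()


def preprocess_notes(notes: pd.DataFrame, *,
                     min_chars: int = MIN_NOTE_CHARS) -> pd.DataFrame:
    """Clean and aggregate notes into one text per case.

    Per case: exact-duplicate texts are removed, notes shorter than
    ``min_chars`` characters are dropped, each note is cleaned (special-
    character runs removed, whitespace runs collapsed to single spaces), and
    the survivors are concatenated in descending recency — the most recent
    note first. Cases with no surviving notes are absent from the result.

    Parameters
    ----------
    notes : frame with columns case_id, datetime, text.
    """
    if notes.empty:
        return pd.DataFrame(columns=["case_id", "text", "n_notes"])
    df = notes.drop_duplicates(subset=["case_id", "text"], keep="first")
    df = df.loc[df["text"].str.len() >= min_chars]
    df = df.sort_values(["case_id", "datetime"], ascending=[True, False],
                        kind="stable")
    cleaned = df["text"].map(clean_text)
    grouped = (pd.DataFrame({"case_id": df["case_id"], "clean": cleaned})
               .groupby("case_id", sort=True)["clean"])
    return pd.DataFrame({
        "case_id": grouped.apply(" ".join).index,
        "text": grouped.apply(" ".join).to_numpy(),
        "n_notes": grouped.size().to_numpy(),
    })


def chunk_text(text: str, max_units: int = MAX_CHUNK_UNITS) -> list[str]:
    """Split text into ceil(units / max_units) contiguous chunks of
    whitespace tokens, order preserved; the final short chunk is kept."""
    if not text:
        raise ValueError("cannot chunk empty text")
    tokens = text.split()
    return [" ".join(tokens[i:i + max_units])
            for i in range(0, len(tokens), max_units)]


def aggregate_chunk_scores(probs: Sequence[float], c: float) -> float:
    """Aggregate chunk probabilities: (P_max + P_mean·(n/C)) / (1 + n/C)."""
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("cannot aggregate an empty probability sequence")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("chunk probabilities must lie in [0, 1]")
    if c <= 0:
        raise ValueError("scaling factor C must be positive")
    n = probs.size
    ratio = n / c
    return float((probs.max() + probs.mean() * ratio) / (1.0 + ratio))


class HashedBagOfWordsScorer:
    """Default chunk scorer: hashed bag-of-words + logistic regression.

    Chunk-level training labels are inherited from the case-level endpoint
    (every chunk of a positive case is labelled positive). Stands behind the
    ChunkScorer contract so any stronger scorer can be dropped in.
    """

    def __init__(self, n_features: int = 2**16, seed: int = 0, C: float = 1.0):
        self._vec = HashingVectorizer(n_features=n_features, alternate_sign=False,
                                      norm="l2")
        self._clf = LogisticRegression(C=C, max_iter=1000, random_state=seed)
        self.seed = seed

    def fit(self, chunks: Sequence[str], labels: Sequence[int]):
        x = self._vec.transform(chunks)
        self._clf.fit(x, np.asarray(labels))
        return self

    def score(self, chunks: Sequence[str]) -> np.ndarray:
        x = self._vec.transform(chunks)
        return self._clf.predict_proba(x)[:, 1]


def score_cases(processed: pd.DataFrame, scorer: ChunkScorer,
                c: float, max_units: int = MAX_CHUNK_UNITS) -> pd.DataFrame:
    """Chunk, score and aggregate each case's text.

    Returns a frame (case_id, n, p_max, p_mean, p_final) — the per-case NLP
    risk score table.
    """
    case_ids, all_chunks, spans = [], [], []
    for rec in processed.itertuples(index=False):
        chunks = chunk_text(rec.text, max_units)
        spans.append((len(all_chunks), len(all_chunks) + len(chunks)))
        all_chunks.extend(chunks)
        case_ids.append(rec.case_id)
    probs = scorer.score(all_chunks) if all_chunks else np.empty(0)
    rows = []
    for cid, (lo, hi) in zip(case_ids, spans):
        p = probs[lo:hi]
        rows.append((cid, hi - lo, float(p.max()), float(p.mean()),
                     aggregate_chunk_scores(p, c)))
    return pd.DataFrame(rows, columns=["case_id", "n", "p_max", "p_mean", "p_final"])


def chunk_probabilities(processed: pd.DataFrame, scorer: ChunkScorer,
                        max_units: int = MAX_CHUNK_UNITS) -> dict[str, np.ndarray]:
    """Per-case chunk probability vectors (inputs to C tuning)."""
    out = {}
    for rec in processed.itertuples(index=False):
        chunks = chunk_text(rec.text, max_units)
        out[rec.case_id] = scorer.score(chunks)
    return out


def tune_c(case_probs: dict[str, np.ndarray], labels: pd.Series,
           grid: Sequence[float] = DEFAULT_C_GRID,
           threshold: float = 0.5) -> tuple[float, pd.DataFrame]:
    """Select the scaling factor C maximizing F1 of thresholded P_final.

    The grid is scanned in order; ties break to the smallest C. Returns the
    winning C and the full per-grid F1 report.
    """
    if len(grid) == 0:
        raise ValueError("C grid must be non-empty")
    ids = list(case_probs.keys())
    y = labels.loc[ids].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("F1 is undefined: labels contain a single class")
    p_max = np.array([case_probs[i].max() for i in ids])
    p_mean = np.array([case_probs[i].mean() for i in ids])
    n = np.array([case_probs[i].size for i in ids], dtype=float)
    rows = []
    best_c, best_f1 = None, -np.inf
    for c in grid:
        ratio = n / c
        p_final = (p_max + p_mean * ratio) / (1.0 + ratio)
        f1 = f1_score(y, (p_final >= threshold).astype(int), zero_division=0)
        rows.append((float(c), float(f1)))
        if f1 > best_f1:  # strict: first (smallest) C wins ties
            best_c, best_f1 = float(c), float(f1)
    return best_c, pd.DataFrame(rows, columns=["C", "f1"])


def fit_note_scores(notes: pd.DataFrame, labels: pd.Series,
                    train_case_ids: Sequence[str], *, seed: int = 0,
                    scorer: ChunkScorer | None = None,
                    grid: Sequence[float] = DEFAULT_C_GRID,
                    max_units: int = MAX_CHUNK_UNITS,
                    ) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """End-to-end note scoring: preprocess, train the chunk scorer on the
    training cases, tune C on them, and score every case with notes.

    Returns (scores frame, tuned C, per-grid F1 report). Cases without
    surviving notes are absent from the scores frame; downstream stages
    treat their NLP risk score as a missing feature.
    """
    processed = preprocess_notes(notes)
    train_mask = processed["case_id"].isin(set(train_case_ids))
    train = processed.loc[train_mask]
    if train.empty:
        raise ValueError("no training cases have notes")
    chunks, chunk_labels = [], []
    for rec in train.itertuples(index=False):
        cs = chunk_text(rec.text, max_units)
        chunks.extend(cs)
        chunk_labels.extend([int(labels.loc[rec.case_id])] * len(cs))
    scorer = scorer or HashedBagOfWordsScorer(seed=seed)
    scorer.fit(chunks, chunk_labels)
    train_probs = chunk_probabilities(train, scorer, max_units)
    best_c, report = tune_c(train_probs, labels, grid)
    scores = score_cases(processed, scorer, best_c, max_units)
    return scores, best_c, report
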