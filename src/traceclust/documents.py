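"""Actor-week bag-of-words corpus construction.

The collection of events, with their occurrence counts, performed by one
actor in one calendar week forms one *document*; the vocabulary is the set
of distinct target-action tokens.  The corpus is held as a sparse CSR count
matrix plus a metadata table keyed by (actor_id, year, week).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from traceclust.errors import EmptyCorpusError, VocabularyMismatchError
from traceclust.ingest import WeekedEvent


@dataclass(frozen=True)
class Vocabulary:
    """Ordered, deduplicated token list with a token -> column index map."""

    tokens: tuple[str, ...]
    index: dict[str, int]

    @classmethod
    def from_tokens(cls, tokens) -> "Vocabulary":
        ordered = tuple(sorted(set(tokens)))
        return cls(tokens=ordered, index={t: i for i, t in enumerate(ordered)})

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        tokens = [l for l in Path(path).read_text().splitlines() if l]
        return cls(tokens=tuple(tokens), index={t: i for i, t in enumerate(tokens)})


@dataclass(frozen=True)
class Document:
    """One actor-week with its token counts."""

    actor_id: str
    year: int
    week: int
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


class DocumentCorpus:
    """Sparse actor-week count matrix over a shared vocabulary.

    ``matrix`` is documents x vocabulary (CSR, integer counts); ``meta`` has
    one row per document with columns actor_id, year, week, total, aligned
    with the matrix rows.
    """

    def __init__(self, vocabulary: Vocabulary, matrix: sp.csr_matrix, meta: pd.DataFrame):
        self.vocabulary = vocabulary
        self.matrix = matrix
        self.meta = meta.reset_index(drop=True)

    @property
    def n_documents(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_tokens_total(self) -> int:
        return int(self.matrix.sum())

    def documents(self):
        """Iterate rows as :class:`Document` objects (mainly for inspection)."""
        for i, row in self.meta.iterrows():
            sl = self.matrix.getrow(i).tocoo()
            counts = {
                self.vocabulary.tokens[j]: int(v) for j, v in zip(sl.col, sl.data)
            }
            yield Document(row["actor_id"], int(row["year"]), int(row["week"]), counts)

    def save(self, directory: str | Path) -> None:
        """Write vocabulary (text), counts (MatrixMarket) and metadata (CSV)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.vocabulary.save(directory / "vocabulary.txt")
        scipy.io.mmwrite(directory / "counts.mtx", self.matrix)
        self.meta.to_csv(directory / "documents.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "DocumentCorpus":
        directory = Path(directory)
        vocab = Vocabulary.load(directory / "vocabulary.txt")
        matrix = sp.csr_matrix(scipy.io.mmread(directory / "counts.mtx"))
        meta = pd.read_csv(directory / "documents.csv")
        return cls(vocab, matrix, meta)


def build_vocabulary(
    events: list[WeekedEvent], min_token_count: int = 1
) -> Vocabulary:
    """Distinct event tokens, sorted lexicographically for determinism.

    ``min_token_count`` is a frequency floor (corpus-wide): tokens rarer
    than it are excluded.  The default of 1 applies no floor — raw counts
    are the modeled quantity.
    """
    if not events:
        raise EmptyCorpusError("cannot build a vocabulary from zero events")
    counts = Counter(ev.target_action for ev in events)
    tokens = [t for t, c in counts.items() if c >= min_token_count]
    if not tokens:
        raise EmptyCorpusError("frequency floor removed every token")
    return Vocabulary.from_tokens(tokens)


def build_corpus(events: list[WeekedEvent], vocabulary: Vocabulary) -> DocumentCorpus:
    """Aggregate events into one document per (actor, year, week).

    Token counts are conserved: the sum of all document totals equals the
    number of input events.  Documents are ordered by (actor_id, year,
    week), so construction is invariant to the event order.
    """
    unknown = sorted({ev.target_action for ev in events} - set(vocabulary.tokens))
    if unknown:
        raise VocabularyMismatchError(
            f"{len(unknown)} token(s) not in vocabulary: {unknown[:10]}"
        )
    groups: dict[tuple[str, int, int], Counter] = {}
    for ev in events:
        key = (ev.actor_id, ev.year, ev.week)
        groups.setdefault(key, Counter())[ev.target_action] += 1
    keys = sorted(groups)
    rows, cols, vals = [], [], []
    for i, key in enumerate(keys):
        for tok, c in groups[key].items():
            rows.append(i)
            cols.append(vocabulary.index[tok])
            vals.append(c)
    matrix = sp.csr_matrix(
        (vals, (rows, cols)),
        shape=(len(keys), len(vocabulary)),
        dtype=np.int64,
    )
    meta = pd.DataFrame(
        {
            "actor_id": [k[0] for k in keys],
            "year": [k[1] for k in keys],
            "week": [k[2] for k in keys],
            "total": np.asarray(matrix.sum(axis=1)).ravel().astype(int)
            if keys
            else [],
        }
    )
    return DocumentCorpus(vocabulary, matrix, meta)
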