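"""LDA fitting, BIC scoring and model selection over (K, restart) grids.

Topic models are fit with batch variational Bayes (scikit-learn's
``LatentDirichletAllocation``) under symmetric Dirichlet priors
alpha = eta = 1/K.  Each fit is scored with the Bayesian information
criterion

    BIC = -2 * logL + k * ln(n)

where ``logL`` is the variational lower bound on the corpus log-likelihood
(the fitting algorithm's standard likelihood proxy), ``n`` is the total
token count, and ``k`` counts the free parameters.  By default only the
topic-word parameters are counted, k = K*(V-1): the per-document topic
vectors are latent quantities of the generative model, not free parameters,
and counting them would penalize the document count twice.  The alternative
k = K*(V-1) + D*(K-1) is available via ``bic_param_mode='full'``.

Model selection fits every (n_topics, restart-seed) combination and picks
the minimum-BIC fit automatically; the report keeps every candidate's score
and the top tokens of the best fits so that a human can override the
automatic choice (``force_n_topics``) after inspection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import LatentDirichletAllocation

from traceclust.documents import DocumentCorpus
from traceclust.errors import EmptyCorpusError, VocabularyMismatchError


@dataclass
class LdaFit:
    """A fitted topic model: distributions, likelihood proxy, BIC, seed."""

    n_topics: int
    topic_word: np.ndarray  # (K, V), rows sum to 1
    doc_topic: np.ndarray  # (D, K), rows sum to 1
    log_likelihood: float  # variational lower bound, nats
    seed: int
    bic: float
    vocabulary_tokens: tuple[str, ...] = ()
    model: LatentDirichletAllocation | None = field(default=None, repr=False)

    def top_tokens(self, n: int = 5) -> list[list[str]]:
        """The ``n`` highest-probability tokens of each topic."""
        out = []
        for row in self.topic_word:
            idx = np.argsort(row)[::-1][:n]
            out.append([self.vocabulary_tokens[j] for j in idx])
        return out

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.topic_word, columns=list(self.vocabulary_tokens)).to_csv(
            directory / "topic_word.csv", index_label="topic"
        )


def fit_lda(
    corpus: DocumentCorpus,
    n_topics: int,
    seed: int,
    doc_topic_prior: float | None = None,
    topic_word_prior: float | None = None,
    max_iter: int = 20,
    bic_param_mode: str = "topic_word",
) -> LdaFit:
    """Fit one LDA model with batch variational Bayes; deterministic per seed.

    Priors default to symmetric 1/K.  Warns (but still fits) when
    ``n_topics`` exceeds the number of documents, and when the corpus has a
    single token type, in which case every topic is the point mass on it.
    """
    if corpus.n_documents == 0:
        raise EmptyCorpusError("cannot fit LDA on an empty corpus")
    if n_topics < 2:
        raise ValueError("n_topics must be >= 2")
    if n_topics > corpus.n_documents:
        warnings.warn(
            f"n_topics={n_topics} exceeds the number of documents "
            f"({corpus.n_documents}); the fit is likely degenerate",
            stacklevel=2,
        )
    if len(corpus.vocabulary) == 1:
        warnings.warn(
            "corpus has a single token type; all topics are identical",
            stacklevel=2,
        )
    alpha = doc_topic_prior if doc_topic_prior is not None else 1.0 / n_topics
    eta = topic_word_prior if topic_word_prior is not None else 1.0 / n_topics
    model = LatentDirichletAllocation(
        n_components=n_topics,
        doc_topic_prior=alpha,
        topic_word_prior=eta,
        learning_method="batch",
        max_iter=max_iter,
        random_state=seed,
    )
    X = corpus.matrix
    doc_topic = model.fit_transform(X)
    topic_word = model.components_ / model.components_.sum(axis=1, keepdims=True)
    log_likelihood = float(model.score(X))
    fit = LdaFit(
        n_topics=n_topics,
        topic_word=topic_word,
        doc_topic=doc_topic,
        log_likelihood=log_likelihood,
        seed=seed,
        bic=math.nan,
        vocabulary_tokens=corpus.vocabulary.tokens,
        model=model,
    )
    fit.bic = bic_score(fit, corpus, mode=bic_param_mode)
    return fit


def bic_score(fit: LdaFit, corpus: DocumentCorpus, mode: str = "topic_word") -> float:
    """BIC = -2*logL + k*ln(n) with n = total token count; lower is better.

    ``mode='topic_word'`` uses k = K*(V-1); ``mode='full'`` adds D*(K-1)
    for the per-document topic mixtures.
    """
    if fit.vocabulary_tokens and fit.vocabulary_tokens != corpus.vocabulary.tokens:
        raise VocabularyMismatchError("fit and corpus vocabularies differ")
    K = fit.n_topics
    V = len(corpus.vocabulary)
    D = corpus.n_documents
    if mode == "topic_word":
        k = K * (V - 1)
    elif mode == "full":
        k = K * (V - 1) + D * (K - 1)
    else:
        raise ValueError(f"unknown bic_param_mode {mode!r}")
    n = corpus.n_tokens_total
    if n == 0:
        raise EmptyCorpusError("corpus has zero tokens")
    return -2.0 * fit.log_likelihood + k * math.log(n)


@dataclass
class ModelSelectionReport:
    """Scores of every (n_topics, seed) candidate plus the selected fit."""

    candidates: pd.DataFrame  # columns n_topics, seed, log_likelihood, bic
    selected: LdaFit
    top_tokens: list[list[str]]
    n_best_reported: int = 5

    def best_models(self) -> pd.DataFrame:
        """The lowest-BIC candidates, for human inspection."""
        return self.candidates.head(self.n_best_reported)

    def to_json_dict(self) -> dict:
        return {
            "selected_n_topics": int(self.selected.n_topics),
            "selected_seed": int(self.selected.seed),
            "selected_bic": float(self.selected.bic),
            "top_tokens": self.top_tokens,
            "candidates": self.candidates.to_dict(orient="records"),
        }


def model_selection(
    corpus: DocumentCorpus,
    topic_range=range(10, 21),
    n_inits: int = 50,
    master_seed: int = 0,
    force_n_topics: int | None = None,
    max_iter: int = 20,
    bic_param_mode: str = "topic_word",
    n_top_tokens: int = 5,
) -> ModelSelectionReport:
    """Fit all (K, restart) combinations and select the minimum-BIC model.

    Restart seeds are ``master_seed + i`` for i in 0..n_inits-1, applied per
    topic number.  When ``force_n_topics`` is given, selection is restricted
    to that K (mirroring a human override after inspecting the report) but
    all candidates are still scored.
    """
    topic_range = list(topic_range)
    if not topic_range:
        raise ValueError("topic_range is empty")
    if n_inits < 1:
        raise ValueError("n_inits must be >= 1")
    rows = []
    fits: dict[tuple[int, int], LdaFit] = {}
    for K in topic_range:
        for i in range(n_inits):
            seed = master_seed + i
            fit = fit_lda(
                corpus, K, seed, max_iter=max_iter, bic_param_mode=bic_param_mode
            )
            fits[(K, seed)] = fit
            rows.append(
                {
                    "n_topics": K,
                    "seed": seed,
                    "log_likelihood": fit.log_likelihood,
                    "bic": fit.bic,
                }
            )
    candidates = (
        pd.DataFrame(rows)
        .sort_values(["bic", "n_topics", "seed"], kind="stable")
        .reset_index(drop=True)
    )
    pool = candidates
    if force_n_topics is not None:
        pool = candidates[candidates["n_topics"] == force_n_topics]
        if pool.empty:
            raise ValueError(
                f"force_n_topics={force_n_topics} is not in topic_range {topic_range}"
            )
    best = pool.iloc[0]
    selected = fits[(int(best["n_topics"]), int(best["seed"]))]
    return ModelSelectionReport(
        candidates=candidates,
        selected=selected,
        top_tokens=selected.top_tokens(n_top_tokens),
    )


def assign_topic_distributions(fit: LdaFit, corpus: DocumentCorpus) -> np.ndarray:
    """Per-document topic distributions (rows sum to 1) under a fitted model."""
    if fit.vocabulary_tokens != corpus.vocabulary.tokens:
        raise VocabularyMismatchError("fit and corpus vocabularies differ")
    if fit.model is None:
        raise ValueError("fit does not carry its estimator; refit to assign")
    return fit.model.transform(corpus.matrix)
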