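"""Sentence perplexity from pluggable per-word probability providers.

Perplexity is the exponentiated mean negative log word probability,

    PP = (prod_i p_i) ** (-1/N) = exp(-(1/N) * sum_i ln p_i),

computed in log space; lower perplexity means a more predictable sentence.
Any language model can act as a provider; a small add-k smoothed n-gram
provider is included so the pipeline is testable without a neural model.
An arithmetic-mean variant (1 / mean(p_i)) is available behind a flag for
comparison with the literal "inverse of the mean probability" reading.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SentenceProbabilities",
    "PerplexityScore",
    "perplexity",
    "NgramProvider",
    "ngram_provider",
    "target_word_probability",
    "OOV",
]

OOV = "<unk>"


@dataclass
class SentenceProbabilities:
    """Per-token conditional probabilities for one sentence."""

    tokens: list[str]
    probabilities: np.ndarray
    provider_id: str = "unknown"
    sentence_id: object = None

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.tokens) != len(self.probabilities):
            raise ValueError("one probability per token required")


@dataclass
class PerplexityScore:
    sentence_id: object
    perplexity: float
    log_prob_sum: float
    n_tokens: int


def perplexity(sp: SentenceProbabilities,
               mean: str = "geometric") -> PerplexityScore:
    """Sentence perplexity; ``mean`` selects the geometric (standard) or
    arithmetic variant."""
    p = sp.probabilities
    if p.size < 1:
        raise ValueError("sentence must contain at least one token")
    bad = np.nonzero((p <= 0) | (p > 1))[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"probability out of (0, 1] at token index {i} "
            f"({sp.tokens[i]!r}: {p[i]})"
        )
    logs = np.log(p)
    if mean == "geometric":
        pp = float(np.exp(-logs.mean()))
    elif mean == "arithmetic":
        pp = float(1.0 / p.mean())
    else:
        raise ValueError("mean must be 'geometric' or 'arithmetic'")
    return PerplexityScore(sentence_id=sp.sentence_id, perplexity=pp,
                           log_prob_sum=float(logs.sum()),
                           n_tokens=int(p.size))


def target_word_probability(sp: SentenceProbabilities,
                            target_index: int) -> float:
    """Conditional probability of one token, for the covariate table."""
    if not 0 <= target_index < len(sp.tokens):
        raise IndexError(
            f"target index {target_index} outside sentence of "
            f"{len(sp.tokens)} tokens"
        )
    return float(sp.probabilities[target_index])


class NgramProvider:
    """Add-k smoothed unigram/bigram model over a closed vocabulary + OOV.

    Probabilities are conditional: unigram p(w) or bigram p(w | w_prev) with
    a start-of-sentence context for the first token.  For every context the
    probabilities over vocabulary-plus-OOV sum to one.
    """

    BOS = "<s>"

    def __init__(self, corpus: list[list[str]], order: int = 1,
                 k: float = 1.0):
        if not corpus or all(len(s) == 0 for s in corpus):
            raise ValueError("corpus must contain at least one token")
        if order not in (1, 2):
            raise ValueError("order must be 1 (unigram) or 2 (bigram)")
        if k <= 0:
            raise ValueError("smoothing constant k must be positive")
        self.order = order
        self.k = float(k)
        self.vocab = sorted({w for s in corpus for w in s})
        self.v_size = len(self.vocab) + 1  # + OOV
        self.unigrams = Counter(w for s in corpus for w in s)
        self.n_tokens = sum(self.unigrams.values())
        self.bigrams: Counter = Counter()
        self.context_totals: Counter = Counter()
        if order == 2:
            for s in corpus:
                prev = self.BOS
                for w in s:
                    self.bigrams[(prev, w)] += 1
                    self.context_totals[prev] += 1
                    prev = w

    def _canon(self, w: str) -> str:
        return w if w in self.unigrams or w == self.BOS else OOV

    def word_probability(self, word: str, prev: str | None = None) -> float:
        w = self._canon(word)
        count_w = 0 if w == OOV else self.unigrams[w]
        if self.order == 1:
            return (count_w + self.k) / (self.n_tokens + self.k * self.v_size)
        ctx = self._canon(prev if prev is not None else self.BOS)
        c_pair = self.bigrams[(ctx, word)] if w != OOV else 0
        c_ctx = self.context_totals[ctx]
        return (c_pair + self.k) / (c_ctx + self.k * self.v_size)

    def score(self, tokens: list[str],
              sentence_id: object = None) -> SentenceProbabilities:
        probs = []
        prev = self.BOS
        for w in tokens:
            probs.append(self.word_probability(w, prev=prev))
            prev = w
        return SentenceProbabilities(
            tokens=list(tokens), probabilities=np.array(probs),
            provider_id=f"ngram{self.order}-addk{self.k}",
            sentence_id=sentence_id,
        )


def ngram_provider(corpus: list[list[str]], order: int = 1,
                   k: float = 1.0) -> NgramProvider:
    """Factory for :class:`NgramProvider` (kept for a functional API)."""
    return NgramProvider(corpus, order=order, k=k)
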