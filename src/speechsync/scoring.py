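"""Comprehension scoring: word intelligibility, word order, word-order index.

Intelligibility (experiment-1 style) is the percentage of reference words
present in the response, matched as a case-insensitive, punctuation-stripped
token multiset (each response token can account for at most one reference
token of the same type).  Word-order judgements (experiment-2 style) are
binary.  The control experiment's word-order index is, per item, the
percentage of control participants who guessed the correct order from the
target words alone.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WordOrderTrial",
    "tokenize",
    "score_intelligibility",
    "score_word_order",
    "word_order_index",
]

_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace."""
    return _PUNCT.sub("", text.lower()).split()


def score_intelligibility(reference: str | list[str],
                          response: str | list[str]) -> float:
    """Percent of reference words correctly repeated (multiset matching)."""
    ref = tokenize(reference) if isinstance(reference, str) else [
        w.lower() for w in reference]
    resp = tokenize(response) if isinstance(response, str) else [
        w.lower() for w in response]
    if not ref:
        raise ValueError("reference sentence must contain at least one word")
    ref_c, resp_c = Counter(ref), Counter(resp)
    matched = sum(min(n, resp_c[w]) for w, n in ref_c.items())
    return 100.0 * matched / len(ref)


@dataclass
class WordOrderTrial:
    participant: object
    item: object
    syllabic_rate: float
    target1: str
    target2: str
    true_first: str
    chosen_first: str


def score_word_order(trial: WordOrderTrial) -> int:
    """1 if the word chosen as first matches the true first target."""
    pair = {trial.target1, trial.target2}
    if trial.chosen_first not in pair:
        raise ValueError(
            f"chosen word {trial.chosen_first!r} not among targets {pair}"
        )
    if trial.true_first not in pair:
        raise ValueError(
            f"true first word {trial.true_first!r} not among targets {pair}"
        )
    return int(trial.chosen_first == trial.true_first)


def word_order_index(control_trials: pd.DataFrame) -> pd.DataFrame:
    """Per-item percentage of control participants guessing the order.

    Expects columns ``item`` and ``correct`` (0/1).  Items without
    responses are absent from the output; callers joining the index onto a
    trial table should treat missing items as flagged.
    """
    if not {"item", "correct"}.issubset(control_trials.columns):
        raise ValueError("control trials need 'item' and 'correct' columns")
    g = control_trials.groupby("item")["correct"]
    out = pd.DataFrame({
        "item": g.mean().index,
        "word_order_index": 100.0 * g.mean().to_numpy(float),
        "n_responses": g.size().to_numpy(int),
    })
    if (out["n_responses"] < 1).any():  # pragma: no cover - defensive
        raise ValueError("item with zero responses")
    return out.reset_index(drop=True)


def zscore_index(index: pd.Series | np.ndarray) -> np.ndarray:
    """z-score a word-order index for use as a model covariate."""
    x = np.asarray(index, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd
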