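"""Life-course sentence construction.

A life-course sentence is the chronologically ordered token sequence of one
person's register events.  Construction follows the register conventions:

* codes are normalized and truncated per code system — ICD-10 diagnoses to 4
  characters, ATC medications to 5, SKS procedures to 6; adversity labels
  pass through unchanged,
* events within the same calendar year are randomly shuffled (register
  recording delays make within-year order uninformative),
* tokens with corpus-wide count below ``min_count`` (default 20) are removed
  before sentences are emitted, so training contexts never contain dropped
  tokens.

ICD-10 codes are held internally in undotted form ("G47.3" -> "G473");
:func:`display_code` re-renders the dot for presentation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "truncate_code",
    "display_code",
    "Vocabulary",
    "LifeCourseSentence",
    "build_sentences",
    "sentence_length_distribution",
    "write_corpus",
    "read_corpus",
]

_TRUNCATION = {"diagnosis": 4, "medication": 5, "procedure": 6}


def truncate_code(code: str, system: str) -> str:
    """Normalize and truncate a register code to its system's granularity.

    Diagnoses (ICD-10) keep 4 significant characters after dot removal,
    medications (ATC) 5, procedures (SKS) 6.  Adversity labels are opaque
    and returned unchanged.
    """
    if not code:
        raise ValueError("empty code")
    if system == "adversity":
        return code
    try:
        limit = _TRUNCATION[system]
    except KeyError:
        raise ValueError(f"unknown code system: {system!r}") from None
    return code.replace(".", "")[:limit]


def display_code(token: str, system: str) -> str:
    """Re-render an internal token for display (re-dot ICD-10 diagnoses)."""
    if system == "diagnosis" and len(token) > 3:
        return token[:3] + "." + token[3:]
    return token


@dataclass(frozen=True)
class LifeCourseSentence:
    """Ordered token sequence for one person, with parallel event years."""

    person_id: int
    tokens: tuple[str, ...]
    years: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.years):
            raise ValueError("tokens and years must be parallel")

    def __len__(self) -> int:
        return len(self.tokens)


class Vocabulary:
    """Retained tokens with contiguous indices, corpus counts and systems."""

    def __init__(self, tokens: list[str], counts: list[int], systems: list[str]):
        self.tokens = list(tokens)
        self.counts = list(int(c) for c in counts)
        self.systems = list(systems)
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "token": self.tokens,
                "index": np.arange(len(self.tokens)),
                "count": self.counts,
                "system": self.systems,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_sentences(
    events: pd.DataFrame,
    min_count: int = 20,
    seed: int = 0,
    truncate: bool = True,
) -> tuple[list[LifeCourseSentence], Vocabulary]:
    """Turn an event table into life-course sentences plus the vocabulary.

    Tokens are truncated codes; corpus-wide counts below ``min_count`` are
    filtered before sentence emission.  Per person, tokens are sorted by
    year, with a seed-governed uniform random permutation inside each
    (person, year) block.  Persons with no retained token yield no sentence.
    """
    if events.empty:
        raise ValueError("events table is empty")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")

    df = events[["person_id", "year", "code", "system"]].copy()
    if truncate:
        df["token"] = [truncate_code(c, s) for c, s in zip(df["code"], df["system"])]
    else:
        df["token"] = df["code"].astype(str)

    counts = Counter(df["token"])
    retained = {t for t, c in counts.items() if c >= min_count}
    df = df[df["token"].isin(retained)]

    # Vocabulary ordered by descending count, ties by token string: stable,
    # and the order Huffman coding wants anyway.
    vocab_tokens = sorted(retained, key=lambda t: (-counts[t], t))
    token_system = dict(zip(df["token"], df["system"]))
    vocabulary = Vocabulary(
        vocab_tokens,
        [counts[t] for t in vocab_tokens],
        [token_system[t] for t in vocab_tokens],
    )

    rng = np.random.default_rng(seed)
    sentences: list[LifeCourseSentence] = []
    df = df.sort_values(["person_id", "year"], kind="stable")
    for pid, group in df.groupby("person_id", sort=True):
        tokens: list[str] = []
        years: list[int] = []
        for year, block in group.groupby("year", sort=True):
            block_tokens = list(block["token"])
            perm = rng.permutation(len(block_tokens))
            tokens.extend(block_tokens[i] for i in perm)
            years.extend([int(year)] * len(block_tokens))
        if tokens:
            sentences.append(LifeCourseSentence(int(pid), tuple(tokens), tuple(years)))
    return sentences, vocabulary


def sentence_length_distribution(sentences: list[LifeCourseSentence]) -> dict[int, int]:
    """Exact histogram of sentence lengths (used to justify the window size)."""
    hist: Counter[int] = Counter(len(s) for s in sentences)
    return dict(sorted(hist.items()))


def fraction_within_window(sentences: list[LifeCourseSentence], window: int) -> float:
    """Fraction of sentences fully covered by a symmetric context window."""
    if not sentences:
        return float("nan")
    hist = sentence_length_distribution(sentences)
    total = sum(hist.values())
    covered = sum(n for length, n in hist.items() if length <= window)
    return covered / total


def write_corpus(sentences: list[LifeCourseSentence], path) -> None:
    """One whitespace-delimited line per person (plain-text corpus format)."""
    with open(path, "w") as fh:
        for s in sentences:
            fh.write(" ".join(s.tokens) + "\n")


def read_corpus(path) -> list[list[str]]:
    with open(path) as fh:
        return [line.split() for line in fh if line.strip()]
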