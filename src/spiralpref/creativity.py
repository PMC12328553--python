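"""Divergent-thinking scoring of free associations to spiral prompts.

Participants write free associations to each of two prompts (an Archimedean
and a golden spiral).  Responses are canonicalized (lower-cased, normalized by
a pluggable stemmer/lemmatizer, then merged through a synonym lexicon, e.g.
"snail shell" -> "snail").  Two scores follow:

* fluency: the number of associations a participant produced, and
* originality: the sum of 1/n over their associations, where n is how often
  that association occurs for the same prompt across all participants - a
  unique association contributes 1, a common one little.

Group contrasts use a label-permutation test on the difference in means (exact
enumeration when feasible) and Welch's t with Cohen's d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

Normalizer = Callable[[str], str]


def _default_normalizer(text: str) -> str:
    """Lower-case and collapse whitespace/punctuation; no language model."""
    cleaned = "".join(c if c.isalnum() else " " for c in text.lower())
    return " ".join(cleaned.split())


def canonicalize(
    raw: str,
    lexicon: dict[str, str] | None = None,
    normalizer: Normalizer = _default_normalizer,
) -> str:
    """Reduce a free-text response to its canonical association token.

    The normalizer handles inflection (a stemmer or lemmatizer can be plugged
    in); the lexicon merges semantically equivalent tokens and is applied to a
    fixed point so the mapping is idempotent.
    """
    if raw is None or not str(raw).strip():
        raise ValueError("empty association text")
    token = normalizer(str(raw))
    if not token:
        raise ValueError(f"text {raw!r} normalized to an empty token")
    if lexicon:
        seen = {token}
        while token in lexicon:
            token = normalizer(lexicon[token])
            if token in seen:  # cycle guard
                break
            seen.add(token)
    return token


def canonicalize_records(
    records: pd.DataFrame,
    lexicon: dict[str, str] | None = None,
    normalizer: Normalizer = _default_normalizer,
) -> pd.DataFrame:
    """Add a ``token`` column to a (participant_id, prompt, response) table."""
    required = {"participant_id", "prompt", "response"}
    if not required.issubset(records.columns):
        raise ValueError(f"association table needs columns {sorted(required)}")
    out = records.copy()
    out["token"] = [
        canonicalize(r, lexicon=lexicon, normalizer=normalizer)
        for r in out["response"]
    ]
    return out


def fluency(records: pd.DataFrame, participants=None) -> pd.Series:
    """Association count per participant (0 for listed but silent ones)."""
    counts = records.groupby("participant_id").size()
    if participants is not None:
        counts = counts.reindex(participants, fill_value=0)
    return counts.rename("fluency").astype(int)


def frequency_table(records: pd.DataFrame) -> pd.Series:
    """Occurrences of each (prompt, token) pair across all participants."""
    if "token" not in records.columns:
        raise ValueError("records must be canonicalized first (token column)")
    return records.groupby(["prompt", "token"]).size().rename("n")


def originality_scores(
    records: pd.DataFrame, freq: pd.Series | None = None
) -> pd.DataFrame:
    """Per-participant fluency and originality (sum of 1/n per association).

    Frequencies are per prompt: an association counts as common only among
    responses to the same spiral.
    """
    if freq is None:
        freq = frequency_table(records)
    keys = list(zip(records["prompt"], records["token"]))
    missing = [k for k in keys if k not in freq.index]
    if missing:
        raise ValueError(f"tokens missing from frequency table: {missing[:5]}")
    per_record = np.array([1.0 / freq[k] for k in keys])
    out = (
        pd.DataFrame(
            {
                "participant_id": records["participant_id"],
                "orig": per_record,
            }
        )
        .groupby("participant_id")["orig"]
        .agg(originality="sum", fluency="count")
    )
    return out[["fluency", "originality"]]


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    seed: int | None


def permutation_test(
    values,
    labels,
    b: int = 10_000,
    seed: int | None = None,
    alternative: str = "greater",
    plus_one: bool = False,
) -> PermutationResult:
    """Two-group permutation test on the difference in means.

    The statistic is mean(group 1) - mean(group 2) where groups follow the
    order of first appearance in ``labels``; under ``alternative='greater'``
    the p-value is the proportion of label permutations whose difference is
    >= the observed one.  When the number of distinct label assignments is at
    most ``b``, all of them are enumerated instead of sampling.  ``plus_one``
    applies the (k+1)/(B+1) correction (off by default).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError("exactly two group labels required")
    mask1 = labels == uniq[0]
    n1, n = int(mask1.sum()), len(values)
    if n1 == 0 or n1 == n:
        raise ValueError("both groups must be non-empty")
    sign = {"greater": 1.0, "less": -1.0}.get(alternative)
    if sign is None:
        raise ValueError("alternative must be 'greater' or 'less'")

    def diff(m1: np.ndarray) -> float:
        return values[m1].mean() - values[~m1].mean()

    observed = diff(mask1)
    n_assign = math.comb(n, n1)
    if n_assign <= b:
        diffs = np.array(
            [
                diff(np.isin(np.arange(n), idx))
                for idx in combinations(range(n), n1)
            ]
        )
        k = int(np.sum(sign * diffs >= sign * observed - 1e-12))
        p = (k + plus_one) / (n_assign + plus_one)
        return PermutationResult(observed, float(p), n_assign, True, seed)
    rng = np.random.default_rng(seed)
    # B random label shuffles at once: argsort of uniform noise per row
    perm = np.argsort(rng.random((b, n)), axis=1)
    sums1 = values[perm[:, :n1]].sum(axis=1)
    diffs = sums1 / n1 - (values.sum() - sums1) / (n - n1)
    k = int(np.sum(sign * diffs >= sign * observed - 1e-12))
    p = (k + plus_one) / (b + plus_one)
    return PermutationResult(observed, float(p), b, False, seed)


def welch_t(group_a, group_b) -> tuple[float, float, float, float]:
    """Welch's t with Satterthwaite df, one-sided p (a > b), pooled-SD Cohen d."""
    a = np.asarray(group_a, dtype=float)
    c = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(c) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and c.var(ddof=1) == 0:
        raise ValueError("t undefined: zero variance in both groups")
    res = stats.ttest_ind(a, c, equal_var=False, alternative="greater")
    pooled = math.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(c) - 1) * c.var(ddof=1))
        / (len(a) + len(c) - 2)
    )
    d = (a.mean() - c.mean()) / pooled
    return float(res.statistic), float(res.df), float(res.pvalue), float(d)


def fluency_originality_correlation(scores: pd.DataFrame) -> float:
    """Pearson r between fluency and originality across participants."""
    if len(scores) < 3:
        raise ValueError("need at least 3 participants")
    f = scores["fluency"].astype(float)
    o = scores["originality"].astype(float)
    if f.std() == 0 or o.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(f, o).statistic)
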