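"""Pairwise-choice analyses: preference orders, Borda scores, Bradley-Terry.

Each participant chooses one spiral from each of the three pairs (AR, L1),
(L1, GO), (AR, GO).  A triple of choices either induces a unique transitive
ranking of the three stimuli or is cyclic (intransitive) and is excluded.
Transitive rankings are aggregated two ways:

* Borda-sum rule: 2 / 1 / 0 points per participant for the stimulus preferred
  twice / once / never, summed and normalized by the total points awarded, and
* the Bradley-Terry model P(i beats j) = pi_i / (pi_i + pi_j), fitted by
  maximum likelihood (Zermelo's minorization-maximization iteration) on the
  pairwise win counts, reported as log-abilities anchored at a reference
  stimulus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_STIMULI = ("AR", "L1", "GO")


@dataclass(frozen=True)
class PreferenceOrder:
    participant: object
    ranking: tuple[str, ...] | None  # None marks an intransitive triple

    @property
    def transitive(self) -> bool:
        return self.ranking is not None


def derive_orders(choices: pd.DataFrame) -> tuple[list[PreferenceOrder], list]:
    """Map each participant's choice triple to a ranking; flag cyclic triples.

    ``choices`` must hold columns participant_id, left, right, chosen with one
    row per (participant, unordered pair).  Returns the orders (intransitive
    participants flagged with ranking None) and the exclusion list.
    """
    required = {"participant_id", "left", "right", "chosen"}
    if not required.issubset(choices.columns):
        raise ValueError(f"choices table needs columns {sorted(required)}")
    orders: list[PreferenceOrder] = []
    excluded: list = []
    for pid, rows in choices.groupby("participant_id", sort=True):
        stimuli = sorted(set(rows["left"]) | set(rows["right"]))
        pairs = {frozenset((l, r)) for l, r in zip(rows["left"], rows["right"])}
        expected = {frozenset(p) for p in itertools.combinations(stimuli, 2)}
        if len(rows) != len(expected) or pairs != expected:
            raise ValueError(f"participant {pid!r}: incomplete or duplicated pairs")
        bad = rows[~rows.apply(lambda r: r["chosen"] in (r["left"], r["right"]), axis=1)]
        if len(bad):
            raise ValueError(f"participant {pid!r}: chosen stimulus not in its pair")
        wins = rows["chosen"].value_counts().reindex(stimuli, fill_value=0)
        if sorted(wins) == list(range(len(stimuli))):
            ranking = tuple(wins.sort_values(ascending=False).index)
            orders.append(PreferenceOrder(pid, ranking))
        else:  # cyclic choices: every stimulus wins the same number of times
            orders.append(PreferenceOrder(pid, None))
            excluded.append(pid)
    return orders, excluded


def order_distribution(
    orders: list[PreferenceOrder],
) -> tuple[pd.Series, pd.Series]:
    """Proportions over the six permutations, and first-place (top) shares."""
    rankings = [o.ranking for o in orders if o.transitive]
    if not rankings:
        raise ValueError("no transitive orders")
    stimuli = sorted(rankings[0])
    perms = [" > ".join(p) for p in itertools.permutations(stimuli)]
    counts = pd.Series(0, index=perms, dtype=float)
    for r in rankings:
        counts[" > ".join(r)] += 1
    props = counts / counts.sum()
    top = pd.Series(0.0, index=stimuli)
    for r in rankings:
        top[r[0]] += 1
    return props, top / top.sum()


def borda_scores(orders: list[PreferenceOrder]) -> pd.Series:
    """Normalized Borda-sum score per stimulus.

    Each participant awards 2 points to the stimulus they preferred in both of
    its pairs, 1 to the one preferred once, 0 to the never-preferred one; sums
    are divided by the total points (3 per participant), so scores add to 1.
    """
    if any(not o.transitive for o in orders):
        raise ValueError("intransitive orders must be excluded before Borda scoring")
    if not orders:
        raise ValueError("no orders")
    stimuli = sorted(orders[0].ranking)
    pts = pd.Series(0.0, index=stimuli)
    for o in orders:
        n = len(o.ranking)
        for rank, s in enumerate(o.ranking):
            pts[s] += n - 1 - rank
    return pts / pts.sum()


def pair_counts(
    choices: pd.DataFrame, exclude: list | None = None
) -> pd.DataFrame:
    """Win-count matrix: entry (i, j) is how often i was chosen over j."""
    rows = choices
    if exclude:
        rows = rows[~rows["participant_id"].isin(exclude)]
    stimuli = sorted(set(rows["left"]) | set(rows["right"]))
    w = pd.DataFrame(0, index=stimuli, columns=stimuli, dtype=int)
    for _, r in rows.iterrows():
        loser = r["right"] if r["chosen"] == r["left"] else r["left"]
        w.loc[r["chosen"], loser] += 1
    return w


@dataclass
class BtResult:
    """Bradley-Terry maximum-likelihood abilities, anchored at a reference."""

    abilities: pd.Series  # log-scale lambda, lambda(reference) = 0
    reference: str
    iterations: int
    converged: bool

    def win_probability(self, i: str, j: str) -> float:
        d = self.abilities[i] - self.abilities[j]
        return float(1.0 / (1.0 + np.exp(-d)))


def bt_fit(
    counts: pd.DataFrame,
    reference: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> BtResult:
    """Plain maximum-likelihood Bradley-Terry fit via the Zermelo MM iteration.

    ``counts`` is the square win matrix (wins of row over column).  The
    comparison graph must be connected and no stimulus may have all wins or
    all losses, otherwise the MLE is not identified.
    """
    items = list(counts.index)
    if list(counts.columns) != items:
        raise ValueError("counts must be square with matching index/columns")
    w = counts.to_numpy(dtype=float)
    n = w + w.T  # comparisons per pair
    wins = w.sum(axis=1)
    losses = w.sum(axis=0)
    bad = [items[i] for i in range(len(items)) if wins[i] == 0 or losses[i] == 0]
    if bad:
        raise ValueError(f"no finite MLE: all-or-nothing record for {bad}")
    if not _connected(n > 0):
        raise ValueError("comparison graph is not connected")
    reference = reference if reference is not None else items[0]
    if reference not in items:
        raise ValueError(f"unknown reference {reference!r}")
    pi = np.ones(len(items))
    lam_old = np.zeros(len(items))
    converged = False
    for it in range(1, max_iter + 1):
        denom = (n / (pi[:, None] + pi[None, :]))
        np.fill_diagonal(denom, 0.0)
        pi = wins / denom.sum(axis=1)
        pi /= pi.sum()
        lam = np.log(pi)
        lam -= lam[items.index(reference)]
        if np.max(np.abs(lam - lam_old)) < tol:
            converged = True
            break
        lam_old = lam
    return BtResult(
        abilities=pd.Series(lam, index=items, name="lambda"),
        reference=reference,
        iterations=it,
        converged=converged,
    )


def _connected(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    seen = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in np.nonzero(adj[i])[0]:
            if j not in seen:
                seen.add(int(j))
                frontier.append(int(j))
    return len(seen) == n


def expected_wins(result: BtResult, counts: pd.DataFrame) -> pd.Series:
    """Model-expected total wins per stimulus (score-equation check)."""
    items = list(counts.index)
    lam = result.abilities.reindex(items).to_numpy()
    n = counts.to_numpy(dtype=float) + counts.to_numpy(dtype=float).T
    p = 1.0 / (1.0 + np.exp(-(lam[:, None] - lam[None, :])))
    np.fill_diagonal(p, 0.0)
    return pd.Series((n * p).sum(axis=1), index=items)
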