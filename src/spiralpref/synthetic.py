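"""Synthetic raters, choosers, and association writers.

Every analysis stage can be exercised without the original study data.  The
generators emulate the statistical structure the analyses assume:

* ``gen_ratings`` - three preference groups whose mean rating profiles are
  linear in the stimulus features (width, path length, DCM on their raw
  scales), plus a Gaussian individual intercept and residual noise, clipped
  to the 1-100 rating scale.  Default coefficients are the published
  per-group regression estimates; default group sizes 33/40/45.
* ``gen_choices`` - independent pairwise choices from a Bradley-Terry model;
  intransitive triples arise naturally, as in the study.
* ``gen_associations`` - per-participant association counts are Poisson with
  a group-dependent rate (defaults 3.00 / 4.43 / 5.00 for groups A / L / G),
  split evenly over the two prompts; tokens come from a shared Zipf-like
  vocabulary whose tail exponent differs by group, so that more creative
  groups reach deeper into the rare tail and earn higher originality.

All generators derive independent sub-streams from one master seed
(``numpy.random.SeedSequence(master_seed).spawn``), so each fixture is
bit-reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ratings import GROUP_LABELS

#: published per-group OLS coefficients on (width, path_length, dcm)
DEFAULT_COEFFICIENTS = {
    "A": {"Intercept": 67.6, "width": -0.974, "path_length": 0.364, "dcm": -2.23},
    "L": {"Intercept": 77.2, "width": 4.55, "path_length": -0.642, "dcm": -1.66},
    "G": {"Intercept": 44.4, "width": 0.919, "path_length": -0.456, "dcm": 0.876},
}

#: printed interval-scaled preference scores, used as default abilities
DEFAULT_ABILITIES = {"AR": 0.0, "L1": 0.659, "GO": 0.381}

_SUBSTREAMS = ("ratings", "choices", "associations")


@dataclass
class SynthConfig:
    """Stated world of the generators; field defaults follow the study."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"A": 33, "L": 40, "G": 45}
    )
    coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_COEFFICIENTS.items()}
    )
    # residual and between-rater SDs sized so that, against the fixed-effect
    # spread of the default profiles, roughly 60% of rating variance is
    # residual and ~8% between raters, as in the published decomposition
    residual_sd: float = 16.0
    intercept_sd: float = 6.0
    rating_bounds: tuple[float, float] = (1.0, 100.0)
    abilities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ABILITIES))
    n_choice_participants: int = 79
    fluency_rates: dict[str, float] = field(
        default_factory=lambda: {"A": 3.00, "L": 4.43, "G": 5.00}
    )
    association_group_sizes: dict[str, int] = field(
        default_factory=lambda: {"A": 11, "L": 14, "G": 7}
    )
    vocabulary_size: int = 60
    tail_exponents: dict[str, float] = field(
        default_factory=lambda: {"A": 1.5, "L": 1.1, "G": 0.8}
    )
    prompts: tuple[str, ...] = ("AR", "GO")
    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if self.residual_sd < 0 or self.intercept_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if any(lam <= 0 for lam in self.fluency_rates.values()):
            raise ValueError("fluency rates must be > 0")
        if any(s <= 0 for s in self.tail_exponents.values()):
            raise ValueError("tail exponents must be > 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Named, independent sub-stream of the master seed."""
        children = np.random.SeedSequence(self.master_seed).spawn(len(_SUBSTREAMS))
        return np.random.default_rng(children[_SUBSTREAMS.index(stream)])


def gen_ratings(
    cfg: SynthConfig, features: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Simulate the rating matrix; returns (matrix, true labels, clip rate).

    rating(i, s) = intercept_g + beta_g . features_s + u_i + eps, with
    u_i ~ N(0, intercept_sd^2) and eps ~ N(0, residual_sd^2), clipped to the
    rating bounds.  The clipping rate is returned so callers can verify the
    bounded scale is not distorting the linear structure.
    """
    rng = cfg.rng("ratings")
    stimuli = list(features.index)
    X = features[["width", "path_length", "dcm"]].to_numpy(dtype=float)
    rows, labels, rater_ids = [], [], []
    i = 0
    for g in GROUP_LABELS:
        size = cfg.group_sizes.get(g, 0)
        beta = cfg.coefficients[g]
        profile = beta["Intercept"] + X @ np.array(
            [beta["width"], beta["path_length"], beta["dcm"]]
        )
        for _ in range(size):
            u = rng.normal(0.0, cfg.intercept_sd)
            eps = rng.normal(0.0, cfg.residual_sd, size=len(stimuli))
            rows.append(profile + u + eps)
            labels.append(g)
            rater_ids.append(f"r{i:03d}")
            i += 1
    raw = np.asarray(rows)
    lo, hi = cfg.rating_bounds
    clipped = np.clip(raw, lo, hi)
    clip_rate = float(np.mean(raw != clipped))
    matrix = pd.DataFrame(clipped, index=rater_ids, columns=stimuli)
    matrix.index.name = "rater_id"
    return matrix, pd.Series(labels, index=rater_ids, name="group"), clip_rate


def gen_choices(cfg: SynthConfig) -> pd.DataFrame:
    """Simulate pairwise choices under the Bradley-Terry model.

    Each participant chooses independently on every unordered pair, with
    P(i over j) = exp(lam_i) / (exp(lam_i) + exp(lam_j)); cyclic triples can
    and do occur.
    """
    rng = cfg.rng("choices")
    items = list(cfg.abilities)
    pairs = [(items[i], items[j]) for i in range(len(items)) for j in range(i + 1, len(items))]
    rows = []
    for p in range(cfg.n_choice_participants):
        pid = f"p{p:03d}"
        for left, right in pairs:
            d = cfg.abilities[left] - cfg.abilities[right]
            p_left = 1.0 / (1.0 + np.exp(-d))
            chosen = left if rng.random() < p_left else right
            rows.append((pid, left, right, chosen))
    return pd.DataFrame(rows, columns=["participant_id", "left", "right", "chosen"])


def gen_associations(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate canonical association records; returns (records, labels).

    Counts per (participant, prompt) are Poisson(rate_g / n_prompts); tokens
    are drawn from a rank-frequency power law p(rank) ~ rank^(-s_g) over a
    vocabulary shared across groups, one vocabulary per prompt.
    """
    rng = cfg.rng("associations")
    vocab = {
        prompt: [f"{prompt.lower()}_tok{v:03d}" for v in range(cfg.vocabulary_size)]
        for prompt in cfg.prompts
    }
    ranks = np.arange(1, cfg.vocabulary_size + 1, dtype=float)
    rows, labels, pids = [], [], []
    i = 0
    for g, size in cfg.association_group_sizes.items():
        probs = ranks ** (-cfg.tail_exponents[g])
        probs /= probs.sum()
        lam = cfg.fluency_rates[g] / len(cfg.prompts)
        for _ in range(size):
            pid = f"s{i:03d}"
            pids.append(pid)
            labels.append(g)
            i += 1
            for prompt in cfg.prompts:
                count = rng.poisson(lam)
                for tok_idx in rng.choice(cfg.vocabulary_size, size=count, p=probs):
                    rows.append((pid, prompt, vocab[prompt][tok_idx]))
    records = pd.DataFrame(rows, columns=["participant_id", "prompt", "response"])
    return records, pd.Series(labels, index=pids, name="group")
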