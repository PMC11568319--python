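"""Likert texture-survey statistics and rank correlation with mechanics.

Participants rate each product on a 5-point Likert scale (1 = strongly
disagree, 5 = strongly agree) for twelve texture features. Per-feature
summaries report the per-product mean +/- SD sorted by agreement, with an
across-product Kruskal-Wallis significance flag (a repository convention
for ordinal data; alpha = 0.05). Spearman rank correlation with
tie-averaged ranks links the mechanical stiffness ranking to the perceived
texture rankings; p-values use exact permutation enumeration for n <= 9
and the t-approximation above. The module also scores the two baseline
instruments: the 10-item, 7-point Food Neophobia Survey (totals 10-70) and
the 16-item, 5-point Meat Attachment Questionnaire (totals 16-80), with
reverse-keyed items supplied as configuration rather than hard-coded.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TEXTURE_FEATURES",
    "INSTRUMENTS",
    "LikertTable",
    "FeatureSummary",
    "summarize",
    "rank_with_ties",
    "spearman",
    "instrument_score",
]

TEXTURE_FEATURES = (
    "soft",
    "hard",
    "brittle",
    "chewy",
    "gummy",
    "viscous",
    "springy",
    "sticky",
    "fibrous",
    "fatty",
    "moist",
    "meat-like",
)

#: Baseline instruments: item count, Likert scale maximum, and the
#: conventional reverse-keyed item numbers (1-based; overridable per call).
INSTRUMENTS = {
    "FNS": {"n_items": 10, "scale": (1, 7), "reverse": (1, 4, 6, 9, 10)},
    "MAQ": {"n_items": 16, "scale": (1, 5), "reverse": (6, 9, 11, 16)},
}


@dataclass
class LikertTable:
    """participants x products x features responses, integers 1-5."""

    responses: np.ndarray  # shape (n_participants, n_products, n_features)
    product_ids: tuple[str, ...]
    features: tuple[str, ...] = TEXTURE_FEATURES

    def __post_init__(self) -> None:
        r = np.asarray(self.responses)
        if r.ndim != 3 or r.shape[1] != len(self.product_ids) or r.shape[2] != len(self.features):
            raise ValueError("responses must be participants x products x features")
        if r.size == 0:
            raise ValueError("empty table")
        if not np.issubdtype(r.dtype, np.integer) or r.min() < 1 or r.max() > 5:
            raise ValueError("responses must be integers in 1..5")
        self.responses = r

    @classmethod
    def from_long(cls, df: pd.DataFrame, features: tuple[str, ...] = TEXTURE_FEATURES) -> "LikertTable":
        """Build from a long frame with columns
        participant_id, product_id, feature, score."""
        wide = df.pivot_table(
            index="participant_id", columns=["product_id", "feature"], values="score", aggfunc="first"
        )
        products = tuple(sorted(df["product_id"].unique()))
        arr = np.empty((wide.shape[0], len(products), len(features)), dtype=int)
        for j, p in enumerate(products):
            for k, f in enumerate(features):
                arr[:, j, k] = wide[(p, f)].to_numpy()
        return cls(responses=arr, product_ids=products, features=features)


@dataclass
class FeatureSummary:
    feature: str
    product_ids: tuple[str, ...]  # sorted from highest to lowest agreement
    means: np.ndarray
    sds: np.ndarray
    ranks: np.ndarray  # average ranks of the means, 1 = highest agreement
    significant: bool
    p_value: float


def summarize(table: LikertTable, feature: str, alpha: float = 0.05) -> FeatureSummary:
    """Per-product mean +/- SD of one feature, sorted by agreement, with an
    across-product Kruskal-Wallis significance flag at ``alpha``."""
    if feature not in table.features:
        raise ValueError(f"unknown feature {feature!r}")
    k = table.features.index(feature)
    scores = table.responses[:, :, k]  # participants x products
    means = scores.mean(axis=0)
    sds = scores.std(axis=0, ddof=1) if scores.shape[0] > 1 else np.zeros(means.size)
    groups = [scores[:, j] for j in range(scores.shape[1])]
    if np.ptp(scores) == 0:
        p = 1.0  # identical responses everywhere: nothing to distinguish
    else:
        p = float(stats.kruskal(*groups).pvalue)
    order = np.argsort(-means, kind="stable")
    return FeatureSummary(
        feature=feature,
        product_ids=tuple(table.product_ids[j] for j in order),
        means=means[order],
        sds=sds[order],
        ranks=rank_with_ties(means[order]),
        significant=bool(p < alpha),
        p_value=p,
    )


def rank_with_ties(values) -> np.ndarray:
    """Average ranks in *descending* convention (rank 1 = largest value);
    tied values share the mean of their ranks. Rank sums are n(n+1)/2."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty vector")
    return stats.rankdata(-values, method="average")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise ValueError("constant input; Spearman rho undefined")
    return float(rx @ ry) / denom


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of tie-averaged ranks. For n <=
    ``exact_max_n`` the p-value enumerates all n! orderings of ``y``
    (proportion with |rho| at least the observed, a two-sided exact
    permutation test); larger n uses the usual t-approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-d vectors with n >= 3")
    rx, ry = rank_with_ties(x), rank_with_ties(y)
    rho = _rho_of_ranks(rx, ry)

    n = x.size
    if n <= exact_max_n:
        target = abs(rho) - 1e-12
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_rho_of_ranks(rx, ry[list(perm)])) >= target:
                hits += 1
        p = hits / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, p


def instrument_score(responses, instrument: str, reverse_items=None) -> int:
    """Total score of one participant on a named baseline instrument.

    Reverse-keyed items i are scored as ``(min + max) - response`` on the
    instrument's scale before summation, so totals span the printed ranges
    (FNS 10-70, MAQ 16-80).
    """
    if instrument not in INSTRUMENTS:
        raise ValueError(f"unknown instrument {instrument!r}; known: {sorted(INSTRUMENTS)}")
    inst = INSTRUMENTS[instrument]
    lo, hi = inst["scale"]
    resp = np.asarray(responses)
    if resp.shape != (inst["n_items"],):
        raise ValueError(f"{instrument} expects {inst['n_items']} items, got {resp.shape}")
    if np.any(resp < lo) or np.any(resp > hi) or not np.issubdtype(resp.dtype, np.integer):
        raise ValueError(f"{instrument} responses must be integers in {lo}..{hi}")
    reverse = inst["reverse"] if reverse_items is None else tuple(reverse_items)
    scored = resp.astype(int).copy()
    for item in reverse:
        scored[item - 1] = (lo + hi) - scored[item - 1]
    return int(scored.sum())


def stiffness_perception_correlation(
    E_mean: dict[str, float], table: LikertTable, feature: str = "hard"
) -> tuple[float, float]:
    """Spearman correlation between the mechanical stiffness ranking and the
    ranking of one perceived texture feature (default hardness) across
    products."""
    k = table.features.index(feature)
    prods = [p for p in table.product_ids if p in E_mean]
    if len(prods) < 3:
        raise ValueError("need at least 3 common products")
    mech = [E_mean[p] for p in prods]
    perc = [table.responses[:, table.product_ids.index(p), k].mean() for p in prods]
    return spearman(mech, perc)
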