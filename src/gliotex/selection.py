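"""All-relevant feature selection against continuous CD3 z-scores.

The shadow-feature procedure (Boruta-style) decides, for every feature,
whether it carries information about the outcome beyond chance: each round
appends a permuted "shadow" copy of every feature, fits a random-forest
regressor on the augmented matrix, and scores a *hit* for every undecided
feature whose importance exceeds the maximum shadow importance.  Hit counts
are tested against Binomial(rounds, 1/2) two-sidedly with Bonferroni
correction: significantly many hits confirms a feature, significantly few
rejects it.  Because every feature is judged against chance rather than
against each other, correlated informative features are all confirmed
(all-relevant, not minimal-subset, behavior).

Confirmed features are then pruned greedily by descending importance so
that the retained set has all pairwise |Pearson r| below a threshold
(default 0.6).

A frozen 6-feature CD3-associated panel (histogram kurtosis, NGTDM
contrast, and four GLSZM emphases, all T1-post-contrast) ships as a
packaged resource so the downstream classifier can be run without
re-selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as _resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

R_THRESHOLD_DEFAULT = 0.6


def load_cd3_panel() -> List[str]:
    """The frozen 6-feature CD3-associated panel (all T1-post-contrast)."""
    with _resources.files("gliotex.resources").joinpath("cd3_feature_panel.json").open() as fh:
        return json.load(fh)["features"]


@dataclass
class SelectionResult:
    """Outcome of the shadow-feature procedure.

    ``confirmed``, ``tentative`` and ``rejected`` partition the input
    features.  ``importance`` holds each feature's median importance over
    rounds (used downstream as the pruning order); ``importance_history``
    and ``shadow_max_history`` retain the full per-round traces.
    """

    confirmed: List[str]
    tentative: List[str]
    rejected: List[str]
    importance: Dict[str, float]
    importance_history: pd.DataFrame
    shadow_max_history: List[float]
    n_rounds: int
    seed: int
    prune_log: List[Tuple[str, str, float]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "confirmed": self.confirmed,
                "tentative": self.tentative,
                "rejected": self.rejected,
                "importance": self.importance,
                "shadow_max_history": self.shadow_max_history,
                "n_rounds": self.n_rounds,
                "seed": self.seed,
                "prune_log": [list(t) for t in self.prune_log],
            },
            indent=1,
        )


def boruta_select(
    X: pd.DataFrame,
    y: Sequence[float],
    max_rounds: int = 100,
    seed: int = 0,
    n_estimators: int = 100,
    alpha: float = 0.01,
    resolve_tentative: bool = True,
) -> SelectionResult:
    """Shadow-feature all-relevant selection of CD3-associated features.

    Parameters
    ----------
    X : DataFrame, patients x features (no missing values, >= 10 rows)
    y : continuous outcome (CD3 z-scores); must not be constant
    max_rounds : iteration cap
    seed : drives shadow permutations and forest seeds
    n_estimators : trees per random forest
    alpha : two-sided binomial level, Bonferroni-corrected over features
    resolve_tentative : settle still-undecided features by comparing their
        median importance with the median max-shadow importance

    Notes
    -----
    Importance is the forest's impurity-based feature importance; decisions
    begin once a feature's hit count can reach significance.
    """
    y = np.asarray(y, dtype=np.float64)
    if X.isna().any().any():
        raise ValueError("X contains missing values")
    if len(X) < 10:
        raise ValueError(f"need >= 10 samples, got {len(X)}")
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    if np.all(y == y[0]):
        raise ValueError("outcome is constant; selection undefined")

    rng = np.random.default_rng(seed)
    features = list(X.columns)
    m = len(features)
    alpha_corr = alpha / m
    undecided = set(features)
    confirmed: List[str] = []
    rejected: List[str] = []
    hits = {f: 0 for f in features}
    rounds_seen = {f: 0 for f in features}
    history: List[Dict[str, float]] = []
    shadow_max_history: List[float] = []
    Xv = X.to_numpy(dtype=np.float64)

    n_rounds = 0
    for _ in range(max_rounds):
        if not undecided:
            break
        n_rounds += 1
        shadow = Xv.copy()
        for j in range(m):
            rng.shuffle(shadow[:, j])
        Z = np.concatenate([Xv, shadow], axis=1)
        forest = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features="sqrt",  # mtry = sqrt(p), the usual forest default
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(Z, y)
        imp = forest.feature_importances_
        real_imp = dict(zip(features, imp[:m]))
        shadow_max = float(imp[m:].max())
        history.append(real_imp)
        shadow_max_history.append(shadow_max)

        for f in list(undecided):
            rounds_seen[f] += 1
            if real_imp[f] > shadow_max:
                hits[f] += 1
            r, h = rounds_seen[f], hits[f]
            # two-sided binomial test against p = 1/2
            p_hi = stats.binom.sf(h - 1, r, 0.5)
            p_lo = stats.binom.cdf(h, r, 0.5)
            if p_hi < alpha_corr:
                confirmed.append(f)
                undecided.discard(f)
            elif p_lo < alpha_corr:
                rejected.append(f)
                undecided.discard(f)

    hist_df = pd.DataFrame(history, columns=features)
    tentative = [f for f in features if f in undecided]
    if resolve_tentative and tentative:
        med_shadow = float(np.median(shadow_max_history))
        still = []
        for f in tentative:
            med = float(hist_df[f].median())
            (confirmed if med > med_shadow else rejected).append(f)
        tentative = still

    importance = {f: float(hist_df[f].median()) for f in features}
    order = {f: i for i, f in enumerate(features)}
    return SelectionResult(
        confirmed=sorted(confirmed, key=order.get),
        tentative=sorted(tentative, key=order.get),
        rejected=sorted(rejected, key=order.get),
        importance=importance,
        importance_history=hist_df,
        shadow_max_history=shadow_max_history,
        n_rounds=n_rounds,
        seed=seed,
    )


def prune_correlated(
    X: pd.DataFrame,
    features: Sequence[str],
    r_threshold: float = R_THRESHOLD_DEFAULT,
    importance: Optional[Mapping[str, float]] = None,
) -> Tuple[List[str], List[Tuple[str, str, float]]]:
    """Greedy correlation pruning in descending importance order.

    A feature is kept iff its absolute Pearson correlation with every
    already-kept feature is below ``r_threshold``.  Returns the retained
    list and a log of (dropped, kept_conflicting, r) entries.  Without an
    importance map the input order is used.
    """
    missing = [f for f in features if f not in X.columns]
    if missing:
        raise ValueError(f"features not in X: {missing}")
    if importance is not None:
        ordered = sorted(features, key=lambda f: -importance.get(f, 0.0))
    else:
        ordered = list(features)
    kept: List[str] = []
    log: List[Tuple[str, str, float]] = []
    for f in ordered:
        conflict = None
        for k in kept:
            r = float(np.corrcoef(X[f], X[k])[0, 1])
            if np.isnan(r):
                r = 1.0  # constant column: treat as fully redundant
            if abs(r) >= r_threshold:
                conflict = (k, r)
                break
        if conflict is None:
            kept.append(f)
        else:
            log.append((f, conflict[0], conflict[1]))
    return kept, log


def select_features(
    X: pd.DataFrame,
    y: Sequence[float],
    max_rounds: int = 100,
    seed: int = 0,
    r_threshold: float = R_THRESHOLD_DEFAULT,
    **boruta_kwargs,
) -> Tuple[List[str], SelectionResult]:
    """Full selection stage: shadow-feature confirmation then |r| pruning."""
    result = boruta_select(X, y, max_rounds=max_rounds, seed=seed, **boruta_kwargs)
    retained, log = prune_correlated(
        X, result.confirmed, r_threshold=r_threshold, importance=result.importance
    )
    result.prune_log = log
    return retained, result
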