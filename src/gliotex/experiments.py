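"""Reproducible end-to-end experiments on synthetic cohorts.

These drive the whole pipeline in memory (no disk artifacts) and are used
both by the test suite and by the results-reproduction script.  The
headline experiment is *parameter recovery*: cohorts are simulated with a
known texture-to-CD3 link, and the pipeline must (a) confirm the features
that read out the linked parameter and (b) classify held-out patients
accurately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluate import roc_auc, spearman_concordance
from .model import GPParams, fit_symbolic, predict, split_train_test
from .phantom import (
    DEFAULT_CAUSAL_FEATURES,
    CohortSpec,
    cohort_table,
    generate_cohort,
    iter_cohort_images,
)
from .selection import select_features
from .texture import extract_all


def cohort_features(cspec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort and extract the 86-feature table (in memory)."""
    patients = generate_cohort(cspec)
    rows = []
    for p, volumes, tumors, nawm in iter_cohort_images(patients):
        fb = extract_all(volumes, tumors, {m: nawm for m in volumes})
        rows.append(fb.values)
    X = pd.DataFrame(rows, index=[p.patient_id for p in patients])
    X.index.name = "patient_id"
    return X


@dataclass
class RecoveryResult:
    seed: int
    confirmed: List[str]
    selected: List[str]
    causal_confirmed: bool
    test_auc: float
    train_auc: float
    test_spearman: float = float("nan")


def parameter_recovery(
    seeds: Sequence[int],
    n_patients: int = 150,
    gp_params: Optional[GPParams] = None,
    causal_features: Sequence[str] = DEFAULT_CAUSAL_FEATURES,
    selection_kwargs: Optional[dict] = None,
) -> List[RecoveryResult]:
    """Run the selection + classification recovery experiment per seed.

    For every cohort seed: simulate ``n_patients`` phantoms with the
    default texture-to-CD3 link, extract all 86 features, run the
    shadow-feature selection against the continuous CD3 z-score, check
    that every designated causal feature is confirmed, then train the
    symbolic-regression classifier on the pruned selected features over a
    50/50 split and measure held-out AUC against the binary label.
    """
    gp = gp_params or GPParams(population=300, generations=25)
    sel_kw = selection_kwargs or {}
    out: List[RecoveryResult] = []
    for seed in seeds:
        cspec = CohortSpec(n_patients=n_patients, seed=seed)
        X = cohort_features(cspec)
        meta = cohort_table(generate_cohort(cspec))
        retained, result = select_features(X, meta["cd3_z"], seed=seed, **sel_kw)
        causal_ok = all(f in result.confirmed for f in causal_features)
        features = retained if retained else list(causal_features)
        table = meta.join(X[features])
        train, test, _ = split_train_test(
            table, seed=seed, balance_vars=["age", "kps"]
        )
        mdl = fit_symbolic(train[features], train["cd3_label"], gp, seed=seed)
        scores, _ = predict(mdl, test[features])
        auc = roc_auc(scores, test["cd3_label"])
        rho, _ = spearman_concordance(scores, test["cd3_z"])
        out.append(
            RecoveryResult(
                seed=seed,
                confirmed=result.confirmed,
                selected=features,
                causal_confirmed=causal_ok,
                test_auc=float(auc),
                train_auc=float(mdl.train_auc),
                test_spearman=float(rho),
            )
        )
    return out


def summarize_recovery(results: Iterable[RecoveryResult]) -> Dict[str, float]:
    results = list(results)
    n = len(results)
    return {
        "n_seeds": n,
        "causal_confirmation_rate": sum(r.causal_confirmed for r in results) / n,
        "auc_above_0p8_fraction": sum(r.test_auc > 0.8 for r in results) / n,
        "mean_test_auc": float(np.mean([r.test_auc for r in results])),
        "mean_train_auc": float(np.mean([r.train_auc for r in results])),
        "mean_test_spearman": float(np.mean([r.test_spearman for r in results])),
    }
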