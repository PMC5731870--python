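"""Symbolic-regression classification of CD3 infiltration status.

A genetic-programming search evolves arithmetic expression trees over the
selected features (primitives +, -, *, protected /; terminals are feature
variables and ephemeral constants).  Fitness is the training-set ROC AUC of
the expression's continuous output — the endpoint is binary classification,
so rank separation, not squared error, is what the search rewards.  The
decision threshold is the Youden-optimal point of the training ROC; test
cases are scored by the frozen expression only, so no test outcome ever
reaches the fit.

A transparent logistic-regression baseline on the same features is provided
as a comparator through the same TrainedModel interface.

Programs are stored in prefix order, which makes subtree crossover and
mutation simple slice operations and keeps serialization to a token list
trivial.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .evaluate import kruskal_wallis_balance, roc_auc

_BINARY_OPS = ("add", "sub", "mul", "div")
_OP_SYMBOL = {"add": "+", "sub": "-", "mul": "*", "div": "/"}

# a program is a list of tokens in prefix order:
#   ("op", name)   binary operator
#   ("x", j)       feature j
#   ("c", value)   ephemeral constant
Token = Tuple[str, object]
Program = List[Token]


@dataclass(frozen=True)
class GPParams:
    """Search hyperparameters (defaults: population 500, 50 generations,
    depth cap 6, tournament size 3)."""

    population: int = 500
    generations: int = 50
    max_depth: int = 6
    tournament: int = 3
    p_crossover: float = 0.8
    p_mutation: float = 0.15
    init_depth: Tuple[int, int] = (2, 4)
    const_range: Tuple[float, float] = (-1.0, 1.0)


# ---------------------------------------------------------------------------
# program utilities
# ---------------------------------------------------------------------------

def _arity(tok: Token) -> int:
    return 2 if tok[0] == "op" else 0

def _subtree_end(prog: Program, start: int) -> int:
    """Index one past the subtree rooted at ``start`` (prefix encoding)."""
    need, i = 1, start
    while need:
        need += _arity(prog[i]) - 1
        i += 1
    return i

def program_depth(prog: Program) -> int:
    depth = 0
    stack = [1]
    for tok in prog:
        d = stack.pop()
        depth = max(depth, d)
        stack.extend([d + 1] * _arity(tok))
    return depth

def _random_program(
    rng: np.random.Generator, n_features: int, depth: int, full: bool,
    const_range: Tuple[float, float],
) -> Program:
    """Grow/full initialization to the given depth."""
    prog: Program = []
    def build(d: int) -> None:
        if d >= depth or (not full and d > 1 and rng.random() < 0.3):
            if rng.random() < 0.2:
                prog.append(("c", float(rng.uniform(*const_range))))
            else:
                prog.append(("x", int(rng.integers(n_features))))
        else:
            prog.append(("op", _BINARY_OPS[rng.integers(4)]))
            build(d + 1)
            build(d + 1)
    build(1)
    return prog


def evaluate_program(prog: Program, X: np.ndarray) -> np.ndarray:
    """Vectorized evaluation over the rows of X (features in columns).

    Division is protected (denominators within 1e-12 of zero yield 1) and
    results are clipped to +-1e12, so output is always finite.
    """
    pos = 0
    def ev() -> np.ndarray:
        nonlocal pos
        kind, val = prog[pos]
        pos += 1
        if kind == "x":
            return X[:, val]
        if kind == "c":
            return np.full(X.shape[0], val)
        a = ev()
        b = ev()
        with np.errstate(all="ignore"):
            if val == "add":
                out = a + b
            elif val == "sub":
                out = a - b
            elif val == "mul":
                out = a * b
            else:
                out = np.where(np.abs(b) < 1e-12, 1.0, a / np.where(b == 0, 1.0, b))
        return np.clip(np.nan_to_num(out, nan=0.0, posinf=1e12, neginf=-1e12), -1e12, 1e12)
    out = ev()
    if pos != len(prog):
        raise ValueError("malformed program")
    return out


def program_to_string(prog: Program, names: Sequence[str]) -> str:
    pos = 0
    def render() -> str:
        nonlocal pos
        kind, val = prog[pos]
        pos += 1
        if kind == "x":
            return names[val]
        if kind == "c":
            return f"{val:.4g}"
        a = render()
        b = render()
        return f"({a} {_OP_SYMBOL[val]} {b})"
    return render()


# ---------------------------------------------------------------------------
# trained model
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted CD3-status classifier: expression (or logistic fit) plus a
    training-derived decision threshold."""

    kind: str                       # "symbolic" | "logistic"
    feature_names: List[str]
    threshold: float
    program: Optional[Program] = None
    coef: Optional[List[float]] = None
    intercept: float = 0.0
    seed: int = 0
    params: Optional[GPParams] = None
    train_auc: float = math.nan
    fitness_trace: List[float] = field(default_factory=list)

    @property
    def expression(self) -> str:
        if self.kind == "symbolic":
            return program_to_string(self.program, self.feature_names)
        terms = " + ".join(
            f"{c:.4g}*{n}" for c, n in zip(self.coef, self.feature_names)
        )
        return f"logit({self.intercept:.4g} + {terms})"

    def to_json(self) -> str:
        d = {
            "kind": self.kind,
            "feature_names": self.feature_names,
            "threshold": self.threshold,
            "seed": self.seed,
            "train_auc": self.train_auc,
            "expression": self.expression,
            "fitness_trace": self.fitness_trace,
        }
        if self.kind == "symbolic":
            d["program"] = [list(t) for t in self.program]
            d["params"] = vars(self.params) if self.params else None
            if d["params"]:
                d["params"] = {
                    k: list(v) if isinstance(v, tuple) else v
                    for k, v in d["params"].items()
                }
        else:
            d["coef"] = self.coef
            d["intercept"] = self.intercept
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        params = None
        if d.get("params"):
            p = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["params"].items()
            }
            params = GPParams(**p)
        return cls(
            kind=d["kind"],
            feature_names=d["feature_names"],
            threshold=d["threshold"],
            program=[tuple(t) for t in d["program"]] if "program" in d else None,
            coef=d.get("coef"),
            intercept=d.get("intercept", 0.0),
            seed=d.get("seed", 0),
            params=params,
            train_auc=d.get("train_auc", math.nan),
            fitness_trace=d.get("fitness_trace", []),
        )


def predict(model: TrainedModel, X: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    """Continuous scores and binary labels (score >= threshold) for X."""
    missing = [f for f in model.feature_names if f not in X.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    Xv = X[model.feature_names].to_numpy(dtype=np.float64)
    if model.kind == "symbolic":
        scores = evaluate_program(model.program, Xv)
    else:
        scores = model.intercept + Xv @ np.asarray(model.coef)
    labels = (scores >= model.threshold).astype(int)
    return scores, labels


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _youden_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Training-ROC threshold maximizing sensitivity + specificity - 1."""
    order = np.argsort(-scores, kind="stable")
    s, lab = scores[order], y[order]
    n_pos, n_neg = int(lab.sum()), int(len(lab) - lab.sum())
    tp = np.cumsum(lab)
    fp = np.cumsum(1 - lab)
    # candidate cuts between distinct consecutive scores; the trivial cuts
    # (predict none / predict all) both have J = 0
    best_j, best_thr = 0.0, float(s[0]) + 1.0
    for i in np.flatnonzero(np.diff(s) != 0):
        j = tp[i] / max(n_pos, 1) - fp[i] / max(n_neg, 1)
        if j > best_j:
            best_j = j
            best_thr = float((s[i] + s[i + 1]) / 2.0)
    return best_thr


def fit_symbolic(
    train_X: pd.DataFrame,
    train_y: Sequence[int],
    gp_params: Optional[GPParams] = None,
    seed: int = 0,
) -> TrainedModel:
    """Evolve an expression maximizing training AUC; fully seed-deterministic.

    Standard generational GP: ramped half-and-half initialization,
    tournament selection, subtree crossover and mutation under a depth cap,
    elitism of one.
    """
    p = gp_params or GPParams()
    y = np.asarray(train_y, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    names = list(train_X.columns)
    Xv = train_X.to_numpy(dtype=np.float64)
    nf = len(names)
    rng = np.random.default_rng(seed)

    def fitness(prog: Program) -> float:
        return roc_auc(evaluate_program(prog, Xv), y)

    # ramped half-and-half init
    pop: List[Program] = []
    lo, hi = p.init_depth
    for i in range(p.population):
        depth = lo + (i % (hi - lo + 1))
        full = (i // (hi - lo + 1)) % 2 == 0
        pop.append(_random_program(rng, nf, depth, full, p.const_range))
    fits = [fitness(pr) for pr in pop]
    trace = [max(fits)]

    def tournament() -> Program:
        idx = rng.integers(0, len(pop), size=p.tournament)
        best = max(idx, key=lambda i: fits[i])
        return pop[best]

    def crossover(a: Program, b: Program) -> Program:
        for _ in range(10):
            i = int(rng.integers(len(a)))
            j = int(rng.integers(len(b)))
            child = a[:i] + b[j:_subtree_end(b, j)] + a[_subtree_end(a, i):]
            if program_depth(child) <= p.max_depth:
                return child
        return list(a)

    def mutate(a: Program) -> Program:
        for _ in range(10):
            i = int(rng.integers(len(a)))
            depth = int(rng.integers(1, 4))
            sub = _random_program(rng, nf, depth, False, p.const_range)
            child = a[:i] + sub + a[_subtree_end(a, i):]
            if program_depth(child) <= p.max_depth:
                return child
        return list(a)

    for _ in range(p.generations):
        elite = int(np.argmax(fits))
        new_pop = [list(pop[elite])]
        while len(new_pop) < p.population:
            r = rng.random()
            if r < p.p_crossover:
                child = crossover(tournament(), tournament())
            elif r < p.p_crossover + p.p_mutation:
                child = mutate(tournament())
            else:
                child = list(tournament())
            new_pop.append(child)
        pop = new_pop
        fits = [fitness(pr) for pr in pop]
        trace.append(max(fits))

    best = int(np.argmax(fits))
    prog = pop[best]
    scores = evaluate_program(prog, Xv)
    return TrainedModel(
        kind="symbolic",
        feature_names=names,
        threshold=_youden_threshold(scores, y),
        program=prog,
        seed=seed,
        params=p,
        train_auc=float(fits[best]),
        fitness_trace=[float(t) for t in trace],
    )


def fit_logistic(
    train_X: pd.DataFrame, train_y: Sequence[int], seed: int = 0
) -> TrainedModel:
    """Logistic-regression comparator on standardized features."""
    y = np.asarray(train_y, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    Xv = train_X.to_numpy(dtype=np.float64)
    mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
    sd[sd == 0] = 1.0
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit((Xv - mu) / sd, y)
    # fold standardization into the linear form
    coef = clf.coef_[0] / sd
    intercept = float(clf.intercept_[0] - (clf.coef_[0] * mu / sd).sum())
    scores = intercept + Xv @ coef
    return TrainedModel(
        kind="logistic",
        feature_names=list(train_X.columns),
        threshold=_youden_threshold(scores, y),
        coef=[float(c) for c in coef],
        intercept=intercept,
        seed=seed,
        train_auc=roc_auc(scores, y),
    )


# ---------------------------------------------------------------------------
# cohort splitting
# ---------------------------------------------------------------------------

def split_train_test(
    table: pd.DataFrame,
    seed: int = 0,
    label_col: str = "cd3_label",
    balance_vars: Optional[Sequence[str]] = None,
    max_retries: int = 100,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, float]]:
    """50/50 random split with a Kruskal-Wallis balance report.

    The training half takes the extra case when n is odd.  The draw is
    redone (up to ``max_retries``) if either half lacks one of the classes.
    Returns (train, test, {variable: KW p-value}).
    """
    if len(table) < 4:
        raise ValueError("need at least 4 labeled patients to split")
    labels = table[label_col]
    if labels.nunique() < 2:
        raise ValueError("cohort contains a single class; cannot split")
    n_train = math.ceil(len(table) / 2)
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        perm = rng.permutation(len(table))
        tr = table.iloc[perm[:n_train]]
        te = table.iloc[perm[n_train:]]
        if tr[label_col].nunique() == 2 and te[label_col].nunique() == 2:
            break
    else:
        raise RuntimeError("could not draw a split with both classes in each half")
    if balance_vars is None:
        balance_vars = [
            c for c in table.columns
            if c != label_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    report = kruskal_wallis_balance(tr, te, balance_vars)
    return tr, te, report
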