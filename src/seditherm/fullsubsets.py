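"""Full-subsets model comparison with AICc weights.

All subsets of a predictor pool up to a maximum size (default 3) are
enumerated, excluding any model containing two continuous predictors whose
absolute Pearson correlation reaches the collinearity cutoff (default 0.4).
A null model (intercept + random effects only) is always included.  Fitted
candidates are compared with AICc; Akaike weights ω = exp(−Δ/2) / Σ exp(−Δ/2)
are summed over the models containing each predictor to give its relative
importance.  The "best" model is either the AICc minimum or, with the
parsimony rule, the simplest model within a window (default 2 AICc units)
of the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .glmm import aicc  # noqa: F401  (re-exported: the AICc operator lives with the engine)

__all__ = ["CandidateSet", "enumerate_candidates", "aicc", "compare", "select_best"]


@dataclass
class Candidate:
    predictors: tuple
    interactions: tuple = ()

    @property
    def label(self) -> str:
        parts = list(self.predictors) + [f"{a}:{b}" for a, b in self.interactions]
        return " + ".join(parts) if parts else "null"

    @property
    def size(self) -> int:
        return len(self.predictors)


@dataclass
class CandidateSet:
    pool: tuple
    candidates: list
    exclusion_log: list = field(default_factory=list)

    def __len__(self):
        return len(self.candidates)


def enumerate_candidates(
    pool,
    corr_matrix: pd.DataFrame | None = None,
    max_size: int = 3,
    corr_cutoff: float = 0.4,
    interactions=(),
    factors=(),
) -> CandidateSet:
    """Enumerate admissible candidate models.

    Parameters
    ----------
    pool
        Continuous predictor names.
    corr_matrix
        Pairwise Pearson correlations among the pool (DataFrame indexed by
        predictor name).  ``None`` disables the screen.
    max_size
        Maximum number of predictors per model (factors count toward the cap;
        an interaction consumes only its constituents' slots).
    corr_cutoff
        Two continuous predictors with ``|r| >= corr_cutoff`` never share a
        model.
    interactions
        Iterable of (factor, continuous) pairs appended to any candidate
        containing both members.
    factors
        Factor names, screened only by the size cap (not the correlation
        rule).

    The null model (empty predictor set) is always included.
    """
    if not (0 < corr_cutoff <= 1):
        raise ValueError("corr_cutoff must lie in (0, 1]")
    pool = tuple(pool)
    all_terms = pool + tuple(factors)
    excluded_pairs = set()
    log = []
    if corr_matrix is not None:
        for a, b in combinations(pool, 2):
            r = float(corr_matrix.loc[a, b])
            if abs(r) >= corr_cutoff:
                excluded_pairs.add(frozenset((a, b)))
                log.append({"pair": (a, b), "r": r, "reason": f"|r| >= {corr_cutoff}"})

    candidates = [Candidate(())]
    for size in range(1, max_size + 1):
        for combo in combinations(all_terms, size):
            cont = [t for t in combo if t in pool]
            if any(frozenset(p) in excluded_pairs for p in combinations(cont, 2)):
                continue
            inter = tuple((f, c) for f, c in interactions if f in combo and c in combo)
            candidates.append(Candidate(tuple(combo), inter))
    return CandidateSet(pool=all_terms, candidates=candidates, exclusion_log=log)


def compare(models: dict) -> pd.DataFrame:
    """AICc comparison table with Akaike weights and predictor importance.

    ``models`` maps a label to a fitted model exposing ``aicc_``, ``n_obs_``
    and ``n_params_`` (any :mod:`seditherm.hurdlefit` estimator).  Returns a
    table sorted by AICc with columns ``model, k, loglik, aicc, daicc,
    weight``; per-predictor summed weights are attached as
    ``table.attrs["importance"]`` (a predictor counts in every model whose
    label mentions it, including inside interactions).
    """
    if len(models) < 2:
        raise ValueError("need at least 2 fitted models to compare")
    n_obs = {m.n_obs_ for m in models.values()}
    if len(n_obs) != 1:
        raise ValueError(f"models fitted to differing n_obs: {sorted(n_obs)}")
    rows = []
    for label, m in models.items():
        rows.append(
            {"model": label, "k": m.n_params_, "loglik": m.loglik_, "aicc": m.aicc_}
        )
    tab = pd.DataFrame(rows)
    tab["daicc"] = tab["aicc"] - tab["aicc"].min()
    w = np.exp(-tab["daicc"] / 2)
    tab["weight"] = w / w.sum()
    tab = tab.sort_values(["aicc", "k", "model"]).reset_index(drop=True)
    # exactly one zero delta after tie-breaking by (k, label) order
    tab["daicc"] = tab["aicc"] - tab["aicc"].iloc[0]

    predictors = sorted(
        {t.strip() for label in models if label != "null" for t in _terms_of(label)}
    )
    importance = {
        p: float(tab.loc[[p in _terms_of(lbl) for lbl in tab["model"]], "weight"].sum())
        for p in predictors
    }
    tab.attrs["importance"] = importance
    return tab


def _terms_of(label: str):
    terms = set()
    for part in label.split("+"):
        for t in part.split(":"):
            t = t.strip()
            if t and t != "null":
                terms.add(t)
    return terms


def select_best(table: pd.DataFrame, parsimony_window: float | None = 2.0) -> str:
    """Choose the best model label from a comparison table.

    With ``parsimony_window=None`` the AICc minimum wins; otherwise the model
    with fewest parameters among those within the window of the minimum,
    ties broken by fewer parameters then lexicographic label.
    """
    if table.empty:
        raise ValueError("empty comparison table")
    if parsimony_window is None:
        cand = table.nsmallest(1, "aicc")
    else:
        cand = table[table["daicc"] <= parsimony_window]
    cand = cand.assign(n_terms=[len(_terms_of(lbl)) for lbl in cand["model"]])
    cand = cand.sort_values(["n_terms", "k", "model"])
    return str(cand["model"].iloc[0])
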