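"""Random-forest predictor importance for bear activity and egg diet share.

Two regression forests (default 700 trees, two predictors tried per split)
relate (a) daily per-beach bear activity and (b) herring-egg estimated dietary
content per beach and collection date to resource and context predictors.
Reported per predictor are

* permutation importance: the increase in out-of-bag mean squared error when
  the predictor is permuted, averaged over trees and normalized by the
  standard deviation of the per-tree differences (the %IncMSE convention);
* impurity importance: total decrease in residual-sum-of-squares node
  impurity from splits on the predictor, averaged over trees;

plus an out-of-bag pseudo-R2 (1 - OOB MSE / Var(y)) and partial-dependence
curves.  Categorical predictors (year, location) enter as integer codes; the
trees treat the codes as ordered, which for the handful of levels here only
restricts the partitions a single split can express.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .dynamics import EggTrajectory, windowed_mean_egg_mass

__all__ = [
    "ImportanceResult",
    "assemble_activity_table",
    "assemble_edc_table",
    "fit_importance",
    "partial_dependence",
]

DEFAULT_N_TREES = 700
DEFAULT_MTRY = 2
#: Minimum observations per leaf; matches the customary regression-forest
#: node size of 5.
MIN_LEAF = 5


def assemble_activity_table(
    daily_activity: pd.DataFrame,
    trajectories: Mapping[str, EggTrajectory],
    amphipod_mass: Mapping[str, float],
    *,
    year: int | Mapping[str, int],
) -> pd.DataFrame:
    """Model table for the daily bear-activity forest.

    One row per valid beach x day: response ``bear_count`` plus predictors
    day-of-year, year, location, same-day wolf activity, the beach's constant
    amphipod mass, and the trajectory egg mass for that day (0 for beaches
    that never spawned).

    ``daily_activity`` is the long table from :func:`spawnfeast.events.daily_activity`
    containing at least ``black_bear`` rows; missing ``gray_wolf`` rows count
    as 0.  Beaches lacking an amphipod mass raise.
    """
    df = daily_activity.copy()
    df["date"] = pd.to_datetime(df["date"])
    wide = (
        df.pivot_table(
            index=["beach_id", "date"], columns="species", values="count", fill_value=0
        )
        .reset_index()
    )
    if "black_bear" not in wide.columns:
        raise ValueError("daily activity table contains no black_bear rows")
    if "gray_wolf" not in wide.columns:
        wide["gray_wolf"] = 0

    missing = sorted(set(wide["beach_id"]) - set(amphipod_mass))
    if missing:
        raise ValueError(f"no amphipod mass for beaches: {missing}")

    doy = wide["date"].dt.dayofyear
    if isinstance(year, Mapping):
        years = wide["beach_id"].map(year)
    else:
        years = pd.Series(int(year), index=wide.index)

    egg = [
        trajectories[b].mass_on(d) if b in trajectories else 0.0
        for b, d in zip(wide["beach_id"], doy)
    ]
    return pd.DataFrame(
        {
            "bear_count": wide["black_bear"].astype(float),
            "day_of_year": doy.astype(float),
            "year": years.astype(int),
            "location": wide["beach_id"].astype(str),
            "wolf_activity": wide["gray_wolf"].astype(float),
            "amphipod_mass": wide["beach_id"].map(amphipod_mass).astype(float),
            "egg_mass": egg,
        }
    )


def assemble_edc_table(
    egg_edc: pd.DataFrame,
    trajectories: Mapping[str, EggTrajectory],
    amphipod_mass: Mapping[str, float],
    *,
    year: int | Mapping[str, int],
    window_days: int = 14,
) -> pd.DataFrame:
    """Model table for the herring-egg-EDC forest.

    One row per beach x scat-collection date: response ``egg_edc`` plus
    day-of-year, year, location, amphipod mass, and the mean trajectory egg
    mass over the ``window_days`` days up to and including the collection
    date.
    """
    df = egg_edc.copy()
    df["collection_date"] = pd.to_datetime(df["collection_date"])
    missing = sorted(set(df["beach_id"]) - set(amphipod_mass))
    if missing:
        raise ValueError(f"no amphipod mass for beaches: {missing}")

    doy = df["collection_date"].dt.dayofyear
    if isinstance(year, Mapping):
        years = df["beach_id"].map(year)
    else:
        years = pd.Series(int(year), index=df.index)

    egg14 = [
        windowed_mean_egg_mass(trajectories[b], int(d), window_days) if b in trajectories else 0.0
        for b, d in zip(df["beach_id"], doy)
    ]
    return pd.DataFrame(
        {
            "egg_edc": df["egg_edc"].astype(float),
            "day_of_year": doy.astype(float),
            "year": years.astype(int),
            "location": df["beach_id"].astype(str),
            "amphipod_mass": df["beach_id"].map(amphipod_mass).astype(float),
            "egg_mass": egg14,
        }
    )


@dataclass
class ImportanceResult:
    """Fitted forest with both importance measures and OOB diagnostics."""

    response: str
    predictors: Tuple[str, ...]
    permutation: Dict[str, float]
    impurity: Dict[str, float]
    pseudo_r2: float
    n_trees: int
    mtry: int
    seed: int
    model: RandomForestRegressor = field(repr=False)
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    categories: Dict[str, list] = field(repr=False, default_factory=dict)

    def ranking(self, measure: str = "permutation") -> list[str]:
        """Predictors sorted by decreasing importance."""
        scores = getattr(self, measure)
        return sorted(scores, key=scores.get, reverse=True)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "permutation_importance": self.permutation,
            "impurity_importance": self.impurity,
            "pseudo_r2": self.pseudo_r2,
            "n_trees": self.n_trees,
            "mtry": self.mtry,
            "seed": self.seed,
        }


def _encode(table: pd.DataFrame, response: str):
    predictors = [c for c in table.columns if c != response]
    categories: Dict[str, list] = {}
    X = np.empty((len(table), len(predictors)), dtype=float)
    for j, col in enumerate(predictors):
        s = table[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            cats = sorted(s.astype(str).unique())
            categories[col] = cats
            X[:, j] = s.astype(str).map({c: i for i, c in enumerate(cats)}).to_numpy()
        else:
            X[:, j] = s.to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    return X, y, predictors, categories


def _bootstrap_indices(estimator, n_samples: int) -> np.ndarray:
    # Reproduces the forest's bootstrap draw: each tree's integer random_state
    # seeds a fresh RNG whose first n draws are the in-bag sample indices.
    rng = np.random.RandomState(estimator.random_state)
    return rng.randint(0, n_samples, n_samples)


def fit_importance(
    table: pd.DataFrame,
    response: str,
    n_trees: int = DEFAULT_N_TREES,
    mtry: int = DEFAULT_MTRY,
    seed: int = 0,
) -> ImportanceResult:
    """Fit a regression forest and compute both importance measures.

    Permutation importance of predictor j in tree t is the OOB MSE with j
    permuted minus the unpermuted OOB MSE; the final score is
    ``mean_t / sd_t`` of those differences.  Impurity importance is the RSS
    decrease summed over a tree's splits on j, averaged over trees.
    Pseudo-R2 is computed from OOB ensemble predictions.  Deterministic for a
    given seed.
    """
    if len(table) < 20:
        raise ValueError(f"need >= 20 rows to fit, got {len(table)}")
    X, y, predictors, categories = _encode(table, response)
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors")
    if np.all(y == y[0]):
        raise ValueError("response is constant; importance undefined")
    if mtry > len(predictors):
        raise ValueError(f"mtry={mtry} exceeds the {len(predictors)} predictors")

    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=MIN_LEAF,
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    model.fit(X, y)

    n, p = X.shape
    diffs = np.full((n_trees, p), np.nan)
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, dtype=int)
    perm_rng = np.random.RandomState((int(seed) + 1) % (2**31))

    for t, est in enumerate(model.estimators_):
        inbag = _bootstrap_indices(est, n)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[inbag] = False
        oob_idx = np.flatnonzero(oob_mask)
        if oob_idx.size == 0:
            continue
        X_oob = X[oob_idx]
        pred = est.predict(X_oob)
        oob_sum[oob_idx] += pred
        oob_cnt[oob_idx] += 1
        base_mse = np.mean((y[oob_idx] - pred) ** 2)
        for j in range(p):
            X_perm = X_oob.copy()
            X_perm[:, j] = perm_rng.permutation(X_perm[:, j])
            perm_mse = np.mean((y[oob_idx] - est.predict(X_perm)) ** 2)
            diffs[t, j] = perm_mse - base_mse

    permutation: Dict[str, float] = {}
    for j, name in enumerate(predictors):
        d = diffs[:, j]
        d = d[~np.isnan(d)]
        mean = float(d.mean())
        sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
        permutation[name] = mean / sd if sd > 0 else mean

    impurity = {name: 0.0 for name in predictors}
    for est in model.estimators_:
        tree = est.tree_
        is_internal = tree.children_left != -1
        for node in np.flatnonzero(is_internal):
            left, right = tree.children_left[node], tree.children_right[node]
            # weighted_n_node_samples * impurity is the node's RSS
            decrease = (
                tree.weighted_n_node_samples[node] * tree.impurity[node]
                - tree.weighted_n_node_samples[left] * tree.impurity[left]
                - tree.weighted_n_node_samples[right] * tree.impurity[right]
            )
            impurity[predictors[tree.feature[node]]] += float(decrease)
    impurity = {k: v / n_trees for k, v in impurity.items()}

    seen = oob_cnt > 0
    oob_pred = oob_sum[seen] / oob_cnt[seen]
    mse_oob = float(np.mean((y[seen] - oob_pred) ** 2))
    pseudo_r2 = 1.0 - mse_oob / float(np.var(y))

    return ImportanceResult(
        response=response,
        predictors=tuple(predictors),
        permutation=permutation,
        impurity=impurity,
        pseudo_r2=pseudo_r2,
        n_trees=n_trees,
        mtry=mtry,
        seed=int(seed),
        model=model,
        X=X,
        y=y,
        categories=categories,
    )


def partial_dependence(
    result: ImportanceResult, predictor: str, grid_size: int = 25
) -> Tuple[np.ndarray | list, np.ndarray]:
    """Marginal effect of one predictor on the forest's prediction.

    For each grid value the predictor's column is replaced wholesale and the
    mean prediction over the table recorded.  Numeric predictors use an
    evenly spaced grid over the observed range; categorical predictors use
    their observed levels (returned as the original labels).
    """
    if predictor not in result.predictors:
        raise ValueError(f"unknown predictor {predictor!r}; have {result.predictors}")
    j = result.predictors.index(predictor)
    col = result.X[:, j]
    if predictor in result.categories:
        grid_codes = np.arange(len(result.categories[predictor]), dtype=float)
        grid_out: np.ndarray | list = result.categories[predictor]
    else:
        lo, hi = float(col.min()), float(col.max())
        grid_codes = np.linspace(lo, hi, grid_size)
        grid_out = grid_codes
    preds = np.empty(len(grid_codes))
    X_mod = result.X.copy()
    for i, v in enumerate(grid_codes):
        X_mod[:, j] = v
        preds[i] = float(result.model.predict(X_mod).mean())
    return grid_out, preds
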