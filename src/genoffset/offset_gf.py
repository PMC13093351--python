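"""Gradient-Forest turnover model and offset.

For each candidate SNP a random regression forest predicts the dosage
from the climate predictors plus the latent-factor confounder axes
(U1..UK). Every split's impurity reduction is accrued to its predictor
at the split threshold; a SNP's accrued importances are normalized to
its out-of-bag R² (SNPs with R² ≤ 0 contribute nothing) and summed over
SNPs into per-predictor cumulative-importance "turnover" functions
F_p(x): nondecreasing step functions from 0 to the predictor's total
importance. Importance mass is accumulated on 201 equal-width bins per
predictor over the training range, a declared simplification of the
reference split-density standardization.

Environments map to turnover space by evaluating F_p at each predictor
value, clamped to the training range (no extrapolation beyond the
plateau). The genomic offset between two climates is the Euclidean
distance between their turnover coordinates over climate predictors
only — confounder axes are predictors during training but are excluded
from the distance, since population structure does not change between
periods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .genotypes import GenotypeMatrix

__all__ = ["TurnoverModel", "fit_turnover", "transform_env", "gf_offset"]

N_BINS = 201
FORMAT_VERSION = 1


@dataclass
class TurnoverModel:
    """Per-predictor cumulative-importance step functions with R² weights."""

    predictors: list[str]                 # climate variables + confounders
    climate_predictors: list[str]
    bin_edges: dict[str, np.ndarray]      # N_BINS + 1 edges per predictor
    bin_mass: dict[str, np.ndarray]       # importance mass per bin
    snp_r2: pd.Series                     # OOB R² per SNP (pre-truncation)
    n_trees: int
    mtry: int
    min_leaf: int
    seed: int

    @property
    def confounders(self) -> list[str]:
        return [p for p in self.predictors if p not in self.climate_predictors]

    def total_importance(self, predictor: str) -> float:
        return float(self.bin_mass[predictor].sum())

    def cumulative(self, predictor: str, x) -> np.ndarray:
        """Evaluate F_p: total importance at split thresholds ≤ x.

        A bin's mass counts once x reaches the bin's upper edge, so
        F_p(training minimum) = 0 and F_p(x ≥ training maximum) = total
        importance; values beyond the range clamp to the plateaus.
        """
        edges = self.bin_edges[predictor]
        cum = np.concatenate([[0.0], np.cumsum(self.bin_mass[predictor])])
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(edges[1:], x, side="right")
        return cum[np.clip(idx, 0, N_BINS)]

    def curve(self, predictor: str) -> pd.DataFrame:
        """Cumulative-importance curve as a table (for export/plotting)."""
        edges = self.bin_edges[predictor]
        return pd.DataFrame({
            "x": edges[1:],
            "cumulative_importance": np.cumsum(self.bin_mass[predictor]),
        })

    def to_json(self, path=None) -> str:
        doc = {
            "format_version": FORMAT_VERSION,
            "predictors": self.predictors,
            "climate_predictors": self.climate_predictors,
            "bin_edges": {k: v.tolist() for k, v in self.bin_edges.items()},
            "bin_mass": {k: v.tolist() for k, v in self.bin_mass.items()},
            "snp_r2": self.snp_r2.to_dict(),
            "n_trees": self.n_trees, "mtry": self.mtry,
            "min_leaf": self.min_leaf, "seed": self.seed,
        }
        text = json.dumps(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TurnoverModel":
        text = Path(source).read_text() if isinstance(
            source, (str, Path)) and str(source).endswith(".json") else source
        doc = json.loads(text)
        if doc.get("format_version") != FORMAT_VERSION:
            raise ValueError("unsupported turnover model version")
        return cls(
            predictors=doc["predictors"],
            climate_predictors=doc["climate_predictors"],
            bin_edges={k: np.asarray(v) for k, v in doc["bin_edges"].items()},
            bin_mass={k: np.asarray(v) for k, v in doc["bin_mass"].items()},
            snp_r2=pd.Series(doc["snp_r2"]),
            n_trees=doc["n_trees"], mtry=doc["mtry"],
            min_leaf=doc["min_leaf"], seed=doc["seed"],
        )


def _split_importances(forest: RandomForestRegressor, n_predictors: int):
    """(feature, threshold, impurity-decrease) triplets over all trees."""
    feats, thrs, imps = [], [], []
    for est in forest.estimators_:
        t = est.tree_
        internal = t.children_left != -1
        node = np.nonzero(internal)[0]
        w = t.weighted_n_node_samples
        dec = (w[node] * t.impurity[node]
               - w[t.children_left[node]] * t.impurity[t.children_left[node]]
               - w[t.children_right[node]] * t.impurity[t.children_right[node]])
        feats.append(t.feature[node])
        thrs.append(t.threshold[node])
        imps.append(np.maximum(dec, 0.0))
    return (np.concatenate(feats), np.concatenate(thrs), np.concatenate(imps))


def fit_turnover(G_candidates, predictors: pd.DataFrame,
                 n_trees: int = 500, mtry: int | None = None,
                 min_leaf: int = 5, seed: int = 0,
                 climate_predictors: list[str] | None = None) -> TurnoverModel:
    """Fit per-SNP regression forests and aggregate turnover functions.

    ``predictors`` must contain the (scaled) climate variables and the
    confounder axes as columns; ``climate_predictors`` names the subset
    used in the offset distance (defaults to every column not named
    ``U<k>``).
    """
    Y = (G_candidates.imputed_dosages()
         if isinstance(G_candidates, GenotypeMatrix)
         else np.asarray(G_candidates, dtype=float))
    locus_ids = (G_candidates.locus_ids
                 if isinstance(G_candidates, GenotypeMatrix)
                 else [f"snp{j}" for j in range(Y.shape[1])])
    X = predictors.to_numpy(dtype=float)
    names = list(predictors.columns)
    n, L = Y.shape
    if n < max(10, 2 * min_leaf):
        raise ValueError(f"too few samples (n={n}) to fit regression forests")
    if climate_predictors is None:
        climate_predictors = [p for p in names
                              if not (p.startswith("U") and p[1:].isdigit())]
    p = X.shape[1]
    mtry = mtry if mtry is not None else int(np.ceil(p / 3))

    edges = {nm: np.linspace(X[:, i].min(), X[:, i].max(), N_BINS + 1)
             for i, nm in enumerate(names)}
    mass = {nm: np.zeros(N_BINS) for nm in names}
    r2 = np.full(L, np.nan)
    rng = np.random.default_rng(seed)
    snp_seeds = rng.integers(0, 2 ** 31 - 1, size=L)

    for j in range(L):
        y = Y[:, j]
        if y.std() == 0:
            r2[j] = 0.0
            continue
        forest = RandomForestRegressor(
            n_estimators=n_trees, max_features=mtry,
            min_samples_leaf=min_leaf, bootstrap=True, oob_score=True,
            random_state=int(snp_seeds[j]), n_jobs=1)
        with np.errstate(invalid="ignore"):
            forest.fit(X, y)
        r2[j] = float(forest.oob_score_)
        if r2[j] <= 0:
            continue
        feats, thrs, imps = _split_importances(forest, p)
        total = imps.sum()
        if total <= 0:
            continue
        scale = r2[j] / total
        for i, nm in enumerate(names):
            sel = feats == i
            if not sel.any():
                continue
            idx = np.clip(np.searchsorted(edges[nm][1:], thrs[sel],
                                          side="left"), 0, N_BINS - 1)
            np.add.at(mass[nm], idx, imps[sel] * scale)

    return TurnoverModel(
        predictors=names, climate_predictors=list(climate_predictors),
        bin_edges=edges, bin_mass=mass,
        snp_r2=pd.Series(r2, index=locus_ids, name="oob_r2"),
        n_trees=n_trees, mtry=mtry, min_leaf=min_leaf, seed=seed)


def transform_env(model: TurnoverModel, env: pd.DataFrame,
                  predictors: list[str] | None = None) -> pd.DataFrame:
    """Map climate values into turnover space (cumulative importance).

    Values beyond the training range clamp to the endpoint plateau — the
    model does not extrapolate into novel conditions.
    """
    predictors = predictors or model.climate_predictors
    unknown = [p for p in predictors if p not in model.predictors]
    if unknown:
        raise KeyError(f"unknown predictors: {unknown}")
    missing = [p for p in predictors if p not in env.columns]
    if missing:
        raise KeyError(f"environment table missing predictors: {missing}")
    return pd.DataFrame(
        {p: model.cumulative(p, env[p].to_numpy()) for p in predictors},
        index=env.index)


def gf_offset(model: TurnoverModel, e_cur: pd.DataFrame,
              e_fut: pd.DataFrame) -> np.ndarray:
    """Euclidean distance in turnover space over climate predictors only."""
    tc = transform_env(model, e_cur).to_numpy()
    tf = transform_env(model, e_fut).to_numpy()
    return np.sqrt(((tf - tc) ** 2).sum(axis=1))
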