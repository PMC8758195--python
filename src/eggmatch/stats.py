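"""Clutch-discrimination statistics.

Given per-egg measurements (dimensions, pigment percentage, and the three
pattern scalars), this module asks whether eggs group by clutch, hen or
year:

* a dissimilarity matrix between eggs (Euclidean on z-scored variables, or
  the pattern dissimilarity from the matching stage);
* PERMANOVA - a permutational multivariate ANOVA partitioning squared
  distances among and within groups (Anderson's formulation), implemented
  here from the definition with an exact enumeration option for tiny n;
* non-metric multidimensional scaling for ordination;
* linear discriminant analysis reporting both resubstitution and
  leave-one-out classification rates.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.manifold import MDS
from sklearn.model_selection import LeaveOneOut, cross_val_predict

__all__ = [
    "clutch_summary",
    "PermanovaResult",
    "NmdsResult",
    "LdaResult",
    "COVARIATE_COLUMNS",
    "assemble_feature_vectors",
    "build_dissimilarity_matrix",
    "permanova",
    "nmds",
    "lda_classify",
]

#: covariates used for classification; orientation is circular and becomes
#: a (sin, cos) pair when vectorised
COVARIATE_COLUMNS = [
    "length_mm", "width_mm", "mass_g", "percent_black",
    "n_features", "largest_scale_mm", "dominant_orientation_deg",
]


def clutch_summary(manifest: pd.DataFrame) -> dict:
    """Egg and clutch counts plus mean clutch size from a manifest table."""
    sizes = manifest.groupby("clutch_id").size()
    return {"n_eggs": int(len(manifest)), "n_clutches": int(len(sizes)),
            "mean_clutch_size": float(len(manifest) / len(sizes))}


def assemble_feature_vectors(manifest: pd.DataFrame,
                             pigment: pd.DataFrame,
                             features: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Join measurements into one row per egg and drop incomplete eggs.

    Columns that are missing for every egg (e.g. mass for a species that was
    never weighed) are dropped from the covariate set rather than treated as
    missing data.  Returns the table and the ids of excluded eggs.
    """
    df = manifest.merge(pigment, on="egg_id", how="left").merge(
        features, on="egg_id", how="left")
    all_missing = [c for c in COVARIATE_COLUMNS
                   if c in df.columns and df[c].isna().all()]
    df = df.drop(columns=all_missing)
    cols = [c for c in COVARIATE_COLUMNS if c in df.columns]
    complete = df[cols].notna().all(axis=1)
    excluded = df.loc[~complete, "egg_id"].tolist()
    return df.loc[complete].reset_index(drop=True), excluded


def _encode(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Numeric design matrix; circular orientation becomes sin/cos."""
    out = {}
    for col in columns:
        if col == "dominant_orientation_deg":
            theta = np.radians(df[col].astype(float))
            out["orientation_sin"] = np.sin(theta)
            out["orientation_cos"] = np.cos(theta)
        else:
            out[col] = df[col].astype(float)
    return pd.DataFrame(out, index=df.index)


def build_dissimilarity_matrix(vectors: pd.DataFrame,
                               columns: list[str] | None = None,
                               method: str = "euclidean") -> pd.DataFrame:
    """Symmetric egg-by-egg distance matrix from standardized variables.

    ``method='euclidean'`` z-scores each encoded column first; a constant
    column cannot be standardized and raises an error naming it.
    """
    if method != "euclidean":
        raise ValueError(f"unknown method {method!r}")
    if len(vectors) < 3:
        raise ValueError("need at least 3 eggs")
    columns = columns or [c for c in COVARIATE_COLUMNS if c in vectors.columns]
    X = _encode(vectors, columns)
    sd = X.std(axis=0, ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s) under standardization: {constant}")
    Z = (X - X.mean(axis=0)) / sd
    ids = vectors["egg_id"].tolist() if "egg_id" in vectors else list(vectors.index)
    mat = squareform(pdist(Z.to_numpy()))
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R_squared: float
    p_value: float
    n_permutations: int
    grouping_label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.R_squared <= 1.0:
            raise ValueError("R_squared must lie in [0, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")


def _permanova_stats(d2: np.ndarray, codes: np.ndarray,
                     n_groups: int) -> tuple[float, float]:
    """(pseudo-F, R^2) from squared distances and integer group codes."""
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)  # sum over i<j of d^2 / N
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if df_within <= 0 or ss_within <= 0:
        f = math.inf
    else:
        f = (ss_among / df_among) / (ss_within / df_within)
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return f, min(max(r2, 0.0), 1.0)


def permanova(D: pd.DataFrame | np.ndarray, groups, n_perm: int = 9999,
              seed: int | None = None, grouping_label: str = "clutch",
              permutations: str = "random") -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``R^2 = SS_among / SS_total`` from the squared-distance partition;
    significance by permuting group labels: ``p = (1 + #{F* >= F}) /
    (1 + n_perm)``.  ``permutations='exhaustive'`` enumerates every label
    ordering (only sensible for very small n) and reports the exact p-value
    over all orderings.
    """
    mat = D.to_numpy(dtype=float) if isinstance(D, pd.DataFrame) else np.asarray(D, float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("distance matrix must be square")
    labels, codes = np.unique(np.asarray(list(groups)), return_inverse=True)
    if len(labels) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if len(codes) != mat.shape[0]:
        raise ValueError("groups length must match the matrix")
    d2 = mat**2
    f_obs, r2 = _permanova_stats(d2, codes, len(labels))

    if permutations == "exhaustive":
        n = len(codes)
        if n > 9:
            raise ValueError("exhaustive enumeration limited to n <= 9")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            f_p, _ = _permanova_stats(d2, codes[list(perm)], len(labels))
            count += f_p >= f_obs - 1e-12
            total += 1
        return PermanovaResult(pseudo_F=f_obs, R_squared=r2,
                               p_value=count / total,
                               n_permutations=total, grouping_label=grouping_label)

    if seed is None:
        raise ValueError("a seed is required for random permutations")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_p, _ = _permanova_stats(d2, rng.permutation(codes), len(labels))
        exceed += f_p >= f_obs - 1e-12
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(pseudo_F=f_obs, R_squared=r2, p_value=p,
                           n_permutations=n_perm, grouping_label=grouping_label)


@dataclass
class NmdsResult:
    coordinates: np.ndarray  # (n, n_dims)
    stress: float  # Kruskal stress-1
    converged: bool


def nmds(D: pd.DataFrame | np.ndarray, n_dims: int = 2, seed: int = 0,
         n_init: int = 4, max_iter: int = 300) -> NmdsResult:
    """Non-metric MDS (SMACOF) on a precomputed dissimilarity matrix.

    Non-convergence is reported through the ``converged`` flag rather than
    an exception.
    """
    mat = D.to_numpy(dtype=float) if isinstance(D, pd.DataFrame) else np.asarray(D, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MDS(n_components=n_dims, metric=False, dissimilarity="precomputed",
                    random_state=seed, n_init=n_init, max_iter=max_iter,
                    normalized_stress=True)
        coords = model.fit_transform(mat)
    converged = bool(getattr(model, "n_iter_", max_iter) < max_iter)
    return NmdsResult(coordinates=coords, stress=float(model.stress_),
                      converged=converged)


@dataclass
class LdaResult:
    mean_correct_resub: float  # percent
    mean_correct_loo: float  # percent
    per_group_correct_loo: pd.Series  # percent per group
    confusion_loo: pd.DataFrame
    dropped_covariates: list[str]
    shrinkage_used: bool


def lda_classify(vectors: pd.DataFrame, groups, columns: list[str] | None = None,
                 ) -> LdaResult:
    """Linear discriminant classification of eggs into groups.

    Reports resubstitution and leave-one-out accuracy (mean percent of eggs
    correctly classified, averaged over eggs) plus the LOO confusion table.
    Constant covariates are dropped with a warning; a singular within-group
    covariance triggers shrinkage (lsqr solver, auto shrinkage) and is
    flagged.
    """
    y = np.asarray(list(groups))
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")
    columns = columns or [c for c in COVARIATE_COLUMNS if c in vectors.columns]
    X = _encode(vectors, columns)
    sd = X.std(axis=0, ddof=0)
    dropped = sd[sd == 0].index.tolist()
    if dropped:
        warnings.warn(f"dropping constant covariate(s): {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    Xm = ((X - X.mean()) / X.std(ddof=0)).to_numpy()

    shrinkage_used = False

    def make_model():
        if shrinkage_used:
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        return LinearDiscriminantAnalysis(solver="svd")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = make_model().fit(Xm, y)
        if any("collinear" in str(w.message).lower() for w in caught):
            shrinkage_used = True
            model = make_model().fit(Xm, y)
    resub = float((model.predict(Xm) == y).mean() * 100.0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loo_pred = cross_val_predict(make_model(), Xm, y, cv=LeaveOneOut())
    loo = float((loo_pred == y).mean() * 100.0)
    per_group = (
        pd.DataFrame({"group": y, "hit": loo_pred == y})
        .groupby("group")["hit"].mean() * 100.0)
    confusion = pd.crosstab(pd.Series(y, name="true"),
                            pd.Series(loo_pred, name="predicted"))
    return LdaResult(mean_correct_resub=resub, mean_correct_loo=loo,
                     per_group_correct_loo=per_group, confusion_loo=confusion,
                     dropped_covariates=dropped, shrinkage_used=shrinkage_used)
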