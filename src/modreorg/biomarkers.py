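"""Interhemispheric connectivity indices, GMC averaging, and ROC analysis.

Index A is the mean correlation over a designated set of homotopic
left/right region pairs; index B the mean correlation among the unilateral
members of the same set. Both use raw (unmasked) per-subject correlations.
For index B the default mode averages over the distinct within-hemisphere
pairs, left and right pooled; a ``literal`` mode keeps the 1/n
normalization over all n^2 ordered terms per hemisphere, self-correlations
included, which exceeds 1 by construction and exists only for
comparability.

GMC enters as a precomputed per-subject, per-region table; its influence
on index A can be regressed out on the pooled sample. Classification is
in-sample: a single feature feeds the ROC directly, combined features are
reduced to a logistic score first (no held-out split; resubstitution ROC
estimates are optimistic — see `classify`). AUC is computed by the rank
(concordance) statistic with ties counted one half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from modreorg.atlas_io import RegionAtlas
from modreorg.connectivity import ConnectivityMatrix

logger = logging.getLogger("modreorg")


def index_a(cm: ConnectivityMatrix, atlas: RegionAtlas,
            pairs: str | None = "insula_module_pairs") -> float:
    """Mean correlation over the homotopic pairs of a named subset."""
    pair_list = atlas.subset_pairs(pairs)
    if not pair_list:
        raise ValueError(f"subset {pairs!r} contains no homotopic pairs")
    vals = [cm.cc[atlas.index_of(i), atlas.index_of(j)]
            for i, j in pair_list]
    return float(np.mean(vals))


def index_b(cm: ConnectivityMatrix, atlas: RegionAtlas,
            pairs: str | None = "insula_module_pairs",
            mode: str = "distinct") -> float:
    """Mean correlation among unilateral members of a named pair set.

    ``mode="distinct"`` (default): mean over all unordered distinct
    same-hemisphere pairs, both hemispheres pooled — bounded by [-1, 1].
    ``mode="literal"``: sum of all n^2 ordered terms per hemisphere
    (self-correlations included) divided by the pair count n.
    """
    pair_list = atlas.subset_pairs(pairs)
    n = len(pair_list)
    if n < 2:
        raise ValueError("index B needs at least 2 pairs (no "
                         "within-hemisphere pairs exist otherwise)")
    left = np.array([atlas.index_of(i) for i, _ in pair_list])
    right = np.array([atlas.index_of(j) for _, j in pair_list])
    bl = cm.cc[np.ix_(left, left)]
    br = cm.cc[np.ix_(right, right)]
    if mode == "literal":
        return float((bl.sum() + br.sum()) / n)
    if mode != "distinct":
        raise ValueError(f"unknown index B mode {mode!r}")
    iu = np.triu_indices(n, k=1)
    return float(np.concatenate([bl[iu], br[iu]]).mean())


def module_gmc(gmc: pd.DataFrame, atlas: RegionAtlas,
               regions: list[int] | str | None = "insula_module_pairs"
               ) -> pd.Series:
    """Per-subject mean GMC over a region set.

    ``gmc`` has one row per subject (columns ``subject_id``, ``group`` and
    one column per region id). ``regions`` may be a named subset, an
    explicit id list, or None for all regions.
    """
    if isinstance(regions, str):
        regions = list(atlas.named_subsets.get(regions, ()))
        if not regions:
            raise ValueError(f"unknown or empty region subset")
    elif regions is None:
        regions = list(atlas.region_ids)
    cols = []
    for rid in regions:
        col = str(rid)
        if col not in gmc.columns:
            raise ValueError(f"GMC table has no column for region {rid}")
        cols.append(col)
    block = gmc[cols]
    bad = block.isna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"missing GMC value for subject "
            f"{gmc['subject_id'].iloc[row]!r}, region {cols[col]}"
        )
    out = block.mean(axis=1)
    out.index = gmc["subject_id"]
    return out


def build_biomarker_table(cms: list[ConnectivityMatrix],
                          atlas: RegionAtlas,
                          gmc: pd.DataFrame | None = None,
                          pairs: str = "insula_module_pairs",
                          index_b_mode: str = "distinct") -> pd.DataFrame:
    """Assemble the per-subject biomarker table (one row per subject)."""
    rows = []
    for cm in cms:
        rows.append({
            "subject_id": cm.subject_id,
            "group": cm.group,
            "index_A": index_a(cm, atlas, pairs),
            "index_B": index_b(cm, atlas, pairs, mode=index_b_mode),
        })
    table = pd.DataFrame(rows)
    if gmc is not None:
        gm = module_gmc(gmc, atlas, pairs)
        table["gmc_module_mean"] = table["subject_id"].map(gm).astype(float)
        if table["gmc_module_mean"].isna().any():
            missing = table.loc[table["gmc_module_mean"].isna(),
                                "subject_id"].tolist()
            raise ValueError(f"no GMC rows for subjects {missing[:5]}")
    return table


def control_gmc(bt: pd.DataFrame,
                measure: str = "index_A") -> pd.DataFrame:
    """Regress the GMC module mean out of a biomarker on the pooled sample.

    Ordinary least squares of ``measure`` on (intercept, gmc_module_mean),
    fitted across all subjects regardless of group; adds a
    ``residual_<measure>`` column. With zero GMC variance the residuals
    degrade to the centered measure (warned).
    """
    if len(bt) < 3:
        raise ValueError("GMC control needs at least 3 subjects pooled")
    y = bt[measure].to_numpy(dtype=float)
    g = bt["gmc_module_mean"].to_numpy(dtype=float)
    out = bt.copy()
    if np.std(g) == 0:
        logger.warning("control_gmc: zero GMC variance; residuals are the "
                       "centered %s", measure)
        out[f"residual_{measure}"] = y - y.mean()
        return out
    x = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    out[f"residual_{measure}"] = y - x @ beta
    return out


@dataclass
class GroupStats:
    measure: str
    groups: tuple[str, str]
    t: float
    p: float
    means: tuple[float, float]
    sds: tuple[float, float]
    cohens_d: float
    n: tuple[int, int]

    def to_dict(self) -> dict:
        return {"measure": self.measure, "groups": list(self.groups),
                "t": self.t, "p": self.p, "means": list(self.means),
                "sds": list(self.sds), "cohens_d": self.cohens_d,
                "n": list(self.n)}


def group_stats(bt: pd.DataFrame, measure: str,
                groups: tuple[str, str] = ("CN", "AD")) -> GroupStats:
    """Welch two-sample t-test plus Cohen's d (pooled SD) for one measure."""
    x = bt.loc[bt["group"] == groups[0], measure].to_numpy(dtype=float)
    y = bt.loc[bt["group"] == groups[1], measure].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError(f"need >= 2 subjects per group, got "
                         f"{len(x)} vs {len(y)}")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    sp = np.sqrt(((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
                 / (len(x) + len(y) - 2))
    d = (x.mean() - y.mean()) / sp if sp > 0 else 0.0
    if np.isnan(t):  # identical constant groups
        t, p = 0.0, 1.0
    return GroupStats(measure=measure, groups=groups, t=float(t), p=float(p),
                      means=(float(x.mean()), float(y.mean())),
                      sds=(float(x.std(ddof=1)), float(y.std(ddof=1))),
                      cohens_d=float(d), n=(len(x), len(y)))


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney concordance) statistic, ties = 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_points(scores: np.ndarray, labels: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Step ROC curve (fpr, tpr, thresholds) from (0, 0) to (1, 1).

    Thresholds sweep the distinct score values from high to low; a subject
    is called positive when its score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.r_[True, np.diff(s) != 0]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    idx = np.flatnonzero(np.r_[distinct[1:], True])
    n1, n0 = tp[-1], fp[-1]
    tpr = np.r_[0.0, tp[idx] / n1]
    fpr = np.r_[0.0, fp[idx] / n0]
    thresholds = np.r_[np.inf, s[idx]]
    return fpr, tpr, thresholds


@dataclass
class ClassificationResult:
    features: tuple[str, ...]
    groups: tuple[str, str]
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    weights: dict[str, float] | None
    flipped: bool
    seed: int

    def sensitivity_specificity(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "sensitivity": self.tpr,
                             "specificity": 1.0 - self.fpr})

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "groups": list(self.groups),
            "fpr": self.fpr.tolist(),
            "tpr": self.tpr.tolist(),
            "thresholds": [float(t) if np.isfinite(t) else None
                           for t in self.thresholds],
            "auc": self.auc,
            "weights": self.weights,
            "orientation_flipped": self.flipped,
            "seed": self.seed,
        }


def classify(bt: pd.DataFrame, features: tuple[str, ...],
             groups: tuple[str, str] = ("CN", "AD"),
             seed: int = 0) -> ClassificationResult:
    """In-sample ROC of one feature or of a fitted logistic combination.

    The second group name is the positive class. For a single feature the
    ROC is built directly from the feature values; for several, a logistic
    score is fitted on all subjects and the ROC built from the fitted
    scores. No held-out split is used, so the resulting AUC is a
    resubstitution estimate and optimistic for unseen subjects. The score
    orientation is chosen so the fitted-sample AUC is >= 0.5 (recorded in
    ``orientation_flipped``). AUC uses the concordance method, ties = 1/2.
    """
    features = tuple(features)
    sub = bt[bt["group"].isin(groups)]
    labels = (sub["group"] == groups[1]).to_numpy()
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need >= 2 subjects in each of the two groups")
    x = sub[list(features)].to_numpy(dtype=float)
    weights = None
    if len(features) == 1:
        scores = x[:, 0]
    else:
        from sklearn.exceptions import ConvergenceWarning
        from sklearn.linear_model import LogisticRegression
        import warnings
        model = LogisticRegression(penalty=None, max_iter=2000,
                                   random_state=seed)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(x, labels)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            logger.warning("classify: logistic fit did not converge "
                           "(likely complete separation); using the "
                           "attained score as a rank ordering")
        scores = model.decision_function(x)
        weights = dict(zip(features, (float(c) for c in model.coef_[0])))
        weights["intercept"] = float(model.intercept_[0])
    auc = auc_rank(scores, labels)
    flipped = auc < 0.5
    if flipped:
        scores = -scores
        auc = 1.0 - auc
    fpr, tpr, thr = roc_points(scores, labels)
    return ClassificationResult(features=features, groups=groups,
                                fpr=fpr, tpr=tpr, thresholds=thr,
                                auc=float(auc), weights=weights,
                                flipped=flipped, seed=seed)
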