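"""Differential-metabolite screening on feature tables.

The screen mirrors standard untargeted-metabolomics practice for comparing
the three root groups: occurrence/response filtering, per-sample median
normalization, one-way ANOVA on log2 intensities combined with a fold-change
rule (P < 0.05 and FC > 2.0, both strict), and the usual multivariate views —
PCA, PLS-DA with R2X/R2Y/Q2, and hierarchical clustering with a heatmap.

For three groups the fold change of a feature is defined as the maximum
pairwise ratio of group means (computed on the raw intensity scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

__all__ = [
    "FeatureTable",
    "DifferentialSet",
    "PLSDAResult",
    "HCAResult",
    "filter_features",
    "median_normalize",
    "anova_fc_screen",
    "pca_scores",
    "plsda_fit",
    "hca_heatmap",
]

QC_LABEL = "QC"


@dataclass
class FeatureTable:
    """Features x samples intensity matrix with per-sample group labels."""

    intensities: pd.DataFrame          # features x samples, >= 0
    groups: pd.Series                  # per sample: group label or "QC"
    planted: list = field(default_factory=list)           # synthetic ground truth
    planted_up_group: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.intensities.columns.equals(self.groups.index):
            raise ValueError("group labels must be indexed by sample id")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def sample_groups(self) -> list:
        return [g for g in self.groups.unique() if g != QC_LABEL]

    def without_qc(self) -> "FeatureTable":
        keep = self.groups != QC_LABEL
        return FeatureTable(
            intensities=self.intensities.loc[:, keep],
            groups=self.groups[keep],
            planted=self.planted,
            planted_up_group=self.planted_up_group,
        )

    def to_csv(self, path) -> None:
        out = self.intensities.copy()
        out.loc["__group__"] = self.groups.values
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col=0)
        groups = pd.Series(df.loc["__group__"], name="group")
        df = df.drop(index="__group__").astype(float)
        return cls(intensities=df, groups=groups)


@dataclass
class DifferentialSet:
    """Features passing the ANOVA + fold-change screen."""

    table: pd.DataFrame                 # feature id, fc, p, up_group
    fc_threshold: float
    p_threshold: float
    undefined: list = field(default_factory=list)   # FC undefined (zero mean)

    @property
    def feature_ids(self) -> list:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def filter_features(
    table: FeatureTable, min_response: float = 5000.0, occurrence: float = 0.8
) -> FeatureTable:
    """Keep features detected at >= ``min_response`` in >= ``occurrence`` of
    the samples of at least one non-QC group."""
    if min_response < 0 or occurrence < 0:
        raise ValueError("thresholds must be non-negative")
    X = table.intensities
    keep = pd.Series(False, index=X.index)
    for g in table.sample_groups:
        cols = table.groups[table.groups == g].index
        frac = (X[cols] >= min_response).mean(axis=1)
        keep |= frac >= occurrence
    if not keep.any():
        raise ValueError("no feature survives the response/occurrence filter")
    return FeatureTable(
        intensities=X.loc[keep],
        groups=table.groups,
        planted=[f for f in table.planted if keep.get(f, False)],
        planted_up_group={
            f: g for f, g in table.planted_up_group.items() if keep.get(f, False)
        },
    )


def median_normalize(table: FeatureTable) -> FeatureTable:
    """Scale each sample so its median intensity equals the global mean median."""
    X = table.intensities
    med = X.median(axis=0)
    if (med == 0).any():
        raise ValueError("a sample has zero median intensity")
    scaled = X * (med.mean() / med)
    return FeatureTable(
        intensities=scaled,
        groups=table.groups,
        planted=table.planted,
        planted_up_group=table.planted_up_group,
    )


def anova_fc_screen(
    table: FeatureTable,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    normalize: bool = True,
) -> DifferentialSet:
    """One-way ANOVA across the root groups plus a fold-change rule.

    ANOVA runs on log2 intensities (after optional median normalization); the
    fold change is the maximum pairwise ratio of group means on the raw
    normalized scale.  Both thresholds are strict: p < p_threshold and
    FC > fc_threshold.  Features whose FC is undefined (a zero group mean) are
    excluded and reported in ``undefined``.
    """
    work = table.without_qc()
    groups = work.sample_groups
    if len(groups) < 2:
        raise ValueError("need at least 2 non-QC groups")
    for g in groups:
        if (work.groups == g).sum() < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    if normalize:
        work = median_normalize(work)
    X = work.intensities
    cols_by_group = {g: work.groups[work.groups == g].index for g in groups}

    rows, undefined = [], []
    for fid, x in X.iterrows():
        by_group = [x[cols_by_group[g]].to_numpy(float) for g in groups]
        means = np.array([v.mean() for v in by_group])
        if np.any(means == 0):
            undefined.append(fid)
            continue
        ratios = means[:, None] / means[None, :]
        fc = float(ratios.max())
        up = groups[int(np.argmax(means))]
        with np.errstate(divide="ignore"):
            logs = [np.log2(np.maximum(v, 1e-12)) for v in by_group]
        _, p = stats.f_oneway(*logs)
        rows.append({"feature": fid, "fc": fc, "p": float(p), "up_group": up})
    df = pd.DataFrame(rows, columns=["feature", "fc", "p", "up_group"])
    df = df.set_index("feature")
    hits = df[(df["p"] < p_threshold) & (df["fc"] > fc_threshold)]
    return DifferentialSet(
        table=hits, fc_threshold=fc_threshold, p_threshold=p_threshold,
        undefined=undefined,
    )


def pca_scores(table: FeatureTable, n_components: int = 3):
    """Mean-centered PCA of samples (log2 intensities).

    Returns ``(scores, explained_variance_ratio)`` with scores indexed by
    sample id; QC samples are retained so their clustering can be inspected.
    """
    from sklearn.decomposition import PCA

    X = np.log2(np.maximum(table.intensities.to_numpy(float).T, 1e-12))
    n_components = int(min(n_components, X.shape[0] - 1, X.shape[1]))
    if n_components < 1:
        raise ValueError("not enough samples/features for PCA")
    if np.allclose(X, X[0]):
        raise ValueError("constant matrix: PCA undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    df = pd.DataFrame(
        scores,
        index=table.intensities.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return df, pca.explained_variance_ratio_


@dataclass
class PLSDAResult:
    n_components: int
    r2x: float
    r2y: float
    q2: float
    scores: pd.DataFrame


def plsda_fit(
    table: FeatureTable,
    labels=None,
    n_components: int = 3,
    cv_folds: int = 7,
    seed: int = 0,
) -> PLSDAResult:
    """PLS-DA: PLS2 against one-hot class membership.

    R2X / R2Y are the cumulative fractions of X and Y variance captured by the
    model; Q2 = 1 - PRESS/SS from k-fold cross-validation.
    """
    from sklearn.cross_decomposition import PLSRegression

    from .evaluation import kfold_indices

    work = table.without_qc()
    if labels is None:
        labels = work.groups.to_numpy()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    X = np.log2(np.maximum(work.intensities.to_numpy(float).T, 1e-12))
    Y = (labels[:, None] == classes[None, :]).astype(float)
    n = X.shape[0]
    a = int(min(n_components, n - 1, X.shape[1]))
    if a < 1:
        raise ValueError("component count exceeds the data rank")

    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    pls = PLSRegression(n_components=a, scale=False)
    pls.fit(Xc, Yc)
    T, P, Q = pls.x_scores_, pls.x_loadings_, pls.y_loadings_
    r2x = 1.0 - ((Xc - T @ P.T) ** 2).sum() / (Xc**2).sum()
    r2y = 1.0 - ((Yc - T @ Q.T) ** 2).sum() / (Yc**2).sum()

    press, ss = 0.0, float((Yc**2).sum())
    for fold in kfold_indices(n, min(cv_folds, n), seed):
        rest = np.setdiff1d(np.arange(n), fold)
        m = PLSRegression(n_components=int(min(a, len(rest) - 1)), scale=False)
        m.fit(X[rest] - X[rest].mean(axis=0), Y[rest] - Y.mean(axis=0))
        pred = m.predict(X[fold] - X[rest].mean(axis=0)) + Y.mean(axis=0)
        press += float(((Y[fold] - pred) ** 2).sum())
    q2 = 1.0 - press / ss

    scores = pd.DataFrame(
        T, index=work.intensities.columns, columns=[f"LV{i+1}" for i in range(a)]
    )
    scores["group"] = labels
    return PLSDAResult(n_components=a, r2x=float(r2x), r2y=float(r2y),
                       q2=float(q2), scores=scores)


@dataclass
class HCAResult:
    feature_linkage: np.ndarray
    sample_linkage: np.ndarray
    feature_order: np.ndarray
    sample_order: np.ndarray
    matrix: pd.DataFrame
    figure_path: str | None = None


def hca_heatmap(
    table_or_matrix,
    metric: str = "euclidean",
    method: str = "average",
    out_png=None,
) -> HCAResult:
    """Hierarchical clustering of features and samples with heatmap ordering.

    Rows (features) are z-scored on log2 intensities before clustering; the
    rendered heatmap runs blue (minimum) to red (maximum).
    """
    if isinstance(table_or_matrix, FeatureTable):
        mat = np.log2(np.maximum(table_or_matrix.intensities.to_numpy(float), 1e-12))
        frame = pd.DataFrame(
            mat,
            index=table_or_matrix.intensities.index,
            columns=table_or_matrix.intensities.columns,
        )
    else:
        frame = pd.DataFrame(table_or_matrix).astype(float)
    if len(frame) < 2:
        raise ValueError("need at least 2 features to cluster")
    if not np.all(np.isfinite(frame.to_numpy())):
        raise ValueError("non-finite values in the matrix")
    z = frame.sub(frame.mean(axis=1), axis=0)
    sd = frame.std(axis=1, ddof=1).replace(0, 1.0)
    z = z.div(sd, axis=0)
    feat_link = linkage(z.to_numpy(), method=method, metric=metric)
    samp_link = linkage(z.to_numpy().T, method=method, metric=metric)
    feat_order = leaves_list(feat_link)
    samp_order = leaves_list(samp_link)

    fig_path = None
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ordered = z.to_numpy()[np.ix_(feat_order, samp_order)]
        fig, ax = plt.subplots(figsize=(6, 6))
        im = ax.imshow(ordered, aspect="auto", cmap="coolwarm")  # blue -> red
        ax.set_xlabel("samples")
        ax.set_ylabel("features")
        fig.colorbar(im, ax=ax, label="z-scored log2 intensity")
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
        fig_path = str(out_png)
    return HCAResult(
        feature_linkage=feat_link,
        sample_linkage=samp_link,
        feature_order=feat_order,
        sample_order=samp_order,
        matrix=z,
        figure_path=fig_path,
    )
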