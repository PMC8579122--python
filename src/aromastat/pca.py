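"""Autoscaled PCA of per-repetition sensory means, with RMSECV model selection.

The PCA input matrix has one row per sample x repetition panel mean and one
column per significant attribute.  Columns are autoscaled (mean 0, sd 1,
ddof=1) before a singular-value decomposition; the number of components is
chosen from the explained variance together with the root mean square error
of leave-one-row-out cross-validation (RMSECV): each row is held out in turn,
the scaling and the PCA are refit on the remaining rows, the held-out row is
projected and reconstructed, and the reconstruction RMSE is aggregated per
component count.  Biplot coordinates pair component scores with correlation
loadings (the correlation between each attribute and each score vector),
which are bounded in [-1, 1].

Signs are fixed so the largest-magnitude loading of every component is
positive, making outputs deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PcaModel", "autoscale", "fit_pca", "rmsecv", "biplot_coords", "per_repetition_means"]


def autoscale(matrix: pd.DataFrame):
    """Centre each column to mean 0 and scale to sd 1 (ddof=1).

    Returns ``(scaled, means, sds)``.  A zero-variance column cannot be
    autoscaled and is rejected by name.
    """
    X = matrix.astype(float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    dead = sds.index[(sds == 0) | ~np.isfinite(sds)].tolist()
    if dead:
        raise ValueError(f"zero-variance column(s) cannot be autoscaled: {dead}")
    return (X - means) / sds, means, sds


@dataclass
class PcaModel:
    """SVD-based PCA of an autoscaled matrix.

    Attributes
    ----------
    loadings : DataFrame (attributes x components)
    scores : DataFrame (rows x components), zero column means
    singular_values : ndarray
    explained : ndarray, per-component explained variance (%)
    cumulative : ndarray, cumulative explained variance (%)
    means, sds : Series, the autoscaling parameters (when fit via columns)
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    singular_values: np.ndarray
    explained: np.ndarray
    cumulative: np.ndarray
    means: pd.Series | None = None
    sds: pd.Series | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def reconstruct(self, k: int) -> pd.DataFrame:
        """Rank-k reconstruction of the autoscaled matrix."""
        if not 0 <= k <= self.n_components:
            raise ValueError(f"k must be in [0, {self.n_components}]")
        T = self.scores.iloc[:, :k].to_numpy()
        P = self.loadings.iloc[:, :k].to_numpy()
        return pd.DataFrame(T @ P.T, index=self.scores.index, columns=self.loadings.index)


def fit_pca(scaled: pd.DataFrame) -> PcaModel:
    """Fit a PCA to an autoscaled matrix by SVD.

    The explained variance share of component a is ``s_a^2 / sum(s^2) * 100``;
    trailing zero singular values of a rank-deficient input simply contribute
    0%.  Component signs follow the largest-magnitude loading.
    """
    X = scaled.to_numpy(dtype=float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    V = Vt.T
    # deterministic sign: largest-|loading| entry of each component positive
    for a in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, a])))
        if V[j, a] < 0:
            V[:, a] = -V[:, a]
            U[:, a] = -U[:, a]
    scores = U * s
    total = float(np.sum(s**2))
    explained = 100.0 * s**2 / total if total > 0 else np.zeros_like(s)
    comps = [f"PC{a + 1}" for a in range(len(s))]
    return PcaModel(
        loadings=pd.DataFrame(V, index=scaled.columns, columns=comps),
        scores=pd.DataFrame(scores, index=scaled.index, columns=comps),
        singular_values=s,
        explained=explained,
        cumulative=np.cumsum(explained),
    )


def rmsecv(matrix: pd.DataFrame, max_k: int):
    """Leave-one-row-out RMSECV per component count, and the selected count.

    For each held-out row the autoscaling and PCA are refit on the training
    rows only.  Each entry of the held-out row (scaled with the training
    parameters) is then predicted from the *other* entries of that row: the
    row with entry j deleted is regressed onto the rank-k loadings with row j
    deleted (least squares), and entry j is reconstructed from the resulting
    scores.  Predicting an entry from itself would make the error curve
    decrease monotonically in k and hide overfitting; the element-wise
    scheme is the standard chemometrics remedy and yields the usual U-shaped
    curve.  RMSECV(k) is the RMS prediction error over all held-out entries;
    k = 0 predicts every entry as the training column mean, so RMSECV(0) is
    the RMS of the scaled held-out rows themselves.  The selected k is the
    global minimum, ties (within 1e-9 relative) resolved toward the smaller
    k.

    Returns ``(errors, selected_k)`` with ``errors`` indexed 0..max_k.
    """
    X = matrix.astype(float)
    n, p = X.shape
    if n < 3:
        raise ValueError("leave-one-out RMSECV needs at least 3 rows")
    if not 1 <= max_k < min(n, p):
        raise ValueError(f"max_k must be in [1, {min(n, p) - 1})")
    sse = np.zeros(max_k + 1)
    count = 0
    for i in range(n):
        train = X.drop(X.index[i])
        scaled, means, sds = autoscale(train)
        model = fit_pca(scaled)
        x = ((X.iloc[i] - means) / sds).to_numpy(dtype=float)
        V = model.loadings.to_numpy()
        sse[0] += float(np.sum(x**2))
        for k in range(1, max_k + 1):
            kk = min(k, V.shape[1])
            Vk = V[:, :kk]
            pred = np.empty_like(x)
            for j in range(p):
                mask = np.arange(p) != j
                t, *_ = np.linalg.lstsq(Vk[mask], x[mask], rcond=None)
                pred[j] = Vk[j] @ t
            sse[k] += float(np.sum((x - pred) ** 2))
        count += p
    errors = np.sqrt(sse / count)
    floor = errors.min()
    # smallest k whose error ties the global minimum (numerical tolerance)
    selected = int(np.flatnonzero(errors <= floor * (1 + 1e-9) + 1e-12)[0])
    return pd.Series(errors, index=pd.RangeIndex(max_k + 1, name="n_components")), selected


def biplot_coords(model: PcaModel, pair=(1, 2)):
    """Scores and correlation loadings for a chosen pair of components.

    Correlation loadings are the Pearson correlations between each autoscaled
    attribute and the two score vectors: ``loading * singular / (sqrt(n-1) *
    sd_attribute)`` with unit attribute sd after autoscaling.  They are
    bounded in [-1, 1] and drawn as vectors on the biplot.

    Returns ``(scores_df, loadings_df)`` with two columns each.
    """
    a, b = pair
    if a == b:
        raise ValueError("biplot needs two distinct components")
    for idx in (a, b):
        if not 1 <= idx <= model.n_components:
            raise ValueError(f"component {idx} out of range 1..{model.n_components}")
    n = model.scores.shape[0]
    cols = [f"PC{a}", f"PC{b}"]
    scores = model.scores[cols].copy()
    corr = model.loadings[cols].to_numpy() * model.singular_values[[a - 1, b - 1]] / np.sqrt(
        n - 1
    )
    loadings = pd.DataFrame(corr, index=model.loadings.index, columns=cols)
    return scores, loadings


def per_repetition_means(
    scores: pd.DataFrame, attributes=None
) -> pd.DataFrame:
    """Sample x repetition panel-mean matrix (rows) by attribute (columns).

    Each entry is the mean score over assessors for one sample in one
    replicate session; this is the PCA input.  Row index: (sample,
    replicate).
    """
    sub = scores if attributes is None else scores[scores["attribute"].isin(attributes)]
    if sub.empty:
        raise ValueError("no scores for the requested attributes")
    mat = (
        sub.groupby(["sample", "replicate", "attribute"])["value"]
        .mean()
        .unstack("attribute")
    )
    if mat.isna().any().any():
        missing = mat.stack(dropna=False)
        missing = missing[missing.isna()]
        raise ValueError(f"missing sample x replicate x attribute cells: {missing.index.tolist()[:10]}")
    if attributes is not None:
        mat = mat[[a for a in attributes if a in mat.columns]]
    return mat
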