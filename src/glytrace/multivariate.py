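"""PCA and LDA-based condition-importance ranking.

The condition-ranking analysis asks which medium condition (carbon source
× dose) best separates the four hepatic cell systems.  Observations are
(metabolite, replicate) pairs labeled by cell model; features are the
conditions; each cell holds the control-normalized abundance of that
metabolite for that replicate under that condition.  Fisher LDA is fit on
this design, per-discriminant importance is the squared discriminant
coefficient, the share of discriminatory power per discriminant is its
eigenvalue divided by the eigenvalue total ("proportion of trace"), and a
condition's score is the proportion-of-trace-weighted sum of its squared
coefficients.  Ranking the scores in descending order identifies the most
influential condition.

PCA is a plain eigendecomposition of the (optionally log10-transformed,
centered, scaled) sample × feature matrix, with a deterministic sign
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .core_io import SampleMeta, SchemaError
from .preprocess import NormalizedTable

__all__ = ["PcaResult", "LdaImportance", "pca", "build_lda_design", "lda_importance", "top_k"]

log = logging.getLogger(__name__)


@dataclass
class PcaResult:
    scores: pd.DataFrame        # sample × component
    loadings: pd.DataFrame      # feature × component
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12) or evr.sum() > 1 + 1e-9:
            raise SchemaError("pca: explained_variance_ratio must be non-increasing and sum <= 1")


@dataclass
class LdaImportance:
    coefficients: pd.DataFrame          # feature × discriminant
    proportion_of_trace: np.ndarray     # per discriminant, sums to 1
    condition_scores: dict[str, float]
    metabolite_scores: dict[str, float]
    ranking: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        pot = self.proportion_of_trace
        if np.any(pot < -1e-12) or abs(pot.sum() - 1) > 1e-9:
            raise SchemaError("lda: proportion_of_trace must be >= 0 and sum to 1")
        if sorted(self.ranking) != sorted(self.condition_scores):
            raise SchemaError("lda: ranking must be a permutation of the conditions")
        if any(v < 0 for v in self.condition_scores.values()):
            raise SchemaError("lda: condition scores must be >= 0")


def _rank(scores: dict[str, float]) -> list[str]:
    """Descending by score; scores equal within 1e-6 relative are ties,
    broken lexicographically by name."""
    scale = max((abs(v) for v in scores.values()), default=1.0) or 1.0
    return sorted(scores, key=lambda c: (-round(scores[c] / scale, 6), c))


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    flip = np.ones(loadings.shape[1])
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            flip[k] = -1.0
    return flip


def pca(
    nt: NormalizedTable,
    center: bool = True,
    scale: bool = False,
    transform: str = "none",
) -> PcaResult:
    """PCA of the sample × metabolite matrix of a normalized table.

    ``transform='log10'`` log-transforms (requires strictly positive
    values); centering subtracts the feature mean; scaling divides by the
    feature standard deviation (ddof=1).  Component sign is fixed so each
    loading column's largest-magnitude entry is positive.
    """
    if nt.values.isna().any().any():
        raise SchemaError("pca: missing values present; apply drop_incomplete first")
    X = nt.values.T.to_numpy(dtype=float)  # samples × features
    if transform == "log10":
        if np.any(X <= 0):
            raise SchemaError("pca: log10 transform requires strictly positive values")
        X = np.log10(X)
    elif transform != "none":
        raise ValueError(f"pca: unknown transform {transform!r}")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    n, p = X.shape
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    ncomp = min(n, p)
    total = float(np.sum(S**2))
    evr = (S**2 / total) if total > 0 else np.zeros(ncomp)
    flip = _fix_signs(Vt.T)
    loadings = Vt.T * flip
    scores = (U * S) * flip
    comps = [f"PC{k + 1}" for k in range(ncomp)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=nt.samples, columns=comps),
        loadings=pd.DataFrame(loadings, index=nt.metabolites, columns=comps),
        explained_variance_ratio=evr,
    )


def build_lda_design(
    nt: NormalizedTable, meta: SampleMeta
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Reshape a control-normalized table into the condition-feature design.

    Rows are (metabolite, replicate) pairs labeled by cell model; columns
    are conditions; values are normalized abundances.  Rows with a missing
    value under any condition are dropped and reported.  Returns
    ``(design, labels, row_info)`` where ``row_info`` has columns
    metabolite/replicate/cell_model aligned with the design rows.
    """
    idx = meta.indexed()
    missing = [s for s in nt.samples if s not in idx.index]
    if missing:
        raise SchemaError(f"build_lda_design: samples without metadata: {missing}")
    sub = idx.loc[nt.samples]
    conditions = sorted(sub["condition"].unique())
    models = sorted(sub["cell_model"].unique())

    for model in models:
        present = set(sub.loc[sub["cell_model"] == model, "condition"])
        gone = [c for c in conditions if c not in present]
        if gone:
            raise SchemaError(f"build_lda_design: condition(s) {gone} entirely missing for {model!r}")

    long = nt.values.rename_axis("metabolite").reset_index().melt(
        id_vars="metabolite", var_name="sample_id", value_name="value"
    )
    long = long.merge(
        sub[["cell_model", "condition", "replicate"]].rename_axis("sample_id").reset_index(),
        on="sample_id",
    )
    wide = long.pivot_table(
        index=["metabolite", "replicate", "cell_model"],
        columns="condition",
        values="value",
        aggfunc="first",
        dropna=False,
    )[conditions]
    complete = wide.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.warning("build_lda_design: dropped %d incomplete (metabolite, replicate) rows", n_dropped)
    wide = wide[complete]
    row_info = wide.index.to_frame(index=False)
    design = pd.DataFrame(wide.to_numpy(), columns=conditions)
    labels = row_info["cell_model"].rename("label")
    return design, labels, row_info


def lda_importance(
    design: pd.DataFrame,
    labels: pd.Series,
    weight_by_trace: bool = True,
    row_info: pd.DataFrame | None = None,
    ridge: float | None = None,
) -> LdaImportance:
    """Fisher LDA with squared-coefficient condition importance.

    Solves the generalized eigenproblem Sb v = λ Sw v; discriminant
    coefficients are scaled to unit pooled within-class variance, with the
    sign of each column fixed so its largest-magnitude entry is positive.
    ``proportion_of_trace[k] = λ_k / Σλ``.  Condition score(j) = Σ_k
    w_k c_{jk}² with w_k the proportion of trace (or 1 if
    ``weight_by_trace=False``).  Metabolite scores (available when
    ``row_info`` carries the metabolite of each design row) are Σ_k
    w_k (mean discriminant-k coordinate of that metabolite's rows)².
    Ranking ties are broken lexicographically by condition name.
    """
    X = design.to_numpy(dtype=float)
    y = np.asarray(labels)
    n, p = X.shape
    classes = np.unique(y)
    C = len(classes)
    if C < 2:
        raise SchemaError("lda_importance: need >= 2 classes")
    if n <= C:
        raise SchemaError("lda_importance: need more observations than classes")

    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for cls in classes:
        Xc = X[y == cls]
        mu = Xc.mean(axis=0)
        d = Xc - mu
        Sw += d.T @ d
        delta = (mu - grand)[:, None]
        Sb += len(Xc) * (delta @ delta.T)

    if ridge is not None:
        Sw = Sw + ridge * np.eye(p)
    try:
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
    except scipy.linalg.LinAlgError:
        if ridge is not None:
            raise SchemaError("lda_importance: within-class scatter singular even with ridge")
        eps = 1e-8 * (np.trace(Sw) / p if np.trace(Sw) > 0 else 1.0)
        log.warning("lda_importance: singular within-class scatter; adding ridge %.3g", eps)
        evals, evecs = scipy.linalg.eigh(Sb, Sw + eps * np.eye(p))
    order = np.argsort(evals)[::-1]
    ndisc = min(C - 1, p)
    evals = np.clip(evals[order][:ndisc], 0, None)
    V = evecs[:, order][:, :ndisc]

    # unit pooled within-class variance per discriminant
    Sw_cov = Sw / (n - C)
    for k in range(ndisc):
        wvar = float(V[:, k] @ Sw_cov @ V[:, k])
        if wvar > 0:
            V[:, k] /= np.sqrt(wvar)
    V = V * _fix_signs(V)

    total = float(evals.sum())
    pot = evals / total if total > 0 else np.full(ndisc, 1.0 / ndisc)
    w = pot if weight_by_trace else np.ones(ndisc)

    cond_names = list(design.columns)
    scores = (V**2) @ w
    condition_scores = {c: float(s) for c, s in zip(cond_names, scores)}
    ranking = _rank(condition_scores)

    metabolite_scores: dict[str, float] = {}
    if row_info is not None and "metabolite" in row_info.columns:
        coords = (X - grand) @ V  # observation coordinates on the discriminants
        cdf = pd.DataFrame(coords, index=row_info["metabolite"].to_numpy())
        means = cdf.groupby(level=0).mean()
        mscores = (means.to_numpy() ** 2) @ w
        metabolite_scores = {m: float(s) for m, s in zip(means.index, mscores)}

    disc = [f"LD{k + 1}" for k in range(ndisc)]
    return LdaImportance(
        coefficients=pd.DataFrame(V, index=cond_names, columns=disc),
        proportion_of_trace=pot,
        condition_scores=condition_scores,
        metabolite_scores=metabolite_scores,
        ranking=ranking,
    )


def top_k(imp: LdaImportance, k: int) -> list[str]:
    """Top-k metabolites by importance score, descending; ties broken
    lexicographically."""
    if k < 1:
        raise ValueError("top_k: k must be >= 1")
    return _rank(imp.metabolite_scores)[:k]
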