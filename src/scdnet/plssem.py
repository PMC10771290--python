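"""Partial least squares path modeling (PLS-SEM) with reflective blocks.

Implements the classical iterative PLS path-modeling algorithm with mode-A
(reflective) measurement: indicators are standardized, construct scores are
weighted sums of their block's indicators, inner proxies are formed from
neighbouring construct scores under a configurable weighting scheme
(``path`` by default), and outer weights are updated as the correlation of
each indicator with its construct's inner proxy until the weights settle.
Path coefficients are then ordinary least squares among the standardized
construct scores.

The module also provides the standard reflective measurement diagnostics —
composite reliability rho_c = (sum lambda)^2 / [(sum lambda)^2 + sum(1 -
lambda^2)], average variance extracted AVE = mean(lambda^2) and the
indicator-by-construct cross-loading matrix — plus percentile-bootstrap
path inference and a label-permutation multigroup comparison of path
coefficients between two independently fitted groups.

Conventions fixed here (and documented in the package methods note):
standardization uses the sample standard deviation (ddof=1); construct
score signs are anchored so each block's largest-|loading| indicator loads
positively; permutation p-values use the add-one convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "PLSFit",
    "MGAResult",
    "BootstrapResult",
    "fit_pls_path_model",
    "composite_reliability",
    "average_variance_extracted",
    "cross_loading_matrix",
    "compute_composite_scores",
    "bootstrap_path_significance",
    "permutation_multigroup_test",
]

_SCHEMES = ("centroid", "factorial", "path")


@dataclass(frozen=True)
class ModelSpec:
    """Structural and measurement specification of a PLS path model.

    Parameters
    ----------
    constructs:
        Ordered construct (latent variable) names.
    indicator_map:
        Mapping indicator column -> construct name; every indicator belongs
        to exactly one construct.
    inner_paths:
        Directed acyclic edges ``(source, target)`` between constructs.
    weighting_scheme:
        Inner weighting scheme, one of ``centroid``, ``factorial``, ``path``.
    """

    constructs: tuple[str, ...]
    indicator_map: dict[str, str]
    inner_paths: tuple[tuple[str, str], ...]
    weighting_scheme: str = "path"
    max_iter: int = 300
    tol: float = 1e-7

    def __init__(
        self,
        constructs,
        indicator_map,
        inner_paths,
        weighting_scheme: str = "path",
        max_iter: int = 300,
        tol: float = 1e-7,
    ) -> None:
        object.__setattr__(self, "constructs", tuple(constructs))
        object.__setattr__(self, "indicator_map", dict(indicator_map))
        object.__setattr__(
            self, "inner_paths", tuple((str(a), str(b)) for a, b in inner_paths)
        )
        object.__setattr__(self, "weighting_scheme", weighting_scheme)
        object.__setattr__(self, "max_iter", int(max_iter))
        object.__setattr__(self, "tol", float(tol))
        self._validate()

    def _validate(self) -> None:
        if self.weighting_scheme not in _SCHEMES:
            raise ValueError(
                f"weighting_scheme must be one of {_SCHEMES}, "
                f"got {self.weighting_scheme!r}"
            )
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        known = set(self.constructs)
        if len(known) != len(self.constructs):
            raise ValueError("construct names must be unique")
        for ind, c in self.indicator_map.items():
            if c not in known:
                raise ValueError(f"indicator {ind!r} maps to unknown construct {c!r}")
        empty = known - set(self.indicator_map.values())
        if empty:
            raise ValueError(f"constructs without indicators: {sorted(empty)}")
        for a, b in self.inner_paths:
            if a not in known or b not in known:
                raise ValueError(f"inner path ({a!r}, {b!r}) uses unknown construct")
            if a == b:
                raise ValueError("self-loop in inner paths")
        self._toposort()  # raises on cycles

    def _toposort(self) -> list[str]:
        indeg = {c: 0 for c in self.constructs}
        for _, b in self.inner_paths:
            indeg[b] += 1
        order, stack = [], [c for c in self.constructs if indeg[c] == 0]
        succ: dict[str, list[str]] = {c: [] for c in self.constructs}
        for a, b in self.inner_paths:
            succ[a].append(b)
        while stack:
            c = stack.pop()
            order.append(c)
            for b in succ[c]:
                indeg[b] -= 1
                if indeg[b] == 0:
                    stack.append(b)
        if len(order) != len(self.constructs):
            raise ValueError("inner_paths must be acyclic")
        return order

    @property
    def indicators(self) -> list[str]:
        """Indicators grouped by construct, in construct order."""
        return [
            ind
            for c in self.constructs
            for ind, cc in self.indicator_map.items()
            if cc == c
        ]

    def predecessors(self, construct: str) -> list[str]:
        return [a for a, b in self.inner_paths if b == construct]

    def endogenous(self) -> list[str]:
        return [c for c in self.constructs if self.predecessors(c)]


@dataclass
class PLSFit:
    """Fitted PLS path model for one sample."""

    model: ModelSpec
    outer_weights: pd.Series  # per indicator
    loadings: pd.Series  # per indicator, correlation with own score
    path_coefficients: dict[tuple[str, str], float]
    scores: pd.DataFrame  # subject x construct, standardized
    r_squared: dict[str, float]
    rho_c: dict[str, float]
    ave: dict[str, float]
    cross_loadings: pd.DataFrame  # indicator x construct
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class MGAResult:
    """Permutation multigroup comparison of one path coefficient."""

    path: tuple[str, str]
    observed_diff: float
    beta_a: float
    beta_b: float
    n_permutations: int
    n_excluded: int
    p_value: float
    seed: int


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile-bootstrap inference for the inner path coefficients."""

    ci_lower: dict[tuple[str, str], float]
    ci_upper: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    n_boot: int
    n_skipped: int
    seed: int


# ----------------------------------------------------------------------
# core numpy engine


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    return (X - mu) / sd


def _fit_core(
    X: np.ndarray,
    blocks: list[np.ndarray],
    pred_idx: list[np.ndarray],
    neigh_idx: list[np.ndarray],
    scheme: str,
    max_iter: int,
    tol: float,
):
    """Iterative PLS weight estimation on pre-standardized X.

    blocks[k]    : column indices of construct k's indicators
    pred_idx[k]  : construct indices of k's structural predecessors
    neigh_idx[k] : construct indices adjacent to k in the inner graph

    Returns (weights per block, scores n x k, n_iter, converged).
    """
    n, p = X.shape
    k = len(blocks)
    inv = 1.0 / (n - 1)
    col_block = np.empty(p, dtype=int)
    for j, b in enumerate(blocks):
        col_block[b] = j
    starts = np.array([b[0] for b in blocks])
    succ_idx = [
        np.setdiff1d(neigh_idx[j], pred_idx[j], assume_unique=False)
        for j in range(k)
    ]
    w = np.empty(p)
    for b in blocks:
        w[b] = 1.0 / np.sqrt(len(b))

    def make_scores(wvec):
        Y = np.add.reduceat(X * wvec, starts, axis=1)  # blocks are contiguous
        mu = Y.mean(axis=0)
        Yc = Y - mu
        sd = np.sqrt((Yc * Yc).sum(axis=0) * inv)
        if np.any(sd == 0):
            raise FloatingPointError("degenerate construct score (zero variance)")
        return Yc / sd

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        Y = make_scores(w)
        C = (Y.T @ Y) * inv
        E = np.zeros((k, k))
        for j in range(k):
            nb = neigh_idx[j]
            if nb.size == 0:
                continue
            if scheme == "centroid":
                E[j, nb] = np.sign(C[j, nb])
            elif scheme == "factorial":
                E[j, nb] = C[j, nb]
            else:  # path
                pj = pred_idx[j]
                if pj.size:
                    E[j, pj] = np.linalg.solve(C[np.ix_(pj, pj)], C[pj, j])
                sj = succ_idx[j]
                if sj.size:
                    E[j, sj] = C[j, sj]
        Z = Y @ E.T
        mu = Z.mean(axis=0)
        Zc = Z - mu
        zsd = np.sqrt((Zc * Zc).sum(axis=0) * inv)
        dead = zsd == 0
        if np.any(dead):  # isolated construct: keep its own score as proxy
            Zc[:, dead] = Y[:, dead]
            zsd = np.where(dead, 1.0, zsd)
        Zs = Zc / zsd
        new_w = (X * Zs[:, col_block]).sum(axis=0) * inv
        norms = np.sqrt(np.add.reduceat(new_w**2, starts))
        if np.any(norms == 0):
            raise FloatingPointError("outer weights collapsed to zero")
        new_w = new_w / norms[col_block]
        delta = float(np.max(np.abs(new_w - w)))
        w = new_w
        if delta < tol:
            converged = True
            break
    Y = make_scores(w)
    return [w[b] for b in blocks], Y, n_iter, converged


def _paths_and_r2(Y: np.ndarray, pred_idx: list[np.ndarray]):
    """OLS path coefficients of each endogenous score on its predecessors."""
    n = Y.shape[0]
    betas: dict[int, np.ndarray] = {}
    r2: dict[int, float] = {}
    for j, p in enumerate(pred_idx):
        if p.size == 0:
            continue
        Xp = Y[:, p]
        coef, *_ = np.linalg.lstsq(Xp, Y[:, j], rcond=None)
        resid = Y[:, j] - Xp @ coef
        betas[j] = coef
        r2[j] = float(1.0 - (resid @ resid) / (n - 1))
    return betas, r2


def _prepare(data: pd.DataFrame, model: ModelSpec):
    cols = model.indicators
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"indicators missing from data: {missing}")
    X = data[cols].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("missing values in indicator data are not supported")
    sd = X.std(axis=0, ddof=1)
    dead = [cols[i] for i in np.flatnonzero(sd == 0)]
    if dead:
        raise ValueError(f"zero-variance indicator(s): {dead}")
    blocks = []
    start = 0
    for c in model.constructs:
        size = sum(1 for i in cols if model.indicator_map[i] == c)
        blocks.append(np.arange(start, start + size))
        start += size
    cidx = {c: j for j, c in enumerate(model.constructs)}
    pred_idx = [
        np.array([cidx[a] for a in model.predecessors(c)], dtype=int)
        for c in model.constructs
    ]
    neigh = [set() for _ in model.constructs]
    for a, b in model.inner_paths:
        neigh[cidx[a]].add(cidx[b])
        neigh[cidx[b]].add(cidx[a])
    neigh_idx = [np.array(sorted(s), dtype=int) for s in neigh]
    return cols, _standardize(X), blocks, pred_idx, neigh_idx


def fit_pls_path_model(data: pd.DataFrame, model: ModelSpec) -> PLSFit:
    """Fit a PLS path model with mode-A measurement to an indicator table.

    ``data`` must contain one column per mapped indicator; additional
    columns (ids, group labels) are ignored.  Construct scores are
    standardized (ddof=1) and sign-anchored so that each construct's
    largest-|loading| indicator loads positively.
    """
    cols, X, blocks, pred_idx, neigh_idx = _prepare(data, model)
    w, Y, n_iter, converged = _fit_core(
        X, blocks, pred_idx, neigh_idx, model.weighting_scheme, model.max_iter, model.tol
    )
    if not converged:
        warnings.warn(
            f"PLS estimation did not converge in {model.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )

    n = X.shape[0]
    # sign anchoring per construct before any diagnostic is computed
    for j, b in enumerate(blocks):
        lam = (X[:, b].T @ Y[:, j]) / (n - 1)
        lead = int(np.argmax(np.abs(lam)))
        if lam[lead] < 0:
            Y[:, j] = -Y[:, j]
            w[j] = -w[j]

    cross = (X.T @ Y) / (n - 1)  # indicator x construct correlations
    loadings = np.empty(len(cols))
    for j, b in enumerate(blocks):
        loadings[b] = cross[b, j]
    betas_idx, r2_idx = _paths_and_r2(Y, pred_idx)

    path_coefficients: dict[tuple[str, str], float] = {}
    for j, p in enumerate(pred_idx):
        if p.size == 0:
            continue
        tgt = model.constructs[j]
        for pos, src_idx in enumerate(p):
            path_coefficients[(model.constructs[src_idx], tgt)] = float(
                betas_idx[j][pos]
            )
    r_squared = {model.constructs[j]: v for j, v in r2_idx.items()}

    lam_by_construct = {
        c: loadings[blocks[j]] for j, c in enumerate(model.constructs)
    }
    rho_c = {c: composite_reliability(l) for c, l in lam_by_construct.items()}
    ave = {c: average_variance_extracted(l) for c, l in lam_by_construct.items()}

    index = data.index
    subject_ids = (
        data["subject_id"] if "subject_id" in data.columns else pd.Series(index, index=index)
    )
    scores = pd.DataFrame(Y, columns=list(model.constructs), index=index)
    scores.insert(0, "subject_id", subject_ids)

    outer = pd.Series(
        np.concatenate([w[j] for j in range(len(blocks))]), index=cols, name="w"
    )
    return PLSFit(
        model=model,
        outer_weights=outer,
        loadings=pd.Series(loadings, index=cols, name="lambda"),
        path_coefficients=path_coefficients,
        scores=scores,
        r_squared=r_squared,
        rho_c=rho_c,
        ave=ave,
        cross_loadings=pd.DataFrame(cross, index=cols, columns=list(model.constructs)),
        converged=converged,
        n_iter=n_iter,
    )


# ----------------------------------------------------------------------
# measurement diagnostics


def composite_reliability(loadings) -> float:
    """rho_c = (sum lambda)^2 / [(sum lambda)^2 + sum(1 - lambda^2)]."""
    lam = np.asarray(loadings, dtype=float)
    if lam.size == 0:
        raise ValueError("empty loading vector")
    if np.any(np.abs(lam) > 1 + 1e-12):
        raise ValueError("loadings must lie in [-1, 1]")
    s2 = lam.sum() ** 2
    denom = s2 + np.sum(1.0 - lam**2)
    return float(s2 / denom) if denom > 0 else 0.0


def average_variance_extracted(loadings) -> float:
    """AVE = mean of squared loadings."""
    lam = np.asarray(loadings, dtype=float)
    if lam.size == 0:
        raise ValueError("empty loading vector")
    if np.any(np.abs(lam) > 1 + 1e-12):
        raise ValueError("loadings must lie in [-1, 1]")
    return float(np.mean(lam**2))


def cross_loading_matrix(data: pd.DataFrame, fit: PLSFit) -> pd.DataFrame:
    """Indicator-by-construct correlation matrix with a discriminant flag.

    Entry (i, c) is the Pearson correlation of indicator i with construct
    score c.  The returned frame carries the indicator's own construct and
    ``discriminant_valid``: True iff the own-construct loading is the
    largest in absolute value in its row.
    """
    model = fit.model
    cols = model.indicators
    X = _standardize(data[cols].to_numpy(float))
    Y = fit.scores[list(model.constructs)].to_numpy(float)
    n = X.shape[0]
    cross = (X.T @ Y) / (n - 1)
    out = pd.DataFrame(cross, index=cols, columns=list(model.constructs))
    own = [model.indicator_map[i] for i in cols]
    out.insert(0, "construct", own)
    out["discriminant_valid"] = [
        abs(out.loc[i, c]) >= out[list(model.constructs)].loc[i].abs().max() - 1e-12
        for i, c in zip(cols, own)
    ]
    return out


def compute_composite_scores(fit: PLSFit, target_construct: str) -> pd.Series:
    """Standardized per-subject composite score of one construct.

    The score is the construct's standardized weighted indicator sum from
    the fit; for the memory-complaints target the sign convention means
    higher score = more complaints (see sign anchoring).
    """
    if target_construct not in fit.model.constructs:
        raise KeyError(f"unknown construct {target_construct!r}")
    if not fit.converged:
        raise RuntimeError("composite scores require a converged fit")
    s = fit.scores[target_construct].copy()
    s.index = fit.scores["subject_id"]
    s.name = f"composite[{target_construct}]"
    return s


# ----------------------------------------------------------------------
# resampling inference


def _fit_betas(X, blocks, pred_idx, neigh_idx, scheme, max_iter, tol):
    """Weights + per-path betas on raw (unstandardized) indicator matrix."""
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise FloatingPointError("zero-variance indicator in resample")
    Xs = (X - X.mean(axis=0)) / sd
    w, Y, _, conv = _fit_core(Xs, blocks, pred_idx, neigh_idx, scheme, max_iter, tol)
    # anchor signs as in the main fit
    n = Xs.shape[0]
    for j, b in enumerate(blocks):
        lam = (Xs[:, b].T @ Y[:, j]) / (n - 1)
        if lam[int(np.argmax(np.abs(lam)))] < 0:
            Y[:, j] = -Y[:, j]
            w[j] = -w[j]
    betas, _ = _paths_and_r2(Y, pred_idx)
    return w, betas, conv


def _beta_lookup(model: ModelSpec, betas_idx) -> dict[tuple[str, str], float]:
    out = {}
    cidx = {c: j for j, c in enumerate(model.constructs)}
    for j, c in enumerate(model.constructs):
        preds = model.predecessors(c)
        if not preds:
            continue
        for pos, a in enumerate(preds):
            out[(a, c)] = float(betas_idx[j][pos])
    return out


def bootstrap_path_significance(
    data: pd.DataFrame,
    model: ModelSpec,
    n_boot: int,
    seed: int,
) -> BootstrapResult:
    """Percentile-bootstrap confidence intervals and p-values per path.

    Bootstrap fits are sign-aligned to the original fit (construct scores
    anchored the same way) before the path distributions are aggregated.
    Resamples with a zero-variance indicator or a non-convergent fit are
    skipped and counted.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if n_boot < 100:
        warnings.warn(
            "n_boot < 100 gives unstable percentile intervals",
            RuntimeWarning,
            stacklevel=2,
        )
    cols, _, blocks, pred_idx, neigh_idx = _prepare(data, model)
    X = data[cols].to_numpy(float)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    draws: dict[tuple[str, str], list[float]] = {
        (a, b): [] for a, b in model.inner_paths
    }
    n_skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            _, betas_idx, conv = _fit_betas(
                X[idx], blocks, pred_idx, neigh_idx,
                model.weighting_scheme, model.max_iter, model.tol,
            )
        except FloatingPointError:
            n_skipped += 1
            continue
        if not conv:
            n_skipped += 1
            continue
        for edge, val in _beta_lookup(model, betas_idx).items():
            draws[edge].append(val)

    lo, hi, pvals = {}, {}, {}
    for edge, vals in draws.items():
        arr = np.asarray(vals)
        if arr.size == 0:
            raise RuntimeError("all bootstrap resamples failed")
        lo[edge] = float(np.percentile(arr, 2.5))
        hi[edge] = float(np.percentile(arr, 97.5))
        n_ok = arr.size
        p_low = (np.sum(arr <= 0) + 1) / (n_ok + 1)
        p_high = (np.sum(arr >= 0) + 1) / (n_ok + 1)
        pvals[edge] = float(min(1.0, 2.0 * min(p_low, p_high)))
    return BootstrapResult(
        ci_lower=lo, ci_upper=hi, p_values=pvals,
        n_boot=n_boot, n_skipped=n_skipped, seed=seed,
    )


def permutation_multigroup_test(
    data_a: pd.DataFrame,
    data_b: pd.DataFrame,
    model: ModelSpec,
    path: tuple[str, str],
    n_perm: int,
    seed: int,
) -> MGAResult:
    """Permutation test of |beta_A - beta_B| for one inner path.

    Group labels are permuted over the pooled subjects preserving group
    sizes; both group models are refitted per permutation and the absolute
    path-coefficient difference collected.  The p-value uses the add-one
    convention (count of permuted diffs >= observed + 1) / (n + 1).
    Non-convergent permutations are excluded from the count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    path = (str(path[0]), str(path[1]))
    if path not in set(model.inner_paths):
        raise KeyError(f"path {path} not in model")
    cols, _, blocks, pred_idx, neigh_idx = _prepare(
        pd.concat([data_a, data_b], axis=0, ignore_index=True), model
    )
    Xa = data_a[cols].to_numpy(float)
    Xb = data_b[cols].to_numpy(float)
    args = (blocks, pred_idx, neigh_idx, model.weighting_scheme,
            model.max_iter, model.tol)

    def beta_of(X):
        _, betas_idx, conv = _fit_betas(X, *args)
        if not conv:
            raise FloatingPointError("non-convergent fit")
        return _beta_lookup(model, betas_idx)[path]

    beta_a = beta_of(Xa)
    beta_b = beta_of(Xb)
    observed = abs(beta_a - beta_b)

    pool = np.vstack([Xa, Xb])
    na = Xa.shape[0]
    n_total = pool.shape[0]
    rng = np.random.default_rng(seed)
    n_valid = 0
    n_excluded = 0
    count_ge = 0
    for _ in range(n_perm):
        idx = rng.permutation(n_total)
        try:
            diff = abs(beta_of(pool[idx[:na]]) - beta_of(pool[idx[na:]]))
        except FloatingPointError:
            n_excluded += 1
            continue
        n_valid += 1
        if diff >= observed:
            count_ge += 1
    p = (count_ge + 1) / (n_valid + 1)
    return MGAResult(
        path=path,
        observed_diff=float(observed),
        beta_a=float(beta_a),
        beta_b=float(beta_b),
        n_permutations=n_valid,
        n_excluded=n_excluded,
        p_value=float(p),
        seed=seed,
    )
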