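"""Behavioral partial least squares: cross-covariance SVD with permutation
significance and bootstrap stability.

X holds brain-change columns (residualized for age, sex and subject, then
normalized within training groups); Y holds cortisol-change columns
(normalized within groups).  Latent components are singular triplets of
R = Y'X/(n-1): behavior saliences U, brain saliences V, singular values s.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .contrasts import correct_multiplicity

__all__ = [
    "residualize_brain",
    "normalize_within_group",
    "PLSResult",
    "pls_fit",
    "permutation_test",
    "bootstrap_loadings",
    "per_group_expression",
]

logger = logging.getLogger(__name__)


def residualize_brain(
    X: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    subject_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Residualize each column on age, sex, and subject indicators.

    The subject random effect is absorbed as fixed indicator columns (one
    dropped).  If the design would be saturated (at least as many parameters
    as rows), falls back to age + sex only with a warning.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    sex = np.asarray(sex)
    sex_num = (
        sex.astype(float)
        if np.issubdtype(sex.dtype, np.number)
        else (sex == sorted(set(sex.tolist()))[0]).astype(float)
    )
    cols = [np.ones(n), np.asarray(age, dtype=float), sex_num]
    if subject_ids is not None:
        uniq = sorted(set(np.asarray(subject_ids).tolist()))
        if len(cols) + len(uniq) - 1 >= n:
            warnings.warn("subject indicators saturate the design; "
                          "residualizing on age + sex only")
        else:
            for sid in uniq[1:]:
                cols.append((np.asarray(subject_ids) == sid).astype(float))
    D = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    return X - D @ beta


def normalize_within_group(M: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Z-score every column within each group (ddof=1).

    Zero-variance columns within a group are centered only, with a warning.
    """
    M = np.asarray(M, dtype=float).copy()
    groups = np.asarray(groups)
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 rows")
        block = M[mask]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            warnings.warn(f"zero within-group SD in group {g!r}; "
                          "column(s) centered only")
            sd = np.where(zero, 1.0, sd)
        M[mask] = (block - mu) / sd
    return M


@dataclass
class PLSResult:
    singular_values: np.ndarray  # (L,), descending
    covexp: np.ndarray  # percent of cross-covariance per LC, sums to 100
    brain_saliences: np.ndarray  # V, p x L
    behavior_saliences: np.ndarray  # U, q x L
    brain_scores: np.ndarray  # X @ V, n x L
    behavior_scores: np.ndarray  # Y @ U, n x L
    brain_loadings: np.ndarray  # corr(X_j, brain score), p x L
    behavior_loadings: np.ndarray  # corr(Y_k, behavior score), q x L
    perm_p: np.ndarray | None = None
    perm_q: np.ndarray | None = None
    loading_cis: dict = field(default_factory=dict)


def _corr_cols(M: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """corr of each column of M with each score column; nan-safe for zero var."""
    Mc = M - M.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    ms = np.sqrt((Mc ** 2).sum(axis=0))
    ss = np.sqrt((Sc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Mc.T @ Sc) / np.outer(ms, ss)


def _cross_svd(X: np.ndarray, Y: np.ndarray):
    n = X.shape[0]
    R = Y.T @ X / (n - 1)
    U, s, Vt = linalg.svd(R, full_matrices=False)
    return U, s, Vt.T


def pls_fit(X: np.ndarray, Y: np.ndarray) -> PLSResult:
    """Deterministic PLS: SVD of the brain-behavior cross-covariance.

    Each LC is oriented so the largest-magnitude behavior salience is
    positive.  ``covexp`` is s_i^2 / sum s^2 as a percentage.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("NaN in PLS input")
    U, s, V = _cross_svd(X, Y)
    for i in range(len(s)):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            V[:, i] = -V[:, i]
    tot = float((s ** 2).sum())
    covexp = 100.0 * s ** 2 / tot if tot > 0 else np.zeros_like(s)
    brain_scores = X @ V
    behavior_scores = Y @ U
    return PLSResult(
        singular_values=s,
        covexp=covexp,
        brain_saliences=V,
        behavior_saliences=U,
        brain_scores=brain_scores,
        behavior_scores=behavior_scores,
        brain_loadings=_corr_cols(X, brain_scores),
        behavior_loadings=_corr_cols(Y, behavior_scores),
    )


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    groups: np.ndarray | None = None,
    blocks: np.ndarray | None = None,
):
    """Permutation p per latent component with BH-FDR across components.

    Rows of Y are shuffled uniformly by default (within groups if ``groups``
    is given); p_i = (1 + #{s_i^perm >= s_i}) / (n_perm + 1).

    When subjects contribute several rows, uniform row shuffling breaks the
    within-subject dependence that both matrices share (e.g. induced by
    subject-level residualization or by consecutive change scores sharing a
    timepoint) and the test becomes anti-conservative.  Passing per-row
    subject labels as ``blocks`` swaps whole subject blocks between subjects
    with the same number of rows instead, which keeps rows exchangeable
    under the null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    _, s_obs, _ = _cross_svd(X, Y)
    rng = np.random.default_rng(seed)
    n = X.shape[0]

    size_classes: list[list[np.ndarray]] = []
    if blocks is not None:
        blocks = np.asarray(blocks)
        by_size: dict[int, list[np.ndarray]] = {}
        for b in sorted(set(blocks.tolist())):
            idx = np.flatnonzero(blocks == b)
            by_size.setdefault(len(idx), []).append(idx)
        size_classes = list(by_size.values())

    exceed = np.zeros_like(s_obs)
    for _ in range(n_perm):
        if blocks is not None:
            perm = np.arange(n)
            for members in size_classes:
                shuffled = rng.permutation(len(members))
                for src, dst in enumerate(shuffled):
                    perm[members[src]] = members[dst]
        elif groups is not None:
            perm = np.arange(n)
            for g in np.unique(groups):
                idx = np.flatnonzero(groups == g)
                perm[idx] = idx[rng.permutation(len(idx))]
        else:
            perm = rng.permutation(n)
        _, s_p, _ = _cross_svd(X, Y[perm])
        exceed += s_p >= s_obs
    p = (1.0 + exceed) / (n_perm + 1.0)
    q = correct_multiplicity(p, method="bh")
    return p, q


def bootstrap_loadings(
    X: np.ndarray,
    Y: np.ndarray,
    n_boot: int = 100,
    seed: int | None = None,
    subject_ids: np.ndarray | None = None,
    max_retries: int = 10,
):
    """Percentile (2.5/97.5) CIs of loading correlations under row resampling.

    Rows are resampled with replacement as subject blocks when a subject
    spans multiple rows.  Each refit is sign-aligned to the original
    solution by salience congruence.  Degenerate resamples (any constant
    column) are redrawn, up to ``max_retries`` times.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("bootstrap requires n >= 10 rows")
    base = pls_fit(X, Y)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    if subject_ids is not None:
        subject_ids = np.asarray(subject_ids)
        blocks = [np.flatnonzero(subject_ids == s)
                  for s in sorted(set(subject_ids.tolist()))]
    else:
        blocks = [np.array([i]) for i in range(n)]

    brain_draws, behavior_draws = [], []
    for _ in range(n_boot):
        for _retry in range(max_retries + 1):
            pick = rng.integers(len(blocks), size=len(blocks))
            idx = np.concatenate([blocks[i] for i in pick])
            Xb, Yb = X[idx], Y[idx]
            if Xb.std(axis=0).min() > 0 and Yb.std(axis=0).min() > 0:
                break
        else:
            raise RuntimeError("could not draw a non-degenerate resample")
        res = pls_fit(Xb, Yb)
        L = min(res.behavior_saliences.shape[1],
                base.behavior_saliences.shape[1])
        for i in range(L):
            congruence = (
                base.behavior_saliences[:, i] @ res.behavior_saliences[:, i]
                + base.brain_saliences[:, i] @ res.brain_saliences[:, i]
            )
            if congruence < 0:
                res.behavior_saliences[:, i] *= -1
                res.brain_saliences[:, i] *= -1
        scores_b = Xb @ res.brain_saliences
        scores_y = Yb @ res.behavior_saliences
        brain_draws.append(_corr_cols(Xb, scores_b))
        behavior_draws.append(_corr_cols(Yb, scores_y))

    brain_draws = np.stack(brain_draws)  # n_boot x p x L
    behavior_draws = np.stack(behavior_draws)
    return {
        "brain": (
            np.nanpercentile(brain_draws, 2.5, axis=0),
            np.nanpercentile(brain_draws, 97.5, axis=0),
        ),
        "behavior": (
            np.nanpercentile(behavior_draws, 2.5, axis=0),
            np.nanpercentile(behavior_draws, 97.5, axis=0),
        ),
    }


def per_group_expression(result: PLSResult, groups: np.ndarray) -> dict:
    """Pearson r of brain vs behavior scores overall and per group, per LC."""
    groups = np.asarray(groups)
    L = result.brain_scores.shape[1]

    def _r(mask) -> list[float]:
        xs, ys = result.brain_scores[mask], result.behavior_scores[mask]
        out = []
        for i in range(L):
            x, y = xs[:, i], ys[:, i]
            if x.std() == 0 or y.std() == 0:
                out.append(float("nan"))
            else:
                out.append(float(np.corrcoef(x, y)[0, 1]))
        return out

    out = {"Overall": _r(np.ones(len(groups), dtype=bool))}
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() < 3:
            raise ValueError(f"group {g!r} has n < 3")
        out[str(g)] = _r(mask)
    return out
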