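"""Phylogenetically informed iterative random-forest trait imputation.

Trait databases are incomplete, and missingness is blockwise: a species
missing one life-history trait typically misses several. Missing traits
are filled with an iterative random-forest scheme: initialize missing
cells with column means, then repeatedly regress each trait's observed
cells on all other columns and re-predict the missing ones, until the
standardized change between successive imputations first increases
(returning the last improving iterate). Phylogenetic position enters as
extra predictor columns: the leading eigenvectors (default ten) of the
double-centred squared patristic distance matrix, i.e. a principal
coordinates embedding of the tree. Close relatives get similar
eigenvector rows, letting the forests exploit phylogenetic signal.

Because the goal is to place species correctly in the functional space
rather than to recover raw trait values, imputation quality is measured
in position space: species with complete traits are artificially masked
with missingness patterns copied from genuinely incomplete rows, imputed
alongside them, and the normalized root mean square error (NRMSE) between
true and imputed positions — RMSE divided by the occupied range of each
functional dimension — is averaged over repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import dendropy
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import InputError
from .space import FunctionalSpace, project
from .synthetic import mask_traits

__all__ = [
    "PhyloEigenvectors",
    "ImputationResult",
    "ImputationEvaluation",
    "phylo_eigenvectors",
    "average_eigenvectors",
    "rf_impute",
    "evaluate_imputation",
]


@dataclass(frozen=True)
class PhyloEigenvectors:
    """Species x k phylogenetic eigenvector matrix."""

    vectors: pd.DataFrame  # index: species, columns: E1..Ek
    eigenvalues: np.ndarray
    source: str  # "single" or "averaged:<n>"


@dataclass(frozen=True)
class ImputationResult:
    completed: pd.DataFrame
    n_iterations: int
    converged: bool
    oob_error: dict[str, float]


@dataclass(frozen=True)
class ImputationEvaluation:
    nrmse_per_dimension: np.ndarray  # mean across reps, per functional axis
    nrmse_mean: float
    nrmse_se: float
    reps: int
    per_rep: np.ndarray  # rep x dimension NRMSE values


def _patristic_matrix(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    pdm = tree.phylogenetic_distance_matrix()
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return D, labels


def phylo_eigenvectors(tree: dendropy.Tree, k: int = 10) -> PhyloEigenvectors:
    """Principal-coordinate eigenvectors of the patristic distance matrix.

    The squared distance matrix is double-centred (``-0.5 J D^2 J``),
    eigendecomposed, and the first ``k`` eigenvectors scaled by the square
    root of their eigenvalues are returned, sign-fixed so the
    largest-magnitude loading of each column is positive.
    """
    n_tips = len(tree.leaf_nodes())
    if n_tips < 3:
        raise InputError("tree needs at least 3 tips")
    if k >= n_tips:
        raise InputError(f"k must be < number of tips ({n_tips})")
    D, labels = _patristic_matrix(tree)
    n = len(labels)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(eigval[0], 1.0) * 1e-10
    if positive[:k].sum() < k:
        raise InputError(
            f"tree yields only {int(positive.sum())} informative eigenvectors; lower k"
        )
    if eigval[0] > 0 and np.allclose(eigval[: min(n - 1, k + 1)], eigval[0], rtol=1e-8):
        import warnings

        warnings.warn(
            "all leading eigenvalues are (near-)equal — star-like tree, "
            "eigenvector order is arbitrary",
            stacklevel=2,
        )
    vectors = eigvec[:, :k] * np.sqrt(eigval[:k])
    for c in range(k):
        j = int(np.argmax(np.abs(vectors[:, c])))
        if vectors[j, c] < 0:
            vectors[:, c] = -vectors[:, c]
    frame = pd.DataFrame(
        vectors,
        index=pd.Index(labels, name="species_id"),
        columns=[f"E{c + 1}" for c in range(k)],
    )
    return PhyloEigenvectors(vectors=frame, eigenvalues=eigval[:k].copy(), source="single")


def average_eigenvectors(trees: list[dendropy.Tree], k: int = 10) -> PhyloEigenvectors:
    """Average eigenvectors over a set of trees (phylogenetic uncertainty).

    All trees must share the same tip set. Columns of each tree's
    eigenvectors are sign-aligned to the first tree (flipped when the
    correlation is negative) before elementwise averaging.
    """
    if not trees:
        raise InputError("no trees supplied")
    results = []
    for tree in trees:
        ev = phylo_eigenvectors(tree, k)
        if results and list(ev.vectors.index) != list(results[0].vectors.index):
            raise InputError("trees do not share the same tip set")
        results.append(ev)
    ref = results[0].vectors.to_numpy()
    stacked = np.zeros_like(ref)
    for ev in results:
        mat = ev.vectors.to_numpy().copy()
        for c in range(k):
            if np.dot(mat[:, c], ref[:, c]) < 0:
                mat[:, c] = -mat[:, c]
        stacked += mat
    stacked /= len(results)
    frame = pd.DataFrame(
        stacked, index=results[0].vectors.index, columns=results[0].vectors.columns
    )
    eigval = np.mean([ev.eigenvalues for ev in results], axis=0)
    return PhyloEigenvectors(
        vectors=frame, eigenvalues=eigval, source=f"averaged:{len(results)}"
    )


def _mtry(p: int) -> int:
    return max(1, int(np.ceil(p / 3)))


def rf_impute(
    traits: pd.DataFrame,
    eigenvectors: PhyloEigenvectors | None = None,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
) -> ImputationResult:
    """Iteratively impute missing traits with random-forest regressions.

    Traits are visited in order of increasing missingness each sweep. The
    stopping rule compares the standardized change between successive
    imputations (summed over traits) and stops the first time it
    increases, returning the previous iterate. Observed cells are never
    modified.
    """
    missing = traits.isna()
    if not missing.any().any():
        return ImputationResult(
            completed=traits.copy(), n_iterations=0, converged=True, oob_error={}
        )
    if missing.all(axis=0).any():
        col = traits.columns[missing.all(axis=0)][0]
        raise InputError(f"trait {col!r} has no observed values")
    if eigenvectors is None and missing.all(axis=1).any():
        row = traits.index[missing.all(axis=1)][0]
        raise InputError(
            f"species {row!r} has no observed traits and no eigenvectors were given"
        )

    extra = None
    if eigenvectors is not None:
        extra = eigenvectors.vectors.reindex(traits.index)
        if extra.isna().any().any():
            bad = extra.index[extra.isna().any(axis=1)][0]
            raise InputError(f"species {bad!r} is missing from the phylogeny")

    X = traits.copy()
    for col in X.columns:
        X[col] = X[col].fillna(X[col].mean())

    order = missing.sum().sort_values().index  # least missing first
    order = [c for c in order if missing[c].any()]
    rng = np.random.default_rng(seed)
    prev_delta = np.inf
    last_good = X.copy()
    oob: dict[str, float] = {}
    n_iter = 0
    converged = False
    for _ in range(max_iter):
        X_old = X.copy()
        for col in order:
            predictors = X.drop(columns=[col])
            if extra is not None:
                predictors = pd.concat([predictors, extra], axis=1)
            obs = ~missing[col]
            y_obs = X.loc[obs, col]
            if y_obs.nunique() == 1:
                X.loc[missing[col], col] = y_obs.iloc[0]
                oob[col] = 0.0
                continue
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=_mtry(predictors.shape[1]),
                oob_score=True,
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(predictors.loc[obs], y_obs)
            X.loc[missing[col], col] = forest.predict(predictors.loc[missing[col]])
            oob_pred = forest.oob_prediction_
            rng_y = float(y_obs.max() - y_obs.min())
            oob[col] = float(
                np.sqrt(np.mean((oob_pred - y_obs.to_numpy()) ** 2)) / rng_y
            )
        n_iter += 1
        num = 0.0
        den = 0.0
        for col in order:
            new = X.loc[missing[col], col].to_numpy()
            old = X_old.loc[missing[col], col].to_numpy()
            num += float(((new - old) ** 2).sum())
            den += float((new**2).sum())
        delta = num / den if den > 0 else 0.0
        if delta >= prev_delta:
            converged = True
            break
        prev_delta = delta
        last_good = X.copy()
    completed = traits.where(~missing, last_good)
    return ImputationResult(
        completed=completed, n_iterations=n_iter, converged=converged, oob_error=oob
    )


def evaluate_imputation(
    complete: pd.DataFrame,
    pattern_source: pd.DataFrame,
    space_builder: Callable[[pd.DataFrame], FunctionalSpace],
    fraction: float = 0.10,
    reps: int = 100,
    seed: int = 0,
    imputer: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
) -> ImputationEvaluation:
    """Masking-based validation of imputation quality in position space.

    Per repetition: a ``fraction`` of the complete rows is masked with
    missingness patterns copied from the incomplete rows of
    ``pattern_source``; the masked rows are pooled with all genuinely
    incomplete rows and imputed together (a conservative setting — the
    missing-to-complete ratio exceeds the original dataset's); finally the
    true and imputed masked rows are projected into the functional space
    built from the complete table, and the NRMSE per dimension is the RMSE
    of the position error divided by that dimension's occupied range.

    ``imputer`` maps a trait table with missing cells to a completed one;
    the default runs :func:`rf_impute` without eigenvectors. Pass a custom
    callable to evaluate phylogenetically informed or baseline imputers.
    """
    if complete.isna().any().any():
        raise InputError("the reference table must be complete")
    incomplete_rows = pattern_source.index[pattern_source.isna().any(axis=1)]
    if len(incomplete_rows) == 0:
        raise InputError("pattern_source has no incomplete rows")
    space = space_builder(complete)
    true_coords = project(space, complete)
    ranges = true_coords.max() - true_coords.min()

    rng = np.random.default_rng(seed)
    per_rep = np.zeros((reps, space.D))
    for r in range(reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        masked = mask_traits(complete, fraction, pattern_source, seed=rep_seed)
        target_rows = masked.mask.index[masked.mask.any(axis=1)]
        pool = pd.concat([masked.masked, pattern_source.loc[incomplete_rows]])
        if imputer is None:
            completed = rf_impute(pool, seed=rep_seed).completed
        else:
            completed = imputer(pool)
        imputed_rows = completed.loc[target_rows]
        imputed_coords = project(space, imputed_rows)
        err = imputed_coords.to_numpy() - true_coords.loc[target_rows].to_numpy()
        per_rep[r] = np.sqrt((err**2).mean(axis=0)) / ranges.to_numpy()
    rep_means = per_rep.mean(axis=1)
    return ImputationEvaluation(
        nrmse_per_dimension=per_rep.mean(axis=0),
        nrmse_mean=float(rep_means.mean()),
        nrmse_se=float(rep_means.std(ddof=1) / np.sqrt(reps)),
        reps=reps,
        per_rep=per_rep,
    )
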