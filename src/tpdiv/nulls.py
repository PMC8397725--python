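"""Random-assembly null models for functional richness.

A realm occupying less functional space than random assemblages of the
same species count is functionally redundant (clustered); more space
means overdispersion. The null draws assemblages of the observed size
uniformly without replacement from the world's species pool, rebuilding
the density spectrum with the SAME kernel, grid and threshold as the
observed one, and compares functional richness.

Significance uses the rank of the observed value within the pooled set of
null and observed values, with tied ranks averaged:
``p = midrank / (reps + 1)``. Values above 0.975 flag significantly high
richness, below 0.025 significantly low. The standardized effect size is
``(observed - null mean) / null SD``.

Realm-level SES distributions for pairwise comparison are obtained by
bootstrap: each bootstrap SES is computed against a without-replacement
subsample of the null values. All-pairs Welch t tests with Holm
correction are then summarized as a compact letter display (groups
sharing a letter are not significantly different).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import fric
from .errors import DegenerateNullError, InputError
from .tpd import GridSpec, KernelConfig, species_cell_masses, threshold_tpd, tpd_from_masses

__all__ = [
    "NullDistribution",
    "SESResult",
    "CLDResult",
    "null_fric_distribution",
    "ses_and_p",
    "bootstrap_ses",
    "pairwise_cld",
]


@dataclass(frozen=True)
class NullDistribution:
    values: np.ndarray
    n_draw: int
    pool: str
    seed: int

    @property
    def degenerate(self) -> bool:
        return float(np.std(self.values, ddof=1)) == 0.0


@dataclass(frozen=True)
class SESResult:
    observed: float
    ses: float
    p: float
    significant_high: bool
    significant_low: bool


@dataclass(frozen=True)
class CLDResult:
    labels: dict[str, str]
    alpha: float
    p_matrix: dict[tuple[str, str], float]


def null_fric_distribution(
    pool_coords: np.ndarray,
    n_draw: int,
    reps: int = 999,
    *,
    kernel: KernelConfig,
    grid: GridSpec,
    q: float = 0.99,
    seed: int = 0,
    masses: np.ndarray | None = None,
    pool: str = "world",
) -> NullDistribution:
    """FRic of ``reps`` random assemblages drawn from the pool.

    Each draw takes ``n_draw`` species uniformly without replacement.
    ``masses`` may carry precomputed per-species cell masses for the pool
    (see :func:`tpdiv.tpd.species_cell_masses`); caching them changes no
    result, only the runtime.
    """
    pool_coords = np.atleast_2d(np.asarray(pool_coords, dtype=float))
    n_pool = pool_coords.shape[0]
    if n_draw > n_pool:
        raise InputError(f"cannot draw {n_draw} species from a pool of {n_pool}")
    if reps < 2:
        raise InputError("need at least 2 null repetitions")
    if masses is None:
        masses = species_cell_masses(pool_coords, kernel, grid)
    rng = np.random.default_rng(seed)
    values = np.empty(reps)
    for r in range(reps):
        subset = rng.choice(n_pool, size=n_draw, replace=False)
        tpd = threshold_tpd(tpd_from_masses(masses, subset, grid), q)
        values[r] = fric(tpd)
    return NullDistribution(values=values, n_draw=n_draw, pool=pool, seed=seed)


def _mid_rank_p(observed: float, values: np.ndarray) -> float:
    less = int(np.sum(values < observed))
    equal = int(np.sum(values == observed))
    midrank = less + (equal + 2) / 2.0
    return midrank / (len(values) + 1)


def ses_and_p(observed: float, null: NullDistribution) -> SESResult:
    """Standardized effect size and rank p-value against a null distribution."""
    values = np.asarray(null.values, dtype=float)
    sd = float(np.std(values, ddof=1))
    if sd == 0:
        raise DegenerateNullError("null distribution has zero spread")
    ses = (observed - float(values.mean())) / sd
    p = _mid_rank_p(observed, values)
    return SESResult(
        observed=float(observed),
        ses=float(ses),
        p=float(p),
        significant_high=p > 0.975,
        significant_low=p < 0.025,
    )


def bootstrap_ses(
    observed: float,
    null: NullDistribution,
    n_boot: int = 99,
    sample_size: int = 99,
    seed: int = 0,
    max_retries: int = 10,
) -> np.ndarray:
    """Bootstrap SES values from subsamples of the null distribution.

    Each of the ``n_boot`` values is the SES of the observed value against
    a without-replacement subsample of ``sample_size`` null values.
    """
    values = np.asarray(null.values, dtype=float)
    if sample_size > len(values):
        raise InputError("sample_size exceeds the number of null values")
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(max_retries):
            sub = values[rng.choice(len(values), size=sample_size, replace=False)]
            sd = float(np.std(sub, ddof=1))
            if sd > 0:
                out[b] = (observed - float(sub.mean())) / sd
                break
        else:
            raise DegenerateNullError("null subsamples have zero spread")
    return out


def _insert_absorb(groups: list[str], significant: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Insert-absorb compact letter display.

    Start from one letter containing everybody; for each significant pair
    split every letter containing both members; finally drop letters that
    are subsets of others. Guarantees: significant pairs never share a
    letter, non-significant pairs share at least one.
    """
    letters: list[set[str]] = [set(groups)]
    for (a, b), sig in significant.items():
        if not sig:
            continue
        new_letters: list[set[str]] = []
        for letter in letters:
            if a in letter and b in letter:
                new_letters.append(letter - {a})
                new_letters.append(letter - {b})
            else:
                new_letters.append(letter)
        letters = [l for l in new_letters if l]
        # absorb: remove letters contained in another
        letters = [
            l
            for i, l in enumerate(letters)
            if not any(l < m or (l == m and i > j) for j, m in enumerate(letters))
        ]
    # order letters by the best (highest-mean-rank) group they contain for
    # a stable, readable assignment
    order = {g: i for i, g in enumerate(groups)}
    letters.sort(key=lambda l: min(order[g] for g in l))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    labels = {g: "" for g in groups}
    for i, letter in enumerate(letters):
        for g in letter:
            labels[g] += alphabet[i % len(alphabet)]
    return {g: "".join(sorted(lab)) for g, lab in labels.items()}


def pairwise_cld(groups: dict[str, np.ndarray], alpha: float = 0.05) -> CLDResult:
    """All-pairs Welch t tests with Holm correction, as letters.

    ``groups`` maps realm name to a sample of bootstrap SES values.
    Realms sharing a letter are not significantly different at ``alpha``.
    """
    names = list(groups)
    if len(names) < 2:
        raise InputError("need at least 2 groups")
    for name, sample in groups.items():
        if len(np.asarray(sample)) < 3:
            raise InputError(f"group {name!r} has fewer than 3 values")
    pairs = list(itertools.combinations(names, 2))
    raw_p = []
    for a, b in pairs:
        sa, sb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if np.std(sa, ddof=1) == 0 and np.std(sb, ddof=1) == 0:
            p = 1.0 if np.mean(sa) == np.mean(sb) else 0.0
        else:
            p = float(stats.ttest_ind(sa, sb, equal_var=False).pvalue)
        raw_p.append(p)
    adj_p = multipletests(raw_p, alpha=alpha, method="holm")[1]
    p_matrix = dict(zip(pairs, (float(p) for p in adj_p)))
    significant = {pair: p < alpha for pair, p in p_matrix.items()}
    ordered = sorted(names, key=lambda g: -float(np.mean(groups[g])))
    labels = _insert_absorb(ordered, significant)
    return CLDResult(labels=labels, alpha=alpha, p_matrix=p_matrix)
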