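"""Synthetic worlds for trait-based diversity analyses.

Real analyses of this kind combine trait databases, realm species lists,
Red List statuses and phylogenies. This module builds small worlds with the
same statistical structure so that every downstream stage — trait-space
construction, kernel density spectra, null models, extinction scenarios and
trait imputation — can be exercised and validated without external data.

The generated structure mirrors what the analyses assume:

* species trait values are strictly positive and log-normally distributed
  around a handful of "archetype" strategies (dense hotspots in trait space);
* each species belongs to one or more biogeographic realms, with a tunable
  expected fraction of species shared between realms;
* each species carries one IUCN category; the probability of being
  threatened can be tilted toward one end of trait space (large-bodied,
  slow-living species) with a logistic link on the first trait;
* traits with phylogenetic signal are simulated by Brownian motion on a
  birth-death tree, for testing phylogenetically informed imputation;
* missingness patterns can be copied from template rows, reproducing the
  blockwise missingness of real trait databases.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .errors import ConfigurationError, InputError
from .iucn import IUCN_CATEGORIES, THREAT_TILTED

__all__ = [
    "SyntheticConfig",
    "MaskedTraits",
    "gen_trait_table",
    "gen_phylogeny",
    "gen_brownian_traits",
    "gen_realms",
    "assign_iucn_status",
    "mask_traits",
    "write_trait_table",
    "write_memberships",
    "write_status",
    "write_tree",
]

#: Default marginal category mix, loosely matching the global Red List
#: composition for vertebrates (a ~25% threatened fraction, a substantial
#: LC majority, and non-trivial DD and NE shares so coverage-QA paths run).
DEFAULT_CATEGORY_PROBS: dict[str, float] = {
    "CR": 0.05,
    "EN": 0.08,
    "VU": 0.12,
    "NT": 0.08,
    "LC": 0.47,
    "DD": 0.12,
    "NE": 0.08,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic world.

    Parameters
    ----------
    n_species, n_traits, n_archetypes, n_realms
        Sizes; all must be >= 1.
    archetype_spread
        Within-cluster standard deviation on the log scale. Archetype
        centres themselves are drawn from a standard normal per log-trait,
        so spreads well below 1 give visibly clustered hotspots.
    sharing
        Expected fraction of species present in more than one realm.
    threat_bias
        Strength (log-odds per standard deviation of the first log trait)
        of the association between trait values and being threatened.
        0 means statuses are independent of traits.
    category_probs
        Marginal probability of each IUCN category; must cover exactly the
        seven categories and sum to 1.
    seed
        Seed for all randomness in generators taking this config.
    """

    n_species: int = 300
    n_traits: int = 6
    n_archetypes: int = 3
    archetype_spread: float = 0.4
    n_realms: int = 3
    sharing: float = 0.15
    threat_bias: float = 0.0
    category_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_species", "n_traits", "n_archetypes", "n_realms"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0.0 <= self.sharing <= 1.0:
            raise ConfigurationError("sharing must lie in [0, 1]")
        if self.threat_bias < 0:
            raise ConfigurationError("threat_bias must be >= 0")
        if self.archetype_spread < 0:
            raise ConfigurationError("archetype_spread must be >= 0")
        if set(self.category_probs) != set(IUCN_CATEGORIES):
            raise ConfigurationError(
                "category_probs must define exactly the categories "
                + ", ".join(IUCN_CATEGORIES)
            )
        total = float(sum(self.category_probs.values()))
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(f"category_probs must sum to 1, got {total!r}")
        if any(p < 0 for p in self.category_probs.values()):
            raise ConfigurationError("category_probs must be non-negative")


def _species_ids(n: int) -> pd.Index:
    width = max(4, len(str(n)))
    return pd.Index([f"sp{i + 1:0{width}d}" for i in range(n)], name="species_id")


def _trait_names(n: int) -> list[str]:
    return [f"trait{j + 1}" for j in range(n)]


def gen_trait_table(cfg: SyntheticConfig) -> pd.DataFrame:
    """Draw a species x trait table as a mixture of log-normal clusters.

    Archetype centres are i.i.d. standard normal per log-trait; species are
    assigned to archetypes uniformly and scattered around their centre with
    SD ``cfg.archetype_spread`` on the log scale, then exponentiated, so
    every cell is strictly positive.
    """
    rng = np.random.default_rng(cfg.seed)
    centres = rng.standard_normal((cfg.n_archetypes, cfg.n_traits))
    assignment = rng.integers(0, cfg.n_archetypes, size=cfg.n_species)
    log_traits = centres[assignment] + cfg.archetype_spread * rng.standard_normal(
        (cfg.n_species, cfg.n_traits)
    )
    table = pd.DataFrame(
        np.exp(log_traits),
        index=_species_ids(cfg.n_species),
        columns=_trait_names(cfg.n_traits),
    )
    table.attrs["archetype"] = tuple(int(a) for a in assignment)
    return table


def gen_phylogeny(
    n_species: int, birth: float, death: float, seed: int
) -> dendropy.Tree:
    """Simulate an ultrametric binary birth-death tree with ``n_species`` tips.

    Tips are relabelled ``sp0001``... so they match trait tables of the same
    size. The simulation stops at the speciation event that creates the
    n-th extant lineage; every extant tip edge is then extended by one
    exponential waiting time (rate ``n_species * birth``) so terminal
    branches are strictly positive while the tree stays ultrametric.
    """
    if not birth > death or death < 0:
        raise ConfigurationError("need birth > death >= 0")
    if n_species < 2:
        raise ConfigurationError("need n_species >= 2")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth,
        death_rate=death,
        num_extant_tips=n_species,
        rng=rng,
        repeat_until_success=True,
    )
    extra = rng.expovariate(n_species * birth)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    ids = _species_ids(n_species)
    namespace = dendropy.TaxonNamespace()
    for leaf, sp in zip(tree.leaf_node_iter(), ids):
        leaf.taxon = namespace.new_taxon(label=sp)
    tree.taxon_namespace = namespace
    return tree


def gen_brownian_traits(
    tree: dendropy.Tree, n_traits: int, sigma: float, seed: int
) -> pd.DataFrame:
    """Simulate positive traits with Brownian motion along the tree.

    Log-trait values start at 0 at the root and accumulate independent
    normal increments with variance ``sigma**2 * branch_length`` down every
    branch; tip values are exponentiated. Close relatives therefore have
    more similar traits than distant ones.
    """
    if sigma <= 0:
        raise ConfigurationError("sigma must be > 0")
    tips = tree.leaf_nodes()
    if len(tips) < 2:
        raise InputError("tree must have at least 2 tips")
    rng = np.random.default_rng(seed)
    values: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = np.zeros(n_traits)
        else:
            bl = node.edge.length or 0.0
            step = sigma * np.sqrt(bl) * rng.standard_normal(n_traits)
            values[id(node)] = values[id(node.parent_node)] + step
    rows = {leaf.taxon.label: np.exp(values[id(leaf)]) for leaf in tips}
    table = pd.DataFrame.from_dict(rows, orient="index", columns=_trait_names(n_traits))
    table = table.sort_index()
    table.index.name = "species_id"
    return table


def gen_realms(species_ids, cfg: SyntheticConfig) -> pd.DataFrame:
    """Assign every species to >= 1 realm.

    Each species gets one primary realm uniformly at random; with
    probability ``cfg.sharing`` it is additionally placed in one other
    realm, so the expected multi-realm fraction equals ``sharing``
    (except in the degenerate single-realm case, where everyone is
    endemic by construction). ``sharing == 1`` with two realms puts all
    species in both.
    """
    species_ids = list(species_ids)
    if not species_ids:
        raise InputError("species list is empty")
    realms = [f"realm{r + 1}" for r in range(cfg.n_realms)]
    rng = np.random.default_rng(cfg.seed + 1)
    rows: list[tuple[str, str]] = []
    for sp in species_ids:
        primary = int(rng.integers(0, cfg.n_realms))
        membership = [primary]
        if cfg.n_realms > 1 and rng.random() < cfg.sharing:
            extra = int(rng.integers(0, cfg.n_realms - 1))
            if extra >= primary:
                extra += 1
            membership.append(extra)
        rows.extend((sp, realms[r]) for r in sorted(membership))
    return pd.DataFrame(rows, columns=["species_id", "realm"])


def assign_iucn_status(traits: pd.DataFrame, cfg: SyntheticConfig) -> pd.Series:
    """Draw one IUCN category per species, optionally trait-biased.

    A species is threatened (CR/EN/VU/NT) with probability
    ``sigmoid(logit(p_T) + threat_bias * z)`` where ``p_T`` is the marginal
    threatened mass of ``category_probs`` and ``z`` is the standardized log
    of the species' first trait. Within the threatened and non-threatened
    blocks, categories are drawn proportionally to ``category_probs``, so
    with ``threat_bias == 0`` the marginal frequencies equal
    ``category_probs`` exactly.
    """
    first = traits.iloc[:, 0].to_numpy(dtype=float)
    if np.isnan(first).any():
        raise InputError("first trait must be complete to assign statuses")
    probs = np.array([cfg.category_probs[c] for c in IUCN_CATEGORIES])
    threatened_mask = np.array([c in THREAT_TILTED for c in IUCN_CATEGORIES])
    p_threat = float(probs[threatened_mask].sum())
    rng = np.random.default_rng(cfg.seed + 2)

    log_first = np.log(first)
    sd = log_first.std(ddof=0)
    z = (log_first - log_first.mean()) / sd if sd > 0 else np.zeros_like(log_first)

    if 0.0 < p_threat < 1.0:
        logit = np.log(p_threat / (1.0 - p_threat)) + cfg.threat_bias * z
        p_i = 1.0 / (1.0 + np.exp(-logit))
    else:
        p_i = np.full_like(z, p_threat)

    threatened = rng.random(len(z)) < p_i
    cats = np.empty(len(z), dtype=object)
    for block, mask in ((True, threatened), (False, ~threatened)):
        block_cats = [c for c, t in zip(IUCN_CATEGORIES, threatened_mask) if t == block]
        block_p = np.array([cfg.category_probs[c] for c in block_cats])
        if block_p.sum() == 0:
            if mask.any():
                raise ConfigurationError(
                    "category_probs assigns zero mass to a block that received species"
                )
            continue
        block_p = block_p / block_p.sum()
        cats[mask] = rng.choice(block_cats, size=int(mask.sum()), p=block_p)
    return pd.Series(cats, index=traits.index, name="iucn_status")


@dataclass(frozen=True)
class MaskedTraits:
    """A trait table with artificial missingness plus the hidden truth."""

    masked: pd.DataFrame
    mask: pd.DataFrame  # True where a value was removed
    original: pd.DataFrame  # the values that were removed (NaN elsewhere)


def mask_traits(
    traits: pd.DataFrame,
    fraction: float,
    pattern_source: pd.DataFrame | None = None,
    seed: int = 0,
) -> MaskedTraits:
    """Blank out traits in a fraction of the complete rows.

    Exactly ``round(fraction * n_complete)`` complete rows are targeted.
    When ``pattern_source`` is given, each targeted row copies the
    missingness pattern of a randomly chosen incomplete row of the source
    (mirroring how real databases lose whole blocks of traits together);
    otherwise one uniformly chosen cell per targeted row is blanked.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    complete_rows = traits.index[traits.notna().all(axis=1)]
    n_target = int(round(fraction * len(complete_rows)))
    masked = traits.copy()
    mask = pd.DataFrame(False, index=traits.index, columns=traits.columns)
    if n_target == 0:
        original = traits.where(mask)
        return MaskedTraits(masked, mask, original)

    patterns: np.ndarray | None = None
    if pattern_source is not None:
        incomplete = pattern_source.isna()
        incomplete_rows = incomplete.index[incomplete.any(axis=1)]
        if len(incomplete_rows) == 0:
            raise InputError("pattern_source has no incomplete rows")
        patterns = incomplete.loc[incomplete_rows].to_numpy()

    targets = rng.choice(len(complete_rows), size=n_target, replace=False)
    for row_pos in targets:
        sp = complete_rows[row_pos]
        if patterns is not None:
            pat = patterns[int(rng.integers(0, len(patterns)))]
        else:
            pat = np.zeros(traits.shape[1], dtype=bool)
            pat[int(rng.integers(0, traits.shape[1]))] = True
        mask.loc[sp, traits.columns[pat]] = True
    masked = traits.mask(mask)
    original = traits.where(mask)
    return MaskedTraits(masked, mask, original)


# ---------------------------------------------------------------------------
# plain-text writers matching the reader schemas in tpdiv.ingest


def write_trait_table(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, index_label="species_id")


def write_memberships(memberships: pd.DataFrame, path) -> None:
    memberships.to_csv(path, index=False)


def write_status(status: pd.Series, path) -> None:
    status.rename("iucn_status").to_csv(path, index_label="species_id")


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
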