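"""Synthetic presence/absence matrices evolved on a known area tree, and
the Lower-Volga-Valley-like fixture used throughout the test suite.

Characters evolve independently under the symmetric binary chain along
every branch; with a gamma shape set, each character draws a rate
multiplier from the continuous Gamma(alpha, alpha). Because every event of
the symmetric chain is a state flip, the per-branch change count is
Poisson(rate x length) and the child state is the parent state XOR the
count's parity — the simulation records these true per-branch change
counts, which serve as oracles for the mapping engine's expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import TaxonAreaMatrix
from .trees import AreaTree, FlatTree, flatten


class EndemicConstraintError(RuntimeError):
    """Rejection sampling for endemic characters exhausted its retries."""


@dataclass
class SimulationConfig:
    tree: AreaTree                       # generating topology + lengths
    n_characters: int
    gamma_shape: float | None = None     # None = homogeneous rates
    endemic_fraction: float = 0.0        # proportion forced to <= 2 tips
    max_endemic_tips: int = 2
    root_presence_prob: float = 0.5
    seed: int = 0
    name_prefix: str = "sp"

    def __post_init__(self) -> None:
        if self.n_characters < 1:
            raise ValueError("n_characters must be >= 1")
        if not 0.0 <= self.endemic_fraction <= 1.0:
            raise ValueError("endemic_fraction must be in [0, 1]")


@dataclass
class SimulatedData:
    """A simulated matrix with its full generating truth retained."""

    matrix: TaxonAreaMatrix
    node_states: np.ndarray      # (n_nodes, n_characters)
    branch_changes: np.ndarray   # true change counts per branch (n_nodes, n_chars)
    rates: np.ndarray            # per-character rate multipliers
    flat: FlatTree = field(repr=False, default=None)


def _evolve(
    flat: FlatTree,
    rates: np.ndarray,
    root_states: np.ndarray,
    rng: np.random.Generator,
):
    """Vectorised branch-wise evolution; returns (node states, change
    counts per branch), each (n_nodes, n_chars)."""
    n = len(rates)
    states = np.zeros((flat.n_nodes, n), dtype=np.int8)
    changes = np.zeros((flat.n_nodes, n), dtype=np.int64)
    states[flat.root] = root_states
    for node in flat.preorder():
        if node == flat.root:
            continue
        t = flat.lengths[node]
        k = rng.poisson(rates * t)
        changes[node] = k
        states[node] = states[flat.parent[node]] ^ (k & 1).astype(np.int8)
    return states, changes


def simulate_matrix(config: SimulationConfig) -> SimulatedData:
    """Simulate a taxon-area matrix on the configured tree.

    Endemic characters (the leading ``endemic_fraction`` share of columns)
    are produced by rejection until their tip-presence count is between 1
    and ``max_endemic_tips``; a bounded retry budget guards against
    unreachable constraints.
    """
    rng = np.random.default_rng(config.seed)
    flat = flatten(config.tree)
    n = config.n_characters
    n_endemic = int(round(config.endemic_fraction * n))

    def draw(m: int):
        if config.gamma_shape is None:
            r = np.ones(m)
        else:
            r = rng.gamma(config.gamma_shape, 1.0 / config.gamma_shape, size=m)
        roots = (rng.random(m) < config.root_presence_prob).astype(np.int8)
        return r, *_evolve(flat, r, roots, rng)

    rates, states, changes = draw(n)
    if n_endemic:
        counts = states[: flat.n_tips, :n_endemic].sum(axis=0)
        bad = np.flatnonzero(
            (counts < 1) | (counts > config.max_endemic_tips)
        )
        for _ in range(200):
            if bad.size == 0:
                break
            r2, s2, c2 = draw(len(bad))
            ok = (
                (s2[: flat.n_tips].sum(axis=0) >= 1)
                & (s2[: flat.n_tips].sum(axis=0) <= config.max_endemic_tips)
            )
            idx = bad[ok]
            rates[idx] = r2[ok]
            states[:, idx] = s2[:, ok]
            changes[:, idx] = c2[:, ok]
            bad = bad[~ok]
        if bad.size:
            raise EndemicConstraintError(
                f"{bad.size} endemic characters still violate the "
                f"<= {config.max_endemic_tips}-tip constraint after bounded retries"
            )
    names = [f"{config.name_prefix}{j + 1:05d}" for j in range(n)]
    m = TaxonAreaMatrix(
        flat.tip_names, names, states[: flat.n_tips],
        provenance=f"simulate_matrix(seed={config.seed})",
    )
    return SimulatedData(m, states, changes, rates, flat)


# ---------------------------------------------------------------------------
# the LVV-like fixture
#
# 13 floristic areas; the hard-coded truth tree mirrors the structure the
# real analysis recovers: a river-valley/delta clade {P, BK, ZIB, XE, AH,
# BC}, steppe pairs {VP, ZP} and {A, C}, BAC adjacent to the base, and BOG
# — the oldest, species-poorest area — on a long basal branch. The root
# presence probability is biased to 0.9 (most recorded species are
# widespread) so that BOG's long branch decays its expected richness well
# below every other area, making its row sum the strict minimum for any
# seed (Lundberg rooting then always selects BOG).

LVV_AREAS = ["BOG", "BAC", "VP", "ZP", "X", "C", "A", "P", "AH", "BC", "XE", "ZIB", "BK"]

LVV_VALLEY_CLADE = {"P", "BK", "ZIB", "XE", "AH", "BC"}

_LVV_TRUTH_NEWICK = (
    "(BOG:1.0,(BAC:0.18,((VP:0.1,ZP:0.1):0.09,((A:0.1,C:0.1):0.08,"
    "(X:0.14,(((P:0.09,(ZIB:0.06,BK:0.06):0.05):0.045,"
    "(XE:0.09,(AH:0.07,BC:0.07):0.045):0.045):0.06):0.05):0.045):0.05):0.08):0.1);"
)


def lvv_truth_tree() -> AreaTree:
    """The fixture's generating tree (hard-coded constants, so tests are
    stable across versions)."""
    return AreaTree.from_newick(_LVV_TRUTH_NEWICK)


def lvv_fixture(
    n_species: int = 1018, n_endemics: int = 23, seed: int = 0
) -> TaxonAreaMatrix:
    """A 13-area matrix shaped like the Lower Volga Valley survey data:
    ``n_species`` binary characters of which exactly ``n_endemics`` are
    narrow endemics present in at most two areas, most of them restricted
    to the Baer-knoll pair ZIB+BK.
    """
    if n_endemics > n_species:
        raise ValueError("n_endemics cannot exceed n_species")
    rng = np.random.default_rng(seed)
    flat = flatten(lvv_truth_tree())
    order = {name: i for i, name in enumerate(flat.tip_names)}
    zib_bk = np.zeros(flat.n_tips, dtype=np.int8)
    zib_bk[order["ZIB"]] = 1
    zib_bk[order["BK"]] = 1

    n_regular = n_species - n_endemics
    n_zibbk = min((14 * n_endemics) // 23 if n_endemics else 0, n_endemics)
    n_free = n_endemics - n_zibbk

    # widespread characters: gamma rates, presence-biased root, and at
    # least 3 occupied areas (so the endemic count is exact)
    reg_cols = np.empty((flat.n_tips, 0), dtype=np.int8)
    for _ in range(200):
        if reg_cols.shape[1] >= n_regular:
            break
        m = n_regular - reg_cols.shape[1]
        r = rng.gamma(1.0, 1.0, size=2 * m)
        roots = (rng.random(2 * m) < 0.9).astype(np.int8)
        states, _ = _evolve(flat, r, roots, rng)
        tips = states[: flat.n_tips]
        keep = tips.sum(axis=0) >= 3
        reg_cols = np.hstack([reg_cols, tips[:, keep][:, :m]])

    # narrow endemics: low-rate characters arising within the tree (root
    # absent), kept when they occupy 1-2 areas; a quota is constrained to
    # exactly the Baer-knoll pair
    zibbk_cols = np.empty((flat.n_tips, 0), dtype=np.int8)
    free_cols = np.empty((flat.n_tips, 0), dtype=np.int8)
    for _ in range(500):
        need_z = n_zibbk - zibbk_cols.shape[1]
        need_f = n_free - free_cols.shape[1]
        if need_z <= 0 and need_f <= 0:
            break
        m = 64
        r = np.full(m, 0.35)
        roots = np.zeros(m, dtype=np.int8)
        states, _ = _evolve(flat, r, roots, rng)
        tips = states[: flat.n_tips]
        counts = tips.sum(axis=0)
        exact = (tips == zib_bk[:, None]).all(axis=0)
        if need_z > 0:
            zibbk_cols = np.hstack([zibbk_cols, tips[:, exact][:, :need_z]])
        small = (counts >= 1) & (counts <= 2) & ~exact
        if need_f > 0:
            free_cols = np.hstack([free_cols, tips[:, small][:, :need_f]])
    if zibbk_cols.shape[1] < n_zibbk or free_cols.shape[1] < n_free:
        raise EndemicConstraintError("endemic rejection budget exhausted")

    cells = np.hstack([reg_cols, free_cols, zibbk_cols])
    names = [f"sp{j + 1:05d}" for j in range(n_regular)]
    names += [f"endemic{j + 1:03d}" for j in range(n_endemics)]
    return TaxonAreaMatrix(
        list(flat.tip_names), names, cells,
        provenance=f"lvv_fixture(n_species={n_species}, "
                   f"n_endemics={n_endemics}, seed={seed})",
    )
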