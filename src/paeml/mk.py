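"""Binary Mk likelihood with discrete-gamma rate heterogeneity and an
optional invariant-character mixture, plus branch-length/shape optimisation
on a fixed topology.

The model is the two-state symmetric continuous-time Markov chain: gains
(0 -> 1, a species appearing in an area) and losses (1 -> 0, local
extinction) are equally probable, stationary frequencies are (1/2, 1/2),
and the overall rate is normalised to one expected change per unit branch
length. The closed-form transition probabilities are

    P(same)  = (1 + exp(-2 r t)) / 2
    P(differ) = (1 - exp(-2 r t)) / 2

Rate heterogeneity across characters uses Yang's discrete gamma: ``k``
equal-probability classes of Gamma(alpha, alpha), each represented by its
class mean, so the mixture has unit mean rate. The +I variant adds a
zero-rate class of weight ``p_invariant`` that can only produce constant
characters.

No ascertainment-bias (Mkv) conditioning is applied: constant columns are
deliberately informative here, which is what makes the all-zero
"extinct taxa" augmentation meaningful.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .matrix import TaxonAreaMatrix
from .parsimony import canonical_flat, edge_change_counts
from .trees import AreaTree, FlatTree, TreeError, flatten, unflatten

BL_MIN = 1e-6
BL_MAX = 10.0
ALPHA_MIN = 0.02
ALPHA_MAX = 100.0
PINV_MAX = 0.99


@dataclass
class MkModel:
    """Parameters of the binary Mk(+G)(+I) model.

    ``gamma_shape`` of ``None`` means rate homogeneity (no gamma mixture).
    """

    gamma_shape: float | None = None
    n_categories: int = 4
    p_invariant: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        if not 0.0 <= self.p_invariant < 1.0:
            raise ValueError("p_invariant must be in [0, 1)")

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.array([1.0])
        return gamma_category_rates(self.gamma_shape, self.n_categories)


def transition_probability(t: float, rate_multiplier: float = 1.0) -> np.ndarray:
    """2x2 transition matrix of the symmetric binary chain over a branch of
    length ``t`` at the given rate multiplier."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if rate_multiplier <= 0:
        raise ValueError("rate multiplier must be positive")
    e = np.exp(-2.0 * rate_multiplier * t)
    ps = 0.5 * (1.0 + e)
    pd = 0.5 * (1.0 - e)
    return np.array([[ps, pd], [pd, ps]])


def gamma_category_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean rates of the ``k`` equal-probability quantile classes of
    Gamma(alpha, alpha) (unit-mean discretisation)."""
    if k == 1:
        return np.array([1.0])
    bounds = _gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([bounds, [np.inf]])
    lower = np.concatenate([[0.0], bounds])
    # E[X; X < q] for X ~ Gamma(a, rate a) with unit mean is I(a q; a+1)
    partial = gammainc(alpha + 1.0, np.where(np.isinf(upper), np.inf, alpha * upper))
    partial_lo = gammainc(alpha + 1.0, alpha * lower)
    rates = k * (partial - partial_lo)
    return rates / rates.mean()


@dataclass
class LikelihoodResult:
    """Fitted (or evaluated) likelihood of a matrix on a tree."""

    log_likelihood: float
    per_character_log_likelihoods: np.ndarray
    gamma_shape: float | None
    p_invariant: float
    tree: AreaTree
    warnings: list[str] = field(default_factory=list)

    @property
    def neg_log_likelihood(self) -> float:
        return -self.log_likelihood


# ---------------------------------------------------------------------------
# pattern compression and the pruning core


def compress_columns(cells: np.ndarray):
    """Unique site patterns with counts; returns (patterns (n_tips, P),
    inverse index per column, counts per pattern)."""
    patterns, inverse, counts = np.unique(
        cells.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T.astype(np.int8), inverse, counts.astype(float)


def _category_site_likelihoods(
    flat: FlatTree, tipdata: np.ndarray, rates: np.ndarray,
    lengths: np.ndarray,
) -> np.ndarray:
    """(n_categories, n_patterns) per-pattern likelihoods via Felsenstein
    pruning with uniform root frequencies."""
    ncat = len(rates)
    npat = tipdata.shape[1]
    partial = np.empty((flat.n_nodes, ncat, npat, 2))
    r = rates.reshape(-1, 1)
    for node in flat.postorder:
        if node < flat.n_tips:
            partial[node, :, :, 0] = (tipdata[node] == 0)
            partial[node, :, :, 1] = (tipdata[node] == 1)
            continue
        acc = None
        for c in flat.children[node]:
            t = lengths[c]
            if not np.isfinite(t):
                raise TreeError("unset branch length; fit or supply lengths")
            e = np.exp(-2.0 * r * t)          # (ncat, 1)
            ps, pd = 0.5 * (1.0 + e), 0.5 * (1.0 - e)
            c0 = partial[c, :, :, 0]
            c1 = partial[c, :, :, 1]
            tr = np.stack([ps * c0 + pd * c1, pd * c0 + ps * c1], axis=-1)
            acc = tr if acc is None else acc * tr
        partial[node] = acc
    root = partial[flat.root]
    return 0.5 * (root[:, :, 0] + root[:, :, 1])


def pattern_likelihoods(
    flat: FlatTree, tipdata: np.ndarray, model: MkModel,
    lengths: np.ndarray | None = None,
) -> np.ndarray:
    """Mixture likelihood of each site pattern (gamma classes averaged,
    invariant class added)."""
    lengths = flat.lengths if lengths is None else lengths
    rates = model.category_rates()
    cat = _category_site_likelihoods(flat, tipdata, rates, lengths)
    L = cat.mean(axis=0)
    p = model.p_invariant
    if p > 0.0:
        all0 = (tipdata == 0).all(axis=0)
        all1 = (tipdata == 1).all(axis=0)
        L = (1.0 - p) * L + p * 0.5 * (all0 + all1)
    return L


def log_likelihood(
    tree: AreaTree, matrix: TaxonAreaMatrix, model: MkModel | None = None
) -> LikelihoodResult:
    """Total and per-character log-likelihood of the matrix on the tree
    (natural log). Constant columns contribute like any other pattern."""
    model = model or MkModel()
    if set(tree.tip_names) != set(matrix.area_names):
        raise TreeError("tree tips do not match matrix areas")
    flat = flatten(tree, tip_order=matrix.area_names)
    if not np.isfinite(flat.lengths[np.arange(flat.n_nodes) != flat.root]).all():
        raise TreeError("tree has unset branch lengths")
    tipdata, inverse, _ = compress_columns(matrix.cells)
    L = pattern_likelihoods(flat, tipdata, model)
    per_char = np.log(L)[inverse]
    return LikelihoodResult(
        log_likelihood=float(per_char.sum()),
        per_character_log_likelihoods=per_char,
        gamma_shape=model.gamma_shape,
        p_invariant=model.p_invariant,
        tree=tree,
    )


def posterior_mean_rates(
    tree: AreaTree, matrix: TaxonAreaMatrix, model: MkModel
) -> np.ndarray:
    """Posterior mean rate multiplier of every character under the fitted
    mixture (the rate used for stochastic mapping by default; the invariant
    class contributes rate zero)."""
    flat = flatten(tree, tip_order=matrix.area_names)
    tipdata, inverse, _ = compress_columns(matrix.cells)
    rates = model.category_rates()
    cat = _category_site_likelihoods(flat, tipdata, rates, flat.lengths)
    p = model.p_invariant
    wcat = (1.0 - p) / len(rates)
    num = wcat * (rates.reshape(-1, 1) * cat).sum(axis=0)
    den = wcat * cat.sum(axis=0)
    if p > 0.0:
        all0 = (tipdata == 0).all(axis=0)
        all1 = (tipdata == 1).all(axis=0)
        den = den + p * 0.5 * (all0 + all1)
    mean = num / den
    return mean[inverse]


# ---------------------------------------------------------------------------
# optimisation on a fixed topology


class _Objective:
    """Shared state for coordinate-wise optimisation of one topology."""

    def __init__(self, flat: FlatTree, tipdata, counts,
                 gamma: bool, invariant: bool, n_categories: int):
        self.flat = flat
        self.tipdata = tipdata
        self.counts = counts
        self.gamma = gamma
        self.invariant = invariant
        self.k = n_categories
        self.all0 = (tipdata == 0).all(axis=0)
        self.all1 = (tipdata == 1).all(axis=0)

    def model(self, alpha: float, pinv: float) -> MkModel:
        return MkModel(
            gamma_shape=alpha if self.gamma else None,
            n_categories=self.k,
            p_invariant=pinv if self.invariant else 0.0,
        )

    def lnl(self, lengths: np.ndarray, alpha: float, pinv: float) -> float:
        L = pattern_likelihoods(
            self.flat, self.tipdata, self.model(alpha, pinv), lengths
        )
        return float((self.counts * np.log(L)).sum())


def initial_branch_lengths(flat: FlatTree, tipdata, counts) -> np.ndarray:
    """Parsimony change counts scaled by character count (floored)."""
    changes = edge_change_counts(flat, tipdata, counts)
    nchar = counts.sum()
    lengths = np.clip(changes / max(nchar, 1.0), 1e-3, BL_MAX)
    lengths[flat.root] = np.nan
    return lengths


def optimize_on_topology(
    flat: FlatTree,
    tipdata: np.ndarray,
    counts: np.ndarray,
    *,
    gamma: bool = False,
    invariant: bool = False,
    n_categories: int = 4,
    init_lengths: np.ndarray | None = None,
    init_alpha: float = 1.0,
    init_pinv: float = 0.1,
    tol: float = 1e-8,
    max_rounds: int = 50,
    xatol: float = 1e-7,
    second_init: bool = True,
    polish: bool = True,
) -> tuple[np.ndarray, float | None, float, float]:
    """Jointly optimise branch lengths (and alpha, p_inv when enabled) by
    iterated bounded one-dimensional searches; monotone non-decreasing in
    log-likelihood, fully deterministic.

    Coordinate ascent can stall on likelihood ridges (weak data with
    near-saturated branches), so by default a second run from flat uniform
    starting lengths is performed and the better optimum is polished with
    a joint Powell search over log branch lengths.
    Returns (lengths, alpha or None, p_inv, lnL).
    """
    if second_init and init_lengths is None:
        uniform = np.full(flat.n_nodes, 0.2)
        uniform[flat.root] = np.nan
        a = optimize_on_topology(
            flat, tipdata, counts, gamma=gamma, invariant=invariant,
            n_categories=n_categories,
            init_lengths=initial_branch_lengths(flat, tipdata, counts),
            init_alpha=init_alpha, init_pinv=init_pinv,
            tol=tol, max_rounds=max_rounds, xatol=xatol,
            second_init=False, polish=False,
        )
        b = optimize_on_topology(
            flat, tipdata, counts, gamma=gamma, invariant=invariant,
            n_categories=n_categories, init_lengths=uniform,
            init_alpha=init_alpha, init_pinv=init_pinv,
            tol=tol, max_rounds=max_rounds, xatol=xatol,
            second_init=False, polish=False,
        )
        best = a if a[3] >= b[3] else b
        if polish:
            best = _powell_polish(
                flat, tipdata, counts, gamma, invariant, n_categories, best
            )
        return best
    obj = _Objective(flat, tipdata, counts, gamma, invariant, n_categories)
    lengths = (initial_branch_lengths(flat, tipdata, counts)
               if init_lengths is None else init_lengths.copy())
    alpha = init_alpha
    pinv = init_pinv if invariant else 0.0
    current = obj.lnl(lengths, alpha, pinv)
    edges = [n for n in flat.postorder.tolist() if n != flat.root]
    for _ in range(max_rounds):
        before = current
        for e in edges:
            orig = lengths[e]

            def f(x, _e=e):
                lengths[_e] = x
                return -obj.lnl(lengths, alpha, pinv)

            res = minimize_scalar(
                f, bounds=(BL_MIN, BL_MAX), method="bounded",
                options={"xatol": xatol},
            )
            # f mutates lengths[e] during the search: restore or commit
            if -res.fun >= current:
                lengths[e] = res.x
                current = -res.fun
            else:
                lengths[e] = orig
        if gamma:
            def fa(a):
                return -obj.lnl(lengths, a, pinv)
            res = minimize_scalar(
                fa, bounds=(ALPHA_MIN, ALPHA_MAX), method="bounded",
                options={"xatol": xatol},
            )
            if -res.fun >= current:
                alpha = res.x
                current = -res.fun
        if invariant:
            def fp(p):
                return -obj.lnl(lengths, alpha, p)
            res = minimize_scalar(
                fp, bounds=(0.0, PINV_MAX), method="bounded",
                options={"xatol": xatol},
            )
            if -res.fun >= current:
                pinv = res.x
                current = -res.fun
        if current - before <= tol * max(1.0, abs(before)):
            break
    return lengths, (alpha if gamma else None), pinv, current


def _powell_polish(flat, tipdata, counts, gamma, invariant, n_categories,
                   start) -> tuple[np.ndarray, float | None, float, float]:
    """Joint refinement over log branch lengths (+ log alpha, p_inv) from
    the coordinate-ascent optimum; keeps whichever is better."""
    lengths0, alpha0, pinv0, lnl0 = start
    obj = _Objective(flat, tipdata, counts, gamma, invariant, n_categories)
    edges = [n for n in range(flat.n_nodes) if n != flat.root]
    x0 = list(np.log(np.clip(lengths0[edges], BL_MIN, BL_MAX)))
    bounds = [(np.log(BL_MIN), np.log(BL_MAX))] * len(edges)
    if gamma:
        x0.append(np.log(alpha0 if alpha0 else 1.0))
        bounds.append((np.log(ALPHA_MIN), np.log(ALPHA_MAX)))
    if invariant:
        x0.append(pinv0)
        bounds.append((0.0, PINV_MAX))

    lengths = lengths0.copy()

    def f(x: np.ndarray) -> float:
        lengths[edges] = np.exp(x[: len(edges)])
        k = len(edges)
        a = float(np.exp(x[k])) if gamma else 1.0
        if invariant:
            p = float(x[-1])
        else:
            p = 0.0
        return -obj.lnl(lengths, a, p)

    res = minimize(f, np.array(x0), method="Powell", bounds=bounds,
                   options={"xtol": 1e-6, "ftol": 1e-9, "maxfev": 8000})
    if -res.fun <= lnl0:
        return start
    x = res.x
    lengths = lengths0.copy()
    lengths[edges] = np.exp(x[: len(edges)])
    alpha = float(np.exp(x[len(edges)])) if gamma else None
    pinv = float(x[-1]) if invariant else 0.0
    return lengths, alpha, pinv, float(-res.fun)


def fit(
    tree: AreaTree,
    matrix: TaxonAreaMatrix,
    *,
    gamma: bool = False,
    invariant: bool = False,
    n_categories: int = 4,
    tol: float = 1e-8,
) -> LikelihoodResult:
    """Optimise branch lengths (and gamma shape / invariant proportion when
    requested) on the given topology and return the fitted result."""
    if set(tree.tip_names) != set(matrix.area_names):
        raise TreeError("tree tips do not match matrix areas")
    if matrix.n_species < 1:
        raise ValueError("need at least one character")
    flat = canonical_flat(flatten(tree, tip_order=matrix.area_names))
    tipdata, inverse, counts = compress_columns(matrix.cells)
    lengths, alpha, pinv, lnl = optimize_on_topology(
        flat, tipdata, counts,
        gamma=gamma, invariant=invariant, n_categories=n_categories, tol=tol,
    )
    warns: list[str] = []
    non_root = np.arange(flat.n_nodes) != flat.root
    if (lengths[non_root] <= BL_MIN * 2).all():
        warns.append(
            "no variation in the data: all branch lengths at the lower bound"
        )
        _warnings.warn(warns[-1], stacklevel=2)
    model = MkModel(
        gamma_shape=alpha, n_categories=n_categories,
        p_invariant=pinv if invariant else 0.0,
    )
    fitted_flat = FlatTree(flat.tip_names, flat.parent, flat.children,
                           lengths, flat.postorder)
    fitted_tree = unflatten(fitted_flat)
    L = pattern_likelihoods(fitted_flat, tipdata, model, lengths)
    per_char = np.log(L)[inverse]
    return LikelihoodResult(
        log_likelihood=lnl,
        per_character_log_likelihoods=per_char,
        gamma_shape=alpha,
        p_invariant=pinv if invariant else 0.0,
        tree=fitted_tree,
        warnings=warns,
    )
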