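"""Ornstein-Uhlenbeck optimum-shift detection on a phylogeny.

Model: each trait follows a stationary-root OU process with selection strength
alpha, diffusion variance sigma^2 and a piecewise-constant optimum theta that
may jump ("shift") at the start of selected edges.  Tip expectations are then
linear in the shifts: E[y_i] = theta0 + sum_{e in S, e ancestral to i}
beta_e (1 - e^{-alpha (T_i - s_e)}), with tip covariance
V_ij = sigma^2/(2 alpha) e^{-alpha (T_i + T_j - 2 t_mrca(i,j))}.

Shift placement is selected by minimising a phylogenetic BIC
pBIC = -2 logL + p log n + 2 s log m, whose extra 2 s log m term charges for
choosing s of the m edges — conservative relative to the ordinary BIC.
Candidate configurations come from a whitened group-lasso path (edges as
groups across traits) over a grid of alpha values; each candidate is then
refitted exactly by profiled maximum likelihood and the best configuration is
polished by backward elimination.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .exceptions import CollinearityError, InputError, MappingError
from .phylo import Phylogeny

__all__ = [
    "ou_design_matrix",
    "ou_covariance",
    "fit_fixed_config",
    "candidate_configurations",
    "score_pbic",
    "detect_shifts",
    "OUShiftModel",
    "OUShiftResults",
    "ShiftFit",
]

_ALPHA_GRID_SIZE = 16
_HALF_LIFE_RANGE = (0.05, 10.0)  # multiples of tree height
_MAX_EXHAUSTIVE = 300  # complete the candidate list by enumeration below this


def _alpha_grid(height: float, size: int = _ALPHA_GRID_SIZE) -> np.ndarray:
    lo = math.log(2.0) / (_HALF_LIFE_RANGE[1] * height)
    hi = math.log(2.0) / (_HALF_LIFE_RANGE[0] * height)
    return np.geomspace(lo, hi, size)


def ou_design_matrix(tree: Phylogeny, alpha: float, edges=None) -> np.ndarray:
    """Tips x edges matrix X_ie = 1 - e^{-alpha (T_i - s_e)} on ancestral edges.

    ``s_e`` is the depth of the edge's start (parent) node — the
    shift-at-edge-start convention shared with the trait simulator.  Columns
    follow ``tree.edges`` order unless ``edges`` is given.
    """
    if alpha <= 0:
        raise InputError("alpha must be > 0")
    if edges is None:
        edges = tree.edges
    edges = np.asarray(edges, dtype=int)
    T = tree.tip_depths[:, None]
    s = tree.depths[tree.parent[edges]][None, :]
    A = tree.ancestor_matrix[:, edges]
    return np.where(A, 1.0 - np.exp(-alpha * (T - s)), 0.0)


def ou_covariance(tree: Phylogeny, alpha: float, sigma2: float) -> np.ndarray:
    """Stationary-root OU tip covariance (sigma^2/(2 alpha)) e^{-alpha d_ij}."""
    if alpha <= 0 or sigma2 <= 0:
        raise InputError("alpha and sigma2 must be > 0")
    return sigma2 / (2.0 * alpha) * np.exp(-alpha * tree.patristic_gap)


@dataclass
class ShiftFit:
    """Maximum-likelihood fit of one fixed shift configuration."""

    edges: tuple  # sorted shift edge ids (child-node ids)
    alpha: float | np.ndarray  # shared scalar (default) or per-trait array
    sigma2: np.ndarray  # (q,)
    theta0: np.ndarray  # (q,)
    beta: np.ndarray  # (s, q) optimum deltas per shift edge and trait
    log_likelihood: float
    pbic: float | None = None
    shared_alpha: bool = True
    n_tips: int = 0
    n_edges: int = 0
    q: int = 0

    @property
    def n_shifts(self) -> int:
        return len(self.edges)


class _OUWorkspace:
    """Precomputed tree quantities shared by all likelihood evaluations."""

    def __init__(self, tree: Phylogeny, traits: pd.DataFrame):
        if tree.n_tips < 4:
            raise InputError("shift detection needs at least 4 tips")
        missing = [t for t in tree.tip_labels if t not in traits.index]
        extra = [t for t in traits.index if t not in tree.tip_labels]
        if missing or extra:
            raise MappingError(
                f"tip/trait mismatch: missing traits for {missing[:5]}, "
                f"unknown tips {extra[:5]}"
            )
        if traits.isna().any().any():
            raise InputError("trait matrix contains missing values")
        self.tree = tree
        self.Y = traits.loc[tree.tip_labels].to_numpy(dtype=float)
        self.q = self.Y.shape[1]
        self.n = tree.n_tips
        self.D = tree.patristic_gap
        self.edges = tree.edges
        self.m = len(self.edges)
        self.height = tree.height

    def chol(self, alpha: float) -> np.ndarray:
        C = np.exp(-alpha * self.D)
        try:
            return np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return np.linalg.cholesky(C + 1e-10 * np.eye(self.n))

    def profile_loglik(self, alpha: float, edges: tuple, *, want_params: bool = False):
        """Profiled Gaussian log-likelihood at fixed alpha and shift set.

        theta0, beta and sigma^2 are profiled out in closed form (GLS +
        variance MLE); returns the summed log-likelihood across traits.
        """
        L = self.chol(alpha)
        Z = np.empty((self.n, 1 + len(edges)))
        Z[:, 0] = 1.0
        if edges:
            Z[:, 1:] = ou_design_matrix(self.tree, alpha, edges=np.array(edges))
        Wz = solve_triangular(L, Z, lower=True)
        Wy = solve_triangular(L, self.Y, lower=True)
        # rank check on the whitened design
        sv = np.linalg.svd(Wz, compute_uv=False)
        if sv[-1] <= 1e-10 * max(sv[0], 1.0):
            raise CollinearityError(
                f"singular design for shift set {edges} (edge confounded with intercept)"
            )
        coef, *_ = np.linalg.lstsq(Wz, Wy, rcond=None)
        resid = Wy - Wz @ coef
        rss = np.einsum("ij,ij->j", resid, resid)
        v = np.maximum(rss / self.n, 1e-12)  # sigma^2/(2 alpha), floored
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        ll = -0.5 * self.q * self.n * math.log(2 * math.pi) - 0.5 * self.q * logdet
        ll += float(np.sum(-0.5 * self.n * np.log(v) - 0.5 * self.n))
        if not want_params:
            return ll
        theta0 = coef[0].copy()
        beta = coef[1:].copy()
        sigma2 = 2.0 * alpha * v
        return ll, theta0, beta, sigma2

    def optimise_alpha(self, edges: tuple, grid: np.ndarray | None = None):
        """Grid search + golden-section refinement of the profiled likelihood."""
        if grid is None:
            grid = _alpha_grid(self.height)
        vals = np.array([self.profile_loglik(a, edges) for a in grid])
        j = int(np.argmax(vals))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, len(grid) - 1)]
        if lo == hi:
            return float(grid[j]), float(vals[j])
        # golden section on log(alpha)
        invphi = (math.sqrt(5) - 1) / 2
        a, b = math.log(lo), math.log(hi)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc = self.profile_loglik(math.exp(c), edges)
        fd = self.profile_loglik(math.exp(d), edges)
        for _ in range(25):
            if fc > fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = self.profile_loglik(math.exp(c), edges)
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = self.profile_loglik(math.exp(d), edges)
        best = c if fc > fd else d
        fbest = max(fc, fd)
        if fbest >= vals[j]:
            return float(math.exp(best)), float(fbest)
        return float(grid[j]), float(vals[j])


def fit_fixed_config(
    tree: Phylogeny,
    traits: pd.DataFrame,
    edges,
    *,
    alpha: float | None = None,
    shared_alpha: bool = True,
) -> ShiftFit:
    """Maximum-likelihood OU fit for a fixed shift configuration.

    alpha is profiled over a log grid with golden-section refinement (shared
    across traits by default; per-trait behind ``shared_alpha=False``);
    theta0, beta and sigma^2 follow by GLS given alpha.  Pass ``alpha`` to fix
    it instead of optimising.
    """
    ws = _OUWorkspace(tree, traits)
    edges = tuple(sorted(int(e) for e in edges))
    for e in edges:
        if e == tree.root or not 0 <= e < tree.n_nodes:
            raise InputError(f"edge {e} not in tree")
    return _fit_on_workspace(ws, edges, alpha=alpha, shared_alpha=shared_alpha)


def _fit_on_workspace(ws, edges, *, alpha=None, shared_alpha=True) -> ShiftFit:
    if shared_alpha:
        if alpha is None:
            alpha_hat, _ = ws.optimise_alpha(edges)
        else:
            alpha_hat = float(alpha)
        ll, theta0, beta, sigma2 = ws.profile_loglik(alpha_hat, edges, want_params=True)
        fit = ShiftFit(
            edges=edges, alpha=alpha_hat, sigma2=sigma2, theta0=theta0,
            beta=beta, log_likelihood=ll, shared_alpha=True,
            n_tips=ws.n, n_edges=ws.m, q=ws.q,
        )
    else:
        alphas, th, bt, s2, ll_total = [], [], [], [], 0.0
        for j in range(ws.q):
            sub = _OUWorkspace(ws.tree, pd.DataFrame(
                ws.Y[:, [j]], index=ws.tree.tip_labels, columns=["y"]))
            if alpha is None:
                a_j, _ = sub.optimise_alpha(edges)
            else:
                a_j = float(alpha)
            ll_j, t0, b, v = sub.profile_loglik(a_j, edges, want_params=True)
            alphas.append(a_j)
            th.append(t0[0])
            bt.append(b[:, 0])
            s2.append(v[0])
            ll_total += ll_j
        fit = ShiftFit(
            edges=edges, alpha=np.array(alphas), sigma2=np.array(s2),
            theta0=np.array(th), beta=np.array(bt).T if edges else np.zeros((0, ws.q)),
            log_likelihood=ll_total, shared_alpha=False,
            n_tips=ws.n, n_edges=ws.m, q=ws.q,
        )
    fit.pbic = score_pbic(fit)
    return fit


def score_pbic(fit: ShiftFit, tree=None, traits=None) -> float:
    """Phylogenetic BIC: -2 logL + p log n + 2 s log m (lower is better).

    p counts free numeric parameters: per trait sigma^2, theta0 and s betas,
    plus one alpha (shared) or q alphas (per-trait).  The 2 s log m term
    charges for placing s shifts among the m edges.
    """
    del tree, traits  # dimensions travel on the fit itself
    n, m, q, s = fit.n_tips, fit.n_edges, fit.q, fit.n_shifts
    if n == 0 or m == 0:
        raise InputError("fit carries no tree dimensions (unfitted model)")
    p = q * (2 + s) + (1 if fit.shared_alpha else q)
    return float(-2.0 * fit.log_likelihood + p * math.log(n) + 2.0 * s * math.log(m))


# --------------------------------------------------------- candidate search


def _group_soft(B: np.ndarray, thresh: float) -> np.ndarray:
    norms = np.linalg.norm(B, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(norms > 0, np.maximum(0.0, 1.0 - thresh / norms), 0.0)
    return B * scale


def _group_lasso_path(Xw, Yw, s_max, n_lambda=30, max_iter=300, tol=1e-6):
    """FISTA group-lasso path (rows of B are groups).

    Yields, per penalty value, the support ordered by decreasing group norm so
    the caller can also harvest nested prefixes.
    """
    m = Xw.shape[1]
    lam_max = np.max(np.linalg.norm(Xw.T @ Yw, axis=1))
    if lam_max <= 0:
        return []
    lip = np.linalg.norm(Xw, 2) ** 2
    lams = np.geomspace(lam_max * 0.98, lam_max * 1e-3, n_lambda)
    B = np.zeros((m, Yw.shape[1]))
    supports = []
    G = Xw.T @ Xw
    H = Xw.T @ Yw
    for lam in lams:
        Z = B.copy()
        t = 1.0
        for _ in range(max_iter):
            grad = G @ Z - H
            B_new = _group_soft(Z - grad / lip, lam / lip)
            t_new = 0.5 * (1 + math.sqrt(1 + 4 * t * t))
            Z = B_new + (t - 1) / t_new * (B_new - B)
            delta = np.abs(B_new - B).max()
            B, t = B_new, t_new
            if delta < tol * (1.0 + np.abs(B).max()):
                break
        norms = np.linalg.norm(B, axis=1)
        support = np.flatnonzero(norms > 1e-9)
        supports.append(tuple(support[np.argsort(-norms[support], kind="stable")].tolist()))
        if len(support) >= s_max:
            break
    return supports


def candidate_configurations(
    tree: Phylogeny,
    traits: pd.DataFrame,
    s_max: int = 10,
    n_alpha: int = _ALPHA_GRID_SIZE,
):
    """Candidate shift-edge sets from whitened group-lasso paths.

    For each alpha on a log grid (phylogenetic half-life 0.05x to 10x tree
    height), traits and the full edge design are whitened by the inverse
    Cholesky of the alpha-correlation matrix and a group-penalised path (edges
    as groups across traits) is run from zero shifts down to ``s_max``;
    supports along every path are pooled and de-duplicated.  The empty set is
    always included.  When the total number of edge subsets of size <= s_max
    is small, the list is completed by exhaustive enumeration, making the
    downstream search an exact best-subset selection on small trees.
    """
    if s_max < 1:
        raise InputError("s_max must be >= 1")
    ws = _OUWorkspace(tree, traits)
    if s_max >= ws.m:
        raise InputError(f"s_max={s_max} must be < number of edges ({ws.m})")
    seen: set[frozenset] = {frozenset()}
    edge_ids = ws.edges
    root_children = frozenset(int(c) for c in tree.children[tree.root])

    def collect(ids: frozenset):
        """Add a support; if it holds every root-child edge (jointly collinear
        with the intercept), also add the repaired variants dropping one."""
        if not 0 < len(ids) <= s_max:
            return
        seen.add(ids)
        if root_children <= ids:
            for rc in root_children:
                seen.add(ids - {rc})

    for alpha in _alpha_grid(ws.height, n_alpha):
        L = ws.chol(alpha)
        X = ou_design_matrix(tree, alpha)
        Wx = solve_triangular(L, X, lower=True)
        Wy = solve_triangular(L, ws.Y, lower=True)
        w1 = solve_triangular(L, np.ones((ws.n, 1)), lower=True)
        qv = w1 / np.linalg.norm(w1)
        Wy = Wy - qv @ (qv.T @ Wy)
        Wx = Wx - qv @ (qv.T @ Wx)
        norms = np.linalg.norm(Wx, axis=0)
        usable = np.flatnonzero(norms > 1e-8 * max(norms.max(), 1.0))
        for sup in _group_lasso_path(Wx[:, usable], Wy, s_max):
            ordered = [int(edge_ids[usable[j]]) for j in sup]
            # the support itself plus its norm-ordered nested prefixes
            for size in range(1, min(len(ordered), s_max) + 1):
                collect(frozenset(ordered[:size]))
    # exact best-subset completion when the space is small
    total = sum(math.comb(ws.m, s) for s in range(1, min(s_max, ws.m) + 1))
    if total <= _MAX_EXHAUSTIVE:
        for s in range(1, min(s_max, ws.m) + 1):
            for combo in itertools.combinations(edge_ids.tolist(), s):
                seen.add(frozenset(int(e) for e in combo))
    return sorted(seen, key=lambda s: (len(s), sorted(s)))


# -------------------------------------------------------------- model front


@dataclass
class OUShiftResults:
    """Best shift configuration plus the full scored candidate table."""

    best: ShiftFit
    candidates: pd.DataFrame  # columns: edges, n_shifts, log_likelihood, pbic
    tree: Phylogeny = None
    trait_names: list = field(default_factory=list)

    @property
    def shift_edges(self) -> tuple:
        return self.best.edges

    @property
    def shift_edge_labels(self) -> list:
        return [self.tree.edge_label(e) for e in self.best.edges]

    @property
    def pbic(self) -> float:
        return self.best.pbic

    def summary(self) -> str:
        b = self.best
        lines = [
            "Ornstein-Uhlenbeck shift detection",
            "=" * 44,
            f"tips: {b.n_tips}   edges: {b.n_edges}   traits: {b.q}",
            f"alpha ({'shared' if b.shared_alpha else 'per-trait'}): "
            + (f"{b.alpha:.4g}" if b.shared_alpha else np.array2string(b.alpha, precision=4)),
            "sigma2: " + np.array2string(b.sigma2, precision=4),
            "theta0: " + np.array2string(b.theta0, precision=4),
            f"log-likelihood: {b.log_likelihood:.4f}",
            f"pBIC: {b.pbic:.4f}",
            f"shifts ({b.n_shifts}):",
        ]
        for i, e in enumerate(b.edges):
            lines.append(
                f"  {self.tree.edge_label(e) if self.tree else e}: "
                + np.array2string(b.beta[i], precision=4)
            )
        if not b.edges:
            lines.append("  (none — single-regime OU)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        b = self.best
        return {
            "shift_edges": [
                {
                    "edge": int(e),
                    "label": self.tree.edge_label(e) if self.tree else str(e),
                    "beta": b.beta[i].tolist(),
                }
                for i, e in enumerate(b.edges)
            ],
            "alpha": b.alpha if b.shared_alpha else list(b.alpha),
            "sigma2": b.sigma2.tolist(),
            "theta0": b.theta0.tolist(),
            "log_likelihood": b.log_likelihood,
            "pbic": b.pbic,
            "n_shifts": b.n_shifts,
        }


class OUShiftModel:
    """Multivariate OU shift model bound to a tree and trait matrix.

    statsmodels-style: construct from data, then :meth:`fit` runs the full
    candidate search and returns :class:`OUShiftResults`.
    """

    def __init__(self, tree: Phylogeny, traits: pd.DataFrame):
        self.tree = tree
        self.traits = traits
        _OUWorkspace(tree, traits)  # validates the binding eagerly

    @classmethod
    def from_dataframe(cls, traits: pd.DataFrame, tree: Phylogeny) -> "OUShiftModel":
        return cls(tree, traits)

    def fit_fixed(self, edges, **kw) -> ShiftFit:
        return fit_fixed_config(self.tree, self.traits, edges, **kw)

    def fit(self, s_max: int = 10, seed: int = 0, shared_alpha: bool = True,
            n_alpha: int = _ALPHA_GRID_SIZE) -> OUShiftResults:
        return detect_shifts(
            self.tree, self.traits, s_max=s_max, seed=seed,
            shared_alpha=shared_alpha, n_alpha=n_alpha,
        )


def detect_shifts(
    tree: Phylogeny,
    traits: pd.DataFrame,
    s_max: int = 10,
    seed: int = 0,
    shared_alpha: bool = True,
    n_alpha: int = _ALPHA_GRID_SIZE,
) -> OUShiftResults:
    """Search shift configurations and return the minimal-pBIC model.

    Every candidate configuration is refitted exactly and scored; the best is
    polished by backward elimination (drop any shift whose removal lowers the
    pBIC, repeated to a fixpoint).  Fully deterministic; ``seed`` is accepted
    for interface symmetry with the stochastic stages.
    """
    del seed  # the search is deterministic
    ws = _OUWorkspace(tree, traits)
    cands = candidate_configurations(tree, traits, s_max=s_max, n_alpha=n_alpha)
    fits: dict[tuple, ShiftFit] = {}

    def fit_set(edge_set) -> ShiftFit | None:
        key = tuple(sorted(edge_set))
        if key in fits:
            return fits[key]
        try:
            f = _fit_on_workspace(ws, key, shared_alpha=shared_alpha)
        except CollinearityError:
            return None
        fits[key] = f
        return f

    scored = [f for f in (fit_set(c) for c in cands) if f is not None]
    if not scored:
        raise InputError("no fittable candidate configuration")
    screened = sorted({e for c in cands for e in c})  # union of path supports

    def backward(fit: ShiftFit) -> ShiftFit:
        improved = True
        while improved and fit.n_shifts:
            improved = False
            for drop in fit.edges:
                trial = fit_set(set(fit.edges) - {drop})
                if trial is not None and trial.pbic < fit.pbic - 1e-9:
                    fit = trial
                    improved = True
                    break
        return fit

    def forward(fit: ShiftFit) -> ShiftFit:
        improved = True
        while improved and fit.n_shifts < s_max:
            improved = False
            trials = []
            for add in screened:
                if add in fit.edges:
                    continue
                trial = fit_set(set(fit.edges) | {add})
                if trial is not None and trial.pbic < fit.pbic - 1e-9:
                    trials.append(trial)
            if trials:
                fit = min(trials, key=lambda f: (f.pbic, f.edges))
                improved = True
        return fit

    # polish the leading candidates: backward elimination strips spurious
    # edges from supersets of the truth, the screened forward pass rescues
    # shifts the penalised path under-selected; iterate to a fixpoint
    scored.sort(key=lambda f: (f.pbic, f.n_shifts, f.edges))
    polished = []
    for f in scored[:10]:
        prev = None
        while prev is None or f.edges != prev:
            prev = f.edges
            f = forward(backward(f))
        polished.append(f)
    best = min(polished, key=lambda f: (f.pbic, f.n_shifts, f.edges))

    rows = [
        {
            "edges": ",".join(str(e) for e in f.edges),
            "n_shifts": f.n_shifts,
            "log_likelihood": f.log_likelihood,
            "pbic": f.pbic,
        }
        for f in sorted(fits.values(), key=lambda f: f.pbic)
    ]
    table = pd.DataFrame(rows, columns=["edges", "n_shifts", "log_likelihood", "pbic"])
    return OUShiftResults(best=best, candidates=table, tree=tree,
                          trait_names=list(traits.columns))
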