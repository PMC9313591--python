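"""Synthetic data generators: flower outlines, trees, OU traits, trio genotypes.

These generators provide ground-truth inputs for every downstream stage of the
pipeline.  The corolla model is a parametric radial family spanning the
qualitative phenotypes seen in tropical rhododendrons: pentamerous to
seven-lobed fronts with dorsoventral lobing gradients, and side profiles with
straight or curved tubes and unequal upper/lower lips.  It is an engineering
family — realism is not asserted beyond those qualitative features.

All generators are bit-reproducible under a fixed seed (numpy Generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError
from .outlines import Outline
from .phylo import Phylogeny

__all__ = [
    "FlowerParams",
    "OUSimSpec",
    "TrioSimSpec",
    "gen_front_outline",
    "gen_side_outline",
    "gen_tree",
    "sim_ou_traits",
    "sim_genotypes",
]


# --------------------------------------------------------------------- flowers


@dataclass
class FlowerParams:
    """Parameters of the synthetic corolla family.

    Front view: a radial function r(theta) = R * [1 + L(theta) * cos(k(theta - pi/2))]
    with lobe depth L(theta) = L0 * (1 + g * sin(theta)); ``g`` tilts lobe depth
    dorsoventrally (0 = radially symmetric depth).  Optional lateral doubling
    adds two extra lateral lobes (a 7-lobed corolla when k = 5).  Left-right
    noise is radial, anti-symmetric about the vertical axis.

    Side view: a constant-width tube (aperture width 1) of centreline length
    ``tube_length`` and constant signed curvature ``tube_curvature``, joined to
    flaring upper/lower lips whose lengths differ by ``upper_lobe_excess``.
    """

    view: str = "front"
    petal_count: int = 5
    lobe_depth: float = 0.3
    dorsoventral_gradient: float = 0.0
    upper_lower_angle_bias: float = 0.0
    lateral_doubling: bool = False
    tube_length: float = 2.0
    tube_curvature: float = 0.0
    upper_lobe_excess: float = 1.0
    reflex_angle: float = 0.0
    asymmetry_sd: float = 0.0
    n_points: int = 300
    seed: int = 0

    def validate(self) -> None:
        if self.view not in ("front", "side"):
            raise InputError(f"view must be 'front' or 'side', got {self.view!r}")
        if self.n_points < 64:
            raise InputError("n_points must be >= 64")
        if self.view == "front":
            if self.petal_count < 3:
                raise InputError("petal_count must be >= 3")
            if not 0.0 <= self.lobe_depth < 1.0:
                raise InputError("lobe_depth must lie in [0, 1)")
            if self.n_points < 8 * self.petal_count:
                raise InputError(
                    f"n_points={self.n_points} aliases k={self.petal_count} lobes "
                    f"(need >= {8 * self.petal_count})"
                )
        else:
            if self.tube_length < 0:
                raise InputError("tube_length must be >= 0")


def _nearest_vertex(points: np.ndarray, target: np.ndarray) -> int:
    return int(np.argmin(np.sum((points - target) ** 2, axis=1)))


def gen_front_outline(
    params: FlowerParams, specimen_id: str = "synthetic", taxon_id: str = "synthetic"
) -> Outline:
    """Generate a closed, counter-clockwise front-view corolla outline.

    Vertices are placed at uniform angles starting from the top (theta = pi/2);
    four landmarks (left-mid, right-mid, top, bottom) are attached at the axis
    intersections.
    """
    params.validate()
    if params.view != "front":
        raise InputError("gen_front_outline requires view='front'")
    n = params.n_points
    k = params.petal_count
    L0 = params.lobe_depth
    g = params.dorsoventral_gradient
    theta = np.pi / 2 + 2 * np.pi * np.arange(n) / n  # CCW from the top

    # mirror-symmetric angular warp: phi(pi - th) = pi - phi(th)
    phi = theta + params.upper_lower_angle_bias * np.cos(theta)
    depth = L0 * (1.0 + g * np.sin(theta))
    r = 1.0 + depth * np.cos(k * (phi - np.pi / 2))

    if params.lateral_doubling:
        # two extra lobes at the inter-petal trough pair nearest the horizontal
        # axis (a mirror pair about the vertical axis)
        troughs = np.pi / 2 + (2 * np.arange(k) + 1) * np.pi / k
        wrapped = np.angle(np.exp(1j * troughs))  # to (-pi, pi]
        right = troughs[np.argmin(np.abs(wrapped))]
        left = np.pi - right
        amp, width = 0.8 * max(L0, 0.05), 0.15
        for centre in (right, left):
            d = np.angle(np.exp(1j * (theta - centre)))
            r += amp * np.exp(-((d / width) ** 2))

    if params.asymmetry_sd > 0:
        # anti-symmetric radial noise: vertex j pairs with n - j under the
        # vertical-axis mirror; fixed points (top/bottom) stay unperturbed
        rng = np.random.default_rng(params.seed)
        noise = np.zeros(n)
        half = (n + 1) // 2
        eps = rng.normal(0.0, params.asymmetry_sd, size=half - 1)
        noise[1:half] = eps
        noise[n - half + 1 :] = -eps[::-1]
        r = r + noise

    points = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    lm_targets = [np.array([-1.0, 0.0]), np.array([1.0, 0.0]),
                  np.array([0.0, 1.0]), np.array([0.0, -1.0])]
    # snap to the axis-intersection angles, robust to radius modulation
    angles = np.array([np.pi, 0.0, np.pi / 2, 3 * np.pi / 2])
    landmarks = []
    for ang, tgt in zip(angles, lm_targets):
        d = np.angle(np.exp(1j * (theta - ang)))
        landmarks.append(int(np.argmin(np.abs(d))))
    return Outline(
        specimen_id=specimen_id,
        taxon_id=taxon_id,
        view="front",
        points=points,
        landmarks=landmarks,
    )


def gen_side_outline(
    params: FlowerParams, specimen_id: str = "synthetic", taxon_id: str = "synthetic"
) -> Outline:
    """Generate a closed side-view outline: tube plus upper and lower lips.

    Three landmarks are attached: tube base (middle of the base edge), upper-lip
    tip and lower-lip tip.
    """
    params.validate()
    if params.view != "side":
        raise InputError("gen_side_outline requires view='side'")
    w = 1.0
    ell = params.tube_length
    kappa = params.tube_curvature
    if abs(kappa) * ell >= np.pi:
        raise InputError("tube_curvature too large: tube bends back on itself")
    if abs(kappa) * w / 2 >= 1.0:
        raise InputError("tube_curvature too large: inner tube edge self-intersects")

    # centreline and unit tangent/normal at arclength s
    def centre(s):
        if kappa == 0:
            return np.column_stack([s, np.zeros_like(s)])
        return np.column_stack([np.sin(kappa * s) / kappa, (1 - np.cos(kappa * s)) / kappa])

    def frame(s):
        psi = kappa * s
        return np.column_stack([np.cos(psi), np.sin(psi)]), np.column_stack(
            [-np.sin(psi), np.cos(psi)]
        )

    s_end = np.array([ell])
    c_end = centre(s_end)[0]
    tau_end, nrm_end = frame(s_end)
    tau_end, nrm_end = tau_end[0], nrm_end[0]
    corner_up = c_end + nrm_end * w / 2
    corner_dn = c_end - nrm_end * w / 2

    lip_base = 0.8 * w
    flare = 0.8  # rad, fixed lip flare of the family
    excess = params.upper_lobe_excess
    asym = 0.0
    if params.asymmetry_sd > 0:
        asym = float(np.random.default_rng(params.seed).normal(0.0, params.asymmetry_sd))
    len_up = lip_base * excess * (1.0 + asym)
    len_dn = lip_base * (1.0 - asym)

    def rot(vec, ang):
        ca, sa = np.cos(ang), np.sin(ang)
        return np.array([ca * vec[0] - sa * vec[1], sa * vec[0] + ca * vec[1]])

    tip_up = corner_up + rot(tau_end, flare + params.reflex_angle) * len_up
    tip_dn = corner_dn + rot(tau_end, -(flare + params.reflex_angle)) * len_dn
    mouth = c_end + tau_end * 0.15 * w

    base_dn = np.array([0.0, -w / 2])
    base_up = np.array([0.0, w / 2])

    # piecewise path (CCW): base_dn -> lower tube edge -> lower lip tip ->
    # mouth -> upper lip tip -> upper tube edge (reversed) -> base_up -> base
    n_tube = max(8, int(round(params.n_points * 0.25)))
    s_grid = np.linspace(0.0, ell, n_tube)
    _, nrm = frame(s_grid)
    lower_edge = centre(s_grid) - nrm * w / 2
    upper_edge = centre(s_grid) + nrm * w / 2

    def seg(a, b, m):
        t = np.linspace(0.0, 1.0, m, endpoint=False)[1:]
        return a[None, :] + t[:, None] * (b - a)[None, :]

    m_lip = max(4, int(round(params.n_points * 0.06)))
    path = [lower_edge]
    path.append(seg(corner_dn, tip_dn, m_lip))
    path.append(tip_dn[None, :])
    path.append(seg(tip_dn, mouth, m_lip))
    path.append(mouth[None, :])
    path.append(seg(mouth, tip_up, m_lip))
    path.append(tip_up[None, :])
    path.append(seg(tip_up, corner_up, m_lip))
    path.append(upper_edge[::-1])
    path.append(seg(base_up, base_dn, max(4, n_tube // 2)))
    points = np.vstack(path)
    # drop consecutive duplicates
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(points, axis=0), axis=1) > 1e-12
    if np.linalg.norm(points[0] - points[-1]) <= 1e-12:
        keep[-1] = False
    points = points[keep]

    # counter-clockwise
    x, y = points[:, 0], points[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        points = points[::-1]

    landmarks = [
        _nearest_vertex(points, np.array([0.0, 0.0])),
        _nearest_vertex(points, tip_up),
        _nearest_vertex(points, tip_dn),
    ]
    return Outline(
        specimen_id=specimen_id,
        taxon_id=taxon_id,
        view="side",
        points=points,
        landmarks=landmarks,
    )


# ----------------------------------------------------------------------- trees


def gen_tree(n_tips: int, seed: int = 0) -> Phylogeny:
    """Simulate a pure-birth tree rescaled to height 1.0, tips labelled t1..tn.

    Lineages split at unit rate; after the n-th tip appears one further
    exponential waiting time sets the present.  Deterministic under ``seed``.
    """
    if n_tips < 2:
        raise InputError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=int)
    birth = np.zeros(n_nodes)  # time each node's subtending edge starts
    split = np.zeros(n_nodes)  # time each node splits (tips: the present)
    root = n_tips
    next_internal = n_tips + 1

    # active lineages: (parent node id, start time); on split one becomes a
    # new internal node, at the end the survivors become tips
    lin: list[tuple[int, float]] = [(root, 0.0), (root, 0.0)]
    t = 0.0
    while len(lin) < n_tips:
        t += rng.exponential(1.0 / len(lin))
        idx = int(rng.integers(len(lin)))
        par, start = lin.pop(idx)
        node = next_internal
        next_internal += 1
        parent[node] = par
        birth[node] = start
        split[node] = t
        lin.append((node, t))
        lin.append((node, t))
    t += rng.exponential(1.0 / len(lin))
    for tip, (par, start) in enumerate(lin):
        parent[tip] = par
        birth[tip] = start
        split[tip] = t
    length = np.zeros(n_nodes)
    mask = np.arange(n_nodes) != root
    length[mask] = (split[mask] - birth[mask]) / t  # rescale to unit height
    labels = [f"t{i + 1}" for i in range(n_tips)]
    return Phylogeny(parent, length, labels)


# ------------------------------------------------------------------- OU traits


@dataclass
class OUSimSpec:
    """Specification of a multivariate OU trait simulation with optimum shifts.

    ``alpha``/``sigma2``/``theta0`` are scalars or length-q sequences; ``shifts``
    is a list of ``(edge_id, beta)`` with beta scalar or length-q.  Shifts act
    from the start of their edge (the whole edge evolves toward the shifted
    optimum), matching the shift-detection design matrix.
    """

    n_tips: int = 64
    q: int = 1
    alpha: float | np.ndarray = 1.0
    sigma2: float | np.ndarray = 1.0
    theta0: float | np.ndarray = 0.0
    shifts: list = field(default_factory=list)
    seed: int = 0


def sim_ou_traits(tree: Phylogeny, spec: OUSimSpec):
    """Simulate OU traits on ``tree`` by the exact pre-order transition.

    child ~ N(parent * e^{-a l} + theta_e (1 - e^{-a l}), s2/(2a) (1 - e^{-2 a l}));
    the root is drawn from the stationary law N(theta0, s2/(2a)).

    Returns a pandas DataFrame (tips x q) indexed by tip label.
    """
    import pandas as pd

    q = spec.q
    alpha = np.broadcast_to(np.asarray(spec.alpha, dtype=float), (q,)).copy()
    sigma2 = np.broadcast_to(np.asarray(spec.sigma2, dtype=float), (q,)).copy()
    theta0 = np.broadcast_to(np.asarray(spec.theta0, dtype=float), (q,)).copy()
    if np.any(alpha <= 0):
        raise InputError("alpha must be > 0")
    if np.any(sigma2 < 0):
        raise InputError("sigma2 must be >= 0")
    shift_map: dict[int, np.ndarray] = {}
    for edge, beta in spec.shifts:
        edge = int(edge)
        if edge < 0 or edge >= tree.n_nodes or edge == tree.root:
            raise InputError(f"shift edge {edge} not in tree")
        shift_map[edge] = shift_map.get(edge, 0) + np.broadcast_to(
            np.asarray(beta, dtype=float), (q,)
        )

    rng = np.random.default_rng(spec.seed)
    stat_sd = np.sqrt(sigma2 / (2 * alpha))
    values = np.zeros((tree.n_nodes, q))
    theta = np.zeros((tree.n_nodes, q))
    for node in tree.preorder:
        if node == tree.root:
            theta[node] = theta0
            values[node] = theta0 + stat_sd * rng.standard_normal(q)
            continue
        theta[node] = theta[tree.parent[node]] + shift_map.get(node, 0.0)
        l = tree.length[node]
        decay = np.exp(-alpha * l)
        mean = values[tree.parent[node]] * decay + theta[node] * (1 - decay)
        var = sigma2 / (2 * alpha) * (1 - np.exp(-2 * alpha * l))
        values[node] = mean + np.sqrt(var) * rng.standard_normal(q)
    return pd.DataFrame(
        values[: tree.n_tips],
        index=pd.Index(tree.tip_labels, name="tip"),
        columns=[f"trait_{j + 1}" for j in range(q)],
    )


# ------------------------------------------------------------------ genotypes


@dataclass
class TrioSimSpec:
    """Site-pattern generator for one (P1, P2, P3, outgroup) trio.

    Per site a pattern class is drawn from {BBAA, ABBA, BABA, invariant} with
    probabilities {p_b, p_d + f_e, p_d, remainder}: ``baseline_discordance``
    (p_d) is the symmetric discordance from incomplete lineage sorting,
    ``admixture_excess`` (f_e) the extra ABBA probability from gene flow
    (0 = null), ``concordant_prob`` (p_b) the species-tree BBAA probability.
    The implied expectation is D = f_e / (2 p_d + f_e).
    """

    n_sites: int = 10_000
    n_individuals: int = 1
    baseline_discordance: float = 0.1
    admixture_excess: float = 0.0
    concordant_prob: float = 0.2
    block_size: int = 500
    seed: int = 0

    def validate(self) -> None:
        p_d, f_e, p_b = self.baseline_discordance, self.admixture_excess, self.concordant_prob
        if not 0.0 <= p_d <= 0.5:
            raise InputError("baseline_discordance must lie in [0, 0.5]")
        if not 0.0 <= f_e <= 1.0 - 2 * p_d:
            raise InputError("admixture_excess must lie in [0, 1 - 2 p_d]")
        if not 0.0 <= p_b <= 1.0 or p_b + 2 * p_d + f_e > 1.0 + 1e-12:
            raise InputError("pattern probabilities must sum to <= 1")
        if self.n_sites < 0:
            raise InputError("n_sites must be >= 0")
        if self.block_size < 1:
            raise InputError("block_size must be >= 1")
        if self.n_individuals < 1:
            raise InputError("n_individuals must be >= 1")


def sim_genotypes(spec: TrioSimSpec):
    """Draw per-site patterns and return a :class:`~petalspectrum.dstat.GenotypeTable`.

    Populations are named P1, P2, P3, OUT; individuals within a population are
    fixed for the site's allele, the outgroup is fixed ancestral, and block ids
    are assigned contiguously (``site // block_size``).
    """
    from .dstat import GenotypeTable

    spec.validate()
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    p_b, p_d, f_e = spec.concordant_prob, spec.baseline_discordance, spec.admixture_excess
    probs = np.array([p_b, p_d + f_e, p_d, 1.0 - p_b - 2 * p_d - f_e])
    n = spec.n_sites
    pattern = rng.choice(4, size=n, p=probs)  # 0=BBAA 1=ABBA 2=BABA 3=invariant
    freqs = np.zeros((n, 4))
    freqs[pattern == 0, 0] = 1.0
    freqs[pattern == 0, 1] = 1.0
    freqs[pattern == 1, 1] = 1.0
    freqs[pattern == 1, 2] = 1.0
    freqs[pattern == 2, 0] = 1.0
    freqs[pattern == 2, 2] = 1.0
    pops = ["P1", "P2", "P3", "OUT"]
    freq_df = pd.DataFrame(freqs, columns=pops)
    blocks = np.arange(n) // spec.block_size
    popmap = {
        f"{p}_{i + 1}": p for p in pops for i in range(spec.n_individuals)
    }
    dosages = None
    if spec.n_individuals >= 1:
        dos = np.repeat((freqs * 2).astype(np.int8), spec.n_individuals, axis=1)
        dosages = pd.DataFrame(dos, columns=list(popmap))
    return GenotypeTable.from_frequencies(
        freq_df, blocks=blocks, outgroup="OUT", dosages=dosages, popmap=popmap
    )
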