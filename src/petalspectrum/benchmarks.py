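"""Self-contained validation experiments for the pipeline's core claims.

Each function generates its own synthetic data (seeded), runs the relevant
stage end to end, and returns measured quantities.  They back both the
acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import hashlib
import itertools
from pathlib import Path

import numpy as np

from .dstat import jackknife_significance, site_pattern_sums
from .efa import efa_forward, efa_inverse, mirror_coefficients, remove_asymmetric_component
from .exceptions import CollinearityError
from .morphospace import select_k_majority
from .ou import detect_shifts, fit_fixed_config
from .outlines import Outline, resample_uniform
from .simulate import (
    FlowerParams,
    OUSimSpec,
    TrioSimSpec,
    gen_front_outline,
    gen_tree,
    sim_genotypes,
    sim_ou_traits,
)

#: the study's printed outline inventory: (outlines, taxa) per corolla view
FRONT_INVENTORY = (168, 95)
SIDE_INVENTORY = (166, 97)


def inventory_means() -> dict:
    """Mean outlines per taxon implied by the printed inventory counts."""
    return {
        "front_mean_outlines_per_taxon": FRONT_INVENTORY[0] / FRONT_INVENTORY[1],
        "side_mean_outlines_per_taxon": SIDE_INVENTORY[0] / SIDE_INVENTORY[1],
    }


def efa_analytic_suite() -> dict:
    """EFA against closed forms: circle coefficients, invariances, round trip."""
    th = 2 * np.pi * np.arange(512) / 512
    circle = Outline("c", "c", "front",
                     np.column_stack([2 * np.cos(th), 2 * np.sin(th)]))
    c = efa_forward(circle, 8)
    a1, b1, c1, d1 = c.harmonics[0]
    shifted = efa_forward(circle.with_points(circle.points + [5.0, -7.0]), 8)
    drift = float(np.abs(shifted.harmonics - c.harmonics).max())

    flower = resample_uniform(
        gen_front_outline(
            FlowerParams(petal_count=5, lobe_depth=0.3, dorsoventral_gradient=0.3)
        ),
        300,
    )
    fc = efa_forward(flower, 64)
    rec = efa_inverse(fc, flower.n_points)
    roundtrip = float(
        np.mean(np.linalg.norm(rec.points - flower.points, axis=1))
        / flower.centroid_size()
    )
    mm = mirror_coefficients(mirror_coefficients(fc))
    involution_gap = float(np.abs(mm.harmonics - fc.harmonics).max())
    return {
        "circle_a1_error": float(abs(a1 - 2.0)),
        "circle_d1_error": float(abs(d1 - 2.0)),
        "circle_offdiag_max": float(max(abs(b1), abs(c1))),
        "translation_drift": drift,
        "roundtrip_relative_error": roundtrip,
        "mirror_involution_gap": involution_gap,
    }


def symmetry_decomposition_checks() -> dict:
    """Exactness of the left-right asymmetry removal in coefficient space."""
    flower = gen_front_outline(
        FlowerParams(petal_count=5, lobe_depth=0.3, dorsoventral_gradient=0.2,
                     asymmetry_sd=0.05, seed=12)
    )
    c = efa_forward(flower, 32)
    r = remove_asymmetric_component(c)
    m = mirror_coefficients(r)
    mirror_gap = float(np.abs(m.harmonics - r.harmonics).max()) + abs(
        m.offset[1] - r.offset[1]
    )
    sym_power = float(0.5 * np.sum(c.harmonics[:, [0, 3]] ** 2))
    power_gap = abs(r.total_power() - sym_power)
    return {"mirror_invariance_gap": mirror_gap, "power_conservation_gap": power_gap}


def cluster_blob_experiment(seed: int) -> dict:
    """Majority-rule K selection on three well-separated Gaussian blobs."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    X = np.vstack([c + rng.normal(0, 0.1, (50, 2)) for c in centers])
    rep = select_k_majority(X, K_min=2, K_max=20, seed=seed + 1)
    return {"chosen_k": rep.chosen_k, "vote_fraction": rep.vote_margin}


def _pick_clade_edges(tree, n, lo, hi, min_len=0.04):
    chosen = []
    for e in sorted((e for e in tree.edges if e >= tree.n_tips),
                    key=lambda e: -len(tree.tip_sets[e])):
        if lo <= len(tree.tip_sets[e]) <= hi and tree.length[e] >= min_len and all(
            tree.tip_sets[e].isdisjoint(tree.tip_sets[c]) for c in chosen
        ):
            chosen.append(int(e))
        if len(chosen) == n:
            break
    return chosen


def ou_bruteforce_agreement(seed: int, n_datasets: int = 3) -> dict:
    """Shift search vs exhaustive subset enumeration on 6-tip trees, s_max=2."""
    agree = 0
    for k in range(n_datasets):
        tree = gen_tree(6, seed=seed + k)
        shift_edge = int(max(
            (e for e in tree.edges if e >= tree.n_tips),
            key=lambda e: len(tree.tip_sets[e]) * tree.length[e],
        ))
        traits = sim_ou_traits(
            tree,
            OUSimSpec(q=2, alpha=3.0, sigma2=1.0, shifts=[(shift_edge, 4.0)],
                      seed=seed + 100 + k),
        )
        res = detect_shifts(tree, traits, s_max=2)
        best = np.inf
        optimal = set()
        for s in range(3):
            for combo in itertools.combinations(tree.edges.tolist(), s):
                try:
                    fit = fit_fixed_config(tree, traits, combo)
                except CollinearityError:
                    continue
                if fit.pbic < best - 1e-6:
                    best, optimal = fit.pbic, {fit.edges}
                elif fit.pbic <= best + 1e-6:
                    optimal.add(fit.edges)
        if abs(res.pbic - best) <= 1e-6 and res.shift_edges in optimal:
            agree += 1
    return {"agreement_fraction": agree / n_datasets, "n": n_datasets}


def ou_null_conservativeness(seed: int, reps: int = 50, n_tips: int = 100) -> dict:
    """Fraction of no-shift simulations where the empty configuration wins."""
    empty = 0
    for r in range(reps):
        tree = gen_tree(n_tips, seed=seed + r)
        traits = sim_ou_traits(
            tree, OUSimSpec(q=3, alpha=2.0, sigma2=1.0, seed=seed + 10_000 + r)
        )
        res = detect_shifts(tree, traits, s_max=10)
        empty += res.shift_edges == ()
    return {"empty_fraction": empty / reps, "n": reps}


def ou_shift_recovery(seed: int, n_tips: int = 128) -> dict:
    """Recovery of 3 planted shifts (4 stationary SDs per trait, q=3)."""
    tree = gen_tree(n_tips, seed=seed)
    chosen = _pick_clade_edges(tree, 3, lo=10, hi=45)
    alpha, sigma2 = 2.0, 1.0
    beta = 4.0 * np.sqrt(sigma2 / (2 * alpha))
    dirs = [np.array([1.0, 1.0, 1.0]), np.array([1.0, -1.0, 1.0]),
            np.array([-1.0, 1.0, 1.0])]
    traits = sim_ou_traits(
        tree,
        OUSimSpec(q=3, alpha=alpha, sigma2=sigma2,
                  shifts=[(e, beta * d) for e, d in zip(chosen, dirs)],
                  seed=seed + 1),
    )
    res = detect_shifts(tree, traits, s_max=10)

    def family(e):
        return {e, int(tree.parent[e])} | set(tree.children[e])

    recovered = sum(any(f in family(e) for f in res.shift_edges) for e in chosen)
    false_edges = sum(
        all(f not in family(e) for e in chosen) for f in res.shift_edges
    )
    return {"recovered_of_3": recovered, "false_edges": false_edges,
            "n_found": len(res.shift_edges)}


def dstat_null_calibration(seed: int, reps: int = 200, n_sites: int = 100_000) -> dict:
    """Fraction of null (no gene flow) replicates with |Z| > 3."""
    exceed = 0
    for r in range(reps):
        g = sim_genotypes(
            TrioSimSpec(n_sites=n_sites, baseline_discordance=0.1,
                        admixture_excess=0.0, concordant_prob=0.2,
                        block_size=n_sites // 20, seed=seed + r)
        )
        s = site_pattern_sums(g, ("P1", "P2", "P3"))
        _, _, z, _, _ = jackknife_significance(s.blocks)
        exceed += abs(z) > 3
    return {"z_exceed_fraction": exceed / reps, "n": reps}


def dstat_admixture_recovery(seed: int, n_sites: int = 100_000) -> dict:
    """D under f_e = p_d = 0.1 gene flow vs the closed form f_e/(2 p_d + f_e)."""
    g = sim_genotypes(
        TrioSimSpec(n_sites=n_sites, baseline_discordance=0.1,
                    admixture_excess=0.1, concordant_prob=0.3,
                    block_size=n_sites // 20, seed=seed)
    )
    s = site_pattern_sums(g, ("P1", "P2", "P3"))
    D, _, z, _, _ = jackknife_significance(s.blocks)
    return {"D": float(D), "Z": float(z), "expected_D": 1.0 / 3.0, "n": n_sites}


def demo_reproducibility(workdir, seed: int) -> dict:
    """Two demo runs under one seed must produce byte-identical results."""
    from .pipeline import run_demo

    workdir = Path(workdir)
    m1 = run_demo(workdir / "a", seed=seed, n_taxa=16, n_sites=8000)
    m2 = run_demo(workdir / "b", seed=seed, n_taxa=16, n_sites=8000)

    def hashes(d):
        return {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest()
            for f in sorted((Path(d) / "results").iterdir())
            if f.name not in ("run.log", "manifest.json")
        }

    identical = hashes(workdir / "a") == hashes(workdir / "b") and (
        m1["outputs"] == m2["outputs"]
    )
    return {"identical": bool(identical), "n_outputs": len(m1["outputs"])}
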