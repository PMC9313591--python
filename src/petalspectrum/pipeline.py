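"""Config-driven orchestration of the full analysis, plus a synthetic demo.

Stages (per view): canonicalise/resample outlines -> landmark GPA -> harmonic
calibration -> elliptical Fourier coefficients -> left-right asymmetry removal
(front view) -> per-taxon means -> PCA morphospace -> clade hulls +
majority-rule clustering -> OU shift detection on the supplied tree.
Independently: trio D-statistics -> BH correction -> heatmap matrices.

All floating-point CSV output is rounded to 12 significant digits so that
re-running with the same config and seed reproduces byte-identical files; the
manifest records input/output hashes, and per-stage wall times go to the run
log (kept out of the manifest precisely so the manifest is reproducible).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dstat import DStatistics, GenotypeTable
from .efa import (
    calibrate_harmonic_count,
    efa_forward,
    gpa_align,
    mean_shape_per_taxon,
    remove_asymmetric_component,
)
from .exceptions import InputError, ValidationError
from .morphospace import clade_hull_occupancy, fit_pca, select_k_majority
from .ou import detect_shifts
from .outlines import SpecimenTable, canonicalize_orientation, read_outline_table, resample_uniform
from .phylo import Phylogeny

FLOAT_FMT = "%.12g"


def _stage_seed(seed: int, k: int) -> int:
    """Documented fan-out: stage k gets (seed * 100003 + k) mod (2^31 - 1)."""
    return (seed * 100003 + k) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; file paths are resolved at validation."""

    specimens: str = ""
    outlines: str = ""
    landmarks: str | None = None
    tree: str | None = None
    genotypes: str | None = None
    outgroup: str = "OUT"
    views: tuple = ("front", "side")
    n_points: int = 300
    harmonic_threshold: float = 0.99
    n_max_harmonics: int = 64
    remove_asymmetry: dict = field(default_factory=lambda: {"front": True, "side": False})
    pc_count: int = 3
    k_min: int = 2
    k_max: int = 20
    s_max: int = 10
    d_modes: tuple = ("BBAA",)
    jackknife_blocks: int = 20
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(path.read_text())
        elif path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            raise InputError(f"config must be .yaml/.yml/.toml, got {path.suffix!r}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError([f"unknown config keys: {sorted(unknown)}"])
        cfg = cls(**data)
        cfg.views = tuple(cfg.views)
        cfg.d_modes = tuple(cfg.d_modes)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["views"] = list(self.views)
        d["d_modes"] = list(self.d_modes)
        return d


def validate_config(config: PipelineConfig) -> PipelineConfig:
    """Check every constraint, reporting all violations at once."""
    problems = []
    for name in ("specimens", "outlines"):
        p = getattr(config, name)
        if not p:
            problems.append(f"{name} path is required")
        elif not Path(p).exists():
            problems.append(f"{name} file not found: {p}")
    for name in ("landmarks", "tree", "genotypes"):
        p = getattr(config, name)
        if p and not Path(p).exists():
            problems.append(f"{name} file not found: {p}")
    for v in config.views:
        if v not in ("front", "side"):
            problems.append(f"unknown view {v!r}")
    if not 0 < config.harmonic_threshold < 1:
        problems.append("harmonic_threshold must lie in (0, 1)")
    if config.n_max_harmonics < 1:
        problems.append("n_max_harmonics must be >= 1")
    if config.pc_count < 1:
        problems.append("pc_count must be >= 1")
    if config.k_min < 2:
        problems.append("k_min must be >= 2")
    if config.k_max < config.k_min:
        problems.append("k_max must be >= k_min")
    if config.s_max < 1:
        problems.append("s_max must be >= 1")
    for m in config.d_modes:
        if m not in ("BBAA", "min", "tree"):
            problems.append(f"unknown D mode {m!r}")
    if config.jackknife_blocks < 2:
        problems.append("jackknife_blocks must be >= 2")
    if config.n_points < 64:
        problems.append("n_points must be >= 64")
    if problems:
        raise ValidationError(problems)
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FMT)


def _coeff_frame(coeffs_list) -> pd.DataFrame:
    rows = []
    for c in coeffs_list:
        rows.append({"id": c.specimen_id, "taxon_id": c.taxon_id, "view": c.view,
                     "n": 0, "a": c.offset[0], "b": 0.0, "c": c.offset[1],
                     "d": 0.0, "T": c.T})
        for n, (a, b, cc, d) in enumerate(c.harmonics, start=1):
            rows.append({"id": c.specimen_id, "taxon_id": c.taxon_id, "view": c.view,
                         "n": n, "a": a, "b": b, "c": cc, "d": d, "T": c.T})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns the manifest dictionary."""
    config = validate_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = []
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {},
        "outputs": {},
        "summary": {},
    }
    for name in ("specimens", "outlines", "landmarks", "tree", "genotypes"):
        p = getattr(config, name)
        if p:
            manifest["inputs"][name] = _sha256(Path(p))

    def stage(label):
        log_lines.append((label, time.perf_counter()))

    def emit(df, relname, index=False):
        path = outdir / relname
        _write_csv(df, path, index=index)
        manifest["outputs"][relname] = _sha256(path)

    stage("load")
    specimens = SpecimenTable.from_csv(config.specimens)
    outlines = read_outline_table(config.outlines, landmark_path=config.landmarks)
    clade_of = dict(
        zip(specimens.frame["taxon_id"], specimens.frame["clade"])
    )
    tree = Phylogeny.from_newick(Path(config.tree).read_text()) if config.tree else None

    scores_by_view = {}
    for view in config.views:
        stage(f"morphometrics[{view}]")
        subset = [o for o in outlines if o.view == view]
        if not subset:
            continue
        for o in subset:
            o.taxon_id = specimens.taxon_of(o.specimen_id)
            o.clade = clade_of.get(o.taxon_id)
        prepared = [
            resample_uniform(canonicalize_orientation(o), config.n_points) for o in subset
        ]
        aligned, _ = gpa_align(prepared)
        cal = calibrate_harmonic_count(
            aligned, threshold=config.harmonic_threshold, N_max=config.n_max_harmonics
        )
        coeffs = [efa_forward(o, cal.n_harmonics) for o in aligned]
        if config.remove_asymmetry.get(view, view == "front"):
            coeffs = [remove_asymmetric_component(c) for c in coeffs]
        means = mean_shape_per_taxon(coeffs, specimens)
        emit(_coeff_frame(coeffs), f"{view}_coefficients.csv")
        emit(_coeff_frame(means), f"{view}_taxon_mean_coefficients.csv")
        emit(
            pd.DataFrame(
                {"n": np.arange(1, len(cal.mean_cumulative) + 1),
                 "mean_cumulative_power": cal.mean_cumulative}
            ),
            f"{view}_harmonic_power.csv",
        )
        manifest["summary"][f"{view}_n_harmonics"] = cal.n_harmonics

        stage(f"morphospace[{view}]")
        model = fit_pca(means)
        emit(model.scores.reset_index(), f"{view}_scores.csv")
        emit(
            pd.DataFrame(
                {"component": model.scores.columns,
                 "eigenvalue": model.eigenvalues,
                 "variance_fraction": model.variance_fractions}
            ),
            f"{view}_variance.csv",
        )
        hulls = clade_hull_occupancy(model.scores, {t: clade_of.get(t) for t in model.scores.index})
        hull_rows = []
        for clade, info in hulls.items():
            if info["degenerate"]:
                hull_rows.append({"clade": clade, "vertex": -1, "x": np.nan,
                                  "y": np.nan, "area": 0.0, "degenerate": True})
            for i, (x, y) in enumerate(info["polygon"]):
                hull_rows.append({"clade": clade, "vertex": i, "x": x, "y": y,
                                  "area": info["area"], "degenerate": False})
        emit(pd.DataFrame(hull_rows), f"{view}_clade_hulls.csv")

        pc = model.scores.iloc[:, : config.pc_count]
        scores_by_view[view] = pc
        n_taxa = len(pc)
        k_max = min(config.k_max, n_taxa - 1)
        report = select_k_majority(
            pc.to_numpy(), K_min=config.k_min, K_max=k_max,
            seed=_stage_seed(config.seed, 10 + ("front", "side").index(view)),
            taxa=list(pc.index),
        )
        emit(report.vote_table(), f"{view}_cluster_votes.csv")
        emit(
            pd.DataFrame({"taxon_id": pc.index, "cluster": report.labels}),
            f"{view}_cluster_labels.csv",
        )
        manifest["summary"][f"{view}_chosen_k"] = int(report.chosen_k)

        if tree is not None:
            stage(f"ou_shifts[{view}]")
            res = detect_shifts(tree, pc, s_max=config.s_max,
                                seed=_stage_seed(config.seed, 20))
            emit(res.candidates, f"{view}_shift_candidates.csv")
            best_path = outdir / f"{view}_best_shift_model.json"
            best_path.write_text(json.dumps(res.to_dict(), indent=2, sort_keys=True))
            manifest["outputs"][best_path.name] = _sha256(best_path)
            manifest["summary"][f"{view}_n_shifts"] = res.best.n_shifts

    if config.genotypes:
        stage("dstat")
        table = GenotypeTable.from_long_csv(
            config.genotypes, outgroup=config.outgroup, n_blocks=config.jackknife_blocks
        )
        species_tree = tree
        for mode in config.d_modes:
            fitted = DStatistics(table).fit(mode=mode, species_tree=species_tree)
            emit(fitted.table, f"dstat_{mode}_results.csv")
            if len(fitted.results) > 1:
                Dm, Pm = fitted.heatmap()
                emit(Dm, f"dstat_{mode}_heatmap_D.csv", index=True)
                emit(Pm, f"dstat_{mode}_heatmap_padj.csv", index=True)
            manifest["summary"][f"dstat_{mode}_significant"] = int(
                (fitted.table["p_adj"] < 0.05).sum()
            )

    stage("finish")
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    with open(outdir / "run.log", "w") as fh:
        for (label, t0), (_, t1) in zip(log_lines, log_lines[1:]):
            fh.write(f"{label}: {t1 - t0:.3f} s\n")
    return manifest


# ------------------------------------------------------------------- demo


def write_demo_inputs(indir, seed: int = 0, n_taxa: int = 24,
                      specimens_per_taxon: int = 2, n_sites: int = 20000) -> PipelineConfig:
    """Generate a complete synthetic input bundle and its pipeline config.

    Three phenotype groups of taxa are laid out on a simulated tree: nearly
    radial corollas, dorsoventrally graded bilateral corollas and
    lateral-doubled corollas with curved tubes — enough structure for the
    clustering, hull and shift stages to have something to find.
    """
    from .outlines import write_outline_table
    from .simulate import FlowerParams, TrioSimSpec, gen_front_outline, gen_side_outline, gen_tree, sim_genotypes

    indir = Path(indir)
    indir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(_stage_seed(seed, 1))
    tree = gen_tree(n_taxa, seed=_stage_seed(seed, 2))
    (indir / "tree.nwk").write_text(tree.to_newick() + "\n")

    # phenotype groups follow real clades: two disjoint subtrees shift away
    # from the background phenotype, so the OU stage has true regimes to find
    picked = []
    for e in sorted((e for e in tree.edges if e >= tree.n_tips),
                    key=lambda e: -len(tree.tip_sets[e])):
        size = len(tree.tip_sets[e])
        if n_taxa // 6 <= size <= n_taxa // 3 and all(
            tree.tip_sets[e].isdisjoint(tree.tip_sets[p]) for p in picked
        ):
            picked.append(e)
        if len(picked) == 2:
            break
    groups = {t: 0 for t in tree.tip_labels}
    for gi, e in enumerate(picked, start=1):
        for i in tree.tip_sets[e]:
            groups[tree.tip_labels[i]] = gi
    group_front = [
        dict(lobe_depth=0.12, dorsoventral_gradient=0.0, lateral_doubling=False),
        dict(lobe_depth=0.32, dorsoventral_gradient=0.45, lateral_doubling=False),
        dict(lobe_depth=0.30, dorsoventral_gradient=0.2, lateral_doubling=True),
    ]
    group_side = [
        dict(tube_length=1.0, tube_curvature=0.0, upper_lobe_excess=1.0),
        dict(tube_length=2.2, tube_curvature=0.25, upper_lobe_excess=1.25),
        dict(tube_length=3.2, tube_curvature=-0.35, upper_lobe_excess=1.5),
    ]
    outlines, spec_rows = [], []
    for taxon in tree.tip_labels:
        g = groups[taxon]
        clade = f"clade{g + 1}"
        for s in range(specimens_per_taxon):
            sid = f"{taxon}_s{s + 1}"
            fseed = int(rng.integers(2**31 - 1))
            fp = FlowerParams(view="front", petal_count=5, asymmetry_sd=0.02,
                              seed=fseed, **group_front[g])
            # small per-specimen jitter keeps taxa distinguishable but variable
            fp.lobe_depth = float(np.clip(fp.lobe_depth + rng.normal(0, 0.02), 0.02, 0.9))
            outlines.append(gen_front_outline(fp, specimen_id=sid, taxon_id=taxon))
            outlines[-1].clade = clade
            sp = FlowerParams(view="side", asymmetry_sd=0.02, seed=fseed + 1,
                              **group_side[g])
            sp.tube_length = float(max(0.2, sp.tube_length + rng.normal(0, 0.1)))
            outlines.append(gen_side_outline(sp, specimen_id=sid, taxon_id=taxon))
            outlines[-1].clade = clade
            spec_rows.append({"specimen_id": sid, "taxon_id": taxon, "clade": clade,
                              "view": "both"})
    # specimen table needs one row per (specimen, view)
    spec_frame = pd.DataFrame(
        [
            {"specimen_id": r["specimen_id"], "taxon_id": r["taxon_id"],
             "clade": r["clade"], "view": v}
            for r in spec_rows
            for v in ("front", "side")
        ]
    )
    spec_frame.to_csv(indir / "specimens.csv", index=False)
    write_outline_table(outlines, indir / "outlines.csv", landmark_path=indir / "landmarks.csv")

    geno = sim_genotypes(
        TrioSimSpec(n_sites=n_sites, n_individuals=2, baseline_discordance=0.1,
                    admixture_excess=0.12, concordant_prob=0.2,
                    block_size=max(1, n_sites // 20), seed=_stage_seed(seed, 3))
    )
    geno.to_long_csv(indir / "genotypes.csv")

    config = PipelineConfig(
        specimens=str(indir / "specimens.csv"),
        outlines=str(indir / "outlines.csv"),
        landmarks=str(indir / "landmarks.csv"),
        tree=str(indir / "tree.nwk"),
        genotypes=str(indir / "genotypes.csv"),
        n_max_harmonics=32,
        k_max=8,  # proportionate to the demo's 24 taxa
        s_max=6,
        d_modes=("BBAA", "min"),
        seed=seed,
        outdir=str(indir.parent / "results"),
    )
    with open(indir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return config


def run_demo(workdir, seed: int = 0, **kw) -> dict:
    """Generate the synthetic bundle under ``workdir/inputs`` and run it."""
    workdir = Path(workdir)
    config = write_demo_inputs(workdir / "inputs", seed=seed, **kw)
    config.outdir = str(workdir / "results")
    return run_pipeline(config)
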