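"""Trio D-statistics (ABBA-BABA) with block-jackknife significance.

Per site with derived-allele frequencies (p1, p2, p3, pO) for the trio plus
outgroup, the pattern weights are ABBA = (1-p1) p2 p3 (1-pO),
BABA = p1 (1-p2) p3 (1-pO), BBAA = p1 p2 (1-p3) (1-pO);
D = (ABBA - BABA) / (ABBA + BABA).  Under incomplete lineage sorting alone
E[D] = 0; an excess of ABBA indicates gene flow between P2 and P3.

Three trio-arrangement modes are supported: ``BBAA`` (the pair sharing derived
alleles most often plays P1/P2, reported with D >= 0), ``min`` (the smallest
|D| over the three pairings — a lower bound robust to misrooting the trio) and
``tree`` (arrangement fixed by a given species tree).  Significance is by
delete-one contiguous-block jackknife; p-values are Benjamini-Hochberg
adjusted across all tested trios of a run.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    InputError,
    InsufficientBlocksError,
    MappingError,
)

__all__ = [
    "GenotypeTable",
    "TrioDResult",
    "site_pattern_sums",
    "d_statistic",
    "arrange_trio",
    "jackknife_significance",
    "bh_adjust",
    "heatmap_matrix",
    "DStatistics",
    "DStatResults",
]


class GenotypeTable:
    """Biallelic sites as per-population derived-allele frequencies.

    Holds a (sites x populations) frequency frame, contiguous jackknife block
    ids and the designated outgroup.  Individual-level 0/1/2 dosages (plus an
    individual->population map) may be attached; frequencies are derived from
    them ignoring missing calls (coded -1 or NaN).
    """

    def __init__(self, freqs: pd.DataFrame, blocks, outgroup: str,
                 dosages: pd.DataFrame | None = None, popmap: dict | None = None):
        self.freqs = freqs.reset_index(drop=True)
        self.blocks = np.asarray(blocks, dtype=int)
        self.outgroup = str(outgroup)
        self.dosages = dosages
        self.popmap = dict(popmap) if popmap else None
        if self.outgroup not in self.freqs.columns:
            raise MappingError(f"outgroup {self.outgroup!r} not among populations")
        if len(self.blocks) != len(self.freqs):
            raise InputError("block ids and sites disagree in length")
        vals = self.freqs.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12):
            raise InputError("frequencies must lie in [0, 1]")
        if len(self.blocks) and np.any(np.diff(self.blocks) < 0):
            raise InputError("block ids must be contiguous (non-decreasing)")

    # -------------------------------------------------------- constructors

    @classmethod
    def from_frequencies(cls, freqs, blocks=None, outgroup="OUT", n_blocks=20,
                         dosages=None, popmap=None) -> "GenotypeTable":
        freqs = pd.DataFrame(freqs)
        if blocks is None:
            blocks = equal_blocks(len(freqs), n_blocks)
        return cls(freqs, blocks, outgroup, dosages=dosages, popmap=popmap)

    @classmethod
    def from_dosages(cls, dosages: pd.DataFrame, popmap: dict, outgroup="OUT",
                     blocks=None, n_blocks=20) -> "GenotypeTable":
        """Population frequencies = mean dosage / 2, ignoring missing calls."""
        missing_pop = [i for i in dosages.columns if i not in popmap]
        if missing_pop:
            raise MappingError(f"individuals without population: {missing_pop[:5]}")
        vals = dosages.to_numpy(dtype=float)
        vals = np.where(vals < 0, np.nan, vals)
        pops = sorted(set(popmap.values()))
        freq = {}
        for p in pops:
            cols = [j for j, ind in enumerate(dosages.columns) if popmap[ind] == p]
            with np.errstate(invalid="ignore"):
                freq[p] = np.nanmean(vals[:, cols], axis=1) / 2.0
        freqs = pd.DataFrame(freq)
        if blocks is None:
            blocks = equal_blocks(len(freqs), n_blocks)
        return cls(freqs, blocks, outgroup, dosages=dosages, popmap=popmap)

    @classmethod
    def from_long_csv(cls, path, outgroup="OUT", n_blocks=20) -> "GenotypeTable":
        """Read the long CSV dialect (site, block, pop, individual, genotype)."""
        df = pd.read_csv(path)
        need = {"site", "block", "pop", "individual", "genotype"}
        if not need.issubset(df.columns):
            raise InputError(f"long genotype CSV needs columns {sorted(need)}")
        dosages = df.pivot_table(index="site", columns="individual",
                                 values="genotype", aggfunc="first")
        popmap = df.drop_duplicates("individual").set_index("individual")["pop"].to_dict()
        blocks = df.drop_duplicates("site").sort_values("site")["block"].to_numpy()
        return cls.from_dosages(dosages, popmap, outgroup=outgroup, blocks=blocks)

    def to_long_frame(self) -> pd.DataFrame:
        if self.dosages is None or self.popmap is None:
            raise InputError("table carries no individual-level dosages")
        recs = self.dosages.copy()
        recs.insert(0, "site", np.arange(len(recs)))
        recs.insert(1, "block", self.blocks)
        long = recs.melt(id_vars=["site", "block"], var_name="individual",
                         value_name="genotype")
        long["pop"] = long["individual"].map(self.popmap)
        return long[["site", "block", "pop", "individual", "genotype"]].sort_values(
            ["site", "individual"], kind="stable").reset_index(drop=True)

    def to_long_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @property
    def populations(self) -> list:
        return [c for c in self.freqs.columns if c != self.outgroup]

    @property
    def n_sites(self) -> int:
        return len(self.freqs)


def equal_blocks(n_sites: int, n_blocks: int) -> np.ndarray:
    """Contiguous, as-equal-as-possible block assignment of n_sites sites."""
    if n_sites == 0:
        return np.zeros(0, dtype=int)
    return np.minimum(np.arange(n_sites) * n_blocks // max(n_sites, 1), n_blocks - 1)


# ------------------------------------------------------------ pattern sums


@dataclass
class PatternSums:
    """Per-block and total ABBA/BABA/BBAA pattern sums for one labelled trio."""

    trio: tuple  # (P1, P2, P3) labels
    blocks: pd.DataFrame  # columns abba, baba, bbaa indexed by block id
    n_sites: int = 0

    @property
    def abba(self) -> float:
        return float(self.blocks["abba"].sum())

    @property
    def baba(self) -> float:
        return float(self.blocks["baba"].sum())

    @property
    def bbaa(self) -> float:
        return float(self.blocks["bbaa"].sum())

    def totals(self) -> tuple:
        return (self.abba, self.baba, self.bbaa)


def site_pattern_sums(table: GenotypeTable, trio) -> PatternSums:
    """Accumulate frequency-weighted ABBA/BABA/BBAA sums per block for a trio."""
    P1, P2, P3 = trio
    if len({P1, P2, P3}) != 3:
        raise InputError("trio populations must be distinct")
    for p in (P1, P2, P3):
        if p not in table.freqs.columns:
            raise MappingError(f"population {p!r} not in genotype table")
        if p == table.outgroup:
            raise InputError("outgroup cannot appear inside the trio")
    f = table.freqs
    p1 = f[P1].to_numpy(dtype=float)
    p2 = f[P2].to_numpy(dtype=float)
    p3 = f[P3].to_numpy(dtype=float)
    pO = f[table.outgroup].to_numpy(dtype=float)
    valid = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(pO))
    p1, p2, p3, pO = p1[valid], p2[valid], p3[valid], pO[valid]
    blocks = table.blocks[valid]
    w = 1.0 - pO
    abba = (1 - p1) * p2 * p3 * w
    baba = p1 * (1 - p2) * p3 * w
    bbaa = p1 * p2 * (1 - p3) * w
    if len(blocks):
        idx = np.unique(blocks)
        frame = pd.DataFrame(
            {
                "abba": np.bincount(blocks, weights=abba)[idx],
                "baba": np.bincount(blocks, weights=baba)[idx],
                "bbaa": np.bincount(blocks, weights=bbaa)[idx],
            },
            index=pd.Index(idx, name="block"),
        )
    else:
        frame = pd.DataFrame(columns=["abba", "baba", "bbaa"])
    return PatternSums(trio=(P1, P2, P3), blocks=frame, n_sites=int(valid.sum()))


def d_statistic(abba, baba=None) -> float:
    """D = (ABBA - BABA) / (ABBA + BABA); NaN when the denominator is zero."""
    if baba is None:  # accept a PatternSums or (abba, baba[, bbaa]) tuple
        if isinstance(abba, PatternSums):
            abba, baba = abba.abba, abba.baba
        else:
            abba, baba = abba[0], abba[1]
    denom = abba + baba
    if denom <= 0:
        return float("nan")
    return float((abba - baba) / denom)


# ------------------------------------------------------------- arrangement


def _arrangements(sums: PatternSums):
    """The three sister-pair arrangements of a trio, from one labelled sum set.

    Permuting trio roles permutes the pattern sums: with base labels
    (A, B, C) and sums (ABBA, BABA, BBAA),
    sisters (A,B): roles (ABBA, BABA, BBAA);
    sisters (A,C): roles (ABBA, BBAA, BABA);
    sisters (B,C): roles (BABA, BBAA, ABBA).
    Returns per-arrangement dicts with the role-permuted per-block frames.
    """
    A, B, C = sums.trio
    blk = sums.blocks
    def perm(abba, baba, bbaa, trio):
        frame = pd.DataFrame(
            {"abba": blk[abba], "baba": blk[baba], "bbaa": blk[bbaa]}, index=blk.index
        )
        return {"trio": trio, "blocks": frame}

    return [
        perm("abba", "baba", "bbaa", (A, B, C)),
        perm("abba", "bbaa", "baba", (A, C, B)),
        perm("baba", "bbaa", "abba", (B, C, A)),
    ]


def _oriented(arr):
    """Swap P1 and P2 (negating D) so that D >= 0."""
    blk = arr["blocks"]
    d = d_statistic((blk["abba"].sum(), blk["baba"].sum()))
    if not np.isnan(d) and d < 0:
        trio = arr["trio"]
        blk = pd.DataFrame(
            {"abba": blk["baba"], "baba": blk["abba"], "bbaa": blk["bbaa"]},
            index=blk.index,
        )
        return {"trio": (trio[1], trio[0], trio[2]), "blocks": blk}
    return arr


def arrange_trio(sums: PatternSums, mode: str, species_tree=None):
    """Pick the trio arrangement for one of the three calculation modes.

    ``BBAA``: the pair sharing derived alleles most often plays P1/P2 (largest
    BBAA-role sum), P2 oriented so D >= 0; three-way ties are flagged and
    broken lexicographically.  ``min``: the arrangement with the smallest |D|.
    ``tree``: the sister pair is read off the species tree (lexicographic
    P1/P2 order, sign kept).  Returns ``(arrangement dict, tie_flag)``.
    """
    if mode not in ("BBAA", "min", "tree"):
        raise InputError(f"mode must be BBAA, min or tree, got {mode!r}")
    arrs = _arrangements(sums)
    if mode == "tree":
        if species_tree is None:
            raise InputError("tree mode requires a species tree")
        labels = set(species_tree.tip_labels)
        for p in sums.trio:
            if p not in labels:
                raise MappingError(f"trio population {p!r} missing from species tree")
        idx = {p: species_tree.tip_labels.index(p) for p in sums.trio}
        M = species_tree.mrca_depths
        # sisters = pair with the deepest (most recent) MRCA
        pairs = list(itertools.combinations(sums.trio, 2))
        sisters = max(pairs, key=lambda pr: M[idx[pr[0]], idx[pr[1]]])
        for arr in arrs:
            if set(arr["trio"][:2]) == set(sisters):
                t = arr["trio"]
                if t[0] > t[1]:  # deterministic P1/P2 order, D sign kept
                    blk = arr["blocks"]
                    arr = {
                        "trio": (t[1], t[0], t[2]),
                        "blocks": pd.DataFrame(
                            {"abba": blk["baba"], "baba": blk["abba"], "bbaa": blk["bbaa"]},
                            index=blk.index,
                        ),
                    }
                return arr, False
        raise MappingError("species tree arrangement not found")  # pragma: no cover
    if mode == "BBAA":
        bbaa_sums = [arr["blocks"]["bbaa"].sum() for arr in arrs]
        top = max(bbaa_sums)
        winners = [i for i, v in enumerate(bbaa_sums) if v == top]
        tie = len(winners) == 3
        pick = min(winners, key=lambda i: arrs[i]["trio"]) if tie else winners[0]
        return _oriented(arrs[pick]), tie
    # min mode: smallest |D| over the three arrangements
    ds = []
    for arr in arrs:
        blk = arr["blocks"]
        ds.append(abs(d_statistic((blk["abba"].sum(), blk["baba"].sum()))))
    pick = int(np.nanargmin(ds))
    return _oriented(arrs[pick]), False


# --------------------------------------------------------------- jackknife


def jackknife_significance(block_sums: pd.DataFrame):
    """Delete-one-block jackknife SE, Z and two-sided normal p for D.

    ``block_sums`` needs columns abba and baba.  Returns
    ``(D, SE, Z, p, degenerate_flag)``; zero jackknife variance with D = 0
    gives Z = 0, with D != 0 gives p = 0 and the degeneracy flag.
    """
    abba = block_sums["abba"].to_numpy(dtype=float)
    baba = block_sums["baba"].to_numpy(dtype=float)
    A, Bb = abba.sum(), baba.sum()
    usable = np.flatnonzero((A - abba) + (Bb - baba) > 0)
    if len(usable) < 2:
        raise InsufficientBlocksError(
            f"need >= 2 usable jackknife blocks, have {len(usable)}"
        )
    D = d_statistic((A, Bb))
    a_u, b_u = abba[usable], baba[usable]
    d_loo = ((A - a_u) - (Bb - b_u)) / ((A - a_u) + (Bb - b_u))
    Bn = len(usable)
    se = float(np.sqrt((Bn - 1) / Bn * np.sum((d_loo - d_loo.mean()) ** 2)))
    if se == 0:
        if D == 0 or np.isnan(D):
            return D, 0.0, 0.0, 1.0, False
        return D, 0.0, float("inf"), 0.0, True
    z = D / se
    p = float(2.0 * (1.0 - norm.cdf(abs(z))))
    return D, se, float(z), p, False


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------------ results


@dataclass
class TrioDResult:
    """One trio's arranged D-statistic with jackknife significance."""

    P1: str
    P2: str
    P3: str
    mode: str
    abba: float
    baba: float
    bbaa: float
    D: float
    se: float
    Z: float
    p: float
    p_adj: float = float("nan")
    blocks: int = 0
    tie: bool = False
    degenerate: bool = False


def heatmap_matrix(results):
    """P2 x P3 matrices of D (most significant over P1) and adjusted p.

    Cell (P2, P3) takes the trio with maximal |Z| among all P1 choices placing
    that ordered pair; cells with no qualifying trio are NaN ("lack of
    information").  Returns ``(D_matrix, p_adj_matrix)`` DataFrames with
    sorted labels.
    """
    results = list(results)
    if not results:
        raise InputError("no trio results")
    modes = {r.mode for r in results}
    if len(modes) != 1:
        raise InputError(f"mixed arrangement modes: {sorted(modes)}")
    best: dict[tuple, TrioDResult] = {}
    for r in results:
        key = (r.P2, r.P3)
        cur = best.get(key)
        if cur is None or (abs(r.Z) > abs(cur.Z)):
            best[key] = r
    rows = sorted({k[0] for k in best})
    cols = sorted({k[1] for k in best})
    Dm = pd.DataFrame(np.nan, index=rows, columns=cols)
    Pm = pd.DataFrame(np.nan, index=rows, columns=cols)
    for (p2, p3), r in best.items():
        Dm.loc[p2, p3] = r.D
        Pm.loc[p2, p3] = r.p_adj
    Dm.index.name = Pm.index.name = "P2"
    Dm.columns.name = Pm.columns.name = "P3"
    return Dm, Pm


@dataclass
class DStatResults:
    """All trio results of one run, as a tidy table plus heatmap accessors."""

    table: pd.DataFrame
    mode: str
    results: list = field(default_factory=list)

    def heatmap(self):
        return heatmap_matrix(self.results)

    def summary(self) -> str:
        sig = int((self.table["p_adj"] < 0.05).sum()) if len(self.table) else 0
        lines = [
            f"D-statistics ({self.mode} arrangement): {len(self.table)} trios",
            f"significant after BH (p_adj < 0.05): {sig}",
        ]
        if len(self.table):
            top = self.table.sort_values("p_adj").head(5)
            lines.append(top.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def plot_heatmap(self, path=None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        Dm, Pm = self.heatmap()
        fig, ax = plt.subplots(figsize=(1 + 0.4 * Dm.shape[1], 1 + 0.4 * Dm.shape[0]))
        im = ax.imshow(Dm.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_xticks(range(Dm.shape[1]), Dm.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(Dm.shape[0]), Dm.index, fontsize=6)
        ax.set_xlabel("P3")
        ax.set_ylabel("P2")
        fig.colorbar(im, ax=ax, label="D")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=150)
            plt.close(fig)
            return None
        return fig


class DStatistics:
    """ABBA-BABA analysis bound to a genotype table (model/fit interface)."""

    def __init__(self, table: GenotypeTable):
        self.table = table

    def fit(self, mode: str = "BBAA", trios=None, species_tree=None) -> DStatResults:
        """Compute arranged D, jackknife Z and BH-adjusted p for each trio.

        ``trios`` defaults to every unordered triple of non-outgroup
        populations; BH correction is applied jointly across the tested trios.
        """
        pops = self.table.populations
        if trios is None:
            trios = list(itertools.combinations(sorted(pops), 3))
        results: list[TrioDResult] = []
        for trio in trios:
            sums = site_pattern_sums(self.table, trio)
            arr, tie = arrange_trio(sums, mode, species_tree=species_tree)
            blk = arr["blocks"]
            D, se, z, p, degen = jackknife_significance(blk)
            results.append(
                TrioDResult(
                    P1=arr["trio"][0], P2=arr["trio"][1], P3=arr["trio"][2],
                    mode=mode,
                    abba=float(blk["abba"].sum()),
                    baba=float(blk["baba"].sum()),
                    bbaa=float(blk["bbaa"].sum()),
                    D=D, se=se, Z=z, p=p, blocks=len(blk),
                    tie=tie, degenerate=degen,
                )
            )
        p_adj = bh_adjust([r.p for r in results])
        for r, pa in zip(results, p_adj):
            r.p_adj = float(pa)
        table = pd.DataFrame(
            [
                {
                    "P1": r.P1, "P2": r.P2, "P3": r.P3, "mode": r.mode,
                    "ABBA": r.abba, "BABA": r.baba, "BBAA": r.bbaa,
                    "D": r.D, "SE": r.se, "Z": r.Z, "p": r.p, "p_adj": r.p_adj,
                    "blocks": r.blocks,
                }
                for r in results
            ]
        )
        return DStatResults(table=table, mode=mode, results=results)
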