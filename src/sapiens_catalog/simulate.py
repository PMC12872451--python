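"""Synthetic genotype panels with known truth.

The baseline generator is a site-independent drift cascade: each biallelic
site's mutation is placed on one branch of a fixed population tree (with
probability proportional to branch length x rate, an infinite-sites analogue),
given a frequency at the end of its origin branch, and propagated root-to-tip
through Balding-Nichols beta drift with per-branch parameter F — so a child
node's frequency has expectation equal to its parent's (frequency martingale).
Admixture edges mix destination and source frequencies linearly at the recent
end of the destination branch. Terminal genotypes are binomial draws from the
terminal frequencies via per-allele uniform thresholds, which makes paired-seed
runs monotone in the admixture fraction. Great apes are fixed for the
ancestral allele; archaic genomes carry the derived allele only where the
mutation branch is ancestral to them, and drift inside the archaic clade is
modelled like any other population so that archaic-polymorphism ascertainment
selects a non-empty site set.

This emulates deep population stratification with long-term isolation of
southernmost Africa, an out-of-Africa bottleneck, and optional late admixture
into the south; no recombination/linkage, selection, or archaic introgression
into non-Africans is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ALLELE_ABSENT,
    ALLELE_MISSING,
    BASES,
    ChromTable,
    GenotypePanel,
    IndividualMeta,
    PanelError,
)

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION_PARTNERS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass
class BranchSpec:
    """One branch; its name doubles as the name of its lower (child) node."""

    parent: str | None  # parent branch name; None attaches to the root node
    length: float  # generations (mutation-placement weight)
    F: float  # Balding-Nichols drift accumulated along the branch
    rate: float = 1.0  # relative mutation-placement rate

    def __post_init__(self) -> None:
        if not (0.0 <= self.F < 1.0):
            raise PanelError(f"drift parameter F must be in [0, 1), got {self.F}")
        if self.length < 0 or self.rate < 0:
            raise PanelError("branch length and rate must be >= 0")


@dataclass
class AdmixtureEdge:
    """Mix fraction alpha of the source node into the destination node."""

    source: str
    dest: str
    alpha: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise PanelError(f"admixture fraction must be in [0, 1], got {self.alpha}")


@dataclass
class SampleSpec:
    group: str
    node: str
    n: int
    role: str = "human"
    ploidy_mode: str = "diploid"
    udg_status: str = "not_applicable"


@dataclass
class DemographyConfig:
    """Population tree, drift, admixture, sampling and site layout."""

    branches: dict[str, BranchSpec]
    samples: list[SampleSpec]
    admixture: list[AdmixtureEdge] = field(default_factory=list)
    n_sites: int = 10_000
    chromosomes: Mapping[str, int] = field(
        default_factory=lambda: {"1": 50_000_000, "2": 50_000_000}
    )
    ts_tv_ratio: float = 2.0
    effect_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "missense_like": 0.35,
            "synonymous_like": 0.25,
            "other": 0.35,
            "unannotated": 0.05,
        }
    )
    root_freq: tuple = ("loguniform", 0.02, 0.98)
    ref_is_ancestral_prob: float = 0.5
    ape_missing_rate: float = 0.0
    archaic_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise PanelError("n_sites must be positive")
        self.topo_order()  # validates acyclicity / connectivity
        for edge in self.admixture:
            if edge.dest not in self.branches:
                raise PanelError(f"admixture edge destination {edge.dest!r} not a branch")
            if edge.source != "root" and edge.source not in self.branches:
                raise PanelError(f"admixture edge source {edge.source!r} not a branch")
        for s in self.samples:
            if s.node not in self.branches:
                raise PanelError(f"sample node {s.node!r} not a branch")

    def topo_order(self) -> list[str]:
        placed: list[str] = []
        ready = {"root"}
        remaining = dict(self.branches)
        while remaining:
            batch = sorted(
                name
                for name, spec in remaining.items()
                if (spec.parent or "root") in ready
            )
            if not batch:
                raise PanelError(
                    f"branch graph is not a rooted tree (unreachable: {sorted(remaining)})"
                )
            for name in batch:
                placed.append(name)
                ready.add(name)
                del remaining[name]
        return placed

    def ancestors(self, name: str) -> list[str]:
        out = []
        cur = self.branches[name].parent
        while cur is not None:
            out.append(cur)
            cur = self.branches[cur].parent
        return out

    def chrom_table(self) -> ChromTable:
        return ChromTable(dict(self.chromosomes))


@dataclass
class TruthRecord:
    """Per-site truth (origin branch, origin frequency, terminal frequencies)."""

    sites: pd.DataFrame
    node_freq: dict[str, np.ndarray]
    config: DemographyConfig

    def split_generations(self, node_a: str, node_b: str) -> float:
        """True split time (generations before present) between two nodes."""
        cfg = self.config
        depth = {"root": 0.0}
        for name in cfg.topo_order():
            spec = cfg.branches[name]
            depth[name] = depth[spec.parent or "root"] + spec.length
        tree_depth = max(depth.values())
        path_a = [node_a, *cfg.ancestors(node_a), "root"]
        path_b = set([node_b, *cfg.ancestors(node_b), "root"])
        mrca = max((n for n in path_a if n in path_b), key=lambda n: depth[n])
        return tree_depth - depth[mrca]


def _draw_root_freq(spec: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    u = rng.random(n)
    if kind == "loguniform":
        a, b = spec[1], spec[2]
        return a * (b / a) ** u
    if kind == "uniform":
        a, b = spec[1], spec[2]
        return a + (b - a) * u
    if kind == "fixed":
        return np.full(n, float(spec[1]))
    raise PanelError(f"unknown root_freq distribution {kind!r}")


def _bn_drift(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols step: Beta(p(1-F)/F, (1-p)(1-F)/F); E = p."""
    out = p.copy()
    seg = (p > 0) & (p < 1)
    if F > 0 and seg.any():
        k = (1.0 - F) / F
        out[seg] = rng.beta(p[seg] * k, (1.0 - p[seg]) * k)
    return out


def _cascade_order(cfg: DemographyConfig) -> list[str]:
    """Topological branch order with admixture sources preceding destinations."""
    deps: dict[str, set[str]] = {}
    for name, spec in cfg.branches.items():
        deps[name] = set() if spec.parent is None else {spec.parent}
    for e in cfg.admixture:
        if e.source != "root":
            deps[e.dest].add(e.source)
    placed: list[str] = []
    done: set[str] = set()
    remaining = set(deps)
    while remaining:
        batch = sorted(b for b in remaining if deps[b] <= done)
        if not batch:
            raise PanelError(
                "admixture edges create a dependency cycle "
                f"(unresolvable: {sorted(remaining)})"
            )
        placed.extend(batch)
        done.update(batch)
        remaining -= set(batch)
    return placed


def _site_layout(cfg: DemographyConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = sorted(cfg.chromosomes)
    lengths = np.array([cfg.chromosomes[c] for c in chroms], dtype=float)
    total = lengths.sum()
    coords = (np.arange(cfg.n_sites) + 0.5) * total / cfg.n_sites
    bounds = np.cumsum(lengths)
    chrom_idx = np.searchsorted(bounds, coords, side="right")
    offset = np.concatenate([[0.0], bounds[:-1]])
    pos = np.floor(coords - offset[chrom_idx]).astype(int) + 1

    anc = rng.choice(list(BASES), size=cfg.n_sites)
    is_ts = rng.random(cfg.n_sites) < cfg.ts_tv_ratio / (cfg.ts_tv_ratio + 1.0)
    tv_pick = rng.integers(2, size=cfg.n_sites)
    der = np.array(
        [
            _TRANSITION_PARTNER[a] if t else _TRANSVERSION_PARTNERS[a][k]
            for a, t, k in zip(anc, is_ts, tv_pick)
        ]
    )
    anc_is_ref = rng.random(cfg.n_sites) < cfg.ref_is_ancestral_prob
    ref = np.where(anc_is_ref, anc, der)
    alt = np.where(anc_is_ref, der, anc)

    classes = list(cfg.effect_probs)
    probs = np.array([cfg.effect_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    effect = rng.choice(classes, size=cfg.n_sites, p=probs)
    gene = np.array(
        [
            f"G{i // 3:05d}" if eff in ("missense_like", "synonymous_like") else ""
            for i, eff in enumerate(effect)
        ]
    )
    return pd.DataFrame(
        {
            "chrom": np.array(chroms)[chrom_idx],
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "ancestral": anc,
            "effect": effect,
            "gene": gene,
        }
    )


def simulate_panel(cfg: DemographyConfig) -> tuple[GenotypePanel, TruthRecord]:
    """Simulate a genotype panel plus full truth records under ``cfg``.

    Deterministic per seed: identical configs give byte-identical output.
    Dedicated RNG streams per branch and per individual keep paired-seed runs
    comparable when only an admixture fraction changes.
    """
    ss = np.random.SeedSequence(cfg.seed)
    ss_layout, ss_origin, ss_branch_pool, ss_geno_pool = ss.spawn(4)
    rng_layout = np.random.default_rng(ss_layout)
    rng_origin = np.random.default_rng(ss_origin)
    branch_names_sorted = sorted(cfg.branches)
    branch_rng = {
        name: np.random.default_rng(child)
        for name, child in zip(branch_names_sorted, ss_branch_pool.spawn(len(branch_names_sorted)))
    }

    sites = _site_layout(cfg, rng_layout)
    n = cfg.n_sites

    # mutation placement and origin frequency
    order = cfg.topo_order()
    weights = np.array([cfg.branches[b].length * cfg.branches[b].rate for b in order])
    if weights.sum() <= 0:
        raise PanelError("no branch has positive length * rate for mutation placement")
    origin_idx = rng_origin.choice(len(order), size=n, p=weights / weights.sum())
    origin = np.array(order)[origin_idx]
    p_origin = _draw_root_freq(cfg.root_freq, n, rng_origin)

    # frequency cascade root-to-tip; admixture sources must precede destinations
    ancestors = {b: set(cfg.ancestors(b)) for b in order}
    freq: dict[str, np.ndarray] = {"root": np.zeros(n)}
    edges_by_dest: dict[str, list[AdmixtureEdge]] = {}
    for e in cfg.admixture:
        edges_by_dest.setdefault(e.dest, []).append(e)
    cascade_order = _cascade_order(cfg)
    for b in cascade_order:
        spec = cfg.branches[b]
        parent = spec.parent or "root"
        inherited = np.isin(origin, list(ancestors[b])) if ancestors[b] else np.zeros(n, bool)
        f = np.zeros(n)
        f[inherited] = _bn_drift(freq[parent][inherited], spec.F, branch_rng[b])
        own = origin == b
        f[own] = p_origin[own]
        for e in edges_by_dest.get(b, ()):
            if e.source not in freq:
                raise PanelError(
                    f"admixture source {e.source!r} not computed before destination {b!r}"
                )
            f = (1.0 - e.alpha) * f + e.alpha * freq[e.source]
        freq[b] = f

    # genotypes
    n_ind = sum(s.n for s in cfg.samples)
    geno_streams = iter(ss_geno_pool.spawn(n_ind))
    anc_code = np.where(sites["ref"].to_numpy() == sites["ancestral"].to_numpy(), 0, 1)
    der_code = 1 - anc_code
    calls = np.full((n, n_ind, 2), ALLELE_MISSING, dtype=np.int8)
    individuals: list[IndividualMeta] = []
    group_counter: dict[str, int] = {}
    j = 0
    for s in cfg.samples:
        for k in range(s.n):
            rng_ind = np.random.default_rng(next(geno_streams))
            group_counter[s.group] = group_counter.get(s.group, 0) + 1
            ind_id = f"{s.group}_{group_counter[s.group]}"
            if s.role == "great_ape":
                calls[:, j, 0] = anc_code
                calls[:, j, 1] = anc_code
                if cfg.ape_missing_rate > 0:
                    miss = rng_ind.random(n) < cfg.ape_missing_rate
                    calls[miss, j, :] = ALLELE_MISSING
            else:
                p = freq[s.node]
                ploidy = 2 if s.ploidy_mode == "diploid" else 1
                derived = rng_ind.random((n, ploidy)) < p[:, None]
                if s.role == "archaic" and cfg.archaic_error_rate > 0:
                    flip = rng_ind.random((n, ploidy)) < cfg.archaic_error_rate
                    derived |= flip
                for slot in range(ploidy):
                    calls[:, j, slot] = np.where(derived[:, slot], der_code, anc_code)
                if ploidy == 1:
                    calls[:, j, 1] = ALLELE_ABSENT
            individuals.append(
                IndividualMeta(
                    id=ind_id,
                    group=s.group,
                    role=s.role,
                    ploidy_mode=s.ploidy_mode,
                    udg_status=s.udg_status,
                )
            )
            j += 1

    truth_sites = sites.copy()
    truth_sites["origin_branch"] = origin
    truth_sites["p_origin"] = p_origin
    truth = TruthRecord(sites=truth_sites, node_freq=freq, config=cfg)
    panel = GenotypePanel(
        sites[["chrom", "pos", "ref", "alt", "effect", "gene"]], calls, individuals
    )
    return panel, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset_two_pop(
    F: float = 0.05,
    n_per_group: int = 25,
    n_sites: int = 50_000,
    seed: int = 0,
    root_freq: tuple = ("uniform", 0.1, 0.9),
) -> DemographyConfig:
    """Two populations with identical drift F since their split.

    All mutations predate the split (they are placed on the shared ancestral
    branch), the classic Balding-Nichols sampling model under which the
    Weir-Cockerham estimator targets F.
    """
    return DemographyConfig(
        branches={
            "anc": BranchSpec(parent=None, length=1.0, F=0.0),
            "pop1": BranchSpec(parent="anc", length=0.0, F=F),
            "pop2": BranchSpec(parent="anc", length=0.0, F=F),
        },
        samples=[
            SampleSpec(group="pop1", node="pop1", n=n_per_group),
            SampleSpec(group="pop2", node="pop2", n=n_per_group),
            SampleSpec(group="great_ape", node="anc", n=3, role="great_ape"),
        ],
        n_sites=n_sites,
        root_freq=root_freq,
        seed=seed,
    )


def preset_single_population(
    F: float = 0.1,
    n: int = 8,
    n_sites: int = 20_000,
    seed: int = 0,
) -> DemographyConfig:
    """One population with drift F and a symmetric segregating-frequency law.

    Root frequencies are uniform on (0, 1): a symmetric distribution is the
    regime in which the anchor-heterozygote continuity statistic has
    expectation exactly 1/2 under pure drift (drift preserves the symmetry;
    a skewed spectrum biases the conditional expectation away from 1/2).
    """
    return DemographyConfig(
        branches={
            "anc": BranchSpec(parent=None, length=1.0, F=0.0),
            "pop": BranchSpec(parent="anc", length=0.0, F=F),
        },
        samples=[
            SampleSpec(group="pop", node="pop", n=n),
            SampleSpec(group="great_ape", node="anc", n=3, role="great_ape"),
        ],
        n_sites=n_sites,
        root_freq=("uniform", 0.0, 1.0),
        seed=seed,
    )


def preset_admixture(
    alpha: float = 0.5,
    n_sites: int = 30_000,
    n_per_group: int = 15,
    source_drift: float = 0.3,
    target_drift: float = 0.01,
    seed: int = 0,
) -> DemographyConfig:
    """Target population formed as an alpha mixture of two diverged sources."""
    return DemographyConfig(
        branches={
            "anc": BranchSpec(parent=None, length=1.0, F=0.0),
            "srcA": BranchSpec(parent="anc", length=0.0, F=source_drift),
            "srcB": BranchSpec(parent="anc", length=0.0, F=source_drift),
            "target": BranchSpec(parent="srcA", length=0.0, F=target_drift),
        },
        samples=[
            SampleSpec(group="srcA", node="srcA", n=n_per_group),
            SampleSpec(group="srcB", node="srcB", n=n_per_group),
            SampleSpec(group="target", node="target", n=n_per_group),
            SampleSpec(group="great_ape", node="anc", n=3, role="great_ape"),
        ],
        admixture=[AdmixtureEdge(source="srcB", dest="target", alpha=alpha)],
        n_sites=n_sites,
        root_freq=("uniform", 0.1, 0.9),
        seed=seed,
    )


def preset_study_panel(
    n_sites: int = 20_000,
    late_admixture_alpha: float = 0.0,
    probe_group: bool | None = None,
    seed: int = 0,
) -> DemographyConfig:
    """The study-shaped panel: 7 ancient southern Africans, 7 northern San,
    5 southern San, 7 pre-Neolithic Eurasians, 208 panel individuals (8 each
    from 26 populations), 4 archaic genomes and 3 great apes.

    The tree carries a deep southern split, an east/west split, a bottlenecked
    non-African branch and, optionally, a late admixture edge from the east
    into a recent southern probe group (round-number branch lengths; the
    real demography is not a simulation target). With ``late_admixture_alpha
    > 0`` (or ``probe_group=True``) a 4-individual ``southern_recent`` group
    is added as the admixture destination.
    """
    if probe_group is None:
        probe_group = late_admixture_alpha > 0
    branches = {
        "archaic_stem": BranchSpec(parent=None, length=6_000, F=0.30),
        "neandertal": BranchSpec(parent="archaic_stem", length=14_000, F=0.70),
        "denisovan": BranchSpec(parent="archaic_stem", length=14_000, F=0.70),
        "human_stem": BranchSpec(parent=None, length=10_000, F=0.25),
        "southern_stem": BranchSpec(parent="human_stem", length=8_500, F=0.25),
        "ancient_southern": BranchSpec(parent="southern_stem", length=1_500, F=0.08),
        "northern_san": BranchSpec(parent="southern_stem", length=1_500, F=0.08),
        "southern_san": BranchSpec(parent="southern_stem", length=1_500, F=0.08),
        "north_stem": BranchSpec(parent="human_stem", length=4_000, F=0.10),
        "west_stem": BranchSpec(parent="north_stem", length=5_200, F=0.12),
        "east_stem": BranchSpec(parent="north_stem", length=3_500, F=0.09),
        "east_recent": BranchSpec(parent="east_stem", length=1_700, F=0.06),
        "ooa_stem": BranchSpec(parent="east_stem", length=1_700, F=0.30),
        "preneolithic_eurasian": BranchSpec(parent="ooa_stem", length=800, F=0.05),
    }
    samples = [
        SampleSpec(group="ancient_southern", node="ancient_southern", n=7),
        SampleSpec(group="northern_san", node="northern_san", n=7),
        SampleSpec(group="southern_san", node="southern_san", n=5),
        SampleSpec(group="preneolithic_eurasian", node="preneolithic_eurasian", n=7),
    ]
    # 26 panel populations of 8: 4 western, 3 eastern, 19 non-African
    for i in range(4):
        branches[f"panel_w{i + 1}"] = BranchSpec(parent="west_stem", length=800, F=0.04)
        samples.append(SampleSpec(group="panel_1kgp", node=f"panel_w{i + 1}", n=8))
    for i in range(3):
        branches[f"panel_e{i + 1}"] = BranchSpec(parent="east_recent", length=800, F=0.04)
        samples.append(SampleSpec(group="panel_1kgp", node=f"panel_e{i + 1}", n=8))
    for i in range(19):
        branches[f"panel_n{i + 1}"] = BranchSpec(parent="ooa_stem", length=800, F=0.06)
        samples.append(SampleSpec(group="panel_1kgp", node=f"panel_n{i + 1}", n=8))
    samples.append(SampleSpec(group="archaic", node="neandertal", n=3, role="archaic"))
    samples.append(SampleSpec(group="archaic", node="denisovan", n=1, role="archaic"))
    samples.append(SampleSpec(group="great_ape", node="archaic_stem", n=3, role="great_ape"))

    admixture = []
    if probe_group:
        branches["southern_recent"] = BranchSpec(
            parent="southern_stem", length=1_500, F=0.08
        )
        samples.append(SampleSpec(group="southern_recent", node="southern_recent", n=4))
        if late_admixture_alpha > 0:
            admixture.append(
                AdmixtureEdge(
                    source="east_recent",
                    dest="southern_recent",
                    alpha=late_admixture_alpha,
                )
            )
    return DemographyConfig(
        branches=branches,
        samples=samples,
        admixture=admixture,
        n_sites=n_sites,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# aDNA artifacts
# ---------------------------------------------------------------------------

@dataclass
class ArtifactConfig:
    """Coverage, dropout and deamination model for synthetic pileups."""

    mean_coverage: float | Mapping[str, float] = 5.0
    missing_rate: float = 0.05  # per individual-site dropout
    deamination_rate: float = 0.0  # C->T / G->A error rate on non-UDG reads
    base_quality: int = 40
    map_quality: int = 40
    low_quality_fraction: float = 0.1  # reads drawn below the quality threshold
    low_quality_value: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.missing_rate, self.deamination_rate, self.low_quality_fraction):
            if not (0.0 <= rate <= 1.0):
                raise PanelError("artifact rates must be in [0, 1]")


def apply_adna_artifacts(
    panel: GenotypePanel,
    cfg: ArtifactConfig,
    ind_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Generate a long-format pileup table from true genotypes.

    Per individual-site, the read count is Poisson(mean coverage) with an
    extra dropout probability; each read copies one of the individual's true
    alleles. Non-UDG library reads suffer deamination-type errors (C read as
    T, G read as A) at the configured rate; ``udg_status=mixed`` individuals
    get half their reads from each library type. A fraction of reads carries
    sub-threshold base quality to exercise the quality filters.
    """
    rng = np.random.default_rng(cfg.seed)
    if ind_ids is None:
        ind_ids = panel.ids
    base_of = {0: panel.sites["ref"].to_numpy(), 1: panel.sites["alt"].to_numpy()}
    frames = []
    chrom_arr = panel.sites["chrom"].to_numpy()
    pos_arr = panel.sites["pos"].to_numpy()
    for ind_id in ind_ids:
        j = panel.index_of(ind_id)
        meta = panel.individuals[j]
        cov = (
            cfg.mean_coverage[ind_id]
            if isinstance(cfg.mean_coverage, Mapping)
            else cfg.mean_coverage
        )
        counts = rng.poisson(cov, panel.n_sites)
        if cfg.missing_rate > 0:
            counts[rng.random(panel.n_sites) < cfg.missing_rate] = 0
        alleles = panel.calls[:, j, :]
        called_slots = np.maximum((alleles >= 0).sum(axis=1), 1)
        counts[(alleles >= 0).sum(axis=1) == 0] = 0
        site_idx = np.repeat(np.arange(panel.n_sites), counts)
        n_reads = site_idx.size
        if n_reads == 0:
            continue
        slot = rng.integers(0, called_slots[site_idx])
        codes = alleles[site_idx, slot]
        bases = np.where(codes == 0, base_of[0][site_idx], base_of[1][site_idx])
        if meta.udg_status == "non_udg":
            library = np.full(n_reads, "non_udg")
        elif meta.udg_status == "mixed":
            library = np.where(rng.random(n_reads) < 0.5, "udg", "non_udg")
        else:  # udg-treated or modern (not_applicable): damage-free
            library = np.full(n_reads, "udg")
        if cfg.deamination_rate > 0:
            damaged = (library == "non_udg") & (rng.random(n_reads) < cfg.deamination_rate)
            bases = bases.copy()
            bases[damaged & (bases == "C")] = "T"
            bases[damaged & (bases == "G")] = "A"
        bq = np.where(
            rng.random(n_reads) < cfg.low_quality_fraction,
            cfg.low_quality_value,
            cfg.base_quality,
        )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom_arr[site_idx],
                    "pos": pos_arr[site_idx],
                    "individual": ind_id,
                    "base": bases,
                    "bq": bq,
                    "mq": cfg.map_quality,
                    "library": library,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "pos", "individual", "base", "bq", "mq", "library"]
        )
    return pd.concat(frames, ignore_index=True)


__all__ = [
    "AdmixtureEdge",
    "ArtifactConfig",
    "BranchSpec",
    "DemographyConfig",
    "SampleSpec",
    "TruthRecord",
    "apply_adna_artifacts",
    "preset_admixture",
    "preset_study_panel",
    "preset_two_pop",
    "simulate_panel",
]
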