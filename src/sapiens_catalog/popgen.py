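"""Population-genetic statistics on genotype panels and derived dosages.

Implements per-individual heterozygosity, chromosome-weighted pairwise
distance matrices with UPGMA clustering, per-site Weir-Cockerham FST, f3/f4
allele-frequency statistics with archaic-polymorphism ascertainment and a
weighted 5-Mb block jackknife, the anchor-heterozygote continuity statistic,
and a two-by-two-outgroup SFS divergence-time scaffold.

Frequencies are complete-case: at each site a group's derived-allele frequency
is computed over called alleles only, with single-read pseudohaploid
individuals contributing frequencies in {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ChromTable, GenotypePanel, PanelError
from .polarize import DerivedDosage

DEFAULT_BLOCK_BP = 5_000_000


# ---------------------------------------------------------------------------
# block jackknife
# ---------------------------------------------------------------------------

@dataclass
class JackknifeEstimate:
    """A statistic with weighted delete-one-block jackknife uncertainty."""

    value: float
    se: float
    n_blocks: int
    loo: np.ndarray  # leave-one-out estimates, one per non-empty block
    weights: np.ndarray  # informative-site counts per block
    block_size_bp: int = DEFAULT_BLOCK_BP

    @property
    def z(self) -> float:
        return self.value / self.se if self.se > 0 else np.inf * np.sign(self.value)

    def ci95(self) -> tuple[float, float]:
        return self.value - 1.96 * self.se, self.value + 1.96 * self.se


def assign_blocks(
    chroms: np.ndarray, positions: np.ndarray, block_bp: int = DEFAULT_BLOCK_BP
) -> np.ndarray:
    """Contiguous non-overlapping windows [1, B], (B, 2B], ... per chromosome.

    Returns a dense integer block label per site, ordered by (chrom, window).
    """
    positions = np.asarray(positions)
    win = (positions - 1) // int(block_bp)
    keys = pd.MultiIndex.from_arrays([np.asarray(chroms), win])
    codes, _ = pd.factorize(keys, sort=True)
    return codes


def _weighted_jackknife(value: float, loo: np.ndarray, weights: np.ndarray) -> float:
    """Busing-style weighted delete-m_j jackknife standard error.

    ``loo`` are leave-one-block-out estimates; ``weights`` the per-block
    informative counts m_j. For equal weights this reduces to the classic
    delete-one jackknife variance.
    """
    g = len(loo)
    if g < 2:
        raise PanelError("block jackknife needs at least 2 non-empty blocks")
    m = np.asarray(weights, dtype=float)
    n = m.sum()
    h = n / m
    theta_j = g * value - ((1.0 - m / n) * loo).sum()
    pseudo = h * value - (h - 1.0) * loo
    var = np.sum((pseudo - theta_j) ** 2 / (h - 1.0)) / g
    return float(np.sqrt(var))


def block_jackknife(
    values: np.ndarray,
    chroms: np.ndarray,
    positions: np.ndarray,
    chrom_table: ChromTable | None = None,
    block_bp: int = DEFAULT_BLOCK_BP,
) -> JackknifeEstimate:
    """Jackknife the mean of per-site values over 5-Mb physical blocks.

    Block weights are informative-site counts; empty blocks carry no weight
    and do not change the estimate.
    """
    values = np.asarray(values, dtype=float)
    keep = ~np.isnan(values)
    values = values[keep]
    blocks = assign_blocks(np.asarray(chroms)[keep], np.asarray(positions)[keep], block_bp)
    if values.size == 0:
        raise PanelError("no informative sites for jackknife")
    n_blocks = blocks.max() + 1
    sums = np.bincount(blocks, weights=values, minlength=n_blocks)
    counts = np.bincount(blocks, minlength=n_blocks).astype(float)
    nonempty = counts > 0
    sums, counts = sums[nonempty], counts[nonempty]
    if len(counts) < 2:
        raise PanelError("block jackknife needs at least 2 non-empty blocks")
    total, n = sums.sum(), counts.sum()
    value = total / n
    loo = (total - sums) / (n - counts)
    se = _weighted_jackknife(value, loo, counts)
    return JackknifeEstimate(
        value=float(value),
        se=se,
        n_blocks=int(nonempty.sum()),
        loo=loo,
        weights=counts,
        block_size_bp=int(block_bp),
    )


# ---------------------------------------------------------------------------
# diversity and distances
# ---------------------------------------------------------------------------

def heterozygosity(panel: GenotypePanel, ind_id: str) -> float:
    """Heterozygous genotype calls over total genotype calls for one diploid."""
    j = panel.index_of(ind_id)
    calls = panel.calls[:, j, :]
    full = (calls >= 0).all(axis=1)
    if not full.any():
        raise PanelError(f"{ind_id}: no called diploid genotypes")
    het = calls[full, 0] != calls[full, 1]
    return float(het.sum() / full.sum())


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-chromosome parts."""

    labels: list[str]
    matrix: np.ndarray
    per_chrom: dict[str, np.ndarray]
    weights: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def pairwise_distances(
    panel: GenotypePanel,
    chrom_table: ChromTable,
    ind_ids: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Average per-site allele-frequency distance over co-called sites.

    Per site the distance between two individuals is the absolute difference
    of their within-individual alt-allele fractions; per-chromosome averages
    are combined with weights proportional to chromosome length (chromosome
    length / total length over chromosomes with data, so weights sum to 1).
    """
    if ind_ids is None:
        ind_ids = panel.ids
    if len(ind_ids) < 2:
        raise PanelError("pairwise distances need at least 2 individuals")
    panel.check_chromosomes(chrom_table)
    idx = panel.indices_of(ind_ids)
    calls = panel.calls[:, idx, :]
    called = calls >= 0
    n_called = called.sum(axis=2)
    n_alt = ((calls == 1) & called).sum(axis=2)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_called > 0, n_alt / np.maximum(n_called, 1), np.nan)

    chrom_arr = panel.sites["chrom"].to_numpy()
    k = len(ind_ids)
    per_chrom: dict[str, np.ndarray] = {}
    for chrom in dict.fromkeys(chrom_arr):
        sub = frac[chrom_arr == chrom]
        mat = np.full((k, k), np.nan)
        for a in range(k):
            for b in range(a, k):
                both = ~np.isnan(sub[:, a]) & ~np.isnan(sub[:, b])
                if both.any():
                    d = np.abs(sub[both, a] - sub[both, b]).mean()
                    mat[a, b] = mat[b, a] = d
        per_chrom[chrom] = mat

    lengths = {c: chrom_table[c] for c in per_chrom}
    total = sum(lengths.values())
    weights = {c: length / total for c, length in lengths.items()}
    genome = np.zeros((k, k))
    for chrom, mat in per_chrom.items():
        genome += weights[chrom] * np.nan_to_num(mat)
    np.fill_diagonal(genome, 0.0)
    return DistanceMatrix(
        labels=list(ind_ids), matrix=genome, per_chrom=per_chrom, weights=weights
    )


def upgma(labels: Sequence[str], matrix: np.ndarray) -> str:
    """Average-linkage agglomeration to a rooted ultrametric tree (newick).

    Branch lengths place every leaf at height 0 and each internal node at half
    the merged inter-cluster distance. Tied merge candidates are resolved by
    the lexicographically smallest (label, label) pair.
    """
    matrix = np.asarray(matrix, dtype=float)
    if len(labels) < 2:
        raise PanelError("UPGMA needs at least 2 labels")
    if np.isnan(matrix).any():
        raise PanelError("UPGMA distance matrix contains NaN")
    clusters = {
        i: {"newick": lab, "size": 1, "height": 0.0, "min_label": lab}
        for i, lab in enumerate(labels)
    }
    dist = {
        (i, j): float(matrix[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    next_id = len(labels)
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                tuple(sorted((clusters[kv[0][0]]["min_label"], clusters[kv[0][1]]["min_label"]))),
            ),
        )
        (i, j), dij = best
        ci, cj = clusters.pop(i), clusters.pop(j)
        height = dij / 2.0
        a, b = sorted((ci, cj), key=lambda c: c["min_label"])
        newick = (
            f"({a['newick']}:{height - a['height']:.17g},"
            f"{b['newick']}:{height - b['height']:.17g})"
        )
        new = {
            "newick": newick,
            "size": ci["size"] + cj["size"],
            "height": height,
            "min_label": a["min_label"],
        }
        # UPGMA update: size-weighted average of distances to the merged pair
        for k in list(clusters):
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(k, next_id), max(k, next_id))] = (
                ci["size"] * dik + cj["size"] * djk
            ) / (ci["size"] + cj["size"])
        dist.pop((i, j), None)
        clusters[next_id] = new
        next_id += 1
    return next(iter(clusters.values()))["newick"] + ";"


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    per_site: np.ndarray  # NaN at skipped/undefined sites
    weighted: float  # sum(a) / sum(a+b+c), the VCFtools "weighted" aggregate
    mean: float  # mean of per-site ratios
    n_used: int
    n_skipped: int


def weir_cockerham_fst(
    dd: DerivedDosage, group_a: Sequence[str], group_b: Sequence[str]
) -> FstResult:
    """Per-site Weir & Cockerham (1984) theta for two populations.

    Uses the two-allele variance components a (among populations),
    b (among individuals within populations) and c (within individuals);
    per-site theta = a/(a+b+c). Individuals contribute at a site only with a
    full diploid call. Sites where either group has fewer than two called
    alleles are skipped; sites with a zero denominator (monomorphic in the
    sample) are excluded from both aggregates.
    """
    r = 2.0
    out = np.full(dd.n_sites, np.nan)
    num = np.zeros(dd.n_sites)
    den = np.zeros(dd.n_sites)
    stats = []
    for ids in (group_a, group_b):
        idx = dd.indices_of(ids)
        dos = dd.dosage[:, idx].astype(np.float64)
        full = dd.called[:, idx] == 2
        n_i = full.sum(axis=1).astype(float)  # diploid individuals with data
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, np.nansum(np.where(full, dos, 0), axis=1) / (2 * n_i), np.nan)
            h_i = np.where(n_i > 0, np.where(full, dos == 1, False).sum(axis=1) / n_i, np.nan)
        stats.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats
    ok = (n1 >= 1) & (n2 >= 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)

        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2

    denom = a + b + c
    defined = ok & np.isfinite(denom) & (denom != 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[defined] = (a / denom)[defined]
    num[defined] = a[defined]
    den[defined] = denom[defined]
    n_used = int(defined.sum())
    if n_used == 0:
        raise PanelError("no sites with defined FST components")
    return FstResult(
        per_site=out,
        weighted=float(num.sum() / den.sum()),
        mean=float(np.nanmean(out)),
        n_used=n_used,
        n_skipped=int(dd.n_sites - n_used),
    )


# ---------------------------------------------------------------------------
# f-statistics
# ---------------------------------------------------------------------------

def archaic_polymorphic_mask(dd: DerivedDosage, id1: str, id2: str) -> np.ndarray:
    """Ascertainment: sites polymorphic within the pair (e.g. Altai, Denisovan).

    Both individuals must be called and the derived allele segregating among
    their called alleles (0 < derived < called).
    """
    i1, i2 = dd.indices_of([id1, id2])
    c = dd.called[:, i1].astype(int) + dd.called[:, i2].astype(int)
    d = np.nan_to_num(dd.dosage[:, i1]) + np.nan_to_num(dd.dosage[:, i2])
    both = (dd.called[:, i1] > 0) & (dd.called[:, i2] > 0)
    return both & (d > 0) & (d < c)


def _per_site_f4(dd, a, b, c, d):
    pa, pb, pc, pd_ = (dd.group_frequency(g) for g in (a, b, c, d))
    return (pa - pb) * (pc - pd_)


def f4(
    dd: DerivedDosage,
    a: Sequence[str],
    b: Sequence[str],
    c: Sequence[str],
    d: Sequence[str],
    chrom_table: ChromTable | None = None,
    ascertainment: np.ndarray | None = None,
    block_bp: int = DEFAULT_BLOCK_BP,
) -> JackknifeEstimate:
    """f4(A, B; C, D) = mean over sites of (pA - pB)(pC - pD), block jackknifed.

    Sites require a defined frequency in all four groups (complete case);
    ``ascertainment`` optionally restricts the informative set (e.g. to sites
    polymorphic between two archaic genomes).
    """
    vals = _per_site_f4(dd, a, b, c, d)
    if ascertainment is not None:
        vals = np.where(ascertainment, vals, np.nan)
    return block_jackknife(
        vals,
        dd.sites["chrom"].to_numpy(),
        dd.sites["pos"].to_numpy(),
        chrom_table,
        block_bp,
    )


def f3_vanilla(
    dd: DerivedDosage,
    target: Sequence[str],
    a: Sequence[str],
    b: Sequence[str],
    chrom_table: ChromTable | None = None,
    ascertainment: np.ndarray | None = None,
    block_bp: int = DEFAULT_BLOCK_BP,
) -> JackknifeEstimate:
    """f3(T; A, B) = mean of (pT - pA)(pT - pB), without normalization.

    Significantly negative values (Z < -3 by block jackknife) indicate the
    target is admixed between sources related to A and B.
    """
    pt, pa, pb = (dd.group_frequency(g) for g in (target, a, b))
    vals = (pt - pa) * (pt - pb)
    if ascertainment is not None:
        vals = np.where(ascertainment, vals, np.nan)
    return block_jackknife(
        vals,
        dd.sites["chrom"].to_numpy(),
        dd.sites["pos"].to_numpy(),
        chrom_table,
        block_bp,
    )


# ---------------------------------------------------------------------------
# continuity statistic
# ---------------------------------------------------------------------------

def continuity_statistic(
    dd: DerivedDosage,
    anchor_id: str,
    probe_ids: Sequence[str] | str,
    block_bp: int = DEFAULT_BLOCK_BP,
) -> JackknifeEstimate:
    """Derived-allele proportion in a probe at sites heterozygous in an anchor.

    Conditions on diploid heterozygous sites of the anchor individual and
    counts the fraction of the probe's called alleles carrying the derived
    state. Forward in time from the anchor population the expectation stays at
    1/2 under pure drift and drops with gene flow from a diverged source. The
    anchor probed against itself gives exactly 0.5.
    """
    if isinstance(probe_ids, str):
        probe_ids = [probe_ids]
    ai = dd.indices_of([anchor_id])[0]
    het = (dd.called[:, ai] == 2) & (dd.dosage[:, ai] == 1)
    if not het.any():
        raise PanelError(f"anchor {anchor_id} has no heterozygous sites")
    d, c = dd.group_counts(probe_ids)
    use = het & (c > 0)
    if not use.any():
        raise PanelError("probe has no calls at anchor-heterozygous sites")
    chroms = dd.sites["chrom"].to_numpy()[use]
    positions = dd.sites["pos"].to_numpy()[use]
    d, c = d[use], c[use]
    blocks = assign_blocks(chroms, positions, block_bp)
    n_blocks = blocks.max() + 1
    d_sum = np.bincount(blocks, weights=d, minlength=n_blocks)
    c_sum = np.bincount(blocks, weights=c, minlength=n_blocks)
    nonempty = c_sum > 0
    d_sum, c_sum = d_sum[nonempty], c_sum[nonempty]
    if len(c_sum) < 2:
        raise PanelError("block jackknife needs at least 2 non-empty blocks")
    value = d_sum.sum() / c_sum.sum()
    loo = (d_sum.sum() - d_sum) / (c_sum.sum() - c_sum)
    se = _weighted_jackknife(value, loo, c_sum)
    return JackknifeEstimate(
        value=float(value),
        se=se,
        n_blocks=int(nonempty.sum()),
        loo=loo,
        weights=c_sum,
        block_size_bp=int(block_bp),
    )


# ---------------------------------------------------------------------------
# two-by-two SFS and divergence scaffold
# ---------------------------------------------------------------------------

@dataclass
class DivergenceConfig:
    """Filters and rescaling constants for divergence-time estimation."""

    mutation_rate: float = 1.45e-8  # per bp per generation
    generation_time: float = 29.0  # years
    qual_min: float = 30.0
    min_allele_depth: int = 4
    coverage_percentiles: tuple[float, float] = (5.0, 95.0)

    def __post_init__(self) -> None:
        lo, hi = self.coverage_percentiles
        if not (0 <= lo < hi <= 100):
            raise PanelError("coverage percentiles must satisfy 0 <= lo < hi <= 100")
        if min(self.mutation_rate, self.generation_time, self.qual_min) <= 0:
            raise PanelError("rates and times must be positive")


def tt_site_filter(
    sites: pd.DataFrame,
    depths: np.ndarray,
    allele_depths: np.ndarray,
    cfg: DivergenceConfig,
    ancestral_ok: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Site filter for the divergence scaffold; returns (pass, reason).

    A site passes iff QUAL > qual_min, the ancestral state is assigned among
    ref/alt, every individual's total depth lies within its own [lo, hi]
    coverage percentiles, and the supporting allele depth reaches
    ``min_allele_depth`` in every individual. The first failing check (qual,
    ancestral, coverage, depth) is reported.
    """
    n = len(sites)
    if depths.shape[0] != n or allele_depths.shape[0] != n:
        raise PanelError("depth matrices must have one row per site")
    qual_ok = sites["qual"].to_numpy() > cfg.qual_min
    anc_ok = np.ones(n, dtype=bool) if ancestral_ok is None else np.asarray(ancestral_ok)
    lo, hi = cfg.coverage_percentiles
    lo_b = np.percentile(depths, lo, axis=0)
    hi_b = np.percentile(depths, hi, axis=0)
    cov_ok = ((depths >= lo_b) & (depths <= hi_b)).all(axis=1)
    ad_ok = (allele_depths >= cfg.min_allele_depth).all(axis=1)
    passing = qual_ok & anc_ok & cov_ok & ad_ok
    reasons = []
    for i in range(n):
        if passing[i]:
            reasons.append("")
        elif not qual_ok[i]:
            reasons.append("qual")
        elif not anc_ok[i]:
            reasons.append("ancestral")
        elif not cov_ok[i]:
            reasons.append("coverage")
        else:
            reasons.append("depth")
    return passing, reasons


def _all_blocks(chrom_table: ChromTable, block_bp: int) -> tuple[list[tuple[str, int]], np.ndarray]:
    """All (chrom, window) blocks covering the genome, with callable lengths."""
    keys: list[tuple[str, int]] = []
    lengths: list[float] = []
    for chrom in sorted(chrom_table.lengths):
        length = chrom_table[chrom]
        n_win = int(np.ceil(length / block_bp))
        for w in range(n_win):
            keys.append((chrom, w))
            lengths.append(min(length, (w + 1) * block_bp) - w * block_bp)
    return keys, np.asarray(lengths, dtype=float)


@dataclass
class TwoByTwoSfs:
    """Joint derived-dosage spectrum of two diploid individuals.

    ``counts[i, j]`` is the number of informative sites with dosage *i* in
    individual 1 and *j* in individual 2; per-block counts and callable block
    lengths support the jackknife of downstream estimates.
    """

    counts: np.ndarray  # (3, 3)
    block_counts: np.ndarray  # (n_blocks, 3, 3)
    block_lengths: np.ndarray  # callable bp per block
    total_length: float

    @property
    def n_informative(self) -> int:
        return int(self.counts.sum())


def two_by_two_sfs(
    dos1: np.ndarray,
    dos2: np.ndarray,
    chroms: np.ndarray,
    positions: np.ndarray,
    chrom_table: ChromTable,
    site_filter: np.ndarray | None = None,
    block_bp: int = DEFAULT_BLOCK_BP,
) -> TwoByTwoSfs:
    """Count the 3x3 joint dosage spectrum over passing, fully-called sites."""
    dos1 = np.asarray(dos1, dtype=float)
    dos2 = np.asarray(dos2, dtype=float)
    ok = ~np.isnan(dos1) & ~np.isnan(dos2)
    if site_filter is not None:
        ok &= np.asarray(site_filter, dtype=bool)
    keys, lengths = _all_blocks(chrom_table, block_bp)
    key_index = {k: i for i, k in enumerate(keys)}
    block_counts = np.zeros((len(keys), 3, 3), dtype=np.int64)
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    for i in np.flatnonzero(ok):
        w = int((positions[i] - 1) // block_bp)
        bi = key_index.get((chroms[i], w))
        if bi is None:
            raise PanelError(f"site {chroms[i]}:{positions[i]} outside chromosome table")
        block_counts[bi, int(dos1[i]), int(dos2[i])] += 1
    counts = block_counts.sum(axis=0)
    if counts.sum() == 0:
        raise PanelError("zero informative sites in two-by-two SFS")
    return TwoByTwoSfs(
        counts=counts,
        block_counts=block_counts,
        block_lengths=lengths,
        total_length=float(lengths.sum()),
    )


@dataclass
class DivergenceEstimate:
    t_generations: float
    se_generations: float
    t_years: float
    n_informative: int
    d_xy: float  # between-individual pairwise difference rate per bp
    het1: float
    het2: float

    def ci95_generations(self) -> tuple[float, float]:
        return (
            self.t_generations - 1.96 * self.se_generations,
            self.t_generations + 1.96 * self.se_generations,
        )

    def ci95_years(self, generation_time: float = 29.0) -> tuple[float, float]:
        lo, hi = self.ci95_generations()
        return lo * generation_time, hi * generation_time


def _tt_moment(counts: np.ndarray, length: float, mu: float) -> tuple[float, float, float, float]:
    """Net-divergence moment statistic from a 3x3 dosage spectrum.

    d_xy is the probability one allele from each individual differs; the
    within-individual heterozygosities estimate (ancestral) diversity 4*N*mu,
    so (d_xy - mean het) / (2*mu) estimates the split time in generations
    under equal ancestral and descendant population sizes.
    """
    if length <= 0:
        raise PanelError("callable length must be positive")
    i = np.arange(3)[:, None]
    j = np.arange(3)[None, :]
    mismatch = (i * (2 - j) + (2 - i) * j) / 4.0
    d_xy = float((counts * mismatch).sum() / length)
    h1 = float(counts[1, :].sum() / length)
    h2 = float(counts[:, 1].sum() / length)
    t = (d_xy - (h1 + h2) / 2.0) / (2.0 * mu)
    return t, d_xy, h1, h2


def estimate_divergence(tt: TwoByTwoSfs, cfg: DivergenceConfig) -> DivergenceEstimate:
    """Split time between two diploid individuals from their two-by-two SFS.

    Point estimate by the net-divergence moment statistic; uncertainty by
    weighted 5-Mb block jackknife (block weights = informative-site counts);
    chronological rescaling T_years = T_generations * generation_time.
    """
    if tt.n_informative == 0:
        raise PanelError("degenerate SFS: no informative sites")
    mu = cfg.mutation_rate
    value, d_xy, h1, h2 = _tt_moment(tt.counts, tt.total_length, mu)
    m = tt.block_counts.sum(axis=(1, 2)).astype(float)
    nonempty = m > 0
    if nonempty.sum() < 2:
        raise PanelError("block jackknife needs at least 2 non-empty blocks")
    loo = np.array(
        [
            _tt_moment(
                tt.counts - tt.block_counts[b],
                tt.total_length - tt.block_lengths[b],
                mu,
            )[0]
            for b in np.flatnonzero(nonempty)
        ]
    )
    se = _weighted_jackknife(value, loo, m[nonempty])
    return DivergenceEstimate(
        t_generations=value,
        se_generations=se,
        t_years=value * cfg.generation_time,
        n_informative=tt.n_informative,
        d_xy=d_xy,
        het1=h1,
        het2=h2,
    )


__all__ = [
    "DEFAULT_BLOCK_BP",
    "DistanceMatrix",
    "DivergenceConfig",
    "DivergenceEstimate",
    "FstResult",
    "JackknifeEstimate",
    "TwoByTwoSfs",
    "archaic_polymorphic_mask",
    "assign_blocks",
    "block_jackknife",
    "continuity_statistic",
    "estimate_divergence",
    "f3_vanilla",
    "f4",
    "heterozygosity",
    "pairwise_distances",
    "tt_site_filter",
    "two_by_two_sfs",
    "upgma",
    "weir_cockerham_fst",
]
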