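"""The *Homo sapiens*-specific (HSS) variant catalogue.

A derived variant is HSS when every one of the four archaic genomes (three
Neandertals and one Denisovan) is called and carries only the ancestral
allele, while at least one derived allele is observed among the *Homo sapiens*
individuals. On the HSS site set the module builds per-group derived-allele
frequency spectra at a projected sample size, counts fixed-derived variants,
partitions presence across groups (Venn logic), screens for sites fixed in one
group but variable in another, ranks frequency differentials (a local-
adaptation screen), and exports gene lists for external enrichment tools.

Definitions used throughout (frequency = derived alleles / called alleles,
complete-case per site):

- *present* in a group: >= 1 derived allele among called alleles;
- *fixed*: every called allele derived, with at least ``min_called`` alleles;
- *variable*: derived observed but not fixed (0 < count < called) — so
  fixed / variable / absent partition the sites with data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datatypes import PanelError
from .polarize import DerivedDosage

logger = logging.getLogger(__name__)

REASON_ARCHAIC_MISSING = "archaic_missing"
REASON_ARCHAIC_DERIVED = "archaic_derived"
REASON_NO_HUMAN_DERIVED = "no_human_derived"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for reported percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classify_hss(
    dd: DerivedDosage,
    archaic_ids: Sequence[str],
    human_ids: Sequence[str],
    allow_any_archaic_count: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Per-site HSS classification with reason codes for rejected sites.

    Returns ``(is_hss, reasons)`` where reasons are empty strings for HSS
    sites and one of ``archaic_missing`` / ``archaic_derived`` /
    ``no_human_derived`` otherwise (checked in that order).
    """
    if len(archaic_ids) != 4 and not allow_any_archaic_count:
        raise PanelError(
            f"expected exactly 4 archaic individuals, got {len(archaic_ids)} "
            "(pass allow_any_archaic_count=True to override)"
        )
    a_idx = dd.indices_of(archaic_ids)
    archaic_called = (dd.called[:, a_idx] > 0).all(axis=1)
    archaic_derived = np.nansum(dd.dosage[:, a_idx], axis=1) > 0
    human_derived_sum, _ = dd.group_counts(human_ids)
    human_derived = human_derived_sum >= 1

    is_hss = archaic_called & ~archaic_derived & human_derived
    reasons = []
    for i in range(dd.n_sites):
        if is_hss[i]:
            reasons.append("")
        elif not archaic_called[i]:
            reasons.append(REASON_ARCHAIC_MISSING)
        elif archaic_derived[i]:
            reasons.append(REASON_ARCHAIC_DERIVED)
        else:
            reasons.append(REASON_NO_HUMAN_DERIVED)
    return is_hss, reasons


@dataclass
class Spectrum:
    """Derived-allele frequency spectrum at projected allele count ``m``.

    ``counts[k-1]`` is the (possibly fractional, under hypergeometric
    projection) number of sites with ``k`` derived alleles in the projected
    sample, k = 1..m; the fixed class k = m is included.
    """

    group: str
    m: int
    counts: np.ndarray
    mode: str
    n_candidate: int
    n_skipped: int  # sites with fewer than m called alleles in the group

    @property
    def mass(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.group, "k": np.arange(1, self.m + 1), "count": self.counts}
        )


def group_spectrum(
    dd: DerivedDosage,
    site_mask: np.ndarray,
    group: str,
    ids: Sequence[str],
    m: int,
    projection_mode: str = "hypergeometric",
    seed: int | None = None,
) -> Spectrum:
    """Project each site's derived count to ``m`` alleles and accumulate.

    ``hypergeometric`` adds each site's expected class membership (the exact
    distribution of the derived count in a draw of ``m`` alleles without
    replacement); ``subsample`` draws one such sample per site with a seeded
    RNG. Sites where the group has fewer than ``m`` called alleles are skipped
    and counted.
    """
    if m <= 0:
        raise PanelError("projected allele count m must be positive")
    d, c = dd.group_counts(ids)
    d, c = d[site_mask], c[site_mask]
    ok = c >= m
    counts = np.zeros(m, dtype=float)
    if projection_mode in ("hypergeometric", "hypergeometric_expectation"):
        for di, ci in zip(d[ok].astype(int), c[ok].astype(int)):
            k = np.arange(1, m + 1)
            counts += hypergeom.pmf(k, ci, di, m)
    elif projection_mode in ("subsample", "random_subsample"):
        rng = np.random.default_rng(seed)
        for di, ci in zip(d[ok].astype(int), c[ok].astype(int)):
            k = int(rng.hypergeometric(di, ci - di, m))
            if k > 0:
                counts[k - 1] += 1
    else:
        raise PanelError(f"unknown projection_mode {projection_mode!r}")
    return Spectrum(
        group=group,
        m=m,
        counts=counts,
        mode=projection_mode,
        n_candidate=int(ok.sum()),
        n_skipped=int((~ok).sum()),
    )


def fixed_variants(
    dd: DerivedDosage,
    site_mask: np.ndarray,
    ids: Sequence[str],
    min_called: int = 1,
) -> np.ndarray:
    """Mask (over all dd sites) of sites fixed-derived in the group.

    Fixed: every called allele is derived and at least ``min_called`` alleles
    are called. Sites outside ``site_mask`` are False.
    """
    if min_called < 1:
        raise PanelError("min_called must be >= 1")
    d, c = dd.group_counts(ids)
    return site_mask & (c >= min_called) & (d == c) & (c > 0)


def presence(dd: DerivedDosage, site_mask: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    """Mask of sites with >= 1 observed derived allele in the group."""
    d, _ = dd.group_counts(ids)
    return site_mask & (d >= 1)


def variable_mask(dd: DerivedDosage, site_mask: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    """Mask of sites segregating in the group (0 < derived count < called)."""
    d, c = dd.group_counts(ids)
    return site_mask & (d >= 1) & (d < c)


@dataclass
class VennPartition:
    """Exact subset-membership counts of per-group presence sets."""

    groups: list[str]
    counts: dict[tuple[str, ...], int] = field(default_factory=dict)

    @property
    def union_count(self) -> int:
        return sum(self.counts.values())

    def present_count(self, group: str) -> int:
        return sum(n for subset, n in self.counts.items() if group in subset)

    def unique_count(self, group: str) -> int:
        return self.counts.get((group,), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subset": "&".join(subset), "count": n}
            for subset, n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["subset", "count"])


def venn_partition(
    dd: DerivedDosage,
    site_mask: np.ndarray,
    groups: Mapping[str, Sequence[str]],
) -> VennPartition:
    """Partition catalogued sites by exactly which groups show the derived allele."""
    names = list(groups)
    if len(names) < 2:
        raise PanelError("venn_partition needs at least 2 groups")
    pres = {}
    for name, ids in groups.items():
        p = presence(dd, site_mask, ids)
        _, c = dd.group_counts(ids)
        if int((c[site_mask] > 0).sum()) == 0:
            logger.warning("group %s has no called alleles at any catalogued site", name)
        pres[name] = p
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for subset in combinations(names, r):
            in_subset = np.ones(dd.n_sites, dtype=bool)
            for name in names:
                in_subset &= pres[name] if name in subset else ~pres[name]
            counts[subset] = int((site_mask & in_subset).sum())
    return VennPartition(groups=names, counts=counts)


def unique_fraction(partition: VennPartition, focal: str) -> float:
    """Percentage of the focal group's present sites found in no other group.

    Reported with one-decimal half-up rounding, matching display convention;
    NaN when the focal group shows no derived sites at all.
    """
    if focal not in partition.groups:
        raise PanelError(f"group {focal!r} not in partition {partition.groups}")
    present = partition.present_count(focal)
    if present == 0:
        return float("nan")
    return round_half_up(100.0 * partition.unique_count(focal) / present, 1)


def variable_where_panel_fixed(
    dd: DerivedDosage,
    site_mask: np.ndarray,
    panel_ids: Sequence[str],
    probe_ids: Sequence[str],
    min_called: int = 1,
) -> tuple[int, float]:
    """Of sites fixed-derived in the panel group, the % variable in the probe.

    Returns ``(n_panel_fixed, pct_variable_in_probe)``; the percentage is NaN
    when the panel fixes no sites.
    """
    fixed = fixed_variants(dd, site_mask, panel_ids, min_called=min_called)
    n_fixed = int(fixed.sum())
    if n_fixed == 0:
        return 0, float("nan")
    var = variable_mask(dd, fixed, probe_ids)
    return n_fixed, round_half_up(100.0 * int(var.sum()) / n_fixed, 1)


def rank_frequency_differential(
    dd: DerivedDosage,
    site_mask: np.ndarray,
    focal_ids: Sequence[str],
    panel_ids: Sequence[str],
    top_n: int = 10,
    min_called: int = 1,
) -> pd.DataFrame:
    """Rank focal fixed-derived sites by focal minus panel derived frequency.

    Descending by differential, ties broken by genome order (chrom, pos);
    the classic screen for candidate local adaptation.
    """
    if top_n <= 0:
        raise PanelError("top_n must be positive")
    fixed = fixed_variants(dd, site_mask, focal_ids, min_called=min_called)
    f_freq = dd.group_frequency(focal_ids)
    p_freq = dd.group_frequency(panel_ids)
    idx = np.flatnonzero(fixed)
    table = dd.sites.iloc[idx].copy()
    table["focal_freq"] = f_freq[idx]
    table["panel_freq"] = p_freq[idx]
    table["differential"] = table["focal_freq"] - table["panel_freq"]
    table = table.sort_values(
        ["differential", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    )
    cols = ["chrom", "pos", "ref", "alt", "focal_freq", "panel_freq", "differential"]
    for extra in ("gene", "effect"):
        if extra in table.columns:
            cols.append(extra)
    return table[cols].head(top_n).reset_index(drop=True)


def export_gene_list(site_table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Aggregate a site table into unique gene symbols with supporting-site counts.

    Returns ``(genes, n_unannotated)`` where unannotated sites (no gene label)
    are counted separately instead of entering the gene list.
    """
    if "gene" not in site_table.columns:
        return pd.DataFrame(columns=["gene", "n_sites"]), len(site_table)
    gene = site_table["gene"].fillna("")
    annotated = site_table[gene != ""]
    n_unannotated = int((gene == "").sum())
    genes = (
        annotated.groupby("gene")
        .size()
        .rename("n_sites")
        .reset_index()
        .sort_values(["n_sites", "gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return genes, n_unannotated


__all__ = [
    "Spectrum",
    "VennPartition",
    "classify_hss",
    "export_gene_list",
    "fixed_variants",
    "group_spectrum",
    "presence",
    "rank_frequency_differential",
    "round_half_up",
    "unique_fraction",
    "variable_mask",
    "variable_where_panel_fixed",
    "venn_partition",
]
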