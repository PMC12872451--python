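"""Ancestral-state assignment from great-ape outgroups and derived dosages.

The ancestral state at a biallelic site is the consensus base among the great
apes (chimpanzee, gorilla, orangutan) that have data there: at least one ape
must have data, all apes with data must agree, and the agreed base must equal
the site's ref or alt allele. Heterozygous ape calls are treated as no-data
(conservative: an ape polymorphic at the site is uninformative for consensus).
Sites whose consensus base matches neither allele are ``off_panel``; sites with
no ape data or ape disagreement are ``undetermined``; both are excluded from
derived-allele analyses and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import GenotypePanel, IndividualMeta, PanelError

ANC_UNDETERMINED = -1
ANC_OFF_PANEL = -2

_STATUS = {0: "ref", 1: "alt", ANC_UNDETERMINED: "undetermined", ANC_OFF_PANEL: "off_panel"}


@dataclass
class AncestralAssignment:
    """Per-site ancestral allele codes (0=ref, 1=alt, -1 undetermined, -2 off-panel)."""

    ancestral: np.ndarray
    n_apes_with_data: np.ndarray

    @property
    def included(self) -> np.ndarray:
        return self.ancestral >= 0

    @property
    def n_excluded(self) -> int:
        return int((~self.included).sum())

    def status(self) -> list[str]:
        return [_STATUS[int(a)] for a in self.ancestral]

    def report(self, sites: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": sites["chrom"],
                "pos": sites["pos"],
                "ancestral": [
                    {0: r, 1: a}.get(int(c), _STATUS[int(c)])
                    for c, r, a in zip(self.ancestral, sites["ref"], sites["alt"])
                ],
                "n_apes": self.n_apes_with_data,
                "status": self.status(),
            }
        )


def assign_ancestral(
    site_alleles: tuple[str, str],
    ape_calls: Mapping[str, str | tuple[str, str] | None],
) -> tuple[int, int]:
    """Consensus ancestral call at one site.

    ``ape_calls`` maps ape name to a base, a pair of bases (a heterozygous
    pair counts as no-data), or ``None``/missing. Returns ``(ancestral_code,
    n_apes_with_data)``.
    """
    ref, alt = site_alleles
    observed: list[str] = []
    for call in ape_calls.values():
        if call is None:
            continue
        if isinstance(call, (tuple, list)):
            uniq = set(call)
            if len(uniq) != 1:
                continue  # heterozygous ape: uninformative
            call = next(iter(uniq))
        observed.append(call)
    if not observed:
        return ANC_UNDETERMINED, 0
    if len(set(observed)) != 1:
        return ANC_UNDETERMINED, len(observed)
    base = observed[0]
    if base == ref:
        return 0, len(observed)
    if base == alt:
        return 1, len(observed)
    return ANC_OFF_PANEL, len(observed)


def assign_ancestral_panel(
    panel: GenotypePanel, ape_ids: Sequence[str] | None = None
) -> AncestralAssignment:
    """Vectorized consensus over the panel's ``role=great_ape`` columns.

    Ape calls are allele-coded in the panel, so the agreed base always matches
    ref or alt here; ``off_panel`` states arise only from sidecar base calls
    (see :func:`assign_ancestral`).
    """
    if ape_ids is None:
        ape_ids = panel.ids_with_role("great_ape")
    if not ape_ids:
        raise PanelError("no great-ape individuals available for polarization")
    idx = panel.indices_of(ape_ids)
    calls = panel.calls[:, idx, :]  # (sites, apes, 2)
    called = calls >= 0
    any_called = called.any(axis=2)
    # homozygous = all called slots share one code (haploid single slot counts)
    n_alt = ((calls == 1) & called).sum(axis=2)
    n_called = called.sum(axis=2)
    homozygous = any_called & ((n_alt == 0) | (n_alt == n_called))
    ape_code = np.where(n_alt > 0, 1, 0)

    n_data = homozygous.sum(axis=1)
    sum_codes = (ape_code * homozygous).sum(axis=1)
    agree_ref = sum_codes == 0
    agree_alt = sum_codes == n_data

    ancestral = np.full(panel.n_sites, ANC_UNDETERMINED, dtype=np.int8)
    has = n_data > 0
    ancestral[has & agree_ref] = 0
    ancestral[has & agree_alt] = 1
    return AncestralAssignment(ancestral=ancestral, n_apes_with_data=n_data.astype(int))


@dataclass
class DerivedDosage:
    """Derived-allele dosage matrix over polarized (included) sites.

    ``dosage[i, j]`` counts derived alleles among individual *j*'s called
    alleles at included site *i* (NaN when no allele is called); ``called``
    holds the number of called alleles (0-2).
    """

    sites: pd.DataFrame
    dosage: np.ndarray  # float32, NaN = missing
    called: np.ndarray  # int8
    individuals: list[IndividualMeta]
    ancestral: np.ndarray  # 0=ref or 1=alt per included site
    n_excluded_undetermined: int = 0
    n_excluded_off_panel: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def indices_of(self, ind_ids) -> np.ndarray:
        ids = self.ids
        return np.array([ids.index(i) for i in ind_ids], dtype=int)

    def group_counts(self, ind_ids) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (derived allele count, called allele count) over a group."""
        idx = self.indices_of(ind_ids)
        d = np.nansum(self.dosage[:, idx].astype(np.float64), axis=1)
        c = self.called[:, idx].sum(axis=1).astype(np.int64)
        return d, c

    def group_frequency(self, ind_ids) -> np.ndarray:
        """Derived-allele frequency over called alleles (NaN where none called)."""
        d, c = self.group_counts(ind_ids)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(c > 0, d / np.maximum(c, 1), np.nan)


def derived_dosage(
    panel: GenotypePanel, assignment: AncestralAssignment
) -> DerivedDosage:
    """Convert allele-coded calls to derived dosages over polarized sites.

    Sites with undetermined or off-panel ancestral state are excluded and
    counted; excluded + included always equals the input site count.
    """
    if len(assignment.ancestral) != panel.n_sites:
        raise PanelError("assignment length does not match panel sites")
    keep = assignment.included
    anc = assignment.ancestral[keep]
    calls = panel.calls[keep]  # (sites, ind, 2)
    called = calls >= 0
    n_called = called.sum(axis=2).astype(np.int8)
    derived_code = (1 - anc)[:, None, None]  # derived allele = the non-ancestral one
    n_derived = ((calls == derived_code) & called).sum(axis=2)
    dosage = n_derived.astype(np.float32)
    dosage[n_called == 0] = np.nan
    return DerivedDosage(
        sites=panel.sites.loc[keep].reset_index(drop=True),
        dosage=dosage,
        called=n_called,
        individuals=list(panel.individuals),
        ancestral=anc.astype(np.int8),
        n_excluded_undetermined=int((assignment.ancestral == ANC_UNDETERMINED).sum()),
        n_excluded_off_panel=int((assignment.ancestral == ANC_OFF_PANEL).sum()),
    )


__all__ = [
    "ANC_OFF_PANEL",
    "ANC_UNDETERMINED",
    "AncestralAssignment",
    "DerivedDosage",
    "assign_ancestral",
    "assign_ancestral_panel",
    "derived_dosage",
]
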