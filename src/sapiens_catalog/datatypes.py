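"""Core containers for genotype panels and their metadata.

Coordinates are 1-based inclusive (VCF convention) everywhere. Genotypes are
stored allele-coded (ref/alt/missing), not dosage-coded: derived dosages are
computed only after polarization, so reassigning the ancestral state never
mutates stored calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")

# allele codes in the calls array
ALLELE_REF = 0
ALLELE_ALT = 1
ALLELE_MISSING = -1
#: second allele slot of a haploid / pseudohaploid individual
ALLELE_ABSENT = -2

ROLES = ("human", "archaic", "great_ape")
PLOIDY_MODES = ("diploid", "pseudohaploid")
UDG_STATUSES = ("udg", "non_udg", "mixed", "not_applicable")
SEXES = ("XX", "XY", "unknown")

EFFECT_CLASSES = ("missense_like", "synonymous_like", "other", "unannotated")


class PanelError(ValueError):
    """Invalid panel content (malformed records, violated invariants)."""


@dataclass(frozen=True)
class IndividualMeta:
    """Per-individual metadata: group membership, role and library handling."""

    id: str
    group: str
    role: str = "human"
    ploidy_mode: str = "diploid"
    udg_status: str = "not_applicable"
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PanelError(
                f"unknown role {self.role!r} for individual {self.id!r}; "
                f"allowed roles: {', '.join(ROLES)}"
            )
        if self.ploidy_mode not in PLOIDY_MODES:
            raise PanelError(
                f"unknown ploidy_mode {self.ploidy_mode!r} for {self.id!r}; "
                f"allowed: {', '.join(PLOIDY_MODES)}"
            )
        if self.udg_status not in UDG_STATUSES:
            raise PanelError(
                f"unknown udg_status {self.udg_status!r} for {self.id!r}; "
                f"allowed: {', '.join(UDG_STATUSES)}"
            )
        if self.sex not in SEXES:
            raise PanelError(
                f"unknown sex {self.sex!r} for {self.id!r}; allowed: {', '.join(SEXES)}"
            )


@dataclass
class ChromTable:
    """Chromosome lengths; weights are each chromosome's fraction of the total."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise PanelError(f"chromosome {chrom!r} has non-positive length {length}")

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def weight(self, chrom: str) -> float:
        return self.lengths[chrom] / self.total_length

    def weights(self) -> dict[str, float]:
        total = self.total_length
        return {c: length / total for c, length in self.lengths.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    @classmethod
    def from_tsv(cls, path) -> "ChromTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        if not {"chrom", "length"}.issubset(df.columns):
            raise PanelError(f"{path}: chromosome table needs columns chrom, length")
        return cls(dict(zip(df["chrom"], df["length"].astype(int))))


@dataclass(frozen=True)
class PileupRead:
    base: str
    base_quality: int
    map_quality: int
    library_udg: str  # "udg" or "non_udg"

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise PanelError(f"pileup read base {self.base!r} not in {BASES}")
        if self.base_quality < 0 or self.map_quality < 0:
            raise PanelError("pileup read qualities must be >= 0")
        if self.library_udg not in ("udg", "non_udg"):
            raise PanelError(f"library_udg must be 'udg' or 'non_udg', got {self.library_udg!r}")


@dataclass
class PileupSite:
    """Reads covering one site for one individual."""

    chrom: str
    pos: int
    reads: list[PileupRead] = field(default_factory=list)


class GenotypePanel:
    """Sites x individuals allele-coded genotype matrix.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom, pos, ref, alt`` (1-based positions) and
        optionally ``effect`` and ``gene``. Biallelic SNVs only.
    calls
        int8 array of shape ``(n_sites, n_individuals, 2)`` with values
        0 (ref allele), 1 (alt allele), -1 (missing), -2 (absent slot for
        haploid-mode individuals).
    individuals
        Ordered individual metadata; ids must be unique.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        calls: np.ndarray,
        individuals: Sequence[IndividualMeta],
    ) -> None:
        self.sites = sites.reset_index(drop=True)
        self.calls = np.asarray(calls, dtype=np.int8)
        self.individuals = list(individuals)
        self._validate()

    # -- basic shape & lookup ------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def index_of(self, ind_id: str) -> int:
        try:
            return self.ids.index(ind_id)
        except ValueError:
            raise KeyError(f"individual {ind_id!r} not in panel") from None

    def indices_of(self, ind_ids: Iterable[str]) -> np.ndarray:
        return np.array([self.index_of(i) for i in ind_ids], dtype=int)

    def ids_in_group(self, group: str) -> list[str]:
        return [ind.id for ind in self.individuals if ind.group == group]

    def ids_with_role(self, role: str) -> list[str]:
        return [ind.id for ind in self.individuals if ind.role == role]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.group)
        return list(seen)

    # -- invariants ----------------------------------------------------------

    def _validate(self) -> None:
        required = {"chrom", "pos", "ref", "alt"}
        if not required.issubset(self.sites.columns):
            raise PanelError(f"sites table needs columns {sorted(required)}")
        if self.calls.shape != (self.n_sites, self.n_individuals, 2):
            raise PanelError(
                f"calls shape {self.calls.shape} != "
                f"({self.n_sites}, {self.n_individuals}, 2)"
            )
        ids = self.ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate individual id(s): {', '.join(dupes)}")
        if self.n_sites:
            ref = self.sites["ref"].to_numpy()
            alt = self.sites["alt"].to_numpy()
            bad = [
                i
                for i in range(self.n_sites)
                if ref[i] not in BASES or alt[i] not in BASES or ref[i] == alt[i]
            ]
            if bad:
                row = self.sites.iloc[bad[0]]
                raise PanelError(
                    f"site {row['chrom']}:{row['pos']} is not a biallelic SNV "
                    f"({row['ref']}/{row['alt']})"
                )
            for chrom, sub in self.sites.groupby("chrom", sort=False):
                pos = sub["pos"].to_numpy()
                if np.any(np.diff(pos) <= 0):
                    raise PanelError(
                        f"positions not strictly increasing on chromosome {chrom}"
                    )

    def check_chromosomes(self, chrom_table: ChromTable) -> None:
        unknown = sorted(set(self.sites["chrom"]) - set(chrom_table.lengths))
        if unknown:
            raise PanelError(
                f"chromosome(s) {', '.join(unknown)} not present in chromosome table"
            )

    # -- derived views -------------------------------------------------------

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per site x individual: (#alt alleles called, #called alleles)."""
        called = self.calls >= 0
        n_called = called.sum(axis=2)
        n_alt = ((self.calls == ALLELE_ALT) & called).sum(axis=2)
        return n_alt, n_called

    def subset_individuals(self, ind_ids: Sequence[str]) -> "GenotypePanel":
        idx = self.indices_of(ind_ids)
        return GenotypePanel(
            self.sites.copy(), self.calls[:, idx, :], [self.individuals[i] for i in idx]
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask, dtype=bool)
        return GenotypePanel(
            self.sites.loc[mask].reset_index(drop=True),
            self.calls[mask],
            list(self.individuals),
        )

    def with_individuals(self, individuals: Sequence[IndividualMeta]) -> "GenotypePanel":
        return GenotypePanel(self.sites.copy(), self.calls.copy(), individuals)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<GenotypePanel {self.n_sites} sites x {self.n_individuals} individuals>"
        )


def is_transition(ref: str, alt: str) -> bool:
    """True iff {ref, alt} is a purine<->purine or pyrimidine<->pyrimidine pair.

    Transitions (A<->G, C<->T) are the substitution classes mimicked by
    post-mortem cytosine deamination, hence masked in non-UDG ancient data.
    """
    if ref not in BASES or alt not in BASES:
        raise PanelError(f"is_transition needs single bases, got {ref!r}/{alt!r}")
    if ref == alt:
        raise PanelError("is_transition needs two distinct bases")
    return {ref, alt} in ({"A", "G"}, {"C", "T"})


def transition_mask(sites: pd.DataFrame) -> np.ndarray:
    """Boolean per-site mask of transition (A/G or C/T) sites."""
    ref = sites["ref"].to_numpy()
    alt = sites["alt"].to_numpy()
    pur = (ref == "A") & (alt == "G") | (ref == "G") & (alt == "A")
    pyr = (ref == "C") & (alt == "T") | (ref == "T") & (alt == "C")
    return pur | pyr


__all__ = [
    "ALLELE_ABSENT",
    "ALLELE_ALT",
    "ALLELE_MISSING",
    "ALLELE_REF",
    "BASES",
    "ChromTable",
    "EFFECT_CLASSES",
    "GenotypePanel",
    "IndividualMeta",
    "PanelError",
    "PileupRead",
    "PileupSite",
    "is_transition",
    "transition_mask",
]
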