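"""Genotype-level ancient-DNA preparation.

Pseudohaploidization draws one random sequencing read per site per individual
(minimum base and mapping quality 30 by default) and codes its allele as the
hemizygous genotype. Post-mortem cytosine deamination mimics transitions, so
for individuals with only non-UDG-treated libraries all transition sites are
coded missing; for individuals with both library types, only UDG-library reads
are sampled at transition sites while transversion sites draw from all passing
reads regardless of library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    ALLELE_ABSENT,
    ALLELE_MISSING,
    GenotypePanel,
    IndividualMeta,
    PanelError,
    PileupSite,
    is_transition,
)


@dataclass
class PrepConfig:
    """Quality thresholds and sampling policy for pseudohaploidization."""

    min_base_quality: int = 30
    min_map_quality: int = 30
    seed: int = 0
    #: disable only to demonstrate deamination bias; leave on for analysis
    mask_transitions: bool = True

    def __post_init__(self) -> None:
        if self.min_base_quality < 0 or self.min_map_quality < 0:
            raise PanelError("quality thresholds must be >= 0")


@dataclass
class SexCallResult:
    """X/autosome (and optional Y/autosome) coverage ratios and the sex call."""

    ratio_x_aut: float
    ratio_y_aut: float | None
    call: str  # "XX", "XY" or "unknown"
    xx_min: float = 0.8
    xy_max: float = 0.6


def _passing_reads(site: PileupSite, ref: str, alt: str, cfg: PrepConfig) -> list:
    return [
        r
        for r in site.reads
        if r.base_quality >= cfg.min_base_quality
        and r.map_quality >= cfg.min_map_quality
        and r.base in (ref, alt)
    ]


def pseudohaploid_call(
    site: PileupSite,
    site_alleles: tuple[str, str],
    cfg: PrepConfig,
    rng: np.random.Generator,
    udg_mode: str = "udg",
) -> str | None:
    """Draw one allele for one individual at one site; ``None`` means missing.

    The draw is uniform over reads passing both quality thresholds whose base
    matches ref or alt. Transition sites are missing under ``udg_mode=
    'non_udg'`` and restricted to UDG-library reads under ``'mixed'``.
    """
    ref, alt = site_alleles
    transition = is_transition(ref, alt)
    reads = _passing_reads(site, ref, alt, cfg)
    if transition and cfg.mask_transitions:
        if udg_mode == "non_udg":
            return None
        if udg_mode == "mixed":
            reads = [r for r in reads if r.library_udg == "udg"]
    if not reads:
        return None
    return reads[int(rng.integers(len(reads)))].base


def determine_sex(
    cov_x: float,
    cov_autosome: float,
    cov_y: float | None = None,
    xx_min: float = 0.8,
    xy_max: float = 0.6,
) -> SexCallResult:
    """Assign genetic sex from the X/autosome coverage ratio.

    An individual with two X chromosomes is expected at a ratio near 1, one
    with a single X near 0.5. Ratios between the configurable bands yield
    ``unknown`` rather than a forced call.
    """
    if cov_autosome <= 0:
        raise PanelError("autosomal coverage must be > 0")
    if cov_x < 0 or (cov_y is not None and cov_y < 0):
        raise PanelError("coverages must be >= 0")
    rx = cov_x / cov_autosome
    ry = cov_y / cov_autosome if cov_y is not None else None
    if rx >= xx_min:
        call = "XX"
    elif rx <= xy_max:
        call = "XY"
    else:
        call = "unknown"
    return SexCallResult(ratio_x_aut=rx, ratio_y_aut=ry, call=call, xx_min=xx_min, xy_max=xy_max)


def pseudohaploidize(
    pileup: pd.DataFrame,
    sites: pd.DataFrame,
    individuals: list[IndividualMeta],
    cfg: PrepConfig,
) -> GenotypePanel:
    """Pseudohaploidize a whole panel from a long-format pileup table.

    A single seeded RNG stream is consumed in (chrom, pos, individual id)
    order, so output is byte-reproducible and invariant to input row order.
    Cells with no passing read (or masked by the transition rules) are missing.
    """
    from .datatypes import transition_mask

    rng = np.random.default_rng(cfg.seed)
    ind_index = {ind.id: j for j, ind in enumerate(individuals)}
    udg_modes = {ind.id: ind.udg_status for ind in individuals}

    calls = np.full((len(sites), len(individuals), 2), ALLELE_MISSING, dtype=np.int8)
    calls[:, :, 1] = ALLELE_ABSENT

    site_ref = sites[["chrom", "pos", "ref", "alt"]].copy()
    site_ref["site_i"] = np.arange(len(sites))
    site_ref["is_ts"] = transition_mask(sites)
    df = pileup.merge(site_ref, on=["chrom", "pos"], how="inner")
    df = df[df["individual"].isin(ind_index)]
    df = df[
        (df["bq"] >= cfg.min_base_quality)
        & (df["mq"] >= cfg.min_map_quality)
        & ((df["base"] == df["ref"]) | (df["base"] == df["alt"]))
    ]
    if cfg.mask_transitions and len(df):
        mode = df["individual"].map(udg_modes)
        drop = df["is_ts"] & (
            (mode == "non_udg") | ((mode == "mixed") & (df["library"] != "udg"))
        )
        df = df[~drop]
    if len(df):
        # canonical row order: draws depend only on pileup content, not input order
        df = df.sort_values(
            ["site_i", "individual", "base", "bq", "mq", "library"], kind="mergesort"
        ).reset_index(drop=True)
        # one uniform per read in canonical order; the max within each
        # (site, individual) cell is a uniform pick among its passing reads
        df["r"] = rng.random(len(df))
        winners = df.loc[df.groupby(["site_i", "individual"], sort=True)["r"].idxmax()]
        site_i = winners["site_i"].to_numpy()
        ind_j = winners["individual"].map(ind_index).to_numpy()
        is_alt = (winners["base"] == winners["alt"]).to_numpy()
        calls[site_i, ind_j, 0] = np.where(is_alt, 1, 0)

    metas = [
        IndividualMeta(
            id=ind.id,
            group=ind.group,
            role=ind.role,
            ploidy_mode="pseudohaploid",
            udg_status=ind.udg_status,
            sex=ind.sex,
        )
        for ind in individuals
    ]
    return GenotypePanel(sites, calls, metas)


__all__ = [
    "PrepConfig",
    "SexCallResult",
    "determine_sex",
    "pseudohaploid_call",
    "pseudohaploidize",
]
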