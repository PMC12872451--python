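"""Shared fixtures: small random dosage panels and VCF text helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sapiens_catalog.datatypes import ChromTable, IndividualMeta
from sapiens_catalog.polarize import DerivedDosage

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1,length=50000000>\n"
    "##contig=<ID=2,length=50000000>\n"
    '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotation">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf_text(path, records, samples=("s1", "s2")):
    """Write a small VCF from (chrom, pos, ref, alt, info, genotypes) tuples."""
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    lines = [VCF_HEADER + cols]
    for chrom, pos, ref, alt, info, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def make_dd(
    dosage: np.ndarray,
    called: np.ndarray | None = None,
    chroms=None,
    positions=None,
    groups=None,
    effects=None,
    genes=None,
) -> DerivedDosage:
    """Build a DerivedDosage directly from matrices for oracle tests."""
    dosage = np.asarray(dosage, dtype=np.float32)
    n_sites, n_ind = dosage.shape
    if called is None:
        called = np.where(np.isnan(dosage), 0, 2).astype(np.int8)
    if chroms is None:
        chroms = np.where(np.arange(n_sites) < n_sites // 2, "1", "2")
    if positions is None:
        pos = np.empty(n_sites, dtype=int)
        for c in np.unique(chroms):
            m = chroms == c
            pos[m] = (np.arange(m.sum()) + 1) * 1000
        positions = pos
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": "A", "alt": "C"}
    )
    if effects is not None:
        sites["effect"] = effects
    if genes is not None:
        sites["gene"] = genes
    if groups is None:
        groups = ["g"] * n_ind
    individuals = [
        IndividualMeta(id=f"i{j}", group=groups[j]) for j in range(n_ind)
    ]
    return DerivedDosage(
        sites=sites,
        dosage=dosage,
        called=np.asarray(called, dtype=np.int8),
        individuals=individuals,
        ancestral=np.zeros(n_sites, dtype=np.int8),
    )


def random_dd(rng: np.random.Generator, n_sites=200, n_ind=12, missing=0.1) -> DerivedDosage:
    """Random diploid dosage matrix with missingness over two chromosomes."""
    dosage = rng.integers(0, 3, size=(n_sites, n_ind)).astype(np.float32)
    mask = rng.random((n_sites, n_ind)) < missing
    dosage[mask] = np.nan
    return make_dd(dosage)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def chrom_table():
    return ChromTable({"1": 50_000_000, "2": 50_000_000})
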