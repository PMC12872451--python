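"""Coalescent backend for divergence-time validation.

The drift-cascade generator has no linkage and no explicit time axis below the
branch level, so split-time recovery is exercised against a standard
coalescent simulation instead: two diploid individuals sampled from two
populations that split a known number of generations ago, with recombination
and infinite-sites mutations. The simulation truth (the split time) is the
quantity :func:`sapiens_catalog.popgen.estimate_divergence` must recover.
"""

from __future__ import annotations

import msprime
import numpy as np

from .datatypes import ChromTable


def simulate_split_pair(
    split_generations: float,
    ne: float = 10_000.0,
    ne_ancestral: float | None = None,
    chrom_length: float = 25_000_000.0,
    n_chrom: int = 2,
    mutation_rate: float = 1.45e-8,
    recombination_rate: float = 1e-8,
    seed: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, ChromTable]:
    """Simulate one diploid from each of two populations split T generations ago.

    ``split_generations = 0`` samples both individuals from a single
    population (the null of no divergence). Chromosomes are independent
    replicates. Returns perfectly polarized derived dosages for the two
    individuals plus per-site chromosome labels, 1-based positions, and the
    chromosome table.

    Dosages are derived-allele counts (0/1/2) read off the tree sequence, i.e.
    polarization is exact, matching the great-ape-consensus ideal.
    """
    if ne_ancestral is None:
        ne_ancestral = ne
    demography = msprime.Demography()
    if split_generations > 0:
        demography.add_population(name="A", initial_size=ne)
        demography.add_population(name="B", initial_size=ne)
        demography.add_population(name="ANC", initial_size=ne_ancestral)
        demography.add_population_split(
            time=split_generations, derived=["A", "B"], ancestral="ANC"
        )
        samples = [
            msprime.SampleSet(1, population="A", ploidy=2),
            msprime.SampleSet(1, population="B", ploidy=2),
        ]
    else:
        demography.add_population(name="A", initial_size=ne)
        samples = [msprime.SampleSet(2, population="A", ploidy=2)]

    ss = np.random.SeedSequence(seed)
    dos1, dos2, chroms, positions = [], [], [], []
    lengths: dict[str, int] = {}
    for c, child in enumerate(ss.spawn(n_chrom), start=1):
        anc_seed, mut_seed = (int(s) % (2**31 - 2) + 1 for s in child.generate_state(2))
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demography,
            sequence_length=chrom_length,
            recombination_rate=recombination_rate,
            random_seed=anc_seed,
        )
        mts = msprime.sim_mutations(
            ts,
            rate=mutation_rate,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=mut_seed,
        )
        chrom_name = f"c{c}"
        lengths[chrom_name] = int(chrom_length)
        for var in mts.variants():
            derived = (var.genotypes != 0).astype(int)
            dos1.append(int(derived[0] + derived[1]))
            dos2.append(int(derived[2] + derived[3]))
            chroms.append(chrom_name)
            positions.append(int(np.floor(var.site.position)) + 1)
    return (
        np.array(dos1, dtype=float),
        np.array(dos2, dtype=float),
        np.array(chroms),
        np.array(positions, dtype=int),
        ChromTable(lengths),
    )


__all__ = ["simulate_split_pair"]
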