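"""Readers and writers: VCF 4.2, panel metadata TSV, pileup TSV, output tables.

All tabular outputs are TSV with a header line, optionally preceded by ``#``
comment lines carrying provenance (command, seed, version).
"""

from __future__ import annotations

import io as _stdio
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import __version__
from .datatypes import (
    ALLELE_ABSENT,
    ALLELE_MISSING,
    BASES,
    ChromTable,
    GenotypePanel,
    IndividualMeta,
    PanelError,
    PileupRead,
    PileupSite,
)

logger = logging.getLogger(__name__)

# SnpEff-style terms mapped onto the coarse effect classes used downstream.
_MISSENSE_TERMS = (
    "missense_variant",
    "stop_gained",
    "stop_lost",
    "start_lost",
)
_SYNONYMOUS_TERMS = ("synonymous_variant", "stop_retained_variant", "start_retained")


def classify_effect(ann: str | None) -> str:
    """Map a SnpEff-style annotation string to an effect class.

    ``missense_like`` covers amino acid-altering consequences (missense and
    stop/start gain/loss); ``synonymous_like`` covers protein-silent coding
    changes; anything else annotated is ``other``; no annotation is
    ``unannotated``.
    """
    if ann is None or ann == "" or ann == ".":
        return "unannotated"
    if any(term in ann for term in _MISSENSE_TERMS):
        return "missense_like"
    if any(term in ann for term in _SYNONYMOUS_TERMS):
        return "synonymous_like"
    return "other"


def _gene_from_ann(ann: str | None) -> str:
    """Gene symbol from the first entry of a SnpEff ANN field (4th '|' field)."""
    if not ann or ann == ".":
        return ""
    first = ann.split(",")[0]
    fields = first.split("|")
    return fields[3] if len(fields) > 3 else ""


def read_vcf(
    path,
    effect_field_name: str = "ANN",
    chrom_table: ChromTable | None = None,
) -> GenotypePanel:
    """Read a multi-sample VCF into a :class:`GenotypePanel`.

    Multiallelic records and indels are dropped (with a logged count). The
    optional SnpEff-compatible annotation field is parsed into per-site effect
    classes and gene symbols. Phase is ignored. Haploid genotype entries are
    stored in the first allele slot with the second slot marked absent.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows: list[tuple] = []
    calls: list[np.ndarray] = []
    n_dropped = 0
    n_records = 0
    for rec_i, variant in enumerate(vcf, start=1):
        n_records += 1
        ref, alts = variant.REF, variant.ALT
        if (
            len(alts) != 1
            or len(ref) != 1
            or len(alts[0]) != 1
            or ref not in BASES
            or alts[0] not in BASES
        ):
            n_dropped += 1
            continue
        if chrom_table is not None and variant.CHROM not in chrom_table:
            raise PanelError(
                f"{path}: record {rec_i} ({variant.CHROM}:{variant.POS}): "
                f"unknown chromosome {variant.CHROM!r}"
            )
        ann = variant.INFO.get(effect_field_name) if effect_field_name else None
        row_calls = np.full((len(samples), 2), ALLELE_MISSING, dtype=np.int8)
        for s_i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # last element is the phase flag
            if len(alleles) == 1:
                row_calls[s_i, 1] = ALLELE_ABSENT
                a = alleles[0]
                row_calls[s_i, 0] = a if a in (0, 1) else ALLELE_MISSING
            else:
                for slot in (0, 1):
                    a = alleles[slot]
                    row_calls[s_i, slot] = a if a in (0, 1) else ALLELE_MISSING
        rows.append(
            (
                variant.CHROM,
                variant.POS,
                ref,
                alts[0],
                classify_effect(ann),
                _gene_from_ann(ann),
            )
        )
        calls.append(row_calls)
    if n_dropped:
        logger.info("%s: %d record(s) dropped (multiallelic or indel)", path, n_dropped)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "effect", "gene"])
    call_arr = (
        np.stack(calls, axis=0)
        if calls
        else np.zeros((0, len(samples), 2), dtype=np.int8)
    )
    individuals = [IndividualMeta(id=s, group=s) for s in samples]
    panel = GenotypePanel(sites, call_arr, individuals)
    panel.dropped_records = n_dropped  # type: ignore[attr-defined]
    panel.input_records = n_records  # type: ignore[attr-defined]
    return panel


def write_vcf(panel: GenotypePanel, path, chrom_table: ChromTable | None = None) -> None:
    """Write a panel as uncompressed VCF 4.2 (GT only, plus ANN when present)."""
    has_effect = "effect" in panel.sites.columns
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=sapiens-catalog {__version__}\n")
        if chrom_table is not None:
            for chrom, length in chrom_table.lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in dict.fromkeys(panel.sites["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
        if has_effect:
            fh.write(
                '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotation">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.ids)
            + "\n"
        )
        effects = panel.sites["effect"].to_numpy() if has_effect else None
        genes = (
            panel.sites["gene"].fillna("").to_numpy()
            if "gene" in panel.sites.columns
            else None
        )
        for i, row in enumerate(panel.sites.itertuples(index=False)):
            info = "."
            if effects is not None and effects[i] != "unannotated":
                term = {
                    "missense_like": "missense_variant",
                    "synonymous_like": "synonymous_variant",
                    "other": "intergenic_region",
                }[effects[i]]
                gene = genes[i] if genes is not None else ""
                info = f"ANN={row.alt}|{term}|MODIFIER|{gene}"
            gts = []
            for j in range(panel.n_individuals):
                a0, a1 = panel.calls[i, j]
                s0 = "." if a0 == ALLELE_MISSING else str(int(a0))
                if a1 == ALLELE_ABSENT:
                    gts.append(s0)
                else:
                    s1 = "." if a1 == ALLELE_MISSING else str(int(a1))
                    gts.append(f"{s0}/{s1}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_effects_tsv(path) -> pd.DataFrame:
    """Sidecar effect annotation: columns chrom, pos, effect, gene."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = {"chrom", "pos", "effect"}
    if not required.issubset(df.columns):
        raise PanelError(f"{path}: effects sidecar needs columns {sorted(required)}")
    if "gene" not in df.columns:
        df["gene"] = ""
    return df


def apply_effects(panel: GenotypePanel, effects: pd.DataFrame) -> GenotypePanel:
    """Join a sidecar effect table onto the panel's site table."""
    sites = panel.sites.drop(columns=["effect", "gene"], errors="ignore")
    merged = sites.merge(
        effects[["chrom", "pos", "effect", "gene"]], on=["chrom", "pos"], how="left"
    )
    merged["effect"] = merged["effect"].fillna("unannotated")
    merged["gene"] = merged["gene"].fillna("")
    return GenotypePanel(merged, panel.calls, panel.individuals)


# -- panel metadata ----------------------------------------------------------

PANEL_COLUMNS = ["id", "group", "role", "ploidy_mode", "udg_status", "sex"]


def read_panel(path) -> list[IndividualMeta]:
    """Read individual metadata from a TSV with header id/group/role/...

    Raises on duplicate ids and on unknown role/ploidy/UDG values.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"id", "group", "role", "ploidy_mode", "udg_status"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"{path}: panel table missing column(s) {sorted(missing)}")
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise PanelError(f"{path}: duplicate individual id(s): {', '.join(sorted(set(dupes)))}")
    metas = []
    for row in df.itertuples(index=False):
        metas.append(
            IndividualMeta(
                id=row.id,
                group=row.group,
                role=row.role,
                ploidy_mode=row.ploidy_mode,
                udg_status=row.udg_status,
                sex=getattr(row, "sex", "") or "unknown",
            )
        )
    return metas


def write_panel(individuals: Sequence[IndividualMeta], path, comments: Iterable[str] = ()) -> None:
    df = pd.DataFrame(
        [
            (i.id, i.group, i.role, i.ploidy_mode, i.udg_status, i.sex)
            for i in individuals
        ],
        columns=PANEL_COLUMNS,
    )
    write_table(df, path, comments=comments)


# -- pileups -----------------------------------------------------------------

PILEUP_COLUMNS = ["chrom", "pos", "individual", "base", "bq", "mq", "library"]


def read_pileup(path) -> pd.DataFrame:
    """Read a long-format pileup TSV (one row per read)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise PanelError(f"{path}: pileup table missing column(s) {sorted(missing)}")
    return df


def pileup_sites(df: pd.DataFrame) -> Iterable[tuple[str, PileupSite]]:
    """Yield (individual_id, PileupSite) groups from a long-format pileup table."""
    for (chrom, pos, ind), sub in df.groupby(["chrom", "pos", "individual"], sort=True):
        reads = [
            PileupRead(r.base, int(r.bq), int(r.mq), r.library)
            for r in sub.itertuples(index=False)
        ]
        yield ind, PileupSite(chrom=chrom, pos=int(pos), reads=reads)


# -- generic tables & trees --------------------------------------------------

def provenance_comments(command: str = "", seed: int | None = None) -> list[str]:
    out = [f"version: sapiens-catalog {__version__}"]
    if command:
        out.insert(0, f"command: {command}")
    if seed is not None:
        out.append(f"seed: {seed}")
    return out


def write_table(records, path, comments: Iterable[str] = ()) -> None:
    """Write records (DataFrame or list of dicts) as a commented TSV."""
    if records is None:
        raise PanelError("write_table: records must not be None")
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    buf = _stdio.StringIO()
    for line in comments:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_newick(newick: str, path) -> None:
    """Write a newick tree string (terminating ';' added if absent)."""
    text = newick.strip()
    if not text.endswith(";"):
        text += ";"
    Path(path).write_text(text + "\n")
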