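"""Access to the packaged reference fixtures.

The distribution tables ship as literal TSV transcriptions; the
reference trees encode the nested row structure of those tables, with
polytomies wherever relative branching order is not asserted.

Rows naming higher groups (e.g. ``Obazoa`` in the eukaryote table, or
``FCB_group`` in the prokaryote table) correspond to *internal* nodes
of the reference trees and are treated by the reconstruction module as
clade-level observations.
"""

from __future__ import annotations

from importlib import resources

from . import profiles, taxa
from .profiles import (ABSENT, EIGHT_FAMILIES, GENERIC_FAMILY, PhyleticMatrix,
                       merge, read_matrix)

TABLE_NAMES = ("table1", "table2", "table3", "table5", "table6")
TREE_NAMES = ("eukaryota", "prokaryota", "combined")

#: Supergroup-level named ancestors of the eukaryote tree.
SUPERGROUPS = ("Diaphoretickes", "Amorphea", "Excavata")

#: Reporting rows of the supergroup ancestral-state table, in order.
TABLE5_NODES = ("Diaphoretickes", "Amorphea", "CRuMs", "Ancyromonadida",
                "Malawimonadida", "Discoba", "Metamonada", "LECA")

#: Reporting rows of the deep-ancestor table, in order.
TABLE6_NODES = ("LECA", "FECA", "Alphaproteobacteria", "Cyanobacteria",
                "Deltaproteobacteria", "Archaea", "LUCA")


def _data(name: str) -> str:
    return (resources.files("phyprof") / "data" / name).read_text(encoding="utf-8")


def load_table(name: str) -> PhyleticMatrix:
    if name not in TABLE_NAMES:
        raise LookupError(f"unknown table fixture {name!r}; have {TABLE_NAMES}")
    import io
    return read_matrix(io.StringIO(_data(f"{name}.tsv")))


def load_table_text(name: str) -> str:
    if name not in TABLE_NAMES:
        raise LookupError(f"unknown table fixture {name!r}; have {TABLE_NAMES}")
    return _data(f"{name}.tsv")


def load_tree(name: str) -> taxa.TaxonomyTree:
    if name not in TREE_NAMES:
        raise LookupError(f"unknown tree fixture {name!r}; have {TREE_NAMES}")
    return taxa.read_newick(_data(f"{name}.nwk").strip())


def eukaryote_matrix() -> PhyleticMatrix:
    """Merged eukaryote distribution (coarse table + Obazoa detail)."""
    return merge(load_table("table1"), load_table("table2"))


def combined_matrix() -> PhyleticMatrix:
    """Eukaryote + prokaryote matrix used for the deep-ancestor table.

    Prokaryote rows contribute a single generic character
    (:data:`~phyprof.profiles.GENERIC_FAMILY`), taken from the
    single-domain column of the prokaryote survey: short C1A peptidases
    are the candidate progenitors of the eukaryotic families, so the
    generic character tracks them.  Because the generic character
    denotes an *undifferentiated* prokaryote-type peptidase, eukaryote
    rows are scored absent for it, and prokaryote rows are scored
    absent for the named eukaryotic families (no orthologous gene
    families exist in prokaryotes).
    """
    euk = eukaryote_matrix()
    prok = load_table("table3")
    generic = PhyleticMatrix(
        prok.taxa, [GENERIC_FAMILY],
        {(t, GENERIC_FAMILY): prok.get(t, "single_domain") for t in prok.taxa})
    combined = merge(euk, generic)
    for taxon in prok.taxa:
        for family in combined.families:
            if family != GENERIC_FAMILY:
                combined.set(taxon, family, ABSENT)
    for taxon in euk.taxa:
        combined.set(taxon, GENERIC_FAMILY, ABSENT)
    return combined


def seed_alignment(family: str) -> list[tuple[str, str]]:
    """Packaged seed alignment for a family profile as (id, residues)."""
    text = _data(f"seeds/{family}.fasta")
    records: list[tuple[str, str]] = []
    current: list[str] = []
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(current)))
            name = line[1:].split()[0]
            current = []
        else:
            current.append(line.strip())
    if name is not None:
        records.append((name, "".join(current)))
    return records
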