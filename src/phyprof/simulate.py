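"""Synthetic data with recorded ground truth.

Everything downstream is tested against this module: binary gene
content evolving on a rooted species tree under a gain/loss jump
process, protein sequences evolving by Poisson substitution along the
same tree (catalytic triad columns never mutate), rare cross-clade
transfers, and the named benchmark regimes.

The substitution model replaces a residue with one of the other 19
uniformly, so observed p-distances saturate like a 20-state
Jukes-Cantor process; the Poisson correction recovers path lengths to
within a few percent at moderate divergence.

Named regimes (mixture settings live here as configuration data, so
tests read the truth from config rather than from code):

* ``archaea_default`` — a clade of "archaeal" single-gene sequences of
  which a configured fraction was acquired from deeply diverged
  "bacterial" donor lineages.
* ``five_hgt_cases`` — five independent bacteria-to-eukaryote
  transfers with distinct donor clades, mirrored on a gene tree.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import fixtures, genetree
from .ancrec import GAIN, LOSS, AncestralStateMap, Event, node_ids
from .classify import AMINO_ACIDS, SequenceRecord
from .profiles import ABSENT, EIGHT_FAMILIES, PRESENT, PhyleticMatrix
from .taxa import Node, TaxonomyTree

#: Families whose zymogens carry the N-terminal inhibitory propeptide.
I29_FAMILIES = ("cathL", "cathH", "cathF", "p26_29")

I29_LENGTH = 60
MATURE_LENGTH = 150
#: Catalytic triad positions within the mature domain (0-based).
TRIAD_POSITIONS = (25, 120, 142)

#: Mixture and size settings for the named benchmark regimes.
NAMED_CONFIGS: dict[str, dict] = {
    "archaea_default": {
        "n": 200,
        "transferred_fraction": 0.56,
        "native_divergence": (0.1, 0.3),
        "donor_divergence": 0.5,
        "transfer_divergence": 0.05,
        "seed": 42,
    },
    "five_hgt_cases": {
        "seed": 101,
        "cases": [
            {"donor": "Cyanobacteria", "recipients": [("Rotifer_A", "Metazoa"),
                                                      ("Rotifer_B", "Metazoa")]},
            {"donor": "Firmicutes", "recipients": [("Ascomycota_A", "Fungi"),
                                                   ("Ascomycota_B", "Fungi")]},
            {"donor": "Chloroflexi",
             "recipients": [("GreenAlga_A", "Chloroplastida"),
                            ("GreenAlga_B", "Chloroplastida"),
                            ("Chytrid_A", "Fungi")]},
            {"donor": "Streptomycetes", "recipients": [("Ascomycota_C", "Fungi")]},
            {"donor": "Bacteroidetes", "recipients": [("Dinoflagellate_A", "SAR"),
                                                      ("Dinoflagellate_B", "SAR")]},
        ],
        "recipient_clades": ["Metazoa", "Fungi", "Chloroplastida", "SAR"],
        "natives_per_clade": 3,
        "clade_divergence": 0.5,
        "within_clade_divergence": 0.1,
        "donor_base_divergence": 0.4,
        "transfer_stem_divergence": 0.15,
        "post_transfer_divergence": 0.55,
        "donor_ref_divergence": 0.05,
    },
}

__all__ = [
    "SimConfig",
    "Transfer",
    "yule_tree",
    "family_archetype",
    "i29_archetype",
    "mutate",
    "simulate_content",
    "simulate_sequences",
    "seed_alignment",
    "archaea_default",
    "five_hgt_cases",
    "make_fixture",
    "NAMED_CONFIGS",
    "I29_FAMILIES",
    "TRIAD_POSITIONS",
]


@dataclass(frozen=True)
class Transfer:
    family: str
    donor: str      # donor leaf taxon
    recipient: str  # recipient leaf taxon
    divergence: float = 0.05  # extra divergence after the jump


@dataclass
class SimConfig:
    seed: int
    n_leaves: int = 16
    tree_height: float = 1.0
    species_tree: Optional[TaxonomyTree] = None
    families: Sequence[str] = EIGHT_FAMILIES
    gain_rate: float = 0.05
    loss_rate: float = 0.5
    subst_rate: float = 0.3   # substitutions / site / unit branch length
    transfers: list[Transfer] = field(default_factory=list)

    def tree(self, rng: np.random.Generator) -> TaxonomyTree:
        if self.species_tree is not None:
            return self.species_tree
        return yule_tree(self.n_leaves, rng, height=self.tree_height)


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------


def yule_tree(n_leaves: int, rng: np.random.Generator,
              height: float = 1.0) -> TaxonomyTree:
    """Pure-birth tree with ``n_leaves`` tips, scaled to the given height."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    root = Node("N0")
    tips = [root]
    birth_times = {id(root): 0.0}
    now = 0.0
    counter = 0
    while len(tips) < n_leaves:
        now += float(rng.exponential(1.0 / len(tips)))
        i = int(rng.integers(len(tips)))
        parent = tips.pop(i)
        parent.length = now - birth_times[id(parent)] if parent.parent else None
        if parent.parent is not None:
            parent.length = now - birth_times[id(parent)]
        for _ in range(2):
            counter += 1
            child = Node(f"N{counter}")
            parent.add_child(child)
            birth_times[id(child)] = now
            tips.append(child)
    end = now + float(rng.exponential(1.0 / len(tips)))
    for k, tip in enumerate(tips):
        tip.length = end - birth_times[id(tip)]
    # scale to requested height (depth below the root split) and name leaves
    depth = end - birth_times[id(root.children[0])]
    scale = height / depth if depth > 0 else 1.0
    tree = TaxonomyTree(root)
    leaf_no = 0
    for node in tree.preorder():
        if node.length is not None:
            node.length = max(node.length * scale, 1e-6)
        if node.is_leaf:
            leaf_no += 1
            node.label = f"T{leaf_no}"
    return tree


# ---------------------------------------------------------------------------
# Gene-content evolution
# ---------------------------------------------------------------------------


def simulate_content(config: SimConfig
                     ) -> tuple[PhyleticMatrix, AncestralStateMap, TaxonomyTree]:
    """Evolve binary family content down the tree; return truth alongside.

    Each family starts present at the root and evolves as a two-state
    jump process with the configured gain/loss rates; every jump is
    recorded as a branch-mapped event.
    """
    rng = np.random.default_rng(config.seed)
    tree = config.tree(rng)
    ids = node_ids(tree)
    truth = AncestralStateMap(method="truth", families=list(config.families))
    cells: dict[tuple[str, str], str] = {}
    for family in config.families:
        states: dict[int, int] = {}
        for node in tree.preorder():
            if node.parent is None:
                states[id(node)] = 1
            else:
                state = states[id(node.parent)]
                t = node.branch_length()
                elapsed = 0.0
                while True:
                    rate = config.loss_rate if state == 1 else config.gain_rate
                    if rate <= 0:
                        break
                    wait = float(rng.exponential(1.0 / rate))
                    if elapsed + wait > t:
                        break
                    elapsed += wait
                    state = 1 - state
                    truth.events.append(Event(
                        parent=ids[id(node.parent)], child=ids[id(node)],
                        family=family, kind=GAIN if state == 1 else LOSS))
                states[id(node)] = state
            truth.states[(ids[id(node)], family)] = (
                PRESENT if states[id(node)] else ABSENT)
            if node.is_leaf:
                cells[(node.label, family)] = (
                    PRESENT if states[id(node)] else ABSENT)
        truth.gain_node[family] = ids[id(tree.root)]
    matrix = PhyleticMatrix([l for l in tree.leaf_labels],
                            list(config.families), cells)
    return matrix, truth, tree


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def _family_rng(family: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(family.encode()) + salt)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def i29_archetype() -> str:
    return _random_protein(I29_LENGTH, _family_rng("I29"))


def family_archetype(family: str) -> tuple[str, tuple[int, ...]]:
    """Deterministic archetype sequence and its protected positions.

    The mature domain carries the catalytic triad (Cys/His/Asn) at
    fixed columns; zymogen families get the shared propeptide segment
    prepended, and the long type-1 family a C-terminal extension
    placing its total length within 500-650 residues.
    """
    rng = _family_rng(family)
    mature = list(_random_protein(MATURE_LENGTH, rng))
    c, h, n = TRIAD_POSITIONS
    mature[c], mature[h], mature[n] = "C", "H", "N"
    offset = 0
    parts = []
    if family in I29_FAMILIES:
        parts.append(i29_archetype())
        offset = I29_LENGTH
    parts.append("".join(mature))
    if family == "type1_long":
        total = int(rng.integers(500, 651))
        parts.append(_random_protein(total - sum(len(p) for p in parts), rng))
    protected = tuple(offset + p for p in TRIAD_POSITIONS)
    return "".join(parts), protected


def mutate(seq: str, divergence: float, rng: np.random.Generator,
           protected: Sequence[int] = ()) -> str:
    """Poisson substitution: expected ``divergence`` events per free site."""
    free = [i for i in range(len(seq)) if i not in set(protected)]
    n_events = int(rng.poisson(divergence * len(free)))
    out = list(seq)
    for _ in range(n_events):
        pos = free[int(rng.integers(len(free)))]
        current = out[pos]
        choices = [a for a in AMINO_ACIDS if a != current]
        out[pos] = choices[int(rng.integers(19))]
    return "".join(out)


def simulate_sequences(config: SimConfig, content: PhyleticMatrix,
                       tree: TaxonomyTree,
                       ) -> tuple[list[SequenceRecord], dict[str, str]]:
    """One protein per (leaf, present family), evolved along the tree.

    Returns the records plus an origin map (sequence id ->
    ``"vertical"`` or ``"hgt:<donor taxon>"``).  Transfers replace the
    recipient's copy with a mutated copy of the donor-leaf sequence.
    """
    rng = np.random.default_rng(config.seed + 7919)
    records: list[SequenceRecord] = []
    origins: dict[str, str] = {}
    leaf_seqs: dict[tuple[str, str], str] = {}
    for family in content.families:
        archetype, protected = family_archetype(family)
        seqs: dict[int, str] = {}
        for node in tree.preorder():
            if node.parent is None:
                seqs[id(node)] = archetype
            else:
                d = config.subst_rate * node.branch_length()
                seqs[id(node)] = mutate(seqs[id(node.parent)], d, rng, protected)
            if node.is_leaf:
                leaf_seqs[(node.label, family)] = seqs[id(node)]

    for transfer in config.transfers:
        donor_seq = leaf_seqs[(transfer.donor, transfer.family)]
        _, protected = family_archetype(transfer.family)
        leaf_seqs[(transfer.recipient, transfer.family)] = mutate(
            donor_seq, transfer.divergence, rng, protected)

    transferred = {(t.recipient, t.family): t.donor for t in config.transfers}
    for (taxon, family), seq in leaf_seqs.items():
        if content.get(taxon, family) != PRESENT:
            continue
        rec_id = f"{taxon}|{family}"
        records.append(SequenceRecord(id=rec_id, taxon=taxon, residues=seq,
                                      true_family=family))
        donor = transferred.get((taxon, family))
        origins[rec_id] = "vertical" if donor is None else f"hgt:{donor}"
    return records, origins


def seed_alignment(family: str, n_seeds: int = 9,
                   divergence: float = 0.6) -> list[tuple[str, str]]:
    """Deterministic aligned seed set for profile construction.

    Divergence is high enough that only the protected catalytic
    columns remain perfectly conserved, which is what lets the profile
    builder locate the triad unambiguously.
    """
    if family == "I29":
        archetype, protected = i29_archetype(), ()
    else:
        archetype, protected = family_archetype(family)
    rng = _family_rng(family, salt=977)
    rows = [(f"{family}_seed1", archetype)]
    for k in range(2, n_seeds + 1):
        rows.append((f"{family}_seed{k}",
                     mutate(archetype, divergence, rng, protected)))
    # only the catalytic machinery may be perfectly conserved: break any
    # column that survived untouched in every seed by chance
    protected_set = set(protected)
    last_name, last_seq = rows[-1]
    last = list(last_seq)
    for col in range(len(archetype)):
        if col in protected_set:
            continue
        if all(seq[col] == archetype[col] for _, seq in rows):
            choices = [a for a in AMINO_ACIDS if a != archetype[col]]
            last[col] = choices[int(rng.integers(19))]
    rows[-1] = (last_name, "".join(last))
    return rows


# ---------------------------------------------------------------------------
# Named regimes
# ---------------------------------------------------------------------------


@dataclass
class HgtBenchmark:
    records: list[SequenceRecord]
    clades: dict[str, str]                 # taxon -> clade
    true_transferred: set[str]             # transferred sequence ids
    tree: Optional[TaxonomyTree] = None    # gene tree (five-case fixture)
    expected_events: Optional[int] = None
    config: dict = field(default_factory=dict)


def archaea_default(seed: Optional[int] = None, n: Optional[int] = None,
                    ) -> HgtBenchmark:
    """Archaeal gene set with a configured horizontally acquired mixture."""
    cfg = dict(NAMED_CONFIGS["archaea_default"])
    if seed is not None:
        cfg["seed"] = seed
    if n is not None:
        cfg["n"] = n
    rng = np.random.default_rng(cfg["seed"])
    n = cfg["n"]
    n_transfer = round(cfg["transferred_fraction"] * n)
    native_arch = _random_protein(MATURE_LENGTH, _family_rng("archaea_native"))
    bact_arch = _random_protein(MATURE_LENGTH, _family_rng("bacteria_c1a"))

    records: list[SequenceRecord] = []
    clades: dict[str, str] = {}
    transferred: set[str] = set()
    lo, hi = cfg["native_divergence"]
    for i in range(n - n_transfer):
        taxon = f"Arch_sp{i + 1}"
        d = float(rng.uniform(lo, hi))
        rec = SequenceRecord(id=f"arch_native_{i + 1}", taxon=taxon,
                             residues=mutate(native_arch, d, rng))
        records.append(rec)
        clades[taxon] = "Archaea"
    for j in range(n_transfer):
        taxon = f"Arch_sp{n - n_transfer + j + 1}"
        donor_taxon = f"Bact_donor{j + 1}"
        donor_lineage = mutate(bact_arch, cfg["donor_divergence"], rng)
        donor_ref = mutate(donor_lineage, cfg["transfer_divergence"], rng)
        acquired = mutate(donor_lineage, cfg["transfer_divergence"], rng)
        rec = SequenceRecord(id=f"arch_hgt_{j + 1}", taxon=taxon,
                             residues=acquired)
        records.append(rec)
        records.append(SequenceRecord(id=f"bact_ref_{j + 1}", taxon=donor_taxon,
                                      residues=donor_ref))
        clades[taxon] = "Archaea"
        clades[donor_taxon] = "Bacteria"
        transferred.add(rec.id)
    return HgtBenchmark(records=records, clades=clades,
                        true_transferred=transferred, config=cfg)


def five_hgt_cases(seed: Optional[int] = None) -> HgtBenchmark:
    """Five independent bacteria-to-eukaryote transfers plus natives."""
    cfg = dict(NAMED_CONFIGS["five_hgt_cases"])
    if seed is not None:
        cfg["seed"] = seed
    rng = np.random.default_rng(cfg["seed"])
    euk_arch = _random_protein(MATURE_LENGTH, _family_rng("euk_native_c1a"))
    bact_arch = _random_protein(MATURE_LENGTH, _family_rng("bact_donor_c1a"))

    records: list[SequenceRecord] = []
    clades: dict[str, str] = {}
    transferred: set[str] = set()

    for clade in cfg["recipient_clades"]:
        base = mutate(euk_arch, cfg["clade_divergence"], rng)
        for k in range(cfg["natives_per_clade"]):
            taxon = f"{clade}_sp{k + 1}"
            rec = SequenceRecord(
                id=f"native_{clade}_{k + 1}", taxon=taxon,
                residues=mutate(base, cfg["within_clade_divergence"], rng))
            records.append(rec)
            clades[taxon] = clade

    for case in cfg["cases"]:
        donor = case["donor"]
        donor_base = mutate(bact_arch, cfg["donor_base_divergence"], rng)
        for r in range(2):
            taxon = f"{donor}_sp{r + 1}"
            rec = SequenceRecord(
                id=f"donor_{donor}_{r + 1}", taxon=taxon,
                residues=mutate(donor_base, cfg["donor_ref_divergence"], rng))
            records.append(rec)
            clades[taxon] = donor
        # one transferred ancestral copy per case: recipients diversify
        # from it, so each case forms a clade on the gene tree
        transfer_point = mutate(donor_base, cfg["transfer_stem_divergence"], rng)
        for taxon, clade in case["recipients"]:
            rec = SequenceRecord(
                id=f"hgt_{taxon}", taxon=taxon,
                residues=mutate(transfer_point,
                                cfg["post_transfer_divergence"], rng))
            records.append(rec)
            clades[taxon] = clade
            transferred.add(rec.id)

    alignment = [(r.id, r.residues) for r in records]
    tree = genetree.neighbor_joining(genetree.distance_matrix(alignment))
    return HgtBenchmark(records=records, clades=clades,
                        true_transferred=transferred, tree=tree,
                        expected_events=len(cfg["cases"]), config=cfg)


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------


def _write_fasta(records: Sequence[SequenceRecord], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def make_fixture(name: str, outdir: str | Path) -> list[Path]:
    """Write a named fixture to ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if name in fixtures.TABLE_NAMES:
        path = outdir / f"{name}.tsv"
        path.write_text(fixtures.load_table_text(name), encoding="utf-8")
        written.append(path)
    elif name in ("five_hgt_cases", "archaea_default"):
        bench = five_hgt_cases() if name == "five_hgt_cases" else archaea_default()
        fasta = outdir / f"{name}.fasta"
        _write_fasta(bench.records, fasta)
        written.append(fasta)
        clades = outdir / f"{name}_clades.tsv"
        with open(clades, "w", encoding="utf-8") as fh:
            fh.write("taxon\tclade\n")
            for taxon, clade in bench.clades.items():
                fh.write(f"{taxon}\t{clade}\n")
        written.append(clades)
        taxa_map = outdir / f"{name}_taxa.tsv"
        with open(taxa_map, "w", encoding="utf-8") as fh:
            fh.write("id\ttaxon\n")
            for rec in bench.records:
                fh.write(f"{rec.id}\t{rec.taxon}\n")
        written.append(taxa_map)
        truth = outdir / f"{name}_truth.json"
        truth.write_text(json.dumps({
            "transferred_ids": sorted(bench.true_transferred),
            "expected_events": bench.expected_events,
            "config": bench.config,
        }, indent=2, default=str), encoding="utf-8")
        written.append(truth)
        if bench.tree is not None:
            from .taxa import write_newick
            nwk = outdir / f"{name}_genetree.nwk"
            nwk.write_text(write_newick(bench.tree) + "\n", encoding="utf-8")
            written.append(nwk)
    else:
        raise LookupError(f"unknown fixture {name!r}")
    return written
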