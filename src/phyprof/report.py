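"""Pipeline orchestration, manifests, and human-readable tables.

A single JSON config drives the stages; every run writes a manifest
with input/output hashes so that deterministic stages can be verified
byte-for-byte across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

from . import ancrec, classify, fixtures, genetree, hgt, profiles, simulate, taxa

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

STAGES = ("classify", "matrix", "ancrec", "genetree", "hgt", "tables")

__all__ = ["run_pipeline", "render_ancestral_table", "load_fasta",
           "load_clades", "STAGES"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_fasta(path: str | Path,
               taxa_map: Optional[dict[str, str]] = None
               ) -> list[classify.SequenceRecord]:
    records = []
    name, chunks = None, []
    taxa_map = taxa_map or {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seq = "".join(chunks)
                    records.append(classify.SequenceRecord(
                        id=name, taxon=taxa_map.get(name, name.split("|")[0]),
                        residues=seq))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        records.append(classify.SequenceRecord(
            id=name, taxon=taxa_map.get(name, name.split("|")[0]),
            residues="".join(chunks)))
    return records


def load_clades(path: str | Path) -> dict[str, str]:
    clades = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.lower().startswith("taxon"):
            parts = header.rstrip("\n").split("\t")
            if len(parts) == 2:
                clades[parts[0]] = parts[1]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 2:
                clades[parts[0]] = parts[1]
    return clades


def render_ancestral_table(asm: ancrec.AncestralStateMap,
                           nodes: Sequence[str],
                           families: Optional[Sequence[str]] = None) -> str:
    """TSV of ancestral states (one row per node, one family per column)."""
    families = list(asm.families if families is None else families)
    cells = {}
    for node in nodes:
        for fam in families:
            try:
                cells[(node, fam)] = asm.state(node, fam)
            except KeyError as exc:
                raise LookupError(
                    f"node {node!r} was not reconstructed for {fam!r}") from exc
    matrix = profiles.PhyleticMatrix(list(nodes), families, cells)
    return profiles.write_matrix(matrix)


def _load_matrix(spec: str) -> profiles.PhyleticMatrix:
    if spec == "fixtures:eukaryote":
        return fixtures.eukaryote_matrix()
    if spec == "fixtures:combined":
        return fixtures.combined_matrix()
    if spec.startswith("fixtures:"):
        return fixtures.load_table(spec.split(":", 1)[1])
    return profiles.read_matrix(spec)


def _load_tree(spec: str) -> taxa.TaxonomyTree:
    if spec.startswith("fixtures:"):
        return fixtures.load_tree(spec.split(":", 1)[1])
    with open(spec, encoding="utf-8") as fh:
        return taxa.read_newick(fh.read().strip())


def build_default_profiles() -> list[classify.FamilyProfile]:
    """Profiles for the packaged seed alignments (eight + two families)."""
    out = []
    for family in profiles.EIGHT_FAMILIES + profiles.EXTRA_FAMILIES:
        seeds = [seq for _, seq in fixtures.seed_alignment(family)]
        out.append(classify.build_profile(seeds, family))
    return out


def build_i29_profile() -> classify.FamilyProfile:
    """Propeptide domain model; no catalytic triad to locate."""
    seeds = [seq for _, seq in fixtures.seed_alignment("I29")]
    return classify.build_profile(seeds, "I29", require_triad=False)


def run_pipeline(config: dict, outdir: str | Path) -> Path:
    """Execute the configured stages in order; write a run manifest.

    Halts on the first failing stage, retaining partial outputs and
    recording the failure cause in the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config,
        "seed": config.get("seed"),
        "stages": {},
        "outputs": {},
    }
    stages = config.get("stages", [])
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")

    state: dict = {}
    try:
        for stage in stages:
            t0 = time.perf_counter()
            _run_stage(stage, config, outdir, state)
            manifest["stages"][stage] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 4),
            }
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        _finish_manifest(manifest, outdir)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    _finish_manifest(manifest, outdir)
    return outdir


def _finish_manifest(manifest: dict, outdir: Path) -> None:
    for path in sorted(outdir.glob("*")):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest["outputs"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str), encoding="utf-8")


def _run_stage(stage: str, config: dict, outdir: Path, state: dict) -> None:
    logger.info("stage %s starting", stage)
    if stage == "classify":
        records = load_fasta(config["fasta"],
                             load_clades(config["taxa_map"])
                             if config.get("taxa_map") else None)
        profs = build_default_profiles()
        i29 = build_i29_profile()
        cfg = classify.AssignConfig(
            e_cutoff=float(config.get("e_cutoff", classify.DEFAULT_E_CUTOFF)))
        assignments = [classify.assign(r, profs, cfg, i29_profile=i29)
                       for r in records]
        state["records"] = records
        state["assignments"] = assignments
        with open(outdir / "assignments.tsv", "w", encoding="utf-8") as fh:
            fh.write("id\ttaxon\tfamily\tscore\tmargin\tevalue\t"
                     "triad_ok\thas_i29\tlength_class\n")
            for rec, a in zip(records, assignments):
                fh.write(f"{a.sequence_id}\t{rec.taxon}\t{a.family}\t"
                         f"{a.score:.2f}\t{a.margin:.2f}\t{a.evalue:.3g}\t"
                         f"{a.triad_ok}\t{a.has_i29}\t{a.length_class}\n")
    elif stage == "matrix":
        if "assignments" in state:
            pairs = [(r.taxon, a.family)
                     for r, a in zip(state["records"], state["assignments"])
                     if a.family != classify.UNCLASSIFIED]
            surveyed = list(dict.fromkeys(r.taxon for r in state["records"]))
            fams = list(dict.fromkeys(f for _, f in pairs)) or list(
                profiles.EIGHT_FAMILIES)
            matrix = profiles.matrix_from_assignments(pairs, surveyed, fams)
        else:
            matrix = _load_matrix(config["matrix"])
        state["matrix"] = matrix
        profiles.write_matrix(matrix, outdir / "matrix.tsv")
    elif stage == "ancrec":
        matrix = state.get("matrix") or _load_matrix(config["matrix"])
        tree = _load_tree(config["tree"])
        method = config.get("method", "dollo")
        if method == "dollo":
            asm = ancrec.dollo_reconstruct(matrix, tree)
        elif method == "ml":
            asm = ancrec.ml_reconstruct(matrix, tree)
        else:
            raise ValueError(f"unknown reconstruction method {method!r}")
        state["asm"], state["tree"] = asm, tree
        nodes = [ancrec.node_ids(tree)[id(n)] for n in tree.preorder()]
        (outdir / "states.tsv").write_text(
            render_ancestral_table(asm, nodes), encoding="utf-8")
        with open(outdir / "events.tsv", "w", encoding="utf-8") as fh:
            fh.write("parent\tchild\tfamily\tevent\n")
            for ev in asm.events:
                fh.write(f"{ev.parent or ''}\t{ev.child}\t{ev.family}\t"
                         f"{ev.kind}\n")
    elif stage == "genetree":
        records = state.get("records") or load_fasta(
            config["fasta"],
            load_clades(config["taxa_map"]) if config.get("taxa_map") else None)
        alignment = [(r.id, r.residues) for r in records]
        tree = genetree.neighbor_joining(genetree.distance_matrix(alignment))
        state["genetree"] = tree
        (outdir / "genetree.nwk").write_text(
            taxa.write_newick(tree) + "\n", encoding="utf-8")
    elif stage == "hgt":
        records = state.get("records") or load_fasta(
            config["fasta"],
            load_clades(config["taxa_map"]) if config.get("taxa_map") else None)
        clades = load_clades(config["clades"])
        threshold = float(config.get("threshold", hgt.DEFAULT_THRESHOLD))
        focal = config.get("focal_clade")
        if isinstance(focal, str):
            focal = [focal]
        calls, incomparable = [], 0
        for rec in records:
            if focal and clades[rec.taxon] not in focal:
                continue
            try:
                call = hgt.flag(hgt.anomaly_score(rec, records, clades),
                                threshold)
            except hgt.IncomparableError:
                incomparable += 1
                logger.info("incomparable sequence %s", rec.id)
                continue
            calls.append(call)
        gtree = state.get("genetree")
        if gtree is not None:
            taxon_of = {r.id: r.taxon for r in records}
            flagged_ids = {c.sequence_id for c in calls if c.flagged}
            calls = [hgt.assign_donor(c, gtree, clades, taxon_of, flagged_ids)
                     if c.flagged else c for c in calls]
            calls = hgt.cluster_events(calls, gtree)
        state["hgt_calls"] = calls
        with open(outdir / "hgt_calls.tsv", "w", encoding="utf-8") as fh:
            fh.write("id\trecipient\tin_identity\tout_identity\tscore\t"
                     "flagged\tdonor\tevent_id\n")
            for c in calls:
                fh.write(f"{c.sequence_id}\t{c.recipient_clade}\t"
                         f"{c.in_identity:.3f}\t{c.out_identity:.3f}\t"
                         f"{c.score:+.3f}\t{c.flagged}\t"
                         f"{c.donor_clade or ''}\t{c.event_id or ''}\n")
        native, transferred, _ = hgt.origin_fractions(calls, incomparable)
        (outdir / "hgt_summary.json").write_text(json.dumps({
            "native_fraction": native,
            "transferred_fraction": transferred,
            "incomparable": incomparable,
            "events": len({c.event_id for c in calls if c.event_id}),
        }, indent=2), encoding="utf-8")
    elif stage == "tables":
        asm = state.get("asm")
        tree = state.get("tree")
        if asm is None:
            raise ValueError("tables stage requires a prior ancrec stage")
        level = config.get("level", list(fixtures.TABLE5_NODES))
        families = config.get("families")
        (outdir / "ancestral_table.tsv").write_text(
            render_ancestral_table(asm, level, families), encoding="utf-8")
    logger.info("stage %s done", stage)
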