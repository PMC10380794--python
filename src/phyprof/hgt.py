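"""Horizontal-transfer detection by conservation anomaly.

A sequence is suspicious when its best identity to sequences *outside*
its own clade exceeds its best identity to in-clade relatives — the
alien-index family of criteria, operationalized here as the identity
differential with a tunable threshold (default 0.10; the underlying
biological criterion is qualitative, so the cut-off is explicit
configuration, not a claimed constant).

Flagged calls are grouped into independent transfer events by
single-linkage clustering: two calls join when they share a donor
clade and form a pure clade together on the gene tree.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from Bio import Align

from .classify import SequenceRecord
from .taxa import TaxonomyTree, mrca_node

DEFAULT_THRESHOLD = 0.10

__all__ = [
    "HgtCall",
    "IncomparableError",
    "identity",
    "anomaly_score",
    "flag",
    "assign_donor",
    "cluster_events",
    "origin_fractions",
]


class IncomparableError(ValueError):
    """No in-group comparator exists for the sequence."""


@dataclass(frozen=True)
class HgtCall:
    sequence_id: str
    recipient_clade: str
    in_identity: float
    out_identity: float
    score: float  # out - in
    donor_clade: Optional[str] = None
    flagged: bool = False
    event_id: Optional[int] = None


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 2.0
_aligner.mismatch_score = -1.0
_aligner.open_gap_score = -5.0
_aligner.extend_gap_score = -0.5


def identity(a: str, b: str) -> float:
    """Fraction identical over aligned residue pairs.

    Equal-length pairs are compared position-wise (the common case for
    sequences of one gene family without indels); unequal lengths fall
    back to a global DP alignment.
    """
    if len(a) == len(b):
        matches = sum(1 for x, y in zip(a, b) if x == y)
        return matches / len(a)
    alignment = _aligner.align(a, b)[0]
    matches = 0
    pairs = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for x, y in zip(a[a0:a1], b[b0:b1]):
            pairs += 1
            if x == y:
                matches += 1
    return matches / pairs if pairs else 0.0


def anomaly_score(seq: SequenceRecord,
                  db: Sequence[SequenceRecord],
                  clades: dict[str, str]) -> HgtCall:
    """Identity differential of ``seq`` against a clade-labelled database.

    In-group: same clade, different taxon (same-taxon sequences would
    self-match recent duplicates).  Out-group: any other clade.
    Raises :class:`IncomparableError` when no in-group comparator
    exists, so the caller can report the sequence unscored.
    """
    recipient = clades[seq.taxon]
    best_in = None
    best_out = None
    best_out_clade = None
    for other in db:
        if other.id == seq.id:
            continue
        clade = clades[other.taxon]
        if clade == recipient:
            if other.taxon == seq.taxon:
                continue
            ident = identity(seq.residues, other.residues)
            if best_in is None or ident > best_in:
                best_in = ident
        else:
            ident = identity(seq.residues, other.residues)
            if best_out is None or ident > best_out:
                best_out = ident
                best_out_clade = clade
    if best_in is None:
        raise IncomparableError(
            f"no in-group comparator for {seq.id!r} in clade {recipient!r}")
    if best_out is None:
        raise IncomparableError(f"no out-group sequence for {seq.id!r}")
    return HgtCall(sequence_id=seq.id, recipient_clade=recipient,
                   in_identity=best_in, out_identity=best_out,
                   score=best_out - best_in, donor_clade=best_out_clade)


def flag(call: HgtCall, threshold: float = DEFAULT_THRESHOLD) -> HgtCall:
    """Flag iff score >= threshold (boundary inclusive, documented)."""
    return replace(call, flagged=call.score >= threshold)


def assign_donor(call: HgtCall, tree: TaxonomyTree,
                 clades: dict[str, str],
                 taxon_of: dict[str, str],
                 exclude: Optional[set[str]] = None) -> HgtCall:
    """Donor clade from the gene-tree sister group of the flagged tip.

    Walking rootward from the tip, the first sister set containing
    non-recipient-clade leaves votes by majority; ties give
    ``"ambiguous"``.  ``exclude`` lists tip ids that must not vote —
    typically all flagged calls, so co-transferred sequences of other
    recipient clades do not masquerade as donors.
    """
    exclude = exclude or set()
    tip = tree.find(call.sequence_id)
    node = tip
    while node.parent is not None:
        sisters = [l for sib in node.parent.children if sib is not node
                   for l in sib.leaves()]
        labels = [clades[taxon_of[l.label]] for l in sisters
                  if l.label not in exclude
                  and clades.get(taxon_of.get(l.label, "")) not in
                  (None, call.recipient_clade)]
        if labels:
            counts: dict[str, int] = {}
            for lab in labels:
                counts[lab] = counts.get(lab, 0) + 1
            ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                return replace(call, donor_clade="ambiguous")
            return replace(call, donor_clade=ranked[0][0])
        node = node.parent
    return replace(call, donor_clade="ambiguous")


def cluster_events(calls: Sequence[HgtCall], tree: TaxonomyTree,
                   link_rule: str = "donor") -> list[HgtCall]:
    """Single-linkage clustering of flagged calls into transfer events.

    ``link_rule``:
      * ``"donor"`` (default): two calls join iff same donor clade and
        the clade spanning both tips contains only tips of same-donor
        flagged calls (joint monophyly).
      * ``"donor_recipient"``: additionally requires equal recipient
        clades.

    Returns the calls with ``event_id`` assigned (flagged calls only);
    the number of distinct ids is the inferred independent-event count.
    """
    if link_rule not in ("donor", "donor_recipient"):
        raise ValueError(f"unknown link rule {link_rule!r}")
    flagged = [c for c in calls if c.flagged]
    tips = {}
    for call in flagged:
        try:
            tips[call.sequence_id] = tree.find(call.sequence_id)
        except KeyError as exc:
            raise KeyError(
                f"flagged call {call.sequence_id!r} absent from gene tree"
            ) from exc

    by_donor: dict[str, set[str]] = {}
    for call in flagged:
        by_donor.setdefault(call.donor_clade, set()).add(call.sequence_id)

    parent = {c.sequence_id: c.sequence_id for c in flagged}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        parent[find(x)] = find(y)

    for i, a in enumerate(flagged):
        for b in flagged[i + 1:]:
            if a.donor_clade != b.donor_clade:
                continue
            if link_rule == "donor_recipient" \
                    and a.recipient_clade != b.recipient_clade:
                continue
            anc = mrca_node(tree, [tips[a.sequence_id], tips[b.sequence_id]])
            leaves = {l.label for l in anc.leaves()}
            if leaves <= by_donor[a.donor_clade]:
                union(a.sequence_id, b.sequence_id)

    roots: dict[str, int] = {}
    out = []
    for call in calls:
        if not call.flagged:
            out.append(call)
            continue
        root = find(call.sequence_id)
        if root not in roots:
            roots[root] = len(roots) + 1
        out.append(replace(call, event_id=roots[root]))
    return out


def origin_fractions(calls: Sequence[HgtCall],
                     incomparable: int = 0) -> tuple[float, float, int]:
    """(native fraction, transferred fraction, incomparable count).

    Fractions are over scored sequences and sum to 1 exactly.
    """
    scored = len(calls)
    if scored == 0:
        raise ValueError("no scored sequences to summarize")
    transferred = sum(1 for c in calls if c.flagged)
    native = scored - transferred
    return native / scored, transferred / scored, incomparable
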