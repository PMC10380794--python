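"""Rooted reference taxonomy trees with named ancestors.

Trees are stored as explicit parent/child node graphs read from Newick
text.  Internal nodes may carry labels (e.g. ``LECA``, ``FECA``,
``Diaphoretickes``) which the reconstruction and HGT modules use to
address ancestors and clades.  Leaf labels are required to be unique;
internal labels are resolved on demand and must be unambiguous at
lookup time.

Branch lengths are optional in the input.  A node whose length was not
given reports ``DEFAULT_BRANCH_LENGTH`` (1.0) through
:meth:`Node.branch_length`, but round-trips through
:func:`write_newick` without a length so that I/O is faithful.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

DEFAULT_BRANCH_LENGTH = 1.0

__all__ = [
    "Node",
    "TaxonomyTree",
    "NewickError",
    "TreeValidationError",
    "read_newick",
    "write_newick",
    "mrca",
    "clade_of",
    "reroot",
]


class NewickError(ValueError):
    """Malformed Newick text; ``offset`` is the character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class TreeValidationError(ValueError):
    """Structurally invalid tree (duplicate leaves, bad lengths, ...)."""


class Node:
    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length  # None means "not given"
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []

    # -- structure ---------------------------------------------------------
    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def branch_length(self) -> float:
        return DEFAULT_BRANCH_LENGTH if self.length is None else self.length

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def ancestors(self) -> Iterator["Node"]:
        node = self.parent
        while node is not None:
            yield node
            node = node.parent

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, children={len(self.children)})"


class TaxonomyTree:
    """A rooted tree with unique leaf labels and addressable ancestors."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for leaf in self.root.leaves():
            if leaf.label is None:
                raise TreeValidationError("unlabelled leaf")
            if leaf.label in seen:
                raise TreeValidationError(f"duplicate leaf label {leaf.label!r}")
            seen.add(leaf.label)
        for node in self.root.preorder():
            if node.length is not None and node.length < 0:
                raise TreeValidationError(
                    f"negative branch length on {node.label!r}"
                )

    # -- queries -----------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def find(self, label: str) -> Node:
        """Resolve a (leaf or internal) label to its unique node."""
        hits = [n for n in self.root.preorder() if n.label == label]
        if not hits:
            raise KeyError(f"no node labelled {label!r}")
        if len(hits) > 1:
            raise TreeValidationError(f"label {label!r} is ambiguous")
        return hits[0]

    def __contains__(self, label: str) -> bool:
        return any(n.label == label for n in self.root.preorder())

    def n_nodes(self) -> int:
        return sum(1 for _ in self.root.preorder())

    def copy(self) -> "TaxonomyTree":
        return read_newick(write_newick(self))


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_LABEL_TERMINATORS = set("(),:;[]' \t\n\r")


def read_newick(text: str) -> TaxonomyTree:
    """Parse a Newick string into a :class:`TaxonomyTree`.

    Supports quoted labels, internal-node labels, branch lengths, and
    polytomies/unary nodes.  Raises :class:`NewickError` with a
    character offset on syntax errors and :class:`TreeValidationError`
    on duplicate leaf labels.
    """
    pos = 0
    n = len(text)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and text[pos] in " \t\n\r":
            pos += 1

    def parse_label() -> Optional[str]:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == "'":
            end = pos + 1
            chunks = []
            while True:
                if end >= n:
                    raise NewickError("unterminated quoted label", pos)
                if text[end] == "'":
                    if end + 1 < n and text[end + 1] == "'":  # escaped quote
                        chunks.append(text[pos + 1 : end + 1])
                        pos = end + 1
                        end += 2
                        continue
                    break
                end += 1
            chunks.append(text[pos + 1 : end])
            pos = end + 1
            return "".join(chunks)
        start = pos
        while pos < n and text[pos] not in _LABEL_TERMINATORS:
            pos += 1
        return text[start:pos] or None

    def parse_length() -> Optional[float]:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == ":":
            pos += 1
            skip_ws()
            start = pos
            while pos < n and (text[pos].isdigit() or text[pos] in "+-.eE"):
                pos += 1
            try:
                return float(text[start:pos])
            except ValueError:
                raise NewickError("invalid branch length", start) from None
        return None

    def parse_clade() -> Node:
        nonlocal pos
        skip_ws()
        node = Node()
        if pos < n and text[pos] == "(":
            open_at = pos
            pos += 1
            while True:
                node.add_child(parse_clade())
                skip_ws()
                if pos >= n:
                    raise NewickError("unbalanced parentheses", open_at)
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise NewickError(f"unexpected character {text[pos]!r}", pos)
        node.label = parse_label()
        node.length = parse_length()
        return node

    root = parse_clade()
    skip_ws()
    if pos >= n or text[pos] != ";":
        raise NewickError("expected ';' at end of tree", pos)
    pos += 1
    skip_ws()
    if pos != n:
        raise NewickError("trailing characters after ';'", pos)
    return TaxonomyTree(root)


def _format_label(label: Optional[str]) -> str:
    if label is None:
        return ""
    if any(c in _LABEL_TERMINATORS for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: TaxonomyTree) -> str:
    def fmt(node: Node) -> str:
        s = ""
        if node.children:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
        s += _format_label(node.label)
        if node.length is not None:
            s += f":{node.length:g}"
        return s

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Clade queries
# ---------------------------------------------------------------------------


def mrca(tree: TaxonomyTree, labels: Iterable[str]) -> str:
    """Label of the most recent common ancestor of the given labels.

    Labels may name leaves or internal nodes.  The MRCA of a single
    label is the node itself.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("mrca of an empty label set")
    nodes = [tree.find(lab) for lab in labels]
    node = mrca_node(tree, nodes)
    return node.label


def mrca_node(tree: TaxonomyTree, nodes: list[Node]) -> Node:
    paths = []
    for node in nodes:
        path = [node] + list(node.ancestors())
        paths.append(list(reversed(path)))  # root-first
    shortest = min(len(p) for p in paths)
    anc = tree.root
    for depth in range(shortest):
        candidate = paths[0][depth]
        if all(p[depth] is candidate for p in paths):
            anc = candidate
        else:
            break
    return anc


def clade_of(tree: TaxonomyTree, leaf: str, level: Iterable[str]) -> str:
    """The unique ancestor of ``leaf`` whose label is in ``level``.

    ``level`` is expected to be a set of node labels that partitions
    the leaves (e.g. the eukaryotic supergroups).  A leaf that is
    itself named in ``level`` is its own clade.
    """
    level = set(level)
    node = tree.find(leaf)
    if not node.is_leaf:
        raise KeyError(f"{leaf!r} is not a leaf")
    if node.label in level:
        return node.label
    for anc in node.ancestors():
        if anc.label in level:
            return anc.label
    raise LookupError(f"leaf {leaf!r} is not covered by level {sorted(level)}")


def reroot(tree: TaxonomyTree, outgroup: str) -> TaxonomyTree:
    """Reroot so that ``outgroup`` is a child of the new root.

    The branch leading to the outgroup is split in half.  Internal
    labels are preserved on their (re-oriented) nodes.
    """
    work = tree.copy()
    og = work.find(outgroup)
    if og.parent is None:
        return work  # already the root
    if og.parent is work.root and len(work.root.children) == 2:
        return work  # already rooted on this branch

    # Detach path from outgroup's parent up to the old root, then hang
    # the reversed path under a fresh root.
    half = og.branch_length() / 2.0
    new_root = Node()
    old_parent = og.parent
    old_parent.children.remove(og)
    og.parent = None
    og.length = None if og.length is None else half

    new_root.add_child(og)
    # Reverse parent chain: old_parent becomes the other child.
    prev = new_root
    prev_len: Optional[float] = None if og.length is None else half
    node: Optional[Node] = old_parent
    while node is not None:
        upper = node.parent
        upper_len = node.length
        if upper is not None:
            upper.children.remove(node)
        node.parent = None
        prev.add_child(node)
        node.length = prev_len
        prev_len = upper_len
        prev = node
        node = upper
    # The old root may now be a unary pass-through; splice it out.
    _suppress_unary(new_root)
    return TaxonomyTree(new_root)


def _suppress_unary(root: Node) -> None:
    for node in list(root.preorder()):
        if node is root:
            continue
        if len(node.children) == 1 and node.label is None:
            child = node.children[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent
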