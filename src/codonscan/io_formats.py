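"""Readers and writers for the formats the pipeline touches.

Sequence sets (FASTA), phylogenies (Newick with PAML-style ``#k`` branch
marks for foreground labelling), gene→GO annotation tables (TSV) and GO
DAG edge lists (TSV). All tabular outputs are TSV with a header line so
runs diff cleanly.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "SequenceSet",
    "TreeNode",
    "PhyloTree",
    "read_fasta",
    "write_fasta",
    "parse_newick",
    "write_newick",
    "read_annotations",
    "write_annotations",
    "read_go_dag",
    "write_go_dag",
    "FormatError",
]

GO_ID_RE = re.compile(r"^GO:\d{7}$")

_NUC_CHARS = set("ACGTN-")  # '-' so aligned sequences round-trip
# 20 amino acids plus ambiguity codes; '*' tolerated so raw translations load.
_PROT_CHARS = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


@dataclass
class SequenceSet:
    """An ordered collection of named sequences over one alphabet.

    Names are unique and non-empty; nucleotide sequences are restricted to
    A, C, G, T, N and stored upper-case.
    """

    records: dict[str, str]
    alphabet: str  # "nucleotide" | "protein"

    def __post_init__(self) -> None:
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = _NUC_CHARS if self.alphabet == "nucleotide" else _PROT_CHARS
        clean: dict[str, str] = {}
        for name, seq in self.records.items():
            if not name:
                raise FormatError("empty sequence name")
            seq = seq.upper()
            bad = set(seq) - allowed
            if bad:
                raise FormatError(
                    f"illegal character(s) {sorted(bad)} in {self.alphabet} "
                    f"sequence {name!r}"
                )
            clean[name] = seq
        self.records = clean

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def items(self):
        return self.records.items()

    def names(self) -> list[str]:
        return list(self.records)


def read_fasta(path, alphabet: str) -> SequenceSet:
    """Read a multi-record FASTA file into a :class:`SequenceSet`.

    Records keep file order. A duplicate header, or a character illegal for
    the declared alphabet, raises :class:`FormatError`.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        records[rec.id] = str(rec.seq)
    return SequenceSet(records=records, alphabet=alphabet)


def write_fasta(seqs: SequenceSet, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """A node of a rooted tree; ``length`` and ``mark`` describe the branch
    leading to this node (ignored on the root)."""

    name: str = ""
    length: float = 0.0
    mark: int = 0
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted phylogeny with per-branch lengths and integer marks.

    Branches are identified by the clade below them: a terminal branch by
    its leaf name, an internal branch by the ``+``-joined sorted leaf names
    of its clade. This keeps "the BMR terminal branch" well defined no
    matter how the tree was written or rooted.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        for node in self.postorder():
            for child in node.children:
                child.parent = node
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise FormatError("duplicate leaf names in tree")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            for child in node.children:
                yield from walk(child)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            yield node
            for child in node.children:
                yield from walk(child)

        return walk(self.root)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[TreeNode]:
        """All non-root nodes, i.e. one per branch."""
        return [n for n in self.postorder() if n is not self.root]

    def clade_leaves(self, node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.name]
        out: list[str] = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            else:
                stack.extend(n.children)
        return sorted(out)

    def branch_id(self, node: TreeNode) -> str:
        return node.name if node.is_leaf else "+".join(self.clade_leaves(node))

    def branch_ids(self) -> list[str]:
        return [self.branch_id(n) for n in self.branches()]

    def marked_branches(self, mark: int | None = None) -> set[str]:
        """Branch ids carrying a ``#k`` mark (any non-zero mark, or one
        specific value)."""
        return {
            self.branch_id(n)
            for n in self.branches()
            if (n.mark != 0 if mark is None else n.mark == mark)
        }

    def find_branch(self, branch_id: str) -> TreeNode:
        for node in self.branches():
            if self.branch_id(node) == branch_id:
                return node
        raise KeyError(f"no branch {branch_id!r} in tree")

    def copy(self) -> "PhyloTree":
        return parse_newick(write_newick(self))

    def __len__(self) -> int:
        return len(self.leaves())


# -- Newick with PAML branch marks ----------------------------------------

_TOKEN_RE = re.compile(r"\s*([(),;:]|#\s*\d+|[^\s(),;:#]+)")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string; ``#k`` after a label or length marks the branch.

    Both ``name #1:0.3`` and ``name:0.3 #1`` place mark 1 on the branch
    above ``name`` (the dialect PAML control files use for foreground
    branches). Negative branch lengths and unbalanced parentheses raise
    :class:`FormatError`.
    """
    tokens: list[str] = []
    pos = 0
    stripped = text.strip()
    while pos < len(stripped):
        m = _TOKEN_RE.match(stripped, pos)
        if m is None:
            raise FormatError(f"cannot tokenize newick at offset {pos}")
        tokens.append(m.group(1).replace(" ", ""))
        pos = m.end()
    if not tokens or tokens[-1] != ";":
        raise FormatError("newick string must end with ';'")
    tokens = tokens[:-1]

    idx = 0

    def peek() -> str | None:
        return tokens[idx] if idx < len(tokens) else None

    def take() -> str:
        nonlocal idx
        tok = tokens[idx]
        idx += 1
        return tok

    def parse_subtree() -> TreeNode:
        node = TreeNode()
        if peek() == "(":
            take()
            node.children.append(parse_subtree())
            while peek() == ",":
                take()
                node.children.append(parse_subtree())
            if peek() != ")":
                raise FormatError("unbalanced parentheses in newick")
            take()
        # optional label, marks, length (mark may precede or follow length)
        if peek() not in (None, ",", ")", ":", ";") and not peek().startswith("#"):
            node.name = take()
        while (tok := peek()) is not None and (tok == ":" or tok.startswith("#")):
            if tok == ":":
                take()
                length_tok = peek()
                if length_tok is None:
                    raise FormatError("missing branch length after ':'")
                try:
                    node.length = float(take())
                except ValueError as exc:
                    raise FormatError(f"bad branch length {length_tok!r}") from exc
                if node.length < 0:
                    raise FormatError(f"negative branch length {node.length}")
            else:
                take()
                node.mark = int(tok[1:])
        return node

    root = parse_subtree()
    if idx != len(tokens):
        raise FormatError("trailing tokens after newick tree")
    if not root.children and not root.name:
        raise FormatError("empty newick tree")
    return PhyloTree(root)


def write_newick(tree: PhyloTree, lengths: bool = True) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            s = node.name
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.name
        if node is not tree.root:
            if node.mark:
                s += f" #{node.mark}"
            if lengths:
                s += f":{node.length!r}"  # repr: shortest exact round-trip
        return s

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# GO annotations and DAG
# ---------------------------------------------------------------------------


def _iter_tsv_rows(path, n_cols: int, header: tuple[str, ...]) -> Iterator[list[str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and tuple(p.strip() for p in parts) == header:
                continue  # optional header line
            if len(parts) != n_cols:
                raise FormatError(f"{path}:{lineno}: expected {n_cols} columns")
            yield parts


def read_annotations(path) -> dict[str, set[str]]:
    """Read a gene→GO TSV (columns ``gene``, ``go_id``, one pair per line).

    Lines for the same gene merge into one term set; a malformed GO id
    raises :class:`FormatError`.
    """
    table: dict[str, set[str]] = {}
    for gene, go_id in _iter_tsv_rows(path, 2, ("gene", "go_id")):
        if not GO_ID_RE.match(go_id):
            raise FormatError(f"{path}: malformed GO id {go_id!r}")
        table.setdefault(gene, set()).add(go_id)
    return table


def write_annotations(table: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tgo_id\n")
        for gene in sorted(table):
            for go_id in sorted(table[gene]):
                fh.write(f"{gene}\t{go_id}\n")


def read_go_dag(path) -> dict[str, set[str]]:
    """Read a child→parent GO edge list (columns ``child_go``, ``parent_go``)."""
    dag: dict[str, set[str]] = {}
    for child, parent in _iter_tsv_rows(path, 2, ("child_go", "parent_go")):
        for go_id in (child, parent):
            if not GO_ID_RE.match(go_id):
                raise FormatError(f"{path}: malformed GO id {go_id!r}")
        dag.setdefault(child, set()).add(parent)
    return dag


def write_go_dag(dag: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("child_go\tparent_go\n")
        for child in sorted(dag):
            for parent in sorted(dag[child]):
                fh.write(f"{child}\t{parent}\n")
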