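"""NCBI taxonomy subtree extraction for taxon-restricted BLAST databases.

A protein database restricted to one clade (here typically Actinopterygii,
taxid 7898, the ray-finned fishes) is built by listing every taxid in the
clade's subtree and handing that list to ``blastdbcmd``/``makeblastdb``.
This module parses the ``nodes.dmp`` dump dialect, enumerates subtrees
iteratively (real dumps exceed 2.5M nodes, so no recursion), and writes the
one-taxid-per-line filter list the external tools expect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable

from .errors import ParseError, StructuralError

__all__ = [
    "TaxonomyTree",
    "parse_nodes",
    "parse_names",
    "subtree_taxids",
    "write_taxid_list",
]

#: NCBI convention: the global root is its own parent.
ROOT_TAXID = 1


@dataclass
class TaxonomyTree:
    """Parent pointers (and optional names) for a taxonomy dump.

    Roots are nodes that are their own parent. Every other node's parent
    chain must terminate at a root; cycles are rejected at parse time.
    """

    parent_of: dict[int, int]
    names: dict[int, str] = field(default_factory=dict)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.parent_of

    def __len__(self) -> int:
        return len(self.parent_of)


def _split_dmp(line: str) -> list[str]:
    # nodes.dmp rows are "<field>\t|\t<field>\t|\t...\t|" — split on the pipe
    # and strip the tab padding so plain "a|b" test rows also parse.
    return [f.strip("\t ") for f in line.rstrip("\n").rstrip("|\t ").split("|")]


def parse_nodes(stream: IO[str] | str | Iterable[str]) -> TaxonomyTree:
    """Parse a ``nodes.dmp``-dialect file into a :class:`TaxonomyTree`.

    Only the first two fields (taxid, parent taxid) are used. Self-parented
    nodes are accepted as roots; a cycle among non-root nodes raises
    :class:`StructuralError`.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    parent_of: dict[int, int] = {}
    for lineno, raw in enumerate(stream, start=1):
        if not raw.strip():
            continue
        fields = _split_dmp(raw)
        if len(fields) < 2:
            raise ParseError("expected at least taxid and parent fields", line=lineno)
        try:
            taxid = int(fields[0])
            parent = int(fields[1])
        except ValueError as exc:
            raise ParseError(f"non-integer taxid field: {exc}", line=lineno) from exc
        parent_of[taxid] = parent

    _check_acyclic(parent_of)
    return TaxonomyTree(parent_of=parent_of)


def _check_acyclic(parent_of: dict[int, int]) -> None:
    # Iterative chain-walk with memoisation: every node must reach a
    # self-parented root without revisiting a node on its own chain.
    ok: set[int] = {t for t, p in parent_of.items() if t == p}
    for start in parent_of:
        chain: list[int] = []
        on_chain: set[int] = set()
        node = start
        while node not in ok:
            if node in on_chain:
                raise StructuralError(
                    f"cycle in taxonomy involving taxid {node}"
                )
            if node not in parent_of:
                raise StructuralError(
                    f"taxid {node} has parent chain leaving the tree "
                    f"(missing node {node})"
                )
            chain.append(node)
            on_chain.add(node)
            node = parent_of[node]
        ok.update(chain)


def parse_names(
    stream: IO[str] | str | Iterable[str], name_class: str = "scientific name"
) -> dict[int, str]:
    """Parse a ``names.dmp``-dialect file, keeping one name class per taxid."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    names: dict[int, str] = {}
    for lineno, raw in enumerate(stream, start=1):
        if not raw.strip():
            continue
        fields = _split_dmp(raw)
        if len(fields) < 4:
            raise ParseError("expected taxid, name, unique name, class", line=lineno)
        try:
            taxid = int(fields[0])
        except ValueError as exc:
            raise ParseError(f"non-integer taxid field: {exc}", line=lineno) from exc
        if fields[3] == name_class:
            names[taxid] = fields[1]
    return names


def subtree_taxids(tree: TaxonomyTree, root: int) -> set[int]:
    """All taxids whose ancestor chain passes through ``root``, including root.

    Single pass to build child lists, then an explicit-stack DFS, so dumps of
    millions of nodes never hit the interpreter recursion limit.
    """
    if root not in tree.parent_of:
        raise KeyError(f"taxid {root} not present in taxonomy")
    children: dict[int, list[int]] = {}
    for taxid, parent in tree.parent_of.items():
        if taxid == parent:  # self-parented root: not a child of itself
            continue
        children.setdefault(parent, []).append(taxid)

    result: set[int] = set()
    stack = [root]
    while stack:
        node = stack.pop()
        if node in result:
            continue
        result.add(node)
        stack.extend(children.get(node, ()))
    return result


def write_taxid_list(taxids: set[int] | Iterable[int], stream: IO[str]) -> None:
    """Write one taxid per line in ascending order (a blastdbcmd filter list)."""
    taxids = set(taxids)
    if not taxids:
        raise ValueError("refusing to write an empty taxid list")
    for taxid in sorted(taxids):
        stream.write(f"{taxid}\n")


def read_taxid_list(stream: IO[str] | str) -> set[int]:
    """Inverse of :func:`write_taxid_list`."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    return {int(line) for line in stream if line.strip()}
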