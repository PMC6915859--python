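"""Extended Newick serialization.

Dialect notes:

* the outdegree-1 root is part of the object and is serialized explicitly:
  the top-level expression has a single child, so the two-taxon tree is
  written ``((1,2));`` rather than ``(1,2);``;
* each reticulate node carries a hybrid tag ``#H1, #H2, ...`` numbered in
  first-traversal order; its child subtree is written at the first
  occurrence, the second occurrence is the bare tag;
* leaves are rendered as their taxon integers;
* branch lengths are not modeled — the reader tolerates and discards
  ``:length`` annotations; the writer never emits them.

Output is deterministic: children are ordered by their path-count vector
(the canonical subtree invariant), so isomorphic networks built in
different orders serialize identically.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from .. import netcore
from ..errors import ContractError, FormatError, StructuralError
from ..isocheck import path_count_vectors
from ..netcore import PhyloNetwork

ENewickString = str


# -- writer ---------------------------------------------------------------

def write_enewick(N: PhyloNetwork) -> ENewickString:
    bad = netcore.validate(N)
    if bad:
        raise ContractError("write_enewick requires a valid network: " + "; ".join(bad))
    vec = path_count_vectors(N)
    tags: Dict[int, int] = {}

    def render(v: int) -> str:
        label = N.leaf_label.get(v)
        if label is not None:
            return str(label)
        if N.indegree(v) == 2:
            tag = tags.get(v)
            if tag is not None:
                return f"#H{tag}"
            tag = len(tags) + 1
            tags[v] = tag
            (child,) = N.children(v)
            return f"({render(child)})#H{tag}"
        kids = sorted(N.children(v), key=lambda c: (vec[c], N.indegree(c)),
                      reverse=True)
        return "(" + ",".join(render(c) for c in kids) + ")"

    (top,) = N.children(N.root)
    return "(" + render(top) + ");"


# -- reader ---------------------------------------------------------------

class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> FormatError:
        return FormatError(msg, pos=self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self, ch: str) -> None:
        if self.peek() != ch:
            raise self.error(f"expected {ch!r}, found {self.peek()!r}")
        self.pos += 1

    def skip_ws(self) -> None:
        while self.peek() and self.peek() in " \t\r\n":
            self.pos += 1

    def read_name(self) -> str:
        start = self.pos
        while self.peek() and self.peek() not in "(),;:#":
            self.pos += 1
        return self.text[start:self.pos].strip()

    def read_hybrid_tag(self) -> str:
        start = self.pos
        self.take("#")
        while self.peek() and self.peek() not in "(),;:#":
            self.pos += 1
        tag = self.text[start:self.pos]
        if len(tag) < 2:
            raise self.error("empty hybrid tag")
        return tag

    def skip_length(self) -> None:
        if self.peek() == ":":
            self.pos += 1
            while self.peek() and self.peek() not in "(),;":
                self.pos += 1


def read_enewick(s: ENewickString, *, require_valid: bool = True) -> PhyloNetwork:
    """Parse an extended Newick string into a :class:`PhyloNetwork`.

    Hybrid tags must appear exactly twice, with the child subtree given at
    exactly one occurrence; leaves must be integer-named.  With
    ``require_valid`` (the default) the result must pass ``validate``.
    """
    p = _Parser(s)
    N = PhyloNetwork()
    hybrids: Dict[str, int] = {}
    hybrid_occurrences: Dict[str, int] = {}
    hybrid_subtree_at: Dict[str, int] = {}

    def parse_node() -> int:
        p.skip_ws()
        children: List[int] = []
        has_parens = p.peek() == "("
        if has_parens:
            p.take("(")
            children.append(parse_node())
            p.skip_ws()
            while p.peek() == ",":
                p.take(",")
                children.append(parse_node())
                p.skip_ws()
            p.take(")")
        name = p.read_name()
        tag: Optional[str] = None
        if p.peek() == "#":
            tag = p.read_hybrid_tag()
        p.skip_length()
        p.skip_ws()

        if tag is not None:
            node = hybrids.get(tag)
            if node is None:
                node = N.new_node()
                hybrids[tag] = node
            hybrid_occurrences[tag] = hybrid_occurrences.get(tag, 0) + 1
            if hybrid_occurrences[tag] > 2:
                raise p.error(f"hybrid tag {tag} used more than twice "
                              "(reticulate nodes have indegree 2)")
            if children:
                if tag in hybrid_subtree_at:
                    raise p.error(f"hybrid tag {tag} has a subtree at two occurrences")
                hybrid_subtree_at[tag] = node
                if len(children) != 1:
                    raise p.error(f"hybrid node {tag} must have exactly one child")
                N.add_edge(node, children[0])
            return node

        node = N.new_node()
        for c in children:
            N.add_edge(node, c)
        if not children:
            if not name:
                raise p.error("leaf without a name")
            try:
                taxon = int(name)
            except ValueError:
                raise p.error(f"leaf name {name!r} is not a taxon integer") from None
            try:
                N.set_leaf_label(node, taxon)
            except Exception:
                raise p.error(f"duplicate taxon {taxon}") from None
        # internal node names (other than hybrid tags) are tolerated and dropped
        return node

    top = parse_node()
    p.skip_ws()
    if p.peek() == ";":
        p.take(";")
    p.skip_ws()
    if p.pos != len(p.text):
        raise p.error("trailing characters after the network expression")

    for tag, occ in hybrid_occurrences.items():
        if occ != 2:
            raise FormatError(f"hybrid tag {tag} appears {occ} time(s); expected 2")
        if tag not in hybrid_subtree_at:
            raise FormatError(f"hybrid tag {tag} never given a child subtree")
    N.root = top
    if require_valid:
        bad = netcore.validate(N)
        if bad:
            raise StructuralError(
                "parsed network is not a valid rooted binary phylogenetic network: "
                + "; ".join(bad))
    return N
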