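"""Edge-list text format: one ``parent<TAB>child`` line per edge.

Node names are free-form; sink nodes (leaves) must be named by their taxon
integer.  Blank lines and ``#`` comment lines are ignored.  The writer
names internal nodes ``v<id>`` and leaves by their taxon.
"""

from __future__ import annotations

from typing import Dict

from .. import netcore
from ..errors import ContractError, FormatError, StructuralError
from ..netcore import PhyloNetwork


def write_edgelist(N: PhyloNetwork) -> str:
    bad = netcore.validate(N)
    if bad:
        raise ContractError("write_edgelist requires a valid network: " + "; ".join(bad))

    def name(v: int) -> str:
        t = N.leaf_label.get(v)
        return str(t) if t is not None else f"v{v}"

    return "".join(f"{name(u)}\t{name(v)}\n" for u, v in N.sorted_edges())


def read_edgelist(text: str, *, require_valid: bool = True) -> PhyloNetwork:
    N = PhyloNetwork()
    names: Dict[str, int] = {}

    def node(name: str, lineno: int) -> int:
        v = names.get(name)
        if v is None:
            v = N.new_node()
            names[name] = v
        return v

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise FormatError(f"line {lineno}: expected 'parent<TAB>child', got {raw!r}")
        N.add_edge(node(parts[0], lineno), node(parts[1], lineno))

    if not names:
        raise FormatError("empty edge list")
    for name, v in names.items():
        if N.outdegree(v) == 0:
            try:
                taxon = int(name)
            except ValueError:
                raise FormatError(f"sink node {name!r} is not named by a taxon integer") \
                    from None
            N.set_leaf_label(v, taxon)
    sources = [v for v in N.nodes() if N.indegree(v) == 0]
    N.root = sources[0] if len(sources) == 1 else None
    if require_valid:
        bad = netcore.validate(N)
        if bad:
            raise StructuralError(
                "edge list is not a valid rooted binary phylogenetic network: "
                + "; ".join(bad))
    return N
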