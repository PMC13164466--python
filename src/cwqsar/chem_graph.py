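"""SMILES-attribute featurization.

A compound's descriptor is built from three attribute families extracted
from its SMILES string:

* ``S_k``   — single SMILES-atoms: the smallest indivisible tokens of the
  string (one character, a two-letter organic-subset element such as ``Cl``
  or ``Br``, or a whole bracket atom ``[...]``);
* ``SS_k``  — ordered pairs of adjacent SMILES-atoms (sliding window of 2);
* ``NNC_k`` — nearest-neighbor codes of the hydrogen-suppressed molecular
  graph: for each heavy-atom vertex, ``100*N_T + 10*N_C + N_X`` where
  ``N_T`` is the vertex degree, ``N_C`` the number of carbon neighbors and
  ``N_X`` the number of non-carbon neighbors.

Attribute keys use a fixed-width 12-character spelling padded with ``'.'``
(e.g. ``"=..........."``, ``"N...(......."``, ``"NNC-C...321."``) so that
reports line up column-wise and keys compare by string equality.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .errors import InvariantError, MalformedSmilesError

__all__ = [
    "AttributeKind",
    "AttributeKey",
    "MolecularGraph",
    "tokenize",
    "sk_attributes",
    "ssk_attributes",
    "build_graph",
    "nnc_code",
    "nnc_attributes",
    "featurize",
]

#: organic-subset atom symbols that stand alone (outside brackets)
_ORGANIC_UPPER = set("BCNOPSFI")
_ORGANIC_AROMATIC = set("bcnops")
_TWO_LETTER = ("Cl", "Br")
_BOND_CHARS = set("=#-/\\:")

_BRACKET_ELEMENT_RE = re.compile(r"\[\d*([A-Z][a-z]?|[a-z])")

CANONICAL_WIDTH = 12


class AttributeKind(str, Enum):
    SK = "SK"
    SSK = "SSK"
    NNC = "NNC"


@dataclass(frozen=True, order=True)
class AttributeKey:
    """A molecular attribute identified by its canonical 12-char code."""

    kind: AttributeKind
    code: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code

    @classmethod
    def sk(cls, token: str) -> "AttributeKey":
        return cls(AttributeKind.SK, token.ljust(CANONICAL_WIDTH, "."))

    @classmethod
    def ssk(cls, first: str, second: str) -> "AttributeKey":
        # first token occupies a 4-char field; pairs keep SMILES order
        code = (first.ljust(4, ".") + second).ljust(CANONICAL_WIDTH, ".")
        return cls(AttributeKind.SSK, code)

    @classmethod
    def nnc(cls, element: str, code: int) -> "AttributeKey":
        text = ("NNC-" + element).ljust(8, ".") + f"{code:03d}" + "."
        return cls(AttributeKind.NNC, text)


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into indivisible SMILES-atom tokens.

    Bracket atoms ``[...]`` and the two-letter elements ``Cl``/``Br`` are
    single tokens; every other character is its own token.  Concatenating
    the result reproduces the input exactly.
    """
    if not smiles:
        raise MalformedSmilesError("empty SMILES string")
    if not smiles.isascii():
        raise MalformedSmilesError("SMILES must be ASCII")
    tokens: list[str] = []
    depth = 0
    i = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i + 1)
            if j == -1:
                raise MalformedSmilesError("unbalanced '['", position=i)
            tokens.append(smiles[i : j + 1])
            i = j + 1
            continue
        if ch == "]":
            raise MalformedSmilesError("']' without matching '['", position=i)
        if ch == "(":
            depth += 1
        elif ch == ")":
            if depth == 0:
                raise MalformedSmilesError("')' without matching '('", position=i)
            depth -= 1
        if smiles[i : i + 2] in _TWO_LETTER:
            tokens.append(smiles[i : i + 2])
            i += 2
            continue
        tokens.append(ch)
        i += 1
    if depth:
        raise MalformedSmilesError("unbalanced '('", position=smiles.rindex("("))
    return tokens


def sk_attributes(tokens: Sequence[str]) -> Counter:
    """One ``S_k`` attribute per token, with multiplicity."""
    return Counter(AttributeKey.sk(t) for t in tokens)


def ssk_attributes(tokens: Sequence[str]) -> Counter:
    """One ``SS_k`` attribute per adjacent token pair, in SMILES order."""
    return Counter(
        AttributeKey.ssk(a, b) for a, b in zip(tokens, tokens[1:])
    )


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed molecular graph.

    ``vertices`` lists ``(index, element)`` in SMILES order; ``edges`` is a
    set of sorted index pairs (no self-loops, no duplicates).
    """

    vertices: list[tuple[int, str]]
    edges: set[tuple[int, int]]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i, _ in self.vertices}
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj


def _bracket_element(token: str, position: int) -> str:
    m = _BRACKET_ELEMENT_RE.match(token)
    if m is None:
        raise MalformedSmilesError(
            f"cannot read element from bracket atom {token!r}", position=position
        )
    el = m.group(1)
    if el.islower():  # aromatic bracket atom, e.g. [nH]
        el = el.upper()
    return el


def build_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into its hydrogen-suppressed graph.

    Follows chain/branch/ring-closure semantics.  Aromatic lowercase atoms
    become vertices of the corresponding element; bracket atoms contribute
    a vertex of their bare element; explicit hydrogens are suppressed.
    Bond order is ignored — only adjacency matters for NNC codes.
    """
    tokens = tokenize(smiles)
    vertices: list[tuple[int, str]] = []
    edges: set[tuple[int, int]] = set()
    prev: int | None = None
    stack: list[int | None] = []
    ring_open: dict[str, int] = {}
    pending_bond: int | None = None  # position of a bond char awaiting an atom
    pos = 0
    for tok in tokens:
        tok_pos = pos
        pos += len(tok)
        element: str | None = None
        if tok.startswith("["):
            element = _bracket_element(tok, tok_pos)
        elif tok in _TWO_LETTER or tok in _ORGANIC_UPPER:
            element = tok
        elif tok in _ORGANIC_AROMATIC:
            element = tok.upper()
        if element is not None:
            if element == "H":
                # hydrogen-suppressed: no vertex, and the bond to it vanishes
                pending_bond = None
                continue
            idx = len(vertices)
            vertices.append((idx, element))
            if prev is not None:
                edges.add(tuple(sorted((prev, idx))))  # type: ignore[arg-type]
            prev = idx
            pending_bond = None
            continue
        if tok in _BOND_CHARS:
            if prev is None:
                raise MalformedSmilesError("bond symbol before any atom", position=tok_pos)
            pending_bond = tok_pos
            continue
        if tok.isdigit():
            if prev is None:
                raise MalformedSmilesError("ring closure before any atom", position=tok_pos)
            if tok in ring_open:
                other = ring_open.pop(tok)
                if other == prev:
                    raise MalformedSmilesError(
                        f"ring closure {tok} forms a self-loop", position=tok_pos
                    )
                edges.add(tuple(sorted((other, prev))))  # type: ignore[arg-type]
            else:
                ring_open[tok] = prev
            pending_bond = None
            continue
        if tok == "(":
            if prev is None:
                raise MalformedSmilesError("branch before any atom", position=tok_pos)
            stack.append(prev)
            continue
        if tok == ")":
            prev = stack.pop()
            continue
        if tok == ".":
            if pending_bond is not None:
                raise MalformedSmilesError("dangling bond before '.'", position=pending_bond)
            prev = None
            continue
        # stereo / charge marks outside brackets: no graph effect
        if tok in ("@", "+", "-", "%"):
            continue
        raise MalformedSmilesError(f"unexpected token {tok!r}", position=tok_pos)
    if ring_open:
        digit = sorted(ring_open)[0]
        raise MalformedSmilesError(f"unmatched ring-closure digit {digit!r}")
    if pending_bond is not None:
        raise MalformedSmilesError("dangling bond symbol", position=pending_bond)
    return MolecularGraph(vertices=vertices, edges=edges)


def nnc_code(n_total: int, n_carbon: int, n_noncarbon: int) -> int:
    """Nearest-neighbor code ``100*N_T + 10*N_C + N_X`` for one vertex."""
    if min(n_total, n_carbon, n_noncarbon) < 0:
        raise InvariantError("neighbor counts must be non-negative")
    if n_total != n_carbon + n_noncarbon:
        raise InvariantError(
            f"N_T ({n_total}) must equal N_C + N_X ({n_carbon}+{n_noncarbon})"
        )
    return 100 * n_total + 10 * n_carbon + n_noncarbon


def nnc_attributes(graph: MolecularGraph) -> Counter:
    """One NNC attribute per vertex of the hydrogen-suppressed graph."""
    adj = graph.adjacency()
    element = dict(graph.vertices)
    counts: Counter = Counter()
    for idx, el in graph.vertices:
        neighbors = adj[idx]
        n_t = len(neighbors)
        n_c = sum(1 for j in neighbors if element[j] == "C")
        counts[AttributeKey.nnc(el, nnc_code(n_t, n_c, n_t - n_c))] += 1
    return counts


def featurize(smiles: str) -> Counter:
    """Full attribute multiset of a compound: S_k + SS_k + NNC_k."""
    smiles = smiles.strip()
    tokens = tokenize(smiles)
    attrs = sk_attributes(tokens)
    attrs.update(ssk_attributes(tokens))
    attrs.update(nnc_attributes(build_graph(smiles)))
    return attrs


def featurize_many(smiles_list: Iterable[str]) -> list[Counter]:
    return [featurize(s) for s in smiles_list]
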