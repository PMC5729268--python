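"""Presence/absence matrix, Dollo mapping onto a species tree, branch support.

A retroposon insertion is gained once and essentially never precisely
excised, so under Dollo parsimony the taxa carrying a marker must form a
clade.  A marker whose presence set matches no branch of the species tree is
a *conflict* — hemiplasy through incomplete lineage sorting, or (rarely)
homoplasy — and is reported, never resolved automatically.

Branch support uses a hard-polytomy null: under an unresolved trichotomy
each of the three quartet resolutions is equally likely to fix, so the
number of markers supporting the observed branch among all informative
markers is Binomial(n, 1/3); the reported p-value is the exact upper tail.
"""

from __future__ import annotations

import logging
import operator

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import dendropy
import pandas as pd

from retromark.markers import MarkerRecord
from retromark.trees import branch_id, clade_of, iter_branches

__all__ = [
    "PresenceAbsenceMatrix", "MarkerMapping", "BranchSupport",
    "build_matrix", "map_markers", "branch_support_test",
]


@dataclass
class PresenceAbsenceMatrix:
    """Taxa x markers state table with entries '1', '0' and '?'."""

    states: pd.DataFrame  # index = taxa, columns = marker ids, dtype str

    @property
    def taxa(self) -> list[str]:
        return list(self.states.index)

    @property
    def markers(self) -> list[str]:
        return list(self.states.columns)

    def column_sets(self, marker: str) -> tuple[set[str], set[str], set[str]]:
        """(present, absent, unknown) taxon sets of one marker column."""
        col = self.states[marker]
        ones = set(col.index[col == "1"])
        zeros = set(col.index[col == "0"])
        unknown = set(col.index) - ones - zeros
        return ones, zeros, unknown

    def to_tsv(self, path: str) -> None:
        self.states.to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path: str) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(df)


@dataclass
class MarkerMapping:
    """Placement of one marker on the species tree."""

    marker_id: str
    supported_branch: str | None
    conflict: bool
    compatible_branches: set[str] = field(default_factory=set)


@dataclass
class BranchSupport:
    """Exact polytomy-null test for one branch.

    n_support markers favour the branch; n_conflict_a / n_conflict_b favour
    the two alternative resolutions of the local quartet.
    """

    branch: str
    n_support: int
    n_conflict_a: int
    n_conflict_b: int
    p_value: float


def build_matrix(records: list[MarkerRecord]) -> PresenceAbsenceMatrix:
    """Assemble the matrix from validated markers; invalid ones are dropped.

    Raises on duplicate locus ids.  Columns that end up without both a
    present and an absent entry (possible only from degenerate inputs) are
    excluded and logged.
    """
    seen: set[str] = set()
    cols: dict[str, dict[str, str]] = {}
    taxa: list[str] = []
    state_char = {"present": "1", "absent": "0", "ambiguous": "?"}
    for rec in records:
        if rec.locus_id in seen:
            raise ValueError(f"duplicate locus_id {rec.locus_id!r}")
        seen.add(rec.locus_id)
        if not rec.valid:
            continue
        col = {c.taxon: state_char[c.state] for c in rec.calls}
        if "1" not in col.values() or "0" not in col.values():
            logging.getLogger(__name__).warning(
                "marker %s excluded: no informative contrast", rec.locus_id)
            continue
        cols[rec.locus_id] = col
        for t in col:
            if t not in taxa:
                taxa.append(t)
    df = pd.DataFrame(index=taxa, columns=list(cols), dtype=object)
    for mid, col in cols.items():
        for t in taxa:
            df.loc[t, mid] = col.get(t, "?")
    return PresenceAbsenceMatrix(df.fillna("?"))


def map_markers(matrix: PresenceAbsenceMatrix,
                tree: dendropy.Tree) -> list[MarkerMapping]:
    """Map every marker onto the branch whose clade explains it.

    A marker maps to branch *b* when its present taxa equal
    ``clade(b) & non-? taxa`` (its absent taxa are then automatically outside
    the clade).  '?' entries can leave several nested branches compatible; in
    that case the most recent (smallest-clade) one is reported as supported
    and the rest listed.  A marker compatible with no branch is a Dollo
    conflict.
    """
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    for t in matrix.taxa:
        if t not in leaves:
            raise ValueError(f"matrix taxon {t!r} is not a leaf of the tree")
    branch_clades = [(branch_id(n), clade_of(n)) for n in iter_branches(tree)]
    out: list[MarkerMapping] = []
    for marker in matrix.markers:
        ones, zeros, unknown = matrix.column_sets(marker)
        non_q = ones | zeros
        compatible = [
            (bid, clade) for bid, clade in branch_clades
            if (clade & non_q) == ones and ones
        ]
        if not compatible:
            out.append(MarkerMapping(marker, None, True))
            continue
        supported = min(compatible, key=lambda bc: len(bc[1]))[0]
        out.append(MarkerMapping(marker, supported, False,
                                 {bid for bid, _ in compatible}))
    return out


def branch_support_test(n1: int, n2: int, n3: int,
                        branch: str = "") -> BranchSupport:
    """Exact binomial polytomy test for one branch.

    With n = n1+n2+n3 informative markers and equiprobable quartet
    resolutions under a hard polytomy, returns P(X >= n1) for
    X ~ Binomial(n, 1/3), computed as an exact integer tail sum.
    """
    try:
        n1, n2, n3 = (operator.index(v) for v in (n1, n2, n3))
    except TypeError:
        raise ValueError("marker counts must be integers") from None
    if min(n1, n2, n3) < 0:
        raise ValueError("marker counts must be non-negative")
    n = n1 + n2 + n3
    tail = sum(comb(n, k) * 2 ** (n - k) for k in range(n1, n + 1))
    p = Fraction(tail, 3 ** n) if n else Fraction(1)
    return BranchSupport(branch, n1, n2, n3, float(p))


def _alternative_sets(node: dendropy.Node) -> list[frozenset[str]] | None:
    """Discordant local-quartet resolutions of an internal branch (or None)."""
    parent = node.parent_node
    if parent is None or len(node.child_nodes()) != 2:
        return None
    siblings = [c for c in parent.child_nodes() if c is not node]
    if len(siblings) != 1:
        return None
    a, b = (clade_of(c) for c in node.child_nodes())
    c = clade_of(siblings[0])
    return [a | c, b | c]


def branch_support(matrix: PresenceAbsenceMatrix, tree: dendropy.Tree,
                   mappings: list[MarkerMapping] | None = None
                   ) -> dict[str, BranchSupport]:
    """Polytomy-null support for every internal branch.

    n1 counts markers mapping to the branch; n2 and n3 count conflicting
    markers whose presence set matches one of the two discordant resolutions
    of the branch's local quartet (restricted to the marker's non-? taxa).
    """
    if mappings is None:
        mappings = map_markers(matrix, tree)
    by_marker = {m.marker_id: m for m in mappings}
    out: dict[str, BranchSupport] = {}
    for node in iter_branches(tree):
        if node.is_leaf():
            continue
        bid = branch_id(node)
        alts = _alternative_sets(node)
        n1 = sum(1 for m in mappings if m.supported_branch == bid)
        n2 = n3 = 0
        if alts is not None:
            for marker in matrix.markers:
                if not by_marker[marker].conflict:
                    continue
                ones, zeros, _ = matrix.column_sets(marker)
                non_q = ones | zeros
                if ones and ones == (alts[0] & non_q):
                    n2 += 1
                elif ones and ones == (alts[1] & non_q):
                    n3 += 1
        out[bid] = branch_support_test(n1, n2, n3, branch=bid)
    return out


def annotate_tree(tree: dendropy.Tree,
                  supports: dict[str, BranchSupport]) -> dendropy.Tree:
    """Label internal nodes with 'n1/n2/n3' marker counts for newick export."""
    for node in iter_branches(tree):
        bid = branch_id(node)
        if bid in supports and not node.is_leaf():
            s = supports[bid]
            node.label = f"{s.n_support}/{s.n_conflict_a}/{s.n_conflict_b}"
    return tree
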