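"""Parsimony Duplication-Transfer-Loss (DTL) gene/species tree reconciliation.

Given a rooted binary gene tree whose leaves are labelled with species,
and a rooted binary species tree, find a minimum-cost reconciliation
under the undated DTL model: speciations are free, duplications cost
``delta``, transfers cost ``tau`` (the recipient may be any species
lineage neither ancestral nor descendant to the donor), and losses cost
``lam``.  Gene lineages passing through a species node while surviving
in only one child incur a speciation-loss (one loss); a lineage may also
jump to an incomparable lineage while its source copy dies, a
transfer-loss (one transfer plus one loss).  The gene root may map to
any species node with no charge above it.

The dynamic program runs over (gene node, species node) pairs in
postorder, with a shortest-path relaxation per gene node that prices
chains of speciation-losses and transfer-losses between events.  An
optional "dead" (unsampled/extinct) lineage runs parallel to the whole
species tree: chains may enter it for ``tau + lam`` (the sampled copy is
lost) and leave it for ``tau`` alone (losses inside the unsampled
lineage are unobservable), and binary transfer events may use it as
donor or recipient for ``tau``.

``brute_force_cost`` is an independent testing oracle: it exhaustively
enumerates every mapping of gene nodes to species nodes and derives the
forced events and cheapest loss chains per mapping.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy

from .trees import Chronogram, CladeDef, parse_newick

__all__ = [
    "DEAD",
    "CostVector",
    "Event",
    "Reconciliation",
    "reconcile",
    "brute_force_cost",
    "extract_transfers",
    "check_time_consistency",
]

INF = math.inf

#: Identifier of the auxiliary unsampled ("dead") lineage in event records.
DEAD = "dead_lineage"


@dataclass(frozen=True)
class CostVector:
    """Event costs: delta (duplication), tau (transfer), lam (loss)."""

    delta: float = 1.0
    tau: float = 1.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.delta < 0 or self.tau < 0 or self.lam < 0:
            raise ValueError(f"event costs must be nonnegative: {self}")

    @classmethod
    def parse(cls, text: str) -> "CostVector":
        """Parse 'delta,tau,lam' (e.g. '1,3,1')."""
        parts = [p.strip() for p in text.split(",")]
        if len(parts) != 3:
            raise ValueError(f"expected three comma-separated costs, got {text!r}")
        return cls(*(float(p) for p in parts))


@dataclass(frozen=True)
class Event:
    """One reconciliation event.

    ``kind`` is one of speciation, duplication, transfer, loss,
    speciation-loss, transfer-loss.  Losses and compound loss events
    carry no gene node.  Transfers and transfer-losses carry donor and
    recipient species-node identifiers (``DEAD`` for the unsampled
    lineage).
    """

    kind: str
    species_node: str
    gene_node: str | None = None
    donor: str | None = None
    recipient: str | None = None


@dataclass
class Reconciliation:
    total_cost: float
    mapping: dict[str, str]
    events: list[Event]
    cost_vector: CostVector
    dead_lineage_used: bool
    species_leafsets: dict[str, frozenset[str]] = field(default_factory=dict)

    def recomputed_cost(self) -> float:
        """Total cost recomputed from the witness event list.

        Duplications cost delta; transfers and transfer-losses cost tau;
        each loss, speciation-loss, and the loss half of a transfer-loss
        costs lam — except that a transfer-loss leaving the dead lineage
        charges no loss (losses in the unsampled lineage are free).
        """
        c = self.cost_vector
        total = 0.0
        for ev in self.events:
            if ev.kind == "duplication":
                total += c.delta
            elif ev.kind == "transfer":
                total += c.tau
            elif ev.kind in ("loss", "speciation-loss"):
                total += c.lam
            elif ev.kind == "transfer-loss":
                total += c.tau
                if ev.donor != DEAD:
                    total += c.lam
        return total


# ---------------------------------------------------------------------------
# indexed tree representation


class _Indexed:
    """Postorder-indexed rooted binary tree with leaf-set bookkeeping."""

    def __init__(self, tree: dendropy.Tree, kind: str):
        self.names: list[str] = []
        self.children: list[tuple[int, ...]] = []
        self.parent: list[int] = []
        self.labels: list[str | None] = []  # leaf labels
        self.leafsets: list[frozenset[str]] = []
        index: dict[dendropy.Node, int] = {}
        counter = itertools.count()
        for nd in tree.postorder_node_iter():
            kids = nd.child_nodes()
            if kids and len(kids) != 2:
                raise ValueError(
                    f"{kind} tree is not binary: a node has {len(kids)} children "
                    "(polytomies are rejected, not resolved)"
                )
            i = len(self.names)
            index[nd] = i
            if not kids:
                label = nd.taxon.label if nd.taxon is not None else nd.label
                if not label:
                    raise ValueError(f"{kind} tree has an unlabelled leaf")
                self.labels.append(label)
                self.leafsets.append(frozenset({label}))
                self.names.append(label)
                self.children.append(())
            else:
                ci = tuple(index[k] for k in kids)
                self.labels.append(None)
                self.leafsets.append(self.leafsets[ci[0]] | self.leafsets[ci[1]])
                name = None
                if nd.taxon is not None and nd.taxon.label:
                    name = nd.taxon.label
                elif nd.label:
                    name = nd.label
                self.names.append(name if name else f"{kind[0]}{next(counter)}")
                self.children.append(ci)
            self.parent.append(-1)
        for i, kids in enumerate(self.children):
            for k in kids:
                self.parent[k] = i
        # resolve duplicate auto-names defensively
        seen: dict[str, int] = {}
        for i, nm in enumerate(self.names):
            if nm in seen:
                k = seen[nm] + 1
                seen[nm] = k
                self.names[i] = f"{nm}#{k}"
            else:
                seen[nm] = 0
        self.root = len(self.names) - 1
        self.n = len(self.names)
        self.internal = [i for i in range(self.n) if self.children[i]]
        self.leaves = [i for i in range(self.n) if not self.children[i]]

    def ancestor_matrix(self) -> list[list[bool]]:
        """anc[x][y] is True iff x is an ancestor of or equal to y."""
        anc = [[False] * self.n for _ in range(self.n)]
        for x in range(self.n):
            anc[x][x] = True
        for y in range(self.n):
            p = self.parent[y]
            while p != -1:
                anc[p][y] = True
                p = self.parent[p]
        return anc


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    if isinstance(tree, Chronogram):
        return tree.tree
    if isinstance(tree, str):
        return parse_newick(tree)
    raise TypeError(f"expected a tree, got {type(tree)!r}")


def _validate_leaf_labels(gene: _Indexed, species: _Indexed) -> None:
    sp_labels = {species.labels[i] for i in species.leaves}
    if len(sp_labels) != len(species.leaves):
        raise ValueError("species tree leaf labels are not unique")
    missing = {gene.labels[i] for i in gene.leaves} - sp_labels
    if missing:
        raise ValueError(
            f"gene leaf label(s) absent from species tree: {sorted(missing)}"
        )


# ---------------------------------------------------------------------------
# chain graph: prices of loss chains between events


def _incomparable(species: _Indexed, anc: list[list[bool]]) -> list[list[int]]:
    return [
        [z for z in range(species.n) if not anc[x][z] and not anc[z][x]]
        for x in range(species.n)
    ]


def _chain_relax(
    costs: CostVector,
    species: _Indexed,
    incomp: list[list[int]],
    dead: bool,
    base: list[float],
) -> tuple[list[float], list[tuple[str, int] | None]]:
    """Cheapest cost of a loss chain from each entry point to an event.

    ``base[x]`` is the cost of stopping (holding the event) at ``x``;
    index ``species.n`` is the dead lineage when enabled.  Returns the
    relaxed values and predecessor steps ('sl' speciation-loss to child,
    'tl' transfer-loss to an incomparable node or the dead lineage,
    'td' transfer out of the dead lineage); ``None`` marks a stop.
    """
    n = species.n + (1 if dead else 0)
    a = list(base)
    pred: list[tuple[str, int] | None] = [None] * n
    d = species.n  # dead index
    for _ in range(n + 1):
        changed = False
        for x in range(species.n):
            for xc in species.children[x]:
                v = costs.lam + a[xc]
                if v < a[x]:
                    a[x], pred[x] = v, ("sl", xc)
                    changed = True
            jump = costs.tau + costs.lam
            for z in incomp[x]:
                v = jump + a[z]
                if v < a[x]:
                    a[x], pred[x] = v, ("tl", z)
                    changed = True
            if dead:
                v = jump + a[d]
                if v < a[x]:
                    a[x], pred[x] = v, ("tl", d)
                    changed = True
        if dead:
            for z in range(species.n):
                v = costs.tau + a[z]
                if v < a[d]:
                    a[d], pred[d] = v, ("td", z)
                    changed = True
        if not changed:
            break
    return a, pred


def _chain_matrix(
    costs: CostVector,
    species: _Indexed,
    incomp: list[list[int]],
    dead: bool,
) -> list[list[float]]:
    """All-pairs chain costs T[entry][stop] for the brute-force oracle."""
    n = species.n + (1 if dead else 0)
    T = []
    for stop in range(n):
        base = [INF] * n
        base[stop] = 0.0
        a, _ = _chain_relax(costs, species, incomp, dead, base)
        T.append(a)  # a[entry] = cost entry -> stop
    # transpose to T[entry][stop]
    return [[T[stop][entry] for stop in range(n)] for entry in range(n)]


# ---------------------------------------------------------------------------
# the dynamic program


def reconcile(
    gene_tree,
    species_tree,
    costs: CostVector = CostVector(),
    dead_lineage: bool = False,
) -> Reconciliation:
    """Minimum-cost undated DTL reconciliation with one witness history.

    Both trees must be rooted and binary; every gene-tree leaf must be
    labelled with a species-tree leaf label (duplicate labels denote
    distinct gene copies).  Ties are broken by a fixed event-preference
    order (speciation < transfer < duplication), then by species-node
    postorder index; exactly one most-parsimonious witness is returned.
    """
    gene = _Indexed(_as_tree(gene_tree), "gene")
    species = _Indexed(_as_tree(species_tree), "species")
    _validate_leaf_labels(gene, species)
    anc = species.ancestor_matrix()
    incomp = _incomparable(species, anc)
    nS = species.n + (1 if dead_lineage else 0)
    d = species.n  # dead index (valid only when dead_lineage)
    sp_leaf_index = {species.labels[i]: i for i in species.leaves}

    # per gene node: event cost c[x], chain cost a[x], and choice records
    C: list[list[float]] = [[] for _ in range(gene.n)]
    A: list[list[float]] = [[] for _ in range(gene.n)]
    PRED: list[list[tuple[str, int] | None]] = [[] for _ in range(gene.n)]
    CHOICE: list[list[tuple | None]] = [[] for _ in range(gene.n)]

    for u in range(gene.n):
        kids = gene.children[u]
        c = [INF] * nS
        choice: list[tuple | None] = [None] * nS
        if not kids:
            c[sp_leaf_index[gene.labels[u]]] = 0.0
            choice[sp_leaf_index[gene.labels[u]]] = ("leaf",)
        else:
            v1, v2 = kids
            a1, a2 = A[v1], A[v2]
            # bests over incomparable nodes for the transfer move
            def best_incomp(avals: list[float], x: int) -> tuple[float, int]:
                best, arg = INF, -1
                pool = incomp[x] if x < species.n else list(range(species.n))
                for z in pool:
                    if avals[z] < best:
                        best, arg = avals[z], z
                if dead_lineage and x < species.n and avals[d] < best:
                    best, arg = avals[d], d
                return best, arg

            for x in range(nS):
                best, pick = INF, None
                # speciation (preference order: speciation < transfer < duplication)
                if x < species.n and species.children[x]:
                    l, r = species.children[x]
                    v = a1[l] + a2[r]
                    if v < best:
                        best, pick = v, ("spec", v1, l, v2, r)
                    v = a1[r] + a2[l]
                    if v < best:
                        best, pick = v, ("spec", v1, r, v2, l)
                # transfer: one child stays, the other enters an incomparable
                # lineage (or the dead lineage, or leaves it when x is dead)
                b2, z2 = best_incomp(a2, x)
                v = costs.tau + a1[x] + b2
                if v < best:
                    best, pick = v, ("trans", v1, v2, z2)
                b1, z1 = best_incomp(a1, x)
                v = costs.tau + a2[x] + b1
                if v < best:
                    best, pick = v, ("trans", v2, v1, z1)
                # duplication
                v = costs.delta + a1[x] + a2[x]
                if v < best:
                    best, pick = v, ("dup", v1, v2)
                c[x], choice[x] = best, pick
        a, pred = _chain_relax(costs, species, incomp, dead_lineage, c)
        C[u], A[u], PRED[u], CHOICE[u] = c, a, pred, choice

    croot = C[gene.root]
    total = min(croot)
    root_x = croot.index(total)  # lowest postorder index on ties

    # -- witness reconstruction -----------------------------------------
    def name_of(x: int) -> str:
        return DEAD if x == species.n else species.names[x]

    mapping: dict[str, str] = {}
    events: list[Event] = []
    dead_used = False

    def emit_event(u: int, x: int) -> None:
        nonlocal dead_used
        mapping[gene.names[u]] = name_of(x)
        if x == species.n:
            dead_used = True
        pick = CHOICE[u][x]
        if pick is None:
            raise AssertionError("witness reconstruction reached an invalid state")
        if pick[0] == "leaf":
            return
        if pick[0] == "spec":
            _, va, xa, vb, xb = pick
            events.append(
                Event("speciation", species_node=name_of(x), gene_node=gene.names[u])
            )
            emit_chain(va, xa)
            emit_chain(vb, xb)
        elif pick[0] == "dup":
            _, va, vb = pick
            events.append(
                Event("duplication", species_node=name_of(x), gene_node=gene.names[u])
            )
            emit_chain(va, x)
            emit_chain(vb, x)
        else:  # transfer
            _, vstay, vmove, z = pick
            if z == species.n:
                dead_used = True
            events.append(
                Event(
                    "transfer",
                    species_node=name_of(x),
                    gene_node=gene.names[u],
                    donor=name_of(x),
                    recipient=name_of(z),
                )
            )
            emit_chain(vstay, x)
            emit_chain(vmove, z)

    def emit_chain(u: int, entry: int) -> None:
        nonlocal dead_used
        x = entry
        guard = 0
        while PRED[u][x] is not None:
            step, nxt = PRED[u][x]
            if step == "sl":
                events.append(Event("speciation-loss", species_node=name_of(x)))
            else:  # 'tl' or 'td'
                if x == species.n or nxt == species.n:
                    dead_used = True
                events.append(
                    Event(
                        "transfer-loss",
                        species_node=name_of(x),
                        donor=name_of(x),
                        recipient=name_of(nxt),
                    )
                )
            x = nxt
            guard += 1
            if guard > 4 * nS + 4:
                raise AssertionError("loss-chain reconstruction did not terminate")
        emit_event(u, x)

    emit_event(gene.root, root_x)

    leafsets = {species.names[i]: species.leafsets[i] for i in range(species.n)}
    return Reconciliation(
        total_cost=total,
        mapping=mapping,
        events=events,
        cost_vector=costs,
        dead_lineage_used=dead_used,
        species_leafsets=leafsets,
    )


# ---------------------------------------------------------------------------
# exhaustive oracle


def brute_force_cost(
    gene_tree,
    species_tree,
    costs: CostVector = CostVector(),
    dead_lineage: bool = False,
    max_leaves: int = 6,
) -> float:
    """Minimum DTL cost by exhaustive enumeration of gene-node mappings.

    Every assignment of internal gene nodes to species nodes (and the
    dead lineage, when enabled) is enumerated; for each, the forced
    event at every gene node and the cheapest loss chains connecting it
    to its children's positions are priced, and the overall minimum is
    returned.  Intended purely as a testing oracle; refuses gene trees
    with more than ``max_leaves`` leaves.
    """
    gene = _Indexed(_as_tree(gene_tree), "gene")
    species = _Indexed(_as_tree(species_tree), "species")
    _validate_leaf_labels(gene, species)
    if len(gene.leaves) > max_leaves:
        raise ValueError(
            f"brute force limited to {max_leaves} gene leaves, "
            f"got {len(gene.leaves)}"
        )
    anc = species.ancestor_matrix()
    incomp = _incomparable(species, anc)
    nS = species.n + (1 if dead_lineage else 0)
    T = _chain_matrix(costs, species, incomp, dead_lineage)
    # min over incomparable entries: M[x][stop] = min_{z inc x} T[z][stop]
    pools = [incomp[x] for x in range(species.n)]
    if dead_lineage:
        pools = [p + [species.n] for p in pools] + [list(range(species.n))]
    M = [
        [min((T[z][s] for z in pools[x]), default=INF) for s in range(nS)]
        for x in range(nS)
    ]
    sp_leaf_index = {species.labels[i]: i for i in species.leaves}
    fixed = {u: sp_leaf_index[gene.labels[u]] for u in gene.leaves}
    internal = gene.internal
    tau, delta = costs.tau, costs.delta

    def local(x: int, y1: int, y2: int) -> float:
        best = INF
        if x < species.n and species.children[x]:
            l, r = species.children[x]
            best = min(best, T[l][y1] + T[r][y2], T[l][y2] + T[r][y1])
        best = min(
            best,
            tau + T[x][y1] + M[x][y2],
            tau + T[x][y2] + M[x][y1],
            delta + T[x][y1] + T[x][y2],
        )
        return best

    best_total = INF
    for combo in itertools.product(range(nS), repeat=len(internal)):
        m = dict(zip(internal, combo))
        m.update(fixed)
        total = 0.0
        for u in internal:
            v1, v2 = gene.children[u]
            total += local(m[u], m[v1], m[v2])
            if total >= best_total:
                break
        if total < best_total:
            best_total = total
    return best_total


# ---------------------------------------------------------------------------
# transfer extraction and time consistency

from .assess import HGTConstraint  # noqa: E402  (no cycle: assess imports trees only)


def _transfer_events(rec: Reconciliation) -> list[Event]:
    return [ev for ev in rec.events if ev.kind in ("transfer", "transfer-loss")]


def _node_in_chronogram(
    chronogram: Chronogram, leafset: frozenset[str]
) -> dendropy.Node:
    return chronogram.mrca(leafset)


def extract_transfers(
    rec: Reconciliation, species_chronogram: Chronogram
) -> list[HGTConstraint]:
    """One HGT constraint per transfer event in the witness history.

    Donor and recipient clades are the leaf sets below the donor and
    recipient species nodes.  Transfers to or from the dead lineage are
    reported but flagged untestable (no clade exists for that side).
    """
    if rec.species_leafsets:
        sp_leaves = frozenset().union(
            *(s for s in rec.species_leafsets.values())
        )
        if sp_leaves != species_chronogram.leaf_labels:
            raise ValueError(
                "chronogram leaf set does not match the reconciled species tree"
            )
    out = []
    for i, ev in enumerate(_transfer_events(rec)):
        dead = DEAD in (ev.donor, ev.recipient)
        donor_taxa = rec.species_leafsets.get(ev.donor, frozenset())
        recip_taxa = rec.species_leafsets.get(ev.recipient, frozenset())
        out.append(
            HGTConstraint(
                id=f"hgt{i}",
                donor=CladeDef(ev.donor, donor_taxa or frozenset({DEAD})),
                recipient=CladeDef(ev.recipient, recip_taxa or frozenset({DEAD})),
                mode="crown-crown",
                testable=not dead,
            )
        )
    return out


def check_time_consistency(
    rec: Reconciliation, chronogram: Chronogram
) -> dict[str, bool]:
    """Interval-overlap check per transfer in the witness history.

    A transfer requires donor and recipient lineages to be
    contemporaneous: the donor edge's time span [child age, parent age]
    must overlap the recipient edge's span (open intervals; touching
    endpoints do not count).  Transfers involving the dead lineage are
    omitted (untestable).  Keys are ``hgt{i}`` in witness order,
    matching :func:`extract_transfers`.
    """
    out: dict[str, bool] = {}
    for i, ev in enumerate(_transfer_events(rec)):
        if DEAD in (ev.donor, ev.recipient):
            continue
        spans = []
        for name in (ev.donor, ev.recipient):
            node = _node_in_chronogram(chronogram, rec.species_leafsets[name])
            child_age = chronogram.age(node)
            parent = node.parent_node
            parent_age = chronogram.age(parent) if parent is not None else INF
            spans.append((child_age, parent_age))
        (c1, p1), (c2, p2) = spans
        out[f"hgt{i}"] = max(c1, c2) < min(p1, p2)
    return out
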