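"""Synthetic data emulating the study inputs: dated species trees, gene histories
with duplication/transfer/loss, protein alignments with rate heterogeneity and
indels (and an acidic compositional bias for halophilic families), and
sigmoidal folded-fraction vs. salt-concentration curves.

Every generator is a pure function of (parameters, seed): repeated calls are
byte-identical, and the returned :class:`SimulationTruth` carries everything a
recovery test needs (true tree, true gapped ancestors, event list, seed).
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment import Alignment, GAP
from .models import SubstitutionModel, build_rate_matrix
from .trees import DatedSpeciesTree, Node, Tree

__all__ = [
    "EventRecord",
    "SimulationTruth",
    "StabilityCurve",
    "simulate_species_tree",
    "simulate_gene_history",
    "replay_events",
    "simulate_alignment",
    "simulate_stability_curve",
    "scale_branch_lengths",
]


class SimulationError(ValueError):
    pass


class _BDNode(Node):
    """Birth-death simulation node carrying absolute times."""

    __slots__ = ("_time", "_end")


# ---------------------------------------------------------------------------
# dated species trees


def simulate_species_tree(
    n_taxa: int, birth: float, death: float, seed: int
) -> DatedSpeciesTree:
    """Birth–death tree conditioned on ``n_taxa`` surviving leaves.

    Forward (Gillespie) simulation from a single lineage; runs that go extinct
    are restarted. The present is the moment the ``n_taxa``-th lineage
    appears; extinct side branches are pruned, so all leaves sit at age 0.
    """
    if n_taxa < 2:
        raise SimulationError("need at least 2 taxa")
    if not birth > death or death < 0:
        raise SimulationError("need birth > death >= 0")
    rng = np.random.default_rng(seed)
    total_rate = birth + death
    p_speciate = birth / total_rate
    while True:
        root = _BDNode()
        root._time = 0.0
        alive = [root]
        t = 0.0
        while 0 < len(alive) < n_taxa:
            t += rng.exponential(1.0 / (total_rate * len(alive)))
            k = rng.integers(len(alive))
            node = alive.pop(int(k))
            node._end = t
            if rng.random() < p_speciate:
                for _ in range(2):
                    child = _BDNode()
                    child._time = t
                    node.add_child(child)
                    alive.append(child)
            # else: death -- lineage simply ends
        if alive:
            break
    # the present sits one (censored) waiting time after the n-th lineage
    # appeared, so the youngest speciation is strictly older than the leaves
    present = t + rng.exponential(1.0 / (total_rate * n_taxa))
    for leaf in alive:
        leaf._end = present
    pruned = _prune_dead(root, survivors=set(map(id, alive)))
    tree = Tree(pruned)
    # branch lengths and ages in time units
    for node in tree.postorder():
        node.age = present - node._end
    for node in tree.preorder():
        node.length = None if node.parent is None else node.parent.age - node.age
    for i, leaf in enumerate(sorted(tree.leaves(), key=lambda n: n._time)):
        leaf.label = f"S{i + 1}"
    tree.label_internal(prefix="N")
    return DatedSpeciesTree(tree)


def _prune_dead(root: Node, survivors: set[int]) -> Node:
    """Keep only lineages ancestral to surviving leaves; suppress unary nodes."""

    def rec(node: Node) -> Optional[Node]:
        if node.is_leaf:
            return node if id(node) in survivors else None
        kept = [c for c in (rec(c) for c in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        node.children = []
        for c in kept:
            node.add_child(c)
        return node

    out = rec(root)
    if out is None:
        raise SimulationError("no survivors")  # pragma: no cover - caller restarts
    out.parent = None
    return out


# ---------------------------------------------------------------------------
# gene histories under duplication / transfer / loss


@dataclass
class EventRecord:
    """One event of a simulated gene history (ages count back from the present)."""

    kind: str  # speciation | duplication | transfer | loss
    time: float
    donor: str  # species branch (label of the branch's child node)
    recipient: Optional[str] = None  # transfers only
    gene_node: Optional[str] = None  # label in the pruned gene tree, if it survived
    lineage: int = -1
    child_lineages: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "time": float(self.time),
            "donor": self.donor,
            "recipient": self.recipient,
            "gene_node": self.gene_node,
            "lineage": self.lineage,
            "child_lineages": list(self.child_lineages),
        }


class _GNode(Node):
    __slots__ = ("time", "lineage")


def simulate_gene_history(
    stree: DatedSpeciesTree,
    dup_rate: float,
    transfer_rate: float,
    loss_rate: float,
    seed: int,
    replace: bool = False,
) -> tuple[Optional[Tree], list[EventRecord]]:
    """One gene lineage enters at the species root; D/T/L fire as independent
    Poisson processes along species branches; speciations bifurcate surviving
    lineages.

    Transfers copy the lineage into a uniformly chosen contemporaneous other
    branch; with ``replace=True`` the recipient branch's resident gene copies
    are lost at the transfer (the horizontal-replacement scenario). Branch
    lengths of the returned tree are in time units (see
    :func:`scale_branch_lengths`). Returns ``(None, events)`` if every lineage
    is lost.
    """
    if min(dup_rate, transfer_rate, loss_rate) < 0:
        raise SimulationError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    total = dup_rate + transfer_rate + loss_rate
    sroot = stree.root
    branches = [n for n in stree.tree.postorder() if n.parent is not None]
    branches.sort(key=lambda n: n.label)

    events: list[EventRecord] = []
    next_lineage = [0]
    # lineage bookkeeping: id -> (species branch node, current age); fate filled on termination
    fate: dict[int, EventRecord | str] = {}
    leaf_species: dict[int, Node] = {}
    lineage_on: dict[int, Node] = {}
    dead: set[int] = set()
    heap: list[tuple[float, int, int]] = []  # (-age of next wake-up, counter, lineage)
    counter = [0]

    _pending: dict[int, tuple[float, bool]] = {}

    def spawn2(branch: Node, age: float) -> int:
        """Spawn a lineage on ``branch`` at ``age``; schedules its next event."""
        lid = next_lineage[0]
        next_lineage[0] += 1
        lineage_on[lid] = branch
        if total > 0:
            ev_age = age - rng.exponential(1.0 / total)
        else:
            ev_age = -np.inf
        if ev_age > branch.age:
            _pending[lid] = (ev_age, True)
            heapq.heappush(heap, (-ev_age, counter[0], lid))
        else:
            _pending[lid] = (branch.age, False)
            heapq.heappush(heap, (-branch.age, counter[0], lid))
        counter[0] += 1
        return lid

    # the gene lineage enters at the species root: an immediate speciation
    root_children: list[int] = [spawn2(c, sroot.age) for c in sroot.children]
    root_event = EventRecord(
        kind="speciation", time=sroot.age, donor=sroot.label or "root",
        lineage=-1, child_lineages=tuple(root_children),
    )
    events.append(root_event)

    def alive_branches_at(age: float, exclude: Node) -> list[Node]:
        out = []
        for b in branches:
            if b is exclude:
                continue
            if b.parent.age > age > b.age:
                out.append(b)
        return out

    while heap:
        neg_age, _, lid = heapq.heappop(heap)
        if lid in dead:
            continue
        age = -neg_age
        pend_age, is_event = _pending[lid]
        if pend_age != age:
            continue  # stale entry
        branch = lineage_on[lid]
        if not is_event:
            # branch boundary
            if branch.is_leaf:
                fate[lid] = "extant"
                leaf_species[lid] = branch
            else:
                kids = [spawn2(c, branch.age) for c in branch.children]
                ev = EventRecord("speciation", branch.age, branch.label,
                                 lineage=lid, child_lineages=tuple(kids))
                events.append(ev)
                fate[lid] = ev
            continue
        # a D/T/L event on this branch at this age
        u = rng.random()
        if u < loss_rate / total:
            ev = EventRecord("loss", age, branch.label, lineage=lid)
            events.append(ev)
            fate[lid] = ev
            dead.add(lid)
        elif u < (loss_rate + dup_rate) / total:
            kids = (spawn2(branch, age), spawn2(branch, age))
            ev = EventRecord("duplication", age, branch.label, lineage=lid,
                             child_lineages=kids)
            events.append(ev)
            fate[lid] = ev
        else:
            candidates = alive_branches_at(age, exclude=branch)
            if not candidates:
                # no contemporaneous recipient: the attempt is a no-op; reschedule
                if total > 0:
                    ev_age = age - rng.exponential(1.0 / total)
                else:  # pragma: no cover
                    ev_age = -np.inf
                if ev_age > branch.age:
                    _pending[lid] = (ev_age, True)
                    heapq.heappush(heap, (-ev_age, counter[0], lid))
                else:
                    _pending[lid] = (branch.age, False)
                    heapq.heappush(heap, (-branch.age, counter[0], lid))
                counter[0] += 1
                continue
            recipient = candidates[int(rng.integers(len(candidates)))]
            if replace:
                for other, ob in list(lineage_on.items()):
                    if ob is recipient and other not in dead and other not in fate and other != lid:
                        ev_l = EventRecord("loss", age, recipient.label, lineage=other)
                        events.append(ev_l)
                        fate[other] = ev_l
                        dead.add(other)
            kids = (spawn2(branch, age), spawn2(recipient, age))
            ev = EventRecord("transfer", age, branch.label, recipient=recipient.label,
                             lineage=lid, child_lineages=kids)
            events.append(ev)
            fate[lid] = ev

    gtree = _assemble_gene_tree(root_event, fate, leaf_species, events)
    return gtree, events


def _assemble_gene_tree(
    root_event: EventRecord,
    fate: dict[int, "EventRecord | str"],
    leaf_species: dict[int, Node],
    events: list[EventRecord],
) -> Optional[Tree]:
    # deterministic per-species copy numbering by lineage id
    copy_no: dict[int, str] = {}
    per_species: dict[str, int] = {}
    for lid in sorted(leaf_species):
        sp = leaf_species[lid].label
        per_species[sp] = per_species.get(sp, 0) + 1
        copy_no[lid] = f"{sp}|{per_species[sp]}"

    node_of_event: dict[int, _GNode] = {}

    def build(lid: int) -> Optional[_GNode]:
        f = fate.get(lid)
        if f == "extant":
            n = _GNode(copy_no[lid])
            n.time = 0.0
            n.lineage = lid
            return n
        if f is None or f.kind == "loss":
            return None
        kids = [build(c) for c in f.child_lineages]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        n = _GNode()
        n.time = f.time
        n.lineage = lid
        for k in kids:
            n.add_child(k)
        node_of_event[id(f)] = n
        return n

    kids = [build(c) for c in root_event.child_lineages]
    kids = [k for k in kids if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        root = kids[0]
    else:
        root = _GNode()
        root.time = root_event.time
        root.lineage = -1
        node_of_event[id(root_event)] = root
        for k in kids:
            root.add_child(k)
    for node in Tree(root).preorder():
        node.length = None if node.parent is None else node.parent.time - node.time
    tree = Tree(root)
    tree.label_internal(prefix="g")
    for ev in events:
        n = node_of_event.get(id(ev))
        ev.gene_node = n.label if n is not None else None
    return tree


def replay_events(stree: DatedSpeciesTree, events: list[EventRecord]) -> Optional[Tree]:
    """Rebuild the gene tree implied by an event list (round-trip check).

    Speciation records name the species node where they happen; the species
    tree resolves which branches the child lineages were spawned on, so every
    surviving (fate-less) lineage can be placed on its leaf branch.
    """
    by_label = {n.label: n for n in stree.tree.postorder()}
    fate: dict[int, EventRecord | str] = {}
    root_event = None
    spawned_on: dict[int, Node] = {}
    for ev in events:
        if ev.lineage == -1 and ev.kind == "speciation":
            root_event = ev
        else:
            fate[ev.lineage] = ev
        node = by_label[ev.donor]
        if ev.kind == "speciation":
            branches = list(node.children)
        elif ev.kind == "transfer":
            branches = [node, by_label[ev.recipient]]
        else:
            branches = [node] * len(ev.child_lineages)
        for c, br in zip(ev.child_lineages, branches):
            spawned_on[c] = br
    if root_event is None:
        raise SimulationError("event list has no root speciation")
    leaf_species: dict[int, Node] = {}
    for lid, br in spawned_on.items():
        if lid not in fate:
            fate[lid] = "extant"
            leaf_species[lid] = br
    return _assemble_gene_tree(root_event, fate, leaf_species, [])


def scale_branch_lengths(tree: Tree, factor: float) -> Tree:
    """Convert time-unit branch lengths to expected replacements per site."""
    out = tree.copy()
    for node in out.postorder():
        if node.length is not None:
            node.length *= factor
    return out


# ---------------------------------------------------------------------------
# sequence evolution with indels


@dataclass
class SimulationTruth:
    """Ground truth of one simulated family: tree, gapped ancestors, events, seed."""

    gene_tree: Tree
    ancestors: dict[str, str]  # internal node label -> gapped true sequence
    events: list[EventRecord] = field(default_factory=list)
    site_categories: Optional[np.ndarray] = None
    params: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "params": self.params,
                "events": [e.to_dict() for e in self.events],
                "ancestors": self.ancestors,
            },
            indent=1,
            sort_keys=True,
        )


def simulate_alignment(
    gtree: Tree,
    model: SubstitutionModel,
    root_length: int,
    indel_rate: float = 0.0,
    mean_indel_len: float = 3.0,
    halophilic_bias: Optional[np.ndarray] = None,
    seed: int = 0,
) -> tuple[Alignment, SimulationTruth]:
    """Evolve a protein alignment down a gene tree.

    The root sequence is drawn from the stationary frequencies (or the
    supplied halophilic bias, which also re-parameterizes Q so the bias is the
    stationary composition of the process). Each site carries one gamma
    category drawn at the root and inherited. Indel events fire per branch as
    a Poisson process with rate ``indel_rate`` per site per unit length,
    insertion or deletion with equal probability, geometric lengths. Column
    bookkeeping keeps the true alignment exact — no aligner runs downstream.
    """
    if root_length < 1:
        raise SimulationError("root_length must be >= 1")
    if halophilic_bias is not None:
        bias = np.asarray(halophilic_bias, float)
        if bias.shape != (model.n_states,) or np.any(bias <= 0) or abs(bias.sum() - 1) > 1e-9:
            raise SimulationError("halophilic_bias is not a valid frequency vector")
        model = model.with_frequencies(bias)
    rng = np.random.default_rng(seed)
    rm = build_rate_matrix(model)
    rates = model.rates()
    n_states = model.n_states
    gtree = gtree.copy()
    gtree.label_internal(prefix="g")

    # master column order; each column has a unique id
    master: list[int] = list(range(root_length))
    next_col = [root_length]

    def draw_states(n: int) -> np.ndarray:
        return rng.choice(n_states, size=n, p=model.pi)

    root_states = draw_states(root_length)
    root_cats = rng.integers(model.K, size=root_length)
    # node -> list of (col_id, state, cat) in sequence order
    seqs: dict[Node, list[tuple[int, int, int]]] = {
        gtree.root: [(j, int(root_states[j]), int(root_cats[j])) for j in range(root_length)]
    }

    P_cache: dict[tuple[int, float], np.ndarray] = {}

    def P(cat: int, t: float) -> np.ndarray:
        key = (cat, t)
        if key not in P_cache:
            P_cache[key] = rm.transition_matrix(t * rates[cat])
        return P_cache[key]

    for node in gtree.preorder():
        if node is gtree.root:
            continue
        parent_seq = seqs[node.parent]
        t = node.length or 0.0
        # substitutions, per category
        new_seq: list[tuple[int, int, int]] = []
        if parent_seq:
            cats = np.array([c for _, _, c in parent_seq])
            states = np.array([s for _, s, c in parent_seq])
            child_states = np.empty(len(parent_seq), dtype=np.int64)
            for cat in range(model.K):
                mask = cats == cat
                if not mask.any():
                    continue
                Pm = P(cat, t)
                u = rng.random(int(mask.sum()))
                cum = np.cumsum(Pm[states[mask]], axis=1)
                child_states[mask] = (u[:, None] < cum).argmax(axis=1)
            new_seq = [
                (col, int(st), int(cat))
                for (col, _, cat), st in zip(parent_seq, child_states)
            ]
        # indels
        if indel_rate > 0 and new_seq:
            n_events = rng.poisson(indel_rate * t * len(new_seq))
            for _ in range(n_events):
                if not new_seq:
                    break
                length = int(rng.geometric(1.0 / mean_indel_len))
                if rng.random() < 0.5:  # insertion
                    pos = int(rng.integers(len(new_seq) + 1))
                    states_new = draw_states(length)
                    cats_new = rng.integers(model.K, size=length)
                    ids = list(range(next_col[0], next_col[0] + length))
                    next_col[0] += length
                    # place the new columns in the master order after the left
                    # neighbour column (or at the very front)
                    if pos == 0:
                        anchor = master.index(new_seq[0][0])
                    else:
                        anchor = master.index(new_seq[pos - 1][0]) + 1
                    master[anchor:anchor] = ids
                    new_seq[pos:pos] = [
                        (cid, int(s), int(c)) for cid, s, c in zip(ids, states_new, cats_new)
                    ]
                else:  # deletion
                    start = int(rng.integers(len(new_seq)))
                    del new_seq[start : start + length]
        seqs[node] = new_seq

    # assemble the true alignment over columns present in at least one leaf
    leaves = gtree.leaves()
    present_cols = set()
    for lf in leaves:
        present_cols.update(col for col, _, _ in seqs[lf])
    ordered = [c for c in master if c in present_cols]
    col_pos = {c: i for i, c in enumerate(ordered)}
    L = len(ordered)

    def gapped(node: Node) -> str:
        row = [GAP] * L
        for col, st, _ in seqs[node]:
            if col in col_pos:
                row[col_pos[col]] = model.alphabet[st]
        return "".join(row)

    alignment = Alignment([lf.label for lf in leaves], [gapped(lf) for lf in leaves])
    ancestors = {n.label: gapped(n) for n in gtree.internal_nodes()}
    site_cats = np.full(L, -1, dtype=np.int64)
    for col, _, cat in seqs[gtree.root]:
        if col in col_pos:
            site_cats[col_pos[col]] = cat
    truth = SimulationTruth(
        gene_tree=gtree,
        ancestors=ancestors,
        site_categories=site_cats,
        params={
            "root_length": root_length,
            "indel_rate": indel_rate,
            "mean_indel_len": mean_indel_len,
            "halophilic_bias": None if halophilic_bias is None else list(map(float, halophilic_bias)),
            "alpha": model.alpha,
            "K": model.K,
        },
        seed=seed,
    )
    return alignment, truth


# ---------------------------------------------------------------------------
# salt-stability transition curves


@dataclass
class StabilityCurve:
    """Folded fraction vs. salt concentration (M); increasing for halophiles,
    which unfold when the salt concentration drops."""

    salt: str
    concentrations: np.ndarray
    fractions: np.ndarray
    true_midpoint: Optional[float] = None
    true_width: Optional[float] = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, float)
        self.fractions = np.asarray(self.fractions, float)
        if np.any(np.diff(self.concentrations) <= 0):
            raise SimulationError("concentrations must be strictly increasing")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise SimulationError("fractions outside [0, 1]")

    def to_csv(self) -> str:
        lines = ["concentration_M,folded_fraction"]
        for c, f in zip(self.concentrations, self.fractions):
            lines.append(f"{c:.6g},{f:.6g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_csv(cls, text: str, salt: str = "KCl") -> "StabilityCurve":
        rows = [ln for ln in text.strip().splitlines() if ln and not ln[0].isalpha()]
        data = np.array([[float(x) for x in ln.split(",")[:2]] for ln in rows])
        return cls(salt, data[:, 0], data[:, 1])


def logistic_folded_fraction(c, midpoint: float, width: float):
    return 1.0 / (1.0 + np.exp(-(np.asarray(c, float) - midpoint) / width))


def simulate_stability_curve(
    mf_half: float,
    width: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
    salt: str = "KCl",
) -> StabilityCurve:
    """Noisy logistic transition curve with known midpoint (the M^f½ truth)."""
    if not width > 0:
        raise SimulationError("width must be positive")
    conc = np.asarray(concentrations, float)
    f = logistic_folded_fraction(conc, mf_half, width)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = np.clip(f + rng.normal(0.0, noise_sd, size=f.shape), 0.0, 1.0)
    return StabilityCurve(salt, conc, f, true_midpoint=mf_half, true_width=width)
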