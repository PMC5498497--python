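"""Maximum-parsimony trees over haplotype alignments.

The Fitch algorithm scores a fixed topology (gaps and N as wildcards);
``mp_search`` finds a best topology by exact branch-and-bound for small leaf
counts and by randomized stepwise addition followed by NNI and SPR hill
climbing otherwise, honouring user monophyly constraints. Trees are rooted
on the first outgroup, and a Fitch backtrace assigns every mutation to a
branch — the per-branch counts that the molecular clock consumes.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass

import numpy as np

BASE_MASK = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 15, "-": 15}
MASK_BASE = {1: "A", 2: "C", 4: "G", 8: "T"}
WILDCARD = 15


# ---------------------------------------------------------------------------
# tree structure


class Node:
    __slots__ = ("name", "children", "parent", "mutations", "k", "age", "age_se",
                 "tip_age")

    def __init__(self, name: str | None = None):
        self.name = name
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.mutations: list[tuple[int, str, str]] = []  # (column, from, to)
        self.k: int = 0  # mutation count on the branch to the parent
        self.age: float | None = None  # years before present
        self.age_se: float | None = None
        self.tip_age: float = 0.0  # sampling age of a dated tip, years BP

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted tree with per-branch mutation assignments and optional ages."""

    def __init__(self, root: Node):
        self.root = root
        self.parsimony_length: int | None = None

    # -- traversal ---------------------------------------------------------
    def postorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def leafset(self, node: Node) -> frozenset:
        out = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.add(n.name)
            stack.extend(n.children)
        return frozenset(out)

    # -- queries -----------------------------------------------------------
    def mrca(self, names) -> Node:
        names = set(names)
        missing = names - set(self.leaf_names())
        if missing:
            raise ValueError(f"unknown leaves: {sorted(missing)}")
        best = None
        for node in self.postorder():
            if names <= self.leafset(node):
                best = node
                break
        return best if best is not None else self.root

    def is_monophyletic(self, names) -> bool:
        return self.leafset(self.mrca(names)) == frozenset(names)

    @property
    def tree_length(self) -> int:
        return sum(n.k for n in self.postorder() if n.parent is not None)

    # -- I/O ---------------------------------------------------------------
    def newick(self, lengths: str | None = "k") -> str:
        """Newick string; ``lengths`` is 'k' (mutation counts), 'age' (branch
        durations in years), or None. Children are sorted for determinism."""

        def fmt(node: Node) -> str:
            if node.is_leaf:
                label = node.name
            else:
                label = "(" + ",".join(sorted(fmt(c) for c in node.children)) + ")"
            if lengths == "k" and node.parent is not None:
                label += f":{node.k}"
            elif lengths == "age" and node.parent is not None:
                dur = (node.parent.age or 0.0) - (node.age or 0.0)
                label += f":{dur:.6g}"
            return label

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, source: str, lengths: str = "k") -> "PhyloTree":
        """Parse newick (string or path) via dendropy; edge lengths go to
        ``k`` (rounded) when lengths='k', or are accumulated into node ages
        (years before present) when lengths='age'."""
        import dendropy

        text = source
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, ValueError):
            pass
        dtree = dendropy.Tree.get(data=text, schema="newick")
        root = Node()
        mapping = {dtree.seed_node: root}
        for dnode in dtree.preorder_node_iter():
            if dnode is dtree.seed_node:
                continue
            node = Node(dnode.taxon.label if dnode.taxon else None)
            if lengths == "k":
                node.k = int(round(dnode.edge.length or 0))
            mapping[dnode.parent_node].add(node)
            mapping[dnode] = node
        tree = cls(root)
        if lengths == "age":
            depth = {root: 0.0}
            for dnode in dtree.preorder_node_iter():
                if dnode is dtree.seed_node:
                    continue
                depth[mapping[dnode]] = depth[mapping[dnode.parent_node]] + (
                    dnode.edge.length or 0.0
                )
            max_depth = max(depth[n] for n in mapping.values() if n.is_leaf)
            for node, d in depth.items():
                node.age = max_depth - d
        return tree


# ---------------------------------------------------------------------------
# Fitch scoring on PhyloTree


def _profiles(sequences: dict[str, str], columns=None) -> dict[str, np.ndarray]:
    ids = list(sequences)
    L = len(sequences[ids[0]])
    cols = range(L) if columns is None else columns
    out = {}
    for sid in ids:
        seq = sequences[sid]
        out[sid] = np.array([BASE_MASK.get(seq[c], WILDCARD) for c in cols], dtype=np.uint8)
    return out


def fitch_length(tree: PhyloTree, sequences: dict[str, str]) -> int:
    """Minimal substitution count of the topology over all columns.

    Gaps and N are wildcards. Polytomies are scored by folding children
    sequentially (exact for binary trees).
    """
    prof = _profiles(sequences)
    total, _ = _fitch_tree(tree, prof)
    return total


def _fitch_tree(tree: PhyloTree, prof: dict[str, np.ndarray]):
    states: dict[int, np.ndarray] = {}
    total = 0
    for node in tree.postorder():
        if node.is_leaf:
            if node.name not in prof:
                raise ValueError(f"leaf {node.name!r} has no sequence")
            states[id(node)] = prof[node.name]
            continue
        cur = states[id(node.children[0])]
        for child in node.children[1:]:
            other = states[id(child)]
            inter = cur & other
            empty = inter == 0
            total += int(empty.sum())
            cur = np.where(empty, cur | other, inter)
        states[id(node)] = cur
    return total, states


def fitch_root_sets(tree: PhyloTree, sequences: dict[str, str]) -> list[frozenset]:
    """Per-column Fitch state sets at the root (bases, wildcards excluded)."""
    prof = _profiles(sequences)
    _, states = _fitch_tree(tree, prof)
    root_masks = states[id(tree.root)]
    return [
        frozenset(b for m, b in MASK_BASE.items() if mask & m) for mask in root_masks
    ]


def assign_branch_mutations(
    tree: PhyloTree, sequences: dict[str, str], ancestral: str | None = None
) -> PhyloTree:
    """Fitch backtrace: fix one most-parsimonious base per node and column and
    record every state change on the branch where it happens.

    Ties at the root go to the ancestral base when it is in the root set,
    otherwise to the alphabetically first member; below the root, ties go to
    the parent's state (the root side). On binary trees the total number of
    recorded mutations equals the Fitch length.
    """
    prof = _profiles(sequences)
    _, states = _fitch_tree(tree, prof)
    L = len(next(iter(prof.values())))
    final: dict[int, np.ndarray] = {}
    root_masks = states[id(tree.root)]
    root_final = np.empty(L, dtype=np.uint8)
    for j in range(L):
        mask = int(root_masks[j])
        if ancestral is not None and BASE_MASK.get(ancestral[j], 0) & mask:
            root_final[j] = BASE_MASK[ancestral[j]]
        else:
            root_final[j] = min(m for m in MASK_BASE if mask & m)
    final[id(tree.root)] = root_final
    tree.root.mutations = []
    tree.root.k = 0
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_final = final[id(node.parent)]
        own = states[id(node)]
        keep = (own & parent_final) > 0
        chosen = np.where(keep, parent_final, _lowest_bit(own))
        final[id(node)] = chosen
        changed = np.nonzero(chosen != parent_final)[0]
        node.mutations = [
            (int(j), MASK_BASE[int(parent_final[j])], MASK_BASE[int(chosen[j])])
            for j in changed
        ]
        node.k = len(node.mutations)
    return tree


def _lowest_bit(masks: np.ndarray) -> np.ndarray:
    return masks & (-masks.astype(np.int16)).astype(np.uint8)


def reroot_on_edge(tree: PhyloTree, node: Node) -> PhyloTree:
    """New tree rooted on the branch above ``node`` (topology only; branch
    counts and ages must be (re)assigned afterwards)."""
    if node.parent is None:
        return tree

    def copy_down(n: Node) -> Node:
        n2 = Node(n.name)
        n2.tip_age = n.tip_age
        for c in n.children:
            n2.add(copy_down(c))
        return n2

    def hang_up(n: Node, coming_from: Node) -> Node:
        """``n`` re-rooted away from ``coming_from``; unary pass-throughs
        (the old root) are spliced out."""
        n2 = Node(n.name)
        n2.tip_age = n.tip_age
        for c in n.children:
            if c is not coming_from:
                n2.add(copy_down(c))
        if n.parent is not None:
            n2.add(hang_up(n.parent, n))
        if n2.name is None and len(n2.children) == 1:
            only = n2.children[0]
            only.parent = None
            return only
        return n2

    root = Node()
    root.add(copy_down(node))
    root.add(hang_up(node.parent, node))
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# nested-tuple machinery for tree search (planted trees)
#
# A candidate topology over leaf indices is a nested pair-tuple planted at
# leaf 0: the full tree is (0, T). Fitch length is rooting-invariant, so
# scoring the planted form scores the unrooted topology.


def _tuple_leafset(t, cache):
    key = id(t)
    if key in cache:
        return cache[key]
    if isinstance(t, int):
        out = frozenset((t,))
    else:
        out = _tuple_leafset(t[0], cache) | _tuple_leafset(t[1], cache)
    cache[key] = out
    return out


def _insertions(t, new):
    """All trees obtained by attaching ``new`` on any edge of ``t``."""
    yield (t, new)
    if not isinstance(t, int):
        for left in _insertions(t[0], new):
            yield (left, t[1])
        for right in _insertions(t[1], new):
            yield (t[0], right)


def _subtree_positions(t, path=()):
    yield t, path
    if not isinstance(t, int):
        yield from _subtree_positions(t[0], path + (0,))
        yield from _subtree_positions(t[1], path + (1,))


def _replace(t, path, new):
    if not path:
        return new
    if path[0] == 0:
        return (_replace(t[0], path[1:], new), t[1])
    return (t[0], _replace(t[1], path[1:], new))


def _prune(t, path):
    """Remove the subtree at ``path``; the sibling replaces the parent."""
    parent_path, which = path[:-1], path[-1]

    def rebuild(node, p):
        if len(p) == 0:
            return node[1 - which]
        if p[0] == 0:
            return (rebuild(node[0], p[1:]), node[1])
        return (node[0], rebuild(node[1], p[1:]))

    return rebuild(t, parent_path)


def _satisfies(t, constraints, all_leaves, present=None) -> bool:
    """Every constraint (restricted to ``present``) is an unrooted split of
    the tree planted at leaf 0: either the constrained set itself, or (when
    it contains leaf 0) its complement, equals some subtree leafset of ``t``."""
    cache: dict[int, frozenset] = {}
    sets = {_tuple_leafset(s, cache) for s, _ in _subtree_positions(t)}
    universe = frozenset(all_leaves if present is None else (all_leaves & present))
    for c in constraints:
        cr = c if present is None else (c & present)
        if 0 in cr:
            cr = universe - cr
        if len(cr) < 2 or len(universe - cr) < 1:
            continue
        if cr not in sets:
            return False
    return True


def _check_laminar(constraints) -> None:
    for a, b in itertools.combinations(constraints, 2):
        if a & b and not (a <= b or b <= a):
            raise ValueError("monophyly constraints conflict (overlap without nesting)")


# ---------------------------------------------------------------------------
# search


def variable_columns(sequences: dict[str, str]) -> list[int]:
    ids = list(sequences)
    L = len(sequences[ids[0]])
    cols = []
    for j in range(L):
        bases = {sequences[i][j] for i in ids} & set("ACGT")
        if len(bases) > 1:
            cols.append(j)
    return cols


def mp_search(
    sequences: dict[str, str],
    constraints: list[set] | None = None,
    outgroup_ids: list[str] | None = None,
    seed: int = 0,
    exact_threshold: int = 10,
    n_starts: int = 3,
    max_spr_rounds: int = 3,
) -> PhyloTree:
    """Best-found maximum-parsimony tree, rooted on the first outgroup.

    Exact branch-and-bound for up to ``exact_threshold`` leaves; otherwise
    randomized stepwise addition (``n_starts`` seeded starts) with NNI and
    SPR hill climbing that never accepts a constraint-breaking move. Among
    equally parsimonious results the lexicographically lowest newick wins.
    """
    ids = list(sequences)
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    outgroup_ids = [o for o in (outgroup_ids or []) if o in sequences]
    # leaf 0 = planted root (first outgroup when available)
    ordered = list(ids)
    if outgroup_ids:
        ordered.remove(outgroup_ids[0])
        ordered.insert(0, outgroup_ids[0])
    index_of = {name: i for i, name in enumerate(ordered)}
    cons = [frozenset(index_of[n] for n in c) for c in (constraints or []) if len(c) >= 2]
    all_leaves = frozenset(range(len(ordered)))
    # a constraint containing the planted leaf is checked as its complement
    _check_laminar([all_leaves - c if 0 in c else c for c in cons])

    cols = variable_columns(sequences)
    # collapse identical site patterns; weights preserve the length
    patterns: dict[tuple, int] = {}
    for j in cols:
        pat = tuple(BASE_MASK.get(sequences[i][j], WILDCARD) for i in ordered)
        patterns[pat] = patterns.get(pat, 0) + 1
    if patterns:
        pat_list = list(patterns)
        weights = np.array([patterns[p] for p in pat_list])
        mat = np.array(pat_list, dtype=np.uint8)  # (P, n)
    else:
        weights = np.ones(0, dtype=int)
        mat = np.zeros((0, len(ordered)), dtype=np.uint8)
    prof = {i: mat[:, i].copy() for i in range(len(ordered))}

    def wscore(t) -> int:
        memo: dict[int, tuple] = {}
        return _wplanted(t, prof, weights, memo)

    n = len(ordered)
    if n <= exact_threshold and not cons:
        best_t, best_len = _branch_and_bound(n, prof, weights)
    else:
        best_t, best_len = None, None
        rng = random.Random(seed)
        for _ in range(n_starts):
            t = _stepwise_addition(n, prof, weights, cons, all_leaves, rng)
            t, length = _hill_climb(t, prof, weights, cons, all_leaves, max_spr_rounds)
            if best_len is None or length < best_len:
                best_t, best_len = t, length
            elif length == best_len:
                # lexicographic newick tie-break for reproducibility
                if _canon(t, ordered) < _canon(best_t, ordered):
                    best_t = t
    tree = _to_phylo(best_t, ordered)
    tree.parsimony_length = best_len
    # root on the edge separating the outgroups from the ingroup when the
    # ingroup forms a clade/split, otherwise keep the planted rooting
    if outgroup_ids:
        non_og = set(ids) - set(outgroup_ids)
        if len(non_og) >= 2:
            mrca = tree.mrca(non_og)
            if tree.leafset(mrca) == frozenset(non_og) and mrca.parent is not None:
                tree = reroot_on_edge(tree, mrca)
                tree.parsimony_length = best_len
    all_names = frozenset(ids)
    splits = {tree.leafset(n) for n in tree.postorder()}
    for c in cons:
        names = frozenset(ordered[i] for i in c)
        if names not in splits and (all_names - names) not in splits:
            raise AssertionError(f"constraint {sorted(names)} violated by search result")
    return tree


def _wplanted(t, prof, weights, memo) -> int:
    def score(node):
        if id(node) in memo:
            return memo[id(node)]
        if isinstance(node, int):
            return prof[node], 0
        s1, c1 = score(node[0])
        s2, c2 = score(node[1])
        inter = s1 & s2
        empty = inter == 0
        res = (np.where(empty, s1 | s2, inter), c1 + c2 + int(weights[empty].sum()))
        if not isinstance(node, int):
            memo[id(node)] = res
        return res

    state, count = score(t)
    return count + int(weights[(state & prof[0]) == 0].sum())


def _scan_score(t, prof, weights, memo) -> int:
    """Like _wplanted but read-only on the memo (safe across candidates)."""

    def score(node):
        if id(node) in memo:
            return memo[id(node)]
        if isinstance(node, int):
            return prof[node], 0
        s1, c1 = score(node[0])
        s2, c2 = score(node[1])
        inter = s1 & s2
        empty = inter == 0
        return np.where(empty, s1 | s2, inter), c1 + c2 + int(weights[empty].sum())

    state, count = score(t)
    return count + int(weights[(state & prof[0]) == 0].sum())


def _fill_weighted_memo(t, prof, weights, memo):
    if id(t) in memo:
        return memo[id(t)]
    if isinstance(t, int):
        res = (prof[t], 0)
    else:
        s1, c1 = _fill_weighted_memo(t[0], prof, weights, memo)
        s2, c2 = _fill_weighted_memo(t[1], prof, weights, memo)
        inter = s1 & s2
        empty = inter == 0
        res = (np.where(empty, s1 | s2, inter), c1 + c2 + int(weights[empty].sum()))
    memo[id(t)] = res
    return res


def _stepwise_addition(n, prof, weights, cons, all_leaves, rng):
    order = list(range(1, n))
    rng.shuffle(order)
    t = order[0] if len(order) == 1 else (order[0], order[1])
    present = {0, order[0]} | ({order[1]} if len(order) > 1 else set())
    for leaf in order[2:]:
        present.add(leaf)
        memo: dict[int, tuple] = {}
        _fill_weighted_memo(t, prof, weights, memo)
        best, best_len = None, None
        for cand in _insertions(t, leaf):
            if cons and not _satisfies(cand, cons, all_leaves, frozenset(present)):
                continue
            length = _scan_score(cand, prof, weights, memo)
            if best_len is None or length < best_len:
                best, best_len = cand, length
        if best is None:
            raise ValueError("constraints admit no insertion point")
        t = best
    return t


def _hill_climb(t, prof, weights, cons, all_leaves, max_spr_rounds):
    cur_len = _wplanted(t, prof, weights, {})
    improved = True
    while improved:  # NNI to local optimum
        improved = False
        memo: dict[int, tuple] = {}
        _fill_weighted_memo(t, prof, weights, memo)
        for cand in _nni_neighbors(t):
            if cons and not _satisfies(cand, cons, all_leaves):
                continue
            length = _scan_score(cand, prof, weights, memo)
            if length < cur_len:
                t, cur_len, improved = cand, length, True
                break
    for _ in range(max_spr_rounds):
        t2, len2 = _spr_pass(t, cur_len, prof, weights, cons, all_leaves)
        if len2 >= cur_len:
            break
        t, cur_len = t2, len2
        # re-polish with NNI after a successful SPR round
        improved = True
        while improved:
            improved = False
            memo = {}
            _fill_weighted_memo(t, prof, weights, memo)
            for cand in _nni_neighbors(t):
                if cons and not _satisfies(cand, cons, all_leaves):
                    continue
                length = _scan_score(cand, prof, weights, memo)
                if length < cur_len:
                    t, cur_len, improved = cand, length, True
                    break
    return t, cur_len


def _nni_neighbors(t):
    for sub, path in _subtree_positions(t):
        if isinstance(sub, int):
            continue
        x, y = sub
        if not isinstance(x, int):
            a, b = x
            yield _replace(t, path, ((a, y), b))
            yield _replace(t, path, ((b, y), a))
        if not isinstance(y, int):
            a, b = y
            yield _replace(t, path, (b, (a, x)))
            yield _replace(t, path, (a, (b, x)))


def _spr_pass(t, cur_len, prof, weights, cons, all_leaves):
    best_t, best_len = t, cur_len
    positions = list(_subtree_positions(t))
    for sub, path in positions:
        if not path:  # cannot prune the whole tree
            continue
        remainder = _prune(t, path)
        if isinstance(remainder, int):
            continue
        memo: dict[int, tuple] = {}
        _fill_weighted_memo(remainder, prof, weights, memo)
        _fill_weighted_memo(sub, prof, weights, memo)
        for rsub, rpath in _subtree_positions(remainder):
            cand = _replace(remainder, rpath, (rsub, sub))
            if cons and not _satisfies(cand, cons, all_leaves):
                continue
            length = _scan_score(cand, prof, weights, memo)
            if length < best_len:
                best_t, best_len = cand, length
    return best_t, best_len


def _branch_and_bound(n, prof, weights):
    best = {"t": None, "len": None}

    def recurse(t, next_leaf):
        partial = _wplanted(t, prof, weights, {})
        if best["len"] is not None and partial >= best["len"]:
            return  # adding leaves never decreases the Fitch length
        if next_leaf == n:
            if best["len"] is None or partial < best["len"]:
                best["t"], best["len"] = t, partial
            return
        for cand in _insertions(t, next_leaf):
            recurse(cand, next_leaf + 1)

    if n == 3:
        t = (1, 2)
        return t, _wplanted(t, prof, weights, {})
    recurse((1, 2), 3)
    return best["t"], best["len"]


def _canon(t, ordered) -> str:
    def fmt(node):
        if isinstance(node, int):
            return ordered[node]
        a, b = fmt(node[0]), fmt(node[1])
        return "(" + ",".join(sorted((a, b))) + ")"

    return fmt((0, t))


def _to_phylo(t, ordered) -> PhyloTree:
    root = Node()

    def build(node, parent):
        if isinstance(node, int):
            parent.add(Node(ordered[node]))
        else:
            inner = parent.add(Node())
            build(node[0], inner)
            build(node[1], inner)

    root.add(Node(ordered[0]))
    build(t, root)
    return PhyloTree(root)


def exhaustive_search(sequences: dict[str, str]) -> tuple[int, int]:
    """(optimal length, number of topologies) by full enumeration.

    Intended as an oracle for small instances (<= 8 leaves)."""
    ids = list(sequences)
    n = len(ids)
    if n > 8:
        raise ValueError("exhaustive enumeration limited to 8 leaves")
    prof_full = _profiles(sequences)
    prof = {i: prof_full[ids[i]] for i in range(n)}
    weights = np.ones(len(next(iter(prof.values()))), dtype=int)

    def all_trees(leaves):
        if len(leaves) == 1:
            yield leaves[0]
            return
        first, rest = leaves[0], leaves[1:]
        for t in all_trees(rest):
            yield from _insertions(t, first)

    best = None
    count = 0
    for t in all_trees(list(range(1, n))):
        count += 1
        length = _wplanted(t, prof, weights, {})
        if best is None or length < best:
            best = length
    return best, count
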