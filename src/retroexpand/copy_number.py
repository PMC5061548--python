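"""Copy-number estimation from shotgun reads, by three complementary methods.

1. minimum — 1:1-ortholog recovery: a reference paralog counts as present in
   the focal genome when uniquely assigned reads cover enough of it.
2. average — normalized read depth: summed mean depth over the gene family
   divided by the mean depth of single-copy control regions, with a
   percentile-bootstrap 95% CI over fixed-size windows.
3. maximum — dated gene-tree/species-tree reconciliation: reference paralogs
   missing from the focal sample whose divergence predates the species split
   are counted as unsampled (present but unobserved) genes.

Read assignment scores every read against every reference with bit-parallel
semi-global alignment; ties contribute fractional (1/k) depth so the depth
estimator stays unbiased for near-identical copies, while ortholog recovery
uses uniquely assigned reads only (an ambiguous read is not evidence that a
specific paralog is present).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .trees import Node, SpeciesTree, TreeError, mrca

# ---------------------------------------------------------------------------
# read assignment
# ---------------------------------------------------------------------------

@dataclass
class ReadAssignment:
    read_id: str
    genes: tuple[str, ...]           # best-scoring reference gene(s)
    identity: float                  # percent identity of the best alignment
    status: str                      # unique | ambiguous | unassigned
    spans: tuple[tuple[int, int], ...] = ()  # [start, end) on each best gene

    def __post_init__(self) -> None:
        if self.status == "unique" and len(self.genes) != 1:
            raise ValueError("unique assignment must name exactly one gene")
        if self.status == "ambiguous" and len(self.genes) < 2:
            raise ValueError("ambiguous assignment needs >= 2 tied genes")


@dataclass
class DepthProfile:
    """Per-reference per-position depth (fractional for ambiguous reads) and
    unique-read-only depth."""

    depth: dict[str, np.ndarray]
    unique_depth: dict[str, np.ndarray]
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lengths:
            self.lengths = {g: arr.size for g, arr in self.depth.items()}

    def mean_depth(self, gene: str, unique: bool = False) -> float:
        arr = (self.unique_depth if unique else self.depth)[gene]
        return float(arr.mean()) if arr.size else 0.0

    def breadth(self, gene: str, depth_min: float = 1.0, unique: bool = True) -> float:
        arr = (self.unique_depth if unique else self.depth)[gene]
        return float((arr >= depth_min).mean()) if arr.size else 0.0


def assign_reads(reads, reference_genes: dict[str, str], min_identity: float = 90.0,
                 min_aligned_len: int = 30) -> tuple[list[ReadAssignment], DepthProfile]:
    """Assign each read to its best-matching reference gene(s).

    Every read is aligned semi-globally against every reference; the best
    edit-distance wins, exact ties are ambiguous, and reads whose best
    identity falls below ``min_identity`` percent (or whose alignment is
    shorter than ``min_aligned_len``) are unassigned. Ambiguous reads add
    1/k depth to each of the k tied genes.
    """
    if not 0 < min_identity <= 100:
        raise ValueError("min_identity must lie in (0, 100]")
    gene_ids = sorted(reference_genes)
    if not gene_ids:
        raise ValueError("reference gene set is empty")
    read_list = getattr(reads, "reads", reads)
    if not read_list:
        depth = {g: np.zeros(len(reference_genes[g])) for g in gene_ids}
        uniq = {g: np.zeros(len(reference_genes[g])) for g in gene_ids}
        return [], DepthProfile(depth, uniq)

    depth = {g: np.zeros(len(reference_genes[g])) for g in gene_ids}
    uniq = {g: np.zeros(len(reference_genes[g])) for g in gene_ids}
    assignments: list[ReadAssignment] = []
    for read in read_list:
        seq = getattr(read, "sequence", None) or (read if isinstance(read, str) else None)
        rid = getattr(read, "read_id", None) or f"read{len(assignments)}"
        if seq is None:
            raise TypeError("reads must be Read objects or strings")
        best_d = None
        hits: list[tuple[str, tuple[int, int]]] = []
        for gid in gene_ids:
            target = reference_genes[gid]
            if len(seq) > len(target):
                continue
            res = edlib.align(seq, target, mode="HW", task="locations")
            d = res["editDistance"]
            if best_d is None or d < best_d:
                best_d = d
                loc = res["locations"][0]
                hits = [(gid, (loc[0], loc[1] + 1))]
            elif d == best_d:
                loc = res["locations"][0]
                hits.append((gid, (loc[0], loc[1] + 1)))
        if best_d is None:
            assignments.append(ReadAssignment(rid, (), 0.0, "unassigned"))
            continue
        identity = 100.0 * (1.0 - best_d / len(seq))
        aligned_len = min(e - s for _, (s, e) in hits)
        if identity < min_identity or aligned_len < min_aligned_len:
            assignments.append(ReadAssignment(rid, (), identity, "unassigned"))
            continue
        genes = tuple(g for g, _ in hits)
        spans = tuple(sp for _, sp in hits)
        status = "unique" if len(genes) == 1 else "ambiguous"
        assignments.append(ReadAssignment(rid, genes, identity, status, spans))
        w = 1.0 / len(genes)
        for gid, (s, e) in hits:
            depth[gid][s:e] += w
            if status == "unique":
                uniq[gid][s:e] += 1.0
    return assignments, DepthProfile(depth, uniq)


# ---------------------------------------------------------------------------
# minimum: 1:1-ortholog recovery
# ---------------------------------------------------------------------------

def recovered_orthologs(assignments: Sequence[ReadAssignment],
                        depth_profile: DepthProfile, breadth_min: float = 0.5,
                        depth_min: float = 1.0) -> tuple[set[str], int]:
    """Reference genes recovered from the read sample, and the minimum
    copy-number estimate (their count).

    A gene is recovered when the fraction of its positions with unique-read
    depth >= ``depth_min`` reaches ``breadth_min``. Ambiguous reads are not
    evidence of presence for any specific paralog.
    """
    if not 0 < breadth_min <= 1:
        raise ValueError("breadth_min must lie in (0, 1]")
    if depth_min < 1:
        raise ValueError("depth_min must be >= 1")
    recovered = {g for g in depth_profile.unique_depth
                 if depth_profile.breadth(g, depth_min, unique=True) >= breadth_min}
    return recovered, len(recovered)


# ---------------------------------------------------------------------------
# average: normalized read depth
# ---------------------------------------------------------------------------

def depth_copy_number(depth_profile: DepthProfile, control_ids: Iterable[str],
                      family_ids: Optional[Iterable[str]] = None,
                      window: int = 100, n_boot: int = 1000,
                      seed: int = 0) -> tuple[float, tuple[float, float]]:
    """Copy number as family read depth normalized by single-copy depth.

    Estimate = (summed mean depth across family genes) / (mean depth over the
    control regions). The 95% CI is a seeded percentile bootstrap over
    fixed-size windows resampled within the family and control sets.
    """
    controls = sorted(set(control_ids))
    if not controls:
        raise ValueError("at least one control region is required")
    family = sorted(set(family_ids) if family_ids is not None
                    else set(depth_profile.depth) - set(controls))
    if not family:
        raise ValueError("family gene set is empty")

    def windows(ids: list[str]) -> np.ndarray:
        means = []
        for g in ids:
            arr = depth_profile.depth[g]
            for i in range(0, arr.size, window):
                chunk = arr[i:i + window]
                if chunk.size >= max(window // 2, 1):
                    means.append(chunk.mean())
        return np.asarray(means)

    fam_w = windows(family)
    ctl_w = windows(controls)
    ctl_mean = float(np.concatenate([depth_profile.depth[g] for g in controls]).mean())
    if ctl_mean <= 0:
        raise ValueError("control regions have zero depth; ratio uncomputable")
    fam_sum = sum(depth_profile.mean_depth(g) for g in family)
    estimate = fam_sum / ctl_mean

    rng = np.random.default_rng(seed)
    n_fam = len(family)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        f = fam_w[rng.integers(0, fam_w.size, fam_w.size)].mean() * n_fam
        c = ctl_w[rng.integers(0, ctl_w.size, ctl_w.size)].mean()
        boots[b] = f / c if c > 0 else np.nan
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(estimate), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# maximum: reconciliation with unsampled-gene rules
# ---------------------------------------------------------------------------

@dataclass
class Reconciliation:
    """LCA (most-parsimonious duplication-loss) mapping of a gene tree onto a
    species tree."""

    mapping: dict[int, Node]          # id(gene node) -> species node
    duplications: set[int]            # id(gene node) of duplication nodes
    losses: dict[str, int]            # species branch (child-node name) -> loss count
    gene_tree: Node
    species_tree: Node

    @property
    def n_duplications(self) -> int:
        return len(self.duplications)

    @property
    def n_losses(self) -> int:
        return sum(self.losses.values())

    def species_of(self, gene_node: Node) -> Node:
        return self.mapping[id(gene_node)]

    def is_duplication(self, gene_node: Node) -> bool:
        return id(gene_node) in self.duplications


def reconcile_lca(gene_tree: Node, species_tree, leaf_map: dict[str, str]) -> Reconciliation:
    """Standard LCA reconciliation: map every gene node to the MRCA of its
    leaves' species; a node is a duplication iff its mapping equals a child's
    mapping; losses are read off the mapping gaps along each gene-tree edge.
    """
    sroot = species_tree.root if isinstance(species_tree, SpeciesTree) else species_tree
    if not gene_tree.is_binary() or not sroot.is_binary():
        raise TreeError("reconciliation requires rooted binary trees")
    sp_by_name = {n.name: n for n in sroot.walk() if n.name}
    parent_of: dict[int, Optional[Node]] = {id(sroot): None}
    depth: dict[int, int] = {id(sroot): 0}
    for n in sroot.walk():
        for c in n.children:
            parent_of[id(c)] = n
            depth[id(c)] = depth[id(n)] + 1

    mapping: dict[int, Node] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            sp_name = leaf_map.get(node.name)
            if sp_name is None or sp_name not in sp_by_name:
                raise ValueError(f"gene leaf {node.name!r} is not mapped to a species leaf")
            mapping[id(node)] = sp_by_name[sp_name]
        else:
            a, b = (mapping[id(c)] for c in node.children)
            mapping[id(node)] = mrca(a, b)

    duplications: set[int] = set()
    for node in gene_tree.walk():
        if not node.is_leaf and any(mapping[id(c)] is mapping[id(node)]
                                    for c in node.children):
            duplications.add(id(node))

    losses: dict[str, int] = {}

    def count_losses(upper: Node, lower: Node, parent_is_dup: bool) -> None:
        # walk the species path from lower up to upper; each off-path child
        # of an intermediate node hosts a loss (duplication parents also lose
        # at the upper node itself)
        path = [lower]
        n = lower
        while n is not upper:
            n = parent_of[id(n)]
            if n is None:
                raise TreeError("gene leaf maps outside the species tree")
            path.append(n)
        # path[0]=lower ... path[-1]=upper
        intermediates = path[1:-1]
        stops = list(intermediates) + ([upper] if parent_is_dup and upper is not lower else [])
        on_path = {id(p) for p in path}
        for s in stops:
            for child in s.children:
                if id(child) not in on_path:
                    losses[child.name] = losses.get(child.name, 0) + 1

    for node in gene_tree.walk():
        for child in node.children:
            count_losses(mapping[id(node)], mapping[id(child)],
                         id(node) in duplications)
    return Reconciliation(mapping, duplications, losses, gene_tree, sroot)


def brute_force_reconciliation_cost(gene_tree: Node, species_tree,
                                    leaf_map: dict[str, str]) -> tuple[int, int]:
    """Exhaustive minimum over all valid gene->species mappings of
    (duplications, losses). Independent oracle for :func:`reconcile_lca`;
    exponential, suitable only for tiny trees."""
    sroot = species_tree.root if isinstance(species_tree, SpeciesTree) else species_tree
    sp_by_name = {n.name: n for n in sroot.walk() if n.name}
    parent_of: dict[int, Optional[Node]] = {id(sroot): None}
    for n in sroot.walk():
        for c in n.children:
            parent_of[id(c)] = n

    def ancestors_incl(n: Node) -> list[Node]:
        out = [n]
        while parent_of[id(out[-1])] is not None:
            out.append(parent_of[id(out[-1])])
        return out

    anc_sets = {id(n): {id(a) for a in ancestors_incl(n)} for n in sroot.walk()}

    def is_anc_or_eq(a: Node, b: Node) -> bool:
        return id(a) in anc_sets[id(b)]

    def dist(upper: Node, lower: Node) -> int:
        d = 0
        n = lower
        while n is not upper:
            n = parent_of[id(n)]
            d += 1
        return d

    gene_nodes = list(gene_tree.postorder())
    internal = [n for n in gene_nodes if not n.is_leaf]
    fixed = {id(n): sp_by_name[leaf_map[n.name]] for n in gene_nodes if n.is_leaf}

    # any valid mapping must place an internal node at an ancestor-or-equal of
    # every leaf species below it; enumerate exactly those candidates
    snodes = list(sroot.walk())
    candidates: list[list[Node]] = []
    for n in internal:
        below = {id(fixed[id(l)]) for l in n.leaves()}
        cands = [s for s in snodes
                 if all(id(s) in anc_sets[b] for b in below)]
        candidates.append(cands)

    best = (np.inf, np.inf, np.inf)
    for combo in itertools.product(*candidates):
        mapping = dict(fixed)
        for n, s in zip(internal, combo):
            mapping[id(n)] = s
        ok = True
        for n in internal:
            for c in n.children:
                if not is_anc_or_eq(mapping[id(n)], mapping[id(c)]):
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        dups = 0
        losses = 0
        for n in internal:
            mv = mapping[id(n)]
            ca, cb = (mapping[id(c)] for c in n.children)
            # a speciation requires the node to sit exactly at the MRCA of its
            # children's mappings, with both children strictly below it (in
            # distinct subtrees); anything else is a duplication
            is_dup = (ca is mv or cb is mv or _mrca_ids(ca, cb, anc_sets, parent_of) is not mv)
            if is_dup:
                dups += 1
            for c in n.children:
                d = dist(mv, mapping[id(c)])
                losses += d if is_dup else max(d - 1, 0)
        cost = (dups + losses, dups, losses)
        if cost < best:
            best = cost
    return int(best[1]), int(best[2])


def _mrca_ids(a: Node, b: Node, anc_sets: dict, parent_of: dict) -> Node:
    n = a
    while id(n) not in anc_sets[id(b)]:
        n = parent_of[id(n)]
    return n


def count_unsampled(missing_ages: Iterable[float], split_time: float) -> int:
    """Unsampled-gene rule: a missing reference paralog is inferred present
    but unsequenced iff its divergence (duplication) age predates the focal
    species split."""
    if split_time <= 0:
        raise ValueError("split_time must be positive")
    return sum(1 for a in missing_ages if a > split_time)


def infer_unsampled(reconciliation: Optional[Reconciliation], dated_gene_tree: Node,
                    focal_species: str, reference_species: str, split_time: float,
                    ancient_mode: bool = False,
                    focal_evidence: Optional[set[str]] = None) -> dict:
    """Classify reference paralogs absent from the focal sample and return the
    maximum copy-number estimate.

    A gene lineage alive at the species split that left reference descendants
    but no sampled focal descendant must have been present in the focal
    genome's ancestor: it is counted *unsampled* (present but unsequenced).
    Equivalently, a missing reference paralog is unsampled iff its divergence
    from the sampled genes predates the split. Missing paralogs whose entire
    lineage postdates the split arose on the reference lineage and are
    reference-specific duplicates (``ancient_mode``, used for deeply diverged
    focal taxa such as the mastodon) or focal-lineage losses otherwise.
    """
    if split_time <= 0:
        raise ValueError("split_time must be positive")
    for node in dated_gene_tree.walk():
        if not node.is_leaf and node.age <= 0:
            raise ValueError("gene tree lacks (positive) node ages")
    leaves = dated_gene_tree.leaves()
    focal_names = {n.name for n in leaves
                   if n.species == focal_species
                   or n.name.startswith(f"{focal_species}_")}
    evidence = focal_names | (set(focal_evidence) if focal_evidence else set())

    def has_focal(node: Node) -> bool:
        return any(l.name in evidence for l in node.leaves())

    # gene lineages crossing the split: edges (u, v) with v.age <= split < u.age
    crossing: list[Node] = []
    if dated_gene_tree.age <= split_time:
        crossing = [dated_gene_tree]  # single founding lineage at the split
    else:
        for node in dated_gene_tree.walk():
            for child in node.children:
                if child.age <= split_time < node.age:
                    crossing.append(child)

    unsampled: set[str] = set()
    other_missing: set[str] = set()
    for sub in crossing:
        ref_in_sub = sorted(l.name for l in sub.leaves() if l.name not in focal_names)
        if not has_focal(sub) and ref_in_sub:
            unsampled.add(ref_in_sub[0])  # one unsampled gene per crossing lineage
    for leaf in leaves:
        if leaf.name in evidence:
            continue
        # missing paralogs inside an evidence-bearing crossing lineage postdate
        # the split (they arose on the reference lineage)
        sub_root = leaf
        while sub_root.parent is not None and sub_root.parent.age <= split_time:
            sub_root = sub_root.parent
        if has_focal(sub_root) and not _is_paired(leaf, focal_names, split_time):
            other_missing.add(leaf.name)
    sampled = len(focal_names) + len({l.name for l in leaves} &
                                     (set(focal_evidence) if focal_evidence else set()))
    category = "reference_specific_paralog" if ancient_mode else "focal_lineage_loss"
    return {
        "unsampled": unsampled,
        "n_unsampled": len(unsampled),
        "sampled": sampled,
        "maximum": sampled + len(unsampled),
        category: other_missing,
    }


def _is_paired(ref_leaf: Node, focal_names: set[str], split_time: float) -> bool:
    parent = ref_leaf.parent
    if parent is None or parent.age > split_time:
        return False
    return any(any(l.name in focal_names for l in sib.leaves())
               for sib in parent.children if sib is not ref_leaf)


# ---------------------------------------------------------------------------
# composite estimate
# ---------------------------------------------------------------------------

@dataclass
class CopyNumberEstimate:
    minimum: int
    average: float
    ci_low: float
    ci_high: float
    maximum: int
    recovered: tuple[str, ...] = ()
    unsampled: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.minimum > self.maximum:
            raise ValueError("minimum estimate exceeds maximum estimate")
        if not self.ci_low <= self.average <= self.ci_high:
            raise ValueError("average must lie inside its confidence interval")

    @property
    def envelope(self) -> tuple[int, int]:
        """Combined [min, max] range across the three methods."""
        return (self.minimum, self.maximum)


def graft_orthologs(reference_tree: Node, recovered: Iterable[str],
                    focal_species: str, split_time: float) -> tuple[Node, dict[str, str]]:
    """Joint gene tree: each recovered reference paralog gains a focal
    ortholog as a sister at the species-split age. Returns the tree and the
    gene-leaf -> species map for reconciliation."""
    tree = reference_tree.copy()
    leaf_map: dict[str, str] = {}
    ref_species = {l.species for l in reference_tree.leaves() if l.species}
    ref_sp = next(iter(ref_species)) if len(ref_species) == 1 else "reference"
    if tree.is_leaf:  # single-copy family: the graft becomes the root
        leaf_map[tree.name] = tree.species or ref_sp
        if tree.name in set(recovered):
            cherry = Node(age=split_time, event="speciation")
            cherry.add(Node(tree.name, tree.age, event="extant", species=tree.species))
            focal_child = cherry.add(Node(f"{focal_species}__{tree.name}", 0.0,
                                          event="extant", species=focal_species))
            leaf_map[focal_child.name] = focal_species
            return cherry, leaf_map
        return tree, leaf_map
    for leaf in list(tree.leaves()):
        leaf_map[leaf.name] = leaf.species or ref_sp
        if leaf.name in set(recovered):
            cherry = Node(age=split_time, event="speciation")
            ref_child = Node(leaf.name, leaf.age, event="extant", species=leaf.species)
            focal_child = Node(f"{focal_species}__{leaf.name}", 0.0,
                               event="extant", species=focal_species)
            parent = leaf.parent
            if parent is None:
                raise TreeError("cannot graft onto a single-leaf tree root")
            idx = parent.children.index(leaf)
            parent.children[idx] = cherry
            cherry.parent = parent
            cherry.add(ref_child)
            cherry.add(focal_child)
            leaf_map[focal_child.name] = focal_species
    return tree, leaf_map


def estimate_copy_number(reads, reference_genes: dict[str, str],
                         reference_tree: Node, focal_species: str,
                         reference_species: str, split_time: float,
                         control_regions: dict[str, str],
                         min_identity: float = 90.0, breadth_min: float = 0.5,
                         depth_min: float = 1.0, window: int = 100,
                         n_boot: int = 1000, seed: int = 0,
                         ancient_mode: bool = False,
                         parent_gene: Optional[str] = None) -> CopyNumberEstimate:
    """Compose the three estimators into one record for a focal genome.

    ``reference_genes`` are the reference species' family sequences (the
    parent gene may be included); ``control_regions`` are single-copy
    sequences used only for depth normalization.
    """
    refs = dict(reference_genes)
    refs.update(control_regions)
    assignments, profile = assign_reads(reads, refs, min_identity=min_identity)
    family_ids = list(reference_genes)
    rec_profile = DepthProfile(
        {g: profile.depth[g] for g in family_ids},
        {g: profile.unique_depth[g] for g in family_ids},
    )
    recovered, minimum = recovered_orthologs(assignments, rec_profile,
                                             breadth_min=breadth_min,
                                             depth_min=depth_min)
    average, (lo, hi) = depth_copy_number(
        profile, control_ids=control_regions, family_ids=family_ids,
        window=window, n_boot=n_boot, seed=seed,
    )
    tree_recovered = {g for g in recovered if g != parent_gene}
    result = infer_unsampled(None, reference_tree, focal_species,
                             reference_species, split_time,
                             ancient_mode=ancient_mode,
                             focal_evidence=tree_recovered)
    unsampled = set(result["unsampled"])
    maximum = len(tree_recovered) + len(unsampled)
    if parent_gene is not None:
        # the single-copy source gene predates any split: counted either as
        # recovered or as unsampled
        maximum += 1
        if parent_gene not in recovered:
            unsampled.add(parent_gene)
    return CopyNumberEstimate(
        minimum=minimum, average=float(average), ci_low=float(lo),
        ci_high=float(hi), maximum=max(maximum, minimum),
        recovered=tuple(sorted(recovered)),
        unsampled=tuple(sorted(unsampled)),
    )
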