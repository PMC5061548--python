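"""Synthetic data generator for retrogene-family expansion studies.

Emulates the genomic structure the inference modules assume: a single
retrotransposition of a parent gene onto a stem lineage, a quiescent interval
followed by birth-death expansion through segmental duplication of gene+flank
windows carrying shared transposable-element (TE) fingerprints, a diagnostic
15-30 bp deletion shared by every retrogene, ORF-disrupting mutations in a
subset of copies, uniform-coverage modern shotgun reads and short low-coverage
ancient reads, and expression tables in which a minority of copies are
transcribed.

Substitutions use a two-parameter transition/transversion model applied per
branch (one hit per site per branch; adequate at the divergences simulated
here). Sequences are manipulated as numpy uint8 arrays with A,C,G,T = 0..3.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig, derive_rng
from .trees import Node, SpeciesTree, build_species_tree, prune_to_leaves
from .trajectory import TimeSeries

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOP_CODONS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return arr


def decode(arr: np.ndarray) -> str:
    return _ALPHABET[arr].tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def _mutate_k2p(arr: np.ndarray, time: float, rate: float, kappa: float,
                rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability 1-exp(-rate*time); transitions
    (A<->G, C<->T) occur kappa times as often as each transversion class."""
    if time <= 0 or rate <= 0:
        return arr.copy()
    p = 1.0 - np.exp(-rate * time)
    out = arr.copy()
    hit = np.nonzero(rng.random(arr.size) < p)[0]
    if hit.size == 0:
        return out
    is_ts = rng.random(hit.size) < kappa / (kappa + 2.0)
    ts_idx = hit[is_ts]
    out[ts_idx] = arr[ts_idx] ^ 2  # A<->G, C<->T
    tv_idx = hit[~is_ts]
    out[tv_idx] = (arr[tv_idx] + 1 + 2 * rng.integers(0, 2, tv_idx.size)) % 4
    return out


def _mutate_uniform(arr: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability p to a uniformly chosen other base."""
    out = arr.copy()
    hit = np.nonzero(rng.random(arr.size) < p)[0]
    out[hit] = (arr[hit] + rng.integers(1, 4, hit.size)) % 4
    return out


def random_coding_sequence(length: int, rng: np.random.Generator,
                           utr5: int = 60, utr3: int = 90) -> str:
    """Random nucleotide sequence containing a single long ATG-initiated ORF.

    Layout: ATG-free 5' UTR, ORF (ATG + non-stop codons + TAA), 3' tail.
    """
    if length < utr5 + utr3 + 60:
        raise ValueError("length too short to host an ORF")
    n_codons = (length - utr5 - utr3 - 6) // 3

    def random_stretch(n: int) -> str:
        s = decode(rng.integers(0, 4, n).astype(np.uint8))
        while "ATG" in s:
            s = s.replace("ATG", "ATC", 1)
        return s

    codons = []
    while len(codons) < n_codons:
        c = decode(rng.integers(0, 4, 3).astype(np.uint8))
        if c not in _STOP_CODONS and c != "ATG":
            codons.append(c)
    orf = "ATG" + "".join(codons) + "TAA"
    tail = length - utr5 - len(orf)
    return random_stretch(utr5) + orf + random_stretch(tail)


# ---------------------------------------------------------------------------
# gene-family history
# ---------------------------------------------------------------------------

@dataclass
class Event:
    kind: str          # retrotransposition | duplication | loss
    time: float        # MY before present
    species: str       # name of the species-tree node whose branch hosts the event
    lineage: int       # gene lineage identifier


@dataclass
class GeneFamilyHistory:
    """Complete simulated history: event list, dated gene tree, truth tables.

    The gene tree's leaves are extant copies (age = species tip age,
    ``event="extant"``) and loss tips (``event="loss"``); internal nodes are
    duplications or speciations, all dated in MY before present. The origin
    (retrotransposition time) predates the gene-tree root.
    """

    species_tree: SpeciesTree
    gene_tree: Node
    origin_age: float
    events: list[Event]
    config: SimulationConfig

    def extant_leaves(self, species: Optional[str] = None) -> list[Node]:
        leaves = [n for n in self.gene_tree.leaves() if n.event == "extant"]
        if species is not None:
            leaves = [n for n in leaves if n.species == species]
        return leaves

    def copy_number(self, species: str) -> int:
        return len(self.extant_leaves(species))

    def true_copy_numbers(self) -> dict[str, int]:
        out = {name: 0 for name in self.species_tree.tip_names()}
        for leaf in self.extant_leaves():
            out[leaf.species] += 1
        return out

    def gene_tree_for(self, species: str, include_losses: bool = False) -> Optional[Node]:
        """Gene tree restricted to one species' copies (plus, optionally, loss
        tips on that species' root-to-tip path)."""
        keep = {n.name for n in self.extant_leaves(species)}
        if include_losses:
            path = {n.name for n in self.species_tree.path_to(species)}
            keep |= {n.name for n in self.gene_tree.leaves()
                     if n.event == "loss" and n.species in path}
        return prune_to_leaves(self.gene_tree, keep)

    def events_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.kind, e.time, e.species, e.lineage) for e in self.events],
            columns=["kind", "time_my", "species_branch", "lineage"],
        )


def _first_event(t0: float, t_end: float, in_clade: bool, cfg: SimulationConfig,
                 rng: np.random.Generator) -> Optional[tuple[float, str]]:
    """First duplication/loss on the interval (t_end, t0], walking piecewise-
    constant total rate from older to younger times. Returns None if the
    lineage reaches t_end untouched."""
    boundaries = sorted({b for piece in cfg.duplication_rate for b in piece[:2]})
    t = t0
    while t > t_end:
        lam = cfg.dup_rate_at(t) if in_clade else 0.0
        total = lam + cfg.loss_rate
        seg_end = max([b for b in boundaries if b < t] + [t_end])
        seg_end = max(seg_end, t_end)
        if total <= 0:
            t = seg_end
            continue
        wait = rng.exponential(1.0 / total)
        if t - wait > seg_end:
            kind = "duplication" if rng.random() < lam / total else "loss"
            return (t - wait, kind)
        t = seg_end
    return None


def simulate_gene_family(species_tree, config: SimulationConfig,
                         seed: Optional[int] = None) -> GeneFamilyHistory:
    """Simulate a retrogene family along a dated species tree.

    One retrotransposition at ``config.t_retro`` on the stem branch above
    ``config.retro_host``; thereafter each gene lineage duplicates at rate
    lambda(t) (optionally restricted to ``config.duplication_clade``) and is
    lost at rate mu. Fully reproducible from the seed.
    """
    stree = build_species_tree(species_tree)
    host = stree.find(config.retro_host)
    upper = host.parent.age if host.parent is not None else float("inf")
    if not host.age < config.t_retro < upper:
        raise ValueError(
            f"t_retro={config.t_retro} must lie on the stem branch above "
            f"{config.retro_host} (interval ({host.age}, {upper}))"
        )
    rng = derive_rng(config.seed if seed is None else seed, "gene_family")
    clade = (stree.clade_names(config.duplication_clade)
             if config.duplication_clade else None)
    events: list[Event] = [Event("retrotransposition", config.t_retro, host.name, 0)]
    counter = [0]

    def next_id() -> int:
        counter[0] += 1
        return counter[0]

    def descend(t0: float, sp: Node, lineage: int) -> Node:
        in_clade = clade is None or sp.name in clade
        ev = _first_event(t0, sp.age, in_clade, config, rng)
        if ev is None:
            if sp.is_leaf:
                return Node(age=sp.age, event="extant", species=sp.name)
            node = Node(name=sp.name, age=sp.age, event="speciation", species=sp.name)
            for child_sp in sp.children:
                node.add(descend(sp.age, child_sp, lineage))
            return node
        t_ev, kind = ev
        events.append(Event(kind, t_ev, sp.name, lineage))
        if kind == "loss":
            return Node(age=t_ev, event="loss", species=sp.name)
        node = Node(age=t_ev, event="duplication", species=sp.name)
        node.add(descend(t_ev, sp, lineage))
        node.add(descend(t_ev, sp, next_id()))
        return node

    root = descend(config.t_retro, host, 0)
    # stable copy names per species, in traversal order
    per_species: dict[str, int] = {}
    for leaf in root.leaves():
        if leaf.event == "extant":
            k = per_species.get(leaf.species, 0) + 1
            per_species[leaf.species] = k
            leaf.name = f"{leaf.species}_rtg{k:02d}"
        elif leaf.event == "loss":
            leaf.name = f"loss_{leaf.species}_{leaf.age:.4f}_{id(leaf) & 0xffff:x}"
    # deterministic loss-tip names
    for i, leaf in enumerate(n for n in root.leaves() if n.event == "loss"):
        leaf.name = f"loss{i:03d}_{leaf.species}"
    events.sort(key=lambda e: -e.time)
    return GeneFamilyHistory(stree, root, config.t_retro, events, config)


def reference_gene_tree(species: str = "african_elephant",
                        dup_ages: Sequence[float] = (40, 37, 34, 31, 28, 26, 24,
                                                     22, 20, 18, 16, 14, 12, 10,
                                                     8, 6, 4, 2),
                        prefix: str = "TP53RTG") -> Node:
    """Fixed dated gene tree for a reference retrogene family.

    A pectinate tree whose duplication ages tile the post-quiescence expansion
    window; with the default 18 ages it yields 19 extant copies named
    ``TP53RTG1..TP53RTG19``. Used as the deterministic reference family for
    estimator tests and the worked pipeline example.
    """
    ages = sorted(dup_ages, reverse=True)
    n = len(ages) + 1

    def build(i: int) -> Node:
        leaf = Node(name=f"{prefix}{i + 1}", age=0.0, event="extant", species=species)
        if i == len(ages):
            return leaf
        node = Node(age=ages[i], event="duplication", species=species)
        node.add(leaf)
        node.add(build(i + 1))
        return node

    root = build(0)
    root.validate_ages()
    assert len(root.leaves()) == n
    return root


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """Evolved sequences for a gene family: retrogene copies plus, per
    species, the undeleted parent gene (keys ``TP53_<species>``)."""

    sequences: dict[str, str]
    parent_ids: dict[str, str]          # species -> parent gene id
    deletion_span: tuple[int, int]      # [start, end) in root-sequence coordinates
    disrupted: set[str]                 # copies given a premature stop
    root_sequence: str

    def copies(self, species: Optional[str] = None) -> dict[str, str]:
        parents = set(self.parent_ids.values())
        out = {k: v for k, v in self.sequences.items() if k not in parents}
        if species is not None:
            out = {k: v for k, v in out.items() if k.startswith(species) or "_" not in k}
        return out

    def write_fasta(self, path: str | Path, ids: Optional[Iterable[str]] = None) -> None:
        write_fasta(path, {k: self.sequences[k] for k in (ids or sorted(self.sequences))})


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _evolve_on_tree(node: Node, seq: np.ndarray, cfg: SimulationConfig,
                    rng: np.random.Generator, out: dict[str, np.ndarray],
                    t_from: float) -> None:
    branch = t_from - node.age
    evolved = _mutate_k2p(seq, branch, cfg.substitution_rate, cfg.kappa, rng)
    if node.is_leaf:
        if node.event != "loss":
            out[node.name] = evolved
        return
    for child in node.children:
        _evolve_on_tree(child, evolved, cfg, rng, out, node.age)


def _scrub_orfs(seq: str, rng: np.random.Generator, min_aa: int = 25) -> str:
    """Insert premature stops until no forward-frame ATG ORF of >= min_aa remains."""
    from .repertoire import _longest_orf

    s = seq
    for _ in range(100):
        start, aa = _longest_orf(s)
        if start is None or aa < min_aa:
            return s
        k = int(rng.integers(2, max(3, aa // 2)))
        pos = start + 3 * k
        s = s[:pos] + "TGA" + s[pos + 3:]
    return s


def evolve_sequences(history_or_tree, config: SimulationConfig,
                     root_sequence: Optional[str] = None,
                     seed: Optional[int] = None,
                     origin_age: Optional[float] = None) -> SequenceSet:
    """Evolve sequences for every extant gene copy (plus per-species parents).

    All retrogene copies share one diagnostic deletion introduced on the
    retrotransposition branch; substitutions accrue proportional to branch
    length; a configured fraction of copies receive ORF-disrupting premature
    stop codons. Accepts a :class:`GeneFamilyHistory` or a bare dated gene
    tree (then ``origin_age`` anchors the stem; parents are generated for the
    species named on the leaves, diverging at the origin).
    """
    cfg = config
    rng = derive_rng(cfg.seed if seed is None else seed, "sequences")
    if root_sequence is None:
        root_sequence = random_coding_sequence(cfg.gene_length, rng)
    if not root_sequence:
        raise ValueError("root sequence must be non-empty")
    if len(root_sequence) <= cfg.deletion_length + 100:
        raise ValueError("root sequence must exceed deletion length + 100 nt")
    root_arr = encode(root_sequence)

    if isinstance(history_or_tree, GeneFamilyHistory):
        history = history_or_tree
        gene_root = history.gene_tree
        origin = history.origin_age
        species_list = sorted({n.species for n in history.extant_leaves()})
        stree = history.species_tree
    else:
        history = None
        gene_root = history_or_tree
        origin = origin_age if origin_age is not None else gene_root.age
        species_list = sorted({n.species or n.name for n in gene_root.leaves()
                               if n.event != "loss"})
        stree = None

    del_start = cfg.deletion_offset
    del_end = del_start + cfg.deletion_length
    if del_end > len(root_sequence):
        raise ValueError("diagnostic deletion extends past the root sequence")
    retro_root = np.concatenate([root_arr[:del_start], root_arr[del_end:]])

    seqs: dict[str, np.ndarray] = {}
    _evolve_on_tree(gene_root, retro_root, cfg, rng, seqs, origin)

    # parent (undeleted) gene per species; orthologs share ancestral states
    # along the species tree, diverging only at their species splits
    parent_ids: dict[str, str] = {sp: f"TP53_{sp}" for sp in species_list}
    if stree is not None:
        wanted = set(species_list)

        def descend_parent(sp_node, arr: np.ndarray, t_from: float) -> None:
            evolved = _mutate_k2p(arr, t_from - sp_node.age, cfg.substitution_rate,
                                  cfg.kappa, rng)
            if sp_node.is_leaf:
                if sp_node.name in wanted:
                    seqs[parent_ids[sp_node.name]] = evolved
                return
            for child in sp_node.children:
                descend_parent(child, evolved, sp_node.age)

        descend_parent(stree.find(cfg.retro_host), root_arr, origin)
    else:
        tip_age = min(n.age for n in gene_root.leaves())
        for sp in species_list:
            seqs[parent_ids[sp]] = _mutate_k2p(root_arr, origin - tip_age,
                                               cfg.substitution_rate, cfg.kappa, rng)

    out = {k: decode(v) for k, v in seqs.items()}
    disrupted: set[str] = set()
    copy_ids = [k for k in out if k not in set(parent_ids.values())]
    for cid in sorted(copy_ids):
        if rng.random() < cfg.orf_disruption_prob:
            out[cid] = _scrub_orfs(out[cid], rng)
            disrupted.add(cid)
    return SequenceSet(out, parent_ids, (del_start, del_end), disrupted, root_sequence)


# ---------------------------------------------------------------------------
# locus assembly
# ---------------------------------------------------------------------------

@dataclass
class Feature:
    name: str
    start: int  # 0-based half-open
    end: int
    kind: str   # gene | flank | control
    labels: tuple[str, ...] = ()


@dataclass
class Locus:
    gene_id: str
    contig: str
    gene_start: int
    gene_end: int
    strand: str
    flank_left: str
    flank_right: str
    fingerprints: tuple[str, ...]
    parent_gene: Optional[str]   # extant locus this copy was segmentally duplicated from
    mechanism: str               # truth label


@dataclass
class SyntheticGenome:
    species: str
    contigs: dict[str, str]
    features: dict[str, list[Feature]]
    loci: list[Locus]

    def control_ids(self) -> list[str]:
        return [c for c in self.contigs if c.startswith("control_")]

    def gene_sequences(self) -> dict[str, str]:
        out = {}
        for locus in self.loci:
            out[locus.gene_id] = self.contigs[locus.contig][locus.gene_start:locus.gene_end]
        return out

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(path, self.contigs)


def _leftmost_extant(node: Node) -> Optional[str]:
    for leaf in node.leaves():
        if leaf.event != "loss":
            return leaf.name
    return None


def assemble_loci(history_or_tree, seqset: SequenceSet, config: SimulationConfig,
                  species: Optional[str] = None,
                  seed: Optional[int] = None) -> SyntheticGenome:
    """Embed each gene copy in a genomic contig with TE-fingerprinted flanks.

    In segmental mode each duplicate's flanks are copied (with drift) from its
    parent locus and all family loci share the configured fingerprint labels;
    in independent-retrotransposition mode every copy receives unrelated
    flanks and its own fingerprints. Five single-copy control contigs of
    family-average gene length are included for depth normalization.
    """
    cfg = config
    rng = derive_rng(cfg.seed if seed is None else seed, f"loci:{species}")
    if isinstance(history_or_tree, GeneFamilyHistory):
        if species is None:
            raise ValueError("species required when assembling from a history")
        tree = history_or_tree.gene_tree_for(species)
        parent_gene_id = seqset.parent_ids.get(species)
    else:
        tree = history_or_tree
        species = species or next(iter({n.species for n in tree.leaves()}), "sample")
        parent_gene_id = seqset.parent_ids.get(species)
    if tree is None:
        raise ValueError(f"species {species!r} has no extant gene copies")

    contigs: dict[str, str] = {}
    features: dict[str, list[Feature]] = {}
    loci: list[Locus] = []
    fl = cfg.flank_length

    def random_flank() -> str:
        return decode(rng.integers(0, 4, fl).astype(np.uint8))

    def add_locus(gene_id: str, left: str, right: str,
                  fingerprints: tuple[str, ...], parent: Optional[str],
                  mechanism: str) -> None:
        seq = seqset.sequences[gene_id]
        contig = f"contig_{gene_id}"
        contigs[contig] = left + seq + right
        features[contig] = [
            Feature(f"{gene_id}_flank5", 0, fl, "flank", fingerprints),
            Feature(gene_id, fl, fl + len(seq), "gene"),
            Feature(f"{gene_id}_flank3", fl + len(seq), fl + len(seq) + fl,
                    "flank", fingerprints),
        ]
        loci.append(Locus(gene_id, contig, fl, fl + len(seq), "+", left, right,
                          fingerprints, parent, mechanism))

    if cfg.mechanism == "segmental":
        def walk(node: Node, left: str, right: str) -> None:
            if node.is_leaf:
                if node.event != "loss":
                    add_locus(node.name, left, right, cfg.te_fingerprint, None,
                              "segmental_duplication")
                return
            # first child keeps the parental locus; the second is the new copy
            walk(node.children[0], left, right)
            new_left = decode(_mutate_uniform(encode(left), cfg.flank_drift, rng))
            new_right = decode(_mutate_uniform(encode(right), cfg.flank_drift, rng))
            walk(node.children[1], new_left, new_right)
            parent_id = _leftmost_extant(node.children[0])
            first_new = _leftmost_extant(node.children[1])
            if first_new is not None and parent_id is not None:
                for locus in loci:
                    if locus.gene_id == first_new and locus.parent_gene is None:
                        locus.parent_gene = parent_id
                        break

        walk(tree, random_flank(), random_flank())
    else:
        order = [n for n in tree.leaves() if n.event != "loss"]
        for i, leaf in enumerate(order):
            labels = (f"TE_{leaf.name}_a", f"TE_{leaf.name}_b")
            parent = _leftmost_extant(tree) if i > 0 else None
            add_locus(leaf.name, random_flank(), random_flank(), labels,
                      parent if leaf.name != parent else None,
                      "independent_retrotransposition")

    # the parent (source) gene sits at an unrelated single-copy locus
    if parent_gene_id and parent_gene_id in seqset.sequences:
        add_locus(parent_gene_id, random_flank(), random_flank(),
                  ("L2_ANC", "MIR_ANC"), None, "parent")

    family_lengths = [len(seqset.sequences[l.gene_id]) for l in loci]
    ctrl_len = int(round(float(np.mean(family_lengths)))) if family_lengths else cfg.gene_length
    for i in range(cfg.n_control_regions):
        cid = f"control_{i + 1}"
        contigs[cid] = decode(rng.integers(0, 4, ctrl_len).astype(np.uint8))
        features[cid] = [Feature(cid, 0, ctrl_len, "control")]
    return SyntheticGenome(species, contigs, features, loci)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class Read:
    read_id: str
    sequence: str
    quality: str
    contig: str
    start: int
    end: int


@dataclass
class ReadSet:
    reads: list[Read]
    paired: bool = False

    def __len__(self) -> int:
        return len(self.reads)

    def to_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def simulate_reads(genome_or_contigs, config: SimulationConfig,
                   ancient: bool = False, seed: Optional[int] = None) -> ReadSet:
    """Shotgun reads with uniform start positions and per-base errors.

    Expected read count is coverage * total_length / read_length. Ancient
    mode draws read lengths uniformly from the configured short range and
    uses the (low) ancient coverage.
    """
    cfg = config
    contigs = (genome_or_contigs.contigs
               if isinstance(genome_or_contigs, SyntheticGenome)
               else dict(genome_or_contigs))
    rng = derive_rng(cfg.seed if seed is None else seed,
                     "reads_ancient" if ancient else "reads")
    coverage = cfg.ancient_coverage if ancient else cfg.coverage
    lo, hi = cfg.ancient_read_length
    mean_len = (lo + hi) / 2 if ancient else cfg.read_length
    min_contig = min((len(s) for s in contigs.values()), default=0)
    if not ancient and contigs and cfg.read_length > min_contig:
        raise ValueError("read length exceeds the shortest contig")
    paired = cfg.paired and not ancient

    reads: list[Read] = []
    for contig_id in sorted(contigs):
        seq = contigs[contig_id]
        L = len(seq)
        n = rng.poisson(coverage * L / mean_len) if coverage > 0 else 0
        if paired:
            n = max(n // 2, 0)
        for i in range(n):
            if ancient:
                rl = int(rng.integers(lo, hi + 1))
                rl = min(rl, L)
            else:
                rl = cfg.read_length
            if paired:
                ins = min(cfg.insert_size, L)
                start = int(rng.integers(0, L - ins + 1))
                frag = seq[start:start + ins]
                r1 = frag[:rl]
                r2 = revcomp(frag[-rl:])
                for mate, (s, a, b) in enumerate(
                        [(r1, start, start + rl), (r2, start + ins - rl, start + ins)], 1):
                    s = _apply_errors(s, cfg.error_rate, rng)
                    reads.append(Read(f"{contig_id}_{i}/{mate}", s, "I" * len(s),
                                      contig_id, a, b))
            else:
                start = int(rng.integers(0, L - rl + 1))
                s = _apply_errors(seq[start:start + rl], cfg.error_rate, rng)
                reads.append(Read(f"{contig_id}_{i}", s, "I" * len(s),
                                  contig_id, start, start + rl))
    return ReadSet(reads, paired=paired)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = encode(seq)
    return decode(_mutate_uniform(arr, rate, rng))


# ---------------------------------------------------------------------------
# expression and body size
# ---------------------------------------------------------------------------

def simulate_expression(history_or_ids, config: SimulationConfig,
                        species: str = "african_elephant",
                        seed: Optional[int] = None) -> pd.DataFrame:
    """FPKM table in which the parent gene and a configured minority of
    retrogene copies are expressed; the remainder are silent.

    Returns a DataFrame with columns ``gene_id`` and ``fpkm``; the parent
    gene always carries the highest abundance.
    """
    cfg = config
    rng = derive_rng(cfg.seed if seed is None else seed, "expression")
    if isinstance(history_or_ids, GeneFamilyHistory):
        copies = [n.name for n in history_or_ids.extant_leaves(species)]
        parent = f"TP53_{species}"
    else:
        copies = list(history_or_ids)
        parent = f"TP53_{species}"
    n_high = min(cfg.expressed_high, len(copies))
    n_low = min(cfg.expressed_low, max(len(copies) - n_high, 0))
    chosen = list(rng.choice(len(copies), size=n_high + n_low, replace=False)) \
        if (n_high + n_low) else []
    fpkm = {parent: cfg.parent_fpkm}
    for rank, idx in enumerate(chosen):
        fpkm[copies[idx]] = cfg.fpkm_high if rank < n_high else cfg.fpkm_low
    for cid in copies:
        fpkm.setdefault(cid, 0.0)
    df = pd.DataFrame({"gene_id": list(fpkm), "fpkm": list(fpkm.values())})
    return df.sort_values("gene_id", ignore_index=True)


#: Proboscidean body mass through time (MY before present, kg). Shape follows
#: published compilations of proboscidean body-size evolution: small stem taxa
#: until ~40 MY, then a sustained rise to elephant scale.
PROBOSCIDEA_BODY_SIZE = (
    (60.0, 5.0), (55.0, 8.0), (50.0, 12.0), (45.0, 20.0), (40.0, 35.0),
    (35.0, 120.0), (30.0, 400.0), (25.0, 900.0), (20.0, 1800.0),
    (15.0, 3000.0), (10.0, 4500.0), (5.0, 6000.0), (0.0, 7000.0),
)


def body_size_series(table_or_preset="proboscidea_fixture") -> TimeSeries:
    """Body-mass-through-time series from a (time MY, mass kg) table or the
    packaged proboscidean fixture."""
    if isinstance(table_or_preset, str):
        if table_or_preset != "proboscidea_fixture":
            raise ValueError(f"unknown body size preset {table_or_preset!r}")
        rows = PROBOSCIDEA_BODY_SIZE
    elif isinstance(table_or_preset, pd.DataFrame):
        rows = list(table_or_preset.itertuples(index=False, name=None))
    else:
        rows = list(table_or_preset)
    if not rows:
        raise ValueError("body size table is empty")
    times = [float(t) for t, _ in rows]
    if len(set(times)) != len(times):
        raise ValueError("duplicate time points in body size table")
    order = np.argsort(times)[::-1]
    t = np.array(times)[order]
    v = np.array([float(m) for _, m in rows])[order]
    return TimeSeries(t, v, kind="linear")
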