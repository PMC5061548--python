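import dataclasses

import numpy as np
import pytest

from conftest import make_controls
from retroexpand.config import SimulationConfig
from retroexpand import simulate as sim
from retroexpand.trees import build_species_tree


def cfg_with(**kw):
    return dataclasses.replace(SimulationConfig(seed=0), **kw)


# ---------------------------------------------------------------------------
# gene-family histories
# ---------------------------------------------------------------------------

def test_no_duplication_no_loss_gives_single_copy(paenungulata):
    cfg = cfg_with(duplication_rate=((40.0, 0.0, 0.0),), loss_rate=0.0,
                   duplication_clade=None)
    h = sim.simulate_gene_family(paenungulata, cfg)
    truth = h.true_copy_numbers()
    assert truth["outgroup"] == 0  # retrotransposition postdates the outgroup split
    for sp in ("hyrax", "manatee", "mastodon", "african_elephant",
               "asian_elephant", "mammoth"):
        assert truth[sp] == 1


def test_quiescent_window_has_no_duplications(paenungulata):
    for seed in range(5):
        h = sim.simulate_gene_family(paenungulata, SimulationConfig(seed=seed))
        for e in h.events:
            if e.kind == "duplication":
                assert e.time <= 40.0


def test_negative_rate_rejected():
    with pytest.raises(ValueError):
        cfg_with(duplication_rate=((40.0, 0.0, -1.0),))


def test_t_retro_must_lie_on_stem(paenungulata):
    cfg = cfg_with(t_retro=50.0)  # younger than the Paenungulata crown
    with pytest.raises(ValueError):
        sim.simulate_gene_family(paenungulata, cfg)


def test_pure_birth_mean_matches_analytic_expectation():
    """Pure-birth expansion: E[N] = exp(integral of lambda dt)."""
    stree = build_species_tree({"name": "root", "age": 50.0,
                                "children": [{"name": "A"}, {"name": "B"}]})
    lam = 0.0736
    cfg = cfg_with(t_retro=64.0, retro_host="root",
                   duplication_rate=((40.0, 0.0, lam),),
                   duplication_clade=None, loss_rate=0.0)
    counts = []
    for seed in range(2000):
        h = sim.simulate_gene_family(stree, cfg, seed=seed)
        counts.append(h.copy_number("A"))
    counts = np.asarray(counts, dtype=float)
    expected = np.exp(lam * 40.0)
    se = counts.std(ddof=1) / np.sqrt(counts.size)
    assert abs(counts.mean() - expected) < 3 * se


def test_event_conservation_on_each_species_path(paenungulata):
    """Along any root-to-tip path: extant copies + losses = duplications + 1."""
    cfg = cfg_with(loss_rate=0.02, seed=7)
    h = sim.simulate_gene_family(paenungulata, cfg)
    for sp in ("asian_elephant", "african_elephant", "mammoth"):
        tree = h.gene_tree_for(sp, include_losses=True)
        if tree is None:
            continue
        extant = sum(1 for l in tree.leaves() if l.event != "loss")
        losses = sum(1 for l in tree.leaves() if l.event == "loss")
        dups = sum(1 for n in tree.walk() if not n.is_leaf)
        assert extant + losses == dups + 1


def test_simulation_outputs_are_deterministic(paenungulata, tmp_path):
    cfg = SimulationConfig(seed=42)
    outputs = []
    for run in range(2):
        h = sim.simulate_gene_family(paenungulata, cfg)
        ss = sim.evolve_sequences(h, cfg)
        genome = sim.assemble_loci(h, ss, cfg, species="african_elephant")
        reads = sim.simulate_reads(genome, cfg)
        fa, fq, tsv = (tmp_path / f"{run}.fa", tmp_path / f"{run}.fq",
                       tmp_path / f"{run}.tsv")
        ss.write_fasta(fa)
        reads.to_fastq(fq)
        h.events_df().to_csv(tsv, sep="\t", index=False)
        outputs.append((fa.read_bytes(), fq.read_bytes(), tsv.read_bytes()))
    assert outputs[0] == outputs[1]


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def test_zero_rate_copies_equal_root_minus_deletion():
    cfg = cfg_with(substitution_rate=0.0, orf_disruption_prob=0.0)
    tree = sim.reference_gene_tree()
    ss = sim.evolve_sequences(tree, cfg, origin_age=65.0)
    s, e = ss.deletion_span
    expected = ss.root_sequence[:s] + ss.root_sequence[e:]
    for gid, seq in ss.copies().items():
        assert seq == expected
    assert ss.sequences["TP53_african_elephant"] == ss.root_sequence


def test_deletion_length_bookkeeping(reference_family):
    cfg, tree, ss = reference_family
    parent = ss.sequences["TP53_african_elephant"]
    for gid, seq in ss.copies().items():
        assert len(seq) == len(parent) - cfg.deletion_length


def test_empty_root_sequence_rejected(reference_family):
    cfg, tree, _ = reference_family
    with pytest.raises(ValueError):
        sim.evolve_sequences(tree, cfg, root_sequence="", origin_age=65.0)


def test_identity_falls_with_path_length(reference_family):
    from scipy import stats

    cfg, tree, ss = reference_family
    leaves = {l.name: l for l in tree.leaves()}
    depth = {}

    def fill(node, d):
        depth[node.name or id(node)] = d
        for c in node.children:
            fill(c, d + (node.age - c.age))

    fill(tree, 0.0)
    # path length between two leaves = depth_a + depth_b - 2 * depth_mrca
    from retroexpand.trees import mrca

    rng = np.random.default_rng(0)
    names = sorted(ss.copies())
    idents, paths = [], []
    for _ in range(100):
        a, b = rng.choice(names, size=2, replace=False)
        sa, sb = ss.sequences[a], ss.sequences[b]
        ident = np.mean([x == y for x, y in zip(sa, sb)])
        m = mrca(leaves[a], leaves[b])
        paths.append(2 * m.age)
        idents.append(ident)
    rho = stats.spearmanr(paths, idents).statistic
    assert rho < 0


def test_orf_disruption_fraction_and_effect():
    cfg = cfg_with(orf_disruption_prob=1.0)
    tree = sim.reference_gene_tree()
    ss = sim.evolve_sequences(tree, cfg, origin_age=65.0)
    from retroexpand.repertoire import assess_coding_potential

    assert ss.disrupted == set(ss.copies())
    for gid in ss.disrupted:
        coding, _ = assess_coding_potential(ss.sequences[gid])
        assert not coding


# ---------------------------------------------------------------------------
# locus assembly
# ---------------------------------------------------------------------------

def _cherry_tree():
    from retroexpand.trees import Node

    root = Node(age=5.0, event="duplication", species="sp")
    root.add(Node("copy_a", 0.0, event="extant", species="sp"))
    root.add(Node("copy_b", 0.0, event="extant", species="sp"))
    return root


def test_zero_flank_drift_gives_identical_flanks(reference_family):
    cfg, _, _ = reference_family
    cfg0 = dataclasses.replace(cfg, flank_drift=0.0)
    tree = _cherry_tree()
    ss = sim.evolve_sequences(tree, cfg0, origin_age=65.0, seed=3)
    genome = sim.assemble_loci(tree, ss, cfg0, species="sp", seed=3)
    child = next(l for l in genome.loci if l.parent_gene)
    parent = next(l for l in genome.loci if l.gene_id == child.parent_gene)
    assert child.flank_left == parent.flank_left
    assert child.flank_right == parent.flank_right


def test_flank_drift_sets_expected_identity():
    idents = []
    for seed in range(50):
        cfg = cfg_with(flank_drift=0.1, seed=seed)
        tree = _cherry_tree()
        ss = sim.evolve_sequences(tree, cfg, origin_age=65.0, seed=seed)
        genome = sim.assemble_loci(tree, ss, cfg, species="sp", seed=seed)
        child = next(l for l in genome.loci if l.parent_gene)
        parent = next(l for l in genome.loci if l.gene_id == child.parent_gene)
        both = child.flank_left + child.flank_right, parent.flank_left + parent.flank_right
        idents.append(np.mean([x == y for x, y in zip(*both)]))
    assert abs(np.mean(idents) - 0.9) < 0.02


def test_independent_mode_flanks_look_random():
    cfg = cfg_with(mechanism="independent_retrotransposition", seed=5)
    tree = sim.reference_gene_tree(dup_ages=(20, 15, 10))
    ss = sim.evolve_sequences(tree, cfg, origin_age=65.0, seed=5)
    genome = sim.assemble_loci(tree, ss, cfg, species="african_elephant", seed=5)
    fam = [l for l in genome.loci if l.mechanism != "parent"]
    a, b = fam[0], fam[1]
    ident = np.mean([x == y for x, y in zip(a.flank_left, b.flank_left)])
    assert abs(ident - 0.25) < 0.08
    assert a.fingerprints != b.fingerprints


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def test_zero_coverage_gives_no_reads():
    cfg = cfg_with(coverage=0.0)
    contigs = make_controls(2, 2000, seed=1)
    assert len(sim.simulate_reads(contigs, cfg)) == 0


def test_read_count_matches_coverage_expectation():
    cfg = cfg_with(coverage=10.0, read_length=100, error_rate=0.0)
    contigs = make_controls(10, 10_000, seed=2)  # 100 kb total
    counts = [len(sim.simulate_reads(contigs, cfg, seed=s)) for s in range(20)]
    assert abs(np.mean(counts) - 10_000) < 4 * np.sqrt(10_000 / 20) + 50


def test_error_free_reads_are_exact_substrings():
    cfg = cfg_with(error_rate=0.0, coverage=3.0)
    contigs = make_controls(2, 1500, seed=3)
    reads = sim.simulate_reads(contigs, cfg, seed=3)
    assert len(reads) > 0
    for r in reads.reads:
        assert r.sequence == contigs[r.contig][r.start:r.end]


def test_ancient_reads_are_short_and_sparse():
    cfg = cfg_with(ancient_coverage=0.5, coverage=10.0)
    contigs = make_controls(4, 3000, seed=4)
    ancient = sim.simulate_reads(contigs, cfg, ancient=True, seed=4)
    modern = sim.simulate_reads(contigs, cfg, ancient=False, seed=4)
    lo, hi = cfg.ancient_read_length
    assert all(lo <= len(r.sequence) <= hi for r in ancient.reads)
    assert len(ancient) < len(modern) / 4


def test_read_longer_than_contig_rejected():
    cfg = cfg_with(read_length=500)
    with pytest.raises(ValueError):
        sim.simulate_reads({"tiny": "ACGT" * 50}, cfg)


def test_paired_reads_flank_the_fragment():
    cfg = cfg_with(paired=True, error_rate=0.0, coverage=5.0)
    contigs = make_controls(1, 2000, seed=6)
    reads = sim.simulate_reads(contigs, cfg, seed=6)
    assert reads.paired
    r1 = next(r for r in reads.reads if r.read_id.endswith("/1"))
    assert r1.sequence == contigs[r1.contig][r1.start:r1.end]
    r2 = next(r for r in reads.reads if r.read_id.endswith("/2"))
    assert r2.sequence == sim.revcomp(contigs[r2.contig][r2.start:r2.end])


# ---------------------------------------------------------------------------
# expression and body size
# ---------------------------------------------------------------------------

def test_all_silent_expression():
    cfg = cfg_with(expressed_high=0, expressed_low=0)
    df = sim.simulate_expression([f"rtg{i}" for i in range(19)], cfg, species="sp")
    retro = df[df.gene_id != "TP53_sp"]
    assert (retro.fpkm == 0).all()
    assert df[df.gene_id == "TP53_sp"].fpkm.item() > 0


def test_default_expression_has_three_expressed_retrogenes():
    from retroexpand.expression import call_expressed, fpkm_to_tpm

    cfg = SimulationConfig(seed=9)
    df = sim.simulate_expression([f"rtg{i}" for i in range(19)], cfg, species="sp")
    tpm = fpkm_to_tpm(dict(zip(df.gene_id, df.fpkm)))
    expressed = call_expressed(tpm)
    retro_expressed = expressed - {"TP53_sp"}
    assert len(retro_expressed) == 3
    assert "TP53_sp" in expressed
    assert df.fpkm.max() == df[df.gene_id == "TP53_sp"].fpkm.item()


def test_body_size_fixture_rises_toward_present():
    ts = sim.body_size_series()
    assert np.all(np.diff(ts.values) > 0)  # times descend, mass rises
    assert ts.times[-1] == 0.0


@pytest.mark.parametrize("bad", [[], [(10, 5), (10, 7)]])
def test_body_size_invalid_tables_rejected(bad):
    with pytest.raises(ValueError):
        sim.body_size_series(bad)


def test_body_size_single_row():
    ts = sim.body_size_series([(12.0, 250.0)])
    assert len(ts) == 1 and ts.values[0] == 250.0
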