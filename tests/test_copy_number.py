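import numpy as np
import pytest

from conftest import make_controls, make_orthologs
from oracles import random_reconciliation_case
from retroexpand.config import SimulationConfig
from retroexpand import simulate as sim
from retroexpand.copy_number import (
    CopyNumberEstimate,
    DepthProfile,
    assign_reads,
    brute_force_reconciliation_cost,
    count_unsampled,
    depth_copy_number,
    estimate_copy_number,
    infer_unsampled,
    reconcile_lca,
    recovered_orthologs,
)
from retroexpand.trees import Node, TreeError, build_species_tree


# ---------------------------------------------------------------------------
# read assignment
# ---------------------------------------------------------------------------

@pytest.fixture()
def paralog_pair():
    rng = np.random.default_rng(0)
    a = sim.decode(rng.integers(0, 4, 300).astype(np.uint8))
    b = list(a)
    b[150] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[150]]  # one diagnostic site
    return {"pA": a, "pB": "".join(b)}


def test_read_over_diagnostic_site_is_unique(paralog_pair):
    read = paralog_pair["pA"][120:220]
    asn, _ = assign_reads([read], paralog_pair)
    assert asn[0].status == "unique"
    assert asn[0].genes == ("pA",)
    assert asn[0].identity == 100.0


def test_read_from_identical_region_is_ambiguous(paralog_pair):
    read = paralog_pair["pA"][0:100]
    asn, prof = assign_reads([read], paralog_pair)
    assert asn[0].status == "ambiguous"
    assert set(asn[0].genes) == {"pA", "pB"}
    # fractional depth: half a read's weight on each paralog
    assert prof.depth["pA"].sum() == pytest.approx(50.0)
    assert prof.depth["pB"].sum() == pytest.approx(50.0)
    assert prof.unique_depth["pA"].sum() == 0


def test_low_identity_read_is_unassigned(paralog_pair):
    rng = np.random.default_rng(1)
    read = list(paralog_pair["pA"][100:200])
    for pos in rng.choice(100, size=15, replace=False):  # 85% identity
        read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
    asn, _ = assign_reads(["".join(read)], paralog_pair, min_identity=90.0)
    assert asn[0].status == "unassigned"

    with pytest.raises(ValueError):
        assign_reads(["ACGT" * 25], paralog_pair, min_identity=0.0)


def test_fractional_depth_conserves_read_bases(paralog_pair):
    rng = np.random.default_rng(2)
    reads = [paralog_pair["pA"][i:i + 100]
             for i in rng.integers(0, 200, size=40)]
    asn, prof = assign_reads(reads, paralog_pair)
    assigned = [a for a in asn if a.status != "unassigned"]
    expected = sum(np.mean([e - s for s, e in a.spans]) for a in assigned)
    total = prof.depth["pA"].sum() + prof.depth["pB"].sum()
    assert total == pytest.approx(expected, rel=1e-9)


def test_no_reads_recovers_nothing(paralog_pair):
    asn, prof = assign_reads([], paralog_pair)
    recovered, minimum = recovered_orthologs(asn, prof)
    assert recovered == set() and minimum == 0


# ---------------------------------------------------------------------------
# depth-based copy number
# ---------------------------------------------------------------------------

def test_single_copy_family_estimates_one():
    import dataclasses

    cfg = dataclasses.replace(SimulationConfig(seed=5), coverage=20.0)
    contigs = make_controls(4, 1000, seed=5)
    names = sorted(contigs)
    family = {names[0]: contigs[names[0]]}
    controls = {k: contigs[k] for k in names[1:]}
    reads = sim.simulate_reads(contigs, cfg, seed=5)
    _, prof = assign_reads(reads, contigs)
    est, (lo, hi) = depth_copy_number(prof, control_ids=controls,
                                      family_ids=family, seed=1)
    assert est == pytest.approx(1.0, abs=0.25)
    assert lo <= 1.0 <= hi


def test_zero_control_depth_rejected(paralog_pair):
    # a read over the diagnostic site maps uniquely, leaving pB depth-free
    _, prof = assign_reads([paralog_pair["pA"][120:220]], paralog_pair)
    with pytest.raises(ValueError):
        depth_copy_number(prof, control_ids=["pB"], family_ids=["pA"], seed=0)


def test_estimate_invariant_to_coverage_scaling():
    import dataclasses

    ests = []
    for cov in (5.0, 10.0):
        cfg = dataclasses.replace(SimulationConfig(seed=6), coverage=cov)
        contigs = make_controls(6, 1000, seed=6)
        names = sorted(contigs)
        family = {n: contigs[n] for n in names[:2]}
        controls = {n: contigs[n] for n in names[2:]}
        reads = sim.simulate_reads(contigs, cfg, seed=6)
        _, prof = assign_reads(reads, contigs)
        est, ci = depth_copy_number(prof, control_ids=controls,
                                    family_ids=family, seed=2)
        ests.append((est, ci))
    (e1, ci1), (e2, ci2) = ests
    assert ci1[0] <= e2 <= ci1[1]  # doubling coverage stays inside the CI


# ---------------------------------------------------------------------------
# reconciliation
# ---------------------------------------------------------------------------

def _leaf(name, sp):
    return Node(name, 0.0, species=sp)


def test_congruent_tree_has_no_events():
    stree = build_species_tree({"age": 10, "children": [{"name": "A"}, {"name": "B"}]})
    g = Node(age=10)
    g.add(_leaf("a1", "A"))
    g.add(_leaf("b1", "B"))
    rec = reconcile_lca(g, stree, {"a1": "A", "b1": "B"})
    assert rec.n_duplications == 0 and rec.n_losses == 0


def test_root_duplication_two_full_copies():
    stree = build_species_tree({"age": 10, "children": [{"name": "A"}, {"name": "B"}]})
    g = Node(age=20)
    for i in (1, 2):
        sub = Node(age=10)
        sub.add(_leaf(f"a{i}", "A"))
        sub.add(_leaf(f"b{i}", "B"))
        g.add(sub)
    rec = reconcile_lca(g, stree, {"a1": "A", "b1": "B", "a2": "A", "b2": "B"})
    assert rec.n_duplications == 1 and rec.n_losses == 0
    assert rec.species_of(g).name == "root" or rec.species_of(g) is rec.species_tree


def test_duplication_with_one_loss():
    stree = build_species_tree({"age": 10, "children": [{"name": "A"}, {"name": "B"}]})
    g = Node(age=20)
    sub = Node(age=10)
    sub.add(_leaf("a1", "A"))
    sub.add(_leaf("b1", "B"))
    g.add(sub)
    g.add(_leaf("a2", "A"))
    rec = reconcile_lca(g, stree, {"a1": "A", "b1": "B", "a2": "A"})
    assert rec.n_duplications == 1
    assert rec.losses == {"B": 1}


def test_errors_on_bad_inputs():
    stree = build_species_tree({"age": 10, "children": [{"name": "A"}, {"name": "B"}]})
    g = Node(age=5)
    g.add(_leaf("a1", "A"))
    g.add(_leaf("x", "X"))
    with pytest.raises(ValueError):
        reconcile_lca(g, stree, {"a1": "A", "x": "X"})
    nonbinary = Node(age=5)
    for n in ("p", "q", "r"):
        nonbinary.add(_leaf(n, "A"))
    with pytest.raises(TreeError):
        reconcile_lca(nonbinary, stree, {"p": "A", "q": "A", "r": "A"})


def test_lca_matches_brute_force_on_random_cases():
    rng = np.random.default_rng(7)
    for _ in range(40):
        g, s, m = random_reconciliation_case(rng)
        rec = reconcile_lca(g, s, m)
        assert (rec.n_duplications, rec.n_losses) == \
            brute_force_reconciliation_cost(g, s, m)


# ---------------------------------------------------------------------------
# unsampled-gene rules
# ---------------------------------------------------------------------------

def _missing_paralog_tree(split=8.0):
    """Reference paralogs m1 (div 30 MY) and m2 (div 12 MY) above a sampled
    ortholog pair, m3-m5 (div 5, 3, 2 MY) below it."""
    root = Node(age=30.0)
    root.add(_leaf("m1", "african"))
    n12 = root.add(Node(age=12.0))
    n12.add(_leaf("m2", "african"))
    cherry = n12.add(Node(age=split))
    cherry.add(_leaf("asian_ortholog", "asian"))
    c5 = cherry.add(Node(age=5.0))
    c5.add(_leaf("m3", "african"))
    c3 = c5.add(Node(age=3.0))
    c3.add(_leaf("m4", "african"))
    c2 = c3.add(Node(age=2.0))
    c2.add(_leaf("m5", "african"))
    c2.add(_leaf("sampled_ref", "african"))
    return root


def test_count_unsampled_hand_rule():
    assert count_unsampled([12, 30, 5, 3, 2], split_time=8) == 2
    assert count_unsampled([30, 20, 10], split_time=25) == 1  # mastodon variant
    with pytest.raises(ValueError):
        count_unsampled([10], split_time=0)


def test_unsampled_from_dated_tree():
    tree = _missing_paralog_tree()
    result = infer_unsampled(None, tree, "asian", "african", split_time=8.0,
                             focal_evidence={"sampled_ref"})
    assert result["unsampled"] == {"m1", "m2"}
    assert result["maximum"] == result["sampled"] + 2
    assert result["focal_lineage_loss"] == {"m3", "m4", "m5"}


def test_unsampled_ancient_mode_labels_reference_paralogs():
    tree = _missing_paralog_tree()
    result = infer_unsampled(None, tree, "asian", "african", split_time=8.0,
                             ancient_mode=True, focal_evidence={"sampled_ref"})
    assert "reference_specific_paralog" in result
    assert result["reference_specific_paralog"] == {"m3", "m4", "m5"}


def test_nothing_missing_means_no_unsampled():
    root = Node(age=8.0)
    root.add(_leaf("ref1", "african"))
    root.add(_leaf("focal1", "asian"))
    result = infer_unsampled(None, root, "asian", "african", split_time=8.0)
    assert result["unsampled"] == set()
    assert result["maximum"] == 1


def test_unsampled_monotone_in_split_time():
    tree = _missing_paralog_tree()
    counts = [infer_unsampled(None, tree, "asian", "african", split_time=s)
              ["n_unsampled"] for s in (1.0, 4.0, 8.0, 15.0, 29.0, 40.0)]
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# composite estimator on the fixed reference family
# ---------------------------------------------------------------------------

# 14 sampled orthologs: the absent five are the deep singletons RTG7/RTG8/RTG12
# (divergences 24/22/14 MY, older than the 8 MY split -> unsampled) and the
# youngest twins RTG18/RTG19 (2 MY apart, post-split reference duplicates
# whose reads are largely ambiguous at 100 nt)
PRESENT_14 = tuple(f"TP53RTG{i}" for i in (1, 2, 3, 4, 5, 6, 9, 10, 11, 13,
                                           14, 15, 16, 17))


def _focal_read_setup(reference_family, present, seed, coverage=None,
                      ancient=False, divergence_my=8.0):
    import dataclasses

    cfg, tree, ss = reference_family
    if coverage is not None:
        cfg = dataclasses.replace(cfg, coverage=coverage)
    parent = ss.parent_ids["african_elephant"]
    templates = make_orthologs(ss, list(present) + [parent],
                               divergence_my=divergence_my,
                               cfg=cfg, seed=seed)
    gene_len = len(ss.sequences[parent])
    controls = make_controls(5, gene_len, seed=seed + 1000)
    templates.update(controls)
    reads = sim.simulate_reads(templates, cfg, ancient=ancient, seed=seed)
    ref_genes = {g: ss.sequences[g] for g in ss.copies()}
    ref_genes[parent] = ss.sequences[parent]
    return cfg, tree, ss, parent, controls, reads, ref_genes


def test_estimate_brackets_truth_for_full_family(reference_family):
    # a focal genome that split from the reference after the youngest
    # duplication carries a 1:1 ortholog of every reference paralog
    present = tuple(f"TP53RTG{i}" for i in range(1, 20))
    cfg, tree, ss, parent, controls, reads, refs = _focal_read_setup(
        reference_family, present, seed=21, coverage=10.0, divergence_my=1.0)
    est = estimate_copy_number(reads, refs, tree, focal_species="sister_genome",
                               reference_species="african_elephant",
                               split_time=1.0, control_regions=controls,
                               seed=1, parent_gene=parent)
    truth = 20  # 19 retrogenes + the parent gene
    assert est.minimum <= truth <= est.maximum
    assert est.ci_low <= truth <= est.ci_high


def test_estimate_single_copy_family():
    cfg = SimulationConfig(seed=31)
    rng = np.random.default_rng(31)
    gene = sim.decode(rng.integers(0, 4, 1000).astype(np.uint8))
    tree = Node("only_gene", 0.0, species="african_elephant")
    controls = make_controls(3, 1000, seed=32)
    templates = {"focal__only_gene": gene, **controls}
    reads = sim.simulate_reads(templates, cfg, seed=33)
    est = estimate_copy_number(reads, {"only_gene": gene}, tree,
                               focal_species="asian",
                               reference_species="african_elephant",
                               split_time=8.0, control_regions=controls, seed=2)
    assert est.minimum == 1 and est.maximum == 1
    assert est.average == pytest.approx(1.0, abs=0.25)


def test_ancient_reads_under_recover(reference_family):
    cfg, tree, ss, parent, controls, reads, refs = _focal_read_setup(
        reference_family, PRESENT_14, seed=41, ancient=True)
    est = estimate_copy_number(reads, refs, tree, focal_species="asian",
                               reference_species="african_elephant",
                               split_time=25.0, control_regions=controls,
                               seed=3, ancient_mode=True, parent_gene=parent)
    assert est.minimum < len(PRESENT_14)
    assert est.maximum >= est.minimum


def test_grafted_joint_tree_reconciles_cleanly():
    """Attaching a focal ortholog to every recovered reference paralog gives a
    joint tree whose reconciliation against the two-species tree has no
    duplications beyond the reference family's own."""
    from retroexpand.copy_number import graft_orthologs

    ref_tree = sim.reference_gene_tree(dup_ages=(30, 20, 10), prefix="REF")
    grafted, leaf_map = graft_orthologs(ref_tree, ["REF1", "REF3"],
                                        focal_species="asian", split_time=8.0)
    stree = build_species_tree({"age": 8.0, "children": [
        {"name": "african_elephant"}, {"name": "asian"}]})
    rec = reconcile_lca(grafted, stree, leaf_map)
    # 3 duplications inherited from the reference family; the 2 ungrafted
    # paralogs are seen as losses on the focal branch
    assert rec.n_duplications == 3
    assert rec.losses.get("asian", 0) == 2


def test_estimate_validation():
    with pytest.raises(ValueError):
        CopyNumberEstimate(minimum=5, average=3.0, ci_low=2.0, ci_high=4.0,
                           maximum=4)
    with pytest.raises(ValueError):
        CopyNumberEstimate(minimum=1, average=9.0, ci_low=2.0, ci_high=4.0,
                           maximum=4)
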