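# retroexpand

Simulation and inference toolkit for the expansion history of a retrogene
family — a gene copied back into the genome through reverse transcription of
its mRNA and then multiplied by repeated segmental duplication. The motivating
system is the elephant lineage, where the tumor suppressor *TP53* was
retroduplicated once on the paenungulate stem (~64 MY ago) and the resulting
retrogene family later expanded to ~19 copies in parallel with the evolution
of very large body size. `retroexpand` makes every step of that analysis a
tested, reusable operation and provides a synthetic-data generator with the
same statistical structure so each estimator can be validated against known
truth.

## What it computes

**Repertoire characterization** (`retroexpand.repertoire`): local alignment
with affine gaps, reciprocal-best-hit orthology, coding potential and ORF
size, diagnostic 15–30 bp deletions shared by all retrogenes in an MSA,
paralog-specific PCR amplicon prediction, and classification of each
duplicate's origin (segmental duplication vs independent retrotransposition)
from flank identity (≥ 80%) and shared transposable-element fingerprints.

**Copy number from shotgun reads** (`retroexpand.copy_number`), by three
complementary estimators for a focal genome scored against a reference gene
set:

- *minimum* — 1:1-ortholog recovery: a reference paralog counts as present
  when uniquely assigned reads cover ≥ 50% of it;
- *average* — normalized read depth: summed family depth over single-copy
  control depth, `N̂ = Σ_g d̄_g / d̄_ctrl`, with a seeded percentile bootstrap
  95% CI over 100 nt windows;
- *maximum* — dated gene-tree reconciliation: a gene lineage crossing the
  focal/reference split with no sampled focal descendant is an *unsampled*
  gene (present but unsequenced); LCA duplication–loss reconciliation is
  provided and checked against exhaustive search.

**Copy number through time** (`retroexpand.trajectory`): the lineage count
N(t) ancestral to a focal species' copies from a dated gene tree, and its
correlation with a body-size-through-time series using circular-shift
permutation tests that respect autocorrelation.

**Expression** (`retroexpand.expression`): `TPM_i = FPKM_i / Σ FPKM × 10⁶`,
expressed-gene calls at TPM ≥ 2 (inclusive), and unique-read counts per
paralog.

**Synthetic data** (`retroexpand.simulate`): dated species trees (including a
seven-taxon elephant/mammoth/mastodon/hyrax/manatee preset), birth–death
gene-family histories with a quiescent interval and clade-restricted
expansion, two-parameter (transition/transversion) sequence evolution with the
shared diagnostic deletion and ORF-disrupting mutations, gene+flank loci with
TE fingerprints, modern and ancient (short, low-coverage) FASTQ read sets, and
FPKM/body-size tables.

## Worked example

```python
from retroexpand.pipeline import run_end_to_end

report = run_end_to_end(seed=4)
print(report["true_copy_numbers"])
print(report["estimates"]["asian_elephant"])
print(report["trajectory"])
```

prints (elided):

```
{'hyrax': 1, 'manatee': 1, 'mastodon': 3, 'african_elephant': 29,
 'asian_elephant': 29, 'mammoth': 25, 'outgroup': 0}
{'true_copies': 30, 'true_shared_at_split': 17.0,
 'minimum': 11, 'average': 29.42, 'ci95': [24.68, 35.11], 'maximum': 17, ...}
{'r': 0.985, 'p_value': 0.016, 'n': 61, 'copies_at_present': 29.0}
```

Reading the numbers: the simulated Asian elephant genome carries 30 family
members (29 retrogene copies + the parent gene). The depth estimator tracks
that total (29.4, CI covering 30) because every copy's reads land somewhere in
the family. The reference-anchored estimators see only lineages shared with
the African elephant reference at the 8 MY split (17 here): ortholog recovery
gives the minimum (11) and the unsampled-gene rule the maximum (17) —
focal-lineage duplications after the split are invisible to them, exactly the
behavior the minimum/maximum bracket is meant to express. The copy-number
trajectory and the packaged body-size series rise together (r = 0.985,
circular-shift p = 0.016). The same run classifies every duplicate locus as
segmental (shared TE fingerprints, flank identity ≥ 80%) and calls 3 of the
simulated retrogenes expressed at TPM ≥ 2.

The same pipeline is scriptable from the shell:

```bash
retroexpand run-all --out results/run1 --seed 4
retroexpand simulate --out results/sim --seed 7
retroexpand expression --fpkm results/sim/fpkm.tsv
```

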