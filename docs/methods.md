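# Methods

This note documents the models, estimators, parameter choices and known
limitations of `retroexpand`, in the order data flows through the package.

## Species trees and time

All times are millions of years (MY) before present, present = 0; coordinates
are 0-based half-open throughout. The packaged `paenungulata` species tree
places the paenungulate crown (hyrax vs elephants+sea cows) at 64.2 MY, the
mastodon–elephant split at 25 MY, the African vs (Asian elephant, mammoth)
split at 8 MY, and the Asian elephant–mammoth split at 6 MY. The
Afrotheria-level outgroup split (80 MY) and the manatee–elephant split
(60 MY) use standard timetree values. Extinct tips carry specimen ages:
mastodon 0.09 MY, mammoth 0.011 MY.

## Gene-family simulator

A single retrotransposition seeds the family at `t_retro` on the stem branch
above `retro_host`. The default `t_retro = 65.0` MY places the event on the
Paenungulata stem, just above the 64.2 MY crown: a stem event must predate
the crown, and 65 lies inside the credibility window of dated analyses of
this family. Afterwards each gene lineage duplicates at a piecewise-constant
rate λ(t) and is lost at constant rate μ, simulated by competing exponential
waiting times walked across the rate-change boundaries (exact for
piecewise-constant rates). Gene lineages split passively at speciations.

Defaults encode the study scenario: quiescence until 40 MY, then
λ = 0.0736 events/lineage/MY on (40, 0] — the pure-birth rate whose expected
extant count after 40 MY is e^(0.0736×40) ≈ 19 copies — restricted to the
proboscidean clade (`duplication_clade`), so hyrax and manatee retain single
retrogene copies. Empirical per-lineage duplication/loss rates are not known
for this family; λ is a free parameter documented here, and μ defaults to 0
(the tests exercise μ > 0 separately). The `duplication_clade` field extends
the time-only rate with a lineage restriction because the emulated expansion
is clade-specific; setting it to `None` recovers a homogeneous birth–death
process, which is what the pure-birth calibration test uses.

Pure-birth mean copy number is verified against e^(∫λ dt) within three Monte
Carlo standard errors at 2000 replicates, and event bookkeeping satisfies
extant + losses = duplications + 1 along every root-to-tip path.

## Sequence evolution

Substitutions follow a two-parameter transition/transversion model
(κ = 2 by default) applied per branch with hit probability 1 − e^(−r·t); a
site mutates at most once per branch, a fine approximation at the ≤ 25%
divergences simulated here, and the identity-vs-path-length monotonicity test
covers exactly the property downstream thresholds rely on. The default rate
r = 0.002 subs/site/MY reproduces the observed ~80–83% retrogene-to-parent
identity after a 65 MY origin (2 × 65 × 0.002 ≈ 0.26 expected hits/site
before multiple-hit saturation). The root sequence is a random 1000 nt gene
with a single long ATG-initiated ORF; parent-gene orthologs evolve along the
species tree (sharing ancestral states until their species split), and
retrogene copies evolve along the gene tree after losing a single diagnostic
deletion (default 21 nt, in-frame, inside the ORF) on the retrotransposition
branch. A configured fraction of copies (default 5/19, matching the packaged
repertoire's noncoding fraction) receives premature stop codons, inserted
repeatedly until no forward-frame ORF of ≥ 25 aa remains, so coding-potential
truth is unambiguous.

## Loci, fingerprints, reads

Each copy is embedded in a contig as flank + gene + flank (flanks 500 nt). In
segmental mode the new copy of each duplication inherits its parent locus's
flanks with `flank_drift` substitutions/site (default 0.05) applied once, and
all family loci share the TE fingerprint label set; in
independent-retrotransposition mode every copy gets unrelated flanks and
private fingerprints. Five single-copy control contigs of family-average gene
length are emitted for depth normalization. Reads have uniform start
positions, expected count coverage × length / read-length (Poisson), per-base
error 0.002, quality placeholder `I`. Modern defaults: 100 nt single-end at
5× (between the deep modern genomes and the sparser ancient sets the analysis
style targets). Ancient mode: lengths uniform on [40, 100] nt at 0.5×, no
deamination damage model (a damage flag is reserved but off; the 90% identity
floor used in assignment absorbs moderate damage in practice).

## Read assignment and the three copy-number estimators

Every read is scored against every reference with bit-parallel semi-global
(infix) alignment; the best edit distance wins, exact ties are *ambiguous*,
and reads below 90% identity (the deep-divergence mapping floor) or 30 nt
aligned are *unassigned*.

- **Minimum (1:1 orthology).** Recovery requires unique-read breadth:
  ≥ 50% of a reference gene's positions covered by ≥ 1 uniquely assigned
  read. Ambiguous reads are deliberately *not* evidence of presence — with
  near-identical paralogs they would mark absent copies as present. The
  flip side, documented and tested, is that paralog pairs younger than a few
  MY (≲ 1% diverged) are near-invisible to 100 nt unique reads: most of their
  read pairs tie. The recovery thresholds (breadth 0.5 at depth 1) are
  configurable conventions, not fitted values.
- **Average (normalized depth).** Ambiguous reads contribute fractional 1/k
  depth to each of the k tied genes, so total family depth is conserved and
  the ratio estimator stays unbiased for arbitrarily similar copies. The
  estimate is Σ over family genes of mean depth, divided by pooled mean
  control depth; the 95% CI is a percentile bootstrap (1000 replicates,
  seeded) over 100 nt windows resampled within the family and control sets.
  The estimator is invariant to coverage scaling by construction.
- **Maximum (reconciliation with unsampled genes).** On the dated reference
  gene tree, every gene lineage alive at the focal/reference split that left
  reference descendants was present in the focal ancestor; if none of its
  descendants were recovered from the focal reads it is counted as one
  *unsampled* gene. This lineage-crossing formulation is equivalent to the
  per-paralog rule "missing and divergence age > split ⇒ unsampled" when
  missing paralogs attach individually, and handles whole missing clades
  without double counting. For deeply diverged focal taxa (`ancient_mode`,
  e.g. mastodon at a 25 MY split) missing paralogs younger than the split are
  reported as reference-lineage-specific duplicates rather than losses.
  LCA reconciliation (`reconcile_lca`) computes duplication nodes and
  per-branch losses and is tested against an exhaustive search over all valid
  gene→species mappings.

A reference-anchored method cannot see focal-lineage duplications that
postdate the split; the pipeline therefore reports, next to the true copy
number, the true number of lineages shared at the split, and checks
minimum ≤ truth and maximum ≥ shared-at-split.

## Repertoire operations

The local aligner scores matches +1, mismatches −2, and a gap of length L at
−5 − 2L (BLAT-like stringency, configurable); ties between co-optimal
alignments resolve to the smallest start on the first sequence, then the
second. Percent identity counts matches over aligned columns including
internal gaps. The dynamic program runs on Biopython's C engine behind this
scoring convention; tests compare it against an independent brute-force
enumeration of alignment paths. Coding potential is the longest ATG-initiated
ORF over the three forward frames (genes are supplied stranded), length in aa
excluding the stop, with a permissive 25 aa floor — the packaged repertoire's
shortest ORF is 79 aa, so the floor only filters spurious micro-ORFs.
Diagnostic-deletion detection requires, per column, gaps in 100% of ingroup
rows (configurable fraction) and no gap in any outgroup row, then reports
maximal runs of 15–30 columns. Amplicon prediction uses exact primer matching
by default (paralog-specific primers are designed exact); all forward/reverse
site combinations are reported and multiplicity is flagged. The mechanism
classifier calls a duplicate segmental when mean flank identity to its parent
locus is ≥ 80% and the TE fingerprint labels match; flank identity is
per-site for equal-length flanks (edit-distance based otherwise), and loci
without flanks are skipped with a warning.

## Trajectory and correlation

N(t) counts gene-tree edges spanning time t that are ancestral to the focal
species' sampled copies; with loss tips included (restrict the tree to the
focal path first) the curve steps −1 at loss ages and +1 at duplication ages.
The default grid is 1 MY bins from the family origin to the present. Copy
number resamples as a step function (it is a count); body mass linearly. The
packaged body-size fixture rises from ~5 kg at 60 MY to 7000 kg at present,
following published compilations of proboscidean body-size evolution.
Correlation significance uses circular-shift permutations (all n−1 distinct
shifts when fewer than `n_perm`), which preserves each series'
autocorrelation under the null; i.i.d. shuffling would badly overstate
significance for trending series. The null calibration test verifies the
permutation p-value is uniform for white-noise pairs.

## Expression

TPM_i = FPKM_i / Σ FPKM × 10⁶; the expressed call is inclusive at TPM ≥ 2.
FPKM estimation from raw RNA-seq is out of scope — tables are inputs or
simulator outputs. The expression simulator gives the parent gene the highest
abundance and a configured minority of copies (default 1 high + 2 low of 19)
nonzero FPKM, the rest zero, so the expressed set is exact generator truth.

## What the synthetic data does and does not capture

The generator reproduces the features the estimators depend on: shared
diagnostic deletion, paralog divergence proportional to duplication age,
fingerprinted flank inheritance, uniform modern coverage, short sparse
ancient reads, and a minority-expressed family. It does not model real TE
sequence content, recombination-mediated duplication, indels beyond the
diagnostic deletion and engineered frameshifts, GC/coverage bias, paired-end
insert-size variation (pairs are simulated but assigned per mate), or
post-mortem DNA damage. Passing tests therefore demonstrate correctness of
the estimators under these idealized conditions, not performance on real
ancient DNA.

## Problem sizes and determinism

Test and acceptance runs use 1000 nt genes, a 19-copy reference family, 5×
modern / 0.5× (or 0.2×) ancient coverage, 50-replicate parameter-recovery
loops, 1000 bootstrap replicates and up to 10⁴ permutations — sizes at which
every property is measurable in seconds to a couple of minutes on one CPU.
All randomness flows from one master seed; per-stage generators are derived
by hashing a stage label into the seed sequence, so outputs are byte-stable
and adding a stage never perturbs another stage's stream.
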