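# Methods

## Off-target attribution screen

The screen asks, for every somatic mutation unique to an edited clone,
whether Cas9 guided by any of the transfected gRNAs could plausibly have
caused it.

**Somatic differencing.** Both callsets are normalized (shared prefix/suffix
trimming, indel left-alignment against the reference — the standard
parsimony procedure, stopping at the contig edge where the representation
is already leftmost) and differenced by exact (chrom, pos, ref, alt) key.
Indels longer than 50 nt are excluded; variant calling itself is out of
scope — the pipeline consumes per-sample VCFs, and genotype-evidence
subtleties are the callers' concern.

**Window scan.** The wild-type reference window (100 bp of flank either
side of the REF-allele span, truncated and flagged at contig edges) is
scanned exhaustively and gaplessly at every offset on both strands for
protospacer + PAM. Windows are ≤ ~300 bp, so exhaustive search is exact and
replaces a heuristic aligner (word size and gapping would otherwise be
unspecified free parameters). The scanner is vectorised (byte comparison
over a sliding-window view); tests hold it equal to a naive double-loop
oracle on 1,000 random windows.

**Attribution criteria.** A mutation is attributed when some scanned site
satisfies all of:

* PAM matches NRG (IUPAC; R = A/G). PAM positions do not count toward the
  mismatch threshold (`pam_strict`, default on; the relaxed mode folds PAM
  mismatches into the count instead).
* The predicted blunt cut — 3 bp 5′ of the PAM, reported as the coordinate
  of the base on the PAM-distal side of the cut bond, orientation-corrected
  for strand — lies within `cut_proximity_tol` of the variant anchor.
  "Proximal" is not a defined quantity, so the tolerance is explicit;
  default 5 bp, since NHEJ indels cluster within a few bases of the cut.
* Either ≤ 5 protospacer mismatches (encoding "fewer than six"), or the
  10-bp PAM-proximal seed matches exactly.

The variant anchor is the POS for SNVs/MNVs/insertions and the midpoint of
the deleted span for deletions (resection treated symmetrically). A variant
attributed by any guide is attributed; all attributing guides are recorded,
with the reason taken from the lowest-mismatch eligible site. Attributed
variants whose evidence is a 0-mismatch, design-PAM (NGG) site cutting
inside a registered target locus are partitioned as on-target; the report
partition (on-target / off-target attributed / unattributed) is checked to
be exhaustive and disjoint.

Matching is gapless: the criteria are phrased in base mismatches and a
contiguous seed, so bulge-tolerant alignment is deliberately out of scope.
A genomic N never matches any IUPAC code (and breaks PAM and seed):
ambiguous sequence must not create an attribution.

## Antigen coverage

Seven blood-group systems, each removable by one gene knockout
(GYPB, RHAG for Rh_null regulator type, ACKR1, KEL, FUT1, BCAM, SLC14A1).
A patient profile is the set of systems their existing (or, for the two
untransfused Fy(a−b−) individuals, anticipated) alloantibodies require
absent; service is subset containment. McLeod patients carry an explicit
flag rather than an eighth system: XK removal causes acanthocytosis and is
not a candidate knockout, so they are never servable here. Panel planning
is greedy (largest marginal gain, ties to survey-table row order) with an
exhaustive ≤ 2⁷-subset optimum as oracle; on this 7-element universe greedy
is verified equal to optimal.

## Cohort reconstruction

Only the survey's marginals are public, not per-patient antibody
combinations, so the generator emits *a* consistent realisation: 54
profiled patients (plus 2 McLeod) carrying 77 system instances — counts
MNS 22, Rh 19, Duffy 12, Kell 10, H 8, Lutheran 3, Kidd 3 — with exactly
19 multi-system patients. The three Lutheran and three Kidd patients are
single-system and disjoint, and multi-system combinations are confined to
the five major systems: this is the unique reading under which the
seven-panel count (54), the five-panel count (48) and the +3/+3 marginal
gains are simultaneously consistent with the marginals. The instance
arithmetic forces 35 single-, 15 double- and 4 triple-system patients
(35 + 30 + 12 = 77); assignment is randomized largest-remaining-count with
seeded tie-breaks, then validated against every invariant before return.
Coverage numbers are therefore realisation-invariant; only such quantities
are asserted across seeds.

## Proteome arithmetic

Ratios are quotients of replicate means (two technical replicates per
condition); log₂ values are reported alongside. Filtering keeps records
with FDR q ≤ 0.01 and ≥ 2 peptides — the q-value is an input column, since
FDR estimation belongs to the search engine, as does channel normalization
(ratios are taken as direct mean quotients). Percent reductions are rounded
half-up to integer percent, matching the precision at which they are
reported. The headline summary is the share of membrane/cytoskeletal
records with ratio ≤ 1/fold_threshold (default 2).

## Synthetic data

All generators are pure functions of (parameters, seed), with per-stage
streams spawned from one master `SeedSequence` in fixed order so stages
never perturb each other.

* **Genome**: i.i.d. bases at 41 % GC (human-like), default 100 kb;
  rejection-checked to contain no ≤ 1-mismatch copy of any guide. Guides
  are random 20-mers (one per knockout target gene) with homopolymer runs
  capped at 3 nt so planted indels stay anchored under left-alignment.
* **Sites**: written into the genome with exactly the specified mismatch
  positions, PAM and strand; verified by re-scanning in tests. On-target
  sites use AGG (NGG); adversarial datasets add, per guide, a near-miss
  site (6 mismatches, one breaking the seed, NRG PAM — attributable by
  neither clause) and an attributable off-target site (3 PAM-distal
  mismatches, intact seed, NRG-but-not-NGG PAM).
* **Edits**: deletions (2–12 nt) centred on the cut bond, insertions placed
  into it, emitted as normalized VCF-style records; biallelic flags are
  registry metadata (the VCFs are sites-only).
* **Background**: SNVs at a fixed count (default 200 on 100 kb), split into
  a germline-like shared set and a clone-private set (default 50/50), and
  excluded by default from within flank + protospacer + PAM (123 bp) of any
  implanted site so ground truth is unambiguous.
* **Proteome**: log-normal baseline abundances with multiplicative
  replicate noise (`noise_cv`, default 5 %; 0 reproduces planted ratios
  exactly). Planted proteins carry the published ratios and always pass the
  filters; 2 % of the membrane-category background is drawn at ≥ twofold
  reduction — the residual disruption level the knockout line exhibits —
  and small fractions of single-peptide (5 %) and high-FDR (3 %) records
  exercise the filters.

What the simulators do *not* emulate: read-level sequencing error and
coverage variation (callsets are consumed as truth), caller-specific
artefacts, linked variation, bulged off-target sites, repair-outcome
spectra (indel sizes are uniform, not microhomology-driven), antigen-level
serology below the system level, and search-engine/channel effects in the
proteome. Passing tests therefore demonstrate the correctness of the
arithmetic and the attribution logic under the stated conditions, not
performance on real WGS or MS data — in particular, the desk-scale null
off-target result shows the criteria do not fire on clean background, not
that no real off-target edit exists.

## Problem sizes and numerics

Default analysis sizes — 100 kb genome, 5 guides, 5 planted edits, 200
background SNVs, 56-patient cohort, 1,000-protein table — keep every stage
exact and fast while preserving the structure of the full-scale procedure.
Coordinates are 1-based inclusive throughout (VCF convention). Scan order
is deterministic (plus strand ascending offset, then minus); panel
tie-breaks follow survey-table row order; attribution ties resolve toward
the lowest mismatch count, then the nearest cut. Degenerate inputs are
defined rather than erroneous where sensible: windows shorter than the
query scan to empty, `cut_offset` 0 degenerates to the last protospacer
base (the guide type itself requires 0 < offset < L), and empty panels
serve nobody.

## Known limitations

Gapless matching misses bulged off-targets; the cut-proximity tolerance is
a declared constant, not fitted; somatic differencing is representation-
exact (records that differ after normalization are different variants);
the cohort is one consistent realisation of under-determined marginals;
and no thermodynamic or learned off-target score is computed — the screen
implements attribution rules, not activity prediction.
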