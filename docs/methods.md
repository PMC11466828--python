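# Methods

## The repeated-mismatch model

A kidney-transplant recipient who also receives third-party MSCs faces two
donor HLA repertoires. The package analyzes each patient as a *triad*
(recipient, kidney donor, MSC donor) at two resolutions:

**Split-antigen level.** Each two-field allele maps to a WHO serologic split
designation through a versioned serology table. For each counted locus
(A, B, C, DR, DQ) the donor's mismatch set is the set of donor split
antigens absent from the recipient's split antigens at that locus. Set
semantics mean a homozygous donor contributes an antigen once, so per-locus
counts are 0–2. DR splits are taken from DRB1 only by default; DR51/52/53
(from DRB3/4/5) can be included with a switch. DQ splits come from DQB1.

**Amino-acid level.** For donor allele *d* and solvent-accessible position
*p*, the donor residue is mismatched iff no recipient allele in the
comparison scope carries that residue at *p*. The comparison scope is
intralocus for class I (recipient A alleles for an A-locus donor allele,
etc.) and, by default, interlocus for class II: DR and DQB donor alleles are
checked against the pooled recipient DRB1/3/4/5 + DQB1 beta chains
(`scope="intralocus"` restricts to the donor allele's own locus). Mismatches
are collected per locus group — class I, DR, DQB — as **unique (position,
residue) pairs**, pooled over the donor's one or two alleles per locus with
duplicates counted once.

A **repeated mismatch** is the intersection of the kidney-donor and
MSC-donor mismatch sets, per locus (splits) or per locus group (residues).
This intersection is only well defined because pairs are identified by
(group, position, residue): two donors may carry the same mismatched residue
on alleles of different loci within the DR group, and at the group level
those are the same epitope unit. Per-locus origin is therefore not part of
the pair identity.

Conventions that matter:

* **Positions** are mature-protein, 1-based (leader peptide excluded) —
  the numbering behind residue labels such as "55R".
* **Null alleles** (N suffix) express no surface protein; they are excluded
  both from donor mismatch contributions and from the recipient matching
  pool.
* **Unknown residues** are uninformative, never evidence: a donor unknown
  never produces a mismatch, and a recipient unknown never confirms a
  match. This keeps two laws exact — adding a recipient allele can never
  increase a mismatch count, and an interlocus mismatch set is always a
  subset of the intralocus one — and it keeps the interlocus pool usable
  when loci have different alignment coverage. The flip side: a truncated
  recipient sequence cannot veto mismatches at positions it does not cover.
* **DQA1/DPA1** are carried for bead identity but excluded from the
  headline counts (groups are class I, DR, DQB).

## Bead-panel interpretation

A single-antigen bead carries one class I protein or a class II beta/alpha
pair. A bead is positive iff its background-corrected MFI (BCM) is at or
above the threshold (default 1,000; BCM is an input — vendor background
correction is out of scope). Three operations build on the partition:

* **Self-background flag**: any positive bead carrying one of the
  recipient's own alleles marks the whole panel as background and
  suppresses DSA interpretation. The default is this strict any-positive
  rule; a magnitude-ratio variant (self BCM ≥ 0.7 × the maximum positive
  BCM) is available for the reading that compares self and allo signal
  strength.
* **DSA assignment** labels each positive bead self / shared /
  kidney-donor / msc-donor / third-party by **second-field allele
  identity** of the bead's class I or beta-chain allele. Serologic
  similarity is deliberately never used: a DQ6-group bead is third-party
  unless its exact allele is carried by a donor, because split-level
  inference is a documented source of DSA misclassification.
* **Candidate target residues**: the lenient set contains masked
  (position, residue) pairs present on every positive bead's group allele
  and absent from the recipient scope; the strict set additionally requires
  absence from every negative bead's group allele ("uniquely shared by all
  reactive beads"). Candidates are ranked by the number of negative beads
  they exclude, ties broken by (position, residue) for determinism.
  Residues in perfect linkage across the panel are indistinguishable by
  construction and are reported together.

## Cohort statistics

Per-patient repeated amino-acid counts are summarized per locus group by
median and IQR; the patient total is class I + DR + DQB. Patients without
amino-acid data (e.g. no material for high-resolution typing) are excluded
and listed. Even-n medians are the mean of the two central order statistics.

Two cohorts are compared on the per-patient totals with the two-sided
Mann–Whitney rank-sum test. The headline p-value is the normal
approximation with mid-ranks for ties, tie-corrected variance

U = R₁ − n₁(n₁+1)/2,  z = (U − n₁n₂/2) / √(n₁n₂/12 · (n+1 − Σ(tⱼ³−tⱼ)/(n(n−1))))

and **no continuity correction**. When n₁+n₂ ≤ 20 the permutation
distribution is enumerated exactly (all C(n₁+n₂, n₁) relabelings) and two
exact values are reported alongside:

* `p_exact` — conventional two-sided: the proportion of relabelings whose
  U deviates from its mean at least as much as observed;
* `p_exact_mid` — the mid-p variant with half weight on the observed tie
  class, which is the exact counterpart of the uncorrected normal
  approximation and tracks it within 0.02 on generator cohorts with
  n₁, n₂ ≥ 8. The conventional `p_exact` carries the full weight of the
  tie class and can sit up to ~0.04 from the asymptotic value on heavily
  tied count data; on the packaged published totals the three values are
  0.0544 (asymptotic), 0.0565 (exact), 0.0530 (mid-p).

Degenerate input (zero variance across the pooled sample) returns p = 1
with a warning. A single comparison is performed, so no multiple-testing
correction applies; α = 0.05. DSA association is reported descriptively
(totals stratified by DSA status; tallies of patients repeating a named
residue who did or did not form an antibody against it) — no model is
fitted.

## Packaged reference data (synthetic)

Real full-scale protein alignments and the published solvent-accessibility
definition are not redistributed; the packaged files are a small
**synthetic** stand-in (filenames carry `_synthetic`, the mask and serology
files carry version strings `synthetic-*-1.0`) built to encode documented
allele-level facts rather than real sequences:

* an 87-position DQB1-like alignment of 11 alleles in which the
  DQ4/DQ5/DQ6-group beta chains (including DQB1\*06:02 and DQB1\*06:03)
  carry arginine at position 55 while the DQ2/DQ7/DQ8/DQ9 alleles do not;
* the DQ7 / DQ8 / DQ4 worked-example triad (DQB1\*03:01 recipient,
  \*03:02 kidney, \*04:02 MSC — the DQ4 assignment used is \*04:02) has
  zero repeated split mismatches and exactly three repeated amino-acid
  mismatches (26L, 37Y, 74A);
* toy 12-position class I, DRB and DQA1 loci (6 alleles each; one allele
  carries an unresolved residue at a masked position to exercise the
  unknown-handling rules);
* a serology table covering every packaged allele and an accessibility
  mask per locus.

Results computed against this bundle demonstrate the machinery, not real
immunogenetics; production analyses must point the loaders at real
alignment, mask and serology files (the mask file's version string is
propagated into every output header precisely so that results are
reproducible per mask).

## Synthetic-cohort generator

`simulate_triads` samples recipient and kidney-donor typings independently
per locus (two draws with replacement — homozygosity arises naturally; no
linkage between loci, a deliberate non-goal). Each patient receives a pool
of candidate MSC donors (default 10). Under the `avoid-repeated-split`
policy, candidates sharing any split-antigen mismatch with the kidney
donor's mismatch set at A, B, DR or DQ are rejected; if none qualifies, the
least-violating candidate is accepted and the patient is flagged —
mirroring the accepted DQ repeat that real selection protocols sometimes
cannot avoid. Ground-truth reports are computed by a deliberately naive
brute-force oracle (`oracle.py`, explicit double loops sharing no code with
the engine), so generator/engine agreement is a meaningful test.

`simulate_sab` builds one bead per pool allele (DQB1 beads paired with a
fixed DQA1 alpha chain). BCM values are log-normal: background median 100,
implanted-antibody median 5,000 (an order of magnitude above the 1,000
cutoff, matching the magnitudes such assays report for clear positives),
sigma 0.35 in log space. At these defaults the positive/negative separation
is effectively never crossed, which is what makes the 100%
implant-recovery property testable; raising sigma toward the threshold
separation degrades recovery gracefully (observable, not asserted). The
implant scenario requires the target residue to be a true mismatch (absent
from the recipient) and raises every carrying bead; the self-background
scenario raises one recipient-allele bead to a median of 2,000. All
randomness flows from explicit integer seeds; equal seeds give
byte-identical outputs.

What passing the synthetic tests shows — and what it does not: the engine
implements the stated definitions exactly (oracle equivalence over 1,000
seeded triads), the selection policy and assay logic behave as specified,
and the statistics reproduce the published cohort numbers from the packaged
per-patient counts. It does not validate against real IMGT-derived
alignments, real allele/haplotype frequencies, linkage disequilibrium, or
the immunogenicity question of which mismatches actually elicit antibodies.

## Problem sizes

The default test suite runs ~1,000 oracle-checked triads, 200 paired
policy cohorts, 100+ implant panels and full exact Mann–Whitney
enumerations at n=18; it completes in well under a minute on one CPU, as
does `scripts/acceptance.py`. These sizes were chosen as the smallest at
which the property tests are meaningful (the spec-scale laws quote 1,000
triads and ≥100 panels); everything scales linearly if larger runs are
wanted.

## Known limitations

* The two excluded patients of the unselected cohort (no high-resolution
  typing) illustrate a hard boundary the package enforces rather than works
  around: no imputation of second-field typing from serologic data is
  offered, because it is a documented source of DSA misclassification.
* Published per-patient mismatch counts are carried as data
  (`studies.py`); they cannot be recomputed because the underlying typings
  were never published.
* HLA-DP is typed in such studies but not analyzed; eplet-registry
  annotation, T-cell epitope scores (PIRCHE-style) and MFI normalization
  across assay vendors are out of scope.
* The cohort-wide sum of repeated split antigens in the unselected cohort
  is reported per locus and left for the user to aggregate; published
  aggregate phrasings of that number are ambiguous, so the package does not
  hard-code one.
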