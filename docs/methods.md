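# Methods

## The estimand

For a proteome, the disulfide abundance parameter *f* is the fraction of
structure-mapped cysteines lying within a Cα–Cα cutoff (default 8 Å,
strict `<`) of at least one other mapped cysteine of the same chain,
pooled over the proteome: *f* = Σ hits / Σ mapped.  The pooling is a ratio
of totals, not a mean of per-protein fractions, which makes it invariant
to how proteins are batched and robust to proteins with one or two mapped
cysteines.  A cysteine with several partners below the cutoff is one hit
(count-once rule).  The method underestimates true disulfide content:
alignment errors and genuine structural divergence can separate a bonded
pair past the cutoff, but cannot conjure proximity for unbonded cysteines
kept far apart; the estimator's bias is therefore one-sided (downward).

The structure-database control *f*′ asks the same question of deposited
structures directly: cysteines present in SSBOND records over cysteines
observed in ATOM records, with LINK-record cysteines removed from the
denominator (they coordinate metals or other ligands) and entries binding
Zn or Fe excluded wholesale.  Both counts use residues observed in ATOM
records, not SEQRES, so numerator and denominator share provenance.
Other metals (Cu, Ni, …) are not excluded by default but the element set
is configurable.  Optional redundancy removal clusters chains at 95 %
sequence identity, keeping the first-seen representative.

## Pipeline stages and parameters

1. **Filters** (in this order):
   - *minimum cysteines*: proteins with fewer than 2 raw cysteines are
     removed — they cannot hold an intramolecular disulfide;
   - *secretion*: secreted/periplasmic proteins are removed because
     extracytosolic compartments are oxidizing and disulfide-rich
     regardless of organism.  Modes: a built-in three-condition heuristic
     (below), an external exclusion list, or off;
   - *spacing mask*: any cysteine within 5 residues of another loses
     mapping eligibility (both members of a close pair are removed).  This
     sidelines CXXC-type metal motifs whose cysteines would otherwise
     masquerade as disulfide partners.  The mask affects eligibility only;
     the protein itself stays, and a protein whose eligible set drops
     below 2 simply contributes 0 mapped cysteines.  "Within 5" is read as
     separation ≤ 5; the threshold is configurable.
   The parity analysis runs after the secretion filter and before the
   spacing mask — it counts whole-protein cysteine totals, including
   proteins with 0 or 1 cysteines (which enter the table but not the bias
   statistic).  Ambiguous residues (X/B/Z) and selenocysteine (U) are not
   counted as cysteine.

2. **Homolog search.**  Default internal mode scores each library sequence
   with Smith–Waterman (BLOSUM62; a gap of length *k* costs 11 + *k*) and
   converts scores to E-values with the Karlin–Altschul form
   E = K·m·n·exp(−λS), λ = 0.267, K = 0.041 (gapped BLOSUM62 convention).
   This is a stand-in for BLAST: it reproduces accept/reject behaviour at
   the E < 10⁻⁴ gate, not BLAST's exact E-values.  Precomputed hits in
   12-column blast-tabular form are accepted instead.  Hits sort by
   ascending E-value, ties by descending score then lexicographic id; one
   structure — the best hit — is used per protein.

3. **Realignment.**  The mapped positions are recomputed with an
   affine-gap Gotoh dynamic program under BLOSUM62 (open 11, extend 1).
   End gaps are free by default (semi-global) because structures are
   frequently fragments of the query; a strict global mode exists.
   Traceback is deterministic: diagonal, then query-consuming, then
   target-consuming moves; within a gap, closing it is preferred over
   extending on ties.  When every alignment scores negative, the
   free-end-gap optimum is the empty alignment with score 0 and no aligned
   columns (identity defined as 0).  Scores are small integers summed as
   floats, so exact equality comparisons in the traceback are safe.

4. **Placement and proximity.**  An eligible cysteine maps when its query
   position sits in a match column whose structure residue has a Cα; the
   structure residue need *not* be cysteine (the query is overlaid onto
   the fold).  Distances are intra-chain only; intermolecular disulfides
   are deliberately out of the measurement and are instead surfaced by the
   odd-cysteine annotation: a mapped non-hit cysteine is labelled
   *metal-proximal* (Cα within 8 Å of a HET metal atom), else
   *surface-candidate* (fewer than 12 other Cα within 10 Å), else
   *buried-unpaired*.  The neighbour-count thresholds are coarse
   Cα-density proxies for solvent exposure, chosen to separate chain
   termini/loops from cores in the CA-only models; both are parameters.

5. **Reporting.**  Tiers at *f* > 0.15 (significant), > 0.25 (high),
   > 0.35 (very high), strict inequalities.  Strain deduplication removes,
   within a species, later entries whose mapped-protein count is within
   ±10 % of the first-listed (parent) entry.  The parity bias
   b = (even≥2 − odd≥3)/(even≥2 + odd≥3) with a two-sided exact binomial
   p-value at null 0.5 is this package's scalar extension of the visual
   sawtooth analysis and is labelled "extension" in report output.

## The synthetic generator

The generator emulates the survey's inputs with known truth; it is the
basis of every end-to-end test.

- **Structures** are CA-only chains: 3.8 Å virtual-bond random walks with
  soft self-avoidance (non-adjacent Cα ≥ 3.5 Å, steps resampled up to a
  bounded retry budget).  Paired cysteines are steered together — the walk
  tracks a shrinking target radius while approaching a pair's second
  member, and the final step is sampled exactly on the two-sphere
  intersection circle — landing the pair's Cα separation inside
  [4.0, 6.5] Å, comfortably under the 8 Å criterion.  Free cysteines must
  end ≥ 10 Å from every other cysteine Cα (and ≥ 9 Å from planted metals),
  comfortably outside it; chains violating a constraint are regenerated,
  and an explicit geometry error advises a longer chain when the budget is
  exhausted.  SSBOND records are written for pairs; CXXC motifs get a Zn
  HETATM plus LINK records.  No side chains are modelled: the criterion is
  Cα–Cα, so SG atoms are unnecessary.

- **Proteins** derive from their structure's sequence with substitutions
  at a controlled divergence.  Planted cysteines are never substituted and
  substitutions never introduce new cysteines; body residues are drawn
  from a cysteine-free background composition (Robinson–Robinson
  frequencies, C removed and renormalized) so the planted cysteines are
  the only ones and the truth accounting is exact.  A deterministic
  round(true_f·n) of the proteins carry one disulfide pair; the rest carry
  two spatially separated free cysteines; optional fractions add a
  prepended signal peptide (default 0.20), a CXXC+Zn motif (0.10), or one
  extra unpaired cysteine (0.10).  The realized pooled fraction is
  recorded in the truth object over all proteins' eligible cysteines and
  is the authoritative value; requesting true_f = 1 together with odd
  extras is rejected as infeasible.

- **Signal peptides** are built to satisfy the detector's three
  conditions (K/R in the first 7 residues; a 10-residue window in residues
  2–25 with ≥ 8 hydrophobics; a cleavage site in residues 15–40 with −3/−1
  small residues) and contain no cysteine.  The detector is a documented
  stand-in for trained position-weight-matrix predictors: on the
  generator's conditions it shows recall ≈ 1 on planted peptides and a
  ~1–2 % false-positive rate on background decoys.  On real proteomes its
  error rates are unknown; exact reproduction of an external predictor's
  calls goes through the exclusion-list mode.

- **Parity proteomes** are sequence-only.  The independent mode plants
  cysteines per residue with probability 0.035.  Note the bias statistic
  is only asymptotically centred at 0 under independence: because even≥2
  starts one count earlier than odd≥3, small mean cysteine counts give a
  positive offset (≈ +0.2 at mean 2.3).  The default rate puts ≈ 6
  cysteines on a 150–200 aa protein, where the offset is ≈ +0.01 and
  150-protein replicates keep E|bias| ≈ 0.07.

What the generator does **not** emulate: realistic folds and packing
densities, insertions/deletions between query and structure (divergence is
substitution-only), compositional bias, paralogy (each protein has exactly
one true structure), multi-chain entries, and cysteine loss in the
structure.  Passing tests therefore demonstrate the correctness of the
pipeline's bookkeeping and geometry under controlled homology, not
field accuracy on diverged real proteomes, where alignment error makes *f*
an underestimate.

## Problem sizes and validation

The test suite and `scripts/acceptance.py` validate, at sizes chosen to
keep a full run around a minute: alignment scores against exhaustive
enumeration of all alignments (200 random pairs, lengths ≤ 7, plus an
independent cross-check against Biopython's aligner); the count-once
proximity rule against O(n²) scans (500 point sets, ≤ 12 points);
parameter recovery on 200-protein bundles at planted fractions
0.0/0.3/0.6/0.9 and 10 % divergence (observed |error| ≤ 0.06, always
downward) with exact recovery of 0.0 and 1.0 at zero divergence;
*f*′ exactness on 20 planted structure entries; parity bias = 1 on fully
paired proteomes and mean |bias| < 0.1 over 200 independent-cysteine
replicates; and the filter/dedup rules against brute force.  The f vs f′
Pearson correlation across bundles is ≈ 1 by construction (both track the
planted fraction); on real data it is a consistency check, not a
validation.

## Known limitations

- One structure per protein: multiple-hit consensus is not attempted.
- Intra-chain proximity only; intermolecular disulfides are annotated as
  surface candidates rather than measured.
- The internal E-value is calibrated for the gate, not for BLAST parity;
  use tabular hits for exact reproduction of a BLAST-based survey.
- The secretion heuristic is coarse; organism-specific predictors should
  be supplied via the exclusion list when available.
- PDB parsing is ATOM-record based (first altloc, first model); mmCIF is
  out of scope.
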