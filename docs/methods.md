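# Methods

## Scope and model

`hydromine` re-implements, as a tested library, the desk-side half of a
metagenomic PET-hydrolase discovery study: homolog retrieval against a
reference enzyme, catalytic-triad filtering, sequence-similarity-network
(SSN) candidate selection, class I/II typing, catalytic-loop and
physicochemical profiling, distance-based phylogeny, and the enzyme-assay
quantification math. Wet-lab quantities (fold-improvements in PET
degradation, melting temperatures) and database-snapshot-dependent hit
counts are outside what a reusable library can reproduce; the package
instead demonstrates each computation on labeled synthetic data whose
ground truth is known by construction, plus the packaged IsPETase
reference sequence (UniProt A0A0K8P6T7, verified against six published
positional anchors: W159, the G-x-S-x-G motif with S160, D206, H237, the
S238 gatekeeper, and cysteines 203/239 and 273/289).

## Alignment and similarity

Pairwise alignment is affine-gap dynamic programming (Needleman–Wunsch /
Smith–Waterman via Biopython's `PairwiseAligner`) under BLOSUM62 with the
EMBOSS-needle gap convention: a gap of length *L* costs
`gap_open + gap_extend·L`, default 10 + 0.5·L. Two conventions are
reported on every alignment so either can be compared with external
tools: **identity** = identical columns / all alignment columns (gaps in
the denominator), **similarity** = columns whose residue pair has a
strictly positive substitution score / all columns. `X` scores 0 against
everything; ambiguity codes (B/Z/U) are rejected at parse time. Optimal
alignments are not always unique; the aligner's first traceback is
deterministic, which is the contract downstream code relies on. Anchor
translation (triad mapping, loop analysis) uses that single optimal
global alignment. Multiple alignment is replaced by a star alignment
onto a designated center: every row is an independent optimal pairwise
alignment, which keeps column maps and insertion blocks exactly testable
at the cost of not modelling residue correlations between non-center
sequences — sufficient for anchor mapping and loop-insertion detection,
not for profile building from distant homologs.

## Homolog search

The profile-HMM search of a production pipeline is deliberately replaced
by two simpler, fully specified scorers: (1) a log-odds PSSM with
column score `log2(((count_r + pc·bg_r)/(n_eff + pc))/bg_r)` (pseudocount
`pc`, background `bg`, columns with >50% gaps dropped, unseen-residue
scores floored at −20), scanned gap-free and normalized by the profile's
maximum attainable score; (2) local alignment normalized by the query
self-score, so the query scores exactly 1.0. The default acceptance
threshold of 0.25 was chosen for the synthetic benchmark (planted
homologs at ≥40% identity vs composition-preserving shuffled decoys) and
gives recall = precision = 1.0 there; it is a configuration value, not a
statistical cutoff, and no E-value machinery is provided.

## Triad filtering

A `TriadSpec` holds 1-based anchor positions on the full-length
reference (signal peptide included, matching how S160/D206/H237 are
quoted for IsPETase). The acid position accepts Asp or Glu by default,
since serine-hydrolase triads are Ser/His/Asp-Glu; a strict-Asp mode is
available. A candidate passes iff all three anchors map through the
global alignment onto non-gap residues in their allowed sets. Verdicts
are per-candidate and independent of the rest of the input.

## Networks and trees

SSN edges keep unordered pairs whose metric clears a threshold; metrics
are global score per alignment column (default for networks), identity,
or similarity. Clusters are connected components labeled by their
lexicographically smallest member, which makes labels invariant to input
order. Candidate selection returns non-reference members of any
reference-containing component. Component counts are monotone
non-decreasing in the threshold.

Trees use canonical neighbor joining (scikit-bio) on p-distances
(fraction of differing positions over mutually ungapped columns;
optional Poisson correction −ln(1−p)). NJ is exact on additive matrices;
negative branch-length estimates on non-additive input are clamped to
zero and flagged. A maximum-likelihood tree is out of scope for this
package; NJ with bootstrap is the documented approximation. Bootstrap
resamples alignment columns with replacement using a single
`numpy.random.Generator` seeded by the caller, with sequences processed
in sorted-id order — the package's reproducibility contract — and
reports, for each internal bipartition of the full-alignment tree, the
percentage of replicate trees containing it. An all-identical alignment
yields a flagged star tree whose trivial bipartitions are reported as
fully supported.

## Class I/II typing

Class II PET hydrolases (IsPETase, PE-H) carry an extra disulfide bond
and extra residues after the gatekeeper serine in the catalytic
histidine loop; class I enzymes (TfH, LCC) lack both. The decision rule
is boolean: class II iff both aligned disulfide positions are Cys AND
the loop carries at least one residue beyond the canonical class-I
length. Because the default alignment reference (IsPETase) is itself
class II, the extra-residue count is measured relative to class I:
`extra = max(0, reference_extra_residues + insertions − deletions)`
within a window (default 10 reference columns) after the gatekeeper,
where `reference_extra_residues` (default 3) is how many extras the
reference itself carries. With a class-I reference, set it to 0. This
keeps the rule consistent whichever side of the divide the reference
sits on. Defaults — gatekeeper 238, His 237, disulfide pair (203, 239) —
are IsPETase full-length numbering and are configurable for other
references.

## Charge model and pI

Net charge is the per-group Henderson–Hasselbalch sum over K/R/H side
chains and the N-terminus (basic) and D/E/C/Y side chains and the
C-terminus (acidic). The default pKa table is the single-value
Bjellqvist-style set used by common "theoretical pI" calculators
(N-term 7.5, C-term 3.55, K 10.0, R 12.0, H 5.98, D 4.05, E 4.45,
C 9.0, Y 10.0); the EMBOSS table is selectable. The model ignores
position-specific terminal corrections, folded-state pKa shifts, and
disulfide-engaged cysteines — on IsPETase it agrees with Biopython's
full Bjellqvist implementation to 0.01 pH units, but both are
sequence-only predictions. The charge is strictly decreasing in pH and
changes sign on [0, 14] (the termini guarantee it), so the pI is the
unique root, found by bisection to 1e-3 pH by default and reported to
two decimals.

## Assay quantification

Calibration is ordinary least squares of signal on concentration;
quantities are reported in µM, rates in µM·min⁻¹ or A260·min⁻¹, enzyme
in nM, NaCl in M, temperature in °C. Initial rates are the OLS slope
over the first 25% of time points by default (the window is
configurable; outliers are never removed — the reported r² lets the
caller judge). The combined A260 rate is split into product rates with
the constant endpoint-ratio assumption: `mhet = A260/(ε_T·r + ε_M)`,
`tpa = r·mhet`, which conserves signal exactly by construction
(`ε_T·tpa + ε_M·mhet ≡ A260`). Negative quantified concentrations are
floored at zero and flagged rather than erased. Condition optima use a
deterministic tie-break (lowest temperature, then NaCl, then pH).

## Synthetic data: what it does and does not show

The sequence generator plants real serine-hydrolase architecture — a
G-x-S-x-G nucleophile motif at ~55% of the length, catalytic Asp and His
downstream, a gatekeeper Ser after the His, a class-II cysteine pair —
into otherwise uniform-random sequences, then derives family members by
uniform substitutions (no rate matrix, no indels) to a target identity
±0.02, with optional triad knockouts; decoys are composition-preserving
shuffles, so score separation tests that the search is not driven by
composition. Default benchmark shape: 3 families × 5 members at 0.6–0.9
identity, 10 decoys; the search benchmark uses 1 × 20 members at 0.4–0.9
identity with 80 decoys, putting planted homologs at the 40% identity
floor. The assay model generates linear-then-saturating product curves
(defaults 0.8 µM/min TPA, 0.5 µM/min MHET, 30 min linear phase, molar
responses 0.017 and 0.012 A260/µM, 500 nM enzyme in 4 M NaCl at pH 8,
55 °C, reads every 2 min for 60 min) with i.i.d. Gaussian read noise.
Passing tests on these benchmarks shows the algorithms invert their own
forward models exactly and separate planted structure from noise; it
does not show robustness to real mutational processes (indels, rate
heterogeneity, compositional bias) or to structured assay artifacts
(drift, path-length effects, HPLC integration error). Every generator is
a pure function of (config, seed), and tests assert byte-identical
reruns.

## Problem sizes

Test and demo sizes (sequences of length ~180, pools of ≤100, bootstrap
≤1000 replicates on toy alignments, 50 assay replicates) were chosen so
the whole suite and the acceptance script each run in well under a
minute while still exercising every code path at non-trivial scale.

## Known limitations

- Checks against the published MG1–MG10 enzyme values (pI 9.23/6.41,
  the MG8 RYD loop at 260–262, Ser 171, 68% similarity of MG3 to
  IsPETase) require those sequences, which the package cannot
  redistribute; the corresponding tests fail with instructions until a
  user supplies `tests/data/sd1_mg_enzymes.fasta`.
- The star alignment is not a substitute for progressive MSA at low
  identity; anchor mapping below ~40% identity should be treated with
  caution.
- The homolog search reports normalized scores, not E-values; thresholds
  must be calibrated per database.
- Database hit counts from any particular metagenome snapshot are not
  reproducible by design and are not targets of this package.
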