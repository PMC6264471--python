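# Methods

This note documents the models and procedures implemented in
`milkpeptidome`, the parameters that matter, and the choices made where
the design was genuinely open.

## Coordinate system and references

All peptide and cleavage-site coordinates are 1-based inclusive on
**mature** protein sequences — the chain left after removal of the
secretory signal peptide — because milk peptidomics conventionally
numbers residues that way.  FASTA headers annotate the signal length
(`signal=N`) and whether the stored sequence is the precursor or mature
chain; precursors are converted at load.

The packaged reference covers the major casein and whey substrates of
milk digestion: bovine β-casein, α<sub>s1</sub>-, α<sub>s2</sub>- and
κ-casein, β-lactoglobulin and α-lactalbumin, plus human β-casein,
α<sub>s1</sub>-casein and κ-casein.  Lower-abundance proteins
(osteopontin, lactoferrin, immunoglobulin components, …) are not
bundled; any FASTA in the same header dialect extends the reference.
The reference is deliberately data, not code: the loaders validate the
20-letter alphabet, uniqueness of accessions, and round-trip exactly.

## Species assignment

Assignment is literal exact substring search against the dual human +
bovine proteome: `human` / `bovine` if the peptide occurs in proteins of
exactly one species, `both` if in at least one protein of each,
`unassigned` otherwise.  The four labels partition any peptide set.
Isoleucine and leucine are **not** collapsed even though they are
isobaric in MS, because identification tables distinguish them and
literal matching is reproducible; an I/L-collapsed mode exists behind a
flag for sensitivity analysis.  Sequences matching several proteins
within one species keep all loci; per-protein rollups attribute such
peptides fractionally (1/n per parent) by default, with an
exact-attribution mode, since whole-count attribution would double-count
shared tryptic-like fragments.

## Per-residue digestion maps

The intensity map of a protein puts, at residue *i*, the sum over
peptides covering *i* of the peptide's sample-type-summed ion intensity,
so the map total equals Σ intensity × peptide length (an invariant the
tests verify against a brute-force accumulator).  For gastric maps the
feed signal is removed **per peptide before mapping**: each peptide's
milk + fortifier intensity is subtracted from its gastric intensity and
floored at zero.  The floor is a modeling choice — negative digestion
signal is meaningless — and guarantees the subtracted map is pointwise
dominated by the raw gastric map.

Hydrophobicity profiles use the Tanford transfer-free-energy scale with
a 7-residue window and linear weight decay to 25% at the window edges
(weights 0.25, 0.5, 0.75, 1, 0.75, 0.5, 0.25, renormalized where the
window is truncated at the chain ends).  Profiles of a sequence and its
reverse are mirror images because the weights are symmetric.

Ortholog overlays come from an optimal global alignment (BLOSUM62, gap
open −11, extend −1, via Biopython's pairwise aligner); the first
optimal alignment of the dynamic program is taken, which fixes
tie-breaking deterministically.  Maps are emitted unnormalized;
normalization conventions differ between studies, so scaling is left to
the consumer.

## Cleavage sites and P1/P1′ statistics

A peptide spanning *a..b* of its parent evidences hydrolysis of the
bonds (*a−1, a*) and (*b, b+1*); a terminus coinciding with the mature
protein's own terminus is not a cleavage site.  Sites are merged per
(protein, bond) with the number of supporting peptide termini retained,
so: count-weighted P1/P1′ distributions tally **termini** (matching
per-peptide tabulations), intensity weighting assigns each terminus its
peptide's full sample-type-summed intensity (not halved — each terminus
is independent evidence of its bond), and protease attribution operates
on **distinct bonds**.  The exact accounting (2 × peptides − terminal
coincidences = Σ support counts) is verified on random fixtures.

The P4..P4′ context is padded with `-` where the window runs off a
protein end; padded positions count as mismatches during attribution
because truncated contexts carry less evidence.

## Protease attribution

Specificity matrices give, per subsite, allowed residues, hard
restrictions (which veto a match regardless of the mismatch allowance),
and optionally experimentally observed cleavage octamers (which match at
zero mismatches by definition).  A context matches a protease when at
most `max_mismatches` (default 3) subsites fall outside the allowed
sets and no restriction is violated.

Each site gets exactly one category: the fewest-mismatch candidate.
When the minimal set is exactly {cathepsin D, pepsin} the joint
`CTSD/PGA3` category is reported — the two acid proteases' specificities
overlap too strongly to separate.  Remaining ties are resolved by
observed-over-predicted, then a fixed priority (PLG > PGA3 > CTSD >
ELANE > F2 > KLK6 > KLK11) chosen to favor the compartment-dominant
enzymes; any fixed order would do, determinism is the point.  Milk
attributions exclude cathepsin D and pepsin by default since both
require gastric acidity for activity (configurable).

The packaged matrices are approximations assembled from published
subsite preferences: plasmin and kallikrein 11 tryptic-like (P1 ∈
{K,R}), kallikrein 6 additionally chymotryptic at Tyr, thrombin P1 = R
with a P2 Gly/Pro preference, elastase P1 ∈ {A,V,S,G,T,I}, pepsin P1 ∈
{F,L,Y,W,M,E} and cathepsin D P1 ∈ {F,L,W,Y,M}, both with hydrophobic
P1′ preference and a hard no-proline-P1′ restriction.  Pepsin's P1′ set
is restricted to hydrophobic/aromatic residues; without that restriction
the glutamate-rich caseins yield implausibly Glu-dominated digests.
Exact MEROPS exports can be substituted — matrices are a TSV, one row
per protease, `*` for wildcard, `!X` for restrictions.

## The digestion simulator

The simulator emulates the study structure the pipeline targets: five
milk samples (human proteins, milk proteases), one bovine fortifier
sample, five gastric samples (both proteomes, acid proteases, plus
surviving feed peptides).  Per sample type, every bond whose full
context matches a protease matrix at zero mismatches is cut
independently with probability `cleavage_probability × activity`, and
single-pass fragments of ≥ 7 residues (the identification floor of
peptidomic database search) form the pool.  Each biological sample then
observes each pool peptide with probability 1 − `missingness`, drawing a
base-10 log-normal intensity (μ = 6, σ = 0.8 — peak areas around 10⁶
with an order-of-magnitude spread, a typical LC-MS dynamic range).

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `cleavage_probability` | 0.6 | partial digestion: most eligible bonds cut somewhere, intact stretches remain |
| `protease_activity` | acid proteases and plasmin 1.0; elastase 0.2; thrombin/kallikreins 0.2–0.3 | lets tryptic-like (K/R) cuts dominate milk and Leu/Phe/Glu cuts dominate gastric pools despite elastase's much broader eligible-bond set |
| `min_peptide_length` | 7 | database search does not identify shorter peptides |
| `missingness` | 0.2 | produces the observed mix of fully conserved and sporadic peptides across five samples |
| `carryover_survival` | 0.3 | feed peptides that persist in the stomach keep a fraction of their feed intensity |
| `carryover_retention` | 0.1 | probability a feed peptide escapes further gastric degradation at all; yields a milk-to-gastric overlap of roughly a fifth to a quarter of gastric human peptides |

Digestion is single-pass (fragments are not re-digested) — sufficient
for testing attribution, though real gastric digestion is progressive.
Bonds with end-truncated contexts are never cut, symmetric with the
attribution rule that padding mismatches.  Fixing the seed fixes the
output byte for byte; all per-stage seeds derive from one seed sequence.

What the simulator does **not** emulate: spectra, retention times,
charge states, identification error, exopeptidase trimming ladders, and
protein-abundance differences between substrates (every protein is
digested as if equally abundant).  Passing tests therefore demonstrate
correctness of the downstream accounting and the recoverability of
generating proteases under the stated model — not performance on real
peptidomes, where unmodeled proteases and exopeptidases leave most
sites unassigned.

A second generator, `study_scale_table`, emits a synthetic stand-in
peptide table whose *marginal* structure matches the published study
(5,264 peptides; 1,722 bovine / 3,399 human / 138 indistinguishable;
538 fortifier peptides; per-sample means 719.6 milk and 1,720.8
gastric; 185 and 310 fully conserved peptides).  Its sequences are
random; it exercises ingestion and count summaries at scale.  The
printed species splits sum to 5,259 against the printed 5,264 total, so
five peptides are left species-unassigned to satisfy both figures.

## Bioactive homology search

Similarity is identity-scored global alignment: match 1, mismatch and
gap 0, with gap placement among co-optimal alignments fixed by an
infinitesimal penalty.  The maximal identity count under this scoring
is the longest-common-subsequence length, computed exactly by dynamic
programming, and

    percent_similarity = 100 × identities / max(len(query), len(reference)).

The denominator is the longer sequence — the key underspecified choice
in web database searches — so a short query cannot trivially score 100%
against a long reference, and 100% with equal lengths means identity.
End gaps are therefore effectively penalized; a free-end-gap variant was
considered and rejected as the default because bioactivity generally
requires the full motif.  Matches at or above the threshold (default
80%) carry their exact percentage and the reference entry's full
function list (one match per entry, never duplicated per function).
Results are monotone in the threshold.  The search imposes no length
floor; length filtering belongs to identification, not annotation.

The packaged reference of 58 literature bioactive milk peptides (ACE-
inhibitory, antimicrobial, antioxidant, DPP-IV-inhibitory, opioid,
immunomodulatory, …) is a fixture for testing and a seed users should
extend from a current bioactive-peptide database export.

## Conservation and per-protein summaries

The conservation level of a peptide is the number of samples (of one
type) it was identified in.  The headline "percent fully conserved"
figure divides the level-*n* count by the **mean per-sample** peptide
count (total identifications / number of samples); the alternative
union-count denominator is reported alongside, since either reading is
defensible and the two differ substantially.

Inferential statistics (mixed models, post-hoc multiple-comparison
procedures) are intentionally out of scope; the package emits
descriptive tables suitable for any downstream statistical environment.

## Numerical and reproducibility notes

* All randomness flows from explicit integer seeds through NumPy
  generators; pipeline reruns with one seed are byte-identical
  (checksummed manifests verify this).
* Distribution tables are exact rational ratios scaled to percent;
  tests compare at `pytest.approx` double precision.
* Degenerate inputs are values, not crashes, wherever a value makes
  sense: an unmapped protein yields an all-zero profile, an absent
  peptide an empty locus list, an empty conservation pool a zero
  summary.  Empty inputs where a distribution is demanded (P1
  frequencies of zero sites) raise.
* Problem sizes in the test suite — a nine-protein reference, five
  stochastic digestion replicates (≥ 400 attributed sites) for
  parameter recovery, 100-fixture oracle sweeps — were chosen so the
  whole suite runs in seconds while every acceptance property is
  exercised well above its required sample size.
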