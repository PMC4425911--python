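# Methods

## The study system

The package targets a concrete discovery problem: multi-copy endogenous
retroviruses of the HERV-K (HML-2) family integrated inside centromeric
repeat arrays, which are missing from the reference assembly. Two lineages
organize the design. A full-length lineage (K111-like) has the canonical
LTR–gag–pro–pol–env–LTR structure, a 6-bp target-site duplication (GAATTC)
on both sides, and sits in CER:D22Z3 repeats. An older, 5′-truncated
lineage (K222-like) lacks the 5′LTR and gag, has lost the last 9 bp of its
3′LTR (ACCCCTTCA), carries no recognizable target-site duplication, and is
flanked by a related repeat family (pCER:D22Z8) about 71.8% identical to
CER:D22Z3; its 5′ flank joins the provirus through a fixed 13-bp junction
motif, ACATATACCCAGT. Because neither lineage is in the reference, every
stage works either on sequences obtained directly (PCR products, templates)
or on reads screened by local sequence content rather than by mapping.

## Synthetic genomes (synthgen)

The generator emits the structures above with full ground truth.

* **Repeat families.** A monomer is the tandem concatenation of eight 48-bp
  segment variants (384 bp). Segment variants diverge from a canonical
  segment at 8% per site — enough intra-monomer variation to make the
  periodicity non-trivial while keeping segments recognizably homologous.
  The sister family is derived by independent per-site substitution at
  probability 1 − 0.718, matching the documented inter-family identity;
  the realized identity of each draw is recorded in metadata.
* **Primer planting.** Assay primer footprints from the shipped panel are
  written into the repeat monomers and provirus features at fixed
  coordinates, chosen so the documented diagnostic product sizes are
  reproduced exactly by in-silico PCR: flank primer → pro-gene reverse
  primer products of 171 bp and 464 bp on the truncated template, and a
  422-bp flank → 5′LTR product on the full-length template. Feature sizes
  follow the canonical ~9.7-kb provirus layout (LTRs 968 bp, gag 2.1 kb,
  pro 1 kb, pol 2.7 kb, env 2 kb) so position-named primers land in the
  right genes.
* **Placement.** Default placement spans chromosomes {1, 7, 12, 13, 14, 15,
  18, 21, 22}: one truncated copy on 1/18/21/22 and several on 7/12/13/14/15
  (19 in total), plus one full-length copy per chromosome. Copies sit in
  CER spacer arrays with two flank monomers (768 bp) per side, so ≥20 bp of
  flank context always exists for the junction screen. Each truncated copy
  receives 0–3 private substitutions, uniform over the 20 flank + 20
  provirus bases adjacent to the junction (the junction motif itself is
  kept intact). Confining them to this window makes every private
  substitution visible to a junction-spanning read — the in-silico analogue
  of the chromosome-specific variants that let real copies be told apart.
* **Reads.** Uniform start positions, random strand,
  round(depth·L/read_length) reads per chromosome, substitution-only errors
  (uniform over the three alternatives). No indels: the screen is
  mismatch-based, and indel errors would only change recall through an
  error process the screen does not model.
* **qPCR.** Ct = intercept + slope·log₁₀(copies) + N(0, σ²), slope default
  −1/log₁₀2 ≈ −3.3219 (100% efficiency), intercept 40 (Ct of a single
  copy), σ default 0. Zero or negative copy input is a parameter error; "no
  amplification" is represented by an absent row, not a fabricated Ct.

What the generator does **not** emulate: higher-order alpha-satellite
structure, indel mutation, diploidy/heterozygosity, library-preparation
bias, or quality-score error profiles. Passing tests therefore demonstrate
the correctness of the procedures under clean substitution-only conditions,
not their robustness to real sequencing artifacts.

## Junction screen (junctions)

A read is junction evidence if either orientation contains, contiguously:
the last `min_flank` (20) bases of the flank, the full junction motif, and
the first `min_provirus` (20) bases of the provirus, with at most
`max_mismatch` (1) substitutions **in total** across the three segments.
The single tolerance is interpreted as a whole-read budget because one
tolerance attaches to the whole three-part criterion; a per-segment budget
is available as an option by constructing models accordingly. The 13-bp
junction motif must match within the same budget — it is the diagnostic
recombination-spot sequence, so it gets no free mismatches.

Matching slides the 53-bp diagnostic window over the read. With a budget of
at most 1, any admissible placement leaves one half of the junction motif
exact, so candidate placements are seeded by exact search for the two
junction halves (lossless by pigeonhole) and only candidates pay the
mismatch count; larger budgets fall back to scanning all offsets.

Reference exclusion drops any hit whose read is contained end-to-end in a
user-supplied decoy FASTA (either orientation, ≤k substitutions). A decoy
set replaces whole-genome alignment: the contract — "the read also matches
reference sequence" — is preserved at desk scale.

Clustering assigns each read to its fewest-mismatch model; ties across
models with different variant signatures (or different locus groups) are
ambiguous and excluded. A "unique hit location" is a distinct variant
signature by default — copies are distinguished by their private
substitutions, not by read start coordinates, which are meaningless without
a reference — with distinct junction offsets selectable as an alternative
definition. A locus group passes with ≥ `min_locations` (3) unique
locations in **every** sample (flag-selectable to "any").

## In-silico PCR (pcr)

Primer sites are found by Hamming scan of both template orientations
(default tolerance 1 mismatch per primer, no 3′-anchoring requirement —
the simplest defensible tolerance, exposed in config). Products are
enumerated for every convergent pair up to `max_product` (default 15,000,
the long-range-kit regime) and reported smallest-first, matching the
kinetic bias of PCR toward the shortest product. Degenerate bases are not
supported (the shipped panel contains none). Genotyping reduces amplicon
lists to presence/absence per expected size range.

## Recombination scan (recomb)

Per window (200 columns, step 10 — the window is the documented analysis
choice, the step a resolution/cost trade-off), the fraction of comparable
columns where the query equals each parent is computed; gap columns are
non-comparable and excluded from denominators, and windows with <50%
comparable columns are flagged. Breakpoints are called at boundaries of
best-parent runs when the winning margin exceeds `min_delta` (0.02,
below the ~1% divergence floor of near-identical recombinants — anything
smaller is noise) somewhere within the run on each side; the transition
windows themselves straddle the crossover and are near-ties by
construction, so the margin test applies to the runs, not the boundary
windows. Each call is then refined to the interval between the bracketing
informative columns (query matches exactly one parent), which for an exact
single-crossover chimera always contains the true column and is typically
a few informative-site spacings wide. Switch significance is a two-sided
Fisher exact test on informative sites tabulated left/right of the
breakpoint against the favored parent — a stand-in contract for the
unspecified internal test of the original scanning tool, at α = 0.05.
Equivalence with that tool is not claimed.

## Phylogenetics and dating (phylo)

* **K2P.** d = −½ ln[(1 − 2P − Q)√(1 − 2Q)] over comparable columns; gaps
  and N are dropped (N never counts as a match). Saturated pairs raise a
  distinct error rather than returning a clipped value.
* **NJ.** Classic Saitou–Nei agglomeration; ties on the Q criterion are
  broken by the lexicographically smallest pair of subtree labels, making
  the topology deterministic. Negative branch lengths are clamped to zero
  with a warning (standard practice). Additive matrices are recovered
  exactly (tested against path-sum reconstruction and an independent NJ
  implementation).
* **Bootstrap.** Site resampling with replacement, K2P + NJ per replicate,
  support = % of replicates containing each internal bipartition.
  Bayesian tree inference is deliberately out of scope; aligned FASTA can
  be exported for external tools.
* **LTR clock.** age = d/(2r) with d the K2P divergence of the two LTRs of
  one provirus (identical at integration). No default rate is supplied —
  the rate is a required input, since published analyses inherit it from
  earlier work rather than restating it. A missing LTR raises a distinct
  not-applicable error: the clock is undefined for 5′-truncated proviruses.
* **Dollo dating.** With one gain and any number of losses, the gain edge
  is the stem of the MRCA of carrier tips; the integration time lies
  between the MRCA age (lower) and its parent's age (upper). Losses are the
  minimal count of maximal all-absent subtrees inside the carrier clade
  (exact at these tree sizes). The bundled dated primate tree uses the
  divergence times 25 Myr (New World monkey split), 20 (Old World
  monkey–ape), 16 (orangutan), 10 (baboon vs macaque+AGM), 8 (gorilla),
  6 (human–chimpanzee), 5 (macaque–AGM). For the five-carrier pattern the
  interval is (20, 25) Myr with one loss; for the human+chimpanzee-only
  pattern it is (6, 8) Myr — the 6-Myr human–chimp split is the lower
  bound of that interval ("present in both ⇒ older than the split"), while
  the upper bound comes from the adjacent older divergence.

## Quantitation (quant)

Standard curves are least-squares fits of Ct on log₁₀(copies) (≥3 distinct
dilution points); efficiency 10^(−1/slope) − 1 is carried by the fitted
slope, with no forced 100%. Replicate Cts are averaged before conversion
(standard qPCR practice), copies = 10^((Ct − intercept)/slope), and targets
are divided by the single-copy normalizer TOP3A. The older lineage's copy
number is combined-assay copies minus specific-assay copies; a negative
difference is floored at zero and flagged rather than raised, since noise
can cross zero at low copy numbers. ChIP enrichment is 2^(ΔCt) versus IgG
(base 2 — the perfect-doubling ΔCt convention; no efficiency correction),
with a two-sample two-tailed t-test across replicates and significance
stars at 0.05/0.01/0.001.

## Problem sizes and numerics

The default test/demonstration conditions are: 9 chromosomes, 19 truncated
+ 9 full-length loci (~286 kb of genome), 30× coverage of 100-bp reads
(~86,000 reads) for the screen; 100 chimeras of 3-kb parents at 95%
identity plus 100 pure-parent controls for the scan; 16 simulated samples
spanning 8–61 and 207–968 copies per genome at 0.25-Ct noise for the
subtraction estimator; 968-bp LTRs over 500 replicates for clock recovery;
and 1,000 bootstrap replicates where support saturation is asserted
(the API default is 10,000). Alignment scoring is fixed at match +2,
mismatch −3, gap open −5, extend −2 (a gap of length L costs open +
extend·L); the identity denominator excludes gap columns by default, with
the count-gaps-as-mismatch policy available and both reported where the
distinction matters. Coordinates are 0-based half-open throughout; strand
is "+" unless stated.

## Known limitations

Single-crossover recombinants only (no multi-breakpoint history
reconstruction); pre-aligned input for the scan and tree stages (no
multiple-alignment inference); substitution-only error and mutation
models; no quality-aware read handling; no thermodynamic primer modeling;
Dollo dating reports losses but cannot distinguish loss from incomplete
lineage fixation — with carriers and non-carriers interleaved among close
relatives, both explanations fit the same pattern.
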