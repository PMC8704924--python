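# Methods

## Scope and model

`carotannot` automates the desk-side identification of carotenoids from
unit-resolution positive-mode LC–MS/MS supported by DAD absorption spectra.
It is a *rule-based* annotator, not a spectral-library matcher: on a ~1 Da
instrument the information content of an MS² spectrum is essentially (i)
the neutral-mass hypotheses implied by the ion species and (ii) which
canonical neutral losses explain the fragments. The pipeline encodes
exactly that, plus the two UV-vis descriptors that discriminate isomers
mass spectrometry cannot.

Assumptions baked into the defaults:

* **Nominal-mass arithmetic.** All default masses (proton 1.0; losses
  18/32/92/106) are nominal, matching how unit-resolution data are read in
  practice. A monoisotopic mode (proton 1.00728, exact loss masses) exists
  for high-resolution data but is untested against real spectra.
* **Ion species.** Only M•⁺, [M+H]⁺ and [2M+H]⁺ are modeled. Sodiated or
  ammoniated adducts are not, even though such buffers are common; the loss
  table and the species enumeration are the extension points.
* **Charge 1, positive polarity.** No isotope-pattern handling.
* **No chromatographic deconvolution.** Co-eluting precursors are
  identified independently; a peak's candidate list is the union of its
  precursors' candidate lists.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `precursor_tol` / `fragment_tol` | 1.5 | Da | ion-trap data show residuals up to ~1.3 Da between related signals; dimer pairing uses 2·tol because two measured values enter the relation |
| `max_loss_depth` | 3 | – | deepest combination needed in practice (3 waters); configurable |
| water multiplicity cap | 3 | – | the trihydroxy xanthophylls end the ladder |
| evidence weights | 2/2/1/1/1/0.5 | – | mass match and fragment-derived group consistency each outrank any single plausibility argument (producer, UV-vis, isomer rule); dimer corroboration is a half-weight bonus. Chosen to mirror the reasoning order of published identifications; all overridable |
| `isomer_intensity_threshold` | 20 | % base peak | the literature contrast is "low" (~5%) vs "high" (~50%) water-loss intensity; any threshold strictly between reproduces both published calls |
| band window | 15 | nm | minimum separation of vibronic bands |
| cis window / height | 320–370 nm, 5% of band II | – | curated; exposed in config |

Group consistency treats the observed hydroxyl count as a **lower bound**
(`observed ≤ record`), because water-loss ladders are routinely incomplete
in trap spectra; a methanol loss requires a methoxy group; polyene losses
(92/106) are consistent with every carotenoid and never discriminate.
Producer incompatibility *demotes* by exactly the producer weight
(implemented as a zero-weight demotion note versus a positive-weight
compatibility note, keeping all evidence weights non-negative and the score
an exact sum); it never removes a candidate, so recall is unaffected by the
taxon setting.

## The %III/II convention

The fine-structure index follows the standard carotenoid convention: band
III is the longest-wavelength maximum, band II the one before it (the
global maximum region), and both heights are measured from the trough
between them, giving %III/II = 100·(A_III − A_min)/(A_II − A_min). This
makes the index exactly invariant under scaling and constant baseline
offsets, which the tests verify. When a spectrum has fewer than two bands,
or band II does not rise above the trough, the index is *absent* (never
infinite). Published %III/II values can also be attached directly to a peak
(`ChromPeak.percent_iii_ii`) when only figure inserts, not traces, exist —
this is how the packaged fixture carries its two determinations (20 and
54). Whether a long-wavelength *shoulder* (as opposed to a resolved
maximum) should count as band III is deliberately left to the band-finding
window: shoulders that never form a local maximum do not count.

## The reference table

Twelve curated records (the xanthophylls and carotenes relevant to
bacterial pigment work plus the common standards). Masses are derived from
molecular formulas and re-validated at load (> 1 Da disagreement is a load
error). Producer sets and hydroxyl counts are transcribed from the
identification literature; `15-apo-carotenal` additionally stores the
trap-observed neutral mass 283.6 Da beside its formula mass, since the
exact structure intended by that name is ambiguous in the source material.
Lutein's diagnostic fragments (551-region water loss marked high-intensity,
plus 430/494/495) and the fine-structure ranges are curator-supplied
defaults: each range brackets published determinations (zeaxanthin's range
contains 20, lutein's contains 54) and ranges were kept disjoint *within
each near-isobaric mass group* so that UV-vis evidence actually
discriminates where mass cannot. Users can replace the whole table
(`--db`, `load_reference(path)`).

## The synthetic-data generator

`simulate_dataset` emulates what the instrument would record for a random
draw of reference compounds: species drawn from
{M•⁺ 0.5, [M+H]⁺ 0.4, [2M+H]⁺ 0.1} (a dimer peak always includes its
co-eluting monomer spectrum, which is how dimers are recognized);
fragments from a fixed loss recipe — the water ladder up to the hydroxyl
count, one methanol loss per methoxy compound, the 92/106 chain losses for
compounds whose class leaves the polyene chain as the dominant channel
(carotenes, methoxy/acyclic, apo, keto), and one combined loss
(methanol+xylene, water+toluene or toluene+xylene as applicable); Gaussian
m/z jitter (default σ = 0.3 Da); lognormal relative intensities rescaled to
percent of base peak; fragment dropout (default 0.1). Records carrying a
literature-reported water-loss intensity behaviour (lutein "high",
zeaxanthin "low") draw that one intensity from the matching band
(40–95% vs 1–15%), so the isomer rule can be exercised against ground
truth. DAD traces are three Gaussian bands (σ = 10 nm, 2 nm grid) whose
band-III height is solved numerically so that the *extracted* %III/II hits
the midpoint of the record's range; compounds without a range get a single
broad band.

What the generator does **not** emulate — and hence what passing benchmarks
do not show about real data: retention behaviour (RTs are synthetic and
unused by the classifier), chromatographic peak shapes and co-elution of
distinct compounds, isotope envelopes, adducts beyond the three species,
ring-cleavage fragments outside the loss grammar, cis-peak absorption, and
instrument-specific intensity response. Benchmarks on this generator
measure the internal consistency of the rule system under noise, not
field performance.

Benchmark conditions used by the test suite: 200 peaks at σ = 0.3 Da with
seed 11 for the ≥ 90% top-1 recovery check (observed: 100%), the same size
at σ = 0 for the exactness check on mass-unique compounds, and 80-peak runs
at σ ∈ {0, 0.3, 1.0} for the monotone-degradation check. These sizes give
stable rates in a few seconds of CPU.

## Numerical choices and tie-breaks

* Loss matching enumerates the full multiset lattice (< 50 combinations at
  default depth) and selects by (|mass error|, fewest components,
  lexicographic loss names); the tests verify exact equivalence with an
  independently written brute-force enumeration on random instances.
* `fragment_mz + total_loss + mass_error == precursor` holds exactly by
  construction.
* Candidate ranking sorts by (−score, record name); within one precursor a
  record is kept once, under its best (score, smallest |mass error|)
  species hypothesis. Reports are therefore byte-identical across runs.
* Degenerate inputs: empty MGF files and fragmentless blocks are warnings,
  not errors; unexplainable fragments and mass-lookup misses are ordinary
  results ("Unknown"); division guards make %III/II absent rather than
  infinite.

## Known limitations

* The packaged in-paper fixture carries one documented numeric
  inconsistency from its source: peak 2's printed water-loss arithmetic
  (584.4 → 564.4, a 20.0 Da delta) fails the 1.5 Da tolerance, so the
  hydroxyl count for that peak rests on its 567.0 fragment alone. The
  values are kept as printed rather than reconciled.
* Scoring weights are heuristics, not calibrated probabilities; scores are
  comparable within a peak, not across datasets.
* The producer filter is only as good as the curated producer sets; it is
  deliberately a demotion so that a surprising-but-real producer (the very
  thing pigment screening looks for) is never hidden.
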