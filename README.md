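# carotannot

Rule-based carotenoid identification for **unit-resolution LC–MS/MS + DAD**
data, built for the situation microbial-pigment labs actually face: an
ion-trap instrument with ~1 Da accuracy, no authentic standards, and a peak
table full of isobaric xanthophylls. `carotannot` turns the reasoning a
spectroscopist performs at the desk into a tested, reproducible pipeline
that outputs *ranked* candidate identifications with an explicit evidence
trail — including honest "Unknown" calls.

## The method

For each chromatographic peak, every co-eluting precursor *m/z* is carried
through three stages:

1. **Ion-species resolution.** Carotenoids ionize in positive ESI as radical
   cations M•⁺ (neutral mass = *m/z*), protonated molecules [M+H]⁺
   (neutral = *m/z* − 1) and, for apocarotenoids, protonated dimers [2M+H]⁺
   (neutral = (*m/z* − 1)/2, nominal proton mass). A co-eluting pair (a, b)
   with |b − (2(a−1)+1)| ≤ 2·tol is flagged as a monomer/dimer pair and the
   monomer's [M+H]⁺ hypothesis is promoted; lone signals keep *both* the
   M•⁺ and [M+H]⁺ hypotheses.
2. **Neutral-loss annotation.** Each MS² fragment is explained as the
   multiset of canonical carotenoid losses — water 18 Da (hydroxyl),
   methanol 32 Da (methoxy), toluene 92 Da and xylene 106 Da (polyene
   chain) — minimizing |mass error| at depth ≤ 3 (water up to ×3). The
   annotations yield a functional-group profile: the maximum observed water
   multiplicity is a *lower bound* on the hydroxyl count.
3. **Evidence-weighted candidate scoring.** Each neutral-mass hypothesis is
   looked up in a packaged reference table and scored:
   mass match (2.0) + group consistency (2.0) + producer plausibility for
   the source taxon (1.0; a *demotion*, never a rejection) + the
   lutein/zeaxanthin isomer rule (1.0; lutein shows an intense [M−H₂O]
   fragment near *m/z* 551 and diagnostics at 430/494/495) + UV-vis fine
   structure %III/II falling in the compound's range (1.0) + corroborating
   dimer pairing (0.5). Ties rank alphabetically, so output is deterministic.

The DAD module extracts band maxima (380–560 nm), the fine-structure index
%III/II = 100·(A_III − A_min)/(A_II − A_min) with both band heights
referenced to the trough between bands II and III (scale- and
baseline-invariant), and a cis-peak flag (local maximum in 320–370 nm at
≥ 5% of band II).

A seeded synthetic-data generator (`simulate_dataset`) produces
ground-truth-labeled datasets — species mixtures, loss-grammar fragments,
lognormal intensities, m/z jitter, three-band Gaussian DAD spectra with
class-specific %III/II — so the whole pipeline is benchmarked without any
download.

## Worked example

The package ships a seven-peak dataset transcribed from a published
LC-UV/vis-MS/MS study of an Antarctic *Flavobacterium* pigment extract:

```python
import carotannot as ca

dataset = ca.table1_fixture()           # 7 peaks, 14 co-eluting precursors
db = ca.load_reference()                # packaged table, 12 carotenoids
report = ca.annotate_dataset(dataset, db, taxon="bacteria")
print(report[["peak_id", "precursor_mz", "rank", "compound", "score"]]
      .head(12).to_string(index=False))
```

```
peak_id precursor_mz  rank           compound score
      1        585.2     1        caloxanthin  5.00
      1        585.2     2         capsanthin  2.00
      1        585.2     3 lutein-5,6-epoxide  2.00
      2        584.4     1        caloxanthin  5.00
      2        584.4     2         capsanthin  4.00
      2        584.4     3 lutein-5,6-epoxide  4.00
      2        413.7     1            Unknown
      3        284.6     1   15-apo-carotenal  5.50
      3          567     1   15-apo-carotenal  5.50
      4        568.6     1         zeaxanthin  7.00
      4        568.6     2             lutein  4.00
      5        621.7     1            Unknown
```

Reading the output: peak 1's *m/z* 585.2 loses three waters (566/549/531),
so of the three isobaric candidates at 584 Da only the trihydroxy
caloxanthin is group-consistent, and the two plant-only pigments are
additionally demoted for a bacterial source (score 5.0 vs 2.0). Peak 3's
co-eluting 284.6/567.0 pair resolves as the protonated monomer and dimer of
a 283.6 g/mol apocarotenoid. Peak 4 (55.3% of total area) has a weak
water-loss fragment (4.9%) and %III/II = 20, both zeaxanthin-like, so
zeaxanthin (7.0) outranks its isomer lutein (4.0). Signals with no
reference mass within tolerance stay "Unknown" — a first-class result.

The same pipeline is exposed as a CLI:

```bash
carotannot fixture --out demo/
carotannot annotate --peaks demo/peaks.csv --taxon bacteria --out report.tsv
carotannot simulate --seed 11 --n-peaks 200 --out sim/
```

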