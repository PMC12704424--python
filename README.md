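# sipracs

A toolkit for identifying *in situ* pollutant-degrading microbes by combining
**stable isotope probing (SIP)** with **Raman-activated cell sorting (RACS)**
readouts, plus the degradation-kinetics statistics that accompany such
studies.

When a microbial community is fed a ¹³C-labeled substrate (here:
2-methylnaphthalene in soil microcosms), only the organisms that actually
assimilate it incorporate the heavy isotope into their biomolecules. That
leaves two independent fingerprints:

1. **Single-cell Raman red-shift.** Heavier carbon lowers vibrational
   frequencies; the protein-backbone Amide III band moves from ~1105 cm⁻¹ in
   unlabeled cells to ~1082 cm⁻¹ (a shift of ~−23 cm⁻¹) in labeled cells.
   Locating that band per cell gives a direct active/inactive call.
2. **DNA buoyant density.** ¹³C-DNA migrates to heavier CsCl-gradient
   fractions. With a parallel ¹²C control, a taxon's **relative enrichment
   factor** is

   REF = (¹³C_heavy / ¹³C_light) / (¹²C_heavy / ¹²C_light),

   where each term is the taxon's mean relative abundance over replicate
   samples of that treatment × fraction class ("light" 1.7042–1.7089 g/ml,
   "heavy" 1.7342–1.7411 g/ml). Taxa with mean abundance > 0.5% **and**
   REF > 1.5 are called active degraders.

The package implements the full analysis chain as a library:

| module | what it does |
| --- | --- |
| `sipracs.synthgen` | Seeded generators: Gaussian-band Raman spectra with fluorescence background, paired ¹²C/¹³C fraction tables, first-order decay series, enzyme panels |
| `sipracs.raman` | AsLS baseline correction, vector normalization, sub-grid band localization, labeled/unlabeled classification, band-intensity ANOVA |
| `sipracs.sip` | Density-window fraction classing, REF computation with pseudocount handling, active-taxon screening, bootstrap intervals |
| `sipracs.kinetics` | Removal percent, weighted log-linear first-order fits, Pearson enzyme–removal correlation, Welch/ANOVA group tests |
| `sipracs.io` / `sipracs.pipeline` / `sipracs.cli` | TSV/YAML/JSON dialects, the seeded end-to-end replay pipeline with hashed manifest, and a thin `sipracs` command |

## Worked example

`examples/` holds one short script per capability. The single-cell screen
(`examples/01_classify_raman_cells.py`) simulates 150 hyphal spectra from a
¹³C microcosm with 10 active cells planted, preprocesses and classifies each:

```
cells profiled: 150
cells called 13C-labeled: 10
mean Amide III shift of labeled cells: -22.9 cm-1
band 1105 cm-1: F = 23767.1, p = 2.48e-165
band 1082 cm-1: F = 21713.5, p = 1.91e-162
```

The classifier recovers exactly the planted count; the mean shift is the
¹³C Amide III signature, and the ANOVA shows the two cell groups separate
sharply at both band positions. The SIP screen
(`examples/02_ref_screen.py`) recovers the planted active taxon:

```
ASVs screened: 20
active taxa (abundance > 0.5%, REF > 1.5): 1
  ASV_1: REF = 50.5, mean abundance = 12.4%
REF range of inactive taxa: 0.52 - 0.72
```

and the kinetics layer (`examples/03_kinetics_enzymes.py`) fits the
first-order rate constant and reproduces the canonical removal summary —
`removal_percent(5, 2.01)` prints as `59.8`%:

```
true k = 0.1302 /day; fitted k = 0.1321 /day (95% CI 0.1246 - 0.1397)
half-life = 5.2 days
  day    0: 5.06 mg/kg  (0.0% removed)
  day    3: 3.44 mg/kg  (32.1% removed)
  day    7: 1.97 mg/kg  (61.2% removed)
  day   14: 0.85 mg/kg  (83.2% removed)
LiP activity vs removal: R^2 = 1.00, p = 0.000629
```

`examples/04_full_replay.py` (or `sipracs replay --seed 1 --out OUT`) runs
all stages end to end and writes every intermediate table plus a manifest of
SHA-256 hashes; identical seeds reproduce identical bytes.

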