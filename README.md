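# novoscreen

Analysis pipeline for combinatorial **binder-fusion agonist screens**:
libraries of synthetic cytokine-like agonists built by fusing pairs of
receptor-binding protein domains with flexible linkers, screened for
phospho-STAT (pSTAT1/3/4/5/6) activation in primary immune cells by
phospho-flow cytometry.

The package is aimed at computational biologists working with such screens.
It provides:

* **registry** — a validated catalogue of receptor-binding domains
  (33-binder fixture included: 9 newly designed binders for γc, βc, IFNAR1,
  TSLPR, IL12Rβ1, IFNAR2, IL10Rβ, IL4Rα and IL2Rβ, plus 24 previously
  developed binders);
* **library_builder** — all-by-all enumeration of fusion constructs
  (n² ordered constructs for n binders; 33 binders → 1,089 constructs
  spanning 561 unique receptor pairings), FASTA + manifest output;
* **synthetic_screen** — a seeded generator of screen measurement tables
  with planted ground truth (dual-receptor bridging, single-receptor
  clustering, or inactive), multi-donor variability, and natural-cytokine
  positive controls, so every downstream stage is testable without any
  experimental data;
* **hit_calling** — per-stratum 0–1 normalization, the `mean + 6×SEM`
  signaling call against three unstimulated controls, an adaptive cutoff for
  weakly-responding strata, and a ≥2-of-3-donor reproducibility gate;
* **dose_response** — bounded four-parameter Hill fits and triage into
  *saturable* / *non-saturating* / *no-signal* mechanisms;
* **ko_analysis** — receptor-dependence verdicts from single-receptor
  knockouts;
* **cli_reporting** — a `novoscreen` command-line pipeline with a
  reproducible JSON report.

## The model

A bifunctional ligand at dose `d` bridges receptors 1 and 2 (surface
densities `r1`, `r2`, binder affinities `kd1`, `kd2`) into a signaling
ternary complex with abundance

```
T(d) = α · (r1/ρ)(r2/ρ) · d / ((kd1 + d)(kd2 + d))
```

which is single-peaked with its maximum at `d = √(kd1·kd2)` — the classic
high-dose **hook effect**, where excess ligand occupies the two receptors on
separate molecules. Observed signal is the saturating transform
`emax · T/(T + K_half)`; it vanishes when either receptor is absent, which is
what the knockout analysis exploits. Signal from domain self-association
(**clustering**) instead grows without plateau,
`slope · (r/ρ) · occupancy(d) · log(1 + d/kd)`, and involves one receptor
only. The pSTAT signature of a construct comes from the *private* receptor
of the pair (shared subunits such as γc, βc, gp130 act as assembly
platforms), with an optional pSTAT5 leak for flexible fusions.

Hit calling follows the screen's statistic: within each donor × cell type ×
pSTAT stratum, scores are min–max normalized to 0–1 and a condition is
called signaling when it exceeds the unstimulated-control mean by 6×SEM
(n = 3 controls). Under a Gaussian null this call has a closed-form per-test
false-positive rate, `P(t₂ > 3) ≈ 0.0477`, which the test suite verifies by
Monte Carlo against the implementation.

## Worked example

```
novoscreen run-all --seed 1 --out-dir out/
cat out/report.txt
```

prints (abridged):

```
novoscreen pipeline report
  seed               : 1
  library size       : 1089
  unique pairings    : 561
  reproducible hits  : 97 constructs
  hits by mechanistic class:
    ifnar1_based            : 18
    cytokine_growth_factor  : 49
    common_common           : 3
    other                   : 27
  dose-response confusion (planted->called):
    clustering->non_saturating  : 6
    ternary->saturable          : 14
  knockout dual-dependent: 4 of 4 tested
```

Reading this: all 33² = 1,089 ordered fusions over 561 distinct receptor
pairings were screened in silico across three donors and six PBMC
populations; 97 constructs passed the 6×SEM + 2-of-3-donor reproducibility
gate in at least two pathway × cell-type combinations. The 20 strongest hits
were titrated and classified — every planted bridging mechanism came back
*saturable* and every planted clustering mechanism *non-saturating* — and
for the four flagship pairings (βc–γc, γc–gp130, IL7Rα–IFNAR1,
IL21Rα–IFNAR1) knocking out either receptor abolished the signaling call,
confirming dual-receptor dependence.

Individual stages are available as `novoscreen build-library`,
`simulate-screen`, `call-hits`, `dose-response` and `ko-test`; see
`novoscreen --help`.

## Caveats

The packaged binder affinities for the nine newly designed binders are
synthetic placeholders drawn once from the 1–200 nM range (per-binder values
are not published as text), and prior-work binders carry no affinity (`NA`).
Cell-panel receptor densities are plausibility-scale configuration. See
`docs/methods.md` for the model's assumptions and limitations.
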