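# pgpscreen

Analytics for screening campaigns of plant-growth-promoting (PGP) and
antifungal microbial isolates — the kind of study where dozens of culturable
endophytes (e.g. actinobacteria recovered from plant roots and leaves) are
phenotyped for PGP traits, confronted with fungal phytopathogens in dual
culture, ranked to pick elite strains, and the winners taken into a pot
trial.

It is written for microbiologists and biocontrol researchers who have such
tables — trait assay readouts, an isolate × pathogen inhibition matrix, pot
trial measurements — and want the downstream arithmetic to be reproducible,
auditable and scriptable rather than living in a spreadsheet.

## What it computes

**Assay quantification** (`pgpscreen.assay_quant`)

* standard-curve calibration by ordinary least squares,
  A = m·c + b, with inversion c = (A − b)/m and r² quality control;
* dual-culture inhibition, %I = 100·(C − T)/C from control/test mycelial
  diameters;
* CAS-shuttle siderophore units, %S = 100·(Ar − As)/Ar from reference and
  sample absorbances at 630 nm;
* seed germination percentage; chlorophyll a/b from DMSO-extract
  absorbances, Chla = 11.75·A663 − 2.35·A645, Chlb = 18.61·A645 − 3.96·A663.

**Bonitur scoring** (`pgpscreen.bonitur`) — an additive 41-point scale:
IAA and phosphate solubilization earn 0–3 points by upper-inclusive binning,
five further traits (ammonia, N₂ fixation, ACC deaminase, siderophore,
chitinase) earn 1 point each, and each of ten pathogens earns 0–3 points by
inhibition percentage, so max = 3 + 3 + 5 + 10·3 = 41. Isolates get dense
ranks (ties share a rank), and `audit_scores` reconciles recomputed score
cards against a published score table, flagging every cell-level
disagreement and any published row whose own points do not sum to its
printed total.

**Campaign summaries** (`pgpscreen.screen_summary`) — per-trait prevalence
(a quantitative trait counts as positive iff detected, i.e. non-ND),
per-pathogen antagonism spectra, broad-spectrum isolate detection,
genus/tissue composition, and value extremes with isolate attribution.

**Pot-trial statistics** (`pgpscreen.growth_trial`) — per-treatment
mean ± SE summaries (SE = sd/√n), log₂ fold change of treatment means
versus the control mean, classic one-way ANOVA per parameter per timepoint,
and PCA of the standardized replicate × parameter matrix.

**Synthetic data** (`pgpscreen.synthetic_data`) — seeded generators for
whole campaigns and pot trials with configurable prevalences, value ranges,
fold changes and replicate noise, so every stage is testable end-to-end.

The package ships a transcription of a published 51-isolate orchid-endophyte
campaign (roster, trait table, 51 × 10 inhibition matrix, published score
table) under `pgpscreen.fixtures`, including a metadata file recording every
internal inconsistency of the printed source.

## Worked example

```python
from pgpscreen import fixtures, bonitur, screen_summary

profiles = fixtures.load_trait_table()
matrix = fixtures.load_inhibition_matrix()
cards = [bonitur.score_isolate(p, matrix.row(p.isolate_id)) for p in profiles]
ranked = bonitur.rank_isolates(cards)
for c in ranked[:5]:
    print(f"{c.rank}  {c.isolate_id:7s} PGP {c.pgp_subtotal:2d} "
          f"+ antifungal {c.antifungal_subtotal:2d} = {c.total}")

prev = screen_summary.trait_prevalence(profiles)
print(f"phosphate solubilizers: {prev['p_solub'].count}/51 "
      f"({prev['p_solub'].percentage}%)")
print("broad-spectrum antagonists:",
      screen_summary.antagonism_spectrum(matrix).broad_spectrum)
```

prints

```
1  VCLA3   PGP 11 + antifungal 23 = 34
2  RVRA7   PGP 11 + antifungal 21 = 32
3  DNLA13  PGP  5 + antifungal 26 = 31
3  VCRA2   PGP  3 + antifungal 28 = 31
4  RRR46   PGP  7 + antifungal 14 = 21
phosphate solubilizers: 25/51 (49.02%)
broad-spectrum antagonists: ['DNLA13', 'VCRA2']
```

VCLA3 tops the scale with 34 of 41 points (strong on every PGP trait, eight
pathogens inhibited), RVRA7 is second with 32; DNLA13 and VCRA2 tie on 31 —
they inhibit everything but carry weak PGP profiles. The prevalence line
says 25 of the 51 isolates solubilized phosphate at all, and exactly two
isolates inhibit all ten pathogens.

## Command line

```
pgpscreen simulate --kind screen --seed 7 --out-dir data/
pgpscreen score  --traits data/traits.csv --inhibition data/inhibition.csv \
                 --out-dir results/
pgpscreen report --roster data/roster.csv --traits data/traits.csv \
                 --inhibition data/inhibition.csv --out results/campaign.json
pgpscreen trial  --records trial_records.csv --out-dir results/trial/
pgpscreen quantify --standards standards.csv --readouts readouts.csv \
                 --out concentrations.csv
```

Every command logs to stderr and writes a `run_manifest.json` (inputs,
config hash, seed) beside its outputs. Exit codes: 0 success, 2 I/O,
3 validation/format, 4 configuration.

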