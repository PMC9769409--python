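{
  "description": "Transcriptions of the published screening campaign tables: isolate roster (morphology + tissue origin), per-isolate PGP trait table, isolate x pathogen dual-culture inhibition matrix, and the published bonitur score table used for audits.",
  "files": {
    "table1_roster.csv": "51 isolates with colony morphology and tissue origin, stored verbatim.",
    "table2_traits.csv": "51 isolates x 10 PGP/enzyme traits; quantitative cells as 'mean ± SE' (n=3), ND = not detected, +/- flags.",
    "table3_inhibition.csv": "51 isolates x 10 fungal pathogens, percent mycelial growth inhibition as 'mean ± SE' (n=3); '-' = no activity.",
    "table4_published_scores.csv": "Published per-trait bonitur points, totals and dense ranks for the seven top isolates, stored as printed (including internal inconsistencies)."
  },
  "pathogen_order": [
    "P. hypobrunnea", "F. solani", "R. solani", "F. oxysporum", "C. capsici",
    "P. lamaensis", "P. theae", "C. eragrostidis", "N. sphaerica", "G. cingulata"
  ],
  "known_discrepancies": [
    "Source abstract/prose give DNRA1 phosphate solubilization as 289.7 ± 11.9 but the trait table prints 289.7 ± 11.1; the table value is kept.",
    "Prose gives RVRA7 phosphate solubilization SE as 5.0 but the trait table prints 0.8; the table value is kept.",
    "Prose states 27 isolates antagonized at least one pathogen, but the printed inhibition matrix has 28 rows with at least one value; the matrix is kept and the recomputed count is exposed.",
    "Prose states siderophore production ranged from 10 to 50% while the trait table lists 61.2 and 59.4; the table values are kept.",
    "Roster tissue origins as printed give 35 root / 16 leaf, not the stated 33 root / 18 leaf; CALA1 is printed as Root although its code pattern suggests leaf. The roster is stored verbatim and validate_roster reports the mismatch.",
    "The roster (table 1) lists MORA2 but not DMLA1; the trait table (table 2) lists DMLA1 but not MORA2. Both are stored verbatim; validate_roster reports the difference.",
    "MOLA1 vs P. theae is printed '51.2 ± 04'; the SE is transcribed as 0.4 (means are unaffected).",
    "Published score rows for DNLA13 and VCRA2 are inconsistent with their own trait/inhibition values (and, for VCRA2, the printed points sum to 28, not the printed total 30); they are stored as printed and surfaced by audit_scores."
  ]
}
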