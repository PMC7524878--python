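# mintscreen

Activity-guided screening of mint essential oils: which compound in a
complex, variable natural mixture carries the bioactivity?

Essential oils from closely related Lamiaceae (mints and their relatives)
differ sharply in composition and in allelopathic activity — their vapors
can suppress germination of neighboring plants. `mintscreen` implements the
comparative screen that exploits this diversity as a logical filter: profile
the oils of many accessions by GC, assay each oil's inhibition of cress
(*Lepidium sativum*) seed germination, and rank compounds by how tightly
their abundance tracks bioactivity across the panel. Top candidates are then
characterized directly by dose–response analysis and cytotoxicity assays in
tobacco BY-2 cells. Because a comparative screen is worthless on
misidentified plants, the accession panel is first authenticated with the
*psbA-trnH* plastid barcode (neighbor-joining tree with bootstrap support,
outgroup rooting, and automatic flagging of declared-label conflicts).

The core statistic is the per-compound **bioactivity score**

```
B = (1/n) · Σᵢ a(i) · g(i)
```

where, over the *n* accessions of the panel, *a(i)* is the compound's
relative GC peak area (%) in accession *i*'s oil and *g(i)* is the
germination inhibition (%) caused by that oil. A compound that made up 100%
of every oil, with every oil fully inhibitory, would score 10,000. Candidate
dose–response curves use the four-parameter log-logistic
`f(d) = c + (d' − c)/(1 + (EC50/d)^b)`; cytotoxicity is read out as Evans
Blue dye-exclusion mortality (% stained of 600 cells × 3 replicates) and as
AO/EB nucleus color-class distributions, with cell-line sensitivity
differences quantified as EC50 fold changes.

The package is aimed at natural-product and chemical-ecology groups running
comparative bioassay panels, and ships a fully parameterized synthetic-data
generator (sequences, GC tables, count tables, intensity tables, with
exported ground truth) so the entire pipeline is testable end to end.

## Worked example

Generate a synthetic study and run the full screen:

```
$ mintscreen simulate --scenario paper_scenario --seed 42 --out demo/study
$ mintscreen run --study demo/study --outgroup ACC10 --reps 1000 --seed 42 \
      --out demo/report
$ cat demo/report.txt
mintscreen report
=================

Authentication: ok
  flagged ACC03: declared Mentha longifolia, placed with Mentha spicata (support 100%)
  flagged ACC06: declared Mentha spicata, placed with Mentha longifolia (support 100%)

Bioactivity: ok
  1. menthone/isomenthone  B=1549.3
  2. menthol  B=881.1
  3. 1,8-cineole  B=485.9
  4. carvone  B=420.9
  5. limonene  B=407.7
  6. pulegone  B=231.0
  7. linalool  B=185.7
  excluded (positive controls): citral

Dose-response: ok
  limonene: EC50=83.5 (LL.2), slope=0.338, converged=True
  linalool: EC50=0.1374 (LL.2), slope=0.785, converged=True
  menthol: EC50=0.07669 (LL.2), slope=0.611, converged=True
  menthone/isomenthone: EC50=0.00254 (LL.2), slope=0.473, converged=True

Cytotoxicity: ok
  menthone/isomenthone: EC50 fold WT/tubulin-marker = 3.98

AO/EB: ok
```

Reading the output: the two accessions whose declared species labels were
swapped by the generator (ACC03/ACC06) are flagged with full bootstrap
support — on real data this is the "your herbarium label is wrong" alarm.
The planted active compound, the pooled menthone/isomenthone pair, tops the
candidate ranking (B ≈ 1550 of a possible 10,000), with citral set aside as
the positive control rather than silently dropped. Germination EC50s are in
nominal ppm (menthone/isomenthone is active far below the other
monoterpenes; limonene's EC50 sits far above the tested range, i.e. it is
essentially inactive); the cytotoxicity section recovers the tubulin-marker
line's planted 4-fold sensitization (estimated 3.98). Every number above is
a recovery of a ground-truth value stored in `demo/study/ground_truth.json`.

Each stage is also available separately (`authenticate`, `chem`,
`doseresponse`, `score`, `cytotox`, `report`); the same functionality is
importable from Python via `mintscreen.run_screen` and the per-module
functions.

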