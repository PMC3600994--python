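# l1evo

Evolutionary analysis of LINE-1 (L1) retrotransposon families in a mammalian
genome, built as a tested, reusable pipeline with a ground-truthed simulator.

L1 is the dominant autonomous transposable element of mammals: a ~6-7 kb
element with an internal promoter in the 5'UTR, two open reading frames
(ORF1, an RNA-binding/chaperone protein with a coiled-coil domain; ORF2, an
endonuclease + reverse transcriptase), and a 3'UTR.  L1 evolves as a chain
of replicatively dominant *families*; families recruit novel promoters,
exchange internal sequence by template-switch recombination, and are dated
by the neutral divergence their genomic copies have accumulated.  `l1evo`
implements every stage of such an analysis:

* **simulate** — a master-lineage amplification simulator: a chain of
  family progenitors evolving under Jukes-Cantor substitutions (rate *r*
  per site per MY), promoter replacements, prefix-transfer recombination,
  lateral introductions, copy deposition with 5' truncation, and a full
  machine-readable truth table.
* **mine** — full-length element recovery: translated (six-frame, 5-aa
  seeded, BLOSUM62-extended) search with the reverse-transcriptase domain,
  14 kb windows, second-pass annotation of ORF1/EN/RT/3'UTR, 3 kb upstream
  extraction, intactness filtering.
* **classify** — promoter typing against a 5'UTR library, single-linkage
  clustering of unassigned promoters into novel types, family definition by
  neighbor-joining + bootstrap on the 3' terminus with star-phylogeny
  validation, plurality consensus building and age-ordered Roman-numeral
  naming.
* **phylo** — p/JC/K2P/TN93 distances with pairwise deletion, Saitou-Nei
  neighbor joining, column-bootstrap support, Fitch (Hartigan) parsimony
  for counting promoter replacements.
* **recomb** — MaxChi (50 bp windows, 2x2 chi-square
  n(ad-bc)^2/((a+b)(c+d)(a+c)(b+d)), permutation null of the maximum),
  a Chimaera-like informative-site variant driving an all-triplets scan,
  bootscan traces, breakpoint verification by flanking trees, segmentation
  into recombination-free blocks.
* **selection** — Nei-Gojobori counting dN/dS (pathway-averaged differences,
  stop-free opportunity so S + N = 3 per codon, Jukes-Cantor correction,
  jackknife SE) with per-site binomial tests and Benjamini-Hochberg control,
  summarised per region x recombination-free segment.
* **orf1** — decomposition of the length polymorphism region (LPR) into
  66/42 bp units (deletion variants surface as their occupied lengths, e.g.
  45 = 66 - 21), Sankoff parsimony for unit-edit event histories, and a
  heptad-periodicity coiled-coil scan (hydrophobic registers a/d).
* **ages** — 3'UTR dating: CpG and polypurine-tract masking, mean pairwise
  divergence with column-bootstrap SE, conversion age = d x 0.55 MY/%, and
  lateral-transfer detection from long stem branches against a simulated
  vertical-descent null.

## Worked example

Run the full pipeline on the default simulated genome (3 Mb, six families
spanning 9.2-0.25 MY, 25 copies each, 40% truncation):

```bash
l1evo run --out demo --seed 0
```

which prints the truth-comparison block of the run:

```
age_interval_coverage   0.6667
family_ari      0.9763
mining_precision        0.989
mining_recall   0.989
n_families_detected     6
n_families_true 6
n_true_recomb_events    0
n_verified_events       0
```

Reading: of the 91 full-length copies planted, 98.9% were recovered as
full length with 98.9% precision; clustering the mined elements by promoter
type + 3'-terminus phylogeny reproduced the six simulated families
(adjusted Rand index 0.98); the true insertion ages fell inside the +-1 SE
age intervals for 4/6 families (the interval is one standard error, not a
95% CI); and no recombination events were called on this recombination-free
history.  `demo/families.tsv` then holds the named family table (e.g.
`A_I ... age 0.22 MY` for the family simulated at 0.25 MY), with the
consensus-level event, selection, LPR/coiled-coil and lateral-transfer
tables alongside.

Every stage is also callable as a library function; see the module
docstrings (`l1evo.recomb.detect_events`, `l1evo.ages.estimate_family_age`,
...) and `l1evo --help` for the `simulate`, `mine`, `recomb` and `run`
subcommands.

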