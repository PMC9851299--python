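# abnovo

**Evaluation framework for de novo peptide sequencing and antibody
sequence assembly.**

De novo sequencing tools infer peptide sequences directly from tandem
mass spectra, without a sequence database. For unknown antibodies — whose
variable regions are absent from public databases — this is the only
route to the sequence, but every tool makes characteristic mistakes and
fragment spectra are imperfect (missing cleavage sites, noise peaks).
`abnovo` provides the full measurement stack needed to benchmark such
tools and to judge whether their output can be assembled back into a
full-length antibody chain:

- **Mass-based matching.** A predicted amino acid counts as correct when
  its residue mass agrees with the reference within 0.1 Da *and* the
  prefix mass before it agrees within 0.5 Da. Aggregates are AA recall
  `Σ matched / Σ truth AAs`, AA precision `Σ matched / Σ predicted AAs`
  and peptide recall (fraction of spectra with a fully correct
  prediction). Sweeping the confidence score yields precision–recall
  curves and their AUC, plus the confidence cutoff at which AA precision
  first reaches 50%.
- **Spectrum quality annotation.** For every cleavage site, eight ion
  types (b, b²⁺, b−NH₃, b−H₂O, y, y²⁺, y−NH₃, y−H₂O) are matched against
  peaks within 0.5 Da; a site with no matched ion is *missing*. The
  *noise factor* is the number of non-fragment peaks above the
  dataset-median noise intensity divided by the number of fragment
  peaks. Peptide recall is stratified along both axes and by length.
- **Error taxonomy.** Incorrect predictions are classified into 11
  categories: permutations of the first/last three residues, n-for-n
  residue replacements (n = 1…6, the single-residue case including
  near-isobaric 1-for-2 splits such as Q vs GA), more than six wrong
  residues, and "other".
- **De Bruijn assembly.** Predictions above the 50%-precision confidence
  cutoff are decomposed into k-mers (k = 7) weighted by positional
  confidence; contigs are iterated heaviest paths, locally aligned
  (Smith–Waterman: match +2, mismatch −1, gap open −2, extend −1) to the
  reference chain, and summarised as mapped contigs, longest contig,
  sequence coverage and per-column accuracy.
- **Synthetic benchmark generator.** Multi-enzyme in-silico digests
  (trypsin, chymotrypsin, asp-N, lys-C, glu-C, proteinase K, …) of
  bundled synthetic antibody chains, HCD-style spectra with controlled
  site dropout and noise, and mock predictor output with a controlled
  error mixture and confidence scores correlated with correctness — so
  every stage is testable offline with known ground truth.

## Worked example

Simulate a three-enzyme digest of the bundled 220-residue synthetic
light chain, with a quarter of predictions badly wrong and smaller doses
of single-residue replacements and terminal inversions:

```bash
abnovo simulate --out-dir demo --seed 42 \
    --error-mixture "replace_1_by_1_or_2:0.15,inversion_last_3:0.1,more_than_6_wrong:0.25"
```

This writes `spectra.mgf`, `ground_truth.tsv`, `predictions.tsv`,
`reference.fasta`, the simulator's defect log, assembled `contigs.fasta`
and a combined `report.json`. For seed 42 the report contains:

```
n_spectra        31
aa_recall        0.6043      aa_precision  0.6027
peptide_recall   0.4839      PR AUC        0.5817
assembly         coverage 76.82%, accuracy 98.40%,
                 13 mapped contigs, longest 31 aa
error profile    16 errors / 31 predictions
                 more_than_6_wrong 0.625, replace_1_by_1_or_2 0.375
```

Reading: the injected corruption halves peptide recall; AA-level recall
and precision sit near 0.60 because badly wrong predictions still leave
most other residues intact. Assembly of the confidence-filtered
predictions recovers three quarters of the chain at 98% per-column
accuracy — corrupted peptides fragment the de Bruijn graph, which is
exactly the failure mode seen when assembling real tool output. With an
all-correct mixture (`--error-mixture ""`) the same pipeline reaches
coverage 94% and accuracy 100%.

Each stage is also available separately (`abnovo evaluate`,
`abnovo annotate`, `abnovo classify-errors`, `abnovo assemble`,
`abnovo run`); `--help` documents the file formats, which are plain MGF,
FASTA and TSV so real tool output can be dropped in.

As a library:

```python
import numpy as np
from abnovo import SimulationConfig, simulate_dataset, aggregate_metrics

ds = simulate_dataset(SimulationConfig(error_mixture={"more_than_6_wrong": 0.3}),
                      np.random.default_rng(1))
m = aggregate_metrics(ds.predictions, ds.ground_truth)
print(m.aa_precision, m.peptide_recall)
```

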