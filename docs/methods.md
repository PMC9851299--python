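# Methods

This note documents the models and procedures implemented in `abnovo`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show
about real data.

## Mass arithmetic

All comparisons are monoisotopic. Residue masses come from the standard
20-residue table (via pyteomics); modification deltas are stored at full
precision — carbamidomethylation +57.021464 Da, oxidation +15.994915 Da,
deamidation +0.984016 Da — and round to the conventional two-decimal
labels (+57.02, +15.99, +0.98). Deamidation is modelled on asparagine
and glutamine (glycine cannot deamidate); the modification set is
config-exposed so other readings are runnable. The canonical peptide
string writes modifications as bracketed signed deltas (`C[+57.02]`,
`M[+15.99]`, `N[+0.98]`), and parse/format round-trip exactly.

Fragment m/z values follow the usual identities: b(1+) at site *i* is
the prefix mass plus a proton, y(1+) is the complementary suffix plus
water plus a proton, 2+ variants carry two protons over charge two, and
neutral-loss variants subtract NH₃ (17.02655 Da) or H₂O (18.01056 Da)
from the singly charged ion. The b/y complementarity identity
`mz(b,i) + mz(y,i) = M + 2·1.00728` holds to below 1e−9 Da and is
enforced in the test suite.

Isoleucine and leucine are distinct symbols with identical mass: mass
comparisons treat them as equal, symbol comparisons do not. Q and K
differ by 0.036 Da, below the matching tolerance — the matcher is
deliberately blind to this substitution, as are the instruments.

## Amino-acid matching

The matcher walks the two prefix-mass arrays with two pointers. At
pointers (i, j): if the prefix masses *before* the residues agree within
0.5 Da, both advance and a match is counted iff the residue masses agree
within 0.1 Da; otherwise the pointer with the smaller prefix advances.
This realises the maximal order-preserving matching under the same
pairwise criterion — verified against an exhaustive dynamic-programming
oracle on 10 000 random pairs of length ≤ 8. Peptide-level correctness
is a full-length AA match, not string equality, so I/L (and Q/K)
substitutions count as correct.

Aggregation denominators: AA recall divides by all ground-truth residues
(spectra with no surviving prediction contribute zero matches); AA
precision divides by residues of emitted predictions only; peptide
recall divides by ground-truth spectra (PSM-level, not unique-sequence).
Predictions without a ground-truth spectrum are excluded and counted as
unvalidated.

## PR curves and the confidence cutoff

Thresholds are the sorted unique peptide-level scores (evenly subsampled
to `n_thresholds`, default 50); each point re-aggregates the metrics at
that cutoff. AUC is the trapezoid of precision over recall after sorting
points by ascending recall (ties keep the higher precision first), plus
a rectangle anchoring the lowest-recall point back to recall zero.
Points with undefined precision (no emitted prediction) are excluded
from the integral. This definition is pinned so that independent
reimplementations agree; with perfectly separated scores it reduces to
`max recall × 1.0`.

The assembly cutoff is the smallest observed score threshold at which
the AA precision of the surviving predictions reaches the target
(default 50%); threshold 0 is always a candidate, and an unreachable
target returns the maximal score with a warning flag rather than a
silent value.

## Spectrum annotation

For each cleavage site, the eight HCD ion types are matched against
peaks within 0.5 Da. Site evidence records the nearest in-tolerance peak
per ion type, but *every* peak inside a tolerance window is a fragment
peak (two near-coincident theoretical ions may share a nearest peak
while a second peak sits in range); a peak matched by several ions
counts once. A site with no matched ion of any type is missing. Peaks
that are not fragment evidence are noise; the dataset-median noise
intensity is computed once over the pooled non-fragment peaks and passed
explicitly, keeping single-spectrum annotation pure. The noise factor
counts noise peaks whose intensity *strictly exceeds* that median,
divided by the fragment-peak count; with zero fragment peaks it is
undefined (None) and binned separately. A peak within tolerance of any
theoretical ion is signal even if it was injected as noise — collisions
resolve in favour of signal, and exactness tests use collision-free
placement.

## Error taxonomy

The classifier is a total function with a fixed priority order:

1. full AA match → correct;
2. terminal inversions (equal length): the first and/or last three
   residues hold the same residue masses in a different order while the
   remaining positions match positionally; "inversion" means any
   permutation, with a `strict_reversal` flag narrowing it to exact
   reversals; both-ends inversions require length ≥ 7;
3. replacements: after anchoring the longest positionally matched prefix
   and suffix (non-overlapping, ties keep the prefix), a truth window of
   1 against a prediction window of 1 or 2, or equal windows of 2…6;
4. more than six wrong: truth residues minus matched residues exceeds 6;
5. other (e.g. two residues replaced by four).

The order puts terminal permutations — which formally are also 3-for-3
replacements — into the inversion categories, keeping the categories
disjoint. Replacement categories accept any substitution of the stated
window sizes (mass consistency is not required); length-changing windows
other than 1→2 fall to "other".

## Synthetic benchmark

The generator emulates what a multi-enzyme antibody study measures,
with ground truth attached to every artifact.

**Digestion.** ExPASy-convention cleavage rules (trypsin C-terminal of
K/R not before P; chymotrypsin C-terminal of F/W/Y/L not before P; asp-N
N-terminal of D; glu-C C-terminal of E; lys-C/lys-N; thermolysin,
elastase, aLP and proteinase K as broad declared specificities). Rules
are declared, config-overridable constants — the broad proteases have no
single canonical specificity. At zero missed cleavages each digest
partitions the chain; overlapping products from different enzymes are
what makes assembly possible.

**Spectra.** Each digest peptide in the configured length window
(default 7–30 residues) yields one spectrum at a random configured
charge (2–3). Cleavage sites drop out independently with probability
0.15 by default — chosen so that most peptides with a dozen sites miss
at least one fragment ion, the regime real HCD data sits in. Retained
sites always emit b and y (1+), other ion types with probability 0.5;
peak m/z deviates from theory by at most 0.02 Da. Noise-peak counts are
Poisson (mean 60 by default), positions uniform over m/z 100–2000,
intensities exponential below the lognormal signal intensities. Because
ion series of different sites can coincide within 0.5 Da, emitted ions
that would fall inside a dropped site's matching window are suppressed,
and the defect log records the *observable* missing sites — exactly what
annotation sees. `collision_free_noise` additionally keeps noise peaks
1.5 tolerances away from every theoretical ion so the log is exact.

**Mock predictions.** Each spectrum's error type is drawn from the
configured mixture (remainder correct). Corruptions are constructed to
land in their category — terminal windows are permuted with at least one
mass-visible change, replacement windows are rewritten with residues
mass-distinct from the originals, the 1-for-2 case draws from a
near-isobaric split pool (Q/K→GA, N→GG, R→GV, W→SV; all within 0.5 Da) —
and each corruption is verified against the classifier, resampling on
the rare failure, so the generated labels are exact by construction.
Confidence scores: correct predictions draw from Beta(8,2)·100,
incorrect from Beta(2,8)·100 — overlapping but stochastically ordered,
so PR curves are non-degenerate; constants (100/0) give the calibrated
oracle. Positional scores jitter ±5 around the peptide score.

**Reference chains.** Two bundled synthetic chains (220 and 450
residues, mirroring light- and heavy-chain lengths) were generated once
from vertebrate-average residue frequencies. The light chain was
screened at generation time so that the three-enzyme digest at zero
missed cleavages tiles every position with peptides of length ≥ 7 and
the assembler round-trips it to 100% coverage and accuracy — the
error-free reconstruction guarantee the test suite pins. Random chains
of this composition typically satisfy the screen immediately; the screen
exists so the bundled constant is guaranteed to.

**What the simulator does not model:** learned fragmentation intensity
patterns, retention time, chimeric spectra, isotope envelopes, ETD ion
series, and tool-specific error correlations (error type is independent
of spectrum quality given the mixture). Passing tests therefore
demonstrate correctness of the measurement machinery under controlled
conditions, not the performance of any real sequencing tool on real
antibody data.

## Assembly

k-mers (default k = 7) collapse modified residues to their base letter —
assembly targets the backbone sequence; `--keep-mods` retains them.
Node weight accumulates the mean positional confidence of every window
spelling the k-mer; consecutive windows add the mean of their two
weights to the connecting edge. Any two nodes overlapping by k−1 are
additionally linked by a structural zero-weight edge, which is how reads
from different enzymes join. Contig extraction repeats up to `top_n`
(default 20) times: break cycles by deleting the lightest edge of each
cycle, take the maximum-total-weight path (nodes plus edges) of the DAG
by dynamic programming, spell it, remove its nodes. This
iterated-heaviest-path rule is a declared interpretation of
confidence-weighted de Bruijn assembly — deterministic, and exact on
error-free tilings.

Contigs align to the reference by local Smith–Waterman (match +2,
mismatch −1, gap open −2, gap extend −1; Biopython's PairwiseAligner,
checked against an exhaustive DP oracle). A contig is *mapped* when its
aligned columns number ≥ k with ≥ 50% identity — a declared, config-
exposed stand-in for an aligner E-value. Coverage is the fraction of
reference positions spanned by mapped alignments; accuracy pools exact
per-column matches over all mapped contigs' aligned columns, counting
I↔L as a mismatch unless `--il-equivalent` is set; with no mapped contig
accuracy is undefined rather than zero.

## Numerical and degenerate-input conventions

All tolerances are strict inequalities on absolute differences.
Undefined ratios (precision with nothing emitted, noise factor with no
fragment peaks, accuracy with no mapped contig) are `None`/null, never
0, and are reported with their zero denominators. Ties in heaviest-path
extraction resolve by node insertion order; seeded runs are
bit-reproducible. Problem sizes used by the acceptance script — a
220-residue chain for the round-trip, 2000 spectra for the mixed-error
benchmark, 1000 spectra for annotation fidelity — are the package's
standard benchmark sizes and complete in seconds.

## Known limitations

The matcher inherits the field's mass-blindness (I/L, Q/K, GA/Q);
"accuracy" at the AA level is therefore an upper bound on symbol-level
accuracy. The error classifier's anchoring is greedy and can label
pathological multi-window corruptions as "other". Assembly has no
scaffolding, homology polishing or CDR annotation; heavy-chain-scale
references fragment into many contigs exactly as real data does.
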