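# Methods

This note documents the motif grammars and their resolution conventions,
the statistical procedures, the generative model of the synthetic-data
module, and the numerical and design choices that were genuinely open.

## Motif grammars and search criteria

All scanning operates on the DNA alphabet A/C/G/T/N; N never matches — it
breaks G-runs, arms, repeat units, spacers, loops and Z-DNA steps.
Coordinates are 0-based half-open throughout the library; GFF3 input is
converted at the boundary (1-based inclusive), BED output stays 0-based.

| class | grammar | defaults |
|---|---|---|
| G4 | ≥ `g4_min_runs` G-runs of ≥ `g4_min_run` G separated by loops of `g4_loop_min`–`g4_loop_max` nt | 4 runs of ≥3 G, loops 1–7 nt |
| cruciform | arm–spacer–arm, right arm = reverse complement of left | arm ≥6, spacer ≤3 |
| triplex | arm–spacer–arm, right arm = reverse of left, purine **or** pyrimidine fraction of the whole site ≥ `triplex_min_purity` | arm ≥10, spacer ≤8, purity ≥0.9 |
| slipped | unit–spacer–unit with identical units | unit ≥10, spacer ≤10 |
| Z-DNA | every adjacent dinucleotide step in `z_allowed_dinucleotides` | length ≥12, steps {GC, CG, GT, TG, AC, CA} |

The defaults follow the common non-B motif-database conventions and are
all configurable (`ScanParams`, or the `[scan]` section of an INI config).
"G-runs of at least three guanines" is the standard G3+N1–7 reading; a
stricter ≥4 is one parameter away.

**Maximality and overlap resolution.**  A scanner's candidate set is every
grammar-valid site (for G4: every substring admitting *some* decomposition
under the grammar, decided by dynamic programming over run-start
positions; loops may contain G).  Candidates are ranked by start
ascending, then span descending, then arm/unit length descending, then
spacer ascending, and selected greedily so that no two kept hits of one
(class, strand) overlap.  This leftmost-greedy, longest-first convention
is deterministic and is reproduced independently by the brute-force
oracles in the test-suite.  Degenerate inputs behave sensibly under it:
a homopolymer is never an inverted repeat, but genuinely is a mirror and a
direct repeat once long enough, and is reported as such.

**Strands.**  G4 is the only class scanned on both strands (the analysis
distinguishes template from non-template G4); the other four grammars are
reverse-complement symmetric and are scanned on the sense sequence only.
One caveat: while the candidate grammars are exactly strand-symmetric, the
greedy selection is not mirror-invariant in contrived cases where
same-class candidates overlap asymmetrically; for isolated sites (the
realistic regime, and everything the simulator plants) symmetry is exact.

**Cross-class exclusion.**  After within-class resolution, every hit that
shares ≥1 forward-coordinate position with a hit of a *different* class is
removed — both members of the pair, since the source procedure states only
that overlapped occurrences were excluded; removing a single member is
available as a switch (`scan_all(..., remove_both=False)`).

**Polypyrimidine tract.**  The 3′-most window of 20 nt, fully inside the
last 40 nt of an intron, with ≤5 purines.  N counts as a purine
(conservative), and when several windows qualify the most 3′ one is
reported, since the functional tract abuts the 3′ splice site.  Triplex
hits overlapping this tract are discarded before any counting, so that
pyrimidine-rich splice elements cannot masquerade as triplex signal.

## Exon models and profiles

Entries (transcript-level exon chains, GFF3 or BED12) are filtered in
order: exact-coordinate duplicates collapse to one; entries whose genomic
spans overlap another surviving entry are removed (both members,
strand-agnostic — the strictest reading, which avoids double counting);
entries with more than three exons are removed.  Every internal exon of a
retained entry yields one record; for the three-exon cassette entries that
is the middle exon.  Upstream/downstream is defined in transcription
orientation, and intron sequences are reverse-complemented as needed so
the scanners always see the sense (non-template) strand 5′→3′.  A G4 hit
on that sequence is therefore a non-template hit; a hit on its reverse
complement is a template hit.

The proximal window is the min(500, intron length) nt abutting the exon
(3′ end of the upstream intron, 5′ end of the downstream one); a hit is
counted as proximal when it overlaps the window by at least one base.  No
intron-length filter is applied beyond the windowing itself.

## Statistics

* **Background probability** = skipped / all exons with both flanking
  introns.
* **Partial correlation**: residual-on-residual Pearson *r* after
  regressing each of *x* and *y* on intron length (with intercept);
  *t = r√((n−3)/(1−r²))*, *p* from Student's t with *n − 3* df (one
  control variable).  The binary skipping indicator is used as-is
  (point-biserial flavour); no transformation is applied.  Zero residual
  variance raises a degenerate-statistic error rather than returning NaN.
* **Proportion test**: pooled-variance two-sample z without continuity
  correction, one-sided with alternative skipped > constitutive; its exact
  size at the scales used in the tests is 0.0500 at α = 0.05.
* **Logistic model**: Newton–Raphson (IRLS) via statsmodels with
  tolerance 1e-8 and ≤100 iterations; coefficients are unstandardized
  (per-unit change on the logit scale); Wald z = β̂/SE with normal
  p-values.  Perfect or quasi-separation (statsmodels exception,
  non-convergence, or non-finite standard errors) raises a diagnostic
  error instead of returning coefficients.  The design matrix has a fixed,
  documented 12-column order (lengths first, then per-region counts for
  cruciform, G4, slipped, triplex, Z-DNA); G4 strands are summed for the
  regression (a single G4 predictor per region) but kept separate in all
  stratified tables — `merge_g4_strands=False` gives the 14-column
  variant.
* **Multiple testing**: p-values are reported raw, mirroring the source
  convention of raw values with significance stars (* <0.01, ** <0.001,
  *** <0.0001); a Benjamini–Hochberg `q_value` column is appended to the
  report tables for information but never gates anything.

## Synthetic data: what it emulates, and what it does not

Each entry is a three-exon gene on its own contig (random orientation);
the middle exon is the analyzed one.  Intron lengths are log-normal with
median 1.5 kb and σ = 0.7, truncated to [200, 10000] nt — chosen for a
realistic heavy right tail; the truncation keeps scan time bounded.
Background sequence is i.i.d. at GC 0.42 (mammalian intron-like).  Motif
instances are planted at configurable Poisson rates per (class, region,
strand); the defaults (triplex 0.15, G4 0.10 per strand, slipped 0.08,
Z-DNA 0.05, cruciform 0.03 per intron) loosely mirror the observed
prevalence ordering of the five classes in real introns.

Instance construction is deliberately constrained so a planted site cannot
collide with another class's grammar: G4 loops and guards are pyrimidines
with ≤2 consecutive C (no accidental runs, inverted repeats or Z steps),
triplex arms/spacers are purines with ≤2 consecutive G, Z-DNA instances
are GT- or AC-alternating tracts of 12–19 nt (GC alternation is a perfect
inverted repeat; ≥20 nt of any dinucleotide repeat is a direct repeat),
and any instance block in which another class's scanner still fires is
re-drawn.  One or two guard bases flank each instance to stop the scanners
from extending a match beyond the planted coordinates.  After planting,
the whole intron is scanned; if any planted instance is not recovered at
its exact coordinates (class, strand and both ends), the intron is redrawn
— planted recall is therefore 100% by construction, and the redraw rate is
a few percent.  Accidental background occurrences *outside* the planted
sites are expected (about 1–2 inverted repeats per 1.5 kb at this GC) and
are kept, counted and reported in the truth table.

The skipping label is drawn from a logistic model over the realized
13-vector (intercept + the standard 12 design columns) of the emitted
intron content — planted plus accidental occurrences after the PPT and
cross-class filters, i.e. exactly the counts the pipeline will recompute —
optionally plus `g_run_effect` × (maximum upstream template-strand G-run).
Generating labels downstream of the realized counts makes the generative
model and the pipeline's measurement identical, so parameter-recovery
experiments test estimation rather than an errors-in-variables artefact.
The default coefficient vector is the null model whose intercept
reproduces a background skipping probability of 0.148.  With
`confound_intron_length` set, planting rates scale linearly with intron
length, so counts correlate with length and only a length-adjusted
analysis is calibrated — this is the switch the confounding-control
experiment uses, paired with a nonzero length coefficient (4e-4 per nt,
intercept −0.6, n = 1500 per replicate).  The experiment is sized so the
unadjusted test rejects at the 0.01 star convention with power ≈ 1, and
the intercept keeps the skipping probability near 0.5, where the Bernoulli
variance is flat in intron length: with a rarer outcome, the length-driven
heteroskedasticity of counts and outcome makes the partial-correlation
t approximation itself mildly anticonservative — a property of the test,
not of the implementation, and one that does not vanish with sample size.

What the simulator does **not** model: splice-site and branch-point
sequence, conservation structure, dinucleotide composition beyond GC,
transcript-level coupling between neighbouring entries, and any species
contrast beyond what region-specific rates/coefficients induce.  Passing
tests on synthetic data therefore demonstrate the correctness of the
scanners, the bookkeeping and the statistics — not that real introns obey
the generative model.

## Problem sizes used by the test-suite and acceptance script

The oracle-equivalence checks use 100 sequences of ≤300 nt per scanner
(about half carrying planted instances, so the comparisons exercise real
hits); planted-recall re-scans a 320-entry dataset with rates ×4 (≥1000
instances); calibration uses 20,000 proportion-test replicates and 400–500
logistic fits at n = 600; parameter recovery runs the full pipeline on
20,000 entries in the test-suite and 4,000 in `scripts/acceptance.py`; the
confounding experiment uses 100 (tests) or 60 (script) replicates of 1000
entries each.  These sizes keep each experiment's Monte-Carlo error small
relative to the bands it asserts.

## Known limitations

* Direct-repeat candidate enumeration is quadratic in the length of
  low-complexity runs (e.g. long microsatellites in user-supplied
  genomes); synthetic backgrounds are i.i.d. and unaffected.  No
  low-complexity masking is applied.
* The G4 grammar, like the standard G3+N1–7 pattern, accepts degenerate
  decompositions of very long pure-G tracts (a G15 run is formally a
  quadruplex); such tracts essentially never occur at realistic GC.
* Thermodynamic or structure-based scoring (G4Hunter-style scores, Z-hunt,
  folding energies, R-loop prediction) is out of scope: detection is
  purely grammatical, as is appropriate for reproducing a motif-count
  analysis.
* Partial correlation treats the binary outcome linearly; the logistic
  model is the principled complement and both are reported.
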