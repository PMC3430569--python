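# Methods

This note records the generative model, its parameters (units, defaults, and
rationale), what the synthetic data does and does not emulate, numerical
choices, and limitations. Nothing here claims empirical accuracy beyond what
the test suite actually computes.

## 1. References and fragment pool

`simulate.make_references` draws i.i.d. reference sequences at a target GC
(default 0.5): an endogenous "nuclear" contig, a circular mitochondrial
contig (default 16,660 bp), a decoy contig (for competitive filtering), and
several microbial contigs. Random references have no repeat structure, motif
bias, or real phylogenetic signal — they exist so that mapping, uniqueness,
and damage profiling have exact ground truth.

Each simulated molecule draws an **origin** from a mixture (default
endogenous nuclear 1%, mitochondrial 0.05%, decoy 1%, microbial 97.95% —
ancient-sample-like dominance of environmental DNA).

### Endogenous fragmentation

Strand breaks are modelled per phosphodiester bond. A bond 5′ of base *b*
cleaves with probability

  q · λ_dep  if *b* is a purine (the base is lost: depurination),
  q     otherwise (plain nick; no base lost),

with `base_nick_rate` q = 0.0073 and `depurination_odds` λ_dep = 4 (unitless
odds multiplier ≥ 1). Fragment length is therefore *emergent*: mean ≈
1/(q·E[weight]) ≈ 55 nt at defaults, matching the short-fragment regime.
The probability that the base 3′ of a break is a purine has the closed form
λf/(λf + (1−f)) for genome purine fraction f; the test suite inverts this to
recover λ_dep from simulated truth.

The 3′-end chemistry of each fragment depends on the break type:
depurination-type breaks are mostly blocked (`dep_end_chem`: 80% 3′-phosphate,
10% OH, 10% other-blocked; β-elimination at abasic sites leaves
phosphorylated/blocked termini), nick-type breaks are mostly clean
(`nick_end_chem`: 60% OH). The identity of the lost base is recorded as truth
for −2 composition analysis.

### Exogenous fragments

Microbial/decoy ("modern") molecules skip the bond model: geometric lengths
(mean 180 nt, min 30), no deamination, and mostly 3′-phosphate ends
(`exo_end_chem`: 82% phosphate, 8% OH). The high blocked fraction makes
phosphatase treatment raise *total* yield while *decreasing* the endogenous
percentage — the direction the real channel tallies show — because the
blocked exogenous majority gains more than the endogenous minority.

### Deamination

Each template C converts to T independently with probability

  min(1, p_base + p_end5·e^(−d5/λ) + p_end3·e^(−d3/λ))

where d5/d3 are distances (nt) to the 5′/3′ fragment ends, p_base = 0.01,
p_end5 = 0.20, p_end3 = 0.45, λ = 3 nt. Single-stranded 3′ overhang-like
excess at the 3′ terminus produces the read-frame G→A excess at read start
(the read's 5′ end is the template's 3′ end). Converted positions are stored
as truth (`deam_sites`), enabling exact parameter-recovery tests.

## 2. Template preparation

* **Denaturation**: each fragment survives (stays single-stranded and in
  solution) with probability logistic((T − Tm)/s), Tm = t0 + t_gc·GC −
  t_dam·deam_fraction + t_len·log10(L) (°C; t0 = 60, t_gc = 20, t_dam = 100,
  t_len = 8, s = 3). Short, damaged, AT-rich endogenous fragments melt at
  80 °C; long GC-balanced microbial fragments mostly need 95 °C. At 95 °C an
  extra per-bond nick rate (0.01) fragments molecules further, shortening
  reads — the trade-off that makes 80 °C preferable despite lower yield.
* **Phosphatase** (optional): 3′-phosphate → 3′-OH, idempotent; blocked
  non-phosphate ends stay blocked.
* **Poly-A tailing + capture**: only 3′-OH templates are tailed
  (Poisson-length tails, mean 90 nt); capture requires ≥ 25 nt of tail.
* **Fill-and-lock**: dTTP fills the tail *and* any genomic 3′ A-run; the lock
  engages at the first non-A template base scanning 3′→5′ (success
  probability 0.90 for G — the terminating nucleotide preference — and 0.55
  otherwise, giving the −1 G enrichment); sequencing starts at the next
  base. With probability 0.05 the fill stalls early, leaving ≥ 2 template
  A's unfilled that are then read as leading T's (the artifact the QC
  leading-T trim removes).
* **Reads**: reverse complement of the template from the lock site, with
  per-base substitution 0.005, deletion 0.03, insertion 0.015 (deletion-heavy,
  as in flow-based single-molecule chemistry), length capped by a normal
  draw (mean 33 nt, cap 60). Channels can add flow-artifact reads (bases
  tracking the CTAG flow order) and spike-oligo reads (default 85% of a
  spiked channel, 2% of them chimeric).

Truth labels (`origin`, −1/−2 context bases, deamination sites, error
counts) ride along on every read.

## 3. Read QC

Order: leading-T trim → minimum length (25 nt) → flow-artifact filter →
spike removal. The flow-artifact score is flows-per-base minimized over
starting phases in the flow order (periodic reads score 1.0, random ≈ 2.5;
threshold 1.25). Spike detection aligns read vs oligo (and reverse
complement) with edlib in semi-global mode and removes reads with normalized
identity ≥ 0.64 (0.8 identity × 0.8 coverage). Accounting is exact:
surviving = input − short − artifact − spike.

## 4. Mapping

Glocal alignment: global in the read, local in the reference (terminal
reference gaps free), match +1, mismatch −2, linear gap −2; no soft
clipping, since terminal damage must stay in the alignment. Candidate
windows come from a 12-mer index (diagonal binning); references ≤ 600 bp are
scanned exhaustively; circular references are end-padded and positions
normalized. The row-wise DP is vectorized with a running-maximum trick for
the linear-gap horizontal chains. Score ties at multiple end columns are
enumerated for uniqueness detection and resolved toward the *highest* end
column so a 3′-terminal mismatch is reported as a mismatch, not traded for a
read gap. MAPQ = min(60, 2·(best − max(second, 0))); "unique" requires a
strictly best placement. Competitive filtering drops reads whose decoy
alignment scores ≥ 0.9 of the target score. SAM I/O uses pysam with =/X
CIGAR operators.

## 5. Damage profiling

Misincorporation tables count the 12 substitution types plus indels by
1-based read position from either end, with per-base opportunities from the
reference; minus-strand events are complemented into the read frame.
Cumulative G→A over positions 1..k is the running sum of per-position
frequencies. Composition context tallies the read +1 base and the reference
−1/−2 bases upstream of the read start (read-strand orientation): −1 records
the lock preference (G excess), −2 the lost base at depurination breaks
(purine excess).

## 6. Channel statistics

A packaged TSV fixture carries per-channel read/bp tallies (nuclear and
mitochondrial) from published tSMS runs of two Pleistocene horse-bone
extracts. From raw counts the package recomputes endogenous percentages
(mitochondrial reads included), phosphatase fold changes (pairs whose read
enrichment < 2 are flagged as failed channels and excluded from enrichment
ranges, not from ratio-decrease summaries), megabase totals, and
mitochondrial coverage.

**Spiking expectation**: Rmin = Σ wᵢRᵢ over unspiked channels with
Rᵢ = nuclear reads / total reads and wᵢ ∝ pooled volume / loaded volume;
expected endogenous reads in the spiked channel are the 5%/95% quantiles of
Binomial(n_spiked, Rmin). The binomial quantile ("smallest k with
CDF ≥ q") uses exact integer arithmetic for n ≤ 5000 — floats are dyadic
rationals, so ties such as CDF(166; 333, ½) = ½ are decided exactly — and
`scipy.stats.binom.ppf` above that.

**Consensus**: pileup of M/X columns (indels ignored); depth-2 sites are
called only when both bases agree (expected concordance (1−e)² + e²/3 for
uniform errors e); depth ≥ 3 sites need a strict majority.

## 7. Seeding and reproducibility

One scenario seed fans out through `numpy.random.SeedSequence.spawn` to
per-stage, per-channel streams, so each stage is independently rerunnable and
a rerun with the same seed is byte-identical (tested on the summary JSON).
Every run records a SHA-256 hash of its full configuration.

## What the simulator does not emulate

* Real genome composition: references are i.i.d.; no repeats, CpG effects,
  or true mitochondrial/nuclear homology.
* Double-stranded molecules: templates are single strands; strand pairing,
  overhang structure, and nick translation are abstracted into the per-end
  deamination asymmetry.
* Optics and image registration: spiked channels need a spike *fraction*,
  but focus, registration failure, and per-field variation are not modelled.
* Quality scores: FASTQ qualities are constant placeholders.
* The melting model is a phenomenological logistic, not thermodynamics
  (nearest-neighbour ΔG is out of scope); its parameters were chosen to
  separate short damaged fragments from long undamaged ones at 80 °C.

## Limitations

* Fold-change magnitudes from simulation depend on the assumed end-chemistry
  mixtures; only directions (more reads, lower endogenous %, shorter reads at
  95 °C, weaker G→A after re-digestion) are asserted by tests.
* The mapper is exact but O(read × window) per candidate; it is built for
  simulated genomes of ~10⁵–10⁶ bp, not production-scale references.
* Consensus handles substitutions only; indel consensus is out of scope.
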