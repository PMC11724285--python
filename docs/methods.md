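# Methods

## The sensor model

ADAR enzymes deaminate adenosine to inosine in double-stranded RNA; the
cell reads inosine as guanosine. A hairpin transcript carrying an in-frame
UAG stop codon opposite a CCA triplet presents the A-C mismatch context
ADAR prefers: editing rewrites UAG to UIG (read UGG, tryptophan) and
translation runs through into a downstream reporter. The deaminase domain
contacts roughly 20 bp of duplex around the editing site, so the sensor
logic is geometric: whatever controls formation of that duplex controls
editing.

The package models the hairpin as two helices flanking the mismatch:

```
5'-[domain a]-C C A-[b*]-[loop]
              |   |   |||
3'-[domain a*]-G A U-[b ]------'
```

`len_a` counts the a-side base pairs *including* the G:C closure between
the UAG's G and the CCA's first C; `len_b` counts the b-side pairs
including the U:A pair. A substrate therefore holds `len_a + len_b`
Watson-Crick pairs spanning `len_a + len_b + 1` positions with the central
mismatch. The defaults, 10 and 12 bp, are the editing-optimal geometry; the
7 + 9 bp variant is the minimal model substrate. Under this convention the
`domain_a`/`domain_a*` sequence features carry `len_a - 1` bases (the
closure base pair lives in the triplets); an alternative bookkeeping that
puts the closures outside `len_a`/`len_b` would make the same molecule but
break the printed 16-pair / 23-span arithmetic, so it is not used.

Sensing variants all disable and conditionally restore that duplex:

* **RNA sensor** — domain a collapses to a single junction cytosine and
  domain a* becomes a 39-nt sensing arm, the exact reverse complement of a
  target window. Hybridisation rebuilds the duplex: arm:target pairs, the
  junction C pairing the target base 3' of the window, and the
  intramolecular CCA:UAG closures. The engineered mismatch never sits in
  the arm. The junction-pairing target base is *excluded* from the 39-nt
  arm count (arm + 1 junction base), one of two defensible readings of the
  arm-length convention.
* **SNV sensor** — the arm complements the *variant* window, so the arm
  base abutting the UAG's G (the discriminator) is the complement of the
  alternate allele. The variant transcript leaves only the central A-C
  mismatch; the wild type adds a second mismatch next to the editing site,
  which suppresses editing. Wobble (G:U) apposition is counted as a
  mismatch here: discrimination is scored on strict Watson-Crick identity,
  the conservative choice for a yes/no sensor. Insertions and deletions
  are deliberately not sensed.
* **Aptamer sensor** — layout
  `[a]-[CCA]-[b*]-[loop]-[b]-[blocker]-[UAG]-[aptamer]-[a*]`, blocker =
  reverse complement of a window of the aptamer (18 nt by default). In the
  OFF state the blocker:aptamer stem forms and, because the UAG sits
  *between* blocker and aptamer in sequence, every stem pair encloses the
  UAG: any UAG:CCA pair would cross the stem and is topologically
  forbidden in a nested fold. Ligand binding releases the blocker and the
  editable duplex re-forms. Spacer lengths 0-4 nt are searched in
  increasing order and the first layout passing the two-state check is
  returned.

## Folding and verification

Structure checks use a weighted Nussinov maximum-pairing dynamic programme
(GC = 3, AU = 2, GU = 1; wobble only on RNA; minimum loop 3) with
forced-unpaired constraints — deliberately not a thermodynamic model. It
is exactly reproducible, oracle-verifiable by exhaustive enumeration, and
sufficient for presence/absence pairing questions. Consequences of that
choice are handled explicitly:

* **Traceback ties.** Scanning a region, the last position pairs with the
  outermost admissible partner achieving the optimum (helix continuation),
  else stays unpaired. Score-equivalent relabelings of the active-state
  multiloop exist (the junction cytosine and the CCA cytosines can swap G
  partners at equal score), so intended-pair verification is a threshold
  test — a design passes when at least 90% of its intended Watson-Crick
  pairs appear in the optimal fold — rather than a demand for one exact
  labeling. Plain substrate helices recover 1.0; active sensing states
  typically recover ~0.96.
* **Two-state ON proxy.** Ligand occupancy is modelled by forcing the
  whole aptamer **and blocker** unpaired, then requiring all intended b:b*
  and UAG:CCA-region pairs in the constrained optimum. Forcing only the
  aptamer looks more literal but is unusable under pair-count scoring: the
  released single-stranded blocker trades the intended duplex for isolated
  lone pairs that carry no entropic cost in this model, a fold no
  thermodynamic treatment would favour. The OFF check (unconstrained
  optimum must contain no UAG:CCA pair) is unchanged and is the
  discriminating half: it fails whenever the blocker cannot cage the UAG.
* Active-state folds concatenate sensor and target window through a 10-nt
  forced-unpaired linker; target coordinates are reported in window space.

## Site scanning

Candidate windows must be ambiguity-free, give an arm with no in-frame
stop codon under the cassette frame, and offer a junction base that pairs
the retained sensor cytosine (in `cca_source="target"` mode this becomes:
the target itself presents the full CCA triplet 3' of the window). The
published workflow chose among 3-5 sites empirically, so the ranking here
is an explicit heuristic, not a fitted model: context tier x 10, minus one
per duplex adenosine (each is a potential bystander edit), plus 0.5 per
G/C in the 6 window bases nearest the junction nick (hybridisation
stability where discrimination happens). Ties break toward fewer
adenosines, then the 5'-most window.

## Reporter cassette

Element order BFP-P2A-linker-sensor-GFP (configurable): BFP precedes the
sensor so its expression is edit-independent and normalises transfection
dose; GFP is gated by the sensor UAG. The insert is padded with 0-2 bases
per side (C preferred, then G — cytosine cannot start a stop codon) so its
length is 0 mod 3 and the UAG is codon-aligned. The assembly audit demands
exactly one in-frame stop before the GFP terminator pre-edit and none
post-edit. Shipped BFP/GFP flanks are deterministic seeded surrogate ORFs
(40 codons) — the cassette logic depends only on frame and stop content,
not on fluorophore identity — and real ORFs can be supplied for export.
The P2A and 2xGGGGS linker are real coding sequences. The MS2 tether
default is a synthetic 21-nt stem-loop built without uridine so it can
never introduce a stop in any frame; the phage hairpin can be supplied
instead. Stem fillers are drawn from a seeded generator rejecting
homopolymers > 3 nt and stop triplets in any frame on either strand, with
a deterministic retry loop against boundary-codon stops, so every design
is a pure function of its parameters and seed.

The shipped ATP aptamer is the canonical 40-nt ATP-binding RNA aptamer.
The NF-kB aptamer default is a synthetic 29-mer surrogate (the published
29-nt aptamer, Kd ~5 nM, is not reproduced here); both defaults are
user-overridable, and blocker windows were chosen so the blocker is
stop-free.

## Editing quantification

The amplicon chain mirrors standard practice at desk scale: end-trimming
below Q20 and discarding reads over 10% N; merging mates via the
maximal-identity overlap (>= 10 nt, >= 90% identity, disagreements to the
higher-quality base); fit alignment of each merged read into the amplicon
(match +2 / mismatch -3 / gap open -5 / extend -2, reference end gaps
free, better-scoring strand, exact-substring fast path) via Biopython's
pairwise aligner; then a pileup. For every reference adenosine,
`edit_pct = 100 G/(A+G)` where `A+G >= 50` (min depth), with non-central
positions flagged as bystanders above 2% — the ceiling a well-behaved
sensor duplex should respect. Edits are counted on the reference sense
strand only; reverse-strand reads are reverse-complemented by the aligner
before counting. The upstream tools it stands in for (adapter trimmers,
mergers, genome aligners, editing callers) do not publish one canonical
parameter set, so these defaults are documented as this package's own.

## Synthetic data and what passing means

Generators are pure functions of (config, seed) and every output carries a
truth table of realised ground truth; downstream checks compare against
the truth table, never against re-simulation. Reads: each simulated
molecule flips each programmed site A->G independently, both mates observe
the same molecule, substitution errors at 0.1%, constant Q36 with 2% of
positions at Q12 to exercise trimming, paired 150-bp reads with small
start jitter over a ~240-nt amplicon. Flow events: lognormal channels with
per-cell BFP-GFP coupling, a programmed activation factor, an
untransfected fraction with autofluorescent-level BFP, plus dead-cell and
doublet fractions to exercise the scatter gates. Not emulated: PCR
duplicates and chimeras, quality-by-cycle decay, indel errors, spectral
spillover, instrument drift. Passing tests therefore certify estimator
logic and calibration under clean generative conditions, not robustness
to every artefact of real instruments.

Study-scale defaults are fixed once: depth 2000 and 60% conversion for
editing recovery (the reported conversion rate for the sensor plus
exogenous RNA), 10,000 events and activation 100 for flow recovery,
20-seed repetitions for calibration properties. Recovery tolerances are 3
binomial sigma for a single editing run, < 1 percentage point mean
absolute error over seeds, and +/-10% for fold activation.

## Flow analysis

Gates follow live (FSC/SSC rectangle) -> singlet (SSC area/height ratio
band) -> BFP-positive, with thresholds derived as quantiles of a
vector-only control table (fixed numeric thresholds available). The
normalised intensity is the per-cell GFP/BFP ratio summarised by the
median — robust to lognormal tails — with the population mean available
because the underlying protocol does not state which was used; fold
activation is the plus/minus ratio of summaries and is invariant to any
common multiplicative calibration of the GFP channel.

## Known limitations

* Pair-count folding cannot rank near-isoenergetic structures; all
  structural conclusions are presence/absence of intended pairs, not
  stability estimates, and no pseudoknots or ΔG values are produced.
* Absolute editing efficiency and fold activation are wet-lab quantities;
  nothing here predicts them from sequence.
* The scanner works on the given strand of a mature transcript and does
  not model RNA accessibility or expression level.
* Alignment assumes an amplicon (<= 2000 nt) reference; this is not a
  genome-scale aligner, and indels are handled but not called as variants.
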