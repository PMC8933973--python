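# Methods

## Model and procedure

`pepcover` treats family-level targeted proteomics as a set-cover problem
over tryptic peptides. For one target CAZyme family the community is split
into target proteins *T* and a background *B* (everything else, including
unannotated proteins and all other families — uniqueness must hold against
the *whole* community, or a measured transition could come from an
unrelated protein). The target peptidome is built under assay-realistic
constraints; the background peptidome deliberately is not.

**Consensus annotation.** A protein is a CAZyme when at least two of the
three dbCAN2 search tools report a family. HMMER labels win outright
(HMM domain models are the most specific evidence); when HMMER is silent
the exact-label intersection of DIAMOND and Hotpep is used, and an empty
intersection discards the protein. The intersection is taken on raw labels
(subfamily suffixes intact); collapsing to the family happens only at
targeting and census time, which keeps the rule independent of row order
and of how a subfamily happens to be written. Subfamily collapse for
targeting (GH13_20 → GH13) reflects that assays are designed per family,
not per subfamily.

**Target peptidome.**

- *100 % clustering*: exact duplicates and sequences contained in a longer
  retained sequence are removed (the behavior of CD-HIT at `-c 1.0`, which
  discards partial or fragmented gene calls). The longest sequence
  represents a cluster; ties go to the lexicographically smallest protein
  id. Implementation: sequences sorted by decreasing length, containment
  tested against a NUL-separated concatenation of retained sequences —
  O(total length) per query via the C substring search, ample for
  community-scale inputs.
- *N-terminal trim*: the first 24 residues are dropped as a positional
  surrogate for signal-peptide cleavage — secreted hydrolases lose their
  signal peptide during maturation, so peptides from that region would
  never be observed. No predictor is run; 24 residues is used for every
  seed. Seeds of ≤ 24 residues contribute nothing.
- *Digestion*: cleave C-terminal to K or R unless the next residue is P;
  zero missed cleavages. The concatenation of the output equals the input
  (checked as a property test), and digestion is idempotent on its own
  output.
- *Filter*: keep peptides of 6–25 residues composed solely of the 20
  canonical amino acids and free of Met and Cys (both prone to artifactual
  modification in MS workflows). Peptides containing ambiguity codes
  (X/B/Z/U) are dropped — an unresolved residue makes the peptide's mass
  undefined, so it cannot be targeted.

**Background peptidome.** Digestion only: no clustering, no trim, no
filter. Any exact tryptic peptide the background can produce disqualifies
a candidate, which makes uniqueness strictly harder and therefore
conservative; a deduplicated background would change nothing because
uniqueness is a set-membership test.

**Uniqueness** is an exact string comparison between tryptic peptides. An
optional I = L equivalence mode folds Leu onto Ile before comparison
(isobaric residues are indistinguishable by MS); it is off by default so
results are exact sequence statements, and it must be applied to both sides
at once.

**Greedy minimum cover.** Each round selects the peptide whose current
protein set is largest, removes those proteins from every remaining
peptide's set, and drops emptied peptides. Ties are broken by the
lexicographically smallest peptide string, which makes the output a pure
function of the peptidome (order invariance is property-tested). Target
proteins with no unique peptide are reported in a residual list rather
than silently dropped. Greedy is the right tool here: minimum set cover is
NP-hard, greedy achieves the classical ln(n) approximation, and on the
random instances the test suite draws, the greedy size exceeds the
exhaustive optimum by < 1 % on average. An exhaustive search
(`brute_force_min_cover`, bitmask subsets, refused above 15 peptides)
exists purely as a test oracle.

**Analytics.** Coverage at cutoff *k* = (covered proteins in the first *k*
groups) / (total target seeds) × 100; the denominator is the seed count, so
the curve speaks about the non-redundant family population. EC groups key
each peptide by the set of distinct EC numbers of its covered proteins
(unannotated proteins contribute "N/A"), reproducing composite
substrate-specificity categories when one peptide spans proteins of
different activities. Phylum composition counts covered proteins per
phylum; `peptides_to_cover_taxon` defaults to the ranked-prefix convention
(how far down the family-wide list an assay must go), with a
`greedy-subset` mode giving the smaller count a phylum-focused design would
need — both exist because the family-wide list is taxa-agnostic and shares
peptides across phyla.

## Synthetic communities

The generator emulates the one property the method exploits: family
members share conserved sequence blocks against a non-family background.

- Random protein sequences are drawn from approximate natural amino-acid
  frequencies (K+R ≈ 11 %), so mean tryptic peptide length is ≈ 9 residues
  and the 6–25 filter passes a realistic fraction.
- Planted blocks are 8–14 residues from an alphabet excluding K/R/P/M/C,
  terminated by K or R, and inserted as `R<block>A` at a uniformly random
  position past residue 24. The guard R forces cleavage before the block,
  the trailing A forces cleavage after it, and the position bound keeps the
  block clear of the N-terminal trim — so every planted block is released
  intact and passes the filter by construction (asserted in the tests).
- Defaults describe the recovery study condition: 50 MAGs over three phyla
  (Firmicutes 0.5 / Bacteroidetes 0.3 / Proteobacteria 0.2), three GH
  families of 20 members each with one planted block, 30–60 background
  proteins per MAG of 120–400 residues. `decoy_rate` copies planted blocks
  into background proteins to destroy uniqueness in a controlled way;
  `single_tool_fraction` annotates members via one tool only to exercise
  the consensus discard; ~5 % of background proteins get non-target CAZyme
  annotations so the census and the other-family background are non-empty.
  With several blocks per family, each member carries each block with
  probability `block_share` (0.6, at least one), giving the greedy cover
  partial-coverage structure.
- All randomness flows from a single `random.Random(seed)`; identical specs
  produce byte-identical file trees.

What the generator does **not** emulate: phylogenetic sequence evolution
(family members share exact blocks, not homologous-but-diverged ones),
assembly artifacts, chimeric MAGs, or realistic domain architecture.
Passing tests therefore demonstrate the pipeline's logic — consensus,
digestion, uniqueness, cover — not the empirical peptide yields of any real
community, which depend on how conserved real families are at the exact
tryptic-peptide level.

## Numerical and design choices

- Problem sizes: the oracle suites use 1000 random sequences (digestion)
  and 500 random instances of ≤ 12 peptides × 15 proteins (cover), sizes at
  which exhaustive search is exact and fast; the recovery study uses the
  50-MAG default community (~2300 proteins). These run in seconds.
- Ties everywhere resolve lexicographically (peptides) or by smallest id
  (cluster representatives) — determinism is a requirement, the specific
  order is not.
- Degenerate inputs: empty FASTA → empty list; a family with no members →
  explicit error; every seed shorter than the trim → explicit
  empty-peptidome error; an empty *unique* set is a reportable outcome
  (exit code 3 in the CLI), not a crash.
- `FamilySpec` accepts either a per-family member total (`n_members`,
  matching how study conditions are usually stated) or a per-MAG range
  (`members_per_mag`); exactly one must be given.

## Known limitations

- Uniqueness is exact-string only; near-isobaric peptides other than I/L
  are not considered, and no retention-time or detectability model is
  applied — the output is a candidate panel, not a finished acquisition
  method.
- The greedy cover optimizes protein counts only; it does not prefer
  peptides from catalytic domains or any other biological prior.
- Census class proportions count multi-class proteins once per class, so
  classes are not mutually exclusive events; the vector is a composition of
  annotations, not of proteins.
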