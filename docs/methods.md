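# Methods

## Cut geometry and site finding

Each enzyme is stored as an IUPAC recognition motif plus two integer
offsets, `cut_top` and `cut_bottom`, measured in bases from the first motif
position on the top strand.  `cut_top < cut_bottom` encodes a 5′ overhang
(the single-stranded extension is `motif[cut_top:cut_bottom]`),
`cut_top > cut_bottom` a 3′ overhang, equality a blunt cut.  The bundled
registry's offsets were cross-checked against the REBASE-derived catalogue
in Biopython's `Bio.Restriction` (the test suite repeats this check), and
buffer activities, incubation temperatures and methylation-sensitivity
flags are stored as data only — digestion kinetics, star activity and
methylation blocking are not modelled.

Site positions are reported 1-based at the first motif base on the top
strand.  This convention is calibrated against the bundled vector template,
which carries its XbaI site at 423 and EcoRI site at 396.  Circular
topology is handled by extending the scan window by `motif_length − 1`
wrapped bases, so origin-spanning sites are found; positions remain within
`1..length`.  Concrete (ACGT) sequences are scanned with an overlapping
regular-expression pass; sequences containing degenerate codes fall back to
a subset-aware IUPAC matcher in which `N` in an adapter slot matches any
motif position.

Digestion splits the top strand at top-strand cut coordinates, so
concatenating fragment top strands reconstructs the input exactly (each
overhang counted once); a linear molecule with *k* cuts yields *k* + 1
fragments, a circular one *k*.  Cohesive-end compatibility is evaluated on
the *resolved* bases of the actual fragment (relevant for DdeI's `TNA` and
ApoI/BstYI's `R/Y` overhangs), not on the degenerate motif.  Cuts from
distinct sites whose cut intervals intersect raise an error rather than
guessing an order.

## Bundled reference data and synthetic stand-ins

Three bundled tables carry `_synthetic` in their names because they are
constructed stand-ins for reference material that is not redistributable
here:

- `puc19_synthetic.fasta` — a 2,686 bp circular sequence with the cloning
  vector's published landmarks planted at their printed coordinates
  (`GAATTC` at 396, `TCTAGA` at 423, the 215F/774R primer annealing sites),
  and no other Design-1 recognition sites.  Coordinate-dependent results
  (site positions, the 27 bp EcoRI–XbaI spacer, amplicon fragment lengths
  182/27/351) therefore reproduce exactly; the background sequence is
  random 50% GC DNA.
- `index_tags_synthetic.csv` — the universal in-line index sets.  The
  printed tags are kept verbatim at their printed versions (R1 A–D, R2
  1–4); remaining versions are generated once under the published
  constraints: lengths cycling 6/7/8/9 nt, minimum pairwise Levenshtein
  distance 3 within each set, prefix-freeness, and no ≥5 bp in-set
  recognition site in any assembled adapter.  The universal R2 tag #5 is
  deliberately chosen to re-create the BamHI site inside the Design-2
  adapter, and a per-design override table substitutes a safe tag for
  Design 2 — reproducing, mechanically, the one published index exception.
  9-nt tags are admitted with a warning flag rather than rejected.
- `itru_primers_synthetic.csv` — a small plate of 8 i5 + 8 i7 external
  8-nt indexes (pairwise distance ≥ 3).  Multiplexing capacities are always
  computed from counts given as arguments, so the published 384-primer
  figures do not depend on this file.

Adapter oligo strings are templates with an index slot: the Read-1 top
strand carries the tag as sequenced and its phosphorylated bottom partner
the reverse complement; Read-2 is mirrored, with the functional bottom
strand carrying the tag and the truncated dummy top strand ending in five
lowercase, non-complementary bases.  Validation checks motif collisions
only for recognition sites of ≥5 bp from the design's own enzyme sets:
4-bp motifs occur once per ~256 bp by chance and cannot be excluded from
30–45-nt oligos, and the single published collision (BamHI) is a 6-cutter.

## Ligation–digestion cycling model

The simulation represents molecules as chains of parts (genomic fragments,
adapter stubs) joined at recorded junctions.  Per ligation phase, two
random pairwise matching passes run (so an insert can acquire both adapters
within one temperature cycle): each molecule contacts at most one partner,
found through an overhang-indexed lookup, and joins with probability
`ligation_efficiency`.  Ends can ligate when their polarities match, their
single-stranded extensions are reverse-complementary after IUPAC
resolution, and at least one side carries a 5′ phosphate — which is why
unphosphorylated Read-2 adapters never self-ligate.  Per digestion phase,
every junction whose local duplex re-creates a recognition site of an
active enzyme is cleaved independently with probability
`recut_probability`, restoring the original parts.  Cycling runs
`n_ligation_digestion_cycles` times (default 2) and always ends on a
digestion phase.

Key emergent behaviours, rather than coded rules: Read-1 adapter dimers
re-create the blocking enzyme's site at the seam and are cleaved; a
blocking-enzyme-cut genomic fragment ligated to a Read-1 adapter re-creates
the site and is preferentially re-cleaved; re-ligation of two fragments cut
by the same enzyme re-creates that enzyme's site; an adapter joined to a
*primary*-enzyme fragment does **not** re-create any site (the adapter
deliberately lacks the completing bases) and is stable.

Deliberate simplifications: no ligation kinetics (a single per-contact
efficiency), no circularization or inverted head-to-head genomic joins,
chimera formation only between compatible cohesive ends, and blunt-end
joining not modelled.  `recut_probability` stands in for the unknown
effective concentration/activity of the third enzyme; its default (0.75)
leaves a minority of blocking-site products intact after the final
digestion, qualitatively matching the observation that third-enzyme loci
persist in real libraries.  Tests of ratio recovery set it to 0 so the
planted third-enzyme fraction passes through unchanged.

## Library molecules, size selection and reads

Amplifiable constructs are exactly those of class `desired` or
`third_site_locus` with a complete bottom strand: only the bottom strand
carries full-length adapter sequence on both ends, so everything else drops
out during PCR.  One library molecule is made per amplifiable construct;
copy-number effects are introduced at read sampling instead (each molecule
yields `depth` identical clusters, its PCR-duplicate group), because no
cycle-level amplification-bias model is warranted by available data.  In
`umi_mode` the i5 slot receives a fresh random 8-mer per template molecule.

Molecule length is the exact strand length of the assembled construct:
flow-cell grafting sequences (29 + 24 nt), two 8-nt external indexes, the
fixed stub regions, both in-line tags, and the insert; for Design 1 with
6-nt tags the constant flanks total 154 nt.  Size selection keeps molecules
with `total_length` inside the inclusive window `center·(1 ± tol)`,
default 550 bp ± 10% → [495, 605].

Reads are literal substrings of the assembled top/bottom strands: R1 =
in-line tag + remnant + insert, R2 = mirrored from the other end, I1 = i7,
I2 = i5 or the 8N tag.  The cut-site remnant is derived by junction
arithmetic — adapter suffix after the tag, then the genomic bases past the
enzyme's cut (`GCTAGA` for XbaI, `GCTAGC` for NheI, `TAATTC` on the EcoRI
side in Design 1).  Errors are uniform substitutions at `error_rate` on all
four reads; no indels and no quality decay (constant Phred 40).  All
randomness flows from one seed; identical configurations produce
byte-identical FASTQ output.

## Synthetic templates

`make_synthetic_genome` produces random DNA of configurable length and GC
with recognition sites planted at recorded positions; chance occurrences
elsewhere are reported, not scrubbed.  The plate simulator instead builds
cassette templates — (first-or-blocking site, ~380–430 bp spacer, second
site) separated by 1.5 kb fillers — and *does* scrub chance sites outside
the planted spans, so the planted locus count and third-enzyme fraction are
exact ground truth.  Each cassette is a third-enzyme locus independently
with probability `third_fraction` (default 0.2).  Insert lengths are drawn
so every cassette molecule falls inside the default size window, while
filler-derived fragments (~1.6 kb molecules) are excluded by size
selection; this gives a clean, countable truth table.  What this generator
does **not** emulate: repetitive elements, site-density inhomogeneity,
allelic length variation, GC-coverage bias and index-dependent enzyme
efficiency — so passing round-trip tests demonstrate the correctness of
the molecular bookkeeping and the demultiplexer, not performance on real
genomic libraries.

Default problem sizes — 48–60 planted loci per well, a 20-fold adapter
excess over fragments, sequencing depth 3–8 — were chosen so a full
96-well simulation yields at least ~100 reads per sample with stable
statistics; at these sizes a plate simulates in well under a minute.

## Demultiplexing

Assignment is outside-in: external 8-nt indexes (Hamming distance,
tolerance 0–2, unique-nearest or unassigned) resolve the plate, then
in-line tags resolve the well.  Variable-length tags are resolved by
anchoring: a candidate tag matches only if the expected remnant follows
immediately after it (tag region within `internal_mismatch_tol`, remnant
per mode), which disambiguates prefix-sharing tags.  Any ambiguity —
ties on external indexes, multiple consistent wells — yields *unassigned*
with a reason, never an arbitrary choice; with distance-3 codes a tie
implies at least two errors.

Remnant modes mirror two-pass cut-site workflows: `exact` accepts only the
intended remnant; `rescue1` additionally rescues one mismatch to the
intended remnant, but classifies as third-enzyme only on an *exact* third
remnant, so sequencing errors can push reads to unassigned yet cannot
inflate the third-enzyme fraction (a deliberate conservative bias — single
errors inside true third remnants are lost); `disabled` performs no remnant
gating and flags third-enzyme reads by exact match for statistics only.
The third-enzyme proportion is reported as third / (intended + third) per
sample, pooled, with across-sample mean and SD.

PCR duplicates are collapsed on the key (8N tag, first 30 bases of R1,
first 30 bases of R2); the first read of each key is kept.  The 30-base
prefix default makes tag collisions between distinct molecules harmless
while tolerating indels beyond the prefix.  Normalized coverage is
approximated as mean reads per distinct post-trim R1 30-mer divided by the
sample's retained reads.

## Numerical and interface choices

- Levenshtein distances are computed with `edlib`; a quadratic
  dynamic-programming oracle verifies them in the tests.  Hamming distance
  is used for fixed-length external indexes.
- The locus-count expectation uses an independent-bases model: per-position
  cut probabilities from GC-weighted motif probabilities, geometric
  inter-cut distances, a factor 2 for the two end orderings of a
  Read-1/Read-2 fragment; it agrees with Monte-Carlo digestion within
  sampling error and is linear in genome length.
- The blunt Read-2 registry entry is recorded verbatim from its source with
  a warning flag (it is likely a transcription error for a sticky-end
  cutter); having no cohesive end, it is excluded from combination
  enumeration, which then yields exactly 72 combinations (9 Read-1 primary
  cutters × 8 sticky Read-2 cutters).
- Exit codes: 0 success, 1 validation failure, 2 usage error.  Every output
  directory receives a manifest (version, resolved configuration, input
  SHA-256 digests, seed, timestamp); reruns with identical manifest inputs
  reproduce data outputs byte-for-byte for the deterministic subcommands.

## Known limitations

Wet-lab quantities (yields, molarities, gel behaviour) are out of scope;
the ligation model is a matching process, not kinetics; coverage ratios
between intended and third-enzyme loci are configurable but not asserted
(no mechanistic model of index-dependent third-enzyme efficiency is
fitted); locus assembly, quality trimming and population-genetic analysis
are left to external tools.
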