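# Methods

This note records the models, conventions, numerical choices, and open
design decisions behind genodraw, and what the synthetic-data tests do
and do not demonstrate.

## Sequence model and coordinates

Internally every coordinate is 0-based half-open; GenBank's 1-based
inclusive convention exists only at the file boundary (conversion:
`start-1, end` on read, the inverse on write). Half-open arithmetic
makes scaling and ribbon geometry additive with no ±1 bookkeeping.
Compound (`join`) locations become multi-segment features; a location
wrapping the origin of a circular sequence arrives from the parser
already split at the origin, which is the only sensible linear
rendering. `source` features are dropped (they span the whole record
and carry no drawable information). Records whose sequence is not
materialized (CONTIG-only GenBank entries) are kept for feature
drawing but refused, with an explicit error, by the homology and GC
operations — partial functionality instead of a hard failure.

## Style cascade

A feature specification is (type scope, regex filter, qualifier field,
partial style, draw flag). Resolution starts from a fully-set default
style and folds the cascade in list order: each matching spec
overwrites exactly the properties it sets. "More specific overrides"
is therefore realized purely by list position — no CSS-like
specificity metric — which keeps the behaviour predictable and is how
the canonical transposase/IS431 example composes. Matching is
case-insensitive by default (annotation capitalization is inconsistent
across pipelines) with a per-spec `case_sensitive` override; field
`any` searches every qualifier value, notes included.

Two deliberate choices where the behaviour was open:

- a spec that sets no style property is allowed only if it hides its
  matches (`draw: false`); a spec that neither styles nor hides would
  silently do nothing, which is always a configuration mistake.
- *any* matching spec with `draw: false` hides the feature; the
  last-writer-wins rule applies to the eight style properties only.
- unmatched features are drawn with the defaults, controllable by the
  cascade-level `draw_unmatched` switch; both behaviours are useful
  and neither is obviously canonical.

## Homology

External searches call BLAST+ in two-sequence (`-subject`) mode with
tabular output: `blastn` with program defaults, `tblastx` with the
bacterial genetic code (NCBI translation table 11) for both sequences
and an e-value ceiling of 1e-3. Whatever the installed BLAST+ version
uses as blastn defaults (word size, dust filtering) is accepted as-is.

The builtin aligner is an exact-seed (default k=11, both strands),
ungapped, x-drop (default 20, match +1 / mismatch −2) local extender
with per-diagonal merging of overlapping extensions. It is ungapped by
design: it exists for offline use and for tests, where the fixtures
are substitution-only, so an ungapped model recovers every planted
region and its achieved identity exactly. Its e-value is reported as a
0.0 sentinel ("not estimated"), which trivially passes any
non-negative e-value threshold. With 10% substitutions the expected
score drift is +0.7/bp, so an x-drop of 20 essentially never
terminates inside a ≥90%-identity region, while in unrelated
background (expected −1.25/bp) extensions stop within ~16 bp; trimmed
to the best-scoring span, reported intervals may overshoot a planted
boundary by a few chance-matching bases, which is why recovery is
scored as interval coverage rather than exact-endpoint equality.

Hits are normalized to forward-strand intervals on both sequences plus
an `inverted` flag; the cache encodes inversion the BLAST way
(sstart > send). The cache is a directory with one 12-column tabular
file per (query, subject, program) key, so adding a custom pair or
tightening display thresholds never re-runs a search. Reciprocal
pairs are distinct entries — BLAST output is not symmetric. Adjacent
pairing excludes self-pairs; custom pairing allows them, since
self-comparison is a deliberate user choice.

## Layout

The bp→pixel scale is set by the longest *active* sequence spanning the
drawable width (canvas width minus two margins, default 1200 and 40
px); the same scale applies to every sequence. Best-hit positioning
chains each sequence to its predecessor in panel order: the anchor is
the surviving hit of maximal aligned length (ties: higher bitscore,
then smaller query start) and the anchor-interval *midpoints* are
aligned — midpoints, not starts, because midpoint alignment is
symmetric for inverted hits. A sequence with no hit to its
predecessor inherits the predecessor's offset; finally all offsets are
translated so the minimum is 0. Chaining to the predecessor (rather
than to one designated reference) is the adopted reading of "align the
largest shared region between two sequences"; no global multi-sequence
optimization is attempted. Sequences are never auto-reverse-
complemented — reverse-complement display is an explicit per-sequence
option. Canvas height is derived from content (sequences, spacing,
decoration bands); width is a configuration input, but the rendered
document grows rightward when offsets push content past it, since
clipping a figure is never the desired outcome.

## Decorations

GC content is (G+C)/(A+C+G+T) per window; GC-skew is (G−C)/(G+C),
zero where G+C is 0. Ambiguity codes are excluded from numerator and
denominator so N-runs in draft assemblies do not bias the profile; an
all-ambiguous window yields 0 and a gap flag. Windows advance by
`step` (constraint: step ≤ window); a trailing partial window is
included when at least half a window of sequence remains. Defaults of
window 1000 / step 100 are a conventional choice for multi-kb
prokaryotic regions, not derived from anything. Profiles are computed
on the *displayed* orientation so tracks line up with the drawing.
The GC track is filled between the curve and the profile-mean baseline
and is display-scaled to the observed value range (a fixed [0,1] axis
renders typical ±5% variation invisibly); skew uses the zero baseline
on the full [−1,1] range. Scale bars use a {1,2,5}×10^k tick interval
whose tick count is nearest the target, ties to the coarser interval.

## Rendering

The figure is a flat, ordered primitive list; order is z-order:
decoration tracks, then ribbons, then sequence lines, then feature
glyphs, labels, legend and scale — ribbons sit beneath annotations so
large homology blocks never obscure genes. Arrow heads are capped at
12 px and never exceed the glyph; glyphs under 1 px after scaling are
widened to 1 px so short features stay visible. Multi-segment
features draw one body per segment joined by a thin connector, with
the strand head only on the terminal segment. Inverted ribbons
default to the crossed-quadrilateral convention (self-explanatory
without a legend) with an optional distinct-colour mode. All colours
are normalized to lowercase hex and floats formatted by one fixed rule,
which makes the SVG serializer byte-deterministic for a fixed version
string; PNG is a rasterization of the same primitive list via the Agg
backend. No label anti-collision is attempted.

## Configuration

Projects and display configurations share one YAML schema
discriminated by a `kind` tag, so the two can never be confused
silently. Loading is strict — unknown keys are rejected with their
full key path — and sequence paths are stored relative to the project
file so projects survive directory moves. A display configuration
carries exactly the feature, homology, legend, and decoration groups,
with no paths and no record ids (decoration scopes are widened to
`all` on export); applying one replaces those groups and nothing else.
A format-version integer gates loading; older minor versions load with
defaults filled in.

## Synthetic data

The generator emulates the *structure* the engine consumes — annotated
features with realistic mobile-element vocabulary, shared regions of
controlled length/identity/orientation — not real genomes: background
is i.i.d. at the requested GC with no repeat structure unless planted,
and identity targets are realized by substitutions only (exactly
round(L·(1−t)) of them, each to a different base, so achieved identity
is within half a substitution of the target). Both choices keep the
ungapped aligner an exact oracle. Consequently, passing tests
demonstrate correctness of parsing, styling, search, geometry, and
serialization — they do not demonstrate alignment sensitivity on
gapped, repeat-rich, or low-identity real data, for which external
BLAST+ is the intended search engine. The demo set (three ~10 kb
records, one direct 2 kb region at 95% identity, one inverted 1.5 kb
region at 92%) and the acceptance sweep (20 pairs of 5–6 kb records
with one direct and one inverted planted region of 300–900 bp at
90–100% identity) are sized to exercise every code path while keeping
the whole suite and the acceptance script inside a few seconds on one
CPU. Generated GenBank files pin the LOCUS date so repeated runs are
byte-identical.

## Known limitations

- No gapped alignment in the builtin aligner; no protein-level or
  locally-collinear-block comparison.
- Chained (pairwise) best-hit positioning can drift over many
  sequences; there is no global offset optimization.
- No circular plots, no interactive output, no label anti-collision.
- EMBL input, protein sequences, and online accession fetching are out
  of scope; qualifier fields beyond gene/product/locus_tag/note are
  reachable only through `field: any`.
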