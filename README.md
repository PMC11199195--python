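# genodraw

Linear comparison figures for annotated prokaryotic sequences — a
headless library and CLI for people studying mobile genetic elements,
plasmids, and other genomic regions whose evolution shows up as changes
in gene synteny, content, and nucleotide composition.

Given one or more GenBank files (FASTA also works, without
annotations) and a declarative YAML project, genodraw draws every
sequence on one shared scale, one below the other, with:

- **regex-driven feature styling** — an ordered cascade of *feature
  specifications*; each selects features by type and by an unanchored
  regular-expression search over a qualifier field (`gene`, `product`,
  `locus_tag`, `note`, or `any`) and sets only the style properties it
  names. Later specs override earlier ones property by property, so a
  broad rule (`transposase|tnp[ABC]` in field `any` → fill pink) can be
  refined by a narrow one (`IS431` in field `product` → diagonal
  hatching) without restating the fill.
- **homology ribbons** — local-alignment hits between chosen sequence
  pairs (adjacent pairs by default, or an explicit "custom" pair list),
  from external BLAST+ (`blastn` with program defaults, or `tblastx`
  with translation table 11 and an e-value cutoff of 1e-3) or from a
  built-in exact-seed ungapped aligner that needs no external binary.
  Hits are cached in 12-column tabular BLAST format, filtered by
  length / identity / e-value, shaded on an identity colour ramp, and
  inverted hits are drawn as crossed polygons.
- **best-hit horizontal alignment** — each sequence can be shifted so
  the midpoint of its largest surviving hit against the sequence above
  it shares a vertical axis with the matching interval there.
- **decoration tracks** — sliding-window GC content
  ((G+C)/(A+C+G+T)) and GC-skew ((G−C)/(G+C)), and 1-2-5-interval
  scale bars, for all sequences or a subset.

Output is deterministic SVG (byte-identical for identical inputs) with
optional PNG rasterization. A synthetic-data generator produces
GenBank fixtures with planted features and planted shared regions of
known identity and orientation, so the whole pipeline is testable
offline.

## Worked example

```sh
genodraw fixtures demo --seed 1    # synthetic GenBank files + project
genodraw render demo/demo_project.yaml --svg demo/fig.svg --png demo/fig.png
```

which prints:

```
wrote 3 sequence file(s), 20 features, 2 planted homologies
wrote demo/demo_project.yaml
wrote demo/fig.svg
wrote demo/fig.png
```

The generated project contains three ~10 kb mobile-element-like
records. Records 1–2 share a direct 2 kb region planted at 95%
identity; records 2–3 share an inverted 1.5 kb region at 92%. In the
figure, transposase genes are pink in every sequence, the IS431-family
transposase additionally carries diagonal hatching, the two planted
regions appear as a trapezoid and a crossed ribbon, best-hit
positioning puts each shared region on a common vertical axis, and
each sequence carries a GC-content track and a scale bar.

Programmatic use mirrors the CLI:

```python
from genodraw import load_project, render_project, write_svg

project = load_project("demo/demo_project.yaml")
write_svg(render_project(project), "fig.svg")
```

A *display configuration* (`genodraw` export/apply, or
`export_display_config` / `apply_display_config`) carries only the
feature, homology, legend, and decoration parameters — no paths, no
record ids — so one styling can be reused across sequence sets.

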