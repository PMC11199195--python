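"""Synthetic annotated-sequence generator with recorded ground truth.

Builds small GenBank files that exercise every part of the pipeline
without downloads or external programs: i.i.d. background nucleotides
at a requested GC, planted features with gene/product/locus_tag/note
qualifiers drawn from a mobile-genetic-element vocabulary (transposase
products, tnpA/B/C gene names, an IS431-family entry, recombinases,
resistance genes), and planted shared regions realized by copying a
segment between records and applying substitutions to reach a target
identity — reverse-complemented for inverted orientation.  Everything
is driven by one seed; the emitted files are byte-identical across
runs, and a JSON sidecar records exactly what was planted.

Substitution-only mutation and repeat-free backgrounds are deliberate:
they keep the ungapped builtin aligner an exact oracle for what must be
recovered.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError

__all__ = [
    "PlantedFeature",
    "PlantedHomology",
    "FixtureSpec",
    "GroundTruthFeature",
    "GroundTruthHomology",
    "GroundTruth",
    "generate",
    "demo_spec",
]

_BASES = np.array(list("ACGT"))
_LOCUS_DATE = "01-JAN-1980"  # pinned so generated files are byte-identical

#: annotation vocabulary: (ftype, gene, product, note)
_VOCAB = [
    ("CDS", "tnpA", "transposase of IS431mec", "insertion sequence element"),
    ("CDS", "tnpB", "transposase", "mobile element protein"),
    ("CDS", "tnpC", "transposase accessory protein", "mobile element protein"),
    ("CDS", "mecA", "methicillin resistance protein MecA", "PBP2a"),
    ("CDS", "ccrA", "cassette chromosome recombinase CcrA", "site-specific recombinase"),
    ("CDS", "ccrB", "cassette chromosome recombinase CcrB", "site-specific recombinase"),
    ("CDS", "repA", "replication initiator protein RepA", "plasmid replication"),
    ("CDS", None, "hypothetical protein", "uncharacterized"),
    ("CDS", "ant4", "aminoglycoside nucleotidyltransferase", "resistance determinant"),
    ("tRNA", None, "tRNA-Lys", "transfer RNA"),
]


@dataclass
class PlantedFeature:
    """One feature to annotate: position, strand, qualifiers."""

    record: int  # index into the record list
    ftype: str = "CDS"
    length: int = 900
    strand: int = 1
    qualifiers: dict[str, list[str]] = field(default_factory=dict)
    start: int | None = None  # None: placed left-to-right automatically


@dataclass
class PlantedHomology:
    """One shared region: copied from record_a into record_b."""

    record_a: int
    record_b: int
    length: int = 2000
    identity: float = 100.0  # target percent identity
    inverted: bool = False
    start_a: int | None = None
    start_b: int | None = None


@dataclass
class FixtureSpec:
    """Everything the generator needs; the seed fixes all randomness."""

    n_records: int = 2
    min_length_bp: int = 9000
    max_length_bp: int = 11000
    gc: float = 0.5
    features: list[PlantedFeature] = field(default_factory=list)
    homologies: list[PlantedHomology] = field(default_factory=list)
    seed: int = 0
    file_stem: str = "fixture"
    multi_record: bool = False  # all records in one file vs one file each


@dataclass(frozen=True)
class GroundTruthFeature:
    record_id: str
    start: int
    end: int
    strand: int
    ftype: str
    qualifiers: dict


@dataclass(frozen=True)
class GroundTruthHomology:
    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identity: float  # achieved, not target
    inverted: bool


@dataclass
class GroundTruth:
    """What was actually written: exact coordinates and identities."""

    features: list[GroundTruthFeature] = field(default_factory=list)
    homologies: list[GroundTruthHomology] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            features=[
                GroundTruthFeature(
                    **{**f, "qualifiers": {k: list(v) for k, v in f["qualifiers"].items()}}
                )
                for f in data["features"]
            ],
            homologies=[GroundTruthHomology(**h) for h in data["homologies"]],
        )


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(np.arange(4), size=length, p=p)


def _validate(spec: FixtureSpec, lengths: list[int]) -> None:
    """Reject infeasible specs before anything is written."""
    for pf in spec.features:
        if not 0 <= pf.record < spec.n_records:
            raise ConfigError(f"planted feature references record {pf.record}")
        limit = lengths[pf.record]
        if pf.length > limit or (pf.start is not None and pf.start + pf.length > limit):
            raise ConfigError(
                f"planted feature ({pf.length} bp) does not fit record "
                f"{pf.record} ({limit} bp)"
            )
    for ph in spec.homologies:
        for idx in (ph.record_a, ph.record_b):
            if not 0 <= idx < spec.n_records:
                raise ConfigError(f"planted homology references record {idx}")
            if ph.length > lengths[idx]:
                raise ConfigError(
                    f"planted homology ({ph.length} bp) does not fit record "
                    f"{idx} ({lengths[idx]} bp)"
                )
        if not 0 < ph.identity <= 100:
            raise ConfigError("homology identity target must lie in (0, 100]")


def _place(
    rng: np.random.Generator,
    length: int,
    seg_len: int,
    taken: list[tuple[int, int]],
    forced: int | None,
) -> int:
    if forced is not None:
        return forced
    for _ in range(200):
        start = int(rng.integers(0, length - seg_len + 1))
        if all(start + seg_len <= lo or start >= hi for lo, hi in taken):
            taken.append((start, start + seg_len))
            return start
    raise ConfigError(
        f"could not place a {seg_len} bp segment without overlap; "
        f"the fixture spec is too crowded"
    )


def _mutate_to_identity(
    rng: np.random.Generator, segment: np.ndarray, identity: float
) -> tuple[np.ndarray, float]:
    """Apply exactly round(L*(1-t)) substitutions; return achieved identity."""
    length = len(segment)
    k = int(round(length * (1.0 - identity / 100.0)))
    mutated = segment.copy()
    if k > 0:
        sites = rng.choice(length, size=k, replace=False)
        shifts = rng.integers(1, 4, size=k)  # always a *different* base
        mutated[sites] = (mutated[sites] + shifts) % 4
    return mutated, 100.0 * (length - k) / length


def generate(
    spec: FixtureSpec, outdir: str | Path
) -> tuple[list[Path], GroundTruth]:
    """Write the GenBank file(s) plus a ground-truth JSON sidecar.

    Returns the written sequence-file paths (in record order for
    per-record files) and the in-memory ground truth.  Raises before
    writing anything when the spec cannot be realized.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(spec.seed)
    lengths = [
        int(rng.integers(spec.min_length_bp, spec.max_length_bp + 1))
        for _ in range(spec.n_records)
    ]
    _validate(spec, lengths)
    outdir.mkdir(parents=True, exist_ok=True)

    seqs = [_random_sequence(rng, n, spec.gc) for n in lengths]
    ids = [f"{spec.file_stem.upper()}{i + 1:02d}" for i in range(spec.n_records)]
    truth = GroundTruth()
    taken: dict[int, list[tuple[int, int]]] = {i: [] for i in range(spec.n_records)}

    # homologies first: they rewrite sequence content
    for ph in spec.homologies:
        start_a = _place(rng, lengths[ph.record_a], ph.length, taken[ph.record_a], ph.start_a)
        start_b = _place(rng, lengths[ph.record_b], ph.length, taken[ph.record_b], ph.start_b)
        source = seqs[ph.record_a][start_a : start_a + ph.length]
        copy, achieved = _mutate_to_identity(rng, source, ph.identity)
        if ph.inverted:
            copy = 3 - copy[::-1]  # A<->T, C<->G under the 0..3 encoding
        seqs[ph.record_b][start_b : start_b + ph.length] = copy
        truth.homologies.append(
            GroundTruthHomology(
                query_id=ids[ph.record_a],
                subject_id=ids[ph.record_b],
                q_start=start_a,
                q_end=start_a + ph.length,
                s_start=start_b,
                s_end=start_b + ph.length,
                identity=round(achieved, 3),
                inverted=ph.inverted,
            )
        )

    features_by_record: dict[int, list[tuple[PlantedFeature, int]]] = {}
    cursors = {i: 150 for i in range(spec.n_records)}
    for pf in spec.features:
        if pf.start is not None:
            start = pf.start
        else:
            start = cursors[pf.record] + int(rng.integers(50, 400))
            if start + pf.length > lengths[pf.record]:
                raise ConfigError(
                    f"auto-placed features overflow record {pf.record}; "
                    f"use explicit starts or a longer record"
                )
            cursors[pf.record] = start + pf.length
        features_by_record.setdefault(pf.record, []).append((pf, start))

    paths: list[Path] = []
    biorecords: list[SeqRecord] = []
    for i, rid in enumerate(ids):
        residues = "".join(_BASES[seqs[i]])
        rec = SeqRecord(
            Seq(residues),
            id=rid,
            name=rid,
            description=f"synthetic fixture sequence {i + 1}",
            annotations={
                "molecule_type": "DNA",
                "topology": "linear",
                "data_file_division": "BCT",
                "date": _LOCUS_DATE,
            },
        )
        for j, (pf, start) in enumerate(features_by_record.get(i, [])):
            quals = {k: list(v) for k, v in pf.qualifiers.items()}
            quals.setdefault("locus_tag", [f"{rid}_{j + 1:03d}"])
            rec.features.append(
                SeqFeature(
                    SimpleLocation(start, start + pf.length, strand=pf.strand),
                    type=pf.ftype,
                    qualifiers=quals,
                )
            )
            truth.features.append(
                GroundTruthFeature(
                    record_id=rid,
                    start=start,
                    end=start + pf.length,
                    strand=pf.strand,
                    ftype=pf.ftype,
                    qualifiers=quals,
                )
            )
        biorecords.append(rec)

    if spec.multi_record:
        path = outdir / f"{spec.file_stem}.gbk"
        SeqIO.write(biorecords, str(path), "genbank")
        paths.append(path)
    else:
        for rec in biorecords:
            path = outdir / f"{spec.file_stem}_{rec.id}.gbk"
            SeqIO.write([rec], str(path), "genbank")
            paths.append(path)
    truth.to_json(outdir / f"{spec.file_stem}_truth.json")
    return paths, truth


def demo_spec(seed: int = 0) -> FixtureSpec:
    """Three ~10 kb mobile-element-like records with the full vocabulary.

    Record 0 and 1 share a direct 2 kb region at 95% identity; record 1
    and 2 share an inverted 1.5 kb region at 92% — enough structure to
    exercise styling, ribbons, best-hit alignment, and decorations.
    """
    features = []
    for rec_idx in range(3):
        for k, (ftype, gene, product, note) in enumerate(_VOCAB):
            if (rec_idx + k) % 3 == 0:
                continue  # vary annotation density across records
            quals: dict[str, list[str]] = {"product": [product], "note": [note]}
            if gene:
                quals["gene"] = [gene]
            features.append(
                PlantedFeature(
                    record=rec_idx,
                    ftype=ftype,
                    length=250 if ftype == "tRNA" else 800,
                    strand=1 if k % 2 == 0 else -1,
                    qualifiers=quals,
                )
            )
    return FixtureSpec(
        n_records=3,
        min_length_bp=9500,
        max_length_bp=10500,
        gc=0.45,
        features=features,
        homologies=[
            PlantedHomology(record_a=0, record_b=1, length=2000, identity=95.0),
            PlantedHomology(record_a=1, record_b=2, length=1500, identity=92.0, inverted=True),
        ],
        seed=seed,
        file_stem="demo",
    )
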