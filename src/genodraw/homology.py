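"""Homology search, filtering, pair selection, and hit caching.

Hits between two displayed sequences come either from external BLAST+
(``blastn`` with program defaults, or ``tblastx`` with the bacterial
genetic code, translation table 11, and an e-value cutoff of 1e-3) or
from a builtin exact-seed ungapped extender that needs no external
binary.  All hits are normalized to 0-based half-open intervals on the
*forward* strand of both sequences, with an ``inverted`` flag marking
hits that map the query to the reverse strand of the subject.

Hits are cached per (query, subject, program) in 12-column tabular
BLAST format (``qseqid sseqid pident length mismatch gapopen qstart
qend sstart send evalue bitscore``) so a search between a given pair is
run only once per project.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import reverse_complement

from .errors import ConfigError, ParseError, SearchError
from .seqio import SequenceRecord

__all__ = [
    "HomologyHit",
    "HomologyConfig",
    "builtin_search",
    "run_external_search",
    "blast_command",
    "filter_hits",
    "select_pairs",
    "cache_hits",
    "load_cached_hits",
    "compute_homology",
]

#: e-value placeholder used by the builtin aligner ("not estimated")
BUILTIN_EVALUE_SENTINEL = 0.0

_MATCH_SCORE = 1
_MISMATCH_SCORE = -2


@dataclass(frozen=True)
class HomologyHit:
    """One filtered local-alignment hit between two sequences.

    Intervals are 0-based half-open on the forward strand of each
    sequence; ``inverted`` is true when the query interval aligns to the
    reverse strand of the subject.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    percent_identity: float
    align_length: int
    evalue: float
    bitscore: float
    inverted: bool = False

    def __post_init__(self) -> None:
        if not (self.q_start < self.q_end and self.s_start < self.s_end):
            raise ValueError("hit intervals must be non-empty half-open ranges")
        if self.align_length < 1:
            raise ValueError("align_length must be >= 1")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must lie in [0, 100]")


@dataclass
class HomologyConfig:
    """Search program, hit filters, pairing mode, and cache location."""

    program: str = "builtin"  # blastn | tblastx | builtin
    min_length: int = 0
    min_identity: float = 0.0
    max_evalue: float = 10.0
    pairing: str = "adjacent"  # adjacent | custom
    custom_pairs: list[tuple[str, str]] = field(default_factory=list)
    cache_path: str | None = None
    seed_length: int = 11
    x_drop: int = 20

    def __post_init__(self) -> None:
        if self.program not in ("blastn", "tblastx", "builtin"):
            raise ConfigError(f"unknown homology program {self.program!r}")
        if self.pairing not in ("adjacent", "custom"):
            raise ConfigError(f"unknown pairing mode {self.pairing!r}")
        if min(self.min_length, self.min_identity, self.max_evalue) < 0:
            raise ConfigError("homology thresholds must be non-negative")
        self.custom_pairs = [tuple(p) for p in self.custom_pairs]


# ---------------------------------------------------------------------------
# builtin seed-and-extend aligner


def _extend(q: str, s: str, qi: int, si: int, k: int, x_drop: int) -> tuple[int, int]:
    """Ungapped x-drop extension of an exact k-mer seed.

    Returns the trimmed query interval [lo, hi) of the best-scoring
    extension through (qi, si) on this diagonal.
    """
    # rightwards from the seed end
    hi = qi + k
    cur = best = 0
    i, j = qi + k, si + k
    while i < len(q) and j < len(s):
        cur += _MATCH_SCORE if q[i] == s[j] else _MISMATCH_SCORE
        if cur > best:
            best, hi = cur, i + 1
        elif best - cur > x_drop:
            break
        i += 1
        j += 1
    # leftwards from the seed start
    lo = qi
    cur = best = 0
    i, j = qi - 1, si - 1
    while i >= 0 and j >= 0:
        cur += _MATCH_SCORE if q[i] == s[j] else _MISMATCH_SCORE
        if cur > best:
            best, lo = cur, i
        elif best - cur > x_drop:
            break
        i -= 1
        j -= 1
    return lo, hi


def _search_one_orientation(
    q: str, s: str, seed_length: int, x_drop: int
) -> list[tuple[int, int, int]]:
    """All merged extensions of exact seeds; (diag, q_lo, q_hi) tuples."""
    index: dict[str, list[int]] = {}
    for j in range(len(s) - seed_length + 1):
        index.setdefault(s[j : j + seed_length], []).append(j)
    covered: dict[int, list[tuple[int, int]]] = {}
    for qi in range(len(q) - seed_length + 1):
        positions = index.get(q[qi : qi + seed_length])
        if not positions:
            continue
        for si in positions:
            diag = qi - si
            spans = covered.setdefault(diag, [])
            if any(lo <= qi and qi + seed_length <= hi for lo, hi in spans):
                continue  # seed already inside an accepted extension
            lo, hi = _extend(q, s, qi, si, seed_length, x_drop)
            spans.append((lo, hi))
    out: list[tuple[int, int, int]] = []
    for diag, spans in covered.items():
        spans.sort()
        merged: list[list[int]] = []
        for lo, hi in spans:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        out.extend((diag, lo, hi) for lo, hi in merged)
    return out


def builtin_search(
    query: SequenceRecord,
    subject: SequenceRecord,
    seed_length: int = 11,
    x_drop: int = 20,
    min_identity: float = 0.0,
) -> list[HomologyHit]:
    """Exact-seed, ungapped, x-drop local search on both subject strands.

    A dependency-free stand-alone nucleotide aligner: every exact
    ``seed_length``-mer shared between query and subject (forward and
    reverse-complement) is extended without gaps until the running score
    drops ``x_drop`` below its maximum, then trimmed to the best-scoring
    span.  Overlapping extensions on one diagonal are merged.  The
    e-value is reported as the 0.0 sentinel (not estimated); the
    bitscore column carries the raw ungapped score.  Output order is
    deterministic: (q_start, s_start, inverted).
    """
    if seed_length < 4:
        raise ConfigError(f"seed_length must be >= 4, got {seed_length}")
    q = query.require_residues("homology search")
    s = subject.require_residues("homology search")
    hits: list[HomologyHit] = []
    for oriented, inverted in ((s, False), (reverse_complement(s), True)):
        for diag, q_lo, q_hi in _search_one_orientation(q, oriented, seed_length, x_drop):
            s_lo, s_hi = q_lo - diag, q_hi - diag
            length = q_hi - q_lo
            matches = sum(
                1 for a, b in zip(q[q_lo:q_hi], oriented[s_lo:s_hi]) if a == b
            )
            identity = 100.0 * matches / length
            if identity < min_identity:
                continue
            score = matches * _MATCH_SCORE + (length - matches) * _MISMATCH_SCORE
            if inverted:  # map back to the forward strand of the subject
                s_lo, s_hi = len(s) - s_hi, len(s) - s_lo
            hits.append(
                HomologyHit(
                    query_id=query.record_id,
                    subject_id=subject.record_id,
                    q_start=q_lo,
                    q_end=q_hi,
                    s_start=s_lo,
                    s_end=s_hi,
                    percent_identity=round(identity, 3),
                    align_length=length,
                    evalue=BUILTIN_EVALUE_SENTINEL,
                    bitscore=float(score),
                    inverted=inverted,
                )
            )
    hits.sort(key=lambda h: (h.q_start, h.s_start, h.inverted))
    return hits


# ---------------------------------------------------------------------------
# external BLAST+


def blast_command(program: str, query_path: str, subject_path: str) -> list[str]:
    """Build the BLAST+ argv for one pair (bl2seq mode, tabular output).

    blastn runs with program defaults; tblastx uses the bacterial
    genetic code (translation table 11) for both sequences and an
    e-value cutoff of 1e-3.
    """
    cmd = [program, "-query", query_path, "-subject", subject_path, "-outfmt", "6"]
    if program == "tblastx":
        cmd += ["-query_gencode", "11", "-db_gencode", "11", "-evalue", "1e-3"]
    elif program != "blastn":
        raise ConfigError(f"unsupported external program {program!r}")
    return cmd


def run_external_search(
    pair: tuple[SequenceRecord, SequenceRecord],
    program: str,
    workdir: str | Path | None = None,
) -> list[HomologyHit]:
    """Run blastn or tblastx on one sequence pair and parse the hits."""
    query, subject = pair
    if shutil.which(program) is None:
        raise SearchError(
            f"external search program {program!r} not found on PATH; install "
            f"BLAST+ or switch the homology program to 'builtin'"
        )
    q = query.require_residues("external homology search")
    s = subject.require_residues("external homology search")
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        qpath = Path(tmp) / "query.fa"
        spath = Path(tmp) / "subject.fa"
        qpath.write_text(f">{query.record_id}\n{q}\n")
        spath.write_text(f">{subject.record_id}\n{s}\n")
        cmd = blast_command(program, str(qpath), str(spath))
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise SearchError(
                f"{program} exited with status {proc.returncode}: "
                f"{proc.stderr.strip()}"
            )
        return _parse_tabular(proc.stdout.splitlines(), source=f"{program} output")


def _parse_tabular(lines, source: str) -> list[HomologyHit]:
    """Parse 12-column tabular BLAST lines into normalized hits."""
    hits: list[HomologyHit] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 12:
            raise ParseError(
                f"{source}, line {lineno}: expected 12 tab-separated columns, "
                f"got {len(cols)}"
            )
        try:
            qid, sid = cols[0], cols[1]
            pident = float(cols[2])
            length = int(cols[3])
            qstart, qend = int(cols[6]), int(cols[7])
            sstart, send = int(cols[8]), int(cols[9])
            evalue = float(cols[10])
            bitscore = float(cols[11])
        except ValueError as exc:
            raise ParseError(f"{source}, line {lineno}: {exc}") from exc
        inverted = False
        if qstart > qend:
            qstart, qend = qend, qstart
            inverted = not inverted
        if sstart > send:
            sstart, send = send, sstart
            inverted = not inverted
        hits.append(
            HomologyHit(
                query_id=qid,
                subject_id=sid,
                q_start=qstart - 1,  # 1-based inclusive -> 0-based half-open
                q_end=qend,
                s_start=sstart - 1,
                s_end=send,
                percent_identity=pident,
                align_length=length,
                evalue=evalue,
                bitscore=bitscore,
                inverted=inverted,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# filtering and pairing


def filter_hits(hits: list[HomologyHit], cfg: HomologyConfig) -> list[HomologyHit]:
    """Keep hits passing length AND identity AND e-value thresholds.

    Order is preserved.  The builtin aligner's 0.0 e-value sentinel
    always passes the (non-negative) e-value threshold.
    """
    return [
        h
        for h in hits
        if h.align_length >= cfg.min_length
        and h.percent_identity >= cfg.min_identity
        and h.evalue <= cfg.max_evalue
    ]


def select_pairs(
    records: list[SequenceRecord], cfg: HomologyConfig
) -> list[tuple[str, str]]:
    """Sequence pairs to compare, in drawing order.

    ``adjacent`` pairs each active sequence with the next one below it
    (self-pairs excluded); ``custom`` takes the configured pairs,
    dropping any whose member is inactive.  A custom pair naming an
    unknown record id is a configuration error.
    """
    known = {r.record_id for r in records}
    active = [r.record_id for r in records if r.active]
    if cfg.pairing == "adjacent":
        return [
            (a, b) for a, b in zip(active, active[1:]) if a != b
        ]
    for a, b in cfg.custom_pairs:
        for rid in (a, b):
            if rid not in known:
                raise ConfigError(f"custom blast pair references unknown record {rid!r}")
    active_set = set(active)
    return [
        (a, b) for a, b in cfg.custom_pairs if a in active_set and b in active_set
    ]


# ---------------------------------------------------------------------------
# cache (12-column tabular BLAST dialect)


def _fmt(value: float) -> str:
    """Float -> shortest exact decimal text (round-trips through float())."""
    return repr(float(value))


def cache_hits(
    hits: list[HomologyHit], path: str | Path, program: str = "builtin"
) -> None:
    """Write hits as 12-column tabular BLAST plus one comment header.

    The header records the program and the record-id mapping; inverted
    hits are encoded the BLAST way, with subject coordinates reversed
    (sstart > send, 1-based inclusive).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ids: list[str] = []
    for h in hits:
        for rid in (h.query_id, h.subject_id):
            if rid not in ids:
                ids.append(rid)
    lines = [f"# genodraw homology cache program={program} records={','.join(ids)}"]
    for h in hits:
        sstart, send = h.s_start + 1, h.s_end
        if h.inverted:
            sstart, send = send, sstart
        mismatch = h.align_length - round(h.align_length * h.percent_identity / 100.0)
        lines.append(
            "\t".join(
                [
                    h.query_id,
                    h.subject_id,
                    _fmt(h.percent_identity),
                    str(h.align_length),
                    str(mismatch),
                    "0",
                    str(h.q_start + 1),
                    str(h.q_end),
                    str(sstart),
                    str(send),
                    _fmt(h.evalue),
                    _fmt(h.bitscore),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def load_cached_hits(path: str | Path) -> list[HomologyHit]:
    """Inverse of :func:`cache_hits` on the 12 tabular columns."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"homology cache {path} does not exist")
    with open(path) as fh:
        return _parse_tabular(fh, source=str(path))


# ---------------------------------------------------------------------------
# orchestration


def _pair_cache_file(cache_dir: Path, qid: str, sid: str, program: str) -> Path:
    safe = lambda s: "".join(c if c.isalnum() or c in "._-" else "_" for c in s)
    return cache_dir / f"{safe(qid)}__{safe(sid)}__{program}.tsv"


def compute_homology(
    records: list[SequenceRecord],
    cfg: HomologyConfig,
    workdir: str | Path | None = None,
) -> dict[tuple[str, str], list[HomologyHit]]:
    """Raw (unfiltered) hits for every selected pair, using the cache.

    Each (query, subject, program) pair is searched at most once; prior
    results are reloaded from ``cfg.cache_path`` (a directory) when
    present.  Filtering thresholds are applied later, at draw time, so
    tightening them never triggers a re-search.
    """
    by_id = {r.record_id: r for r in records}
    cache_dir = Path(cfg.cache_path) if cfg.cache_path else None
    result: dict[tuple[str, str], list[HomologyHit]] = {}
    for qid, sid in select_pairs(records, cfg):
        cache_file = (
            _pair_cache_file(cache_dir, qid, sid, cfg.program) if cache_dir else None
        )
        if cache_file is not None and cache_file.exists():
            result[(qid, sid)] = load_cached_hits(cache_file)
            continue
        pair = (by_id[qid], by_id[sid])
        if cfg.program == "builtin":
            hits = builtin_search(
                pair[0], pair[1], seed_length=cfg.seed_length, x_drop=cfg.x_drop
            )
        else:
            hits = run_external_search(pair, cfg.program, workdir=workdir)
        if cache_file is not None:
            cache_hits(hits, cache_file, program=cfg.program)
        result[(qid, sid)] = hits
    return result
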