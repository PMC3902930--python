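"""Exon models, entry filtering, flanking-intron extraction and per-intron
motif profiles.

Entries are transcript-level exon chains read from GFF3 or BED12, paired
with a tab-separated label file assigning each entry ``SKIPPED`` (cassette)
or ``CONSTITUTIVE``.  Entry filtering follows three rules applied in order:
exact-coordinate duplicates are collapsed to one; entries whose genomic
spans overlap a different surviving entry are *both* removed; entries with
more than three exons are removed.

"Upstream" and "downstream" introns are defined in transcription
orientation: for a minus-strand entry the upstream intron is the intron
genomically to the right of the exon, and its sequence is
reverse-complemented so that every intron handed to the scanners reads
5'->3' on the sense (non-template) strand.  Consequently a G4 hit found on
the scanned sequence itself lies on the non-template strand, and a hit
found on its reverse complement lies on the template strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .scan import (
    MotifHit,
    ScanParams,
    Strand,
    StructureClass,
    find_polypyrimidine_tract,
    scan_all,
)
from .seq import revcomp

__all__ = [
    "Orientation",
    "ExonLabel",
    "Region",
    "GeneEntry",
    "ExonRecord",
    "IntronProfile",
    "FilterStats",
    "load_entries",
    "filter_entries",
    "extract_flanking_introns",
    "profile_intron",
    "profile_records",
    "background_probability",
    "profiles_to_frame",
    "COUNT_KEYS",
]


class Orientation(str, Enum):
    PLUS = "+"
    MINUS = "-"


class ExonLabel(str, Enum):
    SKIPPED = "SKIPPED"
    CONSTITUTIVE = "CONSTITUTIVE"


class Region(str, Enum):
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"


#: keys of the per-intron count map, G4 split by strand
COUNT_KEYS = (
    "g4_template",
    "g4_nontemplate",
    "cruciform",
    "triplex",
    "slipped",
    "zdna",
)

_CLASS_KEY = {
    StructureClass.CRUCIFORM: "cruciform",
    StructureClass.TRIPLEX: "triplex",
    StructureClass.SLIPPED: "slipped",
    StructureClass.ZDNA: "zdna",
}


@dataclass(frozen=True)
class GeneEntry:
    """A transcript entry: an exon chain on one strand of one contig."""

    entry_id: str
    chrom: str
    orientation: Orientation
    exons: tuple[tuple[int, int], ...]  # genomic order, 0-based half-open
    label: Optional[ExonLabel] = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exons_transcription_order(self) -> tuple[tuple[int, int], ...]:
        if self.orientation is Orientation.PLUS:
            return self.exons
        return tuple(reversed(self.exons))


@dataclass(frozen=True)
class ExonRecord:
    """A classified internal exon with both flanking introns.

    ``upstream_intron`` is 5' of the exon in transcription orientation
    regardless of genomic strand; intervals are genomic, 0-based half-open.
    """

    entry_id: str
    chrom: str
    orientation: Orientation
    exon: tuple[int, int]
    label: ExonLabel
    upstream_intron: tuple[int, int]
    downstream_intron: tuple[int, int]
    upstream_seq: str = ""
    downstream_seq: str = ""


@dataclass
class IntronProfile:
    """Motif counts of one flanking intron (sequence in transcription
    orientation)."""

    exon_ref: str
    region: Region
    intron_length: int
    counts: dict[str, int]
    proximal_counts: dict[str, int]
    max_g_run_template: int
    max_g_run_nontemplate: int
    n_triplex_removed_ppt: int = 0


@dataclass
class FilterStats:
    n_input: int = 0
    n_duplicates_collapsed: int = 0
    n_overlap_removed: int = 0
    n_many_exon_removed: int = 0
    n_retained: int = 0


# ---------------------------------------------------------------------------
# loading

def _parse_labels(labels_path: str) -> dict[str, ExonLabel]:
    labels: dict[str, ExonLabel] = {}
    with open(labels_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed label line: {line!r}")
            if parts[0] == "entry_id":  # optional header
                continue
            labels[parts[0]] = ExonLabel(parts[1].strip().upper())
    return labels


def _load_gff3(path: str) -> list[GeneEntry]:
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    entries = []
    parents = [f for t in ("mRNA", "transcript") for f in db.features_of_type(t)]
    for feat in sorted(parents, key=lambda f: f.id):
        exons = sorted(
            (child.start - 1, child.end)  # GFF3 is 1-based inclusive
            for child in db.children(feat, featuretype="exon")
        )
        if not exons:
            continue
        if feat.strand not in ("+", "-"):
            raise ValueError(f"entry {feat.id} has no strand")
        entries.append(
            GeneEntry(feat.id, feat.seqid, Orientation(feat.strand), tuple(exons))
        )
    return entries


def _load_bed12(path: str) -> list[GeneEntry]:
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 requires 12 columns, got {len(f)}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            count = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != count or len(offsets) != count:
                raise ValueError(f"entry {name}: blockCount mismatch")
            exons = tuple(
                (start + o, start + o + s) for o, s in zip(offsets, sizes)
            )
            entries.append(GeneEntry(name, chrom, Orientation(strand), exons))
    return entries


def load_entries(annotation_path: str, labels_path: str) -> list[GeneEntry]:
    """Parse a GFF3 or BED12 annotation and attach SKIPPED/CONSTITUTIVE
    labels from a two-column TSV.

    Raises ``ValueError`` for malformed coordinates and ``KeyError`` naming
    the entry when the label file references an unknown entry id.
    """
    ext = os.path.splitext(annotation_path)[1].lower()
    if ext in (".gff", ".gff3"):
        entries = _load_gff3(annotation_path)
    elif ext in (".bed", ".bed12"):
        entries = _load_bed12(annotation_path)
    else:
        raise ValueError(f"unrecognized annotation format: {annotation_path}")
    for e in entries:
        for s, t in e.exons:
            if not 0 <= s < t:
                raise ValueError(f"entry {e.entry_id}: malformed exon ({s}, {t})")
    labels = _parse_labels(labels_path)
    known = {e.entry_id for e in entries}
    for entry_id in labels:
        if entry_id not in known:
            raise KeyError(
                f"label file references unknown entry id {entry_id!r}"
            )
    out = []
    for e in entries:
        if e.entry_id in labels:
            out.append(
                GeneEntry(e.entry_id, e.chrom, e.orientation, e.exons,
                          labels[e.entry_id])
            )
        else:
            out.append(e)
    return out


# ---------------------------------------------------------------------------
# filtering

def filter_entries(
    entries: Iterable[GeneEntry],
) -> tuple[list[GeneEntry], FilterStats]:
    """Apply the three entry filters in order: collapse exact-coordinate
    duplicates, drop every pair of span-overlapping entries (both members),
    drop entries with more than three exons."""
    entries = list(entries)
    stats = FilterStats(n_input=len(entries))
    seen: set = set()
    deduped = []
    for e in entries:
        key = (e.chrom, e.orientation, e.exons)
        if key in seen:
            stats.n_duplicates_collapsed += 1
            continue
        seen.add(key)
        deduped.append(e)
    # span-overlap removal among the dedup survivors (strand-agnostic)
    by_chrom: dict[str, list[GeneEntry]] = {}
    for e in deduped:
        by_chrom.setdefault(e.chrom, []).append(e)
    overlapping: set[str] = set()
    for chrom_entries in by_chrom.values():
        chrom_entries = sorted(chrom_entries, key=lambda e: e.span)
        for i, e in enumerate(chrom_entries):
            s1, t1 = e.span
            for other in chrom_entries[i + 1 :]:
                s2, t2 = other.span
                if s2 >= t1:
                    break
                overlapping.add(e.entry_id)
                overlapping.add(other.entry_id)
    no_overlap = [e for e in deduped if e.entry_id not in overlapping]
    stats.n_overlap_removed = len(deduped) - len(no_overlap)
    retained = [e for e in no_overlap if len(e.exons) <= 3]
    stats.n_many_exon_removed = len(no_overlap) - len(retained)
    stats.n_retained = len(retained)
    return retained, stats


# ---------------------------------------------------------------------------
# intron extraction

def extract_flanking_introns(entry: GeneEntry, genome) -> list[ExonRecord]:
    """ExonRecords (with intron sequences) for every internal exon of an
    entry.

    ``genome`` is a mapping of contig name to sequence supporting
    ``genome[chrom][start:end]`` (e.g. a ``pyfaidx.Fasta``).  First and last
    exons lack one flank and produce no record.  Both intron sequences are
    returned 5'->3' in transcription orientation (reverse-complemented for
    minus-strand entries).
    """
    if entry.label is None:
        raise ValueError(f"entry {entry.entry_id} has no label")
    records = []
    exons = entry.exons
    contig = genome[entry.chrom]
    contig_len = len(contig)
    for i in range(1, len(exons) - 1):
        left = (exons[i - 1][1], exons[i][0])
        right = (exons[i][1], exons[i + 1][0])
        for s, t in (left, right):
            if not 0 <= s < t <= contig_len:
                raise ValueError(
                    f"entry {entry.entry_id}: intron ({s}, {t}) outside "
                    f"contig {entry.chrom} (length {contig_len})"
                )
        left_seq = str(contig[left[0] : left[1]])
        right_seq = str(contig[right[0] : right[1]])
        if entry.orientation is Orientation.PLUS:
            up, down = left, right
            up_seq, down_seq = left_seq, right_seq
        else:
            up, down = right, left
            up_seq, down_seq = revcomp(right_seq), revcomp(left_seq)
        records.append(
            ExonRecord(
                entry_id=entry.entry_id,
                chrom=entry.chrom,
                orientation=entry.orientation,
                exon=exons[i],
                label=entry.label,
                upstream_intron=up,
                downstream_intron=down,
                upstream_seq=up_seq,
                downstream_seq=down_seq,
            )
        )
    return records


# ---------------------------------------------------------------------------
# profiling

def _interval_overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def profile_intron(
    intron_seq: str,
    region: Region,
    params: Optional[ScanParams] = None,
    window: int = 500,
    exon_ref: str = "",
    _hits: Optional[dict[StructureClass, list[MotifHit]]] = None,
) -> IntronProfile:
    """Scan one intron (given 5'->3' in transcription orientation) and count
    motifs overall and in the exon-proximal window.

    G4 hits on the scanned (sense) strand are counted as non-template; hits
    on its reverse complement as template.  Triplex hits overlapping the
    intron's polypyrimidine tract are removed before counting.  The
    proximal window is the min(window, length) nt abutting the exon: the 3'
    end for an upstream intron, the 5' end for a downstream intron; a hit
    is proximal when it overlaps that window.
    """
    if not intron_seq:
        raise ValueError("empty intron sequence")
    params = params or ScanParams()
    n = len(intron_seq)
    region = Region(region)
    hits = dict(scan_all(intron_seq, params) if _hits is None else _hits)
    ppt = find_polypyrimidine_tract(intron_seq, params)
    n_removed = 0
    if ppt is not None:
        kept_triplex = []
        for h in hits[StructureClass.TRIPLEX]:
            if _interval_overlaps((h.start, h.end), ppt):
                n_removed += 1
            else:
                kept_triplex.append(h)
        hits[StructureClass.TRIPLEX] = kept_triplex
    if region is Region.UPSTREAM:
        prox = (max(0, n - window), n)
    else:
        prox = (0, min(window, n))

    counts = {key: 0 for key in COUNT_KEYS}
    proximal = {key: 0 for key in COUNT_KEYS}
    max_run = {Strand.FORWARD: 0, Strand.REVERSE_COMPLEMENT: 0}
    for cls, cls_hits in hits.items():
        for h in cls_hits:
            if cls is StructureClass.G4:
                key = (
                    "g4_nontemplate"
                    if h.scanned_strand is Strand.FORWARD
                    else "g4_template"
                )
                max_run[h.scanned_strand] = max(
                    max_run[h.scanned_strand], int(h.attributes["max_g_run"])
                )
            else:
                key = _CLASS_KEY[cls]
            counts[key] += 1
            if _interval_overlaps((h.start, h.end), prox):
                proximal[key] += 1
    return IntronProfile(
        exon_ref=exon_ref,
        region=region,
        intron_length=n,
        counts=counts,
        proximal_counts=proximal,
        max_g_run_template=max_run[Strand.REVERSE_COMPLEMENT],
        max_g_run_nontemplate=max_run[Strand.FORWARD],
        n_triplex_removed_ppt=n_removed,
    )


def profile_records(
    records: Iterable[ExonRecord],
    params: Optional[ScanParams] = None,
    window: int = 500,
) -> pd.DataFrame:
    """Profile both flanking introns of every record; see
    :func:`profiles_to_frame` for the schema."""
    rows = []
    for rec in records:
        for region, seq in (
            (Region.UPSTREAM, rec.upstream_seq),
            (Region.DOWNSTREAM, rec.downstream_seq),
        ):
            prof = profile_intron(seq, region, params, window, rec.entry_id)
            rows.append((rec, prof))
    return profiles_to_frame(rows)


def profiles_to_frame(
    rows: Iterable[tuple[ExonRecord, IntronProfile]]
) -> pd.DataFrame:
    """Long-format profile table: one row per (exon, region) with total and
    proximal counts, intron length and the per-strand maximum G-run."""
    out = []
    for rec, prof in rows:
        row = {
            "entry_id": rec.entry_id,
            "label": rec.label.value,
            "region": prof.region.value,
            "intron_length": prof.intron_length,
            "max_g_run_template": prof.max_g_run_template,
            "max_g_run_nontemplate": prof.max_g_run_nontemplate,
            "n_triplex_removed_ppt": prof.n_triplex_removed_ppt,
        }
        for key in COUNT_KEYS:
            row[f"n_{key}"] = prof.counts[key]
            row[f"prox_{key}"] = prof.proximal_counts[key]
        out.append(row)
    columns = (
        ["entry_id", "label", "region", "intron_length"]
        + [f"n_{k}" for k in COUNT_KEYS]
        + [f"prox_{k}" for k in COUNT_KEYS]
        + ["max_g_run_template", "max_g_run_nontemplate", "n_triplex_removed_ppt"]
    )
    return pd.DataFrame(out, columns=columns)


def background_probability(records: Iterable[ExonRecord]) -> float:
    """Proportion of SKIPPED exons among all exons with both flanking
    introns (i.e. all ExonRecords)."""
    records = list(records)
    if not records:
        raise ValueError("background probability undefined on an empty record set")
    n_skipped = sum(1 for r in records if r.label is ExonLabel.SKIPPED)
    return n_skipped / len(records)
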