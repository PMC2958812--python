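"""Genome and annotation I/O with circular-coordinate arithmetic.

A :class:`Genome` holds one circular replicon: an uppercase DNA string over
``{A, C, G, T, N}``, a list of annotated features, and optionally the
position of the replication origin (oriC).  Internal coordinates are
0-based half-open throughout; circular positions are normalized mod L, and
intervals that wrap around the origin of the coordinate system are
represented with ``end > L`` (so ``end - start`` is always the interval
length).

Readers accept single-record FASTA plus an optional GenBank flat file or
GFF3 annotation; writers emit GFF3 (1-based inclusive), BED (0-based
half-open) and TSV with deterministic record ordering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
from Bio import SeqIO

VALID_BASES = set("ACGTN")

#: feature kinds that mask DNA as "coding" for intergenic extraction
GENE_KINDS = frozenset({"CDS", "rRNA", "tRNA"})


@dataclass(frozen=True)
class Feature:
    """Annotated interval: 0-based half-open, start normalized to [0, L)."""

    start: int
    end: int
    strand: str = "+"
    kind: str = "CDS"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty/inverted feature [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class Genome:
    """One circular replicon with annotations and an optional oriC."""

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    oric: Optional[int] = None
    circular: bool = True

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
        if len(self.sequence) == 0:
            raise ValueError("empty genome sequence")
        L = len(self.sequence)
        self.features = [
            dataclasses.replace(f, start=f.start % L, end=f.start % L + (f.end - f.start))
            for f in self.features
        ]
        if self.oric is not None:
            self.oric = self.oric % L

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of the circular interval [start, end); end may exceed L."""
        L = self.length
        if end < start:
            raise ValueError(f"inverted interval [{start}, {end})")
        if end - start > L:
            raise ValueError(f"interval longer than genome: [{start}, {end})")
        length = end - start
        start %= L
        return (self.sequence + self.sequence)[start : start + length]

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Genome({self.id!r}, L={self.length}, features={len(self.features)}, oriC={self.oric})"


@dataclass(frozen=True)
class IntergenicRegion:
    """Maximal interval overlapping no gene-class feature (0-based, half-open,
    end may exceed L for the wraparound interval)."""

    genome_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self):
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length does not match interval")


# ---------------------------------------------------------------------------
# reading


def _read_single_fasta(fasta_path: str | Path):
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"{fasta_path}: expected exactly one FASTA record, found {len(records)}"
        )
    return records[0]


def _sniff_annotation_format(path: str | Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith("LOCUS"):
                return "genbank"
            return "gff3"
    raise ValueError(f"{path}: empty annotation file")


def _features_from_genbank(path: str | Path, genome_id: str) -> list[Feature]:
    record = SeqIO.read(str(path), "genbank")
    rid = record.id.split(".")[0]
    if genome_id.split(".")[0] not in (rid, record.name):
        raise ValueError(
            f"annotation record {record.id!r} does not match genome {genome_id!r}"
        )
    feats = []
    for f in record.features:
        if f.type == "source":
            continue
        strand = "+" if (f.location.strand or 1) >= 0 else "-"
        feats.append(
            Feature(
                start=int(f.location.start),
                end=int(f.location.end),
                strand=strand,
                kind=f.type,
            )
        )
    return feats


def _features_from_gff3(path: str | Path, genome_id: str) -> list[Feature]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    seen_ids = set()
    for f in db.all_features():
        seen_ids.add(f.seqid)
        if f.featuretype in ("region", "source"):
            continue
        feats.append(
            Feature(
                start=f.start - 1,  # GFF3 is 1-based inclusive
                end=f.end,
                strand=f.strand if f.strand in ("+", "-") else ".",
                kind=f.featuretype,
            )
        )
    if seen_ids and genome_id not in seen_ids and genome_id.split(".")[0] not in {
        s.split(".")[0] for s in seen_ids
    }:
        raise ValueError(
            f"annotation seqids {sorted(seen_ids)} do not match genome {genome_id!r}"
        )
    return feats


def read_genome(
    fasta_path: str | Path,
    annotation_path: str | Path | None = None,
    oric: Optional[int] = None,
) -> Genome:
    """Read a single-record FASTA plus an optional GenBank/GFF3 annotation.

    The annotation format is sniffed from the file content.  An unannotated
    genome is allowed (``features == []``).
    """
    record = _read_single_fasta(fasta_path)
    genome_id = record.id
    features: list[Feature] = []
    if annotation_path is not None:
        fmt = _sniff_annotation_format(annotation_path)
        if fmt == "genbank":
            features = _features_from_genbank(annotation_path, genome_id)
        else:
            features = _features_from_gff3(annotation_path, genome_id)
    return Genome(id=genome_id, sequence=str(record.seq), features=features, oric=oric)


# ---------------------------------------------------------------------------
# intergenic extraction


def intergenic_regions(
    genome: Genome,
    min_length: int = 1,
    gene_kinds: frozenset[str] = GENE_KINDS,
) -> list[IntergenicRegion]:
    """Maximal circular intervals not overlapping any gene-class feature.

    The wraparound interval (crossing position 0) is included once, with
    ``end > L``.  Intervals shorter than ``min_length`` are dropped.  With
    no features the whole circle is one region.
    """
    L = genome.length
    gene_iv = sorted(
        (f.start, min(f.end, f.start + L)) for f in genome.features if f.kind in gene_kinds
    )
    if not gene_iv:
        return [
            IntergenicRegion(genome.id, 0, L, genome.sequence)
        ] if L >= min_length else []

    # unfold wraparound gene intervals (end > L) onto the start of the circle
    unfolded: list[tuple[int, int]] = []
    for s, e in gene_iv:
        if e > L:
            unfolded.append((s, L))
            unfolded.append((0, e - L))
        else:
            unfolded.append((s, e))
    unfolded.sort()

    # merge
    merged: list[list[int]] = []
    for s, e in unfolded:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    regions: list[IntergenicRegion] = []
    if len(merged) == 1 and merged[0][0] == 0 and merged[0][1] >= L:
        return []  # fully coding
    # gaps between consecutive merged intervals
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        if e1 < s2:
            regions.append(
                IntergenicRegion(genome.id, e1, s2, genome.fetch(e1, s2))
            )
    # wraparound gap: from last feature end, through the origin, to first start
    last_end = merged[-1][1]
    first_start = merged[0][0]
    if genome.circular:
        gap_len = (first_start - last_end) % L
        if gap_len > 0:
            regions.append(
                IntergenicRegion(
                    genome.id, last_end, last_end + gap_len, genome.fetch(last_end, last_end + gap_len)
                )
            )
    else:  # linear: leading and trailing gaps separately
        if first_start > 0:
            regions.append(IntergenicRegion(genome.id, 0, first_start, genome.fetch(0, first_start)))
        if last_end < L:
            regions.append(IntergenicRegion(genome.id, last_end, L, genome.fetch(last_end, L)))

    regions = [r for r in regions if r.end - r.start >= min_length]
    regions.sort(key=lambda r: r.start)
    return regions


# ---------------------------------------------------------------------------
# writing predictions and genomes


def _site_fields(site) -> dict:
    if dataclasses.is_dataclass(site) and not isinstance(site, type):
        d = dataclasses.asdict(site)
    elif isinstance(site, dict):
        d = dict(site)
    else:
        raise TypeError(f"cannot serialize site of type {type(site).__name__}")
    if "genome_id" not in d or "start" not in d:
        raise ValueError("site must carry genome_id and start")
    if "end" not in d:
        if "arm_len" in d and "spacer_len" in d:
            d["end"] = d["start"] + 2 * d["arm_len"] + d["spacer_len"]
        elif "width" in d:
            d["end"] = d["start"] + d["width"]
        elif "sequence" in d:
            d["end"] = d["start"] + len(d["sequence"])
        else:
            raise ValueError("site must carry end, width, or sequence")
    d.setdefault("score", ".")
    d.setdefault("strand", "+")
    return d


def write_predictions(sites: Sequence, path: str | Path, format: str = "TSV") -> Path:
    """Write predicted sites as GFF3, BED, or TSV.

    GFF3 uses 1-based inclusive coordinates, BED 0-based half-open; TSV
    carries every field of the site records.  Records are ordered by
    (genome id, start) for deterministic output.
    """
    fmt = format.upper()
    if fmt not in ("GFF3", "BED", "TSV"):
        raise ValueError(f"unknown prediction format {format!r} (use GFF3, BED or TSV)")
    path = Path(path)
    rows = sorted((_site_fields(s) for s in sites), key=lambda d: (d["genome_id"], d["start"]))
    with open(path, "w") as fh:
        if fmt == "GFF3":
            fh.write("##gff-version 3\n")
            for d in rows:
                fh.write(
                    "\t".join(
                        [
                            str(d["genome_id"]),
                            "difskew",
                            str(d.get("kind", "predicted_site")),
                            str(d["start"] + 1),
                            str(d["end"]),
                            str(d["score"]),
                            str(d["strand"]),
                            ".",
                            ";".join(
                                f"{k}={v}"
                                for k, v in sorted(d.items())
                                if k not in ("genome_id", "start", "end", "score", "strand", "kind")
                            )
                            or ".",
                        ]
                    )
                    + "\n"
                )
        elif fmt == "BED":
            fh.write('track name="difskew_predictions"\n')
            for d in rows:
                fh.write(
                    f"{d['genome_id']}\t{d['start']}\t{d['end']}\t"
                    f"{d.get('name', d.get('kind', 'site'))}\t{d['score']}\t{d['strand']}\n"
                )
        else:  # TSV
            keys: list[str] = []
            for d in rows:
                for k in d:
                    if k not in keys:
                        keys.append(k)
            if not keys:
                keys = ["genome_id", "start", "end", "score", "strand"]
            fh.write("\t".join(keys) + "\n")
            for d in rows:
                fh.write("\t".join(str(d.get(k, "")) for k in keys) + "\n")
    return path


def read_predictions_bed(path: str | Path) -> list[dict]:
    """Re-parse a BED file written by :func:`write_predictions`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            out.append(
                dict(genome_id=chrom, start=int(start), end=int(end), name=name,
                     score=score, strand=strand)
            )
    return out


def read_predictions_gff3(path: str | Path) -> list[dict]:
    """Re-parse a GFF3 file written by :func:`write_predictions`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            out.append(
                dict(genome_id=cols[0], kind=cols[2], start=int(cols[3]) - 1,
                     end=int(cols[4]), score=cols[5], strand=cols[6])
            )
    return out


def write_genome(genome: Genome, fasta_path: str | Path, gff_path: str | Path | None = None) -> None:
    """Write a genome as FASTA (wrapped at 70 columns) and optionally GFF3."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.id}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    if gff_path is not None:
        L = genome.length
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {genome.id} 1 {L}\n")
            for i, f in enumerate(sorted(genome.features, key=lambda x: (x.start, x.end))):
                # wraparound features are split across the origin for GFF3
                segments = (
                    [(f.start, L), (0, f.end - L)] if f.end > L else [(f.start, f.end)]
                )
                for s, e in segments:
                    fh.write(
                        f"{genome.id}\tdifskew_sim\t{f.kind}\t{s + 1}\t{e}\t.\t{f.strand}\t"
                        f"{0 if f.kind == 'CDS' else '.'}\tID={f.kind.lower()}_{i:05d}\n"
                    )
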