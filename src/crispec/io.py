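"""Readers, writers and run configuration.

FASTA and FASTQ go through Biopython; BED and the extended site TSV are
plain text.  BED uses 0-based half-open coordinates with the mismatch count
in the score column; the TSV mirrors every ``OfftargetSite`` field and uses
1-based inclusive start coordinates (declared in a header comment) so the
two can be cross-checked by eye.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .guides import OfftargetSite


class FastqRecord(NamedTuple):
    id: str
    seq: str
    qual: str


class BedRecord(NamedTuple):
    contig: str
    start: int
    end: int
    name: str
    score: int
    strand: str


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record, line-wrapped FASTA -> {id: uppercase sequence}."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq(path: str | Path) -> list[FastqRecord]:
    """4-line FASTQ records, Phred+33.  Empty file -> empty list."""
    out: list[FastqRecord] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append(FastqRecord(rec.id, str(rec.seq).upper(), qual))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ in {path} near record {len(out) + 1}: {exc}") from exc
    return out


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            if len(rec.seq) != len(rec.qual):
                raise ValueError(f"record {i} ({rec.id}): sequence/quality length mismatch")
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")


def write_bed(sites: Sequence[OfftargetSite], path: str | Path) -> None:
    """6-column BED: chrom, start, end, name, score (= n_mismatch), strand."""
    with open(path, "w") as fh:
        for s in sites:
            if s.start >= s.end:
                raise ValueError(f"site {s.site_id} has start >= end")
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.site_id}\t{s.n_mismatch}\t{s.strand}\n")


def read_bed(path: str | Path) -> list[BedRecord]:
    out: list[BedRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 BED columns")
            contig, start, end, name, score, strand = fields[:6]
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            out.append(BedRecord(contig, start, end, name, int(score), strand))
    return out


_TSV_COLUMNS = (
    "site_id guide_id contig start_1based end strand protospacer pam "
    "n_mismatch mismatch_positions seed_mismatches ssr_flag"
).split()


def write_sites_tsv(sites: Sequence[OfftargetSite], path: str | Path) -> None:
    """Extended per-site TSV (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for s in sites:
            mism = ",".join(map(str, s.mismatch_positions)) or "."
            fh.write(
                "\t".join(
                    map(
                        str,
                        (
                            s.site_id, s.guide_id, s.contig, s.start + 1, s.end, s.strand,
                            s.protospacer, s.pam, s.n_mismatch, mism, s.seed_mismatches,
                            int(s.ssr_flag),
                        ),
                    )
                )
                + "\n"
            )


def read_sites_tsv(path: str | Path) -> list[OfftargetSite]:
    out: list[OfftargetSite] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("site_id"):
                continue
            f = dict(zip(_TSV_COLUMNS, line.rstrip("\n").split("\t")))
            positions = () if f["mismatch_positions"] == "." else tuple(
                int(x) for x in f["mismatch_positions"].split(",")
            )
            out.append(
                OfftargetSite(
                    guide_id=f["guide_id"],
                    contig=f["contig"],
                    start=int(f["start_1based"]) - 1,
                    end=int(f["end"]),
                    strand=f["strand"],
                    protospacer=f["protospacer"],
                    pam=f["pam"],
                    n_mismatch=int(f["n_mismatch"]),
                    mismatch_positions=positions,
                    seed_mismatches=int(f["seed_mismatches"]),
                    ssr_flag=bool(int(f["ssr_flag"])),
                )
            )
    return out


@dataclass
class RunConfig:
    """Top-level configuration for ``run_pipeline`` (YAML/JSON serialisable).

    With ``genome_path`` unset the pipeline synthesises its own fixture from
    ``sim`` and the three site counts; otherwise genome, panel and per-site
    read files are loaded from the named paths (the layout written by
    ``FixtureBundle.write``).
    """

    seed: int = 7
    n_true_offtargets: int = 3
    n_ssr_noise_sites: int = 5
    n_clean_sites: int = 20
    flank: int = 100
    quant_window: int = 10
    max_mm: int = 5
    pam_offtarget: str = "NRG"
    sim: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    ssr_thresholds: dict = field(default_factory=dict)
    genome_path: str | None = None
    sites_path: str | None = None
    reads_dir: str | None = None
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
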