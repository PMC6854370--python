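"""Guide design and off-target enumeration for SpCas9.

Guides are 17-20-nt spacers adjacent to an NGG PAM; candidate off-target
sites are genomic loci whose protospacer differs from the spacer by a bounded
number of mismatches next to an NRG PAM (R = A or G).  Shortening a spacer at
its 5' (PAM-distal) end can only reduce the mismatch count at any locus, so
truncated guides accumulate off-target candidates -- the mechanism this module
exists to expose.

Conventions
-----------
* Coordinates are 0-based half-open on the forward strand, for both strands.
* Mismatch positions are numbered 1..spacer_len starting at the PAM-proximal
  base; the seed region is positions 1-12.
* The blunt cut site sits 3 bp 5' of the PAM.  Its genomic junction
  coordinate therefore does not depend on spacer length, which is what lets
  hits from differently truncated guides collapse onto one locus.
* Bulged (gapped) alignments are not searched; the model is mismatch-only.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .sequence import IUPAC, is_acgt, revcomp

SPACER_LENGTHS = (17, 18, 19, 20)
SEED_SIZE = 12  # PAM-proximal positions counted as the seed region
PAM_LEN = 3

GenomeLike = Union[str, Mapping[str, str]]


def _as_genome(genome: GenomeLike, default_contig: str = "seq") -> dict[str, str]:
    if isinstance(genome, str):
        return {default_contig: genome.upper()}
    return {c: s.upper() for c, s in genome.items()}


@dataclass(frozen=True)
class Guide:
    """A spacer with its genomic locus (locus span covers spacer + PAM)."""

    id: str
    spacer: str
    contig: str
    start: int
    end: int
    strand: str
    pam_on: str = "NGG"
    cut_offset: int = 3  # bp 5' of the PAM

    def __post_init__(self) -> None:
        if self.spacer_len not in SPACER_LENGTHS:
            raise ValueError(f"spacer length {self.spacer_len} outside {SPACER_LENGTHS}")
        if self.end - self.start != self.spacer_len + PAM_LEN:
            raise ValueError("locus span must equal spacer_len + PAM length")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def spacer_len(self) -> int:
        return len(self.spacer)

    @property
    def cut_site(self) -> int:
        """Genomic junction coordinate of the blunt cut (cut between j-1 and j)."""
        if self.strand == "+":
            return self.end - PAM_LEN - self.cut_offset
        return self.start + PAM_LEN + self.cut_offset


@dataclass(frozen=True)
class OfftargetSite:
    """A candidate locus matching a guide at ``n_mismatch`` spacer mismatches."""

    guide_id: str
    contig: str
    start: int
    end: int
    strand: str
    protospacer: str
    pam: str
    n_mismatch: int
    mismatch_positions: tuple[int, ...] = ()  # 1-based from the PAM-proximal end
    seed_mismatches: int = 0
    ssr_flag: bool = False
    cut_offset: int = field(default=3, compare=False)

    def __post_init__(self) -> None:
        if self.n_mismatch != len(self.mismatch_positions):
            raise ValueError("n_mismatch must equal len(mismatch_positions)")
        if self.seed_mismatches > self.n_mismatch:
            raise ValueError("seed_mismatches cannot exceed n_mismatch")

    @property
    def spacer_len(self) -> int:
        return len(self.protospacer)

    @property
    def cut_site(self) -> int:
        if self.strand == "+":
            return self.end - len(self.pam) - self.cut_offset
        return self.start + len(self.pam) + self.cut_offset

    @property
    def site_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}:{self.strand}"


def enumerate_guides(
    seq: str,
    spacer_len: int,
    pam_pattern: str = "NGG",
    contig: str = "seq",
) -> list[Guide]:
    """All guides of ``spacer_len`` adjacent to a PAM, on both strands.

    Minus-strand guides are reported in forward-strand coordinates.  A
    sequence too short to hold spacer + PAM yields an empty list.
    """
    if spacer_len not in SPACER_LENGTHS:
        raise ValueError(f"spacer_len must be one of {SPACER_LENGTHS}")
    seq = seq.upper()
    n = len(seq)
    plen = len(pam_pattern)
    guides: list[Guide] = []

    def scan(s: str) -> list[tuple[int, str]]:
        hits = []
        for p in range(spacer_len, len(s) - plen + 1):
            spacer = s[p - spacer_len : p]
            if matches_pam(pam_pattern, s[p : p + plen]) and is_acgt(spacer):
                hits.append((p - spacer_len, spacer))
        return hits

    for start, spacer in scan(seq):
        guides.append(
            Guide(
                id=f"{contig}:{start}:+:{spacer_len}",
                spacer=spacer,
                contig=contig,
                start=start,
                end=start + spacer_len + plen,
                strand="+",
                pam_on=pam_pattern,
            )
        )
    rc = revcomp(seq)
    for rc_start, spacer in scan(rc):
        start = n - (rc_start + spacer_len + plen)
        guides.append(
            Guide(
                id=f"{contig}:{start}:-:{spacer_len}",
                spacer=spacer,
                contig=contig,
                start=start,
                end=start + spacer_len + plen,
                strand="-",
                pam_on=pam_pattern,
            )
        )
    guides.sort(key=lambda g: (g.start, g.strand))
    return guides


def matches_pam(pattern: str, seq: str) -> bool:
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC[p] for p, b in zip(pattern.upper(), seq))


def truncate_guide(g: Guide, new_len: int) -> Guide:
    """Trim the spacer at its 5' (PAM-distal) end; cut site is unchanged."""
    if new_len >= g.spacer_len:
        raise ValueError(f"new_len {new_len} must be shorter than {g.spacer_len}")
    if new_len < min(SPACER_LENGTHS):
        raise ValueError(f"new_len {new_len} below minimum {min(SPACER_LENGTHS)}")
    d = g.spacer_len - new_len
    if g.strand == "+":
        start, end = g.start + d, g.end
    else:
        start, end = g.start, g.end - d
    return dataclasses.replace(
        g, id=f"{g.id}|{new_len}nt", spacer=g.spacer[d:], start=start, end=end
    )


def _scan_strand(seq: str, spacer: str, max_mm: int, pam_pattern: str) -> list[tuple[int, int]]:
    """(offset, n_mismatch) for every spacer+PAM match on one strand (vectorised)."""
    L, plen, n = len(spacer), len(pam_pattern), len(seq)
    if n < L + plen:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(arr, L + plen)
    sp = np.frombuffer(spacer.encode("ascii"), dtype=np.uint8)
    mm = (win[:, :L] != sp).sum(axis=1)
    ok = mm <= max_mm
    for k, code in enumerate(pam_pattern.upper()):
        allowed = np.frombuffer("".join(sorted(IUPAC[code])).encode("ascii"), dtype=np.uint8)
        ok &= np.isin(win[:, L + k], allowed)
    return [(int(i), int(mm[i])) for i in np.flatnonzero(ok)]


def find_offtargets(
    g: Guide,
    genome: GenomeLike,
    max_mm: int = 5,
    pam_pattern: str = "NRG",
) -> list[OfftargetSite]:
    """Complete both-strand scan for loci within ``max_mm`` spacer mismatches.

    The on-target locus is included (``n_mismatch == 0``).  A genome base of
    ``N`` (or any non-ACGT code) counts as a mismatch against the spacer;
    PAM codes follow IUPAC semantics.  Results are sorted by (contig, start).
    """
    if not is_acgt(g.spacer):
        raise ValueError(f"guide spacer contains non-ACGT characters: {g.spacer!r}")
    if not 0 <= max_mm <= 5:
        raise ValueError("max_mm must be between 0 and 5")
    contigs = _as_genome(genome, default_contig=g.contig)
    L = g.spacer_len
    plen = len(pam_pattern)
    sites: list[OfftargetSite] = []

    def mk_site(contig: str, start: int, strand: str, proto: str, pam: str, mm: int) -> OfftargetSite:
        positions = tuple(sorted(L - k for k in range(L) if proto[k] != g.spacer[k]))
        return OfftargetSite(
            guide_id=g.id,
            contig=contig,
            start=start,
            end=start + L + plen,
            strand=strand,
            protospacer=proto,
            pam=pam,
            n_mismatch=mm,
            mismatch_positions=positions,
            seed_mismatches=sum(p <= SEED_SIZE for p in positions),
            cut_offset=g.cut_offset,
        )

    for contig, seq in contigs.items():
        n = len(seq)
        for i, mm in _scan_strand(seq, g.spacer, max_mm, pam_pattern):
            sites.append(mk_site(contig, i, "+", seq[i : i + L], seq[i + L : i + L + plen], mm))
        rc = revcomp(seq)
        for i, mm in _scan_strand(rc, g.spacer, max_mm, pam_pattern):
            start = n - (i + L + plen)
            sites.append(mk_site(contig, start, "-", rc[i : i + L], rc[i + L : i + L + plen], mm))
    sites.sort(key=lambda s: (s.contig, s.start, s.strand))
    return sites


def count_by_mismatch(sites: Sequence[OfftargetSite]) -> dict[int, int]:
    """Site counts keyed by mismatch number 0..5 (absent classes count 0)."""
    counts = Counter(s.n_mismatch for s in sites)
    return {m: counts.get(m, 0) for m in range(6)}


@dataclass(frozen=True)
class OverlapTable:
    """Venn-style membership of off-target loci across spacer lengths.

    Loci are keyed by (contig, cut-site junction, strand) so that hits of
    different spacer lengths at the same locus collapse onto one key.
    """

    lengths: tuple[int, ...]
    region_counts: dict[tuple[int, ...], int]
    shared_sites: tuple[tuple[str, int, str], ...]

    @property
    def n_shared(self) -> int:
        return len(self.shared_sites)

    def union_size(self) -> int:
        return sum(self.region_counts.values())


def overlap_across_lengths(
    site_sets: Mapping[int, Sequence[OfftargetSite]],
) -> OverlapTable:
    """Venn membership counts of cut-site loci across >= 2 spacer lengths."""
    if len(site_sets) < 2:
        raise ValueError("need site sets for at least two spacer lengths")
    contig_sets = [
        {s.contig for s in sites} for sites in site_sets.values() if len(sites) > 0
    ]
    for a in contig_sets:
        for b in contig_sets:
            if a and b and not (a & b):
                raise ValueError("inconsistent contig namespaces between site sets")
    keys_by_len = {
        length: {(s.contig, s.cut_site, s.strand) for s in sites}
        for length, sites in site_sets.items()
    }
    lengths = tuple(sorted(site_sets))
    membership: dict[tuple[str, int, str], tuple[int, ...]] = {}
    for key in set().union(*keys_by_len.values()):
        membership[key] = tuple(l for l in lengths if key in keys_by_len[l])
    region_counts = dict(Counter(membership.values()))
    shared = tuple(sorted(k for k, v in membership.items() if v == lengths))
    return OverlapTable(lengths=lengths, region_counts=region_counts, shared_sites=shared)
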