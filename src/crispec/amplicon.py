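"""Read QC, alignment to reference amplicons, and indel quantification.

The editing efficiency of a site is the percentage of aligned reads that
carry an insertion or deletion inside a window around the Cas9 cut position
(default +/- 10 bp).  Substitutions never count as editing: NHEJ repair of a
blunt double-strand break leaves indels, while substitutions in deep
sequencing data are overwhelmingly base-calling errors.

Alignment is deterministic semi-global pairwise alignment with affine gap
penalties (match +2, mismatch -3, gap open -8, gap extend -1; end gaps
free), via Biopython's ``PairwiseAligner``.  Indels are left-aligned within
repeat context before window testing so that slippage indels at an SSR get
one canonical placement.
"""

from __future__ import annotations

import warnings
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from Bio import Align

from .guides import OfftargetSite
from .io import FastqRecord
from .sequence import revcomp


@dataclass(frozen=True)
class AmpliconRef:
    """A reference amplicon around one cut site."""

    id: str
    sequence: str
    guide_id: str
    cut_pos: int
    quant_window: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.cut_pos < len(self.sequence):
            raise ValueError("cut_pos outside amplicon")
        if self.quant_window < 0:
            raise ValueError("quant_window must be >= 0")

    @property
    def cut_near_end(self) -> bool:
        """Amplicon design rule: cut within 100 bp of either end."""
        n = len(self.sequence)
        return self.cut_pos <= 100 or n - self.cut_pos <= 100


@dataclass(frozen=True)
class Indel:
    kind: str  # "ins" | "del"
    ref_start: int
    length: int
    seq: str = ""  # inserted bases for "ins"


@dataclass(frozen=True)
class ReadAlignment:
    strand: str
    score: float
    n_match: int
    indels: tuple[Indel, ...]


@dataclass(frozen=True)
class AlleleCall:
    read_id: str
    status: str  # "WT" | "indel" | "discarded_unaligned"
    indel_size: int = 0  # net signed in-window size (negative = deletion)
    indel_start: int | None = None
    in_window: bool = False


@dataclass(frozen=True)
class SiteQuant:
    """Per-site read accounting for one sample."""

    site_id: str
    n_total: int
    n_aligned: int
    n_indel: int
    allele_spectrum: Mapping[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.n_indel <= self.n_aligned <= self.n_total:
            raise ValueError("need n_indel <= n_aligned <= n_total")
        if sum(self.allele_spectrum.values()) != self.n_indel:
            raise ValueError("allele spectrum must sum to n_indel")

    @property
    def efficiency(self) -> float:
        """Editing efficiency in percent of aligned reads."""
        if self.n_aligned == 0:
            return 0.0
        return 100.0 * self.n_indel / self.n_aligned


def qc_filter(
    reads: Sequence[FastqRecord],
    min_len: int = 35,
    adapters: Sequence[str] = (),
) -> list[FastqRecord]:
    """Trim 3' adapters, drop reads containing N or shorter than ``min_len``.

    An adapter is trimmed where a read suffix exactly matches an adapter
    prefix with at least 8 bases of overlap (leftmost such occurrence).
    Reads shorter than ``min_len`` after trimming are discarded; order is
    preserved.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    adapters = [a.upper() for a in adapters]
    out: list[FastqRecord] = []
    for idx, rec in enumerate(reads):
        if len(rec.seq) != len(rec.qual):
            raise ValueError(f"malformed FASTQ record at index {idx} ({rec.id})")
        seq, qual = rec.seq.upper(), rec.qual
        for adapter in adapters:
            cut = _find_adapter(seq, adapter)
            if cut is not None:
                seq, qual = seq[:cut], qual[:cut]
        if "N" in seq:
            continue
        if len(seq) < min_len:
            continue
        out.append(FastqRecord(rec.id, seq, qual))
    return out


def _find_adapter(seq: str, adapter: str, min_overlap: int = 8) -> int | None:
    for i in range(len(seq) - min_overlap + 1):
        tail = seq[i:]
        if len(tail) <= len(adapter) and adapter.startswith(tail):
            return i
    return None


def make_aligner(
    match: float = 2, mismatch: float = -3, gap_open: float = -8, gap_extend: float = -1
) -> Align.PairwiseAligner:
    """Semi-global affine-gap aligner (free end gaps on both sequences)."""
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    try:
        a.end_gap_score = 0
    except AttributeError:  # older attribute spelling
        a.target_end_gap_score = 0
        a.query_end_gap_score = 0
    return a


def _extract(aln, ref_seq: str, read_seq: str) -> tuple[int, tuple[Indel, ...]]:
    t_blocks, q_blocks = aln.aligned
    n_match = 0
    indels: list[Indel] = []
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        n_match += sum(a == b for a, b in zip(ref_seq[ts:te], read_seq[qs:qe]))
    for k in range(1, len(t_blocks)):
        dt = int(t_blocks[k][0] - t_blocks[k - 1][1])
        dq = int(q_blocks[k][0] - q_blocks[k - 1][1])
        pos = int(t_blocks[k - 1][1])
        if dt > 0:
            indels.append(Indel("del", pos, dt))
        if dq > 0:
            indels.append(
                Indel("ins", pos + dt, dq, read_seq[int(q_blocks[k - 1][1]) : int(q_blocks[k][0])])
            )
    return n_match, tuple(indels)


def _left_align(indels: Sequence[Indel], ref_seq: str) -> list[Indel]:
    """Shift each indel maximally left within its repeat context."""
    out: list[Indel] = []
    for ind in sorted(indels, key=lambda d: d.ref_start):
        if ind.kind == "del":
            s, k = ind.ref_start, ind.length
            while s > 0 and ref_seq[s - 1] == ref_seq[s + k - 1]:
                s -= 1
            out.append(Indel("del", s, k))
        else:
            p, ins = ind.ref_start, ind.seq
            while p > 0 and ins and ref_seq[p - 1] == ins[-1]:
                ins = ref_seq[p - 1] + ins[:-1]
                p -= 1
            out.append(Indel("ins", p, len(ins), ins))
    return out


def align_to_amplicon(
    read: str,
    ref: AmpliconRef,
    aligner: Align.PairwiseAligner | None = None,
    min_identity: float = 0.6,
) -> ReadAlignment | None:
    """Best-scoring alignment of the read against the reference and its
    reverse complement; ``None`` means the read is discarded as unaligned
    (fewer than ``min_identity`` of its bases matching)."""
    if not read:
        raise ValueError("empty read")
    aligner = aligner or make_aligner()
    read = read.upper()
    best = None
    for strand, seq in (("+", read), ("-", revcomp(read))):
        aln = aligner.align(ref.sequence, seq)[0]
        if best is None or aln.score > best[1].score:
            best = (strand, aln, seq)
    strand, aln, seq = best
    if len(aln.aligned[0]) == 0:
        return None
    n_match, indels = _extract(aln, ref.sequence, seq)
    if n_match < min_identity * len(read):
        return None
    return ReadAlignment(strand=strand, score=float(aln.score), n_match=n_match, indels=indels)


def call_read(aln: ReadAlignment | None, ref: AmpliconRef, read_id: str = "") -> AlleleCall:
    """Classify one aligned read as WT or indel using the cut-site window.

    A read is an edit call iff at least one insertion or deletion intersects
    the closed window [cut_pos - w, cut_pos + w] after left alignment.
    Substitutions are ignored; out-of-window indels leave the read WT.
    """
    if aln is None:
        return AlleleCall(read_id, "discarded_unaligned")
    lo, hi = ref.cut_pos - ref.quant_window, ref.cut_pos + ref.quant_window
    in_events: list[Indel] = []
    out_events: list[Indel] = []
    for ind in _left_align(aln.indels, ref.sequence):
        if ind.kind == "del":
            hit = ind.ref_start <= hi and ind.ref_start + ind.length - 1 >= lo
        else:
            hit = lo <= ind.ref_start <= hi
        (in_events if hit else out_events).append(ind)
    if in_events:
        net = sum(d.length if d.kind == "ins" else -d.length for d in in_events)
        first = in_events[0]
        if net == 0:  # offsetting events; report the first event's signed size
            net = first.length if first.kind == "ins" else -first.length
        return AlleleCall(read_id, "indel", net, min(d.ref_start for d in in_events), True)
    if out_events:
        return AlleleCall(read_id, "WT", 0, out_events[0].ref_start, False)
    return AlleleCall(read_id, "WT", 0, None, False)


def quantify_site(
    reads: Sequence[FastqRecord],
    ref: AmpliconRef,
    min_len: int = 35,
    adapters: Sequence[str] = (),
    aligner: Align.PairwiseAligner | None = None,
) -> SiteQuant:
    """QC -> align -> call for one read set; identical reads are memoised."""
    aligner = aligner or make_aligner()
    kept = qc_filter(reads, min_len=min_len, adapters=adapters)
    if not reads:
        warnings.warn(f"no reads for site {ref.id}", stacklevel=2)
    cache: dict[str, AlleleCall] = {}
    n_aligned = 0
    n_indel = 0
    spectrum: Counter[tuple[int, int]] = Counter()
    for rec in kept:
        call = cache.get(rec.seq)
        if call is None:
            if rec.seq == ref.sequence:
                call = AlleleCall(rec.id, "WT", 0, None, False)
            else:
                call = call_read(align_to_amplicon(rec.seq, ref, aligner=aligner), ref, rec.id)
            cache[rec.seq] = call
        if call.status != "discarded_unaligned":
            n_aligned += 1
        if call.status == "indel":
            n_indel += 1
            spectrum[(call.indel_size, call.indel_start)] += 1
    if kept and n_aligned == 0:
        warnings.warn(f"no aligned reads for site {ref.id}", stacklevel=2)
    return SiteQuant(
        site_id=ref.id,
        n_total=len(reads),
        n_aligned=n_aligned,
        n_indel=n_indel,
        allele_spectrum=dict(spectrum),
    )


def extract_target_regions(
    genome: Mapping[str, str],
    sites: Sequence[OfftargetSite],
    flank: int = 100,
    quant_window: int = 10,
) -> list[AmpliconRef]:
    """One amplicon per site: genome[cut - flank, cut + flank), clamped at
    contig edges (the cut position shifts accordingly)."""
    refs: list[AmpliconRef] = []
    for site in sites:
        if flank < site.spacer_len:
            raise ValueError("flank must be at least the spacer length")
        if site.contig not in genome:
            raise KeyError(f"contig {site.contig!r} not present in genome")
        seq = genome[site.contig]
        cut = site.cut_site
        lo, hi = max(0, cut - flank), min(len(seq), cut + flank)
        refs.append(
            AmpliconRef(
                id=site.site_id,
                sequence=seq[lo:hi].upper(),
                guide_id=site.guide_id,
                cut_pos=cut - lo,
                quant_window=quant_window,
            )
        )
    return refs
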