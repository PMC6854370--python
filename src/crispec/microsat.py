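"""Perfect and compound microsatellite (SSR) detection and site flagging.

Short tandem repeats mutate by replication slippage at rates far above the
genomic background, so an SSR inside or next to a candidate Cas9 target site
produces indel signal that is indistinguishable from genome editing.  This
module finds perfect repeats of 1-6-nt units, merges neighbouring runs into
compound records, and flags target sites whose flanks contain one.

Reporting semantics follow MISA-style conventions: a repeat qualifies when
its complete-unit count reaches the unit-length-specific minimum (defaults
1:10, 2:6, 3:5, 4:5, 5:5, 6:5); qualifying runs within ``max_interruption``
bases merge into a compound record.  An extra "extension" rule absorbs a
*sub-threshold* run of a different unit sitting flush against a qualifying
run (e.g. the GA tail of (CA)8(GA)2) -- a deliberate deviation from strict
MISA semantics, because compound motifs of exactly that shape are the ones
that matter for target-site instability.

Composition strings are literal: re-expanding ``(CA)8TT(GA)6`` reproduces the
genomic substring exactly, interruption bases included.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .guides import OfftargetSite
from .sequence import is_primitive

DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

_BLOCK_RE = re.compile(r"\(([ACGT]+)\)(\d+)|([ACGT]+)")


@dataclass(frozen=True)
class SsrThresholds:
    """Reporting thresholds for the SSR scanner.

    min_repeats
        Minimum complete-unit count per unit length (1-6 nt).
    max_interruption
        Maximum gap (bases) between qualifying runs merged into a compound.
    min_adjacent_units
        Complete-unit count a sub-threshold run needs to be absorbed into an
        adjacent qualifying run (extension rule); only applies with 0 gap.
    extend_adjacent
        Toggle for the extension rule.
    """

    min_repeats: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_REPEATS))
    max_interruption: int = 100
    min_adjacent_units: int = 2
    extend_adjacent: bool = True

    def __post_init__(self) -> None:
        for ul, k in self.min_repeats.items():
            if ul not in range(1, 7) or k < 1:
                raise ValueError(f"bad min_repeats entry {ul}:{k}")
        if self.max_interruption < 1 or self.min_adjacent_units < 1:
            raise ValueError("thresholds must be >= 1")


@dataclass(frozen=True)
class Microsatellite:
    """A perfect or compound tandem repeat with a literal composition string."""

    start: int
    end: int
    motif_class: int  # unit length of the longest member run
    composition: str
    kind: str  # "perfect" | "compound"

    def __post_init__(self) -> None:
        if self.end - self.start != len(expand_composition(self.composition)):
            raise ValueError("span does not match expanded composition length")
        if self.kind not in ("perfect", "compound"):
            raise ValueError(f"bad kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def expand_composition(composition: str) -> str:
    """Expand ``(CA)8(GA)2`` / ``A(CA)7GA`` style strings to literal bases."""
    out: list[str] = []
    pos = 0
    for m in _BLOCK_RE.finditer(composition):
        if m.start() != pos:
            raise ValueError(f"malformed composition string {composition!r}")
        pos = m.end()
        if m.group(1) is not None:
            count = int(m.group(2))
            if count < 1:
                raise ValueError(f"repeat count must be >= 1 in {composition!r}")
            out.append(m.group(1) * count)
        else:
            out.append(m.group(3))
    if pos != len(composition) or not out:
        raise ValueError(f"malformed composition string {composition!r}")
    return "".join(out)


def _tandem_runs(seq: str, min_units: Mapping[int, int]) -> list[tuple[int, int, int, str, int]]:
    """All maximal complete-unit tandem runs meeting per-unit-length minima.

    Returns (start, end, unit_len, unit, count) tuples.  A run is located via
    the self-match vector m[i] = (seq[i] == seq[i+ul]); a maximal stretch of
    r consecutive matches spans r+ul bases with floor((r+ul)/ul) complete
    units.  Non-primitive units are skipped (their runs surface at the true
    period).
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    acgt = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    runs: list[tuple[int, int, int, str, int]] = []
    for ul, min_count in sorted(min_units.items()):
        if n < 2 * ul:
            continue
        eq = (arr[:-ul] == arr[ul:]) & acgt[:-ul] & acgt[ul:]
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            r = int(e - s)
            count = (r + ul) // ul
            if count < min_count:
                continue
            unit = seq[s : s + ul]
            if not is_primitive(unit):
                continue
            runs.append((int(s), int(s) + count * ul, ul, unit, count))
    return runs


def find_perfect_ssrs(seq: str, t: SsrThresholds | None = None) -> list[Microsatellite]:
    """All non-overlapping maximal perfect SSRs meeting the thresholds.

    Overlaps between runs of different unit lengths are resolved in favour of
    the longer span, ties leftmost, then the shorter unit.
    """
    t = t or SsrThresholds()
    seq = seq.upper()
    candidates = _tandem_runs(seq, t.min_repeats)
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    occupied = np.zeros(len(seq), dtype=bool)
    chosen: list[Microsatellite] = []
    for s, e, ul, unit, count in candidates:
        if occupied[s:e].any():
            continue
        occupied[s:e] = True
        chosen.append(Microsatellite(s, e, ul, f"({unit}){count}", "perfect"))
    chosen.sort(key=lambda m: m.start)
    return chosen


def _adjacent_run(
    seq: str, pos: int, forward: bool, t: SsrThresholds, limit: int
) -> tuple[int, int, str, int] | None:
    """Best sub-threshold tandem run flush against ``pos`` (0-gap).

    Returns (start, end, unit, unit_len) of the longest such run with at
    least ``min_adjacent_units`` complete units, bounded by ``limit``
    (exclusive end going forward, inclusive floor going backward).  Units of
    2-6 bp only: two identical adjacent bases occur at a quarter of all run
    boundaries by chance and carry no slippage signal, so mononucleotide
    runs never join a compound through this rule.
    """
    best: tuple[int, int, str, int] | None = None
    for ul in range(2, 7):
        if forward:
            if pos + ul > limit:
                continue
            unit = seq[pos : pos + ul]
            if len(unit) < ul or not is_primitive(unit) or not set(unit) <= set("ACGT"):
                continue
            e = pos + ul
            while e + ul <= limit and seq[e : e + ul] == unit:
                e += ul
            count = (e - pos) // ul
            cand = (pos, e, unit, ul)
        else:
            if pos - ul < limit:
                continue
            unit = seq[pos - ul : pos]
            if len(unit) < ul or not is_primitive(unit) or not set(unit) <= set("ACGT"):
                continue
            s = pos - ul
            while s - ul >= limit and seq[s - ul : s] == unit:
                s -= ul
            count = (pos - s) // ul
            cand = (s, pos, unit, ul)
        if count >= t.min_adjacent_units:
            span = cand[1] - cand[0]
            if best is None or span > best[1] - best[0] or (span == best[1] - best[0] and ul < best[3]):
                best = cand
    return best


def merge_compound(
    ssrs: Sequence[Microsatellite], seq: str, t: SsrThresholds | None = None
) -> list[Microsatellite]:
    """Merge qualifying SSRs into compound records and absorb flush tails.

    Qualifying runs separated by at most ``max_interruption`` bases merge,
    with the interruption bases kept literally in the composition.  With
    ``extend_adjacent`` on, a 0-gap neighbouring run of a different unit with
    >= ``min_adjacent_units`` repeats is absorbed as well.
    """
    t = t or SsrThresholds()
    seq = seq.upper()
    recs = sorted(ssrs, key=lambda m: m.start)
    out: list[Microsatellite] = []
    i = 0
    while i < len(recs):
        members = [recs[i]]
        parts = [recs[i].composition]
        cur_start, cur_end = recs[i].start, recs[i].end
        j = i + 1
        while j < len(recs) and recs[j].start - cur_end <= t.max_interruption:
            gap = seq[cur_end : recs[j].start]
            if gap:
                parts.append(gap)
            parts.append(recs[j].composition)
            members.append(recs[j])
            cur_end = recs[j].end
            j += 1
        kind = "compound" if len(members) > 1 else members[0].kind
        if t.extend_adjacent:
            floor = out[-1].end if out else 0
            ceil = recs[j].start if j < len(recs) else len(seq)
            while True:
                run = _adjacent_run(seq, cur_end, forward=True, t=t, limit=ceil)
                if run is None:
                    break
                s, e, unit, _ = run
                parts.append(f"({unit}){(e - s) // len(unit)}")
                cur_end = e
                kind = "compound"
            while True:
                run = _adjacent_run(seq, cur_start, forward=False, t=t, limit=floor)
                if run is None:
                    break
                s, e, unit, _ = run
                parts.insert(0, f"({unit}){(e - s) // len(unit)}")
                cur_start = s
                kind = "compound"
        motif_class = max(members, key=lambda m: m.length).motif_class
        out.append(Microsatellite(cur_start, cur_end, motif_class, "".join(parts), kind))
        i = j
    return out


def scan_sequence(seq: str, t: SsrThresholds | None = None) -> list[Microsatellite]:
    """Convenience: perfect scan followed by compound merging."""
    t = t or SsrThresholds()
    return merge_compound(find_perfect_ssrs(seq, t), seq, t)


def flag_sites(
    sites: Sequence[OfftargetSite],
    genome: Mapping[str, str],
    flank: int = 100,
    t: SsrThresholds | None = None,
) -> tuple[list[OfftargetSite], dict[str, float]]:
    """Set ``ssr_flag`` on sites whose flanked window overlaps any SSR.

    The window is [start - flank, end + flank), clamped to the contig with a
    warning.  Returns the flagged site list and the per-guide flagged
    proportion (flagged / total).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    t = t or SsrThresholds()
    genome = {c: s.upper() for c, s in genome.items()}
    ssrs_by_contig = {c: scan_sequence(s, t) for c, s in genome.items()}
    flagged: list[OfftargetSite] = []
    for site in sites:
        if site.contig not in genome:
            raise KeyError(f"site contig {site.contig!r} missing from genome")
        n = len(genome[site.contig])
        lo, hi = site.start - flank, site.end + flank
        if lo < 0 or hi > n:
            warnings.warn(
                f"flanked window for {site.site_id} clamped to contig bounds", stacklevel=2
            )
            lo, hi = max(0, lo), min(n, hi)
        flag = any(m.start < hi and m.end > lo for m in ssrs_by_contig[site.contig])
        flagged.append(dataclasses.replace(site, ssr_flag=flag))
    proportions: dict[str, float] = {}
    for gid in {s.guide_id for s in flagged}:
        mine = [s for s in flagged if s.guide_id == gid]
        proportions[gid] = sum(s.ssr_flag for s in mine) / len(mine)
    return flagged, proportions
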