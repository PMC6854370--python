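"""Synthetic genomes, planted target sites and simulated read sets.

The generator builds toy study material with known truth so that every
downstream stage -- off-target search, SSR flagging, indel quantification,
classification -- can be tested without external data.  It emulates a
capture-panel experiment: a random genome carries one on-target protospacer
per guide plus planted candidate loci at 0-5 mismatches under an NRG PAM;
a subset of those loci sit next to a planted microsatellite; per-site
control and edited read sets are drawn from the surrounding amplicon.

Read model
----------
* Each edited read carries exactly one indel whose left edge sits at the
  cut position; its signed size is drawn from ``indel_size_dist``.
* At an SSR locus a read additionally gains or loses one whole repeat unit
  (equiprobable) with probability ``stutter_rate``, in both the control and
  the edited sample -- slippage does not care about Cas9.
* Substitution errors hit each base independently; they never create indels.
* Reads are full amplicon length at constant Q30; no pairing, no adapters,
  no machine error profile.

All randomness flows through one seeded ``numpy`` generator in documented
order (edit draw, size draw, insertion bases, stutter draw, stutter
direction, substitution mask, substituted bases -- per read), so identical
configuration yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .guides import Guide, OfftargetSite, truncate_guide
from .io import FastqRecord, write_bed, write_fasta, write_fastq, write_sites_tsv
from .microsat import expand_composition
from .sequence import DNA, revcomp

QUAL_CHAR = "?"  # constant Q30, Phred+33

#: Default induced-indel size spectrum (negative = deletion).  The real
#: NHEJ spectrum is locus-dependent; this is a deletion-skewed mix with
#: small insertions, typical of Cas9 blunt-cut repair.
DEFAULT_INDEL_SIZE_DIST: dict[int, float] = {
    -1: 0.30, -2: 0.15, -3: 0.15, -4: 0.10, -5: 0.05, -6: 0.05, 1: 0.15, 2: 0.05,
}

#: Compound/perfect SSR compositions planted at noise sites, cycled in order.
SSR_COMPOSITIONS = ("(CA)8(GA)2", "A(CA)7GA", "(CA)8GA", "(AT)7", "(A)12")

#: Per-site true editing rates for planted functional off-targets, cycled.
TRUE_OFFTARGET_RATES = (0.514, 0.317, 0.105)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiment."""

    genome_length: int = 30_000
    gc_fraction: float = 0.41
    edit_rate: float = 0.6
    indel_size_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEL_SIZE_DIST)
    )
    subst_error_rate: float = 0.001
    stutter_rate: float = 0.05
    n_reads: int = 300
    seed: int = 7

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        for name in ("gc_fraction", "edit_rate", "subst_error_rate", "stutter_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if 0 in self.indel_size_dist:
            raise ValueError("indel_size_dist must not contain size 0")
        if any(p < 0 for p in self.indel_size_dist.values()):
            raise ValueError("indel_size_dist probabilities must be >= 0")
        if abs(sum(self.indel_size_dist.values()) - 1.0) > 1e-9:
            raise ValueError("indel_size_dist must sum to 1")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def make_genome(length: int, gc_fraction: float, seed) -> str:
    """Random uppercase A/C/G/T sequence with the given expected GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction outside [0, 1]")
    rng = _rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    idx = rng.choice(4, size=length, p=p)
    return idx.astype(np.uint8).tobytes().translate(bytes.maketrans(b"\0\1\2\3", b"ACGT")).decode()


def plant_site(
    genome: str,
    spacer: str,
    pam: str,
    n_mismatches: int,
    position: int,
    strand: str = "+",
    rng=0,
    occupied: list[tuple[int, int]] | None = None,
) -> tuple[str, dict]:
    """Overwrite ``genome`` with a protospacer+PAM at exactly ``n_mismatches``.

    Mismatch positions and replacement bases are drawn from ``rng``.  The PAM
    is written intact.  For strand '-', the reverse complement is written so
    reading the minus strand reproduces protospacer+PAM.  ``occupied`` (a
    mutable list of half-open intervals) enforces disjoint planting.
    """
    rng = _rng(rng)
    L = len(spacer)
    site_len = L + len(pam)
    if not 0 <= n_mismatches <= min(5, L):
        raise ValueError("n_mismatches must be between 0 and 5")
    if position < 0 or position + site_len > len(genome):
        raise ValueError("site does not fit in genome")
    if strand not in "+-":
        raise ValueError(f"bad strand {strand!r}")
    span = (position, position + site_len)
    if occupied is not None:
        for s, e in occupied:
            if span[0] < e and span[1] > s:
                raise ValueError(f"planted site {span} overlaps existing site ({s}, {e})")
        occupied.append(span)
    proto = list(spacer)
    mm_idx = sorted(int(k) for k in rng.choice(L, size=n_mismatches, replace=False))
    for k in mm_idx:
        proto[k] = rng.choice([b for b in DNA if b != spacer[k]])
    protospacer = "".join(proto)
    insert = protospacer + pam if strand == "+" else revcomp(protospacer + pam)
    genome = genome[: position] + insert + genome[position + site_len :]
    record = {
        "start": position,
        "end": position + site_len,
        "strand": strand,
        "protospacer": protospacer,
        "pam": pam,
        "n_mismatch": n_mismatches,
        # 1-based from the PAM-proximal end
        "mismatch_positions": tuple(sorted(L - k for k in mm_idx)),
    }
    return genome, record


def plant_ssr(genome: str, composition: str, position: int) -> str:
    """Overwrite ``genome`` with the literal expansion of ``composition``."""
    expansion = expand_composition(composition)
    if position < 0 or position + len(expansion) > len(genome):
        raise ValueError("SSR does not fit in genome")
    return genome[: position] + expansion + genome[position + len(expansion) :]


def _longest_run(sub: str) -> tuple[int, str]:
    """(offset, unit) of the longest >=2-unit tandem run inside ``sub``."""
    from .microsat import _tandem_runs

    runs = _tandem_runs(sub.upper(), {ul: 2 for ul in range(1, 7)})
    if not runs:
        raise ValueError("ssr_span contains no tandem repeat of >= 2 units")
    s, e, _, unit, _ = max(runs, key=lambda r: (r[1] - r[0], -r[2]))
    return s, unit


def simulate_reads(
    amplicon: str,
    cut_pos: int,
    cfg: SimulationConfig,
    ssr_span: tuple[int, int] | None = None,
    rng=None,
    id_prefix: str = "read",
) -> tuple[list[FastqRecord], pd.DataFrame]:
    """Simulate ``cfg.n_reads`` full-length reads of ``amplicon``.

    Returns the reads and a per-read truth table (read_id, edited,
    indel_size, stuttered, stutter_size, n_subst).  Stutter inserts/deletes
    one whole unit of the longest repeat run inside ``ssr_span``, at the
    run's left edge.
    """
    if not amplicon:
        raise ValueError("empty amplicon")
    if not 0 <= cut_pos < len(amplicon):
        raise ValueError(f"cut_pos {cut_pos} out of range")
    rng = _rng(cfg.seed if rng is None else rng)
    amplicon = amplicon.upper()
    sizes = np.array(sorted(cfg.indel_size_dist))
    probs = np.array([cfg.indel_size_dist[int(s)] for s in sizes])
    probs = probs / probs.sum()
    if ssr_span is not None:
        s0, s1 = ssr_span
        if not 0 <= s0 < s1 <= len(amplicon):
            raise ValueError("ssr_span out of range")
        run_off, unit = _longest_run(amplicon[s0:s1])
        anchor = s0 + run_off
    records: list[FastqRecord] = []
    rows: list[tuple] = []
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in range(cfg.n_reads):
        ops: list[tuple[int, str, str | int]] = []  # (pos, kind, payload)
        edited = bool(rng.random() < cfg.edit_rate)
        size = 0
        if edited:
            size = int(rng.choice(sizes, p=probs))
            if size < 0:
                if cut_pos - size > len(amplicon):
                    raise ValueError("deletion extends past amplicon end")
                ops.append((cut_pos, "del", -size))
            else:
                ins = rng.choice(4, size=size).astype(np.uint8)
                ops.append((cut_pos, "ins", bases[ins].tobytes().decode()))
        stuttered = False
        stutter_size = 0
        if ssr_span is not None and cfg.stutter_rate > 0:
            if rng.random() < cfg.stutter_rate:
                stuttered = True
                gain = bool(rng.random() < 0.5)
                stutter_size = len(unit) if gain else -len(unit)
                if gain:
                    ops.append((anchor, "ins", unit))
                else:
                    ops.append((anchor, "del", len(unit)))
        seq = amplicon
        for pos, kind, payload in sorted(ops, key=lambda o: o[0], reverse=True):
            if kind == "del":
                seq = seq[:pos] + seq[pos + payload :]
            else:
                seq = seq[:pos] + payload + seq[pos:]
        n_subst = 0
        if cfg.subst_error_rate > 0:
            mask = rng.random(len(seq)) < cfg.subst_error_rate
            if mask.any():
                chars = list(seq)
                for j in np.flatnonzero(mask):
                    chars[j] = rng.choice([b for b in DNA if b != chars[j]])
                seq = "".join(chars)
                n_subst = int(mask.sum())
        rid = f"{id_prefix}{i}"
        records.append(FastqRecord(rid, seq, QUAL_CHAR * len(seq)))
        rows.append((rid, edited, size if edited else 0, stuttered, stutter_size, n_subst))
    truth = pd.DataFrame(
        rows, columns=["read_id", "edited", "indel_size", "stuttered", "stutter_size", "n_subst"]
    )
    return records, truth


@dataclass
class FixtureBundle:
    """Everything a full pipeline run needs, with its ground truth."""

    genome: dict[str, str]
    guides: list[Guide]
    sites: list[OfftargetSite]
    amplicons: dict[str, tuple[str, int]]  # site_id -> (sequence, cut_pos)
    reads: dict[str, dict[str, list[FastqRecord]]]  # site_id -> sample -> reads
    truth: pd.DataFrame
    read_truth: dict[str, dict[str, pd.DataFrame]]
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "reads").mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_fasta(
            {sid: seq for sid, (seq, _) in self.amplicons.items()}, outdir / "amplicons.fa"
        )
        write_bed(self.sites, outdir / "sites.bed")
        write_sites_tsv(self.sites, outdir / "sites.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        for sid, samples in self.reads.items():
            safe = sid.replace(":", "_")
            for sample, recs in samples.items():
                write_fastq(recs, outdir / "reads" / f"{safe}.{sample}.fastq")


def make_fixture(
    cfg: SimulationConfig | None = None,
    n_true_offtargets: int = 3,
    n_ssr_noise_sites: int = 5,
    n_clean_sites: int = 20,
    flank: int = 100,
    contig: str = "chr1",
) -> FixtureBundle:
    """Build the default synthetic capture-panel experiment.

    The panel holds one on-target site (0 mismatches, NGG PAM) plus the
    requested numbers of functional off-targets (edited sample only), SSR
    noise sites (stutter in both samples, no editing) and clean sites
    (neither).  Guides at lengths 20/19/18/17 target the on-target locus.
    """
    cfg = cfg or SimulationConfig()
    if min(n_true_offtargets, n_ssr_noise_sites, n_clean_sites) < 0:
        raise ValueError("site counts must be >= 0")
    if n_true_offtargets + n_ssr_noise_sites + n_clean_sites == 0:
        raise ValueError("fixture needs at least one site besides the on-target")
    rng = np.random.default_rng(cfg.seed)
    slot = 2 * flank + 300
    kinds: list[tuple[str, int]] = [("on_target", 0)]
    kinds += [("true_offtarget", (1, 2, 3)[i % 3]) for i in range(n_true_offtargets)]
    kinds += [("ssr_noise", (2, 3)[i % 2]) for i in range(n_ssr_noise_sites)]
    kinds += [("clean", (1, 2, 3, 4, 5)[i % 5]) for i in range(n_clean_sites)]
    needed = len(kinds) * slot + 2 * flank + 200
    if cfg.genome_length < needed:
        raise ValueError(
            f"genome_length {cfg.genome_length} too small for {len(kinds)} sites (need >= {needed})"
        )
    genome = make_genome(cfg.genome_length, cfg.gc_fraction, rng)
    spacer20 = "".join(rng.choice(list(DNA), size=20))
    occupied: list[tuple[int, int]] = []
    ssr_comps = itertools.cycle(SSR_COMPOSITIONS)
    rates = itertools.cycle(TRUE_OFFTARGET_RATES)
    site_meta: list[dict] = []
    for idx, (kind, mm) in enumerate(kinds):
        pos = 200 + idx * slot + int(rng.integers(0, 100))
        if kind == "on_target":
            strand = "+"
            pam = rng.choice(list(DNA)) + "GG"
        elif kind == "ssr_noise":
            strand = "+"  # keeps the planted SSR immediately 3' of the PAM
            pam = rng.choice(list(DNA)) + rng.choice(["A", "G"]) + "G"
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            pam = rng.choice(list(DNA)) + rng.choice(["A", "G"]) + "G"
        genome, rec = plant_site(genome, spacer20, pam, mm, pos, strand, rng, occupied)
        meta = dict(rec, kind=kind, ssr=False, composition="", true_edit_rate=0.0)
        if kind == "on_target":
            meta["true_edit_rate"] = cfg.edit_rate
        elif kind == "true_offtarget":
            meta["true_edit_rate"] = next(rates)
        elif kind == "ssr_noise":
            comp = next(ssr_comps)
            expansion = expand_composition(comp)
            ssr_pos = rec["end"]  # flush with the PAM
            genome = plant_ssr(genome, comp, ssr_pos)
            occupied.append((ssr_pos, ssr_pos + len(expansion)))
            meta.update(ssr=True, composition=comp, ssr_span=(ssr_pos, ssr_pos + len(expansion)))
        site_meta.append(meta)

    on = site_meta[0]
    g20 = Guide(
        id="sgR-20", spacer=spacer20, contig=contig,
        start=on["start"], end=on["end"], strand=on["strand"],
    )
    guides = [g20] + [
        dataclasses.replace(truncate_guide(g20, l), id=f"sgR-{l}") for l in (19, 18, 17)
    ]

    sites: list[OfftargetSite] = []
    for meta in site_meta:
        sites.append(
            OfftargetSite(
                guide_id="sgR-20",
                contig=contig,
                start=meta["start"],
                end=meta["end"],
                strand=meta["strand"],
                protospacer=meta["protospacer"],
                pam=meta["pam"],
                n_mismatch=meta["n_mismatch"],
                mismatch_positions=meta["mismatch_positions"],
                seed_mismatches=sum(p <= 12 for p in meta["mismatch_positions"]),
                ssr_flag=meta["ssr"],
            )
        )

    amplicons: dict[str, tuple[str, int]] = {}
    reads: dict[str, dict[str, list[FastqRecord]]] = {}
    read_truth: dict[str, dict[str, pd.DataFrame]] = {}
    truth_rows = []
    for meta, site in zip(site_meta, sites):
        cut = site.cut_site
        lo, hi = cut - flank, cut + flank
        amp = genome[lo:hi]
        amplicons[site.site_id] = (amp, flank)
        span = None
        if meta["ssr"]:
            s0, s1 = meta["ssr_span"]
            span = (s0 - lo, s1 - lo)
        stutter = cfg.stutter_rate if meta["ssr"] else 0.0
        reads[site.site_id] = {}
        read_truth[site.site_id] = {}
        for sample, rate in (("control", 0.0), ("edited", meta["true_edit_rate"])):
            sample_cfg = dataclasses.replace(cfg, edit_rate=rate, stutter_rate=stutter)
            recs, rt = simulate_reads(
                amp, flank, sample_cfg, ssr_span=span, rng=rng,
                id_prefix=f"{site.site_id}|{sample}|",
            )
            reads[site.site_id][sample] = recs
            read_truth[site.site_id][sample] = rt
        truth_rows.append(
            {
                "site_id": site.site_id,
                "kind": meta["kind"],
                "contig": contig,
                "start": meta["start"],
                "end": meta["end"],
                "strand": meta["strand"],
                "n_mismatch": meta["n_mismatch"],
                "ssr": meta["ssr"],
                "ssr_composition": meta["composition"],
                "true_edit_rate": meta["true_edit_rate"],
                "stutter_rate": stutter,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return FixtureBundle(
        genome={contig: genome},
        guides=guides,
        sites=sites,
        amplicons=amplicons,
        reads=reads,
        truth=truth,
        read_truth=read_truth,
        config=cfg,
    )
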