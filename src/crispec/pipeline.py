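"""Capture-panel decision rules, the T7ENI formula, and the full pipeline.

A candidate site is judged from a paired control/edited quantification:

1. control aligned reads < ``min_reads``            -> ``low_coverage``
2. control efficiency >= ``control_max_efficiency`` -> ``background_unstable``
   (the site is intrinsically indel-noisy; a flanking microsatellite is the
   usual suspect and is recorded alongside)
3. edited efficiency >= threshold                   -> ``validated_offtarget``
4. otherwise                                        -> ``clean``

Rule order matters: a shallow site is never reported clean, and an unstable
site is never promoted to a validated off-target no matter how high its
edited signal -- the signal cannot be attributed to Cas9.  Sites failing the
background rule are retained and labelled rather than dropped, so the noise
budget stays reportable.

The T7 endonuclease I estimate converts gel band intensities to an indel
fraction: ``100 * (1 - sqrt(1 - (b + c) / (a + b + c)))`` with ``a`` the
uncut product and ``b``, ``c`` the cut products.  The square root accounts
for heteroduplex formation by random reannealing of mutant and wild-type
strands.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .amplicon import SiteQuant, extract_target_regions, make_aligner, quantify_site
from .guides import OfftargetSite, count_by_mismatch, find_offtargets
from .io import RunConfig, read_fasta, read_fastq, read_sites_tsv
from .microsat import SsrThresholds, flag_sites
from .simulate import FixtureBundle, SimulationConfig, make_fixture

STATUSES = ("validated_offtarget", "clean", "background_unstable", "low_coverage")


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for site classification.

    min_reads
        Minimum aligned control reads for a site to be assessable.
    control_max_efficiency
        Control-sample editing efficiency (percent) at or above which the
        site counts as background-unstable.
    edited_min_efficiency
        Edited-sample efficiency (percent) required to validate; defaults to
        ``control_max_efficiency`` for symmetry.
    """

    min_reads: int = 10
    control_max_efficiency: float = 1.0
    edited_min_efficiency: float | None = None

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not 0.0 <= self.control_max_efficiency <= 100.0:
            raise ValueError("control_max_efficiency outside [0, 100]")
        if self.edited_min_efficiency is not None and not (
            0.0 <= self.edited_min_efficiency <= 100.0
        ):
            raise ValueError("edited_min_efficiency outside [0, 100]")

    @property
    def validation_threshold(self) -> float:
        if self.edited_min_efficiency is None:
            return self.control_max_efficiency
        return self.edited_min_efficiency


@dataclass(frozen=True)
class GelBands:
    """Integrated band intensities from a T7ENI digest gel."""

    a: float  # uncut product
    b: float  # cut product 1
    c: float  # cut product 2

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("band intensities must be >= 0")
        if self.a + self.b + self.c == 0:
            raise ValueError("at least one band intensity must be positive")


def t7e1_indel_pct(bands: GelBands | tuple[float, float, float]) -> float:
    """Indel percentage from T7ENI gel densitometry (bounded in [0, 100])."""
    if not isinstance(bands, GelBands):
        bands = GelBands(*bands)
    cut_fraction = (bands.b + bands.c) / (bands.a + bands.b + bands.c)
    return 100.0 * (1.0 - math.sqrt(1.0 - cut_fraction))


@dataclass(frozen=True)
class SiteReport:
    site_id: str
    control: SiteQuant
    edited: SiteQuant
    ssr_flag: bool
    status: str

    @property
    def edited_efficiency(self) -> float:
        return self.edited.efficiency


def classify_site(
    control: SiteQuant,
    edited: SiteQuant,
    ssr_flag: bool = False,
    t: Thresholds | None = None,
) -> SiteReport:
    """Apply the coverage -> background -> validation rule chain."""
    t = t or Thresholds()
    if control.site_id != edited.site_id:
        raise ValueError(
            f"mismatched site ids: control {control.site_id!r} vs edited {edited.site_id!r}"
        )
    if control.n_aligned < t.min_reads:
        status = "low_coverage"
    elif control.efficiency >= t.control_max_efficiency:
        status = "background_unstable"
    elif edited.efficiency >= t.validation_threshold:
        status = "validated_offtarget"
    else:
        status = "clean"
    return SiteReport(control.site_id, control, edited, ssr_flag, status)


@dataclass(frozen=True)
class CoverageSummary:
    n_covered: int
    n_shallow: int
    n_uncaptured: int

    @property
    def n_sites(self) -> int:
        return self.n_covered + self.n_shallow + self.n_uncaptured

    @property
    def fractions(self) -> tuple[float, float, float]:
        n = self.n_sites
        if n == 0:
            return (0.0, 0.0, 0.0)
        return (self.n_covered / n, self.n_shallow / n, self.n_uncaptured / n)


def capture_coverage(quants: Sequence[SiteQuant], min_reads: int = 10) -> CoverageSummary:
    """Partition sites into covered (>= min_reads), shallow (1..min_reads-1)
    and uncaptured (0 reads)."""
    covered = sum(q.n_total >= min_reads for q in quants)
    uncaptured = sum(q.n_total == 0 for q in quants)
    shallow = len(quants) - covered - uncaptured
    return CoverageSummary(covered, shallow, uncaptured)


@dataclass
class PipelineResult:
    site_reports: list[SiteReport]
    sites: list[OfftargetSite]
    site_table: pd.DataFrame
    length_table: pd.DataFrame
    coverage: CoverageSummary
    ssr_proportions: dict[str, float]
    log: list[str] = field(default_factory=list)
    bundle: FixtureBundle | None = None

    def status_counts(self, include_on_target: bool = False) -> dict[str, int]:
        counts = {s: 0 for s in STATUSES}
        for rep, site in zip(self.site_reports, self.sites):
            if site.n_mismatch == 0 and not include_on_target:
                continue
            counts[rep.status] += 1
        return counts

    @property
    def on_target_report(self) -> SiteReport | None:
        for rep, site in zip(self.site_reports, self.sites):
            if site.n_mismatch == 0:
                return rep
        return None


def _site_table(reports: Sequence[SiteReport], sites: Sequence[OfftargetSite]) -> pd.DataFrame:
    rows = []
    for rep, site in zip(reports, sites):
        rows.append(
            {
                "site_id": rep.site_id,
                "contig": site.contig,
                "start": site.start,
                "end": site.end,
                "strand": site.strand,
                "n_mismatch": site.n_mismatch,
                "seed_mismatches": site.seed_mismatches,
                "ssr_flag": rep.ssr_flag,
                "control_reads": rep.control.n_aligned,
                "control_efficiency": rep.control.efficiency,
                "edited_reads": rep.edited.n_aligned,
                "edited_efficiency": rep.edited.efficiency,
                "status": rep.status,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute off-target flagging -> quantification -> classification.

    Without ``genome_path`` the input is a synthesised fixture; with it, the
    genome/panel/reads are loaded from the files a fixture writes.  Outputs
    (``sites_report.tsv``, ``guide_summary.tsv``, ``run_log.txt``) are
    written when ``out_dir`` is set.
    """
    log: list[str] = [f"config: {cfg.to_dict()}"]
    thresholds = Thresholds(**cfg.thresholds)
    ssr_t = SsrThresholds(**cfg.ssr_thresholds)
    bundle: FixtureBundle | None = None
    if cfg.genome_path is None:
        sim = SimulationConfig(**{**cfg.sim, "seed": cfg.sim.get("seed", cfg.seed)})
        bundle = make_fixture(
            sim,
            n_true_offtargets=cfg.n_true_offtargets,
            n_ssr_noise_sites=cfg.n_ssr_noise_sites,
            n_clean_sites=cfg.n_clean_sites,
            flank=cfg.flank,
        )
        genome, guides, panel, reads = bundle.genome, bundle.guides, bundle.sites, bundle.reads
        log.append(f"fixture: {len(panel)} panel sites, seed {sim.seed}")
    else:
        genome = read_fasta(cfg.genome_path)
        panel = read_sites_tsv(cfg.sites_path)
        reads = {}
        for site in panel:
            safe = site.site_id.replace(":", "_")
            reads[site.site_id] = {
                sample: read_fastq(Path(cfg.reads_dir) / f"{safe}.{sample}.fastq")
                for sample in ("control", "edited")
            }
        guides = []
        log.append(f"loaded genome {cfg.genome_path}, {len(panel)} panel sites")

    flagged, ssr_props = flag_sites(panel, genome, flank=cfg.flank, t=ssr_t)
    log.append(f"ssr-flagged proportions per guide: {ssr_props}")
    refs = {
        r.id: r
        for r in extract_target_regions(genome, flagged, flank=cfg.flank, quant_window=cfg.quant_window)
    }
    aligner = make_aligner()
    reports: list[SiteReport] = []
    for site in flagged:
        ref = refs[site.site_id]
        qc = quantify_site(reads[site.site_id]["control"], ref, aligner=aligner)
        qe = quantify_site(reads[site.site_id]["edited"], ref, aligner=aligner)
        reports.append(classify_site(qc, qe, ssr_flag=site.ssr_flag, t=thresholds))
    coverage = capture_coverage([r.control for r in reports], thresholds.min_reads)
    site_table = _site_table(reports, flagged)
    log.append(f"thresholds: {thresholds}")

    length_rows = []
    on_rep = next(
        (rep for rep, s in zip(reports, flagged) if s.n_mismatch == 0), None
    )
    validated = sum(
        rep.status == "validated_offtarget" and s.n_mismatch > 0
        for rep, s in zip(reports, flagged)
    )
    ssr_fraction = (
        sum(s.ssr_flag for s in flagged) / len(flagged) if flagged else 0.0
    )
    for g in guides:
        predicted = find_offtargets(g, genome, max_mm=cfg.max_mm, pam_pattern=cfg.pam_offtarget)
        length_rows.append(
            {
                "spacer_len": g.spacer_len,
                "guide_id": g.id,
                "on_target_efficiency": on_rep.edited.efficiency if on_rep else float("nan"),
                "predicted_offtargets": len(predicted) - 1,  # excludes the on-target hit
                "mismatch_counts": count_by_mismatch(predicted),
                "validated_offtargets": validated,
                "ssr_flagged_fraction": ssr_fraction,
            }
        )
    length_columns = [
        "spacer_len", "guide_id", "on_target_efficiency", "predicted_offtargets",
        "mismatch_counts", "validated_offtargets", "ssr_flagged_fraction",
    ]
    length_table = pd.DataFrame(length_rows, columns=length_columns)
    length_table = length_table.sort_values("spacer_len", ascending=False).reset_index(drop=True)

    result = PipelineResult(
        site_reports=reports,
        sites=flagged,
        site_table=site_table,
        length_table=length_table,
        coverage=coverage,
        ssr_proportions=ssr_props,
        log=log,
        bundle=bundle,
    )
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        site_table.to_csv(out / "sites_report.tsv", sep="\t", index=False)
        length_table.drop(columns=["mismatch_counts"]).to_csv(
            out / "guide_summary.tsv", sep="\t", index=False
        )
        (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return result


def compare_lengths(results: Mapping[int, PipelineResult]) -> pd.DataFrame:
    """Per-spacer-length comparison rows pulled from pipeline results."""
    if len(results) < 2:
        raise ValueError("need results for at least two spacer lengths")
    rows = []
    for length in sorted(results, reverse=True):
        table = results[length].length_table
        row = table[table["spacer_len"] == length]
        if row.empty:
            raise ValueError(f"result for length {length} lacks a matching summary row")
        rows.append(row.iloc[0])
    return pd.DataFrame(rows).reset_index(drop=True)
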